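import numpy as np
import pandas as pd
import pytest

from spermprog.setstats import chisq_enrichment, replication_extent
from spermprog.simulate import (
    CELLS,
    MARKS,
    SimulationConfig,
    epigenome_track,
    expected_group_means,
    generate_annotation,
    generate_embryo_counts,
    generate_epigenome_tracks,
    generate_fibers,
    generate_ortholog_map,
    generate_truth,
)

SMALL = dict(n_genes=60, gene_spacing=5000)


class TestAnnotation:
    def test_even_spacing_alternating_strand(self):
        cfg = SimulationConfig(n_genes=10, chrom_length=10**6)
        ann = generate_annotation(cfg)
        assert len(ann) == 10
        assert (ann["strand"] == "+").sum() == 5
        assert np.all(np.diff(ann["tss"]) == cfg.gene_spacing)

    def test_deterministic(self):
        cfg = SimulationConfig(**SMALL, seed=5)
        pd.testing.assert_frame_equal(generate_annotation(cfg), generate_annotation(cfg))

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_annotation(SimulationConfig(n_genes=100, chrom_length=1000))


class TestTruth:
    def test_mark_pattern_invariants(self):
        cfg = SimulationConfig(n_genes=2000, seed=1)
        t = generate_truth(cfg)
        prog = t[t["class"] == "programmed"]
        assert prog["H3K4me2_spermatid"].all() and prog["H3K4me3_spermatid"].all()
        assert not prog["H3K4me2_sperm"].any()
        assert prog["H3K27me3_sperm"].all() and prog["H3K27me3_spermatid"].all()
        assert (prog["true_logfc"] > 0).all()
        active = t[t["class"] == "active"]
        assert active["H3K4me2_sperm"].all() and active["H3K4me3_spermatid"].all()
        assert not active["H3K27me3_sperm"].any()
        assert (active["true_logfc"] == 0).all()
        unmarked = t[t["class"] == "unmarked"]
        mark_cols = [f"{m}_{c}" for m in MARKS for c in CELLS]
        assert not unmarked[mark_cols].to_numpy().any()

    def test_programmed_count_binomially_plausible(self):
        cfg = SimulationConfig(n_genes=5000, fraction_programmed=0.01, seed=2)
        n_prog = (generate_truth(cfg)["class"] == "programmed").sum()
        sd = np.sqrt(5000 * 0.01 * 0.99)
        assert abs(n_prog - 50) <= 3 * sd

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(fraction_programmed=0.0)

    def test_down_regulated_minority_flag(self):
        cfg = SimulationConfig(
            n_genes=4000, fraction_programmed=0.05, programmed_down_fraction=0.3, seed=3
        )
        t = generate_truth(cfg)
        prog = t[t["class"] == "programmed"]
        down = prog[prog["true_logfc"] < 0]
        assert 0 < len(down) < len(prog)
        # down-programmed genes carry K4 in sperm instead of spermatid
        assert down["H3K4me2_sperm"].all()
        assert not down["H3K4me2_spermatid"].any()


class TestTracks:
    def _cfg(self, **kw):
        base = dict(
            n_genes=20,
            gene_spacing=5000,
            background_noise_sd=0.0,
            basal_k4=0.0,
            basal_k27=0.0,
            basal_k9=0.0,
            retention_sd=0.0,
            amplitude_sd=0.0,
            meth_expr_coupling=0.0,
            k27_expr_coupling=0.0,
            seed=4,
        )
        base.update(kw)
        return SimulationConfig(**base)

    def test_unmarked_gene_has_zero_mark_signal(self):
        cfg = self._cfg()
        ann = generate_annotation(cfg)
        truth = generate_truth(cfg)
        track = epigenome_track(ann, truth, cfg, "H3K4me3", "spermatid")
        unmarked = truth.index[~truth["H3K4me3_spermatid"]][0]
        tss = int(ann.set_index("gene_id").loc[unmarked, "tss"])
        assert track.window_sum(cfg.chrom, tss - 1000, tss + 1000) == 0.0

    def test_marked_gene_window_integrates_gaussian_bump(self):
        """Noise-free window sum ~ height * sqrt(2 pi) * sd."""
        cfg = self._cfg()
        ann = generate_annotation(cfg)
        truth = generate_truth(cfg)
        track = epigenome_track(ann, truth, cfg, "H3K27me3", "sperm")
        marked = truth.index[truth["H3K27me3_sperm"]][0]
        tss = int(ann.set_index("gene_id").loc[marked, "tss"])
        expected = cfg.mark_signal_height * np.sqrt(2 * np.pi) * cfg.mark_sd
        got = track.window_sum(cfg.chrom, tss - 2000, tss + 2000)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_sperm_occupancy_ratio(self):
        cfg = self._cfg()
        ann = generate_annotation(cfg)
        truth = generate_truth(cfg)
        sperm = epigenome_track(ann, truth, cfg, "occupancy", "sperm")
        sptd = epigenome_track(ann, truth, cfg, "occupancy", "spermatid")
        tss = int(ann["tss"].iloc[0])
        ratio = sperm.window_sum(cfg.chrom, tss - 500, tss + 500) / sptd.window_sum(
            cfg.chrom, tss - 500, tss + 500
        )
        assert ratio == pytest.approx(cfg.sperm_amplitude_ratio, rel=1e-9)

    def test_tracks_nonnegative_and_deterministic(self):
        cfg = SimulationConfig(n_genes=15, seed=6)
        ann = generate_annotation(cfg)
        truth = generate_truth(cfg)
        t1 = epigenome_track(ann, truth, cfg, "methylation", "sperm")
        t2 = epigenome_track(ann, truth, cfg, "methylation", "sperm")
        arr = t1.values[cfg.chrom]
        assert (arr >= 0).all()
        np.testing.assert_array_equal(arr, t2.values[cfg.chrom])

    def test_all_tracks_generated(self):
        cfg = SimulationConfig(n_genes=10, seed=7)
        ann, truth = generate_annotation(cfg), generate_truth(cfg)
        tracks = generate_epigenome_tracks(ann, truth, cfg)
        assert len(tracks) == (len(MARKS) + 3) * 2

    def test_unknown_kind_rejected(self):
        cfg = SimulationConfig(n_genes=10)
        ann, truth = generate_annotation(cfg), generate_truth(cfg)
        with pytest.raises(ValueError, match="unknown track kind"):
            epigenome_track(ann, truth, cfg, "H3K36me3", "sperm")


class TestCounts:
    def test_paired_shape_and_determinism(self):
        cfg = SimulationConfig(n_genes=200, n_experiments=4, seed=8)
        truth = generate_truth(cfg)
        cm1 = generate_embryo_counts(truth, cfg)
        cm2 = generate_embryo_counts(truth, cfg)
        assert cm1.counts.shape == (200, 8)
        assert cm1.n_experiments == 4
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)

    def test_true_logfc_matches_group_mean_ratio(self):
        cfg = SimulationConfig(n_genes=1000, seed=9)
        truth = generate_truth(cfg)
        m_a, m_b = expected_group_means(truth, cfg)
        np.testing.assert_allclose(
            np.log2(m_b / m_a), truth["true_logfc"].to_numpy(), atol=1e-9
        )

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = SimulationConfig(
            n_genes=400, nb_dispersion=0.0, depth_sd=0.0, effect_logfc=0.0, seed=10
        )
        truth = generate_truth(cfg)
        cm = generate_embryo_counts(truth, cfg)
        m_a, _ = expected_group_means(truth, cfg)
        arr = cm.counts.to_numpy()
        keep = m_a > 50
        ratio = arr[keep].var(axis=1, ddof=1) / arr[keep].mean(axis=1)
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.15)

    def test_counts_nonnegative_integers(self):
        cfg = SimulationConfig(n_genes=100, seed=11)
        cm = generate_embryo_counts(generate_truth(cfg), cfg)
        arr = cm.counts.to_numpy()
        assert np.issubdtype(arr.dtype, np.integer)
        assert (arr >= 0).all()


class TestOrthologsAndFibers:
    def test_ortholog_map_fraction(self):
        cfg = SimulationConfig(n_genes=1000, seed=12)
        truth = generate_truth(cfg)
        m = generate_ortholog_map(truth, cfg, mapped_fraction=0.8)
        assert 700 <= len(m) <= 900
        assert m["target"].str.startswith("HS_").all()

    def test_mean_extent_near_target(self):
        cfg = SimulationConfig(n_genes=10, seed=13)
        fibers = generate_fibers(200, 0.3, cfg)
        extents = replication_extent(fibers)
        # Beta(mean 0.3, concentration 5) sd ~ 0.19; 3 sd of the mean
        assert abs(extents.mean() - 0.3) <= 3 * 0.19 / np.sqrt(200)

    def test_extent_boundary_rejected(self):
        cfg = SimulationConfig(n_genes=10)
        with pytest.raises(ValueError):
            generate_fibers(10, 1.0, cfg)

    def test_fibers_deterministic(self):
        cfg = SimulationConfig(n_genes=10, seed=14)
        f1 = generate_fibers(20, 0.4, cfg)
        f2 = generate_fibers(20, 0.4, cfg)
        assert f1.fibers == f2.fibers

    def test_segments_within_fiber(self):
        cfg = SimulationConfig(n_genes=10, seed=15)
        for _, total, reps in generate_fibers(50, 0.5, cfg).fibers:
            for s, e in reps:
                assert 0 <= s < e <= total + 1e-9


class TestEndToEndRecovery:
    def test_misregulated_set_enriched_for_programmed_pattern(self):
        """quantify -> DE -> gene sets: the misregulated call is
        chi-square-enriched for spermatid-K4 AND both-K27 genes."""
        from spermprog.de import run_de

        cfg = SimulationConfig(n_genes=2000, seed=16)
        truth = generate_truth(cfg)
        cm = generate_embryo_counts(truth, cfg)
        de = run_de(cm)
        mis = set(de.index[de["misregulated"]])
        assert len(mis) >= 5
        pattern = (
            truth["H3K4me2_spermatid"]
            & truth["H3K27me3_sperm"]
            & truth["H3K27me3_spermatid"]
            & ~truth["H3K4me2_sperm"]
        )
        pattern_genes = set(truth.index[pattern])
        res = chisq_enrichment(
            len(mis & pattern_genes), len(mis), len(pattern_genes), len(truth)
        )
        assert res.direction == "over"
        assert res.p < 0.05
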