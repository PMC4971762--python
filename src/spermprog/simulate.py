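"""Seeded generator for gamete epigenomes, paired embryo counts,
ortholog maps, fibers, and the ground-truth table used for recovery
testing.

The generative model mirrors the epigenetic-programming picture the
analysis is built to detect: a small fraction of "programmed" genes
carry H3K27me3 in both gametes but H3K4me2/3 in the spermatid only, and
are up-regulated in spermatid-derived embryos; "active" genes carry
H3K4me2/3 in both cells, "repressed" genes H3K27me3 (half of them also
H3K9me3) in both, and "unmarked" genes nothing. Embryo expression means
are coupled to the paternal-cell marks (activating marks raise,
repressive marks lower, the mean), which is what makes the programmed
class differentially expressed and gives the mark-expression partial
correlations their signs. Nucleosome occupancy and DNA methylation get
a bump at every TSS with sperm amplitude 1.5x the spermatid one.

All randomness flows from one integer seed through named child streams
(one per generator call), so identical configs give byte-identical
outputs regardless of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GROUP_A, GROUP_B, CountMatrix, CoverageTrack, FiberSet

MARKS = ["H3K4me2", "H3K4me3", "H3K27me3", "H3K9me3"]
CELLS = ["sperm", "spermatid"]
CLASSES = ["programmed", "active", "repressed", "unmarked"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults follow the scale of the real study: 7 paired experiments,
    ~1% truly shifted genes at log2 effect 1.5, NB dispersion 0.05,
    million-read libraries, 5-kb gene spacing.
    """

    n_genes: int = 5000
    n_experiments: int = 7
    gene_spacing: int = 5000
    chrom: str = "chrS"
    chrom_length: int | None = None  # defaults to n_genes * gene_spacing
    fraction_programmed: float = 0.01
    programmed_down_fraction: float = 0.0  # minority down-regulated class
    effect_logfc: float = 1.5
    k4_response_logfc: float = 2.0  # K4me2/3 boost at non-bivalent promoters
    repression_logfc: float = 1.0  # per-unit-dose deficit of K27me3-marked genes
    k9_logfc: float = 0.5
    nb_dispersion: float = 0.05
    library_size: float = 1e6
    depth_sd: float = 0.1  # per-sample lognormal depth variation
    mark_signal_height: float = 20.0
    mark_sd: float = 300.0  # Gaussian bump width, bp
    background_noise_sd: float = 0.5
    retention_sd: float = 0.9  # per-gene histone-retention factor (shared by marks)
    amplitude_sd: float = 0.4  # per-gene, per-mark dose spread
    programmed_baseline_boost: float = 1.0  # log2; developmental genes are expressed
    # transcription-coupled basal chromatin (fraction of full mark height
    # per 2-fold baseline expression): K4 scales with expression,
    # K27/K9/methylation anti-scale
    basal_k4: float = 0.5
    basal_k27: float = 0.5
    basal_k9: float = 0.25
    basal_sd: float = 0.5  # per-mark lognormal noise on the basal amplitude
    meth_expr_coupling: float = 0.3  # log2 methylation decrease per baseline z
    k27_expr_coupling: float = 0.5  # highly transcribed Polycomb targets lose K27
    occupancy_height: float = 10.0
    methylation_height: float = 10.0
    sperm_amplitude_ratio: float = 1.5
    input_level: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length is None:
            self.chrom_length = self.n_genes * self.gene_spacing
        if not (0 < self.fraction_programmed < 1):
            raise ValueError("fraction_programmed must lie in (0, 1)")
        for name in (
            "n_genes",
            "n_experiments",
            "gene_spacing",
            "library_size",
            "mark_signal_height",
            "mark_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # effect_logfc = 0 is the null configuration used for calibration
        if self.effect_logfc < 0 or self.nb_dispersion < 0 or self.background_noise_sd < 0:
            raise ValueError("effect, dispersion and noise sd must be nonnegative")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def child_rng(seed: int, *tokens) -> np.random.Generator:
    """Named child stream: one generator per (seed, token path)."""
    key = tuple(zlib.crc32(str(t).encode()) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


# ---------------------------------------------------------------------------
# annotation and truth


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced TSSs on one chromosome, alternating strand."""
    if config.n_genes * config.gene_spacing > config.chrom_length:
        raise ValueError(
            f"chromosome too small: need {config.n_genes * config.gene_spacing} bp, "
            f"have {config.chrom_length}"
        )
    tss = config.gene_spacing // 2 + config.gene_spacing * np.arange(config.n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(config.n_genes)],
            "chrom": config.chrom,
            "strand": np.where(np.arange(config.n_genes) % 2 == 0, "+", "-"),
            "tss": tss,
        }
    )


def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene class, true log2 fold-change, and mark presence.

    Non-programmed genes split active/repressed/unmarked 50/25/25.
    H3K9me3 is placed on a random half of the repressed class (both
    cells). true_logfc is the realized per-gene effect: the design
    effect scaled by the gene's H3K4me2/3 dose (mean 1 across genes),
    positive for programmed genes, negative for the optional
    down-programmed minority, zero elsewhere.
    """
    rng = child_rng(config.seed, "truth")
    n = config.n_genes
    f = config.fraction_programmed
    cls = rng.choice(
        CLASSES, size=n, p=[f, (1 - f) * 0.5, (1 - f) * 0.25, (1 - f) * 0.25]
    )
    down = np.zeros(n, dtype=bool)
    if config.programmed_down_fraction > 0:
        down = (cls == "programmed") & (
            rng.random(n) < config.programmed_down_fraction
        )
    truth = pd.DataFrame(
        {"gene_id": [f"g{i:05d}" for i in range(n)], "class": cls}
    ).set_index("gene_id")
    programmed = cls == "programmed"
    active = cls == "active"
    repressed = cls == "repressed"
    k9 = repressed & (rng.random(n) < 0.5)

    for mark in ("H3K4me2", "H3K4me3"):
        truth[f"{mark}_sperm"] = active | (programmed & down)
        truth[f"{mark}_spermatid"] = active | (programmed & ~down)
    for cell in CELLS:
        truth[f"H3K27me3_{cell}"] = programmed | repressed
        truth[f"H3K9me3_{cell}"] = k9
    k4_dose = (
        _expression_dose(config, "H3K4me2") + _expression_dose(config, "H3K4me3")
    ) / 2.0
    truth["true_logfc"] = np.where(
        programmed & ~down,
        config.effect_logfc * k4_dose,
        np.where(down, -config.effect_logfc * k4_dose, 0.0),
    )
    return truth


# ---------------------------------------------------------------------------
# epigenome tracks


def _add_bump(arr: np.ndarray, center: int, height: float, sd: float) -> None:
    radius = int(4 * sd)
    lo, hi = max(0, center - radius), min(len(arr), center + radius + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += height * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _baseline_expression(config: SimulationConfig) -> np.ndarray:
    """Per-gene baseline expression propensity (lognormal, natural-log
    mean 4, sd 1.5) — drawn once per seed and shared by the count
    generator and the transcription-coupled basal chromatin."""
    rng = child_rng(config.seed, "baseline")
    return rng.lognormal(4.0, 1.5, config.n_genes)


def _baseline_z(config: SimulationConfig) -> np.ndarray:
    """Standardized log baseline expression (unit normal across genes)."""
    return (np.log(_baseline_expression(config)) - 4.0) / 1.5


def _retention_factor(config: SimulationConfig) -> np.ndarray:
    """Shared per-gene histone-retention factor: bivalent promoters keep
    correlated doses of every histone mark (mean 1 across genes)."""
    rng = child_rng(config.seed, "retention")
    return rng.lognormal(-config.retention_sd**2 / 2, config.retention_sd, config.n_genes)


def _gene_amplitudes(config: SimulationConfig, kind: str) -> np.ndarray:
    """Per-gene amplitude (dose) factors, shared between the two cell
    types of the same kind so sperm/spermatid signals correlate.

    Histone marks multiply the shared retention factor by a per-mark
    lognormal dose; occupancy and methylation vary independently. All
    factors have mean 1.
    """
    rng = child_rng(config.seed, "amplitude", kind)
    dose = rng.lognormal(-config.amplitude_sd**2 / 2, config.amplitude_sd, config.n_genes)
    if kind in MARKS:
        return _retention_factor(config) * dose
    return dose


def _expression_dose(config: SimulationConfig, kind: str) -> np.ndarray:
    """Effective dose a mark exerts on expression: a saturating
    (square-root) response to the promoter amplitude, normalized to
    mean 1. Saturation keeps realized effect sizes concentrated around
    the design effect while preserving the dose-expression covariance
    the network stage detects."""
    # sqrt of a mean-1 lognormal(-(r2+s2)/2, sqrt(r2+s2)) has mean
    # exp(-(r2+s2)/8); divide it out so E[dose] = 1
    sigma2 = config.retention_sd**2 + config.amplitude_sd**2
    return np.sqrt(_gene_amplitudes(config, kind)) * np.exp(sigma2 / 8)


def _k27_dose(config: SimulationConfig) -> np.ndarray:
    """Effective Polycomb dose on a marked gene: the per-gene amplitude
    damped on highly transcribed genes (they titrate K27me3 away). Used
    both for the H3K27me3 track amplitude and the repression of
    expression, so chromatin and counts stay consistent."""
    return _gene_amplitudes(config, "H3K27me3") * np.exp2(
        -config.k27_expr_coupling * _baseline_z(config)
    )


def epigenome_track(
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    kind: str,
    cell: str,
) -> CoverageTrack:
    """One synthetic coverage track.

    kind is a histone mark, 'occupancy', 'methylation' or 'input'; cell
    is 'sperm' or 'spermatid'. Marked genes (or every gene, for
    occupancy/methylation) get a Gaussian bump at the TSS; the input is
    flat. Nonnegative background noise (half-normal) covers everything.
    """
    if cell not in CELLS:
        raise ValueError(f"unknown cell {cell!r}")
    rng = child_rng(config.seed, "track", kind, cell)
    arr = np.abs(rng.normal(0.0, config.background_noise_sd, config.chrom_length))
    tss = annotation["tss"].to_numpy()
    cell_ratio = config.sperm_amplitude_ratio if cell == "sperm" else 1.0
    if kind == "input":
        arr += config.input_level
    elif kind == "occupancy":
        amp = config.occupancy_height * cell_ratio * _gene_amplitudes(config, kind)
        for i in range(len(tss)):
            _add_bump(arr, tss[i], amp[i], config.mark_sd)
    elif kind == "methylation":
        # promoter methylation anti-correlates with expression propensity
        amp = (
            config.methylation_height
            * cell_ratio
            * _gene_amplitudes(config, kind)
            * np.exp2(-config.meth_expr_coupling * _baseline_z(config))
        )
        for i in range(len(tss)):
            _add_bump(arr, tss[i], amp[i], config.mark_sd)
    elif kind in MARKS:
        marked = truth[f"{kind}_{cell}"].to_numpy().astype(float)
        dose = _k27_dose(config) if kind == "H3K27me3" else _gene_amplitudes(config, kind)
        amp = config.mark_signal_height * (
            marked * dose + _basal_amplitude(config, kind)
        )
        for i in np.flatnonzero(amp > 1e-9):
            _add_bump(arr, tss[i], amp[i], config.mark_sd)
    else:
        raise ValueError(f"unknown track kind {kind!r}")
    return CoverageTrack({config.chrom: arr}, label=f"{kind}_{cell}")


def _basal_amplitude(config: SimulationConfig, mark: str) -> np.ndarray:
    """Transcription-coupled basal mark amplitude (fraction of the full
    mark height): H3K4me2/3 scale with baseline expression, H3K27me3
    and H3K9me3 against it, each with independent per-mark noise."""
    coeff = {
        "H3K4me2": (config.basal_k4, 1.0),
        "H3K4me3": (config.basal_k4, 1.0),
        "H3K27me3": (config.basal_k27, -1.0),
        "H3K9me3": (config.basal_k9, -1.0),
    }[mark]
    base, sign = coeff
    if base <= 0:
        return np.zeros(config.n_genes)
    rng = child_rng(config.seed, "basal", mark)
    noise = rng.lognormal(-config.basal_sd**2 / 2, config.basal_sd, config.n_genes)
    return base * np.exp2(sign * _baseline_z(config)) * noise


def generate_epigenome_tracks(
    annotation: pd.DataFrame, truth: pd.DataFrame, config: SimulationConfig
) -> dict[tuple[str, str], CoverageTrack]:
    """All tracks as a dict keyed by (kind, cell). Convenient for small
    configs; for large genomes build tracks one at a time with
    :func:`epigenome_track`."""
    kinds = MARKS + ["occupancy", "methylation", "input"]
    return {
        (kind, cell): epigenome_track(annotation, truth, config, kind, cell)
        for kind in kinds
        for cell in CELLS
    }


# ---------------------------------------------------------------------------
# embryo counts


def expected_group_means(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-gene expression means for the sperm- and
    spermatid-embryo groups, scaled so the mean library is
    ``library_size``.

    Expression responds to the dose of the paternal-cell marks:
    log2 mean = log2 baseline
    + k4(cell) * (dose_K4me2 * K4me2(cell) + dose_K4me3 * K4me3(cell)) / 2
    - repression_logfc * dose_K27 * K27me3(cell)
    - k9_logfc * dose_K9 * K9me3(cell),
    where the K4 response coefficient k4(cell) is k4_response_logfc at
    a plain active promoter but attenuated to effect_logfc when the
    promoter is bivalent (K27me3 present in that cell): Polycomb
    dominates the K4 response. The repressive terms are identical in
    the two cells for every class, so the spermatid/sperm log-ratio
    equals the truth table's true_logfc exactly (programmed genes are
    bivalent in the spermatid, hence shift by effect_logfc times their
    K4 dose).
    """
    baseline = _baseline_expression(config)
    # activation saturates with dose; repression scales linearly with it
    dose = {m: _expression_dose(config, m) for m in ("H3K4me2", "H3K4me3")}
    dose["H3K27me3"] = _k27_dose(config)
    dose["H3K9me3"] = _gene_amplitudes(config, "H3K9me3")
    programmed = (truth["class"] == "programmed").to_numpy()
    means = []
    for cell in CELLS:
        k27 = truth[f"H3K27me3_{cell}"].to_numpy()
        k4_coeff = np.where(k27, config.effect_logfc, config.k4_response_logfc)
        logmult = config.programmed_baseline_boost * programmed + (
            0.5
            * k4_coeff
            * (
                dose["H3K4me2"] * truth[f"H3K4me2_{cell}"].to_numpy()
                + dose["H3K4me3"] * truth[f"H3K4me3_{cell}"].to_numpy()
            )
            - config.repression_logfc * dose["H3K27me3"] * k27
            - config.k9_logfc * dose["H3K9me3"] * truth[f"H3K9me3_{cell}"].to_numpy()
        )
        means.append(baseline * np.exp2(logmult))
    m_sperm, m_spermatid = means
    scale = config.library_size / ((m_sperm.sum() + m_spermatid.sum()) / 2)
    return m_sperm * scale, m_spermatid * scale


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def generate_embryo_counts(truth: pd.DataFrame, config: SimulationConfig) -> CountMatrix:
    """Paired NB count matrix: 2 * n_experiments samples, one
    sperm-embryo and one spermatid-embryo sample per experiment, with
    per-sample lognormal depth variation."""
    rng = child_rng(config.seed, "counts")
    m_sperm, m_spermatid = expected_group_means(truth, config)
    group_means = {GROUP_A: m_sperm, GROUP_B: m_spermatid}
    cols, design_rows = {}, []
    for exp in range(1, config.n_experiments + 1):
        for group in (GROUP_A, GROUP_B):
            name = f"{group}_{exp}"
            depth = rng.lognormal(0.0, config.depth_sd)
            cols[name] = _nb_draw(rng, group_means[group] * depth, config.nb_dispersion)
            design_rows.append((name, group, exp))
    counts = pd.DataFrame(cols, index=truth.index).astype(np.int64)
    design = pd.DataFrame(design_rows, columns=["sample", "group", "experiment"])
    return CountMatrix(counts=counts, design=design)


# ---------------------------------------------------------------------------
# ortholog map and fibers


def generate_ortholog_map(
    truth: pd.DataFrame, config: SimulationConfig, mapped_fraction: float = 0.8
) -> pd.DataFrame:
    """1:1 map of a random subset of genes to a synthetic target-species
    id space."""
    rng = child_rng(config.seed, "orthologs")
    genes = truth.index.to_numpy()
    mapped = genes[rng.random(len(genes)) < mapped_fraction]
    return pd.DataFrame({"source": mapped, "target": [f"HS_{g}" for g in mapped]})


def generate_fibers(
    n_fibers: int,
    mean_extent: float,
    config: SimulationConfig,
    label: str = "fiber",
    concentration: float = 5.0,
) -> FiberSet:
    """Combed-fiber set: lengths uniform on 50-250 kb, per-fiber
    replicated fraction Beta-distributed with the requested mean,
    realized as non-overlapping replicated segments."""
    if not (0 < mean_extent < 1):
        raise ValueError("mean_extent must lie in the open interval (0, 1)")
    rng = child_rng(config.seed, "fibers", label)
    fibers = []
    for i in range(n_fibers):
        length = rng.uniform(50.0, 250.0)
        extent = rng.beta(mean_extent * concentration, (1 - mean_extent) * concentration)
        rep_total = extent * length
        m = 1 + rng.poisson(2)
        seg_lens = rep_total * rng.dirichlet(np.ones(m))
        gaps = (length - rep_total) * rng.dirichlet(np.ones(m + 1))
        reps, pos = [], 0.0
        for j in range(m):
            pos += gaps[j]
            reps.append((pos, pos + seg_lens[j]))
            pos += seg_lens[j]
        fibers.append((f"{label}_{i:04d}", length, reps))
    return FiberSet(fibers=fibers)


# ---------------------------------------------------------------------------
# Gaussian graphical models (network recovery testing)


def sparse_pair_precision(k: int, edges, strength: float = 0.3) -> np.ndarray:
    """Precision matrix with unit diagonal and -strength on the given
    (i, j) edges; the caller must pick edges keeping it positive
    definite (disjoint pairs always are). Planted |pcor| = strength."""
    omega = np.eye(k)
    for i, j in edges:
        omega[i, j] = omega[j, i] = -strength
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise ValueError("requested edge set makes the precision indefinite")
    return omega


def saturated_sign_precision(k: int = 7, strength: float = 0.3) -> np.ndarray:
    """Fully connected planted model: Omega = (1 - s) I + s u u^T with
    u an alternating +/-1 pattern. Positive definite for s in (0, 1);
    every pair has partial correlation -s * u_i * u_j (|pcor| = s)."""
    if not (0 < strength < 1):
        raise ValueError("strength must lie in (0, 1)")
    u = np.array([1 if i % 2 == 0 else -1 for i in range(k)], dtype=float)
    return (1 - strength) * np.eye(k) + strength * np.outer(u, u)


def true_partial_correlations(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    pcor = -precision / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def sample_ggm(precision: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws from N(0, inv(precision))."""
    cov = np.linalg.inv(precision)
    return rng.multivariate_normal(np.zeros(len(precision)), cov, size=n, method="cholesky")
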