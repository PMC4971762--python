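"""End-to-end orchestration: simulate -> quantify -> DE -> integrate ->
enrich -> fibers, from one validated config, with deterministic seeding,
stage caching by config hash, and machine-readable outputs.

Single-process execution; each stage writes TSV outputs (atomically, via
a .partial rename) plus a summary JSON and a manifest recording the
config hash, seed and per-stage row counts. Rerunning with an identical
config skips completed stages unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import network as net_mod
from . import quantify as quant_mod
from . import setstats
from .io import GROUP_A, GROUP_B, CountMatrix, write_annotation_bed, write_counts, write_fibers_bed, write_gene_set
from .simulate import (
    CELLS,
    MARKS,
    SimulationConfig,
    epigenome_track,
    generate_annotation,
    generate_embryo_counts,
    generate_fibers,
    generate_truth,
)

logger = logging.getLogger("spermprog")


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    """Raised with every config problem collected, not just the first."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


@dataclass
class PipelineConfig:
    fdr_strict: float = 0.05
    fdr_relaxed: float = 0.4
    lfc_min: float = 0.2
    min_consistent: int | None = None  # default: n_experiments - 1
    q_peaks: float = 0.05
    q_edges: float = 0.05
    flank_level: int = 1000
    flank_metagene: int = 2000
    bin_size: int = 50
    pseudocount: float = 1.0
    shrinkage: float | str = "auto"
    network_gene_set: str = "extended"  # or "misregulated"
    n_fibers: int = 200
    fiber_mean_extent: float = 0.35
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        # one seed drives everything, including the generator
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_THRESHOLDS_01 = ["fdr_strict", "fdr_relaxed", "q_peaks", "q_edges"]


def validate_mapping(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain mapping, collecting every
    error; unknown keys are warned about and ignored."""
    errors: list[str] = []
    raw = dict(raw or {})
    sim_raw = raw.pop("simulation", {}) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"simulation"}
    sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            logger.warning("config: unknown key %r ignored", key)
            continue
        kwargs[key] = value
    sim_kwargs = {}
    for key, value in sim_raw.items():
        if key not in sim_known:
            logger.warning("config: unknown simulation key %r ignored", key)
            continue
        sim_kwargs[key] = value
    for key in _THRESHOLDS_01:
        if key in kwargs and not (0 < float(kwargs[key]) <= 1):
            errors.append(f"{key} = {kwargs[key]} outside (0, 1]")
    if "lfc_min" in kwargs and float(kwargs["lfc_min"]) < 0:
        errors.append(f"lfc_min = {kwargs['lfc_min']} must be nonnegative")
    if "network_gene_set" in kwargs and kwargs["network_gene_set"] not in (
        "extended",
        "misregulated",
    ):
        errors.append(f"network_gene_set = {kwargs['network_gene_set']!r} unknown")
    if "fiber_mean_extent" in kwargs and not (0 < float(kwargs["fiber_mean_extent"]) < 1):
        errors.append(f"fiber_mean_extent = {kwargs['fiber_mean_extent']} outside (0, 1)")
    try:
        sim = SimulationConfig(**sim_kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"simulation: {exc}")
        sim = SimulationConfig()
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(simulation=sim, **kwargs)


def validate_config(path: str) -> PipelineConfig:
    """Parse a YAML config file (empty file -> full defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return validate_mapping(raw)


# ---------------------------------------------------------------------------
# atomic writers


def _atomic_write_df(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    df.to_csv(tmp, sep="\t", **kwargs)
    tmp.rename(path)


def _atomic_write_json(obj, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    tmp.rename(path)


# ---------------------------------------------------------------------------
# stages


def _stage_quantify(annotation, truth, config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter levels and peak calls for every (kind, cell).

    Tracks are generated one at a time and released, so large synthetic
    genomes stay within desk-scale memory.
    """
    sim = config.simulation
    levels = {}
    peak_rows = []
    for cell in CELLS:
        input_track = epigenome_track(annotation, truth, sim, "input", cell)
        for kind in MARKS + ["occupancy", "methylation"]:
            ip = epigenome_track(annotation, truth, sim, kind, cell)
            name = f"{kind}_{cell}"
            levels[name] = quant_mod.promoter_level(
                ip, input_track, annotation, config.flank_level, config.pseudocount
            )
            if kind in MARKS:
                peaks = quant_mod.call_promoter_peaks(
                    ip, input_track, annotation, config.flank_level, config.q_peaks
                )
                peaks = peaks.reset_index()
                peaks.insert(0, "cell", cell)
                peaks.insert(0, "mark", kind)
                peak_rows.append(peaks)
            del ip
        del input_track
    level_table = pd.DataFrame(levels)
    level_table.index.name = "gene_id"
    peak_table = pd.concat(peak_rows, ignore_index=True)
    return level_table, peak_table


def _stage_integrate(
    level_table: pd.DataFrame,
    cm: CountMatrix,
    gene_set: set[str],
    config: PipelineConfig,
) -> dict[str, net_mod.PcorNetwork]:
    networks = {}
    for cell, group in ((CELLS[0], GROUP_A), (CELLS[1], GROUP_B)):
        features = {
            mark: level_table[f"{mark}_{cell}"] for mark in MARKS
        }
        features["occupancy"] = level_table[f"occupancy_{cell}"]
        features["meDNA"] = level_table[f"methylation_{cell}"]
        features["expression"] = de_mod.group_mean_logcpm(cm, group)
        X = net_mod.build_feature_matrix(features, gene_set)
        networks[cell] = net_mod.infer_network(X, config.shrinkage, config.q_edges)
    return networks


def _stage_enrich(
    peak_table: pd.DataFrame, mis: set[str], universe: list[str]
) -> pd.DataFrame:
    """Chi-square over-representation of promoter peaks on the
    misregulated set versus genome-wide, per (mark, cell)."""
    rows = []
    for (mark, cell), sub in peak_table.groupby(["mark", "cell"]):
        peaked = set(sub.loc[sub["has_peak"], "gene_id"])
        hits_set = len(mis & peaked)
        res = setstats.chisq_enrichment(hits_set, len(mis), len(peaked), len(universe))
        rows.append(
            (
                mark,
                cell,
                100.0 * hits_set / len(mis),
                100.0 * len(peaked) / len(universe),
                res.chi2,
                res.p,
                res.direction,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["mark", "cell", "pct_misregulated", "pct_genome_wide", "chi2", "p", "direction"],
    )


def run_pipeline(config: PipelineConfig, outdir: str, force: bool = False) -> dict:
    """Run every stage in dependency order; returns the summary dict.

    Outputs land in ``outdir``; a manifest records the config hash, the
    seed and per-stage row counts. If a manifest with the same config
    hash and a complete summary already exist, the run is skipped unless
    ``force``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    summary_path = out / "summary.json"
    chash = config.config_hash()
    if not force and manifest_path.exists() and summary_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == chash:
            logger.info("pipeline: outputs up to date for config %s, skipping", chash)
            return json.loads(summary_path.read_text())

    manifest = {"config_hash": chash, "seed": config.seed, "stages": {}}
    summary: dict = {"config_hash": chash, "seed": config.seed}
    sim = config.simulation

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        logger.info("pipeline stage %-22s done", name)
        return result

    # --- simulate
    def do_simulate():
        annotation = generate_annotation(sim)
        truth = generate_truth(sim)
        cm = generate_embryo_counts(truth, sim)
        write_annotation_bed(annotation, out / "annotation.bed")
        _atomic_write_df(truth, out / "truth.tsv")
        write_counts(cm, out / "counts.tsv", out / "design.tsv")
        manifest["stages"]["simulate"] = {"genes": len(annotation), "samples": len(cm.samples)}
        return annotation, truth, cm

    annotation, truth, cm = run_stage("simulate", do_simulate)

    # --- quantify
    def do_quantify():
        level_table, peak_table = _stage_quantify(annotation, truth, config)
        _atomic_write_df(level_table, out / "promoter_levels.tsv")
        _atomic_write_df(peak_table, out / "peaks.tsv", index=False)
        manifest["stages"]["quantify"] = {
            "levels": int(level_table.size),
            "peaks_called": int(peak_table["has_peak"].sum()),
        }
        return level_table, peak_table

    level_table, peak_table = run_stage("quantify", do_quantify)

    # --- differential expression
    def do_de():
        de = de_mod.run_de(
            cm,
            min_consistent=config.min_consistent,
            fdr_strict=config.fdr_strict,
            fdr_relaxed=config.fdr_relaxed,
            lfc_min=config.lfc_min,
        )
        mis, ext = de_mod.define_gene_sets(
            de, config.fdr_strict, config.fdr_relaxed, config.lfc_min
        )
        _atomic_write_df(de, out / "de.tsv", index_label="gene_id")
        write_gene_set(mis, out / "misregulated.txt")
        write_gene_set(ext, out / "extended.txt")
        manifest["stages"]["differential_expression"] = {
            "tested": len(de),
            "fdr_significant": int((de["fdr"] < config.fdr_strict).sum()),
            "misregulated": len(mis),
            "extended": len(ext),
        }
        return de, mis, ext

    de, mis, ext = run_stage("differential_expression", do_de)
    n_up = int((de.loc[de["misregulated"], "logFC"] > 0).sum())
    summary["de"] = {
        "tested": len(de),
        "fdr_significant": int((de["fdr"] < config.fdr_strict).sum()),
        "misregulated": len(mis),
        "misregulated_up": n_up,
        "extended": len(ext),
        "dispersion": float(de.attrs["dispersion"]),
    }

    # --- integrate
    def do_integrate():
        gene_set = ext if config.network_gene_set == "extended" else mis
        networks = _stage_integrate(level_table, cm, gene_set, config)
        for cell, network in networks.items():
            _atomic_write_df(network.edges, out / f"network_{cell}.tsv", index=False)
        manifest["stages"]["integrate"] = {
            cell: int(network.edges["kept"].sum()) for cell, network in networks.items()
        }
        return networks

    networks = run_stage("integrate", do_integrate)
    summary["network"] = {
        cell: {
            "shrinkage": float(net.shrinkage),
            "n_kept": int(net.edges["kept"].sum()),
            "kept_edges": [
                {
                    "edge": f"{r.node_a}--{r.node_b}",
                    "pcor": round(float(r.pcor), 4),
                    "sign": r.sign,
                }
                for r in net.kept_edges().itertuples()
            ],
        }
        for cell, net in networks.items()
    }

    # --- enrich
    def do_enrich():
        enrich = _stage_enrich(peak_table, mis, list(annotation["gene_id"]))
        _atomic_write_df(enrich, out / "enrichment.tsv", index=False)
        manifest["stages"]["enrich"] = {"tests": len(enrich)}
        return enrich

    enrich = run_stage("enrich", do_enrich)
    summary["enrichment"] = enrich.to_dict(orient="records")

    # --- fibers
    def do_fibers():
        rows = {}
        for cell in CELLS:
            fibers = generate_fibers(
                config.n_fibers, config.fiber_mean_extent, sim, label=cell
            )
            write_fibers_bed(fibers, out / f"fibers_{cell}.bed")
            rows[cell] = setstats.replication_extent(fibers)
        d, p = setstats.ks_two_sample(rows[CELLS[0]], rows[CELLS[1]])
        extents = pd.DataFrame(
            {
                "cell": np.repeat(CELLS, [len(rows[c]) for c in CELLS]),
                "fiber_id": np.concatenate([rows[c].index for c in CELLS]),
                "extent": np.concatenate([rows[c].to_numpy() for c in CELLS]),
            }
        )
        _atomic_write_df(extents, out / "fiber_extents.tsv", index=False)
        manifest["stages"]["fibers"] = {"n_fibers": int(len(extents))}
        return {
            "ks_D": float(d),
            "ks_p": float(p),
            "mean_extent": {c: float(rows[c].mean()) for c in CELLS},
        }

    summary["fibers"] = run_stage("fibers", do_fibers)

    _atomic_write_json(manifest, manifest_path)
    _atomic_write_json(summary, summary_path)
    return summary
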