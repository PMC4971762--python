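"""Gene-set statistics, overlap tests, ortholog projection, two-sample
KS comparisons, and DNA-fiber replication-extent summaries.

Chi-square enrichment follows the Pearson statistic on the 2x2 table
without continuity correction by default (a flag enables the corrected
variant). All multi-term families are BH-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FiberSet
from .multtest import bh_adjust

logger = logging.getLogger("spermprog")


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2 [[hits_set, miss_set], [hits_bg, miss_bg]]
    chi2: float
    p: float
    direction: str  # over | under | none


def chisq_enrichment(
    hits_in_set: int,
    set_size: int,
    hits_in_background: int,
    background_size: int,
    correction: bool = False,
) -> ContingencyResult:
    """Pearson chi-square on the 2x2 set-vs-background table, df = 1.

    direction compares the set proportion with the background
    proportion. Equal proportions short-circuit to chi2 = 0, p = 1
    (this also covers tables that would otherwise be degenerate, e.g. a
    term covering the whole universe).
    """
    if set_size <= 0 or background_size <= 0:
        raise ValueError("set and background sizes must be positive")
    if hits_in_set > set_size or hits_in_background > background_size:
        raise ValueError("hits exceed the corresponding size")
    if min(hits_in_set, hits_in_background) < 0:
        raise ValueError("negative hit count")
    table = np.array(
        [
            [hits_in_set, set_size - hits_in_set],
            [hits_in_background, background_size - hits_in_background],
        ],
        dtype=np.int64,
    )
    prop_set = hits_in_set / set_size
    prop_bg = hits_in_background / background_size
    if np.isclose(prop_set, prop_bg):
        return ContingencyResult(table=table, chi2=0.0, p=1.0, direction="none")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("degenerate table: expected cell count of zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    direction = "over" if prop_set > prop_bg else "under"
    return ContingencyResult(table=table, chi2=float(chi2), p=float(p), direction=direction)


def overlap_test(set_a, set_b, universe) -> dict:
    """Venn counts and the upper-tail hypergeometric probability of at
    least the observed overlap."""
    a, b, u = set(set_a), set(set_b), set(universe)
    outside = (a | b) - u
    if outside:
        raise ValueError(f"{len(outside)} elements outside the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return {
        "overlap": k,
        "only_a": len(a - b),
        "only_b": len(b - a),
        "neither": len(u - a - b),
        "p": p,
    }


def project_orthologs(gene_set, ortholog_map: pd.DataFrame) -> set[str]:
    """Project a gene set through a (source, target) ortholog map:
    union of targets of mapped genes, duplicates collapsed; unmapped
    genes are counted and logged."""
    if ortholog_map.empty:
        raise ValueError("empty ortholog map")
    genes = set(gene_set)
    mapped_sources = set(ortholog_map["source"])
    unmapped = genes - mapped_sources
    if unmapped:
        logger.info("ortholog projection: %d genes unmapped", len(unmapped))
    sub = ortholog_map[ortholog_map["source"].isin(genes)]
    return set(sub["target"])


def term_enrichment(
    gene_set, term_map: dict[str, set[str]], universe, method: str = "chisq"
) -> pd.DataFrame:
    """Per-term enrichment of a gene set against a user-supplied
    gene -> terms map (flattened to term -> genes), BH across terms.

    method 'chisq' uses the Pearson test, 'hypergeom' the upper-tail
    hypergeometric probability. Terms with no universe members are
    skipped with a warning.
    """
    genes, u = set(gene_set), set(universe)
    if genes - u:
        raise ValueError("gene set contains genes outside the universe")
    rows = []
    for term, members in sorted(term_map.items()):
        members_u = set(members) & u
        if not members_u:
            logger.warning("term %r has no universe members; skipped", term)
            continue
        hits_set = len(genes & members_u)
        if method == "chisq":
            res = chisq_enrichment(hits_set, len(genes), len(members_u), len(u))
            stat, p, direction = res.chi2, res.p, res.direction
        elif method == "hypergeom":
            p = float(stats.hypergeom.sf(hits_set - 1, len(u), len(members_u), len(genes)))
            stat = float(hits_set)
            expected = len(members_u) * len(genes) / len(u)
            direction = (
                "over" if hits_set > expected else "under" if hits_set < expected else "none"
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((term, hits_set, len(members_u), stat, p, direction))
    out = pd.DataFrame(
        rows, columns=["term", "hits_in_set", "term_size", "stat", "p", "direction"]
    ).set_index("term")
    if not out.empty:
        out["q"] = bh_adjust(out["p"])
    return out


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison.

    D = sup |ECDF_x - ECDF_y|; p from the asymptotic Kolmogorov
    distribution at sqrt(m n / (m + n)) * D.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("empty sample")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / m
    cdf_y = np.searchsorted(y, grid, side="right") / n
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = m * n / (m + n)
    p = float(stats.kstwobign.sf(np.sqrt(en) * d)) if d > 0 else 1.0
    return d, min(1.0, p)


def merge_intervals(intervals) -> list[tuple[float, float]]:
    """Merge overlapping/adjacent half-open intervals."""
    ivs = sorted((float(s), float(e)) for s, e in intervals)
    merged: list[list[float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def replication_extent(fibers: FiberSet) -> pd.Series:
    """Per-fiber replicated fraction: merged replicated length divided
    by the total fiber length."""
    out = {}
    for fid, total, reps in fibers.fibers:
        if total <= 0:
            raise ValueError(f"fiber {fid!r}: nonpositive total length")
        merged = merge_intervals(reps)
        for s, e in merged:
            if s < 0 or e > total:
                raise ValueError(f"fiber {fid!r}: replicated interval outside fiber")
        out[fid] = sum(e - s for s, e in merged) / total
    return pd.Series(out, name="replication_extent")
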