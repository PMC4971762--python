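"""Paired two-group count-based differential expression.

The pipeline mirrors the classic count-based exact-test workflow:
median-of-ratios size factors, a method-of-moments common negative
binomial dispersion, a conditional NB exact test on normalized group
sums, BH control of the FDR, and — on top of the FDR < 0.05 call — a
cross-replicate sign-consistency filter: a gene is "misregulated" only
if its per-experiment fold-changes agree in direction in at least
``min_consistent`` of the E paired experiments (default E - 1, i.e.
6 of 7). A relaxed "extended" set (FDR <= 0.4 and |logFC| >= 0.2) is
also defined for network analyses.

logFC is log2(spermatid_embryo / sperm_embryo) throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUP_A, GROUP_B, CountMatrix
from .multtest import bh_adjust

logger = logging.getLogger("spermprog")

#: pseudocount for per-experiment and overall fold-changes (normalized counts)
LFC_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# normalization and dispersion


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean across samples over
    genes positive in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "consider a pseudo-reference fallback"
        )
    log_ref = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - log_ref[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame, design: pd.DataFrame, sf: pd.Series
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    phi_g = max(0, (s^2 - m) / m^2) with s^2 the within-group pooled
    variance and m the grand mean of the normalized counts.
    """
    norm = counts / sf
    groups = design.groupby("group")["sample"].apply(list)
    n_tot, ss = 0, np.zeros(len(counts))
    for _, samples in groups.items():
        if len(samples) < 2:
            raise ValueError("need at least two samples per group")
        sub = norm[samples].to_numpy()
        ss += sub.shape[1] * sub.var(axis=1, ddof=0)
        n_tot += len(samples)
    s2 = ss / (n_tot - len(groups))
    m = norm.to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m > 0, (s2 - m) / np.square(m), 0.0)
    return pd.Series(np.maximum(phi, 0.0), index=counts.index, name="dispersion")


def common_dispersion(phi: pd.Series) -> float:
    """Median of the per-gene dispersions."""
    return float(np.median(phi.to_numpy()))


# ---------------------------------------------------------------------------
# the conditional NB exact test


def _nb_logpmf(s: np.ndarray, mu: float, phi: float) -> np.ndarray:
    if phi <= 0:
        return stats.poisson.logpmf(s, mu)
    r = 1.0 / phi
    return stats.nbinom.logpmf(s, r, r / (r + mu))


def nb_exact_test(
    a: np.ndarray, b: np.ndarray, phi: float, full_support_max: int = 4000
) -> float:
    """Two-sided conditional NB exact test on normalized, rounded counts.

    Conditioning on the total S = S_a + S_b, the probability of a split
    s is w(s) = NB(s; mu_a, phi/n_a) * NB(S - s; mu_b, phi/n_b),
    normalized, with the null means proportional to group size. The
    two-sided p sums w(s) over all splits no more probable than the
    observed one (ties, including the observed split, counted once).
    At phi = 0 this reduces to the exact conditional binomial test.

    For very large totals the support is truncated to a window of
    +/- 16 conditional standard deviations around the null mean (always
    including the observed split); the excluded tail mass is far below
    the floating-point resolution of the result.
    """
    if phi < 0:
        raise ValueError("dispersion must be nonnegative")
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    sa, sb = int(a.sum()), int(b.sum())
    total = sa + sb
    if total == 0:
        logger.debug("nb_exact_test: zero total, p = 1 by convention")
        return 1.0
    na, nb_ = len(a), len(b)
    mu_a = total * na / (na + nb_)
    mu_b = total - mu_a
    if total <= full_support_max:
        s = np.arange(total + 1)
    else:
        var = mu_a + (phi / na) * mu_a**2 if phi > 0 else mu_a
        half = int(16 * np.sqrt(var)) + 1
        lo = max(0, min(int(mu_a) - half, sa))
        hi = min(total, max(int(mu_a) + half, sa))
        s = np.arange(lo, hi + 1)
    logw = _nb_logpmf(s, mu_a, phi / na) + _nb_logpmf(total - s, mu_b, phi / nb_)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    w_obs = w[np.searchsorted(s, sa)]
    p = float(w[w <= w_obs * (1 + 1e-7)].sum())
    return min(1.0, p)


# ---------------------------------------------------------------------------
# consistency filter and gene sets


def per_experiment_logfc(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """log2 fold-change (spermatid/sperm embryo) within each paired
    experiment, on pseudocounted normalized counts."""
    norm = cm.counts / sf
    cols = {}
    for exp, sub in cm.design.groupby("experiment"):
        s_a = sub.loc[sub["group"] == GROUP_A, "sample"].iloc[0]
        s_b = sub.loc[sub["group"] == GROUP_B, "sample"].iloc[0]
        cols[f"logfc_exp{exp}"] = np.log2(
            (norm[s_b] + LFC_PSEUDOCOUNT) / (norm[s_a] + LFC_PSEUDOCOUNT)
        )
    return pd.DataFrame(cols, index=cm.counts.index)


def consistency_filter(lfc: pd.DataFrame | np.ndarray, min_consistent: int) -> np.ndarray:
    """True where at least ``min_consistent`` experiments agree in sign
    (zeros count toward neither direction)."""
    arr = np.asarray(lfc, dtype=float)
    e = arr.shape[1]
    if not (1 <= min_consistent <= e):
        raise ValueError(f"min_consistent must be in 1..{e}")
    pos = (arr > 0).sum(axis=1)
    neg = (arr < 0).sum(axis=1)
    return np.maximum(pos, neg) >= min_consistent


def expressed_filter(
    cm: CountMatrix, cpm_min: float = 1.0, min_samples: int = 2
) -> pd.Series:
    """Keep genes with counts-per-million > cpm_min in >= min_samples."""
    lib = cm.counts.sum(axis=0)
    cpm = cm.counts * 1e6 / lib
    return (cpm > cpm_min).sum(axis=1) >= min_samples


def define_gene_sets(
    de: pd.DataFrame,
    fdr_strict: float = 0.05,
    fdr_relaxed: float = 0.4,
    lfc_min: float = 0.2,
) -> tuple[set[str], set[str]]:
    """The misregulated set (FDR < strict AND sign-consistent) and the
    extended set (FDR <= relaxed AND |logFC| >= lfc_min)."""
    for t in (fdr_strict, fdr_relaxed):
        if not (0 < t <= 1):
            raise ValueError("FDR thresholds must lie in (0, 1]")
    mis = set(de.index[(de["fdr"] < fdr_strict) & de["consistent"]])
    ext = set(de.index[(de["fdr"] <= fdr_relaxed) & (de["logFC"].abs() >= lfc_min)])
    return mis, ext


def expression_correlation(x, y, subset=None) -> float:
    """Pearson correlation of two per-gene expression vectors, optionally
    restricted to a gene subset."""
    x, y = pd.Series(x), pd.Series(y)
    if subset is not None:
        subset = list(subset)
        x, y = x.loc[subset], y.loc[subset]
    if len(x) < 3:
        raise ValueError("need at least 3 genes")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("zero variance in expression vector")
    return float(stats.pearsonr(x.to_numpy(), y.to_numpy())[0])


# ---------------------------------------------------------------------------
# full DE run


def run_de(
    cm: CountMatrix,
    min_consistent: int | None = None,
    fdr_strict: float = 0.05,
    fdr_relaxed: float = 0.4,
    lfc_min: float = 0.2,
    cpm_min: float = 1.0,
    min_expressed_samples: int = 2,
) -> pd.DataFrame:
    """Run the full paired DE pipeline and return the per-gene table.

    Columns: logFC, logCPM, p, fdr, consistent, misregulated, extended,
    and one logfc_exp<i> column per experiment. Genes failing the
    expressed filter are dropped before testing.
    """
    if min_consistent is None:
        min_consistent = cm.n_experiments - 1
    keep = expressed_filter(cm, cpm_min, min_expressed_samples)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("DE: dropped %d genes below the expressed filter", n_dropped)
    counts = cm.counts[keep]
    if counts.empty:
        raise ValueError("no genes pass the expressed filter")
    sf = size_factors(counts)
    phi = common_dispersion(estimate_dispersion(counts, cm.design, sf))

    samples_a = cm.samples_of(GROUP_A)
    samples_b = cm.samples_of(GROUP_B)
    norm = counts / sf
    scaled_a = np.rint(norm[samples_a].to_numpy()).astype(np.int64)
    scaled_b = np.rint(norm[samples_b].to_numpy()).astype(np.int64)
    p = np.array(
        [nb_exact_test(scaled_a[i], scaled_b[i], phi) for i in range(len(counts))]
    )
    fdr = bh_adjust(p)

    mean_a = norm[samples_a].mean(axis=1).to_numpy()
    mean_b = norm[samples_b].mean(axis=1).to_numpy()
    logfc = np.log2((mean_b + LFC_PSEUDOCOUNT) / (mean_a + LFC_PSEUDOCOUNT))
    lib = counts.sum(axis=0)
    logcpm = np.log2((counts * 1e6 / lib).mean(axis=1).to_numpy() + LFC_PSEUDOCOUNT)

    cm_kept = CountMatrix(counts=counts, design=cm.design)
    lfc_exp = per_experiment_logfc(cm_kept, sf)
    consistent = consistency_filter(lfc_exp, min_consistent)

    de = pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": logcpm,
            "p": p,
            "fdr": fdr,
            "consistent": consistent,
        },
        index=counts.index,
    )
    de = pd.concat([de, lfc_exp], axis=1)
    mis, ext = define_gene_sets(de, fdr_strict, fdr_relaxed, lfc_min)
    de["misregulated"] = de.index.isin(mis)
    de["extended"] = de.index.isin(ext)
    de.attrs["dispersion"] = phi
    de.attrs["size_factors"] = sf.to_dict()
    return de


def group_mean_logcpm(cm: CountMatrix, group: str, genes=None) -> pd.Series:
    """Mean log2 counts-per-million (effective library, pseudocount 0.5)
    over the samples of one embryo group — the expression feature used
    by the network stage."""
    sf = size_factors(cm.counts)
    lib = cm.counts.sum(axis=0) * sf
    cpm = cm.counts.div(lib, axis=1) * 1e6
    samples = cm.design.loc[cm.design["group"] == group, "sample"]
    out = np.log2(cpm[list(samples)] + LFC_PSEUDOCOUNT).mean(axis=1)
    if genes is not None:
        out = out.loc[list(genes)]
    return out.rename(f"expression_{group}")
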