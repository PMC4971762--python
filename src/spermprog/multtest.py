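"""Benjamini-Hochberg step-up FDR adjustment (shared by every family of
tests in the package: genes, peaks, terms, network edges)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """BH step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
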