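import numpy as np
import pandas as pd
import pytest

from spermprog.io import CountMatrix, CoverageTrack


@pytest.fixture
def annotation():
    """Four genes on two chromosomes, both strands."""
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "strand": ["+", "-", "+", "-"],
            "tss": [1000, 1000, 3000, 2000],
        }
    )


@pytest.fixture
def uniform_track():
    return CoverageTrack({"chr1": np.full(6000, 3.0), "chr2": np.full(6000, 3.0)})


def make_counts(counts: np.ndarray, n_experiments: int) -> CountMatrix:
    """Paired count matrix from a genes x (2E) array; columns alternate
    sperm/spermatid within each experiment."""
    samples, rows = [], []
    for e in range(1, n_experiments + 1):
        for group in ("sperm_embryo", "spermatid_embryo"):
            samples.append(f"{group}_{e}")
            rows.append((f"{group}_{e}", group, e))
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(counts.shape[0])],
        columns=samples,
    )
    design = pd.DataFrame(rows, columns=["sample", "group", "experiment"])
    return CountMatrix(counts=df, design=design)
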