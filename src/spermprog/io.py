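"""Readers, writers and core genomic containers.

All coordinates inside the package are 0-based half-open (BED convention).
GTF/GFF input (1-based closed) is converted on read. Chromosome names are
matched by exact string comparison; no "chr" aliasing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("spermprog")

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss"]

#: the two embryo groups of the paired design
GROUP_A = "sperm_embryo"
GROUP_B = "spermatid_embryo"


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome, 0-based.

    ``clipped`` records whether the interval was truncated at a
    chromosome boundary when it was constructed from a window request.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Per-chromosome nonnegative signal at base resolution.

    Values are dense numpy arrays, one per chromosome. ``total_signal``
    is the sum of all stored values; window sums are served from cached
    cumulative sums so repeated promoter queries are O(1).
    """

    def __init__(self, values: dict[str, np.ndarray], label: str = ""):
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for chrom, arr in self.values.items():
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: coverage must be one-dimensional")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative coverage value")
        self.label = label
        self._cumsum: dict[str, np.ndarray] = {}

    @property
    def total_signal(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom])

    def _cum(self, chrom: str) -> np.ndarray:
        if chrom not in self._cumsum:
            arr = self.values[chrom]
            cs = np.empty(len(arr) + 1)
            cs[0] = 0.0
            np.cumsum(arr, out=cs[1:])
            self._cumsum[chrom] = cs
        return self._cumsum[chrom]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of signal on [start, end), clipped to the chromosome."""
        if chrom not in self.values:
            return 0.0
        n = len(self.values[chrom])
        lo, hi = max(0, start), min(n, end)
        if lo >= hi:
            return 0.0
        cs = self._cum(chrom)
        return float(cs[hi] - cs[lo])

    def window_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values on [start, end); positions outside the
        chromosome are NaN (used to keep clipped metagene windows
        unbiased)."""
        out = np.full(end - start, np.nan)
        if chrom not in self.values:
            return out
        arr = self.values[chrom]
        lo, hi = max(0, start), min(len(arr), end)
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: v * factor for c, v in self.values.items()}, label=self.label
        )


@dataclass
class CountMatrix:
    """Integer gene x sample counts with a paired two-group design.

    ``design`` has one row per sample with columns ``sample``, ``group``
    and ``experiment``; every experiment index carries exactly one
    sample of each group.
    """

    counts: pd.DataFrame  # genes x samples, integer
    design: pd.DataFrame  # sample, group, experiment

    def __post_init__(self) -> None:
        validate_design(self.counts, self.design)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_experiments(self) -> int:
        return int(self.design["experiment"].nunique())

    def samples_of(self, group: str) -> list[str]:
        d = self.design.set_index("experiment").sort_index()
        return list(d.loc[d["group"] == group, "sample"])


@dataclass
class FiberSet:
    """Combed DNA fibers: per-fiber total length (kb or bp, any single
    unit) and replicated sub-intervals on the fiber's own axis."""

    fibers: list[tuple[str, float, list[tuple[float, float]]]] = field(
        default_factory=list
    )

    def __len__(self) -> int:
        return len(self.fibers)


# ---------------------------------------------------------------------------
# annotation


def _tss_from_bed(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end - 1


def read_annotation(path: str, feature: str | None = None) -> pd.DataFrame:
    """Read gene annotation from a BED-like table or a GTF/GFF file.

    Returns a DataFrame with columns gene_id, chrom, strand, tss (0-based).
    The TSS is the feature start for + strand genes and end-1 for - strand
    genes. Duplicate gene_ids keep the first occurrence with a warning.
    """
    path = str(path)
    if path.endswith((".gtf", ".gff", ".gff3", ".gtf.gz", ".gff.gz")):
        rows = _read_gtf(path, feature or "gene")
    else:
        rows = _read_bed_annotation(path)
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    dup = df["gene_id"].duplicated()
    if dup.any():
        logger.warning(
            "annotation: %d duplicated gene_id rows dropped (first kept)",
            int(dup.sum()),
        )
        df = df[~dup]
    return df.reset_index(drop=True)


def _read_bed_annotation(path: str) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 BED columns "
                    f"(chrom start end name score strand), got {len(parts)}"
                )
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if not (0 <= start_i < end_i):
                raise FormatError(f"{path}:{lineno}: invalid interval")
            rows.append((name, chrom, strand, _tss_from_bed(start_i, end_i, strand)))
    return rows


def _read_gtf(path: str, feature: str) -> list[tuple]:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type(feature):
        if feat.strand not in ("+", "-"):
            raise FormatError(f"{path}: unknown strand {feat.strand!r} on {feat.id}")
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        # gffutils keeps GTF 1-based closed coordinates; convert
        start0, end0 = feat.start - 1, feat.end
        rows.append((gid, feat.seqid, feat.strand, _tss_from_bed(start0, end0, feat.strand)))
    return rows


def write_annotation_bed(annotation: pd.DataFrame, path: str, width: int = 1) -> None:
    """Write TSS positions as BED6 (one `width`-bp interval per gene)."""
    with open(path, "w") as fh:
        for row in annotation.itertuples():
            if row.strand == "+":
                start, end = row.tss, row.tss + width
            else:
                start, end = row.tss - width + 1, row.tss + 1
            fh.write(f"{row.chrom}\t{max(0, start)}\t{end}\t{row.gene_id}\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# coverage


def read_coverage(path: str, label: str = "") -> CoverageTrack:
    """Read a 4-column bedGraph into a dense CoverageTrack.

    Overlapping intervals are summed (additive pileup semantics);
    uncovered positions are zero.
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except pd.errors.EmptyDataError:
        return CoverageTrack({}, label=label or str(path))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed bedGraph ({exc})") from exc
    if (df["end"] <= df["start"]).any():
        bad = int(df.index[(df["end"] <= df["start"])][0]) + 1
        raise FormatError(f"{path}: end <= start at data line {bad}")
    if (df["value"] < 0).any():
        bad = int(df.index[(df["value"] < 0)][0]) + 1
        raise FormatError(f"{path}: negative value at data line {bad}")
    values: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        length = int(sub["end"].max())
        delta = np.zeros(length + 1)
        np.add.at(delta, sub["start"].to_numpy(), sub["value"].to_numpy())
        np.add.at(delta, sub["end"].to_numpy(), -sub["value"].to_numpy())
        values[str(chrom)] = np.cumsum(delta[:-1])
    return CoverageTrack(values, label=label or str(path))


def write_coverage(track: CoverageTrack, path: str) -> None:
    """Write a CoverageTrack as bedGraph (run-length encoded, zero runs
    skipped)."""
    with open(path, "w") as fh:
        for chrom in track.values:
            arr = track.values[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# counts


def validate_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    required = {"sample", "group", "experiment"}
    missing = required - set(design.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    design_samples = set(design["sample"])
    for s in counts.columns:
        if s not in design_samples:
            raise FormatError(f"sample {s!r} in count matrix missing from design")
    groups = sorted(design["group"].unique())
    if len(groups) != 2:
        raise FormatError(f"expected exactly two groups, got {groups}")
    for exp, sub in design.groupby("experiment"):
        per_group = sub.groupby("group").size()
        if sorted(per_group.index) != groups or (per_group != 1).any():
            raise FormatError(f"unpaired experiment {exp}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("non-numeric count value")
    if np.any(arr < 0):
        raise FormatError("negative count")
    if np.any(arr != np.floor(arr)):
        gi, si = np.argwhere(arr != np.floor(arr))[0]
        raise FormatError(
            f"non-integer count {arr[gi, si]!r} at gene "
            f"{counts.index[gi]!r}, sample {counts.columns[si]!r}"
        )


def read_counts(path: str, design_path: str) -> CountMatrix:
    """Read a genes x samples TSV count matrix plus its design table."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", dtype={"sample": str})
    design = design[[c for c in ("sample", "group", "experiment") if c in design.columns]]
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    cm = CountMatrix(counts=counts, design=design)
    return cm


def write_counts(cm: CountMatrix, counts_path: str, design_path: str) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    cm.design.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog map, gene sets, fibers


def read_ortholog_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["source", "target"]
    if df.isna().any().any() or (df == "").any().any():
        raise FormatError(f"{path}: empty gene id in ortholog map")
    return df


def read_gene_set(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_fibers_bed(path: str) -> FiberSet:
    """Read fibers from BED6: chrom column = fiber_id, one `total` record
    named 'total' spanning [0, L) and 'rep' records for replicated
    segments."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["fiber", "start", "end", "name", "score", "strand"],
        dtype={"fiber": str, "name": str},
    )
    fibers = []
    for fid, sub in df.groupby("fiber", sort=False):
        totals = sub[sub["name"] == "total"]
        if len(totals) != 1:
            raise FormatError(f"fiber {fid!r}: expected exactly one 'total' record")
        total_len = float(totals.iloc[0]["end"] - totals.iloc[0]["start"])
        reps = [
            (float(r.start), float(r.end))
            for r in sub[sub["name"] == "rep"].itertuples()
        ]
        fibers.append((str(fid), total_len, reps))
    return FiberSet(fibers=fibers)


def write_fibers_bed(fibers: FiberSet, path: str) -> None:
    with open(path, "w") as fh:
        for fid, total, reps in fibers.fibers:
            fh.write(f"{fid}\t0\t{total:g}\ttotal\t0\t+\n")
            for s, e in reps:
                fh.write(f"{fid}\t{s:g}\t{e:g}\trep\t0\t+\n")
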