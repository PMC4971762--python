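"""TSS-anchored quantification of epigenomic coverage tracks.

Three views of promoter signal, all anchored at the transcription start
site (TSS):

* metagene profiles — average signal per bin as a function of distance
  from the TSS, orientation-flipped so upstream is always to the left;
* per-gene promoter levels — depth-scaled, pseudocounted log2 IP/input
  over a symmetric TSS window;
* promoter peak calls — a Poisson upper-tail test of the integerized IP
  window count against an input-derived local expectation, with
  Benjamini-Hochberg control across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CoverageTrack, GenomicInterval
from .multtest import bh_adjust

#: minimum expected count for the Poisson peak test
LAMBDA_FLOOR = 1.0


@dataclass
class MetageneProfile:
    bin_centers: np.ndarray  # bp relative to TSS, negative upstream
    mean_signal: np.ndarray
    n_genes: int


def tss_window(tss: int, strand: str, flank: int, chrom: str = "") -> GenomicInterval:
    """Symmetric window [tss - flank, tss + flank), clipped at 0."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    start = tss - flank
    clipped = start < 0
    return GenomicInterval(
        chrom=chrom, start=max(0, start), end=tss + flank, strand=strand, clipped=clipped
    )


def _per_million(track: CoverageTrack) -> float:
    total = track.total_signal
    if total <= 0:
        raise ValueError(f"empty track {track.label!r}")
    return 1e6 / total


def metagene_profile(
    track: CoverageTrack,
    annotation: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 50,
    depth_normalize: bool = False,
) -> MetageneProfile:
    """Average signal around the TSS, binned.

    Per gene, the +/- flank window is extracted, flipped for - strand
    genes, and averaged per base within each bin; the profile is the
    unweighted mean over genes. Windows clipped at chromosome edges
    contribute only their available bases (NaN elsewhere).
    """
    if flank <= 0 or bin_size <= 0 or (2 * flank) % bin_size != 0:
        raise ValueError("bin size must divide 2*flank")
    scale = _per_million(track) if depth_normalize else 1.0
    n_bins = 2 * flank // bin_size
    usable = annotation[annotation["chrom"].isin(track.values.keys())]
    if usable.empty:
        raise ValueError("no genes overlap the track's chromosomes")
    per_gene = np.full((len(usable), n_bins), np.nan)
    for i, row in enumerate(usable.itertuples()):
        win = track.window_values(row.chrom, row.tss - flank, row.tss + flank)
        if row.strand == "-":
            win = win[::-1]
        per_gene[i] = np.nanmean(win.reshape(n_bins, bin_size), axis=1)
    centers = np.arange(n_bins) * bin_size - flank + bin_size / 2.0
    with np.errstate(invalid="ignore"):
        mean_signal = np.nanmean(per_gene, axis=0) * scale
    return MetageneProfile(bin_centers=centers, mean_signal=mean_signal, n_genes=len(usable))


def _window_sums(track: CoverageTrack, annotation: pd.DataFrame, flank: int) -> np.ndarray:
    return np.array(
        [
            track.window_sum(row.chrom, row.tss - flank, row.tss + flank)
            for row in annotation.itertuples()
        ]
    )


def promoter_level(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    annotation: pd.DataFrame,
    flank: int = 1000,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2(IP/input) promoter level.

    Window sums are scaled to signal-per-million of their track and
    pseudocounted, so every gene gets a finite level:
    level = log2((ip_win*1e6/ip_total + c) / (input_win*1e6/input_total + c)).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ip_scale, in_scale = _per_million(ip), _per_million(input_track)
    ip_win = _window_sums(ip, annotation, flank) * ip_scale
    in_win = _window_sums(input_track, annotation, flank) * in_scale
    level = np.log2((ip_win + pseudocount) / (in_win + pseudocount))
    return pd.Series(level, index=annotation["gene_id"].to_numpy(), name="level")


def call_promoter_peaks(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    annotation: pd.DataFrame,
    flank: int = 1000,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Poisson promoter-window peak test.

    The input window sum is depth-matched to the IP total; the IP window
    sum is rounded to an integer count k, and p = P(Poisson(lambda) >= k)
    with lambda = max(matched input count, 1). q is BH over all genes;
    has_peak = q < q_threshold.
    """
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must be in (0, 1)")
    ip_total, in_total = ip.total_signal, input_track.total_signal
    if ip_total <= 0 or in_total <= 0:
        raise ValueError("empty track")
    depth_match = ip_total / in_total
    k_ip = np.rint(_window_sums(ip, annotation, flank)).astype(np.int64)
    lam = np.maximum(_window_sums(input_track, annotation, flank) * depth_match, LAMBDA_FLOOR)
    p = poisson_upper_tail(k_ip, lam)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": annotation["gene_id"].to_numpy(),
            "k_ip": k_ip,
            "lam": lam,
            "p": p,
            "q": q,
            "has_peak": q < q_threshold,
        }
    ).set_index("gene_id")


def poisson_upper_tail(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """P(X >= k) for X ~ Poisson(lam); 1 when k = 0."""
    k = np.asarray(k)
    return stats.poisson.sf(k - 1, np.asarray(lam, dtype=float))


def percent_with_peak(peaks: pd.DataFrame, gene_set) -> float:
    """Percentage of the gene set carrying a called peak."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    missing = set(genes) - set(peaks.index)
    if missing:
        raise KeyError(f"{len(missing)} genes absent from peak table")
    return 100.0 * float(peaks.loc[genes, "has_peak"].sum()) / len(genes)


def peaks_to_bed(
    peaks: pd.DataFrame, annotation: pd.DataFrame, path: str, flank: int = 1000
) -> None:
    """Write called peaks as BED6 with score = -10*log10(q), capped at 1000."""
    ann = annotation.set_index("gene_id")
    with open(path, "w") as fh:
        for gid, row in peaks[peaks["has_peak"]].iterrows():
            a = ann.loc[gid]
            score = min(1000, int(round(-10 * np.log10(max(row["q"], 1e-100)))))
            fh.write(
                f"{a.chrom}\t{max(0, a.tss - flank)}\t{a.tss + flank}\t{gid}\t{score}\t{a.strand}\n"
            )
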