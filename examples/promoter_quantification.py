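"""Quantify promoter chromatin signal at transcription start sites.

Builds small synthetic ChIP-like tracks, then computes a TSS metagene
profile of nucleosome occupancy, per-gene log2 IP/input promoter levels
for H3K27me3, and the percentage of genes with called H3K4me2 peaks
genome-wide versus on the programmed genes (the Fig-4C-style contrast).
"""

from spermprog.quantify import call_promoter_peaks, metagene_profile, percent_with_peak, promoter_level
from spermprog.simulate import SimulationConfig, epigenome_track, generate_annotation, generate_truth

config = SimulationConfig(n_genes=300, seed=2)
annotation = generate_annotation(config)
truth = generate_truth(config)

occupancy = epigenome_track(annotation, truth, config, "occupancy", "sperm")
profile = metagene_profile(occupancy, annotation, flank=2000, bin_size=50)
peak_bin = profile.bin_centers[profile.mean_signal.argmax()]
print(f"occupancy metagene over {profile.n_genes} genes: "
      f"max {profile.mean_signal.max():.2f} at {peak_bin:+.0f} bp from the TSS")

ip = epigenome_track(annotation, truth, config, "H3K27me3", "sperm")
inp = epigenome_track(annotation, truth, config, "input", "sperm")
levels = promoter_level(ip, inp, annotation, flank=1000)
marked = truth["H3K27me3_sperm"]
print(f"H3K27me3 level (log2 IP/input): marked genes {levels[marked.to_numpy()].mean():+.2f}, "
      f"unmarked {levels[(~marked).to_numpy()].mean():+.2f}")

k4 = epigenome_track(annotation, truth, config, "H3K4me2", "spermatid")
peaks = call_promoter_peaks(k4, inp, annotation, flank=1000)
programmed = truth.index[truth["class"] == "programmed"]
print(f"H3K4me2 peaks (spermatid): {percent_with_peak(peaks, truth.index):.0f}% genome-wide, "
      f"{percent_with_peak(peaks, programmed):.0f}% of programmed genes")
print()
print("Marked promoters separate cleanly from unmarked ones; programmed genes")
print("carry spermatid H3K4me2 far above the genome-wide rate, the pattern the")
print("enrichment stage tests formally.")
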