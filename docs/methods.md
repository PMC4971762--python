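# Methods

This note documents the statistical procedures, the generative model
behind the synthetic data, the defaults and why they were chosen, and
the known limits of what the test suite demonstrates.

## Coordinates and input formats

All genomic coordinates are 0-based half-open (BED convention); GTF/GFF
input (1-based closed) is converted on read, so a + strand gene's TSS is
its start and a − strand gene's TSS is end − 1. Chromosome names are
matched exactly — no "chr" aliasing — and mismatches surface as counts
of dropped genes rather than silent renames. bedGraph intervals are
summed where they overlap (additive pileup semantics). Duplicate gene
ids keep the first record with a logged warning.

## TSS-anchored quantification

Promoter windows are TSS ± flank (default 1 kb for levels and peaks,
2 kb with 50-bp bins for metagene profiles), clipped at chromosome
edges; clipped genes keep their reduced window, and per-base means keep
that unbiased. Metagene windows are orientation-flipped for − strand
genes so upstream is always left. Depth normalization is
signal-per-million of the track total.

Promoter level = log2((IP_win·1e6/IP_tot + c)/(input_win·1e6/input_tot + c))
with pseudocount c = 1 signal-per-million unit, so every gene has a
finite level and the statistic is antisymmetric under swapping IP and
input.

Peak calling is deliberately simple and fully specified: the input
window sum is depth-matched to the IP total, the IP window sum is
rounded to a count k, and p = P(Poisson(λ) ≥ k) with
λ = max(matched input, 1). The λ floor stops empty input windows from
producing spurious calls; k = 0 gives p = 1, so a gene with no IP
signal can never be a peak. BH is applied per (mark, cell) family with
q < 0.05 by default. This is a promoter-window test, not a genome-wide
peak caller.

## Paired differential expression

Normalization is median-of-ratios against the geometric-mean reference
over genes positive in all samples, rescaled to geometric mean 1.
Dispersion is method-of-moments on normalized counts,
φ_g = max(0, (s² − m̄)/m̄²) with the within-group pooled variance, and the
test uses the common dispersion = median over genes. The median of
noisy per-gene moment estimates sits slightly below a constant true φ
(right-skewed sampling distribution), so the test runs mildly above nominal; the
calibration tests bound the simulated-null type-I error at α = 0.05 by
0.06 to reflect that.

The exact test conditions on the total of the normalized, rounded
counts: with group sums S_a, S_b and null means proportional to group
size, w(s) ∝ NB(s; μ_a, φ/n_a)·NB(S−s; μ_b, φ/n_b) over splits
s = 0..S, and the two-sided p sums all w(s) ≤ w(S_a)·(1+1e−7) — ties,
including the observed split, count once; the relative tolerance
absorbs floating-point ties. At φ = 0 this is the exact conditional
binomial test, which the oracle suite checks to 1e−12. For totals above
4000 the support is truncated to ±16 conditional standard deviations
around the null mean (always including the observed split); the
excluded mass is below 1e−50 and unit tests confirm agreement with the
full enumeration. S = 0 returns p = 1 by convention.

Per-experiment fold-changes use pseudocount 0.5 on normalized counts,
log2((spermatid/sf + 0.5)/(sperm/sf + 0.5)), which is finite and
sign-stable; the consistency filter requires the same sign in at least
min_consistent experiments (default E − 1, zeros counting toward
neither side). Genes are pre-filtered to counts-per-million > 1 in ≥ 2
samples. The misregulated set is {FDR < 0.05 ∧ consistent}; the
extended set {FDR ≤ 0.4 ∧ |logFC| ≥ 0.2}.

## Feature integration and networks

The feature matrix inner-joins per-gene promoter levels of the four
marks, occupancy, methylation, and the embryo expression of the
matching group (mean log2 counts-per-million on effective libraries,
pseudocount 0.5), dropping genes missing any feature (logged) and
z-scoring each column; a constant column or a feature covering < 80% of
the gene set is an error, since either would make the correlation
matrix meaningless.

Partial correlations come from inverting S* = (1−λ)R + λI. The default
λ is the closed-form Schäfer–Strimmer intensity toward the
identity-correlation target, clipped to [0, 1]; λ = 0 is available and
is what the residual-regression oracle tests use. Edge significance is
analytic: t = pcor·√((n−k)/(1−pcor²)) on n − k degrees of freedom,
two-sided, BH over the 21 edges of a 7-node network. The t statistic is
computed from the *sample* (λ = 0) partial correlation: that is the
estimator whose sampling distribution the t theory describes, whereas
the shrunk estimate is biased toward zero by construction and would
make the test increasingly conservative exactly when n is small and λ
large. The shrunk value is still what the network reports as the edge
weight, and a seeded permutation test (column rotation) is provided as
a cross-check. Networks keep isolated nodes; edges are signed, with
|pcor| as weight.

The pipeline computes the sperm network (sperm features vs sperm-embryo
expression) and the spermatid network (spermatid features vs
spermatid-embryo expression) on the extended gene set by default. The
strict misregulated set is nearly a single gene class under the
generative model, so its feature columns carry little contrast at
n ≈ 40; the relaxed set mixes classes and is the configuration under
which the analysis has useful power (`network_gene_set` switches this).

## Set statistics and fibers

χ² enrichment is the Pearson statistic on the 2×2 set-vs-background
table without continuity correction (a flag enables it), df = 1,
direction from the proportion comparison; exactly equal proportions
short-circuit to (χ² = 0, p = 1, none), which also covers tables a
zero margin would otherwise degenerate. Overlap tests use the
upper-tail hypergeometric probability. Term enrichment runs one test
per user-supplied term (χ² or hypergeometric) with BH across terms.
The KS statistic is the exact sup-difference of the two ECDFs with the
asymptotic Kolmogorov p at √(mn/(m+n))·D — adequate at the ≥ 125
observations typical of fiber assays; small-sample exactness is only
used as a test oracle. Replication extent merges overlapping replicated
segments before dividing by fiber length, so it is invariant to how a
replicated tract is split.

## The synthetic-data generator

The generator emulates the epigenetic-programming model: each gene is
programmed (probability 1%, H3K27me3 in both cells, H3K4me2/3 in the
spermatid only, up-regulated in spermatid-derived embryos), or else
active (50% of the rest; K4 marks in both cells), repressed (25%;
K27me3 in both, half also H3K9me3), or unmarked (25%). Defaults follow
the scale of the motivating study: 5000 genes at 5-kb spacing, 7 paired
experiments, NB dispersion 0.05, million-read libraries, log2 design
effect 1.5. All randomness flows from one integer seed through named
child streams (SeedSequence spawn keys), so outputs are byte-identical
across runs and independent of call order.

Expression model. Baseline propensities L_g are lognormal(μ=4, σ=1.5).
The expected mean for the embryo group of cell c is

    mean_c(g) = L_g · 2^( boost·programmed + k4_c·(d2·K4me2_c + d3·K4me3_c)/2
                          − rep·d27·K27_c − k9·d9·K9_c )

where d are per-gene doses (below), the K4 response coefficient k4_c is
2.0 at a plain active promoter but attenuated to the design effect 1.5
when the promoter is bivalent in that cell (Polycomb dominates the K4
response), rep = 1.0 and k9 = 0.5 are the repressive couplings, and
boost = 1 log2 places programmed (developmentally important) genes in
the detectable expression range. Because every repressive term and the
boost are identical in the two cells, the spermatid/sperm log-ratio of
a programmed gene is exactly the design effect times its K4 dose
(mean 1 across genes), and zero for every other class; effect = 0 is
the null configuration. Counts are NB draws per sample with per-sample
lognormal depth variation (sd 0.1) so size-factor estimation is
genuinely exercised.

Doses and tracks. Marked genes carry a Gaussian bump (sd 300 bp) at the
TSS with height = mark height (20) × dose; the dose is a shared
histone-retention factor (lognormal, log-sd 0.9 — bivalent promoters
retain correlated amounts of all marks) times a per-mark factor
(log-sd 0.4), normalized to mean 1. Activation responds to the square
root of the dose (saturating response: realized effects stay
concentrated near the design effect) while repression is linear in it,
and the Polycomb dose is damped on highly expressed genes
(2^−0.5z, z the standardized log baseline). On top of the class
structure, all genes carry transcription-coupled basal chromatin:
H3K4me2/3 bump amplitude scales with baseline expression
(0.5·2^z per unit height), H3K27me3/H3K9me3 against it, each with
independent lognormal noise (log-sd 0.5) — the genome-wide
mark–expression correlations real ChIP data shows, and the channel that
lets the partial-correlation stage find mark-specific expression edges.
Occupancy and methylation get a bump at every TSS with sperm amplitude
1.5× the spermatid one and a shared per-gene amplitude stream, so
sperm/spermatid methylation levels correlate across genes; methylation
is additionally anti-coupled to expression (2^−0.3z). Inputs are flat;
half-normal background noise (sd 0.5) covers every track.

Fibers are 50–250 kb with Beta-distributed replicated fractions
(mean as requested, concentration 5) realized as non-overlapping
segments via Dirichlet splits, so the per-fiber extent is exact by
construction.

What the generator does not emulate: read-level artifacts (GC,
mappability, fragment-length effects), inter-experiment biological
heterogeneity (non-programmed genes have exactly zero true fold-change,
which makes the relaxed FDR ≤ 0.4 set far smaller relative to the
strict set than in real data), continuous class boundaries, and any
sequence content. Passing tests therefore demonstrate correctness of
the statistics and recovery under the stated model, not performance on
real libraries.

## Problem sizes and numerical choices

The suite and the acceptance script run at the default 5000-gene scale
for recovery and at 120–2500 genes for unit-level checks; Gaussian
graphical model recovery uses 7 nodes × 1000 observations × 50
replicates. The planted model for recovery is the saturated 7-node
precision 0.7·I + 0.3·uu^T (u an alternating ±1 pattern): all 21 edges
have |pcor| = 0.3 with signs −u_i u_j, every tested edge is a true
edge, and exact kept-set recovery is therefore a pure power check —
with sparse planted graphs the analytic BH test at q < 0.05 admits a
false edge in roughly a fifth of runs, which is the expected behavior
of the test, not an implementation defect. Sparse recovery (planted
edges recovered with correct signs, false extras rare) is checked
separately.

Degenerate inputs are handled explicitly: empty tracks are errors where
a ratio would be undefined; zero conditional totals give p = 1; fibers
with replicated segments outside the fiber, malformed rows (with line
numbers), unpaired designs, non-integer counts, and out-of-range
thresholds all raise immediately, and config validation collects every
error before reporting.

## Known limitations

The DE test ignores the pairing when computing the conditional
distribution (pairing enters only through the consistency filter), the
common-dispersion estimate is slightly downward-biased, the peak caller
is promoter-window-only, and the network stage assumes approximately
Gaussian z-scored features. The generator's couplings are mechanistic
placeholders chosen for realism of the induced correlations, not
estimates of any real biology.
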