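# Methods

This note documents the statistical model behind `cnclonality`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducibility.

## Data model and coordinates

All coordinates are 1-based inclusive internally; BED input (0-based,
half-open) is converted at the read boundary and the conversion is its own
inverse. Markers are totally ordered by (chromosome rank in the layout,
position), and a single `MarkerTrack` is shared by every sample in an
analysis, so marker indices are comparable across samples. The packaged
default layout has the 39 autosomal arms (acrocentric p-arms of
chromosomes 13, 14, 15, 21 and 22 excluded — the standard convention for
SNP-array copy-number work), with hg19-scale coordinates. Sex chromosomes
are excluded by default; a custom layout table can be supplied. Genome
build is treated as opaque: the pipeline only requires that all inputs use
consistent coordinates.

Missing values are explicit NaNs. Profiles with more than 20% missing
markers are rejected. Markers missing in one member of a compared pair are
handled at segmentation time (see below); the logLR comparison operates on
arm-level calls and footprints, which are defined on the shared track.

## Preprocessing

Log-ratios are log2 of each sample's probe intensity over the mean
intensity of the normal reference samples. Probes inside known germline
CNV regions are removed before resolution reduction, so inherited variants
do not masquerade as somatic events. Block averaging collapses runs of
`block_size` (default 100) adjacent markers to their mean position and mean
log-ratio, shrinking i.i.d. noise by ~1/√100; at SNP6 scale this takes
~1.5M post-exclusion probes to ~15,000 markers.

Blocks are anchored at the start of each chromosome *arm*, not each
chromosome, so a block never straddles a centromere. A trailing partial
block keeps its own output marker when it holds at least half a block
(`min_final_block_fraction` = 0.5); otherwise it merges into the previous
block. This bounds the variability of output marker spacing. Inside a
block the mean skips missing values; a block is missing only if all its
inputs are.

Median centering (genome-wide median of non-missing values subtracted) is
applied after block averaging and before segmentation, because arm calls
are made against a zero diploid baseline.

## Single-change-per-arm segmentation

Each arm is scanned for the interval (i..j), of at least
`min_segment_markers` (default 3) markers, maximising the absolute
two-sample statistic

    T(i,j) = (mean inside − mean outside) / (σ̂ √(1/n_in + 1/n_out)).

The whole-arm interval competes using the z-score mean·√m/σ̂. The noise
scale σ̂ is estimated robustly per sample from within-arm lag-1
differences, σ̂ = 1.4826·median(|Δx|)/√2, pooled across arms by the median;
a true change-point contributes a single outlying difference and does not
inflate the estimate. σ̂ is floored at 1e-6 so noiseless input degrades
gracefully.

An arm is NORMAL if neither |T| nor the whole-arm |z| reaches the change
threshold τ (default 5.0). Otherwise the *calling segment* is the central
segment when there are two breakpoints, the more outstanding (larger
|mean|) of the two segments when there is one, and the whole arm when
there is none; the call is GAIN/LOSS only if the calling segment's mean
clears the magnitude gate δ_min (default 0.10), which suppresses
statistically significant but biologically negligible shifts. τ = 5 keeps
the family-wise false-call rate across ~39 arms × ~380 markers well below
1% per genome (property-tested); both τ and δ_min are configurable.

Interval/complement ambiguity: an interval and its complement carry
identical |T| by construction. Ties within a relative tolerance of 1e-10
resolve to the smallest (i, j) in scan order, deterministically, and the
exhaustive reference scan applies the same rule.

A called segment whose genomic span is shorter than 2.3 Mb and overlaps a
known germline CNV region by ≥1 bp is reset to NORMAL (breakpoints
cleared). Resetting, rather than excising and re-segmenting the arm, is
the conservative choice: it can only remove evidence, never create it.

## The logLR clonality measure

For a pair with per-arm calls (c₁, c₂), smoothed cohort marginals
π_a(c) = (count + 1)/(n + 3), and Jaccard footprint overlap s_a on
concordantly called arms, the per-arm likelihood under independence is
q_a = π_a(c₁)π_a(c₂). Under the clonal alternative a fraction ξ of events
is shared:

    logLR = max_ξ Σ_a log[(ξ·m_a + (1−ξ)·q_a) / q_a],

with m_a = π_a(c)·s_a (concordant gain/loss), π_a(NORMAL)
(concordant-normal), or 0 (discordant). ξ is maximised over the grid
{0, 0.01, …, 1}; ties take the smallest ξ. Because ξ = 0 is in the grid,
logLR ≥ 0 always, and the statistic is exactly symmetric in the two
samples. Rare concordant events contribute log(s/π)-scale evidence; common
ones (1q gain at ~0.73, 16q loss at ~0.53 in lobular disease) contribute
little — which is precisely why cohort marginals enter the measure.
Marginals are estimated on the full cohort including the tested pair by
default; a leave-pair-out variant is available
(`ClonalityConfig.leave_pair_out`).

## Empirical null, p-values, classification

The reference distribution is the logLR over all unordered pairs of
samples from different patients, computed with the same marginals and
configuration as the real pairs (optionally subsampled, seeded, when the
cross-patient set is large). p = (1 + #{null ≥ obs})/(1 + n_null) — the
add-one rank estimator, never exactly 0. Classification: **clonal** if
obs exceeds the null maximum (strictly one-sided, high side), **equivocal**
if within the null range but p < α (default 0.05), **independent**
otherwise. A warning is logged when the null has fewer than 50 pairs.

A property worth knowing: the logLR has a point mass at exactly 0. For an
independent pair the derivative of the mixture log-likelihood at ξ = 0 is
Σ(m_a/q_a − 1); each discordant arm contributes −1 while each
concordant-normal arm contributes only ~0.1, so event-carrying independent
genomes typically maximise at ξ̂ = 0 and score logLR = 0, giving p = 1.
p-values are therefore *sub-uniform* (conservative) under the null rather
than exactly uniform: P(p ≤ α) ≤ α holds at the usual α, and the
clonal-or-equivocal rate at α = 0.05 sits near 5%, but a two-sided KS test
against the uniform distribution rejects because of the atom at p = 1.
This is a structural feature of a nonnegative profile-maximised LR
statistic, not a calibration failure in the operative (type-I error)
sense.

## Synthetic-data generator

`simulate_pair`/`simulate_cohort` emulate block-averaged SNP-array
profiles under the study conditions: 15,000 markers allocated to arms
proportional to arm length (largest-remainder rounding); per-arm event
rates 0.73 for 1q gain and 0.53 for 16q loss (the rates reported for
low-grade lobular breast lesions) and 0.10 elsewhere, split evenly between
gain and loss; half of events span the whole arm, the rest cover a uniform
10–80% interior fraction; event shift ±0.45 on the log2 scale (roughly a
single-copy change attenuated by typical tumor purity), multiplied by a
contamination factor φ ∈ (0,1]; i.i.d. Gaussian noise with σ = 0.25 per
marker (the post-block-averaging noise scale at which arm events of a few
hundred markers are detectable but individual markers are not). A clonal
pair shares ancestor events drawn per arm with probability ξ_true·rate
(default ξ_true = 0.8) with *identical* footprints, then accrues private
events on the remaining arms with probability (1−ξ_true)·rate; an
independent pair is two unrelated draws. All randomness flows through
numpy's PCG64 generator, named in the truth metadata, so fixtures are
bit-reproducible.

What the generator does **not** emulate: probe-level intensity artifacts
(GC/fragment-length waves), allele-specific signal, multi-copy amplitude
levels, more than one event per arm, subclonal mosaicism beyond the
shared/private dichotomy, and breakpoint jitter between the two samples of
a clonal pair (shared footprints are exactly identical). Passing tests
therefore demonstrate the statistical machinery under an idealised noise
model; on real arrays, wavy baselines and imperfect breakpoint concordance
will reduce the Jaccard overlap of truly shared events and shrink logLR
toward the null.

## Problem sizes used in validation

The built-in studies (`cnclonality.benchmark`) use: 200 random arms of up
to 200 markers for oracle equivalence of the segmentation scan; a
500-patient independent cohort (1,000 profiles, 15,000 markers) with a
200-pair subsampled null for calibration; and 10 replicate 20-patient
cohorts (50% clonal pairs, 200-pair nulls) for sensitivity and
false-clonal rate. These sizes give binomial standard errors of ~1% on the
reported rates while keeping a full validation run to a few minutes on one
CPU.

## Known limitations

- The per-arm likelihood is a deliberately simple mixture; it ignores
  correlation between arms (e.g. co-occurring 1q gain and 16q loss) and
  treats the marginals as known rather than estimated, so small cohorts
  make the null distribution itself noisy.
- "At most one change per arm" undercalls complex arms; a second real
  event on an arm is absorbed into flanks or shifts the single detected
  interval.
- The 2.3 Mb CNV filter resets the whole arm to NORMAL rather than
  excising the segment and rescanning; a real somatic event co-located
  with a germline CNV is lost.
- With a small reference pool the "clonal" rule (outside the entire null)
  is sensitive to the null maximum, a single order statistic; below ~50
  null pairs a warning is emitted and classifications should be treated
  cautiously.
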