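# Methods

## Coordinate and data model

All internal coordinates are 0-based half-open. WIG (1-based) and GTF
(1-based closed) are converted at the I/O boundary; BED passes through
unchanged. Depth tracks store one float per base because library-size
normalization produces non-integer depths. N bases are legal in
sequences: they reduce the effective length of every composition
statistic and can form neither CpGs nor C/G counts; sliding windows with
more than 20% N are reported missing.

## Normalization

Like-assay samples are scaled to a common total depth,
`factor = target / total`, with the target defaulting to the arithmetic
mean of the like-sample totals ("auto"); an explicit constant is accepted
for reproducibility across runs. MAP tracks are background-subtracted
*before* totals are computed, because dispersed off-target reads would
otherwise skew the scaling constant. Background is defined as a per-base
depth floor (default 2, configurable): bases at or below the floor are
zeroed. This is the simplest rule consistent with the motivation; CAP
tracks are not floored since CAP enrichment shows minimal intervening
background. Scaling commutes with window-binning, which the tests assert.

## Peak calling (H/L/G)

Bases at depth ≥ H are marked; marked runs separated by ≤ G unmarked
bases merge into a candidate spanning first to last marked base (interior
gap bases count toward the span, flanking gaps never do); candidates with
span ≥ L are reported. The gap test is inclusive (a gap of exactly G bp
merges): "permitted gap" is read as an allowance. The caller is verified
exactly against a brute-force base-marking/run-enumeration oracle on
randomized tracks, and is superset-monotone under relaxing any parameter.

Default profiles (H=3, L=400, G=30 at mean depth 5 reads/bp) were
calibrated on the synthetic fixtures. The load-bearing observation is
that with Poisson noise the caller's effective detection threshold is set
by the spacing of above-threshold bases relative to G: a large G chains
even weakly retained regions into full-length spans and destroys the
distinction between retention levels, so G is kept small relative to
island length.

## CpG metrics

The observed/expected ratio uses the Gardiner–Garden convention
`oe = n_CpG · L / (n_C · n_G)` — the convention behind the classical 0.6
prediction threshold — with CpGs counted by overlapping dinucleotide
scan. o/e is undefined (reported as a sentinel, not 0 or NaN
arithmetic) when a sequence has no C or no G. o/e is invariant under
reverse complement, asserted property-wise. Density bins over CpGs per
100 bp are `<5, 5–6, 6–7, 7–8, 8–9, >9` with integer boundaries assigned
right-open and 9.0 falling in `>9`, keeping the six labels exhaustive;
the boundary convention is declared, not inferred.

## Classification

A CGI extended by the flank (default 100 bp) that contains a gene's TSS
is ATSS; otherwise overlap of the extended CGI with any gene body makes
it intragenic; else intergenic. ATSS takes precedence because the
categories are exclusive and promoter status is the biologically
privileged call; a CGI near two TSSs is still simply ATSS. The TSS is the
5′ base of the supplied model (start for +, end−1 for −); transcript
isoforms can be collapsed to one span per gene with a provided helper,
but classification itself always uses one TSS per model. Classification
partitions every CGI set and is order-invariant; growing the flank can
only grow the ATSS set.

## Differential methylation

Window means (100 bp window, 20 bp slide) are converted back to window
totals (mean × window length) for the read-floor test: per-read
identities are not recoverable from a depth track, so the 4-read floor
applies to depth mass on the normalized scale (both choices
configurable). When both totals are below the floor the ratio is forced
to 1; otherwise the ratio is `(T_test + ε) / (T_ref + ε)` with
pseudocount ε = 1 read, which keeps a zero reference window finite — the
floor rule is only specified for the both-low case. The +1 call requires
a frame of m = 10 consecutive windows containing ≥ k = 9 windows with
log2 ratio > 2 (there must *exist* such a frame; the 9 exceedances need
not be consecutive); −1 is the mirrored rule. CGIs with fewer than 10
windows (< 280 bp) are non-evaluable and score 0 with a flag; a
proportional alternative (≥ ⌈0.9 n⌉ of n windows) sits behind a switch.
If both directions fire on one CGI the signal is mixed and the score is
0, which preserves the antisymmetry dm(a,b) = −dm(b,a) exactly.

Tumour consensus: tumour-specific CGIs are methylated (+1) in at least
`min_tumour` (3) tumours and at most `max_normal` (0) normals;
normal-only is the mirrored rule; shared requires ≥ 1 methylated sample
in each group. The three subsets are disjoint by construction.
Conservation over an ortholog pair table reports, per positional class,
the percentage of species-A-methylated CGIs also methylated in species
B; intergenic CGIs are excluded by default because syntenic mapping away
from genes is unreliable.

## Summaries

Composite profiles anchor at interval midpoints (intervals vary in
length) and take 500 bp window means every 100 bp across ±2.5 kb,
reporting median and quartiles per offset; windows truncated by a
chromosome end contribute nothing for that interval. Density-bin
summaries average depth over each CGI's central 2 kb. Pearson correlation
is computed over every contiguous 1 kb window mean — zero-zero windows
retained — and reported as undefined (sentinel) when a binned vector has
zero variance. Welch's t uses the Welch–Satterthwaite degrees of freedom;
the degenerate both-variances-zero case raises unless the means are
equal. All figure-level outputs are plain TSV tables.

## Synthetic data

The generator defines the study conditions; its defaults are fixed and
tests report against them.

* **Background genome**: a first-order Markov base chain. All transition
  rows equal a base distribution except the C row, whose C→G entry is
  damped so the realised o/e (`T[C,G]/πG`) hits the target; a fixed-point
  iteration corrects the base distribution so the stationary composition
  still matches the requested G+C (default 40%, o/e 0.21). Realised
  whole-sequence o/e lands within ±0.03 at 1 Mb.
* **Islands**: ~1 kb (Normal(1000, 150) clipped to [400, 1600]) Markov
  segments at 65% G+C. The default o/e population is 85% CpG-rich
  (Normal(0.8, 0.1), ≈ 8–9 CpGs/100 bp, the "one CpG per ten bases"
  regime) and 15% CpG-poor (Uniform(0.24, 0.32), ≈ 2.5–3.4 CpGs/100 bp),
  the latter emulating the CpG-deficient islands only a relaxed wash
  recovers. Island sequences are resampled until the realised o/e is
  within 0.10 of target so truth labels stay faithful. Placement honours
  the requested positional class (48/26/26% ATSS/intragenic/intergenic)
  and is verified with the classifier itself at plant time, with ≥ 2 kb
  between islands.
* **Methylation truth**: independent Bernoulli per (CGI, somatic tissue)
  with class-specific rates — ATSS 3%, intragenic 24%, intergenic 14% —
  the germline always unmethylated. Bulk-genome CpGs are 75% methylated
  (midpoint of the typical 70–80%); a methylated CGI is 90% methylated.
* **Tracks**: the genome is tiled into 500 bp fragments (fixed tiling for
  reproducibility; random shear sits behind a flag) and each fragment
  gets a retention probability: CAP, logistic in unmethylated-CpG density
  with midpoint 5.0 CpGs/100 bp (stringent wash) or 3.5 (relaxed) and
  unit slope — the salt concentration is abstracted to this midpoint,
  since no quantitative retention curve is available; MAP, a step at
  1 methyl-CpG/100 bp; H3K4me3, linear gain in CpG density at
  unmethylated islands (the link is monotone by assumption; the linear
  form is a modelling choice); RNAPII, active-promoter indicator. Depth
  is per-base Poisson at `mean_depth × retention + background` (defaults
  5 and 0.1 reads/bp).
* **Stringency coupling**: two independent Poisson draws cannot satisfy
  pointwise coverage nesting, so the stringent-wash track is generated by
  binomial thinning of the relaxed-wash draw — marginally each track is
  Poisson at its own rate, and per-base depth is nested deterministically,
  as the physical wash (a subset of retained fragments) would produce.

What the simulation does *not* model: read-level artefacts (mappability,
GC bias, duplicates), fragment-boundary effects beyond fixed tiling,
copy-number changes in tumours, correlated methylation between tissues
(an optional mode seeds correlation, defaults independent), and realistic
chromosome counts. Passing tests therefore demonstrate the correctness
of the algorithms under the stated statistical model, not robustness to
every artefact of real sequencing data.

## Problem sizes

The reference study uses a 2 Mb genome, 100 islands and mean depth
5 reads/bp; the density fixture 1.2 Mb / 90 islands; the X-inactivation
fixture 400 kb / 30 islands; the tumour cohort 1 Mb / 60 islands with
5 + 5 samples. These sizes give every statistic comfortable resolution
(binomial standard errors of a few percent) while keeping the whole
suite and the acceptance script to seconds of runtime.

## Known limitations

The background-removal rule and the H/L/G defaults stand in for
per-sample values that would normally be tuned per purification; both are
configurable. The read floor operates on depth mass rather than read
count. Orthology is consumed as an input table, never computed. The
acceptance quantities are properties of the synthetic study (recovery,
calibration, monotonicity, concordance), not genome-scale counts, which
are not reproducible at desk scale.
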