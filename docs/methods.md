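# Methods

`gcbias` measures base-composition bias in sequencing libraries and models
its dominant source, per-cycle PCR amplification bias. This note records
the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic pipeline does and does not demonstrate.

## The bias curve

The central statistic is an observed/expected coverage curve over %GC.
The reference is cut into 50-bp windows (sliding by default, tiled
optionally); each window is binned by its exact GC base count (granularity
100/window = 2% for 50-bp windows; the count is kept as an exact rational
times 100, never rounded through floats before binning). For each bin b,

    relative_value(b) = (reads_b / windows_b) / mean_{a in anchor} (reads_a / windows_a)

where the anchor bins are 48-52% GC, so every curve equals 1 on average
over the mid-GC anchor by construction. Values are stored linear; log10
is a plotting choice. Bins with no windows are absent; bins with windows
but no reads are reported as 0 so that depletion is visible to the
plateau and fold-change statistics.

A 101-base read spans at least two 50-bp windows, so "reads per window"
needs a counting rule. Each usable read (mapped, primary, non-duplicate;
MAPQ threshold 0 by default) is counted once, in the valid window
containing its alignment-span midpoint — ties go to the left window for
even spans, and on overlapping sliding grids the candidate whose center
is nearest the midpoint wins. One-to-one counting keeps totals intact
and is unbiased under uniform coverage. Reads whose midpoint lies in no
valid window (ambiguity, contig edge) are dropped and counted. Windows
overlapping any non-ACGT base are excluded from both the numerator and
the denominator, keeping observed and expected consistent.

Coverage evenness is summarized two more ways:

* **Under-coverage fraction** — the share of non-ambiguous bases whose
  per-base read-overlap count is *strictly* below one-tenth (configurable)
  of the genome-wide mean; the mean itself excludes ambiguous bases.
* **Locus representation** — mean per-base coverage of a locus divided by
  the genome-wide mean; a pooled mode (total read-bases over total locus
  length) for panels too shallow to score per locus.

Bins whose assigned reads average below Q20 (mean over reads of each
read's mean base quality) can be masked; masked bins keep their values
but are flagged, and masks propagate through fold-change as a union.
Fold-change itself is a per-bin ratio of two curves sharing the same
anchor definition. Pooling libraries concatenates reads before binning —
the curve of the merged library, not an average of curves.

## The qPCR assay

Quantities come from a log-linear standard curve, Cq = intercept +
slope·log10(quantity), fit by ordinary least squares to a dilution
series; amplification efficiency is 10^(−1/slope) − 1 (1.0 at perfect
doubling, slope −log2 10 ≈ −3.32). The pipeline order is fixed and
asserted by a regression test, because it is not commutative:

1. quantify each replicate Cq;
2. omit a replicate if its quantity is ≤ 3× the no-template-control
   quantity for that locus (the filter runs on the quantity scale per
   replicate; an NTC that never amplified is quantity 0 and keeps
   everything positive);
3. average surviving duplicates (mean, with min/max as the range);
4. divide every locus by the mean of the two panel loci closest to 50%
   GC (all tied loci enter the denominator), or by a designated
   control-locus set when one exists.

The flat segment of a profile is the **plateau**: the maximal-length
contiguous run of points, in %GC order, containing at most one point
with relative abundance strictly below 0.7. Among equally long runs, the
run whose closest point to 50% GC is nearest wins, then the leftmost —
a deterministic tie-break; only the "≤ 1 point below 0.7" rule is
externally fixed, the tie-break is this package's choice.

## The amplification model

Each PCR cycle, every template copy duplicates independently with
probability p(g), a function of the fragment's %GC:

    p(g) = p_max · σ((g − low_mid)/low_scale) · σ((high_mid − g)/high_scale)

with σ the standard logistic. The product of two logistics is the
simplest shape with independently placed AT-side and GC-side shoulders;
either shoulder can be disabled. Expected amplification after n cycles
is (1+p)^n, so the predicted abundance of GC bin g relative to a mid-GC
anchor is ((1+p(g))/(1+p(50)))^n, and an observed curve inverts to a
per-cycle relative efficiency r(g) = value(g)^(1/n) (non-positive bins
are flagged non-invertible). The stochastic counterpart is a
Galton–Watson process — new copies ~ Binomial(current, p) per cycle,
vectorized over fragments — which matches the closed form exactly in
the mean. Reagent exhaustion/saturation is deliberately omitted: the
10-cycle enrichment regime is treated as exponential. Amplification acts
on the whole fragment's %GC, not on windowed GC, because PCR acts on
molecules.

**Protocol presets are calibrated emulations, not mechanism.** Ramp
rate, denaturation time, betaine, enzyme choice and extension
temperature are not modelled physically; a preset name simply selects a
parameter bundle shaped to reproduce each protocol family's published
phenomenology (plateau endpoints, hundredth-scale collapse above ~65% GC
for the standard fast-ramp protocol, tenth-scale loss below ~12% GC,
right-shifted plateau with betaine, wide plateau for the two-enzyme
blend, a flat profile for a PCR-free library). The shoulder parameters
were placed by hand-inverting the logistic at the published endpoints;
they are fixtures, documented as such, and `fit_relative_efficiency` is
the tool for calibrating new ones from data.

## The synthetic-data generator

The generator emulates the study design the assay was built around: a
three-component composite genome (components at 19%, 51% and 69% mean
GC with full-scale lengths 23/4.6/4.6 Mb, scaled down — 1:100 gives the
322-kb desk-scale genome used throughout), shearing to a gamma
length distribution (default mode 225 bp, spread 40 bp; the sheared
modes are published, the spread is a fixture), gel size selection
(insert ± tolerance, apparent gel size 90 bp larger than the insert),
per-cycle amplification via the branching process, and 101-base paired,
inward-facing reads sampled with replacement proportional to copy
number, with ground-truth coordinates. Per-read quality is a clipped
normal (mean 35, sd 3) with an optional linear droop above a GC onset,
which exists solely to exercise Q20 masking — there is no per-base error
model. qPCR runs are emulated from a chosen standard curve with
Gaussian Cq noise per replicate (default sd 0.2 cycles, duplicates) and
noiseless standards (five-fold series, 75,125 down to ~5 genome
equivalents). Mass-to-copies conversion uses 650 g/mol per base pair
(660 is supported by passing the constant explicitly; both round the
170-fg endpoint to 5 copies).

Genome composition is a block model: block GC follows a stationary
AR(1) series (default block 1 kb, sd 0.08, lag-1 correlation 0.8)
recentred so the realized component GC hits its target, clipped to
[0,1] and quantized to the 2% window-bin grid; within a block, G/C
positions are evenly interleaved (Bresenham placement with a random
phase; which strong/weak base occupies a position is random). The point
of this construction is *controllability*: every 50-bp window and every
fragment inside a block carries the block's GC almost exactly, so the
window-GC histogram — and hence the expected side of the bias curve —
is directly shaped by the block-GC distribution, and window GC,
fragment GC and the model's p(g) refer to the same quantity. Components
with a boundary target (GC 0 or 1) use constant block GC, since
symmetric block noise is impossible there.

What this does **not** emulate: real local base composition (no
homopolymer/dinucleotide structure, no Markov correlation), sequencing
error, duplicates, adapters, mappability, or cluster-density effects.
Passing tests therefore demonstrate that the *statistics and the
amplification model* behave as specified on data whose ground truth is
known — not that any particular wet-lab protocol has these exact
parameters.

## Validation design and problem sizes

Every statistic is checked against an independent oracle at small size:
window GC against a character-by-character recount, the plateau against
an exhaustive O(n²) scan of all contiguous runs (1,000 random panels of
up to 30 points), under-coverage against a per-base tally (100 random
instances up to 10 kb), assignment against a per-read brute-force
midpoint search, the OLS standard curve against the normal equations,
and the branching mean against (1+p)^n over a (p, n) grid at 10⁴
replicates per cell. SAM and TSV representations of the same simulated
reads must produce bit-identical curves.

The end-to-end check simulates the standard-protocol library (scale
0.002, ~12k selected fragments, 10 cycles, 5×10⁵ reads) and compares
the measured curve bin for bin against the model's expectation at three
standard errors. One subtlety matters: a read's 50-bp window GC and its
fragment's GC are different random variables wherever GC changes within
a fragment length, so the GC-only closed form is only the
infinitely-fine-domain limit of what the pipeline samples. The
bin-level expectation is therefore computed by
`expected_library_curve`, which evaluates the branching mean fragment
by fragment on the actual library and places read midpoints
deterministically; the error band combines multinomial read sampling,
paired-read clustering (both mates of a template are correlated) and
the closed-form Galton–Watson variance. Against the pure GC-only curve
the pipeline is held to the published phenomenology instead:
well-covered bins above 70% GC below 0.05, the 6% GC bin near
one-tenth, and log-scale correlation above 0.98 on well-covered bins.
The flat-input control (uniform read starts, and the PCR-free preset
run end to end) must keep every bin with ≥200 expected reads inside
1 ± 3/√(expected).

Problem sizes (322-kb genome for flat tests, 64-kb for the end-to-end
recovery, 3–6×10⁵ reads, 10⁴ Monte-Carlo replicates) were chosen so the
statistical bands above are decisive while the whole suite runs in
seconds on a laptop.

## Known limitations

* Preset parameters are phenomenological; do not interpret shoulder
  positions as melting physics.
* The plateau tie-break and the read-midpoint assignment rule are
  package decisions; other reasonable conventions (e.g. counting a read
  in every overlapped window) would shift curves slightly.
* Whether published histograms used sliding or tiled windows is
  ambiguous; both are supported, sliding is the default.
* The qPCR background filter operates on the quantity scale; a ΔCq
  reading of "three-fold above background" is equivalent only for ideal
  efficiency.
* Fragment-level statistics assume every fragment is sequenceable;
  there is no adapter-ligation or cluster-formation bias model.
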