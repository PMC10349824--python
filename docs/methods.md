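# Methods

## Positional decay models

All models describe the expected RNA abundance covering a genome
position as a function of time after rifampicin addition, under
steady-state synthesis (rate α), first-order decay (constant λ) and
constant elongation (rate v).  Internally everything is in minutes and
nucleotides; per-second laboratory rates are multiplied by 60 on
ingestion.  Negative times are rejected; at a breakpoint the later
branch applies.

The piecewise forms are implemented in their continuity-consistent
version.  Three of the variants admit more than one literal reading of
their final branch; we resolve each by requiring continuity and the
physical interpretation that once the last polymerase has passed a
position, what remains is pure exponential decay from the value attained
at that moment (a "frozen peak"):

* post-transcriptional decay — the final branch is
  (α/λ)·exp(−λ(t − L/v)), the amplitude fixed by continuity at t = L/v;
* pre-steady-state expression — decay starts from the frozen peak
  (α/λ)(1 − exp(−λ t_rif)) at t = n/v + t_rif;
* rifampicin-sensitive termination (RST) — decay starts from the frozen
  peak α/λ − (αβ/λ)·exp(−λ n_term/v) at t = n/v.

Under the RST model the maximal relative increase over the
pre-rifampicin plateau is β(1 − e^(−λ n_term/v))/(1 − β), which
inverts to the smallest terminator–TSS distance yielding a given
detectability threshold, −(v/λ)·ln(1 − thr(1−β)/β).  When the threshold
exceeds β/(1−β) the event is undetectable at any distance and the
function returns infinity rather than raising.

Derived quantities: half-life t½ = ln2/λ; termination percentage
t_p = (1 − 2^{R_synt})·100 (never clamped in computation, so positive
synthesis ratios give negative values); steady-state full-length
fraction e^{−λL/v} under co-transcriptional decay.

## Stochastic simulator

Transcripts are contiguous coordinate runs stored as 5′/3′ end pairs in
separate pools (growing, paused, full-length; sense and antisense
independently).  Each simulated second applies, in a fixed order:
initiation (Bernoulli per TSS; suppressed after the rifampicin step),
antisense initiation (one antisense TSS, elongating toward position 1),
an optional initiation-rate switch, pause release, elongation by the
integer step v, pause entry (tested when the 3′ end crosses the pause
site), decay, termination, and counting.  Within-step atomicity follows
this list; collisions are resolved before counting.

Decay modes: *co* (growing/paused transcripts truncate to their 3′-most
position, full-length transcripts are deleted), *post* (full-length
deleted only), *endo_exo* (the rightmost contained endonuclease site
becomes the new 5′ end; defined for the sense transcript only).
Termination: reaching the total length (positions clipped to the
length); a fixed per-step probability; partial termination at a site,
tested within a window of one elongation step so no polymerase can jump
the site untested, with the 3′ end clipped to the site on termination;
and collision termination, where sense/antisense pairs whose 3′ ends lie
within a 30-nt window collide and the sense transcript terminates with
probability `ti_prob_sense`, otherwise the antisense one.  Each
antisense polymerase pairs with at most one sense polymerase per step
(nearest 3′ end in the window) and each sense polymerase is used once —
this prevents a single sense polymerase from terminating several
antisense transcripts in one step.  Sense–sense collisions and
collisions without termination are not modeled.  Counting includes
paused and full-length transcripts; antisense species are counted
separately.  Replicates use independent RNG streams spawned from the
master seed, so a result is bit-reproducible given the seed.

Because actions are Bernoulli per 1-s step, steady-state counts sit
~λ·1 s below the continuous-time value (e.g. 59.4 vs 60 for α = 0.6/s,
λ = 0.01/s); the simulator-vs-model tests allow for this with a small
absolute floor on top of the 3-standard-error band.

What the generator emulates: delayed-exponential decay curves, the
positional steady-state profiles of the decay modes, collision
interference with its transient post-rifampicin increase, Poisson-like
technical noise (optional resampling of every count).  What it does not
emulate: coverage biases along transcripts, library-size or
normalization artifacts, overdispersion beyond Poisson, and genome-scale
transcript density.  Passing tests therefore demonstrate correctness of
the inference given the model class, not robustness to every artifact
of real libraries.

## Preprocessing

Coverage is averaged into 50-nt bins addressed by the 1-based coordinate
of their last nucleotide; a ragged final bin is averaged over its actual
width and retained.  Bins with a grand-mean count below 10 are dropped
(the threshold applies to the grand mean over replicates and time
points; configurable).  Microarray probes additionally drop shapes
incompatible with decay (maximum at the last or minimum at the first
time point), and probes whose final time point lies below 4000 A.U. are
fitted with the constant-background model variant.  Runs of bins with
gaps over 300 nt split into independent coverage segments, which bounds
the quadratic segmentation.

RST candidates: each bin gets an indicator (+1 when any post-rifampicin
time point of the replicate-mean series exceeds t = 0 by more than
7.5%), the indicator sequence is segmented by the DP with the
absolute-deviation score and split penalty 10, and segments with ≥ 75%
positive bins are flagged, together with the bins covering 1000 nt
upstream (strand-aware) so the pre-RST phase is fitted with the same
model.

## Curve fitting

Each bin is normalized to the peak of its across-replicate mean series
and fitted across all replicates simultaneously (stacked residuals,
equal weights) by bounded trust-region least squares.  The objective is
continuous but non-differentiable at the delay breakpoints, so fitting
is multi-start: a coarse grid over the nonlinear parameters — delay on
the observed time points and their midpoints, ten log-spaced half-lives
between 0.25 and 30 min — with closed-form amplitudes (every model is
linear in its amplitude parameters once delay and λ are fixed),
followed by a polish from the best cells.  Bounds: amplitude ≥ 0,
λ ∈ [10⁻⁴, 10³]/min, delay ∈ [0, t_max], bg ≥ 0, β ∈ [0, 1].  The RST
model is parameterized by (amplitude, β, λ, delay, delay_increase) with
delay_increase = fraction·delay so its ordering constraint is a box
bound.  A bin that cannot be fitted is flagged and excluded downstream
rather than raising.

The RST model has two extra free parameters and can absorb noise into a
spurious β > 0.  Following the fit-selection rule, all converged
candidate fits within 20% of the best residual are collected — a plain
β = 0 fit is always among them — and the one with the smallest β is
returned.  Shrinking the range increases sensitivity at the cost of
false positives.

## Segmentation

The optimal segmentation of a coverage segment minimizes the sum of
per-fragment scores plus a penalty P per split (maximized with negative
penalty for transcription units); the prefix recursion is solved exactly
in O(n²) scorer calls, no pruning.  Ties break toward fewer fragments,
then leftmost boundaries.  Minimum fragment length is 3 bins (1 for the
RST indicator track).

Scorers: the delay track fits delay against position by least squares
with the slope clipped to [0, 1/60] min/nt (elongation ≥ 1 nt/s) and
scores the L1 residuals; half-life and TI tracks score L1 deviations
from the mean; the abundance track does the same on log2 values to
stabilize the spread.  All three support iterative outlier removal: the
point with the largest absolute residual is dropped, the fit recomputed,
and a fixed outlier penalty N added, up to min(⌈0.4 n⌉, 10) outliers;
the count with the minimal combined score wins.  Outliers are excluded
from fragment parameter estimates and marked in the output.

Hierarchy: delay fragments are segmented first, half-life fragments
inside them, abundance fragments inside those; a child never crosses a
parent boundary.  TI (termination-factor) fragments are computed on the
contiguous runs of RST-fitted bins inside each delay fragment.

Default penalties: delay split 3.5, delay outlier 2.5 (the values used
with the high-resolution RNA-seq grids), RST indicator 10, TU −0.75.
Half-life and abundance default to split 2.0 / outlier 1.5 and TI to
1.0 / 0.75 — chosen so that, at the per-bin estimator noise of the
10-point grid, planted two-fold steps over ≥3 bins split while pure
noise does not; the automatic penalty estimation can replace them.  The
estimator segments a sample of coverage segments over a penalty grid,
tests every adjacent pair (ANCOVA for delay, Welch's t-test otherwise,
α = 0.05) and selects the penalty maximizing (#significant −
#non-significant) splits, ties to the larger penalty.  Split tests use
all member bins, outliers included: testing on outlier-pruned members
makes DP-selected splits in pure noise almost always "significant"
(post-selection bias) and drives the criterion to the lowest penalty.
Even so, post-selection bias means the criterion may legitimately settle
on a moderate rather than maximal penalty on pure noise; what it
reliably avoids is the over-fragmenting low end.

Transcription units: each junction between consecutive delay fragments
scores (s − e) + ln(s) + 0.5, where e is the fitted delay at the last
bin of the 5′ fragment and s at the first bin of the 3′ fragment.  The
log term means a 3′ fragment starting near delay 0 (a fresh TSS) can
never be absorbed, and it crosses ≈ 0 at s = 0.6 min, the delay at which
a continuing transcript becomes more plausible than a new one.  The
"+0.5" applies per junction.  Because the total TU score decomposes over
junctions, the maximizing DP reduces exactly to keeping a junction iff
its score beats the split penalty (−0.75); fragments with fitted start
delay ≤ 0 always open a new TU.

## Event statistics

Between adjacent fragments within one coverage segment: a delay drop
inside a TU is an internal-TSS candidate (iTSS_I), tested by Welch's
t-test on the two projected-delay distributions (fitted delay at the
midpoint between the fragments plus each fragment's fit residuals);
slope differences are tested by ANCOVA (interaction of position with
fragment membership) and reported as velocity changes (v = 1/slope);
half-life and TI fold changes use Welch's t-test on member-bin values.
Between consecutive abundance fragments of the same TU, the synthesis
ratio R_synt (half-life values trimmed to the abundance fragment's
bins) is classified: above the (−0.5, 0.2) window → new internal TSS
(iTSS_II); below → (partial) termination, with t_p as the termination
percentage; inside the window with |log2 half-life FC| ≥ 1 and p ≤ 0.05
→ processing/stabilization site (differential operon decay).  The
R_synt p-value comes from a one-way MANOVA (Pillai's trace — the robust
default among the four classical statistics) on the joint (half-life,
log2 abundance) response.  Normality is assumed throughout; p-values
are Benjamini–Hochberg-adjusted within each event type.

A caveat worth knowing: the projected-delay t-test ignores the
extrapolation uncertainty of the two line fits, so its null p-values
are anti-conservative (roughly 30% fall below 0.05 on simulated pure
noise).  Genuine delay drops score orders of magnitude lower
(p < 10⁻⁴ in the recovery tests), so the ranking is informative even
though the nominal level is not; the BH adjustment inherits this
property.

Observed RST segments pass three filters: length ≥ 5 bins, mean fitted
termination rate ≥ 0.15, and ≥ 75% of bins (rounded up) with rate
≥ 0.15 — the rate criterion uses the segment mean.  Against the
background probability prop_BG (flagged bins / total bins) the chance of
a length-n run containing ≥ ⌈0.75 n⌉ flagged bins under pure noise is
the binomial tail P(X ≥ ⌈0.75 n⌉), X ~ Bin(n, prop_BG); the expected
number of chance segments is reported per length.

## Problem sizes and numerical choices

The test suite runs entirely on generated data at desk scale: coverage
segments of 16–100 bins, 3–50 simulated replicates, the 10-point
sampling grid 0–15 min.  The elongation-rate accuracy experiment runs
the full 36-combination grid (three decay constants 0.003465736,
0.01155, 0.00578 s⁻¹ × three initiation rates 0.2, 0.4, 0.8 s⁻¹ × four
velocities 15, 30, 45, 60 nt/s, triplicate 1000-nt transcripts, Poisson
noise, delay penalties 3.5/2.5) with five repetitions per combination,
and excludes fitted velocities above the 120 nt/s physiological bound;
each simulation settles for L/v plus four half-lives before rifampicin.
DP brute-force cross-checks enumerate every segmentation up to n = 12.

Degenerate inputs: series without positive signal, fragments too short
for a test, or zero-variance t-tests yield flagged fits, nan p-values,
or p = 1 for exactly identical groups — never exceptions.  Fits with
fewer time points than parameters + 1 (4 for the plain model, 5 for
RST) are refused.

## Known limitations

Delay-based estimates (velocities, TU boundaries, iTSS_I) rest on few
informative time points and are intrinsically noisy; fitted velocities
scatter widely around the truth even in simulation, which is why the
120 nt/s exclusion exists.  The models assume steady state at t = 0 and
a single constant elongation rate per fragment.  Only one antisense TSS
is supported per simulation.  Spike-in or LOESS normalization is
upstream of this package: inputs are assumed normalized.  Per-coverage-
segment computations are independent and could run concurrently, but
the implementation is single-threaded; desk-scale inputs gain nothing
from parallelism.
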