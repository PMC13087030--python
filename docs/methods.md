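# Methods

This note records the models, estimators, numerical choices and known
limitations of the package, in the order data flow through it.

## Three-state tracking simulator

Molecules evolve as a continuous-time Markov chain over {free,
transiently bound, stably bound} with association rates k_bind_T,
k_bind_S out of the free state and dissociation rates k_off_T, k_off_S
back to it. The chain is sampled exactly (exponential sojourns); the
stationary distribution solves πQ = 0, and
`params_from_occupancies` builds rate sets realizing target occupancies
through detailed balance on the star-shaped state graph.

Free molecules diffuse with D_free inside a reflecting disk of radius
`nucleus_radius` (default 5 µm). Displacements over an interval are drawn
as single Gaussian steps with a radial fold-back at the boundary; once
the step s.d. reaches half the nucleus radius the position is redrawn
from the stationary uniform law instead (exact in that limit; the
fold-back is a boundary-layer approximation acceptable because free
positions only matter for track linking, not for kinetics). Bound
molecules are frozen at the binding position; transient and stable states
share the localization error σ_loc (default 25 nm per axis), which also
stands in for slow chromatin motion.

One localization per illuminated frame is emitted at the mid-exposure
position plus Gaussian error. Two detection rules shape the emitted data:

- **Motion blur.** A frame in which the molecule accumulated a
  diffusional r.m.s. displacement above `blur_radius` (default 0.3 µm)
  during the exposure yields no detection. At 10 ms exposures free
  molecules stay below it; at 500 ms they blur out, so slow movies
  contain only bound-molecule tracks — the reason long exposures are used
  for residence-time imaging in the first place. Without this rule, free
  molecules at slow schemes produce chance re-linked two-frame tracks
  that contaminate every survival curve.
- **Photobleaching.** After each illuminated frame the fluorophore
  bleaches with probability p_bleach, so P(track ≥ n frames) carries the
  factor (1 − p_bleach)^(n−1). The bleach clock runs on illuminated
  frames only, which is what lets multi-interval imaging separate it from
  dissociation.

Localizations are linked into tracks with a nearest-neighbour radius
(scheme defaults 0.52/0.39/0.65 µm for fast/continuous/time-lapse,
matching common tracker settings at 130 nm pixels), allowing one missing
frame. Tracks reaching the last movie frame are flagged and censored in
survival analysis. The ground-truth summary (state occupancies, sojourn
statistics, stable-entry rate) is computed from the exact state paths,
independent of detection. The realized stable-association event rate
divides stable-state entries by *non-stable* molecule-time, making it
directly comparable to the binding frequency ν = 1/τ_search.

Default movie sizes are 1000 frames (fast), 600 (continuous) and 60
(time-lapse): long against the mean observation window that p_bleach
allows, so longer movies would only add empty tail.

## Jump-distance analysis

`fit_jump_cdf` fits F(u) = 1 − Σ Aᵢ exp(−u/4DᵢΔt) to the empirical CDF of
squared displacements by least squares at every observed u. Amplitudes
live on the simplex via a softmax parameterization and the Dᵢ are kept
strictly ascending via cumulative log-increments; ten multi-starts (one
deterministic, spanning the observed u quantiles) guard against local
minima. Errors are s.d.s over bootstrap refits on 80 % subsamples.

The bound fraction is the summed amplitude of components with
D ≤ 0.1 µm²/s rather than A₁ alone: with three free components the fit
occasionally splits the immobile population (whose apparent D is
σ_loc²/Δt ≈ 0.06 µm²/s) across two slow components, and the sum is
invariant to that split. The 0.1 µm²/s ceiling sits an order of magnitude
below any plausible nucleoplasmic diffusion coefficient.

Degenerate input (all u = 0) returns A₁ = 1 at the configured D floor.

## Survival curves and the dissociation-rate spectrum

The survival time of a track is (illuminated-frame span − 1) × cycle
time. Survival counts N(n) are tallied from n = 2 and extended with the
observed-empty tail bins up to the movie length: "no track lasted ≥ n"
is an observation, and keeping those zeros anchors the slow end of the
rate grid against the bleaching number.

The inversion models each survival curve as

    N_c(n) ≈ γ_g(c) · Σ_k w_ck S_k exp(−k[(n−1)τ_c + t_exp]) (1−p)^(n−1)

over a fixed log-spaced rate grid (default 200 rates, 10⁻⁴–10 s⁻¹),
jointly across curves with a shared bleach number a_b = −ln(1−p) scanned
over a grid (default 60 values, 0–1.5 per frame). The decay exponent is
the exact bound duration a track of n frames implies. Three amplitude
weights w distinguish how tracks sample the event distribution:

- *initial* (track starts on frame 0): the binding was in progress when
  observation began — a length-biased sample, occupancy-weighted, w = 1/k;
- *later*: events initiated during the movie, with the
  partial-first-cycle detection factor w = (1 − e^{−kτ_c})/(kτ_c);
- *event*: one track per event conditioned on the two-frame minimum
  (synthetic survival data), w = 1 with the decay counted from the first
  tallied point.

Ignoring this distinction is not an option at realistic bleach levels:
in-progress tracks dominate the stable population and would inflate the
event amplitudes of slow rates by their residence times.

Two structural constraints stabilize the otherwise ill-posed inversion:
all slow-scheme *initial* curves share one normalization (the same
molecule ensemble is imaged under each scheme, so relative track counts
across schemes pin the bound-state mixture), and the immobile prefixes of
fast-scheme tracks (cut at the first jump > 0.12 µm, tallied from four
frames to exclude free-molecule prefixes) contribute an almost pure
bleaching readout that anchors a_b.

For each candidate a_b the non-negative amplitudes are solved either by
NNLS on Poisson-weighted counts (`objective="ls"`, the default) or by
multiplicative Kullback–Leibler updates treating the counts as Poisson
observations (`objective="poisson"`, used by the end-to-end pipeline;
count likelihoods handle the sparse tails where the slow rates live).
The a_b with the lowest objective wins; amplitudes are then normalized to
the event spectrum S. Errors come from refitting 80 % track subsamples,
with the bleach scan narrowed around the point estimate.

**State spectrum and identifiability horizon.** State amplitudes are
s_k ∝ S_k/k. Rates slower than 1/(longest observable survival span) are
excluded from state weighting: their fitted amplitudes are boundary
artifacts of the grid inversion, and the 1/k weight would let a
sub-percent artifact at 10⁻⁴ s⁻¹ dominate the state spectrum ~10⁴-fold.

**Long-bound summaries.** A grid inversion returns each physical rate as
a cluster of adjacent grid points, so the long-lived component is
selected cluster-wise: a contiguous amplitude run whose state-weighted
mean residence reaches the 50 s threshold is included whole (never below
a third of the threshold); isolated spikes reduce to the plain
1/k ≥ 50 s rule. τ_long is the inverse of the state-weighted mean *rate*
of that set — identical to the mean of 1/k for a sharp component, but
stable under smear, where a mean of 1/k is dominated by whatever lands on
the slowest grid points. The flux balance
τ_search = (1 − f_long) τ_long / f_long, ν = 1/τ_search treats all
non-stably-bound time as search time; f_long = 0 reports ν = 0 with an
infinite search time.

**Accuracy envelopes.** These are measured properties of the chain, not
aspirations. With 30 % bleaching per frame each molecule is observable
for ~3.3 illuminated frames; at 500 molecules per scheme the ~30–90
stable tracks bound the Fisher information so that se(k_slow) ≈ k_slow —
residence times are then order-of-magnitude estimates, and the recovered
f_long scatters by ×/÷2 (with a ~−30 % systematic from transient-cluster
smear under the 1/k weighting that persists even at 20 000 molecules).
The bound fraction, bleach number and τ_long (at a few thousand
molecules) are recovered reliably. Tests assert these envelopes where
they are what the data support, and the strict study-scale tolerances in
the acceptance suite where those are the claim under test.

## Motif statistics

PFMs are raw JASPAR counts; no pseudocounts. The CpG score is invariant
to uniform positive rescaling of the matrix (the Weight normalization
cancels it) and orientation-sensitive — no reverse complementing happens
anywhere. The CpG call is strictly greater than 6. The P/E score averages
the promoter indicator over promoter/enhancer occurrences and is
undefined (an error) without any; occurrences overlapping both a promoter
and an enhancer count as promoter, with a warning. The pioneer-TF tally
uses the exact two-sided Fisher test on the 2×2 table.

## Chromatin rules

All coordinates are BED-style 0-based half-open; overlap means ≥ 1 bp.
Differential classes use relative change versus control with pseudocount
ε = 0.5 (thresholds 20 % for histone marks, 30 % for TFs). H2A.Z classes
are rank-based with floor cutoffs at 3 %, 25 % and 75 % and stable-order
tie breaking, so they are invariant to monotone score transforms and give
exactly {3, 22, 50, 25} on 100 distinct scores. The rescue rule compares
depletion losses (ctrl − IAA) between lines with a multiplicative 10 %
margin; a second formulation (score retained within 10 % of the
catalytic-dead line's own control) is available behind `rule="results"`.
Turnover groups take the earliest timepoint losing ≥ 50 % of the
baseline. Methylation margins are inclusive at ±5 percentage points.
Promoters span TSS −1000/+500 strand-aware; active/bivalent/inactive
classes follow H3K4me3/H3K27me3 overlap, enhancers (outside promoters)
follow H3K27ac/H3K4me1/H3K27me3; the TSS nucleosome is TSS ±20 bp with
400 bp ∓1-nucleosome flanks. K-means runs on per-row z-scores, k = 6, ten
restarts, fixed seed; constant rows are dropped with a warning and
labelled −1, and partitions are compared only up to relabeling.

## Accessibility

Shrake–Rupley SASA with a deterministic golden-spiral point set (default
960 points; no randomness anywhere), neighbour search via a k-d tree, and
arbitrary probe radii. Element radii are ProtOr-like defaults
(C 1.70, N 1.55, O 1.52, P 1.80, S 1.80 Å, overridable); waters and
common ions are dropped on reading; alternate locations resolve to the
highest occupancy. Because the external tools' radius tables differ, the
supported quantity is the free/bound *ratio* of a selection's SASA, not
absolute areas. Rotation invariance is limited to the quadrature
resolution (~0.5 % at 960 points) since the point grid is fixed in space;
translation is exact.

The synthetic nucleosome–remodeler model is a geometric stand-in built
from realistic dimensions (147-bp DNA superhelix of radius 42 Å wrapped
1.65 turns around a 35 Å histone core, plus a lobed ~1 MDa remodeler blob
engaging one face); it is not derived from any deposited structure. On
it, 20–30 Å probes find the DNA 2.5–2.8× less accessible when the
remodeler is engaged. The toy ring fixtures provide analytically
checkable geometries (identity, distant occluder, half-swallowed ring).

## Synthetic-data generators

`make_genomic_fixture` plants classes that the classifiers must recover
exactly: differential effects at ±50–60 % (well beyond the 20 % band,
with stable peaks wiggling within ±5 %), rescue at 1.5× the wild-type
loss, turnover series crossing 50 % loss exactly at their group's
timepoint, methylation shifts at twice the margin, spike-in counts
{100 000, 200 000, 125 000, 160 000}, one promoter of each class, and the
reference PWMs (uniform, perfect-CG, one random). Everything is
bit-reproducible for a fixed seed. What passing these recovery tests
shows is that the rules are implemented exactly as stated — not that the
thresholds would cleanly separate classes in noisy real data, where
effect sizes straddle the thresholds.

## Known limitations

- No detection physics beyond the blur rule: no PSF, no localization
  failures, no mis-linking between molecules (density is effectively
  zero). Real tracking-error rates would fold into a_b per scheme.
- Single-rate photophysics: no blinking or dark-state recovery.
- The spectrum inversion carries no Tikhonov term; robustness comes from
  the resampling scheme, the structural constraints above and the
  cluster-wise summaries. Amplitudes of components separated by less than
  ~a factor of three in rate are not resolved.
- The regulatory annotation takes mark peaks at face value; no signal
  thresholds or peak quality filtering.
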