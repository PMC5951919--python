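# Methods

This note documents the models, estimators and numerical choices behind
`smkinetics`, and what the synthetic-data generator does and does not
emulate.

## Generative model of a binding trace

Each simulated molecule is independently assigned:

* **activity** — with probability `inactive_fraction` (default 0.4) the
  molecule never binds; this reproduces the binding-incompetent
  subpopulation seen in surface-immobilization experiments;
* **a kinetic class** — one of the configured `(label, koff, weight)`
  classes, fixed for the whole trace (static heterogeneity: a molecule's
  dissociation rate does not switch mid-trace);
* **a binding history** — a continuous-time two-state Markov chain with
  unbound→bound rate `kon·c` and bound→unbound rate `koff`, simulated by
  Gillespie draws and only then binned to camera frames. Binning in
  continuous time avoids the geometric-discretization bias a per-frame
  Bernoulli simulation would introduce at the 0.1 s frame interval.
  Events shorter than a frame may be invisible in the binned trace; the
  exact event list is kept in `GroundTruth` so detection-limit behaviour
  is itself testable.

The acceptor (Cy5) channel reads `intensity_off` (100 a.u.) plus the
frame's bound-time fraction times `intensity_on − intensity_off`
(300 a.u.), plus Gaussian noise (`noise_sd = 50`), i.e. a per-frame
signal-to-noise ratio of 6 — chosen so that default traces clear the
selection thresholds (S/N > 3 binding mode, > 4 smFRET mode) with
margin. Each binding event carries a fresh Cy5 dye that photobleaches
with exponential lifetime 64 s; a bleached tRNA remains bound but dark
until it dissociates. The donor (Cy3) bleaches once per trace
(default lifetime 90 s).

**Frame convention.** Frames are 0-indexed; all dwell arithmetic is in
seconds; dwell durations from idealized traces are integer multiples of
the frame interval (0.1 s default, matching 10 Hz acquisition).

## smFRET traces

A hidden state per molecule is drawn from the configured
`(mean E, sd E, weight)` states (static by default; an optional
transition rate turns molecules into CTMC hoppers with stationary
weights). Per-frame apparent efficiency is Gaussian around the state
mean, truncated to the conventional clamp range [−0.2, 1.2]. Donor and
acceptor intensities are anti-correlated with conserved total
`T = intensity_on`; acceptor bleaching sends E to ~0 with the donor
recovering the full total, donor bleaching ends the trace. Gamma
correction and quantum-yield calibration are deliberately absent: all
efficiencies are apparent, as in the experiments modelled.

## Trace selection (QC)

smFRET mode requires single-step photobleaching of the total signal,
S/N > 4:1 across the bleach step, median per-frame total intensity
> 300 a.u., and total fluorescence duration > 10 s. The "total
intensity" criterion is read as *median per-frame* donor+acceptor: a
trace-summed reading would scale with trace length and could not have a
length-independent threshold. Binding mode requires acceptor-channel
S/N > 3:1, at least two binding events, and a visible donor at the
start of the movie (later donor bleach does not disqualify a trace —
the donor only identifies an immobilized molecule).

Binding-event counting during QC uses a provisional mid-level threshold
(midpoint between the 5th percentile and the mean of the ten brightest
frames), deliberately independent of the SKM module. The brightest-frames
estimate, rather than a high percentile, keeps rare fast binders — which
may occupy well under 0.5% of frames — detectable.

Photobleach steps are found by the best two-segment piecewise-constant
least-squares split (O(n) with prefix sums); a step is significant when
the level drop exceeds 3× the pooled residual sd. A second significant
level change on either side of the step marks a multi-step trace
(aggregate) and fails the single-step criterion.

## Segmental k-means idealization

SKM alternates (i) Viterbi segmentation under two Gaussian emission
classes with an estimated transition matrix and (ii) re-estimation of
class centres, widths and transitions from the segmentation, until the
labels are fixed (or 100 iterations). Three robustness choices matter in
practice, all validated against generator truth:

* class centres/widths are re-estimated by **median/MAD** rather than
  mean/sd — frames straddling an event edge sit at intermediate levels
  and otherwise inflate the bound-class width until short events are
  absorbed into baseline;
* transition probabilities are **floored at 0.002** — re-estimated
  matrices otherwise become so sticky on event-sparse traces that short
  events stop being detected, a positive feedback;
* initialization splits at the midpoint between a low percentile and the
  mean of the ten brightest frames — Lloyd-style 2-means collapses onto
  the baseline noise tail when bound frames are rare.

If an iteration would lower the Viterbi objective (possible with robust
re-estimation), the best previous iterate is kept, so the reported
objective path is non-decreasing. Ties in the Viterbi recursion break
toward the unbound class (conservative on binding). With these choices,
event detection on default simulated traces is ≥ 97% for events of ≥ 2
frames and per-event durations are unbiased (measured against ground
truth); 1-frame events are detected about half the time, 0-frame events
never — the basis of the dead-time model below.

## Dwell extraction and censoring

Runs of equal labels become alternating dwells tiling the trace. The
first and last runs are flagged censored (their true length extends past
the observation window), and bound runs ending at a known acceptor
bleach frame are flagged censored with reason `bleach`. For *survival
fitting of unbound dwells* the start-of-trace run is treated as a
complete observation (`DwellSet.survival_inputs`): the residual lifetime
of an exponential dwell seen from an arbitrary start is itself
exponential with the same rate, and counting it as censored measurably
biases `τ_unbound` upward (≈ +12% on default simulations).

## Survival fitting

Durations are recorded as whole frames, so a kept dwell of
`k ≥ min_frames` frames corresponds to an underlying duration longer
than `(min_frames − ½)·Δt`. The exponential(-mixture) likelihood is
therefore left-truncated at `t₀ = (min_frames − ½)·Δt` (default
`min_frames = 2`, i.e. dwells shorter than two frames are discarded as
the dead time). This half-frame continuity correction keeps the MLE
unbiased to first order even for rates as fast as 1.4 s⁻¹ (measured
bias < 1% at large n); truncating at the naive `2Δt` would inflate fast
rates by several percent.

The MLE handles right-censoring exactly (survival-function terms with
the same truncation normalizer); weights are reported on the
pre-truncation scale. The single-component case is closed-form
(`λ = n_complete/Σ(t−t₀)`); the two-component case is optimized by
L-BFGS-B on (log-rates, logit-weight) from three moment-based starts.
The least-squares route fits `Σ wᵢ·exp(−λᵢ(t−t₀))` to the midpoint
empirical survival of the complete dwells. Standard errors come from a
seeded nonparametric bootstrap (200 resamples by default). Model
selection between 1 and 2 components uses BIC with a strong-evidence
rule (ΔBIC > 10, non-degenerate second component) — the simpler model
wins otherwise.

Per-molecule kinetic classes are assigned by posterior allocation of
each complete bound dwell to a mixture component; a molecule is
fast/medium when ≥ 80% of its dwells allocate to one component, mixed
otherwise, indeterminate with fewer than two complete dwells. With
overlapping components (rate ratio ≲ 10) individual long-ish fast dwells
routinely cross the posterior boundary, so class *fractions* are only
recoverable when the components are well separated; the tests use a
ratio ≈ 40 mixture for that reason.

## Pipeline corrections

Two analytic corrections connect the fitted observables to the physical
rate constants; both use only quantities available to a real experiment
(fitted components plus the independently measured bleach rate):

* **Bleach subtraction.** A bound event ends observably by dissociation
  or by Cy5 bleaching, whichever comes first, so each observed component
  decays at `koff + k_bleach` with unchanged mixture weights;
  `k_bleach = 1/64 s⁻¹` is subtracted from fitted bound rates.
* **Unbound-lifetime correction.**
  `τ_u,corr = (τ̂_u − dark)·(1 − p_miss)`, where `p_miss` is the
  probability that a bound event is invisible (it rounds to zero frames,
  or to one frame with ≈ ½ phase-dependent detection) — invisible events
  merge the flanking unbound dwells — and `dark` is the mean
  bound-but-dark residual appended to an apparent unbound dwell when the
  event ended by bleaching
  (`Σ wᵢ·(k_bleach/λᵢ,obs)·(1/λᵢ,corr)`).

On default simulations these corrections move end-to-end `kon` errors
from −4…−10% to within ±4%.

## FRET analysis

Efficiencies are clamped to [−0.2, 1.2]; frames after the first detected
bleach (or with non-positive corrected total) are invalid. Ensemble
histograms pool the first 50 valid frames per selected trace with bin
width 0.02 over the clamp range (binning is a package choice; the
convention the analysis mirrors does not state one). Mixture fitting is
nonlinear least squares of a Gaussian sum on the binned density —
matching the spreadsheet-style workflow such histograms are usually fit
with — initialized at density peaks with quantile fallback; fractions
are normalized component areas. Background estimation defaults to the
post-bleach baseline when explicit backgrounds are not supplied.
Zero/low-FRET populations are only physically meaningful when the
acceptor is confirmed by direct red excitation; the trace container
carries the excitation mode so callers can enforce this.

## Colocalization

Spot detection smooths the average image with a 1 px Gaussian (matched
filter), takes 3×3 local maxima above `median + 3σ` (robust σ), confirms
each candidate by its raw integrated window intensity, refines centres
by 5×5 centroid and merges maxima closer than 3 px to the brighter one.
On the default simulated field (100 spots, S/N 6) recall is ≥ 0.98 with
≤ 2 false positives and ≤ 0.5 px centre error. Matching is greedy
nearest-neighbour within a 2 px radius (exposed as a flag; the
underlying experiments do not report theirs), with an optional
user-supplied affine mapping for channel registration — estimating the
registration itself is out of scope.

## Hill fits

`f = plateau·cⁿ/(K_dⁿ+cⁿ)` with `n` fixed (default 1). The plateau is
free by default, since filter-based protection assays rarely saturate at
exactly 1.0; fitting is on the linear concentration scale. Bootstrap
standard errors resample titration points. Grossly non-monotone data is
fitted anyway but flagged.

## Problem sizes

Analyses in the test-suite and acceptance script run at desk scale:
dwell-recovery checks use 1500–2000 dwells (matching the data volume of
a few hundred analyzed molecules); FRET-histogram recovery uses 100
molecules × 50 frames; end-to-end condition runs use 300–2200 simulated
molecules at 9000 frames (15-minute movies at 10 Hz, several pooled
replicate fields of ≥ 100 molecules each). The larger counts are chosen
by power analysis: resolving a 27%-weight fast component at rate ratio
~40, or two components at ratio ~5, to a few percent requires several
thousand pooled dwells — more than a single wet-lab movie yields, which
is why multi-replicate pooling is assumed.

## What the generator does not emulate

No optical simulation (PSF drift, EMCCD gain statistics, chromatic
aberration), no diffusion or rebinding of the ligand pool, no baseline
drift, no donor–acceptor crosstalk or gamma factors, no aminoacylation
chemistry. Passing tests therefore demonstrate correctness of the
estimators under the stated stochastic model — two-state Markov binding
with static heterogeneity, Gaussian camera noise, exponential
photobleaching — not robustness to every artifact of real microscope
data.

## Known limitations

* Missed-event handling is the fixed-dead-time model plus the analytic
  `p_miss` correction; no full hidden-Markov missed-event likelihood.
* Two idealization states only; multi-state FRET idealization is not
  provided (transition-density analysis accepts externally idealized
  E-sequences).
* The two-component MLE is stable for rate ratios ≳ 3 with both weights
  ≳ 0.1; closer mixtures are flagged degenerate rather than deconvolved.
* Heterogeneity class fractions are biased toward "mixed" for
  overlapping components, as discussed above.
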