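# Methods

## Measurement model

Each well of a microplate is read repeatedly for optical density (absorbance
at 595 nm) and fluorescence at two emissions (525 and 585 nm, excitation
485 nm). All fluorescence signals are modelled as linear sums of two
components. For a tagged strain,

    f525 = g + a
    f585 = rg·g + ra·a

with `g` the reporter signal at 525 nm, `a` the cellular autofluorescence at
525 nm, `rg` the reporter's emission ratio 585/525 (a spectral constant;
0.065/0.570 ≈ 0.114 for EGFP, user-overridable for other fluorophores), and
`ra` the corresponding autofluorescence ratio. Wild-type (untagged) wells
have `f525 = a_WT`, `f585 = ra·a_WT`. The key assumptions are (i) `ra` is
the same function of OD for tagged and wild-type cells, even though the
amounts `a` and `a_WT` may differ, and (ii) components mix linearly. (i) is
strictly weaker than the equal-growth, equal-autofluorescence-per-cell
assumptions behind the bacterial subtraction method, which is retained only
as a comparison baseline.

## Gaussian-process engine

All smoothing, interpolation and error propagation uses zero-mean GP
regression with fixed per-point Gaussian noise. Kernels:

* squared exponential `σ² exp(−(x−x′)²/2ℓ²)` — smooth fluctuations (media
  baselines, noise interpolation, OD calibration component);
* linear `σ_b²·x·x′` — keeps calibration extrapolation sane;
* neural network (Williams' arcsine form, amplitude `σ`, bias scale `σ₀`,
  input scale `σ₁`) — sigmoid-like prior samples, suited to the saturating
  rise of `ra` with OD. The parameterization is this package's choice; only
  the qualitative "sigmoid-like samples" requirement is inherited.

Hyperparameters are optimized in log space by maximizing the log marginal
likelihood with scipy's truncated-Newton (TNC) bounded minimizer, 5 seeded
random restarts, and bounds of ±log(10⁴) around data-scaled initial values.
A TNC "line search failed" stall is accepted as convergence (it routinely
occurs at the optimum on flat evidence surfaces); running out of function
evaluations is not, and triggers the fallback paths described below. The
evidence computation is validated against an independent multivariate-normal
log-density evaluation to 1e-8 on every kernel family.

Noise handling has three modes: fixed per-point standard deviations
(empirical estimates), a single learned constant (`"learn"`), and a learned
scale on a supplied relative profile (`("learn_scaled", profile)`). Cholesky
factorizations add escalating diagonal jitter (1e-9 to 1e-3 of the mean
diagonal) before declaring numerical failure. Posterior function sampling
uses the full joint covariance at the query points.

Per-point noise is estimated empirically as the sample standard deviation
(n−1 denominator) of the k points nearest in the input coordinate, the point
itself included, ties broken by index, floored at 1e-12: k=10 along time for
media wells, k=20 along OD for the wild-type ratio, and k=20 along time for
the tagged channels. On trending data this windowed estimate deliberately
includes trend spread, so error bars are conservative during fast
transients and the zero-measurement-noise limit of the reported uncertainty
is the trend contribution, not zero.

## Pipeline stages

**Media correction.** Media-only wells drift slightly over a run. Each
channel's pooled media readings are fitted with a squared-exponential GP and
10-nearest-point noise; if that optimization fails to converge, the fit is
retried with a single learned constant noise (`mode_used` records the path).
The posterior-mean baseline is subtracted from every cell well; media wells
are then dropped. Negative corrected values are reported, never clipped, and
counted in the QC table. Baseline uncertainty is not propagated further —
the sampling stage propagates `ra` and calibration uncertainty only.

**OD calibration.** A doubling dilution series (1× … 256× by default) of a
dense culture gives exact relative densities (undiluted = 1.0) against
measured ODs. The OD→density map is a GP with a squared-exponential + linear
kernel. The series' error is multiplicative on the measured OD while the
densities are exact, and through a near-power-law map that converts to
y-noise proportional to density, so the fit learns one noise scale on a
profile proportional to density. The posterior mean must be non-decreasing
on a 200-point grid; extrapolation beyond the calibrated range is allowed
but flagged. Without a calibration file the identity map is used with a
prominent warning. The hemocytometer anchor (a relative density of 1.0 ≈
1.46×10⁷ cells/mL at OD ≈ 1.2) can be stored as optional metadata but is
never used in computation.

**ra(OD).** Pointwise ratios `f585/f525` of all media-corrected wild-type
wells are pooled and ordered by OD (points with non-positive f525 are
excluded with a warning); the neural-network-kernel GP is fitted with
20-nearest-point noise, and the noise magnitudes themselves are fitted with
a squared-exponential GP so the expected ratio error can be interpolated to
the tagged strain's ODs. Wild-type cultures should start at lower OD than
tagged ones so the support covers early time points; lookups outside the
support are flagged.

**Direct estimate.** Per time point, the wild-type ratio is averaged over
replicates; the replicate-averaged wild-type OD is smoothed by robust local
quadratic regression (tricube weights, span 15% of points, 2 bisquare
reweighting iterations) and projected onto the nearest monotone curve
(growth can plateau or dip late; lookups beyond the monotone range reuse the
value at the maximum attained OD, flagged). Tagged ODs map through this
OD→ratio lookup, `g = (ra·f525 − f585)/(ra − rg)` is computed per replicate,
averaged, smoothed, and divided by calibrated density. Fast, but no error
bars.

**Bayesian estimate.** With a flat prior and the autofluorescence integral
extended over the whole real line (safe when the posterior of `a` is peaked
above zero; a diagnostic flags time points where the implied `a` is within
2σ of zero), the likelihood of `g` is Gaussian with mean
`(f585 − ra·f525)/(rg − ra)` — identical to the direct estimate — and sd
`sqrt(σ585² + ra²σ525²)/|rg − ra|`. Per replicate the pipeline draws 50
joint `ra` sample functions at the tagged ODs (posterior draws plus
independent noise from the interpolated ratio error), one sampled
OD-calibration curve per `ra` sample, and 1000 `g` samples per (ra sample,
time point), each divided by the paired density sample. All samples are
pooled per time point across `ra` draws and replicates; the pooled mean and
sd are the estimate and error bar. `g` is never truncated at zero — the
likelihood admits negative values and clipping would bias low-expression
estimates upward; negative pooled means are flagged. Combinations with an
`ra` sample at or below `rg` (ill-posed inversion) are dropped and counted
(warning above 10%, error above 50%). The sampler defaults to drawing from
the closed-form Gaussian; a rejection sampler (uniform envelope over
±6 sd against the unnormalized likelihood kernel, envelope width a package
choice) is kept, selectable, and validated to be distributionally identical
by KS test. A single experiment seed deterministically derives per-group,
per-replicate, per-stage substreams, so results are bit-reproducible.

## Synthetic experiments

The generator is the package's ground-truth instrument, not a fixture: it
runs the measurement model forward. Logistic growth of relative density
(defaults: initial 0.149 for wild-type and 0.182 for tagged — starting ODs
≈ 0.25 and 0.3, wild-type deliberately lower — rate 0.5/h, capacity 1.0); a
saturating density→OD map `1.8·d/(1 + d/2)` (undiluted calibration density
1.0 ↔ OD 1.2, nonlinearity visible from OD ≈ 0.5); `ra` rising sigmoidally
0.4→0.6 across the OD range; autofluorescence 100 a.u. per density unit
(with an adjustable tagged/wild-type factor to reproduce the subtraction
method's failure mode); reporter expression off, constant, or a smoothstep
induction ramp (default 0→150 a.u./cell between 2 h and 10 h); linear media
drift per channel; independent Gaussian noise per reading (OD 0.003,
f525 1.0, f585 0.5 a.u.). Readings every 12 minutes, ~20 h. A multiplicative
noise option exists to probe model misspecification but is excluded from the
validation gates.

What the generator does not emulate: evaporation, well-position bias,
photobleaching, diauxic growth by default (available as a scenario),
settling or clumping, and any mechanistic gene-regulation dynamics. Passing
recovery tests therefore demonstrates correctness of the inference given the
measurement model, not robustness to every artifact of real plates.

## Validation design

The reference recovery experiment uses 3 media, 3 wild-type and 3 tagged
wells with 100 time points and the default scenario, with the full 50×1000
sampling budget — small enough to run in seconds, large enough that GP fits
and coverage fractions are stable. Coverage is assessed as the fraction of
time points where mean ± 2 sd covers the truth (target ≥ 90%). Accuracy is
assessed where the true per-cell signal exceeds five times the noise floor,
defined as the estimate's own standard deviation: at lower signal-to-noise
the per-point deviation is dominated by the measurement noise of individual
readings and a pointwise relative bound is not statistically meaningful,
which is exactly what the error bars are for. The dilution-series check
evaluates recovered density at true ODs below 0.5 (the map's linear-regime
shoulder). The subtraction baseline's failure is quantified as the z-score
of its time-averaged per-cell estimate under a zero-expression,
20%-lower-autofluorescence scenario.

## Numerical choices and limitations

* Jitter ladder 1e-9…1e-3 × mean diagonal; ill-conditioning guard
  |ra − rg| < 1e-6; noise floor 1e-12.
* Time grids across wells must agree within 1% of the sampling interval and
  are snapped to per-point medians; missing readings are rejected, not
  imputed.
* Time correlation of `g` is not modelled (time points are treated
  independently, matching the sampling scheme); the error bars are pointwise.
* The OD↔time correspondence used to transfer `ra` assumes monotone growth;
  post-diauxic OD declines are handled by isotonic projection plus flags,
  not modelled.
* Media-fit uncertainty is not propagated; with several media replicates it
  is small against the channel noise.
* One fluorophore per well; the algebra generalizes to more channels but the
  matrix case is not implemented.
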