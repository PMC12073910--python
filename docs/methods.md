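# Methods

## Acquisition model

All computations assume a direction-averaged dMRS experiment on a fixed
protocol: six b-values [0.01, 1.012, 4.03, 9.06, 16.09, 25.1] ms/μm²,
four tetrahedral encoding directions (±1, ±1, ±1 with unit norm),
effective gradient duration 26.4 ms, effective separation 62.5 ms, and 24
individually stored transients per (b, direction) condition. Spectra are
parameterized by a 3000 Hz bandwidth and 2048 complex points. Units are
b in ms/μm² and diffusivities in μm²/ms throughout.

## Signal models

Four forms map parameters to normalized attenuation S(b)/S₀:

1. **Monoexponential** — exp(−b·ADC). Pure Gaussian diffusion; only
   meaningful at low b, so fits use b < 5 ms/μm².
2. **Kurtosis representation** — exp(−b·ADC + b²·ADC²·K/6), a
   second-order cumulant expansion fitted for b < 10 ms/μm². Beyond the
   turnover b\* = 3/(ADC·K) the expression rises again; evaluation past
   b\* emits a warning rather than an error, because bounded optimizers
   legitimately sweep that region.
3. **Astro-sticks** — the powder average of one-dimensional diffusion
   along randomly oriented sticks, (√π/2)·erf(√(b·D))/√(b·D). For
   b·D < 10⁻⁶ the 4-term Taylor series 1 − x/3 + x²/10 − x³/42 avoids
   the 0/0; the series and the closed form agree to ~10⁻¹⁸ at the
   switchover.
4. **Modified astro-sticks** — the same hemisphere integral with
   Deff(θ) = Dintra·(1 − Kintra·Dintra·b·cos²θ) substituted for Dintra,
   exactly in that algebraic form (no 1/6 cumulant factor inside Deff;
   the standard cumulant convention would rescale Kintra by 6 but not
   change the model family). The integral over cosθ ∈ [0, 1] is
   Gauss–Legendre quadrature of order 96; doubling the order moves no
   value on the bounded parameter box by more than 10⁻⁸, and a
   `check_convergence` flag re-verifies this at call time.

At permitted bound values (Kintra·Dintra·b > 1) Deff goes negative at
small θ and the integrand grows exponentially. The signal is still
computed as written, a validity helper reports the regime, and the
fitting objective adds a large smooth penalty there so optima stay in
the physical region; results whose optimum violates it are flagged
invalid.

Two analytic limits serve as diagnostics and test oracles. With
cosθ uniform on [0, 1], D_app = Dintra·cos²θ has ⟨cos²θ⟩ = 1/3 and
⟨cos⁴θ⟩ = 1/5, so small-b stick decays look like ADC = Dintra/3 with
apparent kurtosis 3·Var(D_app)/⟨D_app⟩² = 12/5, independent of Dintra.
At high b the stick powder average scales as b^(−1/2); between the two
highest protocol b-values the exact log-log slope is within 0.01 of −1/2
for Dintra ≳ 0.25 but sits at −0.478 at Dintra = 0.2, where b·Dintra ≈ 3
is not yet asymptotic — a real property of the model, reproduced by the
Monte-Carlo oracle, not a numerical artifact.

A seeded Monte-Carlo orientation average (uniform cosθ, ≥10⁴ samples,
standard error reported) provides a brute-force cross-check of both
stick forms; tests require agreement of closed form, quadrature and
Monte Carlo within 10⁻⁸ and 3 standard errors respectively. Where a grid
of parameter points is compared at once, the Monte-Carlo draws use
common random numbers so the comparison family does not accumulate
independent 3σ tail events.

## Fitting

Each model is fitted to a decay curve by Levenberg–Marquardt least
squares (lmfit) on the unweighted residuals between measured amplitudes
and S₀·S(b; θ) over the model's b-range. Choices where the procedure was
genuinely open:

* **S₀ is a free positive nuisance parameter** rather than a fixed
  normalization by the lowest-b point, so that single point's noise does
  not propagate into every residual. Per-point uncertainties are carried
  for reporting; weighting by them is available but off by default.
* **Initialization**: ADC from a log-linear fit of the two lowest
  b-points; the kurtosis fit starts from that ADC with K = 1; the stick
  fit starts at 3× that ADC (inverting the small-b relation); the
  modified-stick fit starts from the stick solution with Kintra = 0.05.
  Five seeded random restarts within bounds guard the shallow
  ADC–K / Dintra–Kintra trade-off; the best objective is kept, and the
  whole procedure is deterministic given (data, spec, seed).
* **Bounds**: 10⁻⁶ ≤ diffusivities ≤ 1.0 μm²/ms (free-metabolite
  ceiling), 0 ≤ kurtosis parameters ≤ 3.0. An estimate within 10⁻⁴ of
  its lower bound is flagged `at_lower_bound`; such estimates are
  excluded from trajectory statistics as unreliable, reproducing the
  "converged to zero" exclusions that occur in practice when a
  higher-order term is not supported by the data.
* 1σ uncertainties come from the covariance of the least-squares
  solution at the optimum.

A dense grid search over the bounded parameter box (with the scale
profiled out analytically) is used in tests as an independent optimality
oracle; one consequence worth recording is that a noiseless stick decay
with Dintra = 0.45 fitted by the kurtosis representation on the b < 10
points has its true global optimum at ADC ≈ 0.140, K ≈ 1.66: at
b·Dintra ≈ 4 the fit is far below the small-b limit K = 12/5, and both
the optimizer and the grid oracle agree on that value.

## Transient quality control

A simplified stand-in for full spectral preprocessing, operating on
synthetic single-peak spectra (spectral quantification against a
metabolite basis set is out of scope; downstream fitting consumes only
peak areas, for which windowed integration of well-separated singlets
suffices):

1. **Phase/frequency correction** per transient on the reference peak
   (NAA singlet, 2.01 ± 0.1 ppm search window). The peak is located with
   sub-bin precision by a noise-corrected power centroid within ±2
   linewidths of the coarse magnitude maximum, iterated to its fixed
   point so the estimate is translation-equivariant; the phase is read
   off the transient's discrete-time Fourier transform evaluated exactly
   at the centroid frequency (reading it at the nearest grid bin instead
   would pick up up to ~0.4 rad of dispersion twist). Corrections
   smaller than their own estimation precision (floors 0.25 Hz and
   0.05 rad, scaled up as noise/peak grows) are not applied, making the
   correction idempotent except for transients whose reference peak is
   ambiguous at low SNR. Transients whose peak does not rise 2× above
   the noise floor (estimated from the outer eighths of the spectrum)
   are marked uncorrectable.
2. **Peak thresholding** per (b, direction) condition: transients whose
   reference-peak amplitude falls below median − 2.5 × 1.4826 × MAD of
   the condition's amplitudes are discarded as motion-corrupted. The
   constant is configurable; 2.5 robust σ catches half-amplitude
   corruption essentially always while mis-flagging clean transients at
   the sub-percent level inherent to any fixed-σ rule.
3. **Quantification**: kept transients are averaged per condition and
   each metabolite's amplitude is the integral of the real part over its
   window (tNAA 2.01, tCr 3.03, tCho 3.22, all ± 0.1 ppm). The tCr and
   tCho windows graze by 0.01 ppm; overlaps beyond 0.015 ppm are a
   configuration error.
4. **Direction averaging**: arithmetic mean across directions per b,
   uncertainty SD/√n, unusable conditions dropped with a warning.

## Synthetic cohorts

The generator produces the structure the analysis assumes, not raw
realism: 25 subjects, ages uniform on 25–80, two regions (cerebellum,
PCC), three metabolites, one record per subject-region.

* **Ground truth**: stick model with region/metabolite-typical
  diffusivities (cerebellum 0.346/0.325/0.287, PCC 0.440/0.407/0.440
  μm²/ms for tNAA/tCho/tCr) — values representative of adult gray
  matter. Optional linear age slopes per parameter, zero by default (the
  null hypothesis); the truth is retained on each record for recovery
  scoring.
* **Area noise**: Gaussian relative noise on per-direction areas
  (spectral-fit area estimates are approximately Gaussian at these
  precisions), interpolating linearly in b from 3 % at the lowest b to
  metabolite/region-specific 4–10 % at the highest, then direction
  averaged. Truncation keeps amplitudes positive.
* **Tissue fractions**: moment-matched lognormal draws per class
  (strictly positive — a truncated Gaussian would pile mass at the
  floor and blow up the fGM/fWM covariate), means/SDs of
  0.82/0.12/0.06 ± 0.05/0.05/0.03 (cerebellum) and
  0.69/0.14/0.17 ± 0.07/0.03/0.08 (PCC), renormalized to sum to 1, with
  a linear gray-matter decline across the age range (17 % cerebellum,
  4 % PCC) that preserves the cohort mean.
* **Transient level** (optional): each transient is a sum of Lorentzian
  singlets (linewidth 4.5 Hz) attenuated by the forward model, with
  complex Gaussian noise calibrated so peak height over noise SD equals
  the target SNR (~18–24 at b≈0, falling to ~6–7 at the highest b
  through the model attenuation alone), plus per-transient phase jitter
  (SD 0.3 rad), frequency drift (SD 1.5 Hz) and a 5 % fraction of
  half-amplitude (motion-corrupted) transients. The carrier frequency is
  fixed at 127.7 MHz (3 T protons) purely for the Hz↔ppm conversion.
* **Determinism**: the master seed spawns independent substreams per
  subject, region and curve, so cohorts are byte-reproducible and any
  sub-quantity can be regenerated in isolation.

What the generator does **not** emulate: multi-metabolite spectral
overlap and baselines, Rician magnitude bias at the area level, cardiac
pulsation, eddy currents, b-value jitter across directions (available as
a knob, off by default), and any nonlinearity in the age trends. Passing
recovery and calibration tests therefore demonstrates correctness of the
pipeline under its stated noise model, not robustness to every artifact
of real acquisitions.

## Statistics

Per (region, metabolite, model, parameter) cell, after removing
at-bound, invalid and non-finite estimates (each removal logged with its
reason):

* OLS of estimate on age (statsmodels); two-sided slope p from the t
  distribution with n−2 df; 95 % confidence and prediction bands on 100
  evenly spaced ages over the observed range. Degenerate inputs are
  special-cased: an exactly constant response returns slope 0 with p = 1,
  and a zero-residual exact line returns p = 0 rather than NaN.
* OLS with age and fGM/fWM regressors, per-coefficient two-sided
  p-values (n−3 df), uncorrected. A design whose condition number
  exceeds 10¹⁰ is reported as collinear rather than fitted.
* Independent two-sample t-test between age < 50 and age ≥ 50 (50
  belongs to the older group). Welch's unequal-variance form is the
  default — the two groups have unequal sizes and no pairing exists in a
  cross-sectional design — with Student's pooled form behind a flag.
  Bonferroni correction applies to the t-test family only, m = 6 per
  diffusion metric (2 regions × 3 metabolites), threshold 0.05/6 ≈
  0.0083, strict inequality.

Under the null generator the slope test holds its 5 % level (checked
over 500 simulated cohorts). Note that a 36-cell grid tested at the
corrected threshold still has a ~26 % chance of at least one spurious
significant cell per cohort; single-draw "no significant cell" outcomes
are therefore probabilistic, and the suite treats the rate, not any one
draw, as the calibrated quantity.

## Problem sizes

Defaults were chosen so the whole suite and the acceptance script each
run in well under half an hour on one CPU: 200 replicates for recovery
bias, 500 cohorts for type-I calibration, 2×10⁵ Monte-Carlo orientations
per grid point (10×10 grid) for the oracle cross-check, and 40-replicate
QC detection runs. All are parameters, not constants, and scale up
without code changes.

## Known limitations

* The QC chain is built for isolated singlets; overlapping multiplets
  would bias both the centroid frequency estimate and windowed areas.
* Area-level noise is Gaussian by construction; at very low SNR real
  magnitude data acquire a Rician floor the generator only reproduces at
  the transient level.
* The modified-stick Kintra is weakly identified on six b-values when
  the true value is near zero; its frequent collapse to the bound (and
  exclusion) is expected behaviour, mirrored in the synthetic cohorts.
* External decay data are supported through a documented CSV schema;
  no vendor MRS formats are read.
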