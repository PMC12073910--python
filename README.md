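# metabdiff

Diffusion-weighted MR spectroscopy (dMRS) measures how intracellular brain
metabolites — tNAA (neuronal), tCho (glial), tCr (both) — diffuse inside
the cells that contain them, giving microstructural markers that water
diffusion MRI cannot separate by cell type. `metabdiff` implements the
analysis chain for cross-sectional dMRS studies of gray matter: forward
signal models, bounded model fitting, simplified transient-level quality
control, a synthetic cohort generator, and age-trajectory statistics. It
is aimed at spectroscopists who want a tested, reproducible pipeline for
direction-averaged metabolite decay curves, and at methodologists who
want to simulate such studies end to end.

## Models

For a diffusion weighting $b$ (ms/μm²) the direction-averaged signal
$S(b)/S_0$ is described by four forms:

* **Monoexponential** (Gaussian): $S = e^{-b\,\mathrm{ADC}}$, fitted for
  $b < 5$ ms/μm².
* **Kurtosis representation**:
  $S = \exp(-b\,\mathrm{ADC} + \tfrac{1}{6} b^2 \mathrm{ADC}^2 K)$,
  fitted for $b < 10$ ms/μm² (valid below the turnover
  $b^* = 3/(\mathrm{ADC}\cdot K)$).
* **Astro-sticks**: metabolites confined to randomly oriented
  one-dimensional processes,
  $S = \int_0^1 e^{-b D_\mathrm{intra} \cos^2\theta}\, d\cos\theta
     = \frac{\sqrt{\pi}}{2}\,
       \frac{\mathrm{erf}\sqrt{b D_\mathrm{intra}}}{\sqrt{b D_\mathrm{intra}}}$,
  fitted at all b. At high b it scales as $b^{-1/2}$.
* **Modified astro-sticks**: the same powder average with an effective
  intra-stick diffusivity
  $D_\mathrm{eff} = D_\mathrm{intra}\,
   (1 - K_\mathrm{intra} D_\mathrm{intra} b \cos^2\theta)$,
  capturing restrictions along the processes (e.g. spines); evaluated by
  Gauss–Legendre quadrature.

Fits are Levenberg–Marquardt least squares (lmfit) with all parameters
positive, diffusivities ≤ 1.0 μm²/ms (free-metabolite ceiling) and
kurtosis parameters ≤ 3.0, plus a free scale $S_0$. Estimates that
collapse onto the lower bound are flagged and excluded from the
statistics, which comprise per-parameter age regression with 95 %
confidence/prediction bands, a multivariate model
$y \sim \beta_0 + \beta_1\,\mathrm{age} + \beta_2\, f_{GM}/f_{WM}$, and a
Welch t-test between subjects younger and older than 50 with Bonferroni
threshold $0.05/6$ (2 regions × 3 metabolites).

## Worked example

```bash
python examples/02_fit_decay.py
```

```
ground truth: stick model, Dintra = 0.346 um^2/ms

monoexp          (3 b-values)  ADC = 0.0946 +/- 0.0029
kurtosis         (4 b-values)  ADC = 0.1089 +/- 0.0008,  K = 1.7673 +/- 0.0237
astrosticks      (6 b-values)  Dintra = 0.3546 +/- 0.0098
mod_astrosticks  (6 b-values)  Dintra = 0.3546 +/- 0.0326,  Kintra = 0.0000 +/- 0.0137 [at lower bound]
```

One noisy decay curve (6 b-values from 0.01 to 25.1 ms/μm², tetrahedral
direction average, ~3–4 % area noise) was generated from the stick model
and fitted by all four forms. The stick fit recovers the generating
diffusivity within its 1σ error; the monoexponential ADC lands near
$D_\mathrm{intra}/3$, the orientation average of a stick; and
$K_\mathrm{intra}$ collapses onto its lower bound because the generating
model had no intra-stick kurtosis — exactly the condition under which the
trajectory analysis discards an estimate as unreliable.

The other scripts in `examples/` walk through the signal models, the
transient QC chain, a full synthetic cohort, and the age-trajectory
statistics. A thin CLI mirrors the pipeline stages
(`metabdiff simulate | qc | fit | trajectories | report`).

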