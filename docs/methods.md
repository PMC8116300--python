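# Methods

## Measurement model

A two-pellet thermoluminescent dosimeter card carries a pellet behind a 1 mm
aluminium filter (*covered*, counts `N_C`) and a bare pellet (*uncovered*,
`N_U`). The filter transmits the full gamma signal but only a fraction `t`
of the beta signal (`t = 0.25` for a ⁹⁰Sr/⁹⁰Y source), so

    N_C = N_γ + t·N_β,        N_U = N_γ + N_β.

Counts here are background-corrected heat-phase TL integrals. With the beta
count fraction `θ = N_β / N_U` and calibration factors `k_γ`, `k_β`
(mSv·count⁻¹, estimated as `k = D / N̄` from a batch irradiated with a known
dose `D`), the component doses are

    D_γ = N_U (1 − θ) k_γ,    D_β = N_U θ k_β.

All three engines share this map; they differ only in how uncertainty about
`θ` and `k` is handled.

* **Classical**: `θ` from the solved pair (field mode) or supplied
  (validation mode); uncertainties combined to first order (exact
  differential) and reported doubled (`k = 2`).
* **Bayesian**: the count integral is modelled as Gaussian,
  `N ~ Normal(N_U, σ_N)`; the likelihood of a candidate dose is the count
  density at the implied counts `D / ((1−θ) k_γ)` (gamma) or `D / (θ k_β)`
  (beta). Gaussian priors are placed on `θ` (truncated to [0, 1] and
  renormalised) and/or `k` (truncated positive), matching the three
  knowledge states: option 1 — `p(θ)` with `k` known; option 2 — `θ` known
  with `p(k)`; option 3 — both unknown. The marginal posterior of the dose
  is tabulated on a grid, its mode is the point estimate, and its width is
  the Cramér–Rao bound `1/√|∂² ln P/∂D²|` at the mode, reported doubled as
  an approximate 95% highest-density interval.
* **Monte Carlo**: a randomised realisation of the same model — draw `θ`
  and/or `k` from their (truncated) priors, optionally redraw `N`, push
  through the dose map, and summarise 100,000 dose samples as mean ± 2 sd.

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `t` | beta transmission of the covered filter | 0.25 | ⁹⁰Sr/⁹⁰Y behind 1 mm Al |
| `σ_N` | Gaussian spread of the count integral | 5% of `N_U` | pellet-batch CVs are a few percent; the spread is a convention, not a measurement, and the reported mode is insensitive to it at the 0.001 mSv reporting resolution (tested) |
| `σ_θ` | θ-prior width in validation runs | 1% of `θ̂` | validation uses a precisely known beam composition; in field mode `σ_θ` is propagated from the count spreads by the exact differential of `θ = (N_U−N_C)/((1−t)N_U)` |
| `k̂ ± σ_k` | calibration factor and spread | from the calibration CSV | the spread is the *batch* spread (not the standard error of the mean), which is what a Gaussian prior on a single pellet's factor needs |
| `n_iter` | Monte Carlo iterations | 100,000 | mean standard error ≪ 0.001 mSv at typical spreads |
| dose reporting | 3 decimals in mSv, 2σ (`k = 2`) uncertainties | — | matches routine dosimetry reporting |

Bundled validation campaign (`tldose.scenarios`): `k_γ = 9.29·10⁻⁷ ±
0.20·10⁻⁷`, `k_β = 8.17·10⁻⁷ ± 0.28·10⁻⁷` mSv·count⁻¹, and five mixed
exposures of ≈1 mSv total with beta fractions 10–90%. The gamma dose always
uses the 9.29·10⁻⁷ factor and the beta dose the uncovered 8.17·10⁻⁷ factor;
because that mapping cannot be deduced from a calibration table's layout,
run configurations carry an explicit component → factor selection.

## Numerical choices

* **Quadrature.** All marginalisations are trapezoidal on uniform grids
  covering ±6 prior sigmas (512 nodes per axis), truncated to `θ ∈ [0, 1]`
  and `k > 0` with the prior renormalised on the truncated support. The
  integrands are smooth, rapidly decaying Gaussian products, so quadrature
  error is orders of magnitude below the 0.001 mSv reporting resolution
  (verified against a brute-force midpoint-Riemann oracle to 10⁻⁴ of the
  peak, and against degenerate-prior reductions to 10⁻⁶).
* **Dose grid.** 4,096 uniform points on `[0, 2·N_U·k_max]`
  (sub-0.001 mSv resolution for ≈1 mSv doses); the upper limit is expanded
  ×1.5 while boundary density exceeds 10⁻⁹ of the peak.
* **Option 3 evaluation.** θ enters the double integral only through the
  implied component counts `c = D/g(θ)`, so the inner k-marginal is
  tabulated once on a dense `c` grid (32,768 nodes) and reused across the
  θ quadrature through a cubic spline — equivalent to the direct nested
  quadrature to ~10⁻⁹ of the peak at a small fraction of its cost.
* **Mode.** Grid argmax refined by quadratic interpolation through the
  three surrounding points; a boundary maximum raises a grid-coverage
  error, a multimodal tabulation warns and returns the global maximum.
* **Curvature.** The log-density second derivative at the mode is a central
  finite difference on the grid (exact for a Gaussian posterior, since its
  log-density is quadratic; < 0.1% error verified on tabulated Gaussians).
* **Truncated sampling.** Monte Carlo truncated-Gaussian draws use
  rejection (acceptance ≫ 99% for realistic spreads), so a fixed seed
  reproduces the sample stream bit-for-bit; a warning is raised if more
  than 1% of a prior's mass lies outside its truncation bounds.
* **Degenerate inputs.** `θ = 0` (beta) and `θ = 1` (gamma) make the
  dose-to-counts map singular and raise a dedicated error; a background
  exceeding the counts, nonpositive calibration counts, and a covered
  count above the uncovered count (negative implied beta) are reported as
  errors rather than clamped — except that a negative implied beta within
  `2σ_N` of zero may be clamped to zero with a warning when explicitly
  enabled, for low-beta fields with noise.

## Design choices that were genuinely open

* **θ provenance.** Validation uses a known `θ̂` (the bundled scenarios
  carry the measured count split); field use solves the covered/uncovered
  pair. Both paths exist and the report records which was used — the two
  must not be conflated, because measured count pairs carry noise that the
  validation split has already absorbed.
* **Mode vs mean.** The marginal-posterior mode is the point estimate. At
  calibration-level spreads the mode sits `O(σ_k²/k̂²)` (≈0.1%) below the
  classical value and the mean the same order above it — both well inside
  the reported uncertainty, but visible in the third decimal for the widest
  beta spreads. The Monte Carlo engine reports the sample *mean*, which
  equals the classical value exactly in expectation; the two engines
  therefore agree in distribution but can differ by ~0.001 mSv in the
  point estimate at 10⁵ iterations, which is why cross-engine point
  comparisons in the tests run at moderate iteration counts or compare at
  the reporting precision.
* **Count-spread mode for MC.** `fixed-counts` (default) reproduces
  central-value validation; `resampled-counts` draws `N` per iteration and
  is the mode whose sample spread is comparable with the Bayesian width
  (the posterior always contains the count likelihood). The doubled
  Cramér–Rao width and the resampled 2 sd agree to a few percent (tested
  at 10%).

## Synthetic data: what it does and does not emulate

The generator emulates the *statistical* structure of real pellet
measurements: Gaussian count distributions with a few-percent CV from
pellet-to-pellet sensitivity variation (multiplicative, CV-parameterised —
deliberately not Poisson, since reader-scaled TL counts at ~10⁶ have far
more than Poisson spread), batch-mean readouts per card position (default
10 pellets per position), and forward exposures through the calibration
map, with the covered-position beta response expressed as a covered `k_β`
(what a calibration campaign actually measures) rather than an explicit
`t × sensitivity` product. Virtual calibration campaigns for hypothetical
sources write standard calibration CSVs flagged `virtual`.

It does **not** emulate glow-curve shape, energy dependence of the
response, fading/annealing, backgrounds, or dose nonlinearity. Passing
recovery tests therefore demonstrates the correctness of the estimation
chain under the stated statistical model, not robustness to those physical
effects.

Problem sizes used by the bundled validation and tests: five scenarios ×
three options × two components for the engine cross-checks; 200 random
exposures at 2% pellet noise (10 pellets per position, component doses
drawn from 0.3–1.0 mSv) for parameter recovery; 10⁵ Monte Carlo iterations
throughout.

## Known limitations

* The Gaussian likelihood/prior assumption is checked only through the
  R² ≥ 0.85 shape criterion on binned batch histograms; small batches
  (≈150 pellets) fail that criterion in a noticeable fraction of random
  realisations even when truly Gaussian, so the flag is advisory.
* The Cramér–Rao value is a lower bound used as the reported width, per the
  method's convention; it is exact only for log-quadratic posteriors.
* Posteriors are gridded, not sampled: adequate for this 1-D dose problem,
  not a general MCMC replacement; non-Gaussian priors are out of scope.
* Only the two-equation covered/uncovered system is solved; multi-filter
  least-squares unfolding is out of scope.
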