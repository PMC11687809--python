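# Methods

## Model and hypotheses

The null model is the geometric distribution on {1, 2, …},
`p_i(θ) = (1−θ)^{i−1} θ`, with unknown success probability θ ∈ (0, 1)
estimated by maximum likelihood, `θ̂ = 1/x̄`. Boundary estimates are treated
as errors, never clamped: a sample in which every observation equals 1 gives
`θ̂ = 1`, where the test statistics are undefined
(`DegenerateSampleError`). The delta-method (Wald) interval
`θ̂ ± z · θ̂ √((1−θ̂)/n)` is reported alongside; it is an approximation
whose coverage is only asymptotic, and it is presentation, not part of the
test decision.

## Test statistics

Data enter as a frequency table over cells `1..k`, with `k` always defined
by the data (last non-empty cell). Interior empty cells are retained — they
carry cumulative-deviation terms — while cells beyond `k` are excluded.
Cumulative deviations are `Z_j = S_j − n·H_j` with `S` the running count sum
and `H` the closed-form geometric CDF; using the closed form rather than a
pmf cumsum avoids cancellation in `Z` at large `k`. The statistics are

- Watson: `W² = n⁻¹ Σ Z_i² p_i`,
- Anderson–Darling: `A² = n⁻¹ Σ Z_i² p_i / (H_i (1−H_i))`.

Counts may be fractional at this layer so that exact-fit fixtures
(`o_i = n p_i`) can exercise the zero of both statistics; integrality is a
property of real data, not a mathematical requirement.

All `1 − H_i` factors are computed as `(1−θ)^i` directly. `H_i` saturates
to 1.0 in double precision near `i ≈ 53/log2(1/(1−θ))`, which is *inside*
the truncation ranges used for the asymptotics; the survival form keeps the
A² weights finite there.

## Asymptotic null distribution

Cell counts are multinomial, so `(o − e)/√n` has limiting covariance
`Σ₀ = D − PPᵀ` and the cumulative deviations `Z = R(o − e)` have covariance
`Σ = RΣ₀Rᵀ` (equivalently `min(H_i,H_j) − H_iH_j`; both constructions are
implemented and cross-checked). Estimating θ subtracts the rank-one term
`bbᵀ/(bᵀD⁻¹b)` from `Σ₀`, with `b_j = dp_j/dθ = (1−θ)^{j−2}(1−jθ)` in
closed form; `bᵀD⁻¹b` is the truncated Fisher information and converges to
`1/(θ²(1−θ))`. Each statistic is `ZᵀVZ/n` with diagonal weight `V = D`
(W²) or `V = DG⁻¹` (A², `G_ii = H_i(1−H_i)`), so the limit law is
`Σ λ_i ν_i²` with `λ_i` the eigenvalues of `V^{1/2}ΣV^{1/2}`.

Numerics: the matrix is explicitly symmetrised and passed to a symmetric
eigensolver. Eigenvalues below `1e-10·λ_max` (including the numerically
zero one produced by the rank-one MLE correction, and O(1e-9) round-off
negatives from the `k×k` partial-sum products at `k` in the hundreds) are
clipped to zero; if clipping would move more than `1e-6` of the trace the
construction is declared inconsistent and an error is raised instead.

### Truncation

The infinite support is cut at `k` chosen in two stages: a floor ensuring
residual mass `(1−θ)^k < 1e-10`, then doubling until the target upper
quantile of the induced law changes by less than `5e-5` (`choose_truncation`).
The tolerance is this package's choice of "converged". Inside `gof_test`,
continuous p-values use a fixed truncation of twice the mass floor — the
convergence checks run during table generation show the doubled floor is
already converged at every tabulated θ, and this keeps per-test cost flat.

## Tail probabilities of Σ λ_i ν_i²

Evaluated by numerical inversion of the characteristic function (Imhof's
formula). The oscillatory integral is truncated where the envelope
`1/(u·Π(1+λ_i²u²)^{1/4})` makes the remainder provably below `1e-9`
(using the alternating-series half-period bound, which is what keeps the
truncation finite when the eigenvalues span many orders of magnitude), and
integrated by composite Gauss–Legendre quadrature with panels no wider than
one phase half-period, doubling the panel count until successive estimates
agree to `1e-8`. Weights below `1e-9·λ_max` are dropped first: they
perturb tail probabilities by under `1e-7` but stretch the integration
range enormously. Two degenerate regimes bypass quadrature exactly: `q`
negligible relative to `Σλ` (tail = 1) and all-equal weights
(`λ·χ²_m`, evaluated by the χ² survival function). Quantiles come from
bracketing plus Brent root search (`xtol = 1e-10`).

Accuracy is verified three ways in the suite: against χ²₁ and exponential
closed forms (≤1e-5), against a seeded Monte Carlo oracle (3 binomial
standard errors at 10⁶ draws), and against the published percentage-point
grids (every cell within ±0.01, most within ±0.001).

## Critical-value tables and p-values

`generate_table` rebuilds the upper-tail percentage points over a θ grid at
the seven conventional levels (0.50…0.01); the packaged grids (one per
statistic, estimated-θ mode, θ = 0.05…0.95) regenerate in ≈2.5 minutes on
one CPU and ship as CSV with shortest-repr floats (bit-exact round trip via
`float_precision="round_trip"`). Bracketed p-values interpolate critical
values linearly in θ between adjacent grid rows — nearest-row lookup gives
identical brackets on the packaged examples, so the choice is immaterial
there — and the continuous p-value, computed from a fresh spectrum at θ̂,
always falls inside the bracket. The continuous value is the recommended
path; the bracket is kept for classical table-style reporting.

## Monte Carlo validation

`simulate_statistics` draws geometric samples by inverse CDF
(`1 + ⌊ln(1−U)/ln(1−θ)⌋`), re-estimates θ̂ per replicate, and evaluates both
statistics in a fully vectorised batch (25 000 replicates of n = 100 run in
well under a second). Replicates that draw all ones — possible at large θ
and small n — are redrawn and counted, since θ̂ = 1 leaves the statistics
undefined; at the configurations validated here the count is zero or
negligible, but the diagnostic is always reported. Empirical percentage
points use linear order-statistic (type-7) quantiles; at 25 000 replicates
the quantile convention is far inside the Monte Carlo error. The default
replicate count is 25 000; a handful of unit tests use 5 000 with widened
tolerances for speed.

## Run extraction

`runs_from_series` groups consecutive same-sign first differences of a
numeric series into maximal runs. Tied consecutive values have no direction;
the treatment is exposed as a required `zero_policy` (`error`/`break`/`drop`)
with no default, because any silent choice would change the run-length
distribution. Under `break`, adjacent runs need not alternate in direction.

## What the synthetic data does and does not show

The simulation layer generates *exactly* iid geometric data, so passing
Monte Carlo and type-I calibration checks demonstrates correctness of the
statistics, the asymptotics and the decision rule under the null — not
robustness of the geometric model to real-world features such as serial
dependence of market moves, regime changes in θ, or tie handling in price
series (the example run-length tables come from real indices, but enter the
package as fixed frequency tables). Power against specific alternatives is
not studied here.

## Known limitations

- The characteristic-function inversion is designed for the spectra this
  problem produces (at least three weights of comparable magnitude after
  cleaning); quadratic forms that are essentially one or two unequal weights
  are rejected rather than evaluated inaccurately (exact equal-weight cases
  are dispatched to the χ² form).
- The Wald interval for θ is not part of the test and can be poor at small
  n or extreme θ.
- Asymptotic critical values are accurate for moderately large n (the
  finite-sample simulations show close agreement by n ≈ 100 for mid-range
  θ); for small n, use `geomgof simulate` to generate empirical points.
- `mle_theta`'s x̄ is the truncated-sample mean; the estimator assumes the
  data really are counts on {1, 2, …} with no censoring.
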