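# Methods

## Problem and model

Two correlations r₁ᵧ = corr(X₁, Y) and r₂ᵧ = corr(X₂, Y) computed on the
same sample of n triplets are *dependent with overlapping variables*: they
share Y. Testing H₀: ρ₁ᵧ = ρ₂ᵧ therefore needs the sampling covariance of
the two correlations, which every test here builds — directly or on the
Fisher-z scale — from the third sample correlation r₁₂ and the determinant
of the 3×3 correlation matrix,

    R = 1 − r₁ᵧ² − r₂ᵧ² − r₁₂² + 2 r₁ᵧ r₂ᵧ r₁₂.

The reference model is the trivariate normal, which exists (non-degenerate)
exactly when the population analogue of R is strictly positive. That
constraint defines the feasibility region handled by `depcorr.feasibility`:
at fixed (ρ₁₂, ρ₁ᵧ), admissible ρ₂ᵧ form the open interval
ρ₁₂ρ₁ᵧ ± √((1−ρ₁₂²)(1−ρ₁ᵧ²)); along the null diagonal ρ₁ᵧ = ρ₂ᵧ = ρ the
bound is |ρ| < √((1+ρ₁₂)/2). Boundary cases (determinant zero) are treated
as infeasible throughout.

## The ten tests and their numerical conventions

`depcorr.stat_tests` implements nine statistic-form tests (Pearson–Filon,
Olkin, Hotelling, standard Williams, Hendrickson–Stanley–Hills on the raw
correlation scale; Dunn–Clark, Steiger, Hittner–May–Silver,
Meng–Rosenthal–Rubin on the Fisher-z scale) and Zou's interval for
ρ₁ᵧ − ρ₂ᵧ. Conventions that matter:

- **Undefined statistics.** Each statistic divides by a square root of a
  data-dependent radicand. A radicand ≤ 10⁻¹² is treated as non-positive
  and the statistic is reported as NaN with `applicable=False` — an
  explicit value, not an exception, so simulation sweeps can count the
  events. The guard band (rather than a strict ≤ 0 test) exists because
  radicands within rounding error of zero produce overflow artifacts
  without being statistically meaningful; exact-boundary samples are
  measure-zero.
- **Decisions.** Two-sided p = 2(1 − CDF(|stat|)) under the named
  reference (standard normal, or Student t with n − 3 df for Hotelling,
  Williams, HSH); rejection is recorded per tail at α/2 each. Zou's test
  has no p-value: it rejects iff L > 0 (upper) or U < 0 (lower). An
  undefined statistic or interval never rejects.
- **Meng–Rosenthal–Rubin.** The factor f = (1−r₁₂)/(2(1−r²̄)) is used as
  computed by default; the statistic is then undefined when f ≥ 1/r²̄
  (h ≤ 0), which happens inside the feasibility ellipse only when
  r₁₂ ≤ 2 − √5 ≈ −0.236 (the mean squared correlation can reach
  2/(3 − r₁₂) there only for such r₁₂). The original prescription
  f := min(f, 1) is available via `cap_f=True` and makes the statistic
  computable on the whole cube.
- **Hittner–May–Silver.** The pooled quantity is implemented as printed in
  the comparative study this package characterises:
  r̄_z = exp(2Z̄ − 1)/exp(2Z̄ + 1) with Z̄ the mean Fisher z. As written this
  reduces to the constant e⁻² ≈ 0.1353 whatever the data. That constant is
  what produces the test's two signature behaviours — cube-wide
  applicability (the pooled covariance stays below 1 for every r₁₂ < 1)
  and gross liberality once ρ₁₂ is large and positive and the common
  correlation moves away from zero, with accuracy retained near ρ = 0
  where the covariance term r₁₂ is asymptotically correct. Had the pooling
  been the exact back-transform tanh(Z̄), the statistic would be
  numerically indistinguishable from Steiger's (accurate, and *not*
  defined on the whole cube); reproducing the documented behaviour of the
  test as studied requires the printed form, so that is the
  implementation. The test is flagged "not recommended" either way.
- **Sign-flip for unsigned comparisons.** `flip_for_unsigned` negates X₂:
  (r₁ᵧ, r₂ᵧ, r₁₂) → (r₁ᵧ, −r₂ᵧ, −r₁₂). The transform is an involution, and
  which variable is negated only flips the sign of the resulting
  statistic, not its magnitude or p-value.
- The Zou covariance c_Z and the Dunn–Clark covariance c_DC are two
  printed groupings of the same expression; a test asserts the identity.

Every statistic is validated two ways: against an independently coded
scalar transcription of its classical algebraic form on 1,000 random
feasible triplets (relative agreement 10⁻¹⁰), and against 50-digit sympy
arithmetic at a reference point. The standard Williams implementation
additionally reproduces eight published worked-example values to the
printed four decimals.

## Data generation

`depcorr.datagen` draws n triplets with a prescribed correlation matrix
(Cholesky factor applied to iid standard normals) and maps them to
non-normal marginals:

- **Beta (incl. uniform = Beta(1,1)):** inverse-CDF transform
  X = F⁻¹(Φ(Z); a, b), separately parameterised per variable. Marginals
  are exact; correlations of the generating normals are *approximately*
  preserved — for uniform marginals the transformed correlation is exactly
  (6/π) asin(ρ/2), a bias that vanishes at ρ ∈ {−1, 0, 1} and peaks at
  about 0.018 in between (0.0174 at ρ = .5). The bias is measured in
  tests, not corrected, matching the design being emulated.
- **Lognormal(0,1):** X = exp(Z). The transformed correlation is
  (e^ρ − 1)/(e − 1), inverted in closed form to pre-adjust the generating
  matrix; attainable targets are bounded below by −1/e ≈ −0.3679, and the
  pre-adjusted (normal-scale) matrix must itself be positive definite,
  which trims the target range further. Sweep points violating either
  constraint are skipped with a logged warning.
- **Contaminated normal:** with probability 1 − p the standard trivariate
  normal, with probability p (default .1) the same correlation matrix
  scaled to common variance v ∈ {2, 4, 10}; the mixture's correlation
  matrix is exactly the target. Marginal kurtosis is
  3(1 − p + p v²)/(1 − p + p v)² (3.223, 4.438, 9.058 for the three v).

`analytic_moments` returns closed-form skewness and non-excess kurtosis
per marginal (scipy's beta/lognorm machinery; the mixture formula above).
The lognormal values are skewness (e+2)√(e−1) ≈ 6.185 and kurtosis
e⁴ + 2e³ + 3e² − 3 ≈ 113.936; empirical moments of lognormal samples
converge extremely slowly because of the tail weight, so tests hold the
lognormal only to loose tolerances at desk sample sizes.

## Monte Carlo engine

`depcorr.simulate` evaluates conditions = (population correlations,
sample size, marginals). Per condition it draws `reps` samples, computes
the three sample correlations of each (vectorised over replications),
applies each requested test two-sidedly at α, and records per-tail
rejection counts plus undefined counts. **Undefined statistics count as
non-rejections with denominator reps** — the proportion-out-of-N rule —
but the counts are reported so the choice is auditable.

Null sweeps walk the diagonal ρ₁ᵧ = ρ₂ᵧ in steps of 0.02 (default),
keeping |ρ| ≤ √((1+ρ₁₂)/2) − step/2; the half-step margin avoids
near-singular matrices. Power sweeps use the symmetric lattice: from
diagonal reference points (−0.96 … 0.96, step 0.04) step k·0.04 down in
ρ₁ᵧ and up in ρ₂ᵧ, keeping feasible points above the diagonal (the tests
are antisymmetric, so below-diagonal points are redundant). Each lattice
point keeps its reference as the mean correlation while |Δρ| grows, which
is what lets power be summarised against |Δρ| at fixed mean.

Randomness: one master seed; condition i uses
`SeedSequence(master, spawn_key=(i,))`, so outcome tables are independent
of evaluation order and any condition can be reproduced alone. Identical
config + seed gives byte-identical output CSVs.

**Scales.** The engine defaults to 2×10⁴ replications (binomial SE at
.05 ≈ 0.0015) and the package's own acceptance checks run at
10⁴–10⁵ replications per condition — sizes chosen so the whole suite runs
in about a minute on one core while leaving the ±3-SE acceptance bands
(anchored at 2×10⁴, [.0454, .0546] around .05) wide relative to estimator
noise. Full-scale sweeps (5×10⁵ accuracy / 2×10⁵ power over the complete
ρ₁₂ × diagonal × n grid) are supported through `SimulationConfig` but are
cluster-scale by design.

## What the generators do and do not emulate

The synthetic data match the study conditions exactly: prescribed
correlation matrices, exact beta/lognormal marginals, exact mixture
contamination. They do not emulate features of real data such as
measurement error, ordinal scales, missingness mechanisms, order
restrictions between variables, or non-normality specified via moments
rather than distributional form. Passing tests therefore certify the
implementations and the documented behaviour of the tests under these
specific distributions — not robustness to every non-normality
encountered in practice, which the robustness results themselves show to
be unattainable in general.

## Known limitations

- Only the two-variables-vs-one overlapping design: no omnibus k > 2
  tests, no independent-correlation or non-overlapping comparisons, no
  robust/rank-based alternatives.
- Attainable-correlation bounds for arbitrary non-normal marginals (which
  can shrink the space of true nulls drastically, e.g. to (−.640, .862)
  for a lognormal paired with a chi-square) are documented here but not
  computed by the package.
- The feasibility machinery is specific to the trivariate case; nothing
  generalises to larger correlation matrices.
- Complete-case handling only in `correlations_from_data` (the tests
  assume one common n for all three correlations); the dropped-row count
  is reported.
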