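# depcorr

Statistical tests for comparing two **dependent correlations with
overlapping variables**: given one sample of *n* observations of
(X₁, X₂, Y), are X₁ and X₂ equally correlated with Y?

The common malpractice is to test each correlation separately against zero
and compare the verdicts (or the p-values); with n = 120 and α = .05 an
r of .180 is "significant" while .179 is not, yet that says nothing about
whether ρ₁ᵧ and ρ₂ᵧ differ. `depcorr` implements the ten classical tests of
H₀: ρ₁ᵧ = ρ₂ᵧ, the feasibility geometry of trivariate correlation matrices,
correlated non-normal data generators, and a Monte Carlo engine that
measures each test's Type I error, power, applicability and robustness. It
is aimed at applied researchers comparing predictors (psychometrics,
epidemiology, any correlational field) and at methodologists studying the
tests themselves.

## The tests

All tests consume the three sample Pearson correlations r₁ᵧ = corr(X₁, Y),
r₂ᵧ = corr(X₂, Y), r₁₂ = corr(X₁, X₂) and the sample size n. The
recommended default is the **standard Williams t**,

```
t_W = (r₁ᵧ − r₂ᵧ) √[ (n−3)(1 + r₁₂) / (2R + r̄² ((n−3)/(n−1)) (1 − r₁₂)³) ],
R   = 1 − r₁ᵧ² − r₂ᵧ² − r₁₂² + 2 r₁ᵧ r₂ᵧ r₁₂,     r̄ = (r₁ᵧ + r₂ᵧ)/2,
```

referred to Student's t with n − 3 df. Also provided: Pearson–Filon,
Olkin, Hotelling, Hendrickson–Stanley–Hills (all statistic-form), the
Fisher-z based Dunn–Clark, Steiger, Hittner–May–Silver and
Meng–Rosenthal–Rubin z tests, and Zou's confidence interval for
ρ₁ᵧ − ρ₂ᵧ (reject iff L > 0 or U < 0). Every statistic involves a square
root whose radicand can go non-positive for some samples; such cases are
reported as *undefined* (NaN, `applicable=False`), never raised, so
simulations can count them. Five of the tests (Williams, Dunn–Clark,
Steiger, Meng–Rosenthal–Rubin without the f ≤ 1 cap, Zou) hold the nominal
size across the feasible parameter space under normality; the other five
are computed but labelled *not recommended (accuracy)*.

Comparisons of *unsigned* strength (H₀: ρ₁ᵧ = −ρ₂ᵧ) use the sign-flip
device (`--unsigned` / `flip_for_unsigned`): replace X₂ by −X₂, i.e. test
(r₁ᵧ, −r₂ᵧ, −r₁₂, n).

## Worked example

Right- and left-hand 2D–4D digit ratios (X₁, X₂) versus Java programming
grade (Y) in n = 73 students: r₁ᵧ = −.22 (significant against zero),
r₂ᵧ = −.13 (not significant), r₁₂ = .46.

```
$ depcorr test --test williams --r1y -0.22 --r2y -0.13 --r12 0.46 --n 73
      williams  stat = -0.7420 (df = 70)  p = 0.461  reject = False
```

Despite the "one significant, one not" pattern, there is no evidence that
the two digit ratios are differently correlated with the grade
(t_W = −0.742, p = .461). `--all` prints every test; note how the five
dependable tests agree closely while the inadvisable ones are flagged:

```
$ depcorr test --all --r1y -0.22 --r2y -0.13 --r12 0.46 --n 73
 pearson_filon  stat = -0.7567  p = 0.449  reject = False  [not recommended (accuracy)]
         olkin  stat = -0.7567  p = 0.449  reject = False  [not recommended (accuracy)]
     hotelling  stat = -0.7432 (df = 70)  p = 0.460  reject = False  [not recommended (accuracy)]
      williams  stat = -0.7420 (df = 70)  p = 0.461  reject = False
           hsh  stat = -0.7432 (df = 70)  p = 0.460  reject = False  [not recommended (accuracy)]
    dunn_clark  stat = -0.7402  p = 0.459  reject = False
       steiger  stat = -0.7397  p = 0.460  reject = False
           hms  stat = -0.7430  p = 0.457  reject = False  [not recommended (accuracy)]
           mrr  stat = -0.7391  p = 0.460  reject = False
           zou  CI = (-0.3228,  0.1466)  reject = False
```

Other entry points:

```
$ depcorr feasible --rho12 0.5 --rho1y 0          # admissible rho2y in (-0.8660, 0.8660)
$ depcorr from-data table.csv --cols X1,X2,Y      # correlations from raw data, then test
$ depcorr generate --dist mixture:10 --rho12 0 --rho1y 0 --rho2y 0 --n 1000 --seed 7 --out s.csv
$ depcorr simulate --config cfg.yaml --mode type1 --out rates.csv
$ depcorr moments --dist 'beta:2,5'               # skewness = 0.596  kurtosis = 2.880
```

The same functionality is a library: `CorrelationTriplet`,
`evaluate_test`, `zou_interval`, `applicability_mask`, `is_feasible`,
`sample_triplets`, `type1_sweep`, `power_sweep`, `robustness_sweep`.

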