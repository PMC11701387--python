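"""Correlated trivariate data generators: normal, beta, lognormal, mixture.

All non-normal generators start from a trivariate standard normal sample
with a prescribed correlation matrix and either transform the marginals by
the inverse-CDF method (beta, lognormal) or contaminate the sample with a
same-correlation, larger-variance component (normal mixture).  This keeps
the dependence structure tied to the generating correlation matrix: the
mixture preserves it exactly, the lognormal transform changes it in closed
form (so targets can be hit by pre-adjusting the normal correlations), and
the beta transform preserves it nearly exactly for the shapes used here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .feasibility import PopulationCorrelations, is_feasible

__all__ = [
    "DistributionSpec",
    "TrivariateSample",
    "sample_trivariate_normal",
    "transform_beta",
    "transform_lognormal",
    "lognormal_correlation",
    "lognormal_base_correlation",
    "sample_mixture",
    "sample_triplets",
    "analytic_moments",
]

_FAMILIES = ("normal", "beta", "lognormal", "mixture")

#: Correlations between lognormal variables cannot go below -1/e.
LOGNORMAL_CORRELATION_FLOOR = -float(np.exp(-1.0))


@dataclass(frozen=True)
class DistributionSpec:
    """Marginal distribution family and parameters for one variable.

    family "normal" and "lognormal" take no parameters; "beta" takes shapes
    ``a, b > 0`` (a = b = 1 is the uniform); "mixture" is the contaminated
    normal drawing from N(0, 1) with probability 1 - mix_p and from a
    normal with variance ``mix_var`` otherwise (defaults: mix_p = 0.1).
    """

    family: str
    a: float | None = None
    b: float | None = None
    mix_p: float | None = None
    mix_var: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.family == "beta":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ValueError("beta family requires shapes a > 0 and b > 0")
        if self.family == "mixture":
            if self.mix_p is None:
                object.__setattr__(self, "mix_p", 0.1)
            if self.mix_var is None or self.mix_var <= 1.0:
                raise ValueError("mixture family requires mix_var > 1")
            if not 0.0 < self.mix_p < 1.0:
                raise ValueError("mixture family requires mix_p in (0, 1)")

    @classmethod
    def normal(cls) -> "DistributionSpec":
        return cls("normal")

    @classmethod
    def uniform(cls) -> "DistributionSpec":
        return cls("beta", a=1.0, b=1.0)

    @classmethod
    def beta(cls, a: float, b: float) -> "DistributionSpec":
        return cls("beta", a=a, b=b)

    @classmethod
    def lognormal(cls) -> "DistributionSpec":
        return cls("lognormal")

    @classmethod
    def mixture(cls, mix_var: float, mix_p: float = 0.1) -> "DistributionSpec":
        return cls("mixture", mix_p=mix_p, mix_var=mix_var)


@dataclass(frozen=True)
class TrivariateSample:
    """n observed triplets of (X1, X2, Y) with their generating targets."""

    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray
    seed: object
    target: PopulationCorrelations

    def __post_init__(self) -> None:
        if not (len(self.x1) == len(self.x2) == len(self.y)):
            raise ValueError("x1, x2, y must have equal length")
        if len(self.x1) < 4:
            raise ValueError("need n >= 4 observations")

    @property
    def n(self) -> int:
        return len(self.x1)

    def as_array(self) -> np.ndarray:
        """Stack as an (n, 3) array in column order (X1, X2, Y)."""
        return np.column_stack([self.x1, self.x2, self.y])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_trivariate_normal(
    p: PopulationCorrelations, n: int, seed
) -> TrivariateSample:
    """n iid triplets from the standard trivariate normal with correlations p.

    Independent standard normals are mapped through the Cholesky factor of
    the correlation matrix; deterministic given the seed.
    """
    if not is_feasible(p):
        raise ValueError(f"correlations {p} are not positive definite")
    root = np.linalg.cholesky(p.matrix)
    z = _rng(seed).standard_normal((n, 3)) @ root.T
    return TrivariateSample(x1=z[:, 0], x2=z[:, 1], y=z[:, 2], seed=seed, target=p)


def transform_beta(
    s: TrivariateSample, specs: tuple[DistributionSpec, DistributionSpec, DistributionSpec]
) -> TrivariateSample:
    """Inverse-CDF transform of a normal sample to beta marginals.

    Each variable becomes F^-1(Phi(Z); a, b) with its own shapes, so the
    marginals are exactly Beta(a, b) while the correlations of the
    generating normals are approximately preserved.
    """
    if len(specs) != 3 or any(spec.family != "beta" for spec in specs):
        raise ValueError("transform_beta requires three beta DistributionSpecs")
    cols = [
        stats.beta.ppf(stats.norm.cdf(col), spec.a, spec.b)
        for col, spec in zip((s.x1, s.x2, s.y), specs)
    ]
    return replace(s, x1=cols[0], x2=cols[1], y=cols[2])


def lognormal_correlation(rho_normal):
    """Correlation of exp(Z1), exp(Z2) when corr(Z1, Z2) = rho_normal.

    Equals (exp(rho) - 1)/(e - 1); its range over rho in [-1, 1] is
    [-1/e, 1], which is why strongly negative lognormal correlations are
    unattainable.
    """
    rho_normal = np.asarray(rho_normal, dtype=float)
    out = np.expm1(rho_normal) / (np.e - 1.0)
    return float(out) if out.ndim == 0 else out


def lognormal_base_correlation(rho_target):
    """Normal-scale correlation producing a given lognormal correlation.

    Inverts :func:`lognormal_correlation`: rho = ln(1 + rho_target (e - 1)).
    Raises for targets at or below the floor -1/e.
    """
    rho_target = np.asarray(rho_target, dtype=float)
    if np.any(rho_target <= LOGNORMAL_CORRELATION_FLOOR):
        raise ValueError(
            "lognormal correlations below -exp(-1) ~ -0.3679 are unattainable"
        )
    out = np.log1p(rho_target * (np.e - 1.0))
    return float(out) if out.ndim == 0 else out


def transform_lognormal(s: TrivariateSample) -> TrivariateSample:
    """Exponentiate a standard normal sample to Lognormal(0, 1) marginals.

    To hit target correlations after the transform, generate the normal
    sample at :func:`lognormal_base_correlation` of the targets.
    """
    return replace(s, x1=np.exp(s.x1), x2=np.exp(s.x2), y=np.exp(s.y))


def sample_mixture(
    p: PopulationCorrelations, v: float, mix_p: float, n: int, seed
) -> TrivariateSample:
    """Contaminated trivariate normal with correlation matrix p.

    Each triplet comes from the standard trivariate normal with probability
    1 - mix_p and from the same-correlation normal with common variance v
    (covariance v * P) otherwise; the mixture's correlation matrix is
    therefore exactly P.
    """
    if v <= 0:
        raise ValueError("mixture variance v must be positive")
    if not 0.0 < mix_p < 1.0:
        raise ValueError("mix_p must lie in (0, 1)")
    if not is_feasible(p):
        raise ValueError(f"correlations {p} are not positive definite")
    rng = _rng(seed)
    root = np.linalg.cholesky(p.matrix)
    z = rng.standard_normal((n, 3)) @ root.T
    contaminated = rng.random(n) < mix_p
    z[contaminated] *= np.sqrt(v)
    return TrivariateSample(x1=z[:, 0], x2=z[:, 1], y=z[:, 2], seed=seed, target=p)


def sample_triplets(
    p: PopulationCorrelations,
    n: int,
    specs: tuple[DistributionSpec, DistributionSpec, DistributionSpec],
    seed,
) -> TrivariateSample:
    """Draw n triplets with marginals per spec and target correlations p.

    Dispatches on family: plain normal sampling; beta via inverse-CDF of a
    normal sample at the target correlations (preservation is approximate
    but near-exact); lognormal via exponentiation of a normal sample at the
    pre-adjusted base correlations; mixture via contamination.  Lognormal
    and mixture must apply to all three variables; beta/normal specs may be
    mixed freely per variable.
    """
    families = [spec.family for spec in specs]
    if "mixture" in families:
        if len(set((s.family, s.mix_p, s.mix_var) for s in specs)) != 1:
            raise ValueError("mixture sampling requires one shared spec for all variables")
        return sample_mixture(p, specs[0].mix_var, specs[0].mix_p, n, seed)
    if "lognormal" in families:
        if set(families) != {"lognormal"}:
            raise ValueError("lognormal sampling requires all three variables lognormal")
        base = PopulationCorrelations(
            rho12=lognormal_base_correlation(p.rho12),
            rho1y=lognormal_base_correlation(p.rho1y),
            rho2y=lognormal_base_correlation(p.rho2y),
        )
        return replace(transform_lognormal(sample_trivariate_normal(base, n, seed)), target=p)
    normal = sample_trivariate_normal(p, n, seed)
    if set(families) == {"normal"}:
        return normal
    # per-variable beta (or identity for normal) transforms
    cols = []
    for col, spec in zip((normal.x1, normal.x2, normal.y), specs):
        if spec.family == "normal":
            cols.append(col)
        else:
            cols.append(stats.beta.ppf(stats.norm.cdf(col), spec.a, spec.b))
    return replace(normal, x1=cols[0], x2=cols[1], y=cols[2])


def analytic_moments(spec: DistributionSpec) -> tuple[float, float]:
    """Closed-form skewness and (non-excess) kurtosis of a marginal.

    Beta and lognormal values come from scipy's distribution machinery;
    the contaminated normal has skewness 0 and kurtosis
    3 (1 - p + p v^2) / (1 - p + p v)^2.
    """
    if spec.family == "normal":
        return 0.0, 3.0
    if spec.family == "beta":
        skew, excess = stats.beta.stats(spec.a, spec.b, moments="sk")
        return float(skew), float(excess) + 3.0
    if spec.family == "lognormal":
        skew, excess = stats.lognorm.stats(1.0, moments="sk")
        return float(skew), float(excess) + 3.0
    p, v = spec.mix_p, spec.mix_var
    kurt = 3.0 * (1.0 - p + p * v**2) / (1.0 - p + p * v) ** 2
    return 0.0, float(kurt)
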