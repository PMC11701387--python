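"""Ten tests for the equality of two dependent correlations sharing a variable.

All tests address H0: rho1y = rho2y from the sample correlations r1y =
corr(X1, Y), r2y = corr(X2, Y), r12 = corr(X1, X2) and the sample size n.
Nine come as a test statistic referred to the standard normal (Pearson-Filon,
Olkin, Dunn-Clark, Steiger, Hittner-May-Silver, Meng-Rosenthal-Rubin) or to
Student's t with n - 3 df (Hotelling, standard Williams,
Hendrickson-Stanley-Hills); the tenth (Zou) is a confidence interval for
rho1y - rho2y that rejects when the interval excludes zero.

Every statistic involves a square root whose radicand depends on the sample
correlations and is not guaranteed positive; when it is not, the statistic
is undefined for that sample.  Undefined values are represented by NaN
(never an exception) so that simulations can count them.

The module-level test functions accept either a :class:`CorrelationTriplet`
or broadcastable arrays ``(r1y, r2y, r12, n)``; the array form is what the
Monte Carlo engine uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALL_TESTS",
    "RECOMMENDED_TESTS",
    "RADICAND_TOL",
    "CorrelationTriplet",
    "TestResult",
    "ZouInterval",
    "fisher_z",
    "inverse_fisher_z",
    "correlations_from_data",
    "pearson_filon_z",
    "olkin_z",
    "hotelling_t",
    "williams_t",
    "hsh_t",
    "dunn_clark_z",
    "steiger_z",
    "hms_z",
    "mrr_z",
    "zou_interval",
    "zou_bounds",
    "statistic",
    "evaluate_test",
    "flip_for_unsigned",
    "applicability_mask",
]

#: Names of the ten tests, in presentation order.
ALL_TESTS = (
    "pearson_filon",
    "olkin",
    "hotelling",
    "williams",
    "hsh",
    "dunn_clark",
    "steiger",
    "hms",
    "mrr",
    "zou",
)

#: The five tests with acceptable Type I error across the parameter space,
#: in order of preference (standard Williams first).
RECOMMENDED_TESTS = ("williams", "dunn_clark", "steiger", "mrr", "zou")

#: Tests whose reference distribution is Student's t with n - 3 df.
_STUDENT_T_TESTS = frozenset({"hotelling", "williams", "hsh"})

#: Radicands at or below this are treated as undefined: boundary samples are
#: measure-zero and values this small only produce overflow artifacts.
RADICAND_TOL = 1e-12


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CorrelationTriplet:
    """Sample correlations (r1y, r2y, r12) and the common sample size n."""

    r1y: float
    r2y: float
    r12: float
    n: int

    def __post_init__(self) -> None:
        for name in ("r1y", "r2y", "r12"):
            value = getattr(self, name)
            if not -1.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {value}")
        if int(self.n) != self.n or self.n < 4:
            raise ValueError(f"n must be an integer >= 4, got {self.n}")
        object.__setattr__(self, "n", int(self.n))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test applied to one correlation triplet.

    ``statistic`` and ``p_two_sided`` are NaN when the test is undefined for
    the sample (``applicable`` is then False and neither tail rejects).  For
    the Zou test ``p_two_sided`` is NaN by construction and the decision
    comes from the interval, reported in ``interval``.
    """

    test_name: str
    statistic: float
    reference: str  # "standard_normal" or "student_t"
    df: int | None
    p_two_sided: float
    reject_lower: bool
    reject_upper: bool
    applicable: bool
    alpha: float
    interval: "ZouInterval | None" = None

    @property
    def reject(self) -> bool:
        return self.reject_lower or self.reject_upper


@dataclass(frozen=True)
class ZouInterval:
    """Confidence interval (L, U) for rho1y - rho2y with its building blocks.

    l_i/u_i are the back-transformed per-correlation confidence limits and
    l_i_star/u_i_star their Fisher-z scale counterparts.  The null is
    rejected iff L > 0 or U < 0.
    """

    L: float
    U: float
    l1: float
    l2: float
    u1: float
    u2: float
    l1_star: float
    l2_star: float
    u1_star: float
    u2_star: float
    z_crit: float
    alpha: float

    @property
    def applicable(self) -> bool:
        return bool(np.isfinite(self.L) and np.isfinite(self.U))


# ---------------------------------------------------------------------------
# building blocks


def fisher_z(r):
    """Fisher's variance-stabilizing transformation z = atanh(r).

    Strictly increasing and odd; requires |r| < 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z`: r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def correlations_from_data(table, columns=None):
    """Pairwise Pearson correlations of a 3-column table.

    Parameters
    ----------
    table : DataFrame or array-like of shape (n, 3)
        Observations of (X1, X2, Y), in that column order unless ``columns``
        names the three columns of a DataFrame.
    columns : sequence of three labels, optional
        Column labels (X1, X2, Y) to select from a DataFrame.

    Returns
    -------
    (CorrelationTriplet, int)
        The three correlations with the complete-case sample size, and the
        number of rows dropped for missing values.
    """
    if isinstance(table, pd.DataFrame):
        frame = table[list(columns)] if columns is not None else table
        if frame.shape[1] != 3:
            raise ValueError("expected exactly 3 columns of observations")
        values = frame.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        if values.ndim != 2 or values.shape[1] != 3:
            raise ValueError("expected an (n, 3) table of observations")
    complete = ~np.isnan(values).any(axis=1)
    dropped = int((~complete).sum())
    values = values[complete]
    n = values.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 complete rows, got {n}")
    if np.any(values.std(axis=0) == 0.0):
        raise ValueError("zero-variance column: correlations are undefined")
    corr = np.corrcoef(values, rowvar=False)
    triplet = CorrelationTriplet(
        r1y=float(corr[0, 2]), r2y=float(corr[1, 2]), r12=float(corr[0, 1]), n=n
    )
    return triplet, dropped


def flip_for_unsigned(t: CorrelationTriplet) -> CorrelationTriplet:
    """Map the triplet to the one obtained by replacing X2 with -X2.

    Turns a test of H0: rho1y = rho2y into one of H0: rho1y = -rho2y, the
    device used to compare unsigned strengths of correlation when r1y and
    r2y differ in sign.  Involution: applying it twice returns the input.
    """
    return CorrelationTriplet(r1y=t.r1y, r2y=-t.r2y, r12=-t.r12, n=t.n)


def _as_arrays(t_or_r1y, r2y=None, r12=None, n=None):
    if isinstance(t_or_r1y, CorrelationTriplet):
        t = t_or_r1y
        return (
            np.asarray(t.r1y, float),
            np.asarray(t.r2y, float),
            np.asarray(t.r12, float),
            np.asarray(t.n, float),
            True,
        )
    if r2y is None or r12 is None or n is None:
        raise TypeError("pass a CorrelationTriplet or all of (r1y, r2y, r12, n)")
    return (
        np.asarray(t_or_r1y, float),
        np.asarray(r2y, float),
        np.asarray(r12, float),
        np.asarray(n, float),
        False,
    )


def _maybe_scalar(out, scalar: bool):
    out = np.asarray(out)
    return float(out) if scalar and out.ndim == 0 else out


def _det_r(r1y, r2y, r12):
    # |P| on sample correlations; also Hotelling's R.
    return 1.0 - r1y**2 - r2y**2 - r12**2 + 2.0 * r1y * r2y * r12


def _guarded_sqrt_ratio(num, radicand):
    """num * sqrt(1 / radicand) with NaN where the radicand is not positive."""
    radicand = np.asarray(radicand, dtype=float)
    bad = ~(radicand > RADICAND_TOL)
    safe = np.where(bad, 1.0, radicand)
    with np.errstate(invalid="ignore"):
        out = np.asarray(num, dtype=float) / np.sqrt(safe)
    return np.where(bad, np.nan, out)


# ---------------------------------------------------------------------------
# the ten tests


def pearson_filon_z(t_or_r1y, r2y=None, r12=None, n=None):
    """Pearson-Filon z statistic (standard normal reference)."""
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    radicand = (
        (1.0 - r1y**2) ** 2
        + (1.0 - r2y**2) ** 2
        - 2.0 * r12 * (1.0 - r1y**2 - r2y**2)
        + r1y * r2y * (1.0 - r1y**2 - r2y**2 - r12**2)
    )
    out = _guarded_sqrt_ratio((r1y - r2y) * np.sqrt(n), radicand)
    return _maybe_scalar(out, scalar)


def olkin_z(t_or_r1y, r2y=None, r12=None, n=None):
    """Olkin z statistic, in the corrected Hendrickson-Collins form."""
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    radicand = (
        (1.0 - r1y**2) ** 2
        + (1.0 - r2y**2) ** 2
        - 2.0 * r12**3
        - (2.0 * r12 - r1y * r2y) * (1.0 - r1y**2 - r2y**2 - r12**2)
    )
    out = _guarded_sqrt_ratio((r1y - r2y) * np.sqrt(n), radicand)
    return _maybe_scalar(out, scalar)


def hotelling_t(t_or_r1y, r2y=None, r12=None, n=None):
    """Hotelling t statistic (Student's t with n - 3 df).

    Defined exactly on the triplets compatible with a trivariate normal
    distribution: the radicand is 2R with R the correlation-matrix
    determinant.
    """
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    R = _det_r(r1y, r2y, r12)
    out = _guarded_sqrt_ratio((r1y - r2y) * np.sqrt((n - 3.0) * (1.0 + r12)), 2.0 * R)
    return _maybe_scalar(out, scalar)


def williams_t(t_or_r1y, r2y=None, r12=None, n=None):
    """Standard Williams t statistic (Student's t with n - 3 df).

    t = (r1y - r2y) * sqrt[(n-3)(1+r12) / (2R + rbar^2 ((n-3)/(n-1)) (1-r12)^3)]
    with rbar = (r1y + r2y)/2.  The recommended default test.
    """
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    R = _det_r(r1y, r2y, r12)
    rbar = (r1y + r2y) / 2.0
    denom = 2.0 * R + rbar**2 * ((n - 3.0) / (n - 1.0)) * (1.0 - r12) ** 3
    num = (r1y - r2y) * np.sqrt((n - 3.0) * (1.0 + r12))
    # the full radicand is (n-3)(1+r12)/denom: positive iff denom > 0
    # (for 1 + r12 > 0; at r12 = -1 the numerator vanishes anyway)
    out = _guarded_sqrt_ratio(num, denom * np.where((1.0 + r12) > 0, 1.0, np.nan))
    return _maybe_scalar(out, scalar)


def hsh_t(t_or_r1y, r2y=None, r12=None, n=None):
    """Hendrickson-Stanley-Hills t statistic (Student's t with n - 3 df).

    Hotelling's denominator plus (r1y - r2y)^2 (1 - r12)^3 / (4(n-1)), so
    |t_HSH| <= |t_H| wherever both are defined.
    """
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    R = _det_r(r1y, r2y, r12)
    denom = 2.0 * R + (r1y - r2y) ** 2 * (1.0 - r12) ** 3 / (4.0 * (n - 1.0))
    num = (r1y - r2y) * np.sqrt((n - 3.0) * (1.0 + r12))
    out = _guarded_sqrt_ratio(num, denom * np.where((1.0 + r12) > 0, 1.0, np.nan))
    return _maybe_scalar(out, scalar)


def _c_dunn_clark(r1y, r2y, r12):
    num = r12 * (1.0 - r1y**2 - r2y**2) - 0.5 * r1y * r2y * (
        1.0 - r1y**2 - r2y**2 - r12**2
    )
    return num / ((1.0 - r1y**2) * (1.0 - r2y**2))


def _c_pooled(rbar, r12):
    # Dunn-Clark covariance with both correlations replaced by a pooled value
    num = r12 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
        1.0 - 2.0 * rbar**2 - r12**2
    )
    return num / (1.0 - rbar**2) ** 2


def _fisher_diff_z(r1y, r2y, r12, n, c):
    bad = (np.abs(r1y) >= 1.0) | (np.abs(r2y) >= 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dz = np.arctanh(np.where(bad, 0.0, r1y)) - np.arctanh(np.where(bad, 0.0, r2y))
    out = _guarded_sqrt_ratio(dz * np.sqrt(n - 3.0), 2.0 - 2.0 * c)
    return np.where(bad, np.nan, out)


def dunn_clark_z(t_or_r1y, r2y=None, r12=None, n=None):
    """Dunn-Clark z statistic on Fisher-z transformed correlations."""
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    c = _c_dunn_clark(r1y, r2y, r12)
    return _maybe_scalar(_fisher_diff_z(r1y, r2y, r12, n, c), scalar)


def steiger_z(t_or_r1y, r2y=None, r12=None, n=None):
    """Steiger z statistic: Dunn-Clark with the mean correlation pooled in."""
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    c = _c_pooled((r1y + r2y) / 2.0, r12)
    return _maybe_scalar(_fisher_diff_z(r1y, r2y, r12, n, c), scalar)


def hms_z(t_or_r1y, r2y=None, r12=None, n=None):
    """Hittner-May-Silver z statistic, as specified in the comparative study.

    Structurally the Steiger statistic with the pooled correlation replaced
    by rbar_z = exp(2*Zbar - 1) / exp(2*Zbar + 1), Zbar being the mean of
    the two Fisher z values.  Note that this expression reduces to the
    constant exp(-2) ~ 0.1353 whatever the data, which is what gives the
    test its two signature properties: it is defined for every triplet on
    the open cube (the pooled covariance stays below 1 for r12 < 1), and it
    is grossly liberal once r12 is large and positive and the common
    correlation moves away from zero, because the covariance term then
    tracks r12 rather than the actual correlation between the Fisher z's.
    Had the pooling been the exact back-transform tanh(Zbar), the statistic
    would essentially coincide with Steiger's; see the methods notes.
    """
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    bad = (np.abs(r1y) >= 1.0) | (np.abs(r2y) >= 1.0)
    with np.errstate(invalid="ignore"):
        zbar = 0.5 * (
            np.arctanh(np.where(bad, 0.0, r1y)) + np.arctanh(np.where(bad, 0.0, r2y))
        )
    rbar_z = np.exp(2.0 * zbar - 1.0) / np.exp(2.0 * zbar + 1.0)
    c = _c_pooled(rbar_z, r12)
    out = np.where(bad, np.nan, _fisher_diff_z(r1y, r2y, r12, n, c))
    return _maybe_scalar(out, scalar)


def mrr_z(t_or_r1y, r2y=None, r12=None, n=None, cap_f: bool = False):
    """Meng-Rosenthal-Rubin z statistic.

    z = (Z1y - Z2y) * sqrt[(n-3) / (2 (1 - r12) h)] with
    h = (1 - f*r2bar) / (1 - r2bar), f = (1 - r12) / (2 (1 - r2bar)) and
    r2bar the mean squared correlation.

    With ``cap_f=False`` (the default used throughout the comparisons) f is
    used as computed and the statistic is undefined when f >= 1/r2bar (h
    <= 0); with ``cap_f=True`` the original prescription f := min(f, 1) is
    applied, which makes the statistic computable on the whole cube.
    """
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    bad = (np.abs(r1y) >= 1.0) | (np.abs(r2y) >= 1.0)
    r2bar = (r1y**2 + r2y**2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (1.0 - r12) / (2.0 * (1.0 - r2bar))
        if cap_f:
            f = np.minimum(f, 1.0)
        h = (1.0 - f * r2bar) / (1.0 - r2bar)
        dz = np.arctanh(np.where(bad, 0.0, r1y)) - np.arctanh(np.where(bad, 0.0, r2y))
    out = _guarded_sqrt_ratio(dz * np.sqrt(n - 3.0), 2.0 * (1.0 - r12) * h)
    return _maybe_scalar(np.where(bad, np.nan, out), scalar)


def zou_bounds(t_or_r1y, r2y=None, r12=None, n=None, alpha: float = 0.05):
    """Lower and upper limits (L, U) of Zou's interval for rho1y - rho2y.

    Vectorized core of :func:`zou_interval`; returns (L, U) arrays with NaN
    where a radicand is negative or a correlation sits on the boundary.
    """
    r1y, r2y, r12, n, scalar = _as_arrays(t_or_r1y, r2y, r12, n)
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    bad = (np.abs(r1y) >= 1.0) | (np.abs(r2y) >= 1.0)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z_crit / np.sqrt(n - 3.0)
    with np.errstate(invalid="ignore"):
        z1 = np.arctanh(np.where(bad, 0.0, r1y))
        z2 = np.arctanh(np.where(bad, 0.0, r2y))
    l1, u1 = np.tanh(z1 - half), np.tanh(z1 + half)
    l2, u2 = np.tanh(z2 - half), np.tanh(z2 + half)
    c = (
        (r12 - 0.5 * r1y * r2y) * (1.0 - r1y**2 - r2y**2 - r12**2) + r12**3
    ) / ((1.0 - r1y**2) * (1.0 - r2y**2))
    diff = r1y - r2y
    rad_l = (r1y - l1) ** 2 + (u2 - r2y) ** 2 - 2.0 * c * (r1y - l1) * (u2 - r2y)
    rad_u = (u1 - r1y) ** 2 + (r2y - l2) ** 2 - 2.0 * c * (u1 - r1y) * (r2y - l2)
    with np.errstate(invalid="ignore"):
        L = np.where(rad_l >= 0.0, diff - np.sqrt(np.abs(rad_l)), np.nan)
        U = np.where(rad_u >= 0.0, diff + np.sqrt(np.abs(rad_u)), np.nan)
    L = np.where(bad, np.nan, L)
    U = np.where(bad, np.nan, U)
    return _maybe_scalar(L, scalar), _maybe_scalar(U, scalar)


def zou_interval(t: CorrelationTriplet, alpha: float = 0.05) -> ZouInterval:
    """Zou's 100(1-alpha)% confidence interval for rho1y - rho2y.

    Rejects H0: rho1y = rho2y whenever L > 0 or U < 0.  Undefined limits
    (negative radicand, |r| = 1) are reported as NaN with
    ``interval.applicable`` False.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    z_crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = z_crit / np.sqrt(t.n - 3.0)
    if abs(t.r1y) >= 1.0 or abs(t.r2y) >= 1.0:
        nan = float("nan")
        return ZouInterval(nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, z_crit, alpha)
    z1, z2 = fisher_z(t.r1y), fisher_z(t.r2y)
    l1s, u1s = z1 - half, z1 + half
    l2s, u2s = z2 - half, z2 + half
    L, U = zou_bounds(t, alpha=alpha)
    return ZouInterval(
        L=float(L),
        U=float(U),
        l1=float(np.tanh(l1s)),
        l2=float(np.tanh(l2s)),
        u1=float(np.tanh(u1s)),
        u2=float(np.tanh(u2s)),
        l1_star=float(l1s),
        l2_star=float(l2s),
        u1_star=float(u1s),
        u2_star=float(u2s),
        z_crit=z_crit,
        alpha=alpha,
    )


_STATISTIC_FUNCS = {
    "pearson_filon": pearson_filon_z,
    "olkin": olkin_z,
    "hotelling": hotelling_t,
    "williams": williams_t,
    "hsh": hsh_t,
    "dunn_clark": dunn_clark_z,
    "steiger": steiger_z,
    "hms": hms_z,
    "mrr": mrr_z,
}


def statistic(name, t_or_r1y, r2y=None, r12=None, n=None, cap_f: bool = False):
    """Evaluate the named test statistic (vectorized; NaN where undefined).

    Not valid for "zou", which has no statistic form -- use
    :func:`zou_bounds` or :func:`zou_interval`.
    """
    if name == "zou":
        raise ValueError("the Zou test is interval-based; use zou_bounds")
    try:
        func = _STATISTIC_FUNCS[name]
    except KeyError:
        raise ValueError(f"unknown test {name!r}; expected one of {ALL_TESTS}") from None
    if name == "mrr":
        return func(t_or_r1y, r2y, r12, n, cap_f=cap_f)
    return func(t_or_r1y, r2y, r12, n)


def evaluate_test(
    name: str,
    t: CorrelationTriplet,
    alpha: float = 0.05,
    cap_f: bool = False,
) -> TestResult:
    """Run one named test on a triplet: statistic, p-value and decision.

    Two-sided p-values are 2*(1 - CDF(|stat|)) under the reference
    distribution; rejection is recorded per tail at alpha/2 each.  The Zou
    test has no p-value: its decision comes from the interval position.
    Undefined statistics yield ``applicable=False`` and no rejection.
    """
    if name not in ALL_TESTS:
        raise ValueError(f"unknown test {name!r}; expected one of {ALL_TESTS}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if name == "zou":
        interval = zou_interval(t, alpha=alpha)
        ok = interval.applicable
        return TestResult(
            test_name=name,
            statistic=float("nan"),
            reference="standard_normal",
            df=None,
            p_two_sided=float("nan"),
            reject_lower=bool(ok and interval.U < 0.0),
            reject_upper=bool(ok and interval.L > 0.0),
            applicable=ok,
            alpha=alpha,
            interval=interval,
        )
    value = statistic(name, t, cap_f=cap_f)
    if name in _STUDENT_T_TESTS:
        reference, df = "student_t", t.n - 3
        dist = stats.t(df)
    else:
        reference, df = "standard_normal", None
        dist = stats.norm
    ok = bool(np.isfinite(value))
    if ok:
        p = float(2.0 * dist.sf(abs(value)))
        crit = float(dist.ppf(1.0 - alpha / 2.0))
        reject_lower = value < -crit
        reject_upper = value > crit
    else:
        value, p = float("nan"), float("nan")
        reject_lower = reject_upper = False
    return TestResult(
        test_name=name,
        statistic=float(value),
        reference=reference,
        df=df,
        p_two_sided=p,
        reject_lower=bool(reject_lower),
        reject_upper=bool(reject_upper),
        applicable=ok,
        alpha=alpha,
    )


def applicability_mask(
    name: str,
    r12: float,
    grid_step: float = 0.01,
    n: int = 100,
    cap_f: bool = False,
):
    """Boolean grid over (r1y, r2y) marking where the test is defined.

    The grid covers the interior values -1 + grid_step, ..., 1 - grid_step
    in both coordinates at the given sample value of r12.  Returns
    ``(values, mask)`` with ``mask[i, j]`` True iff the statistic (or Zou
    interval) is defined at ``r1y = values[i], r2y = values[j]``.
    """
    if not 0.0 < grid_step < 1.0:
        raise ValueError("grid_step must lie in (0, 1)")
    if name not in ALL_TESTS:
        raise ValueError(f"unknown test {name!r}; expected one of {ALL_TESTS}")
    count = int(round(2.0 / grid_step)) - 1
    values = np.round(-1.0 + grid_step * np.arange(1, count + 1), 10)
    r1y, r2y = np.meshgrid(values, values, indexing="ij")
    if name == "zou":
        L, U = zou_bounds(r1y, r2y, r12, n)
        mask = np.isfinite(L) & np.isfinite(U)
    else:
        mask = np.isfinite(statistic(name, r1y, r2y, r12, n, cap_f=cap_f))
    return values, mask
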