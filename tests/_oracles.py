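"""Independent scalar re-implementations of the test statistics.

These are deliberately coded from the classical algebraic forms of each
statistic (different groupings, scalar arithmetic, explicit intermediate
steps) so they share no code path with the package.  They serve as
arithmetic oracles: wherever both routes are defined they must agree to
high relative precision.
"""

import math

import sympy


def fisher_z(r):
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


def pearson_filon(r1, r2, r12, n):
    k = r12 * (1 - r1**2 - r2**2) - 0.5 * r1 * r2 * (1 - r1**2 - r2**2 - r12**2)
    den = (1 - r1**2) ** 2 + (1 - r2**2) ** 2 - 2 * k
    if den <= 0:
        return math.nan
    return (r1 - r2) * math.sqrt(n) / math.sqrt(den)


def olkin(r1, r2, r12, n):
    common = 1 - r1**2 - r2**2 - r12**2
    den = (
        (1 - r1**2) ** 2
        + (1 - r2**2) ** 2
        - 2 * r12**3
        - 2 * r12 * common
        + r1 * r2 * common
    )
    if den <= 0:
        return math.nan
    return (r1 - r2) * math.sqrt(n) / math.sqrt(den)


def _det(r1, r2, r12):
    return 1 - r1**2 - r2**2 - r12**2 + 2 * r1 * r2 * r12


def hotelling(r1, r2, r12, n):
    R = _det(r1, r2, r12)
    if R <= 0 or (1 + r12) <= 0:
        return math.nan
    return (r1 - r2) * math.sqrt(n - 3) * math.sqrt(1 + r12) / math.sqrt(2 * R)


def williams(r1, r2, r12, n):
    # classical (n-1)-form of the radicand, algebraically identical to the
    # (n-3)-form used by the implementation
    R = _det(r1, r2, r12)
    rbar = (r1 + r2) / 2
    den = 2 * R * (n - 1) / (n - 3) + rbar**2 * (1 - r12) ** 3
    if den <= 0 or (1 + r12) <= 0:
        return math.nan
    return (r1 - r2) * math.sqrt((n - 1) * (1 + r12) / den)


def hsh(r1, r2, r12, n):
    R = _det(r1, r2, r12)
    den = 2 * R + ((r1 - r2) ** 2 * (1 - r12) ** 3) / (4 * n - 4)
    if den <= 0 or (1 + r12) <= 0:
        return math.nan
    return (r1 - r2) * math.sqrt((n - 3) * (1 + r12)) / math.sqrt(den)


def _cov_pooled(a, r12):
    return (r12 * (1 - 2 * a**2) - (a**2 / 2) * (1 - 2 * a**2 - r12**2)) / (
        (1 - a**2) * (1 - a**2)
    )


def dunn_clark(r1, r2, r12, n):
    c = (
        r12 * (1 - r1**2 - r2**2) - (r1 * r2 / 2) * (1 - r1**2 - r2**2 - r12**2)
    ) / ((1 - r1**2) * (1 - r2**2))
    var = (2 - 2 * c) / (n - 3)
    if var <= 0:
        return math.nan
    return (fisher_z(r1) - fisher_z(r2)) / math.sqrt(var)


def steiger(r1, r2, r12, n):
    c = _cov_pooled((r1 + r2) / 2, r12)
    var = (2 - 2 * c) / (n - 3)
    if var <= 0:
        return math.nan
    return (fisher_z(r1) - fisher_z(r2)) / math.sqrt(var)


def hms(r1, r2, r12, n):
    zbar = (fisher_z(r1) + fisher_z(r2)) / 2
    pooled = math.exp(2 * zbar - 1) / math.exp(2 * zbar + 1)
    c = _cov_pooled(pooled, r12)
    var = (2 - 2 * c) / (n - 3)
    if var <= 0:
        return math.nan
    return (fisher_z(r1) - fisher_z(r2)) / math.sqrt(var)


def mrr(r1, r2, r12, n, cap_f=False):
    r2bar = (r1**2 + r2**2) / 2
    f = (1 - r12) / (2 * (1 - r2bar))
    if cap_f and f > 1:
        f = 1.0
    h = (1 - f * r2bar) / (1 - r2bar)
    var = 2 * (1 - r12) * h / (n - 3)
    if var <= 0:
        return math.nan
    return (fisher_z(r1) - fisher_z(r2)) / math.sqrt(var)


def zou(r1, r2, r12, n, alpha=0.05, z_crit=None):
    from scipy.stats import norm

    zc = norm.ppf(1 - alpha / 2) if z_crit is None else z_crit
    z1, z2 = fisher_z(r1), fisher_z(r2)
    shift = zc / math.sqrt(n - 3)
    l1 = math.tanh(z1 - shift)
    u1 = math.tanh(z1 + shift)
    l2 = math.tanh(z2 - shift)
    u2 = math.tanh(z2 + shift)
    c = (
        (r12 - r1 * r2 / 2) * (1 - r1**2 - r2**2 - r12**2) + r12**3
    ) / ((1 - r1**2) * (1 - r2**2))
    rad_l = (r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2)
    rad_u = (u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2)
    L = r1 - r2 - math.sqrt(rad_l) if rad_l >= 0 else math.nan
    U = r1 - r2 + math.sqrt(rad_u) if rad_u >= 0 else math.nan
    return L, U


SCALAR_ORACLES = {
    "pearson_filon": pearson_filon,
    "olkin": olkin,
    "hotelling": hotelling,
    "williams": williams,
    "hsh": hsh,
    "dunn_clark": dunn_clark,
    "steiger": steiger,
    "hms": hms,
    "mrr": mrr,
}


def highprec(name, r1, r2, r12, n, digits=50):
    """Evaluate one statistic in 50-digit sympy arithmetic from rationals."""
    r1, r2, r12 = (sympy.Rational(str(v)) for v in (r1, r2, r12))
    n = sympy.Integer(n)
    R = 1 - r1**2 - r2**2 - r12**2 + 2 * r1 * r2 * r12
    atanh = sympy.atanh
    if name == "pearson_filon":
        den = (
            (1 - r1**2) ** 2
            + (1 - r2**2) ** 2
            - 2 * r12 * (1 - r1**2 - r2**2)
            + r1 * r2 * (1 - r1**2 - r2**2 - r12**2)
        )
        expr = (r1 - r2) * sympy.sqrt(n) / sympy.sqrt(den)
    elif name == "olkin":
        den = (
            (1 - r1**2) ** 2
            + (1 - r2**2) ** 2
            - 2 * r12**3
            - (2 * r12 - r1 * r2) * (1 - r1**2 - r2**2 - r12**2)
        )
        expr = (r1 - r2) * sympy.sqrt(n) / sympy.sqrt(den)
    elif name == "hotelling":
        expr = (r1 - r2) * sympy.sqrt((n - 3) * (1 + r12) / (2 * R))
    elif name == "williams":
        rbar = (r1 + r2) / 2
        den = 2 * R + rbar**2 * sympy.Rational(n - 3, n - 1) * (1 - r12) ** 3
        expr = (r1 - r2) * sympy.sqrt((n - 3) * (1 + r12) / den)
    elif name == "hsh":
        den = 2 * R + (r1 - r2) ** 2 * (1 - r12) ** 3 / (4 * (n - 1))
        expr = (r1 - r2) * sympy.sqrt((n - 3) * (1 + r12) / den)
    elif name == "dunn_clark":
        c = (
            r12 * (1 - r1**2 - r2**2)
            - sympy.Rational(1, 2) * r1 * r2 * (1 - r1**2 - r2**2 - r12**2)
        ) / ((1 - r1**2) * (1 - r2**2))
        expr = (atanh(r1) - atanh(r2)) * sympy.sqrt((n - 3) / (2 - 2 * c))
    elif name == "steiger":
        a = (r1 + r2) / 2
        c = (
            r12 * (1 - 2 * a**2)
            - sympy.Rational(1, 2) * a**2 * (1 - 2 * a**2 - r12**2)
        ) / (1 - a**2) ** 2
        expr = (atanh(r1) - atanh(r2)) * sympy.sqrt((n - 3) / (2 - 2 * c))
    elif name == "hms":
        zbar = (atanh(r1) + atanh(r2)) / 2
        a = sympy.exp(2 * zbar - 1) / sympy.exp(2 * zbar + 1)
        c = (
            r12 * (1 - 2 * a**2)
            - sympy.Rational(1, 2) * a**2 * (1 - 2 * a**2 - r12**2)
        ) / (1 - a**2) ** 2
        expr = (atanh(r1) - atanh(r2)) * sympy.sqrt((n - 3) / (2 - 2 * c))
    elif name == "mrr":
        r2bar = (r1**2 + r2**2) / 2
        f = (1 - r12) / (2 * (1 - r2bar))
        h = (1 - f * r2bar) / (1 - r2bar)
        expr = (atanh(r1) - atanh(r2)) * sympy.sqrt((n - 3) / (2 * (1 - r12) * h))
    else:
        raise ValueError(name)
    return float(expr.evalf(digits))
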