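"""Monte Carlo engine for accuracy (Type I error), power and robustness.

Each experimental condition pairs a population correlation structure with a
sample size and marginal distributions.  Per condition the engine draws
``reps`` independent samples of n triplets, computes the three sample
correlations of each sample, applies the requested tests two-sidedly at
level alpha, and records rejection counts per tail plus the number of
samples on which each statistic was undefined.  Undefined statistics count
as non-rejections: the rejection rate denominator is always ``reps``.

Every condition consumes a dedicated random substream derived from the
master seed and the condition's position in the sweep, so results do not
depend on evaluation order and any single condition can be reproduced in
isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stat_tests
from .datagen import (
    DistributionSpec,
    LOGNORMAL_CORRELATION_FLOOR,
    lognormal_base_correlation,
    sample_triplets,
)
from .feasibility import (
    PopulationCorrelations,
    correlation_grid,
    diagonal_range,
    is_feasible,
)

__all__ = [
    "SimulationConfig",
    "build_power_lattice",
    "type1_sweep",
    "power_sweep",
    "robustness_sweep",
]

logger = logging.getLogger(__name__)

_NORMAL_SPECS = (
    DistributionSpec.normal(),
    DistributionSpec.normal(),
    DistributionSpec.normal(),
)

#: Largest number of triplets simulated at once (memory guard).
_CHUNK_VALUES = 4_000_000

_OUTPUT_COLUMNS = [
    "test",
    "dist",
    "rho12",
    "rho1y",
    "rho2y",
    "n",
    "reps",
    "reject_lower",
    "reject_upper",
    "undefined",
    "rate",
    "se",
    "seed",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a sweep: tests, correlation grids, sample sizes, marginals.

    Defaults mirror the reference experimental design: rho12 from -0.9 to
    0.9 in steps of 0.15, null points along the identity diagonal every
    0.02, power-lattice spacing 0.04, n in {20, 50, 100, 200} and
    two-sided alpha = 0.05.  ``reps`` defaults to a desk-scale 20,000
    (binomial SE at 0.05 of about 0.0015); raise it for full-scale runs.
    """

    tests: tuple[str, ...] = stat_tests.RECOMMENDED_TESTS
    rho12_values: tuple[float, ...] = tuple(correlation_grid(-0.9, 0.9, 0.15))
    diagonal_step: float = 0.02
    lattice_step: float = 0.04
    n_values: tuple[int, ...] = (20, 50, 100, 200)
    reps: int = 20_000
    alpha: float = 0.05
    dist_specs: tuple[DistributionSpec, DistributionSpec, DistributionSpec] = _NORMAL_SPECS
    seed: int = 0
    cap_f: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.tests) - set(stat_tests.ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.diagonal_step <= 0 or self.lattice_step <= 0:
            raise ValueError("step sizes must be positive")
        if len(self.dist_specs) != 3:
            raise ValueError("dist_specs must name the marginals of X1, X2, Y")

    @property
    def dist_label(self) -> str:
        parts = []
        for spec in self.dist_specs:
            if spec.family == "beta":
                parts.append(f"beta({spec.a:g},{spec.b:g})")
            elif spec.family == "mixture":
                parts.append(f"mixture(p={spec.mix_p:g},v={spec.mix_var:g})")
            else:
                parts.append(spec.family)
        return "|".join(parts)


def _condition_rng(master_seed: int, index: int) -> np.random.Generator:
    # fixed substream rule: (master seed, condition index) -> generator
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def _sample_correlations(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise Pearson correlations per replication; block is (reps, n, 3)."""
    centred = block - block.mean(axis=1, keepdims=True)
    ss = np.sqrt(np.einsum("rni,rni->ri", centred, centred))
    x1, x2, y = centred[:, :, 0], centred[:, :, 1], centred[:, :, 2]
    r1y = np.einsum("rn,rn->r", x1, y) / (ss[:, 0] * ss[:, 2])
    r2y = np.einsum("rn,rn->r", x2, y) / (ss[:, 1] * ss[:, 2])
    r12 = np.einsum("rn,rn->r", x1, x2) / (ss[:, 0] * ss[:, 1])
    return r1y, r2y, r12


def _tally(
    tests, r1y, r2y, r12, n, alpha, cap_f
) -> dict[str, tuple[int, int, int]]:
    """Per-test (lower rejections, upper rejections, undefined) counts."""
    crit_norm = sps.norm.ppf(1.0 - alpha / 2.0)
    crit_t = sps.t.ppf(1.0 - alpha / 2.0, n - 3)
    counts = {}
    for name in tests:
        if name == "zou":
            L, U = stat_tests.zou_bounds(r1y, r2y, r12, n, alpha=alpha)
            undefined = ~(np.isfinite(L) & np.isfinite(U))
            lower = np.where(undefined, False, U < 0.0)
            upper = np.where(undefined, False, L > 0.0)
        else:
            value = stat_tests.statistic(name, r1y, r2y, r12, n, cap_f=cap_f)
            crit = crit_t if name in ("hotelling", "williams", "hsh") else crit_norm
            undefined = ~np.isfinite(value)
            lower = np.where(undefined, False, value < -crit)
            upper = np.where(undefined, False, value > crit)
        counts[name] = (int(lower.sum()), int(upper.sum()), int(undefined.sum()))
    return counts


def _run_condition(
    cfg: SimulationConfig, p: PopulationCorrelations, n: int, rng
) -> dict[str, tuple[int, int, int]]:
    totals = {name: np.zeros(3, dtype=int) for name in cfg.tests}
    remaining = cfg.reps
    chunk = max(1, _CHUNK_VALUES // (3 * n))
    while remaining > 0:
        reps = min(chunk, remaining)
        sample = sample_triplets(p, reps * n, cfg.dist_specs, rng)
        block = sample.as_array().reshape(reps, n, 3)
        r1y, r2y, r12 = _sample_correlations(block)
        for name, counts in _tally(
            cfg.tests, r1y, r2y, r12, n, cfg.alpha, cfg.cap_f
        ).items():
            totals[name] += counts
        remaining -= reps
    return {name: tuple(v) for name, v in totals.items()}


def _sweep(cfg: SimulationConfig, points: list[PopulationCorrelations]) -> pd.DataFrame:
    rows = []
    index = 0
    for p in points:
        for n in cfg.n_values:
            rng = _condition_rng(cfg.seed, index)
            counts = _run_condition(cfg, p, n, rng)
            for name in cfg.tests:
                lower, upper, undefined = counts[name]
                rate = (lower + upper) / cfg.reps
                rows.append(
                    {
                        "test": name,
                        "dist": cfg.dist_label,
                        "rho12": p.rho12,
                        "rho1y": p.rho1y,
                        "rho2y": p.rho2y,
                        "n": n,
                        "reps": cfg.reps,
                        "reject_lower": lower,
                        "reject_upper": upper,
                        "undefined": undefined,
                        "rate": rate,
                        "se": float(np.sqrt(rate * (1.0 - rate) / cfg.reps)),
                        "seed": cfg.seed,
                    }
                )
            index += 1
    return pd.DataFrame(rows, columns=_OUTPUT_COLUMNS)


def _null_points(cfg: SimulationConfig) -> list[PopulationCorrelations]:
    """Feasible null points (rho12, rho, rho) on the diagonal grid.

    The common correlation steps by ``diagonal_step`` and stays a safety
    margin of half a step inside the open feasibility bound, avoiding
    near-singular correlation matrices.  With lognormal marginals the
    targets are additionally restricted to the attainable range above -1/e.
    """
    lognormal = any(s.family == "lognormal" for s in cfg.dist_specs)
    points = []
    for rho12 in cfg.rho12_values:
        if lognormal and rho12 <= LOGNORMAL_CORRELATION_FLOOR:
            logger.warning("skipping rho12=%s: unattainable with lognormal marginals", rho12)
            continue
        bound = diagonal_range(rho12) - cfg.diagonal_step / 2.0
        k_max = int(np.floor(bound / cfg.diagonal_step))
        rhos = np.round(cfg.diagonal_step * np.arange(-k_max, k_max + 1), 10)
        for rho in rhos:
            p = PopulationCorrelations(rho12=float(rho12), rho1y=float(rho), rho2y=float(rho))
            if not is_feasible(p):
                logger.warning("skipping infeasible null point %s", p)
                continue
            if lognormal:
                # lognormal targets must be attainable (above -1/e) AND the
                # pre-adjusted normal-scale matrix must itself be feasible
                if rho <= LOGNORMAL_CORRELATION_FLOOR:
                    logger.warning("skipping %s: below the lognormal floor", p)
                    continue
                base = PopulationCorrelations(
                    rho12=lognormal_base_correlation(rho12),
                    rho1y=lognormal_base_correlation(float(rho)),
                    rho2y=lognormal_base_correlation(float(rho)),
                )
                if not is_feasible(base):
                    logger.warning("skipping %s: infeasible generating matrix", p)
                    continue
            points.append(p)
    return points


def type1_sweep(cfg: SimulationConfig) -> pd.DataFrame:
    """Empirical Type I error over the feasible null diagonal.

    Returns one row per (test, null point, n) with per-tail rejection
    counts, undefined counts, the aggregate rejection rate out of ``reps``
    and its binomial standard error.
    """
    return _sweep(cfg, _null_points(cfg))


def build_power_lattice(rho12: float, step: float = 0.04) -> list[PopulationCorrelations]:
    """Feasible alternatives (rho1y < rho2y) on the symmetric power lattice.

    Starting from reference points on the identity diagonal (-0.96 to 0.96
    in the given step), each ray subtracts k*step from rho1y and adds
    k*step to rho2y, keeping only points above the diagonal that are
    feasible at the given rho12.  Every lattice point therefore keeps its
    reference value as the mean (rho1y + rho2y)/2 while |rho1y - rho2y|
    grows along the ray.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    points = []
    refs = correlation_grid(-1.0 + step, 1.0 - step, step)
    for ref in refs:
        k = 1
        while True:
            rho1y = np.round(ref - k * step, 10)
            rho2y = np.round(ref + k * step, 10)
            if rho1y <= -1.0 or rho2y >= 1.0:
                break
            if is_feasible(rho12, rho1y, rho2y):
                points.append(
                    PopulationCorrelations(
                        rho12=float(rho12), rho1y=float(rho1y), rho2y=float(rho2y)
                    )
                )
            k += 1
    return points


def power_sweep(cfg: SimulationConfig) -> pd.DataFrame:
    """Rejection rate at false nulls over the power lattice.

    Output rows carry the lattice coordinates plus the derived effect
    measures |rho1y - rho2y| (``delta``) and the mean correlation
    (``mean_rho``) used in power summaries.
    """
    points = []
    for rho12 in cfg.rho12_values:
        points.extend(build_power_lattice(rho12, cfg.lattice_step))
    frame = _sweep(cfg, points)
    frame["delta"] = np.abs(frame["rho1y"] - frame["rho2y"])
    frame["mean_rho"] = (frame["rho1y"] + frame["rho2y"]) / 2.0
    return frame


def robustness_sweep(cfg: SimulationConfig) -> pd.DataFrame:
    """Type I error sweep under non-normal marginals.

    X1 and X2 must share a distribution family (and parameters) so that
    the null rho1y = rho2y stays true after transformation; a mixed-family
    pair would silently break the null being tested.
    """
    s1, s2 = cfg.dist_specs[0], cfg.dist_specs[1]
    if (s1.family, s1.a, s1.b, s1.mix_p, s1.mix_var) != (
        s2.family,
        s2.a,
        s2.b,
        s2.mix_p,
        s2.mix_var,
    ):
        raise ValueError(
            "X1 and X2 must have identical marginal specs in a null sweep"
        )
    return type1_sweep(cfg)
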