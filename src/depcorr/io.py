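"""File I/O: correlation-triplet records, result tables, simulation configs.

CSV files are comma-separated with a header row, UTF-8, '.' decimal; JSON
mirrors the CSV schema.  Simulation configs are YAML or JSON mappings whose
keys mirror :class:`~depcorr.simulate.SimulationConfig`; unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .datagen import DistributionSpec
from .simulate import SimulationConfig
from .stat_tests import CorrelationTriplet, TestResult

__all__ = [
    "read_triplets",
    "results_frame",
    "write_results",
    "read_results",
    "parse_dist_spec",
    "read_sim_config",
]

_TRIPLET_COLUMNS = ("r1y", "r2y", "r12", "n")

_CONFIG_KEYS = {
    "tests",
    "rho12_values",
    "diagonal_step",
    "lattice_step",
    "n_values",
    "reps",
    "alpha",
    "dist_specs",
    "seed",
    "cap_f",
}


def read_triplets(path) -> list[tuple[str, CorrelationTriplet]]:
    """Read labelled correlation triplets from a CSV or JSON file.

    Requires columns/fields r1y, r2y, r12, n; an optional ``label`` column
    names each record (defaulting to the row number).  Invalid rows raise a
    ValueError naming the offending row.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError("JSON triplet file must contain a list of records")
        frame = pd.DataFrame.from_records(records)
    else:
        frame = pd.read_csv(path)
    missing = [c for c in _TRIPLET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        label = str(getattr(row, "label", row_number))
        try:
            triplet = CorrelationTriplet(
                r1y=float(row.r1y), r2y=float(row.r2y), r12=float(row.r12), n=int(row.n)
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {row_number} ({label!r}): {exc}") from None
        out.append((label, triplet))
    return out


def results_frame(
    records: list[tuple[str, CorrelationTriplet, list[TestResult]]]
) -> pd.DataFrame:
    """One output row per (record, test), full precision."""
    rows = []
    for label, triplet, results in records:
        for res in results:
            rows.append(
                {
                    "label": label,
                    "r1y": triplet.r1y,
                    "r2y": triplet.r2y,
                    "r12": triplet.r12,
                    "n": triplet.n,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "df": res.df if res.df is not None else "",
                    "p": res.p_two_sided,
                    "ci_lower": res.interval.L if res.interval else "",
                    "ci_upper": res.interval.U if res.interval else "",
                    "reject": res.reject,
                    "applicable": res.applicable,
                    "alpha": res.alpha,
                }
            )
    return pd.DataFrame(rows)


def write_results(frame: pd.DataFrame, path) -> None:
    """Write a results table as CSV (re-readable by :func:`read_results`)."""
    frame.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def parse_dist_spec(text) -> DistributionSpec:
    """Parse a marginal spec from CLI/config shorthand.

    Accepts "normal", "uniform", "beta:a,b", "lognormal", "mixture:v" or
    "mixture:v,p", or a mapping like {"family": "beta", "a": 2, "b": 5}.
    """
    if isinstance(text, DistributionSpec):
        return text
    if isinstance(text, dict):
        return DistributionSpec(**text)
    name, _, args = str(text).strip().partition(":")
    name = name.lower()
    if name == "normal":
        return DistributionSpec.normal()
    if name == "uniform":
        return DistributionSpec.uniform()
    if name == "lognormal":
        return DistributionSpec.lognormal()
    if name == "beta":
        try:
            a, b = (float(v) for v in args.split(","))
        except ValueError:
            raise ValueError(f"beta spec needs 'beta:a,b', got {text!r}") from None
        return DistributionSpec.beta(a, b)
    if name == "mixture":
        parts = args.split(",") if args else []
        if len(parts) == 1:
            return DistributionSpec.mixture(float(parts[0]))
        if len(parts) == 2:
            return DistributionSpec.mixture(float(parts[0]), mix_p=float(parts[1]))
        raise ValueError(f"mixture spec needs 'mixture:v[,p]', got {text!r}")
    raise ValueError(f"unknown distribution spec {text!r}")


def read_sim_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("simulation config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("tests", "rho12_values", "n_values"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "dist_specs" in kwargs:
        specs = kwargs["dist_specs"]
        if len(specs) != 3:
            raise ValueError("dist_specs must list the marginals of X1, X2, Y")
        kwargs["dist_specs"] = tuple(parse_dist_spec(s) for s in specs)
    return SimulationConfig(**kwargs)
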