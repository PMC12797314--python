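"""Census CSV I/O and result serialization.

The census schema is one row per individual per year:

    id, plot, year, size_mm, alive, retracted, flowers[, recruit]

with 0/1 flags, flowers = 0 for retracted rows and an empty size for death
rows.  ``read_census`` validates the table invariants and reports
violations with their CSV line numbers.  ``write_report`` serializes a
pipeline result as a set of plain-text artifacts (a JSON metrics report,
CSV tables, the fitted models and a run manifest) that the package's own
readers can load back.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import FittedRates, PipelineResult

__all__ = [
    "CensusSchemaError",
    "CensusValidationError",
    "read_census",
    "write_census",
    "write_fitted_rates",
    "read_fitted_rates",
    "export_megamatrix",
    "write_report",
]

REQUIRED_COLUMNS = ["id", "plot", "year", "size_mm", "alive", "retracted", "flowers"]


class CensusSchemaError(ValueError):
    """The census file does not have the expected columns/types."""


class CensusValidationError(ValueError):
    """Rows violate the census invariants."""


def read_census(path) -> pd.DataFrame:
    """Read and validate a census CSV.

    Violated invariants are reported with 1-based CSV line numbers (the
    header is line 1).
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CensusSchemaError(f"{path.name}: missing required column(s) {missing}")
    if "recruit" not in table.columns:
        table["recruit"] = 0

    lines = table.index.to_numpy() + 2  # header occupies line 1
    problems: list[str] = []

    size = pd.to_numeric(table["size_mm"], errors="coerce")
    bad_size = table["size_mm"].notna() & size.isna()
    for ln in lines[bad_size.to_numpy()]:
        problems.append(f"line {ln}: non-numeric size_mm")
    table["size_mm"] = size
    for col in ("year", "alive", "retracted", "flowers", "recruit"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna()
        for ln in lines[bad.to_numpy()]:
            problems.append(f"line {ln}: non-numeric {col}")
        table[col] = vals
    if problems:
        raise CensusSchemaError(f"{path.name}: " + "; ".join(problems[:20]))
    table = table.astype({"year": int, "alive": int, "retracted": int, "flowers": int, "recruit": int})

    dup = table.duplicated(subset=["id", "year"], keep=False)
    for ln in lines[dup.to_numpy()][:20]:
        problems.append(f"line {ln}: individual has more than one row for this year")
    viol = (table["flowers"] > 0) & (table["retracted"] == 1)
    for ln in lines[viol.to_numpy()]:
        problems.append(f"line {ln}: flowers > 0 on a retracted row (flowers must be 0 while retracted)")
    alive_nosize = (table["alive"] == 1) & (~(table["size_mm"] > 0))
    for ln in lines[alive_nosize.to_numpy()]:
        problems.append(f"line {ln}: alive row without a positive size")
    # rows after the first death of an individual
    order = table.sort_values(["id", "year"], kind="mergesort")
    dead_before = order.groupby("id")["alive"].transform(lambda s: (s == 0).cumsum().shift(fill_value=0) > 0)
    for ln in (order.index.to_numpy() + 2)[dead_before.to_numpy()]:
        problems.append(f"line {ln}: row after the individual's death row")
    if problems:
        raise CensusValidationError(f"{path.name}: " + "; ".join(sorted(problems)[:20]))
    return table.sort_values(["id", "year"], kind="mergesort").reset_index(drop=True)


def write_census(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.to_csv(path, index=False, float_format="%.4f")


def write_fitted_rates(rates: FittedRates, path) -> None:
    with open(path, "w") as fh:
        json.dump(rates.to_dict(), fh, indent=1, sort_keys=True)


def read_fitted_rates(path) -> FittedRates:
    with open(path) as fh:
        return FittedRates.from_dict(json.load(fh))


def export_megamatrix(mm, directory) -> list[Path]:
    """Write the four blocks and the assembled operator as dense text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, block in (("Kuu", mm.Kuu), ("Kur", mm.Kur), ("Kru", mm.Kru), ("Krr", mm.Krr), ("A", mm.A)):
        p = directory / f"megamatrix_{name}.txt"
        np.savetxt(p, block, header=f"{name} block, scenario={mm.scenario}, N={mm.grid.n}")
        written.append(p)
    return written


def _metrics_payload(result: PipelineResult) -> dict:
    comp = result.comparison
    payload = {
        "scenario_lambda": {
            "with_contraction": comp.with_contraction.lam,
            "without_contraction": comp.without_contraction.lam,
            "delta_lambda": comp.delta_lambda,
        },
        "recruit_probability": result.rates.p_r,
        "offspring": result.rates.offspring.to_dict(),
        "elasticity": {
            "vital_rates": {k: float(v) for k, v in result.elasticities.vital_rates.items()},
            "kernel_sum": result.elasticities.elasticity_sum,
            "delta": result.elasticities.delta,
        },
        "models": {
            rate: {
                "form": m.form,
                "random_effects": sorted(k for k in m.sigma2 if k != "_spline"),
                "aic": m.aic,
                "n_obs": m.n_obs,
            }
            for rate, m in result.rates.models.items()
        },
    }
    for label, m in (
        ("with_contraction", comp.with_contraction),
        ("without_contraction", comp.without_contraction),
    ):
        if m.annual:
            payload.setdefault("annual_lambda", {})[label] = {
                "mean": float(np.mean(list(m.annual.values()))),
                "interval": list(m.interval),
            }
    if result.true_lambda is not None:
        payload["ground_truth"] = {
            "lambda_with_contraction": result.true_lambda,
            "recovery_error": abs(comp.with_contraction.lam - result.true_lambda),
        }
    return payload


def write_report(result: PipelineResult, directory) -> dict[str, Path]:
    """Write the full artifact set for a pipeline run.

    Produces ``metrics.json``, ``annual_lambdas.csv``,
    ``stable_structure.csv``, ``reproductive_values.csv``,
    ``elasticities.csv``, ``fitted_models.json`` and ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    comp = result.comparison
    grid = result.grid
    files: dict[str, Path] = {}

    files["metrics"] = directory / "metrics.json"
    with open(files["metrics"], "w") as fh:
        json.dump(_metrics_payload(result), fh, indent=1, sort_keys=True)

    years = sorted(set(comp.with_contraction.annual) | set(comp.without_contraction.annual))
    annual = pd.DataFrame(
        {
            "year": years,
            "lambda_with": [comp.with_contraction.annual.get(y, np.nan) for y in years],
            "lambda_without": [comp.without_contraction.annual.get(y, np.nan) for y in years],
        }
    )
    files["annual_lambdas"] = directory / "annual_lambdas.csv"
    annual.to_csv(files["annual_lambdas"], index=False)

    frames = []
    for label, m in (("with_contraction", comp.with_contraction), ("without_contraction", comp.without_contraction)):
        frames.append(
            pd.DataFrame(
                {
                    "scenario": label,
                    "size": grid.midpoints,
                    "w_unretracted": m.w_unretracted,
                    "w_retracted": m.w_retracted,
                }
            )
        )
    files["stable_structure"] = directory / "stable_structure.csv"
    pd.concat(frames).to_csv(files["stable_structure"], index=False)

    frames = []
    for label, m in (("with_contraction", comp.with_contraction), ("without_contraction", comp.without_contraction)):
        frames.append(
            pd.DataFrame(
                {
                    "scenario": label,
                    "size": grid.midpoints,
                    "v_unretracted": m.v_unretracted,
                    "v_retracted": m.v_retracted,
                }
            )
        )
    files["reproductive_values"] = directory / "reproductive_values.csv"
    pd.concat(frames).to_csv(files["reproductive_values"], index=False)

    el = result.elasticities
    files["elasticities"] = directory / "elasticities.csv"
    pd.DataFrame(
        {
            "rate": list(el.vital_rates.keys()),
            "elasticity": [float(v) for v in el.vital_rates.values()],
            "sensitivity": [float(v) * el.lam for v in el.vital_rates.values()],
            "delta": el.delta,
        }
    ).to_csv(files["elasticities"], index=False)

    files["fitted_models"] = directory / "fitted_models.json"
    write_fitted_rates(result.rates, files["fitted_models"])

    files["manifest"] = directory / "manifest.json"
    manifest = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "census_rows": int(len(result.census)),
        "individuals": int(result.census["id"].nunique()),
    }
    with open(files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return files
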