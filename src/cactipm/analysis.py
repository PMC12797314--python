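"""Asymptotic and annual population dynamics of the discretized model.

The dominant eigenvalue of the megamatrix is the asymptotic population
growth rate lambda; its right eigenvector (normalized to sum one) is the
stable size-by-state structure w, and its left eigenvector (scaled so that
<v, w> = 1) holds the reproductive values v.  Annual growth rates are
obtained by shifting each vital-rate model that retained a year random
effect by that year's conditional-mode intercept deviation, rebuilding the
kernel and recomputing lambda; the reported lambda interval is the min-max
range of this annual series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .kernels import IPMGrid, Megamatrix, VitalRateSet, build_megamatrix

__all__ = [
    "ConvergenceError",
    "PopulationMetrics",
    "ScenarioComparison",
    "dominant_eigentriple",
    "metrics_for",
    "annual_lambdas",
    "lambda_interval",
    "scenario_comparison",
]


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge."""


def _dense_eigentriple(A: np.ndarray):
    vals, vecs = scipy.linalg.eig(A)
    lead = int(np.argmax(vals.real))
    lam = float(vals[lead].real)
    w = np.abs(vecs[:, lead].real)
    lvals, lvecs = scipy.linalg.eig(A.T)
    lead_l = int(np.argmax(lvals.real))
    v = np.abs(lvecs[:, lead_l].real)
    return lam, w, v


def dominant_eigentriple(
    A: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    *,
    dense_fallback: bool = True,
):
    """Dominant eigenvalue and eigenvectors of a nonnegative matrix.

    Power iteration on A (and on A' for the reproductive values) until the
    relative change in lambda drops below ``tol``.  Returns ``(lam, w, v)``
    with ``sum(w) = 1`` and ``<v, w> = 1``.  On non-convergence a dense
    eigendecomposition is used for matrices up to 1000 x 1000 when
    ``dense_fallback`` is enabled, otherwise a :class:`ConvergenceError` is
    raised suggesting it.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(A < 0):
        raise ValueError("matrix must be nonnegative")
    if not np.any(A > 0):
        raise ValueError("matrix must be nonzero")
    n = A.shape[0]

    def power(mat: np.ndarray):
        x = np.full(n, 1.0 / n)
        lam = np.nan
        for _ in range(max_iter):
            y = mat @ x
            norm = y.sum()
            if norm <= 0 or not np.isfinite(norm):
                return None
            y /= norm
            if np.isfinite(lam) and abs(norm - lam) <= tol * abs(lam):
                return float(norm), y
            lam = norm
            x = y
        return None

    right = power(A)
    left = power(A.T)
    if right is None or left is None:
        if dense_fallback and n <= 1000:
            lam, w, v = _dense_eigentriple(A)
        else:
            raise ConvergenceError(
                f"power iteration did not converge in {max_iter} iterations; "
                "consider a dense eigendecomposition fallback"
            )
    else:
        lam, w = right
        _, v = left
    w = w / w.sum()
    v = v / float(v @ w)
    return lam, w, v


@dataclass
class PopulationMetrics:
    """Lambda, stable structure and reproductive values for one scenario."""

    scenario: str
    lam: float
    w: np.ndarray  # length 2N: unretracted block then retracted block
    v: np.ndarray
    grid: IPMGrid
    annual: dict = field(default_factory=dict)  # year -> lambda
    interval: tuple[float, float] | None = None

    @property
    def w_unretracted(self) -> np.ndarray:
        return self.w[: self.grid.n]

    @property
    def w_retracted(self) -> np.ndarray:
        return self.w[self.grid.n :]

    @property
    def v_unretracted(self) -> np.ndarray:
        return self.v[: self.grid.n]

    @property
    def v_retracted(self) -> np.ndarray:
        return self.v[self.grid.n :]

    def marginal_structure(self) -> np.ndarray:
        """Stable size distribution summed over the two states."""
        return self.w_unretracted + self.w_retracted


def metrics_for(
    mm: Megamatrix, tol: float = 1e-10, max_iter: int = 100_000
) -> PopulationMetrics:
    lam, w, v = dominant_eigentriple(mm.A, tol=tol, max_iter=max_iter)
    return PopulationMetrics(scenario=mm.scenario, lam=lam, w=w, v=v, grid=mm.grid)


def _year_deviations(models: dict) -> dict[int, dict[str, float]]:
    """year -> per-rate link-scale intercept deviation (conditional modes)."""
    out: dict[int, dict[str, float]] = {}
    for rate, model in models.items():
        for year, dev in model.year_modes.items():
            out.setdefault(int(year), {})[rate] = float(dev)
    return dict(sorted(out.items()))


def annual_lambdas(
    rates,
    grid: IPMGrid,
    scenario: str = "with_contraction",
    years=None,
    *,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    **kernel_options,
) -> dict[int, float]:
    """Asymptotic lambda of each observed year's kernel.

    ``rates`` is a :class:`~cactipm.pipeline.FittedRates` bundle.  For every
    year, each model that retained a year random effect is shifted by that
    year's conditional-mode deviation on its link scale; models without a
    year effect stay at their population-level curve.
    """
    devs = _year_deviations(rates.models)
    if not devs:
        raise ValueError("no fitted model retained a year random effect")
    if years is None:
        years = sorted(devs)
    out: dict[int, float] = {}
    for year in years:
        year = int(year)
        if year not in devs:
            raise KeyError(f"unknown year label {year!r}: no conditional mode available")
        vrs = rates.on_grid(grid, year_deviations=devs[year])
        mm = build_megamatrix(vrs, grid, scenario=scenario, **kernel_options)
        lam, _, _ = dominant_eigentriple(mm.A, tol=tol, max_iter=max_iter)
        out[year] = lam
    return out


def lambda_interval(annual: dict) -> tuple[float, float]:
    """Min-max range of an annual lambda series."""
    if not annual:
        raise ValueError("empty annual lambda series")
    vals = list(annual.values())
    return (float(min(vals)), float(max(vals)))


@dataclass
class ScenarioComparison:
    with_contraction: PopulationMetrics
    without_contraction: PopulationMetrics

    @property
    def delta_lambda(self) -> float:
        """lambda(without contraction) - lambda(with contraction)."""
        return self.without_contraction.lam - self.with_contraction.lam


def scenario_comparison(
    vrs: VitalRateSet,
    grid: IPMGrid | None = None,
    rates=None,
    *,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    **kernel_options,
) -> ScenarioComparison:
    """Population metrics with and without root contraction, same rates.

    If a fitted-rates bundle is supplied (and any model retained a year
    effect), each scenario's metrics also carry the annual lambda series
    and its min-max interval.
    """
    grid = grid or vrs.grid
    metrics = {}
    for scenario in ("with_contraction", "without_contraction"):
        mm = build_megamatrix(vrs, grid, scenario=scenario, **kernel_options)
        m = metrics_for(mm, tol=tol, max_iter=max_iter)
        if rates is not None and _year_deviations(rates.models):
            m.annual = annual_lambdas(
                rates, grid, scenario, tol=tol, max_iter=max_iter, **kernel_options
            )
            m.interval = lambda_interval(m.annual)
        metrics[scenario] = m
    return ScenarioComparison(
        with_contraction=metrics["with_contraction"],
        without_contraction=metrics["without_contraction"],
    )
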