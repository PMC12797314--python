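"""Sensitivity and elasticity of lambda to kernel entries and vital rates.

Kernel-entry sensitivities follow the classical eigenvector formula
S_ij = v_i w_j (with <v, w> = 1), elasticities E_ij = (A_ij / lambda) S_ij,
which sum to one over the whole operator.  Vital-rate elasticities use
central finite differences under proportional perturbation: the named
rate's response-scale function is multiplied by (1 ± delta) inside the
kernel formulas, lambda is recomputed both times and the elasticity is
(lambda+ - lambda-) / (2 delta lambda).  Density-valued rates (G_u, G_r, c)
are scaled without renormalizing, so the perturbation measures the rate's
contribution to mass flow rather than a relabeling of sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .analysis import dominant_eigentriple
from .kernels import IPMGrid, VitalRateSet, build_megamatrix

__all__ = [
    "ElasticityReport",
    "kernel_sensitivity",
    "kernel_elasticity",
    "vital_rate_elasticity",
    "vital_rate_elasticities",
]

_CAPPED_RATES = ("s", "p_b", "r", "u")  # probabilities: perturbation must stay <= 1


def kernel_sensitivity(w: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Sensitivity matrix S_ij = v_i * w_j (requires <v, w> = 1)."""
    w = np.asarray(w, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if w.shape != v.shape:
        raise ValueError("w and v must have the same length")
    return np.outer(v, w)


def kernel_elasticity(A: np.ndarray, lam: float, S: np.ndarray) -> np.ndarray:
    """Elasticity matrix E_ij = (A_ij / lambda) * S_ij; sums to one."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    A = np.asarray(A, dtype=float)
    if A.shape != np.asarray(S).shape:
        raise ValueError("A and S must have the same shape")
    return A * np.asarray(S, dtype=float) / lam


def _effective_delta(vrs: VitalRateSet, rate_name: str, delta: float) -> tuple[float, bool]:
    """Shrink delta so (1+delta) keeps probabilities <= 1.

    Returns ``(delta, one_sided)``; ``one_sided`` is True when the rate
    already touches 1 and only a backward difference is possible.
    """
    if rate_name not in _CAPPED_RATES:
        return delta, False
    top = float(np.max(getattr(vrs, rate_name), initial=0.0))
    if top <= 0.0:
        return delta, False
    limit = 1.0 / top - 1.0
    if limit <= 1e-9:
        warnings.warn(
            f"rate {rate_name!r} touches 1; its elasticity uses a backward "
            "difference",
            UserWarning,
            stacklevel=3,
        )
        return delta, True
    if delta > limit:
        shrunk = limit * 0.5
        warnings.warn(
            f"perturbation of rate {rate_name!r} by {delta:g} would push a "
            f"probability above 1; using delta={shrunk:g} instead",
            UserWarning,
            stacklevel=3,
        )
        return shrunk, False
    return delta, False


def vital_rate_elasticity(
    vrs: VitalRateSet,
    grid: IPMGrid | None = None,
    scenario: str = "with_contraction",
    rate_name: str = "s",
    delta: float = 1e-4,
    *,
    tol: float = 1e-12,
    max_iter: int = 200_000,
    **kernel_options,
) -> float:
    """Central-difference proportional elasticity of lambda to one vital rate."""
    grid = grid or vrs.grid
    if rate_name not in VitalRateSet.RATE_NAMES:
        raise ValueError(
            f"unknown vital rate {rate_name!r}; expected one of {VitalRateSet.RATE_NAMES}"
        )
    delta, one_sided = _effective_delta(vrs, rate_name, delta)
    lam0, _, _ = dominant_eigentriple(
        build_megamatrix(vrs, grid, scenario=scenario, **kernel_options).A,
        tol=tol,
        max_iter=max_iter,
    )

    def lam_at(factor: float) -> float:
        pert = vrs.scaled(rate_name, factor)
        mm = build_megamatrix(pert, grid, scenario=scenario, validate=False, **kernel_options)
        lam, _, _ = dominant_eigentriple(mm.A, tol=tol, max_iter=max_iter)
        return lam

    if one_sided:
        return (lam0 - lam_at(1.0 - delta)) / (delta * lam0)
    return (lam_at(1.0 + delta) - lam_at(1.0 - delta)) / (2.0 * delta * lam0)


@dataclass
class ElasticityReport:
    """Kernel-level and vital-rate-level perturbation results."""

    scenario: str
    lam: float
    sensitivity: np.ndarray  # 2N x 2N
    elasticity: np.ndarray  # 2N x 2N, sums to 1
    vital_rates: dict  # rate name -> proportional elasticity
    delta: float

    @property
    def elasticity_sum(self) -> float:
        return float(self.elasticity.sum())


def vital_rate_elasticities(
    vrs: VitalRateSet,
    grid: IPMGrid | None = None,
    scenario: str = "with_contraction",
    delta: float = 1e-4,
    *,
    tol: float = 1e-12,
    max_iter: int = 200_000,
    **kernel_options,
) -> ElasticityReport:
    """Full perturbation analysis of one scenario's megamatrix."""
    grid = grid or vrs.grid
    mm = build_megamatrix(vrs, grid, scenario=scenario, **kernel_options)
    lam, w, v = dominant_eigentriple(mm.A, tol=tol, max_iter=max_iter)
    S = kernel_sensitivity(w, v)
    E = kernel_elasticity(mm.A, lam, S)
    per_rate = {
        name: vital_rate_elasticity(
            vrs, grid, scenario, name, delta, tol=tol, max_iter=max_iter, **kernel_options
        )
        for name in VitalRateSet.RATE_NAMES
    }
    return ElasticityReport(
        scenario=scenario,
        lam=lam,
        sensitivity=S,
        elasticity=E,
        vital_rates=per_rate,
        delta=delta,
    )
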