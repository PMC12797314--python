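"""Discretization of the two-state integral projection model.

The population is structured by stem diameter z (mm) and by a discrete
state: unretracted (above ground) or retracted (pulled below ground by root
contraction, frozen at its pre-retraction size z°).  One census interval is
projected by the block operator

    [ n_u ]      [ K_uu  K_ur ] [ n_u ]
    [ n_r ]  ->  [ K_ru  K_rr ] [ n_r ]

with kernels

    K_uu(z', z)  = (1 - r(z)) * [ s(z) * G_u(z', z) + p_b(z) b(z) p_r c(z') ]
    K_ur(z', z°) = u(z°) * s(z°) * G(z', z°)          (G = G_r by default)
    K_ru(z°, z)  = r(z)                                (diagonal: size frozen)
    K_rr(z°, z°) = 1 - u(z°)                           (diagonal)

where s is survival, G_u/G_r the growth densities of unretracted survivors
and of individuals re-emerging by root elongation, p_b the reproduction
probability, b the expected flower count per reproducer, p_r the
flower-to-recruit establishment probability, c the offspring-size density,
r the contraction and u the elongation probability.  Integrals over z are
realized by the midpoint rule on a regular grid; growth and offspring
densities are renormalized within the size domain so that no probability
mass is evicted at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "IPMGrid",
    "VitalRateSet",
    "Megamatrix",
    "make_grid",
    "growth_matrix",
    "offspring_masses",
    "build_megamatrix",
    "SCENARIOS",
]

SCENARIOS = ("with_contraction", "without_contraction")

_PROB_RATES = ("s", "p_b", "r", "u")


@dataclass(frozen=True)
class IPMGrid:
    """Regular midpoint grid on the size domain [lower, upper] (mm)."""

    lower: float
    upper: float
    n: int

    def __post_init__(self):
        if self.upper <= self.lower:
            raise ValueError("grid: upper bound must exceed lower bound")
        if self.n < 1:
            raise ValueError("grid: mesh count must be >= 1")

    @property
    def h(self) -> float:
        return (self.upper - self.lower) / self.n

    @property
    def midpoints(self) -> np.ndarray:
        return self.lower + (np.arange(self.n) + 0.5) * self.h

    @property
    def edges(self) -> np.ndarray:
        return self.lower + np.arange(self.n + 1) * self.h


def make_grid(lower: float, upper: float, n: int) -> IPMGrid:
    return IPMGrid(float(lower), float(upper), int(n))


def growth_matrix(mean_fn, sd: float, grid: IPMGrid) -> np.ndarray:
    """Column-stochastic size-transition matrix from a Gaussian growth model.

    Entry (i, j) is the probability that an individual of size ``z_j`` lands
    in cell i, i.e. the Normal(mean_fn(z_j), sd) mass over cell i, with each
    column renormalized to unit mass within the domain (eviction correction).
    """
    if sd <= 0:
        raise ValueError("growth sd must be > 0")
    z = grid.midpoints
    means = np.asarray(mean_fn(z), dtype=float)
    cdf = norm.cdf((grid.edges[:, None] - means[None, :]) / sd)
    mat = np.diff(cdf, axis=0)
    colsum = mat.sum(axis=0)
    empty = colsum < 1e-300
    if np.any(empty):
        # all mass evicted (mean far outside the domain): nearest boundary cell
        for j in np.flatnonzero(empty):
            idx = 0 if means[j] < grid.lower else grid.n - 1
            mat[:, j] = 0.0
            mat[idx, j] = 1.0
        colsum = mat.sum(axis=0)
    return mat / colsum


def offspring_masses(mean: float, sd: float, grid: IPMGrid) -> np.ndarray:
    """Per-cell offspring-size masses, renormalized over the domain."""
    if sd <= 0:
        raise ValueError("offspring sd must be > 0")
    cdf = norm.cdf((grid.edges - mean) / sd)
    mass = np.diff(cdf)
    total = mass.sum()
    if total < 1e-300:
        raise ValueError("offspring density has no mass inside the size domain")
    return mass / total


@dataclass
class VitalRateSet:
    """The complete set of vital rates evaluated on an IPM grid.

    ``s, p_b, b, r, u`` are response-scale values at the grid midpoints;
    ``G_u, G_r`` are column-stochastic growth matrices; ``c`` holds the
    offspring-size cell masses (summing to one) and ``p_r`` the
    flower-to-recruit establishment probability.
    """

    grid: IPMGrid
    s: np.ndarray
    p_b: np.ndarray
    b: np.ndarray
    r: np.ndarray
    u: np.ndarray
    G_u: np.ndarray
    G_r: np.ndarray
    c: np.ndarray
    p_r: float

    RATE_NAMES = ("s", "G_u", "G_r", "p_b", "b", "r", "u", "c")

    @classmethod
    def from_functions(
        cls,
        grid: IPMGrid,
        *,
        s,
        p_b,
        b,
        r,
        u,
        g_u_mean,
        g_u_sd: float,
        g_r_mean,
        g_r_sd: float,
        offspring_mean: float,
        offspring_sd: float,
        p_r: float,
    ) -> "VitalRateSet":
        z = grid.midpoints
        return cls(
            grid=grid,
            s=np.broadcast_to(np.asarray(s(z), float), z.shape).copy(),
            p_b=np.broadcast_to(np.asarray(p_b(z), float), z.shape).copy(),
            b=np.broadcast_to(np.asarray(b(z), float), z.shape).copy(),
            r=np.broadcast_to(np.asarray(r(z), float), z.shape).copy(),
            u=np.broadcast_to(np.asarray(u(z), float), z.shape).copy(),
            G_u=growth_matrix(g_u_mean, g_u_sd, grid),
            G_r=growth_matrix(g_r_mean, g_r_sd, grid),
            c=offspring_masses(offspring_mean, offspring_sd, grid),
            p_r=float(p_r),
        )

    def validate(self) -> None:
        z = self.grid.midpoints
        for name in _PROB_RATES:
            vals = getattr(self, name)
            bad = (vals < -1e-12) | (vals > 1.0 + 1e-12)
            if np.any(bad):
                j = int(np.argmax(bad))
                raise ValueError(
                    f"vital rate {name!r} outside [0, 1] at size {z[j]:.3f} mm "
                    f"(value {vals[j]:.6g})"
                )
        if np.any(self.b < 0):
            j = int(np.argmax(self.b < 0))
            raise ValueError(f"vital rate 'b' negative at size {z[j]:.3f} mm")
        if not 0.0 <= self.p_r <= 1.0:
            raise ValueError(f"recruit probability p_r outside [0, 1] (value {self.p_r:.6g})")
        if np.any(self.G_u < 0) or np.any(self.G_r < 0) or np.any(self.c < 0):
            raise ValueError("growth/offspring densities must be nonnegative")

    def scaled(self, rate_name: str, factor: float) -> "VitalRateSet":
        """Copy with one rate multiplied by ``factor`` (no renormalization).

        For the density-valued rates (G_u, G_r, c) the whole matrix/vector is
        scaled without re-imposing unit mass, so a proportional perturbation
        measures that rate's contribution to mass flow rather than a
        relabeling of sizes.
        """
        if rate_name not in self.RATE_NAMES:
            raise ValueError(f"unknown vital rate {rate_name!r}")
        kwargs = {
            "grid": self.grid,
            "s": self.s,
            "p_b": self.p_b,
            "b": self.b,
            "r": self.r,
            "u": self.u,
            "G_u": self.G_u,
            "G_r": self.G_r,
            "c": self.c,
            "p_r": self.p_r,
        }
        kwargs[rate_name] = kwargs[rate_name] * factor
        return VitalRateSet(**kwargs)


@dataclass
class Megamatrix:
    """Discretized 2N x 2N two-state IPM operator."""

    grid: IPMGrid
    Kuu: np.ndarray
    Kur: np.ndarray
    Kru: np.ndarray
    Krr: np.ndarray
    scenario: str

    @property
    def A(self) -> np.ndarray:
        return np.block([[self.Kuu, self.Kur], [self.Kru, self.Krr]])


def build_megamatrix(
    vrs: VitalRateSet,
    grid: IPMGrid | None = None,
    scenario: str = "with_contraction",
    *,
    elongation_growth: str = "G_r",
    retracted_survival: bool = True,
    validate: bool = True,
) -> Megamatrix:
    """Assemble the four-block operator from a vital-rate set.

    ``scenario='without_contraction'`` forces r = 0 everywhere (the
    counterfactual population in which root contraction never happens).
    ``elongation_growth`` selects the growth density applied on elongation
    (``'G_r'``, the default, or ``'G_u'``); ``retracted_survival=False``
    drops the survival factor from K_ur, matching the assumption of no
    mortality in retracted individuals.
    """
    grid = grid or vrs.grid
    if grid.n != vrs.grid.n or grid.lower != vrs.grid.lower or grid.upper != vrs.grid.upper:
        raise ValueError("grid does not match the vital-rate set's grid")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if elongation_growth not in ("G_r", "G_u"):
        raise ValueError("elongation_growth must be 'G_r' or 'G_u'")
    if validate:
        vrs.validate()

    r = np.zeros(grid.n) if scenario == "without_contraction" else vrs.r
    one_minus_r = 1.0 - r
    fec = vrs.p_b * vrs.b * vrs.p_r  # per-capita recruit production (column-wise)
    Kuu = vrs.G_u * (vrs.s * one_minus_r)[None, :] + np.outer(vrs.c, fec * one_minus_r)
    g_elong = vrs.G_r if elongation_growth == "G_r" else vrs.G_u
    surv = vrs.s if retracted_survival else np.ones(grid.n)
    Kur = g_elong * (vrs.u * surv)[None, :]
    Kru = np.diag(r)
    Krr = np.diag(1.0 - vrs.u)
    return Megamatrix(grid=grid, Kuu=Kuu, Kur=Kur, Kru=Kru, Krr=Krr, scenario=scenario)
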