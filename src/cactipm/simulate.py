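"""Individual-based synthetic demographic census for a root-contracting cactus.

Generates longitudinal individual x year records (size in mm, survival,
flower counts, root-contraction state) from known ground-truth vital-rate
functions, so that the whole fitting/projection pipeline can be exercised
and validated against the truth without any external data.

Annual event order per individual (census interval t -> t+1):

* unretracted at t: contracts with probability ``r(z)`` (contractors stay
  alive at their current size, which becomes the stored pre-retraction size
  ``z°``); otherwise survives with probability ``s(z)`` and, if surviving,
  grows to ``Normal(g_u(z), sd)``.
* retracted at t: elongates with probability ``u(z°)`` and re-enters the
  unretracted pool at size ``Normal(g_r(z°), sd_r)``.  Retracted individuals
  are not subject to mortality, do not grow and do not reproduce; prolonged
  retraction is terminated by the >5-year censoring rule applied afterwards
  (:func:`apply_censoring_rule`).
* reproduction at t (unretracted only): with probability ``p_b(z)`` the
  individual reproduces and carries a zero-truncated Poisson(``b(z)``)
  number of flowers; each flower independently yields a recruit at t+1 with
  probability ``p_r``, entering at a size drawn from the offspring density.

A small "late discovery" channel adds a few previously overlooked adults to
the census each year, so that new-entrant sizes form the two-component
mixture the recruit-identification step expects in real monitoring data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulationParams",
    "CENSUS_COLUMNS",
    "generate_population",
    "apply_censoring_rule",
    "true_vital_rate_set",
    "true_megamatrix",
]

CENSUS_COLUMNS = ["id", "plot", "year", "size_mm", "alive", "retracted", "flowers", "recruit"]

_REGRESSION_RATES = ("s", "G_u", "G_r", "p_b", "b", "r", "u")


@dataclass
class SimulationParams:
    """Ground-truth parameters of the synthetic population.

    Coefficient pairs are (intercept, slope-in-size) on the link scale:
    logit for the probabilities, log for flower counts.  Growth means are
    piecewise linear in size: annual increment ``increment`` below the
    ``breakpoint`` and declining by ``decline`` mm per mm of size above it,
    emulating the observed slowdown of growth beyond ~35 mm diameter.
    """

    survival: tuple[float, float] = (0.8, 0.08)
    growth_increment: float = 2.0
    growth_breakpoint: float = 35.0
    growth_decline: float = 0.08
    growth_sd: float = 1.5
    regrowth_increment: float = 1.0
    regrowth_decline: float = 0.05
    regrowth_sd: float = 2.0
    reproduction: tuple[float, float] = (-4.0, 0.12)
    flowers: tuple[float, float] = (-0.3, 0.025)
    contraction: tuple[float, float] = (-2.5, -0.08)
    elongation: tuple[float, float] = (1.0, -0.02)
    offspring_mean: float = 8.0
    offspring_sd: float = 2.0
    recruit_probability: float = 0.09
    year_sd: float = 0.3
    plot_sd: float = 0.2
    individual_sd: float = 0.2
    n_individuals: int = 965
    n_years: int = 31
    n_plots: int = 3
    size_range: tuple[float, float] = (0.0, 70.0)
    discovery_rate: float = 2.0
    discovery_mean: float = 30.0
    discovery_sd: float = 10.0
    initial_size_mean: float = 25.0
    initial_size_sd: float = 12.0
    seed: int = 0

    # ---- link-scale linear predictors -------------------------------------
    def eta_survival(self, z):
        return self.survival[0] + self.survival[1] * np.asarray(z, float)

    def eta_reproduction(self, z):
        return self.reproduction[0] + self.reproduction[1] * np.asarray(z, float)

    def eta_flowers(self, z):
        return self.flowers[0] + self.flowers[1] * np.asarray(z, float)

    def eta_contraction(self, z):
        return self.contraction[0] + self.contraction[1] * np.asarray(z, float)

    def eta_elongation(self, z):
        return self.elongation[0] + self.elongation[1] * np.asarray(z, float)

    # ---- response-scale rate functions (zero random-effect deviation) ----
    def s(self, z):
        return expit(self.eta_survival(z))

    def p_b(self, z):
        return expit(self.eta_reproduction(z))

    def b(self, z):
        """Expected flowers per reproducer (zero-truncated Poisson mean)."""
        mu = np.exp(self.eta_flowers(z))
        return mu / np.clip(-np.expm1(-mu), 1e-12, None)

    def r(self, z):
        return expit(self.eta_contraction(z))

    def u(self, z):
        return expit(self.eta_elongation(z))

    def g_u_mean(self, z):
        z = np.asarray(z, float)
        return z + self.growth_increment - self.growth_decline * np.maximum(z - self.growth_breakpoint, 0.0)

    def g_r_mean(self, z):
        z = np.asarray(z, float)
        return z + self.regrowth_increment - self.regrowth_decline * np.maximum(z - self.growth_breakpoint, 0.0)

    def validate(self) -> None:
        lo, hi = self.size_range
        if not hi > lo:
            raise ValueError("size_range: upper bound must exceed lower bound")
        if self.growth_sd <= 0:
            raise ValueError("growth_sd must be > 0")
        if self.regrowth_sd <= 0:
            raise ValueError("regrowth_sd must be > 0")
        if self.offspring_sd <= 0:
            raise ValueError("offspring_sd must be > 0")
        if not lo <= self.offspring_mean <= hi:
            raise ValueError("offspring_mean must lie within size_range")
        if not 0.0 <= self.recruit_probability <= 1.0:
            raise ValueError("recruit_probability must lie in [0, 1]")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        for name in ("year_sd", "plot_sd", "individual_sd", "discovery_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for key in ("survival", "reproduction", "flowers", "contraction", "elongation", "size_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class _Individual:
    uid: int
    plot: int
    size: float
    retracted: bool = False
    dev: dict = field(default_factory=dict)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    draw = rng.normal(mean, sd, size=size)
    return np.clip(draw, lo, hi)


def generate_population(
    params: SimulationParams, seed: int | None = None, *, return_effects: bool = False
):
    """Simulate a longitudinal census table from ground-truth vital rates.

    Returns a tidy frame with columns ``id, plot, year, size_mm, alive,
    retracted, flowers, recruit``; dead individuals get a single terminal
    row with ``alive = 0`` and no size.  The >5-year retraction-censoring
    rule is *not* applied here (see :func:`apply_censoring_rule`).

    With ``return_effects=True`` also returns the drawn year/plot random
    intercept deviations (``{"year": {rate: array}, "plot": {rate: array}}``),
    which parameter-recovery studies can compare against the fitted
    conditional modes.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo, hi = params.size_range
    z_lo, z_hi = max(lo, 0.25), hi - 0.25

    year_dev = {
        rate: rng.normal(0.0, params.year_sd, size=params.n_years)
        for rate in _REGRESSION_RATES
    }
    plot_dev = {
        rate: rng.normal(0.0, params.plot_sd, size=params.n_plots)
        for rate in _REGRESSION_RATES
    }

    def individual_dev():
        if params.individual_sd == 0.0:
            return {}
        return {rate: rng.normal(0.0, params.individual_sd) for rate in _REGRESSION_RATES}

    def dev(ind: _Individual, rate: str, year: int) -> float:
        return (
            year_dev[rate][year]
            + plot_dev[rate][ind.plot]
            + ind.dev.get(rate, 0.0)
        )

    next_uid = 0
    population: list[_Individual] = []
    init_sizes = _truncated_normal(
        rng, params.initial_size_mean, params.initial_size_sd, max(z_lo, 2.0), min(z_hi, 60.0),
        size=params.n_individuals,
    )
    for z0 in init_sizes:
        population.append(
            _Individual(next_uid, int(rng.integers(params.n_plots)), float(z0), dev=individual_dev())
        )
        next_uid += 1

    rows: list[tuple] = []
    recruit_ids: set[int] = set()

    for year in range(params.n_years):
        newcomers: list[_Individual] = []
        n_flowers_by_ind: dict[int, int] = {}
        for ind in population:
            flowers = 0
            if not ind.retracted:
                p_rep = expit(params.eta_reproduction(ind.size) + dev(ind, "p_b", year))
                if rng.random() < p_rep:
                    mu = np.exp(np.clip(params.eta_flowers(ind.size) + dev(ind, "b", year), -30, 30))
                    # zero-truncated Poisson via inverse-cdf conditioning
                    flowers = int(rng.poisson(mu))
                    while flowers == 0:
                        flowers = int(rng.poisson(mu))
            n_flowers_by_ind[ind.uid] = flowers
            rows.append(
                (ind.uid, ind.plot, year, round(float(ind.size), 4), 1, int(ind.retracted), flowers, 0)
            )

        if year == params.n_years - 1:
            break

        survivors: list[_Individual] = []
        for ind in population:
            if ind.retracted:
                p_u = expit(params.eta_elongation(ind.size) + dev(ind, "u", year))
                if rng.random() < p_u:
                    ind.retracted = False
                    mean = params.g_r_mean(ind.size) + dev(ind, "G_r", year)
                    ind.size = float(np.clip(rng.normal(mean, params.regrowth_sd), z_lo, z_hi))
                survivors.append(ind)
                continue
            p_r_contract = expit(params.eta_contraction(ind.size) + dev(ind, "r", year))
            if rng.random() < p_r_contract:
                ind.retracted = True  # stored size = pre-retraction size
                survivors.append(ind)
                continue
            p_s = expit(params.eta_survival(ind.size) + dev(ind, "s", year))
            if rng.random() < p_s:
                mean = params.g_u_mean(ind.size) + dev(ind, "G_u", year)
                ind.size = float(np.clip(rng.normal(mean, params.growth_sd), z_lo, z_hi))
                survivors.append(ind)
            else:
                rows.append((ind.uid, ind.plot, year + 1, np.nan, 0, 0, 0, 0))

        # recruitment: each flower independently establishes with prob p_r
        if params.recruit_probability > 0.0:
            for ind in population:
                nf = n_flowers_by_ind.get(ind.uid, 0)
                if nf == 0:
                    continue
                n_rec = int(rng.binomial(nf, params.recruit_probability))
                for _ in range(n_rec):
                    z_new = float(
                        _truncated_normal(rng, params.offspring_mean, params.offspring_sd, z_lo, z_hi)
                    )
                    newcomers.append(
                        _Individual(next_uid, ind.plot, z_new, dev=individual_dev())
                    )
                    recruit_ids.add(next_uid)
                    next_uid += 1

        # late discoveries of previously overlooked (non-recruit) adults
        if params.discovery_rate > 0.0:
            for _ in range(int(rng.poisson(params.discovery_rate))):
                z_new = float(
                    _truncated_normal(
                        rng, params.discovery_mean, params.discovery_sd, max(z_lo, 5.0), min(z_hi, 60.0)
                    )
                )
                newcomers.append(
                    _Individual(next_uid, int(rng.integers(params.n_plots)), z_new, dev=individual_dev())
                )
                next_uid += 1

        population = survivors + newcomers

    table = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
    # the recruit flag marks the first census row of a true recruit
    first_year = table.groupby("id")["year"].transform("min")
    table["recruit"] = (
        table["id"].isin(recruit_ids) & (table["year"] == first_year) & (table["alive"] == 1)
    ).astype(int)
    table = table.sort_values(["id", "year"], kind="mergesort").reset_index(drop=True)
    if return_effects:
        return table, {"year": year_dev, "plot": plot_dev}
    return table


def apply_censoring_rule(table: pd.DataFrame, max_retracted_years: int = 5) -> pd.DataFrame:
    """Kill individuals retracted for more than ``max_retracted_years`` censuses.

    An individual observed alive-retracted in more than ``max_retracted_years``
    consecutive censuses is recorded dead at the census following the
    threshold year: its (max+1)-th consecutive retracted row becomes a death
    row and any later rows are dropped.  Applying the rule twice is a no-op.
    """
    if max_retracted_years < 1:
        raise ValueError("max_retracted_years must be >= 1")
    if table.empty or not ((table["alive"] == 1) & (table["retracted"] == 1)).any():
        return table.copy().reset_index(drop=True)

    df = table.sort_values(["id", "year"], kind="mergesort").reset_index(drop=True)
    flag = (df["alive"] == 1) & (df["retracted"] == 1)
    # consecutive run length of alive-retracted rows within each individual
    block = (~flag).groupby(df["id"], sort=False).cumsum()
    run = flag.groupby([df["id"], block], sort=False).cumsum()
    kill = flag & (run == max_retracted_years + 1)

    drop_mask = np.zeros(len(df), dtype=bool)
    for idx in np.flatnonzero(kill.to_numpy()):
        uid = df.at[idx, "id"]
        df.at[idx, "alive"] = 0
        df.at[idx, "size_mm"] = np.nan
        df.at[idx, "flowers"] = 0
        df.at[idx, "recruit"] = 0
        later = (df["id"] == uid) & (df.index > idx)
        drop_mask |= later.to_numpy()
    out = df.loc[~drop_mask].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Ground-truth kernels
# ---------------------------------------------------------------------------


def true_vital_rate_set(params: SimulationParams, grid, year_deviations: dict | None = None):
    """Exact (not fitted) vital rates evaluated on an IPM grid.

    ``year_deviations`` optionally maps rate names (s, p_b, b, r, u, G_u,
    G_r) to link-scale intercept shifts, yielding the ground-truth kernel of
    a particular year.
    """
    from .kernels import VitalRateSet

    lo, hi = params.size_range
    if grid.lower > lo or grid.upper < hi:
        raise ValueError("grid narrower than the simulated size domain")
    dv = year_deviations or {}

    def b_shifted(z):
        mu = np.exp(params.eta_flowers(z) + dv.get("b", 0.0))
        return mu / np.clip(-np.expm1(-mu), 1e-12, None)

    return VitalRateSet.from_functions(
        grid,
        s=lambda z: expit(params.eta_survival(z) + dv.get("s", 0.0)),
        p_b=lambda z: expit(params.eta_reproduction(z) + dv.get("p_b", 0.0)),
        b=b_shifted,
        r=lambda z: expit(params.eta_contraction(z) + dv.get("r", 0.0)),
        u=lambda z: expit(params.eta_elongation(z) + dv.get("u", 0.0)),
        g_u_mean=lambda z: params.g_u_mean(z) + dv.get("G_u", 0.0),
        g_u_sd=params.growth_sd,
        g_r_mean=lambda z: params.g_r_mean(z) + dv.get("G_r", 0.0),
        g_r_sd=params.regrowth_sd,
        offspring_mean=params.offspring_mean,
        offspring_sd=params.offspring_sd,
        p_r=params.recruit_probability,
    )


def true_megamatrix(params: SimulationParams, grid, scenario: str = "with_contraction", **kwargs):
    """Megamatrix built from the exact ground-truth vital-rate functions.

    By construction identical to ``build_megamatrix`` applied to the
    ``VitalRateSet`` holding the true functions.
    """
    from .kernels import build_megamatrix

    vrs = true_vital_rate_set(params, grid)
    return build_megamatrix(vrs, grid, scenario=scenario, **kwargs)
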