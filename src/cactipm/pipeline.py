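"""End-to-end orchestration: census -> fitted rates -> kernels -> metrics.

``run_pipeline`` executes the whole analysis: simulate or read a census,
apply the retraction-censoring rule, fit the seven regression rates (full
stepwise selection or a fast direct fit), estimate the offspring-size
mixture and the establishment probability, assemble the megamatrix for the
with/without-contraction scenarios, and compute lambda, stable structures,
reproductive values, annual lambdas and all elasticities.  Every source of
randomness descends from the single configured seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import ScenarioComparison, scenario_comparison
from .config import PipelineConfig
from .kernels import IPMGrid, VitalRateSet, growth_matrix, make_grid, offspring_masses
from .perturbation import ElasticityReport, vital_rate_elasticities
from .simulate import apply_censoring_rule, generate_population, true_megamatrix
from .vitalrates import (
    ExtrapolationWarning,
    FitError,
    OffspringDist,
    VitalRateModel,
    estimate_recruit_probability,
    fit_vital_rate,
    identify_recruits,
    rate_records,
    spec_for,
    stepwise_select,
)

__all__ = ["FittedRates", "PipelineResult", "fit_all_rates", "run_pipeline"]

log = logging.getLogger("cactipm")

REGRESSION_RATES = ("s", "G_u", "G_r", "p_b", "b", "r", "u")

#: fixed-effect forms used by the fast direct fit (no model selection);
#: growth gets the smooth form because its mean bends at the breakpoint.
DIRECT_FORMS = {
    "s": "linear",
    "G_u": "smooth",
    "G_r": "smooth",
    "p_b": "linear",
    "b": "linear",
    "r": "linear",
    "u": "linear",
}


@dataclass
class FittedRates:
    """The complete fitted vital-rate set of one census."""

    models: dict  # rate -> VitalRateModel
    offspring: OffspringDist
    p_r: float
    fixed: dict = field(default_factory=dict)  # rate -> constant (e.g. forced r = 0)

    def on_grid(self, grid: IPMGrid, year_deviations: dict | None = None) -> VitalRateSet:
        """Evaluate all rates on an IPM grid, optionally shifted per year.

        ``year_deviations`` maps rate names to link-scale offsets (the
        conditional modes of a given year); rates without an entry stay at
        their population-level curve.
        """
        devs = year_deviations or {}
        z = grid.midpoints

        def values(rate: str) -> np.ndarray:
            if rate in self.fixed:
                return np.full(grid.n, float(self.fixed[rate]))
            model: VitalRateModel = self.models[rate]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                return model.predict(z, devs.get(rate, 0.0), warn=False)

        def growth(rate: str):
            source = rate if rate in self.models else "G_u"
            model: VitalRateModel = self.models[source]
            dev = devs.get(rate, 0.0)
            return growth_matrix(
                lambda zz: model.predict(zz, dev, warn=False), model.resid_sd, grid
            )

        return VitalRateSet(
            grid=grid,
            s=values("s"),
            p_b=values("p_b"),
            b=values("b"),
            r=values("r"),
            u=values("u"),
            G_u=growth("G_u"),
            G_r=growth("G_r"),
            c=offspring_masses(self.offspring.mean, self.offspring.sd, grid),
            p_r=self.p_r,
        )

    def to_dict(self) -> dict:
        return {
            "models": {k: m.to_dict() for k, m in self.models.items()},
            "offspring": self.offspring.to_dict(),
            "p_r": float(self.p_r),
            "fixed": {k: float(v) for k, v in self.fixed.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedRates":
        return cls(
            models={k: VitalRateModel.from_dict(m) for k, m in d["models"].items()},
            offspring=OffspringDist.from_dict(d["offspring"]),
            p_r=float(d["p_r"]),
            fixed={k: float(v) for k, v in d.get("fixed", {}).items()},
        )


def _new_entrants(census: pd.DataFrame) -> pd.DataFrame:
    """First alive row of every individual not present at the initial census."""
    alive = census[census["alive"] == 1]
    first = alive.sort_values(["id", "year"], kind="mergesort").groupby("id", as_index=False).first()
    return first[first["year"] > int(census["year"].min())]


def estimate_establishment(census: pd.DataFrame) -> tuple[OffspringDist, float]:
    """Offspring-size mixture and pooled recruit probability from a census."""
    entrants = _new_entrants(census)
    dist, is_recruit = identify_recruits(entrants["size_mm"].to_numpy())
    recruit_years = entrants.loc[is_recruit, "year"].to_numpy()
    years = np.arange(int(census["year"].min()), int(census["year"].max()) + 1)
    alive_unretr = census[(census["alive"] == 1) & (census["retracted"] == 0)]
    structures_by_year = alive_unretr.groupby("year")["flowers"].sum()
    structures = np.array([structures_by_year.get(y, 0) for y in years[:-1]], dtype=float)
    recruits = np.array([(recruit_years == y).sum() for y in years[1:]], dtype=float)
    p_r = estimate_recruit_probability(recruits, structures)
    return dist, p_r


def fit_all_rates(
    census: pd.DataFrame,
    *,
    selection: str = "stepwise",
    random_candidates: tuple[str, ...] = ("individual", "year", "plot"),
    force_no_contraction: bool = False,
) -> FittedRates:
    """Fit every vital rate of a census table.

    ``selection='stepwise'`` runs the full backward AIC selection over both
    fixed-effect forms; ``'direct'`` fits each rate once with its
    conventional form and a year random intercept (fast path used for
    large simulation studies).
    """
    models: dict[str, VitalRateModel] = {}
    fixed: dict[str, float] = {}
    rates = list(REGRESSION_RATES)
    if force_no_contraction:
        rates = [x for x in rates if x not in ("r", "u", "G_r")]
        fixed = {"r": 0.0, "u": 1.0}
    for rate in rates:
        records = rate_records(census, rate)
        log.info("fitting %s on %d records", rate, len(records))
        if selection == "stepwise":
            spec = spec_for(rate, random_candidates=random_candidates)
            model = stepwise_select(records, spec)
        else:
            spec = spec_for(rate)
            # small record sets (elongation, regrowth) cannot support an
            # individual-level intercept; keep the year effect everywhere
            effects = ("individual", "year", "plot") if len(records) >= 2000 else ("year",)
            model = fit_vital_rate(
                records, spec, form=DIRECT_FORMS[rate], random_effects=effects
            )
        log.info(
            "  %s: form=%s random=%s AIC=%.2f", rate, model.form,
            tuple(k for k in model.sigma2 if k != "_spline"), model.aic,
        )
        models[rate] = model
    offspring, p_r = estimate_establishment(census)
    log.info("offspring mean %.2f mm (sd %.2f); p_r = %.4f", offspring.mean, offspring.sd, p_r)
    return FittedRates(models=models, offspring=offspring, p_r=p_r, fixed=fixed)


@dataclass
class PipelineResult:
    """In-memory bundle of everything a pipeline run produced."""

    config: PipelineConfig
    census: pd.DataFrame
    rates: FittedRates
    vital_rate_set: VitalRateSet
    comparison: ScenarioComparison
    elasticities: ElasticityReport
    true_lambda: float | None = None  # known only for simulated input

    @property
    def grid(self) -> IPMGrid:
        return self.vital_rate_set.grid


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``."""
    grid = make_grid(config.grid_lower, config.grid_upper, config.grid_n)
    kernel_options = dict(
        elongation_growth=config.elongation_growth,
        retracted_survival=config.retracted_survival,
    )

    if config.simulation is not None:
        params = config.simulation
        log.info(
            "simulating census: %d individuals x %d years (seed %d)",
            params.n_individuals, params.n_years, config.seed,
        )
        census = generate_population(params, seed=config.seed)
    else:
        from .io import read_census

        log.info("reading census from %s", config.census_path)
        census = read_census(config.census_path)
    if config.apply_censoring:
        census = apply_censoring_rule(census, config.max_retracted_years)
    log.info(
        "census: %d rows, %d individuals, years %d-%d",
        len(census), census["id"].nunique(), census["year"].min(), census["year"].max(),
    )

    try:
        rates = fit_all_rates(
            census,
            selection=config.selection,
            random_candidates=config.random_candidates,
            force_no_contraction=config.force_no_contraction,
        )
    except FitError as exc:
        log.error("vital-rate fitting failed: %s", exc)
        raise

    vrs = rates.on_grid(grid)
    comparison = scenario_comparison(
        vrs, grid, rates, tol=config.tol, max_iter=config.max_iter, **kernel_options
    )
    log.info(
        "lambda with contraction %.4f, without %.4f",
        comparison.with_contraction.lam, comparison.without_contraction.lam,
    )
    elasticities = vital_rate_elasticities(
        vrs, grid, "with_contraction", config.delta, **kernel_options
    )

    true_lam = None
    if config.simulation is not None:
        mm_true = true_megamatrix(config.simulation, grid, "with_contraction", **kernel_options)
        from .analysis import dominant_eigentriple

        true_lam, _, _ = dominant_eigentriple(mm_true.A, tol=config.tol, max_iter=config.max_iter)
        log.info("ground-truth lambda %.4f (recovery error %.4f)",
                 true_lam, abs(comparison.with_contraction.lam - true_lam))

    return PipelineResult(
        config=config,
        census=census,
        rates=rates,
        vital_rate_set=vrs,
        comparison=comparison,
        elasticities=elasticities,
        true_lambda=true_lam,
    )
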