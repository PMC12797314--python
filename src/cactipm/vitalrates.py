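"""Size-dependent vital-rate regressions and their AIC-based selection.

Each regression rate (survival s, growths G_u/G_r, reproduction probability
p_b, flower count b, contraction r, elongation u) is modelled on its link
scale as a function of size, either linearly or through a penalized cubic
spline, with optional intercept-only random effects for individual, year
and plot.  Model selection mirrors the field's standard protocol: for each
fixed-effect form, random-effect groupings are backward-eliminated while
elimination does not increase the AIC, and the lower-AIC of the two final
candidates wins (ties resolve toward fewer parameters, i.e. the linear
form).

The offspring-size density c is a two-component Gaussian mixture over
new-entrant sizes (EM initialized from a 2-means partition); the component
with the smaller mean is the recruit/offspring distribution.  The
establishment probability p_r is the pooled ratio of recruits at t+1 to
reproductive structures at t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._fitting import (
    FitError,
    SeparationError,
    SplineBasis,
    fit_penalized_glm,
    get_family,
    group_design,
    make_spline_basis,
)

__all__ = [
    "TABLE_STRUCTURE",
    "ModelSpec",
    "VitalRateModel",
    "OffspringDist",
    "ExtrapolationWarning",
    "spec_for",
    "fit_vital_rate",
    "stepwise_select",
    "predict_rate",
    "fit_offspring_distribution",
    "identify_recruits",
    "estimate_recruit_probability",
    "rate_records",
    "FitError",
    "SeparationError",
]

#: (link, family) structure of each regression rate.
TABLE_STRUCTURE = {
    "s": ("logit", "binomial"),
    "G_u": ("identity", "gaussian"),
    "G_r": ("identity", "gaussian"),
    "p_b": ("logit", "binomial"),
    "b": ("log", "poisson"),
    "r": ("logit", "binomial"),
    "u": ("logit", "binomial"),
}

RANDOM_GROUPINGS = ("individual", "year", "plot")

MIN_OBSERVATIONS = 20


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted data's size support."""


@dataclass(frozen=True)
class ModelSpec:
    """Declares the (link, family) structure and candidates for one rate."""

    rate: str
    link: str
    family: str
    form: str | None = None  # 'linear' | 'smooth' | None (= select)
    random_candidates: tuple[str, ...] = RANDOM_GROUPINGS

    def __post_init__(self):
        if self.rate not in TABLE_STRUCTURE:
            raise ValueError(f"unknown vital rate {self.rate!r}")
        if (self.link, self.family) != TABLE_STRUCTURE[self.rate]:
            raise ValueError(
                f"rate {self.rate!r} must use link={TABLE_STRUCTURE[self.rate][0]!r}, "
                f"family={TABLE_STRUCTURE[self.rate][1]!r}"
            )
        if self.form not in (None, "linear", "smooth"):
            raise ValueError("form must be 'linear', 'smooth' or None")
        for g in self.random_candidates:
            if g not in RANDOM_GROUPINGS:
                raise ValueError(f"unknown random-effect grouping {g!r}")


def spec_for(rate: str, form: str | None = None, random_candidates=RANDOM_GROUPINGS) -> ModelSpec:
    link, family = TABLE_STRUCTURE[rate]
    return ModelSpec(rate=rate, link=link, family=family, form=form, random_candidates=tuple(random_candidates))


def _likelihood_family(spec: ModelSpec) -> str:
    # flower counts of reproducers never include zeros: zero-truncated Poisson
    return "truncated_poisson" if spec.rate == "b" else spec.family


@dataclass
class VitalRateModel:
    """One fitted size-dependent vital rate."""

    rate: str
    link: str
    family: str
    form: str
    coef: np.ndarray  # intercept, size slope
    spline: SplineBasis | None
    spline_coef: np.ndarray | None
    sigma2: dict
    year_modes: dict
    resid_sd: float | None
    aic: float
    loglik: float
    n_obs: int
    support: tuple[float, float]
    selection_trail: list = field(default_factory=list, repr=False)

    @property
    def random_effects(self) -> tuple[str, ...]:
        return tuple(self.sigma2.keys())

    def linpred(self, sizes, year_deviation: float = 0.0) -> np.ndarray:
        z = np.atleast_1d(np.asarray(sizes, dtype=float))
        eta = self.coef[0] + self.coef[1] * z + float(year_deviation)
        if self.spline is not None:
            eta = eta + np.asarray(self.spline.design(z) @ self.spline_coef).ravel()
        return eta

    def predict(self, sizes, year_deviation: float = 0.0, *, warn: bool = True) -> np.ndarray:
        z = np.atleast_1d(np.asarray(sizes, dtype=float))
        if warn and (z.min() < self.support[0] - 1e-9 or z.max() > self.support[1] + 1e-9):
            warnings.warn(
                f"predicting vital rate {self.rate!r} outside the fitted size "
                f"support [{self.support[0]:.1f}, {self.support[1]:.1f}] mm",
                ExtrapolationWarning,
                stacklevel=2,
            )
        eta = self.linpred(z, year_deviation)
        fam = get_family(_likelihood_family_name(self))
        return fam.mean(eta)

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "rate": self.rate,
            "link": self.link,
            "family": self.family,
            "form": self.form,
            "coef": self.coef.tolist(),
            "sigma2": {k: float(v) for k, v in self.sigma2.items()},
            "year_modes": {str(k): float(v) for k, v in self.year_modes.items()},
            "resid_sd": None if self.resid_sd is None else float(self.resid_sd),
            "aic": float(self.aic),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "support": [float(self.support[0]), float(self.support[1])],
        }
        if self.spline is not None:
            d["spline"] = {
                "knots": self.spline.knots.tolist(),
                "degree": int(self.spline.degree),
                "xmin": float(self.spline.xmin),
                "xmax": float(self.spline.xmax),
                "transform": self.spline.transform.tolist(),
                "coef": self.spline_coef.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VitalRateModel":
        spline = None
        spline_coef = None
        if "spline" in d and d["spline"] is not None:
            sd = d["spline"]
            spline = SplineBasis(
                knots=np.asarray(sd["knots"], float),
                degree=int(sd["degree"]),
                xmin=float(sd["xmin"]),
                xmax=float(sd["xmax"]),
                transform=np.asarray(sd["transform"], float),
            )
            spline_coef = np.asarray(sd["coef"], float)
        return cls(
            rate=d["rate"],
            link=d["link"],
            family=d["family"],
            form=d["form"],
            coef=np.asarray(d["coef"], float),
            spline=spline,
            spline_coef=spline_coef,
            sigma2={k: float(v) for k, v in d["sigma2"].items()},
            year_modes={int(k): float(v) for k, v in d["year_modes"].items()},
            resid_sd=None if d.get("resid_sd") is None else float(d["resid_sd"]),
            aic=float(d["aic"]),
            loglik=float(d["loglik"]),
            n_obs=int(d["n_obs"]),
            support=(float(d["support"][0]), float(d["support"][1])),
        )


def _likelihood_family_name(model: VitalRateModel) -> str:
    return "truncated_poisson" if model.rate == "b" else model.family


def predict_rate(model: VitalRateModel, sizes, year_deviation: float = 0.0, *, warn: bool = True) -> np.ndarray:
    """Evaluate a fitted rate on the response scale at the given sizes."""
    return model.predict(sizes, year_deviation, warn=warn)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _validate_records(records: pd.DataFrame, spec: ModelSpec, random_effects) -> pd.DataFrame:
    required = {"size", "response"} | set(random_effects)
    missing = required - set(records.columns)
    if missing:
        raise FitError(f"rate {spec.rate!r}: records missing columns {sorted(missing)}")
    rec = records.dropna(subset=["size", "response"])
    if len(rec) < MIN_OBSERVATIONS:
        raise FitError(
            f"rate {spec.rate!r}: needs >= {MIN_OBSERVATIONS} observations, got {len(rec)}"
        )
    return rec


def fit_vital_rate(
    records: pd.DataFrame,
    spec: ModelSpec,
    *,
    form: str | None = None,
    random_effects: tuple[str, ...] = (),
    nbasis: int = 10,
    s2_init: dict | None = None,
) -> VitalRateModel:
    """Fit one vital-rate model with a given form and random-effect set.

    ``records`` must carry columns ``size`` and ``response`` plus a label
    column for every requested random-effect grouping.
    """
    form = form or spec.form or "linear"
    if form not in ("linear", "smooth"):
        raise FitError("form must be 'linear' or 'smooth'")
    rec = _validate_records(records, spec, random_effects)
    z = rec["size"].to_numpy(dtype=float)
    y = rec["response"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(z), z])

    blocks = []
    spline = None
    if form == "smooth":
        spline = make_spline_basis(float(z.min()), float(z.max()), nbasis=nbasis)
        blocks.append(("_spline", spline.design(z)))
    level_maps = {}
    for g in random_effects:
        zg, levels = group_design(rec[g].to_numpy())
        if len(levels) < 2:
            continue  # a single level is indistinguishable from the intercept
        blocks.append((g, zg))
        level_maps[g] = levels

    fam_name = _likelihood_family(spec)
    res = fit_penalized_glm(
        y, X, blocks, fam_name, label=f"vital rate {spec.rate!r}", s2_init=s2_init
    )

    year_modes = {}
    if "year" in level_maps:
        modes = res.block_coefs["year"]
        year_modes = {int(lv): float(m) for lv, m in zip(level_maps["year"], modes)}
    sigma2 = {g: res.sigma2[g] for g in level_maps}
    if spline is not None:
        sigma2["_spline"] = res.sigma2["_spline"]
    return VitalRateModel(
        rate=spec.rate,
        link=spec.link,
        family=spec.family,
        form=form,
        coef=res.beta,
        spline=spline,
        spline_coef=res.block_coefs.get("_spline"),
        sigma2=sigma2,
        year_modes=year_modes,
        resid_sd=float(np.sqrt(res.phi)) if spec.family == "gaussian" else None,
        aic=res.aic,
        loglik=res.loglik,
        n_obs=res.n_obs,
        support=(float(z.min()), float(z.max())),
    )


def stepwise_select(records: pd.DataFrame, spec: ModelSpec) -> VitalRateModel:
    """Backward AIC elimination of random effects, for linear and smooth forms.

    For each fixed-effect form the full random-effect set is reduced
    greedily: the elimination yielding the lowest AIC is accepted while it
    does not increase the AIC.  The lower-AIC of the two final candidates is
    returned; exact ties go to the linear form (fewer parameters).
    """
    trail: list[tuple[str, tuple[str, ...], float]] = []
    failures: list[str] = []
    finalists: dict[str, VitalRateModel] = {}

    candidates = tuple(
        g for g in spec.random_candidates if g in records.columns and records[g].nunique() > 1
    )

    for form in ("linear", "smooth"):
        if spec.form is not None and form != spec.form:
            continue
        try:
            current_set = candidates
            model = fit_vital_rate(records, spec, form=form, random_effects=current_set)
            trail.append((form, current_set, model.aic))
        except FitError as exc:
            failures.append(f"{form} full model: {exc}")
            continue
        while current_set:
            best_drop, best_model = None, None
            for g in current_set:
                reduced = tuple(x for x in current_set if x != g)
                try:
                    cand = fit_vital_rate(
                        records, spec, form=form, random_effects=reduced,
                        s2_init=model.sigma2,
                    )
                except FitError as exc:
                    failures.append(f"{form} without {g}: {exc}")
                    continue
                trail.append((form, reduced, cand.aic))
                if best_model is None or cand.aic < best_model.aic:
                    best_drop, best_model = g, cand
            if best_model is not None and best_model.aic <= model.aic + 1e-9:
                current_set = tuple(x for x in current_set if x != best_drop)
                model = best_model
            else:
                break
        finalists[form] = model

    if not finalists:
        raise FitError(
            f"rate {spec.rate!r}: every candidate model failed: " + "; ".join(failures)
        )
    if len(finalists) == 1:
        winner = next(iter(finalists.values()))
    else:
        lin, smo = finalists["linear"], finalists["smooth"]
        winner = smo if smo.aic < lin.aic - 1e-9 else lin
    winner.selection_trail = trail
    return winner


# ---------------------------------------------------------------------------
# Offspring distribution and establishment probability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffspringDist:
    """Low-mean component of the new-entrant size mixture (mm)."""

    mean: float
    sd: float
    weight: float

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "weight": self.weight}

    @classmethod
    def from_dict(cls, d: dict) -> "OffspringDist":
        return cls(mean=float(d["mean"]), sd=float(d["sd"]), weight=float(d["weight"]))


def identify_recruits(new_entrant_sizes) -> tuple[OffspringDist, np.ndarray]:
    """Fit the 2-component size mixture and flag the recruit component.

    Returns the offspring distribution (smaller-mean component) and a
    boolean mask marking entrants with posterior probability > 0.5 of
    belonging to it.
    """
    sizes = np.asarray(new_entrant_sizes, dtype=float).ravel()
    sizes = sizes[np.isfinite(sizes)]
    if sizes.size < 10:
        raise ValueError(f"offspring distribution needs >= 10 sizes, got {sizes.size}")
    if np.ptp(sizes) == 0.0:
        raise ValueError("degenerate offspring mixture: all new-entrant sizes identical")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        init_params="kmeans",
        n_init=2,
        reg_covar=1e-6,
        random_state=0,
        max_iter=500,
    ).fit(sizes[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    low = int(np.argmin(means))
    post = gm.predict_proba(sizes[:, None])[:, low]
    dist = OffspringDist(mean=float(means[low]), sd=float(sds[low]), weight=float(weights[low]))
    return dist, post > 0.5


def fit_offspring_distribution(new_entrant_sizes) -> OffspringDist:
    """Two-component Gaussian mixture; returns the smaller-mean component."""
    dist, _ = identify_recruits(new_entrant_sizes)
    return dist


def estimate_recruit_probability(recruits_per_year, structures_per_year) -> float:
    """Pooled ratio of recruits at t+1 to reproductive structures at t.

    The two series must already be aligned so that ``recruits_per_year[i]``
    follows ``structures_per_year[i]``.
    """
    rec = np.asarray(recruits_per_year, dtype=float)
    st = np.asarray(structures_per_year, dtype=float)
    if rec.shape != st.shape:
        raise ValueError("recruit and structure series must have equal length")
    total_structures = float(st.sum())
    if total_structures <= 0:
        raise ValueError("undefined recruit probability: zero reproductive structures")
    return float(np.clip(rec.sum() / total_structures, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Record extraction from a census table
# ---------------------------------------------------------------------------


def rate_records(census: pd.DataFrame, rate: str) -> pd.DataFrame:
    """Response/size pairs for one vital rate from a longitudinal census.

    Transition-based rates pair each row with the same individual's row in
    the following calendar year.  The survival response is restricted to
    non-contracting transitions (contraction and survival are modelled as
    separate, sequential events and retracted individuals are assumed
    immortal), and elongation is conditioned on being observed alive.
    """
    if rate not in TABLE_STRUCTURE:
        raise ValueError(f"unknown vital rate {rate!r}")
    d = census.sort_values(["id", "year"], kind="mergesort").reset_index(drop=True)
    nxt = d.groupby("id", sort=False)[["year", "size_mm", "alive", "retracted"]].shift(-1)
    contig = nxt["year"] == d["year"] + 1

    cur_alive = d["alive"] == 1
    cur_unretr = cur_alive & (d["retracted"] == 0)
    cur_retr = cur_alive & (d["retracted"] == 1)
    nxt_alive = nxt["alive"] == 1
    nxt_retr = nxt_alive & (nxt["retracted"] == 1)
    nxt_unretr = nxt_alive & (nxt["retracted"] == 0)

    def frame(mask, response, size=None):
        out = pd.DataFrame(
            {
                "size": (d["size_mm"] if size is None else size)[mask].to_numpy(dtype=float),
                "response": np.asarray(response[mask], dtype=float),
                "individual": d["id"][mask].to_numpy(),
                "year": d["year"][mask].to_numpy(),
                "plot": d["plot"][mask].to_numpy(),
            }
        )
        return out.dropna(subset=["size", "response"]).reset_index(drop=True)

    if rate == "s":
        mask = cur_unretr & contig & ~nxt_retr
        return frame(mask, nxt_alive.astype(float))
    if rate == "r":
        mask = cur_unretr & contig
        return frame(mask, nxt_retr.astype(float))
    if rate == "u":
        mask = cur_retr & contig & nxt_alive
        return frame(mask, nxt_unretr.astype(float))
    if rate == "G_u":
        mask = cur_unretr & contig & nxt_unretr
        out = frame(mask, nxt["size_mm"])
        return out
    if rate == "G_r":
        mask = cur_retr & contig & nxt_unretr
        return frame(mask, nxt["size_mm"])
    if rate == "p_b":
        mask = cur_unretr
        return frame(mask, (d["flowers"] > 0).astype(float))
    if rate == "b":
        mask = cur_unretr & (d["flowers"] > 0)
        return frame(mask, d["flowers"].astype(float))
    raise AssertionError("unreachable")
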