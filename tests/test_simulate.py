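"""Synthetic census generator: invariants, censoring rule, Monte-Carlo fidelity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import cactipm as c


def params(**kw):
    return dataclasses.replace(c.SimulationParams(), **kw)


# ---------------------------------------------------------------------------
# generate_population
# ---------------------------------------------------------------------------


def test_degenerate_rates_keep_everyone_alive():
    """Survival 1, no contraction, no recruitment: 3 x 5 rows, all alive."""
    p = params(
        survival=(30.0, 0.0),
        contraction=(-30.0, 0.0),
        recruit_probability=0.0,
        discovery_rate=0.0,
        n_individuals=3,
        n_years=5,
    )
    table = c.generate_population(p, seed=0)
    assert len(table) == 15
    assert (table["alive"] == 1).all()
    assert (table["retracted"] == 0).all()
    assert table.groupby("id")["year"].count().eq(5).all()


def test_forced_contraction_and_elongation_alternate():
    """r = u = 1: every retraction spell lasts exactly one census interval."""
    p = params(
        contraction=(30.0, 0.0),
        elongation=(30.0, 0.0),
        recruit_probability=0.0,
        discovery_rate=0.0,
        n_individuals=5,
        n_years=6,
    )
    table = c.generate_population(p, seed=0)
    assert (table["alive"] == 1).all()
    for _, rows in table.groupby("id"):
        states = rows.sort_values("year")["retracted"].to_numpy()
        np.testing.assert_array_equal(states, [0, 1, 0, 1, 0, 1])


def test_census_table_invariants_on_default_run():
    p = params(n_individuals=120, n_years=15)
    table = c.generate_population(p, seed=5)
    # at most one row per individual-year
    assert not table.duplicated(["id", "year"]).any()
    # retracted rows never carry flowers
    assert (table.loc[table["retracted"] == 1, "flowers"] == 0).all()
    # alive rows have positive sizes; death rows none
    assert (table.loc[table["alive"] == 1, "size_mm"] > 0).all()
    assert table.loc[table["alive"] == 0, "size_mm"].isna().all()
    # no rows after the first death
    for _, rows in table.groupby("id"):
        alive = rows.sort_values("year")["alive"].to_numpy()
        if (alive == 0).any():
            assert alive[-1] == 0 and (alive[:-1] == 1).all()
    # retracted individuals keep their stored size
    sub = table[table["alive"] == 1].sort_values(["id", "year"])
    prev = sub.groupby("id")[["size_mm", "retracted"]].shift(1)
    stay_retracted = (sub["retracted"] == 1) & (prev["retracted"] == 1)
    np.testing.assert_allclose(
        sub.loc[stay_retracted, "size_mm"], prev.loc[stay_retracted, "size_mm"]
    )


def test_conservation_without_recruitment_or_discovery():
    """With p_r = 0 and no discoveries, the id pool never grows."""
    p = params(recruit_probability=0.0, discovery_rate=0.0, n_individuals=80, n_years=20)
    table = c.generate_population(p, seed=9)
    counts = table[table["alive"] == 1].groupby("year")["id"].nunique()
    assert (counts.diff().dropna() <= 0).all()


@pytest.mark.parametrize(
    "field, value, message",
    [
        ("growth_sd", -1.0, "growth_sd"),
        ("n_years", 1, "n_years"),
        ("offspring_mean", 200.0, "offspring_mean"),
        ("recruit_probability", 1.5, "recruit_probability"),
        ("year_sd", -0.1, "year_sd"),
    ],
)
def test_invalid_params_error_names_field(field, value, message):
    p = params(**{field: value})
    with pytest.raises(ValueError, match=message):
        c.generate_population(p, seed=0)


# ---------------------------------------------------------------------------
# Monte-Carlo fidelity
# ---------------------------------------------------------------------------


def test_transition_frequencies_match_ground_truth():
    """Empirical survival/contraction/elongation match truth per size bin."""
    p = params(
        year_sd=0.0, plot_sd=0.0, individual_sd=0.0,
        n_individuals=600, n_years=20, discovery_rate=0.0,
    )
    table = c.generate_population(p, seed=12345)
    assert len(table) >= 10_000
    checks = {"s": p.s, "r": p.r, "u": p.u}
    for rate, truth in checks.items():
        rec = c.rate_records(table, rate)
        edges = np.quantile(rec["size"], np.linspace(0, 1, 11))
        bins = np.clip(np.searchsorted(edges[1:-1], rec["size"]), 0, 9)
        for k in range(10):
            sel = bins == k
            n_k = int(sel.sum())
            if n_k < 25:
                continue
            p_true = float(np.mean(truth(rec.loc[sel, "size"])))
            p_emp = float(rec.loc[sel, "response"].mean())
            se = np.sqrt(max(p_true * (1 - p_true), 1e-12) / n_k)
            assert abs(p_emp - p_true) <= 3 * se + 1e-9, (rate, k, p_emp, p_true)


def test_ever_retracted_fraction_matches_independent_simulation():
    """Generator incidence agrees with a hand-rolled per-individual oracle."""
    p = params(year_sd=0.0, plot_sd=0.0, individual_sd=0.0,
               n_individuals=1000, n_years=31)
    table = c.generate_population(p, seed=2024)
    initial = table[table["year"] == 0]["id"].unique()
    ever = table[table["id"].isin(initial)].groupby("id")["retracted"].max()
    frac_gen = float(ever.mean())

    # independent oracle: simulate each founder's state chain directly
    rng = np.random.default_rng(77)
    sizes = table[(table["year"] == 0)].sort_values("id")["size_mm"].to_numpy()
    hits = 0
    for z in sizes:
        retracted, ever_r, alive = False, False, True
        zz = float(z)
        for _ in range(p.n_years - 1):
            if not alive:
                break
            if retracted:
                if rng.random() < expit(p.eta_elongation(zz)):
                    retracted = False
                    zz = float(np.clip(rng.normal(p.g_r_mean(zz), p.regrowth_sd), 0.25, 69.75))
                continue
            if rng.random() < expit(p.eta_contraction(zz)):
                retracted = ever_r = True
                continue
            if rng.random() < expit(p.eta_survival(zz)):
                zz = float(np.clip(rng.normal(p.g_u_mean(zz), p.growth_sd), 0.25, 69.75))
            else:
                alive = False
        hits += ever_r
    frac_oracle = hits / len(sizes)
    n = len(sizes)
    se = np.sqrt(frac_oracle * (1 - frac_oracle) / n)
    assert abs(frac_gen - frac_oracle) <= 3 * np.sqrt(2) * se


# ---------------------------------------------------------------------------
# apply_censoring_rule
# ---------------------------------------------------------------------------


def _toy_table(states):
    """Build a one-individual table from a string of U/R per year."""
    rows = [
        dict(id=1, plot=0, year=t, size_mm=20.0, alive=1,
             retracted=int(s == "R"), flowers=0, recruit=0)
        for t, s in enumerate(states)
    ]
    return pd.DataFrame(rows)


def test_censoring_kills_after_threshold():
    table = _toy_table("URRRRRRRR")  # retracted from year 1 onward
    out = c.apply_censoring_rule(table, max_retracted_years=5)
    # five retracted censuses tolerated, death recorded at the sixth
    assert len(out) == 7
    assert out.iloc[-1]["alive"] == 0 and np.isnan(out.iloc[-1]["size_mm"])
    assert (out.iloc[1:6]["retracted"] == 1).all() and (out.iloc[1:6]["alive"] == 1).all()


def test_censoring_boundary_spares_five_year_spell():
    table = _toy_table("URRRRRU")  # exactly five retracted years, then elongates
    out = c.apply_censoring_rule(table, max_retracted_years=5)
    pd.testing.assert_frame_equal(out, table)


def test_censoring_identity_without_retraction():
    table = _toy_table("UUUU")
    out = c.apply_censoring_rule(table, max_retracted_years=5)
    pd.testing.assert_frame_equal(out, table)


def test_censoring_is_idempotent():
    p = params(contraction=(0.5, -0.02), elongation=(-1.5, 0.0),
               n_individuals=150, n_years=18)
    table = c.generate_population(p, seed=3)
    once = c.apply_censoring_rule(table)
    twice = c.apply_censoring_rule(once)
    pd.testing.assert_frame_equal(once, twice)
    assert len(once) < len(table)  # long retraction spells exist and were cut


# ---------------------------------------------------------------------------
# ground-truth kernels
# ---------------------------------------------------------------------------


def test_true_megamatrix_consistent_with_builder(default_params, grid200):
    mm = c.true_megamatrix(default_params, grid200)
    vrs = c.true_vital_rate_set(default_params, grid200)
    ref = c.build_megamatrix(vrs, grid200)
    assert np.array_equal(mm.A, ref.A)


def test_true_megamatrix_rejects_narrow_grid(default_params):
    with pytest.raises(ValueError, match="narrow"):
        c.true_megamatrix(default_params, c.make_grid(10.0, 60.0, 50))


def test_no_contraction_zeroes_the_retraction_blocks(default_params, grid200):
    p = dataclasses.replace(default_params, contraction=(-40.0, 0.0))
    mm = c.true_megamatrix(p, grid200)
    assert np.allclose(mm.Kru, 0.0, atol=1e-15)
    np.testing.assert_allclose(
        np.diag(mm.Krr), 1.0 - c.true_vital_rate_set(p, grid200).u
    )
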