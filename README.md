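# cactipm

Two-state, size-structured integral projection models (IPMs) for
root-contracting cacti.

Some semi-globose cacti — *Pediocactus bradyi* of northern Arizona is the
motivating case — survive extreme drought by **root contraction**: the
roots shorten and pull the stem below ground, where the plant neither grows
nor reproduces until **root elongation** returns it to the surface.  For a
demographer this raises a concrete question: does the ability to retract
actually increase the long-term population growth rate, or does the lost
growth and reproduction cancel the survival benefit?  `cactipm` is built to
answer that question from longitudinal census data: individual stem
diameters, survival, flower counts and retraction status recorded yearly.

## The model

The population is described by densities `n_u(z, t)` (unretracted, diameter
`z` in mm) and `n_r(z°, t)` (retracted, frozen at pre-retraction diameter
`z°`), projected one census interval by

```
n_u(z', t+1) = ∫ K_uu(z', z) n_u(z, t) dz + ∫ K_ur(z', z°) n_r(z°, t) dz°
n_r(z°, t+1) = ∫ K_ru(z°, z) n_u(z, t) dz + ∫ K_rr(z°, z°) n_r(z°, t) dz°

K_uu = (1 − r(z)) [ s(z) G_u(z'|z) + p_b(z) b(z) p_r c(z') ]
K_ur = u(z°) s(z°) G_r(z'|z°)
K_ru = r(z)                 K_rr = 1 − u(z°)
```

with size-dependent survival `s`, growth densities `G_u`/`G_r`,
reproduction probability `p_b`, flower count `b`, establishment probability
`p_r`, offspring-size density `c`, contraction `r` and elongation `u`.
Discretized on a midpoint grid this becomes a `2N × 2N` megamatrix whose
dominant eigenvalue is the asymptotic growth rate λ, with the stable
size-by-state structure `w` and reproductive values `v` as its right and
left eigenvectors.  The pipeline fits all vital rates (GLMMs/GAMMs with
backward AIC selection of individual/year/plot random intercepts), builds
the operator for a *with-contraction* and a counterfactual
*without-contraction* scenario, extracts λ / `w` / `v` / annual λ series,
and runs a full sensitivity–elasticity analysis.  A tested individual-based
census generator with known ground-truth rates makes every stage verifiable
end to end.  See `docs/methods.md` for the complete model account.

## Worked example

```python
import cactipm as c

# a synthetic 31-year census from known vital rates (the study conditions)
params = c.SimulationParams(n_individuals=400, n_years=31)
census = c.apply_censoring_rule(c.generate_population(params, seed=1))

rates = c.fit_all_rates(census, selection="direct")   # or "stepwise"
grid = c.make_grid(0.0, 70.0, 200)
comp = c.scenario_comparison(rates.on_grid(grid), grid, rates)
print(f"lambda with contraction    = {comp.with_contraction.lam:.4f}")
print(f"lambda without contraction = {comp.without_contraction.lam:.4f}")
print(f"annual lambda range        = {comp.with_contraction.interval}")

report = c.vital_rate_elasticities(rates.on_grid(grid), grid)
for name, e in report.vital_rates.items():
    print(f"elasticity {name:>4} = {e:+.4f}")
```

Output from this exact run:

```
lambda with contraction    = 1.0306
lambda without contraction = 1.0313
annual lambda range        = (1.0052842629830425, 1.0561559238224574)
elasticity    s = +0.9681
elasticity  G_u = +0.9623
elasticity  G_r = +0.0057
elasticity  p_b = +0.0227
elasticity    b = +0.0227
elasticity    r = -0.0008
elasticity    u = +0.0003
elasticity    c = +0.0227
```

Reading: the population grows ~3 % per year; removing root contraction
changes λ by less than 0.001, so contraction is demographically nearly
neutral.  Survival dominates the elasticities, contraction is the only
rate whose increase *lowers* λ, and the fecundity components (`p_b`, `b`,
`c`) are an order of magnitude weaker — the classic long-lived-plant
pattern.  (The ground-truth λ behind this census is 1.0348; the fitted
pipeline recovers it to ±0.004.)

The same pipeline runs from the shell:

```bash
cactipm simulate --seed 1 --out census.csv
cactipm fit --census census.csv --out fitted_models.json
cactipm compare --models fitted_models.json
cactipm all --config config.yaml          # every stage + report files
```

where `config.yaml` holds either a census path or simulation parameters:

```yaml
simulation:
  n_individuals: 400
  n_years: 31
grid_n: 200
selection: stepwise
seed: 1
output_dir: results
```

To analyse a real census instead, provide a CSV with columns
`id, plot, year, size_mm, alive, retracted, flowers` (0/1 flags, empty size
on death rows) and set `census_path` in the config.

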