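# ahc-cua

Cost–utility modelling of **annual health checks (AHC) for adults ageing
with intellectual disability (ID)**, versus standard primary care.

Adults with ID carry a higher burden of age-related disease, much of it
undetected ("diagnostic overshadowing"), and roughly threefold higher
mortality. England incentivises general practices to offer them a yearly
structured health check. This package asks the health-economic question: do
those checks buy enough earlier detection and treatment — of hypertension,
diabetes, glaucoma, cataract, hearing problems, osteoporosis, and bowel and
breast cancer — to justify their cost?

It is written for health economists and modellers: a library of per-condition
annual-cycle Markov cohort models and screening cascades, aggregated into a
lifetime incremental analysis with probabilistic and one-way sensitivity
analysis, plus a CLI and numbered analysis drivers.

## The model in brief

For a hypothetical cohort followed from age 40 until death (absorbing cap at
100), each condition *c* is modelled separately under both strategy arms with
identical parameter draws, and

ΔC = PV(£258 × years alive) + Σ_c ΔC_c,  ΔQ = Σ_c ΔQ_c,  ICER = ΔC/ΔQ,

with costs (2016 GBP, NHS perspective) and QALYs discounted at 3.5%/year to
age 40, trapezoidal half-cycle correction, and background mortality from an
England-like life table with qx tripled for ID. Parameter uncertainty is
propagated by Monte Carlo (beta/gamma/lognormal/truncated-normal
distributions fitted to the published ranges); cost-effectiveness is
summarised by the mean of per-draw ICERs, percentile intervals, and
acceptability probabilities at £20,000 and £30,000 per QALY. Details and all
structural choices: [docs/methods.md](docs/methods.md).

## Worked example

```python
from ahc_cua import ModelContext, evaluate_strategy, icer, paper_parameter_fixture

pset = paper_parameter_fixture()            # the packaged published inputs
ctx = ModelContext.default(pset.metadata)   # synthetic life table, x3 ID mortality
strat = evaluate_strategy(pset.base_points(), ctx)
print(f"incremental cost  GBP {strat.inc_cost_total:,.0f}")
print(f"incremental QALYs {strat.inc_qaly_total:.4f}")
print(f"ICER              GBP {icer(strat.inc_cost_total, strat.inc_qaly_total).value:,.0f}")
```

prints

```
incremental cost  GBP 4,900
incremental QALYs 0.0889
ICER              GBP 55,128
```

i.e. lifetime checks cost about £4,900 per person (almost all of it the
£258/year annuity over ~30 discounted life-years; the condition models net
out to +£138), buy about 0.09 QALYs, and are therefore not cost-effective at
conventional UK thresholds. The same numbers come from
`python analysis/01_base_case.py`, and `ahc-cua base-case` gives the JSON
equivalent.

The numbered drivers under `analysis/` run the full experiment and write
their tables to `results/`:

```bash
python analysis/01_base_case.py               # deterministic base case
python analysis/02_psa.py                     # 1,000-draw PSA summary + draws
python analysis/03_owsa_intervention_cost.py  # check cost at 50/75/100/150
python analysis/04_ce_plane.py                # cost-effectiveness plane CSV
```

The probabilistic analysis yields a mean incremental cost near £4,900, a
mean QALY gain near 0.08, and a mean per-draw ICER of roughly £85,000 to
£100,000 across seeds (the ratio of means is near £60,000 — per-draw ratios
are right-skewed), and shows the yearly check cost is the one parameter that
can flip the conclusion: at £50 per year the acceptability probability at
£20,000/QALY rises to roughly two-thirds.

## Layout

```
src/ahc_cua/
  parameters.py        parameter registry, range resolution, PSA distributions
  mortality.py         life tables, ID adjustment, survival curves
  markov.py            generic cohort engine (trace, half-cycle rewards, PV)
  conditions/          the eight condition models (state models + cascades)
  economics.py         intervention costing, aggregation, ICER/NMB/CEAC
  psa.py               probabilistic and one-way sensitivity drivers
  synthetic.py         Gompertz life tables, packaged fixture, random scenarios
  cli.py               ahc-cua base-case | psa | owsa | ceplane | fixtures export
analysis/              numbered drivers writing results/
scripts/acceptance.py  headline recomputation (above)
```
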