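# obpi-cea

A model-based cost-utility analysis of rolling out multi-professional
simulation training for obstetric emergencies to every maternity unit in
England, evaluated through its effect on **permanent obstetric brachial
plexus injuries (OBPIs)** — nerve injuries sustained during shoulder
dystocia that cause lifelong morbidity and substantial litigation costs.

The package is aimed at health economists and maternity-safety
researchers who want a transparent, tested, configurable version of this
decision model: every input is a plain YAML scalar, every stage is an
importable function, and every result in the analysis scripts is
recomputed from those inputs.

## The model

A decision-tree cohort model compares two strategies over a 30-year
horizon at a fixed annual birth rate *B* = 648,107:

* **current practice** — only the existing covered cohorts
  (244,498 births/yr across nine cohorts with 1–15 years of established
  training) train; everyone else stays at the baseline risk;
* **nationwide rollout** — the remaining 403,609 births/yr enrol as a
  new cohort in model year 1.

A cohort with *k* established years experiences an injury probability
*p(k)* that declines piecewise-linearly from the baseline
*p(0)* = 0.192‰ through *p(4)* = 0.15‰ to *p(12)* = 0, and advances one
index per model year. Expected injuries in year *t* are

> E[OBPI_t] = Σ_cohorts births_c · p(k_c + t − 1) + uncovered · p₀

Costs are per-birth training costs (full programme £16.91/£15.56
first/subsequent year, or £1.79/£1.43 for the standalone
shoulder-dystocia component) plus a litigation-proxied injury cost of
£338,879 per OBPI inflating at 10%/yr, all discounted at 3.5%/yr.
QALYs use utility scores 0.56 (adult with OBPI), 0.80 (parent of an
affected child) and 0.86 (population norm); the **dyadic** QALY is the
equal-weight sum of the adult and parental components. Incremental
cost-effectiveness ratios (ICER = ΔC/ΔE) are classified on the
cost-effectiveness plane; "dominant" means cheaper *and* more
effective. A Monte Carlo probabilistic sensitivity analysis (PSA)
samples birth rate and costs from triangular distributions and the
baseline probability and utilities from method-of-moments beta
distributions, re-running the whole model per draw.

## Worked example

```python
from obpi_cea import compare_scenarios, default_config

config, coverage = default_config()
res = compare_scenarios(config, coverage)
print(res.report_text())
```

prints (full programme variant):

```
Variant: prompt
OBPIs  nationwide 712  current 2,479  difference -1,767
Costs  nationwide GBP 497,027,948  current GBP 2,315,772,124  difference GBP -1,818,744,176
ICER (adult QALYs): GBP -10,186,398 per QALY (dominant); QALY gain 179
ICER (parental QALYs): GBP -3,068,396 per QALY (dominant); QALY gain 593
ICER (dyadic QALYs): GBP -2,358,083 per QALY (dominant); QALY gain 771
```

Nationwide rollout averts about 1,767 permanent OBPIs over 30 years and
saves £1.82 billion (the standalone shoulder-dystocia variant saves
£1.93 billion), so it dominates current practice for every QALY kind —
each negative ICER is a cost saving per QALY gained. QALY gains here
are discounted; with `config.replace(qaly_discounting=False)` the adult
gain is 446.

The same pipeline is scripted in `analysis/01_base_case.py` (base
case), `analysis/02_psa.py` (1,000-draw PSA) and
`analysis/03_ce_planes.py` (cost-effectiveness planes), which write
their tables under `results/`. A CLI wraps the identical calls:
`obpi-cea base`, `obpi-cea psa --draws 1000 --seed 0`,
`obpi-cea generate`, `obpi-cea validate cfg.yaml`.

## Layout

| path | contents |
| --- | --- |
| `src/obpi_cea/params.py` | config, coverage table, decline schedule |
| `src/obpi_cea/cohort.py` | expected-OBPI projection per scenario |
| `src/obpi_cea/economics.py` | training/injury costs, inflation, discounting |
| `src/obpi_cea/outcomes.py` | adult/parental/dyadic QALY accrual |
| `src/obpi_cea/cea.py` | incrementals, ICERs, dominance |
| `src/obpi_cea/psa.py` | distributions, Monte Carlo PSA, CE planes |
| `src/obpi_cea/synthetic.py` | random valid inputs + Bernoulli oracle |
| `src/obpi_cea/cli.py` | command-line orchestration and manifests |
| `docs/methods.md` | modelling assumptions and design choices |
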