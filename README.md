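# fvcea — cost-effectiveness of fluoride varnish for preschoolers

`fvcea` is a decision-analytic modelling package for the question: is
professionally applied fluoride varnish (FV), added to semiannual standard
dental care, good value for money in preventing cavitated caries lesions in
preschool children?  It implements a three-state Markov cohort model with
full deterministic and probabilistic sensitivity analysis, and is aimed at
health-economics and dental-public-health researchers who want a scriptable,
testable alternative to spreadsheet or GUI-based decision trees.

## The model

Children enter the model caries-free at age 2 and are followed for 4 years
in 6-month cycles (8 cycles).  Health states are

- **NC** — *no cavity* (caries-free),
- **C** — *cavity* (at least one untreated cavitated lesion),
- **PC** — *previous cavity* (treated history, currently no cavity).

Per cycle, a caries-free child develops a cavity with probability
*p* = 0.06873.  A child with a cavity is treated within the cycle — glass
ionomer restoration (probability 0.873, success 0.63), Hall-technique crown
(0.004, success 0.98), or extraction (0.123, always succeeds) — moving to
PC on success and staying in C on failure.  From PC a child relapses to C
with probability 0.28 per cycle.  The FV arm multiplies the progression and
restoration-failure probabilities by the pooled relative risk RR = 0.88
(95% CI 0.81–0.95); the treatment mix is unchanged.

Costs (2022 Brazilian Reais): routine semiannual visit R\$118.50 in every
state, glass ionomer R\$179.50, Hall crown R\$254.50, extraction R\$172.50,
and R\$78.00 per FV application each cycle in the varnish arm.  Costs and
effects are discounted at 5% per year.  Effectiveness can be measured as
the probability of never developing a cavity, discounted cavity-free time,
discounted expected cavity episodes, or DALYs (disability weight 0.01 per
year with a cavitated lesion).  Strategies are compared by the incremental
cost-effectiveness ratio ICER = ΔC/ΔE with dominance classification, and
by net monetary benefit NMB(λ) = λ·ΔE − ΔC over a willingness-to-pay grid.

Uncertainty is handled two ways: one-way (tornado) analysis pushing each
parameter to its 95% bounds, and Monte-Carlo probabilistic sensitivity
analysis sampling probabilities from method-of-moments beta fits, costs
from gamma fits (CV fixed at 20%), and the relative risk from a lognormal
fit, summarised as cost-effectiveness acceptability curves.  An
individual-level microsimulation reproduces the same process child by
child and serves as an independent cross-check of every cohort quantity.

## Worked example

```bash
fvcea run-cea --out-dir results
```

prints

```
ever_cavity_avoided: d_cost=540.75 d_effect=0.041346 ICER=13078.48 (no dominance)
daly: d_cost=540.75 d_effect=0.000663 ICER=815971.61 (no dominance)
```

Reading: over 4 years the varnish arm costs R\$540.75 more per child under
this package's accrual scheme, raises the probability of staying cavity-free
by 0.0413 (about 4 children per 100 — the published headline), and avoids
0.00066 DALYs, i.e. roughly R\$13,000 per child kept cavity-free and
R\$0.8 million per DALY averted.  Neither strategy dominates: the varnish
buys health, but at a price far above the R\$60-per-cavity-avoided
willingness-to-pay reported for Brazilian private payers.

The same pipeline is scriptable:

```python
from fvcea import load_parameter_table, run_cea

params = load_parameter_table()           # packaged parameter table
result = run_cea(params, "ever_cavity_avoided")
print(result.icer, result.dominance)
```

Other subcommands: `fvcea run-dsa` (tornado CSV), `fvcea run-psa`
(Monte-Carlo samples + acceptability curves), `fvcea microsim`
(individual-level validation run), `fvcea validate-params` (check a
user-supplied parameter CSV).  All outputs are plain CSV with a run log
recording the parameter-file digest and seeds.

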