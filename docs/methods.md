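# Methods

## Model structure and conventions

The cohort model is a discrete-time Markov chain over three caries states
(no cavity, cavity, previous cavity) with a 6-month cycle and an 8-cycle
(4-year) horizon, from age 2 to age 6.  Conventions adopted where the
structure leaves room:

- **Within-cycle treatment.** A child in the cavity state at the start of
  a cycle is allocated a treatment during that cycle (glass ionomer, Hall
  crown, or extraction, with the fixed mix q = (0.873, 0.004, 0.123)) and
  resolves it within the cycle: success or extraction moves the child to
  previous-cavity at cycle end, restoration failure keeps it in cavity.
  The collapsed cavity row of the transition matrix is therefore
  stay = q·f and move = q·s + q_ext, with f the failure probabilities.
  This same-cycle convention reproduces the published end-of-horizon
  occupancies (57/16/28% standard, 61/13/26% varnish), which a
  next-cycle convention does not.
- **Extraction always succeeds** (probability 1 of reaching
  previous-cavity).  No success probability is given for it in the source
  data, and the state diagram lists extraction as one of the three routes
  into previous-cavity.
- **No half-cycle correction, no mortality or dropout.** Occupancy is
  reported at integer cycle ends; cycle 0 is model entry with the whole
  cohort caries-free.
- **No edge from no-cavity to previous-cavity**, and no remission from
  cavity without treatment; model construction enforces both.

The fluoride-varnish arm multiplies exactly four probabilities by the
relative risk RR = 0.88: progression no-cavity→cavity, glass-ionomer
failure, Hall failure, and relapse previous-cavity→cavity.  The treatment
mix is not scaled — the varnish changes caries activity, not what is done
about an existing cavity.  Products are validated to stay within [0, 1].

## Parameters

The packaged table (`fvcea/data/table1_parameters.csv`) carries, for each
parameter: baseline, 95% bounds (or one-way sensitivity limits), the PSA
distribution family, and the arm it belongs to.  Key defaults, with units:

| parameter | meaning | baseline |
|---|---|---|
| p_nocav_cavity | NC→C per cycle | 0.06873 |
| q_gic / q_hall / q_ext | treatment mix | 0.873 / 0.004 / 0.123 (complement) |
| s_gic / s_hall | per-cycle restoration success | 0.63 / 0.98 |
| p_prev_cavity | PC→C per cycle | 0.28 |
| eff_rr | FV relative risk | 0.88 (0.81–0.95) |
| c_routine | visit cost per cycle, any state | R$118.50 |
| c_gic / c_hall / c_ext | procedure costs | R$179.50 / 254.50 / 172.50 |
| c_fv | FV application per cycle | R$78.00 |
| daly_weight | DALY per year with a cavitated lesion | 0.01 |
| discount_rate_annual | for costs and effects | 0.05 |
| wtp_cavity / wtp_daly | willingness-to-pay references | R$60 / R$40,000 |

Branches the source leaves unstated ("#") are closed as complements so
every chance node sums to one (tolerance 1e-12); stated siblings summing
above one are rejected with the node named.

The table also stores the published one-way bounds for the four derived
FV-arm probabilities (e.g. 0.0586–0.0625 for NC→C).  Inspection shows
these are the products of the baseline RR with the base parameters'
bounds, rounded (0.88 × 0.0665 ≈ 0.0586, 0.88 × 0.14 = 0.1232, …); the
package therefore treats the FV rows as derived expressions everywhere,
while keeping the printed bounds available to `one_way_dsa` on request.

## Cost and effectiveness accrual

Each cycle t = 1..8 contributes, at discount factor (1+r)^(−t/2):

- the routine visit cost weighted by the start-of-cycle state occupancy
  (configurable to end-of-cycle via `state_timing`; with all three state
  costs equal at baseline the choice is numerically invisible),
- expected treatment events (start-of-cycle cavity occupancy × mix) times
  procedure costs,
- in the varnish arm, the application cost every cycle regardless of
  state (visits are semiannual by design).

Effectiveness modes: probability of never developing a cavity
((1−p)^8, undiscounted — a terminal outcome, not a flow); discounted
cavity-free years; discounted expected new-cavity episodes (inflow from
the two non-cavitated states only — a restoration failure is a continuing
episode, not a new one); and discounted DALYs (cavity-state years × 0.01).
Cavity episodes and DALYs are harms: incremental effectiveness is
standard-minus-varnish so that positive always favours the varnish.

This accrual scheme is the package's own documented choice.  It does not
reproduce the per-arm accumulated totals printed in the source analysis
(whose reward placement lives in an unpublished appendix tree and implies,
e.g., a 4-year standard-care total of R$203 against eight R$118.50
visits); those totals are used in the tests only as arithmetic-identity
inputs to the ICER computation.  All incremental structure — the ~4 per
100 children kept cavity-free, the dominance classification, the tornado
ranking — is insensitive to this placement.

## Sensitivity analysis

**One-way (tornado).** Each independent uncertain parameter is set to its
lower and upper bound with everything else at baseline, the full two-arm
comparison is re-run, and bars are ranked by |ICER(high) − ICER(low)|.
The FV derived rows are not varied by default (their uncertainty is
already carried by the base parameters and the RR; varying them
independently at their wide printed bounds double-counts it), but can be
varied explicitly.  With the default design the RR bar is the widest for
both outcomes, matching the source's qualitative finding.

**Distribution fits.** Beta by method of moments from the mean and 95% CI
(s = width/3.92; α = m·k, β = (1−m)·k with k = m(1−m)/s² − 1); the fit
errors out when s² ≥ m(1−m) and collapses to a point mass when the CI has
zero width or the shapes exceed 1e9.  Gamma with SD = 20% of the mean,
giving shape 25 and scale mean/25.  Lognormal for the RR with the median
pinned at the point estimate and σ = (ln high − ln low)/3.92.

**PSA.** 1000 Monte-Carlo iterations by default.  Per iteration every
uncertain independent parameter is drawn from its fitted distribution;
the FV arm is re-derived from the sampled base probabilities and RR, and
complements are re-closed, so each sampled model is internally consistent.
Joint violations (treatment mix above one, an RR product above one) are
rejected and redrawn, preserving the marginal families; rejections are
counted on the result object.  Iteration k draws from
`default_rng([seed, k])`, so runs are byte-reproducible and any single
iteration can be replayed in isolation.  The acceptability curve reports,
on a WTP grid from 0 to twice the deterministic ICER (200 steps by
default), the fraction of iterations with non-negative net monetary
benefit.  About 0.08% of RR draws exceed 1; because the varnish arm is
costlier in every iteration such draws are never accepted at any WTP, so
the curve remains monotone.

## Microsimulation oracle

`simulate_individuals` replays the model child by child with explicit
chance-node draws (onset, treatment allocation, success), using the same
within-cycle convention and the same reward placement as the cohort
engine.  Per-child means are unbiased estimators of the cohort
expectations, which is the basis of the oracle-equivalence tests:
end-state proportions, mean discounted cost, and every effectiveness mode
agree at Monte-Carlo precision (3 binomial/CLT standard errors at
n = 100,000 for the baseline; 4 standard errors across a sweep of 20
random parameter sets at n = 20,000, the wider band reflecting the 120
simultaneous comparisons the sweep makes).

`random_parameter_set` generates structurally valid registries for
property tests: probabilities drawn uniformly over plausible caries-model
ranges, treatment mix below one, a protective RR in (0.5, 1.0], positive
costs.  It emulates the *structure* of real parameter sets, not their
epidemiology: draws are independent, whereas real transition probabilities
and costs are correlated through care patterns; baseline risk does not
vary between children or over time (an assumption the cohort model itself
makes).  Passing tests therefore establish internal consistency of the
engines across the parameter space, not external validity of any one
parameterisation.

## Numerical choices

- Row-stochasticity tolerance 1e-12 at model construction; occupancy
  conservation checked at 1e-10 in tests.
- Complement closure clips the derived branch at 0 when stated siblings
  sum to within 1e-12 of 1.
- ICER is NaN (flagged undefined) when ΔE = 0; dominance then rests on
  cost alone.  ICERs are kept unrounded internally; the CLI rounds
  currency to 2 decimals for display only.
- Dominance: varnish is *dominant* iff (ΔC ≤ 0 and ΔE > 0) or (ΔC < 0 and
  ΔE ≥ 0) in benefit-oriented increments; *dominated* is the mirror;
  otherwise *no dominance*.
- Rejection sampling aborts with an error after 1000 failed redraws of a
  single iteration (unreachable under the packaged parameterisation).

## Problem sizes

The test suite runs the cohort engine at its native size (8 cycles), the
baseline microsimulation at 100,000 children per arm, the random-set
sweep at 20 × 20,000 children × 2 arms, and the PSA at 1000 iterations —
the full analysis sizes; the whole suite completes in a few seconds.

## Known limitations

- The child, not the tooth, is the modelling unit (one cavitated lesion
  per child); tooth-level burden is out of scope.
- No heterogeneity in caries risk, no mortality, no dropout, no adverse
  effects of the varnish.
- Costs stay in 2022 Reais; no inflation or currency adjustment.
- Parameters are sampled independently in the PSA (no correlation
  structure beyond the mechanistic RR linkage between arms).
- The per-arm accumulated totals of the source analysis are not
  reproducible without its unpublished reward tree (see accrual section).
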