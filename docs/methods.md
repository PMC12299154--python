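# Methods

## Model

The herd is a discrete-time Markov chain with a monthly step over cow
states $(AB, PAR, PREG, MIL)$. The model assumes no interaction between
animals (a "cow slot" view: every removed cow is instantly replaced by a
heifer at $(0,1,0,1)$), stationary input rates (no seasonality, genetics
or disease states other than the abortion record) and binomially
distributed monthly events. Two variants share the kernel code:

* **base** — the abortion record is frozen at $AB=0$; every abortion
  returns the cow to open ($PREG=0$) at $MIL+1$ in the same parity;
* **extended** — detectable abortions (gestation month $>2$) are typed:
  rebreeding abortions (RA, share $1 - 1.9/12.5 \approx 84.8\%$) act like
  the base rule but set $AB=\text{RA}$; new-lactation abortions
  (NLA, share $1.9/12.5$) start a fresh lactation at the next parity and
  set $AB=\text{NLA}$. Losses at gestation month $\le 2$ are treated as
  undetected in both variants. The record is monotone
  ($AB' = \max(AB, \text{event})$) and persists until the cow leaves the
  herd; only replacement returns a slot to $AB=0$.

### Event order within a month

Death and involuntary culling resolve first (probabilities from the
monthly rate table; involuntary culling multiplied by 1.9 for cows with
an abortion record in the extended model, capped so the row total cannot
exceed one). Survivors then, in mutually exclusive branches: are
voluntarily culled (open cows exactly at the policy threshold), conceive,
abort, calve (gestation month 9; cows completing parity 15 are retired),
or simply progress one month. This multiplicative competing-risk order is
the convention of the monthly herd models this one follows.

### Voluntary culling semantics

The policy threshold is interpreted as *the* decision month: an open cow
is replaced exactly when $MIL$ equals the threshold. Cows that re-enter
the open pool beyond the threshold — which only happens through abortion
— are kept and re-inseminated while the conception window (months 2–15 of
lactation) allows, and any cow still open at $MIL=24$ is replaced by the
safety bound. We chose this rule over "cull at or beyond the threshold"
because it reproduces the published reference herd structure twice as
closely (0.50% vs 1.07% maximum cell deviation in the second-parity
validation table) and is the only reading that reproduces the published
abortion prevalence (see below). The same safety bound force-replaces a
pregnant cow that would outlive the 24-month lactation grid, which is
unreachable under the packaged conception window.

### Policies

The validation configuration culls open primiparous cows at lactation
month 11 and multiparous cows at month 10. For the published *optimal*
steady state the primiparous threshold moves to month 6 with the
multiparous month kept at the reference 10; that configuration reproduces
the published prevalence of abortion records to the printed digits
(total 2.96%, RA 2.36%, NLA 0.60%). The policy *sweep*
(`sweep_culling_month`) applies the swept month to both parity classes,
which best matches the published net-benefit table at its low end.
`Policy` accepts independent thresholds, so either convention is one
argument away.

## Parameters

All inputs ship as data files under `src/dairyherd/data/` and can be
overridden from YAML (`load_params`).

| parameter | default | units | notes |
|---|---|---|---|
| pregnancy / mortality / involuntary culling | monthly table | probability/month | by month in lactation × parity class (first vs later) |
| abortion hazard, gestation months 2–8 | 3.5, 2.5, 1.5, 0.5, 0.25, 0.1, 0.1 | %/month | sums to 8.45% per pregnancy; month 1 undetectable, month 9 is calving |
| NLA share of detectable abortions | 0.152 | — | = 1.9/12.5 |
| milk reduction RA / NLA | 7.3% / 19.4% | — | applied to the lactation curve while the record persists |
| culling-risk multiplier | 1.9 | — | involuntary culling only, not mortality |
| milk price / calf / carcass price / heifer / vet | 0.36, 100, 1.16, 1300, 50 | USD(/kg) | vet charged per calving by default (`vet_basis`) |
| feed cost lactating / dry; DMI; month length | 0.17, 0.13; 25; 30 | USD/kg DM; kg/day; days | dry feed applies whenever the cow gives no milk |
| milk curve | months 1–10 table | kg/month | parity classes ≤2 / ≥3; months 11–12 carry month 10 forward; milked ≤12 months; dry from gestation month 8 |
| AI cost; cull-cow weight | 0; 563 | USD; kg | calibrated, see below |

### Calibrated economic constants

Two monetary constants appear in the cash-flow identity but not in the
published price table: the insemination charge and the sale weight of a
culled cow. They were fixed once, jointly, against the published
net-benefit table: the month-2 policy produces a sterile two-state herd
whose net benefit involves neither milk dynamics nor AI, so the published
−8.76 USD/cow/month pins the salvage value at ≈653 USD — a cull-cow
weight of 563 kg at 1.16 USD/kg, a realistic Holstein live weight — and
the published benefit levels are only attainable when insemination is not
charged separately (ai\_cost = 0; the packaged price source lists no AI
price, so it is presumably bundled). Both remain ordinary scenario fields;
users tracking AI explicitly should set `ai_cost` to their per-service
price (typically 10–30 USD).

AI, when priced, is charged for every month a cow is open, at least in
lactation month 2, inside the conception window, and not being culled
that month. Salvage is earned on culls only (a dead cow's carcass is
written off — configurable by editing `state_cashflow`), the replacement
heifer is charged on every exit, and calf value, veterinary cost and twin
loss ride on the calving probability. Reported money is rounded to cents
in CSV, kept at full precision in JSON. "Net benefit" is a stationary
expectation per cow slot per month; no discounting is applied anywhere.

## Solvers and numerics

The stationary distribution is computed on the communicating class
reachable from the entry state (breadth-first search on the kernel's
sparsity pattern); structurally feasible but unreachable states (e.g.
$AB=\text{NLA}$ at parity 1) get probability zero. The default solver
replaces one balance equation of $(P^\top - I)\pi = 0$ with the
normalisation and solves the sparse system directly; power iteration
(tolerance $10^{-12}$ in the max norm, cap $10^6$ iterations) is kept as
a cross-check and agrees to $<10^{-8}$ on the extended model. Solutions
are clipped at zero and renormalised; the reported residual
$\lVert \pi P - \pi \rVert_\infty$ is $<10^{-10}$ for every policy in the
sweep. Ties in the sweep argmax resolve to the earliest month.

## Monte-Carlo cohort oracle

`simulate_cohort` advances each cow of a cohort by sampling its kernel
row (inverse-CDF on the ≤4 destinations per state), so it shares *only*
the kernel with the analytic solver, not the linear algebra. Occupancy is
averaged over the months after a burn-in (default: half the horizon,
capped at 300 months — several cow lifetimes, comfortably beyond the
chain's mixing time), and per-month tail counts are kept so Monte-Carlo
errors can be estimated by batch means. With 10,000 cows over 600 months
the empirical occupancy sits within total-variation 0.004 of the analytic
stationary distribution (the test bound is 0.02).

## Randomised rate tables

`random_rate_tables` draws each month's (conception, mortality, culling)
triple from a Dirichlet with a dominant slack component, so row totals
are below one by construction and monthly exits stay in a realistic few-
percent range; conception is confined to lactation months 2–15 and
abortion hazards to gestation months 2–8, mirroring the packaged tables'
support. These fixtures exercise the structural invariants
(stochasticity, stationarity, solver agreement) across the parameter
space; they do not emulate lactation-curve shapes or correlated rates, so
passing them says nothing about the biological realism of any particular
table — the validation against the packaged reference structure covers
that.

## Known limitations and deviations

* The published net-benefit table is reproduced closely at its low end
  (month 3 within 1%) and at the optimum (extended 175.51 vs 178.77,
  base 175.36 vs 178.08, both within 2%), but our curve is nearly flat
  over months 6–9 and peaks at month 8 rather than 6, and it declines
  more gently beyond month 10 (142 vs 123 USD at month 15). The
  published steep late decline would require open late-lactation cows to
  be substantially more costly than the packaged feed and milk tables
  imply; we did not add such a mechanism.
* Accordingly, the extended-minus-base difference starts at exactly zero
  for the sterile month-2 policy and peaks near +0.7 USD around months
  4–6, but does not keep growing to +2.52 at month 15 as published; past
  month 9 the milk penalties on the larger aborted population slightly
  outweigh the faster turnover of aborted cows.
* The rebreeding sensitivity (conception of cows with an abortion record
  scaled by $1-f$, $f$ up to 0.60) loses ≈0.26 USD/cow/month across the
  grid under the month-6 policy — the published order of magnitude
  (1.59) but smaller; the published procedure is not specified precisely
  enough to replicate.
* Abortion effects on days-open beyond the conception scaling, diet
  variants, nitrogen-excretion costs, seasonality, day-resolution states
  and discounting are out of scope.
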