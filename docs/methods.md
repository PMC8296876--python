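# Methods

## The protocol as a stochastic process

One allocation round handles one surplus organ. A donor region is drawn from
the production-weighted donor distribution `P(x) = S_x / Σ S`, where `S_x` is
the number of surplus organs region `x` provided in the period; donors are
i.i.d. across organs. The organ is offered to the centers of the donor's
macroarea in the order of that macroarea's strip, skipping the donor's own
center (the producing region is never asked to use its own surplus organ);
if all refuse, the cascade continues down the other macroarea's strip. Each
queried center accepts independently with its acceptance rate — the ratio of
accepted to offered organs over the period, the only behavioural parameter of
the model. After an acceptance, the strip where it occurred rotates: the
acceptor's slot and the slots of that strip's refusers move to the end in
their original relative order. A fully refused organ is lost and changes
nothing.

Modelling choices where the protocol description is ambiguous (all are
flags or documented variants):

* **Fallback depth.** The narrative of the protocol is contradictory on
  whether the cascade continues past the head of the other macroarea's
  strip. The engine walks the full fallback strip by default, which matches
  the protocol flowchart and the general rotation rule; `fallback_mode:
  head_only` reproduces the narrower reading.
* **Cross-area rotation.** When an organ produced in one macroarea is
  accepted in the other, only the accepting strip rotates: the rotation rule
  is per strip, and the donor strip accepted nothing (the "no acceptance, no
  change" rule applies to it).
* **Simultaneity.** Offers are described as simultaneous with a strip
  position attached; since acceptance priority follows position, they are
  modelled as sequential queries in strip order.
* **Multi-slot centers.** A center occupying several strip slots is queried
  once at its earliest slot and only that slot moves on rotation — the
  simplest rule consistent with index-set bookkeeping. The default Italian
  topology has multiplicity one everywhere, so results there are unaffected.
* **Producer exclusion.** A donor region hosting a center has that center
  skipped entirely (not merely deprioritized).

## Exact per-organ probabilities

The pair of strip arrangements is a Markov chain on a finite state space
(at most the product of the strips' multiset-permutation counts; 4!·2! = 48
for Italy). The engine evolves the full probability vector over reachable
states: for each state it groups donor regions by the pair (macroarea, own
center) — the only donor features the cascade can see — and enumerates the
acceptance position of the cascade analytically, so one evolution step costs
(states × donor groups × strip length). Per organ index `t` it reports the
acceptance probability per center, the loss probability, the position
distribution `T_c^{t,j}` and the position-conditional acceptance
probabilities `P_{c,j}^t`; the product-sum identity
`P_c^t = Σ_j T_c^{t,j} P_{c,j}^t` holds by construction and per-organ
conservation `Σ_c P_c^t + P_lost^t = 1` to 1e-12 is asserted in the tests.

The chain's state space is capped (10^5 states by default); beyond the cap a
`StateSpaceOverflowError` directs users to the Monte Carlo engine.

Because the chain is finite and (for rates in (0,1)) aperiodic, `P_c^t`
converges geometrically in `t`; with the Italian topology at a uniform 26%
rate, successive differences drop below 1e-8 by t ≈ 60. This plateau is the
long-run share of surplus organs each center obtains.

A literal "within-strip" variant of the position-conditional formula —
multiplying the acceptance rate by the probability that the organ was *not*
produced in the center's own regions, instead of conditioning on the donor —
is kept as `position_conditional_probability(..., variant="strip_marginal")`
for comparison. It is a marginal approximation and does not satisfy
conservation, which is why the engine conditions on the donor exactly and
marginalizes afterwards.

The overall use probability of a surplus organ is computed by direct
decomposition over donor regions (production weight × one minus the product
of refusal probabilities over the centers eligible for that donor). Under
full-cascade fallback the eligible *set* does not depend on the arrangement,
so this quantity is constant across organ indices; the tests cross-check it
against `1 − P_lost` from the chain to 1e-12.

## Cumulative (at-least-k) probabilities

Three engines, deliberately kept distinct:

* **exact** (default): DP over (joint strip state × organs obtained by the
  target center), evolved M steps; exact up to floating point.
* **independent**: the Poisson-binomial upper tail of independent indicators
  with means `p_t = P_c^t`, computed by the standard O(M²) convolution DP —
  never by 2^M enumeration. This reproduces the closed product-form sum some
  descriptions of the model print.
* **bahadur**: second-order Bahadur expansion. The joint density of the
  acceptance indicators is the independence product times
  `1 + Σ_{s<t} r_st z_s z_t`, with `z_t` the standardized indicator and
  `r_st` the pairwise correlation taken from the exact chain
  (`law_from_chain` computes marginals and pairwise joints by propagating
  the accept-at-s measure forward). The corrected mass is accumulated
  directly on the count statistic: the correction to `P(count = m)` is
  `Σ_{s<t} r_st E[1{count=m} z_s z_t]`, evaluated exactly by conditioning on
  `(x_s, x_t)` and convolving the remaining indicators. Truncation can
  produce small negative count masses; they are clipped to zero and the
  distribution renormalized, with the clipped mass reported
  (`CumulativeResult.clipped_mass`). Renormalization is skipped when nothing
  was clipped, so a zero-correlation law is bitwise identical to the
  independence engine. Higher-order correlation terms are set to zero
  (the standard second-order truncation).

Rotation makes the indicators genuinely dependent — a center that just
obtained an organ drops to the back of its strip, which anti-correlates
successive acceptances — so the independence engine overstates streaks; the
Bahadur engine captures most of the dependence and the exact engine all of
it. All engines satisfy the boundary contract `P(at least 0) = 1`,
`P(at least M+1) = 0`, monotone non-increasing in `k`.

Degenerate indicators (marginal 0 or 1) have correlation 0 by convention.

## Monte Carlo simulator

`simulate_season` draws one season organ by organ (one uniform for the
donor, one per queried center, stopping at the first acceptance);
`estimate` aggregates `n_reps` independent seasons into per-organ and
at-least-k counts with binomial standard errors `sqrt(f(1−f)/n)`, plus strip
state occupancies. Replicate `i` uses the substream
`SeedSequence(seed, spawn_key=(i,))`, so any season of an estimation run can
be replayed exactly with `simulate_season`; the estimator's interned-state
fast path changes bookkeeping only, not the sampled decisions (asserted in
the tests by replaying seasons). Donor regions are sampled i.i.d. with
replacement, matching the analytic chain's assumption — this is what makes
the simulator a valid oracle for the exact engines. Counts are integers, so
conservation (loss + acceptances = replicates) holds exactly per organ.

## Default study conditions

The shipped Italian configuration (`configs/italy.yaml`, also built by
`italy_fixture()`) has:

* macroarea North, strip Piemonte → Emilia Romagna → Toscana → NITp, with
  NITp a macroregion center covering Lombardia, Veneto, Friuli Venezia
  Giulia, Trentino-Alto Adige, Liguria and Marche; Sardegna and Valle
  d'Aosta as no-center North regions;
* macroarea South, strip Lazio → Sicilia, with Calabria, Basilicata,
  Abruzzo-Molise, Umbria, Campania and Puglia as no-center regions;
* a uniform 26% acceptance rate (the observed mean of the evaluation
  period; 90% and 100% are the standard exploratory settings);
* production weights from the published 2017 per-region donor counts
  (121 Piemonte, 142 Emilia Romagna, 167 Toscana, 130 Veneto, 226
  Lombardia, 50 Sicilia, 117 Lazio; others 0). These are a documented proxy
  for period-specific surplus counts, which are not publicly available; with
  different weights the per-center curves shift but every structural
  property (conservation, rotation fairness, plateau, binomial limit) is
  weight-independent.

The mapping of no-center regions to macroareas is only partially fixed by
the protocol documents; the assignment above is editable in the config file
and affects results only through the production weights (all zero for those
regions by default).

What the synthetic setting does *not* emulate: per-center heterogeneous
acceptance rates (supported by the config, not exercised by the default),
clinical refusal reasons, the 45-minute evaluation window, urgency/
restitution/regional protocols, and geography (cold-ischemia time) beyond
the macroarea split. Passing tests therefore validate the allocation
mechanics and the probability calculus, not a calibrated forecast for any
particular year.

## Numerical choices and problem sizes

* Probabilities are accumulated in double precision over sparse dictionaries
  of reachable states; normalization checks use 1e-12 absolute tolerance.
* The enumeration oracle in the test suite runs 20 random nations with ≤3
  slots per strip at M = 4; the Monte Carlo cross-validation runs the
  Italian configuration at M = 10 with 200,000 seasons in the tests and
  50,000 in the acceptance script, with agreement required within 4
  standard errors (standard error taken from the less degenerate of the
  analytic and empirical values, so exact-zero cells compare exactly).
* The plateau check reads the chain at t = 60, where successive differences
  are ≈1e-8.
* Ties (equal strip positions) cannot occur: positions are a total order.

## Known limitations

* Exactly two macroareas are supported; "the other macroarea" is the whole
  fallback policy. An ordered multi-area fallback is a documented extension
  point, not implemented.
* The Bahadur engine clips negative truncated masses; for strongly negative
  correlation structures the clipped mass can be substantial (it is always
  reported) and the exact engine should be preferred whenever the chain
  fits in memory.
* The cumulative engines report `P(at least k)` for one center at a time;
  joint statements across centers require the Monte Carlo engine.
* No closed-form inversion (finding M for a target probability); sweep M
  via the CLI.
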