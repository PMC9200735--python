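# Methods

This note documents the model, the parameter choices behind the synthetic
study conditions, the calibration machinery, and the numerical decisions a
user should know before trusting or extending results.

## Populations

Three stocks are simulated on a monthly step over a grid of ICES
statistical rectangles (0.5° latitude × 1° longitude, codes like `24E2`),
grouped into named zones.  Zones used as migration endpoints of one
population must be pairwise disjoint; different populations may reuse
rectangles (the Norway lobster mudbank deliberately overlaps the hake
nursery — the source of the undersized-hake bycatch interaction).

**Hake** is length-structured: 1 cm bins on [1, 40) cm, 2 cm on
[40, 100) cm, 10 cm on [100, 130) cm and a 130+ plus-group — 73 classes.
Four zones carry the intra-annual migrations: mature fish aggregate on the
shelf break (spawning zone) at the beginning of January and disperse back
over the shelf at the beginning of April and July; fish reaching 20 cm
(taken as a pure length threshold for "around age 1") spill monthly from
the recruitment zone into the interim-recruitment zone.  Recruitment is a
prescribed deterministic series entering the first class monthly,
January–September only.  Natural mortality is 0.5 yr⁻¹.  Initial
abundance is allocated by the maturity ogive: classes under 20 cm wholly to
the recruitment area, the mature fraction of larger classes to the spawning
area, the remainder to the interim area, and none to the presence area.

**Sole** is age-structured with 7 classes starting at age 2 (ages 0–1 are
not modelled) and a terminal plus-group.  The printed range "ages 2 to 7+"
under-enumerates by one against the stated count of 7; the count is
honoured and the labels run to an 8+ plus-group.  Ageing happens each
January (shift-up with plus-group accumulation) before the annual age-2
recruitment.  A single presence zone is used.

**Norway lobster** is sex-and-length structured: a mixed recruitment class
plus 2-mm carapace bins — males [10, 74) mm and females [10, 54) mm.  The
stated ranges enumerate to 32 and 22 bins; one terminal plus-group per sex
is appended to match the counts of 33 and 23.  Growth happens only at the
April and October moults; October moulting applies to males and to the
immature fraction of each female class only.  Recruits enter the sexed
tracks 50/50 at the spring moult.  Annual recruitment follows a
Beverton–Holt curve R = αS/(β+S) on spawning-stock biomass, distributed
over rectangles like SSB itself.  Female accessibility follows an
8-period burrow/emergence calendar; only ordinal statements are available
("less accessible" in burrow months, "more accessible" April–August), so
the default levels are 0.5 (burrow) and 1.5 (emerged) with males at 1.0 —
calibratable choices, not data.

### Growth matrices

Growth over one event is a column-stochastic transition matrix built under
a uniform-within-bin assumption: mass in [a, b) shifted by the class
increment d spreads uniformly over [a+d, b+d) and is split across
destination bins by interval overlap, overflow accruing to the plus-group.
This is the correction that removes the artefact of growing from a narrow
bin into a wider one: the continuous mean length drifts by exactly d for
every non-terminal class.  When drift is *measured through bin midpoints*,
a discretisation offset appears at bin-width changes (e.g. 1 cm out of
[39, 40) lands wholly in [40, 42), whose midpoint is 41); the
individual-based oracle tallied into the same bins carries the identical
offset, which is why the matrix-vs-oracle comparison is the meaningful
contract (it holds to well under 1%), while drift-equals-increment is
asserted only away from width boundaries.  Plus-groups are absorbing.

## Exploitation

Fishing mortality is the product form
`F = effort · targetfactor · accessibility · selectivity` per class,
applied in the métier's zone only, with an optional per-métier
standardisation constant (default 1; effort is in abstract fishing days, so
only products with catchability are meaningful).  Catch within a month is
partitioned by the Baranov equation; the accounting identity
N = survivors + Σ catches + natural deaths is exact and is verified per
class/zone/month in the tests.

Target factors have three multiplicative components: a fixed per-métier
base, an inter-annual factor, and an estimated component.  Inter-annual
factors are observed-catch ratios over the 2010 base year, keyed
(métier, season, year) for hake, (métier, year) for sole, and (year) for
Norway lobster (identical across its métiers).  For the last four years of
a paper-length horizon they come from a least-squares trend on the
2014–2016 ratios: if the slope is significant at 5% (two-sided t-test with
1 degree of freedom — essentially never with three free points, hence a
`force_significant` switch mirroring the groups for which a trend was
retained), the 2016 value is extended with the slope, halved for the groups
prone to unrealistic effort growth; otherwise the 2016 ratio carries
forward.  Results are floored at 0.

Spanish longliner and gillnetter fleets are described through catch rather
than effort: their hake removals are the French catch of the matching
métier group times an observed Spanish/French ratio per month × length
bin, subtracted from the state after the effort-based catch step (they
exert no effort in the model).  Out-of-area removals are a prescribed
series subtracted proportionally to zone abundance; both removal channels
floor abundance at zero and log any shortfall rather than failing.

## Management and fishers' behaviour

The regime calendar: no quotas during 2010–2012 (the calibration window);
TALs for all stocks 2013–2015; from 2016 TACs for hake and sole (both under
the Landings Obligation) while Norway lobster stays under TALs and outside
the LO.  TAL semantics cap annual landings, with over-quota landings
recorded as discards — applied monthly against cumulative year-to-date
landings, which makes the annual cap an exact invariant.  TAC semantics
never delete catch: once a stock's cumulative catch reaches its TAC under
an enforced LO, métiers expected to catch it (positive previous-calendar-
year catch — the look-back depth is a stated assumption) are flagged for
the rest of the year, strategy effort is re-allocated off flagged métiers
proportionally to the remaining shares (an explicit `inactive`
pseudo-métier guarantees totality when everything is flagged), and target
factors are scaled by min(1, quota remaining / expected catch) with the
previous month's catch as the expectation.  A discard-proportion flag
trigger exists but is disabled unless configured.  Every decision emits a
trace record (flag, re-allocation before/after, target-factor adjustment,
quota values), written as CSV files.

The discard split pre-LO is `max(discard ogive, 1 below MCRS)` per class.
Under the LO, at most the de-minimis fraction of the month's catch may
still be discarded; retained would-be discards are counted against the
catch quota and recorded in the landings fraction (the sellable /
non-sellable distinction below MCRS is not tracked separately).

Within a month the order is: annual January events (sole ageing, sole and
Norway lobster recruitment) → hake monthly recruitment → migrations →
management checks → mortality and the landings/discards split → catch-based
and exogenous removals → growth.  Management-before-mortality and
growth-last are choices (the initial abundances are treated as post-growth
January states); the base run is fully deterministic and bit-reproducible.

## Calibration

Two parameter families are free: accessibilities and target-factor
estimated components.  Estimation is sequential — accessibility sets first,
then target-factor sets — each set minimised jointly with the others held
fixed, using Powell's bounded derivative-free search (small sets: 4–56
accessibilities, 2–20 target factors), relative objective tolerance 1e-6,
optional seeded multi-start.  Objectives are raw-scale sums of squared
residuals; the hake objective adds a length-frequency composition term on
distributions normalised to proportions, both terms carrying weighting
tables keyed (quarter, métier group, fraction) and combined additively.
During a set's optimisation only that stock is simulated: in the quota-free
calibration window the stocks are dynamically independent, so the
restriction is exact, not an approximation.

A structural point that shapes the synthetic truth: a per-quarter
accessibility and per-(group, quarter) estimated components enter F only
through their product, so the two families are not jointly identifiable
from catch alone.  The sequential procedure resolves this by anchoring
target factors at their fixed × inter-annual components while accessibility
is estimated.  The generator therefore sets the truth estimated components
to the neutral value 1 — in a self-consistent synthetic world the
component, whose role is to absorb residual model–data mismatch, has
nothing to absorb — while accessibilities take nontrivial truth values
drawn uniform in [0.4, 1.4].  Recovery is still a genuine optimisation:
accessibilities start at mid-bounds (0.5 after zeroing non-catchable
classes) and target factors at 0.6, far from the truth.

## Synthetic study conditions

The `tiny` preset (the default test condition) covers 2010–2012 on a 3×3
rectangle block with reduced structures (7 hake length bins, 3 sole ages,
recruitment + 3 male + 2 female Norway lobster bins), three métier groups
(gillnetters, coastal whitefish trawlers, Norway lobster trawlers) in two
fleets, monthly efforts of 400–700 days, and base target factors of order
1e-4 chosen so annual fishing mortalities land in the realistic 0.3–1
range.  `small` adds longliners and three managed years (2013–2015);
`paperlike` uses the full class structures, all five métier groups and the
11-year horizon.  Quota amounts for the managed years are set at 80% of
each stock's quota-free annual landings in 2012, so TALs genuinely bind.
Natural mortalities are 0.5 (hake), 0.1 (sole) and 0.3 yr⁻¹ (Norway
lobster); weights follow a cube law for hake and a quadratic carapace
relation for Norway lobster; ogives are logistic with L50s bracketing the
MCRS values (27 cm hake, 24 cm sole, 25 mm Norway lobster carapace).

Observation bundles are built from a truth run at the real data
granularities: hake catch weight per length class × quarter × métier group
× fraction (2010–2012) with unit weighting tables; sole F-at-age per year —
recomputed from truth survival ratios as −ln(N_end/N_start) − M, playing
the role of assessment estimates, not copied from the simulator's own F
bookkeeping — and sole catch per métier × quarter; Norway lobster catch
numbers per sex × length × quarter and monthly landings (2010); landings
per rectangle × quarter.  Noise is multiplicative mean-one lognormal
(σ² = ln(1+CV²)) applied per aggregated cell after the run — observation
error, not process error; the dynamics stay deterministic.  CV = 0
reproduces the truth aggregations exactly.

What the generator does *not* emulate: logbook-level record structure,
vessel heterogeneity, spatial structure within zones beyond static
rectangle weights, environmentally driven recruitment, and real
inter-annual observation series.  Passing tests therefore demonstrate the
machinery (dynamics, accounting, management logic, estimation) is correct
and self-consistent at realistic magnitudes — not that the model fits any
particular real fishery.

## Numerical choices and problem sizes

Bin-overlap growth matrices are renormalised to exact column sums; the
Baranov step uses `expm1` for small-Z stability and treats Z = 0 exactly.
Optimiser evaluations clip parameters at 0 to guard Powell's occasional
ε-negative steps at an active bound.  The noise-free recovery study runs
the optimiser to tolerance; the 20-seed CV = 0.1 study caps each set at 400
objective evaluations — at that budget the pooled median absolute relative
error sits near 5%, well inside the 15% property bound, and the full study
completes in a few minutes on one CPU.  Trace files use fixed numeric
formatting so identical runs are byte-identical.

## Known limitations

* Effort re-allocation redistributes proportionally within a strategy;
  no cross-strategy or economic choice model.
* Expected catch for target-factor scaling is last month's catch — a
  one-step-behind estimate that can overshoot at sharp seasonal
  transitions.
* The TAL cap applies to the effort-based (French) métiers; catch-based
  Spanish removals and out-of-area removals are bookkept outside quota
  accounting.
* Spatial landings are disaggregated from zone level by static rectangle
  weights (uniform by default), so within-zone spatial contrast in Δ maps
  comes entirely from zone membership.
* Point estimation only: the calibration reports no uncertainty.
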