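# baymix

A monthly, spatially explicit simulator of the Bay of Biscay mixed demersal
fishery — northern hake (*Merluccius merluccius*), common sole (*Solea
solea*) and Norway lobster (*Nephrops norvegicus*) — together with the
sequential calibration procedure that ties its catchability parameters to
catch observations, and the skill-assessment statistics used to judge the
fit.

It is written for fisheries modellers who need an operating model of a
mixed fishery: three structured stocks (length-, age- and sex/length-based),
interacting fleets described as *métiers* (a gear × location × target-mix
unit) whose effort shares can be re-allocated in response to management,
and the EU management instruments in force in the area — landings quotas
(TAL), catch quotas (TAC), Minimum Conservation Reference Sizes and the
Landings Obligation with *de minimis* exemptions.  A synthetic-data module
generates reduced-scale configurations with known truth so every stage is
testable without confidential logbook or assessment data.

## The model in brief

Within each month and zone, deaths are partitioned by the Baranov
competing-risks equation.  With métier-specific fishing mortalities
F_m and monthly natural mortality M/12, for each class:

    Z = Σ_m F_m + M/12
    catch_m   = F_m / Z · (1 − e^{−Z}) · N
    survivors = N · e^{−Z}

so N = survivors + Σ catch_m + natural deaths closes exactly.  Fishing
mortality follows a multiplicative catchability decomposition

    F_m(class) = effort_m · targetfactor_{m,pop} · accessibility_pop(class) · selectivity_gear(class)

where the target factor is itself a product of a fixed base per métier, an
inter-annual factor (observed catch ratio year/2010 at stock-specific
granularity) and an estimated component set by calibration.  Growth uses
column-stochastic transition matrices built under a uniform-within-bin
assumption, which corrects the artefact of growing from a narrow bin into a
wider one; Norway lobster grows only at the April and October moults, with
burrow-bound females less accessible outside spring/summer.  Spatial skill
is measured per ICES statistical rectangle r by the landings-distribution
discrepancy

    Δ_r = sim_r / Σ sim − obs_r / Σ obs  ∈ [−1, 1],   Σ_r Δ_r = 0.

Calibration is sequential: per-population accessibilities are estimated
first (hake: one scalar per quarter shared across lengths; sole: one per
age; Norway lobster: one per sex × length class), then the target-factor
estimated components (hake/sole: per métier group × quarter, Norway
lobster: per group), each set minimised jointly by a bounded derivative-free
search against the observation stream matching that stock's data
granularity.

## Worked example

```python
from baymix.synthetic import generate_config
from baymix.engine import run

cfg = generate_config(seed=1, preset="tiny")   # truth config, 2010-2012
store = run(cfg)

for stock in ("hake", "sole", "nephrops"):
    print(f"{stock:9s} 2010: catch {store.annual_catch_tons(stock, 2010):7.1f} t,"
          f" landings {store.annual_landings_tons(stock, 2010):7.1f} t")
```

prints

```
hake      2010: catch  1553.7 t, landings  1429.7 t
sole      2010: catch   971.5 t, landings   928.5 t
nephrops  2010: catch   674.5 t, landings   591.4 t
```

The gap between catch and landings is the discarding the model resolves
per class: undersized fish (below the MCRS) and the gear discard ogives.
From the same store you can pull biomass, SSB, fishing mortality and effort
series, per-rectangle landings (`store.landings_by_rectangle`), and the
management traces (flags, effort re-allocations, target-factor
adjustments).  The command-line surface wraps the same calls:

```bash
baymix synth --preset tiny --seed 42 --out work/      # config + observations
baymix simulate --config work/config.yaml --out runs/ # trace + catch files
baymix calibrate --config work/config.yaml --out cal/ # sequential estimation
baymix validate --config work/config.yaml --out val/  # spatial delta maps
```

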