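"""The monthly simulation loop and its output store.

Each simulated month applies, in order: (1) January-only annual events (sole
ageing, sole and Norway lobster recruitment); (2) hake monthly recruitment
(January-September); (3) migrations; (4) management — quota bookkeeping,
métier flags, effort re-allocation and target-factor adjustment, all traced;
(5) mortality — Baranov catch over all métiers with seasonal accessibility,
plus the landings/discards split and TAL capping; (6) catch-based Spanish
fleet removals and exogenous out-of-area removals; (7) growth — the hake
transition matrix every month, the Norway lobster moult in April and October
only.  The base run is fully deterministic: identical configurations give
bit-identical outputs.

The output store keeps catch in numbers and tons per (month, métier row,
class, fraction) and per-zone abundance accounting (start, survivors,
natural deaths) so that the Baranov closure — initial N = survivors + all
catches + natural deaths — can be verified for every cell of every month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .exploitation import (
    LOState,
    apply_exogenous_removals,
    baranov_catch,
    catch_based_fleet_removals,
    fishing_mortality,
    split_landings_discards,
)
from .management import (
    QuotaRule,
    enforce_quota_on_landings,
    flag_metiers,
    quota_regime,
    reallocate_effort,
    adjust_target_factors,
)
from .populations import (
    PopulationState,
    age_sole,
    hake_migrations,
    nephrops_moult,
    recruit_hake,
    recruit_nephrops,
    recruit_sole,
    spawning_stock_biomass,
)
from .structures import apply_growth

__all__ = ["OutputStore", "run", "step_month", "month_index"]

FRACTIONS = ("landings", "discards")
F_LAND, F_DISC = 0, 1


def month_index(year: int, month: int, start_year: int = 2010) -> int:
    """0-based month index from January of the start year."""
    return (year - start_year) * 12 + (month - 1)


@dataclass
class RowMeta:
    name: str
    group: str
    nationality: str
    zone: str


@dataclass
class OutputStore:
    """Append-only per-month outputs of one run."""

    n_months: int
    start_year: int
    stocks: tuple[str, ...]
    # per stock: (T, n_rows, n_classes, 2) catch in numbers / tons
    catch_n: dict[str, np.ndarray] = field(default_factory=dict)
    catch_w: dict[str, np.ndarray] = field(default_factory=dict)
    rows: dict[str, list[RowMeta]] = field(default_factory=dict)
    # per stock: (T, n_zones, n_classes) accounting arrays
    n_start: dict[str, np.ndarray] = field(default_factory=dict)
    survivors: dict[str, np.ndarray] = field(default_factory=dict)
    natural: dict[str, np.ndarray] = field(default_factory=dict)
    F: dict[str, np.ndarray] = field(default_factory=dict)
    zone_order: dict[str, tuple[str, ...]] = field(default_factory=dict)
    effort: np.ndarray | None = None  # (T, n_metiers) effective days
    metier_names: tuple[str, ...] = ()
    ssb: dict[str, np.ndarray] = field(default_factory=dict)
    biomass: dict[str, np.ndarray] = field(default_factory=dict)
    class_weights: dict[str, np.ndarray] = field(default_factory=dict)
    flags: list = field(default_factory=list)
    realloc_traces: list = field(default_factory=list)
    tf_traces: list = field(default_factory=list)
    quota_values: list = field(default_factory=list)  # (year, stock, type, tons)
    shortfalls: list = field(default_factory=list)  # (t, stock, total shortfall)

    def year_of(self, t: int) -> int:
        return self.start_year + t // 12

    def quarter_of(self, t: int) -> int:
        return (t % 12) // 3 + 1

    # -- aggregations used by calibration and skill assessment ------------

    def _year_quarters(self, years: list[int]) -> list[tuple[int, int]]:
        return [(y, q) for y in years for q in (1, 2, 3, 4)]

    def _months_of(self, year: int, quarter: int | None = None) -> np.ndarray:
        t0 = (year - self.start_year) * 12
        if quarter is None:
            ts = np.arange(t0, t0 + 12)
        else:
            ts = np.arange(t0 + 3 * (quarter - 1), t0 + 3 * quarter)
        return ts[(ts >= 0) & (ts < self.n_months)]

    def group_rows(self, stock: str, nationality: str | None = "FR") -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, rm in enumerate(self.rows[stock]):
            if nationality is not None and rm.nationality != nationality:
                continue
            out.setdefault(rm.group, []).append(i)
        return {g: np.asarray(ix) for g, ix in out.items()}

    def hake_weight_by_lqgf(self, years: list[int]) -> dict[tuple, float]:
        """Hake catch weight (t) per (length class, (year, quarter), métier
        group, fraction) over the given years — the hake objective cells."""
        groups = self.group_rows("hake")
        W = self.catch_w["hake"]
        out: dict[tuple, float] = {}
        for y, q in self._year_quarters(years):
            ts = self._months_of(y, q)
            if len(ts) == 0:
                continue
            sub = W[ts]  # (m, rows, C, 2)
            for g, ix in groups.items():
                for fi, frac in enumerate(FRACTIONS):
                    vals = sub[:, ix, :, fi].sum(axis=(0, 1))
                    for c, v in enumerate(vals):
                        out[(c, (y, q), g, frac)] = float(v)
        return out

    def catch_tons_by_metier_quarter(self, stock: str, years: list[int]) -> dict[tuple, float]:
        """Total catch (t) per (métier, (year, quarter))."""
        W = self.catch_w[stock]
        out: dict[tuple, float] = {}
        for y, q in self._year_quarters(years):
            ts = self._months_of(y, q)
            if len(ts) == 0:
                continue
            tot = W[ts].sum(axis=(0, 2, 3))
            for i, rm in enumerate(self.rows[stock]):
                if rm.nationality == "FR":
                    out[(rm.name, (y, q))] = float(tot[i])
        return out

    def sole_annual_F(self, years: list[int]) -> np.ndarray:
        """Annual fishing mortality per age class (sum of monthly F)."""
        Fs = self.F["sole"]
        return np.stack([Fs[self._months_of(y)].sum(axis=(0, 1)) for y in years])

    def nephrops_numbers_by_slq(self, year: int) -> np.ndarray:
        """Catch numbers per (quarter, class) for one year, both fractions."""
        N = self.catch_n["nephrops"]
        return np.stack(
            [N[self._months_of(year, q)].sum(axis=(0, 1, 3)) for q in (1, 2, 3, 4)]
        )

    def nephrops_monthly_landings(self, year: int) -> np.ndarray:
        """Landings tons per (calendar month, class) for one year."""
        W = self.catch_w["nephrops"]
        ts = self._months_of(year)
        return W[ts][:, :, :, F_LAND].sum(axis=1)

    def landings_by_rectangle(
        self, stock: str, year: int, config: SimulationConfig
    ) -> dict[tuple[int, str], float]:
        """Landings tons per (quarter, rectangle), disaggregated from métier
        zones through the stock's rectangle weights."""
        sc = config.stocks[stock]
        W = self.catch_w[stock]
        out: dict[tuple[int, str], float] = {}
        for q in (1, 2, 3, 4):
            ts = self._months_of(year, q)
            land = W[ts][:, :, :, F_LAND].sum(axis=(0, 2))  # per row
            for i, rm in enumerate(self.rows[stock]):
                if not rm.zone:
                    continue
                w = sc.rect_weights.get(rm.zone)
                if not w:
                    continue
                s = sum(w.values())
                for rect, wt in w.items():
                    key = (q, rect)
                    out[key] = out.get(key, 0.0) + land[i] * wt / s
        return out

    def annual_landings_tons(self, stock: str, year: int) -> float:
        ts = self._months_of(year)
        fr = [i for i, rm in enumerate(self.rows[stock]) if rm.nationality == "FR"]
        return float(self.catch_w[stock][ts][:, fr, :, F_LAND].sum())

    def annual_catch_tons(self, stock: str, year: int) -> float:
        ts = self._months_of(year)
        fr = [i for i, rm in enumerate(self.rows[stock]) if rm.nationality == "FR"]
        return float(self.catch_w[stock][ts][:, fr, :, :].sum())


class _RunContext:
    """Mutable bookkeeping that spans months (flags, cumulative quotas)."""

    def __init__(self, config: SimulationConfig, stocks: tuple[str, ...]):
        self.config = config
        self.stocks = stocks
        self.transitions = {
            s: config.stocks[s].transition for s in stocks
        }  # built once per run; growth matrices are static
        self.flagged: set[str] = set()
        self.flag_year: int | None = None
        self.cum_landings = {s: 0.0 for s in stocks}
        self.cum_catch = {s: 0.0 for s in stocks}
        self.cum_year: int | None = None
        self.prev_year_catch: dict[tuple[str, str], float] = {}
        self.this_year_catch: dict[tuple[str, str], float] = {}
        self.last_month_catch: dict[tuple[str, str], float] = {}

    def roll_year(self, year: int) -> None:
        if self.cum_year != year:
            self.cum_year = year
            self.cum_landings = {s: 0.0 for s in self.stocks}
            self.cum_catch = {s: 0.0 for s in self.stocks}
            self.prev_year_catch = self.this_year_catch
            self.this_year_catch = {}
            self.flagged = set()

    def quota_rules(self, year: int) -> dict[str, QuotaRule]:
        rules = {}
        for s in self.stocks:
            regime = quota_regime(s, year) if year >= self.config.management.first_quota_year else "none"
            amount = self.config.management.quota_amounts.get((s, year), 0.0)
            if regime == "none" or amount <= 0:
                rules[s] = QuotaRule(s, year, "none")
            else:
                rules[s] = QuotaRule(s, year, regime, amount)
        return rules


def _init_store(config: SimulationConfig, stocks: tuple[str, ...]) -> OutputStore:
    T = config.n_months
    store = OutputStore(T, config.start_year, stocks)
    store.metier_names = tuple(m.name for m in config.metiers)
    store.effort = np.zeros((T, len(config.metiers)))
    for s in stocks:
        sc = config.stocks[s]
        rows = [RowMeta(m.name, m.group, m.nationality, m.zones.get(s, "")) for m in config.metiers]
        if s == "hake":
            for g in config.spanish_ratio_tables:
                zone = next((m.zones.get(s, "") for m in config.metiers if m.group == g), "")
                rows.append(RowMeta(f"ES_{g}", g, "ES", zone))
            if config.exogenous_removals is not None:
                rows.append(RowMeta("out_of_area", "out_of_area", "XX", ""))
        store.rows[s] = rows
        C = sc.structure.n_classes
        Z = len(sc.zone_order)
        store.catch_n[s] = np.zeros((T, len(rows), C, 2))
        store.catch_w[s] = np.zeros((T, len(rows), C, 2))
        store.n_start[s] = np.zeros((T, Z, C))
        store.survivors[s] = np.zeros((T, Z, C))
        store.natural[s] = np.zeros((T, Z, C))
        store.F[s] = np.zeros((T, Z, C))
        store.zone_order[s] = sc.zone_order
        store.ssb[s] = np.zeros(T)
        store.biomass[s] = np.zeros(T)
        store.class_weights[s] = sc.life.weight.copy()
    return store


def step_month(
    states: dict[str, PopulationState],
    config: SimulationConfig,
    t: int,
    store: OutputStore,
    ctx: _RunContext,
) -> None:
    """Advance every simulated stock by one month, recording outputs."""
    if t < 0 or t >= config.n_months:
        raise ValueError(f"month index {t} outside horizon [0, {config.n_months})")
    year = config.year_of(t)
    cal = config.calendar_month(t)
    quarter = config.quarter_of(t)
    mgmt = config.management
    ctx.roll_year(year)

    # (1) January annual events -------------------------------------------
    if cal == 1:
        if "sole" in states:
            sc = config.stocks["sole"]
            states["sole"] = age_sole(states["sole"])
            if sc.recruitment_series is not None:
                states["sole"] = recruit_sole(states["sole"], year, sc.recruitment_series)
        if "nephrops" in states:
            sc = config.stocks["nephrops"]
            if sc.beverton_holt is not None:
                ssb, _ = spawning_stock_biomass(states["nephrops"], sc.life, sc.rect_weights)
                states["nephrops"] = recruit_nephrops(states["nephrops"], sc.beverton_holt, ssb)

    # (2) hake monthly recruitment ----------------------------------------
    if "hake" in states:
        sc = config.stocks["hake"]
        if sc.recruitment_series is not None:
            states["hake"] = recruit_hake(states["hake"], year, cal, sc.recruitment_series)

    # (3) migrations -------------------------------------------------------
    if "hake" in states:
        sc = config.stocks["hake"]
        if sc.migrations:
            states["hake"] = hake_migrations(states["hake"], cal, sc.migrations, sc.structure, sc.life)

    # (4) management -------------------------------------------------------
    rules = ctx.quota_rules(year)
    if cal == 1:
        for s, r in rules.items():
            store.quota_values.append((year, s, r.type, r.amount if r.type != "none" else 0.0))
    lo_active = {
        s: (s in mgmt.lo and mgmt.lo[s].active(year)) for s in ctx.stocks
    }
    tac_rules = {s: r for s, r in rules.items() if r.type == "TAC"}
    if tac_rules:
        new_flags = flag_metiers(
            ctx.cum_catch, tac_rules, lo_active, ctx.prev_year_catch, t,
            [m.name for m in config.metiers], discard_threshold=mgmt.discard_threshold,
        )
        for f in new_flags:
            if f.metier not in ctx.flagged:
                ctx.flagged.add(f.metier)
                store.flags.append(f)
    strategies = config.strategies
    if ctx.flagged:
        flag_objs = [f for f in store.flags if f.metier in ctx.flagged]
        strategies = []
        for s in config.strategies:
            ns, traces = reallocate_effort(s, flag_objs, t)
            strategies.append(ns)
            store.realloc_traces.extend(traces)
    tf_scale: dict[str, float] = {}
    if tac_rules and mgmt.adjust_target_factors:
        remaining = {s: r.amount - ctx.cum_catch[s] for s, r in tac_rules.items()}
        factors = {m.name: 1.0 for m in config.metiers}
        expected = {
            (m.name, s): ctx.last_month_catch.get((m.name, s), 0.0)
            for m in config.metiers
            for s in tac_rules
        }
        tf_scale, traces = adjust_target_factors(factors, expected, remaining, t)
        store.tf_traces.extend(traces)

    # effective effort per métier this month
    eff = np.zeros(len(config.metiers))
    for s in strategies:
        for i, m in enumerate(config.metiers):
            eff[i] += s.metier_effort(m.name, cal)
    store.effort[t] = eff

    # (5) mortality: Baranov over all métiers, landings/discards split -----
    month_catch: dict[tuple[str, str], float] = {}
    for sname, state in states.items():
        sc = config.stocks[sname]
        C = sc.structure.n_classes
        store.n_start[sname][t] = state.abundance
        acc = sc.accessibility_per_class(quarter)
        if sc.seasonal_schedule is not None:
            seas = np.array(
                [sc.seasonal_schedule.multiplier(cal, sx) for sx in sc.structure.sex]
            )
            acc = acc * seas
        mcrs_rule = mgmt.mcrs.get(sname)
        below = (
            mcrs_rule.below(sc.class_lengths) if mcrs_rule is not None else np.zeros(C, bool)
        )
        # per-zone Baranov
        metier_rows = {m.name: i for i, m in enumerate(config.metiers)}
        land_total = 0.0
        pending: list[tuple[int, np.ndarray, np.ndarray]] = []  # (row, landings, discards)
        for zi, zname in enumerate(sc.zone_order):
            active = [
                (i, m) for i, m in enumerate(config.metiers)
                if m.zones.get(sname) == zname and eff[i] > 0
            ]
            Fz = np.zeros((max(len(active), 1), C))
            for k, (i, m) in enumerate(active):
                tf = config.target_factors.value(sname, m, quarter, year)
                if tf == 0.0:
                    continue
                tf *= tf_scale.get(m.name, 1.0)
                sel = m.gear.selectivity_at(sname, sc.class_lengths)
                Fz[k] = fishing_mortality(eff[i], tf, acc, sel, m.standardisation, check=False)
            n0 = state.abundance[zi]
            catch, surv, nat = baranov_catch(n0, Fz, sc.life.M, 1.0, check=False)
            state.abundance[zi] = surv
            store.survivors[sname][t, zi] = surv
            store.natural[sname][t, zi] = nat
            store.F[sname][t, zi] = Fz.sum(axis=0)
            for k, (i, m) in enumerate(active):
                lo = None
                if lo_active.get(sname) and sname in mgmt.lo:
                    lo = LOState(True, mgmt.lo[sname].rate(year, m.gear.name))
                dg = m.gear.discard_at(sname, sc.class_lengths)
                landings, discards = split_landings_discards(catch[k], dg, below, lo, check=False)
                pending.append((metier_rows[m.name], landings, discards))
                land_total += float((landings * sc.life.weight).sum()) / 1000.0
        # TAL capping on this month's landings (French effort-based métiers)
        rule = rules[sname]
        scale_land = 1.0
        if rule.type == "TAL" and land_total > 0:
            capped, _ = enforce_quota_on_landings(land_total, 0.0, ctx.cum_landings[sname], rule)
            scale_land = capped / land_total
        wkg = sc.life.weight
        for row, landings, discards in pending:
            if scale_land < 1.0:
                moved = landings * (1.0 - scale_land)
                landings = landings - moved
                discards = discards + moved
            store.catch_n[sname][t, row, :, F_LAND] += landings
            store.catch_n[sname][t, row, :, F_DISC] += discards
            store.catch_w[sname][t, row, :, F_LAND] += landings * wkg / 1000.0
            store.catch_w[sname][t, row, :, F_DISC] += discards * wkg / 1000.0
            mname = store.rows[sname][row].name
            tons = float(((landings + discards) * wkg).sum()) / 1000.0
            month_catch[(mname, sname)] = month_catch.get((mname, sname), 0.0) + tons
        ctx.cum_landings[sname] += land_total * scale_land
        ctx.cum_catch[sname] += float(store.catch_w[sname][t].sum())

    # (6) Spanish catch-based removals and exogenous removals (hake) ------
    if "hake" in states:
        sc = config.stocks["hake"]
        state = states["hake"]
        wkg = sc.life.weight
        row_by_name = {rm.name: i for i, rm in enumerate(store.rows["hake"])}
        for g, table in config.spanish_ratio_tables.items():
            ratio = table.ratios[cal - 1]
            es_row = row_by_name[f"ES_{g}"]
            for i, m in enumerate(config.metiers):
                if m.group != g or m.nationality != "FR" or "hake" not in m.zones:
                    continue
                fr_catch = store.catch_n["hake"][t, i].sum(axis=1)  # both fractions
                removal = catch_based_fleet_removals(fr_catch, ratio)
                if removal.sum() == 0:
                    continue
                zi = state.zone_index(m.zones["hake"])
                new_n, short = apply_exogenous_removals(state.abundance[zi], removal)
                state.abundance[zi] = new_n
                if short.sum() > 0:
                    store.shortfalls.append((t, "hake", float(short.sum())))
                taken = removal - short
                below = (
                    mgmt.mcrs["hake"].below(sc.class_lengths)
                    if "hake" in mgmt.mcrs else np.zeros(len(wkg), bool)
                )
                dg = m.gear.discard_at("hake", sc.class_lengths)
                landings, discards = split_landings_discards(taken, dg, below, None)
                store.catch_n["hake"][t, es_row, :, F_LAND] += landings
                store.catch_n["hake"][t, es_row, :, F_DISC] += discards
                store.catch_w["hake"][t, es_row, :, F_LAND] += landings * wkg / 1000.0
                store.catch_w["hake"][t, es_row, :, F_DISC] += discards * wkg / 1000.0
        if config.exogenous_removals is not None:
            removal = config.exogenous_removals.at(t, sc.structure.n_classes)
            if removal.sum() > 0:
                oa_row = row_by_name["out_of_area"]
                tot = state.abundance.sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    prop = np.where(tot > 0, state.abundance / np.where(tot > 0, tot, 1.0), 0.0)
                taken_tot = np.minimum(removal, tot)
                short = removal - taken_tot
                state.abundance -= prop * taken_tot
                if short.sum() > 0:
                    store.shortfalls.append((t, "hake", float(short.sum())))
                store.catch_n["hake"][t, oa_row, :, F_LAND] += taken_tot
                store.catch_w["hake"][t, oa_row, :, F_LAND] += taken_tot * wkg / 1000.0

    # (7) growth ------------------------------------------------------------
    if "hake" in states:
        T_h = ctx.transitions["hake"]
        if T_h is not None:
            states["hake"].abundance = apply_growth(states["hake"].abundance, T_h)
    if "nephrops" in states and cal in (4, 10):
        sc = config.stocks["nephrops"]
        T_n = ctx.transitions["nephrops"]
        if T_n is not None:
            states["nephrops"] = nephrops_moult(states["nephrops"], cal, T_n, sc.structure, sc.life)

    # month-end bookkeeping -------------------------------------------------
    for sname, state in states.items():
        sc = config.stocks[sname]
        state.month = t + 1
        state.validate()
        store.biomass[sname][t] = float((state.abundance @ sc.life.weight).sum()) / 1000.0
        ssb, _ = spawning_stock_biomass(state, sc.life, None)
        store.ssb[sname][t] = ssb
    for key, v in month_catch.items():
        ctx.this_year_catch[key] = ctx.this_year_catch.get(key, 0.0) + v
    ctx.last_month_catch = month_catch


def run(config: SimulationConfig, only_stocks: tuple[str, ...] | None = None) -> OutputStore:
    """Run the full horizon, returning the output store.

    ``only_stocks`` restricts the simulation to a subset of stocks — exact
    (not approximate) during the quota-free calibration window, where stocks
    are dynamically independent.
    """
    stocks = tuple(config.stocks) if only_stocks is None else tuple(only_stocks)
    for s in stocks:
        if s not in config.stocks:
            raise KeyError(f"unknown stock {s!r}")
    store = _init_store(config, stocks)
    states = {s: config.stocks[s].initial_state() for s in stocks}
    ctx = _RunContext(config, stocks)
    for t in range(config.n_months):
        try:
            step_month(states, config, t, store, ctx)
        except Exception as exc:  # identify the failing month
            raise RuntimeError(
                f"simulation failed at month {t} ({config.year_of(t)}-{config.calendar_month(t):02d}): {exc}"
            ) from exc
    return store
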