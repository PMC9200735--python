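"""Simulation configuration: stocks, fleets and management in one object.

A :class:`SimulationConfig` fully determines a run.  It serialises to plain
dicts (and hence YAML) and back without loss, so synthetic truth
configurations can be written to disk, reloaded and re-run bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exploitation import (
    CatchRatioTable,
    ExogenousRemovalSeries,
    Gear,
    InterAnnualFactorTable,
    Metier,
    Strategy,
    TargetFactorSet,
)
from .grid import Zone, check_disjoint, make_zone
from .management import LOConfig, MCRSRule
from .populations import (
    BevertonHoltParams,
    LifeHistory,
    MigrationRule,
    PopulationState,
    RecruitmentSeries,
    SeasonalAccessibilitySchedule,
)
from .structures import ClassStructure, build_transition_matrix

__all__ = ["StockConfig", "ManagementConfig", "SimulationConfig"]


@dataclass
class StockConfig:
    """Everything the engine needs about one stock."""

    name: str
    structure: ClassStructure
    life: LifeHistory
    zones: dict[str, Zone]  # zone name -> Zone (migration endpoints disjoint)
    zone_order: tuple[str, ...]
    initial: np.ndarray  # (n_zones, n_classes) abundance at the first month
    growth_increments: np.ndarray | None = None  # per class per event
    recruitment_series: RecruitmentSeries | None = None
    beverton_holt: BevertonHoltParams | None = None
    migrations: list[MigrationRule] = field(default_factory=list)
    accessibility: np.ndarray | None = None  # hake: (4,) per quarter; else per class
    seasonal_schedule: SeasonalAccessibilitySchedule | None = None
    rect_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    class_lengths: np.ndarray | None = None  # mean length per class (sole: at age)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (len(self.zone_order), self.structure.n_classes):
            raise ValueError(
                f"stock {self.name!r}: initial abundance shape {self.initial.shape} "
                f"!= (n_zones={len(self.zone_order)}, n_classes={self.structure.n_classes})"
            )
        check_disjoint([self.zones[z] for z in self.zone_order])
        if self.class_lengths is None:
            self.class_lengths = self.structure.midpoints
        if self.accessibility is not None:
            self.accessibility = np.asarray(self.accessibility, dtype=float)
        if not self.rect_weights:
            self.rect_weights = {
                z: {r: 1.0 for r in sorted(self.zones[z].rectangles)} for z in self.zone_order
            }

    @property
    def transition(self) -> np.ndarray | None:
        if self.growth_increments is None:
            return None
        return build_transition_matrix(self.growth_increments, self.structure)

    def initial_state(self) -> PopulationState:
        return PopulationState(self.zone_order, self.initial.copy(), month=0)

    def accessibility_per_class(self, quarter: int) -> np.ndarray:
        """Accessibility broadcast to classes (hake: one scalar per quarter)."""
        if self.accessibility is None:
            return np.ones(self.structure.n_classes)
        if self.name == "hake":
            return np.full(self.structure.n_classes, self.accessibility[quarter - 1])
        return self.accessibility


@dataclass
class ManagementConfig:
    """Quota amounts, MCRS, Landings Obligation and behaviour switches."""

    quota_amounts: dict[tuple[str, int], float] = field(default_factory=dict)
    mcrs: dict[str, MCRSRule] = field(default_factory=dict)
    lo: dict[str, LOConfig] = field(default_factory=dict)
    adjust_target_factors: bool = True
    discard_threshold: float | None = None  # disabled unless configured
    first_quota_year: int = 2013


@dataclass
class SimulationConfig:
    """A complete, runnable description of the fishery."""

    start_year: int
    n_years: int
    stocks: dict[str, StockConfig]
    gears: dict[str, Gear]
    metiers: list[Metier]
    strategies: list[Strategy]
    target_factors: TargetFactorSet
    management: ManagementConfig = field(default_factory=ManagementConfig)
    spanish_ratio_tables: dict[str, CatchRatioTable] = field(default_factory=dict)
    exogenous_removals: ExogenousRemovalSeries | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("horizon must cover at least one year")
        names = [m.name for m in self.metiers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate métier names")
        known = set(names)
        for s in self.strategies:
            missing = set(s.shares) - known
            if missing:
                raise ValueError(f"strategy {s.fleet!r} references unknown métiers {missing}")
        for m in self.metiers:
            for stock, zname in m.zones.items():
                if stock not in self.stocks:
                    raise ValueError(f"métier {m.name!r} references unknown stock {stock!r}")
                if zname not in self.stocks[stock].zones:
                    raise ValueError(
                        f"métier {m.name!r} fishes unknown zone {zname!r} of stock {stock!r}"
                    )

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    def year_of(self, t: int) -> int:
        return self.start_year + t // 12

    @staticmethod
    def calendar_month(t: int) -> int:
        return t % 12 + 1

    @staticmethod
    def quarter_of(t: int) -> int:
        return (t % 12) // 3 + 1

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        d = {
            "start_year": self.start_year,
            "n_years": self.n_years,
            "seed": self.seed,
            "stocks": {},
            "gears": {
                g.name: {"selectivity": {k: list(v) for k, v in g.selectivity.items()},
                          "discard": {k: list(v) for k, v in g.discard.items()}}
                for g in self.gears.values()
            },
            "metiers": [
                {
                    "name": m.name, "gear": m.gear.name, "group": m.group,
                    "zones": dict(m.zones), "base_target": dict(m.base_target),
                    "nationality": m.nationality, "standardisation": m.standardisation,
                }
                for m in self.metiers
            ],
            "strategies": [
                {"fleet": s.fleet, "effort": arr(s.effort),
                 "shares": {k: arr(v) for k, v in s.shares.items()}}
                for s in self.strategies
            ],
            "target_factors": {
                "base": {f"{k[0]}|{k[1]}": v for k, v in self.target_factors.base.items()},
                "estimated": {"|".join(map(str, k)): v for k, v in self.target_factors.estimated.items()},
                "seasonal_estimated": dict(self.target_factors.seasonal_estimated),
                "interannual": {
                    "base_year": self.target_factors.interannual.base_year,
                    "hake": {f"{m}|{s}|{y}": v for (m, s, y), v in self.target_factors.interannual.hake.items()},
                    "sole": {f"{m}|{y}": v for (m, y), v in self.target_factors.interannual.sole.items()},
                    "nephrops": {str(y): v for y, v in self.target_factors.interannual.nephrops.items()},
                },
            },
            "management": {
                "quota_amounts": {f"{s}|{y}": v for (s, y), v in self.management.quota_amounts.items()},
                "mcrs": {s: r.min_length for s, r in self.management.mcrs.items()},
                "lo": {
                    s: {"start_year": c.start_year,
                        "de_minimis": {f"{y}|{g}": v for (y, g), v in c.de_minimis.items()}}
                    for s, c in self.management.lo.items()
                },
                "adjust_target_factors": self.management.adjust_target_factors,
                "discard_threshold": self.management.discard_threshold,
                "first_quota_year": self.management.first_quota_year,
            },
            "spanish_ratio_tables": {g: arr(t.ratios) for g, t in self.spanish_ratio_tables.items()},
            "exogenous_removals": (
                None if self.exogenous_removals is None
                else {str(t): arr(v) for t, v in self.exogenous_removals.removals.items()}
            ),
        }
        for name, sc in self.stocks.items():
            st = sc.structure
            d["stocks"][name] = {
                "structure": {
                    "kind": st.kind, "labels": list(st.labels), "lower": arr(st.lower),
                    "upper": arr(st.upper), "plus_group": arr(st.plus_group), "sex": list(st.sex),
                },
                "life": {"M": sc.life.M, "maturity": arr(sc.life.maturity), "weight": arr(sc.life.weight)},
                "zones": {z: sorted(sc.zones[z].rectangles) for z in sc.zone_order},
                "zone_order": list(sc.zone_order),
                "initial": arr(sc.initial),
                "growth_increments": arr(sc.growth_increments),
                "recruitment_series": (
                    None if sc.recruitment_series is None
                    else {f"{y}|{m}": v for (y, m), v in sc.recruitment_series.values.items()}
                ),
                "beverton_holt": (
                    None if sc.beverton_holt is None
                    else {"alpha": sc.beverton_holt.alpha, "beta": sc.beverton_holt.beta}
                ),
                "migrations": [
                    {"months": list(r.months), "source": r.source,
                     "destinations": dict(r.destinations), "min_length": r.min_length,
                     "mature_only": r.mature_only, "fraction": r.fraction}
                    for r in sc.migrations
                ],
                "accessibility": arr(sc.accessibility),
                "seasonal_schedule": (
                    None if sc.seasonal_schedule is None
                    else {"female_burrow": sc.seasonal_schedule.female_burrow,
                          "female_emerged": sc.seasonal_schedule.female_emerged,
                          "male": sc.seasonal_schedule.male}
                ),
                "rect_weights": {z: dict(w) for z, w in sc.rect_weights.items()},
                "class_lengths": arr(sc.class_lengths),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        gears = {
            name: Gear(name,
                       {k: tuple(v) for k, v in g["selectivity"].items()},
                       {k: tuple(v) for k, v in g["discard"].items()})
            for name, g in d["gears"].items()
        }
        metiers = [
            Metier(m["name"], gears[m["gear"]], m["group"], dict(m["zones"]),
                   dict(m["base_target"]), m.get("nationality", "FR"),
                   m.get("standardisation", 1.0))
            for m in d["metiers"]
        ]
        strategies = [
            Strategy(s["fleet"], np.asarray(s["effort"]),
                     {k: np.asarray(v) for k, v in s["shares"].items()})
            for s in d["strategies"]
        ]
        tf = d["target_factors"]

        def split_key(key: str, types: tuple) -> tuple:
            parts = key.split("|")
            return tuple(t(p) for t, p in zip(types, parts))

        ia = tf["interannual"]
        target_factors = TargetFactorSet(
            base={split_key(k, (str, str)): v for k, v in tf["base"].items()},
            interannual=InterAnnualFactorTable(
                base_year=ia["base_year"],
                hake={split_key(k, (str, int, int)): v for k, v in ia["hake"].items()},
                sole={split_key(k, (str, int)): v for k, v in ia["sole"].items()},
                nephrops={int(k): v for k, v in ia["nephrops"].items()},
            ),
            estimated={
                (lambda p: (p[0], p[1], int(p[2])) if len(p) == 3 else (p[0], p[1]))(k.split("|")): v
                for k, v in tf["estimated"].items()
            },
            seasonal_estimated=dict(tf["seasonal_estimated"]),
        )
        mg = d["management"]
        management = ManagementConfig(
            quota_amounts={split_key(k, (str, int)): v for k, v in mg["quota_amounts"].items()},
            mcrs={s: MCRSRule(s, v) for s, v in mg["mcrs"].items()},
            lo={
                s: LOConfig(s, c["start_year"],
                            {split_key(k, (int, str)): v for k, v in c["de_minimis"].items()})
                for s, c in mg["lo"].items()
            },
            adjust_target_factors=mg["adjust_target_factors"],
            discard_threshold=mg["discard_threshold"],
            first_quota_year=mg["first_quota_year"],
        )
        stocks = {}
        for name, s in d["stocks"].items():
            st = s["structure"]
            structure = ClassStructure(
                st["kind"], tuple(st["labels"]), np.asarray(st["lower"]),
                np.asarray(st["upper"]), np.asarray(st["plus_group"], dtype=bool),
                tuple(st["sex"]),
            )
            stocks[name] = StockConfig(
                name=name,
                structure=structure,
                life=LifeHistory(s["life"]["M"], np.asarray(s["life"]["maturity"]),
                                 np.asarray(s["life"]["weight"])),
                zones={z: make_zone(z, codes) for z, codes in s["zones"].items()},
                zone_order=tuple(s["zone_order"]),
                initial=np.asarray(s["initial"]),
                growth_increments=(None if s["growth_increments"] is None
                                   else np.asarray(s["growth_increments"])),
                recruitment_series=(
                    None if s["recruitment_series"] is None
                    else RecruitmentSeries({split_key(k, (int, int)): v
                                            for k, v in s["recruitment_series"].items()})
                ),
                beverton_holt=(None if s["beverton_holt"] is None
                               else BevertonHoltParams(**s["beverton_holt"])),
                migrations=[
                    MigrationRule(tuple(r["months"]), r["source"], dict(r["destinations"]),
                                  r["min_length"], r["mature_only"], r["fraction"])
                    for r in s["migrations"]
                ],
                accessibility=(None if s["accessibility"] is None
                               else np.asarray(s["accessibility"])),
                seasonal_schedule=(None if s["seasonal_schedule"] is None
                                   else SeasonalAccessibilitySchedule(**s["seasonal_schedule"])),
                rect_weights={z: dict(w) for z, w in s["rect_weights"].items()},
                class_lengths=(None if s["class_lengths"] is None
                               else np.asarray(s["class_lengths"])),
            )
        return cls(
            start_year=d["start_year"], n_years=d["n_years"], stocks=stocks,
            gears=gears, metiers=metiers, strategies=strategies,
            target_factors=target_factors, management=management,
            spanish_ratio_tables={g: CatchRatioTable(np.asarray(t))
                                  for g, t in d["spanish_ratio_tables"].items()},
            exogenous_removals=(
                None if d["exogenous_removals"] is None
                else ExogenousRemovalSeries({int(t): np.asarray(v)
                                             for t, v in d["exogenous_removals"].items()})
            ),
            seed=d.get("seed"),
        )
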