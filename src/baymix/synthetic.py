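"""Synthetic fishery configurations with known truth, and observation bundles.

The generator emulates the structure of the Bay of Biscay mixed demersal
fishery at a reduced scale so every stage — simulation, calibration, skill
assessment — is testable without any external data: four hake zones
(presence, recruitment, interim recruitment, spawning) carrying the spawning
migrations, a single sole presence zone, a single Norway lobster mudbank
zone overlapping the hake nursery (the source of the undersized-hake bycatch
interaction), métier groups drawn from the five real ones, a TAL-then-TAC
management calendar starting after the 2010-2012 calibration window, and
inter-annual effort ratios extended to the last four years by the trend
rule.

Truth accessibilities are drawn from a wide uniform range; the estimated
target-factor components are set at their neutral value 1 — in a
self-consistent synthetic world the estimated component, whose role is to
absorb residual model-data mismatch, has nothing to absorb.  Calibration
recovery starts both families away from these truths.

Observation noise is multiplicative mean-one lognormal applied after
aggregation (observation error, not process error; the dynamics stay
deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import ObservationBundle
from .config import ManagementConfig, SimulationConfig, StockConfig
from .engine import OutputStore, run
from .exploitation import (
    CatchRatioTable,
    ExogenousRemovalSeries,
    Gear,
    InterAnnualFactorTable,
    Metier,
    Strategy,
    TargetFactorSet,
    extrapolate_ratios,
)
from .grid import make_zone
from .management import LOConfig, MCRSRule
from .populations import (
    BevertonHoltParams,
    LifeHistory,
    MigrationRule,
    RecruitmentSeries,
    SeasonalAccessibilitySchedule,
)
from .structures import (
    ClassStructure,
    SEX_FEMALE,
    SEX_MALE,
    SEX_RECRUIT,
    build_class_structures,
)

__all__ = ["ScalePreset", "NoiseModel", "PRESETS", "generate_config", "generate_observations"]


@dataclass(frozen=True)
class ScalePreset:
    """A named problem size for the generator."""

    name: str
    n_years: int
    full_structures: bool  # use the real class structures or reduced ones
    metier_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("a preset must at least cover the calibration window")


PRESETS = {
    "tiny": ScalePreset(
        "tiny", 3, False,
        ("gillnetters", "whitefish_trawlers_coastal", "nephrops_trawlers"),
    ),
    "small": ScalePreset(
        "small", 6, False,
        ("longliners", "gillnetters", "whitefish_trawlers_coastal", "nephrops_trawlers"),
    ),
    "paperlike": ScalePreset(
        "paperlike", 11, True,
        ("longliners", "gillnetters", "whitefish_trawlers_coastal",
         "whitefish_trawlers_offshore", "nephrops_trawlers"),
    ),
}


@dataclass(frozen=True)
class NoiseModel:
    """Mean-one multiplicative lognormal observation noise.

    A cell x becomes x * exp(eps) with eps ~ N(-sigma^2/2, sigma^2) and
    sigma^2 = ln(1 + CV^2), so E[noisy cell] = x for every CV >= 0.
    """

    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("CV must be >= 0")

    def multipliers(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


# -- reduced class structures for the tiny/small presets ---------------------

def _tiny_hake_structure() -> ClassStructure:
    edges = [10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0]
    lower = np.array(edges)
    upper = np.array(edges[1:] + [60.0])
    labels = tuple(f"[{lo:g},{hi:g})" for lo, hi in zip(lower[:-1], upper[:-1])) + ("[50+]",)
    plus = np.zeros(7, bool)
    plus[-1] = True
    return ClassStructure("length-bin", labels, lower, upper, plus)


def _tiny_sole_structure() -> ClassStructure:
    ages = np.array([2.0, 3.0, 4.0])
    plus = np.array([False, False, True])
    return ClassStructure("age", ("age2", "age3", "age4+"), ages, ages + 1.0, plus)


def _tiny_nephrops_structure() -> ClassStructure:
    lower = np.array([0.0, 20.0, 30.0, 40.0, 20.0, 30.0])
    upper = np.array([2.0, 30.0, 40.0, 50.0, 30.0, 40.0])
    labels = ("recruit", "M_[20,30)", "M_[30,40)", "M_[40+]", "F_[20,30)", "F_[30+]")
    sex = (SEX_RECRUIT, SEX_MALE, SEX_MALE, SEX_MALE, SEX_FEMALE, SEX_FEMALE)
    plus = np.array([False, False, False, True, False, True])
    return ClassStructure("sex-length-bin", labels, lower, upper, plus, sex)


def _logistic(x: np.ndarray, x50: float, k: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-k * (x - x50)))


def _interannual_tables(
    rng: np.random.Generator, metiers: list[str], n_years: int, start_year: int
) -> InterAnnualFactorTable:
    """Random-walk catch ratios near 1 for observed years; the last four
    years of a paper-length horizon come from the 2014-2016 trend rule."""
    years = list(range(start_year + 1, start_year + min(n_years, 7)))
    table = InterAnnualFactorTable(base_year=start_year)
    for m in metiers:
        for q in (1, 2, 3, 4):
            r = 1.0
            for y in years:
                r = max(0.2, r * (1.0 + rng.normal(0.0, 0.08)))
                table.hake[(m, q, y)] = r
        r = 1.0
        for y in years:
            r = max(0.2, r * (1.0 + rng.normal(0.0, 0.08)))
            table.sole[(m, y)] = r
    r = 1.0
    for y in years:
        r = max(0.2, r * (1.0 + rng.normal(0.0, 0.08)))
        table.nephrops[y] = r
    if n_years >= 11:  # 2017-2020 by trend extrapolation
        for m in metiers:
            for q in (1, 2, 3, 4):
                base = [table.hake[(m, q, y)] for y in (2014, 2015, 2016)]
                ext = extrapolate_ratios(np.array(base), halve_slope=False, force_significant=(q in (2, 4)))
                for y, v in ext.items():
                    table.hake[(m, q, y)] = v
            base = [table.sole[(m, y)] for y in (2014, 2015, 2016)]
            ext = extrapolate_ratios(np.array(base), halve_slope=True, force_significant=True)
            for y, v in ext.items():
                table.sole[(m, y)] = v
        base = [table.nephrops[y] for y in (2014, 2015, 2016)]
        ext = extrapolate_ratios(np.array(base), halve_slope=True, force_significant=True)
        for y, v in ext.items():
            table.nephrops[y] = v
    return table


def generate_config(seed: int, preset: ScalePreset | str = "tiny") -> SimulationConfig:
    """A fully valid truth configuration, deterministic in ``seed``.

    Truth parameters live inside the returned config: per-stock
    accessibilities (drawn uniform in [0.4, 1.4]) and target-factor
    estimated components (the neutral value 1).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    rng = np.random.default_rng(seed)
    start_year = 2010

    # -- spatial grid: 3x3 block of real ICES rectangles -------------------
    rects = [f"{row}E{col}" for row in (15, 16, 17) for col in (5, 6, 7)]
    hake_zones = {
        "recruitment": make_zone("recruitment", [rects[0]]),
        "interim": make_zone("interim", [rects[1], rects[2]]),
        "spawning": make_zone("spawning", [rects[3]]),
        "presence": make_zone("presence", [rects[4], rects[5]]),
    }
    sole_zone = {"sole_area": make_zone("sole_area", rects[3:7])}
    neph_zone = {"mudbank": make_zone("mudbank", [rects[0], rects[1]])}

    # -- structures --------------------------------------------------------
    if preset.full_structures:
        structs = build_class_structures()
    else:
        structs = {
            "hake": _tiny_hake_structure(),
            "sole": _tiny_sole_structure(),
            "nephrops": _tiny_nephrops_structure(),
        }
    hk, so, ne = structs["hake"], structs["sole"], structs["nephrops"]

    # -- hake --------------------------------------------------------------
    hk_len = hk.midpoints
    hk_mat = _logistic(hk_len, 32.0, 0.35)
    hk_w = 7e-6 * hk_len**3  # kg, cube law
    hk_life = LifeHistory(M=0.5, maturity=hk_mat, weight=hk_w)
    n0 = 4e6 * np.exp(-0.09 * np.arange(hk.n_classes)) * (1.0 + 0.2 * rng.random(hk.n_classes))
    small = hk.lower < 20.0
    init = np.zeros((4, hk.n_classes))
    zone_order_h = ("recruitment", "interim", "spawning", "presence")
    init[0, small] = n0[small]
    init[2, ~small] = n0[~small] * hk_mat[~small]
    init[1, ~small] = n0[~small] * (1.0 - hk_mat[~small])
    hk_growth = np.where(hk.plus_group, 0.0, np.where(hk.lower < 40, 1.0, 0.5))
    rec_vals = {}
    for y in range(start_year, start_year + preset.n_years):
        level = 2e6 * (1.0 + 0.3 * rng.standard_normal())
        for m in range(1, 10):
            rec_vals[(y, m)] = max(2e5, level * (1.0 + 0.2 * rng.standard_normal()) / 9.0)
    hake_migrations = [
        # mature fish aggregate on the shelf break (spawning zone) in January
        MigrationRule((1,), "interim", {"spawning": 1.0}, mature_only=True, fraction=0.9),
        MigrationRule((1,), "presence", {"spawning": 1.0}, mature_only=True, fraction=0.9),
        # partial dispersal back over the shelf at the beginning of April and
        # July; the shelf-break zone keeps some occupancy year-round
        MigrationRule((4,), "spawning", {"interim": 0.5, "presence": 0.5}, fraction=0.6),
        MigrationRule((7,), "spawning", {"interim": 0.5, "presence": 0.5}, fraction=0.6),
        # monthly spill-over of fish >= 20 cm out of the nursery
        MigrationRule(tuple(range(1, 13)), "recruitment", {"interim": 1.0}, min_length=20.0),
    ]
    hake_cfg = StockConfig(
        name="hake", structure=hk, life=hk_life, zones=hake_zones,
        zone_order=zone_order_h, initial=init, growth_increments=hk_growth,
        recruitment_series=RecruitmentSeries(rec_vals), migrations=hake_migrations,
        accessibility=rng.uniform(0.4, 1.4, size=4),
    )

    # -- sole ---------------------------------------------------------------
    so_len = np.linspace(25.0, 25.0 + 4.0 * (so.n_classes - 1), so.n_classes)
    so_mat = np.clip(0.5 + 0.25 * np.arange(so.n_classes), 0.0, 1.0)
    so_w = np.linspace(0.15, 0.15 + 0.1 * (so.n_classes - 1), so.n_classes)
    so_life = LifeHistory(M=0.1, maturity=so_mat, weight=so_w)
    so_init = (2.5e6 * np.exp(-0.45 * np.arange(so.n_classes)))[None, :] * (
        1.0 + 0.2 * rng.random(so.n_classes)
    )
    so_rec = {(y, 1): max(2e5, 1.8e6 * (1.0 + 0.25 * rng.standard_normal()))
              for y in range(start_year, start_year + preset.n_years)}
    sole_cfg = StockConfig(
        name="sole", structure=so, life=so_life, zones=sole_zone,
        zone_order=("sole_area",), initial=so_init,
        recruitment_series=RecruitmentSeries(so_rec),
        accessibility=rng.uniform(0.4, 1.4, size=so.n_classes),
        class_lengths=so_len,
    )

    # -- Norway lobster ------------------------------------------------------
    ne_mat = np.where(np.asarray(ne.sex) == SEX_FEMALE,
                      _logistic(ne.midpoints, 26.0, 0.4), 0.0)
    ne_w = np.maximum(0.002, 2.8e-5 * ne.midpoints**2)  # kg
    ne_life = LifeHistory(M=0.3, maturity=ne_mat, weight=ne_w)
    ne_init = np.zeros((1, ne.n_classes))
    for i, sx in enumerate(ne.sex):
        base = {SEX_RECRUIT: 0.0, SEX_MALE: 1.6e7, SEX_FEMALE: 1.2e7}[sx]
        ne_init[0, i] = base * np.exp(-0.35 * i) * (1.0 + 0.2 * rng.random())
    ne_growth = np.where(ne.plus_group | (np.asarray(ne.sex) == SEX_RECRUIT),
                         0.0, 3.0 if not preset.full_structures else 2.0)
    ne_acc = rng.uniform(0.4, 1.4, size=ne.n_classes)
    ne_acc[np.asarray(ne.sex) == SEX_RECRUIT] = 0.0  # recruits not catchable
    neph_cfg = StockConfig(
        name="nephrops", structure=ne, life=ne_life, zones=neph_zone,
        zone_order=("mudbank",), initial=ne_init, growth_increments=ne_growth,
        beverton_holt=BevertonHoltParams(alpha=3e7, beta=100.0),
        accessibility=ne_acc,
        seasonal_schedule=SeasonalAccessibilitySchedule(),
    )
    stocks = {"hake": hake_cfg, "sole": sole_cfg, "nephrops": neph_cfg}

    # -- gears and métiers ---------------------------------------------------
    gears = {
        "gillnet": Gear("gillnet",
                        selectivity={"hake": (28.0, 0.30), "sole": (27.0, 0.35)},
                        discard={"hake": (25.0, -0.45), "sole": (24.0, -0.6)}),
        "longline": Gear("longline",
                         selectivity={"hake": (33.0, 0.25)},
                         discard={"hake": (26.0, -0.5)}),
        "whitefish_trawl": Gear("whitefish_trawl",
                                selectivity={"hake": (22.0, 0.25), "sole": (25.0, 0.3),
                                             "nephrops": (18.0, 0.12)},
                                discard={"hake": (26.0, -0.35), "sole": (24.0, -0.5),
                                         "nephrops": (25.0, -0.4)}),
        "nephrops_trawl": Gear("nephrops_trawl",
                               selectivity={"nephrops": (28.0, 0.45), "hake": (16.0, 0.35)},
                               discard={"nephrops": (25.0, -0.5), "hake": (28.0, -0.30)}),
    }
    group_gear = {
        "longliners": "longline",
        "gillnetters": "gillnet",
        "whitefish_trawlers_coastal": "whitefish_trawl",
        "whitefish_trawlers_offshore": "whitefish_trawl",
        "nephrops_trawlers": "nephrops_trawl",
    }
    group_zones = {
        "longliners": {"hake": "spawning"},
        "gillnetters": {"hake": "spawning", "sole": "sole_area"},
        "whitefish_trawlers_coastal": {"hake": "interim", "sole": "sole_area",
                                       "nephrops": "mudbank"},
        "whitefish_trawlers_offshore": {"hake": "presence", "sole": "sole_area"},
        # the key technical interaction: Norway lobster trawlers work the
        # mudbank, a hake nursery
        "nephrops_trawlers": {"nephrops": "mudbank", "hake": "recruitment"},
    }
    metiers = []
    base_tf = {}
    for g in preset.metier_groups:
        name = f"{g}_1"
        zones = group_zones[g]
        bt = {s: float(rng.uniform(0.8e-4, 2.0e-4)) for s in zones}
        if g == "nephrops_trawlers" and "hake" in bt:
            bt["hake"] *= 0.4  # undersized-hake bycatch, not targeting
        metiers.append(Metier(name, gears[group_gear[g]], g, zones, bt))
        for s, v in bt.items():
            base_tf[(s, name)] = v

    n_met = len(metiers)
    strategies = []
    # one strategy per pair of métiers (last strategy may hold a single one)
    for i in range(0, n_met, 2):
        group = metiers[i : i + 2]
        shares = {}
        if len(group) == 2:
            a = 0.4 + 0.2 * rng.random()
            shares[group[0].name] = np.full(12, a)
            shares[group[1].name] = np.full(12, 1.0 - a)
        else:
            shares[group[0].name] = np.ones(12)
        effort = np.full(12, float(rng.uniform(400.0, 700.0)))
        strategies.append(Strategy(f"fleet_{i // 2}", effort, shares))

    target_factors = TargetFactorSet(
        base=base_tf,
        interannual=_interannual_tables(rng, [m.name for m in metiers],
                                        preset.n_years, start_year),
        estimated={},  # neutral truth: estimated components are 1
    )

    # -- management -----------------------------------------------------------
    mcrs = {"hake": MCRSRule("hake", 27.0), "sole": MCRSRule("sole", 24.0),
            "nephrops": MCRSRule("nephrops", 25.0)}
    lo = {
        s: LOConfig(s, 2016, {(y, g.name): 0.06 for y in range(2016, start_year + preset.n_years)
                              for g in gears.values()})
        for s in ("hake", "sole")
    }
    management = ManagementConfig(quota_amounts={}, mcrs=mcrs, lo=lo)

    # -- Spanish fleets and out-of-area removals (hake) ----------------------
    spanish = {}
    for g in ("gillnetters", "longliners"):
        if g in preset.metier_groups:
            spanish[g] = CatchRatioTable(
                np.clip(0.3 + 0.1 * rng.standard_normal((12, hk.n_classes)), 0.0, None)
            )
    exo = ExogenousRemovalSeries({
        t: 5e3 * np.ones(hk.n_classes) for t in range(12 * preset.n_years)
    })

    config = SimulationConfig(
        start_year=start_year, n_years=preset.n_years, stocks=stocks, gears=gears,
        metiers=metiers, strategies=strategies, target_factors=target_factors,
        management=management, spanish_ratio_tables=spanish,
        exogenous_removals=exo, seed=seed,
    )

    # quota amounts: 80% of each stock's quota-free annual landings in the
    # last calibration year, so TALs genuinely bind from 2013 onward
    if preset.n_years > 3:
        probe = run(replace(config, n_years=3))
        for s in stocks:
            base_land = probe.annual_landings_tons(s, start_year + 2)
            for y in range(start_year + 3, start_year + preset.n_years):
                config.management.quota_amounts[(s, y)] = max(1.0, 0.8 * base_land)
    return config


def _noisy_dict(d: dict, noise: NoiseModel, rng: np.random.Generator) -> dict:
    keys = sorted(d, key=repr)
    mult = noise.multipliers(rng, len(keys))
    return {k: d[k] * m for k, m in zip(keys, mult)}


def generate_observations(
    store: OutputStore,
    config: SimulationConfig,
    noise: NoiseModel | None = None,
    years: tuple[int, ...] = (2010, 2011, 2012),
) -> ObservationBundle:
    """Build the observation bundle every objective needs from a truth run.

    With CV = 0 the bundle equals the truth aggregations exactly; otherwise
    each aggregated cell is scaled by an independent mean-one lognormal
    draw.  Sole F-at-age plays the role of assessment estimates: it is
    recomputed from the truth survival ratios as
    -ln(N_end / N_start) - M per age and year, not copied from the
    simulator's own F bookkeeping.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    needed = [s for s in ("hake", "sole", "nephrops") if s not in store.stocks]
    if needed:
        raise KeyError(f"truth run is missing stream(s) for stock(s): {needed}")

    hake_weight = store.hake_weight_by_lqgf(list(years))
    groups = sorted({rm.group for rm in store.rows["hake"] if rm.nationality == "FR"})
    weights = {(q, g, f): 1.0 for q in (1, 2, 3, 4) for g in groups
               for f in ("landings", "discards")}

    # sole F-at-age from survival ratios (the assessment-estimate role)
    M = config.stocks["sole"].life.M
    sole_F = []
    for y in years:
        ts = store._months_of(y)
        n0 = store.n_start["sole"][ts][:, 0, :]
        sv = store.survivors["sole"][ts][:, 0, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(n0 > 0, -np.log(np.where(n0 > 0, sv / np.where(n0 > 0, n0, 1.0), 1.0)), 0.0)
        sole_F.append(z.sum(axis=0) - np.where(n0.sum(axis=0) > 0, M, 0.0))
    sole_F = np.stack(sole_F)

    sole_catch = store.catch_tons_by_metier_quarter("sole", list(years))
    neph_numbers = store.nephrops_numbers_by_slq(years[0])
    neph_landings = store.nephrops_monthly_landings(years[0])
    landings_by_rect = {
        s: store.landings_by_rectangle(s, years[0], config) for s in store.stocks
    }

    if noise.cv > 0:
        hake_weight = _noisy_dict(hake_weight, noise, rng)
        sole_F = sole_F * noise.multipliers(rng, sole_F.size).reshape(sole_F.shape)
        sole_catch = _noisy_dict(sole_catch, noise, rng)
        neph_numbers = neph_numbers * noise.multipliers(rng, neph_numbers.size).reshape(neph_numbers.shape)
        neph_landings = neph_landings * noise.multipliers(rng, neph_landings.size).reshape(neph_landings.shape)
        landings_by_rect = {s: _noisy_dict(d, noise, rng) for s, d in landings_by_rect.items()}

    return ObservationBundle(
        hake_weight=hake_weight, sole_F=sole_F, sole_F_years=tuple(years),
        sole_catch=sole_catch, neph_numbers=neph_numbers, neph_landings=neph_landings,
        weights_weight=weights, weights_lfd=dict(weights),
        landings_by_rect=landings_by_rect,
    )
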