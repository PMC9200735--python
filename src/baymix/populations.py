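"""Structured population state and monthly demographic transitions.

State is abundance-at-class per zone (individuals).  All transitions are
deterministic and, absent mortality and recruitment, conserve total abundance.

Stock-specific behaviour:

* hake — monthly growth through a transition matrix; spawning migrations
  (mature fish aggregate on the shelf break in January, disperse in April and
  July) and a monthly spill-over of fish >= 20 cm from the recruitment zone
  into the interim-recruitment zone; monthly recruitment January-September
  from a prescribed series;
* sole — single zone, annual ageing each January followed by recruitment at
  age 2 from a prescribed annual series; ages 0-1 are not modelled;
* Norway lobster — single presence area (the Great Mudbank); annual
  recruitment each January from a Beverton-Holt relationship on spawning
  stock biomass, spread over rectangles proportionally to the SSB
  distribution; moulting (growth) in April for everyone and in October for
  males and immature females only; female accessibility to trawls follows an
  8-period burrow/emergence calendar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import ClassStructure, SEX_FEMALE, SEX_MALE, SEX_RECRUIT, apply_growth

__all__ = [
    "PopulationState",
    "LifeHistory",
    "MigrationRule",
    "RecruitmentSeries",
    "BevertonHoltParams",
    "SeasonalAccessibilitySchedule",
    "apply_natural_mortality",
    "hake_migrations",
    "hake_initial_allocation",
    "recruit_hake",
    "recruit_sole",
    "recruit_nephrops",
    "age_sole",
    "nephrops_moult",
    "spawning_stock_biomass",
]


@dataclass
class PopulationState:
    """Abundance-at-class per zone for one stock at one month."""

    zones: tuple[str, ...]
    abundance: np.ndarray  # (n_zones, n_classes), individuals
    month: int = 0  # simulation month index, 0 = January of the first year

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 2 or self.abundance.shape[0] != len(self.zones):
            raise ValueError("abundance must be (n_zones, n_classes)")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.abundance)):
            raise ValueError("abundance contains non-finite values")
        if np.any(self.abundance < -1e-9):
            raise ValueError("abundance contains negative values")
        np.clip(self.abundance, 0.0, None, out=self.abundance)

    def zone_index(self, name: str) -> int:
        try:
            return self.zones.index(name)
        except ValueError:
            raise KeyError(f"unknown zone {name!r}; have {self.zones}") from None

    def total(self) -> float:
        return float(self.abundance.sum())

    def copy(self) -> "PopulationState":
        # bypass __post_init__: the source state is already validated
        out = object.__new__(PopulationState)
        out.zones = self.zones
        out.abundance = self.abundance.copy()
        out.month = self.month
        return out


@dataclass(frozen=True)
class LifeHistory:
    """Per-class life-history parameters.

    M is the annual natural mortality rate; maturity the fraction mature per
    class in [0, 1]; weight the mean individual weight in kg per class.
    """

    M: float
    maturity: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "maturity", np.asarray(self.maturity, dtype=float))
        object.__setattr__(self, "weight", np.asarray(self.weight, dtype=float))
        if self.M < 0:
            raise ValueError("natural mortality must be >= 0")
        if np.any((self.maturity < 0) | (self.maturity > 1)):
            raise ValueError("maturity fractions must lie in [0, 1]")
        if np.any(self.weight <= 0):
            raise ValueError("mean weights must be positive")


@dataclass(frozen=True)
class MigrationRule:
    """A triggered transfer of (part of) some classes between zones.

    ``destinations`` maps zone name -> proportion (summing to 1).  Eligibility
    combines an optional minimum length (class lower edge, cm) with an
    optional maturity requirement; when maturity is required, only the mature
    fraction of each eligible class moves.
    """

    months: tuple[int, ...]  # calendar months 1-12 that trigger the rule
    source: str
    destinations: dict[str, float]
    min_length: float | None = None
    mature_only: bool = False
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("transferred fraction must be in [0, 1]")
        if self.source in self.destinations:
            raise ValueError("migration source must differ from destinations")
        tot = sum(self.destinations.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("destination proportions must sum to 1")


@dataclass(frozen=True)
class RecruitmentSeries:
    """Prescribed recruit numbers per (year, calendar month).

    Hake recruits arrive monthly January-September; sole annually in January
    (the series carries month 1 entries only).
    """

    values: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (y, m), v in self.values.items():
            if v < 0:
                raise ValueError(f"negative recruitment at {(y, m)}")

    def at(self, year: int, month: int) -> float:
        return float(self.values.get((year, month), 0.0))


@dataclass(frozen=True)
class BevertonHoltParams:
    """Beverton-Holt stock-recruitment: R = alpha * SSB / (beta + SSB).

    alpha is the asymptotic recruit number; beta the spawning-stock biomass
    (tons) at which recruitment reaches half of alpha.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beverton-Holt alpha and beta must be positive")

    def recruits(self, ssb: float) -> float:
        if ssb <= 0:
            return 0.0
        return self.alpha * ssb / (self.beta + ssb)


# The Norway lobster year splits into 8 periods driving female accessibility:
# 1 Jan (burrow), 2 Feb-Mar (burrow), 3 Apr (spring moult, emerged),
# 4-5 May-Aug (emerged), 6 Sep (burrow), 7 Oct (autumn moult, burrow),
# 8 Nov-Dec (burrow).
_MONTH_TO_PERIOD = {1: 1, 2: 2, 3: 2, 4: 3, 5: 4, 6: 4, 7: 5, 8: 5, 9: 6, 10: 7, 11: 8, 12: 8}
_EMERGED_PERIODS = frozenset({3, 4, 5})


@dataclass(frozen=True)
class SeasonalAccessibilitySchedule:
    """Multiplier on catchability per period and sex.

    Males are accessible year-round (multiplier 1).  Females are less
    accessible while in their burrows and more accessible April-August;
    only ordinal information is available, so the default levels
    (0.5 in burrow periods, 1.5 when emerged) are calibratable choices.
    """

    female_burrow: float = 0.5
    female_emerged: float = 1.5
    male: float = 1.0

    def __post_init__(self) -> None:
        if min(self.female_burrow, self.female_emerged, self.male) < 0:
            raise ValueError("accessibility multipliers must be >= 0")
        if self.female_emerged <= self.female_burrow:
            raise ValueError("emerged females must be more accessible than in burrows")

    def multiplier(self, month: int, sex: str) -> float:
        period = _MONTH_TO_PERIOD[month]
        if sex == SEX_FEMALE:
            return self.female_emerged if period in _EMERGED_PERIODS else self.female_burrow
        return self.male


def apply_natural_mortality(state: PopulationState, M: float, dt_months: float) -> PopulationState:
    """Exponential survival: every entry multiplied by exp(-M * dt / 12)."""
    if M < 0 or dt_months <= 0:
        raise ValueError("need M >= 0 and dt > 0")
    out = state.copy()
    out.abundance *= np.exp(-M * dt_months / 12.0)
    return out


def _eligible_fraction(
    structure: ClassStructure, life: LifeHistory | None, rule: MigrationRule
) -> np.ndarray:
    frac = np.full(structure.n_classes, rule.fraction)
    if rule.min_length is not None:
        frac[structure.lower < rule.min_length] = 0.0
    if rule.mature_only:
        if life is None:
            raise ValueError("maturity-conditioned rule needs a LifeHistory")
        frac = frac * life.maturity
    return frac


def hake_migrations(
    state: PopulationState,
    month: int,
    rules: list[MigrationRule],
    structure: ClassStructure,
    life: LifeHistory | None = None,
) -> PopulationState:
    """Apply the hake migration rules triggered in a calendar month.

    Total abundance per class over zones is conserved exactly; moved amounts
    are the per-class eligible fraction of the source zone's occupants.
    """
    out = state.copy()
    for rule in rules:
        if month not in rule.months:
            continue
        si = out.zone_index(rule.source)
        for dest in rule.destinations:
            out.zone_index(dest)  # raises on unknown zone before mutating
        moved = out.abundance[si] * _eligible_fraction(structure, life, rule)
        out.abundance[si] -= moved
        for dest, prop in rule.destinations.items():
            out.abundance[out.zone_index(dest)] += moved * prop
    return out


def hake_initial_allocation(
    n_by_class: np.ndarray,
    life: LifeHistory,
    structure: ClassStructure,
    zones: tuple[str, ...],
    recruitment_zone: str = "recruitment",
    interim_zone: str = "interim",
    spawning_zone: str = "spawning",
) -> PopulationState:
    """Initial spatial allocation of hake abundance-at-length.

    Classes strictly below 20 cm go wholly to the recruitment area (assumed
    under age 1); for classes >= 20 cm the mature fraction goes to the
    spawning area and the remainder to the interim-recruitment area.  The
    presence area starts empty.
    """
    n = np.asarray(n_by_class, dtype=float)
    if np.any(n < 0):
        raise ValueError("initial abundance must be non-negative")
    ab = np.zeros((len(zones), structure.n_classes))
    small = structure.lower < 20.0
    ri = zones.index(recruitment_zone)
    ii = zones.index(interim_zone)
    si = zones.index(spawning_zone)
    ab[ri, small] = n[small]
    big = ~small
    ab[si, big] = n[big] * life.maturity[big]
    ab[ii, big] = n[big] * (1.0 - life.maturity[big])
    return PopulationState(zones, ab)


def recruit_hake(
    state: PopulationState,
    year: int,
    month: int,
    series: RecruitmentSeries,
    recruitment_zone: str = "recruitment",
) -> PopulationState:
    """Monthly hake recruitment into the first length class, Jan-Sep only."""
    if month > 9:
        return state
    r = series.at(year, month)
    if r == 0.0:
        return state
    out = state.copy()
    out.abundance[out.zone_index(recruitment_zone), 0] += r
    return out


def age_sole(state: PopulationState) -> PopulationState:
    """January ageing: shift every age class up one, plus-group accumulating."""
    out = state.copy()
    ab = out.abundance
    ab[:, -1] += ab[:, -2]
    ab[:, 1:-1] = ab[:, :-2]
    ab[:, 0] = 0.0
    return out


def recruit_sole(state: PopulationState, year: int, series: RecruitmentSeries) -> PopulationState:
    """January recruitment at age 2 (first class) from the annual series."""
    out = state.copy()
    out.abundance[:, 0] += series.at(year, 1)
    return out


def recruit_nephrops(
    state: PopulationState,
    bh: BevertonHoltParams,
    ssb_total: float,
    recruit_class: int = 0,
) -> PopulationState:
    """January Beverton-Holt recruitment into the mixed recruitment class.

    With a single presence area the SSB spatial distribution collapses to the
    zone's rectangle weights; recruits inherit that distribution implicitly by
    entering the zone-level state (per-rectangle splits happen at output).
    """
    r = bh.recruits(ssb_total)
    out = state.copy()
    out.abundance[:, recruit_class] += r  # single-zone stock
    return out


def nephrops_moult(
    state: PopulationState,
    month: int,
    T: np.ndarray,
    structure: ClassStructure,
    life: LifeHistory,
    recruit_split: tuple[float, float] = (0.5, 0.5),
) -> PopulationState:
    """Apply a moult event: April for all, October for males and immature
    females only; other months are the identity.

    The mixed recruitment class enters the sexed tracks at the spring moult,
    split male/female by ``recruit_split`` into the first bin of each track.
    """
    if month not in (4, 10):
        return state
    out = state.copy()
    ab = out.abundance
    male = np.asarray(structure.sex) == SEX_MALE
    female = np.asarray(structure.sex) == SEX_FEMALE
    if month == 4:
        grown = apply_growth(ab, T)
        # recruitment class enters the sexed structure at spring moult
        rec = np.asarray(structure.sex) == SEX_RECRUIT
        if rec.any():
            ri = int(np.flatnonzero(rec)[0])
            first_m = int(np.flatnonzero(male)[0])
            first_f = int(np.flatnonzero(female)[0])
            moving = grown[:, ri].copy()
            grown[:, ri] = 0.0
            grown[:, first_m] += moving * recruit_split[0]
            grown[:, first_f] += moving * recruit_split[1]
        out.abundance = grown
    else:  # October: males moult; only the immature fraction of females does
        immature = np.where(female, 1.0 - life.maturity, 1.0)
        immature = np.where(male | female, immature, 0.0)  # recruits wait for spring
        moulting = ab * immature
        staying = ab - moulting
        out.abundance = staying + apply_growth(moulting, T)
    return out


def spawning_stock_biomass(
    state: PopulationState,
    life: LifeHistory,
    rect_weights: dict[str, dict[str, float]] | None = None,
) -> tuple[float, dict[str, float]]:
    """SSB in tons: sum over classes of N * maturity * weight (kg -> t).

    Returns (total, per-rectangle dict).  ``rect_weights`` maps zone name ->
    {rectangle -> weight}; weights are normalised per zone.  Without weights
    the per-rectangle dict is empty.
    """
    per_zone = state.abundance @ (life.maturity * life.weight) / 1000.0
    total = float(per_zone.sum())
    per_rect: dict[str, float] = {}
    if rect_weights:
        for zi, zname in enumerate(state.zones):
            w = rect_weights.get(zname)
            if not w:
                continue
            s = sum(w.values())
            for rect, wt in w.items():
                per_rect[rect] = per_rect.get(rect, 0.0) + per_zone[zi] * wt / s
    return total, per_rect
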