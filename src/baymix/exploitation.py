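"""Fleets, métiers, effort, catchability and catch computation.

Fishing mortality for one métier on one population follows the multiplicative
catchability decomposition

    F(class) = effort * target_factor * accessibility(class) * selectivity(class)

applied only inside the métier's fishing zone; effort is in abstract fishing
days (only products with catchability matter, so no vessel standardisation is
modelled).  The target factor itself is a product of three components: a
fixed base per métier, an inter-annual factor (a ratio of observed catch in a
year over the 2010 base year, at stock-specific granularity) and an estimated
component set by calibration.

Catch within a month is partitioned between métiers and natural mortality by
the Baranov competing-risks equation, which closes exactly: initial abundance
equals survivors plus all métier catches plus natural deaths.

The Spanish longliner and gillnetter fleets are represented through catch
rather than effort: their removals are the French catch of the matching
métier group times an observed Spanish/French catch-ratio table per month and
length bin, subtracted from the state after the effort-based catch step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Gear",
    "Metier",
    "Strategy",
    "TargetFactorSet",
    "InterAnnualFactorTable",
    "CatchRatioTable",
    "ExogenousRemovalSeries",
    "fishing_mortality",
    "baranov_catch",
    "split_landings_discards",
    "interannual_factor",
    "extrapolate_ratios",
    "catch_based_fleet_removals",
    "apply_exogenous_removals",
]

METIER_GROUPS = (
    "longliners",
    "gillnetters",
    "whitefish_trawlers_coastal",
    "whitefish_trawlers_offshore",
    "nephrops_trawlers",
)

LANDINGS = "landings"
DISCARDS = "discards"


@dataclass(frozen=True)
class Gear:
    """A gear with per-stock selectivity and discard ogives.

    Ogives are logistic in length (or age): value(l) = 1/(1+exp(-k(l-l50))).
    Selectivity uses k > 0 (retention grows with size); discard ogives use
    k < 0 (small fish discarded).  ``selectivity``/``discard`` map stock name
    -> (l50, k); stocks absent from ``selectivity`` are not caught.
    """

    name: str
    selectivity: dict[str, tuple[float, float]]
    discard: dict[str, tuple[float, float]] = field(default_factory=dict)

    @staticmethod
    def _ogive(lengths: np.ndarray, l50: float, k: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-k * (np.asarray(lengths, float) - l50)))

    def selectivity_at(self, stock: str, lengths: np.ndarray) -> np.ndarray:
        if stock not in self.selectivity:
            return np.zeros(len(lengths))
        return self._ogive(lengths, *self.selectivity[stock])

    def discard_at(self, stock: str, lengths: np.ndarray) -> np.ndarray:
        if stock not in self.discard:
            return np.zeros(len(lengths))
        return self._ogive(lengths, *self.discard[stock])


@dataclass(frozen=True)
class Metier:
    """A gear x location x target-mix fishing-activity unit.

    ``zones`` maps stock name -> the population zone the métier fishes for
    that stock (absent = does not catch it); ``base_target`` maps stock ->
    the fixed target-factor base component.
    """

    name: str
    gear: Gear
    group: str
    zones: dict[str, str]
    base_target: dict[str, float]
    nationality: str = "FR"
    standardisation: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in METIER_GROUPS and self.group != "inactive":
            raise ValueError(f"unknown métier group {self.group!r}")
        if any(v < 0 for v in self.base_target.values()):
            raise ValueError("base target factors must be >= 0")
        if not self.zones and self.group != "inactive":
            raise ValueError(f"métier {self.name!r} must fish somewhere")


@dataclass
class Strategy:
    """A fleet's monthly effort and its allocation over métiers.

    ``effort`` gives total fishing days per calendar month (1-12);
    ``shares`` maps métier name -> share per month, summing to 1.
    """

    fleet: str
    effort: np.ndarray  # (12,) fishing days per calendar month
    shares: dict[str, np.ndarray]  # métier -> (12,) shares

    def __post_init__(self) -> None:
        self.effort = np.asarray(self.effort, dtype=float)
        if self.effort.shape != (12,) or np.any(self.effort < 0):
            raise ValueError("effort must be 12 non-negative monthly values")
        self.shares = {m: np.asarray(s, dtype=float) for m, s in self.shares.items()}
        tot = sum(self.shares.values())
        if np.any(np.abs(tot - 1.0) > 1e-9):
            raise ValueError("métier shares must sum to 1 every month")

    def metier_effort(self, metier: str, month: int) -> float:
        s = self.shares.get(metier)
        if s is None:
            return 0.0
        return float(self.effort[month - 1] * s[month - 1])


@dataclass
class TargetFactorSet:
    """Three-component multiplicative target factors.

    value(stock, métier, quarter, year) =
        base(stock, métier) * interannual(stock, métier, quarter, year)
        * estimated(stock, group(métier)[, quarter])

    The estimated component is keyed per métier *group*: by (group, quarter)
    for hake and sole, by group alone for Norway lobster.
    """

    base: dict[tuple[str, str], float]  # (stock, métier) -> base
    interannual: "InterAnnualFactorTable"
    estimated: dict[tuple, float] = field(default_factory=dict)
    seasonal_estimated: dict[str, bool] = field(
        default_factory=lambda: {"hake": True, "sole": True, "nephrops": False}
    )

    def estimated_key(self, stock: str, group: str, quarter: int) -> tuple:
        if self.seasonal_estimated.get(stock, True):
            return (stock, group, quarter)
        return (stock, group)

    def value(self, stock: str, metier: "Metier", quarter: int, year: int) -> float:
        b = self.base.get((stock, metier.name), 0.0)
        if b == 0.0:
            return 0.0
        ia = self.interannual.value(stock, metier.name, quarter, year)
        est = self.estimated.get(self.estimated_key(stock, metier.group, quarter), 1.0)
        return b * ia * est


@dataclass
class InterAnnualFactorTable:
    """Inter-annual fleet-dynamics ratios at stock-specific granularity.

    hake: keyed (métier, season, year); sole: (métier, year); Norway
    lobster: (year) — identical for every métier catching it.  The base year
    2010 has ratio 1 by construction.  Seasons alias calendar quarters.
    """

    base_year: int = 2010
    hake: dict[tuple[str, int, int], float] = field(default_factory=dict)
    sole: dict[tuple[str, int], float] = field(default_factory=dict)
    nephrops: dict[int, float] = field(default_factory=dict)

    def value(self, stock: str, metier: str, quarter: int, year: int) -> float:
        if year == self.base_year:
            return 1.0
        if stock == "hake":
            return self.hake.get((metier, quarter, year), 1.0)
        if stock == "sole":
            return self.sole.get((metier, year), 1.0)
        if stock == "nephrops":
            return self.nephrops.get(year, 1.0)
        raise KeyError(f"unknown stock {stock!r}")


def fishing_mortality(
    effort: float,
    target_factor: float,
    accessibility: np.ndarray | float,
    selectivity: np.ndarray,
    standardisation: float = 1.0,
    check: bool = True,
) -> np.ndarray:
    """Per-class monthly fishing mortality for one métier on one population.

    F = effort * target_factor * accessibility * selectivity, linear in every
    factor; applies only in the métier's zone (the caller restricts the zone).
    """
    acc = np.asarray(accessibility, dtype=float)
    sel = np.asarray(selectivity, dtype=float)
    if check:
        if effort < 0 or target_factor < 0 or standardisation < 0:
            raise ValueError("effort and factors must be >= 0")
        if np.any(acc < 0) or np.any(sel < 0):
            raise ValueError("accessibility and selectivity must be >= 0")
    return effort * target_factor * standardisation * acc * sel


def baranov_catch(
    n: np.ndarray,
    f_by_metier: np.ndarray,
    M: float,
    dt_months: float = 1.0,
    check: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Baranov competing-risks catch partition over one time step.

    ``n`` is abundance per class; ``f_by_metier`` is (n_metiers, n_classes).
    With Z = sum_m F_m + M*dt/12 per class, catch_m = F_m/Z * (1-exp(-Z)) * n
    and survivors = n * exp(-Z).  Returns (catch (n_metiers, n_classes),
    survivors, natural_deaths); the accounting closes exactly.
    """
    n = np.asarray(n, dtype=float)
    F = np.atleast_2d(np.asarray(f_by_metier, dtype=float))
    if check and (np.any(n < 0) or np.any(F < 0) or M < 0):
        raise ValueError("abundance, F and M must be >= 0")
    m_step = M * dt_months / 12.0
    Z = F.sum(axis=0) + m_step
    with np.errstate(divide="ignore", invalid="ignore"):
        dead_frac = np.where(Z > 0, -np.expm1(-Z) / np.where(Z > 0, Z, 1.0), 0.0)
    catch = F * (dead_frac * n)
    survivors = n * np.exp(-Z)
    natural = n - survivors - catch.sum(axis=0)
    np.clip(natural, 0.0, None, out=natural)
    return catch, survivors, natural


@dataclass(frozen=True)
class LOState:
    """Landings-Obligation state for one stock-year-gear combination."""

    active: bool = False
    de_minimis: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_minimis <= 1.0:
            raise ValueError("de-minimis rate must lie in [0, 1]")


def split_landings_discards(
    catch: np.ndarray,
    discard_ogive: np.ndarray,
    below_mcrs: np.ndarray,
    lo: LOState | None = None,
    check: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition catch-at-class into landings and discards.

    Pre-LO, the discard probability per class is max(ogive, 1 if below the
    Minimum Conservation Reference Size else 0): undersized catch never
    appears as sellable landings.  Under the Landings Obligation, at most the
    de-minimis fraction of the total catch may still be discarded; the rest
    of the would-be discards is retained and counted against the catch quota
    (recorded in the landings fraction for accounting).
    """
    catch = np.asarray(catch, dtype=float)
    if check and np.any(catch < 0):
        raise ValueError("catch must be >= 0")
    p_discard = np.maximum(np.asarray(discard_ogive, float), np.where(below_mcrs, 1.0, 0.0))
    intended = catch * p_discard
    if lo is not None and lo.active:
        allowed = lo.de_minimis * catch.sum()
        tot = intended.sum()
        if tot > allowed:
            intended = intended * (allowed / tot if tot > 0 else 0.0)
    discards = intended
    landings = catch - discards
    return landings, discards


def interannual_factor(
    obs: dict,
    stock: str,
    metier: str | None = None,
    season: int | None = None,
    year: int = 2010,
    base_year: int = 2010,
) -> float:
    """Observed-catch ratio year over base year at the stock's granularity.

    hake: obs keyed (métier, season, year); sole: (métier, year); Norway
    lobster: (year,) — one ratio shared by every métier catching it.
    """
    if stock == "hake":
        key, base_key = (metier, season, year), (metier, season, base_year)
    elif stock == "sole":
        key, base_key = (metier, year), (metier, base_year)
    elif stock == "nephrops":
        key, base_key = (year,), (base_year,)
    else:
        raise KeyError(f"unknown stock {stock!r}")
    base = obs.get(base_key, 0.0)
    if base <= 0:
        raise ValueError(f"zero base-year ({base_year}) observation for key {base_key}")
    return float(obs.get(key, 0.0)) / float(base)


def extrapolate_ratios(
    ratios_2014_2016: np.ndarray,
    halve_slope: bool = False,
    alpha: float = 0.05,
    force_significant: bool = False,
) -> dict[int, float]:
    """Extend inter-annual ratios to 2017-2020 from the 2014-2016 trend.

    A least-squares line is fitted to the three ratios; if its slope is
    significant at level ``alpha`` (two-sided t-test, 1 degree of freedom —
    rarely so with 3 points, hence ``force_significant`` mirrors the groups
    for which a trend was retained), ratio(y) = ratio(2016) + s*(y-2016) with
    s the slope, halved for the groups prone to unrealistically high effort.
    Otherwise the 2016 ratio carries forward.  Results are floored at 0.
    """
    r = np.asarray(ratios_2014_2016, dtype=float)
    if r.shape != (3,):
        raise ValueError("need exactly three ratios, for 2014, 2015 and 2016")
    years = np.array([2014.0, 2015.0, 2016.0])
    fit = stats.linregress(years, r)
    significant = force_significant or (np.isfinite(fit.pvalue) and fit.pvalue < alpha)
    if significant:
        s = fit.slope / 2.0 if halve_slope else fit.slope
        out = {y: max(0.0, r[2] + s * (y - 2016)) for y in range(2017, 2021)}
    else:
        out = {y: float(r[2]) for y in range(2017, 2021)}
    return out


@dataclass(frozen=True)
class CatchRatioTable:
    """Spanish-over-French catch ratios per (calendar month, length bin)."""

    ratios: np.ndarray  # (12, n_bins)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        if self.ratios.shape[0] != 12 or np.any(self.ratios < 0):
            raise ValueError("ratio table must be (12, n_bins) and >= 0")


def catch_based_fleet_removals(
    french_catch: np.ndarray, ratios: np.ndarray
) -> np.ndarray:
    """Removals of a catch-described fleet: French catch x ratio, elementwise."""
    fc = np.asarray(french_catch, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if fc.shape != r.shape:
        raise ValueError(f"shape mismatch: catch {fc.shape} vs ratios {r.shape}")
    return fc * r


@dataclass(frozen=True)
class ExogenousRemovalSeries:
    """Out-of-area hake removals in numbers per (month index, class), summed
    over the out-of-area métier groups."""

    removals: dict[int, np.ndarray]

    def at(self, t: int, n_classes: int) -> np.ndarray:
        r = self.removals.get(t)
        if r is None:
            return np.zeros(n_classes)
        return np.asarray(r, dtype=float)


def apply_exogenous_removals(
    n: np.ndarray, removals: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract prescribed removals from abundance, flooring at zero.

    Returns (new abundance, shortfall per class); a shortfall is reported,
    not raised — the prescribed series may exceed what the state holds.
    """
    n = np.asarray(n, dtype=float)
    r = np.asarray(removals, dtype=float)
    if np.any(r < 0):
        raise ValueError("removals must be >= 0")
    new = n - r
    shortfall = np.clip(-new, 0.0, None)
    return np.clip(new, 0.0, None), shortfall
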