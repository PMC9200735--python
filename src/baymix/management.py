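"""Quota regimes, MCRS, Landings Obligation and fishers' behaviour.

The management calendar follows the EU Common Fisheries Policy timeline for
the fishery: no quotas during the calibration window 2010-2012, Total
Allowable Landings (TAL) for every stock 2013-2015, then from 2016 Total
Allowable Catch (TAC) for hake and sole (which also fall under the Landings
Obligation) while Norway lobster stays under TALs throughout (it is not
under the LO).

TAL semantics cap annual landings: over-quota landings become discards.  TAC
with the LO bans further targeting instead: métiers expected to catch the
exhausted stock are flagged, fleet effort is re-allocated within each
strategy's métier set away from flagged métiers, and target factors can be
scaled down toward the remaining quota.  Over-quota catch is recorded and
traced, never deleted retroactively.  Every decision emits a trace record so
a run can be audited month by month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exploitation import Strategy

__all__ = [
    "QuotaRule",
    "MCRSRule",
    "LOConfig",
    "MetierFlag",
    "ReallocationTrace",
    "TargetFactorAdjustmentTrace",
    "quota_regime",
    "flag_metiers",
    "reallocate_effort",
    "adjust_target_factors",
    "enforce_quota_on_landings",
]

STOCKS = ("hake", "sole", "nephrops")

FLAG_QUOTA_EXHAUSTED = "quota_exhausted"
FLAG_DISCARD_PROPORTION = "discard_proportion"
FLAG_REASONS = (FLAG_QUOTA_EXHAUSTED, FLAG_DISCARD_PROPORTION)

INACTIVE_METIER = "inactive"

UNBOUNDED_RATIO = float("inf")  # sentinel when expected catch is zero


@dataclass(frozen=True)
class QuotaRule:
    """Annual quota for one stock: TAL caps landings, TAC caps catch."""

    stock: str
    year: int
    type: str  # "TAL" | "TAC" | "none"
    amount: float = 0.0  # tons

    def __post_init__(self) -> None:
        if self.type not in ("TAL", "TAC", "none"):
            raise ValueError(f"unknown quota type {self.type!r}")
        if self.type != "none" and self.amount <= 0:
            raise ValueError("quota amount must be positive when a quota applies")


@dataclass(frozen=True)
class MCRSRule:
    """Minimum Conservation Reference Size: length below which fish cannot be
    sold as landings (cm for fish, carapace mm for Norway lobster)."""

    stock: str
    min_length: float

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("MCRS must be positive")

    def below(self, class_lengths: np.ndarray) -> np.ndarray:
        return np.asarray(class_lengths, float) < self.min_length


@dataclass(frozen=True)
class LOConfig:
    """Landings Obligation configuration for one stock.

    ``de_minimis`` maps (year, gear name) -> exempt discard fraction in
    [0, 1].  Norway lobster is never under the LO.
    """

    stock: str
    start_year: int = 2016
    de_minimis: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stock == "nephrops":
            raise ValueError("Norway lobster is not under the Landings Obligation")
        for k, v in self.de_minimis.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"de-minimis rate {v} out of [0, 1] for {k}")

    def active(self, year: int) -> bool:
        return year >= self.start_year

    def rate(self, year: int, gear: str) -> float:
        return self.de_minimis.get((year, gear), 0.0)


@dataclass(frozen=True)
class MetierFlag:
    month: int  # simulation month index
    metier: str
    reason: str
    value: bool = True

    def __post_init__(self) -> None:
        if self.reason not in FLAG_REASONS:
            raise ValueError(f"unknown flag reason {self.reason!r}")


@dataclass(frozen=True)
class ReallocationTrace:
    month: int
    strategy: str
    origin: str
    share_before: float
    destinations: tuple[str, ...]
    proportions: tuple[float, ...]
    share_after: float


@dataclass(frozen=True)
class TargetFactorAdjustmentTrace:
    month: int
    name: str
    original: float
    new: float
    quota_ratio: dict[str, float]  # stock -> quota_remaining / expected


def quota_regime(stock: str, year: int) -> str:
    """Quota regime in force for a stock-year.

    2010-2012: none (calibration window); 2013-2015: TAL for all stocks;
    from 2016: TAC for hake and sole, TAL for Norway lobster.
    """
    if stock not in STOCKS:
        raise KeyError(f"unknown stock {stock!r}")
    if year <= 2012:
        return "none"
    if year <= 2015:
        return "TAL"
    return "TAL" if stock == "nephrops" else "TAC"


def flag_metiers(
    cumulative_catch: dict[str, float],
    quotas: dict[str, QuotaRule],
    lo_active: dict[str, bool],
    previous_year_catch: dict[tuple[str, str], float],
    month: int,
    metiers: list[str],
    discard_proportion: dict[tuple[str, str], float] | None = None,
    discard_threshold: float | None = None,
) -> list[MetierFlag]:
    """Flag métiers that must stop fishing.

    A métier is flagged when some stock it is expected to catch (judged from
    its previous-year catch composition) has exhausted its catch quota under
    an enforced Landings Obligation.  An optional discard-proportion trigger
    (disabled unless a threshold is configured) flags métiers whose recorded
    discard share of a constrained stock exceeds the threshold.  Flags are
    deterministic in their inputs.
    """
    flags: list[MetierFlag] = []
    exhausted = {
        s
        for s, rule in quotas.items()
        if rule.type == "TAC" and cumulative_catch.get(s, 0.0) >= rule.amount and lo_active.get(s, False)
    }
    for m in metiers:
        for s in exhausted:
            if previous_year_catch.get((m, s), 0.0) > 0.0:
                flags.append(MetierFlag(month, m, FLAG_QUOTA_EXHAUSTED))
                break
        else:
            if discard_threshold is not None and discard_proportion:
                for s in exhausted:
                    if discard_proportion.get((m, s), 0.0) > discard_threshold:
                        flags.append(MetierFlag(month, m, FLAG_DISCARD_PROPORTION))
                        break
    return flags


def reallocate_effort(
    strategy: Strategy, flags: list[MetierFlag], month: int
) -> tuple[Strategy, list[ReallocationTrace]]:
    """Move effort off flagged métiers, proportionally to remaining shares.

    Flagged métiers' shares for the calendar month of ``month`` are zeroed
    and redistributed over the strategy's unflagged métiers in proportion to
    their current shares; shares sum to 1 afterwards.  If every métier is
    flagged the effort parks in an explicit "inactive" pseudo-métier.  One
    trace record is emitted per métier of origin.
    """
    cal = month % 12  # column in the (12,) share vectors
    flagged = {f.metier for f in flags}
    shares = {m: s.copy() for m, s in strategy.shares.items()}
    traces: list[ReallocationTrace] = []
    origin_shares = {m: float(s[cal]) for m, s in shares.items()}
    victims = [m for m in shares if m in flagged and origin_shares[m] > 0]
    if not victims:
        return strategy, [
            ReallocationTrace(month, strategy.fleet, m, origin_shares[m], (m,), (1.0,), origin_shares[m])
            for m in shares
        ]
    receivers = [m for m in shares if m not in flagged]
    pool = sum(origin_shares[m] for m in receivers)
    for m in victims:
        before = origin_shares[m]
        if receivers and pool > 0:
            dests = tuple(receivers)
            props = tuple(origin_shares[r] / pool for r in receivers)
            for r, p in zip(dests, props):
                shares[r][cal] += before * p
        else:  # everything flagged: park effort in the inactive pseudo-métier
            if INACTIVE_METIER not in shares:
                shares[INACTIVE_METIER] = np.zeros(12)
            shares[INACTIVE_METIER][cal] += before
            dests, props = (INACTIVE_METIER,), (1.0,)
        shares[m][cal] = 0.0
        traces.append(
            ReallocationTrace(month, strategy.fleet, m, before, dests, props, 0.0)
        )
    new = Strategy(strategy.fleet, strategy.effort.copy(), shares)
    return new, traces


def adjust_target_factors(
    factors: dict[str, float],
    expected_catch: dict[tuple[str, str], float],
    quota_remaining: dict[str, float],
    month: int = 0,
) -> tuple[dict[str, float], list[TargetFactorAdjustmentTrace]]:
    """Scale target factors toward the remaining quota.

    For each factor (keyed by name), scale = min over constrained stocks of
    min(1, quota_remaining / expected catch); expected catch of 0 leaves the
    factor unchanged (ratio reported as the unbounded sentinel).
    """
    out: dict[str, float] = {}
    traces: list[TargetFactorAdjustmentTrace] = []
    for name, orig in factors.items():
        scale = 1.0
        ratios: dict[str, float] = {}
        for stock, rem in quota_remaining.items():
            exp = expected_catch.get((name, stock), 0.0)
            if exp < 0:
                raise ValueError("expected catch must be >= 0")
            if exp == 0.0:
                ratios[stock] = UNBOUNDED_RATIO
                continue
            r = max(0.0, rem) / exp
            ratios[stock] = r
            scale = min(scale, min(1.0, r))
        new = orig * scale
        out[name] = new
        traces.append(TargetFactorAdjustmentTrace(month, name, orig, new, ratios))
    return out, traces


def enforce_quota_on_landings(
    landings: float,
    discards: float,
    cumulative_landings: float,
    rule: QuotaRule,
) -> tuple[float, float]:
    """Apply TAL capping to one month's landings of a stock.

    With a TAL of A tons and ``cumulative_landings`` already booked this
    year, the month's landings are capped at max(0, A - cumulative); the
    excess is recorded as discards.  TAC rules do not modify the split here
    (over-quota catch triggers flags instead, and is never deleted).
    """
    if rule.type == "none":
        return landings, discards
    if rule.type == "TAC":
        return landings, discards
    room = max(0.0, rule.amount - cumulative_landings)
    landed = min(landings, room)
    return landed, discards + (landings - landed)
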