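"""Sequential calibration of accessibilities and target-factor components.

Catchability has two free parameter families: population accessibility and
the estimated component of the target factors.  They are estimated
sequentially — accessibilities first, then target factors — one parameter
set (parameter type x population) at a time, values within a set estimated
jointly while the other sets stay fixed.  Each set minimises a
sum-of-squared-residuals objective against the observation stream matching
that population's data granularity:

* hake — catch weight per length class, quarter and métier group (and
  fraction) over 2010-2012, optionally combined with a normalised
  length-frequency composition term; both terms carry file-supplied
  weighting tables keyed (quarter, métier group, fraction);
* sole — accessibility against annual fishing mortality per age class
  2010-2012; target factors against catch in weight per métier and quarter;
* Norway lobster — accessibility against catch in numbers per sex, length
  class and quarter in 2010; target factors against monthly landings per
  sex and length class in 2010.

The optimiser is a derivative-free bounded local search (Powell) with
optional multi-start; parameter counts per set are small (at most 56 for
Norway lobster accessibility, 20 for hake target factors).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import SimulationConfig
from .engine import run
from .structures import SEX_RECRUIT

__all__ = [
    "ObservationBundle",
    "ParameterSpec",
    "CalibrationResult",
    "objective_hake",
    "objective_sole_accessibility",
    "objective_nephrops_accessibility",
    "objective_catch_fit",
    "build_parameter_specs",
    "calibrate",
]

CALIBRATION_YEARS = (2010, 2011, 2012)


@dataclass
class ObservationBundle:
    """The heterogeneous observation streams consumed by calibration.

    Keys mirror the granularity of each source: hake cells are
    (class index, (year, quarter), métier group, fraction); sole catch cells
    (métier, (year, quarter)); Norway lobster arrays are (quarter, class) in
    numbers and (calendar month, class) landings tons for 2010.
    """

    hake_weight: dict[tuple, float]
    sole_F: np.ndarray  # (n_years, n_ages)
    sole_F_years: tuple[int, ...]
    sole_catch: dict[tuple, float]
    neph_numbers: np.ndarray  # (4, n_classes), 2010
    neph_landings: np.ndarray  # (12, n_classes), 2010 landings tons
    weights_weight: dict[tuple, float]  # (quarter, group, fraction) -> w
    weights_lfd: dict[tuple, float]
    landings_by_rect: dict[str, dict[tuple[int, str], float]] = field(default_factory=dict)


def objective_hake(
    sim_cells: dict[tuple, float],
    obs_cells: dict[tuple, float],
    weights_weight: dict[tuple, float],
    weights_lfd: dict[tuple, float] | None = None,
    composition: bool = True,
) -> float:
    """Weighted SSR on hake catch weight plus (optionally) length composition.

    Weight residuals are raw-scale per cell; the composition term normalises
    each (quarter, group, fraction) length distribution to proportions before
    squaring.  Weights are looked up by (quarter, group, fraction); a missing
    key is an error naming the key.
    """
    score = 0.0
    groups_seen: dict[tuple, list[tuple]] = {}
    for key in set(sim_cells) | set(obs_cells):
        c, (y, q), g, frac = key
        wkey = (q, g, frac)
        if wkey not in weights_weight:
            raise KeyError(f"missing weighting for {wkey} in the weight table")
        r = sim_cells.get(key, 0.0) - obs_cells.get(key, 0.0)
        score += weights_weight[wkey] * r * r
        groups_seen.setdefault((y, q, g, frac), []).append(key)
    if composition and weights_lfd is not None:
        for (y, q, g, frac), keys in groups_seen.items():
            wkey = (q, g, frac)
            if wkey not in weights_lfd:
                raise KeyError(f"missing weighting for {wkey} in the composition table")
            sim_v = np.array([sim_cells.get(k, 0.0) for k in keys])
            obs_v = np.array([obs_cells.get(k, 0.0) for k in keys])
            if sim_v.sum() > 0:
                sim_v = sim_v / sim_v.sum()
            if obs_v.sum() > 0:
                obs_v = obs_v / obs_v.sum()
            score += weights_lfd[wkey] * float(((sim_v - obs_v) ** 2).sum())
    return float(score)


def objective_sole_accessibility(sim_F: np.ndarray, obs_F: np.ndarray) -> float:
    """SSR of annual fishing mortality per age class."""
    sim_F, obs_F = np.asarray(sim_F), np.asarray(obs_F)
    if sim_F.shape != obs_F.shape:
        raise ValueError(f"F-at-age shape mismatch: {sim_F.shape} vs {obs_F.shape}")
    return float(((sim_F - obs_F) ** 2).sum())


def objective_nephrops_accessibility(sim: np.ndarray, obs: np.ndarray) -> float:
    """SSR of catch numbers per (sex x length class, quarter)."""
    sim, obs = np.asarray(sim), np.asarray(obs)
    if sim.shape != obs.shape:
        raise ValueError(f"catch-numbers shape mismatch: {sim.shape} vs {obs.shape}")
    return float(((sim - obs) ** 2).sum())


def objective_catch_fit(sim, obs, grouping: str) -> float:
    """SSR over the cells of a catch grouping.

    ``grouping`` is "metier_quarter" (dict cells, sole target factors) or
    "month_sex_length" (arrays, Norway lobster target factors).
    """
    if grouping == "metier_quarter":
        keys = set(sim) | set(obs)
        return float(sum((sim.get(k, 0.0) - obs.get(k, 0.0)) ** 2 for k in keys))
    if grouping == "month_sex_length":
        sim, obs = np.asarray(sim), np.asarray(obs)
        if sim.shape != obs.shape:
            raise ValueError(f"shape mismatch: {sim.shape} vs {obs.shape}")
        return float(((sim - obs) ** 2).sum())
    raise ValueError(f"unknown grouping {grouping!r}")


@dataclass
class ParameterSpec:
    """Identity and layout of one jointly-estimated parameter set."""

    name: str  # e.g. "accessibility:hake", "targetfactor:sole"
    keys: list  # one entry per free parameter
    bounds: list[tuple[float, float]]
    x0: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.keys) == len(self.bounds) == len(self.x0)):
            raise ValueError("parameter layout, bounds and start values disagree")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo < hi):
                raise ValueError("bounds must be finite with 0 <= lower < upper")

    @property
    def n(self) -> int:
        return len(self.keys)


def build_parameter_specs(
    config: SimulationConfig,
    acc_bounds: tuple[float, float] = (0.0, 2.0),
    tf_bounds: tuple[float, float] = (0.0, 5.0),
    tf_start: float = 0.6,
) -> list[ParameterSpec]:
    """The six parameter sets in calibration order (accessibility first).

    Hake accessibility is one scalar per quarter shared across length
    classes (4 parameters); sole accessibility one per age class; Norway
    lobster one per sex x length class (the mixed recruitment class is not
    catchable and carries no parameter).  Target-factor estimated components
    are per métier group and quarter for hake and sole (5 groups x 4
    quarters = 20 for hake at full scale), per group alone for Norway
    lobster.
    """
    specs: list[ParameterSpec] = []
    mid = 0.5 * (acc_bounds[0] + acc_bounds[1])
    for stock in ("hake", "sole", "nephrops"):
        if stock not in config.stocks:
            continue
        sc = config.stocks[stock]
        if stock == "hake":
            keys = [("quarter", q) for q in (1, 2, 3, 4)]
        elif stock == "sole":
            keys = [("class", i) for i in range(sc.structure.n_classes)]
        else:
            keys = [("class", i) for i, sx in enumerate(sc.structure.sex) if sx != SEX_RECRUIT]
        specs.append(
            ParameterSpec(
                f"accessibility:{stock}", keys,
                [acc_bounds] * len(keys), np.full(len(keys), mid),
            )
        )
    for stock in ("hake", "sole", "nephrops"):
        if stock not in config.stocks:
            continue
        groups = sorted({
            m.group for m in config.metiers
            if stock in m.zones and m.base_target.get(stock, 0.0) > 0
        })
        if config.target_factors.seasonal_estimated.get(stock, True):
            keys = [(stock, g, q) for g in groups for q in (1, 2, 3, 4)]
        else:
            keys = [(stock, g) for g in groups]
        specs.append(
            ParameterSpec(
                f"targetfactor:{stock}", keys,
                [tf_bounds] * len(keys), np.full(len(keys), tf_start),
            )
        )
    return specs


@dataclass
class CalibrationResult:
    values: dict[str, dict] = field(default_factory=dict)  # set name -> {key: value}
    objectives: dict[str, list[float]] = field(default_factory=dict)  # trajectory
    converged: dict[str, bool] = field(default_factory=dict)

    def final_objective(self, name: str) -> float:
        return self.objectives[name][-1]


def _apply_params(config: SimulationConfig, spec: ParameterSpec, x: np.ndarray) -> None:
    x = np.maximum(np.asarray(x, dtype=float), 0.0)  # guard bound rounding
    kind, stock = spec.name.split(":")
    if kind == "accessibility":
        sc = config.stocks[stock]
        if stock == "hake":
            sc.accessibility = np.asarray(x, dtype=float)
        else:
            acc = np.zeros(sc.structure.n_classes) if sc.accessibility is None else sc.accessibility.copy()
            for key, v in zip(spec.keys, x):
                acc[key[1]] = v
            sc.accessibility = acc
    else:
        for key, v in zip(spec.keys, x):
            config.target_factors.estimated[tuple(key)] = float(v)


def _objective_for(
    spec: ParameterSpec,
    config: SimulationConfig,
    obs: ObservationBundle,
    years: tuple[int, ...],
) -> float:
    kind, stock = spec.name.split(":")
    store = run(config, only_stocks=(stock,))
    if stock == "hake":
        sim = store.hake_weight_by_lqgf(list(years))
        return objective_hake(sim, obs.hake_weight, obs.weights_weight, obs.weights_lfd)
    if stock == "sole":
        if kind == "accessibility":
            return objective_sole_accessibility(
                store.sole_annual_F(list(obs.sole_F_years)), obs.sole_F
            )
        return objective_catch_fit(
            store.catch_tons_by_metier_quarter("sole", list(years)),
            obs.sole_catch, "metier_quarter",
        )
    if kind == "accessibility":
        return objective_nephrops_accessibility(
            store.nephrops_numbers_by_slq(years[0]), obs.neph_numbers
        )
    return objective_catch_fit(
        store.nephrops_monthly_landings(years[0]), obs.neph_landings, "month_sex_length"
    )


def calibrate(
    config: SimulationConfig,
    obs: ObservationBundle,
    specs: list[ParameterSpec] | None = None,
    years: tuple[int, ...] = CALIBRATION_YEARS,
    n_starts: int = 1,
    seed: int = 0,
    xtol: float = 1e-4,
    ftol: float = 1e-6,
    maxfev: int | None = None,
) -> tuple[SimulationConfig, CalibrationResult]:
    """Sequentially estimate every parameter set against the bundle.

    Returns the calibrated configuration (a working copy of ``config``
    restricted to the calibration window internally; the returned object
    keeps the original horizon) and the result with per-set estimates,
    objective trajectories and convergence status.  Deterministic for a
    fixed ``seed`` (used only for multi-start jitter).
    """
    work = copy.deepcopy(config)
    work.n_years = min(config.n_years, len(years))
    if specs is None:
        specs = build_parameter_specs(work)
    order = {"accessibility": 0, "targetfactor": 1}
    specs = sorted(specs, key=lambda s: order[s.name.split(":")[0]])
    rng = np.random.default_rng(seed)
    result = CalibrationResult()
    for spec in specs:
        traj: list[float] = []

        def fun(x: np.ndarray) -> float:
            _apply_params(work, spec, x)
            try:
                score = _objective_for(spec, work, obs, years)
            except RuntimeError as exc:
                raise RuntimeError(f"{exc} (parameters {spec.name}={x.tolist()})") from exc
            traj.append(score)
            return score

        starts = [spec.x0]
        for _ in range(n_starts - 1):
            lo = np.array([b[0] for b in spec.bounds])
            hi = np.array([b[1] for b in spec.bounds])
            starts.append(lo + rng.random(spec.n) * (hi - lo))
        best = None
        for x0 in starts:
            res = optimize.minimize(
                fun, x0, method="Powell", bounds=spec.bounds,
                options={"xtol": xtol, "ftol": ftol,
                         **({"maxfev": maxfev} if maxfev else {})},
            )
            if best is None or res.fun < best.fun:
                best = res
        _apply_params(work, spec, best.x)
        result.values[spec.name] = {k: float(v) for k, v in zip(spec.keys, best.x)}
        traj.append(float(best.fun))  # the retained value; never above traj[0]
        result.objectives[spec.name] = traj
        result.converged[spec.name] = bool(best.success)
    work.n_years = config.n_years
    return work, result
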