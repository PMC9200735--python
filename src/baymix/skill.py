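"""Skill assessment: quarterly fit series and the spatial discrepancy map.

The fit to observations is judged on quarterly aggregates of monthly catch
(hake, sole) or landings (Norway lobster) per métier group, and on the
spatial distribution of landings across ICES rectangles through the
discrepancy statistic

    delta(rect) = sim(rect) / sum_r sim(r)  -  obs(rect) / sum_r obs(r)

computed per stock and quarter.  A positive delta marks an over-simulated
share of the landings distribution in that rectangle, a negative one an
under-simulation; the deltas sum to zero by construction and are invariant
to rescaling either side by a positive constant (only proportions enter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["quarterly_fit", "spatial_delta"]


def quarterly_fit(
    sim_monthly: dict[tuple[int, int], float],
    obs_quarterly: dict[tuple[int, int], float],
) -> pd.DataFrame:
    """Aggregate monthly simulated values to quarters and join observations.

    ``sim_monthly`` maps (year, calendar month) -> tons; ``obs_quarterly``
    maps (year, quarter) -> tons.  Returns a frame with columns year,
    quarter, sim, obs, residual; quarters with no observation keep
    ``obs``/``residual`` as NaN and are counted in the ``missing_obs``
    attribute rather than silently dropped.
    """
    agg: dict[tuple[int, int], float] = {}
    for (y, m), v in sim_monthly.items():
        q = (m - 1) // 3 + 1
        agg[(y, q)] = agg.get((y, q), 0.0) + v
    keys = sorted(set(agg) | set(obs_quarterly))
    rows = []
    missing = 0
    for y, q in keys:
        sim = agg.get((y, q), 0.0)
        obs = obs_quarterly.get((y, q))
        if obs is None:
            missing += 1
            rows.append((y, q, sim, np.nan, np.nan))
        else:
            rows.append((y, q, sim, obs, sim - obs))
    out = pd.DataFrame(rows, columns=["year", "quarter", "sim", "obs", "residual"])
    out.attrs["missing_obs"] = missing
    return out


def spatial_delta(
    sim_landings: dict[str, float],
    obs_landings: dict[str, float],
) -> pd.Series:
    """Per-rectangle discrepancy of landings proportions (sim minus obs).

    Both inputs map rectangle code -> landings (tons) for one stock and
    quarter.  Raises if either total is not strictly positive (the statistic
    is undefined).  Rectangles present on either side are emitted; cells at
    zero on both sides get delta 0 so maps tile the study zone.
    """
    s_tot = sum(sim_landings.values())
    o_tot = sum(obs_landings.values())
    if s_tot <= 0 or o_tot <= 0:
        raise ValueError(
            f"spatial delta undefined: total simulated landings {s_tot}, observed {o_tot}"
        )
    rects = sorted(set(sim_landings) | set(obs_landings))
    delta = {
        r: sim_landings.get(r, 0.0) / s_tot - obs_landings.get(r, 0.0) / o_tot
        for r in rects
    }
    out = pd.Series(delta, name="delta")
    assert abs(out.sum()) < 1e-9
    return out
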