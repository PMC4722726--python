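"""Cell-culture productivity: integral viable cell concentration (IVCC),
specific productivity (q_p), and relative-titer stability trajectories.

Units are enforced exactly as measured: viable cell density in 10^9
cells/L, time in hours, titer in µg/mL, q_p in pg/cell/day.  Over one
interval,

    IVCC = (c_XV1 + c_XV0) / 2 * (t1 - t0)            [10^9 cell*h/L]
    q_p  = (c_P1 - c_P0) / IVCC * 24                  [pg/cell/day]

Intervals are defined between successive sampled passages; the series
mean of q_p is reported as an additional aggregate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ivcc(c_xv1: float, c_xv0: float, t1: float, t0: float) -> float:
    """Trapezoidal integral of viable cell concentration over [t0, t1]."""
    if t1 <= t0:
        raise ValueError(f"t1 must exceed t0 (got t0={t0}, t1={t1})")
    return (c_xv1 + c_xv0) / 2.0 * (t1 - t0)


def specific_productivity(c_p1: float, c_p0: float, ivcc_value: float) -> float:
    """Specific productivity q_p in pg/cell/day from a titer change (µg/mL)
    and the interval IVCC (10^9 cell*h/L)."""
    if ivcc_value <= 0:
        raise ValueError(f"IVCC must be positive, got {ivcc_value}")
    return (c_p1 - c_p0) / ivcc_value * 24.0


def relative_titer_series(titers: "pd.Series | np.ndarray | list[float]") -> np.ndarray:
    """Titer trajectory normalized to the first sampled passage (= 1)."""
    t = np.asarray(titers, dtype=float)
    if t.size == 0:
        raise ValueError("empty titer series")
    if t[0] <= 0:
        raise ValueError("first titer must be positive to normalize")
    return t / t[0]


def analyze_stability(series: pd.DataFrame) -> pd.DataFrame:
    """Per-interval IVCC, q_p and relative titer for one clone's series.

    Expects columns passage, t_hours, viable_density_1e9_per_L,
    titer_ug_per_mL with strictly increasing t_hours.  Returns one row
    per interval between successive sampled passages plus the per-row
    relative titer; the q_p series mean is stored in
    ``result.attrs["qp_mean"]`` and the endpoint retention in
    ``result.attrs["endpoint_retention"]``.
    """
    req = {"passage", "t_hours", "viable_density_1e9_per_L", "titer_ug_per_mL"}
    if not req.issubset(series.columns):
        raise ValueError(f"stability series missing columns: {req - set(series.columns)}")
    s = series.sort_values("passage").reset_index(drop=True)
    if not np.all(np.diff(s["t_hours"]) > 0):
        raise ValueError("t_hours must be strictly increasing across passages")
    if (s["viable_density_1e9_per_L"] < 0).any() or (s["titer_ug_per_mL"] < 0).any():
        raise ValueError("densities and titers must be non-negative")

    rel = relative_titer_series(s["titer_ug_per_mL"])
    rows = []
    for i in range(1, len(s)):
        a, b = s.iloc[i - 1], s.iloc[i]
        iv = ivcc(b["viable_density_1e9_per_L"], a["viable_density_1e9_per_L"],
                  b["t_hours"], a["t_hours"])
        qp = specific_productivity(b["titer_ug_per_mL"], a["titer_ug_per_mL"], iv)
        rows.append(dict(passage_from=int(a["passage"]), passage_to=int(b["passage"]),
                         ivcc=iv, qp=qp, relative_titer=rel[i]))
    out = pd.DataFrame(rows)
    out.attrs["qp_mean"] = float(out["qp"].mean()) if len(out) else np.nan
    out.attrs["endpoint_retention"] = float(rel[-1])
    return out
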