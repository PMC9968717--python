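"""Effect-size analysis: AUEC, percent difference vs placebo, bands.

The comparison statistic of the engine is the area under the effect curve
(AUEC): the trapezoidal integral of an analyte's plasma concentration over a
stated window (default: 24 h on day 20, when dosing has reached its
periodic steady state).  Schedules are compared through the percent
difference between the median AUEC of the treated arm and the median AUEC
of the matched placebo arm; the flanking 5th/95th percentile columns
summarize the distribution of per-individual (paired) percent differences.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .model import ANALYTES
from .trial import PLACEBO_LABEL, SimulationResult

__all__ = [
    "auec",
    "percent_diff_vs_placebo",
    "relative_improvement",
    "AUECSummary",
    "summarize",
    "prediction_bands",
]

#: nested central prediction-interval coverage levels, widest first
BAND_PERCENTILES = ((5, 95), (15, 85), (25, 75), (35, 65), (45, 55))


def auec(time_h: np.ndarray, conc: np.ndarray, window: tuple[float, float]) -> float:
    """Trapezoidal area under the concentration curve over ``window`` (pmol*h/L).

    The series is interpolated linearly at window edges that fall between
    grid points.  ``conc`` may be 1-D or 2-D with time on the last axis (a
    row per individual), in which case a vector of AUECs is returned.
    """
    time_h = np.asarray(time_h, dtype=float)
    conc = np.asarray(conc, dtype=float)
    lo, hi = window
    if not (time_h[0] <= lo < hi <= time_h[-1]):
        raise ValueError(f"window {window} outside the time grid span")
    if np.any(np.diff(time_h) <= 0):
        raise ValueError("time grid must be strictly increasing")
    inside = (time_h > lo) & (time_h < hi)
    t = np.concatenate([[lo], time_h[inside], [hi]])
    if conc.ndim == 1:
        c = np.interp(t, time_h, conc)
        return float(np.trapezoid(c, t))
    interp = np.empty((conc.shape[0], t.size))
    for i in range(conc.shape[0]):
        interp[i] = np.interp(t, time_h, conc[i])
    return np.trapezoid(interp, t, axis=1)


def percent_diff_vs_placebo(treated: float, placebo: float) -> float:
    """``100 * (treated - placebo) / placebo``."""
    if placebo <= 0:
        raise ZeroDivisionError("placebo AUEC must be > 0 for a percent difference")
    return 100.0 * (treated - placebo) / placebo


def relative_improvement(a: float, b: float) -> float:
    """Relative gain of effect magnitude ``a`` over ``b``, in percent.

    Defined as ``100 * (|a| / |b| - 1)``: the ratio of the absolute percent
    differences minus one, so a +135% vs +120% pair of placebo-referenced
    effects is a 12.5% improvement.
    """
    if b == 0:
        raise ZeroDivisionError("reference effect must be non-zero")
    return 100.0 * (abs(a) / abs(b) - 1.0)


def _quantile(x: np.ndarray, q: float) -> float:
    # linear interpolation of order statistics (numpy default convention)
    return float(np.quantile(x, q))


@dataclasses.dataclass(frozen=True)
class AUECSummary:
    """Per arm x analyte AUEC percent differences vs placebo.

    ``median_pct`` follows the median-vs-median convention (percent
    difference of median AUECs); ``p5_pct``/``p95_pct`` are percentiles of
    the per-individual paired percent differences, and ``median_paired_pct``
    is the median of that same paired distribution (both conventions are
    reported so users can compare them).
    """

    window: tuple[float, float]
    n_individuals: int
    table: pd.DataFrame  # index (arm, analyte); columns median_pct, p5_pct, p95_pct, ...

    def to_wide(self) -> pd.DataFrame:
        """One row per arm with (median, p5, p95) column blocks per analyte."""
        wide = self.table.reset_index().pivot(
            index="arm", columns="analyte",
            values=["median_pct", "p5_pct", "p95_pct"],
        )
        wide.columns = [f"{a}_{v.replace('_pct', '')}" for v, a in wide.columns]
        order = [f"{a}_{v}" for a in ANALYTES if a != "benazeprilat"
                 for v in ("median", "p5", "p95")]
        return wide[order]


def summarize(
    result: SimulationResult,
    window: tuple[float, float] | None = None,
    analytes: tuple[str, ...] | None = None,
) -> AUECSummary:
    """AUEC comparison table of every arm against matched placebo."""
    window = window or result.design.auec_window
    analytes = analytes or tuple(a for a in ANALYTES if a != "benazeprilat")
    if PLACEBO_LABEL not in result.concentrations:
        raise ValueError("result has no placebo arm")
    n = result.design.n_individuals
    rows = []
    ana_ix = {a: i for i, a in enumerate(ANALYTES)}
    placebo_auec = {
        a: auec(result.time_h, result.concentrations[PLACEBO_LABEL][:, ana_ix[a], :], window)
        for a in analytes
    }
    for arm in result.arms:
        if arm == PLACEBO_LABEL:
            continue
        c = result.concentrations[arm]
        if c.shape[0] != n:
            raise ValueError(f"arm {arm!r} population does not match placebo")
        for a in analytes:
            treated = auec(result.time_h, c[:, ana_ix[a], :], window)
            base = placebo_auec[a]
            if np.any(base <= 0):
                raise ZeroDivisionError(f"placebo AUEC of {a} is not positive")
            paired = 100.0 * (treated - base) / base
            rows.append(
                {
                    "arm": arm,
                    "analyte": a,
                    "median_pct": percent_diff_vs_placebo(
                        _quantile(treated, 0.5), _quantile(base, 0.5)
                    ),
                    "p5_pct": _quantile(paired, 0.05),
                    "p95_pct": _quantile(paired, 0.95),
                    "median_paired_pct": _quantile(paired, 0.5),
                }
            )
    table = pd.DataFrame(rows).set_index(["arm", "analyte"])
    return AUECSummary(window=window, n_individuals=n, table=table)


def prediction_bands(
    result: SimulationResult,
    analyte: str,
    arm: str | None = None,
) -> pd.DataFrame:
    """Median and nested central prediction bands of one analyte over time.

    Returns a frame indexed by time with columns ``median`` and
    ``p5``/``p95``, ``p15``/``p85``, ... — the 90% prediction interval in
    steps of 10% across the simulated individuals.
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}")
    arm = arm if arm is not None else result.arms[-1]
    if arm not in result.concentrations:
        raise ValueError(f"unknown arm {arm!r}")
    c = result.concentrations[arm][:, ANALYTES.index(analyte), :]
    out = {"median": np.quantile(c, 0.5, axis=0)}
    for lo, hi in BAND_PERCENTILES:
        out[f"p{lo}"] = np.quantile(c, lo / 100.0, axis=0)
        out[f"p{hi}"] = np.quantile(c, hi / 100.0, axis=0)
    return pd.DataFrame(out, index=pd.Index(result.time_h, name="time_h"))
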