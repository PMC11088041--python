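"""Microplate growth kinetics: windowed log-linear µmax and plateau ODmax.

The maximum specific growth rate is the OLS slope of ln(OD600) against
time over the exponential window OD600 0.4-0.9.  Poorly growing cultures
that plateau below OD 0.9 are fitted in a lower window, 0.1-0.5, and
flagged.  ODmax is the mean OD over the detected terminal plateau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "WindowError",
    "fit_mumax",
    "od_max",
    "summarize_replicates",
    "DEFAULT_WINDOW",
    "FALLBACK_WINDOW",
]

DEFAULT_WINDOW = (0.4, 0.9)
FALLBACK_WINDOW = (0.1, 0.5)

#: Relative OD change per hour below which the culture is considered
#: stationary when delimiting the terminal plateau.
PLATEAU_RATE = 0.02


class WindowError(ValueError):
    """Too few points fall inside the fitting window(s)."""


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series for one well."""

    times: tuple[float, ...]
    od600: tuple[float, ...]
    strain_label: str = ""
    condition: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od600):
            raise ValueError("times and od600 must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty growth curve")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if any(v < 0 for v in self.od600):
            raise ValueError("OD600 values must be non-negative")


@dataclass(frozen=True)
class GrowthFit:
    """A fitted µmax with the window actually used, plus ODmax."""

    mu_max: float
    window_low: float
    window_high: float
    n_points: int
    r_squared: float
    od_max: float
    window_fallback_used: bool
    strain_label: str = ""
    condition: str = ""
    replicate_id: str = ""


def od_max(curve: GrowthCurve) -> float:
    """Plateau OD600 at stationary phase.

    The terminal plateau is the longest run of points at the end of the
    curve whose pairwise relative OD change stays below 2% per hour; the
    returned value is the mean OD over that run.  A curve still rising at
    its last point has no plateau: the last OD is returned with a warning.
    """
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od600, dtype=float)
    if len(od) == 1:
        return float(od[0])
    # walk back from the end while consecutive changes look stationary
    start = len(od) - 1
    while start > 0:
        dt = t[start] - t[start - 1]
        prev = max(od[start - 1], 1e-12)
        rate = abs(od[start] - od[start - 1]) / prev / dt
        if rate >= PLATEAU_RATE:
            break
        start -= 1
    if start == len(od) - 1:
        warnings.warn(
            f"no stationary plateau detected for {curve.strain_label or 'curve'}; "
            "returning the final OD600",
            stacklevel=2,
        )
        return float(od[-1])
    return float(od[start:].mean())


def _window_run(
    t: np.ndarray, od: np.ndarray, window: tuple[float, float], policy: str
) -> tuple[np.ndarray, np.ndarray] | None:
    """Points of the chosen contiguous in-window run, or None if < 3."""
    lo, hi = window
    inside = (od >= lo) & (od <= hi)
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(od)
    while i < n:
        if inside[i]:
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            if j - i + 1 >= 3:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    if not runs:
        return None
    if policy == "first":
        a, b = runs[0]
        return t[a:b], od[a:b]
    if policy == "best":
        best, best_r2 = None, -np.inf
        for a, b in runs:
            res = stats.linregress(t[a:b], np.log(od[a:b]))
            if res.rvalue**2 > best_r2:
                best, best_r2 = (a, b), res.rvalue**2
        a, b = best  # type: ignore[misc]
        return t[a:b], od[a:b]
    raise ValueError(f"unknown segment policy {policy!r}")


def fit_mumax(
    curve: GrowthCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
    *,
    fallback_window: tuple[float, float] = FALLBACK_WINDOW,
    segment_policy: str = "first",
    blank: float = 0.0,
) -> GrowthFit:
    """Maximum specific growth rate from a windowed log-linear fit.

    µmax is the slope of ln(OD600) versus time (h) over the first
    contiguous run of points inside the OD window (``segment_policy="best"``
    instead picks the run with the highest r², useful for diauxic curves).
    If the curve's plateau ODmax falls below the upper window bound the
    lower fallback window is selected automatically and flagged.

    ``blank`` is subtracted from all OD values first; non-positive values
    after blanking are dropped with a warning before taking logs.
    """
    if window[0] >= window[1] or fallback_window[0] >= fallback_window[1]:
        raise ValueError("window bounds must satisfy low < high")
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od600, dtype=float) - blank
    if np.any(od <= 0):
        warnings.warn(
            f"dropping {int(np.sum(od <= 0))} non-positive OD values before log transform",
            stacklevel=2,
        )
        keep = od > 0
        t, od = t[keep], od[keep]
    if len(od) < 3:
        raise WindowError("fewer than 3 positive OD points in the curve")

    blanked = GrowthCurve(tuple(t), tuple(od), curve.strain_label, curve.condition, curve.replicate_id)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plateau = od_max(blanked)

    fallback = plateau < window[1]
    selected = fallback_window if fallback else window
    pts = _window_run(t, od, selected, segment_policy)
    if pts is None:
        # the rule-selected window failed; try the other one before erroring
        other = window if fallback else fallback_window
        pts = _window_run(t, od, other, segment_policy)
        if pts is None:
            raise WindowError(
                f"fewer than 3 contiguous points in windows {window} and {fallback_window}; "
                f"curve OD range is [{od.min():.3g}, {od.max():.3g}]"
            )
        selected = other

    tw, odw = pts
    res = stats.linregress(tw, np.log(odw))
    return GrowthFit(
        mu_max=float(res.slope),
        window_low=selected[0],
        window_high=selected[1],
        n_points=len(tw),
        r_squared=float(res.rvalue) ** 2,
        od_max=plateau,
        window_fallback_used=fallback,
        strain_label=curve.strain_label,
        condition=curve.condition,
        replicate_id=curve.replicate_id,
    )


def summarize_replicates(
    fits: list[GrowthFit], *, require_single_group: bool = False
) -> pd.DataFrame:
    """Mean and sample SD of µmax and ODmax per strain/condition.

    Each replicate is fitted separately and averaged here.  Groups with a
    single replicate report NaN SD.  With ``require_single_group=True``
    mixed strain/condition labels raise instead of forming groups.
    """
    if not fits:
        raise ValueError("no fits to summarise")
    df = pd.DataFrame(
        {
            "strain_label": [f.strain_label for f in fits],
            "condition": [f.condition for f in fits],
            "mu_max": [f.mu_max for f in fits],
            "od_max": [f.od_max for f in fits],
        }
    )
    groups = df.groupby(["strain_label", "condition"], sort=False)
    if require_single_group and groups.ngroups > 1:
        labels = sorted({(f.strain_label, f.condition) for f in fits})
        raise ValueError(f"mixed strain/condition labels in one group: {labels}")
    out = groups.agg(
        mu_max_mean=("mu_max", "mean"),
        mu_max_sd=("mu_max", lambda s: s.std(ddof=1)),
        od_max_mean=("od_max", "mean"),
        od_max_sd=("od_max", lambda s: s.std(ddof=1)),
        n=("mu_max", "size"),
    ).reset_index()
    return out
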