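"""Run-theory drought event identification and period aggregation.

A drought event is a maximal run of consecutive months with SPEI at or below
a threshold, kept only if it lasts at least ``min_duration`` months.  Each
event carries

* DD — duration in months (exclusive-end convention, so DD = DTT - DIT),
* DS — severity, the sum of SPEI inside the run (negative),
* DI — intensity, DS / DD.

Period aggregates are MDN (events per year), and the per-event means MDD,
MDS, MDI.  Cells with no events in a period receive 0 for all four (with a
flag), so downstream regressions see complete covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DroughtEvent", "DroughtSummary", "identify_events",
           "summarize_period", "drought_characteristics"]


@dataclass(frozen=True)
class DroughtEvent:
    start: int      # DIT: index of the first month of the run
    end: int        # DTT: index of the first month AFTER the run (exclusive)
    duration: int   # DD = end - start, months
    severity: float  # DS: sum of SPEI over the run
    intensity: float  # DI = DS / DD


@dataclass(frozen=True)
class DroughtSummary:
    n_events: int
    years: float
    mdn: float  # events per year
    mdd: float  # mean event duration, months
    mds: float  # mean event severity
    mdi: float  # mean event intensity
    empty: bool  # True when the zero-event fill convention was applied


def identify_events(
    spei: np.ndarray,
    threshold: float = -0.5,
    min_duration: int = 3,
) -> list[DroughtEvent]:
    """Find maximal runs of SPEI <= threshold lasting >= min_duration months.

    The threshold itself counts as drought (the light-drought class is the
    half-open interval (-1.0, -0.5], so -0.5 is inside it).  Missing (NaN)
    values cannot certify continuity and therefore terminate a run.
    """
    if threshold >= 0.0:
        raise ValueError(f"drought threshold must be negative, got {threshold}")
    if min_duration < 1:
        raise ValueError(f"min_duration must be >= 1, got {min_duration}")
    spei = np.asarray(spei, dtype=float)
    if spei.ndim != 1:
        raise ValueError("spei must be a 1-D time-ordered series")

    in_drought = np.isfinite(spei) & (spei <= threshold)
    events: list[DroughtEvent] = []
    start = None
    for i, flag in enumerate(in_drought):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            events.append(_make_event(spei, start, i))
            start = None
    if start is not None:
        events.append(_make_event(spei, start, len(spei)))
    return [e for e in events if e.duration >= min_duration]


def _make_event(spei: np.ndarray, start: int, end: int) -> DroughtEvent:
    dd = end - start
    ds = float(np.sum(spei[start:end]))
    return DroughtEvent(start=start, end=end, duration=dd,
                        severity=ds, intensity=ds / dd)


def summarize_period(
    events: list[DroughtEvent],
    period: tuple[int, int],
    years: float,
) -> DroughtSummary:
    """Aggregate events whose start month falls in ``period`` = [start, end).

    Events spanning the period boundary are assigned wholly to the period
    containing their start month.  MDN = n / years; MDD, MDS, MDI are
    arithmetic means over the assigned events, or 0 when none fall in the
    period (flagged via ``empty``).
    """
    lo, hi = period
    if hi <= lo:
        raise ValueError(f"empty period [{lo}, {hi})")
    if years <= 0:
        raise ValueError(f"period length in years must be positive, got {years}")
    assigned = [e for e in events if lo <= e.start < hi]
    n = len(assigned)
    if n == 0:
        return DroughtSummary(0, years, 0.0, 0.0, 0.0, 0.0, empty=True)
    return DroughtSummary(
        n_events=n,
        years=years,
        mdn=n / years,
        mdd=float(np.mean([e.duration for e in assigned])),
        mds=float(np.mean([e.severity for e in assigned])),
        mdi=float(np.mean([e.intensity for e in assigned])),
        empty=False,
    )


def drought_characteristics(
    spei_table: pd.DataFrame,
    thresholds: tuple[float, ...] = (-0.5, -1.0),
    periods: dict[str, tuple[int, int]] | None = None,
    min_duration: int = 3,
) -> pd.DataFrame:
    """Per-cell drought summaries from a long-format SPEI table.

    ``spei_table`` has columns cell_id, scale, year, month, spei.  ``periods``
    maps a label to an inclusive year range (start_year, end_year); the
    default is one period spanning each series' full extent.  Event start
    months anchor period assignment.

    Returns one row per (cell_id, scale, threshold, period) with columns
    n_events, mdn, mdd, mds, mdi, empty.
    """
    rows = []
    for (cell_id, scale), sub in spei_table.groupby(["cell_id", "scale"], sort=True):
        sub = sub.sort_values(["year", "month"])
        spei = sub["spei"].to_numpy(dtype=float)
        years_arr = sub["year"].to_numpy()
        if periods is None:
            period_map = {"full": (int(years_arr.min()), int(years_arr.max()))}
        else:
            period_map = periods
        for thr in thresholds:
            events = identify_events(spei, threshold=thr, min_duration=min_duration)
            for label, (y0, y1) in period_map.items():
                idx = np.flatnonzero((years_arr >= y0) & (years_arr <= y1))
                if idx.size == 0:
                    continue
                summ = summarize_period(events, (int(idx[0]), int(idx[-1]) + 1),
                                        years=y1 - y0 + 1)
                rows.append({
                    "cell_id": cell_id, "scale": scale, "threshold": thr,
                    "period": label, "n_events": summ.n_events,
                    "mdn": summ.mdn, "mdd": summ.mdd,
                    "mds": summ.mds, "mdi": summ.mdi, "empty": summ.empty,
                })
    return pd.DataFrame(rows)
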