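"""Rain-event segmentation and sampling-event flagging.

A contiguous rainfall episode qualifies as a *rain event* when its cumulative
depth exceeds 1 mm within some 8-hour window; bursts separated by less than
8 h of dry record belong to the same event, and a dry gap of at least 8 h
terminates it.  A rain event becomes a *sampling event* when at least one
monitored inlet exceeded its stage trigger threshold during the event;
the downstream composite samplers (collector shaft and stream) are triggered
only when at least two inlets triggered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["RainEvent", "classify_events", "flag_sampling_events", "events_to_frame"]


@dataclass
class RainEvent:
    """One rain event: ``start``/``end`` are the first/last wet minutes."""

    event_id: int
    start: pd.Timestamp
    end: pd.Timestamp
    total_mm: float
    is_sampling_event: bool = False
    is_snowmelt: bool = False
    #: per-site trigger outcome for this event: True/False/None (unknown)
    triggers: dict = field(default_factory=dict)

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start


def _check_series(rain: pd.Series) -> pd.Series:
    if not isinstance(rain.index, pd.DatetimeIndex):
        raise TypeError("rainfall series must have a DatetimeIndex")
    if not rain.index.is_monotonic_increasing:
        raise ValueError("rainfall timestamps are not sorted")
    if (np.asarray(rain.values, dtype=float) < 0).any():
        raise ValueError("rainfall depths must be non-negative")
    return rain.astype(float)


def classify_events(
    rain: pd.Series,
    *,
    depth_threshold_mm: float = 1.0,
    window: pd.Timedelta = pd.Timedelta(hours=8),
    min_gap: pd.Timedelta = pd.Timedelta(hours=8),
) -> list[RainEvent]:
    """Segment a regularly sampled rainfall record into rain events.

    Parameters
    ----------
    rain : pd.Series
        Depth per time step (mm), regular DatetimeIndex (typically 1 min).
    depth_threshold_mm : float
        An episode qualifies iff some sliding ``window`` within it
        accumulates strictly more than this depth.
    window, min_gap : pd.Timedelta
        Qualification window and the dry gap that separates episodes.
        A gap of exactly ``min_gap`` terminates the event.

    Notes
    -----
    "Dry" is evaluated on strictly zero recorded depth, matching the 0.1-mm
    gauge quantisation.  The 1-mm test uses a sliding window.
    """
    rain = _check_series(rain)
    if len(rain) < 2:
        return []
    step = rain.index[1] - rain.index[0]
    if not (rain.index[1:] - rain.index[:-1] == step).all():
        raise ValueError("rainfall series must be regularly sampled")

    depths = rain.to_numpy()
    wet = depths > 0
    if not wet.any():
        return []
    gap_steps = int(np.ceil(min_gap / step))
    win_steps = max(int(window / step), 1)

    # maximal wet runs, then merge runs separated by < gap_steps dry steps
    idx = np.flatnonzero(wet)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = []  # (first_wet, last_wet) inclusive
    start = idx[0]
    for b in breaks:
        runs.append((start, idx[b]))
        start = idx[b + 1]
    runs.append((start, idx[-1]))

    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 < gap_steps:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # cumulative depth over any win_steps window inside the episode
    csum = np.concatenate([[0.0], np.cumsum(depths)])
    events: list[RainEvent] = []
    for s, e in merged:
        n = e - s + 1
        seg_tot = csum[e + 1] - csum[s]
        if n <= win_steps:
            best = seg_tot
        else:
            w = csum[s + win_steps : e + 2] - csum[s : e + 2 - win_steps]
            best = float(w.max())
        if best > depth_threshold_mm:
            events.append(
                RainEvent(
                    event_id=len(events) + 1,
                    start=rain.index[s],
                    end=rain.index[e],
                    total_mm=float(seg_tot),
                )
            )
    return events


def flag_sampling_events(
    events: list[RainEvent],
    stages: dict[str, pd.Series],
    thresholds: dict[str, float],
    *,
    min_inlets_for_downstream: int = 2,
    downstream_sites: tuple[str, ...] = ("CS", "ST"),
) -> tuple[list[RainEvent], pd.DataFrame]:
    """Flag sampled events and build the per-site trigger table.

    Per inlet, a composite sample exists for an event iff its stage trigger
    threshold was exceeded during the event window.  The downstream samplers
    (collector shaft, stream) are triggered iff at least
    ``min_inlets_for_downstream`` inlets triggered.  Missing stage data over
    an event window yields ``None`` (unknown), never ``False``.

    Returns the events (copies, with ``is_sampling_event`` and ``triggers``
    filled) and a trigger table (rows: event ids; columns: sites).
    """
    inlet_sites = [s for s in thresholds if s not in downstream_sites]
    out_events: list[RainEvent] = []
    rows = {}
    for ev in events:
        trig: dict[str, bool | None] = {}
        for site in inlet_sites:
            series = stages.get(site)
            if series is None:
                trig[site] = None
                continue
            win = series.loc[ev.start : ev.end]
            if len(win) == 0 or win.isna().all():
                trig[site] = None
            else:
                trig[site] = bool((win.dropna() > thresholds[site]).any())
        n_trig = sum(1 for v in trig.values() if v is True)
        downstream = n_trig >= min_inlets_for_downstream
        for site in downstream_sites:
            trig[site] = downstream
        sampled = any(v is True for v in trig.values())
        out_events.append(replace(ev, is_sampling_event=sampled, triggers=trig))
        rows[ev.event_id] = trig
    # object dtype keeps the True/False/None (unknown) trichotomy intact
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
    table.index.name = "event_id"
    return out_events, table


def events_to_frame(events: list[RainEvent]) -> pd.DataFrame:
    """Events as a table (id, start, end, total_mm, flags)."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "total_mm": [e.total_mm for e in events],
            "is_sampling_event": [e.is_sampling_event for e in events],
            "is_snowmelt": [e.is_snowmelt for e in events],
        }
    ).set_index("event_id", drop=False)
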