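"""Stage-discharge conversion, quickflow separation and discharge ratios.

Inlet discharge is derived from weir stage through a power-law rating curve
that is calibrated only up to a limited stage (discharge ~ 0.5 L/s).  Above
the calibrated range, three extrapolation scenarios (min / mod / high) bound
the unknown true rating, and every downstream quantity is carried as an
ordered (min, mod, high) triple.  The stream quickflow component is isolated
with the Lyne-Hollick recursive digital filter at three filter parameters
(0.9, 0.925, 0.95), yielding low / moderate / high quickflow estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Triple",
    "RatingCurve",
    "DischargeTriple",
    "FastFlowTriple",
    "stage_to_discharge",
    "event_volume",
    "lyne_hollick",
    "separate_fast_flow",
    "fast_flow_series",
    "fast_flow_volumes",
    "discharge_ratios",
    "ExtrapolationWeights",
    "extrapolate_total_inlet_discharge",
]

SCENARIOS = ("min", "mod", "high")
DEFAULT_ALPHAS = (0.9, 0.925, 0.95)


@dataclass(frozen=True)
class Triple:
    """An ordered (min, mod, high) estimate triple."""

    min: float
    mod: float
    high: float

    def __post_init__(self) -> None:
        vals = (self.min, self.mod, self.high)
        finite = [v for v in vals if np.isfinite(v)]
        if any(v < 0 for v in finite):
            raise ValueError(f"triple components must be non-negative: {vals}")
        if len(finite) == 3 and not (self.min <= self.mod + 1e-12 * abs(self.mod) and self.mod <= self.high + 1e-12 * abs(self.high)):
            raise ValueError(f"triple must be ordered min <= mod <= high: {vals}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.min, self.mod, self.high)

    def scale(self, k: float) -> "Triple":
        return type(self)(self.min * k, self.mod * k, self.high * k)


class DischargeTriple(Triple):
    """Event discharge volumes (L): Q_min <= Q_mod <= Q_high."""


@dataclass(frozen=True)
class FastFlowTriple:
    """Stream quickflow volumes (L) at the three filter parameters.

    ``low``/``mod``/``high`` correspond to alpha = 0.9 / 0.925 / 0.95;
    quickflow volume is non-decreasing in alpha on storm hydrographs.
    """

    low: float
    mod: float
    high: float

    def __post_init__(self) -> None:
        if min(self.low, self.mod, self.high) < 0:
            raise ValueError("quickflow volumes must be non-negative")


@dataclass(frozen=True)
class RatingCurve:
    """Power-law weir rating ``Q = a * h**b`` with bounded calibration range.

    Defaults are anchored so that stages of 2 cm and 3 cm correspond to
    about 1.7 and 5 L/min, the trigger discharges of the monitored inlets,
    and the calibrated range ends at the stage giving 0.5 L/s (30 L/min).
    Above ``stage_limit_cm`` the three scenarios continue the power law with
    the exponent scaled by ``exponent_multipliers`` (min / mod / high).

    Units: stage in cm, discharge in L/min.
    """

    coeff: float = 0.2694
    exponent: float = 2.659
    stage_limit_cm: float | None = None
    exponent_multipliers: tuple[float, float, float] = (0.8, 1.0, 1.2)

    def __post_init__(self) -> None:
        if self.coeff <= 0 or self.exponent <= 0:
            raise ValueError("rating coefficient and exponent must be > 0")
        m = self.exponent_multipliers
        if not (0 < m[0] <= m[1] <= m[2]):
            raise ValueError("exponent multipliers must be ordered and > 0")
        if self.stage_limit_cm is None:
            # stage at the calibration limit of ~0.5 L/s
            object.__setattr__(
                self, "stage_limit_cm", float((30.0 / self.coeff) ** (1.0 / self.exponent))
            )

    def discharge(self, stage_cm, scenario: str = "mod"):
        """Discharge (L/min) for stage(s) in cm under one scenario."""
        h = np.asarray(stage_cm, dtype=float)
        if (h < 0).any():
            raise ValueError("stage must be non-negative")
        mult = self.exponent_multipliers[SCENARIOS.index(scenario)]
        lim = self.stage_limit_cm
        q_lim = self.coeff * lim**self.exponent
        with np.errstate(divide="ignore"):
            q = np.where(
                h <= lim,
                self.coeff * h**self.exponent,
                q_lim * np.where(h > 0, (np.maximum(h, lim) / lim), 1.0) ** (self.exponent * mult),
            )
        return q if q.ndim else float(q)

    def stage(self, q_l_min, scenario: str = "mod"):
        """Inverse rating: stage (cm) for discharge(s) in L/min."""
        q = np.asarray(q_l_min, dtype=float)
        if (q < 0).any():
            raise ValueError("discharge must be non-negative")
        mult = self.exponent_multipliers[SCENARIOS.index(scenario)]
        lim = self.stage_limit_cm
        q_lim = self.coeff * lim**self.exponent
        with np.errstate(divide="ignore", invalid="ignore"):
            below = (q / self.coeff) ** (1.0 / self.exponent)
            above = lim * (q / q_lim) ** (1.0 / (self.exponent * mult))
        h = np.where(q <= q_lim, below, above)
        return h if h.ndim else float(h)


def stage_to_discharge(stage: pd.Series, rating: RatingCurve) -> pd.DataFrame:
    """Convert a stage series (cm) to a discharge-scenario frame (L/min).

    Within the calibrated range the three scenario columns coincide.
    """
    if (stage.dropna() < 0).any():
        raise ValueError("negative stage encountered")
    return pd.DataFrame(
        {f"q_{sc}": rating.discharge(stage.to_numpy(), sc) for sc in SCENARIOS},
        index=stage.index,
    )


def event_volume(
    discharge: pd.DataFrame,
    start: pd.Timestamp,
    end: pd.Timestamp,
    recession_tail: pd.Timedelta = pd.Timedelta(hours=2),
) -> DischargeTriple:
    """Trapezoidal event volume (L) over [start, end + recession_tail].

    ``discharge`` must hold columns q_min/q_mod/q_high in L/min; the tail
    captures inlet recession after the last wet minute.
    """
    win = discharge.loc[start : end + recession_tail]
    if len(win) < 2:
        return DischargeTriple(0.0, 0.0, 0.0)
    t_min = (win.index - win.index[0]).total_seconds().to_numpy() / 60.0
    vols = [float(np.trapezoid(win[f"q_{sc}"].to_numpy(), t_min)) for sc in SCENARIOS]
    return DischargeTriple(*vols)


def _lh_pass(q: np.ndarray, alpha: float) -> np.ndarray:
    """One Lyne-Hollick filter pass; returns the baseflow component.

    The first quickflow value is 0 and quickflow is clamped to [0, q]
    at every step.
    """
    f = np.zeros_like(q)
    k = (1.0 + alpha) / 2.0
    for i in range(1, len(q)):
        f[i] = min(max(alpha * f[i - 1] + k * (q[i] - q[i - 1]), 0.0), q[i])
    return q - f


def lyne_hollick(q: np.ndarray, alpha: float, passes: int = 3) -> np.ndarray:
    """Multi-pass Lyne-Hollick separation; returns the quickflow series.

    The standard scheme alternates pass direction (forward, backward,
    forward); each pass filters the baseflow output of the previous one.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("discharge must be non-negative")
    b = q.copy()
    for p in range(passes):
        b = _lh_pass(b[::-1], alpha)[::-1] if p % 2 else _lh_pass(b, alpha)
    return q - b


def separate_fast_flow(discharge: pd.Series, alpha: float, passes: int = 3) -> pd.Series:
    """Quickflow series from a regularly sampled stream discharge series."""
    dt = discharge.index[1:] - discharge.index[:-1]
    if len(dt) and not (dt == dt[0]).all():
        raise ValueError("discharge series must be regularly sampled")
    return pd.Series(lyne_hollick(discharge.to_numpy(), alpha, passes), index=discharge.index)


def fast_flow_series(
    discharge: pd.Series, alpha: float, agg_minutes: int = 15
) -> pd.Series:
    """Quickflow series, optionally on a time-aggregated record.

    The filter parameters (0.9/0.925/0.95) describe recession at the scale
    of tens of minutes to hours, so a 1-min record is averaged to
    ``agg_minutes`` before filtering; storm recessions then fall on the
    quickflow side of the separation.
    """
    s = discharge.resample(f"{agg_minutes}min").mean() if agg_minutes > 1 else discharge
    return separate_fast_flow(s, alpha)


def _window_volume(series: pd.Series, start, end) -> float:
    win = series.loc[start:end]
    if len(win) < 2:
        return 0.0
    t_min = (win.index - win.index[0]).total_seconds().to_numpy() / 60.0
    return float(np.trapezoid(win.to_numpy(), t_min))


def fast_flow_volumes(
    discharge: pd.Series,
    start: pd.Timestamp,
    end: pd.Timestamp,
    alphas: tuple[float, float, float] = DEFAULT_ALPHAS,
    recession_tail: pd.Timedelta = pd.Timedelta(hours=2),
    agg_minutes: int = 15,
    precomputed: dict[float, pd.Series] | None = None,
) -> FastFlowTriple:
    """Event quickflow volumes (L) at the three filter parameters.

    The filter runs over the full record (so spin-up does not bias single
    events), then integrates over the event window plus recession tail.
    ``precomputed`` may hold quickflow series per alpha to avoid
    re-filtering the record for every event.
    """
    vols = []
    for a in alphas:
        fast = precomputed[a] if precomputed else fast_flow_series(discharge, a, agg_minutes)
        vols.append(_window_volume(fast, start, end + recession_tail))
    return FastFlowTriple(*vols)


@dataclass
class RatioTriple:
    """A (min, mod, high) ratio whose components may be undefined."""

    min: float
    mod: float
    high: float
    defined: tuple[bool, bool, bool] = (True, True, True)


def discharge_ratios(
    inlet_triples: list[DischargeTriple],
    stream_volume: float,
    fast: FastFlowTriple | None = None,
) -> tuple[RatioTriple, RatioTriple | None]:
    """Inlet/stream discharge ratios r_Q and (optionally) r_Q,fast.

    r_Q,x = sum_i Q_i,x / Q_stream for each scenario x.  The quickflow
    ratio pairs conservatively: inlet minimum against the *high* quickflow
    estimate and inlet high against the *low* one, so the triple bounds the
    ratio from both sides.  A zero denominator flags the component undefined.
    """
    sums = [sum(t.as_tuple()[j] for t in inlet_triples) for j in range(3)]

    def _ratio(nums, dens):
        vals, flags = [], []
        for n, d in zip(nums, dens):
            if d > 0:
                vals.append(n / d)
                flags.append(True)
            else:
                vals.append(np.nan)
                flags.append(False)
        return RatioTriple(vals[0], vals[1], vals[2], tuple(flags))

    r_q = _ratio(sums, [stream_volume] * 3)
    r_fast = None
    if fast is not None:
        r_fast = _ratio(sums, [fast.high, fast.mod, fast.low])
    return r_q, r_fast


@dataclass(frozen=True)
class ExtrapolationWeights:
    """Catchment-vs-sampled weights for the three extrapolation methods.

    Areas in m²; the sampled quantities refer to the instrumented inlets
    only, the totals to all inlets in the catchment.
    """

    road_area_sampled: float
    road_area_total: float
    agri_area_sampled: float
    agri_area_total: float
    n_inlets_sampled: int
    n_inlets_total: int

    def factors(self) -> dict[str, float | None]:
        """Scale factor per method; ``None`` marks an unavailable method."""
        out: dict[str, float | None] = {}
        out["road_area"] = (
            self.road_area_total / self.road_area_sampled if self.road_area_sampled > 0 else None
        )
        out["agri_area"] = (
            self.agri_area_total / self.agri_area_sampled if self.agri_area_sampled > 0 else None
        )
        out["count"] = (
            self.n_inlets_total / self.n_inlets_sampled if self.n_inlets_sampled > 0 else None
        )
        return out


def extrapolate_total_inlet_discharge(
    measured: list[DischargeTriple], weights: ExtrapolationWeights
) -> dict[str, DischargeTriple | None]:
    """Total inlet discharge Q_inl,tot per extrapolation method.

    Each method scales the measured volume sum by total/sampled weight
    (connected road area, connected agricultural area, or inlet count).
    Methods with zero sampled weight are reported as ``None``.
    """
    sums = [sum(t.as_tuple()[j] for t in measured) for j in range(3)]
    out: dict[str, DischargeTriple | None] = {}
    for method, k in weights.factors().items():
        out[method] = None if k is None else DischargeTriple(*(s * k for s in sums))
    return out
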