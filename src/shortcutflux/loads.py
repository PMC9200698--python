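"""Censored event loads, inlet/stream load ratios and their aggregation.

The analytical limit of quantification (LOQ) interval-censors every
concentration below it: the true value lies in [0, LOQ].  Event loads are
therefore carried as ordered (min, mod, high) triples that combine the
discharge-scenario triple with the censoring bounds,

    f_min = Q_min * c_min,   f_mod = Q_mod * c_min,   f_high = Q_high * c_max,

with c_min = 0 and c_max = LOQ for censored values (c_min = c_max = c
otherwise).  Load ratios between the inlet sum and the stream pair the
bounds conservatively (inlet min over stream high, etc.), and two aggregate
means summarise all (event, substance) cells: the mean of per-cell ratios
and the ratio of load sums.

Units are strict throughout: volumes in L, concentrations in ng/L, loads
in ng.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hydrology import DischargeTriple, ExtrapolationWeights, RatioTriple, Triple

__all__ = [
    "CensoredConcentration",
    "LoadTriple",
    "LoadRatioTriple",
    "event_load",
    "load_ratio",
    "aggregate_ratios",
    "uncertainty_attribution",
    "extrapolate_catchment_load_ratio",
    "LoadCell",
]


@dataclass(frozen=True)
class CensoredConcentration:
    """A concentration measurement with its censoring state.

    ``value`` is the reported concentration (ng/L); for censored samples it
    is ignored in favour of the [0, LOQ] interval.
    """

    value: float
    loq: float
    censored: bool

    def __post_init__(self) -> None:
        if self.loq <= 0:
            raise ValueError("LOQ must be > 0")
        if not self.censored and self.value < 0:
            raise ValueError("concentration must be non-negative")

    @classmethod
    def from_measurement(cls, value: float, loq: float) -> "CensoredConcentration":
        """Censor iff the value lies below the substance LOQ."""
        return cls(value=value, loq=loq, censored=value < loq)

    @property
    def c_min(self) -> float:
        return 0.0 if self.censored else self.value

    @property
    def c_max(self) -> float:
        return self.loq if self.censored else self.value


class LoadTriple(Triple):
    """Event load estimates (ng): f_min <= f_mod <= f_high."""


class LoadRatioTriple(RatioTriple):
    """Inlet/stream load ratio triple; components may be undefined."""


def event_load(discharge: DischargeTriple, conc: CensoredConcentration) -> LoadTriple:
    """Min/mod/high load (ng) from a discharge triple (L) and concentration."""
    return LoadTriple(
        discharge.min * conc.c_min,
        discharge.mod * conc.c_min,
        discharge.high * conc.c_max,
    )


def load_ratio(inlet_loads: list[LoadTriple], stream_load: LoadTriple) -> LoadRatioTriple:
    """Ratio of the inlet load sum to the stream load, bounds cross-paired.

    r_min divides the inlet minimum sum by the stream *high* load and
    r_high the inlet high sum by the stream *min* load, so the interval
    is conservative.  Zero denominators flag the component undefined
    (a fully censored stream sample makes r_high undefined).
    """
    sums = [sum(t.as_tuple()[j] for t in inlet_loads) for j in range(3)]
    dens = [stream_load.high, stream_load.mod, stream_load.min]
    vals, flags = [], []
    for n, d in zip(sums, dens):
        if d > 0:
            vals.append(n / d)
            flags.append(True)
        else:
            vals.append(np.nan)
            flags.append(False)
    return LoadRatioTriple(vals[0], vals[1], vals[2], tuple(flags))


@dataclass
class LoadCell:
    """All load inputs for one (event, substance) cell."""

    event_id: int
    substance: str
    inlet_discharge: list[DischargeTriple]
    inlet_conc: list[CensoredConcentration]
    stream_discharge: DischargeTriple
    stream_conc: CensoredConcentration

    def inlet_loads(self) -> list[LoadTriple]:
        return [event_load(q, c) for q, c in zip(self.inlet_discharge, self.inlet_conc)]

    def stream_load(self) -> LoadTriple:
        return event_load(self.stream_discharge, self.stream_conc)

    def ratio(self) -> LoadRatioTriple:
        return load_ratio(self.inlet_loads(), self.stream_load())


@dataclass
class AggregateRatios:
    """The two aggregate load-ratio summaries.

    ``by_substance`` is the arithmetic mean of the per-cell ratio triples
    over all fully defined cells; ``by_sum`` is the ratio of the inlet load
    sum to the stream load sum with the same conservative pairing.
    """

    by_substance: RatioTriple
    by_sum: RatioTriple
    n_cells: int
    n_excluded: int


def aggregate_ratios(cells: list[LoadCell], inlet_scale: float = 1.0) -> AggregateRatios:
    """Aggregate per-cell load ratios over (event, substance) cells.

    Cells whose ratio has any undefined component (fully censored stream
    load) are excluded from the per-cell mean and counted in
    ``n_excluded``.  ``inlet_scale`` multiplies all inlet loads first
    (used by the catchment extrapolation).

    Raises ``ValueError`` on an empty cell set.
    """
    if not cells:
        raise ValueError("empty cell set")
    ratios = []
    inl_sums = np.zeros(3)
    str_sums = np.zeros(3)
    n_excluded = 0
    for cell in cells:
        inl = [t.scale(inlet_scale) for t in cell.inlet_loads()]
        stream = cell.stream_load()
        r = load_ratio(inl, stream)
        if all(r.defined):
            ratios.append(r)
        else:
            n_excluded += 1
        for j in range(3):
            inl_sums[j] += sum(t.as_tuple()[j] for t in inl)
            str_sums[j] += stream.as_tuple()[j]
    if ratios:
        mean = RatioTriple(
            float(np.mean([r.min for r in ratios])),
            float(np.mean([r.mod for r in ratios])),
            float(np.mean([r.high for r in ratios])),
        )
    else:
        mean = RatioTriple(np.nan, np.nan, np.nan, (False, False, False))
    dens = [str_sums[2], str_sums[1], str_sums[0]]  # cross-pairing
    vals, flags = [], []
    for n, d in zip(inl_sums, dens):
        if d > 0:
            vals.append(float(n / d))
            flags.append(True)
        else:
            vals.append(np.nan)
            flags.append(False)
    by_sum = RatioTriple(vals[0], vals[1], vals[2], tuple(flags))
    return AggregateRatios(mean, by_sum, len(ratios), n_excluded)


def _hold_loq(cell: LoadCell) -> LoadCell:
    """Collapse the censoring interval to its lower (moderate) bound."""

    def fix(c: CensoredConcentration) -> CensoredConcentration:
        return CensoredConcentration(value=c.c_min, loq=c.loq, censored=False)

    return LoadCell(
        cell.event_id,
        cell.substance,
        cell.inlet_discharge,
        [fix(c) for c in cell.inlet_conc],
        cell.stream_discharge,
        fix(cell.stream_conc),
    )


def _hold_discharge(cell: LoadCell) -> LoadCell:
    """Collapse every discharge triple to its moderate scenario."""

    def fix(q: DischargeTriple) -> DischargeTriple:
        return DischargeTriple(q.mod, q.mod, q.mod)

    return LoadCell(
        cell.event_id,
        cell.substance,
        [fix(q) for q in cell.inlet_discharge],
        cell.inlet_conc,
        fix(cell.stream_discharge),
        cell.stream_conc,
    )


def uncertainty_attribution(cells: list[LoadCell]) -> dict[str, dict[str, float | None]]:
    """Share of the aggregate max-min spread due to LOQ vs discharge.

    For each aggregate, the partial spread is recomputed holding one
    uncertainty source at its moderate value (discharge at Q_mod isolates
    the LOQ share; uncensored concentrations at c_min isolate the
    discharge share).  Shares are partial spread / total spread; a zero
    total spread yields ``None``.
    """
    full = aggregate_ratios(cells)
    loq_only = aggregate_ratios([_hold_discharge(c) for c in cells])
    q_only = aggregate_ratios([_hold_loq(c) for c in cells])

    out: dict[str, dict[str, float | None]] = {}
    for name in ("by_substance", "by_sum"):
        tot = getattr(full, name)
        spread = tot.high - tot.min
        if not np.isfinite(spread) or spread <= 0:
            out[name] = {"loq_share": None, "discharge_share": None}
            continue
        loq = getattr(loq_only, name)
        q = getattr(q_only, name)
        out[name] = {
            "loq_share": float((loq.high - loq.min) / spread),
            "discharge_share": float((q.high - q.min) / spread),
        }
    return out


def extrapolate_catchment_load_ratio(
    cells: list[LoadCell], weights: ExtrapolationWeights
) -> dict[str, AggregateRatios | None]:
    """Catchment-scale load ratios: inlet loads scaled per method first.

    Returns one aggregate pair per extrapolation method (road area,
    agricultural area, inlet count); unavailable methods are ``None``.
    """
    out: dict[str, AggregateRatios | None] = {}
    for method, k in weights.factors().items():
        out[method] = None if k is None else aggregate_ratios(cells, inlet_scale=k)
    return out
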