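"""Pipeline configuration: validated on load, unknown keys rejected."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Settings for one end-to-end pipeline run.

    With ``data_dir`` unset the pipeline generates the synthetic study
    system from ``seed``; otherwise the serialised layers in ``data_dir``
    are read.  All stage parameters default to the study conditions.
    """

    seed: int = 0
    data_dir: str | None = None

    # event classification
    event_depth_mm: float = 1.0
    event_window_h: float = 8.0
    event_gap_h: float = 8.0

    # rating / hydrology
    rating_coeff: float = 0.2694
    rating_exponent: float = 2.659
    rating_multipliers: tuple[float, float, float] = (0.8, 1.0, 1.2)
    alphas: tuple[float, float, float] = (0.9, 0.925, 0.95)
    filter_agg_min: int = 15
    recession_tail_min: int = 120
    large_event_mm: float = 10.0

    # connectivity
    road_carving_depth: float = 0.15
    sink_fill_depth: float = 0.10
    mc_runs: int = 100
    run_monte_carlo: bool = False
    drift_radius_m: float = 100.0

    # loads
    n_load_events: int = 3
    censored_substitution: str = "loq"

    # concentration model
    run_lmm: bool = True
    collinearity_threshold: float = 0.7

    # generator scale (used when data_dir is unset)
    grid_nrows: int = 150
    grid_ncols: int = 250
    n_inlets: int = 158
    n_substances: int = 12
    noise_sigma_log10: float = 0.2
    censoring: bool = True
    exact_discharge: bool = False

    def __post_init__(self) -> None:
        if self.censored_substitution not in ("loq", "half", "zero"):
            raise ValueError("censored_substitution must be loq|half|zero")
        if self.n_load_events < 1:
            raise ValueError("n_load_events must be >= 1")
        if not 0 < self.alphas[0] <= self.alphas[1] <= self.alphas[2] < 1:
            raise ValueError("alphas must be ordered within (0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        for key in ("rating_multipliers", "alphas"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    def hash(self) -> str:
        """Stable content hash of the configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
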