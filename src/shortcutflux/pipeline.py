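"""End-to-end pipeline: from raw layers to ratios, attributions and the model.

Stage order mirrors the field study's analysis: event classification and
sampling triggers, surface-runoff connectivity, stage-to-discharge with the
three rating scenarios and quickflow separation, transport-pathway
attribution, censored load ratios with uncertainty attribution and
catchment-scale extrapolation, and finally the random-intercept
concentration model.  Every run emits a machine-readable manifest (package
version, seed, config hash, per-stage row counts) so each number in the
report is traceable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import assign_categories, category_concentration_summary
from .config import PipelineConfig
from .connectivity import (
    ConnectivityParams,
    build_exposure_table,
    condition_dem,
    delineate_contributing_areas,
    flow_directions_dinf,
    monte_carlo_connectivity,
)
from .events import classify_events, events_to_frame, flag_sampling_events
from .hydrology import (
    DischargeTriple,
    ExtrapolationWeights,
    RatingCurve,
    discharge_ratios,
    event_volume,
    extrapolate_total_inlet_discharge,
    fast_flow_series,
    fast_flow_volumes,
    stage_to_discharge,
)
from .lmm import build_model_frame, drop_collinear, fit_lmm
from .loads import (
    CensoredConcentration,
    LoadCell,
    aggregate_ratios,
    extrapolate_catchment_load_ratio,
    uncertainty_attribution,
)
from .substances import default_substances

__all__ = ["Dataset", "ReportBundle", "build_synthetic_dataset", "read_layers", "run_pipeline"]

INLET_ALIASES = ("I1", "I2", "I3", "I4")
DEFAULT_THRESHOLDS = {"I1": 3.0, "I2": 3.0, "I3": 2.0, "I4": 2.0}


@dataclass
class Dataset:
    """The in-memory study dataset consumed by the pipeline."""

    catchment: object
    rainfall: pd.Series
    stages: dict[str, pd.Series]
    stream_q: pd.Series
    samples: pd.DataFrame
    substances: list
    applications: list
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    truth: object | None = None


def build_synthetic_dataset(config: PipelineConfig) -> Dataset:
    """Generate the synthetic study system for a pipeline configuration."""
    from .synthetic import (
        ApplicationConfig,
        CatchmentConfig,
        ObservationConfig,
        RainfallConfig,
        generate_applications,
        generate_catchment,
        generate_rainfall,
        simulate_observations,
    )

    cat_cfg = CatchmentConfig(
        nrows=config.grid_nrows, ncols=config.grid_ncols, n_inlets=config.n_inlets
    )
    catchment = generate_catchment(cat_cfg, seed=config.seed)
    rainfall = generate_rainfall(RainfallConfig(), seed=config.seed)
    substances = default_substances(config.n_substances)
    applications = generate_applications(catchment, substances, ApplicationConfig(), seed=config.seed)
    obs_cfg = ObservationConfig(
        rating=_rating(config),
        connectivity=ConnectivityParams(
            road_carving_depth=config.road_carving_depth, sink_fill_depth=config.sink_fill_depth
        ),
        noise_sigma_log10=config.noise_sigma_log10,
        censoring=config.censoring,
        background_prob=0.0 if config.exact_discharge else 0.01,
    )
    obs = simulate_observations(catchment, rainfall, applications, obs_cfg, seed=config.seed, substances=substances)
    return Dataset(
        catchment=catchment,
        rainfall=rainfall,
        stages=obs.stage_cm,
        stream_q=obs.stream_q_l_min,
        samples=obs.samples,
        substances=substances,
        applications=applications,
        truth=obs.truth,
    )


def write_dataset(ds: Dataset, out_dir) -> None:
    """Serialise every tabular and spatial layer of a dataset."""
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_catchment(ds.catchment, out)
    io.write_rainfall(ds.rainfall, out / "rainfall.csv")
    io.write_stages(ds.stages, out / "stages.csv")
    io.write_series(ds.stream_q, out / "stream_discharge.csv", "q_l_min")
    ds.samples.to_csv(out / "samples.csv", index=False)
    io.write_substances(ds.substances, out / "substances.csv")
    io.write_applications(ds.applications, out / "applications.csv")
    (out / "thresholds.json").write_text(json.dumps(ds.thresholds, indent=1))


def read_layers(config: PipelineConfig) -> Dataset:
    """Read and validate all layers from ``config.data_dir``.

    Schema violations are collected exhaustively and raised as one
    ``SchemaError`` listing every problem.
    """
    from . import io

    src = Path(config.data_dir)
    errors: list[str] = []
    rainfall = stages = stream_q = samples = substances = applications = catchment = None
    try:
        rainfall = io.read_rainfall(src / "rainfall.csv")
    except io.SchemaError as e:
        errors.extend(e.errors)
    except Exception as e:  # noqa: BLE001
        errors.append(f"rainfall.csv: {e}")
    try:
        catchment = io.read_catchment(src)
    except Exception as e:  # noqa: BLE001
        errors.append(f"catchment layers: {e}")
    try:
        stages = io.read_stages(src / "stages.csv")
    except Exception as e:  # noqa: BLE001
        errors.append(f"stages.csv: {e}")
    try:
        stream_q = io.read_series(src / "stream_discharge.csv", "q_l_min")
    except Exception as e:  # noqa: BLE001
        errors.append(f"stream_discharge.csv: {e}")
    try:
        substances = io.read_substances(src / "substances.csv")
    except Exception as e:  # noqa: BLE001
        errors.append(f"substances.csv: {e}")
    try:
        applications = io.read_applications(src / "applications.csv")
    except Exception as e:  # noqa: BLE001
        errors.append(f"applications.csv: {e}")
    try:
        samples = pd.read_csv(src / "samples.csv")
        if substances is not None:
            errors.extend(io.validate_samples(samples, substances))
    except Exception as e:  # noqa: BLE001
        errors.append(f"samples.csv: {e}")
    thresholds = dict(DEFAULT_THRESHOLDS)
    tpath = src / "thresholds.json"
    if tpath.exists():
        thresholds = json.loads(tpath.read_text())
    if errors:
        raise io.SchemaError(errors)
    return Dataset(
        catchment=catchment,
        rainfall=rainfall,
        stages=stages,
        stream_q=stream_q,
        samples=samples,
        substances=substances,
        applications=applications,
        thresholds=thresholds,
    )


def _rating(config: PipelineConfig) -> RatingCurve:
    mult = (1.0, 1.0, 1.0) if config.exact_discharge else tuple(config.rating_multipliers)
    return RatingCurve(
        coeff=config.rating_coeff, exponent=config.rating_exponent, exponent_multipliers=mult
    )


@dataclass
class ReportBundle:
    """All pipeline outputs plus the run manifest."""

    events: pd.DataFrame
    trigger_table: pd.DataFrame
    connectivity: dict
    mc_summary: pd.DataFrame | None
    discharge_ratios: pd.DataFrame
    mean_r_q_fast_large: dict
    discharge_extrapolation: dict
    site_summary: pd.DataFrame
    category_summary: pd.DataFrame
    load_ratio_table: pd.DataFrame
    aggregates: object | None
    uncertainty: dict | None
    catchment_load_extrapolation: dict | None
    lmm_fit: object | None
    lmm_report: object | None
    collinearity: dict | None
    manifest: dict
    exposure: pd.DataFrame | None = None
    ca_map: object | None = None
    load_cells: list | None = None
    categories: pd.Series | None = None
    load_event_ids: list | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(out / "events.csv", index=False)
        self.trigger_table.to_csv(out / "triggers.csv")
        self.discharge_ratios.to_csv(out / "discharge_ratios.csv", index=False)
        self.site_summary.to_csv(out / "site_summary.csv", index=False)
        self.category_summary.to_csv(out / "category_summary.csv", index=False)
        self.load_ratio_table.to_csv(out / "load_ratios.csv", index=False)
        if self.mc_summary is not None:
            self.mc_summary.to_csv(out / "mc_connectivity.csv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        scalars = {
            "connectivity": self.connectivity,
            "mean_r_q_fast_large": self.mean_r_q_fast_large,
            "uncertainty": self.uncertainty,
        }
        (out / "summary.json").write_text(json.dumps(scalars, indent=1, sort_keys=True, default=float))


def _site_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-site concentration overview with LOQ-replacement mean bounds.

    The lower mean bound replaces censored concentrations by 0, the upper
    by the LOQ.
    """
    rows = []
    for site, g in samples.groupby("site"):
        detected = g.loc[~g["censored"]]
        lower = np.where(g["censored"], 0.0, g["value_ng_l"]).mean() if len(g) else np.nan
        upper = np.where(g["censored"], g["loq_ng_l"], g["value_ng_l"]).mean() if len(g) else np.nan
        if len(detected):
            top = detected.loc[detected["value_ng_l"].idxmax()]
            top_sub, top_val = top["substance"], float(top["value_ng_l"])
        else:
            top_sub, top_val = "", np.nan
        rows.append(
            {
                "site": site,
                "n_substances_above_loq": detected["substance"].nunique(),
                "mean_conc_lower_ng_l": float(lower),
                "mean_conc_upper_ng_l": float(upper),
                "max_conc_ng_l": top_val,
                "top_substance": top_sub,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, dataset: Dataset | None = None) -> ReportBundle:
    """Execute the full analysis and return the report bundle.

    ``dataset`` overrides the input source (otherwise synthetic generation
    or ``config.data_dir`` is used).  Raises on empty inputs.
    """
    ds = dataset or (read_layers(config) if config.data_dir else build_synthetic_dataset(config))
    if not ds.substances:
        raise ValueError("no substances configured: empty input")
    catchment = ds.catchment

    # ---- events & triggers ----
    events = classify_events(
        ds.rainfall,
        depth_threshold_mm=config.event_depth_mm,
        window=pd.Timedelta(hours=config.event_window_h),
        min_gap=pd.Timedelta(hours=config.event_gap_h),
    )
    events, trigger_table = flag_sampling_events(events, ds.stages, ds.thresholds)
    events_by_id = {e.event_id: e for e in events}
    events_df = events_to_frame(events)

    # ---- connectivity ----
    params = ConnectivityParams(
        road_carving_depth=config.road_carving_depth, sink_fill_depth=config.sink_fill_depth
    )
    cond = condition_dem(catchment.dem, params, catchment.road_mask)
    fd = flow_directions_dinf(cond, catchment.cell_size)
    ca = delineate_contributing_areas(
        cond,
        fd,
        catchment.destinations(),
        catchment.cell_size,
        agri_mask=catchment.agri_mask,
        road_mask=catchment.road_mask,
    )
    sites = catchment.sites()
    exposure, rejected_apps = build_exposure_table(
        ca, catchment.plots, ds.applications, catchment.road_mask, sites,
        drift_radius_m=config.drift_radius_m,
    )
    inlet_ids = [i.inlet_id for i in catchment.inlets]
    sampled_ids = list(catchment.sampled_aliases.values())
    agri_tot = sum(ca.agri_area.values())
    agri_inlet = sum(ca.agri_area[i] for i in inlet_ids)
    connectivity_summary = {
        "agri_area_m2": agri_tot,
        "frac_agri_via_inlet": agri_inlet / agri_tot if agri_tot else np.nan,
        "frac_agri_direct_stream": ca.agri_area.get("stream", 0.0) / agri_tot if agri_tot else np.nan,
        "frac_agri_sink": ca.agri_area.get("sink", 0.0) / agri_tot if agri_tot else np.nan,
        "frac_sampled_agri_of_inlet_agri": (
            sum(ca.agri_area[i] for i in sampled_ids) / agri_inlet if agri_inlet else np.nan
        ),
        "frac_sampled_road_of_inlet_road": (
            sum(ca.road_area[i] for i in sampled_ids)
            / sum(ca.road_area[i] for i in inlet_ids)
            if sum(ca.road_area[i] for i in inlet_ids)
            else np.nan
        ),
        "rejected_applications": len(rejected_apps),
    }
    weights = ExtrapolationWeights(
        road_area_sampled=sum(ca.road_area[i] for i in sampled_ids),
        road_area_total=sum(ca.road_area[i] for i in inlet_ids),
        agri_area_sampled=sum(ca.agri_area[i] for i in sampled_ids),
        agri_area_total=agri_inlet,
        n_inlets_sampled=len(sampled_ids),
        n_inlets_total=len(inlet_ids),
    )

    mc_summary = None
    if config.run_monte_carlo:
        _, mc_summary = monte_carlo_connectivity(
            catchment.dem,
            params,
            catchment.destinations(),
            roads_mask=catchment.road_mask,
            agri_mask=catchment.agri_mask,
            n_runs=config.mc_runs,
            seed=config.seed,
            cell_size=catchment.cell_size,
        )

    # ---- hydrology ----
    rating = _rating(config)
    tail = pd.Timedelta(minutes=config.recession_tail_min)
    inlet_q = {alias: stage_to_discharge(ds.stages[alias], rating) for alias in INLET_ALIASES if alias in ds.stages}
    inlet_triples: dict[tuple[str, int], DischargeTriple] = {}
    ratio_rows = []
    stream_vol: dict[int, float] = {}
    fast_by_alpha = {
        a: fast_flow_series(ds.stream_q, a, config.filter_agg_min) for a in config.alphas
    }
    for ev in events:
        triples = []
        for alias in INLET_ALIASES:
            t = event_volume(inlet_q[alias], ev.start, ev.end, tail)
            inlet_triples[(alias, ev.event_id)] = t
            triples.append(t)
        win = ds.stream_q.loc[ev.start : ev.end + tail]
        if len(win) >= 2:
            t_min = (win.index - win.index[0]).total_seconds().to_numpy() / 60.0
            v_stream = float(np.trapezoid(win.to_numpy(), t_min))
        else:
            v_stream = 0.0
        stream_vol[ev.event_id] = v_stream
        fast = fast_flow_volumes(
            ds.stream_q, ev.start, ev.end, tuple(config.alphas), tail, precomputed=fast_by_alpha
        )
        r_q, r_fast = discharge_ratios(triples, v_stream, fast)
        ratio_rows.append(
            {
                "event_id": ev.event_id,
                "total_mm": ev.total_mm,
                "is_snowmelt": ev.is_snowmelt,
                "q_inlets_mod_l": sum(t.mod for t in triples),
                "q_stream_l": v_stream,
                "q_fast_mod_l": fast.mod,
                "r_q_min": r_q.min,
                "r_q_mod": r_q.mod,
                "r_q_high": r_q.high,
                "r_q_fast_min": r_fast.min,
                "r_q_fast_mod": r_fast.mod,
                "r_q_fast_high": r_fast.high,
            }
        )
    ratios_df = pd.DataFrame(ratio_rows)
    large = ratios_df[
        (ratios_df["total_mm"] > config.large_event_mm) & (~ratios_df["is_snowmelt"])
    ]
    mean_r_q_fast_large = {
        "n_events": int(len(large)),
        "r_q_fast_min": float(large["r_q_fast_min"].mean()) if len(large) else np.nan,
        "r_q_fast_mod": float(large["r_q_fast_mod"].mean()) if len(large) else np.nan,
        "r_q_fast_high": float(large["r_q_fast_high"].mean()) if len(large) else np.nan,
        "r_q_mod": float(large["r_q_mod"].mean()) if len(large) else np.nan,
    }
    all_triples = [
        inlet_triples[(alias, ev.event_id)] for ev in events for alias in INLET_ALIASES
    ]
    q_extrap = extrapolate_total_inlet_discharge(all_triples, weights)
    discharge_extrapolation = {
        m: (None if t is None else {"min": t.min, "mod": t.mod, "high": t.high})
        for m, t in q_extrap.items()
    }

    # ---- attribution ----
    samples = ds.samples.copy()
    categories = assign_categories(samples, events_by_id, exposure, ds.applications)
    samples["category"] = categories
    kind_of = {s.name: s.kind for s in sites}
    samples["group"] = samples["site"].map(lambda s: kind_of.get(s, "inlet"))
    category_summary = category_concentration_summary(samples)
    site_summary = _site_summary(samples)

    # ---- loads (events with full downstream sampling, top concentration sums) ----
    cs_ok = trigger_table.index[
        (trigger_table.get("CS", pd.Series(dtype=bool)) == True)  # noqa: E712
    ].tolist()
    inlet_samples = samples[samples["group"] == "inlet"]
    conc_for_rank = np.where(
        inlet_samples["censored"], inlet_samples["loq_ng_l"], inlet_samples["value_ng_l"]
    )
    rank = (
        pd.DataFrame({"event_id": inlet_samples["event_id"], "conc": conc_for_rank})
        .groupby("event_id")["conc"]
        .sum()
    )
    candidates = [e for e in rank.sort_values(ascending=False).index if e in cs_ok]
    load_event_ids = sorted(candidates[: config.n_load_events])

    loq_by_sub = {s.name: s.loq_ng_l for s in ds.substances}
    sub_names = [s.name for s in ds.substances]
    sample_idx = samples.set_index(["site", "event_id", "substance"])

    def conc_of(site: str, event_id: int, sub: str) -> CensoredConcentration:
        try:
            row = sample_idx.loc[(site, event_id, sub)]
        except KeyError:
            return CensoredConcentration(value=np.nan, loq=loq_by_sub[sub], censored=True)
        if isinstance(row, pd.DataFrame):
            comp = row[row["sample_type"] == "composite"]
            row = (comp.iloc[0] if len(comp) else row.iloc[0])
        if bool(row["censored"]):
            return CensoredConcentration(value=np.nan, loq=float(row["loq_ng_l"]), censored=True)
        return CensoredConcentration(
            value=float(row["value_ng_l"]), loq=float(row["loq_ng_l"]), censored=False
        )

    cells: list[LoadCell] = []
    cell_rows = []
    for eid in load_event_ids:
        q_inl = [inlet_triples[(alias, eid)] for alias in INLET_ALIASES]
        vs = stream_vol[eid]
        q_stream = DischargeTriple(vs, vs, vs)  # stream discharge uncertainty neglected
        for sub in sub_names:
            cell = LoadCell(
                event_id=eid,
                substance=sub,
                inlet_discharge=q_inl,
                inlet_conc=[conc_of(alias, eid, sub) for alias in INLET_ALIASES],
                stream_discharge=q_stream,
                stream_conc=conc_of("ST", eid, sub),
            )
            cells.append(cell)
            r = cell.ratio()
            cell_rows.append(
                {
                    "event_id": eid,
                    "substance": sub,
                    "r_f_min": r.min,
                    "r_f_mod": r.mod,
                    "r_f_high": r.high,
                    "defined": all(r.defined),
                }
            )
    load_ratio_table = pd.DataFrame(
        cell_rows, columns=["event_id", "substance", "r_f_min", "r_f_mod", "r_f_high", "defined"]
    )
    aggregates = uncertainty = catchment_load = None
    if cells:
        aggregates = aggregate_ratios(cells)
        uncertainty = uncertainty_attribution(cells)
        catchment_load = extrapolate_catchment_load_ratio(cells, weights)

    # ---- concentration model ----
    lmm_fit = lmm_report = collinearity = None
    if config.run_lmm:
        q_mod_rows = [
            {"site": alias, "event_id": ev.event_id, "q_mod_l": inlet_triples[(alias, ev.event_id)].mod}
            for ev in events
            for alias in INLET_ALIASES
        ]
        frame, lmm_report = build_model_frame(
            inlet_samples,
            exposure,
            ds.applications,
            ds.substances,
            pd.DataFrame(q_mod_rows),
            categories.loc[inlet_samples.index],
            events_by_id,
            inlet_sites=list(INLET_ALIASES),
            censored_substitution="loq" if config.censored_substitution != "half" else "half",
        )
        if len(frame) >= 10 and frame["inlet"].nunique() >= 2:
            try:
                frame, collinearity = drop_collinear(frame, threshold=config.collinearity_threshold)
                lmm_fit = fit_lmm(frame)
            except np.linalg.LinAlgError:
                # degenerate design (e.g. constant covariates on noise-free
                # runs): report no fit rather than abort the pipeline
                lmm_fit = None

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_events": len(events),
        "n_sampling_events": int(sum(e.is_sampling_event for e in events)),
        "n_samples": int(len(samples)),
        "n_load_cells": len(cells),
        "n_load_cells_excluded": aggregates.n_excluded if aggregates else 0,
        "load_event_ids": load_event_ids,
        "lmm_rows": (lmm_fit.n_rows if lmm_fit else 0),
    }

    return ReportBundle(
        events=events_df,
        trigger_table=trigger_table,
        connectivity=connectivity_summary,
        mc_summary=mc_summary,
        discharge_ratios=ratios_df,
        mean_r_q_fast_large=mean_r_q_fast_large,
        discharge_extrapolation=discharge_extrapolation,
        site_summary=site_summary,
        category_summary=category_summary,
        load_ratio_table=load_ratio_table,
        aggregates=aggregates,
        uncertainty=uncertainty,
        catchment_load_extrapolation=catchment_load,
        lmm_fit=lmm_fit,
        lmm_report=lmm_report,
        collinearity=collinearity,
        manifest=manifest,
        exposure=exposure,
        ca_map=ca,
        load_cells=cells,
        categories=categories,
        load_event_ids=load_event_ids,
    )
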