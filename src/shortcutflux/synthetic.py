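"""Synthetic study system: catchment, weather, applications and observations.

The generator emulates a small arable catchment of the Swiss Plateau drained
by storm drainage inlets along its farm-track network: a gently sloping DEM
(mean slope 5%, the study value) with correlated micro-relief, 158 inlets on
the road network, field plots with plot-resolved pesticide applications, a
4.5-month spring/summer observation window with 1-min rainfall, and
event-based composite sampling at four instrumented inlets, a collector
shaft and the stream.

Every stochastic mechanism records its ground truth (true per-site loads and
volumes, true transport-category labels, the contributing-area map used to
route mass), so the downstream analysis stages can be validated against
known answers.  The spatial footprint defaults to ~0.15 km² — a scaled
version of the study catchment that preserves per-object densities — while
inlet count, activation thresholds (1.3–3.6 mm), LOQ (20 ng/L) and substance
property ranges match the study conditions.

All random draws descend from a single seed via ``numpy.random.SeedSequence``
spawning, so identical (config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, box

from .attribution import assign_category
from .connectivity import (
    ConnectivityParams,
    build_exposure_table,
    condition_dem,
    delineate_contributing_areas,
    flow_directions_dinf,
)
from .events import RainEvent, classify_events, flag_sampling_events
from .geometry import Inlet, Plot, Road, Site, cell_center, rasterize_polygon
from .hydrology import RatingCurve
from .substances import SubstanceProperties, default_substances

__all__ = [
    "CatchmentConfig",
    "RainfallConfig",
    "ApplicationConfig",
    "ObservationConfig",
    "ApplicationRecord",
    "SyntheticCatchment",
    "GroundTruth",
    "Observations",
    "generate_catchment",
    "generate_rainfall",
    "generate_applications",
    "simulate_observations",
    "simulate_model_frame",
    "DEFAULT_TRUE_COEFS",
]

NG_PER_G = 1.0e9


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CatchmentConfig:
    """Geometry settings for the synthetic catchment."""

    nrows: int = 150
    ncols: int = 250
    cell_size: float = 2.0
    n_inlets: int = 158
    n_road_rows: int = 5
    n_plot_cols: int = 10
    mean_slope: float = 0.05  # toward the stream (bottom edge)
    lateral_slope: float = 0.006  # along-road drainage gradient
    noise_amp_m: float = 0.20
    noise_corr_cells: float = 5.0
    n_pits: int = 0
    pit_depth_m: float = 0.4
    pit_radius_cells: int = 2


@dataclass(frozen=True)
class RainfallConfig:
    """Marked-point-process rainfall settings (1-min resolution, 0.1 mm)."""

    start: str = "2019-04-01"
    end: str = "2019-08-19"
    storm_rate_per_day: float = 0.30
    depth_log_mu: float = float(np.log(3.5))  # mm, lognormal storm totals
    depth_log_sigma: float = 1.0
    max_depth_mm: float = 45.0
    duration_log_mu: float = float(np.log(180.0))  # minutes
    duration_log_sigma: float = 0.7


@dataclass(frozen=True)
class ApplicationConfig:
    """Plot-resolved application settings."""

    window_start: str = "2019-04-01"
    window_end: str = "2019-08-19"
    apps_per_substance: tuple[int, int] = (1, 4)
    rate_g_per_m2: tuple[float, float] = (0.02, 0.3)
    share_in_window: float = 0.96


@dataclass(frozen=True)
class ObservationConfig:
    """Process parameters of the observation simulator."""

    rating: RatingCurve = field(default_factory=RatingCurve)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    activation_mm_range: tuple[float, float] = (1.3, 3.6)
    stream_activation_mm: float = 1.0
    runoff_coeff_field: float = 0.15
    runoff_coeff_farm_track: float = 0.5
    runoff_coeff_concrete: float = 0.8
    wash_fraction_field: float = 0.005
    wash_fraction_road: float = 0.8
    drift_deposit_frac: float = 0.002
    drift_radius_m: float = 100.0
    background_prob: float = 0.01
    background_mean_ng_l: float = 40.0
    reservoir: bool = True
    reservoir_retain: float = 0.2
    reservoir_release: float = 0.5
    stagnant_volume_l: float = 60.0
    grab_release: float = 0.05
    noise_sigma_log10: float = 0.2
    censoring: bool = True
    snowmelt_first_event: bool = False
    snowmelt_road_factor: float = 3.0
    stream_baseflow_l_min: float = 300.0
    other_fast_sources_factor: float = 3.0
    rise_fraction: float = 0.25
    recession_minutes: int = 120
    stage_thresholds_cm: tuple[float, float, float, float] = (3.0, 3.0, 2.0, 2.0)


@dataclass(frozen=True)
class ApplicationRecord:
    """One pesticide application: substance, day, plot and mass."""

    application_id: int
    substance: str
    date: pd.Timestamp
    plot_id: str
    mass_g: float
    area_m2: float

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("applied mass must be > 0")


# --------------------------------------------------------------------------
# catchment


@dataclass
class SyntheticCatchment:
    """The generated study system (geometry only; observations are separate)."""

    config: CatchmentConfig
    dem: np.ndarray
    roads: list[Road]
    road_mask: np.ndarray
    road_surface: np.ndarray  # 0 none, 1 farm_track, 2 concrete
    plots: list[Plot]
    agri_mask: np.ndarray
    inlets: list[Inlet]
    stream_mask: np.ndarray
    sampled_aliases: dict[str, str]  # "I1".."I4" -> inlet_id
    cs_member_ids: list[str]
    wwtp_mask: np.ndarray | None = None

    @property
    def cell_size(self) -> float:
        return self.config.cell_size

    @property
    def catchment_area_m2(self) -> float:
        return self.dem.size * self.cell_size**2

    def destinations(self) -> list[tuple[str, np.ndarray]]:
        """Destination masks for delineation: every inlet plus the stream."""
        dests = []
        for inl in self.inlets:
            m = np.zeros(self.dem.shape, dtype=bool)
            m[inl.row, inl.col] = True
            dests.append((inl.inlet_id, m))
        dests.append(("stream", self.stream_mask))
        if self.wwtp_mask is not None:
            dests.append(("wwtp", self.wwtp_mask))
        return dests

    def sites(self) -> list[Site]:
        """The six monitoring sites: I1-I4, collector shaft, stream."""
        inl_by_id = {i.inlet_id: i for i in self.inlets}
        sites = []
        for alias, iid in self.sampled_aliases.items():
            inl = inl_by_id[iid]
            sites.append(Site(alias, inl.point, (iid,), kind="inlet"))
        nrows = self.dem.shape[0]
        h = self.cell_size
        cs_point = Point(self.dem.shape[1] * h * 0.75, 1.5 * h)
        sites.append(Site("CS", cs_point, tuple(self.cs_member_ids), kind="collector"))
        st_point = Point(self.dem.shape[1] * h * 0.5, 0.5 * h)
        all_ids = tuple(i.inlet_id for i in self.inlets) + ("stream",)
        sites.append(Site("ST", st_point, all_ids, kind="stream"))
        return sites

    def validate(self) -> None:
        """Check the construction invariants."""
        if not np.isfinite(self.dem).all():
            raise AssertionError("DEM has undefined cells")
        near_road = ndimage.binary_dilation(self.road_mask, np.ones((3, 3), dtype=bool))
        for inl in self.inlets:
            if not near_road[inl.row, inl.col]:
                raise AssertionError(f"inlet {inl.inlet_id} not on or adjacent to a road")
        for i, a in enumerate(self.plots):
            for b in self.plots[i + 1 :]:
                inter = a.polygon.intersection(b.polygon).area
                if inter > 1e-9:
                    raise AssertionError(f"plots {a.plot_id}/{b.plot_id} overlap")


def generate_catchment(config: CatchmentConfig = CatchmentConfig(), seed: int = 0) -> SyntheticCatchment:
    """Generate a reproducible synthetic catchment.

    The DEM is a smooth trend (5% mean slope toward the stream along the
    bottom edge, plus a small lateral gradient that lets carved road
    trenches drain along-road) with spatially correlated noise and optional
    explicit pits.  Roads are horizontal farm tracks (one concrete road),
    inlets sit on road cells, and field plots tile the bands between roads.
    """
    if config.nrows < 20 or config.ncols < 20:
        raise ValueError("grid too small: need at least 20x20 cells")
    ss = np.random.SeedSequence(seed)
    rng_dem, rng_inl, rng_plot = [np.random.default_rng(s) for s in ss.spawn(3)]
    nrows, ncols, h = config.nrows, config.ncols, config.cell_size

    rows = np.arange(nrows)[:, None]
    cols = np.arange(ncols)[None, :]
    dem = (
        config.mean_slope * (nrows - 1 - rows) * h
        - config.lateral_slope * cols * h
        + config.lateral_slope * (ncols - 1) * h
    ).astype(float) * np.ones((1, ncols))
    noise = rng_dem.normal(size=(nrows, ncols))
    noise = ndimage.gaussian_filter(noise, config.noise_corr_cells)
    if noise.std() > 0:
        noise = noise / noise.std() * config.noise_amp_m
    dem = dem + noise
    # keep a clean outfall: the stream row stays the lowest
    dem[-1, :] = dem[-1, :].min() - 0.5

    for _ in range(config.n_pits):
        pr = int(rng_dem.integers(5, nrows - 5))
        pc = int(rng_dem.integers(5, ncols - 5))
        rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
        d2 = (rr - pr) ** 2 + (cc - pc) ** 2
        dem -= config.pit_depth_m * np.exp(-d2 / (2.0 * config.pit_radius_cells**2))

    # roads: horizontal lines between 15% and 85% of the grid height
    road_rows = np.unique(
        np.linspace(int(0.15 * nrows), int(0.85 * nrows), config.n_road_rows).astype(int)
    )
    roads, road_mask = [], np.zeros((nrows, ncols), dtype=bool)
    road_surface = np.zeros((nrows, ncols), dtype=np.int8)
    concrete_idx = len(road_rows) // 2
    for k, r in enumerate(road_rows):
        surface = "concrete" if k == concrete_idx else "farm_track"
        y = (nrows - r - 0.5) * h
        roads.append(Road(f"R{k + 1}", LineString([(0.0, y), (ncols * h, y)]), surface))
        road_mask[r, :] = True
        road_surface[r, :] = 2 if surface == "concrete" else 1

    # inlets distributed over road cells
    road_cells = np.argwhere(road_mask)
    n_inl = min(config.n_inlets, len(road_cells))
    pick = rng_inl.choice(len(road_cells), size=n_inl, replace=False)
    inlets = []
    for k, ci in enumerate(np.sort(pick)):
        r, c = road_cells[ci]
        x, y = cell_center(r, c, nrows, h)
        inlets.append(Inlet(f"I{k + 1:03d}", int(r), int(c), float(x), float(y)))

    # plots tile the bands between roads (and above/below the road belt)
    crops = ["grain", "potato", "sugar_beet", "meadow"]
    band_edges = [0] + [int(r) for r in road_rows] + [nrows - 1]
    plots = []
    agri_mask = np.zeros((nrows, ncols), dtype=bool)
    pid = 0
    for bi in range(len(band_edges) - 1) if config.n_plot_cols > 0 else []:
        r0, r1 = band_edges[bi], band_edges[bi + 1]
        top = r0 + 1 if r0 in road_rows or r0 == 0 else r0
        bot = r1 - 1
        if bot - top < 2:
            continue
        widths = rng_plot.dirichlet(np.ones(config.n_plot_cols) * 3.0) * ncols
        edges = np.concatenate([[0], np.cumsum(widths)]).round().astype(int)
        edges[-1] = ncols
        for j in range(config.n_plot_cols):
            c0, c1 = edges[j], edges[j + 1]
            if c1 - c0 < 2:
                continue
            pid += 1
            x0, x1 = c0 * h, c1 * h
            y0, y1 = (nrows - (bot + 1)) * h, (nrows - top) * h
            poly = box(x0 + 0.01, y0 + 0.01, x1 - 0.01, y1 - 0.01)
            plots.append(Plot(f"P{pid:03d}", poly, crops[int(rng_plot.integers(len(crops)))]))
            agri_mask[top : bot + 1, c0:c1] = True

    stream_mask = np.zeros((nrows, ncols), dtype=bool)
    stream_mask[-1, :] = True

    # sampled inlets: I1/I2 from the left half, I3/I4 from the right half
    # (the right half drains through the collector shaft)
    mid = ncols // 2
    left = [i for i in inlets if i.col < mid]
    right = [i for i in inlets if i.col >= mid]
    if len(left) < 2 or len(right) < 2:
        raise ValueError("too few inlets to select sampling sites; increase n_inlets")
    pick_left = rng_inl.choice(len(left), size=2, replace=False)
    pick_right = rng_inl.choice(len(right), size=2, replace=False)
    aliases = {
        "I1": left[pick_left[0]].inlet_id,
        "I2": left[pick_left[1]].inlet_id,
        "I3": right[pick_right[0]].inlet_id,
        "I4": right[pick_right[1]].inlet_id,
    }
    cs_members = [i.inlet_id for i in right]

    cat = SyntheticCatchment(
        config=config,
        dem=dem,
        roads=roads,
        road_mask=road_mask,
        road_surface=road_surface,
        plots=plots,
        agri_mask=agri_mask,
        inlets=inlets,
        stream_mask=stream_mask,
        sampled_aliases=aliases,
        cs_member_ids=cs_members,
    )
    cat.validate()
    return cat


# --------------------------------------------------------------------------
# rainfall


def generate_rainfall(config: RainfallConfig = RainfallConfig(), seed: int = 0) -> pd.Series:
    """1-min rainfall series (mm, quantised to 0.1) from clustered storms.

    Storm arrivals are Poisson in time; each storm carries a lognormal
    total depth and duration and deposits a gamma-shaped intensity
    profile.  The default window (1 Apr - 19 Aug) yields on the order of
    dozens of classifiable rain events with totals of ~1-40 mm.
    """
    start = pd.Timestamp(config.start)
    end = pd.Timestamp(config.end)
    n_days = (end - start).days
    if n_days < 1:
        raise ValueError("rainfall window must be at least 1 day")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    index = pd.date_range(start, end, freq="1min", inclusive="left")
    depths = np.zeros(len(index))
    n_storms = rng.poisson(config.storm_rate_per_day * n_days)
    if n_storms:
        starts = np.sort(rng.integers(0, len(index), size=n_storms))
        totals = np.minimum(
            rng.lognormal(config.depth_log_mu, config.depth_log_sigma, size=n_storms),
            config.max_depth_mm,
        )
        durs = np.clip(
            rng.lognormal(config.duration_log_mu, config.duration_log_sigma, size=n_storms),
            20,
            1500,
        ).astype(int)
        for s0, tot, dur in zip(starts, totals, durs):
            dur = int(min(dur, len(index) - s0))
            if dur < 1:
                continue
            t = np.arange(dur) + 0.5
            profile = t * np.exp(-3.0 * t / dur)  # gamma-like, peaks early
            profile = profile / profile.sum() * tot
            depths[s0 : s0 + dur] += profile
    # quantise on the cumulative curve: totals are preserved to 0.1 mm and
    # light rain appears as occasional 0.1-mm ticks, like a real gauge
    depths = np.diff(np.round(np.cumsum(depths) * 10.0), prepend=0.0) / 10.0
    depths = np.maximum(depths, 0.0)
    return pd.Series(depths, index=index, name="depth_mm")


# --------------------------------------------------------------------------
# applications


def generate_applications(
    catchment: SyntheticCatchment,
    substances: list[SubstanceProperties],
    config: ApplicationConfig = ApplicationConfig(),
    seed: int = 0,
) -> list[ApplicationRecord]:
    """Plot-resolved application records, concentrated in spring/summer.

    At least ``share_in_window`` of the total mass falls inside the study
    window by construction: out-of-window applications (placed before the
    window start) are capped at the complementary mass share.
    """
    if not substances:
        raise ValueError("substances must be non-empty")
    if not catchment.plots:
        return []
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    w0 = pd.Timestamp(config.window_start)
    w1 = pd.Timestamp(config.window_end)
    span_days = (w1 - w0).days
    records: list[ApplicationRecord] = []
    app_id = 0
    lo, hi = config.apps_per_substance
    if lo < 0 or hi < lo:
        raise ValueError("invalid apps_per_substance range")
    for sub in substances:
        n_apps = int(rng.integers(lo, hi + 1))
        in_mass = 0.0
        for _ in range(n_apps):
            plot = catchment.plots[int(rng.integers(len(catchment.plots)))]
            area = plot.polygon.area
            rate = rng.uniform(*config.rate_g_per_m2)
            # applications cluster in the first half of the window (spring)
            day = int(np.clip(rng.normal(span_days * 0.35, span_days * 0.18), 0, span_days - 1))
            app_id += 1
            rec = ApplicationRecord(
                app_id, sub.name, w0 + pd.Timedelta(days=day), plot.plot_id, rate * area, area
            )
            records.append(rec)
            in_mass += rec.mass_g
        if config.share_in_window < 1.0 and n_apps > 0:
            cap = in_mass * (1.0 - config.share_in_window) / config.share_in_window
            mass_out = cap * rng.uniform(0.2, 1.0)
            if mass_out > 0:
                plot = catchment.plots[int(rng.integers(len(catchment.plots)))]
                day_before = int(rng.integers(10, 40))
                app_id += 1
                records.append(
                    ApplicationRecord(
                        app_id,
                        sub.name,
                        w0 - pd.Timedelta(days=day_before),
                        plot.plot_id,
                        mass_out,
                        plot.polygon.area,
                    )
                )
    return sorted(records, key=lambda r: (r.date, r.application_id))


# --------------------------------------------------------------------------
# observation simulator


@dataclass
class GroundTruth:
    """Everything the simulator knows that the analysis must recover."""

    loads: pd.DataFrame  # site, event_id, substance, true_load_ng, app_load_ng, true_conc_ng_l
    volumes: pd.DataFrame  # site, event_id, true_volume_l
    categories: pd.DataFrame  # site, event_id, substance, category
    dest_names: list[str]
    ca_labels: np.ndarray
    mass_applied_ng: float
    mass_to_sites_ng: float
    inlet_volumes: pd.DataFrame  # per (inlet_id, event_id) true runoff volume (L)


@dataclass
class Observations:
    """Simulated monitoring record of one study period."""

    stage_cm: dict[str, pd.Series]
    stream_q_l_min: pd.Series
    samples: pd.DataFrame
    events: list[RainEvent]
    sites: list[Site]
    exposure: pd.DataFrame
    truth: GroundTruth


def _triangle(n_min: int, peak_at: int, volume_l: float) -> np.ndarray:
    """Piecewise-linear unit hydrograph (L/min) whose trapezoid integral
    over the 1-min grid equals ``volume_l`` exactly."""
    q = np.zeros(n_min)
    if n_min < 3 or volume_l <= 0:
        return q
    peak_at = int(np.clip(peak_at, 1, n_min - 2))
    up = np.linspace(0.0, 1.0, peak_at + 1)
    down = np.linspace(1.0, 0.0, n_min - peak_at)
    shape = np.concatenate([up, down[1:]])
    integral = np.trapezoid(shape, dx=1.0)
    return shape * (volume_l / integral)


def simulate_observations(
    catchment: SyntheticCatchment,
    rainfall: pd.Series,
    applications: list[ApplicationRecord],
    config: ObservationConfig = ObservationConfig(),
    seed: int = 0,
    substances: list[SubstanceProperties] | None = None,
) -> Observations:
    """Simulate stages, stream discharge, samples and ground truth.

    Mechanisms: event-scale runoff coefficients per surface class; soil
    wash-off pools that decay at ln2/DT50_soil since application; spray
    drift deposition within 100 m (direct, or on roads draining to the
    site); rare background pulses; and a stagnant-water reservoir in each
    inlet that retains part of every load and re-emits it in later events.
    Concentrations are load/volume with multiplicative lognormal noise;
    values below the substance LOQ are recorded censored with the LOQ
    retained.  Ground truth keeps the uncensored values, true loads and
    volumes, the contributing-area map, and true category labels.
    """
    if substances is None:
        substances = default_substances()
    if applications:
        app_min = min(a.date for a in applications)
        app_max = max(a.date for a in applications)
        if app_max < rainfall.index[0] - pd.Timedelta(days=120) or app_min > rainfall.index[-1]:
            raise ValueError("rainfall and application windows do not overlap")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    h = catchment.cell_size
    cell_area = h * h
    nrows, ncols = catchment.dem.shape

    events = classify_events(rainfall)
    if config.snowmelt_first_event and events:
        events[0] = replace(events[0], is_snowmelt=True)

    # --- connectivity ground truth (same model the analysis will run) ---
    cond = condition_dem(catchment.dem, config.connectivity, catchment.road_mask)
    fd = flow_directions_dinf(cond, h)
    ca = delineate_contributing_areas(
        cond,
        fd,
        catchment.destinations(),
        h,
        agri_mask=catchment.agri_mask,
        road_mask=catchment.road_mask,
    )
    labels = ca.labels
    names = ca.dest_names
    inlet_ids = [i.inlet_id for i in catchment.inlets]
    n_dest = len(inlet_ids) + 1  # inlets + stream (mass destinations)
    dest_index = {iid: k for k, iid in enumerate(inlet_ids)}
    dest_index["stream"] = len(inlet_ids)

    # per-destination surface composition -> event runoff coefficient
    label_of = {nm: k for k, nm in enumerate(names)}
    coeff = np.zeros(n_dest)
    ca_area = np.zeros(n_dest)
    for nm, k in dest_index.items():
        if nm not in label_of:
            continue
        m = labels == label_of[nm]
        n_cells = int(m.sum())
        ca_area[k] = n_cells * cell_area
        if n_cells == 0:
            continue
        n_conc = int((m & (catchment.road_surface == 2)).sum())
        n_track = int((m & (catchment.road_surface == 1)).sum())
        n_field = n_cells - n_conc - n_track
        coeff[k] = (
            n_conc * config.runoff_coeff_concrete
            + n_track * config.runoff_coeff_farm_track
            + n_field * config.runoff_coeff_field
        ) / n_cells
    road_frac = np.zeros(n_dest)
    for nm, k in dest_index.items():
        if nm in label_of and ca_area[k] > 0:
            m = labels == label_of[nm]
            road_frac[k] = float((m & catchment.road_mask).sum() * cell_area) / ca_area[k]

    # per-application fractional overlap with each destination's CA
    sub_names = [s.name for s in substances]
    sub_idx = {s: i for i, s in enumerate(sub_names)}
    props = {s.name: s for s in substances}
    A = len(applications)
    F = np.zeros((A, n_dest))
    plot_masks: dict[str, np.ndarray] = {}
    for ai, app in enumerate(applications):
        pm = plot_masks.get(app.plot_id)
        if pm is None:
            plot = next(p for p in catchment.plots if p.plot_id == app.plot_id)
            pm = rasterize_polygon(plot.polygon, nrows, ncols, h)
            plot_masks[app.plot_id] = pm
        n_cells = int(pm.sum())
        if n_cells == 0:
            continue
        counts = np.bincount(labels[pm], minlength=len(names))
        for nm, k in dest_index.items():
            if nm in label_of:
                F[ai, k] = counts[label_of[nm]] / n_cells

    # drift eligibility: equal split of the drifted mass over nearby dests
    plot_geoms = {p.plot_id: p.polygon for p in catchment.plots}
    inlet_pts = {i.inlet_id: i.point for i in catchment.inlets}
    rr, cc = np.nonzero(catchment.road_mask)
    rx, ry = cell_center(rr, cc, nrows, h)
    road_lbl = labels[rr, cc]
    G = np.zeros((A, n_dest))
    for ai, app in enumerate(applications):
        poly = plot_geoms[app.plot_id]
        eligible = []
        for iid, pt in inlet_pts.items():
            k = dest_index[iid]
            direct = poly.distance(pt) < config.drift_radius_m
            indirect = False
            if not direct:
                ki = label_of.get(iid)
                if ki is not None:
                    sel = road_lbl == ki
                    if sel.any():
                        minx, miny, maxx, maxy = poly.bounds
                        near = (
                            (rx[sel] > minx - config.drift_radius_m)
                            & (rx[sel] < maxx + config.drift_radius_m)
                            & (ry[sel] > miny - config.drift_radius_m)
                            & (ry[sel] < maxy + config.drift_radius_m)
                        )
                        if near.any():
                            pts = np.column_stack([rx[sel][near], ry[sel][near]])
                            for x, y in pts:
                                if poly.distance(Point(x, y)) < config.drift_radius_m:
                                    indirect = True
                                    break
            if direct or indirect:
                eligible.append(k)
        # the stream bank itself
        stream_y = h  # top of the stream row
        if poly.bounds[1] < stream_y + config.drift_radius_m:
            eligible.append(dest_index["stream"])
        if eligible:
            G[ai, eligible] = 1.0 / len(eligible)

    # --- per-inlet activation thresholds and event volumes ---
    act = rng.uniform(*config.activation_mm_range, size=n_dest)
    act[dest_index["stream"]] = config.stream_activation_mm
    E = len(events)
    vol = np.zeros((E, n_dest))  # L
    for ei, ev in enumerate(events):
        excess = np.maximum(ev.total_mm - act, 0.0)
        v = coeff * excess * ca_area  # mm * m2 -> L
        if ev.is_snowmelt:
            v = v * (1.0 + (config.snowmelt_road_factor - 1.0) * road_frac)
        vol[ei] = v

    # --- mass routing: soil pools, drift pools, reservoir ---
    lam_soil = np.array([np.log(2.0) / props[s].dt50_soil_d for s in sub_names])
    lam_water = np.array([np.log(2.0) / props[s].dt50_water_d for s in sub_names])
    app_sub = np.array([sub_idx[a.substance] for a in applications], dtype=int)
    app_mass_ng = np.array([a.mass_g for a in applications]) * NG_PER_G
    app_day = np.array(
        [pd.Timestamp(a.date).normalize().value / 86_400e9 for a in applications]
    )

    # pools are per (application, destination): washing one destination's
    # share must not deplete mass draining elsewhere
    soil_pool = np.zeros((A, n_dest))
    drift_pool = np.zeros((A, n_dest))
    soil_last = app_day.copy()
    res_pool = np.zeros((len(sub_names), n_dest))
    res_last_day = None

    S = len(sub_names)
    emitted = np.zeros((E, S, n_dest))  # app-derived true loads per event (ng)
    mass_to_sites = 0.0

    applied_order = np.argsort(app_day, kind="stable")
    next_app = 0
    for ei, ev in enumerate(events):
        ev_day = pd.Timestamp(ev.start).normalize().value / 86_400e9
        # activate applications that happened up to (and incl.) this day
        while next_app < A and app_day[applied_order[next_app]] <= ev_day:
            ai = applied_order[next_app]
            drift = app_mass_ng[ai] * config.drift_deposit_frac * (G[ai].sum() > 0)
            soil_pool[ai] = (app_mass_ng[ai] - drift) * F[ai]
            drift_pool[ai] = drift * G[ai]
            soil_last[ai] = app_day[ai]
            next_app += 1
        # decay pools to the event day
        dt = np.maximum(ev_day - soil_last, 0.0)
        decay = np.exp(-lam_soil[app_sub] * dt)
        soil_pool *= decay[:, None]
        drift_pool *= decay[:, None]
        soil_last[:] = ev_day
        if res_last_day is not None:
            res_pool *= np.exp(-lam_water * (ev_day - res_last_day))[:, None]
        res_last_day = ev_day

        active = vol[ei] > 0
        if active.any():
            washed_soil = soil_pool[:, active] * config.wash_fraction_field
            washed_drift = drift_pool[:, active] * config.wash_fraction_road
            soil_pool[:, active] -= washed_soil
            drift_pool[:, active] -= washed_drift
            inflow = np.zeros((S, int(active.sum())))
            np.add.at(inflow, app_sub, washed_soil + washed_drift)
            if config.reservoir:
                out = inflow * (1.0 - config.reservoir_retain) + res_pool[:, active] * config.reservoir_release
                res_pool[:, active] = inflow * config.reservoir_retain + res_pool[:, active] * (
                    1.0 - config.reservoir_release
                )
            else:
                out = inflow
            emitted[ei][:, active] = out
            mass_to_sites += float(out.sum())

    truth_mass_applied = float(app_mass_ng.sum())

    # --- hydrographs and stage series ---
    index = rainfall.index
    minute0 = index[0]
    n_min = len(index)
    alias_by_id = {v: k for k, v in catchment.sampled_aliases.items()}
    sampled_ids = list(catchment.sampled_aliases.values())
    stage = {alias: np.zeros(n_min) for alias in catchment.sampled_aliases}
    stream_q = np.full(n_min, config.stream_baseflow_l_min)

    ev_slices = []
    for ev in events:
        i0 = int((ev.start - minute0).total_seconds() // 60)
        i1 = int((ev.end - minute0).total_seconds() // 60)
        i1t = min(i1 + config.recession_minutes, n_min - 1)
        ev_slices.append((i0, i1, i1t))

    for ei, ev in enumerate(events):
        i0, i1, i1t = ev_slices[ei]
        n = i1t - i0 + 1
        peak = max(int(config.rise_fraction * (i1 - i0 + 1)), 1)
        for iid in sampled_ids:
            v = vol[ei, dest_index[iid]]
            if v > 0:
                q = _triangle(n, peak, v)
                stage[alias_by_id[iid]][i0 : i0 + n] += config.rating.stage(q)
        v_stream_fast = vol[ei].sum() * config.other_fast_sources_factor
        if v_stream_fast > 0:
            stream_q[i0 : i0 + n] += _triangle(n, peak, v_stream_fast)

    stage_series = {
        alias: pd.Series(vals, index=index, name="stage_cm") for alias, vals in stage.items()
    }
    stream_series = pd.Series(stream_q, index=index, name="q_l_min")

    # --- sampling triggers ---
    thresholds = dict(zip(["I1", "I2", "I3", "I4"], config.stage_thresholds_cm))
    events, trigger_table = flag_sampling_events(events, stage_series, thresholds)

    # --- site-level loads, volumes, concentrations ---
    sites = catchment.sites()
    exposure, _rej = build_exposure_table(
        ca, catchment.plots, applications, catchment.road_mask, sites,
        drift_radius_m=config.drift_radius_m,
    )

    members = {
        **{alias: [iid] for alias, iid in catchment.sampled_aliases.items()},
        "CS": list(catchment.cs_member_ids),
        "ST": inlet_ids + ["stream"],
    }
    k_of = dest_index

    load_rows, vol_rows, cat_rows, sample_rows = [], [], [], []
    events_by_id = {e.event_id: e for e in events}
    for ei, ev in enumerate(events):
        i0, i1, i1t = ev_slices[ei]
        window_min = i1t - i0
        for site in sites:
            ks = [k_of[m] for m in members[site.name]]
            v_site = float(vol[ei, ks].sum())
            if site.name == "ST":
                # the stream carries all inlet runoff plus other fast sources
                # and baseflow over the event window
                v_site = float(vol[ei].sum() * config.other_fast_sources_factor) + config.stream_baseflow_l_min * window_min
            vol_rows.append({"site": site.name, "event_id": ev.event_id, "true_volume_l": v_site})
            trig = ev.triggers.get(site.name)
            loads_site = emitted[ei][:, ks].sum(axis=1)
            for si, sub in enumerate(sub_names):
                app_load = float(loads_site[si])
                bg = 0.0
                if config.background_prob > 0 and rng.random() < config.background_prob and v_site > 0:
                    bg = rng.exponential(config.background_mean_ng_l) * v_site
                total = app_load + bg
                c_true = total / v_site if v_site > 0 else 0.0
                load_rows.append(
                    {
                        "site": site.name,
                        "event_id": ev.event_id,
                        "substance": sub,
                        "true_load_ng": total,
                        "app_load_ng": app_load,
                        "true_conc_ng_l": c_true,
                    }
                )
                cat = assign_category(site.name, ev.start, sub, exposure, applications)
                cat_rows.append(
                    {
                        "site": site.name,
                        "event_id": ev.event_id,
                        "substance": sub,
                        "category": cat.label,
                    }
                )
                # sample emission
                sample_type = None
                c_sample = c_true
                if site.name in ("CS", "ST"):
                    if trig is True:
                        sample_type = "composite"
                elif trig is True:
                    sample_type = "composite"
                elif ev.is_sampling_event:
                    if v_site > 0:
                        # runoff occurred but stayed below the sampling
                        # trigger: the stagnant water is event water, and
                        # within-event concentrations are constant
                        sample_type = "grab"
                    elif config.reservoir:
                        k = ks[0]
                        pool = float(res_pool[si, k])
                        if pool > 0:
                            c_sample = config.grab_release * pool / config.stagnant_volume_l
                            sample_type = "grab"
                if sample_type is None:
                    continue
                if config.noise_sigma_log10 > 0:
                    c_obs = c_sample * 10.0 ** rng.normal(0.0, config.noise_sigma_log10)
                else:
                    c_obs = c_sample
                loq = props[sub].loq_ng_l
                censored = bool(config.censoring and c_obs < loq)
                sample_rows.append(
                    {
                        "site": site.name,
                        "event_id": ev.event_id,
                        "substance": sub,
                        "sample_type": sample_type,
                        "value_ng_l": np.nan if censored else c_obs,
                        "uncensored_ng_l": c_obs,
                        "loq_ng_l": loq,
                        "censored": censored,
                    }
                )

    inlet_vol_rows = [
        {"inlet_id": iid, "event_id": ev.event_id, "true_volume_l": float(vol[ei, k_of[iid]])}
        for ei, ev in enumerate(events)
        for iid in inlet_ids
    ]

    truth = GroundTruth(
        loads=pd.DataFrame(load_rows),
        volumes=pd.DataFrame(vol_rows),
        categories=pd.DataFrame(cat_rows),
        dest_names=names,
        ca_labels=labels,
        mass_applied_ng=truth_mass_applied,
        mass_to_sites_ng=mass_to_sites,
        inlet_volumes=pd.DataFrame(inlet_vol_rows),
    )
    samples = pd.DataFrame(
        sample_rows,
        columns=[
            "site",
            "event_id",
            "substance",
            "sample_type",
            "value_ng_l",
            "uncensored_ng_l",
            "loq_ng_l",
            "censored",
        ],
    )
    return Observations(
        stage_cm=stage_series,
        stream_q_l_min=stream_series,
        samples=samples,
        events=events,
        sites=sites,
        exposure=exposure,
        truth=truth,
    )


# --------------------------------------------------------------------------
# direct model-frame simulator for the concentration model

#: effects used by the parameter-recovery studies (per-unit slopes)
DEFAULT_TRUE_COEFS = {
    "t_appl": -0.02,  # per day
    "log10_m_appl": 0.8,
    "log10_k_foc": -0.5,
    "dt50_water": 0.003,  # per day
    "dt50_soil": 0.004,  # per day
    "log10_q_mod": 0.0,
}

_CATEGORY_EFFECTS = {"A": 0.0, "B": 0.3, "C": 0.6, "D": 1.0}


def simulate_model_frame(
    n_inlets: int = 6,
    n_per_inlet: int = 60,
    n_substances: int = 20,
    coefs: dict | None = None,
    intercept: float = 1.0,
    re_sd: float = 0.3,
    noise_sd: float = 0.4,
    kow_noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a concentration-model frame with known coefficients.

    Substance-level properties (K_foc, K_ow, DT50s) are drawn once per
    substance; K_ow is a noisy affine copy of K_foc, reproducing the
    near-collinearity of real sorption descriptors.  Returns the frame
    and the true coefficient dictionary (K_ow has a true effect of 0).
    """
    if coefs is None:
        coefs = dict(DEFAULT_TRUE_COEFS)
    rng = np.random.default_rng(seed)
    subs = pd.DataFrame(
        {
            "substance": [f"S{i + 1:02d}" for i in range(n_substances)],
            "log10_k_foc": rng.normal(2.5, 0.6, n_substances),
            "dt50_water": rng.uniform(5, 150, n_substances),
            "dt50_soil": rng.uniform(10, 300, n_substances),
        }
    )
    subs["log10_kow"] = 1.2 * (subs["log10_k_foc"] - 2.5) + 3.0 + rng.normal(
        0, kow_noise_sd, n_substances
    )
    rows = []
    for g in range(n_inlets):
        u = rng.normal(0, re_sd)
        for _ in range(n_per_inlet):
            s = subs.iloc[int(rng.integers(n_substances))]
            t_appl = rng.uniform(0, 60)
            log10_m = rng.normal(2.5, 0.5)
            log10_q = rng.normal(3.0, 0.5)
            cat = str(rng.choice(list(_CATEGORY_EFFECTS)))
            mu = (
                intercept
                + coefs["t_appl"] * t_appl
                + coefs["log10_m_appl"] * log10_m
                + coefs["log10_k_foc"] * s["log10_k_foc"]
                + coefs["dt50_water"] * s["dt50_water"]
                + coefs["dt50_soil"] * s["dt50_soil"]
                + coefs["log10_q_mod"] * log10_q
                + _CATEGORY_EFFECTS[cat]
                + u
            )
            rows.append(
                {
                    "log10_c": mu + rng.normal(0, noise_sd),
                    "t_appl": t_appl,
                    "log10_m_appl": log10_m,
                    "log10_k_foc": s["log10_k_foc"],
                    "log10_kow": s["log10_kow"],
                    "dt50_water": s["dt50_water"],
                    "dt50_soil": s["dt50_soil"],
                    "log10_q_mod": log10_q,
                    "p_transport": cat,
                    "inlet": f"I{g + 1}",
                    "substance": s["substance"],
                }
            )
    truth = dict(coefs)
    truth["log10_kow"] = 0.0
    return pd.DataFrame(rows), truth
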