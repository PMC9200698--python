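"""Surface-runoff connectivity from a DEM: D-infinity routing and contributing areas.

The terrain model follows Tarboton's D-infinity construction: the flow
direction of each cell is the steepest downward slope over eight triangular
facets centred on the cell, and flow is split proportionally between the two
neighbours spanning the chosen facet.  Before routing, the DEM is
*conditioned*: cells under roads are carved down (roads collect runoff in
reality through ruts and verges that a 2-m DEM cannot resolve) and shallow
depressions are filled, while depressions deeper than the fill threshold are
retained as infiltration sinks.

Contributing areas are delineated by routing each cell's unit area down the
D-infinity flow field until it is absorbed by a destination (a storm
drainage inlet, the stream, a WWTP-drained area, or a sink) and assigning
each cell to the destination that receives the largest share (majority
rule); fractional shares are kept internally for area accounting.
Parameter uncertainty (carving and fill depths) is propagated by Monte
Carlo over the full delineation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .geometry import Plot, Road, Site, cell_center, rasterize_polygon

__all__ = [
    "ConnectivityParams",
    "condition_dem",
    "FlowDirections",
    "flow_directions_dinf",
    "flow_accumulation",
    "ContributingAreaMap",
    "delineate_contributing_areas",
    "monte_carlo_connectivity",
    "build_exposure_table",
]

_BIG = 1.0e12  # stands in for "outside the grid" elevations

# facet table: (cardinal offset, diagonal offset)
_FACETS = [
    ((0, 1), (-1, 1)),
    ((-1, 0), (-1, 1)),
    ((-1, 0), (-1, -1)),
    ((0, -1), (-1, -1)),
    ((0, -1), (1, -1)),
    ((1, 0), (1, -1)),
    ((1, 0), (1, 1)),
    ((0, 1), (1, 1)),
]


@dataclass(frozen=True)
class ConnectivityParams:
    """Terrain-conditioning parameters and their Monte Carlo ranges.

    ``road_carving_depth`` (m) is subtracted from cells under roads;
    depressions of depth <= ``sink_fill_depth`` (m) are raised to their
    pour level (with a small drainage gradient), deeper ones are retained
    as sinks.  The ``*_range`` pairs are uniform sampling bounds for the
    Monte Carlo runs.
    """

    road_carving_depth: float = 0.15
    sink_fill_depth: float = 0.10
    road_carving_range: tuple[float, float] = (0.05, 0.30)
    sink_fill_range: tuple[float, float] = (0.02, 0.25)

    def __post_init__(self) -> None:
        if self.road_carving_depth < 0 or self.sink_fill_depth < 0:
            raise ValueError("conditioning depths must be >= 0")


def condition_dem(
    dem: np.ndarray,
    params: ConnectivityParams,
    roads_mask: np.ndarray | None = None,
    *,
    eps: float = 1.0e-6,
) -> np.ndarray:
    """Carve roads and fill shallow depressions; deep ones stay sinks.

    Filling uses a priority-flood sweep from the grid border that raises
    depression cells to their pour level plus a tiny increasing increment
    (``eps``), which guarantees a drainage gradient across filled areas.
    Each filled depression whose maximum fill depth exceeds
    ``params.sink_fill_depth`` is reverted to its original elevations and
    therefore keeps acting as a sink.
    """
    if dem.ndim != 2:
        raise ValueError("dem must be a 2-D array")
    if not np.isfinite(dem).all():
        raise ValueError("dem contains undefined cells")
    z = dem.astype(float).copy()
    if roads_mask is not None:
        if roads_mask.shape != z.shape:
            raise ValueError("roads mask and DEM grids do not match (CRS/grid mismatch)")
        z[roads_mask] -= params.road_carving_depth

    nrows, ncols = z.shape
    filled = z.copy()
    visited = np.zeros_like(z, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    count = 0
    for r in range(nrows):
        for c in (0, ncols - 1):
            heapq.heappush(heap, (z[r, c], count, r, c))
            visited[r, c] = True
            count += 1
    for c in range(1, ncols - 1):
        for r in (0, nrows - 1):
            heapq.heappush(heap, (z[r, c], count, r, c))
            visited[r, c] = True
            count += 1
    while heap:
        level, _, r, c = heapq.heappop(heap)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and not visited[rr, cc]:
                    visited[rr, cc] = True
                    lvl = max(z[rr, cc], level + eps)
                    filled[rr, cc] = lvl
                    heapq.heappush(heap, (lvl, count, rr, cc))
                    count += 1

    raised = filled > z + eps * 0.5
    if raised.any():
        from scipy import ndimage

        labels, n = ndimage.label(raised, structure=np.ones((3, 3), dtype=int))
        for k in range(1, n + 1):
            comp = labels == k
            depth = float((filled[comp] - z[comp]).max())
            if depth > params.sink_fill_depth:
                filled[comp] = z[comp]  # depression retained as sink
    return filled


@dataclass
class FlowDirections:
    """D-infinity flow field: up to two receivers per cell with weights.

    ``receivers[i, k]`` is the flat index of the k-th receiver of flat cell
    ``i`` (-1 if absent) and ``weights[i, k]`` its flow proportion;
    ``angle`` is the steepest-descent direction (radians, only for cells
    with a downslope neighbour) and cells with no downslope neighbour are
    local sinks (``receivers`` both -1).
    """

    shape: tuple[int, int]
    receivers: np.ndarray
    weights: np.ndarray
    angle: np.ndarray
    slope: np.ndarray


def flow_directions_dinf(dem: np.ndarray, cell_size: float = 2.0) -> FlowDirections:
    """Tarboton D-infinity directions on a conditioned DEM."""
    nrows, ncols = dem.shape
    P = np.full((nrows + 2, ncols + 2), _BIG)
    P[1:-1, 1:-1] = dem
    e0 = dem
    h = cell_size
    diag = h * np.sqrt(2.0)

    best_s = np.full(dem.shape, -np.inf)
    best_facet = np.full(dem.shape, -1, dtype=np.int8)
    best_r = np.zeros(dem.shape)

    for fi, ((dr1, dc1), (dr2, dc2)) in enumerate(_FACETS):
        e1 = P[1 + dr1 : nrows + 1 + dr1, 1 + dc1 : ncols + 1 + dc1]
        e2 = P[1 + dr2 : nrows + 1 + dr2, 1 + dc2 : ncols + 1 + dc2]
        s1 = (e0 - e1) / h
        s2 = (e1 - e2) / h
        r = np.arctan2(s2, s1)
        s = np.hypot(s1, s2)
        low = r < 0
        r = np.where(low, 0.0, r)
        s = np.where(low, s1, s)
        hi = r > np.pi / 4
        r = np.where(hi, np.pi / 4, r)
        s = np.where(hi, (e0 - e2) / diag, s)
        take = s > best_s
        best_s = np.where(take, s, best_s)
        best_r = np.where(take, r, best_r)
        best_facet = np.where(take, fi, best_facet)

    n = dem.size
    receivers = np.full((n, 2), -1, dtype=np.int64)
    weights = np.zeros((n, 2))
    angle = np.full(dem.shape, np.nan)

    has_down = best_s > 0
    flat_idx = np.arange(n).reshape(dem.shape)
    for fi, ((dr1, dc1), (dr2, dc2)) in enumerate(_FACETS):
        sel = has_down & (best_facet == fi)
        if not sel.any():
            continue
        rr, cc = np.nonzero(sel)
        w_diag = best_r[sel] / (np.pi / 4)
        w_card = 1.0 - w_diag
        # cardinal receiver
        r1, c1 = rr + dr1, cc + dc1
        ok1 = (r1 >= 0) & (r1 < nrows) & (c1 >= 0) & (c1 < ncols) & (w_card > 0)
        # diagonal receiver
        r2, c2 = rr + dr2, cc + dc2
        ok2 = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols) & (w_diag > 0)
        src = flat_idx[rr, cc]
        receivers[src[ok1], 0] = flat_idx[r1[ok1], c1[ok1]]
        weights[src[ok1], 0] = w_card[ok1]
        receivers[src[ok2], 1] = flat_idx[r2[ok2], c2[ok2]]
        weights[src[ok2], 1] = w_diag[ok2]
        # facet angle measured counter-clockwise from east
        base = np.arctan2(-dr1, dc1)
        sign = np.sign(np.arctan2(-dr2, dc2) - base)
        sign = np.where(sign == 0, 1.0, sign)
        angle[sel] = base + sign * best_r[sel]
    return FlowDirections((nrows, ncols), receivers, weights, angle, best_s)


def _topo_order(dem: np.ndarray) -> np.ndarray:
    """Flat cell indices by descending conditioned elevation.

    D-infinity receivers with positive weight are strictly lower than the
    source cell, so elevation order is a valid topological order.
    """
    return np.argsort(-dem.ravel(), kind="stable")


def flow_accumulation(
    dem: np.ndarray,
    fd: FlowDirections,
    cell_area: float = 1.0,
    absorbing: np.ndarray | None = None,
) -> np.ndarray:
    """Accumulated upslope area per cell (including the cell itself).

    ``absorbing`` cells (boolean grid) retain everything routed into them.
    """
    acc = np.full(dem.size, cell_area)
    absorb = absorbing.ravel() if absorbing is not None else None
    for i in _topo_order(dem):
        if absorb is not None and absorb[i]:
            continue
        for k in range(2):
            j = fd.receivers[i, k]
            if j >= 0:
                acc[j] += fd.weights[i, k] * acc[i]
    return acc.reshape(dem.shape)


@dataclass
class ContributingAreaMap:
    """Hard-labelled contributing areas plus fractional area accounting.

    ``labels`` holds, per cell, the index into ``dest_names`` of the
    destination receiving the largest share of the cell's routed flow.
    ``area``/``frac_area`` are per-destination totals (m²) by majority
    rule and by fractional share; ``agri_area`` and ``road_area``
    restrict the majority-rule areas to the respective masks.
    """

    dest_names: list[str]
    labels: np.ndarray
    cell_size: float
    area: dict[str, float]
    frac_area: dict[str, float]
    agri_area: dict[str, float]
    road_area: dict[str, float]
    n_unrouted: int = 0

    def label_name(self, row: int, col: int) -> str:
        return self.dest_names[self.labels[row, col]]

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.dest_names.index(name)


def delineate_contributing_areas(
    dem: np.ndarray,
    fd: FlowDirections,
    destinations: list[tuple[str, np.ndarray]],
    cell_size: float = 2.0,
    agri_mask: np.ndarray | None = None,
    road_mask: np.ndarray | None = None,
) -> ContributingAreaMap:
    """Assign every cell to the destination receiving most of its flow.

    ``destinations`` are (label, boolean mask) pairs; destination cells
    absorb all inflow.  Cells (or flow fractions) that reach a cell with
    no downslope neighbour — or would leave the grid — are booked to the
    implicit ``"sink"`` destination.  Labels partition the catchment and
    the per-destination fractional areas sum to the catchment area.
    """
    nrows, ncols = dem.shape
    n = dem.size
    names = [name for name, _ in destinations]
    if "sink" not in names:
        names = names + ["sink"]
    k_sink = names.index("sink")
    K = len(names)

    dest_id = np.full(n, -1, dtype=np.int32)
    for ki, (name, mask) in enumerate(destinations):
        dest_id[mask.ravel()] = names.index(name)

    share = np.zeros((n, K), dtype=np.float64)
    order = _topo_order(dem)[::-1]  # ascending: downstream first
    recv, wts = fd.receivers, fd.weights
    n_unrouted = 0
    for i in order:
        d = dest_id[i]
        if d >= 0:
            share[i, d] = 1.0
            continue
        w_tot = 0.0
        for k in range(2):
            j = recv[i, k]
            if j >= 0:
                share[i] += wts[i, k] * share[j]
                w_tot += wts[i, k]
        if w_tot < 1.0 - 1e-12:
            share[i, k_sink] += 1.0 - w_tot
            if w_tot == 0.0:
                n_unrouted += 1

    labels = share.argmax(axis=1).astype(np.int32).reshape(nrows, ncols)
    cell_area = cell_size**2
    area = {nm: float((labels == ki).sum()) * cell_area for ki, nm in enumerate(names)}
    frac_area = {nm: float(share[:, ki].sum()) * cell_area for ki, nm in enumerate(names)}
    agri = {
        nm: (float(((labels == ki) & agri_mask).sum()) * cell_area if agri_mask is not None else 0.0)
        for ki, nm in enumerate(names)
    }
    road = {
        nm: (float(((labels == ki) & road_mask).sum()) * cell_area if road_mask is not None else 0.0)
        for ki, nm in enumerate(names)
    }
    return ContributingAreaMap(names, labels, cell_size, area, frac_area, agri, road, n_unrouted)


def monte_carlo_connectivity(
    dem: np.ndarray,
    params: ConnectivityParams,
    destinations: list[tuple[str, np.ndarray]],
    *,
    roads_mask: np.ndarray | None = None,
    agri_mask: np.ndarray | None = None,
    n_runs: int = 100,
    seed: int = 0,
    cell_size: float = 2.0,
    inlet_prefix: str = "I",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte Carlo over conditioning parameters; 100 runs by default.

    Per run, carving and fill depths are drawn uniformly from the ranges
    in ``params``, the full delineation is executed, and the fractions of
    the agricultural area draining directly to the stream, via inlets, or
    into sinks are recorded.  Returns the per-run table and a summary with
    median and quartiles.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        p = ConnectivityParams(
            road_carving_depth=float(rng.uniform(*params.road_carving_range)),
            sink_fill_depth=float(rng.uniform(*params.sink_fill_range)),
            road_carving_range=params.road_carving_range,
            sink_fill_range=params.sink_fill_range,
        )
        cond = condition_dem(dem, p, roads_mask)
        fd = flow_directions_dinf(cond, cell_size)
        ca = delineate_contributing_areas(
            cond, fd, destinations, cell_size, agri_mask=agri_mask, road_mask=roads_mask
        )
        agri_tot = sum(ca.agri_area.values())
        via_inlet = sum(v for k, v in ca.agri_area.items() if k.startswith(inlet_prefix))
        direct = ca.agri_area.get("stream", 0.0)
        sink = ca.agri_area.get("sink", 0.0)
        rows.append(
            {
                "run": run,
                "road_carving_depth": p.road_carving_depth,
                "sink_fill_depth": p.sink_fill_depth,
                "frac_direct_stream": direct / agri_tot if agri_tot else np.nan,
                "frac_via_inlet": via_inlet / agri_tot if agri_tot else np.nan,
                "frac_sink": sink / agri_tot if agri_tot else np.nan,
            }
        )
    runs = pd.DataFrame(rows).set_index("run")
    cols = ["frac_direct_stream", "frac_via_inlet", "frac_sink"]
    summary = runs[cols].quantile([0.25, 0.5, 0.75]).T
    summary.columns = ["q25", "median", "q75"]
    return runs, summary


def build_exposure_table(
    ca_map: ContributingAreaMap,
    plots: list[Plot],
    applications,
    roads_mask: np.ndarray | None,
    sites: list[Site],
    *,
    drift_radius_m: float = 100.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Intersect contributing areas with plot-resolved application records.

    One row per (site, application) for which at least one transport
    predicate holds: the plot intersects the site's contributing area
    (surface-runoff potential), lies within ``drift_radius_m`` of the site
    point (direct spray drift), or within that radius of a road cell
    draining to the site (indirect spray drift).  Distances are Euclidean
    from the plot polygon to the point.  Applications referencing unknown
    plots are rejected and reported.
    """
    nrows, ncols = ca_map.labels.shape
    h = ca_map.cell_size
    plot_by_id = {p.plot_id: p for p in plots}
    plot_masks = {
        p.plot_id: rasterize_polygon(p.polygon, nrows, ncols, h) for p in plots
    }

    site_rows = []
    rejected: list[str] = []
    for site in sites:
        dest_ids = [ca_map.dest_names.index(l) for l in site.dest_labels if l in ca_map.dest_names]
        ca_mask = np.isin(ca_map.labels, dest_ids)
        if roads_mask is not None:
            draining_roads = ca_mask & roads_mask
            rr, cc = np.nonzero(draining_roads)
            rx, ry = cell_center(rr, cc, nrows, h)
            road_pts = np.column_stack([rx, ry]) if len(rr) else None
        else:
            road_pts = None
        for app in applications:
            plot = plot_by_id.get(app.plot_id)
            if plot is None:
                rejected.append(f"{app.substance} on unknown plot {app.plot_id}")
                continue
            pmask = plot_masks[app.plot_id]
            n_cells = int(pmask.sum())
            n_in = int((pmask & ca_mask).sum())
            runoff = n_in > 0
            mass_in_ca = app.mass_g * (n_in / n_cells) if n_cells else 0.0
            dist = float(plot.polygon.distance(site.point))
            drift_direct = dist < drift_radius_m
            drift_indirect = False
            if road_pts is not None and len(road_pts):
                minx, miny, maxx, maxy = plot.polygon.bounds
                near = (
                    (road_pts[:, 0] > minx - drift_radius_m)
                    & (road_pts[:, 0] < maxx + drift_radius_m)
                    & (road_pts[:, 1] > miny - drift_radius_m)
                    & (road_pts[:, 1] < maxy + drift_radius_m)
                )
                for x, y in road_pts[near]:
                    if plot.polygon.distance(Point(x, y)) < drift_radius_m:
                        drift_indirect = True
                        break
            if runoff or drift_direct or drift_indirect:
                site_rows.append(
                    {
                        "site": site.name,
                        "substance": app.substance,
                        "application_id": app.application_id,
                        "application_date": app.date,
                        "plot_id": app.plot_id,
                        "mass_applied_g": app.mass_g,
                        "mass_in_ca_g": mass_in_ca,
                        "min_distance_m": dist,
                        "runoff": runoff,
                        "drift_direct": drift_direct,
                        "drift_indirect": drift_indirect,
                    }
                )
    # deduplicate the rejection report (one entry per bad application)
    seen: dict[str, None] = {}
    for r in rejected:
        seen.setdefault(r)
    table = pd.DataFrame(
        site_rows,
        columns=[
            "site",
            "substance",
            "application_id",
            "application_date",
            "plot_id",
            "mass_applied_g",
            "mass_in_ca_g",
            "min_distance_m",
            "runoff",
            "drift_direct",
            "drift_indirect",
        ],
    )
    return table, list(seen)
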