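"""Broad-scale space use: kernel UDs, 95% movement ranges, MCPs,
availability regions, random available ranges, and zonal summaries.

The movement range of an individual is the 95% isopleth of a fixed
bivariate Gaussian kernel density estimate of its fixes, with bandwidth
chosen by the *ad hoc* rule: start from the bivariate reference
bandwidth ``h_ref = sigma_hat * n^(-1/6)`` and shrink in steps of
``0.05 * h_ref`` until the isopleth would fragment into disconnected
pieces or grow interior holes, returning the smallest contiguous
bandwidth.  Availability is defined used/available-style: five random
circles of the same area as the observed range, centred uniformly in
the individual's buffered MCP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, Polygon

from .landscape import HABITAT_CODES, Landscape

__all__ = [
    "UtilisationDistribution",
    "MovementRange",
    "RangeSummary",
    "fit_kde",
    "h_ad_hoc",
    "isopleth",
    "mcp",
    "availability_region",
    "sample_available_ranges",
    "summarize_range",
    "asymptote_check",
    "equal_area_radius",
]

ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def equal_area_radius(area_m2: float) -> float:
    """Radius of the circle with the given area (m^2 -> m)."""
    return float(np.sqrt(area_m2 / np.pi))


@dataclass
class UtilisationDistribution:
    """KDE probability mass on a regular grid (top-left anchored)."""

    origin_x: float
    origin_y: float
    cell_size: float
    mass: np.ndarray        # sums to 1
    bandwidth: float
    n_points: int

    @property
    def cell_area(self) -> float:
        return self.cell_size**2


@dataclass
class MovementRange:
    """A 95%-isopleth range (cell set) or a circular available range."""

    individual_id: str
    range_type: str                      # "observed" | "available"
    level: float
    area_m2: float
    centroid: tuple[float, float]
    # observed ranges: grid-aligned cell mask
    mask: np.ndarray | None = None
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 0.0
    # available ranges: circle
    centre: tuple[float, float] | None = None
    radius: float = 0.0

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 1e4

    @property
    def equal_area_radius(self) -> float:
        return equal_area_radius(self.area_m2)

    def contains(self, x, y) -> np.ndarray:
        """Point-membership test (vectorised)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.centre is not None:
            return np.hypot(x - self.centre[0], y - self.centre[1]) <= self.radius
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        ok = (row >= 0) & (row < self.mask.shape[0]) & (col >= 0) & (col < self.mask.shape[1])
        out = np.zeros(x.shape, dtype=bool)
        out[ok] = self.mask[row[ok], col[ok]]
        return out


@dataclass
class RangeSummary:
    individual_id: str
    range_type: str
    proportions: dict[str, float]        # 5 analysed habitat classes
    median_tri: float
    mean_dist_disturbance: float
    mean_dist_rocky: float
    mean_ndvi: float | None
    unmapped_fraction: float

    def as_row(self) -> dict:
        row = {
            "individual_id": self.individual_id,
            "range_type": self.range_type,
            "median_tri": self.median_tri,
            "mean_dist_disturbance": self.mean_dist_disturbance,
            "mean_dist_rocky": self.mean_dist_rocky,
            "mean_ndvi": self.mean_ndvi,
            "unmapped_fraction": self.unmapped_fraction,
        }
        for name, val in self.proportions.items():
            row[f"prop_{name}"] = val
        return row


def fit_kde(points: np.ndarray, h: float, grid_resolution: float | None = None,
            max_cells: int = 512) -> UtilisationDistribution:
    """Fixed bivariate Gaussian KDE evaluated as cell masses on a grid.

    The grid pads at least 3h beyond the point bounding box.  Default
    resolution is h/4, coarsened if needed so neither axis exceeds
    ``max_cells`` cells.  Points are binned to cells before convolution;
    with resolution <= h/4 the binning error is negligible relative to
    the kernel scale.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(points) < 5:
        raise ValueError("need at least 5 points")
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    pad = 3.5 * h
    x0, y1 = points[:, 0].min() - pad, points[:, 1].max() + pad
    x1, y0 = points[:, 0].max() + pad, points[:, 1].min() - pad
    res = grid_resolution if grid_resolution else h / 4.0
    res = max(res, (x1 - x0) / max_cells, (y1 - y0) / max_cells)
    n_cols = max(int(np.ceil((x1 - x0) / res)), 1)
    n_rows = max(int(np.ceil((y1 - y0) / res)), 1)

    col = np.clip(((points[:, 0] - x0) / res).astype(int), 0, n_cols - 1)
    row = np.clip(((y1 - points[:, 1]) / res).astype(int), 0, n_rows - 1)
    hist = np.zeros((n_rows, n_cols))
    np.add.at(hist, (row, col), 1.0)
    mass = ndimage.gaussian_filter(hist, sigma=h / res, mode="constant", truncate=6.0)
    total = mass.sum()
    if total <= 0:
        raise ValueError("degenerate KDE (all mass lost)")
    mass /= total
    return UtilisationDistribution(
        origin_x=x0, origin_y=y1, cell_size=res, mass=mass,
        bandwidth=h, n_points=len(points),
    )


def _isopleth_mask(ud: UtilisationDistribution, level: float) -> np.ndarray:
    flat = ud.mass.ravel()
    order = np.argsort(-flat, kind="stable")  # ties break row-major
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level, side="left")) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.mass.shape)


def _contiguous_no_holes(mask: np.ndarray) -> bool:
    _, n_regions = ndimage.label(mask, structure=ROOK)
    if n_regions != 1:
        return False
    bg, n_bg = ndimage.label(~mask, structure=ROOK)
    border = set(np.unique(np.concatenate([bg[0], bg[-1], bg[:, 0], bg[:, -1]])))
    border.discard(0)
    return len(border) == n_bg


def isopleth(ud: UtilisationDistribution, level: float = 0.95,
             individual_id: str = "", range_type: str = "observed") -> MovementRange:
    """Smallest cell set whose cumulative mass reaches ``level``."""
    mask = _isopleth_mask(ud, level)
    n_cells = int(mask.sum())
    area = n_cells * ud.cell_area
    rows, cols = np.nonzero(mask)
    cx = ud.origin_x + (cols.mean() + 0.5) * ud.cell_size
    cy = ud.origin_y - (rows.mean() + 0.5) * ud.cell_size
    return MovementRange(
        individual_id=individual_id, range_type=range_type, level=level,
        area_m2=area, centroid=(cx, cy), mask=mask,
        origin_x=ud.origin_x, origin_y=ud.origin_y, cell_size=ud.cell_size,
    )


def h_ad_hoc(points: np.ndarray, level: float = 0.95, step: float = 0.05,
             grid_resolution: float | None = None) -> float:
    """Ad hoc bandwidth: shrink ``h_ref`` until the isopleth fragments.

    Returns the smallest ``h`` in ``{h_ref * (1 - step*j)}`` whose
    ``level`` isopleth is one rook-connected region with no interior
    holes; if even ``h_ref`` fragments, returns ``h_ref``.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 5:
        raise ValueError("need at least 5 points")
    sigma = np.sqrt(0.5 * (points[:, 0].var(ddof=1) + points[:, 1].var(ddof=1)))
    if sigma == 0:
        raise ValueError("degenerate point set (zero variance)")
    h_ref = sigma * len(points) ** (-1.0 / 6.0)
    best = h_ref
    j = 0
    while True:
        h = h_ref * (1.0 - step * j)
        if h <= step * h_ref / 2:
            return best
        ud = fit_kde(points, h, grid_resolution)
        if _contiguous_no_holes(_isopleth_mask(ud, level)):
            best = h
            j += 1
        else:
            return h_ref if j == 0 else best


def mcp(points: np.ndarray, fraction: float = 1.0) -> Polygon:
    """Minimum convex polygon of (a fraction of) the fixes.

    With ``fraction < 1`` the points farthest from the centroid are
    peeled before hulling.  Collinear inputs give a degenerate polygon
    with zero area.
    """
    points = np.asarray(points, dtype=float)
    if fraction < 1.0:
        centroid = points.mean(axis=0)
        d = np.hypot(*(points - centroid).T)
        keep = np.argsort(d, kind="stable")[: max(3, int(np.ceil(fraction * len(points))))]
        points = points[keep]
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if hull.geom_type != "Polygon":
        import logging

        logging.getLogger("quollmove").warning("degenerate MCP (collinear points), area 0")
        hull = hull.buffer(0.0) if hull.geom_type == "Polygon" else Polygon()
    return hull


def availability_region(points: np.ndarray, r_max: float, r_focal: float) -> Polygon:
    """Buffer the 100% MCP by ``r_max - r_focal`` (never negative)."""
    buffer = max(r_max - r_focal, 0.0)
    hull = MultiPoint([tuple(p) for p in np.asarray(points, dtype=float)]).convex_hull
    return hull.buffer(buffer)


def sample_available_ranges(
    region: Polygon,
    target_area_m2: float,
    n: int = 5,
    seed: int = 0,
    individual_id: str = "",
) -> list[MovementRange]:
    """``n`` circles of ``target_area_m2``, centres uniform in ``region``.

    Circles may overlap each other, the observed range, and (with a
    warning) extend beyond the region when it is smaller than a circle.
    """
    import logging

    rng = np.random.default_rng(seed)
    radius = equal_area_radius(target_area_m2)
    if region.area < target_area_m2:
        logging.getLogger("quollmove").warning(
            "availability region smaller than the range circle; centres drawn anyway"
        )
    minx, miny, maxx, maxy = region.bounds
    out = []
    while len(out) < n:
        cand = np.column_stack(
            [rng.uniform(minx, maxx, 64), rng.uniform(miny, maxy, 64)]
        )
        for cx, cy in cand:
            if region.contains(Point(cx, cy)):
                out.append(
                    MovementRange(
                        individual_id=individual_id, range_type="available",
                        level=np.nan, area_m2=target_area_m2,
                        centroid=(cx, cy), centre=(cx, cy), radius=radius,
                    )
                )
                if len(out) == n:
                    break
    return out


def summarize_range(mrange: MovementRange, landscape: Landscape) -> RangeSummary:
    """Zonal summary by cell-centre membership.

    Habitat proportions are over the five analysed classes (water is
    excluded from numerators but counts in the denominator); median TRI
    uses the TRI grid's own cell centres; distance and NDVI layers are
    averaged over member habitat cells.  Cells outside the mapped
    raster contribute only to ``unmapped_fraction``.
    """
    hab = landscape.habitat
    hx, hy = hab.cell_centres()
    member = mrange.contains(hx.ravel(), hy.ravel()).reshape(hx.shape)
    codes = hab.values[member]
    mapped = codes != hab.nodata
    n_member = member.sum()
    n_mapped = int(mapped.sum())
    if mrange.centre is not None:
        # count members that fall off the raster entirely
        area_cells = mrange.area_m2 / hab.cell_area
        unmapped = max(0.0, 1.0 - n_mapped / max(area_cells, 1.0))
    else:
        unmapped = 1.0 - n_mapped / max(n_member, 1)
    props = {}
    denom = max(n_mapped, 1)
    for name, code in HABITAT_CODES.items():
        if name == "water":
            continue
        props[name] = float((codes[mapped] == code).sum()) / denom

    tx, ty = landscape.tri.cell_centres()
    tri_member = mrange.contains(tx.ravel(), ty.ravel())
    tri_vals = landscape.tri.values.ravel()[tri_member]
    tri_vals = tri_vals[tri_vals != landscape.tri.nodata]
    median_tri = float(np.median(tri_vals)) if tri_vals.size else np.nan

    def _mean_layer(grid):
        vals = grid.values[member]
        vals = vals[vals != grid.nodata]
        return float(vals.mean()) if vals.size else np.nan

    return RangeSummary(
        individual_id=mrange.individual_id,
        range_type=mrange.range_type,
        proportions=props,
        median_tri=median_tri,
        mean_dist_disturbance=_mean_layer(landscape.dist_disturbance),
        mean_dist_rocky=_mean_layer(landscape.dist_rocky),
        mean_ndvi=_mean_layer(landscape.ndvi) if landscape.ndvi is not None else None,
        unmapped_fraction=float(unmapped),
    )


def asymptote_check(points: np.ndarray, interval: int = 10, level: float = 0.95,
                    rel_tol: float = 0.05, h: float | None = None):
    """Sequential-area asymptote check at ``interval``-fix increments.

    Recomputes the ``level`` KDE area at ``n = interval, 2*interval,
    ...`` with one common bandwidth (ad hoc on the full point set unless
    ``h`` is given), so the sequence reflects accumulating fixes rather
    than bandwidth re-selection.  The asymptote is reached when the last
    three areas pairwise differ by less than ``rel_tol``.
    """
    points = np.asarray(points, dtype=float)
    if h is None:
        h = h_ad_hoc(points, level)
    areas = []
    sizes = list(range(interval, len(points) + 1, interval))
    for n in sizes:
        sub = points[:n]
        try:
            areas.append(isopleth(fit_kde(sub, h), level).area_m2)
        except ValueError:
            areas.append(np.nan)
    areas = np.asarray(areas, dtype=float)
    good = areas[~np.isnan(areas)]
    reached = False
    if len(good) >= 3:
        last = good[-3:]
        reached = bool(
            all(
                abs(a - b) / max(a, b) < rel_tol
                for i, a in enumerate(last)
                for b in last[i + 1:]
            )
        )
    return areas, reached
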