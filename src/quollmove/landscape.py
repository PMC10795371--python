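"""Synthetic mining-landscape generator.

Builds the four co-registered layers the selection analyses consume —
categorical habitat, topographic ruggedness (TRI), distance from mining
disturbance and distance from rocky habitat — plus an optional NDVI
layer, over a patchy mosaic of six habitat classes:

====  =======================
code  habitat
====  =======================
0     spinifex grassland
1     riparian
2     rocky
3     mine pits & waste dumps
4     other disturbed land
5     water
====  =======================

Habitat patches come from per-class smoothed Gaussian random fields
whose additive offsets are iterated until the argmax mosaic matches the
requested class proportions.  TRI is a non-negative roughness field
elevated on rocky cells (so the rocky class has the highest median TRI,
as in real Pilbara terrain); it lives on its own, coarser grid.
Distance layers are exact Euclidean cell-centre distances, zero on the
source class itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .raster import RasterGrid

__all__ = [
    "HABITAT_CODES",
    "HABITAT_NAMES",
    "DISTURBED_CODES",
    "Landscape",
    "generate_landscape",
]

HABITAT_CODES: dict[str, int] = {
    "spinifex": 0,
    "riparian": 1,
    "rocky": 2,
    "pits_waste": 3,
    "other_disturbed": 4,
    "water": 5,
}
HABITAT_NAMES = {v: k for k, v in HABITAT_CODES.items()}
DISTURBED_CODES = (3, 4)

DEFAULT_PROPORTIONS: dict[str, float] = {
    "spinifex": 0.44,
    "riparian": 0.07,
    "rocky": 0.25,
    "pits_waste": 0.11,
    "other_disturbed": 0.11,
    "water": 0.02,
}

# per-class NDVI means mirroring greenness contrasts at an arid mine site
NDVI_MEANS = {0: 0.16, 1: 0.36, 2: 0.19, 3: 0.09, 4: 0.11, 5: 0.05}


@dataclass
class Landscape:
    """Co-registered raster stack used by every selection analysis."""

    habitat: RasterGrid
    tri: RasterGrid
    dist_disturbance: RasterGrid
    dist_rocky: RasterGrid
    ndvi: RasterGrid | None = None

    @property
    def extent(self) -> tuple[float, float, float, float]:
        h = self.habitat
        return (h.origin_x, h.y_min, h.x_max, h.origin_y)

    def covariates_at(self, x, y) -> dict[str, np.ndarray]:
        """End-point covariate lookup used by both simulator and iSSF.

        Returns habitat code plus the continuous layers; callers decide
        how to dummy-code habitat.  Off-raster points get the habitat
        nodata sentinel.
        """
        return {
            "habitat": self.habitat.value_at(x, y),
            "tri": self.tri.value_at(x, y),
            "dist_disturbance": self.dist_disturbance.value_at(x, y),
            "dist_rocky": self.dist_rocky.value_at(x, y),
        }

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        for name in ("habitat", "tri", "dist_disturbance", "dist_rocky", "ndvi"):
            grid = getattr(self, name)
            if grid is not None:
                grid.write(os.path.join(directory, f"{name}.grid"))

    @classmethod
    def read(cls, directory) -> "Landscape":
        import os

        layers = {}
        for name in ("habitat", "tri", "dist_disturbance", "dist_rocky", "ndvi"):
            path = os.path.join(directory, f"{name}.grid")
            layers[name] = RasterGrid.read(path) if os.path.exists(path) else None
        if any(layers[n] is None for n in ("habitat", "tri", "dist_disturbance", "dist_rocky")):
            raise FileNotFoundError(f"{directory}: incomplete landscape layer set")
        return cls(**layers)


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_landscape(
    seed: int,
    n_rows: int = 400,
    n_cols: int = 400,
    cell_size: float = 10.0,
    proportions: Mapping[str, float] | None = None,
    smoothness: float = 24.0,
    tri_cell_size: float = 12.5,
    with_ndvi: bool = True,
) -> Landscape:
    """Generate a patchy six-class landscape with consistent layers.

    ``proportions`` maps class names to target cover fractions (must sum
    to 1 within 1e-9).  Patch size grows with ``smoothness`` (in cells).
    """
    props = dict(DEFAULT_PROPORTIONS if proportions is None else proportions)
    unknown = set(props) - set(HABITAT_CODES)
    if unknown:
        raise ValueError(f"unknown habitat class(es): {sorted(unknown)}")
    for name in HABITAT_CODES:
        props.setdefault(name, 0.0)
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions sum to {total!r}, expected 1")

    rng = np.random.default_rng(seed)
    classes = [name for name in HABITAT_CODES if props[name] > 0]
    fields = {name: _smooth_field(rng, (n_rows, n_cols), smoothness) for name in classes}

    # iterate additive offsets so the argmax mosaic hits target proportions
    offsets = {name: 0.0 for name in classes}
    n_cells = n_rows * n_cols
    stack = np.stack([fields[name] for name in classes])
    target = np.array([props[name] for name in classes])
    off = np.zeros(len(classes))
    for _ in range(200):
        lab = np.argmax(stack + off[:, None, None], axis=0)
        current = np.bincount(lab.ravel(), minlength=len(classes)) / n_cells
        err = target - current
        if np.abs(err).max() < 2e-3:
            break
        off += 1.5 * err
    offsets = dict(zip(classes, off))
    habitat_vals = np.empty((n_rows, n_cols))
    code_of = np.array([HABITAT_CODES[name] for name in classes])
    habitat_vals[:] = code_of[lab]

    origin_x, origin_y = 0.0, n_rows * cell_size
    habitat = RasterGrid(origin_x, origin_y, cell_size, habitat_vals, name="habitat")

    # distance layers: exact Euclidean cell-centre distances, 0 on source cells
    diagonal = float(np.hypot(n_rows, n_cols)) * cell_size  # finite "far" sentinel
    rocky_mask = habitat_vals == HABITAT_CODES["rocky"]
    dist_rocky_vals = ndimage.distance_transform_edt(
        ~rocky_mask, sampling=cell_size
    ) if rocky_mask.any() else np.full_like(habitat_vals, diagonal)
    disturbed_mask = np.isin(habitat_vals, DISTURBED_CODES)
    dist_dist_vals = ndimage.distance_transform_edt(
        ~disturbed_mask, sampling=cell_size
    ) if disturbed_mask.any() else np.full_like(habitat_vals, diagonal)
    dist_rocky = RasterGrid(origin_x, origin_y, cell_size, dist_rocky_vals, name="dist_rocky")
    dist_disturbance = RasterGrid(
        origin_x, origin_y, cell_size, dist_dist_vals, name="dist_disturbance"
    )

    # TRI on its own (coarser) grid: baseline roughness + rocky uplift
    extent_x, extent_y = n_cols * cell_size, n_rows * cell_size
    tri_cols = max(1, int(round(extent_x / tri_cell_size)))
    tri_rows = max(1, int(round(extent_y / tri_cell_size)))
    base = np.abs(_smooth_field(rng, (tri_rows, tri_cols), smoothness / 2)) * 0.6
    txs = origin_x + (np.arange(tri_cols) + 0.5) * tri_cell_size
    tys = origin_y - (np.arange(tri_rows) + 0.5) * tri_cell_size
    tx, ty = np.meshgrid(txs, tys)
    rocky_at_tri = habitat.value_at(tx.ravel(), ty.ravel()).reshape(tri_rows, tri_cols)
    rocky_at_tri = rocky_at_tri == HABITAT_CODES["rocky"]
    uplift = 0.9 + 0.5 * np.abs(_smooth_field(rng, (tri_rows, tri_cols), smoothness / 2))
    tri_vals = base + np.where(rocky_at_tri, uplift, 0.0)
    tri = RasterGrid(origin_x, origin_y, tri_cell_size, tri_vals, name="tri")

    ndvi = None
    if with_ndvi:
        means = np.vectorize(NDVI_MEANS.get)(habitat_vals.astype(int))
        ndvi_vals = np.clip(
            means + 0.04 * _smooth_field(rng, (n_rows, n_cols), smoothness / 2), 0.0, 1.0
        )
        ndvi = RasterGrid(origin_x, origin_y, cell_size, ndvi_vals, name="ndvi")

    return Landscape(habitat, tri, dist_disturbance, dist_rocky, ndvi)
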