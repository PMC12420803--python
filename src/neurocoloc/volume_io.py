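"""NIfTI I/O, grid alignment and parcellation.

Everything downstream of this module works on the atlas grid; this module is
the only place voxel grids are read, written or resampled.  Parcellation
(voxel map -> region vector) and its inverse (painting a region vector back
onto the atlas) are exact adjoints: ``parcellate(broadcast(v)) == v``.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .types import FunctionalImage, LabelAtlas, RegionVector, StatMap

__all__ = [
    "GridMismatchError",
    "load_functional",
    "load_stat_map",
    "load_atlas",
    "save_functional",
    "save_stat_map",
    "save_atlas",
    "parcellate",
    "broadcast",
    "resample_nearest",
]

GRID_ATOL = 1e-5


class GridMismatchError(ValueError):
    """Raised when two volumes are not on the same grid (shape + affine)."""


# ---------------------------------------------------------------------------
# NIfTI round trips


def load_functional(path: str | os.PathLike, tr_seconds: float | None = None) -> FunctionalImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return FunctionalImage(data=data, affine=img.affine, tr_seconds=tr_seconds)


def save_functional(img: FunctionalImage, path: str | os.PathLike) -> None:
    out = nib.Nifti1Image(img.data.astype(np.float32), img.affine)
    out.header.set_zooms((*out.header.get_zooms()[:3], img.tr_seconds))
    nib.save(out, str(path))


def load_stat_map(path: str | os.PathLike, label: str = "stat") -> StatMap:
    img = nib.load(str(path))
    return StatMap(data=np.asanyarray(img.dataobj, dtype=np.float64), affine=img.affine, label=label)


def save_stat_map(stat: StatMap, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(stat.data.astype(np.float32), stat.affine), str(path))


def load_atlas(nifti_path: str | os.PathLike, table_path: str | os.PathLike) -> LabelAtlas:
    img = nib.load(str(nifti_path))
    labels = np.asanyarray(img.dataobj)
    labels = np.rint(labels).astype(np.int32)
    regions = pd.read_csv(table_path, sep="\t")
    return LabelAtlas(labels=labels, affine=img.affine, regions=regions)


def save_atlas(atlas: LabelAtlas, nifti_path: str | os.PathLike, table_path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine), str(nifti_path))
    atlas.regions.to_csv(table_path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Parcellation


def _require_same_grid(shape_a, affine_a, shape_b, affine_b) -> None:
    if tuple(shape_a) != tuple(shape_b) or not np.allclose(affine_a, affine_b, atol=GRID_ATOL):
        raise GridMismatchError(
            f"volumes are not on the same grid: {tuple(shape_a)} vs {tuple(shape_b)}"
        )


def parcellate(stat: StatMap, atlas: LabelAtlas, statistic: str = "mean") -> RegionVector:
    """Reduce a voxel map to one value per atlas region.

    Non-finite voxels are ignored; a region with no finite voxel gets NaN
    (missing), which downstream statistics drop pairwise.
    """
    if statistic != "mean":
        raise ValueError(f"unsupported statistic: {statistic!r}")
    _require_same_grid(stat.data.shape, stat.affine, atlas.labels.shape, atlas.affine)
    ids = atlas.region_ids
    if len(ids) == 0:
        raise ValueError("atlas has no regions")
    labels = atlas.labels.ravel()
    data = stat.data.ravel()
    finite = np.isfinite(data) & (labels > 0)
    maxid = int(ids.max())
    sums = np.bincount(labels[finite], weights=data[finite], minlength=maxid + 1)
    counts = np.bincount(labels[finite], minlength=maxid + 1)
    values = np.full(len(ids), np.nan)
    nonzero = counts[ids] > 0
    values[nonzero] = sums[ids[nonzero]] / counts[ids[nonzero]]
    return RegionVector(values=values, region_ids=ids, name=stat.label)


def broadcast(vec: RegionVector, atlas: LabelAtlas, label: str | None = None) -> StatMap:
    """Paint a region vector onto the atlas grid (background -> NaN)."""
    if not np.array_equal(vec.region_ids, atlas.region_ids):
        raise ValueError("region vector is not aligned to this atlas")
    lut = np.full(int(atlas.region_ids.max()) + 1, np.nan)
    lut[vec.region_ids] = vec.values
    out = np.full(atlas.labels.shape, np.nan)
    inside = atlas.labels > 0
    out[inside] = lut[atlas.labels[inside]]
    return StatMap(data=out, affine=atlas.affine, label=label or vec.name)


def resample_nearest(atlas: LabelAtlas, target_shape, target_affine) -> LabelAtlas:
    """Nearest-neighbour label transfer onto a target grid.

    Labels are never interpolated: the output label set is a subset of
    ``{0} | input labels``.  Voxels mapping outside the source grid get 0.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(target_affine[:3, :3])) < 1e-12:
        raise ValueError("target affine is singular")
    # voxel(target) -> mm -> voxel(source); nearest centre, half-up ties
    src_from_tgt = np.linalg.inv(atlas.affine) @ target_affine
    idx = np.indices(tuple(target_shape), dtype=float).reshape(3, -1)
    coords = src_from_tgt[:3, :3] @ idx + src_from_tgt[:3, 3:4]
    nearest = np.floor(coords + 0.5).astype(int)
    shape = np.array(atlas.labels.shape)[:, None]
    inside = np.all((nearest >= 0) & (nearest < shape), axis=0)
    flat = np.zeros(coords.shape[1], dtype=atlas.labels.dtype)
    flat[inside] = atlas.labels[tuple(nearest[:, inside])]
    out = flat.reshape(tuple(target_shape))
    kept = set(np.unique(out).tolist()) - {0}
    regions = atlas.regions[atlas.regions["id"].isin(kept)].reset_index(drop=True)
    return LabelAtlas(labels=out.astype(atlas.labels.dtype), affine=target_affine, regions=regions)


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge length in mm (column norms of the linear part)."""
    return np.sqrt((np.asarray(affine, dtype=float)[:3, :3] ** 2).sum(axis=0))


def voxel_coords_mm(shape, affine: np.ndarray) -> np.ndarray:
    """(V, 3) world coordinates of every voxel centre, C-order raveling."""
    idx = np.indices(tuple(shape)).reshape(3, -1)
    return (affine[:3, :3] @ idx + affine[:3, 3:4]).T
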