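"""Core in-memory containers shared across the pipeline.

All volumes live on an explicit grid (shape + 4x4 voxel-to-mm affine).  The
atlas grid is the canonical space: every statistical map is kept on it, and
region-level statistics travel as :class:`RegionVector`, the common currency
of all co-localization computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalImage",
    "StatMap",
    "LabelAtlas",
    "RegionVector",
    "CANONICAL_TEMPLATES",
]

#: Canonical receptor/transporter template order used for neurochemical
#: profiles: serotonergic receptors, dopamine receptors/transport, GABA,
#: glutamate, opioid, cannabinoid, noradrenaline and acetylcholine systems.
CANONICAL_TEMPLATES: tuple[str, ...] = (
    "5-HT1a", "5-HT1b", "5-HT2a", "5HT4",
    "D1", "D2", "DAT", "SERT", "FDOPA",
    "GABAa", "NMDA", "mGluR5",
    "MU", "CB1", "NAT", "VAChT",
)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class FunctionalImage:
    """4D voxel time-series grid (x, y, z, t) with affine and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("FunctionalImage data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class StatMap:
    """3D statistical map (t-contrast, LCOR, TFCE score, p-value ...)."""

    data: np.ndarray
    affine: np.ndarray
    label: str = "stat"
    df: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be 3D")
        self.affine = _check_affine(self.affine)

    def same_grid(self, other: "StatMap | LabelAtlas", tol: float = 1e-5) -> bool:
        return (
            self.data.shape == np.asarray(getattr(other, "data", getattr(other, "labels", None))).shape
            and np.allclose(self.affine, other.affine, atol=tol)
        )


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation (0 = background) plus region table.

    ``regions`` is an ordered DataFrame with columns ``id``, ``name``,
    ``x``, ``y``, ``z`` (centroid in mm, world coordinates).
    """

    labels: np.ndarray
    affine: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be nonnegative")
        self.affine = _check_affine(self.affine)
        ids = np.asarray(self.regions["id"])
        if len(ids) != len(set(ids.tolist())):
            raise ValueError("region ids must be unique")
        present = set(np.unique(self.labels).tolist()) - {0}
        if not present <= set(ids.tolist()):
            raise ValueError("atlas contains labels missing from the region table")

    @property
    def region_ids(self) -> np.ndarray:
        return np.asarray(self.regions["id"], dtype=int)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def centroids_mm(self) -> np.ndarray:
        return np.asarray(self.regions[["x", "y", "z"]], dtype=float)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class RegionVector:
    """Per-region scalar values aligned to an atlas region table."""

    values: np.ndarray
    region_ids: np.ndarray
    name: str = "values"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.values.ndim != 1 or self.values.shape != self.region_ids.shape:
            raise ValueError("values and region_ids must be 1D with equal length")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.region_ids, name=self.name)
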