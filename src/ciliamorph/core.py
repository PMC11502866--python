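"""Core data containers shared across the pipeline.

Conventions
-----------
* All world coordinates are in **nanometres** and ordered ``(z, y, x)`` to
  match numpy array indexing of label volumes.
* Voxel indices are 0-based; a world point ``p`` falls into voxel
  ``floor(p / spacing)`` (half-open voxels), and the *centre* of voxel ``i``
  sits at ``(i + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Recognised tubule classes for traced microtubules.
TUBULE_CLASSES = ("A", "B", "singlet", "triplet", "unknown")

#: Semantic classes a label id may map to.  Neighbor cells use the
#: ``neighbor:<type>`` form, e.g. ``neighbor:beta`` or ``neighbor:acinar``.
CORE_LABEL_CLASSES = (
    "background",
    "parent_cell",
    "cilium_membrane",
    "cilium_lumen",
    "axon",
    "nucleus",
)


@dataclass
class Polyline3D:
    """One traced microtubule: an ordered run of 3D points in nm (z, y, x)."""

    points: np.ndarray
    tubule_class: str = "unknown"
    pair_id: int | None = None
    source_id: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if pts.shape[0] < 1:
            raise ValueError("polyline needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("polyline coordinates must be finite")
        if pts.shape[0] > 1 and np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive points must be distinct")
        if self.tubule_class not in TUBULE_CLASSES:
            raise ValueError(f"unknown tubule class {self.tubule_class!r}")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class LabelVolume:
    """3D integer label array + per-axis voxel spacing (nm) + label table.

    ``label_table`` maps integer label ids to semantic class strings; every
    nonzero label present in the array must appear in the table.
    """

    array: np.ndarray
    spacing: tuple[float, float, float]
    label_table: Mapping[int, str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.ndim != 3:
            raise ValueError("label array must be 3D (z, y, x)")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("label array must be integer-typed")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive values (z, y, x) nm")
        table = {int(k): str(v) for k, v in dict(self.label_table).items()}
        present = np.unique(arr)
        missing = [int(v) for v in present if v != 0 and int(v) not in table]
        if missing:
            raise ValueError(f"labels missing from label table: {missing}")
        self.array = arr
        self.spacing = spacing
        self.label_table = table

    def ids_for_class(self, semantic: str) -> list[int]:
        return [k for k, v in self.label_table.items() if v == semantic]

    def require_class(self, semantic: str) -> int:
        ids = self.ids_for_class(semantic)
        if not ids:
            raise ValueError(f"volume has no label of class {semantic!r}")
        if len(ids) > 1:
            raise ValueError(f"multiple labels of class {semantic!r}: {ids}")
        return ids[0]

    def label_at(self, point_nm: np.ndarray) -> int:
        """Label under a world point (half-open voxel convention)."""
        idx = np.floor(np.asarray(point_nm, float) / np.asarray(self.spacing)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.array.shape)):
            raise IndexError(f"point {point_nm} outside volume")
        return int(self.array[tuple(idx)])


@dataclass
class GroupSummary:
    """Descriptive record (mean, sample SD, n) for one measurement group."""

    label: str
    mean: float
    sd: float
    n: int
    units: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class TTestResult:
    """Two-sample t-test outcome for group comparisons."""

    t: float
    df: float
    p: float
    method: str  # "student_pooled" | "welch"
    degenerate: bool = False


@dataclass
class DistanceProfile:
    """Membrane distances sampled along one microtubule.

    ``raw`` and ``smoothed`` are nm values indexed by resampled point index;
    ``sigma`` is the Gaussian smoothing scale in points.
    """

    source_id: int
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    sigma: float = 0.0
    pair_id: int | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.shape != self.raw.shape:
                raise ValueError("raw and smoothed profiles must have equal length")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
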