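"""Spatial-context quantification: ciliary pocket length, cilium-cell /
cilium-cilium / cilium-axon contacts, and group-level contact fractions.

Contacts operationalize the EM observation that cilia and neighbouring
membranes are separated by a few-nm gap rather than touching: a contact is
a patch of ciliary-membrane voxels lying within ``gap_max`` nm of another
cell's label, clustered with 26-connectivity and size-filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelVolume, Polyline3D
from .morphometry import cumulative_arc, resample_polyline

#: Neighbor classes reported by the contact census, in output order.
CENSUS_CLASSES = (
    "beta",
    "non_beta_islet",
    "endothelial",
    "acinar",
    "axon",
    "cilium",
    "unknown",
)


@dataclass
class ContactRecord:
    cilium_id: int
    neighbor_label: int
    neighbor_class: str
    voxel_count: int
    contact_area_nm2: float
    min_gap_nm: float


@dataclass
class PocketMeasurement:
    cilium_id: int
    pocket_length_nm: float
    enclosure_profile: np.ndarray  # fraction of probe ring in parent cell, per axis point
    arc_positions_nm: np.ndarray


def measure_pocket(
    volume: LabelVolume,
    axis: Polyline3D,
    parent_class: str = "parent_cell",
    membrane_radius: float = 125.0,
    enclosure_min: float = 0.75,
    probe_radius_extra: float = 28.0,
    step: float = 50.0,
    n_ring: int = 36,
    cilium_id: int = 0,
) -> PocketMeasurement:
    """Ciliary-pocket length from ring-enclosure profiling along the axis.

    The axis polyline must start at the basal-body end.  At each resampled
    axis point a ring of ``n_ring`` probe points at radius
    ``membrane_radius + probe_radius_extra`` (in the plane normal to the
    local axis direction) is labelled; the enclosure fraction is the share
    of ring points inside the parent cell.  The pocket is the initial
    contiguous run with fraction >= ``enclosure_min``; its arc length is the
    pocket length.
    """
    parent_ids = set(volume.ids_for_class(parent_class))
    if not parent_ids:
        raise ValueError(f"no label of class {parent_class!r} in volume")
    res = resample_polyline(axis, step)
    pts = res.points
    arcs = cumulative_arc(pts)
    # local tangents and an orthonormal ring frame per point
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    angles = np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False)
    radius = membrane_radius + probe_radius_extra
    spacing = np.asarray(volume.spacing)
    shape = np.asarray(volume.array.shape)

    fractions = np.empty(len(pts))
    for i, (p, t) in enumerate(zip(pts, tangents)):
        ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        ring = p + radius * (
            np.cos(angles)[:, None] * u[None, :] + np.sin(angles)[:, None] * v[None, :]
        )
        idx = np.floor(ring / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        if not inside.any():
            raise ValueError("pocket probe ring entirely outside the volume")
        lab = volume.array[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        hit = np.isin(lab, list(parent_ids))
        # out-of-bounds probe points count as not-parent
        fractions[i] = hit.sum() / n_ring

    enclosed = fractions >= enclosure_min
    if not enclosed[0]:
        pocket_len = 0.0
    else:
        last = int(np.argmin(enclosed)) - 1 if not enclosed.all() else len(enclosed) - 1
        pocket_len = float(arcs[last])
    return PocketMeasurement(
        cilium_id=cilium_id,
        pocket_length_nm=pocket_len,
        enclosure_profile=fractions,
        arc_positions_nm=arcs,
    )


def detect_contacts(
    volume: LabelVolume,
    cilium_class: str = "cilium_membrane",
    parent_class: str = "parent_cell",
    gap_max: float = 20.0,
    min_patch: int = 10,
    cilium_id: int = 0,
) -> list[ContactRecord]:
    """Find contact patches between the ciliary membrane and other cells.

    For every label that is neither the cilium itself, its lumen, the parent
    cell nor background, ciliary-membrane voxels within ``gap_max`` nm of
    that label are clustered (26-connectivity); clusters of at least
    ``min_patch`` voxels become :class:`ContactRecord` s.  Contact area is
    the voxel count times one voxel face area.
    """
    from scipy.spatial import cKDTree

    membrane_id = volume.require_class(cilium_class)
    skip = {0, membrane_id}
    skip.update(volume.ids_for_class(parent_class))
    skip.update(volume.ids_for_class("cilium_lumen"))
    membrane_mask = volume.array == membrane_id
    if not membrane_mask.any():
        raise ValueError("cilium membrane label absent from volume")
    spacing = np.asarray(volume.spacing)
    face_area = spacing[1] * spacing[2]
    mem_idx = np.argwhere(membrane_mask)
    records: list[ContactRecord] = []
    structure = np.ones((3, 3, 3), dtype=bool)
    margin = np.ceil(gap_max / spacing).astype(int) + 1
    for label_id in sorted(set(volume.label_table) - skip):
        target = volume.array == label_id
        if not target.any():
            continue
        # exact nearest-target distance for membrane voxels near the target:
        # query a KD-tree over the target's surface voxels (the nearest target
        # voxel to any outside point lies on the surface), limited to membrane
        # voxels within the target's bounding box plus the gap margin
        tgt_idx = np.argwhere(target)
        lo, hi = tgt_idx.min(axis=0) - margin, tgt_idx.max(axis=0) + margin
        cand = np.all((mem_idx >= lo) & (mem_idx <= hi), axis=1)
        if not cand.any():
            continue
        box = tuple(
            slice(max(int(l), 0), int(h) + 1) for l, h in zip(tgt_idx.min(axis=0), tgt_idx.max(axis=0))
        )
        sub = target[box]
        surface = sub & ~ndimage.binary_erosion(sub)
        surf_idx = np.argwhere(surface) + [b.start for b in box]
        tree = cKDTree(surf_idx * spacing)
        dist, _ = tree.query(mem_idx[cand] * spacing, distance_upper_bound=gap_max)
        hit = np.isfinite(dist)
        if not hit.any():
            continue
        near = np.zeros_like(membrane_mask)
        hit_idx = mem_idx[cand][hit]
        near[hit_idx[:, 0], hit_idx[:, 1], hit_idx[:, 2]] = True
        gap_map = np.full(volume.array.shape, np.inf)
        gap_map[hit_idx[:, 0], hit_idx[:, 1], hit_idx[:, 2]] = dist[hit]
        clusters, n_clusters = ndimage.label(near, structure=structure)
        for c in range(1, n_clusters + 1):
            cluster = clusters == c
            count = int(cluster.sum())
            if count < min_patch:
                continue
            records.append(
                ContactRecord(
                    cilium_id=cilium_id,
                    neighbor_label=label_id,
                    neighbor_class=volume.label_table[label_id],
                    voxel_count=count,
                    contact_area_nm2=count * face_area,
                    min_gap_nm=float(gap_map[cluster].min()),
                )
            )
    return records


def _census_class(semantic: str) -> str:
    if semantic.startswith("neighbor:"):
        semantic = semantic.split(":", 1)[1]
    return semantic if semantic in CENSUS_CLASSES else "unknown"


def contact_census(records: list[ContactRecord]) -> pd.DataFrame:
    """Per-cilium contact counts over the canonical neighbor classes."""
    cilia = sorted({r.cilium_id for r in records}) or [0]
    counts = {cid: {cls: 0 for cls in CENSUS_CLASSES} for cid in cilia}
    for r in records:
        counts[r.cilium_id][_census_class(r.neighbor_class)] += 1
    rows = [dict(cilium_id=cid, **counts[cid]) for cid in cilia]
    return pd.DataFrame(rows, columns=["cilium_id", *CENSUS_CLASSES])


def fraction_with_axon_contact(
    census: pd.DataFrame, groups: pd.Series | np.ndarray | list
) -> tuple[float, float, pd.Series]:
    """Percent of cilia with >= 1 axon contact, per group, then mean +/- SD.

    ``groups`` assigns each census row to a biological replicate (animal).
    Returns ``(mean_percent, sd_percent, per_group_percent)``; a single
    group yields SD 0 with a warning.
    """
    df = census.assign(_group=np.asarray(groups))
    per_group = df.groupby("_group")["axon"].apply(lambda s: 100.0 * (s >= 1).mean())
    return _mean_sd(per_group)


def marker_positivity(
    contacts: pd.DataFrame, group_col: str = "group", positive_col: str = "positive"
) -> tuple[float, float, pd.Series]:
    """Percent of axon contacts flagged marker-positive, per group, then
    mean +/- sample SD across groups.

    ``contacts`` has one row per axon contact with a boolean marker flag
    (input annotations; fluorescence colocalization itself is out of scope).
    Groups with zero contacts are excluded with a warning.
    """
    sizes = contacts.groupby(group_col).size()
    empty = sizes[sizes == 0].index.tolist()
    if empty:
        warnings.warn(f"groups with zero contacts excluded: {empty}")
    per_group = contacts.groupby(group_col)[positive_col].apply(
        lambda s: 100.0 * s.astype(bool).mean()
    )
    return _mean_sd(per_group)


def _mean_sd(per_group: pd.Series) -> tuple[float, float, pd.Series]:
    if len(per_group) == 1:
        warnings.warn("single group; SD undefined, reported as 0")
        return float(per_group.iloc[0]), 0.0, per_group
    return float(per_group.mean()), float(per_group.std(ddof=1)), per_group
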