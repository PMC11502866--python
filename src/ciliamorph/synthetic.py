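"""Synthetic cilium scenes with known ground truth.

The generator emulates the geometric and statistical structure of
volume-EM reconstructions of pancreatic-islet primary cilia:

* a basal body of 9 microtubule triplets whose C-tubules stop proximally,
  continuing distally as 9 doublets (A- and B-tubule 25 nm apart) arranged
  in a ring ~40 nm from the ciliary membrane;
* B-tubules terminating before their A-tubules;
* one or two doublets displaced from the ring toward the cilium centre,
  raising their membrane distance from ~40 nm to ~100 nm over a smooth
  ~500 nm transition;
* a ciliary pocket of variable length (parent-cell membrane wrapping the
  proximal cilium with only a few nm of clearance);
* neighbouring cells and an optional axon separated from the ciliary
  membrane by few-nm gaps.

Scenes are voxelized into :class:`~ciliamorph.core.LabelVolume` objects at
the study's voxel sizes (4 nm FIB-SEM, 1.307 nm tomography, 8 nm FIB-SEM)
and bundled with exact per-tubule truth tables, so every downstream
measurement can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GroupSummary, LabelVolume, Polyline3D

#: Fixed A-to-B offset within a doublet, nm (real doublet spacing is 23-30 nm).
DOUBLET_OFFSET_NM = 25.0

#: Arc span of the smoothstep blend for a displacement event, nm.
DISPLACEMENT_RAMP_NM = 500.0

# Default label ids used by the voxelizer.
LABEL_BACKGROUND = 0
LABEL_PARENT = 1
LABEL_MEMBRANE = 2
LABEL_LUMEN = 3
FIRST_NEIGHBOR_LABEL = 4


@dataclass
class AxonemeSpec:
    """Geometry of one synthetic axoneme.

    ``displacement_events`` entries are ``(doublet_index, onset_arc_nm,
    target_membrane_distance_nm)``; the named doublet bends smoothly toward
    the cilium axis until its A-tubule sits at the target distance from the
    membrane, then holds.
    """

    n_doublets: int = 9
    triplet_length: float = 500.0
    a_lengths: tuple[float, ...] = ()
    b_lengths: tuple[float, ...] = ()
    singlet_extension: float = 0.0
    displacement_events: tuple[tuple[int, float, float], ...] = ()
    wiggle_amplitude: float = 8.0
    baseline_membrane_distance: float = 40.0
    membrane_radius: float = 125.0
    allow_inverted: bool = False

    def __post_init__(self) -> None:
        if self.n_doublets < 0:
            raise ValueError("n_doublets must be >= 0")
        self.a_lengths = tuple(float(v) for v in self.a_lengths)
        self.b_lengths = tuple(float(v) for v in self.b_lengths)
        if len(self.a_lengths) != self.n_doublets or len(self.b_lengths) != self.n_doublets:
            raise ValueError(
                "a_lengths and b_lengths must each have one entry per doublet"
            )
        if not self.allow_inverted:
            for i, (a, b) in enumerate(zip(self.a_lengths, self.b_lengths)):
                if b > a:
                    raise ValueError(
                        f"doublet {i}: b_length {b} > a_length {a}; "
                        "set allow_inverted=True for inverted termination"
                    )
        for idx, onset, target in self.displacement_events:
            if not 0 <= idx < self.n_doublets:
                raise ValueError(f"displacement event names missing doublet {idx}")
            if target > self.membrane_radius:
                raise ValueError(
                    f"displacement target {target} nm exceeds membrane radius "
                    f"{self.membrane_radius} nm"
                )
        if self.baseline_membrane_distance >= self.membrane_radius:
            raise ValueError("baseline membrane distance must be < membrane radius")

    @property
    def ring_radius(self) -> float:
        return self.membrane_radius - self.baseline_membrane_distance


@dataclass
class SceneSpec:
    """Voxelization and tissue-context parameters for one scene."""

    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    membrane_radius: float = 125.0
    membrane_thickness: int = 3  # voxels
    pocket_length: float = 0.0
    pocket_gap: float = 8.0
    neighbor_gaps: tuple[tuple[str, float], ...] = ()
    axon_present: bool = False
    axon_gap: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive on all axes")
        if self.pocket_length < 0 or self.pocket_gap < 0 or self.axon_gap < 0:
            raise ValueError("lengths and gaps must be >= 0")
        for cls, gap in self.neighbor_gaps:
            if gap < 0:
                raise ValueError(f"neighbor gap for {cls!r} must be >= 0")


@dataclass
class GroundTruthScene:
    """Bundle of a voxelized scene and the exact truth behind it."""

    volume: LabelVolume
    skeletons: list[Polyline3D]
    axis: Polyline3D
    truth: pd.DataFrame
    events: pd.DataFrame
    pocket_length_true: float
    contact_truth: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# axoneme generation
# ---------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _radius_profile(z: np.ndarray, r0: float, events, membrane_radius: float) -> np.ndarray:
    """Radial position of a doublet's A-tubule along the axis."""
    r = np.full_like(z, r0)
    for onset, target_dist in sorted(events):
        target_r = membrane_radius - target_dist
        s = _smoothstep((z - onset) / DISPLACEMENT_RAMP_NM)
        r = r * (1.0 - s) + target_r * s
    return r


def _wiggle(z: np.ndarray, length: float, amplitude: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Smooth transverse wiggle: 3 low-frequency sinusoids per axis with
    random phases; total transverse magnitude bounded by ``amplitude``."""
    if amplitude == 0.0 or length == 0.0:
        zero = np.zeros_like(z)
        return zero, zero
    weights = np.array([0.5, 0.3, 0.2]) * amplitude / np.sqrt(2.0)
    out = []
    for _axis in range(2):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        w = np.zeros_like(z)
        for k, (a, phi) in enumerate(zip(weights, phases), start=1):
            w += a * np.sin(2.0 * np.pi * k * z / length + phi)
        out.append(w)
    return out[0], out[1]


def _truncate_at_arc(points: np.ndarray, target: float) -> np.ndarray:
    """Cut a finely sampled curve at exact arc length ``target`` (interpolated
    final point)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < target:  # curve arc >= z-extent, so this only guards rounding
        return points
    i = int(np.searchsorted(s, target))
    if i == 0:
        i = 1
    frac = (target - s[i - 1]) / (s[i] - s[i - 1])
    end = points[i - 1] + frac * (points[i] - points[i - 1])
    out = np.vstack([points[:i], end])
    return out


def _polyline_truth(points: np.ndarray) -> tuple[float, float]:
    # independent inline arc/chord computation for the truth table
    seg = np.sqrt(((points[1:] - points[:-1]) ** 2).sum(axis=1))
    length = float(seg.sum())
    chord = float(np.sqrt(((points[-1] - points[0]) ** 2).sum()))
    tort = length / chord if chord > 0 else float("inf")
    return length, tort


def generate_axoneme(
    spec: AxonemeSpec, seed: int, point_step: float = 8.0
) -> tuple[list[Polyline3D], pd.DataFrame]:
    """Generate the microtubule skeletons of one axoneme.

    Returns the polylines (A, B, and triplet C stubs per doublet, plus an
    optional distal singlet) and a truth table with one row per skeleton
    recording the exact arc length and tortuosity of the emitted points.

    The cilium axis runs along +z from the origin; doublet ``i`` sits at
    azimuth ``2*pi*i/n`` on a ring ``membrane_radius -
    baseline_membrane_distance`` from the axis.  Both members of a doublet
    (and its C stub) share the same wiggle and displacement, keeping the
    pair parallel at :data:`DOUBLET_OFFSET_NM`.
    """
    rng = np.random.default_rng(seed)
    polylines: list[Polyline3D] = []
    rows = []
    events_by_doublet: dict[int, list[tuple[float, float]]] = {}
    for idx, onset, target in spec.displacement_events:
        events_by_doublet.setdefault(idx, []).append((float(onset), float(target)))

    sid = 0

    def emit(points, cls, pair_id, doublet_index):
        nonlocal sid
        length, tort = _polyline_truth(points)
        poly = Polyline3D(points, tubule_class=cls, pair_id=pair_id, source_id=sid)
        polylines.append(poly)
        rows.append(
            dict(
                source_id=sid,
                tubule_class=cls,
                pair_id=pair_id,
                doublet_index=doublet_index,
                true_length_nm=length,
                true_tortuosity=tort,
                n_displacement_events=len(events_by_doublet.get(doublet_index, []))
                if cls in ("A", "B")
                else 0,
            )
        )
        sid += 1

    for i in range(spec.n_doublets):
        theta = 2.0 * np.pi * i / max(spec.n_doublets, 1)
        a_len, b_len = spec.a_lengths[i], spec.b_lengths[i]
        z = np.arange(0.0, max(a_len, spec.triplet_length) + point_step, point_step)
        r_a = _radius_profile(
            z, spec.ring_radius, events_by_doublet.get(i, []), spec.membrane_radius
        )
        wx, wy = _wiggle(z, a_len, spec.wiggle_amplitude, rng)
        cos_t, sin_t = np.cos(theta), np.sin(theta)

        def curve(radius_profile):
            x = radius_profile * cos_t + wx
            y = radius_profile * sin_t + wy
            return np.column_stack([z, y, x])

        emit(_truncate_at_arc(curve(r_a), a_len), "A", i, i)
        if b_len > 0:
            emit(_truncate_at_arc(curve(r_a - DOUBLET_OFFSET_NM), b_len), "B", i, i)
        if spec.triplet_length > 0:
            # C-tubule stub: offset tangentially from the B position, ends
            # proximally (before the transition zone)
            cx = (r_a - DOUBLET_OFFSET_NM) * cos_t - DOUBLET_OFFSET_NM * sin_t + wx
            cy = (r_a - DOUBLET_OFFSET_NM) * sin_t + DOUBLET_OFFSET_NM * cos_t + wy
            c_pts = np.column_stack([z, cy, cx])
            emit(_truncate_at_arc(c_pts, spec.triplet_length), "triplet", None, i)

    if spec.singlet_extension > 0 and spec.n_doublets > 0:
        # lone distal singlet continuing past the longest A-tubule, drifting
        # toward the centre
        a_len = max(spec.a_lengths)
        z = np.arange(a_len, a_len + spec.singlet_extension + point_step, point_step)
        drift = _smoothstep((z - a_len) / max(spec.singlet_extension, 1.0))
        r = spec.ring_radius * (1.0 - 0.6 * drift)
        pts = np.column_stack([z, r * np.sin(0.3), r * np.cos(0.3)])
        emit(_truncate_at_arc(pts, spec.singlet_extension), "singlet", None, -1)

    truth = pd.DataFrame(
        rows,
        columns=[
            "source_id",
            "tubule_class",
            "pair_id",
            "doublet_index",
            "true_length_nm",
            "true_tortuosity",
            "n_displacement_events",
        ],
    )
    return polylines, truth


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize_scene(
    skeletons: list[Polyline3D],
    scene: SceneSpec,
    truth: pd.DataFrame | None = None,
    events: tuple[tuple[int, float, float], ...] = (),
    cilium_length: float | None = None,
) -> GroundTruthScene:
    """Voxelize an axoneme into a labelled tissue scene.

    The membrane is a cylindrical shell of ``membrane_thickness`` voxels at
    ``membrane_radius``; the lumen fills the tube; the parent cell forms a
    basal slab and (over ``pocket_length``) a pocket wrapping the cilium with
    ``pocket_gap`` nm of clearance; neighbours and an optional axon occupy
    disjoint angular sectors at their requested surface gaps.  Returned
    skeletons are translated into the volume's world frame (volume corner at
    the origin).
    """
    sz, sy, sx = scene.voxel_spacing
    if scene.membrane_radius < 2 * max(sy, sx):
        raise ValueError("membrane radius below 2 voxels; shell not representable")

    if cilium_length is None:
        if skeletons:
            cilium_length = float(max(p.points[:, 0].max() for p in skeletons)) + 150.0
        else:
            cilium_length = 0.0  # no axoneme -> no cilium tube
    if scene.pocket_length > cilium_length:
        raise ValueError("pocket_length exceeds cilium length")

    shell = scene.membrane_thickness * sx
    r_out = scene.membrane_radius + shell
    max_gap = max(
        [g for _, g in scene.neighbor_gaps] + [scene.axon_gap if scene.axon_present else 0.0],
        default=0.0,
    )
    half_width = r_out + max(max_gap, scene.pocket_gap) + 60.0
    z0 = 10 * sz  # basal parent-cell slab
    z_top = z0 + cilium_length + 12 * sz

    nz = int(np.ceil(z_top / sz))
    ny = int(np.ceil(2 * half_width / sy))
    nx = int(np.ceil(2 * half_width / sx))
    cy, cx = ny * sy / 2.0, nx * sx / 2.0

    zc = (np.arange(nz) + 0.5) * sz
    yc = (np.arange(ny) + 0.5) * sy - cy
    xc = (np.arange(nx) + 0.5) * sx - cx
    rad = np.sqrt(yc[:, None] ** 2 + xc[None, :] ** 2)  # (ny, nx)
    ang = np.arctan2(yc[:, None], xc[None, :])

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    has_cilium = cilium_length > 0
    in_parent_slab = zc < z0
    in_cilium = (zc >= z0) & (zc < z0 + cilium_length)
    in_cap = has_cilium & (zc >= z0 + cilium_length) & (zc < z0 + cilium_length + shell)
    in_pocket = has_cilium & (zc >= z0) & (zc <= z0 + scene.pocket_length)
    in_distal = (zc > z0 + scene.pocket_length + 5 * sz) & (zc < z0 + cilium_length)

    labels[in_parent_slab] = LABEL_PARENT
    lumen2d = rad < scene.membrane_radius
    shell2d = (rad >= scene.membrane_radius) & (rad < r_out)
    labels[in_cilium] = np.where(lumen2d, LABEL_LUMEN, labels[in_cilium])
    labels[in_cilium] = np.where(shell2d, LABEL_MEMBRANE, labels[in_cilium])
    labels[in_cap] = np.where(rad < r_out, LABEL_MEMBRANE, labels[in_cap])

    # ciliary pocket: parent-cell material wrapping the proximal cilium
    pocket2d = rad >= r_out + scene.pocket_gap
    labels[in_pocket] = np.where(pocket2d, LABEL_PARENT, labels[in_pocket])

    # neighbours / axon in disjoint angular sectors of the distal region
    label_table = {
        LABEL_PARENT: "parent_cell",
        LABEL_MEMBRANE: "cilium_membrane",
        LABEL_LUMEN: "cilium_lumen",
    }
    sectors: list[tuple[str, float]] = list(scene.neighbor_gaps)
    if scene.axon_present:
        sectors.append(("axon", scene.axon_gap))
    contact_rows = []
    n_sec = len(sectors)
    next_label = FIRST_NEIGHBOR_LABEL
    for k, (cls, gap) in enumerate(sectors):
        phi = 2.0 * np.pi * k / n_sec
        halfw = np.pi / n_sec - 0.15
        dphi = np.angle(np.exp(1j * (ang - phi)))
        sector2d = (np.abs(dphi) <= halfw) & (rad >= r_out + gap)
        if cls == "axon":
            zmask = in_distal & (zc > z0 + cilium_length - 900.0)
        else:
            zmask = in_distal
        labels[zmask] = np.where(sector2d, next_label, labels[zmask])
        label_table[next_label] = cls
        contact_rows.append(
            dict(label_id=next_label, neighbor_class=cls, gap_nm=float(gap))
        )
        next_label += 1

    present = set(np.unique(labels).tolist())
    label_table = {k: v for k, v in label_table.items() if k in present}
    volume = LabelVolume(labels, scene.voxel_spacing, label_table)

    offset = np.array([z0, cy, cx])
    shifted = [
        Polyline3D(
            p.points + offset,
            tubule_class=p.tubule_class,
            pair_id=p.pair_id,
            source_id=p.source_id,
        )
        for p in skeletons
    ]
    axis = Polyline3D(
        np.array([[z0, cy, cx], [z0 + max(cilium_length, sz), cy, cx]]),
        tubule_class="unknown",
    )
    if truth is None:
        truth = pd.DataFrame(
            columns=[
                "source_id",
                "tubule_class",
                "pair_id",
                "doublet_index",
                "true_length_nm",
                "true_tortuosity",
                "n_displacement_events",
            ]
        )
    events_df = pd.DataFrame(
        [dict(doublet_index=i, onset_arc_nm=o, target_distance_nm=t) for i, o, t in events],
        columns=["doublet_index", "onset_arc_nm", "target_distance_nm"],
    )
    contact_truth = pd.DataFrame(
        contact_rows, columns=["label_id", "neighbor_class", "gap_nm"]
    )
    if len(contact_truth):
        contact_truth["expect_contact"] = contact_truth["gap_nm"] <= 20.0
    else:
        contact_truth["expect_contact"] = pd.Series(dtype=bool)
    return GroundTruthScene(
        volume=volume,
        skeletons=shifted,
        axis=axis,
        truth=truth.copy(),
        events=events_df,
        pocket_length_true=float(scene.pocket_length),
        contact_truth=contact_truth,
        seed=scene.seed,
    )


# ---------------------------------------------------------------------------
# presets and population-level simulation
# ---------------------------------------------------------------------------

def mouse_fibsem_specs(seed: int) -> tuple[AxonemeSpec, SceneSpec]:
    """Mouse FIB-SEM preset: 4 nm voxels, 9 doublets with A 4.57 +/- 0.14 um
    and B 3.03 +/- 1.01 um, 1-2 doublets displaced to 100 nm membrane
    distance, a variable-length pocket, two neighbouring cells (one within
    contact range, one beyond) and an axon at a few-nm gap."""
    rng = np.random.default_rng(seed)
    a = rng.normal(4570.0, 140.0, 9).clip(3800.0, None)
    b = np.minimum(rng.normal(3030.0, 1010.0, 9).clip(800.0, None), a - 200.0)
    n_disp = int(rng.integers(1, 3))
    doublets = rng.choice(9, size=n_disp, replace=False)
    events = tuple(
        (int(d), float(rng.uniform(1200.0, 2600.0)), 100.0) for d in doublets
    )
    axo = AxonemeSpec(
        n_doublets=9,
        triplet_length=500.0,
        a_lengths=tuple(a),
        b_lengths=tuple(b),
        displacement_events=events,
        wiggle_amplitude=8.0,
        baseline_membrane_distance=40.0,
        membrane_radius=125.0,
    )
    scene = SceneSpec(
        voxel_spacing=(4.0, 4.0, 4.0),
        membrane_radius=125.0,
        membrane_thickness=3,
        pocket_length=float(rng.uniform(400.0, 2400.0)),
        pocket_gap=8.0,
        neighbor_gaps=(
            ("neighbor:beta", float(rng.uniform(6.0, 14.0))),
            ("neighbor:acinar", float(rng.uniform(40.0, 60.0))),
        ),
        axon_present=True,
        axon_gap=10.0,
        seed=seed,
    )
    return axo, scene


def human_et_specs(seed: int) -> tuple[AxonemeSpec, SceneSpec]:
    """Human tomography preset: 1.307 nm voxels, shorter and more variable
    tubules (A 2.05 +/- 1.01 um, B 1.20 +/- 0.65 um), inverted termination
    allowed."""
    rng = np.random.default_rng(seed)
    a = rng.normal(2050.0, 1010.0, 9).clip(700.0, None)
    b = rng.normal(1200.0, 650.0, 9).clip(300.0, None)
    b = np.minimum(b, a * 1.1)  # rare inverted pairs tolerated
    events = ((int(rng.integers(0, 9)), float(rng.uniform(600.0, 1200.0)), 100.0),)
    axo = AxonemeSpec(
        n_doublets=9,
        triplet_length=450.0,
        a_lengths=tuple(a),
        b_lengths=tuple(b),
        displacement_events=events,
        wiggle_amplitude=10.0,
        baseline_membrane_distance=40.0,
        membrane_radius=120.0,
        allow_inverted=True,
    )
    scene = SceneSpec(
        voxel_spacing=(1.307, 1.307, 1.307),
        membrane_radius=120.0,
        membrane_thickness=3,
        pocket_length=float(rng.uniform(0.0, 800.0)),
        pocket_gap=8.0,
        neighbor_gaps=(("neighbor:non_beta_islet", float(rng.uniform(6.0, 14.0))),),
        axon_present=False,
        seed=seed,
    )
    return axo, scene


PRESETS = {"mouse-fibsem": mouse_fibsem_specs, "human-et": human_et_specs}


def generate_scene(preset: str = "mouse-fibsem", seed: int = 0) -> GroundTruthScene:
    """Generate and voxelize one full preset scene."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    axo, scene = PRESETS[preset](seed)
    skeletons, truth = generate_axoneme(axo, seed=seed)
    return voxelize_scene(
        skeletons, scene, truth=truth, events=axo.displacement_events
    )


def simulate_population(groups: list[GroupSummary], seed: int) -> pd.DataFrame:
    """Draw per-cell values from each group's normal law (floored at 0).

    Returns a tidy ``(group, value)`` table; reproducible under ``seed``.
    Flooring at zero slightly biases means upward when sd/mean is large.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for g in groups:
        if g.n < 1:
            raise ValueError(f"group {g.label!r} has n < 1")
        vals = np.maximum(rng.normal(g.mean, g.sd, g.n), 0.0)
        frames.append(pd.DataFrame({"group": g.label, "value": vals}))
    if not frames:
        return pd.DataFrame(columns=["group", "value"])
    return pd.concat(frames, ignore_index=True)
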