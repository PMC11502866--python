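"""End-to-end validation suites: parameter recovery on synthetic scenes,
distance-field verification against a brute-force oracle, and the isotropy
simulation.

These suites are what the test suite and the acceptance script both run;
they exercise the full pipeline (generate -> voxelize -> measure) and
compare every measurement against the generator's ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from . import morphometry, profiles, synthetic
from .core import LabelVolume
from .interactions import detect_contacts, measure_pocket
from .stats import simulate_isotropy_experiment


def run_recovery_suite(
    n_scenes: int = 20,
    seed: int = 0,
    preset: str = "mouse-fibsem",
    theta_high: float = 70.0,
    min_run: int = 10,
) -> dict:
    """Parameter recovery over a seeded suite of voxelized scenes.

    For each scene the suite measures, with the ordinary pipeline operations:

    * per-tubule arc length vs the spec-requested length;
    * per-tubule tortuosity vs the generator's truth value;
    * doublet pairing vs the generator's pair assignment (recall);
    * displacement-event detection on each doublet's outer (A) membrane
      profile: sensitivity, false-positive rate, and peak-distance error
      against the 100 nm target;
    * pocket length vs the scene's true pocket length;
    * contact detection vs the constructed neighbor gaps.

    Returns a dict of aggregate metrics plus the per-tubule table.
    """
    rows = []
    pocket_rows = []
    contact_ok = []
    n_events_true = n_events_detected = n_false_positive = n_clean = 0
    peak_errors = []
    peaks = []
    pairs_true = pairs_found = 0

    for s in range(n_scenes):
        scene_seed = int(seed) * 1009 + s
        axo, scene_spec = synthetic.PRESETS[preset](scene_seed)
        skeletons, truth = synthetic.generate_axoneme(axo, seed=scene_seed)
        scene = synthetic.voxelize_scene(
            skeletons, scene_spec, truth=truth, events=axo.displacement_events
        )
        vox = max(scene.volume.spacing)

        # --- skeleton-level morphometry ---------------------------------
        requested = {}
        for i in range(axo.n_doublets):
            requested[("A", i)] = axo.a_lengths[i]
            requested[("B", i)] = axo.b_lengths[i]
            requested[("triplet", i)] = axo.triplet_length
        truth_idx = scene.truth.set_index("source_id")
        for poly in scene.skeletons:
            t = truth_idx.loc[poly.source_id]
            req = requested.get((poly.tubule_class, t["doublet_index"]), np.nan)
            length = morphometry.arc_length(poly)
            tort = morphometry.tortuosity(poly)
            rows.append(
                dict(
                    scene=s,
                    source_id=poly.source_id,
                    tubule_class=poly.tubule_class,
                    length_nm=length,
                    requested_nm=req,
                    length_error_nm=abs(length - req) if np.isfinite(req) else np.nan,
                    tortuosity=tort,
                    tortuosity_rel_error=abs(tort - t["true_tortuosity"])
                    / t["true_tortuosity"],
                )
            )

        # --- doublet pairing --------------------------------------------
        ab = [p for p in scene.skeletons if p.tubule_class in ("A", "B")]
        unpaired = [
            synthetic.Polyline3D(
                p.points, tubule_class=p.tubule_class, source_id=p.source_id
            )
            for p in ab
        ]
        assignment = morphometry.pair_doublets(unpaired)
        true_pairs = {}
        for p in ab:
            true_pairs.setdefault(p.pair_id, set()).add(p.source_id)
        for members in true_pairs.values():
            if len(members) != 2:
                continue
            pairs_true += 1
            a, b = sorted(members)
            if a in assignment and b in assignment and assignment[a] == assignment[b]:
                pairs_found += 1

        # --- displacement events on A profiles --------------------------
        field = profiles.membrane_distance_field(scene.volume)
        displaced = set(scene.events["doublet_index"].astype(int))
        targets = dict(
            zip(
                scene.events["doublet_index"].astype(int),
                scene.events["target_distance_nm"].astype(float),
            )
        )
        for poly in scene.skeletons:
            if poly.tubule_class != "A":
                continue
            doublet = int(truth_idx.loc[poly.source_id, "doublet_index"])
            prof = profiles.smooth_profile(
                profiles.sample_profile(poly, field), sigma=3.0
            )
            events = [
                e
                for e in profiles.detect_major_transitions(prof, theta_high, min_run)
                if e.classification == "major"
            ]
            if doublet in displaced:
                n_events_true += 1
                if events:
                    n_events_detected += 1
                    peak = max(e.peak_nm for e in events)
                    peaks.append(peak)
                    peak_errors.append(abs(peak - targets[doublet]))
            else:
                n_clean += 1
                if events:
                    n_false_positive += 1

        # --- pocket and contacts ----------------------------------------
        pocket = measure_pocket(
            scene.volume,
            scene.axis,
            membrane_radius=scene_spec.membrane_radius,
            step=50.0,
        )
        pocket_rows.append(
            dict(
                scene=s,
                true_nm=scene.pocket_length_true,
                measured_nm=pocket.pocket_length_nm,
                error_nm=abs(pocket.pocket_length_nm - scene.pocket_length_true),
            )
        )
        records = detect_contacts(scene.volume)
        found = {r.neighbor_label for r in records}
        expected = set(
            scene.contact_truth.loc[
                scene.contact_truth["expect_contact"], "label_id"
            ].astype(int)
        )
        contact_ok.append(found == expected)

    tubules = pd.DataFrame(rows)
    pockets = pd.DataFrame(pocket_rows)
    doublet_mask = tubules["tubule_class"].isin(["A", "B"])
    metrics = {
        "n_scenes": n_scenes,
        "voxel_nm": vox,
        "max_length_error_nm": float(
            tubules.loc[doublet_mask, "length_error_nm"].max()
        ),
        "max_tortuosity_rel_error": float(
            tubules.loc[doublet_mask, "tortuosity_rel_error"].max()
        ),
        "pairing_recall": pairs_found / pairs_true if pairs_true else float("nan"),
        "detection_sensitivity": n_events_detected / n_events_true
        if n_events_true
        else float("nan"),
        "false_positive_rate": n_false_positive / n_clean if n_clean else 0.0,
        "max_peak_error_nm": float(max(peak_errors)) if peak_errors else float("nan"),
        "mean_peak_nm": float(np.mean(peaks)) if peaks else float("nan"),
        "max_pocket_error_nm": float(pockets["error_nm"].max()),
        "contact_detection_exact": all(contact_ok),
        "n_true_events": n_events_true,
        "n_clean_doublets": n_clean,
    }
    return {"metrics": metrics, "tubules": tubules, "pockets": pockets}


def _random_membrane_volume(rng, shape=(64, 64, 64), spacing=(4.0, 4.0, 4.0)) -> LabelVolume:
    """Random blob membrane: upper tail of a smoothed noise field."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    thresh = np.quantile(noise, 0.97)
    mask = noise >= thresh
    if not mask.any():  # pathological draw; fall back to random voxels
        mask = rng.random(shape) > 0.999
        mask[0, 0, 0] = True
    labels = np.where(mask, 2, 0).astype(np.uint8)
    return LabelVolume(labels, spacing, {2: "cilium_membrane"})


def run_distance_field_check(
    n_volumes: int = 20, seed: int = 0, shape=(64, 64, 64)
) -> dict:
    """Distance field vs exhaustive nearest-membrane-voxel search.

    For each random volume the EDT-based field is compared with a KD-tree
    nearest-neighbour search over all membrane voxel centres (an independent
    exact oracle).  Returns the worst absolute deviation in voxel units.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_volumes):
        spacing = tuple(float(s) for s in rng.uniform(2.0, 8.0, size=3))
        vol = _random_membrane_volume(rng, shape=shape, spacing=spacing)
        field = profiles.membrane_distance_field(vol)
        sp = np.asarray(spacing)
        pts = np.argwhere(vol.array == 2) * sp
        tree = cKDTree(pts)
        query = np.indices(vol.array.shape).reshape(3, -1).T * sp
        oracle, _ = tree.query(query, k=1)
        diff_nm = np.abs(field.values.ravel() - oracle)
        worst = max(worst, float((diff_nm / sp.min()).max()))
    return {"n_volumes": n_volumes, "max_abs_deviation_voxels": worst}


def run_isotropy_suite(
    n_replicates: int = 100,
    seed: int = 0,
    factor: float = 4.2,
    noise: float = 0.03,
    n_pre: int = 25,
    n_post: int = 25,
    anisotropy: float = 0.2,
) -> dict:
    """Isotropy-validation simulation over seeded replicates.

    Under isotropic expansion the corrected-NCS t-test should not reject
    (p > 0.05) in the large majority of replicates; a single-axis stretch of
    ``anisotropy`` applied to linear dimensions should be flagged
    (p < 0.05).
    """
    null_pass = alt_flag = 0
    for r in range(n_replicates):
        rep_seed = int(seed) * 4099 + r
        iso = simulate_isotropy_experiment(
            factor=factor, noise=noise, n_pre=n_pre, n_post=n_post,
            anisotropy=0.0, quantity="area", seed=rep_seed,
        )
        if iso["ttest"].p > 0.05:
            null_pass += 1
        aniso = simulate_isotropy_experiment(
            factor=factor, noise=noise, n_pre=n_pre, n_post=n_post,
            anisotropy=anisotropy, quantity="linear", seed=rep_seed + 1,
        )
        if aniso["ttest"].p < 0.05:
            alt_flag += 1
    return {
        "n_replicates": n_replicates,
        "null_pass_rate": null_pass / n_replicates,
        "anisotropy_flag_rate": alt_flag / n_replicates,
    }
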