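"""Per-tubule morphometry: arc length, tortuosity, doublet pairing and
termination order, plus class-level length summaries.

Tortuosity is the arc length divided by the end-to-end chord distance
(the standard estimator); it is computed on the raw trace, never on a
resampled one, to avoid smoothing bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GroupSummary, Polyline3D


@dataclass
class TubuleMeasurement:
    source_id: int
    tubule_class: str
    length_nm: float
    tortuosity: float
    pair_id: int | None = None
    terminates_first: bool | None = None


def arc_length(polyline: Polyline3D) -> float:
    """Sum of Euclidean segment lengths in nm; a single point has length 0."""
    pts = polyline.points
    if pts.shape[0] < 2:
        warnings.warn(f"polyline {polyline.source_id} has a single point; length 0")
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def tortuosity(polyline: Polyline3D) -> float:
    """Arc length / end-to-end distance; >= 1 up to numerical slack.

    Coincident endpoints (a closed trace) yield ``inf`` with a warning
    rather than an exception, so batch runs survive degenerate traces.
    """
    pts = polyline.points
    if pts.shape[0] < 2:
        warnings.warn(f"polyline {polyline.source_id} has a single point; tortuosity inf")
        return math.inf
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0.0:
        warnings.warn(f"polyline {polyline.source_id} endpoints coincide; tortuosity inf")
        return math.inf
    return arc_length(polyline) / chord


def cumulative_arc(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(polyline: Polyline3D, step: float) -> Polyline3D:
    """Arc-length-uniform resampling by linear interpolation.

    Endpoints are preserved exactly; the number of interior samples is chosen
    so the spacing is <= ``step``.  A step at or beyond the total length
    degenerates to the two endpoints.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    pts = polyline.points
    if pts.shape[0] < 2:
        return polyline
    s = cumulative_arc(pts)
    total = s[-1]
    n = max(2, int(math.ceil(total / step)) + 1)
    targets = np.linspace(0.0, total, n)
    new = np.column_stack([np.interp(targets, s, pts[:, k]) for k in range(3)])
    # collapse accidental duplicates (possible when input has repeated arcs)
    keep = np.concatenate([[True], np.any(np.diff(new, axis=0) != 0, axis=1)])
    return Polyline3D(
        new[keep],
        tubule_class=polyline.tubule_class,
        pair_id=polyline.pair_id,
        source_id=polyline.source_id,
    )


def _mean_intercurve_distance(a: Polyline3D, b: Polyline3D, n: int = 50) -> float:
    """Mean pointwise distance over n arc fractions of the shorter member."""
    la, lb = arc_length(a), arc_length(b)
    short, other = (a, b) if la <= lb else (b, a)
    ls = min(la, lb)
    if ls == 0:
        return float(np.linalg.norm(a.points[0] - b.points[0]))
    fracs = np.linspace(0.0, 1.0, n)
    ps = _points_at_arc(short, fracs * ls)
    po = _points_at_arc(other, fracs * ls)
    return float(np.mean(np.linalg.norm(ps - po, axis=1)))


def _points_at_arc(poly: Polyline3D, arcs: np.ndarray) -> np.ndarray:
    s = cumulative_arc(poly.points)
    return np.column_stack([np.interp(arcs, s, poly.points[:, k]) for k in range(3)])


def pair_doublets(polylines: list[Polyline3D], max_gap: float = 35.0) -> dict[int, int]:
    """Greedy mutual-nearest matching of tubules into doublet pairs.

    Returns a mapping ``source_id -> pair_id`` covering the matched tubules;
    unmatched tubules are absent (a valid outcome).  The match distance is
    the mean inter-curve distance over 50 evenly spaced arc fractions of the
    shorter member; pairs with mean distance <= ``max_gap`` nm are accepted.

    When both tubules carry a known A/B class, only A-B combinations are
    candidate pairs (a doublet is one A- and one B-tubule; two displaced
    doublets can bring same-class tubules arbitrarily close near the cilium
    centre).  Unknown-class tubules pair freely.
    """
    n = len(polylines)
    if n < 2:
        return {}
    dist = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = polylines[i].tubule_class, polylines[j].tubule_class
            if ci in ("A", "B") and ci == cj:
                continue
            dist[i, j] = dist[j, i] = _mean_intercurve_distance(polylines[i], polylines[j])
    assignment: dict[int, int] = {}
    used = np.zeros(n, dtype=bool)
    pair_id = 0
    # repeatedly take the globally closest mutual pair under the threshold
    while True:
        masked = np.where(used[:, None] | used[None, :], np.inf, dist)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if not np.isfinite(masked[i, j]) or masked[i, j] > max_gap:
            break
        assignment[polylines[i].source_id] = pair_id
        assignment[polylines[j].source_id] = pair_id
        used[i] = used[j] = True
        pair_id += 1
    return assignment


def termination_stats(polylines: list[Polyline3D]) -> tuple[float, pd.DataFrame]:
    """B-before-A termination statistics over paired A/B tubules.

    Returns ``(fraction_B_first, per_pair_table)``.  A pair is "B first" when
    its B member is strictly shorter.  Inverted pairs (B longer than A, seen
    occasionally in human beta cells) are flagged, not dropped.
    """
    by_pair: dict[int, dict[str, Polyline3D]] = {}
    for poly in polylines:
        if poly.pair_id is None or poly.tubule_class not in ("A", "B"):
            continue
        by_pair.setdefault(poly.pair_id, {})[poly.tubule_class] = poly
    rows = []
    for pid, members in sorted(by_pair.items()):
        if "A" not in members or "B" not in members:
            continue
        la, lb = arc_length(members["A"]), arc_length(members["B"])
        rows.append(
            dict(
                pair_id=pid,
                a_length_nm=la,
                b_length_nm=lb,
                delta_length_nm=la - lb,
                b_first=lb < la,
                inverted=lb > la,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["pair_id", "a_length_nm", "b_length_nm", "delta_length_nm", "b_first", "inverted"],
    )
    fraction = float(table["b_first"].mean()) if len(table) else float("nan")
    return fraction, table


def measure_tubules(polylines: list[Polyline3D]) -> pd.DataFrame:
    """Tidy per-tubule measurement table (length, tortuosity, class, pair)."""
    rows = [
        dict(
            source_id=poly.source_id,
            tubule_class=poly.tubule_class,
            length_nm=arc_length(poly),
            tortuosity_ratio=tortuosity(poly),
            pair_id=poly.pair_id,
        )
        for poly in polylines
    ]
    return pd.DataFrame(
        rows, columns=["source_id", "tubule_class", "length_nm", "tortuosity_ratio", "pair_id"]
    )


def summarize_lengths(
    measurements: pd.DataFrame,
    by: str = "tubule_class",
    value: str = "length_nm",
    units: str = "nm",
) -> list[GroupSummary]:
    """Per-class mean / sample SD (n-1) / n.  A single value gets SD 0 with a
    warning rather than NaN."""
    out = []
    for cls, grp in measurements.groupby(by, sort=True):
        vals = grp[value].to_numpy(float)
        if len(vals) == 1:
            warnings.warn(f"group {cls!r} has a single value; SD reported as 0")
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        out.append(GroupSummary(label=str(cls), mean=float(np.mean(vals)), sd=sd, n=len(vals), units=units))
    return out
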