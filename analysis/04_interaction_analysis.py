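#!/usr/bin/env python
"""Spatial context of the simulated mouse cilium: ciliary-pocket length,
contacts with neighbouring cells and the axon, contact census, and
population-level axon-contact / marker-positivity fractions matching the
published screening design (2 animals).

Reads the volume from 01_simulate_scenes.py; writes contact tables under
results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ciliamorph import interactions, io
from ciliamorph.core import Polyline3D
from ciliamorph.reference import (
    AXON_CONTACT_FRACTION,
    SYNAPSIN1_POSITIVE_FRACTION,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20244


def main() -> None:
    volume = io.read_label_volume(OUT / "mouse_scene.h5")
    # straight axis of the simulated cilium (base at the parent-cell slab)
    lumen = volume.require_class("cilium_lumen")
    zs, ys, xs = np.where(volume.array == lumen)
    sz, sy, sx = volume.spacing
    cy, cx = ys.mean() * sy, xs.mean() * sx
    axis = Polyline3D(
        np.array([[zs.min() * sz, cy, cx], [(zs.max() + 1) * sz, cy, cx]])
    )

    pocket = interactions.measure_pocket(volume, axis, membrane_radius=125.0, step=50.0)
    print(f"pocket length: {pocket.pocket_length_nm:.0f} nm "
          f"(enclosure >= 0.75 from the base)")

    records = interactions.detect_contacts(volume)
    census = interactions.contact_census(records)
    io.write_measurements(
        census.rename(columns={c: f"{c}_count" for c in census.columns
                               if c != "cilium_id"}),
        OUT / "mouse_contact_census.csv",
    )
    for r in records:
        print(f"contact: {r.neighbor_class:22s} gap {r.min_gap_nm:5.1f} nm, "
              f"area {r.contact_area_nm2:8.0f} nm^2")

    # population-level fractions: per-cilium axon contacts over 2 animals,
    # drawn at the published rates, then summarized the same way
    rng = np.random.default_rng(SEED)
    frames = []
    for animal in ("m1", "m2"):
        n = 850  # ~1700 cilia over 2 animals in the published screen
        frames.append(pd.DataFrame({
            "cilium_id": range(n),
            "axon": rng.random(n) < AXON_CONTACT_FRACTION.mean / 100.0,
            "animal": animal,
        }))
    screen = pd.concat(frames, ignore_index=True)
    mean, sd, per = interactions.fraction_with_axon_contact(screen, screen["animal"])
    print(f"axon-contact fraction: {mean:.1f} +/- {sd:.1f}% across animals "
          f"(per animal: {', '.join(f'{v:.1f}%' for v in per)})")

    contacts = screen[screen.axon].copy()
    contacts["positive"] = rng.random(len(contacts)) < (
        SYNAPSIN1_POSITIVE_FRACTION.mean / 100.0
    )
    m2, s2, _ = interactions.marker_positivity(
        contacts.rename(columns={"animal": "group"})
    )
    print(f"synapsin-1-positive axon contacts: {m2:.1f} +/- {s2:.1f}%")


if __name__ == "__main__":
    main()
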