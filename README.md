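# ciliamorph

Quantitative 3D morphometry of primary-cilium axonemes for volume electron
microscopy (FIB-SEM, serial-section electron tomography) and ultrastructural
expansion microscopy (U-ExM), built around pancreatic-islet beta-cell cilia.

Primary cilia of beta cells are solitary sensory organelles whose axoneme —
nine peripheral microtubule doublets (an A- and a B-tubule each) extending
from the basal body's triplets — deviates strongly from the textbook 9+0
arrangement: B-tubules terminate before A-tubules, and one or two doublets
leave the peripheral ring and cross toward the cilium centre, raising their
distance to the ciliary membrane from ~40 nm to ~100 nm. The cilia sit in
membrane invaginations (ciliary pockets) of very variable length and touch
neighbouring islet cells, acinar and endothelial cells, and cholinergic
axons across few-nanometre gaps. This package implements the measurements
behind those observations as a tested, reusable pipeline:

* **`morphometry`** — per-tubule arc length `L = Σ‖pᵢ₊₁ − pᵢ‖`, tortuosity
  `τ = L / ‖p_N − p_0‖ ≥ 1`, arc-uniform resampling, greedy mutual-nearest
  doublet pairing, B-before-A termination statistics, per-class
  mean ± SD (sample, n−1) summaries.
* **`profiles`** — anisotropy-aware Euclidean distance transform of the
  ciliary-membrane label, trilinear sampling of the field along each
  microtubule, 1-D Gaussian smoothing (σ = 3 points) of the profile, and
  detection of "major transitions" (smoothed distance > 70 nm sustained
  over ≥ 10 points).
* **`interactions`** — ciliary-pocket length by ring-enclosure profiling
  along the axis, cilium–cell contact patches (membrane voxels within a
  20 nm gap of another cell, 26-connected, size-filtered), contact census
  by neighbour class, and axon-contact / marker-positivity fractions
  (mean ± SD across animals).
* **`stats`** — U-ExM calibration against the 225 nm proximal-centriole
  "biological ruler" (factor = width/225), FWHM of intensity profiles,
  expansion-corrected nucleus size `√area / factor`, and unpaired
  two-tailed t-tests (pooled or Welch) computable directly from printed
  (mean, SD, n) summaries.
* **`synthetic`** — a generator of voxelized cilium scenes (label volumes
  at 4 / 1.307 / 8 nm voxels with membrane, lumen, parent cell, pocket,
  neighbours, axon) with exact per-tubule ground truth, so every
  measurement above is validated by parameter recovery.
* **`io`** — SWC / node-edge-CSV skeletons, TIFF / HDF5 label volumes with
  explicit (z, y, x) nm spacing, tidy measurement CSVs with unit-suffixed
  columns.

## Worked example

```bash
python analysis/01_simulate_scenes.py   # generate mouse + human scenes
python analysis/02_axoneme_morphometry.py
python analysis/03_membrane_profiles.py
python analysis/04_interaction_analysis.py
python analysis/05_calibration_stats.py
```

The morphometry step prints, for the simulated mouse axoneme:

```
--- mouse axoneme ---
  A-tubules: 4.55 +/- 0.14 um (n=9)
  B-tubules: 2.68 +/- 0.77 um (n=9)
  tortuosity 1.0003 (range 1.0000-1.0015)
  doublets paired: 9; B terminates first in 100% of pairs; inverted pairs: 0
```

i.e. the nine A-tubules average 4.55 µm (the mouse preset draws them at
4.57 ± 0.14 µm), every A–B pair is recovered, and all B-tubules terminate
first. The profiling step then finds exactly the displaced doublets planted
by the generator:

```
profiled 9 A-tubules (10253 points at one voxel per point)
  doublet 0: major transition, peak 105 nm (ground truth: displaced)
  doublet 3: major transition, peak 104 nm (ground truth: displaced)
  baseline (non-transition) distance: 41 nm median
```

— the two highlighted doublets peak at ~100 nm from the membrane while the
others stay at the ~40 nm ring, and the statistics step reproduces the
published cilium-length comparisons from their printed summaries:

```
ductal vs beta: t = 9.53, df = 61, p = 1.1e-13
ductal vs non_beta: t = 8.95, df = 41, p = 3.42e-11
beta vs non_beta: t = 0.45, df = 62, p = 0.655
```

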