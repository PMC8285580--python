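# nirsdot

Infant fNIRS diffuse optical tomography, built to answer one question:
**how much do the geometric assumptions of an fNIRS analysis change what
you infer from the data?**

Longitudinal infant studies record dual-wavelength (780/850 nm) optical
intensity between scalp-mounted sources and detectors. Classical
*channel-space* analysis compares responses channel by channel across
infants, implicitly assuming every infant has the same head and the
same array position. Image reconstruction instead warps a head model to
each infant's scalp measurements, registers the array from placement
photographs, models light transport, and inverts it to map haemoglobin
changes onto the cortical surface — at the price of a much heavier
pipeline. `nirsdot` implements both, plus the intermediate streams that
isolate each assumption, and the metrics that quantify how stream
choice moves statistical peaks and anatomical labels.

## What it does

- **Head model** (`head_model`): four-layer tetrahedral head mesh
  (extra-cerebral tissue, CSF, grey matter, white matter) with cranial
  landmarks; scalp curve-walks (planar-section traces), 10-5 positions,
  head measurements (circumference, Ar-Cz-Al, Nz-Cz-Iz), and iterative
  measurement-driven warping: after a global circumference scale, the
  measurement with the greatest error picks each step's warp factor,
  applied to its axis subset (Ar-Cz-Al → x,z; Nz-Cz-Iz → y,z;
  circumference → x,y,z) until all errors fall below 6/6/3 mm.
- **Array registration** (`array_registration`): bilateral 6-source /
  7-detector arrays (17 channels per hemisphere at 2 cm separation)
  placed from photographed displacements of a reference optode along
  scalp axes (Iz→FPz and preauricular→CCPz), with the 1.6 cm
  re-indexing / exclusion rules.
- **Pre-processing** (`preprocessing`): channel pruning (intensity
  floor + cardiac correlation index; dataset dropped if > 40 % of
  channels fail), optical density, spline + wavelet motion correction,
  0.02–0.06 Hz band-pass, the modified Beer–Lambert law with age- and
  wavelength-dependent differential pathlength factors, looking-time
  trial selection (≥ 60 %, minimum three valid trials), and −2..20 s
  block averaging (221 frames at 10 Hz).
- **Photon model** (`photon_model`): analytic diffusion
  Green's-function channel sensitivities (Rytov three-point form, image
  source for the scalp boundary; pluggable for a numerical solver),
  1 %-of-maximum individual grey-matter masks, ≥ ¾-of-cohort group
  masks, and zeroth-order Tikhonov reconstruction
  `x = Jᵀ(JJᵀ + λ² max(diag JJᵀ) I)⁻¹ y` with λ = 0.1, constrained to
  grey-matter nodes.
- **Statistics** (`statistics_mapping`): group node-wise and
  channel-wise two-sample T maps (response window 12–16 s vs 2 s
  pre-stimulus baseline, frames concatenated across subjects),
  Bonferroni corrected (nodes: grey-matter surface count; channels:
  34), and channel-to-cortex projection (local scalp plane fit within a
  radius, inward normal ray, Möller–Trumbore intersection with the
  cortical surface).
- **Comparison metrics** (`comparison_metrics`): peak node/channel,
  peak node offset in a common reference mesh, parcel-label match,
  Jaccard overlap of 50 %-thresholded maps, focality curves,
  head-size/growth correlations, and the combinatorial sub-cohort
  analysis of peak offset versus group size.
- **Synthetic data** (`synthetic_data`): layered ellipsoid head
  phantoms, cohorts with head-size and placement variability, and
  forward-simulated scans with a planted focal cortical response and
  cardiac/drift/white/motion noise — every pipeline stage is testable
  without any external data.
- **Pipelines** (`pipelines`, `cli`): the five processing streams
  (subject parameter, constant head warp, constant array position,
  constant parameter, channel space) end to end, plus the
  recruitment-to-analysis exclusion cascade.

## Worked example

```python
import numpy as np
from nirsdot import CohortSpec
from nirsdot.pipelines import run_study, individual_peak_offsets

# 12 infants, identical head sizes, realistic array-placement scatter
spec = CohortSpec(n_subjects=12, master_seed=11,
                  circumference_cm=(43.0, 0.0), arc_sd_cm=0.0,
                  placement_sd_cm=(0.5, 0.4))
study = run_study(spec, streams=("subject_parameter", "constant_head_warp",
                                 "constant_array_position",
                                 "constant_parameter"))
ref = study.reference_mesh.gm_surface_nodes
for name in ("constant_head_warp", "constant_array_position",
             "constant_parameter"):
    offs = individual_peak_offsets(study.results["subject_parameter"],
                                   study.results[name],
                                   study.phantom, ref, "right")
    print(f"{name:28s} mean peak offset {offs.mean():5.2f} mm")
```

prints

```
constant_head_warp           mean peak offset  0.00 mm
constant_array_position      mean peak offset  6.07 mm
constant_parameter           mean peak offset  6.07 mm
```

Read: when only array placement varies across infants, ignoring the
placement measurements (constant array position / constant parameter)
displaces each infant's reconstructed activation peak by ~6 mm on
average, while ignoring head-size measurements alone (constant head
warp) costs nothing — array position, not head size, is the assumption
that matters. The offsets are Euclidean distances between peak
grey-matter nodes of the window-averaged oxy-haemoglobin images,
measured in the constant-head-warp reference mesh.

A quick CLI round trip:

```bash
nirsdot simulate --n-subjects 4 --seed 0 --out scratch/cohort
nirsdot run-stream --stream subject_parameter --n-subjects 6 --seed 0 \
    --out scratch/results
```

## Limitations

The default forward engine is a homogeneous analytic diffusion model,
not a heterogeneous finite-element solver, and the head phantom is a
layered ellipsoid, not an MRI-derived anatomy; see `docs/methods.md`
for the full model description, parameter defaults, and what the
synthetic studies do and do not demonstrate.
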