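# Methods

## The problem and the model

Channel-space fNIRS analysis treats each source–detector pair as a
fixed anatomical location across infants. Diffuse optical tomography
replaces that assumption with an explicit geometric chain: a head model
warped to the infant's scalp measurements, an optode array registered
from placement measurements, a linear light-transport forward model
`y = J x` from nodal absorption change `x` (mm⁻¹) to channel optical
density change `y`, and a regularised inverse. `nirsdot` implements
five *processing streams* that differ only in which measurements feed
the chain — subject-specific or group-mean head measurements crossed
with subject-specific or group-mean array placements, plus a pure
channel-space stream — so the incremental effect of each assumption can
be isolated and measured.

## Geometry

**Landmark frame.** Iz at the origin, Nz on the positive y-axis, and a
rotation about y that levels the preauricular points' z-coordinates
(closed form: θ = atan2(d_z, d_x) of the Ar−Al vector; the branch is
fixed by requiring Ar on +x). Meshes are stored in mm; head
measurements cross the API in cm and are converted once.

**Curve walks.** A scalp path between two points is the trace of the
scalp surface in the cutting plane through the two points and a third
reference (Cz for the sagittal and coronal landmark curves, the surface
centroid otherwise). Closed section loops are split at the snapped
endpoints and disambiguated either by proximity to the reference point
("over the top") or by length ("short way"). On refined sphere meshes
the trace converges to the great-circle geodesic; at the default scalp
resolution (~4.4 mm edges) arc lengths are within 2 % of analytic
values. The head circumference is the closed scalp trace of the plane
through Nz and Iz spanned by the Nz−Iz and Ar−Al directions — on a
sphere with axis-aligned landmarks, the equator.

**Warping.** The model is first scaled isotropically by the
circumference ratio; thereafter the measurement with the largest
absolute error determines each step's factor (target/measured), applied
to that measurement's axis subset (Ar-Cz-Al → x,z; Nz-Cz-Iz → y,z;
circumference → x,y,z) until all errors are below the tolerances
(6 mm for the two arcs, 3 mm for circumference; a cap of 50 iterations
guards non-convergence, which is reported with the final errors rather
than silently accepted). The tolerance is deliberate: exact fitting of
three coupled arc measurements over-constrains the three axis scales
and produces implausible head shapes. Grey-matter surface, scalp
surface and landmarks ride along with the identical factor sequence, so
node count, ordering and parcel labels are invariant across warps —
all cross-stream offsets are computed by node id in a single reference
mesh (the cohort's constant-head-warp model).

**Array.** Each hemisphere's array is a staggered two-row template
(7 lower + 6 upper optodes, alternating roles; 17 source–detector pairs
at the nominal 2 cm). The row gap is √3/2 × spacing ≈ 17.3 mm so that
diagonal nearest-neighbour pairs are also at 2 cm in the flat template.
On the scalp, each row is laid out by arc length along its own
"parallel" curve (the lower row on the Iz→FPz lateral curve, lifted
rows on sampled offset curves toward CCPz), which preserves in-row
2 cm spacing exactly; diagonal channels bend to ~2.0–2.3 cm because a
flat rigid template has no isometric embedding on a convex scalp.
Placement rules: |x| ≥ 1.6 cm shifts the whole array one channel space
against the displacement sign; |y| > 1.6 cm excludes the infant (the
absolute-value reading is configurable to superior-only).

## Signal chain

Channel pruning uses an intensity floor (device-scale, default 10⁻³ of
unit full scale) and a cardiac quality index: the zero-lag correlation
of the two wavelengths band-passed to 0.5–2.5 Hz, threshold 0.75. A
dataset is dropped when more than 40 % of channels fail. Optical
density is referenced to the channel temporal mean. Motion correction
is two-stage: sliding-window amplitude/variance detection with a
smoothing-spline trend removal inside flagged segments, then a discrete
wavelet decomposition (db4, ≤ 4 levels) whose detail coefficients
outside 1.5 × IQR are zeroed. Residual artifacts exclude, per channel,
every trial whose −2..20 s block overlaps the artifact padded by ±4 s.
The band-pass is a 3rd-order zero-phase Butterworth at 0.02–0.06 Hz.
The MBLL uses packaged extinction coefficients (HbO₂ 710 / HHb 1075.6
at 780 nm; 1058 / 691.6 at 850 nm, cm⁻¹ M⁻¹) and the general DPF
equation (polynomial in wavelength, power law in age; DPF ≈ 5.3 at
780 nm and 4.3 at 850 nm for a 6-month-old). Trials need ≥ 60 %
looking time; subjects need ≥ 3 valid trials. Blocks are −2..20 s at
10 Hz (221 frames), baseline-corrected to the pre-stimulus mean.

## Forward model and inversion

The default sensitivity engine is the continuous-wave diffusion
Green's-function three-point product (Rytov),
`J(r) ∝ G(s,r) G(r,d) / G(s,d) · V(r)`, with
`G(ρ) = exp(−μ_eff ρ)/(4πDρ)`, sources inset one transport mean free
path, the scalp boundary approximated by image sources mirrored in the
channel's local tangent plane, and `V(r)` the node's tetrahedral volume
share (which makes the discrete rows invariant to local node density).
Homogeneous optical properties are packaged per wavelength
(μa ≈ 0.017–0.019 mm⁻¹, μs′ ≈ 0.7–0.8 mm⁻¹). The engine is an explicit
extension point: any callable producing a channel × node matrix on the
same mesh can replace it (e.g. a finite-element solver); everything
downstream is agnostic.

Reconstruction is zeroth-order Tikhonov in the underdetermined form,
`x = Jᵀ(JJᵀ + λ² max(diag JJᵀ) I)⁻¹ y`, λ = 0.1, restricted to
grey-matter volume nodes, factored once per subject and applied to all
221 frames; each wavelength is inverted separately and the pair is
converted to ΔHbO/ΔHbR by the per-node 2×2 extinction solve. Images are
mapped to the grey-matter surface by nearest volume GM node within
3 mm (the phantom's surface nodes are members of the volume cloud, so
the mapping is exact there). Masks: individual = aggregate |J| (column
sum over channels at 780 nm) ≥ 1 % of its maximum, mapped to the
surface; group = nodes present in ≥ ¾ of individual masks.

## Statistics

Group maps concatenate all response-window frames (12–16 s, 41 frames)
of all subjects into one vector per node and compare against the
concatenated baseline frames (−2..0 s, 21 frames) with a two-tailed
two-sample t-test (pooled variance by default; Welch is a switch). The
frames are treated as exchangeable observations — autocorrelation
within the block average is deliberately ignored, which inflates
degrees of freedom; this mirrors the concatenation convention of the
analysis this package reproduces and is retained for comparability,
not endorsed as optimal inference. Bonferroni correction uses the full
grey-matter surface node count for node maps and the full array channel
count (34) for channel maps; zero-variance (undefined) t values are
reported as NaN and never significant. Channel-space results are
carried to the cortex by fitting a plane to the scalp nodes within a
radius of the channel's scalp midpoint and walking the inward normal to
its first cortical intersection (Möller–Trumbore). The radius is 5 mm
on MRI-resolution scalp meshes; on the coarser phantom scalp
(~4.4 mm edges) the pipelines use 8 mm ≈ 2 edge lengths so that at
least three nodes support the fit, and the fit widens automatically if
the in-radius nodes are near-collinear.

## Synthetic data: what it emulates, and what it does not

The phantom is a four-layer concentric ellipsoid (default semi-axes
65 × 72 × 58 mm ≈ 43 cm circumference; ECT 7 mm, CSF 2 mm, GM 4 mm,
WM interior) with icosphere surfaces (642-node cortex, 2562-node
scalp), a Delaunay tetrahedral volume (~1500 nodes), longitude-sector
parcels, and analytic axis landmarks. Cohorts draw head circumference
from age-typical distributions (43.0 ± 1.3 cm at 5 months, 45.0 ± 1.3
at 8, 46.5 ± 1.4 at 12; the two arcs keep the phantom's proportions
± 0.5 cm), placements from N(0, 0.5 cm) × N(0, 0.4 cm) per hemisphere,
and per-subject response amplitudes 1 ± 0.2 µM HbO (HbR = −0.3 × HbO).
At 5 months the Nz-Cz-Iz measurement is recorded absent, as in the
emulated protocol. Scans forward-project a difference-of-gammas HRF
(peak 14 s, centred in the 12–16 s window — the analysis never fits an
HRF, so the shape is generator-only) at a fixed mid-temporal cortical
node with a 12 mm Gaussian kernel, through the subject's own geometry,
and add cardiac (5×10⁻⁴ OD at 1.4 Hz, shared across wavelengths),
linear drift, white noise (2×10⁻⁴ OD), Poisson-timed exponential
motion transients, a 3 % dead-channel rate, and Beta(8,2) looking
fractions. The event schedule alternates VS, NV, V, VS, V, NV at 25 s
spacing, five presentations each.

The phantom is *not* infant anatomy: no gyri, no heterogeneous tissue
in the forward model, one activation site, no between-condition
contrast. Passing tests therefore demonstrate the internal consistency
and the geometric mechanism of the pipeline — not that real infant
data would yield these effect sizes.

## Study sizes and numerical choices

The packaged studies run at desk scale: parameter recovery uses a
3-subject zero-variability, near-noiseless cohort (recovery is judged
on the group window-averaged image peak; in the zero-noise limit the
t-map is variance-dominated and its peak is not an amplitude
estimate); the stream comparison uses 20 subjects with placement
variability only; the combinatorial analysis uses 50 replicates over
sub-cohort sizes 10..N. With a 642-node cortex the internode distance
(~7.5 mm) quantises peak offsets, so the offset-versus-size curve can
be flat for cohorts whose full-sample peaks happen to sit a node or
two apart; the ordering of the streams' mean offsets is the robust
signature. Subjects whose placement draws put the array off the
registration curves are dropped, the synthetic analogue of the
poor-placement exclusion. Ties in peak extraction break to the lowest
node id; Jaccard with an empty union, zero-variance correlations and
undefined t values propagate as NaN with flags rather than exceptions.

## Known limitations

- The analytic semi-infinite diffusion model underestimates partial
  volume effects of CSF; absolute sensitivity magnitudes are not
  calibrated to a photon-transport gold standard (relative spatial
  structure is what the streams compare).
- Depth information is absent by design (no overlapping channels), so
  reconstruction is cortically constrained rather than tomographic.
- The concatenated-frames t-test overstates degrees of freedom; use
  the maps comparatively, not as calibrated p-values.
- WHO growth-standard z-scores are inputs; the package ships no growth
  reference tables.
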