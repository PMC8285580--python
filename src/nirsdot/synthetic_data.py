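"""Synthetic phantoms, cohorts and forward-simulated scans.

Everything the pipeline consumes can be generated here: a four-layer
ellipsoidal head phantom (standing in for an MRI-derived infant head
model), subject cohorts with head-size and array-placement variability,
and dual-wavelength intensity scans in which a focal cortical
haemodynamic response is forward-projected to the channels and buried in
cardiac, drift, white and motion noise.  Ground truth (activation node,
per-subject parameters, seeds) is carried alongside every product so
recovery error can be computed without re-simulation.

The phantom is synthetic by construction: concentric ellipsoidal layers
(extra-cerebral tissue, CSF, grey matter, white matter interior) rather
than real infant anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import Delaunay, cKDTree

from .head_model import HeadMesh, HeadMeasurements, measure_head

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Subject",
    "make_phantom",
    "sample_cohort",
    "simulate_scan",
    "hrf",
    "default_activation_node",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Layered ellipsoid head phantom.

    Semi-axes are (x: left-right, y: front-back, z: up) in mm; layer
    thicknesses are measured inward from the scalp.  Defaults give a
    ~43 cm circumference, matching a 5-month-old infant head.
    """

    semi_axes: tuple[float, float, float] = (65.0, 72.0, 58.0)
    ect_thickness: float = 7.0
    csf_thickness: float = 2.0
    gm_thickness: float = 4.0
    surface_subdivisions: int = 3
    scalp_subdivisions: int = 4     # denser scalp for 5 mm plane fits
    n_parcels: int = 8

    def __post_init__(self) -> None:
        t = self.ect_thickness + self.csf_thickness + self.gm_thickness
        if min(self.ect_thickness, self.csf_thickness, self.gm_thickness) <= 0:
            raise ValueError("layer thicknesses must be positive")
        if t >= min(self.semi_axes):
            raise ValueError("layer thicknesses exceed the smallest semi-axis")


def _shell(semi_axes, depth: float, subdivisions: int) -> trimesh.Trimesh:
    unit = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    scale = np.asarray(semi_axes, float) - depth
    m = unit.copy()
    m.vertices = unit.vertices * scale
    return m


def _inside(points: np.ndarray, semi_axes, depth: float) -> np.ndarray:
    ax = np.asarray(semi_axes, float) - depth
    return np.einsum("ij,ij->i", points / ax, points / ax) <= 1.0 + 1e-9


def make_phantom(spec: PhantomSpec | None = None) -> HeadMesh:
    """Build the four-layer ellipsoid phantom as a :class:`HeadMesh`.

    Landmarks sit at the analytic ellipsoid axis points (Nz/Iz front and
    back, Al/Ar left and right, Cz on top) and the mesh is emitted
    already in the landmark frame (Iz at the origin, Nz on +y).
    """
    spec = spec or PhantomSpec()
    a = np.asarray(spec.semi_axes, float)
    d_csf = spec.ect_thickness                      # ECT/CSF interface depth
    d_gm = d_csf + spec.csf_thickness               # CSF/GM interface (gm surface)
    d_wm = d_gm + spec.gm_thickness                 # GM/WM interface

    scalp = _shell(a, 0.0, spec.scalp_subdivisions)
    gm_surf = _shell(a, d_gm, spec.surface_subdivisions)

    shells = [
        (0.0, 2), (d_csf / 2, 2),                   # ECT
        (d_csf, 2),                                 # CSF side of interface
        (d_gm, spec.surface_subdivisions),          # gm surface nodes (GM)
        (d_gm + spec.gm_thickness / 2, 2),          # mid-GM
        (d_wm + 3.0, 2),                            # shallow WM
    ]
    pts = []
    tissue = []
    for depth, sub in shells:
        v = _shell(a, depth, sub).vertices
        pts.append(v)
        if depth < d_csf - 1e-9:
            t = "ECT"
        elif depth < d_gm - 1e-9:
            t = "CSF"
        elif depth <= d_wm + 1e-9:
            t = "GM"
        else:
            t = "WM"
        tissue.extend([t] * len(v))
    inner = _shell(a, 0.0, 1).vertices * ((min(a) - d_wm - 3.0) / min(a)) * 0.6
    pts.append(inner)
    tissue.extend(["WM"] * len(inner))
    pts.append(np.zeros((1, 3)))
    tissue.append("WM")
    volume_nodes = np.vstack(pts)
    node_tissue = np.asarray(tissue)

    tets = Delaunay(volume_nodes).simplices
    centroids = volume_nodes[tets].mean(axis=1)
    in_csf = _inside(centroids, a, d_csf)
    in_gm = _inside(centroids, a, d_gm)
    in_wm = _inside(centroids, a, d_wm)
    tet_tissue = np.full(len(tets), "ECT", dtype=object)
    tet_tissue[in_csf & ~in_gm] = "CSF"
    tet_tissue[in_gm & ~in_wm] = "GM"
    tet_tissue[in_wm] = "WM"

    # equal-angle longitude sectors about z give ~equal-area parcels
    ang = np.arctan2(gm_surf.vertices[:, 1], gm_surf.vertices[:, 0])
    parcels = np.floor((ang + np.pi) / (2 * np.pi) * spec.n_parcels).astype(int)
    parcels = np.clip(parcels, 0, spec.n_parcels - 1)

    landmarks = {
        "Nz": np.array([0.0, a[1], 0.0]),
        "Iz": np.array([0.0, -a[1], 0.0]),
        "Al": np.array([-a[0], 0.0, 0.0]),
        "Ar": np.array([a[0], 0.0, 0.0]),
        "Cz": np.array([0.0, 0.0, a[2]]),
    }

    mesh = HeadMesh(
        volume_nodes=volume_nodes,
        tetrahedra=tets,
        tissue_labels=np.asarray(tet_tissue, dtype=object),
        gm_surface_nodes=gm_surf.vertices.copy(),
        gm_surface_faces=gm_surf.faces.copy(),
        scalp_surface_nodes=scalp.vertices.copy(),
        scalp_surface_faces=scalp.faces.copy(),
        parcel_labels=parcels,
        landmarks=landmarks,
        node_tissue=node_tissue,
    )
    # emit in the landmark frame: Iz at origin, Nz on +y, Ar/Al level in z
    shift = -mesh.landmarks["Iz"]
    mesh.volume_nodes = mesh.volume_nodes + shift
    mesh.gm_surface_nodes = mesh.gm_surface_nodes + shift
    mesh.scalp_surface_nodes = mesh.scalp_surface_nodes + shift
    mesh.landmarks = {k: v + shift for k, v in mesh.landmarks.items()}
    mesh.validate()
    return mesh

# ---------------------------------------------------------------------------
# cohorts


#: age-cohort head-circumference distributions (cm): mean, SD
_CIRC_BY_AGE = {5: (43.0, 1.3), 8: (45.0, 1.3), 12: (46.5, 1.4)}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic age cohort.

    Head-measurement means default to the age-typical circumference with
    Ar-Cz-Al and Nz-Cz-Iz arcs in the phantom's own proportions; at 5
    months the Nz-Cz-Iz measurement is not taken (recorded absent), as
    in the longitudinal protocol this generator emulates.  Placement
    displacements are zero-mean per hemisphere.  Activation is a focal
    grey-matter response (gamma-shaped HRF peaking inside the 12-16 s
    window) with per-subject amplitude jitter.
    """

    n_subjects: int = 20
    age_months: int = 5
    circumference_cm: tuple[float, float] | None = None  # (mean, SD)
    arc_sd_cm: float = 0.5
    placement_sd_cm: tuple[float, float] = (0.5, 0.4)    # x, y
    activation_node: int | None = None   # gm-surface node; None = default site
    activation_amplitude_um: float = 1.0
    activation_sigma_mm: float = 12.0
    amplitude_jitter: float = 0.2
    hbr_ratio: float = -0.3
    hrf_peak_s: float = 14.0
    cardiac_od: float = 5e-4
    cardiac_hz: float = 1.4
    drift_od_per_s: float = 2e-5
    white_od_sd: float = 2e-4
    motion_rate_hz: float = 0.005
    motion_od: float = 0.02
    p_dead_channel: float = 0.03
    trials_per_condition: int = 5
    looking_beta: tuple[float, float] = (8.0, 2.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.activation_amplitude_um < 0 or not np.isfinite(
            self.activation_amplitude_um
        ):
            raise ValueError("activation amplitude must be finite and >= 0")


@dataclass
class Subject:
    subject_id: str
    age_months: int
    measurements: HeadMeasurements
    placements: dict  # hemisphere -> PlacementMeasurement
    activation_node: int
    activation_amplitude_um: float
    seed: int


def default_activation_node(mesh: HeadMesh, hemisphere: str = "right") -> int:
    """A lateral mid-temporal grey-matter surface node well inside the
    array's field of view (used as the planted activation site)."""
    sign = 1.0 if hemisphere == "right" else -1.0
    centre = mesh.gm_surface_nodes.mean(axis=0)
    target = centre + np.array([sign * 100.0, 0.0, 10.0])
    return int(np.argmin(np.linalg.norm(mesh.gm_surface_nodes - target, axis=1)))


def sample_cohort(spec: CohortSpec, phantom: HeadMesh) -> list[Subject]:
    """Draw a subject cohort: head measurements ~ truncated normal,
    placements ~ normal(0, SD) per hemisphere, deterministic in the
    master seed."""
    from .array_registration import PlacementMeasurement

    rng = np.random.default_rng(spec.master_seed)
    base = measure_head(phantom)
    circ_mean, circ_sd = (
        spec.circumference_cm
        if spec.circumference_cm is not None
        else _CIRC_BY_AGE.get(spec.age_months, _CIRC_BY_AGE[5])
    )
    ar_ratio = base.ar_cz_al / base.circumference
    nz_ratio = base.nz_cz_iz / base.circumference
    act_node = (
        spec.activation_node
        if spec.activation_node is not None
        else default_activation_node(phantom)
    )
    seeds = np.random.SeedSequence(spec.master_seed).generate_state(spec.n_subjects)
    subjects = []
    for i in range(spec.n_subjects):
        circ = 0.0
        while circ <= 0:
            circ = rng.normal(circ_mean, circ_sd)
        ar = max(0.1, rng.normal(circ * ar_ratio, spec.arc_sd_cm))
        nz = max(0.1, rng.normal(circ * nz_ratio, spec.arc_sd_cm))
        meas = HeadMeasurements(
            circumference=circ,
            ar_cz_al=ar,
            nz_cz_iz=None if spec.age_months == 5 else nz,
        )
        placements = {
            hemi: PlacementMeasurement(
                hemi,
                x_disp=rng.normal(0.0, spec.placement_sd_cm[0]),
                y_disp=rng.normal(0.0, spec.placement_sd_cm[1]),
            )
            for hemi in ("left", "right")
        }
        amp = spec.activation_amplitude_um * max(
            0.0, rng.normal(1.0, spec.amplitude_jitter)
        )
        subjects.append(
            Subject(
                subject_id=f"sub-{i + 1:03d}",
                age_months=spec.age_months,
                measurements=meas,
                placements=placements,
                activation_node=act_node,
                activation_amplitude_um=amp,
                seed=int(seeds[i] % (2**31 - 1)),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# scans


def hrf(t: np.ndarray, peak_s: float = 14.0, undershoot: float = 0.25) -> np.ndarray:
    """Difference-of-gammas haemodynamic response, unit peak amplitude.

    The generator-only response model: the analysis block-averages data
    and never fits an HRF, so the shape only needs a plausible rise,
    a peak centred in the 12-16 s response window, and a small
    undershoot.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, float)
    shape1 = 6.0
    g1 = gamma_dist.pdf(t, shape1, scale=peak_s / (shape1 - 1))
    shape2 = 14.0
    g2 = gamma_dist.pdf(t, shape2, scale=1.8 * peak_s / (shape2 - 1))
    h = g1 / g1.max() - undershoot * g2 / g2.max()
    return h / h.max()


def event_schedule(trials_per_condition: int, isi_s: float = 25.0,
                   start_s: float = 30.0):
    """The alternating condition order (VS, NV, V, VS, V, NV) repeated
    until each condition reaches ``trials_per_condition`` presentations."""
    from .preprocessing import StimulusEvent

    order = ("VS", "NV", "V", "VS", "V", "NV")
    counts = {c: 0 for c in ("VS", "NV", "V")}
    events = []
    t = start_s
    k = 0
    while min(counts.values()) < trials_per_condition:
        cond = order[k % len(order)]
        k += 1
        if counts[cond] >= trials_per_condition:
            continue
        counts[cond] += 1
        events.append(StimulusEvent(onset_s=t, condition=cond))
        t += isi_s
    return events


def simulate_scan(
    subject: Subject,
    phantom: HeadMesh,
    array_spec,
    spec: CohortSpec,
    warped_mesh: HeadMesh | None = None,
    positions: dict | None = None,
):
    """Forward-simulate one subject's dual-wavelength scan.

    The phantom is warped to the subject's head measurements and the
    bilateral array registered from the subject's true placements (both
    can be passed pre-computed).  A focal HbO/HbR response at the true
    activation node (Gaussian spatial kernel) is forward-projected
    through the subject-specific sensitivity to channel OD, converted to
    intensity around channel baselines, and buried in cardiac, linear
    drift, white and Poisson-timed motion-spike noise.  Ground truth is
    stored in the returned scan's ``subject`` dict.
    """
    from .array_registration import define_scalp_axes, layout_array
    from .photon_model import compute_sensitivity
    from .preprocessing import FS, WAVELENGTHS, RawScan, extinction_matrix
    from .head_model import warp_head_model

    rng = np.random.default_rng(subject.seed)
    if warped_mesh is None:
        warped_mesh, _ = warp_head_model(phantom, subject.measurements)
    if positions is None:
        positions = {}
        for hemi in ("left", "right"):
            axes = define_scalp_axes(warped_mesh, hemi)
            positions.update(
                layout_array(warped_mesh, hemi, subject.placements[hemi],
                             array_spec, axes)
            )
    channels = [(c.source, c.detector) for c in array_spec.channels()]
    J = compute_sensitivity(warped_mesh, positions, channels)

    if mesh_gm_count := len(warped_mesh.gm_surface_nodes):
        if not 0 <= subject.activation_node < mesh_gm_count:
            raise ValueError("activation node outside the grey-matter surface")
    act_centre = warped_mesh.gm_surface_nodes[subject.activation_node]
    nodes = warped_mesh.volume_nodes[J.node_indices]
    dist2 = np.sum((nodes - act_centre) ** 2, axis=1)
    kernel = np.exp(-dist2 / (2.0 * spec.activation_sigma_mm**2))

    events = event_schedule(spec.trials_per_condition)
    duration = events[-1].onset_s + 40.0
    n = int(duration * FS)
    t = np.arange(n) / FS
    resp = np.zeros(n)
    for ev in events:
        if ev.condition != "V":
            continue
        tt = t - ev.onset_s
        win = tt >= 0
        resp[win] += hrf(tt[win], peak_s=spec.hrf_peak_s)

    E = extinction_matrix() / 10.0  # mm^-1 per µM
    hbo_node = subject.activation_amplitude_um * kernel
    hbr_node = spec.hbr_ratio * hbo_node
    n_ch = len(channels)
    od = np.zeros((n_ch, 2, n))
    for wi, wl in enumerate(WAVELENGTHS):
        dmua_spatial = E[wi, 0] * hbo_node + E[wi, 1] * hbr_node
        ch_gain = J.values[wl] @ dmua_spatial       # OD at response peak
        od[:, wi, :] = ch_gain[:, None] * resp[None, :]

    # physiological + instrumental noise, shared cardiac phase per channel
    for ch in range(n_ch):
        phase = rng.uniform(0, 2 * np.pi)
        cardiac = spec.cardiac_od * np.sin(2 * np.pi * spec.cardiac_hz * t + phase)
        drift = spec.drift_od_per_s * (t - t.mean()) * rng.normal(1.0, 0.3)
        od[ch, 0] += cardiac + drift
        od[ch, 1] += cardiac * rng.normal(1.0, 0.05) + drift
        n_spikes = rng.poisson(spec.motion_rate_hz * duration)
        for _ in range(n_spikes):
            t0 = rng.uniform(0, duration)
            amp = spec.motion_od * rng.standard_normal()
            tau = rng.uniform(0.3, 1.5)
            tr = np.maximum(t - t0, 0.0)
            spike = amp * np.exp(-tr / max(tau, 1e-3)) * (t >= t0)
            od[ch, 0] += spike
            od[ch, 1] += spike

    baselines = rng.lognormal(mean=0.0, sigma=0.3, size=(n_ch, 2, 1))
    dead = rng.random(n_ch) < spec.p_dead_channel
    baselines[dead] = 1e-5
    intensity = baselines * np.exp(-od)
    intensity *= 1.0 + spec.white_od_sd * rng.standard_normal(intensity.shape)
    intensity = np.maximum(intensity, 1e-12)

    looking = rng.beta(*spec.looking_beta, size=len(events))
    return RawScan(
        intensity=intensity,
        events=events,
        looking_fraction=looking,
        subject={
            "subject_id": subject.subject_id,
            "age_months": subject.age_months,
            "seed": subject.seed,
            "truth": {
                "activation_node": subject.activation_node,
                "amplitude_um": subject.activation_amplitude_um,
                "hbr_ratio": spec.hbr_ratio,
                "dead_channels": np.flatnonzero(dead).tolist(),
            },
        },
    )
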