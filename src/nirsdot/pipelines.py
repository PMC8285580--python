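"""End-to-end orchestration of the five processing streams.

A *stream* is a choice of which head measurements warp the head model
and which placement measurements register the array:

==========================  ==================  =================
stream                      head measurements   array placement
==========================  ==================  =================
subject_parameter           subject             subject
constant_head_warp          group mean          subject
constant_array_position     subject             group mean
constant_parameter          group mean          group mean
channel_space               group mean          group mean (projection only)
==========================  ==================  =================

The image streams run warp -> register -> sensitivity -> cortically
constrained reconstruction -> group node-wise statistics; the
channel-space stream skips reconstruction and runs channel-wise
statistics plus cortical projection of channel midpoints.  Group-mean
measurements are computed over the retained cohort.  Warped meshes,
scalp axes and sensitivities are cached by parameter value, so constant
streams reuse one registration across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import preprocessing as pp
from .array_registration import (
    ArraySpec,
    PlacementMeasurement,
    channel_scalp_midpoints,
    define_scalp_axes,
    layout_array,
)
from .head_model import HeadMeasurements, HeadMesh, warp_head_model
from .photon_model import (
    CorticalImage,
    compute_sensitivity,
    group_gm_mask,
    individual_gm_mask,
    make_reconstructor,
    mua_to_hb,
    window_average_image,
)
from .comparison_metrics import PeakResult, peak_element
from .statistics_mapping import TStatMap, channel_tmap, node_tmap, project_channel_to_cortex
from .synthetic_data import Subject

__all__ = [
    "STREAMS",
    "StreamConfig",
    "SubjectRecord",
    "StreamResult",
    "EXCLUSION_ORDER",
    "preprocess_subject",
    "group_mean_measurements",
    "group_mean_placements",
    "run_stream",
    "apply_exclusion_cascade",
    "node_hemisphere_mask",
]

#: stream name -> (head-measurement source, placement source)
STREAMS = {
    "subject_parameter": ("subject", "subject"),
    "constant_head_warp": ("group", "subject"),
    "constant_array_position": ("subject", "group"),
    "constant_parameter": ("group", "group"),
    "channel_space": ("group", "group"),
}


@dataclass(frozen=True)
class StreamConfig:
    stream: str = "subject_parameter"
    condition: str = "V"
    lambda_reg: float = 0.1
    mask_threshold: float = 0.01
    group_mask_fraction: float = 0.75
    response_window: tuple[float, float] = (12.0, 16.0)
    baseline_window: tuple[float, float] = (-2.0, 0.0)
    projection_radius_mm: float = 8.0
    pooled_t: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValueError(f"unknown stream {self.stream!r}; one of {list(STREAMS)}")


@dataclass
class SubjectRecord:
    """One retained subject's preprocessed data."""

    subject: Subject
    block: pp.BlockAverage
    od_block: np.ndarray          # (n_channels, 2, 221)
    valid: bool


@dataclass
class StreamResult:
    """Results bundle of one stream run on one cohort."""

    config: StreamConfig
    tmap: TStatMap
    group_mask: np.ndarray | None
    images: list | None                     # CorticalImage per subject
    window_images: np.ndarray | None        # (n_subjects, n_gm_nodes) HbO
    peaks: dict                             # hemisphere -> PeakResult
    projections: dict | None = None         # channel_space only
    manifest: dict = field(default_factory=dict)


def preprocess_subject(
    scan: pp.RawScan,
    age_years: float,
    condition: str = "V",
) -> SubjectRecord | None:
    """Full channel-level pipeline for one scan.

    Returns None when the dataset fails whole-dataset pruning; the
    record's ``valid`` flag reflects the minimum-trial rule.
    """
    mask = pp.prune_channels(scan)
    if not pp.dataset_valid(mask):
        return None
    od = pp.intensity_to_od(np.maximum(scan.intensity, 1e-12))
    corrected, artifacts = pp.correct_motion(od)
    exclusions = pp.flag_residual_trials(artifacts, scan.events)
    filtered = pp.bandpass(corrected)
    dpfs = tuple(pp.dpf(wl, age_years) for wl in scan.wavelengths)
    hbo, hbr = pp.mbll(filtered, dpfs, scan.channel_separation_cm)
    block = pp.select_trials_and_average(
        hbo, hbr, scan.events, scan.looking_fraction,
        condition=condition, exclusions=exclusions, valid_channels=mask,
        dpfs=dpfs, separation_cm=scan.channel_separation_cm,
    )
    od_block = pp.hb_to_od(block.hbo, block.hbr, dpfs, scan.channel_separation_cm)
    subject = scan.subject if isinstance(scan.subject, Subject) else None
    return SubjectRecord(
        subject=subject if subject is not None else scan.subject,
        block=block,
        od_block=od_block,
        valid=block.subject_valid,
    )


def group_mean_measurements(subjects: list[Subject]) -> HeadMeasurements:
    circ = np.mean([s.measurements.circumference for s in subjects])
    ar = [s.measurements.ar_cz_al for s in subjects]
    nz = [s.measurements.nz_cz_iz for s in subjects]
    return HeadMeasurements(
        circumference=float(circ),
        ar_cz_al=float(np.mean([v for v in ar if v is not None])) if any(
            v is not None for v in ar) else None,
        nz_cz_iz=float(np.mean([v for v in nz if v is not None])) if all(
            v is not None for v in nz) else None,
    )


def group_mean_placements(subjects: list[Subject]) -> dict[str, PlacementMeasurement]:
    out = {}
    for hemi in ("left", "right"):
        out[hemi] = PlacementMeasurement(
            hemi,
            x_disp=float(np.mean([s.placements[hemi].x_disp for s in subjects])),
            y_disp=float(np.mean([s.placements[hemi].y_disp for s in subjects])),
        )
    return out


def node_hemisphere_mask(reference_mesh: HeadMesh, hemisphere: str) -> np.ndarray:
    """Grey-matter surface nodes of one hemisphere (midline at x = 0)."""
    x = reference_mesh.gm_surface_nodes[:, 0]
    return x < 0 if hemisphere == "left" else x >= 0


class _GeometryCache:
    """Warp / registration / sensitivity results keyed by parameter value."""

    def __init__(self, phantom: HeadMesh, array_spec: ArraySpec):
        self.phantom = phantom
        self.array_spec = array_spec
        self._mesh: dict = {}
        self._axes: dict = {}
        self._layout: dict = {}

    @staticmethod
    def _mkey(m: HeadMeasurements):
        return (round(m.circumference, 4),
                None if m.ar_cz_al is None else round(m.ar_cz_al, 4),
                None if m.nz_cz_iz is None else round(m.nz_cz_iz, 4))

    def mesh(self, measurements: HeadMeasurements) -> HeadMesh:
        k = self._mkey(measurements)
        if k not in self._mesh:
            warped, _ = warp_head_model(self.phantom, measurements)
            self._mesh[k] = warped
        return self._mesh[k]

    def positions(self, measurements: HeadMeasurements,
                  placements: dict[str, PlacementMeasurement]) -> dict:
        mk = self._mkey(measurements)
        pk = tuple((h, round(placements[h].x_disp, 4), round(placements[h].y_disp, 4))
                   for h in ("left", "right"))
        key = (mk, pk)
        if key not in self._layout:
            mesh = self.mesh(measurements)
            pos = {}
            for hemi in ("left", "right"):
                ak = (mk, hemi)
                if ak not in self._axes:
                    self._axes[ak] = define_scalp_axes(mesh, hemi)
                pos.update(layout_array(mesh, hemi, placements[hemi],
                                        self.array_spec, self._axes[ak]))
            self._layout[key] = pos
        return self._layout[key]


def _reconstruct_subject(
    mesh: HeadMesh,
    positions: dict,
    record: SubjectRecord,
    array_spec: ArraySpec,
    config: StreamConfig,
) -> tuple[CorticalImage, np.ndarray]:
    """Reconstruct one subject's cortical image under assumed geometry.

    Returns (image, individual gm mask)."""
    from scipy.spatial import cKDTree

    channels = [(c.source, c.detector) for c in array_spec.channels()]
    J = compute_sensitivity(mesh, positions, channels)
    keep = np.asarray(record.block.valid_channels, bool)
    Jk = J.restrict_channels(keep)
    mask = individual_gm_mask(Jk, mesh, threshold_fraction=config.mask_threshold)

    dmua = {}
    for wi, wl in enumerate(J.values):
        W = make_reconstructor(Jk.values[wl], config.lambda_reg)
        dmua[wl] = W @ record.od_block[keep, wi, :]       # (n_nodes, 221)
    hbo_vol, hbr_vol = mua_to_hb(dmua)

    tree = cKDTree(mesh.volume_nodes[J.node_indices])
    dist, idx = tree.query(mesh.gm_surface_nodes)
    ok = dist <= 3.0
    n_frames = record.od_block.shape[-1]
    hbo = np.zeros((len(mesh.gm_surface_nodes), n_frames))
    hbr = np.zeros_like(hbo)
    hbo[ok] = hbo_vol[idx[ok]]
    hbr[ok] = hbr_vol[idx[ok]]
    image = CorticalImage(
        hbo=hbo, hbr=hbr, time=record.block.time, mask=mask,
        lambda_reg=config.lambda_reg,
    )
    return image, mask


def run_stream(
    config: StreamConfig,
    phantom: HeadMesh,
    array_spec: ArraySpec,
    records: list[SubjectRecord],
    cache: _GeometryCache | None = None,
) -> StreamResult:
    """Execute one processing stream on a preprocessed cohort."""
    records = [r for r in records if r.valid]
    if not records:
        raise ValueError("cohort empty after exclusions")
    cache = cache or _GeometryCache(phantom, array_spec)
    subjects = [r.subject for r in records]
    head_src, place_src = STREAMS[config.stream]
    mean_meas = group_mean_measurements(subjects)
    mean_place = group_mean_placements(subjects)
    channel_ids = [c.channel_id for c in array_spec.channels()]
    n_gm = len(phantom.gm_surface_nodes)

    manifest = {
        "stream": config.stream,
        "n_subjects": len(records),
        "config": asdict(config),
        "group_mean_circumference_cm": mean_meas.circumference,
    }

    if config.stream == "channel_space":
        mesh = cache.mesh(mean_meas)
        positions = cache.positions(mean_meas, mean_place)
        tmap = channel_tmap(
            [r.block for r in records], channel_ids,
            response_window=config.response_window,
            baseline_window=config.baseline_window,
            n_comparisons=len(channel_ids), pooled=config.pooled_t,
        )
        mids = channel_scalp_midpoints(mesh, positions, array_spec)
        projections = {}
        for ch in array_spec.channels():
            mid = mids[ch.channel_id]
            pt, node, parcel = project_channel_to_cortex(
                mesh, mid, radius_mm=config.projection_radius_mm
            )
            projections[ch.channel_id] = {
                "point": pt, "gm_node": node, "parcel": parcel,
                "hemisphere": ch.hemisphere,
            }
        peaks = {}
        for hemi in ("left", "right"):
            hemi_mask = np.array([c.hemisphere == hemi
                                  for c in array_spec.channels()])
            dom = tmap.in_domain & hemi_mask & np.isfinite(tmap.t)
            if dom.any():
                pk = peak_element(tmap.t, dom, hemisphere=hemi)
                proj = projections[channel_ids[pk.element]]
                peaks[hemi] = PeakResult(
                    element=proj["gm_node"], value=pk.value,
                    coordinates=proj["point"], parcel_label=proj["parcel"],
                    hemisphere=hemi,
                )
        return StreamResult(config=config, tmap=tmap, group_mask=None,
                            images=None, window_images=None, peaks=peaks,
                            projections=projections, manifest=manifest)

    images, masks = [], []
    for rec in records:
        meas = rec.subject.measurements if head_src == "subject" else mean_meas
        plc = rec.subject.placements if place_src == "subject" else mean_place
        mesh = cache.mesh(meas)
        positions = cache.positions(meas, plc)
        image, mask = _reconstruct_subject(mesh, positions, rec, array_spec, config)
        images.append(image)
        masks.append(mask)
    gmask = group_gm_mask(masks, fraction=config.group_mask_fraction)
    for im in images:
        im.group_mask_applied = True
    tmap = node_tmap(
        images, gmask, n_gm,
        response_window=config.response_window,
        baseline_window=config.baseline_window,
        pooled=config.pooled_t,
    )
    window_images = np.stack([
        window_average_image(im.hbo, im.time, config.response_window)
        for im in images
    ])
    ref_mesh = cache.mesh(mean_meas)
    peaks = {}
    for hemi in ("left", "right"):
        dom = gmask & node_hemisphere_mask(phantom, hemi) & np.isfinite(tmap.t)
        if dom.any():
            peaks[hemi] = peak_element(
                tmap.t, dom,
                coordinates=ref_mesh.gm_surface_nodes,
                parcel_labels=phantom.parcel_labels,
                hemisphere=hemi,
            )
    return StreamResult(config=config, tmap=tmap, group_mask=gmask,
                        images=images, window_images=window_images,
                        peaks=peaks, manifest=manifest)


# ---------------------------------------------------------------------------
# exclusion cascade

#: fixed order of the recruitment-to-analysis exclusion cascade
EXCLUSION_ORDER = (
    "withdrawn",
    "missed_visit",
    "no_nirs",
    "fussy",
    "missing_photos",
    "missing_video",
    "missing_markers",
    "technical",
    "poor_placement",
    "pruning_below_threshold",
    "insufficient_trials",
    "missing_circumference",
)


def apply_exclusion_cascade(roster: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Assign each enrolled dataset its terminal status.

    ``roster`` has one row per dataset and one boolean column per
    criterion (missing columns count as all-False).  The first
    applicable criterion in the fixed cascade order is the terminal
    status; rows with no flags are retained.  Returns (ledger, retained
    count); ledger conservation (retained = enrolled − sum of exclusive
    per-criterion counts) holds by construction.
    """
    status = []
    for _, row in roster.iterrows():
        terminal = "retained"
        for crit in EXCLUSION_ORDER:
            if crit in roster.columns and bool(row[crit]):
                terminal = crit
                break
        status.append(terminal)
    ledger = roster.copy()
    ledger["status"] = status
    retained = int((ledger["status"] == "retained").sum())
    return ledger, retained


# ---------------------------------------------------------------------------
# whole-study convenience

@dataclass
class StudyResult:
    phantom: HeadMesh
    array_spec: ArraySpec
    cohort: list
    records: list
    results: dict                     # stream -> StreamResult
    reference_mesh: HeadMesh          # constant-head-warp model (offset space)


def run_study(
    cohort_spec,
    streams=("subject_parameter", "constant_head_warp",
             "constant_array_position", "constant_parameter", "channel_space"),
    phantom: HeadMesh | None = None,
    array_spec: ArraySpec | None = None,
    config: StreamConfig | None = None,
) -> StudyResult:
    """Simulate a cohort and run the requested processing streams on it."""
    from .array_registration import bright_array_spec
    from .synthetic_data import make_phantom, sample_cohort, simulate_scan

    phantom = phantom if phantom is not None else make_phantom()
    array_spec = array_spec or bright_array_spec()
    base = config or StreamConfig()
    cohort = sample_cohort(cohort_spec, phantom)
    age_years = cohort_spec.age_months / 12.0

    records = []
    kept_subjects = []
    for subject in cohort:
        try:
            scan = simulate_scan(subject, phantom, array_spec, cohort_spec)
        except ValueError:
            # registration off the curve domain: the real-world analogue is
            # exclusion for poor headgear placement
            continue
        rec = preprocess_subject(scan, age_years, condition=base.condition)
        if rec is None or not rec.valid:
            continue
        rec.subject = subject
        records.append(rec)
        kept_subjects.append(subject)

    cache = _GeometryCache(phantom, array_spec)
    results = {}
    for stream in streams:
        cfg = StreamConfig(**{**asdict(base), "stream": stream})
        results[stream] = run_stream(cfg, phantom, array_spec, records, cache)
    reference_mesh = cache.mesh(group_mean_measurements(kept_subjects))
    return StudyResult(
        phantom=phantom,
        array_spec=array_spec,
        cohort=kept_subjects,
        records=records,
        results=results,
        reference_mesh=reference_mesh,
    )


def individual_peak_offsets(
    result_a: StreamResult,
    result_b: StreamResult,
    phantom: HeadMesh,
    reference_nodes: np.ndarray,
    hemisphere: str,
) -> np.ndarray:
    """Per-subject peak node offset (mm) between two image streams.

    Peaks are taken in each subject's HbO window-averaged image within
    the stream's group mask restricted to the hemisphere; offsets are
    Euclidean distances of the two peak node ids in the reference-space
    mesh (the constant-head-warp model)."""
    from .comparison_metrics import peak_node_offset

    hemi = node_hemisphere_mask(phantom, hemisphere)
    offs = []
    for wa, wb in zip(result_a.window_images, result_b.window_images):
        dom_a = result_a.group_mask & hemi
        dom_b = result_b.group_mask & hemi
        pa = peak_element(wa, dom_a)
        pb = peak_element(wb, dom_b)
        offs.append(peak_node_offset(pa, pb, reference_nodes))
    return np.asarray(offs)


def make_subcohort_peaks_fn(
    result_a: StreamResult,
    result_b: StreamResult,
    phantom: HeadMesh,
    hemisphere: str,
    n_gm: int | None = None,
):
    """Closure for the combinatorial analysis: sub-cohort indices ->
    (peak of stream a, peak of stream b) from group node statistics."""
    hemi = node_hemisphere_mask(phantom, hemisphere)
    n_gm = n_gm or len(phantom.gm_surface_nodes)

    def peaks_fn(indices):
        out = []
        for res in (result_a, result_b):
            images = [res.images[i] for i in indices]
            tmap = node_tmap(images, res.group_mask, n_gm,
                             response_window=res.config.response_window,
                             baseline_window=res.config.baseline_window,
                             pooled=res.config.pooled_t)
            dom = res.group_mask & hemi & np.isfinite(tmap.t)
            out.append(peak_element(tmap.t, dom))
        return tuple(out)

    return peaks_fn
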