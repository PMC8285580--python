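"""Four-layer infant head-model geometry.

The head model is a tetrahedral volume mesh with four tissue classes
(white matter, grey matter, cerebrospinal fluid and a combined
extra-cerebral scalp/skull layer), an extracted grey-matter surface
carrying a parcellation, a closed scalp surface, and five cranial
landmarks (Nz, Iz, Al, Ar, Cz).  This module provides

* the landmark coordinate frame (Iz at the origin, Nz on the +y axis,
  the preauricular points levelled in z by a rotation about y),
* scalp curve-walks realised as planar-section traces of the scalp
  surface, with arc-length parameterisation,
* 10-5 scalp positions along the sagittal (Nz-Cz-Iz) and coronal
  (Ar-Cz-Al) curves,
* head-measurement extraction (circumference, Ar-Cz-Al, Nz-Cz-Iz), and
* the iterative measurement-driven warping algorithm that scales axis
  subsets until the warped model reproduces a subject's measurements
  within tolerance.

Meshes are stored in mm; head measurements cross the API boundary in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

__all__ = [
    "HeadMesh",
    "HeadMeasurements",
    "WarpTolerances",
    "CurvePath",
    "WarpConvergenceError",
    "align_to_landmark_frame",
    "curve_walk",
    "closed_section",
    "compute_10_5_positions",
    "measure_head",
    "warp_head_model",
    "parcel_of_node",
    "MIDLINE_10_5_LABELS",
]

TISSUE_CLASSES = ("WM", "GM", "CSF", "ECT")
LANDMARK_NAMES = ("Nz", "Iz", "Al", "Ar", "Cz")

#: 10-5 labels along the Nz -> Iz midline curve, 5 % arc steps inclusive.
MIDLINE_10_5_LABELS = (
    "Nz", "NFpz", "Fpz", "AFpz", "AFz", "AFFz", "Fz", "FFCz", "FCz", "FCCz",
    "Cz", "CCPz", "CPz", "CPPz", "Pz", "PPOz", "POz", "POOz", "Oz", "OIz",
    "Iz",
)


class WarpConvergenceError(RuntimeError):
    """Raised when iterative warping fails to meet tolerance."""


@dataclass
class HeadMesh:
    """Four-layer labelled head mesh with surfaces, landmarks, parcels."""

    volume_nodes: np.ndarray          # (N, 3) mm
    tetrahedra: np.ndarray            # (M, 4) int
    tissue_labels: np.ndarray         # (M,) str, one of TISSUE_CLASSES
    gm_surface_nodes: np.ndarray      # (G, 3) mm
    gm_surface_faces: np.ndarray      # (F, 3) int
    scalp_surface_nodes: np.ndarray   # (S, 3) mm
    scalp_surface_faces: np.ndarray   # (Fs, 3) int
    parcel_labels: np.ndarray         # (G,) int
    landmarks: dict[str, np.ndarray]  # name -> (3,) mm
    node_tissue: np.ndarray | None = None  # (N,) str per volume node

    def __post_init__(self) -> None:
        self.volume_nodes = np.asarray(self.volume_nodes, dtype=float)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=int)
        self.gm_surface_nodes = np.asarray(self.gm_surface_nodes, dtype=float)
        self.scalp_surface_nodes = np.asarray(self.scalp_surface_nodes, dtype=float)
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

    def validate(self) -> None:
        if self.tetrahedra.size and self.tetrahedra.max() >= len(self.volume_nodes):
            raise ValueError("tetrahedra reference nodes outside the volume mesh")
        bad = set(np.unique(self.tissue_labels)) - set(TISSUE_CLASSES)
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")
        if len(self.parcel_labels) != len(self.gm_surface_nodes):
            raise ValueError("one parcel label per grey-matter surface node required")

    def scalp_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.scalp_surface_nodes,
            faces=self.scalp_surface_faces,
            process=False,
        )

    def gm_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.gm_surface_nodes,
            faces=self.gm_surface_faces,
            process=False,
        )

    def copy(self) -> "HeadMesh":
        return HeadMesh(
            volume_nodes=self.volume_nodes.copy(),
            tetrahedra=self.tetrahedra,
            tissue_labels=self.tissue_labels,
            gm_surface_nodes=self.gm_surface_nodes.copy(),
            gm_surface_faces=self.gm_surface_faces,
            scalp_surface_nodes=self.scalp_surface_nodes.copy(),
            scalp_surface_faces=self.scalp_surface_faces,
            parcel_labels=self.parcel_labels,
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
            node_tissue=self.node_tissue,
        )

    def require_landmarks(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.landmarks]
        if missing:
            raise ValueError(f"missing landmark(s): {', '.join(missing)}")


@dataclass(frozen=True)
class HeadMeasurements:
    """Scalar head measurements in cm; nz_cz_iz may be absent (None)."""

    circumference: float
    ar_cz_al: float | None = None
    nz_cz_iz: float | None = None

    def __post_init__(self) -> None:
        for name in ("circumference", "ar_cz_al", "nz_cz_iz"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class WarpTolerances:
    """Convergence tolerances in mm (measurement errors of the warped model)."""

    tol_ar_cz_al: float = 6.0
    tol_nz_cz_iz: float = 6.0
    tol_circumference: float = 3.0
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if min(self.tol_ar_cz_al, self.tol_nz_cz_iz, self.tol_circumference) <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class CurvePath:
    """Ordered scalp polyline with cumulative arc length (mm)."""

    points: np.ndarray     # (n, 3)
    cum_length: np.ndarray  # (n,) starting at 0

    @property
    def length(self) -> float:
        return float(self.cum_length[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc-length ``s`` (mm) from the start; error if off-domain."""
        if s < -1e-9 or s > self.length + 1e-9:
            raise ValueError(
                f"arc position {s:.2f} mm outside curve domain [0, {self.length:.2f}]"
            )
        s = min(max(s, 0.0), self.length)
        i = int(np.searchsorted(self.cum_length, s, side="right") - 1)
        i = min(i, len(self.points) - 2) if len(self.points) > 1 else 0
        if len(self.points) == 1:
            return self.points[0].copy()
        seg = self.cum_length[i + 1] - self.cum_length[i]
        t = 0.0 if seg <= 0 else (s - self.cum_length[i]) / seg
        return (1 - t) * self.points[i] + t * self.points[i + 1]

    def arc_position_of(self, p: np.ndarray) -> float:
        """Arc length of the point on the curve closest to ``p``."""
        i, t, _, _ = _nearest_on_polyline(self.points, np.asarray(p, float))
        seg = self.cum_length[i + 1] - self.cum_length[i]
        return float(self.cum_length[i] + t * seg)


def _cumlen(points: np.ndarray) -> np.ndarray:
    if len(points) == 1:
        return np.zeros(1)
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(d)])


def _nearest_on_polyline(points: np.ndarray, p: np.ndarray):
    """Return (segment index, fraction, foot point, distance) nearest to p."""
    a = points[:-1]
    b = points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d = np.linalg.norm(foot - p, axis=1)
    i = int(np.argmin(d))
    return i, float(t[i]), foot[i], float(d[i])


def _section_loops(surface: trimesh.Trimesh, origin: np.ndarray, normal: np.ndarray):
    sec = surface.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        raise ValueError("plane does not intersect the surface")
    loops = []
    for poly in sec.discrete:
        poly = np.asarray(poly, dtype=float)
        closed = bool(np.allclose(poly[0], poly[-1]))
        loops.append((poly, closed))
    return loops


def closed_section(surface: trimesh.Trimesh, origin, normal, near=None) -> CurvePath:
    """Closed planar-section loop of ``surface``; the loop passing nearest
    ``near`` (default: the plane origin) is returned as a CurvePath whose
    last point repeats the first."""
    origin = np.asarray(origin, float)
    normal = np.asarray(normal, float)
    near = origin if near is None else np.asarray(near, float)
    best = None
    for poly, closed in _section_loops(surface, origin, normal):
        if not closed:
            continue
        d = np.linalg.norm(poly - near, axis=1).min()
        if best is None or d < best[0]:
            best = (d, poly)
    if best is None:
        raise ValueError("no closed section loop found")
    poly = best[1]
    return CurvePath(points=poly, cum_length=_cumlen(poly))


def curve_walk(
    surface: trimesh.Trimesh,
    start,
    end,
    via=None,
    prefer: str = "via",
) -> CurvePath:
    """Trace the scalp path from ``start`` to ``end``.

    The path is the trace of the surface in the cutting plane through
    ``start``, ``end`` and ``via`` (default: the surface vertex centroid).
    When the plane's section is a closed loop the two candidate arcs are
    disambiguated by ``prefer``: ``"via"`` picks the arc passing closest
    to the ``via`` point (use a surface point such as Cz to force the
    over-the-top route), ``"short"`` picks the shorter arc.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if np.allclose(start, end):
        return CurvePath(points=start[None, :], cum_length=np.zeros(1))
    centroid = surface.vertices.mean(axis=0)
    via_pt = centroid if via is None else np.asarray(via, dtype=float)
    normal = np.cross(start - via_pt, end - via_pt)
    if np.linalg.norm(normal) < 1e-9:
        # via collinear with the chord: any plane containing the chord works
        chord = end - start
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, chord)) > 0.9 * np.linalg.norm(chord):
            helper = np.array([0.0, 1.0, 0.0])
        normal = np.cross(chord, helper)
    normal = normal / np.linalg.norm(normal)

    candidates = []
    for poly, closed in _section_loops(surface, start, normal):
        pts = poly[:-1] if closed else poly
        i0, t0, p0, d0 = _nearest_on_polyline(poly, start)
        i1, t1, p1, d1 = _nearest_on_polyline(poly, end)
        snap_cost = d0 + d1
        if closed:
            for arc in _loop_arcs(pts, poly, i0, t0, p0, i1, t1, p1):
                candidates.append((snap_cost, arc))
        else:
            arc = _open_arc(poly, i0, t0, p0, i1, t1, p1)
            candidates.append((snap_cost, arc))
    if not candidates:
        raise ValueError("surface section yielded no usable path")
    min_cost = min(c for c, _ in candidates)
    arcs = [a for c, a in candidates if c < min_cost + 1e-6]
    if len(arcs) > 1:
        if prefer == "short":
            arcs.sort(key=lambda a: _cumlen(a)[-1])
        else:
            arcs.sort(key=lambda a: np.linalg.norm(a - via_pt, axis=1).min())
    pts = arcs[0]
    return CurvePath(points=pts, cum_length=_cumlen(pts))


def _open_arc(poly, i0, t0, p0, i1, t1, p1):
    if (i0, t0) <= (i1, t1):
        mid = poly[i0 + 1 : i1 + 1]
        return np.vstack([p0[None], mid, p1[None]])
    mid = poly[i1 + 1 : i0 + 1][::-1]
    return np.vstack([p0[None], mid, p1[None]])


def _loop_arcs(pts, poly, i0, t0, p0, i1, t1, p1):
    """Both arcs of a closed loop between two snapped points."""
    n = len(pts)

    def arc(ia, ta, pa, ib, tb, pb):
        out = [pa]
        j = (ia + 1) % n
        # vertices strictly between the two snap segments
        steps = 0
        while j != (ib + 1) % n and steps <= n:
            out.append(pts[j])
            j = (j + 1) % n
            steps += 1
        out.append(pb)
        return np.asarray(out)

    a1 = arc(i0, t0, p0, i1, t1, p1)
    a2 = arc(i1, t1, p1, i0, t0, p0)[::-1]
    return [a1, a2]


def align_to_landmark_frame(mesh: HeadMesh) -> HeadMesh:
    """Rigidly transform the mesh into the landmark frame.

    Iz goes to the origin, Nz onto the positive y-axis, and the mesh is
    rotated about y so the preauricular points Ar/Al share (as nearly as
    possible) the same z, with Ar on the positive-x side.
    """
    mesh.require_landmarks()
    out = mesh.copy()
    iz = out.landmarks["Iz"].copy()
    _transform(out, lambda p: p - iz)

    y = out.landmarks["Nz"]
    rot1 = _rotation_aligning(y / np.linalg.norm(y), np.array([0.0, 1.0, 0.0]))
    _transform(out, lambda p: p @ rot1.T)

    d = out.landmarks["Ar"] - out.landmarks["Al"]
    theta = np.arctan2(d[2], d[0])  # rotate about y so d_z -> 0, d_x > 0
    rot2 = Rotation.from_rotvec([0.0, theta, 0.0]).as_matrix()
    _transform(out, lambda p: p @ rot2.T)
    return out


def _rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector u to unit vector v."""
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            helper = np.array([0.0, 0.0, 1.0])
        axis = np.cross(u, helper)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = axis / s
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _transform(mesh: HeadMesh, f) -> None:
    mesh.volume_nodes = f(mesh.volume_nodes)
    mesh.gm_surface_nodes = f(mesh.gm_surface_nodes)
    mesh.scalp_surface_nodes = f(mesh.scalp_surface_nodes)
    mesh.landmarks = {k: f(v[None, :])[0] for k, v in mesh.landmarks.items()}


def compute_10_5_positions(mesh: HeadMesh) -> dict[str, np.ndarray]:
    """10-5 scalp positions from the cranial landmarks.

    Midline points are named with the standard 10-5 labels (Nz ... Iz,
    5 % arc steps, including Fpz and CCPz); the coronal Ar-Cz-Al chain is
    emitted with fractional keys ``cor_<fraction>`` plus ``Cz``.  ``FPz``
    is provided as an alias of ``Fpz``.
    """
    mesh.require_landmarks()
    scalp = mesh.scalp_trimesh()
    lm = mesh.landmarks
    sagittal = curve_walk(scalp, lm["Nz"], lm["Iz"], via=lm["Cz"], prefer="via")
    coronal = curve_walk(scalp, lm["Ar"], lm["Al"], via=lm["Cz"], prefer="via")
    if sagittal.length <= 0 or coronal.length <= 0:
        raise ValueError("degenerate landmark curves")
    out: dict[str, np.ndarray] = {}
    for i, label in enumerate(MIDLINE_10_5_LABELS):
        out[label] = sagittal.point_at(0.05 * i * sagittal.length)
    out["FPz"] = out["Fpz"]
    for i in range(21):
        f = 0.05 * i
        out[f"cor_{f:.2f}"] = coronal.point_at(f * coronal.length)
    out["Al"] = lm["Al"].copy()
    out["Ar"] = lm["Ar"].copy()
    return out


def measure_head(mesh: HeadMesh) -> HeadMeasurements:
    """Head circumference, Ar-Cz-Al and Nz-Cz-Iz scalp distances, in cm.

    The circumference is the closed scalp trace of the plane through Nz
    and Iz spanned by (Nz−Iz) and (Ar−Al); the two arcs are scalp
    curve-walks through Cz.
    """
    mesh.require_landmarks()
    scalp = mesh.scalp_trimesh()
    lm = mesh.landmarks
    normal = np.cross(lm["Nz"] - lm["Iz"], lm["Ar"] - lm["Al"])
    loop = closed_section(scalp, lm["Iz"], normal, near=lm["Iz"])
    ar_cz_al = curve_walk(scalp, lm["Ar"], lm["Al"], via=lm["Cz"], prefer="via")
    nz_cz_iz = curve_walk(scalp, lm["Nz"], lm["Iz"], via=lm["Cz"], prefer="via")
    return HeadMeasurements(
        circumference=loop.length / 10.0,
        ar_cz_al=ar_cz_al.length / 10.0,
        nz_cz_iz=nz_cz_iz.length / 10.0,
    )


#: axis subsets scaled when a given measurement drives a warp step
_WARP_AXES = {
    "circumference": (0, 1, 2),
    "ar_cz_al": (0, 2),
    "nz_cz_iz": (1, 2),
}


def warp_head_model(
    mesh: HeadMesh,
    target: HeadMeasurements,
    tol: WarpTolerances | None = None,
) -> tuple[HeadMesh, list[dict]]:
    """Iteratively warp the head model to a subject's measurements.

    The model is first scaled globally by the circumference ratio, then
    repeatedly re-measured; the measurement with the greatest absolute
    error picks the next warp factor, applied to its axis subset
    (Ar-Cz-Al -> x,z; Nz-Cz-Iz -> y,z; circumference -> x,y,z).  When the
    target Nz-Cz-Iz is absent the warp runs on circumference and
    Ar-Cz-Al only.  The grey-matter surface, scalp surface and landmarks
    ride along with the identical factor sequence, preserving one-to-one
    nodal correspondence.
    """
    tol = tol or WarpTolerances()
    targets_mm = {"circumference": target.circumference * 10.0}
    if target.ar_cz_al is not None:
        targets_mm["ar_cz_al"] = target.ar_cz_al * 10.0
    if target.nz_cz_iz is not None:
        targets_mm["nz_cz_iz"] = target.nz_cz_iz * 10.0
    tols = {
        "circumference": tol.tol_circumference,
        "ar_cz_al": tol.tol_ar_cz_al,
        "nz_cz_iz": tol.tol_nz_cz_iz,
    }

    out = mesh.copy()
    log: list[dict] = []

    def measured_mm():
        m = measure_head(out)
        return {
            "circumference": m.circumference * 10.0,
            "ar_cz_al": m.ar_cz_al * 10.0,
            "nz_cz_iz": m.nz_cz_iz * 10.0,
        }

    def apply(name: str, factor: float) -> None:
        scale = np.ones(3)
        for ax in _WARP_AXES[name]:
            scale[ax] = factor
        _transform(out, lambda p: p * scale)

    m = measured_mm()
    f0 = targets_mm["circumference"] / m["circumference"]
    apply("circumference", f0)
    log.append({"iteration": 0, "measurement": "circumference", "factor": f0})

    for it in range(1, tol.max_iterations + 1):
        m = measured_mm()
        errors = {k: abs(m[k] - t) for k, t in targets_mm.items()}
        log[-1]["errors_mm"] = errors
        if all(errors[k] <= tols[k] for k in errors):
            return out, log
        worst = max(errors, key=lambda k: errors[k])
        factor = targets_mm[worst] / m[worst]
        apply(worst, factor)
        log.append({"iteration": it, "measurement": worst, "factor": factor})

    m = measured_mm()
    errors = {k: abs(m[k] - t) for k, t in targets_mm.items()}
    raise WarpConvergenceError(
        f"warp did not converge in {tol.max_iterations} iterations; "
        f"final errors (mm): {errors}"
    )


def parcel_of_node(mesh: HeadMesh, gm_node_index: int) -> int:
    """Parcel label of a grey-matter surface node (labels ride with nodes)."""
    n = len(mesh.parcel_labels)
    if not 0 <= gm_node_index < n:
        raise IndexError(f"gm node index {gm_node_index} out of range [0, {n})")
    return int(mesh.parcel_labels[gm_node_index])
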