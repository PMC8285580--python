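"""Bilateral optode array registration on a warped head model.

Each hemisphere carries a 6-source / 7-detector array arranged in two
staggered rows (17 channels of 2 cm nearest-neighbour separation).  The
array is registered to the scalp from two lateral photograph
measurements: the displacement of a reference optode (the third lower
optode from the posterior, intended to sit over the tragus) along a
scalp x-axis (Iz to FPz along the side of the head) and a scalp y-axis
(preauricular point to CCPz).  Anterior and superior displacements are
positive.  Arc (geodesic) spacing along the scalp is enforced, so the
physical array does not scale with head size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .head_model import (
    CurvePath,
    HeadMesh,
    _cumlen,
    closed_section,
    compute_10_5_positions,
    curve_walk,
)

__all__ = [
    "Optode",
    "Channel",
    "ArraySpec",
    "PlacementMeasurement",
    "ScalpAxes",
    "bright_array_spec",
    "define_scalp_axes",
    "register_reference_optode",
    "layout_array",
    "apply_placement_rules",
    "channel_scalp_midpoints",
]

HEMISPHERES = ("left", "right")


def hemisphere_prefix(hemisphere: str) -> str:
    """Namespace prefix for optode ids of one hemisphere ("L:" / "R:")."""
    return hemisphere[0].upper() + ":"

#: row separation putting staggered diagonal neighbours at exactly 20 mm
DEFAULT_ROW_SEPARATION = float(np.sqrt(300.0))


@dataclass(frozen=True)
class Optode:
    """One optode of a hemisphere array, in flat array coordinates (mm).

    ``x`` runs posterior->anterior along the lower curve, zero at the
    reference optode; ``y`` is the superior offset of the row.
    """

    optode_id: str
    role: str          # "source" | "detector"
    row: str           # "lower" | "upper"
    x: float
    y: float


@dataclass(frozen=True)
class Channel:
    channel_id: str
    source: str
    detector: str
    hemisphere: str


@dataclass(frozen=True)
class ArraySpec:
    optodes: tuple[Optode, ...]           # one hemisphere template
    channels_per_hemisphere: tuple[tuple[str, str], ...]  # (source, detector)
    reference_optode: str
    nominal_spacing: float = 20.0         # mm

    @property
    def n_sources(self) -> int:
        return sum(o.role == "source" for o in self.optodes)

    @property
    def n_detectors(self) -> int:
        return sum(o.role == "detector" for o in self.optodes)

    def channels(self) -> list[Channel]:
        """All channels of the bilateral array; optode ids are
        hemisphere-namespaced ("L:S1", "R:D3", ...) to match
        :func:`layout_array` output."""
        out = []
        for hemi in HEMISPHERES:
            p = hemisphere_prefix(hemi)
            for i, (s, d) in enumerate(self.channels_per_hemisphere):
                out.append(Channel(f"{hemi[0].upper()}{i + 1:02d}",
                                   p + s, p + d, hemi))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference_optode": self.reference_optode,
                "nominal_spacing_mm": self.nominal_spacing,
                "optodes": [o.__dict__ for o in self.optodes],
                "channels_per_hemisphere": list(self.channels_per_hemisphere),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArraySpec":
        d = json.loads(text)
        return cls(
            optodes=tuple(Optode(**o) for o in d["optodes"]),
            channels_per_hemisphere=tuple(
                (s, det) for s, det in d["channels_per_hemisphere"]
            ),
            reference_optode=d["reference_optode"],
            nominal_spacing=d["nominal_spacing_mm"],
        )


def bright_array_spec(
    spacing: float = 20.0,
    row_separation: float = DEFAULT_ROW_SEPARATION,
) -> ArraySpec:
    """The bilateral 6-source / 7-detector, 17-channels-per-hemisphere array.

    Lower row: 7 optodes (D S D S D S D from posterior) at ``spacing``
    steps; upper row: 6 optodes (S D S D S D) staggered by half a step.
    With ``row_separation = sqrt(3)/2 * spacing`` every nearest-neighbour
    source-detector pair (6 lower-row, 5 upper-row, 6 diagonal) sits at
    the nominal 2 cm separation.  The reference optode is the third
    lower optode from the posterior.
    """
    lower_roles = ["detector", "source", "detector", "source", "detector",
                   "source", "detector"]
    upper_roles = ["source", "detector", "source", "detector", "source",
                   "detector"]
    optodes = []
    counts = {"source": 0, "detector": 0}
    lower_ids, upper_ids = [], []
    for i, role in enumerate(lower_roles):
        counts[role] += 1
        oid = f"{'S' if role == 'source' else 'D'}{counts[role]}"
        # reference (index 2) at x = 0
        optodes.append(Optode(oid, role, "lower", (i - 2) * spacing, 0.0))
        lower_ids.append(oid)
    for j, role in enumerate(upper_roles):
        counts[role] += 1
        oid = f"{'S' if role == 'source' else 'D'}{counts[role]}"
        optodes.append(
            Optode(oid, role, "upper", (j - 2) * spacing + spacing / 2, row_separation)
        )
        upper_ids.append(oid)

    def pair(a: Optode, b: Optode):
        s = a if a.role == "source" else b
        d = b if a.role == "source" else a
        return (s.optode_id, d.optode_id)

    by_id = {o.optode_id: o for o in optodes}
    chans = []
    for ids in (lower_ids, upper_ids):
        for a, b in zip(ids[:-1], ids[1:]):
            chans.append(pair(by_id[a], by_id[b]))
    for j, u in enumerate(upper_ids):   # diagonal neighbours at one spacing
        for i in (j, j + 1):
            a, b = by_id[u], by_id[lower_ids[i]]
            if a.role != b.role and np.hypot(a.x - b.x, a.y - b.y) <= 1.001 * spacing:
                chans.append(pair(a, b))
    spec = ArraySpec(
        optodes=tuple(optodes),
        channels_per_hemisphere=tuple(chans),
        reference_optode="D2",
        nominal_spacing=spacing,
    )
    assert spec.n_sources == 6 and spec.n_detectors == 7
    assert len(spec.channels_per_hemisphere) == 17
    return spec


@dataclass(frozen=True)
class PlacementMeasurement:
    """Lateral displacement of the reference optode, in cm.

    Anterior (x) and superior (y) displacements are positive; posterior
    and inferior are negative.
    """

    hemisphere: str
    x_disp: float
    y_disp: float


def apply_placement_rules(
    placement: PlacementMeasurement,
    shift_threshold: float = 1.6,
    exclude_threshold: float = 1.6,
    abs_y: bool = True,
) -> str:
    """Placement quality rule: keep / shift one channel space / exclude.

    |x| >= 1.6 cm re-indexes the array one full channel space (the shift
    opposes the displacement sign, re-centring the array); y > 1.6 cm
    (on |y| by default) excludes the infant for poor headgear placement.
    Exclusion takes precedence over shifting.
    """
    y = abs(placement.y_disp) if abs_y else placement.y_disp
    if y > exclude_threshold:
        return "exclude"
    if placement.x_disp >= shift_threshold:
        return "shift_backward"
    if placement.x_disp <= -shift_threshold:
        return "shift_forward"
    return "keep"


@dataclass
class ScalpAxes:
    """Arc-parameterised scalp axes of one hemisphere.

    ``x_curve`` runs Iz -> FPz along the lateral side of the head (arc
    length increases anteriorly); ``origin_arc`` is the arc position of
    the intended reference location (the point of the x-curve nearest
    the preauricular point); ``y_anchor`` is the CCPz point toward which
    superior displacements walk.
    """

    hemisphere: str
    x_curve: CurvePath
    origin_arc: float
    y_anchor: np.ndarray
    scalp: object  # trimesh.Trimesh


def define_scalp_axes(mesh: HeadMesh, hemisphere: str) -> ScalpAxes:
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
    pos = compute_10_5_positions(mesh)
    for key in ("FPz", "CCPz"):
        if key not in pos:
            raise ValueError(f"missing 10-5 anchor point {key}")
    scalp = mesh.scalp_trimesh()
    pre = mesh.landmarks["Al" if hemisphere == "left" else "Ar"]
    x_curve = curve_walk(scalp, mesh.landmarks["Iz"], pos["FPz"], via=pre, prefer="via")
    origin_arc = x_curve.arc_position_of(pre)
    return ScalpAxes(
        hemisphere=hemisphere,
        x_curve=x_curve,
        origin_arc=origin_arc,
        y_anchor=pos["CCPz"],
        scalp=scalp,
    )


def _lift(axes: ScalpAxes, base_point: np.ndarray, height: float) -> np.ndarray:
    """Walk ``height`` mm of scalp arc from a point on the x-curve toward
    CCPz (negative heights walk away from it, i.e. inferiorly)."""
    base = np.asarray(base_point, float)
    if abs(height) < 1e-9:
        return base
    centroid = axes.scalp.vertices.mean(axis=0)
    normal = np.cross(base - centroid, axes.y_anchor - centroid)
    loop = closed_section(axes.scalp, base, normal, near=base)
    pts = loop.points[:-1]
    length = loop.length
    s_base = loop.arc_position_of(base)
    s_anchor = loop.arc_position_of(axes.y_anchor)
    # + direction = toward CCPz the short way around the loop
    delta = (s_anchor - s_base) % length
    sign = 1.0 if delta <= length - delta else -1.0
    if abs(height) > length / 2:
        raise ValueError("displacement walks more than half way around the head")
    return loop.point_at((s_base + sign * height) % length)


def register_reference_optode(
    mesh: HeadMesh,
    hemisphere: str,
    placement: PlacementMeasurement,
    axes: ScalpAxes | None = None,
) -> np.ndarray:
    """Scalp point of the reference optode after measured displacement.

    Displacements are applied as scalp arc lengths: x along the Iz-FPz
    curve (anterior positive), then y toward CCPz (superior positive).
    """
    axes = axes or define_scalp_axes(mesh, hemisphere)
    s = axes.origin_arc + placement.x_disp * 10.0
    base = axes.x_curve.point_at(s)
    return _lift(axes, base, placement.y_disp * 10.0)


def layout_array(
    mesh: HeadMesh,
    hemisphere: str,
    placement: PlacementMeasurement,
    spec: ArraySpec,
    axes: ScalpAxes | None = None,
    shift_channel_spaces: int = 0,
) -> dict[str, np.ndarray]:
    """Register every optode of one hemisphere's array to the scalp.

    Each optode's flat array coordinate (x, y) is laid out as arc
    lengths: x along the Iz-FPz curve from the displaced reference
    position, y along the transverse curve toward CCPz.  On the left
    hemisphere anterior is still positive x (the flat template is
    mirrored onto the scalp automatically because the left x-curve runs
    up the left side).  ``shift_channel_spaces`` applies the re-indexing
    rule as a physical shift of whole channel spaces along x.
    """
    axes = axes or define_scalp_axes(mesh, hemisphere)
    s_ref = (
        axes.origin_arc
        + placement.x_disp * 10.0
        + shift_channel_spaces * spec.nominal_spacing
    )
    y_ref = placement.y_disp * 10.0

    # one "parallel" row curve per distinct row height; optodes are placed
    # at their template x-offsets as arc lengths along their own row curve,
    # so the physical (rigid) inter-optode spacing is preserved on the scalp
    row_heights = sorted({y_ref + o.y for o in spec.optodes})
    row_curves: dict[float, tuple[CurvePath, float]] = {}
    for h in row_heights:
        offsets = [o.x for o in spec.optodes if abs(y_ref + o.y - h) < 1e-9]
        if s_ref + min(offsets) < -1e-9 or \
                s_ref + max(offsets) > axes.x_curve.length + 1e-9:
            raise ValueError(
                f"array extends beyond the Iz-FPz curve domain "
                f"(needs arc [{s_ref + min(offsets):.1f}, "
                f"{s_ref + max(offsets):.1f}] of "
                f"[0, {axes.x_curve.length:.1f}])"
            )
        if abs(h) < 1e-9:
            row_curves[h] = (axes.x_curve, s_ref)
            continue
        # generous sampling margin (clipped to the curve domain): the
        # lifted row's arc runs shorter than the base curve's where
        # transverse curves converge toward the vertex
        lo, hi = min(offsets) - 20.0, max(offsets) + 20.0
        grid = np.arange(lo, hi + 4.0, 4.0)
        grid = np.unique(np.concatenate([grid, [0.0]]))
        grid = grid[(s_ref + grid >= 0) & (s_ref + grid <= axes.x_curve.length)]
        pts = np.array(
            [_lift(axes, axes.x_curve.point_at(s_ref + g), h) for g in grid]
        )
        curve = CurvePath(points=pts, cum_length=_cumlen(pts))
        origin = float(curve.cum_length[int(np.where(grid == 0.0)[0][0])])
        row_curves[h] = (curve, origin)

    prefix = hemisphere_prefix(hemisphere)
    positions: dict[str, np.ndarray] = {}
    for o in spec.optodes:
        curve, origin = row_curves[y_ref + o.y]
        try:
            positions[prefix + o.optode_id] = curve.point_at(origin + o.x)
        except ValueError as exc:
            raise ValueError(
                f"optode {o.optode_id} falls off its row curve: {exc}"
            ) from exc
    return positions


def channel_scalp_midpoints(
    mesh: HeadMesh,
    positions: dict[str, np.ndarray],
    spec: ArraySpec,
) -> dict[str, np.ndarray]:
    """Scalp arc midpoint of each channel, keyed by channel id.

    Channels whose optodes are absent from ``positions`` (e.g. a single
    registered hemisphere) are skipped."""
    scalp = mesh.scalp_trimesh()
    out = {}
    for ch in spec.channels():
        if ch.source not in positions or ch.detector not in positions:
            continue
        ps, pd = positions[ch.source], positions[ch.detector]
        if np.allclose(ps, pd):
            out[ch.channel_id] = np.asarray(ps, float)
            continue
        path = curve_walk(scalp, ps, pd, prefer="short")
        out[ch.channel_id] = path.point_at(path.length / 2.0)
    return out
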