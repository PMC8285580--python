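"""Group-level statistical mapping and channel-to-cortex projection.

T-statistic maps compare the response window (12-16 s post-stimulus) to
the pre-stimulus baseline (-2..0 s) across a cohort.  All frames of all
participants in each window are concatenated into one vector per node
(or channel) and compared with a two-tailed two-sample t-test; frames
are treated as exchangeable observations (no autocorrelation
correction), which mirrors the concatenation approach this package
reproduces and is documented as such.  Multiple comparisons are
Bonferroni corrected: node maps over the grey-matter surface node
count, channel maps over the total channel count of the array (34).

Channel scalp midpoints are projected to the cortex by fitting a plane
to the scalp nodes within 5 mm, casting the inward normal ray, and
taking its first grey-matter surface intersection (Möller-Trumbore).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .head_model import HeadMesh

__all__ = [
    "TStatMap",
    "two_sample_t",
    "node_tmap",
    "channel_tmap",
    "ray_triangle_intersect",
    "project_channel_to_cortex",
    "RESPONSE_WINDOW",
    "BASELINE_WINDOW",
]

RESPONSE_WINDOW = (12.0, 16.0)
BASELINE_WINDOW = (-2.0, 0.0)


@dataclass
class TStatMap:
    """Node- or channel-indexed T map with Bonferroni correction."""

    domain: str                   # "gm_nodes" | "channels"
    t: np.ndarray                 # t per element (NaN where undefined/excluded)
    df: int
    n_comparisons: int
    element_ids: list | np.ndarray
    in_domain: np.ndarray         # bool: element entered the test
    chromophore: str = "HbO"
    alpha: float = 0.05

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.n_comparisons

    @property
    def significant(self) -> np.ndarray:
        from scipy import stats

        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.t.sf(np.abs(self.t), self.df)
        sig = np.zeros_like(self.t, dtype=bool)
        ok = np.isfinite(self.t)
        sig[ok] = p[ok] < self.corrected_alpha
        return sig


def two_sample_t(a: np.ndarray, b: np.ndarray, pooled: bool = True):
    """Vectorised two-sample t along the last axis.

    ``a``/``b`` are (..., n1) and (..., n2).  Returns (t, df).  Pooled
    (equal-variance) by default; Welch available via ``pooled=False``.
    Zero-variance-in-both cases yield NaN (undefined, never significant).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.shape[-1], b.shape[-1]
    m1, m2 = a.mean(-1), b.mean(-1)
    v1, v2 = a.var(-1, ddof=1), b.var(-1, ddof=1)
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:
        denom = np.sqrt(v1 / n1 + v2 / n2)
        df = n1 + n2 - 2  # conservative integer df for map thresholding
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, np.nan)
    return t, df


def _window_frames(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    time = np.asarray(time, float)
    return (time >= window[0] - 1e-9) & (time <= window[1] + 1e-9)


def node_tmap(
    images: list,                      # CorticalImage-like, per participant
    group_mask: np.ndarray,
    n_gm_surface_nodes: int,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    chromophore: str = "HbO",
    pooled: bool = True,
) -> TStatMap:
    """Group node-wise T map on the grey-matter surface.

    Per node in the group mask, all response-window frames of all
    participants are concatenated and compared to the concatenated
    baseline-window frames.  Bonferroni correction runs over the full
    grey-matter surface node count.
    """
    if len(images) < 2:
        raise ValueError("need at least two participants")
    attr = "hbo" if chromophore.lower() == "hbo" else "hbr"
    resp = np.concatenate(
        [getattr(im, attr)[:, _window_frames(im.time, response_window)]
         for im in images], axis=1)
    base = np.concatenate(
        [getattr(im, attr)[:, _window_frames(im.time, baseline_window)]
         for im in images], axis=1)
    t, df = two_sample_t(resp, base, pooled=pooled)
    t = np.where(group_mask, t, np.nan)
    return TStatMap(
        domain="gm_nodes",
        t=t,
        df=df,
        n_comparisons=n_gm_surface_nodes,
        element_ids=np.arange(len(t)),
        in_domain=np.asarray(group_mask, bool),
        chromophore=chromophore,
    )


def channel_tmap(
    blocks: list,                      # BlockAverage per participant
    channel_ids: list,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    chromophore: str = "HbO",
    presence_fraction: float = 0.75,
    n_comparisons: int | None = None,
    pooled: bool = True,
) -> TStatMap:
    """Group channel-wise T map.

    A channel enters the test only when present (not pruned) in at
    least three quarters of participants; Bonferroni correction runs
    over the total channel count of the array.
    """
    if len(blocks) < 2:
        raise ValueError("need at least two participants")
    attr = "hbo" if chromophore.lower() == "hbo" else "hbr"
    n_ch = len(channel_ids)
    presence = np.mean([b.valid_channels for b in blocks], axis=0)
    included = presence >= presence_fraction - 1e-12

    t = np.full(n_ch, np.nan)
    df = 0
    for ch in np.flatnonzero(included):
        resp, base = [], []
        for b in blocks:
            if not b.valid_channels[ch]:
                continue
            x = getattr(b, attr)[ch]
            resp.append(x[_window_frames(b.time, response_window)])
            base.append(x[_window_frames(b.time, baseline_window)])
        resp = np.concatenate(resp)
        base = np.concatenate(base)
        t[ch], df = two_sample_t(resp, base, pooled=pooled)
    return TStatMap(
        domain="channels",
        t=t,
        df=df,
        n_comparisons=n_comparisons or n_ch,
        element_ids=list(channel_ids),
        in_domain=included,
        chromophore=chromophore,
    )


# ---------------------------------------------------------------------------
# cortical projection

def ray_triangle_intersect(origin, direction, triangle, eps: float = 1e-12):
    """Möller-Trumbore ray/triangle intersection.

    Returns the intersection point (forward along the ray, t >= 0) or
    None on a miss or a ray parallel to the triangle's plane.
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    v0, v1, v2 = (np.asarray(v, float) for v in triangle)
    e1, e2 = v1 - v0, v2 - v0
    pvec = np.cross(direction, e2)
    det = float(np.dot(e1, pvec))
    if abs(det) < eps:
        return None
    inv = 1.0 / det
    tvec = origin - v0
    u = float(np.dot(tvec, pvec)) * inv
    if u < -1e-12 or u > 1.0 + 1e-12:
        return None
    qvec = np.cross(tvec, e1)
    v = float(np.dot(direction, qvec)) * inv
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return None
    t = float(np.dot(e2, qvec)) * inv
    if t < 0:
        return None
    return origin + t * direction


def _first_hit(origin, direction, vertices, faces):
    """First (smallest-t) Möller-Trumbore hit over a face set, vectorised."""
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
    if not hit.any():
        return None, None
    i = np.flatnonzero(hit)[np.argmin(t[hit])]
    return origin + t[i] * direction, i


def project_channel_to_cortex(
    mesh: HeadMesh,
    midpoint,
    radius_mm: float = 5.0,
) -> tuple[np.ndarray, int, int]:
    """Project a channel's scalp midpoint to the grey-matter surface.

    Scalp nodes within ``radius_mm`` of the midpoint fit a least-squares
    plane; the plane normal is cast inward from the midpoint until it
    first intersects a grey-matter surface face.  The inward direction
    is disambiguated by whichever normal sign actually hits the cortex
    (orientation invariant).  Returns (point, gm node index, parcel label).
    """
    midpoint = np.asarray(midpoint, float)
    d = np.linalg.norm(mesh.scalp_surface_nodes - midpoint, axis=1)
    near = mesh.scalp_surface_nodes[d <= radius_mm]
    if len(near) < 3:
        raise ValueError(
            f"only {len(near)} scalp nodes within {radius_mm} mm of midpoint"
        )
    # the midpoint itself is a scalp point and anchors the fit; if the
    # in-radius vertices are near-collinear (coarse mesh) widen the patch
    # until the plane is well conditioned
    r = radius_mm
    while True:
        pts = np.vstack([near, midpoint[None, :]])
        centred = pts - pts.mean(axis=0)
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        if len(pts) >= 5 and s[1] > 0.2 * s[0]:
            break
        r *= 1.4
        near = mesh.scalp_surface_nodes[d <= r]
        if r > 10 * radius_mm:
            break
    normal = vt[-1]

    best = None
    for sign in (1.0, -1.0):
        pt, face = _first_hit(midpoint, sign * normal,
                              mesh.gm_surface_nodes, mesh.gm_surface_faces)
        if pt is not None:
            dist = np.linalg.norm(pt - midpoint)
            if best is None or dist < best[0]:
                best = (dist, pt, face)
    if best is None:
        raise ValueError("projection ray does not intersect the grey-matter surface")
    _, pt, face = best
    verts = mesh.gm_surface_faces[face]
    node = int(verts[np.argmin(np.linalg.norm(mesh.gm_surface_nodes[verts] - pt,
                                              axis=1))])
    return pt, node, int(mesh.parcel_labels[node])
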