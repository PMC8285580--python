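"""Channel sensitivity modelling and cortically-constrained reconstruction.

The default forward engine is an analytic diffusion-approximation model
for a homogeneous medium bounded by the scalp: channel sensitivity to an
absorption perturbation at node r is the normalised three-point Green's
function product (Rytov form)

    J(r) = G(s, r) G(r, d) / G(s, d),

with G the continuous-wave diffusion Green's function
exp(-mu_eff |r|) / (4 pi D |r|) and the scalp boundary handled by an
image source mirrored in the channel's local tangent plane.  The engine
is pluggable: any callable with the same signature (mesh, optode
positions, channels, optical properties -> channel x node matrix) can
stand in, e.g. a finite-element solver.

Reconstruction is a zeroth-order Tikhonov inversion constrained to the
grey-matter nodes of the volume mesh,

    x = J^T (J J^T + lambda^2 max(diag(J J^T)) I)^{-1} y,

with hyperparameter lambda = 0.1, followed by a per-node 2x2 extinction
solve to convert dual-wavelength absorption changes to HbO/HbR images
mapped onto the grey-matter surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .head_model import HeadMesh
from .preprocessing import WAVELENGTHS, extinction_matrix

__all__ = [
    "OpticalProperties",
    "SensitivityMatrix",
    "CorticalImage",
    "load_optical_properties",
    "compute_sensitivity",
    "sensitivity_com",
    "individual_gm_mask",
    "group_gm_mask",
    "make_reconstructor",
    "reconstruct",
    "mua_to_hb",
    "volume_to_surface",
    "window_average_image",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous baseline optical properties, per wavelength (mm^-1)."""

    mua: dict[float, float]
    musp: dict[float, float]

    def __post_init__(self) -> None:
        for d in (self.mua, self.musp):
            if any(v <= 0 for v in d.values()):
                raise ValueError("optical properties must be positive")


def load_optical_properties(tissue: str = "homogeneous") -> OpticalProperties:
    with resources.files("nirsdot").joinpath(
        "_data/optical_properties.csv"
    ).open() as fh:
        table = pd.read_csv(fh, comment="#")
    sel = table[table.tissue == tissue]
    if sel.empty:
        raise ValueError(f"no optical properties for tissue {tissue!r}")
    return OpticalProperties(
        mua={row.wavelength_nm: row.mua for row in sel.itertuples()},
        musp={row.wavelength_nm: row.musp for row in sel.itertuples()},
    )


@dataclass
class SensitivityMatrix:
    """Channel x volume-node Jacobian per wavelength (OD per mm^-1)."""

    values: dict[float, np.ndarray]       # wavelength -> (n_ch, n_nodes)
    channel_ids: list
    node_indices: np.ndarray              # volume-node indices of columns
    optode_positions: dict
    optical_properties: OpticalProperties
    model_tag: str = "analytic-diffusion"

    def restrict_channels(self, keep: np.ndarray) -> "SensitivityMatrix":
        keep = np.asarray(keep, bool)
        return SensitivityMatrix(
            values={wl: v[keep] for wl, v in self.values.items()},
            channel_ids=[c for c, k in zip(self.channel_ids, keep) if k],
            node_indices=self.node_indices,
            optode_positions=self.optode_positions,
            optical_properties=self.optical_properties,
            model_tag=self.model_tag,
        )


@dataclass
class CorticalImage:
    """Grey-matter surface node HbO/HbR time-courses (µM)."""

    hbo: np.ndarray            # (n_gm_nodes, n_frames)
    hbr: np.ndarray
    time: np.ndarray
    mask: np.ndarray           # bool per gm-surface node
    lambda_reg: float = 0.1
    group_mask_applied: bool = False


def _greens_cw(dist: np.ndarray, mu_eff: float, D: float) -> np.ndarray:
    d = np.maximum(dist, 1e-6)
    return np.exp(-mu_eff * d) / (4.0 * np.pi * D * d)


def compute_sensitivity(
    mesh: HeadMesh,
    optode_positions: dict[str, np.ndarray],
    channels: list[tuple[str, str]],
    props: OpticalProperties | None = None,
    wavelengths=WAVELENGTHS,
    node_indices: np.ndarray | None = None,
    semi_infinite: bool = True,
) -> SensitivityMatrix:
    """Analytic diffusion sensitivity of each channel at each volume node.

    Optodes are taken on the scalp; the effective isotropic source sits
    one transport mean free path (1/musp') inside along the local inward
    normal, and the boundary is modelled by an image source mirrored in
    the channel's local tangent plane (``semi_infinite=False`` gives the
    translation-invariant infinite-medium model).
    """
    props = props or load_optical_properties()
    if node_indices is None:
        if mesh.node_tissue is not None:
            node_indices = np.flatnonzero(mesh.node_tissue == "GM")
        else:
            node_indices = np.arange(len(mesh.volume_nodes))
    nodes = mesh.volume_nodes[node_indices]
    volumes = node_volumes(mesh)[node_indices]  # mm^3 support per node
    centroid = mesh.scalp_surface_nodes.mean(axis=0)

    values: dict[float, np.ndarray] = {}
    for wl in wavelengths:
        mua, musp = props.mua[wl], props.musp[wl]
        D = 1.0 / (3.0 * (mua + musp))
        mu_eff = np.sqrt(mua / D)
        z0 = 1.0 / musp
        J = np.empty((len(channels), len(nodes)))
        for ci, (sid, did) in enumerate(channels):
            ps = np.asarray(optode_positions[sid], float)
            pd_ = np.asarray(optode_positions[did], float)
            mid = 0.5 * (ps + pd_)
            inward = centroid - mid
            inward = inward / np.linalg.norm(inward)
            s_in = ps + z0 * inward
            d_in = pd_ + z0 * inward

            def G(p, q):
                return _greens_cw(np.linalg.norm(q - p, axis=-1), mu_eff, D)

            gs = G(s_in, nodes)
            gd = G(d_in, nodes)
            gsd = float(G(s_in, d_in[None, :])[0])
            if semi_infinite:
                # image sources mirrored in the tangent plane z0 outside
                plane_pt = mid + z0 * (-inward)
                def mirror(p):
                    h = np.dot(p - plane_pt, -inward)
                    return p - 2.0 * h * (-inward)
                gs = gs - G(mirror(s_in), nodes)
                gd = gd - G(mirror(d_in), nodes)
                gsd = gsd - float(G(mirror(s_in), d_in[None, :])[0])
            J[ci] = np.maximum(gs * gd, 0.0) / max(gsd, 1e-300) * volumes
        values[wl] = J
    return SensitivityMatrix(
        values=values,
        channel_ids=list(channels),
        node_indices=np.asarray(node_indices),
        optode_positions=dict(optode_positions),
        optical_properties=props,
        model_tag="analytic-diffusion" + ("-semi-infinite" if semi_infinite else "-infinite"),
    )


def node_volumes(mesh: HeadMesh) -> np.ndarray:
    """Volume support of each mesh node: one quarter of each adjacent
    tetrahedron's volume."""
    v = mesh.volume_nodes
    t = mesh.tetrahedra
    a, b, c, d = (v[t[:, k]] for k in range(4))
    vol = np.abs(np.einsum("ij,ij->i", a - d, np.cross(b - d, c - d))) / 6.0
    out = np.zeros(len(v))
    for k in range(4):
        np.add.at(out, t[:, k], vol / 4.0)
    return out


def sensitivity_com(row: np.ndarray, node_coords: np.ndarray) -> np.ndarray:
    """Sensitivity-weighted centre of mass of one channel's row."""
    w = np.asarray(row, float)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero sensitivity row has no centre of mass")
    return (w[:, None] * node_coords).sum(axis=0) / total


# ---------------------------------------------------------------------------
# grey-matter masks

def individual_gm_mask(
    J: SensitivityMatrix,
    mesh: HeadMesh,
    threshold_fraction: float = 0.01,
    wavelength: float = WAVELENGTHS[0],
    map_radius_mm: float = 3.0,
) -> np.ndarray:
    """Binary grey-matter surface mask: aggregate channel sensitivity
    thresholded at 1 % of its maximum, mapped to the gm surface (each
    surface node takes the nearest volume GM node within ``map_radius_mm``)."""
    vals = J.values[wavelength]
    if vals.shape[0] == 0:
        return np.zeros(len(mesh.gm_surface_nodes), dtype=bool)
    agg = np.abs(vals).sum(axis=0)
    keep = agg >= threshold_fraction * agg.max()
    node_mask = volume_to_surface(
        keep.astype(float), J.node_indices, mesh, radius_mm=map_radius_mm
    )
    return node_mask >= 0.5


def group_gm_mask(masks: list[np.ndarray], fraction: float = 0.75) -> np.ndarray:
    """Node kept iff present in at least ``fraction`` of individual masks."""
    if not masks:
        raise ValueError("need at least one individual mask")
    stack = np.asarray(masks, dtype=bool)
    return stack.mean(axis=0) >= fraction - 1e-12


def volume_to_surface(
    node_values: np.ndarray,
    node_indices: np.ndarray,
    mesh: HeadMesh,
    radius_mm: float = 3.0,
) -> np.ndarray:
    """Map values on volume GM nodes to gm-surface nodes (nearest volume
    node within ``radius_mm``; surface nodes with no neighbour get 0)."""
    tree = cKDTree(mesh.volume_nodes[node_indices])
    dist, idx = tree.query(mesh.gm_surface_nodes)
    out = np.zeros(len(mesh.gm_surface_nodes), dtype=float)
    ok = dist <= radius_mm
    out[ok] = np.asarray(node_values, float)[idx[ok]]
    return out


# ---------------------------------------------------------------------------
# Tikhonov reconstruction

def make_reconstructor(J: np.ndarray, lambda_reg: float = 0.1) -> np.ndarray:
    """Factor the zeroth-order Tikhonov inverse operator once.

    Returns W with x = W @ y, W = J^T (J J^T + lambda^2 max(diag(JJ^T)) I)^-1
    (the underdetermined form; the operator is reused across all frames).
    """
    J = np.asarray(J, float)
    if J.shape[0] == 0:
        raise ValueError("empty channel set")
    JJt = J @ J.T
    alpha = lambda_reg**2 * float(np.max(np.diag(JJt)))
    A = JJt + alpha * np.eye(J.shape[0])
    return J.T @ np.linalg.inv(A)


def reconstruct(
    J: np.ndarray,
    y: np.ndarray,
    lambda_reg: float = 0.1,
) -> np.ndarray:
    """Tikhonov-regularised absorption-change images.

    ``J`` is (n_channels, n_nodes); ``y`` is (n_channels,) or
    (n_channels, n_frames).  Linear in ``y``.
    """
    W = make_reconstructor(J, lambda_reg)
    return W @ np.asarray(y, float)


def mua_to_hb(
    dmua_by_wl: dict[float, np.ndarray],
    ext: np.ndarray | None = None,
    wavelengths=WAVELENGTHS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node extinction solve: dual-wavelength Δµa (mm^-1) -> ΔHbO, ΔHbR (µM).

    Uses the same extinction matrix as the channel-space MBLL without
    pathlength terms; extinctions are converted to mm^-1 per µM.
    """
    ext = extinction_matrix(wavelengths) if ext is None else np.asarray(ext, float)
    E = ext / 10.0  # OD/(µM cm) -> mm^-1 per µM (base-e handled consistently)
    if abs(np.linalg.det(E)) < 1e-30:
        raise np.linalg.LinAlgError("singular extinction matrix")
    Einv = np.linalg.inv(E)
    stacked = np.stack([dmua_by_wl[wl] for wl in wavelengths], axis=0)
    hb = np.einsum("kl,l...->k...", Einv, stacked)
    return hb[0], hb[1]


def window_average_image(
    image: np.ndarray,
    time: np.ndarray,
    window: tuple[float, float] = (12.0, 16.0),
) -> np.ndarray:
    """Temporal mean of each node over the response window (inclusive)."""
    time = np.asarray(time, float)
    if window[0] < time[0] - 1e-9 or window[1] > time[-1] + 1e-9:
        raise ValueError(f"window {window} outside block [{time[0]}, {time[-1]}]")
    sel = (time >= window[0] - 1e-9) & (time <= window[1] + 1e-9)
    return np.asarray(image, float)[..., sel].mean(axis=-1)
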