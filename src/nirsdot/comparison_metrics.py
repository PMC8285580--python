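"""Cross-stream comparison metrics.

Quantifies how the choice of processing stream changes statistical and
anatomical inferences: peak node/channel extraction, peak node offset in
a common reference mesh, cortical-label match, Jaccard overlap of
thresholded maps, focality curves, head-size correlations, and the
combinatorial group-size robustness analysis.

All offsets are Euclidean distances between node positions looked up in
a single reference-space mesh per age (the constant-head-warp model),
exploiting the one-to-one nodal correspondence across warps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PeakResult",
    "CombinatorialResult",
    "peak_element",
    "peak_node_offset",
    "jaccard_overlap",
    "focality_curve",
    "node_areas",
    "regional_max_abs_t",
    "headsize_associations",
    "combinatorial_analysis",
]


@dataclass(frozen=True)
class PeakResult:
    element: int
    value: float
    coordinates: np.ndarray | None = None
    parcel_label: int | None = None
    hemisphere: str | None = None
    chromophore: str = "HbO"


def peak_element(
    values: np.ndarray,
    in_domain: np.ndarray,
    chromophore: str = "HbO",
    coordinates: np.ndarray | None = None,
    parcel_labels: np.ndarray | None = None,
    hemisphere: str | None = None,
) -> PeakResult:
    """Peak of a map: argmax for HbO, argmin (most negative) for HbR.

    ``in_domain`` restricts the search (mask and hemisphere already
    applied by the caller as needed).  Ties break to the lowest element
    id deterministically.
    """
    v = np.asarray(values, float).copy()
    ok = np.asarray(in_domain, bool) & np.isfinite(v)
    if not ok.any():
        raise ValueError("empty masked domain")
    v[~ok] = np.nan
    if chromophore.lower() == "hbo":
        best = np.nanmax(v)
    else:
        best = np.nanmin(v)
    idx = int(np.flatnonzero(v == best)[0])
    return PeakResult(
        element=idx,
        value=float(v[idx]),
        coordinates=None if coordinates is None else np.asarray(coordinates[idx]),
        parcel_label=None if parcel_labels is None else int(parcel_labels[idx]),
        hemisphere=hemisphere,
        chromophore=chromophore,
    )


def peak_node_offset(
    peak_a: int | PeakResult,
    peak_b: int | PeakResult,
    reference_nodes: np.ndarray,
) -> float:
    """Euclidean separation (mm) of two peak node ids looked up in the
    common reference-space mesh coordinates."""
    ia = peak_a.element if isinstance(peak_a, PeakResult) else int(peak_a)
    ib = peak_b.element if isinstance(peak_b, PeakResult) else int(peak_b)
    n = len(reference_nodes)
    if not (0 <= ia < n and 0 <= ib < n):
        raise ValueError("peak node id outside reference mesh topology")
    return float(np.linalg.norm(reference_nodes[ia] - reference_nodes[ib]))


def jaccard_overlap(
    map_a: np.ndarray,
    map_b: np.ndarray,
    threshold_fraction: float = 0.5,
) -> float:
    """Jaccard index (percent) of the two maps' supra-threshold node sets.

    Each map is thresholded at ``threshold_fraction`` of its own maximum
    (self-normalised, so positive rescaling of either map is irrelevant).
    An empty union is undefined and returns NaN.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    a = np.where(np.isfinite(a), a, -np.inf)
    b = np.where(np.isfinite(b), b, -np.inf)
    sa = a >= threshold_fraction * a.max()
    sb = b >= threshold_fraction * b.max()
    union = (sa | sb).sum()
    if union == 0:
        return float("nan")
    return 100.0 * (sa & sb).sum() / union


def node_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-node surface area: one third of each adjacent face's area."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces, int)
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    face_area = 0.5 * np.linalg.norm(cross, axis=1)
    out = np.zeros(len(v))
    for k in range(3):
        np.add.at(out, f[:, k], face_area / 3.0)
    return out


def focality_curve(
    values: np.ndarray,
    areas: np.ndarray,
    in_domain: np.ndarray | None = None,
    thresholds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Supra-threshold cumulative area versus normalised threshold.

    The map is normalised to its (in-domain) maximum; for each
    threshold in 0.50..0.90 (step 0.05 by default) the summed node area
    with normalised value >= threshold is returned.  Non-increasing in
    the threshold by construction.
    """
    if thresholds is None:
        thresholds = np.arange(0.50, 0.901, 0.05)
    v = np.asarray(values, float).copy()
    if in_domain is not None:
        v[~np.asarray(in_domain, bool)] = np.nan
    vmax = np.nanmax(v)
    if not np.isfinite(vmax) or vmax <= 0:
        raise ValueError("map has no positive in-domain values to normalise")
    norm = v / vmax
    areas = np.asarray(areas, float)
    curve = np.array([
        areas[np.nan_to_num(norm, nan=-np.inf) >= th].sum() for th in thresholds
    ])
    return thresholds, curve


def regional_max_abs_t(
    t_values: np.ndarray,
    regions: np.ndarray,
    in_domain: np.ndarray | None = None,
) -> dict:
    """Per-region maximum |t|; regions with no finite elements are absent."""
    t = np.asarray(t_values, float)
    regions = np.asarray(regions)
    ok = np.isfinite(t)
    if in_domain is not None:
        ok &= np.asarray(in_domain, bool)
    out = {}
    for r in np.unique(regions):
        sel = ok & (regions == r)
        if sel.any():
            out[r] = float(np.abs(t[sel]).max())
    return out


def regional_difference(map_a: dict, map_b: dict) -> dict:
    """Paired per-region difference a − b over regions present in both."""
    return {r: map_a[r] - map_b[r] for r in map_a if r in map_b}


def headsize_associations(
    offsets: np.ndarray,
    circumference_deviation: np.ndarray | None = None,
    zscore_change: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Pearson r (with two-sided p) between peak node offset and head-size
    measures: signed and absolute circumference deviation from the group
    mean, and signed and absolute head-circumference z-score change."""
    offsets = np.asarray(offsets, float)

    def corr(x):
        x = np.asarray(x, float)
        ok = np.isfinite(x) & np.isfinite(offsets)
        if ok.sum() < 3:
            raise ValueError("need at least 3 paired finite values")
        if np.std(x[ok]) == 0 or np.std(offsets[ok]) == 0:
            return (float("nan"), float("nan"))
        r, p = stats.pearsonr(offsets[ok], x[ok])
        return (float(r), float(p))

    out: dict[str, tuple[float, float]] = {}
    if circumference_deviation is not None:
        out["circumference_deviation"] = corr(circumference_deviation)
        out["abs_circumference_deviation"] = corr(np.abs(circumference_deviation))
    if zscore_change is not None:
        out["zscore_change"] = corr(zscore_change)
        out["abs_zscore_change"] = corr(np.abs(zscore_change))
    return out


@dataclass
class CombinatorialResult:
    sizes: np.ndarray
    mean_offset: np.ndarray       # mm, per size
    se_offset: np.ndarray
    mismatch_proportion: np.ndarray
    replicates: int
    seed: int


def combinatorial_analysis(
    peaks_fn,
    cohort_size: int,
    reference_nodes: np.ndarray,
    parcel_labels: np.ndarray,
    sizes: np.ndarray | None = None,
    replicates: int = 100,
    seed: int = 0,
) -> CombinatorialResult:
    """Group-size robustness of the stream comparison.

    ``peaks_fn(subject_indices) -> (peak_a, peak_b)`` runs the group
    statistics of both streams on a sub-cohort and returns the two peak
    node ids.  For each size (10..N by default) ``replicates``
    sub-cohorts are drawn without replacement; the mean and standard
    error of the peak node offset and the proportion of mismatching
    parcel labels are aggregated per size.  At size N every draw is the
    full cohort.  Deterministic at fixed seed.
    """
    if cohort_size < 10:
        raise ValueError("cohort must have at least 10 subjects")
    if sizes is None:
        sizes = np.arange(10, cohort_size + 1)
    sizes = np.asarray(sizes, int)
    if sizes.max() > cohort_size:
        raise ValueError("sub-cohort size exceeds cohort size")
    rng = np.random.default_rng(seed)
    mean_off, se_off, mismatch = [], [], []
    for size in sizes:
        n_rep = 1 if size == cohort_size else replicates
        offs, mism = [], []
        for _ in range(n_rep):
            idx = rng.choice(cohort_size, size=size, replace=False)
            pa, pb = peaks_fn(np.sort(idx))
            ia = pa.element if isinstance(pa, PeakResult) else int(pa)
            ib = pb.element if isinstance(pb, PeakResult) else int(pb)
            offs.append(peak_node_offset(ia, ib, reference_nodes))
            mism.append(int(parcel_labels[ia] != parcel_labels[ib]))
        offs = np.asarray(offs, float)
        mean_off.append(offs.mean())
        se_off.append(offs.std(ddof=1) / np.sqrt(len(offs)) if len(offs) > 1 else 0.0)
        mismatch.append(np.mean(mism))
    return CombinatorialResult(
        sizes=sizes,
        mean_offset=np.asarray(mean_off),
        se_offset=np.asarray(se_off),
        mismatch_proportion=np.asarray(mismatch),
        replicates=replicates,
        seed=seed,
    )
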