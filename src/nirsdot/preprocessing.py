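"""Channel-level fNIRS pre-processing.

Pipeline from raw dual-wavelength intensity (10 Hz, 780/850 nm) to
per-condition block-averaged haemoglobin concentration changes, and the
inverse step back to optical density that feeds image reconstruction:

1. channel pruning (intensity floor + cardiac-correlation quality index),
   with whole-dataset rejection when more than 40 % of channels fail;
2. intensity -> optical density (reference = channel temporal mean);
3. motion correction (spline de-trending of flagged segments followed by
   wavelet outlier attenuation) and residual-artifact trial flagging;
4. 0.02-0.06 Hz zero-phase band-pass;
5. modified Beer-Lambert law (MBLL) with age- and wavelength-dependent
   differential pathlength factors;
6. trial selection (looking time >= 60 %, motion flags) and block
   averaging over -2..20 s (221 frames at 10 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import pywt
from scipy import signal

__all__ = [
    "FS",
    "WAVELENGTHS",
    "BLOCK_START_S",
    "BLOCK_END_S",
    "BLOCK_N_FRAMES",
    "block_time_axis",
    "StimulusEvent",
    "RawScan",
    "BlockAverage",
    "prune_channels",
    "dataset_valid",
    "intensity_to_od",
    "correct_motion",
    "flag_residual_trials",
    "bandpass",
    "dpf",
    "extinction_matrix",
    "mbll",
    "hb_to_od",
    "select_trials_and_average",
]

FS = 10.0                     # Hz
WAVELENGTHS = (780.0, 850.0)  # nm
BLOCK_START_S = -2.0
BLOCK_END_S = 20.0
#: inclusive -2..20 s at 10 Hz
BLOCK_N_FRAMES = int(round((BLOCK_END_S - BLOCK_START_S) * FS)) + 1

CONDITIONS = ("VS", "V", "NV", "baseline")


def block_time_axis() -> np.ndarray:
    """Block time axis in seconds, stimulus onset at t = 0."""
    return BLOCK_START_S + np.arange(BLOCK_N_FRAMES) / FS


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    condition: str


@dataclass
class RawScan:
    """Raw dual-wavelength intensity recording with stimulus annotations.

    ``intensity`` has shape (n_channels, n_wavelengths, n_samples) in
    arbitrary units at 10 Hz; ``looking_fraction`` holds one on-screen
    looking-time fraction per trial (same order as ``events``).
    """

    intensity: np.ndarray
    events: list[StimulusEvent]
    looking_fraction: np.ndarray
    wavelengths: tuple[float, float] = WAVELENGTHS
    fs: float = FS
    channel_separation_cm: float = 2.0
    subject: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[-1]

    def trials(self, condition: str) -> list[int]:
        return [i for i, e in enumerate(self.events) if e.condition == condition]


@dataclass
class BlockAverage:
    """Per-channel block-averaged chromophore time-courses (µM)."""

    hbo: np.ndarray            # (n_channels, 221)
    hbr: np.ndarray            # (n_channels, 221)
    time: np.ndarray           # (221,)
    n_trials: np.ndarray       # valid trials averaged, per channel
    valid_channels: np.ndarray  # bool mask
    subject_valid: bool = True
    condition: str = "V"
    separation_cm: float = 2.0
    dpf: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# channel quality

def _cardiac_quality(intensity: np.ndarray, fs: float,
                     band: tuple[float, float]) -> np.ndarray:
    """Zero-lag correlation of the two wavelengths band-passed to the
    cardiac band — the scalp-coupling-style quality index, per channel."""
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, intensity, axis=-1)
    a, b = filtered[:, 0, :], filtered[:, 1, :]
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((a * a).sum(-1) * (b * b).sum(-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(-1) / denom, 0.0)
    return r


def prune_channels(
    raw: RawScan,
    intensity_floor: float = 1e-3,
    sci_threshold: float = 0.75,
    cardiac_band: tuple[float, float] = (0.5, 2.5),
) -> np.ndarray:
    """Valid-channel mask: floor-failing channels are excluded outright,
    the rest must pass the cardiac correlation index."""
    if raw.n_samples / raw.fs < 30.0:
        raise ValueError("need at least 30 s of data for channel pruning")
    mean_int = raw.intensity.mean(axis=-1)      # (n_ch, n_wl)
    floor_ok = (mean_int >= intensity_floor).all(axis=1)
    sci = _cardiac_quality(raw.intensity, raw.fs, cardiac_band)
    return floor_ok & (sci >= sci_threshold)


def dataset_valid(mask: np.ndarray, max_invalid_fraction: float = 0.40) -> bool:
    """Whole-dataset rule: excluded iff more than 40 % of channels invalid."""
    mask = np.asarray(mask, bool)
    return bool((~mask).sum() / mask.size <= max_invalid_fraction)


# ---------------------------------------------------------------------------
# optical density and motion

def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """OD(t) = -ln(I(t) / mean_t I); reference is the channel temporal mean."""
    intensity = np.asarray(intensity, float)
    if (intensity <= 0).any():
        bad = np.unique(np.argwhere(intensity <= 0)[:, 0]).tolist()
        raise ValueError(f"non-positive intensity samples in channels {bad}")
    ref = intensity.mean(axis=-1, keepdims=True)
    return -np.log(intensity / ref)


def _detect_artifacts(x: np.ndarray, fs: float, window_s: float,
                      std_thresh: float, amp_thresh: float) -> np.ndarray:
    """Boolean artifact mask per sample for one 1-D series."""
    w = max(3, int(round(window_s * fs)))
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(xp, w)[: len(x)]
    local_std = view.std(axis=-1)
    local_amp = view.max(axis=-1) - view.min(axis=-1)
    ref_std = np.median(local_std) + 1e-12
    ref_amp = np.median(local_amp) + 1e-12
    return (local_std > std_thresh * ref_std) | (local_amp > amp_thresh * ref_amp)


def _segments(mask: np.ndarray):
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        yield idx[s], idx[e]


def correct_motion(
    od: np.ndarray,
    fs: float = FS,
    window_s: float = 1.0,
    std_thresh: float = 8.0,
    amp_thresh: float = 8.0,
    wavelet: str = "db4",
    iqr_factor: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage motion correction; returns (corrected od, artifact mask).

    Stage 1 detects artifact segments from sliding-window amplitude/std
    jumps and removes a smooth spline trend within each flagged segment.
    Stage 2 runs a discrete wavelet decomposition and zeroes detail
    coefficients outside an interquartile-range band (outlier
    attenuation).  Clean data passes through nearly unchanged.
    """
    od = np.asarray(od, float)
    flat = od.reshape(-1, od.shape[-1])
    out = np.empty_like(flat)
    masks = np.zeros(flat.shape, dtype=bool)
    n = flat.shape[-1]
    for i, x in enumerate(flat):
        if not np.any(x):
            out[i] = x
            continue
        mask = _detect_artifacts(x, fs, window_s, std_thresh, amp_thresh)
        masks[i] = mask
        y = x.copy()
        for s, e in _segments(mask):
            s0, e0 = max(0, s - 2), min(n - 1, e + 2)
            seg = np.arange(s0, e0 + 1)
            if len(seg) > 5:
                from scipy.interpolate import UnivariateSpline
                sp = UnivariateSpline(seg, y[seg], k=3,
                                      s=len(seg) * np.var(y[seg]) * 0.01)
                trend = sp(seg)
            else:
                trend = y[seg]
            anchor = 0.5 * (y[s0] + y[e0])
            y[seg] = y[seg] - trend + anchor
        # wavelet outlier attenuation
        level = min(4, pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len))
        coeffs = pywt.wavedec(y, wavelet, level=level, mode="symmetric")
        for j in range(1, len(coeffs)):
            c = coeffs[j]
            q1, q3 = np.percentile(c, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
            coeffs[j] = np.where((c < lo) | (c > hi), 0.0, c)
        out[i] = pywt.waverec(coeffs, wavelet, mode="symmetric")[:n]
    return out.reshape(od.shape), masks.reshape(od.shape)


def flag_residual_trials(
    artifact_mask: np.ndarray,
    events: list[StimulusEvent],
    fs: float = FS,
    pad_s: float = 4.0,
) -> set[tuple[int, int]]:
    """Per-channel trial exclusions from residual artifacts.

    ``artifact_mask`` is boolean (n_channels, ..., n_samples); a trial is
    excluded for a channel when its -2..20 s block window overlaps any
    flagged section padded by ``pad_s`` on both sides.  Returns a set of
    (channel, trial index) pairs.
    """
    m = np.asarray(artifact_mask, bool)
    if m.ndim > 2:
        m = m.any(axis=tuple(range(1, m.ndim - 1)))
    n = m.shape[-1]
    pad = int(round(pad_s * fs))
    excluded: set[tuple[int, int]] = set()
    for ch in range(m.shape[0]):
        for s, e in _segments(m[ch]):
            w0, w1 = s - pad, e + pad
            for ti, ev in enumerate(events):
                t0 = int(round(ev.onset_s * fs)) + int(BLOCK_START_S * fs)
                t1 = t0 + BLOCK_N_FRAMES - 1
                if t0 <= w1 and t1 >= w0 and 0 <= t0 and t1 < n + pad:
                    excluded.add((ch, ti))
    return excluded


def bandpass(
    od: np.ndarray,
    f_hp: float = 0.02,
    f_lp: float = 0.06,
    fs: float = FS,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase band-pass (forward-backward Butterworth)."""
    sos = signal.butter(order, [f_hp, f_lp], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(od, float), axis=-1)


# ---------------------------------------------------------------------------
# MBLL

#: General-equation DPF coefficients: DPF(lambda, age) =
#: a + b * age_years**c + d * lam**3 + e * lam**2 + f * lam, 690-880 nm.
_DPF_COEFFS = (223.3, 0.05624, 0.8493, -5.723e-7, 0.001245, -0.9025)


def dpf(wavelength: float, age_years: float) -> float:
    """Differential pathlength factor from the published general equation
    (polynomial in wavelength, power law in age)."""
    if not 690.0 <= wavelength <= 880.0:
        raise ValueError(f"wavelength {wavelength} nm outside 690-880 nm")
    if age_years < 0:
        raise ValueError("age must be non-negative")
    a, b, c, d, e, f = _DPF_COEFFS
    lam = float(wavelength)
    return a + b * age_years**c + d * lam**3 + e * lam**2 + f * lam


def extinction_matrix(wavelengths=WAVELENGTHS) -> np.ndarray:
    """2x2 extinction matrix E (rows: wavelengths; cols: HbO, HbR) in
    OD per (µM · cm), from the packaged compilation."""
    with resources.files("nirsdot").joinpath(
        "_data/extinction_coefficients.csv"
    ).open() as fh:
        table = pd.read_csv(fh, comment="#")
    rows = []
    for wl in wavelengths:
        match = table[np.isclose(table.wavelength_nm, wl)]
        if match.empty:
            raise ValueError(f"no packaged extinction data at {wl} nm")
        # cm^-1/M -> OD per µM per cm
        rows.append([match.hbo.iloc[0] * 1e-6, match.hbr.iloc[0] * 1e-6])
    return np.asarray(rows)


def mbll(
    od: np.ndarray,
    dpfs: tuple[float, float],
    separation_cm: float,
    ext: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law.

    ``od`` is (n_channels, 2, n_samples); solves
    OD_l = E[l] . (HbO, HbR) * separation * DPF_l per sample, returning
    (ΔHbO, ΔHbR) in µM, each (n_channels, n_samples).
    """
    ext = extinction_matrix() if ext is None else np.asarray(ext, float)
    A = ext * (separation_cm * np.asarray(dpfs, float))[:, None]
    if abs(np.linalg.det(A)) < 1e-18:
        raise np.linalg.LinAlgError("singular extinction system")
    Ainv = np.linalg.inv(A)
    hb = np.einsum("kl,nlt->nkt", Ainv, np.asarray(od, float))
    return hb[:, 0, :], hb[:, 1, :]


def hb_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    dpfs: tuple[float, float],
    separation_cm: float,
    ext: np.ndarray | None = None,
) -> np.ndarray:
    """Forward MBLL: exact inverse of :func:`mbll`."""
    ext = extinction_matrix() if ext is None else np.asarray(ext, float)
    A = ext * (separation_cm * np.asarray(dpfs, float))[:, None]
    hb = np.stack([hbo, hbr], axis=1)
    return np.einsum("lk,nkt->nlt", A, hb)


def block_average_from_od(block: "BlockAverage") -> np.ndarray:
    """Convenience: block-averaged chromophores back to per-wavelength OD."""
    if block.dpf is None:
        raise ValueError("block average carries no DPF values")
    return hb_to_od(block.hbo, block.hbr, block.dpf, block.separation_cm)


# ---------------------------------------------------------------------------
# trial selection / block averaging

def select_trials_and_average(
    hbo: np.ndarray,
    hbr: np.ndarray,
    events: list[StimulusEvent],
    looking_fraction: np.ndarray,
    condition: str = "V",
    exclusions: set[tuple[int, int]] | None = None,
    valid_channels: np.ndarray | None = None,
    fs: float = FS,
    looking_threshold: float = 0.60,
    min_trials: int = 3,
    dpfs: tuple[float, float] | None = None,
    separation_cm: float = 2.0,
) -> BlockAverage:
    """Block-average the selected condition's valid trials per channel.

    Trials with looking fraction < 60 % are dropped for all channels;
    motion-flagged (channel, trial) pairs are dropped per channel.  The
    block runs -2..20 s (221 frames) relative to onset and is baseline
    corrected to the mean of the pre-stimulus segment.  The subject is
    flagged invalid for the condition when fewer than ``min_trials``
    looking-valid trials remain.
    """
    exclusions = exclusions or set()
    n_ch, n_t = hbo.shape
    pre = int(round(-BLOCK_START_S * fs))
    trial_ids = [i for i, e in enumerate(events) if e.condition == condition]
    looking_ok = [i for i in trial_ids
                  if looking_fraction[i] >= looking_threshold]

    out_hbo = np.zeros((n_ch, BLOCK_N_FRAMES))
    out_hbr = np.zeros((n_ch, BLOCK_N_FRAMES))
    n_used = np.zeros(n_ch, dtype=int)
    for ch in range(n_ch):
        blocks_o, blocks_r = [], []
        for ti in looking_ok:
            if (ch, ti) in exclusions:
                continue
            onset = int(round(events[ti].onset_s * fs))
            i0, i1 = onset - pre, onset - pre + BLOCK_N_FRAMES
            if i0 < 0 or i1 > n_t:
                continue
            bo = hbo[ch, i0:i1] - hbo[ch, i0:i0 + pre].mean()
            br = hbr[ch, i0:i1] - hbr[ch, i0:i0 + pre].mean()
            blocks_o.append(bo)
            blocks_r.append(br)
        if blocks_o:
            out_hbo[ch] = np.mean(blocks_o, axis=0)
            out_hbr[ch] = np.mean(blocks_r, axis=0)
            n_used[ch] = len(blocks_o)
    mask = n_used >= min_trials
    if valid_channels is not None:
        mask = mask & np.asarray(valid_channels, bool)
    return BlockAverage(
        hbo=out_hbo,
        hbr=out_hbr,
        time=block_time_axis(),
        n_trials=n_used,
        valid_channels=mask,
        subject_valid=len(looking_ok) >= min_trials,
        condition=condition,
        separation_cm=separation_cm,
        dpf=dpfs,
    )
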