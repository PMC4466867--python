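"""Dynamic-series preparation: signal-to-concentration conversion, drift
correction, temporal smoothing and truncation.

The conversion assumes a spoiled gradient-echo acquisition.  Per voxel, the
pre-contrast signal mean and the T1 map calibrate the M0 scale; each dynamic
frame's longitudinal rate R1(t) is then solved in closed form from the SPGR
equation, and concentration follows from the linear relaxivity model

    C(t) = (R1(t) - R1(0)) / r1        [mM, with r1 in L mmol^-1 s^-1].

Negative concentrations from noise are deliberately retained: clamping would
bias low-permeability fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spgr import m0_from_baseline, r1_from_signal

__all__ = [
    "ConcentrationSeries",
    "DriftModel",
    "signal_to_concentration",
    "signal_curve_to_concentration",
    "concentration_to_signal_curve",
    "correct_drift",
    "smooth_timecourse",
    "truncate_series",
]


@dataclass
class ConcentrationSeries:
    """Per-voxel contrast-agent concentration versus time (mM)."""

    conc: np.ndarray  # (x, y, z, t)
    frame_times_min: np.ndarray
    injection_index: int
    r1: float  # relaxivity, L mmol^-1 s^-1
    baseline_frames: tuple  # (start, stop) pre-contrast index range

    def __post_init__(self):
        self.frame_times_min = np.asarray(self.frame_times_min, dtype=float)
        if self.conc.shape[-1] != len(self.frame_times_min):
            raise ValueError("frame count mismatch between conc and frame times")
        if not np.all(np.diff(self.frame_times_min) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.r1 <= 0:
            raise ValueError("relaxivity r1 must be positive")
        if self.baseline_frames[1] > self.injection_index:
            raise ValueError("baseline frames must precede the injection index")


@dataclass
class DriftModel:
    """Per-frame multiplicative correction factors estimated from a
    contrast-free reference ROI (e.g. phantom rods)."""

    factors: np.ndarray
    reference_labels: tuple = ()
    mode: str = "per_frame"


def concentration_to_signal_curve(conc, t10_ms, fa_deg, tr_ms, r1, s0=1.0):
    """Forward SPGR transform of a concentration curve (for simulation)."""
    from .spgr import spgr_signal

    r1_t = 1000.0 / t10_ms + r1 * np.asarray(conc, dtype=float)
    return spgr_signal(s0, r1_t, fa_deg, tr_ms)


def signal_curve_to_concentration(signal, t10_ms, fa_deg, tr_ms, r1, baseline):
    """Closed-form inversion of one dynamic signal curve to concentration.

    ``baseline`` is a slice or index array of pre-contrast frames; its mean
    signal and the known pre-contrast T1 calibrate the M0 scale.  Frames
    whose signal cannot be inverted (outside the SPGR range) come back NaN.
    """
    signal = np.asarray(signal, dtype=float)
    s_base = float(np.mean(signal[baseline]))
    m0 = m0_from_baseline(s_base, t10_ms, fa_deg, tr_ms)
    with np.errstate(invalid="ignore"):
        r1_t = r1_from_signal(signal, m0, fa_deg, tr_ms)
    r10 = 1000.0 / t10_ms
    return (r1_t - r10) / r1


def signal_to_concentration(series, t1_map, r1, baseline_frames, injection_index=None):
    """Convert a 4-D dynamic series to a ConcentrationSeries using a T1 map.

    Parameters
    ----------
    series : DynamicSeries
        Must carry flip angle and TR metadata.
    t1_map : RelaxationMap or 3-D array
        Pre-contrast T1 in ms on the series' spatial grid.  Voxels with
        T1 <= 0 or NaN are skipped (NaN output).
    r1 : float
        Contrast-agent relaxivity (L mmol^-1 s^-1); no default on purpose —
        it depends on agent and field strength.
    baseline_frames : (start, stop)
        Index range of pre-contrast frames.
    """
    if series.flip_angle_deg is None or series.tr_ms is None:
        raise ValueError("flip angle and TR metadata required for conversion")
    t1 = t1_map.value if hasattr(t1_map, "value") else np.asarray(t1_map, dtype=float)
    if t1.shape != series.voxels.shape[:3]:
        raise ValueError("T1 map not aligned to the series grid")
    b0, b1 = baseline_frames
    if b1 <= b0:
        raise ValueError("need at least one baseline frame")
    if injection_index is None:
        injection_index = b1

    sig = series.voxels.astype(float)
    base_mean = sig[..., b0:b1].mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = np.isfinite(t1) & (t1 > 0) & (base_mean > 0)
    conc = np.full_like(sig, np.nan)
    fa, tr = series.flip_angle_deg, series.tr_ms
    vt1 = t1[valid]
    m0 = m0_from_baseline(base_mean[valid], vt1, fa, tr)
    r10 = 1000.0 / vt1
    with np.errstate(invalid="ignore"):
        r1_t = r1_from_signal(sig[valid, :], m0[:, None], fa, tr)
    conc[valid, :] = (r1_t - r10[:, None]) / r1
    return ConcentrationSeries(
        conc, series.frame_times / 60.0, injection_index, r1, (b0, b1)
    )


def correct_drift(series, reference, baseline_frames, mode="per_frame"):
    """Scanner-drift correction from a contrast-free reference ROI.

    The per-frame factor is f(t) = mean_ROI(baseline) / mean_ROI(t); in
    ``linear`` mode a straight line is fitted to the raw factors over time
    (robust to ROI noise) and used instead.  All voxels are multiplied by
    f(t), and a DriftModel records the factors.
    """
    from dataclasses import replace

    labels = reference.labels if hasattr(reference, "labels") else np.asarray(reference)
    sel = labels > 0
    if not np.any(sel):
        raise ValueError("empty reference ROI")
    b0, b1 = baseline_frames
    roi_mean = series.voxels[sel, :].mean(axis=0)
    if np.any(roi_mean <= 0):
        raise ValueError("reference ROI mean non-positive at some frame")
    base = roi_mean[b0:b1].mean()
    factors = base / roi_mean
    if mode == "linear":
        coef = np.polyfit(series.frame_times, factors, 1)
        factors = np.polyval(coef, series.frame_times)
    # normalise so baseline frames are exactly 1
    factors = factors / factors[b0:b1].mean()
    corrected = replace(series, voxels=series.voxels * factors)
    labs = tuple(int(v) for v in np.unique(labels[sel]))
    return corrected, DriftModel(factors, labs, mode)


def smooth_timecourse(curve, window):
    """Centred moving average with edge shrinkage; window must be odd.

    The window truncates at the boundaries (shrinking average), so a
    constant curve is unchanged and window = 1 is the identity.
    """
    curve = np.asarray(curve, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > len(curve):
        raise ValueError("window longer than curve")
    if window == 1:
        return curve.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(curve)])
    n = len(curve)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def truncate_series(obj, start_index, end_index):
    """Slice frames [start_index, end_index) of a dynamic or concentration
    series (or a plain 1-D curve), keeping times consistent.

    For a ConcentrationSeries the injection index is remapped; truncation
    that removes all baseline frames (or the injection) is an error because
    conversion/fitting would be impossible.
    """
    import dataclasses

    if isinstance(obj, np.ndarray):
        if not (0 <= start_index < end_index <= len(obj)):
            raise ValueError("invalid truncation range")
        return obj[start_index:end_index]
    if isinstance(obj, ConcentrationSeries):
        n = obj.conc.shape[-1]
        if not (0 <= start_index < end_index <= n):
            raise ValueError("invalid truncation range")
        if start_index >= obj.injection_index:
            raise ValueError("truncation removes all baseline frames")
        new_inj = obj.injection_index - start_index
        b0 = max(obj.baseline_frames[0] - start_index, 0)
        b1 = obj.baseline_frames[1] - start_index
        if b1 <= 0:
            raise ValueError("truncation removes all baseline frames")
        return dataclasses.replace(
            obj,
            conc=obj.conc[..., start_index:end_index],
            frame_times_min=obj.frame_times_min[start_index:end_index],
            injection_index=new_inj,
            baseline_frames=(b0, b1),
        )
    # DynamicSeries
    n = obj.voxels.shape[-1]
    if not (0 <= start_index < end_index <= n):
        raise ValueError("invalid truncation range")
    return dataclasses.replace(
        obj,
        voxels=obj.voxels[..., start_index:end_index],
        frame_times=obj.frame_times[start_index:end_index],
    )
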