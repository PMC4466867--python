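"""Arterial input functions: population model, ROI extraction, bi-exponential fit.

The arterial input function (AIF) ``C_a(t)`` drives every tracer-kinetic
model.  Four sources are supported:

* the Parker population AIF (a mixture of two Gaussians plus a
  sigmoid-modulated exponential, with published population constants),
* a raw curve extracted as the per-frame mean over an arterial ROI,
* a bi-exponential fit to a raw curve, and
* the arithmetic average of several onset-aligned curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AIFCurve",
    "PARKER_CONSTANTS",
    "parker_aif",
    "extract_aif_from_roi",
    "detect_onset",
    "fit_biexponential_aif",
    "average_population_aif",
    "read_aif_csv",
    "write_aif_csv",
]

#: Population constants of the Parker AIF (1.5 T, 0.1 mmol/kg bolus).
#: Units: A1, A2 in mmol*min; T1, T2, sigma1, sigma2 in min; alpha in mmol;
#: beta in 1/min; s in 1/min; tau in min.  Reference data, not tunables.
PARKER_CONSTANTS = {
    "A1": 0.809,
    "A2": 0.330,
    "T1": 0.17046,
    "T2": 0.365,
    "sigma1": 0.0563,
    "sigma2": 0.132,
    "alpha": 1.050,
    "beta": 0.1685,
    "s": 38.078,
    "tau": 0.483,
}


@dataclass
class AIFCurve:
    """Arterial concentration versus time.

    ``kind`` records provenance: ``raw`` (ROI mean), ``biexp_fit`` (fitted
    functional form evaluated on the input grid), or ``parker`` (analytic
    population curve).  ``params`` holds the functional-form parameters when
    applicable.
    """

    times_min: np.ndarray
    conc: np.ndarray
    kind: str = "raw"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.shape != self.conc.shape:
            raise ValueError("times and concentrations must be matching 1-D arrays")
        if len(self.times_min) > 1 and not np.all(np.diff(self.times_min) > 0):
            raise ValueError("AIF times must be strictly increasing")
        if not np.all(np.isfinite(self.conc)):
            raise ValueError("AIF concentrations must be finite")


def _parker_form(t_min, c=PARKER_CONSTANTS):
    """Parker functional form at times >= 0 (minutes since bolus arrival)."""
    t = np.asarray(t_min, dtype=float)
    gauss = np.zeros_like(t)
    for a, mu, sig in ((c["A1"], c["T1"], c["sigma1"]), (c["A2"], c["T2"], c["sigma2"])):
        gauss = gauss + a / (sig * np.sqrt(2.0 * np.pi)) * np.exp(
            -((t - mu) ** 2) / (2.0 * sig**2)
        )
    washout = c["alpha"] * np.exp(-c["beta"] * t) / (1.0 + np.exp(-c["s"] * (t - c["tau"])))
    return gauss + washout


def parker_aif(times_min, onset_min=0.0):
    """Evaluate the Parker population AIF, zero before the bolus onset.

    Parameters
    ----------
    times_min : array-like
        Sample times in minutes (strictly increasing).
    onset_min : float
        Bolus arrival time; the population curve is shifted so its t=0 sits
        at ``onset_min`` and the output is exactly zero before it.
    """
    if onset_min < 0:
        raise ValueError("onset must be non-negative")
    t = np.asarray(times_min, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    shifted = t - onset_min
    conc = np.where(shifted >= 0, _parker_form(np.maximum(shifted, 0.0)), 0.0)
    return AIFCurve(t, conc, kind="parker", params=dict(PARKER_CONSTANTS, onset_min=onset_min))


def extract_aif_from_roi(conc_series, roi, label=None):
    """Per-frame mean concentration over an arterial ROI.

    ``conc_series`` is a ConcentrationSeries (4-D ``conc`` + ``frame_times_min``);
    ``roi`` an ROIMask.  ``label`` selects one ROI label (default: any non-zero).
    """
    labels = roi.labels if hasattr(roi, "labels") else np.asarray(roi)
    sel = labels > 0 if label is None else labels == label
    if not np.any(sel):
        raise ValueError("empty ROI: no voxels selected for AIF extraction")
    curves = conc_series.conc[sel, :]  # (n_voxels, t)
    return AIFCurve(conc_series.frame_times_min, np.nanmean(curves, axis=0), kind="raw")


def detect_onset(curve: AIFCurve, n_baseline=None, k_sd=3.0):
    """First frame index where the curve exceeds baseline mean + k_sd * baseline SD.

    ``n_baseline`` defaults to the first 10 % of frames (at least 3).
    """
    c = curve.conc
    if n_baseline is None:
        n_baseline = max(3, len(c) // 10)
    base = c[:n_baseline]
    thr = base.mean() + k_sd * base.std()
    above = np.nonzero(c > thr)[0]
    if len(above) == 0:
        raise ValueError("no onset detected: curve never exceeds baseline threshold")
    return int(above[0])


def _biexp(t, t0, amp_fast, rate_fast, amp_slow, rate_slow):
    dt = t - t0
    out = amp_fast * np.exp(-rate_fast * dt) + amp_slow * np.exp(-rate_slow * dt)
    return np.where(dt >= 0, out, 0.0)


class AIFFitError(RuntimeError):
    """Bi-exponential AIF fit failed; carries the raw curve for fallback."""

    def __init__(self, message, raw_curve):
        super().__init__(message)
        self.raw_curve = raw_curve


def fit_biexponential_aif(aif: AIFCurve, config=None, t0_min=None):
    """Fit C(t) = A exp(-a (t-t0)) + B exp(-b (t-t0)) for t >= t0, 0 before.

    The onset t0 is detected at the observed upslope unless supplied.  Rates
    are ordered fast-first (a >= b); all parameters are bounded non-negative.
    A degenerate a ~ b solution is returned with a warning (it is equivalent
    to a mono-exponential).
    """
    t, c = aif.times_min, aif.conc
    if t0_min is None:
        try:
            onset_idx = detect_onset(aif)
        except ValueError:
            onset_idx = 0
        peak_idx = onset_idx + int(np.argmax(c[onset_idx:]))
        t0_min = t[max(onset_idx - 1, 0)] if peak_idx > 0 else t[0]
    peak = float(np.max(c))
    if peak <= 0:
        raise AIFFitError("no positive peak: cannot fit bi-exponential", aif)

    def resid(p):
        return _biexp(t, t0_min, *p) - c

    x0 = np.array([0.8 * peak, 3.0, 0.2 * peak, 0.05])
    lb = np.zeros(4)
    ub = np.array([10.0 * peak, 100.0, 10.0 * peak, 100.0])
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise AIFFitError("bi-exponential AIF fit did not converge", aif)
    amp_f, rate_f, amp_s, rate_s = sol.x
    if rate_f < rate_s:  # order fast rate first
        amp_f, rate_f, amp_s, rate_s = amp_s, rate_s, amp_f, rate_f
    if rate_s > 0 and abs(rate_f - rate_s) / rate_f < 1e-4:
        warnings.warn("bi-exponential fit degenerate (a = b): mono-exponential equivalent")
    params = {"A": amp_f, "a": rate_f, "B": amp_s, "b": rate_s, "t0": float(t0_min)}
    fitted = _biexp(t, t0_min, amp_f, rate_f, amp_s, rate_s)
    return AIFCurve(t, fitted, kind="biexp_fit", params=params)


def average_population_aif(aifs, onset_indices=None):
    """Average several AIFs after aligning them at their onsets.

    Curves are shifted so their onsets coincide at t = 0, resampled to a
    common grid (the overlap of supports, at the finest median spacing) by
    linear interpolation, and averaged arithmetically.
    """
    aifs = list(aifs)
    if len(aifs) < 2:
        raise ValueError("need at least 2 curves to average")
    if onset_indices is None:
        onset_indices = []
        for a in aifs:
            try:
                onset_indices.append(detect_onset(a))
            except ValueError:
                onset_indices.append(0)
    shifted = []
    for a, idx in zip(aifs, onset_indices):
        shifted.append((a.times_min - a.times_min[idx], a.conc))
    lo = max(t[0] for t, _ in shifted)
    hi = min(t[-1] for t, _ in shifted)
    if hi <= lo:
        raise ValueError("disjoint time supports: curves do not overlap after alignment")
    dt = min(np.median(np.diff(t)) for t, _ in shifted)
    grid = np.arange(lo, hi + dt / 2, dt)
    stack = np.stack([np.interp(grid, t, c) for t, c in shifted])
    return AIFCurve(grid, stack.mean(axis=0), kind="raw", params={"n_averaged": len(aifs)})


def write_aif_csv(aif: AIFCurve, path):
    """Store an AIF as a 2-column CSV (time_min, conc_mM)."""
    arr = np.column_stack([aif.times_min, aif.conc])
    np.savetxt(path, arr, delimiter=",", header="time_min,conc_mM", comments="")


def read_aif_csv(path):
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return AIFCurve(arr[:, 0], arr[:, 1], kind="raw")
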