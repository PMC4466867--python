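"""Parametric relaxometry maps: variable-flip-angle T1, mono-exponential
T2/T2* decay, and apparent diffusion coefficient (ADC).

Each fitter exists in a linearised form (exact on noiseless data, used as
the seed) and a bounded nonlinear least-squares refinement.  Fitted values
carry hard non-negativity constraints; voxels whose fit is rejected come
back NaN and are counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RelaxometrySeries",
    "RelaxationMap",
    "fit_t1_vfa",
    "fit_exponential_decay",
    "fit_relaxometry_map_parallel",
]

_KINDS = ("t1_vfa", "t2", "t2star", "adc")


@dataclass
class RelaxometrySeries:
    """A stack of acquisitions varying one control value.

    ``control_values`` are flip angles (deg) for ``t1_vfa``, echo times (ms)
    for ``t2``/``t2star``, or b-values (s/mm^2) for ``adc``.
    """

    voxels: np.ndarray  # (x, y, z, k)
    control_values: np.ndarray
    kind: str
    tr_ms: float | None = None

    def __post_init__(self):
        self.control_values = np.asarray(self.control_values, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.voxels.shape[-1] != len(self.control_values):
            raise ValueError("acquisition count mismatch")
        if len(np.unique(self.control_values)) < 2:
            raise ValueError("need >= 2 distinct control values")
        if np.any(self.control_values < 0):
            raise ValueError("control values must be non-negative")
        if self.kind == "t1_vfa" and self.tr_ms is None:
            raise ValueError("TR required for VFA T1 fitting")


@dataclass
class RelaxationMap:
    value: np.ndarray  # T1 ms | T2 ms | ADC mm^2/s
    amplitude: np.ndarray  # M0 / S0
    rss: np.ndarray
    method: str
    kind: str = ""
    n_rejected: int = 0


def _spgr_vfa(m0, t1_ms, alphas_deg, tr_ms):
    e1 = np.exp(-tr_ms / t1_ms)
    a = np.deg2rad(alphas_deg)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def _t1_vfa_linear(sig, alphas_deg, tr_ms):
    """Linearised VFA solution: regress S/sin(a) on S/tan(a); slope = E1."""
    a = np.deg2rad(alphas_deg)
    y = sig / np.sin(a)
    x = sig / np.tan(a)
    xm, ym = x.mean(), y.mean()
    denom = np.sum((x - xm) ** 2)
    if denom == 0:
        return np.nan, np.nan
    e1 = np.sum((x - xm) * (y - ym)) / denom
    if not (0.0 < e1 < 1.0):
        return np.nan, np.nan
    intercept = ym - e1 * xm  # = M0 (1 - E1)
    t1 = -tr_ms / np.log(e1)
    m0 = intercept / (1.0 - e1)
    if m0 <= 0:
        return np.nan, np.nan
    return t1, m0


def fit_t1_vfa(series: RelaxometrySeries, method="linear", config=None):
    """Voxelwise T1 map from variable-flip-angle SPGR data.

    ``linear`` uses the classic S/sin-vs-S/tan regression; ``nlls`` refines
    it with bounded trust-region least squares on the SPGR model (bounds
    keep T1 and M0 non-negative, so refinement can never worsen the RSS of
    a feasible seed).
    """
    if series.kind != "t1_vfa":
        raise ValueError("series kind must be t1_vfa")
    alphas, tr = series.control_values, series.tr_ms
    shape = series.voxels.shape[:3]
    value = np.full(shape, np.nan)
    amp = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    n_rej = 0
    opts = _opts(config)
    for ijk in np.ndindex(shape):
        sig = series.voxels[ijk].astype(float)
        if not np.all(np.isfinite(sig)) or np.all(sig == 0):
            n_rej += 1
            continue
        t1, m0 = _t1_vfa_linear(sig, alphas, tr)
        if not np.isfinite(t1):
            n_rej += 1
            continue
        if method == "nlls":
            sol = least_squares(
                lambda p: _spgr_vfa(p[0], p[1], alphas, tr) - sig,
                x0=[m0, t1],
                bounds=([0.0, 1e-3], [np.inf, 1e7]),
                method="trf",
                xtol=opts["xtol"],
                ftol=opts["ftol"],
                max_nfev=opts["max_nfev"],
            )
            m0, t1 = sol.x
            rss[ijk] = float(sol.fun @ sol.fun)
        else:
            resid = _spgr_vfa(m0, t1, alphas, tr) - sig
            rss[ijk] = float(resid @ resid)
        value[ijk] = t1
        amp[ijk] = m0
    return RelaxationMap(value, amp, rss, method, "t1_vfa", n_rej)


def _opts(config):
    if config is None:
        return dict(xtol=1e-8, ftol=1e-8, max_nfev=500)
    return dict(
        xtol=getattr(config, "param_tol", 1e-8),
        ftol=getattr(config, "func_tol", 1e-8),
        max_nfev=getattr(config, "max_iterations", 500),
    )


def fit_exponential_decay(series: RelaxometrySeries, method="linear", config=None):
    """Mono-exponential decay map: S = S0 exp(-TE/T2) or S = S0 exp(-b ADC).

    The linear method regresses ln S on the control value (non-positive
    signals excluded); ``nlls`` refines it on the exponential model with
    non-negative bounds.  For T2 the fitted decay constant is returned in
    the control value's units (ms); for ADC in mm^2/s.
    """
    if series.kind not in ("t2", "t2star", "adc"):
        raise ValueError("series kind must be t2, t2star or adc")
    x = series.control_values
    shape = series.voxels.shape[:3]
    value = np.full(shape, np.nan)
    amp = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    n_rej = 0
    opts = _opts(config)
    for ijk in np.ndindex(shape):
        sig = series.voxels[ijk].astype(float)
        use = np.isfinite(sig) & (sig > 0)
        if use.sum() < 2:
            n_rej += 1
            continue
        coef = np.polyfit(x[use], np.log(sig[use]), 1)
        rate = max(-coef[0], 0.0)  # decay rate >= 0
        s0 = np.exp(coef[1])
        if method == "nlls":
            sol = least_squares(
                lambda p: p[0] * np.exp(-p[1] * x) - sig,
                x0=[s0, rate],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                method="trf",
                xtol=opts["xtol"],
                ftol=opts["ftol"],
                max_nfev=opts["max_nfev"],
            )
            s0, rate = sol.x
            rss[ijk] = float(sol.fun @ sol.fun)
        else:
            resid = s0 * np.exp(-rate * x) - sig
            rss[ijk] = float(resid @ resid)
        if series.kind == "adc":
            value[ijk] = rate  # ADC in mm^2/s (b in s/mm^2)
        else:
            value[ijk] = np.inf if rate == 0 else 1.0 / rate  # T2 in ms
        amp[ijk] = s0
    return RelaxationMap(value, amp, rss, method, series.kind, n_rej)


def fit_relaxometry_map_parallel(series, method="linear", config=None, mask=None, n_jobs=1):
    """Parallel voxelwise relaxometry fit, identical to serial execution.

    The volume is split along x into contiguous slabs fitted independently
    (joblib); the per-voxel arithmetic is unchanged by the split, so the
    result is bitwise-identical to a serial run.  Masked-out voxels are NaN.
    """
    from dataclasses import replace

    from joblib import Parallel, delayed

    fitter = fit_t1_vfa if series.kind == "t1_vfa" else fit_exponential_decay
    vox = series.voxels
    if mask is not None:
        m = (mask.labels if hasattr(mask, "labels") else np.asarray(mask)) > 0
        vox = np.where(m[..., None], vox, np.nan)
        series = replace(series, voxels=vox)
    if n_jobs == 1:
        return fitter(series, method, config)
    nx = vox.shape[0]
    slabs = np.array_split(np.arange(nx), min(n_jobs, nx))
    parts = Parallel(n_jobs=n_jobs)(
        delayed(fitter)(replace(series, voxels=vox[idx]), method, config) for idx in slabs
    )
    return RelaxationMap(
        np.concatenate([p.value for p in parts]),
        np.concatenate([p.amplitude for p in parts]),
        np.concatenate([p.rss for p in parts]),
        method,
        series.kind,
        sum(p.n_rejected for p in parts),
    )
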