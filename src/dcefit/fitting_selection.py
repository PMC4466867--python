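"""Nonlinear least-squares fitting, nested model selection and fit statistics.

The fitting layer wraps bounded trust-region least squares (multi-start in
Ktrans, which is prone to local minima) around the forward models in
:mod:`dcefit.kinetic_models`.  The linear models (steady-state, Patlak) are
solved exactly by linear least squares with non-negativity handled by an
active-set solver.

Model selection walks the nested hierarchy

    Model 0 (zero) -> Model 1 (steady-state) -> Model 2 (Patlak)
                   -> Model 3 (extended Tofts)

promoting to the next model only when an F-test on the residual improvement
gives p < 0.05 (strictly sequential; the walk stops at the first rejection).

Also here: AIC/AICc, FMI/FRI fit-information fractions, Lin's concordance
correlation coefficient, and delta-method 95 % prediction bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from . import kinetic_models as km
from .aif import AIFCurve

__all__ = [
    "FitResult",
    "ModelSelectionResult",
    "NESTED_HIERARCHY",
    "fit_curve_nlls",
    "multistart_fit",
    "fit_voxelwise_map",
    "f_test_compare",
    "nested_model_fit",
    "aic",
    "fmi_fri",
    "ccc",
    "prediction_bounds",
]

#: Promotion order of the nested hierarchy (index = model number).
NESTED_HIERARCHY = ("zero", "steady_state", "patlak", "ex_tofts")

#: Free parameters per fittable model, in fit-vector order.
MODEL_PARAMS = {
    "zero": (),
    "steady_state": ("v",),
    "patlak": ("ktrans", "vp"),
    "tofts": ("ktrans", "ve"),
    "ex_tofts": ("ktrans", "ve", "vp"),
    "two_cxm": ("ktrans", "ve", "vp", "fp"),
    "tissue_uptake": ("ktrans", "vp", "fp"),
    "fxr": ("ktrans", "ve", "tau_i"),
}

_LINEAR_MODELS = ("zero", "steady_state", "patlak")

#: Default parameter bounds (min, max); overridable via PreferencesConfig.
DEFAULT_BOUNDS = {
    "ktrans": (0.0, 5.0),
    "ve": (1e-6, 1.0),
    "vp": (0.0, 1.0),
    "fp": (1e-6, 50.0),
    "tau_i": (1e-3, 10.0),
    "v": (0.0, 1.0),
}

#: Default multi-start grid for Ktrans (1/min), log-spaced over the
#: physiologically plausible range.
DEFAULT_KTRANS_STARTS = (0.005, 0.05, 0.5, 2.0)


@dataclass
class FitResult:
    model: str
    params: dict
    rss: float
    n: int
    k: int
    residuals: np.ndarray
    param_ci: dict = field(default_factory=dict)
    converged: bool = True
    n_starts_used: int = 1
    jacobian: np.ndarray | None = None

    @property
    def fitted_curve(self):
        return self._data - self.residuals if hasattr(self, "_data") else None


@dataclass
class ModelSelectionResult:
    selected_index: int
    p_values: list
    fit: FitResult

    @property
    def selected_model(self):
        return NESTED_HIERARCHY[self.selected_index]


def _get_bounds(config, name):
    if config is not None:
        b = config.bounds.get(name) if hasattr(config, "bounds") else None
        if b is not None:
            return b
    return DEFAULT_BOUNDS[name]


def _fit_options(config):
    if config is None:
        return dict(xtol=1e-8, ftol=1e-8, max_nfev=500)
    return dict(
        xtol=getattr(config, "param_tol", 1e-8),
        ftol=getattr(config, "func_tol", 1e-8),
        max_nfev=getattr(config, "max_iterations", 500),
    )


def _drop_nan(times, data):
    data = np.asarray(data, dtype=float)
    good = np.isfinite(data)
    return times[good], data[good], good


def _linear_fit(model, times, data, aif):
    """Exact linear least squares for the zero/steady-state/Patlak models."""
    t, ca, dt = km._aif_arrays(aif)
    if model == "zero":
        pred = np.zeros_like(data)
        params = {}
    elif model == "steady_state":
        v = float(np.dot(ca, data) / np.dot(ca, ca))
        pred = v * ca
        params = {"v": v}
    elif model == "patlak":
        design = np.column_stack([km.cumulative_integral(ca, dt), ca])
        coef, _, _, _ = np.linalg.lstsq(design, data, rcond=None)
        ktrans, vp = float(coef[0]), float(coef[1])
        pred = design @ coef
        params = {"ktrans": ktrans, "vp": vp}
    else:  # pragma: no cover
        raise ValueError(model)
    resid = data - pred  # observed minus fitted
    rss = float(resid @ resid)
    return FitResult(model, params, rss, len(data), len(params), resid)


def _model_curve(model, x, aif, acquisition):
    names = MODEL_PARAMS[model]
    return km.model_curve_raw(model, dict(zip(names, x)), aif, acquisition)


def fit_curve_nlls(times_min, data, model, aif, config=None, start=None, acquisition=None):
    """Bounded trust-region least squares of one tissue curve.

    Steady-state and Patlak are solved by exact (non-iterative) linear least
    squares.  NaN frames in ``data`` are dropped (``n`` reduced).  Returns a
    :class:`FitResult` with residuals and 95 % parameter confidence
    intervals from the linearised covariance.
    """
    times_min = np.asarray(times_min, dtype=float)
    _, data_clean, good = _drop_nan(times_min, data)
    if model in _LINEAR_MODELS:
        if not np.all(good):
            raise ValueError("NaN frames unsupported for linear models on a uniform grid")
        res = _linear_fit(model, times_min, data_clean, aif)
        res._data = data_clean
        return res

    names = MODEL_PARAMS[model]
    lb = np.array([_get_bounds(config, p)[0] for p in names])
    ub = np.array([_get_bounds(config, p)[1] for p in names])
    if start is None:
        start = {}
    x0 = np.array(
        [
            np.clip(start.get(p, 0.5 * (_get_bounds(config, p)[0] + _get_bounds(config, p)[1])), lb[i], ub[i])
            for i, p in enumerate(names)
        ]
    )

    def resid_fn(x):
        pred = _model_curve(model, x, aif, acquisition)
        return pred[good] - data_clean

    opts = _fit_options(config)
    with np.errstate(invalid="ignore"):
        sol = least_squares(
            resid_fn,
            x0,
            bounds=(lb, ub),
            method="trf",
            xtol=opts["xtol"],
            ftol=opts["ftol"],
            max_nfev=opts["max_nfev"],
        )
    resid = -sol.fun  # observed minus fitted
    rss = float(resid @ resid)
    n, k = len(data_clean), len(names)
    params = dict(zip(names, (float(v) for v in sol.x)))
    ci = {}
    if n > k:
        s2 = rss / (n - k)
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.pinv(jtj)
            half = stats.t.ppf(0.975, n - k) * np.sqrt(np.maximum(np.diag(cov), 0.0))
            ci = {p: (params[p] - h, params[p] + h) for p, h in zip(names, half)}
        except np.linalg.LinAlgError:  # pragma: no cover
            ci = {}
    res = FitResult(model, params, rss, n, k, resid, ci, bool(sol.success), 1, sol.jac)
    res._data = data_clean
    return res


def multistart_fit(times_min, data, model, aif, config=None, start=None, acquisition=None):
    """Fit from multiple Ktrans starting values; keep the lowest-RSS result.

    Other parameters use a single start (midpoint of bounds, or entries of
    ``start``).  Ties are broken by the first start in the list.
    """
    if model in _LINEAR_MODELS or "ktrans" not in MODEL_PARAMS[model]:
        return fit_curve_nlls(times_min, data, model, aif, config, start, acquisition)
    starts = DEFAULT_KTRANS_STARTS
    if config is not None and getattr(config, "ktrans_starts", None):
        starts = config.ktrans_starts
    best = None
    n_ok = 0
    for kt0 in starts:
        s = dict(start or {})
        s["ktrans"] = kt0
        try:
            res = fit_curve_nlls(times_min, data, model, aif, config, s, acquisition)
            n_ok += 1
        except Exception:
            continue
        if best is None or res.rss < best.rss:  # ties keep the earlier start
            best = res
    if best is None:
        raise RuntimeError("all multistart fits failed")
    best.n_starts_used = len(starts)
    best.converged = best.converged and n_ok > 0
    return best


def f_test_compare(low: FitResult, high: FitResult):
    """F-test for whether the higher-parameter nested model is warranted.

    F = ((rss_low - rss_high)/(k_high - k_low)) / (rss_high/(n - k_high)).
    If the bigger model fits worse (optimizer noise), F is clamped to 0 and
    p = 1 so noise can never trigger a promotion.
    """
    if high.k <= low.k:
        raise ValueError("models not nested: high must have more parameters")
    if high.n != low.n:
        raise ValueError("fits must use the same number of points")
    n, dk = high.n, high.k - low.k
    if n <= high.k:
        raise ValueError("not enough points for the F-test degrees of freedom")
    if high.rss > low.rss:
        warnings.warn("larger model fits worse; F clamped to 0")
        return 0.0, 1.0
    if high.rss == low.rss:  # includes the all-zero perfect-fit case
        return 0.0, 1.0
    if high.rss == 0.0:  # strict improvement down to an exact fit
        return np.inf, 0.0
    f = ((low.rss - high.rss) / dk) / (high.rss / (n - high.k))
    p = float(stats.f.sf(f, dk, n - high.k))
    return float(f), p


def nested_model_fit(times_min, conc, aif, config=None, threshold=0.05):
    """Sequential nested model selection on one concentration curve.

    Fits Model 0 (identically zero), then attempts promotion to the
    steady-state, Patlak and extended Tofts models in turn; each step is
    accepted only if the F-test p-value is below ``threshold``, and the walk
    stops at the first rejection.  Lower-model estimates seed the next
    model's start values.
    """
    conc = np.asarray(conc, dtype=float)
    if not np.any(np.isfinite(conc)):
        raise ValueError("degenerate curve: all values NaN")
    fits = [fit_curve_nlls(times_min, conc, "zero", aif, config)]
    p_values = []
    selected = 0
    for idx in range(1, len(NESTED_HIERARCHY)):
        model = NESTED_HIERARCHY[idx]
        start = dict(fits[-1].params)
        if model == "ex_tofts":
            # seed vp from Patlak, ve at mid-range
            start = {"vp": min(start.get("vp", 0.05), 1.0), "ve": 0.5}
            fit = multistart_fit(times_min, conc, model, aif, config, start)
        else:
            fit = fit_curve_nlls(times_min, conc, model, aif, config, start)
        _, p = f_test_compare(fits[-1], fit)
        p_values.append(p)
        if p < threshold:
            selected = idx
            fits.append(fit)
        else:
            break
    return ModelSelectionResult(selected, p_values, fits[-1])


def _fit_one_voxel(times_min, curve, model, aif, config, acquisition, nested, threshold):
    try:
        if nested:
            sel = nested_model_fit(times_min, curve, aif, config, threshold)
            return sel.selected_index, sel.fit
        return None, multistart_fit(times_min, curve, model, aif, config, None, acquisition)
    except Exception:
        return None, None


def fit_voxelwise_map(
    conc_series,
    aif,
    model,
    mask=None,
    config=None,
    n_jobs=1,
    acquisition=None,
    nested=False,
    threshold=0.05,
    roi_mode=False,
):
    """Fit every masked voxel of a 4-D concentration series independently.

    Returns a dict of 3-D parameter maps (NaN outside the mask or where a
    fit failed) plus ``rss`` and, for nested selection, ``model_index``
    maps, and a count of failed voxels.  With ``roi_mode`` the per-label
    mean curve is fitted once per ROI label instead.  Parallel execution
    (joblib) is bitwise-identical to serial: voxels are independent and the
    work split does not affect per-voxel arithmetic.
    """
    from joblib import Parallel, delayed

    conc = conc_series.conc
    times = conc_series.frame_times_min
    shape = conc.shape[:3]
    if mask is None:
        mask_arr = np.ones(shape, dtype=bool)
    else:
        mask_arr = (mask.labels if hasattr(mask, "labels") else np.asarray(mask)) > 0

    if roi_mode:
        labels_arr = mask.labels if hasattr(mask, "labels") else np.asarray(mask)
        results = {}
        for lab in np.unique(labels_arr):
            if lab == 0:
                continue
            curve = np.nanmean(conc[labels_arr == lab, :], axis=0)
            _, fit = _fit_one_voxel(times, curve, model, aif, config, acquisition, nested, threshold)
            results[int(lab)] = fit
        return results

    idx = np.argwhere(mask_arr)
    curves = [conc[i, j, k, :] for i, j, k in idx]
    if n_jobs == 1:
        fitted = [
            _fit_one_voxel(times, c, model, aif, config, acquisition, nested, threshold)
            for c in curves
        ]
    else:
        fitted = Parallel(n_jobs=n_jobs)(
            delayed(_fit_one_voxel)(times, c, model, aif, config, acquisition, nested, threshold)
            for c in curves
        )

    param_names = MODEL_PARAMS[model] if not nested else ("ktrans", "ve", "vp", "v")
    maps = {p: np.full(shape, np.nan) for p in param_names}
    maps["rss"] = np.full(shape, np.nan)
    if nested:
        maps["model_index"] = np.full(shape, np.nan)
    n_failed = 0
    for (i, j, k), (sel_idx, fit) in zip(idx, fitted):
        if fit is None:
            n_failed += 1
            continue
        for p, v in fit.params.items():
            if p in maps:
                maps[p][i, j, k] = v
        maps["rss"][i, j, k] = fit.rss
        if nested:
            maps["model_index"][i, j, k] = sel_idx
    return maps, n_failed


def aic(fit: FitResult):
    """Akaike information criterion (and small-sample AICc) of a fit.

    AIC = n ln(rss/n) + 2k;  AICc adds 2k(k+1)/(n-k-1).  A perfect fit
    (rss = 0) returns -inf.
    """
    n, k = fit.n, fit.k
    if n <= k + 2:
        raise ValueError("need n > k + 2 for AICc")
    if fit.rss == 0.0:
        return -np.inf, -np.inf
    a = n * np.log(fit.rss / n) + 2 * k
    aicc = a + 2 * k * (k + 1) / (n - k - 1)
    return float(a), float(aicc)


def _moving_average(x, window):
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = window // 2
    out = np.empty_like(x, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    for i in range(n):  # edge shrinkage: truncate the window at boundaries
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def fmi_fri(fit: FitResult, data, window=5):
    """Fraction of modelled information (FMI) and residual information (FRI).

    Residuals are split into a structured part (centred moving average,
    default window 5) and a noise part.  FMI compares the variance explained
    by the model curve with structured residual variance; FRI the structured
    residual variance with noise variance.  Both lie in [0, 1]; a perfect
    fit gives FMI = 1, FRI = 0 (by convention for 0/0).
    """
    data = np.asarray(data, dtype=float)
    if fit.n < 10:
        raise ValueError("need at least 10 points for FMI/FRI")
    if np.var(data) == 0:
        return np.nan, np.nan
    model_curve = data - fit.residuals
    structured = _moving_average(fit.residuals, window)
    noise = fit.residuals - structured
    v_model = float(np.var(model_curve))
    v_struct = float(np.var(structured))
    v_noise = float(np.var(noise))
    fmi = 1.0 if v_model + v_struct == 0 else v_model / (v_model + v_struct)
    fri = 0.0 if v_struct + v_noise == 0 else v_struct / (v_struct + v_noise)
    return fmi, fri


def ccc(x, y):
    """Lin's concordance correlation coefficient (population 1/n moments).

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2): agreement of two
    readings with the identity line, penalising both scatter and bias.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    sx2 = np.var(x)
    sy2 = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        warnings.warn("zero variance and equal means: CCC undefined, returning 0")
        return 0.0
    return float(2.0 * sxy / denom)


def prediction_bounds(fit: FitResult, aif, level=0.95, acquisition=None):
    """Delta-method prediction interval for the fitted curve.

    yhat(t) +/- t_{(1+level)/2, n-k} sqrt(s^2 (1 + g' (J'J)^-1 g)) with
    s^2 = rss/(n-k) and g the parameter gradient of the model at each time
    point (the rows of the final Jacobian).
    """
    n, k = fit.n, fit.k
    if fit.jacobian is None:
        raise ValueError("fit has no Jacobian (linear or zero model)")
    s2 = fit.rss / (n - k)
    jtj = fit.jacobian.T @ fit.jacobian
    try:
        inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        warnings.warn("singular J'J: using pseudo-inverse")
        inv = np.linalg.pinv(jtj)
    g = fit.jacobian
    lever = np.einsum("ij,jk,ik->i", g, inv, g)
    half = stats.t.ppf((1 + level) / 2, n - k) * np.sqrt(s2 * (1.0 + lever))
    yhat = fit._data - fit.residuals
    return yhat - half, yhat + half
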