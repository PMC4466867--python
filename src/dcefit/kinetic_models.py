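"""Forward tracer-kinetic models for DCE-MRI tissue concentration curves.

All models map an arterial input function ``C_a(t)`` to a tissue
concentration curve ``C(t)`` (mM), on the AIF's time grid:

* steady-state:     C = v * C_a                                  (1 parameter)
* Patlak:           C = vp * C_a + Ktrans * int C_a dt           (2)
* Tofts:            C = Ktrans * C_a (*) exp(-(Ktrans/ve) t)     (2)
* extended Tofts:   C = vp * C_a + Tofts term                    (3)
* 2CXM:             two-compartment exchange, bi-exponential
                    impulse response parameterised by
                    (Ktrans, ve, vp, Fp)                         (4)
* tissue uptake:    no-backflux limit of the 2CXM
                    (Ktrans, vp, Fp)                             (3)
* FXR:              shutter-speed (two-site water exchange)
                    model in the signal domain
                    (Ktrans, ve, tau_i)                          (3)

Rates are per minute, volume fractions dimensionless, the intracellular
water lifetime tau_i in seconds (converted internally).  Convolutions use
trapezoid quadrature on a uniform grid; for exponential kernels an exact
O(n) recursion replaces the generic convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, lfilter

from .aif import AIFCurve
from .spgr import spgr_signal

__all__ = [
    "KineticParams",
    "TissueCurve",
    "MODEL_NAMES",
    "convolve_uniform",
    "exp_conv",
    "cumulative_integral",
    "model_steady_state",
    "model_patlak",
    "model_tofts",
    "model_extended_tofts",
    "model_2cxm",
    "model_tissue_uptake",
    "model_fxr_signal",
    "auc_metric",
    "evaluate_model",
]

MODEL_NAMES = (
    "zero",
    "steady_state",
    "patlak",
    "tofts",
    "ex_tofts",
    "two_cxm",
    "tissue_uptake",
    "fxr",
)


@dataclass
class KineticParams:
    """Parameter vector for one kinetic model.

    Only the fields a model uses are meaningful; the rest stay None.
    Invariants (fractions in [0,1], rates >= 0, Ktrans < Fp for the
    flow-limited models) are checked on construction.
    """

    model: str
    ktrans: float | None = None  # volume transfer constant, 1/min
    ve: float | None = None  # extravascular-extracellular volume fraction
    vp: float | None = None  # plasma volume fraction
    fp: float | None = None  # plasma flow per unit tissue volume, 1/min
    tau_i: float | None = None  # intracellular water lifetime, s
    v: float | None = None  # steady-state distribution volume fraction

    def __post_init__(self):
        if self.model not in MODEL_NAMES and self.model != "auc":
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("ve", "vp", "v"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} = {val} outside [0, 1]")
        for name in ("ktrans", "fp", "tau_i"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ve is not None and self.vp is not None and self.ve + self.vp > 1.0 + 1e-12:
            raise ValueError("ve + vp must not exceed 1")
        if self.model in ("two_cxm", "tissue_uptake"):
            if self.fp is None or self.ktrans is None or self.ktrans >= self.fp:
                raise ValueError("flow-limited models need ktrans < fp (extraction E < 1)")

    def as_dict(self):
        return {
            k: v
            for k, v in (
                ("ktrans", self.ktrans),
                ("ve", self.ve),
                ("vp", self.vp),
                ("fp", self.fp),
                ("tau_i", self.tau_i),
                ("v", self.v),
            )
            if v is not None
        }


@dataclass
class TissueCurve:
    """A model-generated tissue curve (concentration in mM, or signal for FXR)."""

    times_min: np.ndarray
    conc: np.ndarray
    generating_params: KineticParams | None = None
    aif_ref: AIFCurve | None = None
    domain: str = "concentration"


# ---------------------------------------------------------------------------
# numerical machinery


def _uniform_dt(times_min, rtol=1e-6):
    """Return the uniform grid spacing, or raise if the grid is non-uniform."""
    d = np.diff(times_min)
    dt = float(np.median(d))
    if np.any(np.abs(d - dt) > rtol * dt):
        raise ValueError("non-uniform time grid: resample before convolution")
    return dt


def resample_uniform(times_min, values):
    """Linear resampling onto a uniform grid at the median spacing."""
    dt = float(np.median(np.diff(times_min)))
    grid = times_min[0] + dt * np.arange(int(round((times_min[-1] - times_min[0]) / dt)) + 1)
    return grid, np.interp(grid, times_min, values)


def convolve_uniform(aif_conc, impulse, dt_min):
    """Causal convolution (aif * impulse)(t) by trapezoid quadrature.

    Both inputs sample their function on the same uniform grid of spacing
    ``dt_min``; the output has the same length.
    """
    a = np.asarray(aif_conc, dtype=float)
    h = np.asarray(impulse, dtype=float)
    if a.shape != h.shape:
        raise ValueError("aif and impulse must have equal length")
    n = len(a)
    full = fftconvolve(a, h)[:n] * dt_min
    # trapezoid endpoint rule: half weight on the first and last sample
    full -= 0.5 * dt_min * (a[0] * h + h[0] * a)
    full[0] = 0.0
    return full


def exp_conv(aif_conc, rate_per_min, dt_min):
    """Convolution with kernel exp(-rate * t), exact for a piecewise-linear input.

    The running integral obeys y[n] = E y[n-1] + c1 a[n] + c0 a[n-1] with
    E = exp(-rate dt) and weights from integrating the linear interpolant of
    the input against the exponential kernel analytically (an exponential
    integrator).  This remains accurate for arbitrarily stiff rates, where
    sampled-kernel quadrature breaks down, and reduces to the trapezoid rule
    as rate -> 0.  Runs in O(n) as an IIR filter.
    """
    a = np.asarray(aif_conc, dtype=float)
    x = rate_per_min * dt_min
    if x < 1e-4:
        # series in x to avoid cancellation; x = 0 is the trapezoid rule
        p = dt_min * (1.0 - x / 2.0 + x**2 / 6.0 - x**3 / 24.0)
        q = dt_min * (0.5 - x / 6.0 + x**2 / 24.0 - x**3 / 120.0)
    else:
        k = rate_per_min
        p = -np.expm1(-x) / k  # int_0^dt e^(-k u) du
        q = 1.0 / k - p / x  # int weight multiplying the new sample
    e = np.exp(-x)
    c1 = q
    c0 = p - q
    out = lfilter([c1, c0], [1.0, -e], a)
    if a[0] != 0.0:
        # the IIR start-up injects a spurious c1*a[0] at n=0 which then decays
        # through the recursion; remove it so the integral starts at zero
        out -= c1 * a[0] * np.exp(-x * np.arange(len(a)))
    return out


def cumulative_integral(values, dt_min):
    """Running trapezoid integral on a uniform grid (zero rate exp_conv)."""
    return exp_conv(values, 0.0, dt_min)


def _aif_arrays(aif):
    if isinstance(aif, AIFCurve):
        t, c = aif.times_min, aif.conc
    else:
        t, c = aif
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
    dt = _uniform_dt(t)
    return t, c, dt


# ---------------------------------------------------------------------------
# concentration-domain models


def model_steady_state(v, aif):
    """One-parameter model C(t) = v * C_a(t): tracer instantly equilibrates
    into a distribution volume fraction v."""
    t, ca, _ = _aif_arrays(aif)
    p = KineticParams("steady_state", v=v)
    return TissueCurve(t, v * ca, p, aif if isinstance(aif, AIFCurve) else None)


def model_patlak(ktrans, vp, aif):
    """Patlak model: vascular term plus unidirectional uptake integral."""
    t, ca, dt = _aif_arrays(aif)
    conc = vp * ca + ktrans * cumulative_integral(ca, dt)
    p = KineticParams("patlak", ktrans=ktrans, vp=vp)
    return TissueCurve(t, conc, p, aif if isinstance(aif, AIFCurve) else None)


def model_tofts(ktrans, ve, aif):
    """Standard Tofts model: exchange between plasma and EES with efflux
    rate constant kep = Ktrans/ve."""
    t, ca, dt = _aif_arrays(aif)
    if ktrans > 0 and ve <= 0:
        raise ValueError("ve must be positive when ktrans > 0")
    if ktrans == 0:
        conc = np.zeros_like(ca)
    else:
        conc = ktrans * exp_conv(ca, ktrans / ve, dt)
    p = KineticParams("tofts", ktrans=ktrans, ve=ve)
    return TissueCurve(t, conc, p, aif if isinstance(aif, AIFCurve) else None)


def model_extended_tofts(ktrans, ve, vp, aif):
    """Extended Tofts model: Tofts exchange term plus a plasma compartment."""
    t, ca, _ = _aif_arrays(aif)
    base = model_tofts(ktrans, ve, aif)
    conc = vp * ca + base.conc
    p = KineticParams("ex_tofts", ktrans=ktrans, ve=ve, vp=vp)
    return TissueCurve(t, conc, p, aif if isinstance(aif, AIFCurve) else None)


def _two_cxm_rates(ktrans, ve, vp, fp):
    """Eigenrates (K+, K-) and fast-pole weight A of the 2CXM impulse response."""
    e = ktrans / fp  # extraction fraction
    ps = fp * e / (1.0 - e)  # permeability-surface area product
    tb = vp / fp  # plasma mean transit time
    tp = vp / (fp + ps)
    te = ve / ps
    s = 1.0 / tp + 1.0 / te
    root = np.sqrt(s * s - 4.0 / (te * tb))
    kpos = 0.5 * (s + root)
    kneg = 0.5 * (s - root)
    # weight fixed by I(0) = Fp and I'(0) = -Fp/TB of the compartmental system
    a_weight = (1.0 / tb - kneg) / (kpos - kneg)
    return kpos, kneg, a_weight


def model_2cxm(ktrans, ve, vp, fp, aif):
    """Two-compartment exchange model (plasma + interstitium, finite flow).

    The impulse response is bi-exponential,
    I(t) = Fp [A e^(-K+ t) + (1-A) e^(-K- t)], with eigenrates from the
    compartmental ODE system and PS derived from the extraction fraction
    E = Ktrans/Fp via PS = Fp E/(1-E).
    """
    t, ca, dt = _aif_arrays(aif)
    p = KineticParams("two_cxm", ktrans=ktrans, ve=ve, vp=vp, fp=fp)
    if ktrans == 0:
        # PS = 0: intravascular single compartment, I(t) = Fp exp(-t Fp/vp)
        conc = fp * exp_conv(ca, fp / vp, dt)
    else:
        kpos, kneg, a_w = _two_cxm_rates(ktrans, ve, vp, fp)
        conc = fp * (a_w * exp_conv(ca, kpos, dt) + (1.0 - a_w) * exp_conv(ca, kneg, dt))
    return TissueCurve(t, conc, p, aif if isinstance(aif, AIFCurve) else None)


def model_tissue_uptake(ktrans, vp, fp, aif):
    """Tissue-uptake model: 2CXM limit with no backflux from the EES.

    I(t) = Fp [(1-E) e^(-t/Tp) + E],  E = Ktrans/Fp,  Tp = vp/(Fp+PS).
    """
    t, ca, dt = _aif_arrays(aif)
    p = KineticParams("tissue_uptake", ktrans=ktrans, vp=vp, fp=fp)
    e = ktrans / fp
    if ktrans == 0:
        conc = fp * exp_conv(ca, fp / vp, dt)
    else:
        ps = fp * e / (1.0 - e)
        tp = vp / (fp + ps)
        conc = fp * ((1.0 - e) * exp_conv(ca, 1.0 / tp, dt) + e * cumulative_integral(ca, dt))
    return TissueCurve(t, conc, p, aif if isinstance(aif, AIFCurve) else None)


# ---------------------------------------------------------------------------
# shutter-speed (FXR) signal model


def fxr_observed_r1(r1e_per_s, r1i_per_s, tau_i_s, p_i):
    """Slow eigenvalue of the two-site water-exchange relaxation matrix (1/s).

    Longitudinal magnetisation exchanges between extracellular (population
    1 - p_i, rate R1e) and intracellular (population p_i, rate R1i) water
    with lifetimes tau_e, tau_i related by detailed balance
    tau_e = tau_i (1 - p_i)/p_i.
    """
    tau_e = tau_i_s * (1.0 - p_i) / p_i
    s = r1e_per_s + r1i_per_s + 1.0 / tau_i_s + 1.0 / tau_e
    d = r1e_per_s - r1i_per_s + 1.0 / tau_e - 1.0 / tau_i_s
    return 0.5 * (s - np.sqrt(d * d + 4.0 / (tau_e * tau_i_s)))


def model_fxr_signal(ktrans, ve, tau_i_s, aif, acquisition):
    """Shutter-speed model: Tofts kinetics observed through finite-rate
    transcytolemmal water exchange, returned in the signal domain.

    ``acquisition`` supplies ``fa_deg``, ``tr_ms``, ``t10_ms``, ``r1``
    (relaxivity, L mmol^-1 s^-1) and ``s0`` (signal scale).  The
    extravascular-extracellular concentration is Ce = C_tofts/ve; the
    intracellular water fraction is tied to 1 - ve.  For ve = 1 (no
    intracellular pool) the model degenerates to fast exchange.
    """
    t, ca, _ = _aif_arrays(aif)
    fa = acquisition["fa_deg"]
    tr_ms = acquisition["tr_ms"]
    r10 = 1000.0 / acquisition["t10_ms"]  # 1/s
    r1 = acquisition["r1"]
    s0 = acquisition.get("s0", 1.0)
    ct = model_tofts(ktrans, ve, aif).conc
    p_i = 1.0 - ve
    if p_i <= 0 or tau_i_s <= 0:
        r1_obs = r10 + r1 * ct  # fast-exchange limit
    else:
        ce = ct / ve
        r1e = r10 + r1 * ce
        r1_obs = fxr_observed_r1(r1e, r10, tau_i_s, p_i)
    sig = spgr_signal(s0, r1_obs, fa, tr_ms)
    p = KineticParams("fxr", ktrans=ktrans, ve=ve, tau_i=tau_i_s)
    return TissueCurve(t, sig, p, aif if isinstance(aif, AIFCurve) else None, domain="signal")


# ---------------------------------------------------------------------------


def auc_metric(times_min, conc, window_min):
    """Area under the concentration curve over [t_start, t_end], mM*min."""
    t_start, t_end = window_min
    t = np.asarray(times_min, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t_start >= t_end:
        raise ValueError("empty AUC window")
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError("AUC window outside time support")
    grid = np.unique(np.concatenate([[t_start, t_end], t[(t > t_start) & (t < t_end)]]))
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def evaluate_model(model, params, aif, acquisition=None):
    """Evaluate a named model from a parameter dict (registry entry point)."""
    if model == "zero":
        t, ca, _ = _aif_arrays(aif)
        return TissueCurve(t, np.zeros_like(ca), KineticParams("zero"))
    if model == "steady_state":
        return model_steady_state(params["v"], aif)
    if model == "patlak":
        return model_patlak(params["ktrans"], params["vp"], aif)
    if model == "tofts":
        return model_tofts(params["ktrans"], params["ve"], aif)
    if model == "ex_tofts":
        return model_extended_tofts(params["ktrans"], params["ve"], params["vp"], aif)
    if model == "two_cxm":
        return model_2cxm(params["ktrans"], params["ve"], params["vp"], params["fp"], aif)
    if model == "tissue_uptake":
        return model_tissue_uptake(params["ktrans"], params["vp"], params["fp"], aif)
    if model == "fxr":
        return model_fxr_signal(params["ktrans"], params["ve"], params["tau_i"], aif, acquisition)
    raise ValueError(f"unknown model {model!r}")


def model_curve_raw(model, params, aif, acquisition=None):
    """Curve values only, without physical-invariant validation.

    Box-bounded optimisers legitimately explore parameter vectors that
    violate joint constraints (e.g. ve + vp > 1) on the way to a solution;
    this entry point evaluates the model arithmetic directly for them.
    """
    t, ca, dt = _aif_arrays(aif)
    if model == "zero":
        return np.zeros_like(ca)
    if model == "steady_state":
        return params["v"] * ca
    if model == "patlak":
        return params["vp"] * ca + params["ktrans"] * cumulative_integral(ca, dt)
    if model == "tofts":
        kt, ve = params["ktrans"], params["ve"]
        return kt * exp_conv(ca, kt / max(ve, 1e-12), dt) if kt > 0 else np.zeros_like(ca)
    if model == "ex_tofts":
        kt, ve, vp = params["ktrans"], params["ve"], params["vp"]
        tofts = kt * exp_conv(ca, kt / max(ve, 1e-12), dt) if kt > 0 else 0.0
        return vp * ca + tofts
    if model == "two_cxm":
        kt, ve, vp, fp = params["ktrans"], params["ve"], params["vp"], params["fp"]
        if kt <= 0:
            return fp * exp_conv(ca, fp / max(vp, 1e-12), dt)
        kt = min(kt, fp * (1.0 - 1e-9))  # keep E < 1 inside the optimiser box
        kpos, kneg, a_w = _two_cxm_rates(kt, max(ve, 1e-12), max(vp, 1e-12), fp)
        return fp * (a_w * exp_conv(ca, kpos, dt) + (1.0 - a_w) * exp_conv(ca, kneg, dt))
    if model == "tissue_uptake":
        kt, vp, fp = params["ktrans"], params["vp"], params["fp"]
        if kt <= 0:
            return fp * exp_conv(ca, fp / max(vp, 1e-12), dt)
        kt = min(kt, fp * (1.0 - 1e-9))
        e = kt / fp
        ps = fp * e / (1.0 - e)
        tp = max(vp, 1e-12) / (fp + ps)
        return fp * ((1.0 - e) * exp_conv(ca, 1.0 / tp, dt) + e * cumulative_integral(ca, dt))
    if model == "fxr":
        return model_fxr_signal(
            params["ktrans"], min(params["ve"], 1.0), params["tau_i"], aif, acquisition
        ).conc
    raise ValueError(f"unknown model {model!r}")
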