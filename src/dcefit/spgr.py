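"""Spoiled gradient-echo (SPGR/FLASH) signal equation and its closed-form inversion.

The steady-state SPGR magnitude signal is

    S = M0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),   E1 = exp(-TR * R1)

with flip angle ``alpha``, repetition time ``TR`` and longitudinal rate
``R1 = 1/T1``.  Both the forward model (used to synthesise dynamic signal)
and the exact inversion ``E1(S)`` (used to convert dynamic signal back to
concentration) live here so that every module shares one implementation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spgr_signal",
    "spgr_e1_from_signal",
    "r1_from_signal",
    "m0_from_baseline",
]


def spgr_signal(m0, r1_per_s, flip_angle_deg, tr_ms):
    """SPGR signal for magnetisation ``m0`` and longitudinal rate ``r1_per_s`` (1/s)."""
    alpha = np.deg2rad(flip_angle_deg)
    e1 = np.exp(-(tr_ms / 1000.0) * np.asarray(r1_per_s, dtype=float))
    return m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def spgr_e1_from_signal(signal, m0, flip_angle_deg):
    """Invert the SPGR equation for E1 = exp(-TR/T1).

    Solving S*(1 - E1*cos a) = M0*sin a*(1 - E1) gives

        E1 = (M0*sin a - S) / (M0*sin a - S*cos a)

    Values outside (0, 1) indicate a non-invertible (noise-dominated) signal
    and are returned as NaN.
    """
    alpha = np.deg2rad(flip_angle_deg)
    s = np.asarray(signal, dtype=float)
    num = m0 * np.sin(alpha) - s
    den = m0 * np.sin(alpha) - s * np.cos(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = num / den
    e1 = np.where((e1 > 0.0) & (e1 < 1.0), e1, np.nan)
    return e1


def r1_from_signal(signal, m0, flip_angle_deg, tr_ms):
    """Longitudinal rate R1 (1/s) solved in closed form from an SPGR signal."""
    e1 = spgr_e1_from_signal(signal, m0, flip_angle_deg)
    return -np.log(e1) / (tr_ms / 1000.0)


def m0_from_baseline(baseline_signal, t10_ms, flip_angle_deg, tr_ms):
    """Calibrate the M0 scale from a pre-contrast signal and known T1.

    With T1 = t10 the SPGR equation is linear in M0, so
    M0 = S / [sin a * (1-E1)/(1-E1 cos a)].
    """
    shape_factor = spgr_signal(1.0, 1000.0 / t10_ms, flip_angle_deg, tr_ms)
    return np.asarray(baseline_signal, dtype=float) / shape_factor
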