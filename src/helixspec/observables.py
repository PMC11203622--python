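"""Pump-probe isotropic signal processing, bi-exponential kinetics,
peak-ratio diagnostics, and CD fractional helicity.

The CD analysis follows the Baldwin relation for per-residue molar
ellipticity at 222 nm:

    f_H = ([θ]₂₂₂ − θ_C) / (θ_H − θ_C)

with the coil and helix baselines θ_C(T) = 2220 − 53·T and
θ_H(T, N_r) = (−44000 + 250·T)·(1 − 3/N_r), T in °C.  The grouping of the
finite-length correction (1 − 3/N_r) over the whole helix baseline is the
Baldwin convention; ``theta_helix`` exposes a switch for the alternative
reading in which only the temperature term is scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import InvalidInputError, UndefinedRatioError


# ---------------------------------------------------------------------------
# Isotropic pump-probe signal (magic-angle-free population observable)
# ---------------------------------------------------------------------------


def isotropic(s_par: np.ndarray, s_perp: np.ndarray) -> np.ndarray:
    """P(t) = (S∥ + 2·S⊥)/3, pointwise, for (t, S) tables on a shared grid."""
    a = np.asarray(s_par, dtype=float)
    b = np.asarray(s_perp, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise InvalidInputError("signals must be equal-shape (n, 2) tables")
    if not np.allclose(a[:, 0], b[:, 0]):
        raise InvalidInputError("parallel/perpendicular time grids differ")
    return np.column_stack([a[:, 0], (a[:, 1] + 2.0 * b[:, 1]) / 3.0])


# ---------------------------------------------------------------------------
# Bi-exponential population decay fits
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    """Result of a bi-exponential fit P(t) = A₁e^{−B₁t} + A₂e^{−B₂t}.

    Rates are ordered so B₁ ≥ B₂ (fast component first).  ``null`` flags a
    degenerate input (all zeros); ``reduced`` flags an effectively
    single-exponential result (one amplitude ≈ 0).
    """

    a1: float
    b1: float
    a2: float
    b2: float
    t_min_ps: float
    residual: float
    null: bool = False
    reduced: bool = False

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-self.b1 * t) + self.a2 * np.exp(-self.b2 * t)


def biexp_fit(p_table: np.ndarray, t_min_ps: float = 0.5) -> DecayFit:
    """Nonlinear least-squares bi-exponential fit on t > ``t_min_ps``.

    Initialisation is deterministic: A₁ = first retained value, B₁ = 1 ps⁻¹,
    A₂ = 0.1·A₁, B₂ = 0.1 ps⁻¹.  Rates are constrained positive.
    """
    tab = np.asarray(p_table, dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 2:
        raise InvalidInputError("p_table must be an (n, 2) table of (t, P)")
    sel = tab[:, 0] > t_min_ps
    if sel.sum() < 6:
        raise InvalidInputError(
            f"need ≥ 6 points beyond t_min={t_min_ps} ps, got {int(sel.sum())}"
        )
    t, p = tab[sel, 0], tab[sel, 1]
    if np.allclose(p, 0.0):
        return DecayFit(0.0, 1.0, 0.0, 0.1, t_min_ps, 0.0, null=True)

    a0 = float(p[0])
    x0 = np.array([a0, 1.0, 0.1 * a0, 0.1])
    lo = np.array([-np.inf, 1e-6, -np.inf, 1e-6])
    hi = np.array([np.inf, np.inf, np.inf, np.inf])

    def resid(x: np.ndarray) -> np.ndarray:
        return x[0] * np.exp(-x[1] * t) + x[2] * np.exp(-x[3] * t) - p

    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                        gtol=1e-14)
    a1, b1, a2, b2 = sol.x
    if b1 < b2:  # ordering convention: fast rate first
        a1, b1, a2, b2 = a2, b2, a1, b1
    scale = max(abs(a1), abs(a2), 1e-300)
    reduced = bool(min(abs(a1), abs(a2)) / scale < 1e-6)
    return DecayFit(float(a1), float(b1), float(a2), float(b2), t_min_ps,
                    float(np.sum(sol.fun**2)), reduced=reduced)


# ---------------------------------------------------------------------------
# Peak-height ratio diagnostics
# ---------------------------------------------------------------------------


def _local_max_height(freq: np.ndarray, vals: np.ndarray, omega: float,
                      window: float = 3.0) -> float:
    sel = np.abs(freq - omega) <= window
    if not sel.any():
        raise InvalidInputError(f"frequency {omega} cm⁻¹ outside grid")
    return float(vals[sel].max())


def peak_ratio_series(
    surface: np.ndarray,
    omega_a: float,
    omega_b: float,
    delays: np.ndarray | None = None,
    window_cm: float = 3.0,
) -> np.ndarray:
    """Height ratio a/b per delay on a pump-probe surface.

    ``surface`` is a long-format (delay, frequency, signal) table.  Heights
    are local maxima within ±``window_cm`` of each target frequency; a zero
    denominator yields NaN for that delay (flagged, not raised).
    """
    tab = np.asarray(surface, dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 3:
        raise InvalidInputError("surface must be a (delay, frequency, signal) table")
    all_delays = np.unique(tab[:, 0])
    if delays is None:
        delays = all_delays
    out = []
    for d in np.asarray(delays, dtype=float):
        if not np.isclose(all_delays, d).any():
            raise InvalidInputError(f"delay {d} ps not present in surface")
        rows = tab[np.isclose(tab[:, 0], d)]
        ha = _local_max_height(rows[:, 1], rows[:, 2], omega_a, window_cm)
        hb = _local_max_height(rows[:, 1], rows[:, 2], omega_b, window_cm)
        out.append([d, ha / hb if hb != 0 else np.nan])
    return np.asarray(out)


def mu4_consistency(linear_ratio: float) -> float:
    """Pump-probe peak ratio predicted from a linear-spectrum peak ratio.

    Pump-probe absorbance scales as μ⁴ while linear absorbance scales as μ²,
    so, oscillator strength being the sole cause, the pump-probe ratio is the
    square of the linear one.
    """
    if linear_ratio <= 0:
        raise InvalidInputError("linear ratio must be positive")
    return linear_ratio**2


# ---------------------------------------------------------------------------
# CD fractional helicity (Baldwin relation)
# ---------------------------------------------------------------------------


def theta_coil(t_celsius: np.ndarray | float) -> np.ndarray | float:
    """Random-coil baseline θ_C(T) = 2220 − 53·T (deg·cm²·dmol⁻¹/residue)."""
    return 2220.0 - 53.0 * np.asarray(t_celsius, dtype=float)


def theta_helix(
    t_celsius: np.ndarray | float, nr: int, scale_full: bool = True
) -> np.ndarray | float:
    """Perfect-helix baseline with finite-length correction.

    Default (Baldwin convention): θ_H = (−44000 + 250·T)·(1 − 3/N_r).
    With ``scale_full=False`` only the temperature term is scaled:
    θ_H = −44000 + 250·T·(1 − 3/N_r).
    """
    if nr < 4:
        raise InvalidInputError("Nr must be ≥ 4 for the helix baseline")
    t = np.asarray(t_celsius, dtype=float)
    if scale_full:
        return (-44000.0 + 250.0 * t) * (1.0 - 3.0 / nr)
    return -44000.0 + 250.0 * t * (1.0 - 3.0 / nr)


@dataclass
class CDRecord:
    theta222: float
    temperature_c: float
    nr: int
    fh: float
    clamped: bool


def helical_fraction(
    theta222: float, t_celsius: float, nr: int, scale_full: bool = True
) -> CDRecord:
    """Fractional helicity f_H = (θ₂₂₂ − θ_C)/(θ_H − θ_C), clamped to [0, 1].

    Strictly monotone decreasing in θ₂₂₂ at fixed T and N_r (θ_H < θ_C for
    physical temperatures).
    """
    th_c = float(theta_coil(t_celsius))
    th_h = float(theta_helix(t_celsius, nr, scale_full))
    if th_h == th_c:
        raise InvalidInputError("θ_H equals θ_C: non-physical baselines")
    fh = (theta222 - th_c) / (th_h - th_c)
    clamped = not (0.0 <= fh <= 1.0)
    return CDRecord(theta222, t_celsius, nr, float(np.clip(fh, 0.0, 1.0)), clamped)
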