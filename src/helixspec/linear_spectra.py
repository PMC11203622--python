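"""Linear amide I spectra and eigenmode delocalization diagnostics.

Two routes to the linear spectrum are provided and must agree for a static
Hamiltonian:

* a time-domain route that propagates the one-exciton wavefunction along the
  (possibly fluctuating) Hamiltonian trajectory and Fourier-transforms the
  dipole autocorrelation, with lifetime damping ``exp(−t/2T)`` — the half
  width at half maximum of the resulting Lorentzian is ``1/(4πcT)``;
* a stick spectrum from direct diagonalization, one line per eigenmode at
  its energy with intensity |μ_n|² (the eigen-basis transition dipole).

Eigenmode diagnostics are binned by frequency: the inverse participation
ratio IPR_j = 1/Σ_n φ_jn⁴ (effective number of sites an eigenmode occupies,
between 1 and N), oscillator strength μ², density of states, and the mean
squared site components per chromophore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    C_CM_PER_PS,
    HamiltonianSeries,
    InvalidInputError,
    Spectrum1D,
    UndefinedRatioError,
    logger,
)

DEFAULT_GRID = np.arange(1500.0, 1800.0 + 0.25, 0.5)
DEFAULT_LIFETIME_PS = 1.0


def lorentzian_hwhm_cm(lifetime_ps: float) -> float:
    """HWHM (cm⁻¹) of the lifetime-broadened line: 1/(4πcT)."""
    return 1.0 / (4.0 * np.pi * C_CM_PER_PS * lifetime_ps)


# ---------------------------------------------------------------------------
# Stick spectrum (direct diagonalization)
# ---------------------------------------------------------------------------


def stick_spectrum(
    h_frame: np.ndarray, dipoles: np.ndarray
) -> list[tuple[float, float]]:
    """Eigenmode energies and squared eigen-basis transition dipoles.

    Returns [(E_n, |μ_n|²), ...] sorted by energy.  Total dipole strength is
    conserved: Σ_n |μ_n|² = Σ_i |μ_i|² (orthogonality of the eigenvectors).
    """
    h = np.asarray(h_frame, dtype=float)
    if not np.allclose(h, h.T, atol=1e-9):
        raise InvalidInputError("Hamiltonian frame must be symmetric")
    evals, evecs = np.linalg.eigh(h)
    mu_eig = evecs.T @ np.asarray(dipoles, dtype=float)  # (N, 3)
    strengths = np.einsum("nk,nk->n", mu_eig, mu_eig)
    return [(float(e), float(s)) for e, s in zip(evals, strengths)]


def broadened_stick_spectrum(
    h_frame: np.ndarray, dipoles: np.ndarray,
    lifetime_ps: float = DEFAULT_LIFETIME_PS,
    grid: np.ndarray | None = None,
) -> Spectrum1D:
    """Stick spectrum convolved with the lifetime Lorentzian."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    gamma = lorentzian_hwhm_cm(lifetime_ps)
    out = np.zeros_like(grid)
    for e, s in stick_spectrum(h_frame, dipoles):
        out += s * gamma / ((grid - e) ** 2 + gamma**2)
    return Spectrum1D(grid, out, {"lifetime_ps": lifetime_ps, "source": "sticks"})


# ---------------------------------------------------------------------------
# Time-domain spectrum (wavefunction propagation)
# ---------------------------------------------------------------------------


def _propagator_step(h: np.ndarray, dt_ps: float) -> np.ndarray:
    """exp(−2πi·c·H·dt) via eigendecomposition (unitary to machine precision)."""
    evals, evecs = np.linalg.eigh(h)
    phase = np.exp(-2j * np.pi * C_CM_PER_PS * evals * dt_ps)
    return (evecs * phase) @ evecs.conj().T


def linear_spectrum_td(
    series: HamiltonianSeries,
    lifetime_ps: float = DEFAULT_LIFETIME_PS,
    grid: np.ndarray | None = None,
    t_max_ps: float = 4.0,
    n_samples: int = 1,
) -> Spectrum1D:
    """Time-domain linear spectrum by one-exciton propagation.

    The response ``R(t) = Σ_j μ^j(0)·F(t)·μ^j(t)·e^{−t/2T}`` (with F the
    time-ordered propagator and j the three lab axes) is accumulated over the
    stored frames and cosine-transformed onto ``grid``.  ``n_samples`` start
    frames are averaged, strided across the trajectory.  For a static series
    this equals the lifetime-broadened stick spectrum.
    """
    if lifetime_ps <= 0:
        raise InvalidInputError("lifetime must be positive")
    dt = series.dt_ps
    if dt > 0.05:
        logger.warning("frame spacing %.3f ps > 0.05 ps: spectra may alias", dt)
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    n_t = int(round(t_max_ps / dt)) + 1
    n_frames = series.n_frames

    starts = [0]
    if n_samples > 1:
        avail = max(n_frames - n_t, 0)
        starts = sorted({int(k) for k in np.linspace(0, avail, n_samples)})

    resp = np.zeros(n_t, dtype=complex)
    for s0 in starts:
        mu0 = series.dipoles[min(s0, n_frames - 1)]
        u = np.eye(series.n_sites, dtype=complex)
        for k in range(n_t):
            f = min(s0 + k, n_frames - 1)
            mu_t = series.dipoles[f]
            resp[k] += np.einsum("nj,nm,mj->", mu_t, u, mu0.astype(complex)).item()
            if k + 1 < n_t:
                u = _propagator_step(series.matrices[f], dt) @ u
    resp /= len(starts)

    t = np.arange(n_t) * dt
    resp *= np.exp(-t / (2.0 * lifetime_ps))
    w = np.ones(n_t)
    w[0] = 0.5  # trapezoid edge
    kernel = np.exp(2j * np.pi * C_CM_PER_PS * np.outer(grid, t))
    # 2πc factor matches the γ-normalized Lorentzian of the stick route
    intensity = (kernel @ (w * resp)).real * dt * (2.0 * np.pi * C_CM_PER_PS)
    return Spectrum1D(grid, intensity,
                      {"lifetime_ps": lifetime_ps, "source": "nise"})


# ---------------------------------------------------------------------------
# Eigenmode summary (frequency-binned diagnostics)
# ---------------------------------------------------------------------------


def ipr(components: np.ndarray) -> float:
    """Inverse participation ratio 1/Σ φ⁴ of a normalized mode vector."""
    phi = np.asarray(components, dtype=float)
    return float(1.0 / np.sum(phi**4))


@dataclass
class EigenmodeSummary:
    """Time-averaged, frequency-binned eigenmode diagnostics.

    Per bin: mean IPR (NaN where no mode fell in the bin), summed oscillator
    strength and density of states (averages per frame), and the mean squared
    site components (n_bins × N).
    """

    bin_edges: np.ndarray
    mean_ipr: np.ndarray
    oscillator_strength: np.ndarray
    density_of_states: np.ndarray
    site_components_sq: np.ndarray
    n_sites: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def eigen_summary(series: HamiltonianSeries, bin_edges: np.ndarray) -> EigenmodeSummary:
    """Diagonalize every frame, bin eigenmodes by energy, time-average."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise InvalidInputError("bin edges must be increasing, ≥ 2 values")
    nb = edges.size - 1
    n = series.n_sites
    ipr_sum = np.zeros(nb)
    ipr_cnt = np.zeros(nb)
    osc = np.zeros(nb)
    dos = np.zeros(nb)
    comp = np.zeros((nb, n))
    for f in range(series.n_frames):
        evals, evecs = np.linalg.eigh(series.matrices[f])
        mu_eig = evecs.T @ series.dipoles[f]
        strength = np.einsum("nk,nk->n", mu_eig, mu_eig)
        idx = np.digitize(evals, edges) - 1
        for j in range(n):
            b = idx[j]
            if b < 0 or b >= nb:
                continue
            phi = evecs[:, j]
            ipr_sum[b] += ipr(phi)
            ipr_cnt[b] += 1
            osc[b] += strength[j]
            dos[b] += 1.0
            comp[b] += phi**2
    nf = series.n_frames
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ipr = np.where(ipr_cnt > 0, ipr_sum / ipr_cnt, np.nan)
        comp_mean = np.where(dos[:, None] > 0, comp / dos[:, None], 0.0)
    return EigenmodeSummary(edges, mean_ipr, osc / nf, dos / nf, comp_mean, n)


# ---------------------------------------------------------------------------
# Second-derivative analysis and band ratios
# ---------------------------------------------------------------------------


def second_derivative(s: Spectrum1D, window: int = 11, polyorder: int = 3) -> Spectrum1D:
    """Savitzky–Golay second derivative on the native grid.

    Overlapping bands that merge in absorbance resolve as distinct minima of
    the second derivative.
    """
    if window % 2 == 0 or window <= polyorder:
        raise InvalidInputError("window must be odd and greater than polyorder")
    if window > s.frequency.size:
        raise InvalidInputError("window larger than spectrum")
    step = float(np.mean(np.diff(s.frequency)))
    d2 = savgol_filter(s.intensity, window, polyorder, deriv=2, delta=step)
    meta = dict(s.metadata)
    meta["derivative"] = 2
    return Spectrum1D(s.frequency, d2, meta)


def band_ratio(
    s: Spectrum1D, omega_a: float, omega_b: float,
    mode: str = "nearest", window_cm: float = 3.0,
) -> float:
    """Intensity ratio a/b at two band positions.

    ``mode='nearest'`` samples the closest grid point; ``mode='local_max'``
    takes the maximum within ±``window_cm`` of each position.
    """
    f = s.frequency
    for om in (omega_a, omega_b):
        if not (f[0] <= om <= f[-1]):
            raise InvalidInputError(f"frequency {om} outside spectral axis")

    def height(om: float) -> float:
        if mode == "local_max":
            sel = np.abs(f - om) <= window_cm
            return float(s.intensity[sel].max())
        return float(s.intensity[np.argmin(np.abs(f - om))])

    hb = height(omega_b)
    if hb == 0.0:
        raise UndefinedRatioError(f"zero intensity at {omega_b} cm⁻¹")
    return height(omega_a) / hb
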