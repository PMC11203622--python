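"""Purely absorptive 2D-IR amide I spectra by wavefunction propagation.

The third-order response is built from the six double-sided pathways
(ground-state bleach, stimulated emission, excited-state absorption, each in
rephasing and nonrephasing time ordering) by chaining one-exciton
propagators along the Hamiltonian trajectory.  Two-quantum states are
treated perturbatively: the basis is the set of site-pair harmonic states
|nm⟩ with a diagonal anharmonic shift Δ on the doubly excited sites, and
transition dipoles obey harmonic scaling (⟨nn|μ⁺|n⟩ = √2 μₙ,
⟨nm|μ⁺|n⟩ = μₘ).  For Δ = 0 the excited-state-absorption pathway cancels
bleach plus emission exactly and the absorptive spectrum vanishes.

Orientational averaging is the isotropic ⟨jjjj⟩ sum over the three lab
axes, matching the j-sum of the linear response.  Lifetime damping
``exp(−t/2T)`` applies on both coherence intervals and ``exp(−T_w/T)`` on
the population interval.

Pathways are evaluated on an absolute-time sweep: all pending two-exciton
vectors (one pair per coherence-time column) advance together through the
per-step propagator, so the number of two-exciton diagonalizations grows
linearly, not quadratically, with the scan lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    C_CM_PER_PS,
    HamiltonianSeries,
    InsufficientDataError,
    InvalidInputError,
    Spectrum2D,
)

DEFAULT_ANHARMONICITY_CM = 16.0
DEFAULT_LIFETIME_PS = 1.0


@dataclass(frozen=True)
class TwoQuantumModel:
    """Perturbative two-quantum treatment: site-pair harmonic basis with a
    diagonal anharmonic shift Δ (cm⁻¹) on doubly excited sites."""

    anharmonicity_cm: float = DEFAULT_ANHARMONICITY_CM

    def __post_init__(self) -> None:
        if self.anharmonicity_cm < 0:
            raise InvalidInputError("anharmonicity must be ≥ 0")


def pair_basis(n: int) -> list[tuple[int, int]]:
    """Ordered site-pair states (p ≤ q), dimension N(N+1)/2."""
    return [(p, q) for p in range(n) for q in range(p, n)]


def two_quantum_hamiltonian(h1: np.ndarray, delta: float) -> np.ndarray:
    """Harmonic-mapping two-exciton Hamiltonian with diagonal shift Δ.

    ⟨pq|H₂|pq⟩ = ε_p + ε_q − δ_pq·Δ; states sharing one site couple through
    the one-exciton J of the differing sites, with √2 on transfers into or
    out of a doubly excited state.
    """
    n = h1.shape[0]
    pairs = pair_basis(n)
    idx = {pq: k for k, pq in enumerate(pairs)}
    h2 = np.zeros((len(pairs), len(pairs)))
    eps = np.diag(h1)
    root2 = np.sqrt(2.0)
    for k, (p, q) in enumerate(pairs):
        h2[k, k] = eps[p] + eps[q] - (delta if p == q else 0.0)
        for c in range(n):
            if p == q:
                if c != p:  # |pp⟩ → |pc⟩
                    kk = idx[(min(p, c), max(p, c))]
                    h2[k, kk] = root2 * h1[p, c]
            else:
                for keep, move in ((p, q), (q, p)):
                    if c == move:
                        continue
                    kk = idx[(min(keep, c), max(keep, c))]
                    h2[k, kk] = (root2 if c == keep else 1.0) * h1[move, c]
    return h2


def raising_operator(dip_axis: np.ndarray) -> np.ndarray:
    """Harmonic one→two-exciton dipole matrix for one lab axis, (P × N).

    ``dip_axis`` is the length-N vector of site dipole components along the
    chosen axis.
    """
    n = dip_axis.shape[0]
    pairs = pair_basis(n)
    b = np.zeros((len(pairs), n))
    for k, (p, q) in enumerate(pairs):
        if p == q:
            b[k, p] = np.sqrt(2.0) * dip_axis[p]
        else:
            b[k, p] = dip_axis[q]
            b[k, q] = dip_axis[p]
    return b


def _step_u(h: np.ndarray, dt: float) -> np.ndarray:
    """exp(−2πi·c·H·dt), unitary to machine precision via eigh."""
    evals, evecs = np.linalg.eigh(h)
    phase = np.exp(-2j * np.pi * C_CM_PER_PS * evals * dt)
    return (evecs * phase) @ evecs.conj().T


@dataclass
class Response2D:
    """Time-domain rephasing/nonrephasing responses on (t1, t3) grids."""

    t1_ps: np.ndarray
    t3_ps: np.ndarray
    rephasing: np.ndarray
    nonrephasing: np.ndarray
    t_wait_ps: float


def response_functions(
    series: HamiltonianSeries,
    t_wait_ps: float,
    t1_max_ps: float = 2.0,
    t3_max_ps: float = 2.0,
    delta_cm: float = DEFAULT_ANHARMONICITY_CM,
    lifetime_ps: float = DEFAULT_LIFETIME_PS,
) -> Response2D:
    """Rephasing and nonrephasing third-order responses at one wait time.

    A single-frame series is treated as static (the frame repeats); a
    multi-frame series must cover t1_max + T_w + t3_max.  Pathway sign
    convention: ground-state bleach and stimulated emission positive,
    excited-state absorption negative, so fundamental diagonal peaks are
    positive in the absorptive spectrum.
    """
    if delta_cm < 0:
        raise InvalidInputError("anharmonicity must be ≥ 0")
    if lifetime_ps <= 0:
        raise InvalidInputError("lifetime must be positive")
    dt = series.dt_ps
    n1 = int(round(t1_max_ps / dt)) + 1
    nw = int(round(t_wait_ps / dt))
    n3 = int(round(t3_max_ps / dt)) + 1
    total = n1 - 1 + nw + n3 - 1
    static = series.n_frames == 1
    if not static and series.n_frames < total + 1:
        raise InsufficientDataError(
            f"trajectory has {series.n_frames} frames but t1+T_w+t3 "
            f"needs {total + 1}"
        )

    n = series.n_sites
    p_dim = n * (n + 1) // 2
    fidx = (lambda k: 0) if static else (lambda k: k)

    r_r = np.zeros((n1, n3), dtype=complex)
    r_nr = np.zeros((n1, n3), dtype=complex)

    # per-step propagators, cached by frame index (one entry when static)
    u1_cache: dict[int, np.ndarray] = {}
    u2_cache: dict[int, np.ndarray] = {}

    def u1(k: int) -> np.ndarray:
        f = fidx(k)
        if f not in u1_cache:
            u1_cache[f] = _step_u(series.matrices[f], dt)
        return u1_cache[f]

    def u2(k: int) -> np.ndarray:
        f = fidx(k)
        if f not in u2_cache:
            u2_cache[f] = _step_u(
                two_quantum_hamiltonian(series.matrices[f], delta_cm), dt
            )
            if not static and len(u2_cache) > 4:
                for key in list(u2_cache)[:-2]:  # bound memory on long sweeps
                    if key != f:
                        del u2_cache[key]
        return u2_cache[f]

    for axis in range(3):
        mu = series.dipoles[:, :, axis]

        def mu_at(k: int) -> np.ndarray:
            return mu[fidx(k)]

        # first-interaction vector ψ0(k) = U(k,0)·μ(0)
        psi0 = np.empty((total + 1, n), dtype=complex)
        psi0[0] = mu_at(0)
        for k in range(total):
            psi0[k + 1] = u1(k) @ psi0[k]

        # per-column states; column a covers τ1 = a, τ2 = a+nw
        eta = np.zeros((n1, n), dtype=complex)    # U(k, τ1)·μ(τ1)
        xi = np.zeros((n1, n), dtype=complex)     # U(k, τ2)·μ(τ2)
        phi_r = np.zeros((p_dim, n1), dtype=complex)
        phi_nr = np.zeros((p_dim, n1), dtype=complex)
        c1 = np.zeros(n1, dtype=complex)
        e_se = np.zeros(n1, dtype=complex)
        k_nr = np.zeros(n1, dtype=complex)
        started = np.zeros(n1, dtype=bool)

        for k in range(total + 1):
            mu_k = mu_at(k)
            if k < n1:  # column k opens: first coherence begins
                eta[k] = mu_k
                c1[k] = mu_k @ psi0[k]
            a2 = k - nw
            if 0 <= a2 < n1:  # column a2 reaches τ2: population closes
                e_se[a2] = mu_k @ psi0[k]
                k_nr[a2] = mu_k @ eta[a2]
                b_k = raising_operator(mu_k)
                xi[a2] = mu_k
                phi_r[:, a2] = b_k @ eta[a2]
                phi_nr[:, a2] = b_k @ psi0[k]
                started[a2] = True
            # columns with τ2 ≤ k ≤ τ2 + n3 − 1 contribute at t3 = k − τ2
            lo = max(0, k - nw - (n3 - 1))
            hi = min(n1 - 1, k - nw)
            if hi >= lo:
                cols = np.arange(lo, hi + 1)
                cols = cols[started[cols]]
                if cols.size:
                    b_k = raising_operator(mu_k)
                    w0 = b_k @ psi0[k]
                    b_idx = k - nw - cols
                    d = xi[cols] @ mu_k            # μ(τ3)·ξ  (GSB)
                    f = eta[cols] @ mu_k           # μ(τ3)·η  (SE_r)
                    g = mu_k @ psi0[k]             # μ(τ3)·ψ0 (SE_nr)
                    esa_r = w0.conj() @ phi_r[:, cols]
                    w_eta = b_k @ eta[cols].T      # (P, n_cols)
                    esa_nr = np.einsum("pc,pc->c", w_eta.conj(), phi_nr[:, cols])
                    r_r[cols, b_idx] += (np.conj(c1[cols]) * d
                                         + np.conj(e_se[cols]) * f - esa_r)
                    r_nr[cols, b_idx] += (c1[cols] * d
                                          + np.conj(k_nr[cols]) * g - esa_nr)
            if k < total:
                u = u1(k)
                live1 = np.arange(min(k + 1, n1))
                eta[live1] = eta[live1] @ u.T
                act = np.where(started)[0]
                act = act[act + nw + n3 - 1 > k]  # still inside a t3 window
                if act.size:
                    xi[act] = xi[act] @ u.T
                    uu2 = u2(k)
                    phi_r[:, act] = uu2 @ phi_r[:, act]
                    phi_nr[:, act] = uu2 @ phi_nr[:, act]

    t1 = np.arange(n1) * dt
    t3 = np.arange(n3) * dt
    damp = np.exp(-np.add.outer(t1, t3) / (2.0 * lifetime_ps))
    damp *= np.exp(-t_wait_ps / lifetime_ps)
    return Response2D(t1, t3, r_r * damp, r_nr * damp, t_wait_ps)


# ---------------------------------------------------------------------------
# Frequency-domain absorptive spectrum
# ---------------------------------------------------------------------------

DEFAULT_GRID_2D = np.arange(1580.0, 1720.0 + 0.25, 0.5)


def _dft_kernels(
    t1: np.ndarray, t3: np.ndarray,
    grid_tau: np.ndarray, grid_m: np.ndarray, sign_tau: float,
) -> tuple[np.ndarray, np.ndarray]:
    w1 = np.ones(t1.size)
    w1[0] = 0.5
    w3 = np.ones(t3.size)
    w3[0] = 0.5
    apod1 = np.cos(0.5 * np.pi * t1 / t1[-1]) if t1.size > 1 else np.ones(1)
    apod3 = np.cos(0.5 * np.pi * t3 / t3[-1]) if t3.size > 1 else np.ones(1)
    k_tau = np.exp(sign_tau * 2j * np.pi * C_CM_PER_PS
                   * np.outer(grid_tau, t1)) * (w1 * apod1)
    k_m = np.exp(2j * np.pi * C_CM_PER_PS * np.outer(grid_m, t3)) * (w3 * apod3)
    return k_tau, k_m


def absorptive(
    resp: Response2D,
    grid_tau: np.ndarray | None = None,
    grid_m: np.ndarray | None = None,
) -> Spectrum2D:
    """Sum of rephasing and nonrephasing double Fourier transforms.

    The rephasing component is transformed with the opposite ω_τ sign so
    both contribute at positive frequencies; the real part is returned.
    Cosine apodization is applied along both time axes and the transform is
    evaluated directly on the requested frequency grids.
    """
    gt = DEFAULT_GRID_2D if grid_tau is None else np.asarray(grid_tau, float)
    gm = DEFAULT_GRID_2D if grid_m is None else np.asarray(grid_m, float)
    if resp.rephasing.shape != resp.nonrephasing.shape:
        raise InvalidInputError("rephasing/nonrephasing grids differ")
    k_tau_r, k_m = _dft_kernels(resp.t1_ps, resp.t3_ps, gt, gm, sign_tau=-1.0)
    k_tau_nr, _ = _dft_kernels(resp.t1_ps, resp.t3_ps, gt, gm, sign_tau=+1.0)
    spec = (k_tau_r @ resp.rephasing @ k_m.T
            + k_tau_nr @ resp.nonrephasing @ k_m.T).real
    return Spectrum2D(gt, gm, spec, t_wait_ps=resp.t_wait_ps,
                      component="absorptive")


def compute_2dir(
    series: HamiltonianSeries,
    t_wait_ps: float,
    grid_tau: np.ndarray | None = None,
    grid_m: np.ndarray | None = None,
    **kwargs,
) -> Spectrum2D:
    """Convenience wrapper: response functions + absorptive transform."""
    return absorptive(response_functions(series, t_wait_ps, **kwargs),
                      grid_tau, grid_m)


def sweep_waittimes(
    series: HamiltonianSeries,
    t_waits_ps: list[float],
    grid_tau: np.ndarray | None = None,
    grid_m: np.ndarray | None = None,
    **kwargs,
) -> list[Spectrum2D]:
    """Absorptive spectra at a list of wait times (batch wrapper)."""
    return [compute_2dir(series, tw, grid_tau, grid_m, **kwargs)
            for tw in t_waits_ps]
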