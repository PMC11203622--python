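"""Seeded generators for every input the pipeline consumes.

This module emulates, at desk scale, the data a solvated-peptide MD and
spectroscopy study would produce: ideal and locally bent α-helical backbones
built by internal-coordinate chain construction, noisy frame sequences with
two-state hydrogen-bond switching, 2D-IR surfaces composed of known tilted
Gaussian peak pairs, bi-exponential pump-probe decays, CD melting curves, and
analytic double-well potentials for free-energy-method tests.

Backbone geometry constants (fixed standard values)
---------------------------------------------------
===========================  =========
bond / angle                 value
===========================  =========
N–CA                         1.458 Å
CA–C                         1.525 Å
C–N (peptide)                1.329 Å
C=O                          1.231 Å
N–H                          1.010 Å
CH3–C (acetyl)               1.500 Å
C–OXT (acid)                 1.320 Å
C(-1)–N–CA                   121.7°
N–CA–C                       111.2°
CA–C–N(+1)                   116.2°
N(+1)–C–O                    122.7°
C(-1)–N–H                    119.5°
ω (trans peptide)            180°
===========================  =========
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import (
    GenerationFailureError,
    InvalidInputError,
    PeptideSpec,
    Spectrum2D,
    THREE_LETTER,
    Trajectory,
)

# bond lengths in nm
_B_N_CA = 0.1458
_B_CA_C = 0.1525
_B_C_N = 0.1329
_B_C_O = 0.1231
_B_N_H = 0.1010
_B_CH3_C = 0.1500
_B_C_OXT = 0.1320

# angles in degrees
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_N_C_O = 122.7
_A_C_N_H = 119.5
_A_CA_C_OXT = 117.0
_A_CA_C_O_TERM = 121.0

IDEAL_PHI = -57.8
IDEAL_PSI = -47.0

HBOND_CUTOFF_NM = 0.35


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from the chain A–B–C (NeRF construction).

    ``bond`` = |C–D|, ``angle_deg`` = ∠(B,C,D), ``torsion_deg`` = dihedral
    A–B–C–D.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(spec: PeptideSpec, phi: np.ndarray, psi: np.ndarray) -> Trajectory:
    """Construct one frame from per-residue φ/ψ arrays (degrees)."""
    n = spec.n_residues
    names: list[str] = []
    res_ids: list[int] = []
    res_names: list[str] = []
    xyz: list[np.ndarray] = []

    def add(name: str, rid: int, rname: str, pos: np.ndarray) -> None:
        names.append(name)
        res_ids.append(rid)
        res_names.append(rname)
        xyz.append(np.asarray(pos, dtype=float))

    # --- mainline N/CA/C chain (cap first), decorations afterwards
    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))

    capped = spec.n_terminal_cap == "acetyl"
    if capped:
        ch3 = np.zeros(3)
        c_ace = np.array([_B_CH3_C, 0.0, 0.0])
        # seed: N(1) in the xy-plane at the CA–C–N angle
        ang = math.radians(180.0 - _A_CA_C_N)
        N[0] = c_ace + _B_C_N * np.array([math.cos(ang), math.sin(ang), 0.0])
        CA[0] = _place(ch3, c_ace, N[0], _B_N_CA, _A_C_N_CA, 180.0)
        C[0] = _place(c_ace, N[0], CA[0], _B_CA_C, _A_N_CA_C, phi[0])
    else:
        N[0] = np.zeros(3)
        CA[0] = np.array([_B_N_CA, 0.0, 0.0])
        ang = math.radians(180.0 - _A_N_CA_C)
        C[0] = CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])

    for i in range(1, n):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])

    # --- carbonyl O per residue (planar sp2: trans to CA about the N(+1)–C axis)
    O = np.empty((n, 3))
    for i in range(n - 1):
        O[i] = _place(CA[i], N[i + 1], C[i], _B_C_O, _A_N_C_O, 180.0)
    # C-terminal carbonyl: defined by ψ of the final residue
    O[n - 1] = _place(N[n - 1], CA[n - 1], C[n - 1], _B_C_O, _A_CA_C_O_TERM,
                      psi[n - 1] + 180.0)

    # --- amide H per residue (trans to the preceding carbonyl O)
    H = np.full((n, 3), np.nan)
    for i in range(n):
        if spec.sequence[i] == "P":
            continue  # proline has no amide H
        if i == 0:
            if capped:
                H[0] = _place(ch3, c_ace, N[0], _B_N_H, _A_C_N_H, 0.0)
            else:
                continue  # free N-terminus: no single amide H modelled
        else:
            H[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_H, _A_C_N_H, 0.0)

    # --- assemble in stable order
    if capped:
        o_ace = _place(ch3, N[0], c_ace, _B_C_O, _A_N_C_O, 180.0)
        add("CH3", 0, "ACE", ch3)
        add("C", 0, "ACE", c_ace)
        add("O", 0, "ACE", o_ace)
    for i in range(n):
        rid = i + 1
        rname = THREE_LETTER[spec.sequence[i]]
        add("N", rid, rname, N[i])
        if np.isfinite(H[i]).all():
            add("H", rid, rname, H[i])
        add("CA", rid, rname, CA[i])
        add("C", rid, rname, C[i])
        add("O", rid, rname, O[i])
    if spec.c_terminal == "carboxylic_acid":
        oxt = _place(N[n - 1], CA[n - 1], C[n - 1], _B_C_OXT, _A_CA_C_OXT,
                     psi[n - 1])
        add("OXT", n, THREE_LETTER[spec.sequence[-1]], oxt)
    else:
        nt = _place(N[n - 1], CA[n - 1], C[n - 1], _B_C_N, _A_CA_C_N, psi[n - 1])
        add("NT", n, THREE_LETTER[spec.sequence[-1]], nt)

    return Trajectory(
        coords=np.asarray(xyz)[None, :, :],
        atom_names=names,
        res_ids=np.asarray(res_ids),
        res_names=res_names,
        spec=spec,
    )


def make_ideal_helix(
    spec: PeptideSpec,
    phi_deg: float = IDEAL_PHI,
    psi_deg: float = IDEAL_PSI,
) -> Trajectory:
    """Single-frame backbone with uniform φ/ψ dihedrals.

    The default φ/ψ = −57.8°/−47.0° produces an ideal α-helix in which every
    interior O(i)···H(i+4) hydrogen-bond distance is ≈ 0.2 nm.
    """
    for name, val in (("phi", phi_deg), ("psi", psi_deg)):
        if not (-180.0 < val <= 180.0):
            raise InvalidInputError(f"{name} must lie in (−180, 180], got {val}")
    n = spec.n_residues
    return _build_backbone(spec, np.full(n, phi_deg), np.full(n, psi_deg))


def hbond_distances(traj: Trajectory, frame: int = 0) -> dict[tuple[int, int], float]:
    """All O(i)···H(i+4) distances (nm) available in one frame."""
    out: dict[tuple[int, int], float] = {}
    n = int(traj.res_ids.max())
    for i in range(1, n - 3):
        ko = traj.atom_index(i, "O")
        kh = traj.atom_index(i + 4, "H")
        if ko < 0 or kh < 0:
            continue
        out[(i, i + 4)] = float(
            np.linalg.norm(traj.coords[frame, ko] - traj.coords[frame, kh])
        )
    return out


def _kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of x onto y."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(u @ vt))
    s[-1] *= d
    e0 = (xc**2).sum() + (yc**2).sum()
    msd = max((e0 - 2.0 * s.sum()) / len(x), 0.0)
    return math.sqrt(msd)


def make_bent_helix(
    spec: PeptideSpec,
    break_positions: list[tuple[int, int]],
    phi_deg: float = IDEAL_PHI,
    psi_deg: float = IDEAL_PSI,
) -> Trajectory:
    """Helix with chosen i→i+4 hydrogen bonds broken by local φ/ψ changes.

    The perturbation is found by a deterministic bounded least-squares search
    over the φ/ψ dihedrals near each break, seeded with a counter-rotated
    ("crankshaft") move ψᵢ → ψᵢ+40°, φᵢ₊₁ → φᵢ₊₁−40°.  Two stages are tried:

    1. *strict* — only the crankshaft dihedrals (ψᵢ, φᵢ₊₁) move and every
       non-target O···H distance is pinned to its ideal-helix value.  This
       succeeds for breaks near the chain termini and leaves all other
       hydrogen bonds untouched.
    2. *relaxed* — dihedrals of residues i−1 … i+5 may move; non-target
       distances only have to stay below the 0.35 nm cutoff.

    The accepted structure must break exactly the requested pairs and stay
    within 0.05 nm RMSD of the ideal helix outside the break spans;
    otherwise a generation-failure error is raised.
    """
    n = spec.n_residues
    for (i, j) in break_positions:
        if not (1 <= i < j <= n) or j != i + 4:
            raise InvalidInputError(f"break pair {(i, j)} must be (i, i+4) within 1..{n}")

    phi0 = np.full(n, phi_deg)
    psi0 = np.full(n, psi_deg)
    if not break_positions:
        return _build_backbone(spec, phi0, psi0)

    ideal = _build_backbone(spec, phi0, psi0)
    ideal_d = hbond_distances(ideal)
    targets = {(i, j) for (i, j) in break_positions}
    pairs = sorted(ideal_d.keys())

    mask = np.ones(ideal.n_atoms, dtype=bool)
    for (bi, bj) in break_positions:
        mask &= ~((ideal.res_ids >= bi) & (ideal.res_ids <= bj))

    def run_stage(resis: list[int], strict: bool) -> Trajectory:
        idx = {r: k for k, r in enumerate(resis)}

        def build(x: np.ndarray) -> Trajectory:
            p = phi0.copy()
            q = psi0.copy()
            for k, r in enumerate(resis):
                p[r - 1] += x[2 * k]
                q[r - 1] += x[2 * k + 1]
            return _build_backbone(spec, p, q)

        def resid(x: np.ndarray) -> np.ndarray:
            t = build(x)
            d = hbond_distances(t)
            out = []
            for pair in pairs:
                val = d[pair]
                if pair in targets:
                    out.append(60.0 * max(0.0, 0.44 - val))
                elif strict:
                    out.append(100.0 * max(0.0, abs(val - ideal_d[pair]) - 0.006))
                else:
                    out.append(40.0 * max(0.0, val - 0.315))
            r = _kabsch_rmsd(t.coords[0][mask], ideal.coords[0][mask])
            out.append(100.0 * max(0.0, r - 0.03))
            out.extend(0.003 * x)
            return np.asarray(out)

        x0 = np.zeros(2 * len(resis))
        for (bi, _) in break_positions:
            x0[2 * idx[bi] + 1] += 40.0  # ψ_i
            if bi + 1 in idx:
                x0[2 * idx[bi + 1]] -= 40.0  # φ_{i+1}
        sol = least_squares(resid, x0, diff_step=1.0, xtol=1e-10, ftol=1e-12,
                            gtol=1e-12, max_nfev=4000)
        return build(sol.x)

    def valid(traj: Trajectory) -> bool:
        d = hbond_distances(traj)
        for pair, val in d.items():
            want_broken = pair in targets
            if want_broken != (val > HBOND_CUTOFF_NM):
                return False
        return _kabsch_rmsd(traj.coords[0][mask], ideal.coords[0][mask]) < 0.05

    strict_resis = sorted({r for (bi, _) in break_positions
                           for r in (bi, min(bi + 1, n))})
    traj = run_stage(strict_resis, strict=True)
    if valid(traj):
        return traj

    lo = max(1, min(b[0] for b in break_positions) - 1)
    hi = min(n, max(b[1] for b in break_positions) + 1)
    traj = run_stage(list(range(lo, hi + 1)), strict=False)
    if valid(traj):
        return traj
    raise GenerationFailureError(
        f"break set {break_positions} unreachable within the bounded search"
    )


# ---------------------------------------------------------------------------
# Noisy trajectories with two-state hydrogen-bond switching
# ---------------------------------------------------------------------------


def make_trajectory(
    base: Trajectory,
    n_frames: int,
    noise_nm: float = 0.0,
    switch_prob: float = 0.0,
    seed: int = 0,
    switch_pairs: list[tuple[int, int]] | None = None,
) -> Trajectory:
    """Frames of ``base`` plus isotropic Gaussian noise and H-bond switching.

    Each pair in ``switch_pairs`` toggles between a formed state (the base
    geometry) and a broken state (a locally bent variant) as a symmetric
    two-state Markov chain with per-frame switch probability ``switch_prob``
    (stationary broken fraction 1/2).  This emulates α-helical hydrogen bonds
    that break and re-form on a picosecond timescale; it is statistics, not
    mechanics.  Fully reproducible from ``seed``.
    """
    if n_frames < 1:
        raise InvalidInputError("n_frames must be ≥ 1")
    if noise_nm < 0:
        raise InvalidInputError("noise_nm must be ≥ 0")
    if not (0.0 <= switch_prob <= 1.0):
        raise InvalidInputError("switch_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = base.coords[0]
    coords = np.repeat(ref[None], n_frames, axis=0)

    if switch_pairs and switch_prob > 0:
        if base.spec is None:
            raise InvalidInputError("H-bond switching requires base.spec")
        for pair in switch_pairs:
            bent = make_bent_helix(base.spec, [pair])
            lo, hi = pair[0] - 2, pair[1] + 2
            window = (base.res_ids >= lo) & (base.res_ids <= hi)
            # Markov chain: state 0 = formed, 1 = broken, start formed
            states = np.empty(n_frames, dtype=int)
            states[0] = 0
            flips = rng.random(n_frames) < switch_prob
            for t in range(1, n_frames):
                states[t] = states[t - 1] ^ int(flips[t])
            broken = states.astype(bool)
            coords[np.ix_(broken, window)] = bent.coords[0][window]

    if noise_nm > 0:
        coords = coords + rng.normal(0.0, noise_nm, size=coords.shape)

    return Trajectory(
        coords=coords,
        atom_names=list(base.atom_names),
        res_ids=base.res_ids.copy(),
        res_names=list(base.res_names),
        timestep_ps=base.timestep_ps,
        spec=base.spec,
    )


def markov_broken_fraction_stationary(switch_prob: float) -> float:
    """Stationary broken-state fraction of the symmetric two-state chain."""
    return 0.5 if switch_prob > 0 else 0.0


# ---------------------------------------------------------------------------
# Synthetic 2D-IR surfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticPeak2D:
    """A tilted 2D Gaussian peak pair: positive fundamental plus an
    equal-magnitude negative lobe displaced by ``anharmonicity`` along ω_m."""

    center_tau: float
    center_m: float
    width_tau: float
    width_m: float
    amplitude: float
    tilt_deg: float = 0.0
    anharmonicity: float = 0.0

    def __post_init__(self) -> None:
        if self.width_tau <= 0 or self.width_m <= 0:
            raise InvalidInputError("peak widths must be positive")
        if self.anharmonicity < 0:
            raise InvalidInputError("anharmonicity must be ≥ 0")


def tilted_gaussian(
    wt: np.ndarray, wm: np.ndarray,
    amplitude: float, c_tau: float, c_m: float,
    s_tau: float, s_m: float, tilt_deg: float,
) -> np.ndarray:
    """Rotated 2D Gaussian evaluated on the outer grid of ``wt`` × ``wm``.

    The principal σ_τ axis is rotated ``tilt_deg`` from the ω_τ axis.
    """
    th = math.radians(tilt_deg)
    dx = wt[:, None] - c_tau
    dy = wm[None, :] - c_m
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return amplitude * np.exp(-0.5 * (u / s_tau) ** 2 - 0.5 * (v / s_m) ** 2)


def make_synthetic_2dir(
    peaks: list[SyntheticPeak2D],
    omega_tau: np.ndarray,
    omega_m: np.ndarray,
    t_wait_ps: float = 0.0,
) -> tuple[Spectrum2D, list[dict[str, float]]]:
    """Sum of tilted Gaussian peak pairs plus the exact analytic volumes.

    Returns the surface and, per input peak, the closed-form volumes
    2π·A·σ_τ·σ_m of its positive and negative components.
    """
    omega_tau = np.asarray(omega_tau, dtype=float)
    omega_m = np.asarray(omega_m, dtype=float)
    for ax in (omega_tau, omega_m):
        if ax.size > 1 and not np.all(np.diff(ax) > 0):
            raise InvalidInputError("grid axes must be strictly increasing")
    grid = np.zeros((omega_tau.size, omega_m.size))
    volumes: list[dict[str, float]] = []
    for p in peaks:
        grid += tilted_gaussian(omega_tau, omega_m, p.amplitude,
                                p.center_tau, p.center_m,
                                p.width_tau, p.width_m, p.tilt_deg)
        v = 2.0 * math.pi * p.amplitude * p.width_tau * p.width_m
        if p.anharmonicity > 0:
            grid += tilted_gaussian(omega_tau, omega_m, -p.amplitude,
                                    p.center_tau, p.center_m - p.anharmonicity,
                                    p.width_tau, p.width_m, p.tilt_deg)
            volumes.append({"positive": v, "negative": -v})
        else:
            volumes.append({"positive": v, "negative": 0.0})
    return Spectrum2D(omega_tau, omega_m, grid, t_wait_ps=t_wait_ps), volumes


# ---------------------------------------------------------------------------
# Bi-exponential decays
# ---------------------------------------------------------------------------


def make_biexp_decay(
    a1: float, b1: float, a2: float, b2: float,
    t_grid: np.ndarray, noise_sd: float = 0.0, seed: int = 0,
) -> np.ndarray:
    """P(t) = A₁·exp(−B₁t) + A₂·exp(−B₂t) (+ Gaussian noise), as (t, P) table."""
    if b1 <= 0 or b2 <= 0:
        raise InvalidInputError("decay rates must be positive")
    t = np.asarray(t_grid, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("t_grid must be strictly increasing")
    p = a1 * np.exp(-b1 * t) + a2 * np.exp(-b2 * t)
    if noise_sd > 0:
        p = p + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return np.column_stack([t, p])


# ---------------------------------------------------------------------------
# CD melting curves
# ---------------------------------------------------------------------------


def make_cd_curve(fh_by_t: np.ndarray, nr: int) -> np.ndarray:
    """θ222(T) table whose round trip through the Baldwin relation is exact.

    ``fh_by_t`` is a (T °C, f_H) table with 0 ≤ f_H ≤ 1; returns (T, θ222)
    with θ222 = θ_C + f_H·(θ_H − θ_C).
    """
    from .observables import theta_coil, theta_helix

    tab = np.asarray(fh_by_t, dtype=float)
    if tab.ndim != 2 or tab.shape[1] != 2:
        raise InvalidInputError("fh_by_t must be an (n, 2) table of (T, fH)")
    t, fh = tab[:, 0], tab[:, 1]
    if np.any((fh < 0) | (fh > 1)):
        raise InvalidInputError("fH values must lie in [0, 1]")
    th_c = theta_coil(t)
    th_h = theta_helix(t, nr)
    theta = th_c + fh * (th_h - th_c)
    return np.column_stack([t, theta])


# ---------------------------------------------------------------------------
# Analytic 2D double wells
# ---------------------------------------------------------------------------


class DoubleWell2D:
    """Smooth 2D potential with two Gaussian wells of calibrated depths.

    ``V(x) = k·|x − centre|² − D₁·g₁(x) − D₂·g₂(x)`` where gᵢ are unit
    Gaussians at the requested minima.  Depths are solved numerically so the
    two grid minima differ by exactly ``delta_g`` and the saddle along the
    minimum-energy path sits ``barrier`` above the global minimum.
    """

    def __init__(self, d1: float, d2: float, sigma: float,
                 p1: np.ndarray, p2: np.ndarray, k_conf: float) -> None:
        self.d1, self.d2, self.sigma = d1, d2, sigma
        self.p1, self.p2 = np.asarray(p1, float), np.asarray(p2, float)
        self.k_conf = k_conf
        self.centre = 0.5 * (self.p1 + self.p2)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        r1 = (x - self.p1[0]) ** 2 + (y - self.p1[1]) ** 2
        r2 = (x - self.p2[0]) ** 2 + (y - self.p2[1]) ** 2
        rc = (x - self.centre[0]) ** 2 + (y - self.centre[1]) ** 2
        s2 = 2.0 * self.sigma**2
        return (self.k_conf * rc
                - self.d1 * np.exp(-r1 / s2)
                - self.d2 * np.exp(-r2 / s2))

    def gradient(self, x: float, y: float) -> np.ndarray:
        s2 = 2.0 * self.sigma**2
        g = np.zeros(2)
        pt = np.array([x, y], float)
        g += 2.0 * self.k_conf * (pt - self.centre)
        for d, p in ((self.d1, self.p1), (self.d2, self.p2)):
            dr = pt - p
            g += d * np.exp(-(dr @ dr) / s2) * (2.0 * dr / s2)
        return g


def _grid_minima_and_saddle(
    pot: DoubleWell2D, p1: np.ndarray, p2: np.ndarray, n: int = 401
) -> tuple[float, float, float]:
    """(V_min1, V_min2, V_saddle) along the straight path on a fine grid."""
    lo = np.minimum(p1, p2) - 4 * pot.sigma
    hi = np.maximum(p1, p2) + 4 * pot.sigma
    gx = np.linspace(lo[0], hi[0], n)
    gy = np.linspace(lo[1], hi[1], n)
    v = pot(gx[:, None], gy[None, :])
    # values near each requested minimum
    def local_min(p: np.ndarray) -> float:
        i = np.argmin(np.abs(gx - p[0]))
        j = np.argmin(np.abs(gy - p[1]))
        w = max(3, n // 20)
        sl = v[max(0, i - w):i + w + 1, max(0, j - w):j + w + 1]
        return float(sl.min())

    # saddle: max of V along the straight line joining the two minima
    lam = np.linspace(0.2, 0.8, 201)
    pts = p1[None] + lam[:, None] * (p2 - p1)[None]
    line = pot(pts[:, 0], pts[:, 1])
    return local_min(p1), local_min(p2), float(np.asarray(line).max())


def make_double_well(
    delta_g_kjmol: float,
    barrier_kjmol: float,
    minima_positions: tuple[tuple[float, float], tuple[float, float]],
) -> DoubleWell2D:
    """Analytic 2D potential with requested minima offset and saddle height.

    ``delta_g_kjmol`` is the depth difference (second minimum above the
    global one, ≥ 0); ``barrier_kjmol`` is the saddle height above the global
    minimum along the path joining them.  Raises when the landscape is
    geometrically malformed (barrier below the upper minimum).
    """
    if delta_g_kjmol < 0:
        raise InvalidInputError("delta_g must be ≥ 0 (second minimum above global)")
    if barrier_kjmol < abs(delta_g_kjmol) / 2:
        raise InvalidInputError("barrier must be ≥ |ΔG|/2 for a well-formed landscape")
    if barrier_kjmol <= delta_g_kjmol:
        raise InvalidInputError(
            "barrier must exceed ΔG, otherwise the upper minimum is not separated"
        )
    p1 = np.asarray(minima_positions[0], float)
    p2 = np.asarray(minima_positions[1], float)
    dist = float(np.linalg.norm(p2 - p1))
    if dist <= 0:
        raise InvalidInputError("minima positions must be distinct")
    sigma = dist / 3.0  # basins broad enough for 0.05 nm metadynamics hills
    k_conf = barrier_kjmol / dist**2  # gentle confinement

    def residuals(params: np.ndarray) -> np.ndarray:
        d1, d2 = params
        pot = DoubleWell2D(d1, d2, sigma, p1, p2, k_conf)
        v1, v2, vs = _grid_minima_and_saddle(pot, p1, p2, n=201)
        return np.array([(v2 - v1) - delta_g_kjmol,
                         (vs - v1) - barrier_kjmol])

    x0 = np.array([barrier_kjmol + delta_g_kjmol + 1.0, barrier_kjmol + 1.0])
    sol = least_squares(residuals, x0, bounds=([0.01, 0.01], [np.inf, np.inf]))
    pot = DoubleWell2D(sol.x[0], sol.x[1], sigma, p1, p2, k_conf)
    v1, v2, vs = _grid_minima_and_saddle(pot, p1, p2, n=801)
    if abs((v2 - v1) - delta_g_kjmol) > 0.01 or abs((vs - v1) - barrier_kjmol) > 0.05:
        raise GenerationFailureError(
            f"double-well calibration failed: ΔG={(v2 - v1):.3f} "
            f"(target {delta_g_kjmol}), barrier={(vs - v1):.3f} "
            f"(target {barrier_kjmol})"
        )
    return pot
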