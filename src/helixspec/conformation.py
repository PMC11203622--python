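"""Trajectory-level conformational analysis.

Covers the four analyses used to characterize the bent↔straight equilibrium
of an α-helix: i→i+4 backbone hydrogen-bond distance series with a 0.35 nm
formed/broken cutoff, principal component analysis of atomic coordinates
with pseudo-trajectories along single components, a desk-scale
well-tempered metadynamics sampler on analytic 2D potentials, and
free-energy-surface analysis (minima, pairwise ΔG with kT conversion, and
lowest-saddle barrier estimates).

The hydrogen-bond collective variables are O(i)···H(i+4) distances (the
carbonyl O of residue i to the amide H of residue i+4); a configuration
switch measures O···N instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    InvalidInputError,
    R_KJ_PER_MOL_K,
    Trajectory,
    logger,
)
from .synthetic_data import HBOND_CUTOFF_NM


# ---------------------------------------------------------------------------
# Hydrogen-bond distance series
# ---------------------------------------------------------------------------


@dataclass
class HBondSeries:
    """Per-pair O(i)···H(i+4) distance time series and classification.

    ``distances[pair]`` is the per-frame distance in nm; ``broken[pair]``
    the corresponding boolean series (distance > cutoff).  Pairs whose amide
    H is absent (e.g. proline at i+4) appear in ``missing``.
    """

    distances: dict[tuple[int, int], np.ndarray]
    broken: dict[tuple[int, int], np.ndarray]
    cutoff_nm: float
    missing: list[tuple[int, int]] = field(default_factory=list)

    def broken_fraction(self, pair: tuple[int, int]) -> float:
        return float(np.mean(self.broken[pair]))


def hbond_series(
    traj: Trajectory,
    pairs: list[tuple[int, int]] | None = None,
    cutoff_nm: float = HBOND_CUTOFF_NM,
    acceptor_atom: str = "O",
    donor_atom: str = "H",
) -> HBondSeries:
    """Distance series for i→i+4 pairs; broken iff distance > cutoff.

    With ``pairs=None`` every available (i, i+4) pair is measured.  Set
    ``donor_atom='N'`` to use the O···N convention instead of O···H.
    """
    n_res = int(traj.res_ids.max())
    if pairs is None:
        pairs = [(i, i + 4) for i in range(1, n_res - 3)]
    distances: dict[tuple[int, int], np.ndarray] = {}
    broken: dict[tuple[int, int], np.ndarray] = {}
    missing: list[tuple[int, int]] = []
    for (i, j) in pairs:
        if not (1 <= i < j <= n_res):
            raise InvalidInputError(f"pair {(i, j)} outside residues 1..{n_res}")
        ka = traj.atom_index(i, acceptor_atom)
        kd = traj.atom_index(j, donor_atom)
        if ka < 0 or kd < 0:
            missing.append((i, j))
            continue
        d = np.linalg.norm(traj.coords[:, ka] - traj.coords[:, kd], axis=1)
        distances[(i, j)] = d
        broken[(i, j)] = d > cutoff_nm
    return HBondSeries(distances, broken, cutoff_nm, missing)


# ---------------------------------------------------------------------------
# Principal component analysis with pseudo-trajectories
# ---------------------------------------------------------------------------


def _kabsch_fit(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rigid superposition of ``mobile`` onto ``ref`` (both (n, 3))."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    u, _, vt = np.linalg.svd(mc.T @ rc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u * [1.0, 1.0, d]) @ vt
    return mc @ rot + ref.mean(axis=0)


@dataclass
class PCAResult:
    """Eigendecomposition of the aligned coordinate covariance."""

    eigenvalues: np.ndarray          # descending, nm²
    eigenvectors: np.ndarray         # (3K, n_modes), columns orthonormal
    projections: np.ndarray          # (n_frames, n_modes), nm
    mean_structure: np.ndarray       # (K, 3), nm
    atom_selection: np.ndarray       # indices into the trajectory atoms
    degenerate: bool = False


def pca(
    traj: Trajectory,
    atom_selection: str = "heavy",
    align: bool = True,
) -> PCAResult:
    """Two-pass-aligned covariance PCA of atomic coordinates.

    Frames are rigid-fit to the first frame, averaged, then refit to the
    average structure before the covariance of coordinates is diagonalized.
    ``atom_selection`` is ``"heavy"`` (non-hydrogen), ``"ca"``, or ``"all"``.
    """
    if traj.n_frames < 3:
        raise InvalidInputError("PCA needs ≥ 3 frames")
    names = np.asarray(traj.atom_names)
    if atom_selection == "heavy":
        sel = np.where(~np.char.startswith(names, "H"))[0]
    elif atom_selection == "ca":
        sel = np.where(names == "CA")[0]
    elif atom_selection == "all":
        sel = np.arange(traj.n_atoms)
    else:
        raise InvalidInputError(f"unknown atom selection {atom_selection!r}")

    x = traj.coords[:, sel, :].copy()
    if align:
        ref = x[0]
        fitted = np.stack([_kabsch_fit(f, ref) for f in x])
        mean1 = fitted.mean(axis=0)
        fitted = np.stack([_kabsch_fit(f, mean1) for f in x])
    else:
        fitted = x
    mean = fitted.mean(axis=0)
    flat = (fitted - mean).reshape(traj.n_frames, -1)
    cov = flat.T @ flat / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = flat @ evecs
    degenerate = bool(evals[0] < 1e-14)
    if degenerate:
        logger.warning("PCA on (near-)identical frames: zero eigenvalues")
    return PCAResult(evals, evecs, projections, mean, sel, degenerate)


def pseudo_trajectory(
    p: PCAResult, component: int = 1, n_frames: int = 20
) -> np.ndarray:
    """Frames sweeping the mean structure along one principal component.

    Returns an (n_frames, K, 3) array: mean + λ·eigenvector with λ linearly
    spaced between the minimum and maximum projection onto the component
    (1-based index).
    """
    if not (1 <= component <= p.eigenvectors.shape[1]):
        raise InvalidInputError(f"component {component} outside rank")
    if n_frames < 2:
        raise InvalidInputError("n_frames must be ≥ 2")
    vec = p.eigenvectors[:, component - 1]
    proj = p.projections[:, component - 1]
    lam = np.linspace(proj.min(), proj.max(), n_frames)
    k = p.mean_structure.shape[0]
    return p.mean_structure[None] + lam[:, None, None] * vec.reshape(1, k, 3)


# ---------------------------------------------------------------------------
# Toy well-tempered metadynamics (overdamped Langevin on analytic potentials)
# ---------------------------------------------------------------------------


@dataclass
class FESGrid:
    """Free energy (kJ/mol) on a (d1, d2) grid in nm."""

    d1: np.ndarray
    d2: np.ndarray
    free_energy: np.ndarray
    temperature_k: float = 298.15
    offset_note: str = "reported relative to the global minimum"

    def __post_init__(self) -> None:
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.free_energy.shape != (self.d1.size, self.d2.size):
            raise InvalidInputError("free-energy grid does not match axes")


def wtmetad(
    potential,
    domain: tuple[tuple[float, float], tuple[float, float]],
    steps: int,
    seed: int,
    height_kjmol: float = 1.2,
    pace: int = 500,
    width_nm: float = 0.05,
    biasfactor: float = 6.0,
    dt: float = 1e-4,
    temperature_k: float = 298.15,
    friction: float = 1.0,
    n_grid: int = 101,
    x0: tuple[float, float] | None = None,
) -> FESGrid:
    """Well-tempered metadynamics on an analytic 2D potential.

    An overdamped Langevin walker explores ``potential`` (callable of two
    scalars/arrays, kJ/mol, with a ``gradient`` method) inside ``domain``
    with reflective boundaries.  Every ``pace`` steps a Gaussian hill of
    initial ``height_kjmol`` — scaled down by exp(−V_bias/((γ−1)kT)) — is
    deposited on a bias grid.  The free-energy estimate is
    −(γ/(γ−1))·⟨V_bias⟩, where ⟨·⟩ averages the bias profile over the second
    half of the hill depositions (the ripple of the instantaneous bias
    averages out while its converged shape does not), shifted so the
    minimum is zero.
    """
    if steps < 0:
        raise InvalidInputError("steps must be ≥ 0")
    if biasfactor <= 1.0:
        raise InvalidInputError("biasfactor γ must exceed 1")
    (x_lo, x_hi), (y_lo, y_hi) = domain
    rng = np.random.default_rng(seed)
    kt = R_KJ_PER_MOL_K * temperature_k
    gx = np.linspace(x_lo, x_hi, n_grid)
    gy = np.linspace(y_lo, y_hi, n_grid)
    if steps < pace:
        logger.warning("run of %d steps deposits no hills: flat bias", steps)
        return FESGrid(gx, gy, np.zeros((n_grid, n_grid)), temperature_k,
                       offset_note="empty bias (run shorter than one pace)")
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]
    v_bias = np.zeros((n_grid, n_grid))

    pos = np.array([0.5 * (x_lo + x_hi), 0.5 * (y_lo + y_hi)]
                   if x0 is None else x0, dtype=float)
    noise_sd = math.sqrt(2.0 * kt * dt / friction)
    kicks = rng.normal(0.0, noise_sd, size=(steps, 2))
    n_escapes = 0

    def bias_and_grad(p: np.ndarray) -> tuple[float, np.ndarray]:
        i = min(max(int((p[0] - x_lo) / dx), 0), n_grid - 2)
        j = min(max(int((p[1] - y_lo) / dy), 0), n_grid - 2)
        fx = (p[0] - gx[i]) / dx
        fy = (p[1] - gy[j]) / dy
        v00, v10 = v_bias[i, j], v_bias[i + 1, j]
        v01, v11 = v_bias[i, j + 1], v_bias[i + 1, j + 1]
        v = (v00 * (1 - fx) * (1 - fy) + v10 * fx * (1 - fy)
             + v01 * (1 - fx) * fy + v11 * fx * fy)
        gxv = ((v10 - v00) * (1 - fy) + (v11 - v01) * fy) / dx
        gyv = ((v01 - v00) * (1 - fx) + (v11 - v10) * fx) / dy
        return v, np.array([gxv, gyv])

    mesh_x = gx[:, None]
    mesh_y = gy[None, :]
    n_hills_total = steps // pace
    v_acc = np.zeros_like(v_bias)
    n_acc = 0
    for s in range(steps):
        vb, gb = bias_and_grad(pos)
        grad = potential.gradient(pos[0], pos[1]) + gb
        pos = pos - grad * dt / friction + kicks[s]
        # reflective boundaries
        for d, (lo, hi) in enumerate(((x_lo, x_hi), (y_lo, y_hi))):
            if pos[d] < lo:
                pos[d] = lo + (lo - pos[d])
                n_escapes += 1
            elif pos[d] > hi:
                pos[d] = hi - (pos[d] - hi)
                n_escapes += 1
            pos[d] = min(max(pos[d], lo), hi)
        if (s + 1) % pace == 0:
            vb, _ = bias_and_grad(pos)
            h = height_kjmol * math.exp(-vb / ((biasfactor - 1.0) * kt))
            # mirror images across the walls compensate the hill mass lost
            # outside the reflective domain
            for cx in (pos[0], 2 * x_lo - pos[0], 2 * x_hi - pos[0]):
                for cy in (pos[1], 2 * y_lo - pos[1], 2 * y_hi - pos[1]):
                    v_bias += h * np.exp(
                        -((mesh_x - cx) ** 2 + (mesh_y - cy) ** 2)
                        / (2.0 * width_nm**2)
                    )
            if (s + 1) // pace > n_hills_total // 2:
                v_acc += v_bias
                n_acc += 1
    if n_escapes:
        logger.info("metadynamics walker reflected %d times", n_escapes)

    gamma = biasfactor
    fes = -(gamma / (gamma - 1.0)) * (v_acc / max(n_acc, 1))
    fes -= fes.min()
    return FESGrid(gx, gy, fes, temperature_k)


# ---------------------------------------------------------------------------
# Free-energy-surface analysis
# ---------------------------------------------------------------------------


@dataclass
class FESAnalysis:
    """Local minima, pairwise ΔG (kJ/mol and kT), and saddle barriers."""

    minima: list[dict]
    delta_g: list[dict]
    temperature_k: float
    kt_kjmol: float


def _local_minima(f: np.ndarray) -> list[tuple[int, int]]:
    """8-neighbour strict local minima of a 2D array."""
    n, m = f.shape
    out = []
    for i in range(n):
        for j in range(m):
            v = f[i, j]
            nb = f[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            if v <= nb.min() and np.count_nonzero(nb == v) == 1:
                out.append((i, j))
    return out


def _saddle_between(f: np.ndarray, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Lowest crossing level connecting two grid cells (max-over-min path).

    Cells are admitted in order of increasing energy; the first level at
    which the two minima join in the same 8-connected component is the
    saddle energy.
    """
    n, m = f.shape
    order = np.argsort(f.ravel())
    parent = np.full(n * m, -1, dtype=int)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ia = a[0] * m + a[1]
    ib = b[0] * m + b[1]
    for flat in order:
        i, j = divmod(int(flat), m)
        parent[flat] = flat
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < n and 0 <= jj < m:
                    nb = ii * m + jj
                    if parent[nb] >= 0:
                        parent[find(nb)] = find(flat)
        if parent[ia] >= 0 and parent[ib] >= 0 and find(ia) == find(ib):
            return float(f[i, j])
    return float(f.max())


def fes_analyze(fes: FESGrid, temperature_k: float | None = None) -> FESAnalysis:
    """Locate minima, convert pairwise ΔG to kT, estimate saddle barriers.

    kT is R·T in kJ/mol (≈ 2.479 kJ/mol at 298.15 K, the default), so e.g.
    4.67 kJ/mol ≈ 1.9 kT and 3.36 kJ/mol ≈ 1.4 kT.
    """
    t_k = temperature_k if temperature_k is not None else fes.temperature_k
    kt = R_KJ_PER_MOL_K * t_k
    f = fes.free_energy
    if not np.isfinite(f).all():
        raise InvalidInputError("free-energy grid contains non-finite values")
    cells = _local_minima(f)
    minima = [
        {"d1": float(fes.d1[i]), "d2": float(fes.d2[j]),
         "free_energy": float(f[i, j]), "cell": (i, j)}
        for (i, j) in sorted(cells, key=lambda c: f[c])
    ]
    pairs = []
    for x in range(len(minima)):
        for y in range(x + 1, len(minima)):
            a, b = minima[x], minima[y]
            dg = b["free_energy"] - a["free_energy"]
            saddle = _saddle_between(f, a["cell"], b["cell"])
            barrier = saddle - a["free_energy"]
            pairs.append({
                "from": x, "to": y,
                "delta_g_kjmol": dg, "delta_g_kt": dg / kt,
                "barrier_kjmol": barrier, "barrier_kt": barrier / kt,
            })
    return FESAnalysis(minima, pairs, t_k, kt)


def kj_per_mol_to_kt(value_kjmol: float, temperature_k: float = 298.15) -> float:
    """Exact kT conversion: value / (R·T)."""
    return value_kjmol / (R_KJ_PER_MOL_K * temperature_k)
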