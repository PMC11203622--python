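"""Per-frame amide I exciton Hamiltonian construction.

Each backbone carbonyl is an amide I chromophore (local oscillator).  The
site-basis Hamiltonian holds local-mode frequencies on the diagonal and
inter-site vibrational couplings off-diagonal; diagonalizing it gives the
delocalized vibrational eigenmodes analysed downstream.

The default site map is deliberately simple and fully self-contained: a
fixed base frequency plus a linear electrostatic term proportional to the
potential difference between the carbonyl C and O atoms, evaluated from a
documented set of fixed backbone partial charges.  Couplings use
transition-dipole coupling (TDC) for non-adjacent pairs and a constant
nearest-neighbour value.  The :class:`SiteMap` interface accepts externally
supplied parameters so that published electrostatic maps can be plugged in.

Default map parameters
----------------------
==============================  ==========================================
base frequency                  1650 cm⁻¹
potential coefficient           15 cm⁻¹ per (e/nm) of φ(C) − φ(O)
source charges (e)              C +0.42, O −0.42, N −0.30, H +0.30,
                                OXT −0.42 (others 0); the chromophore's own
                                residue and its two sequence neighbours are
                                excluded as sources
dipole magnitude                0.37 D
dipole direction                20° from the C=O axis, rotated toward N
                                within the O–C–N plane
dipole origin                   C=O midpoint displaced 0.01 nm toward N
nearest-neighbour coupling      −7 cm⁻¹ (constant, helical default)
TDC prefactor                   5034.12 cm⁻¹·Å³·D⁻² (vacuum)
==============================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    GeometryError,
    HamiltonianSeries,
    InvalidInputError,
    PeptideSpec,
    StructuralError,
    TDC_K_CM_A3_D2,
    Trajectory,
)

#: fixed partial charges (e) used as electrostatic sources by the default map
DEFAULT_CHARGES: dict[str, float] = {
    "C": 0.42, "O": -0.42, "N": -0.30, "H": 0.30, "OXT": -0.42,
}


@dataclass(frozen=True)
class Chromophore:
    """One carbonyl unit: its C and O atoms plus, where present, the N and H
    of the following peptide unit."""

    index: int           # 0-based position, N→C terminal
    unit_res_id: int     # residue carrying the C=O (0 = acetyl cap)
    next_res_id: int | None  # residue supplying N (and H), None at C-terminus


@dataclass(frozen=True)
class ChromophoreSet:
    """Ordered amide I chromophores of a peptide."""

    chromophores: tuple[Chromophore, ...]

    @property
    def n(self) -> int:
        return len(self.chromophores)


def enumerate_oscillators(spec: PeptideSpec) -> ChromophoreSet:
    """One oscillator per backbone carbonyl, N→C ordered.

    Every residue contributes its own carbonyl (the C-terminal residue's
    carbonyl belongs to the terminal acid or amide group), and an acetyl cap
    contributes one more.  The 35-residue acetyl-capped relay helix peptide
    thus has 36 oscillators.
    """
    chromos: list[Chromophore] = []
    k = 0
    if spec.n_terminal_cap == "acetyl":
        chromos.append(Chromophore(k, 0, 1))
        k += 1
    n = spec.n_residues
    for i in range(1, n + 1):
        nxt = i + 1 if i < n else None
        chromos.append(Chromophore(k, i, nxt))
        k += 1
    return ChromophoreSet(tuple(chromos))


@dataclass(frozen=True)
class SiteMap:
    """Pluggable local-frequency / dipole / coupling map.

    ``potential_coefficient`` is the linear response of the site frequency to
    the electrostatic potential difference φ(C) − φ(O) in cm⁻¹ per (e/nm);
    setting it to zero puts every site exactly at ``base_frequency``.
    """

    base_frequency: float = 1650.0
    potential_coefficient: float = 15.0
    charges: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CHARGES))
    dipole_magnitude_debye: float = 0.37
    dipole_angle_deg: float = 20.0
    dipole_offset_nm: float = 0.010
    nn_coupling_cm: float = -7.0
    point_sources: tuple[tuple[float, float, float, float], ...] = ()
    """Extra (q_e, x, y, z) point charges in nm, e.g. solvent stand-ins."""


def _atom_lookup(traj: Trajectory) -> dict[tuple[int, str], int]:
    return {(int(r), n): k
            for k, (r, n) in enumerate(zip(traj.res_ids, traj.atom_names))}


def _chromophore_atoms(
    lookup: dict[tuple[int, str], int], ch: Chromophore
) -> tuple[int, int, int]:
    """(C, O, partner) atom indices; partner is next-N or the terminal O/N."""
    c = lookup.get((ch.unit_res_id, "C"))
    o = lookup.get((ch.unit_res_id, "O"))
    if c is None or o is None:
        raise StructuralError(
            f"chromophore {ch.index} (residue {ch.unit_res_id}) missing C/O atoms"
        )
    if ch.next_res_id is not None:
        p = lookup.get((ch.next_res_id, "N"))
        if p is None:
            raise StructuralError(
                f"chromophore {ch.index} missing N of residue {ch.next_res_id}"
            )
    else:
        p = lookup.get((ch.unit_res_id, "OXT"))
        if p is None:
            p = lookup.get((ch.unit_res_id, "NT"))
        if p is None:
            raise StructuralError(
                f"terminal chromophore {ch.index} missing OXT/NT atom"
            )
    return c, o, p


def transition_dipoles(
    frame: np.ndarray, traj: Trajectory, chromo: ChromophoreSet,
    site_map: SiteMap | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site transition dipole vectors (D) and their origins (nm)."""
    m = site_map or SiteMap()
    lookup = _atom_lookup(traj)
    n = chromo.n
    dip = np.empty((n, 3))
    org = np.empty((n, 3))
    ang = np.radians(m.dipole_angle_deg)
    for ch in chromo.chromophores:
        c, o, p = _chromophore_atoms(lookup, ch)
        rc, ro, rp = frame[c], frame[o], frame[p]
        e_co = ro - rc
        e_co /= np.linalg.norm(e_co)
        # in-plane unit vector perpendicular to C=O, pointing toward N
        v = rp - rc
        v_perp = v - (v @ e_co) * e_co
        nv = np.linalg.norm(v_perp)
        if nv < 1e-12:
            raise GeometryError(f"degenerate O–C–N plane at chromophore {ch.index}")
        v_perp /= nv
        dip[ch.index] = m.dipole_magnitude_debye * (
            np.cos(ang) * e_co + np.sin(ang) * v_perp
        )
        e_cn = (rp - rc) / np.linalg.norm(rp - rc)
        org[ch.index] = 0.5 * (rc + ro) + m.dipole_offset_nm * e_cn
    return dip, org


def site_frequencies(
    frame: np.ndarray, traj: Trajectory, chromo: ChromophoreSet,
    site_map: SiteMap | None = None,
) -> np.ndarray:
    """Local-mode frequencies: base + linear electrostatic shift (cm⁻¹)."""
    m = site_map or SiteMap()
    lookup = _atom_lookup(traj)
    freqs = np.full(chromo.n, m.base_frequency)
    if m.potential_coefficient == 0.0:
        return freqs

    charges = np.array([m.charges.get(name, 0.0) for name in traj.atom_names])
    res_ids = traj.res_ids
    for ch in chromo.chromophores:
        c, o, _ = _chromophore_atoms(lookup, ch)
        # exclude the chromophore's residue and its sequence neighbours
        excl = {ch.unit_res_id - 1, ch.unit_res_id, ch.unit_res_id + 1}
        if ch.next_res_id is not None:
            excl.add(ch.next_res_id)
        sel = (charges != 0.0) & ~np.isin(res_ids, list(excl))
        d_c = np.linalg.norm(frame[sel] - frame[c], axis=1)
        d_o = np.linalg.norm(frame[sel] - frame[o], axis=1)
        phi = float(np.sum(charges[sel] / d_c) - np.sum(charges[sel] / d_o))
        for (q, x, y, z) in m.point_sources:
            src = np.array([x, y, z])
            phi += q / np.linalg.norm(frame[c] - src)
            phi -= q / np.linalg.norm(frame[o] - src)
        freqs[ch.index] += m.potential_coefficient * phi
    return freqs


def couplings(
    frame: np.ndarray, traj: Trajectory, chromo: ChromophoreSet,
    site_map: SiteMap | None = None,
) -> np.ndarray:
    """Symmetric off-diagonal coupling matrix (cm⁻¹).

    Non-adjacent pairs: transition-dipole coupling
    J = k·[μ̂ₙ·μ̂ₘ − 3(μ̂ₙ·r̂)(μ̂ₘ·r̂)]·|μₙ||μₘ|/r³ with k the vacuum
    electrostatic constant 5034.12 cm⁻¹·Å³·D⁻².  Adjacent (nearest-neighbour)
    pairs: the constant map value.
    """
    m = site_map or SiteMap()
    dip, org = transition_dipoles(frame, traj, chromo, m)
    n = chromo.n
    j = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if b - a == 1:
                j[a, b] = j[b, a] = m.nn_coupling_cm
                continue
            rvec = org[b] - org[a]
            r_nm = np.linalg.norm(rvec)
            if r_nm < 0.05:
                raise GeometryError(
                    f"chromophores {a} and {b} coincident (r = {r_nm:.3f} nm)"
                )
            r_ang = r_nm * 10.0
            rhat = rvec / r_nm
            mu_a, mu_b = dip[a], dip[b]
            na, nb = np.linalg.norm(mu_a), np.linalg.norm(mu_b)
            ua, ub = mu_a / na, mu_b / nb
            orient = ua @ ub - 3.0 * (ua @ rhat) * (ub @ rhat)
            val = TDC_K_CM_A3_D2 * orient * na * nb / r_ang**3
            j[a, b] = j[b, a] = val
    return j


def build_frame(
    frame: np.ndarray, traj: Trajectory, chromo: ChromophoreSet,
    site_map: SiteMap | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(H, μ) for one frame: N×N Hamiltonian (cm⁻¹) and N×3 dipoles (D)."""
    h = couplings(frame, traj, chromo, site_map)
    np.fill_diagonal(h, site_frequencies(frame, traj, chromo, site_map))
    dip, _ = transition_dipoles(frame, traj, chromo, site_map)
    return h, dip


def build_series(
    traj: Trajectory,
    spec: PeptideSpec | None = None,
    site_map: SiteMap | None = None,
) -> HamiltonianSeries:
    """Hamiltonian + dipole set for every frame of a trajectory."""
    spec = spec or traj.spec
    if spec is None:
        raise InvalidInputError("a PeptideSpec is required (traj.spec is unset)")
    chromo = enumerate_oscillators(spec)
    n_frames = traj.n_frames
    mats = np.empty((n_frames, chromo.n, chromo.n))
    dips = np.empty((n_frames, chromo.n, 3))
    for f in range(n_frames):
        mats[f], dips[f] = build_frame(traj.coords[f], traj, chromo, site_map)
    return HamiltonianSeries(mats, dips, dt_ps=traj.timestep_ps)
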