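"""Shared domain types, physical constants, and package-wide configuration.

All coordinates are stored internally in nanometres; PDB I/O converts to and
from ångström at the boundary.  Frequencies are in cm⁻¹, times in ps, free
energies in kJ/mol, transition dipoles in debye.  Residue numbering in all
user-facing output is 1-based; an N-terminal acetyl cap carries residue id 0.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants as _const

logger = logging.getLogger("helixspec")

# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

#: speed of light in cm/ps — converts wavenumbers (cm⁻¹) to phase per ps
C_CM_PER_PS: float = _const.c * 100.0 * 1e-12

#: gas constant in kJ mol⁻¹ K⁻¹ — used for kT conversions of free energies
R_KJ_PER_MOL_K: float = _const.R / 1000.0

#: transition-dipole-coupling prefactor in cm⁻¹ Å³ D⁻²:
#: (1/4πε₀) · (1 D)² / (1 Å)³ expressed in wavenumbers.
DEBYE = 1e-21 / _const.c  # C·m per debye
TDC_K_CM_A3_D2: float = (
    1.0 / (4.0 * np.pi * _const.epsilon_0) * DEBYE**2 / (1e-10) ** 3
) / (_const.h * _const.c * 100.0)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: sequence of the myosin relay helix peptide (myosin II residues 465–499)
RELAY_HELIX_SEQUENCE = "SFEQLCINYTNEKLQQFFNHHMFKVEQEEYLKEKI"


class HelixspecError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HelixspecError, ValueError):
    """A precondition on user input was violated."""


class GenerationFailureError(HelixspecError, RuntimeError):
    """A bounded synthetic-structure search could not satisfy its constraints."""


class StructuralError(HelixspecError, ValueError):
    """A structure is missing atoms required by an operation."""


class GeometryError(HelixspecError, ValueError):
    """Physically impossible geometry (e.g. coincident chromophores)."""


class UndefinedRatioError(HelixspecError, ZeroDivisionError):
    """A requested ratio has a zero denominator."""


class InsufficientDataError(HelixspecError, ValueError):
    """A trajectory or table is too short for the requested computation."""


# ---------------------------------------------------------------------------
# Peptide specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideSpec:
    """One-letter sequence plus terminal chemistry of a linear peptide.

    Parameters
    ----------
    sequence:
        One-letter amino-acid string, length ≥ 2.
    n_terminal_cap:
        ``"acetyl"`` or ``"none"``.  An acetyl cap contributes one extra
        backbone carbonyl (and hence one extra amide I oscillator).
    c_terminal:
        ``"carboxylic_acid"`` or ``"amide"``.  Either way the C-terminal
        residue's own carbonyl is counted as an oscillator.
    """

    sequence: str
    n_terminal_cap: str = "acetyl"
    c_terminal: str = "carboxylic_acid"

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise InvalidInputError(
                f"sequence must have ≥ 2 residues, got {len(self.sequence)}"
            )
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise InvalidInputError(f"unknown residue codes: {sorted(bad)}")
        if self.n_terminal_cap not in ("acetyl", "none"):
            raise InvalidInputError(
                f"n_terminal_cap must be 'acetyl' or 'none', got {self.n_terminal_cap!r}"
            )
        if self.c_terminal not in ("carboxylic_acid", "amide"):
            raise InvalidInputError(
                "c_terminal must be 'carboxylic_acid' or 'amide', "
                f"got {self.c_terminal!r}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def relay_helix_spec() -> PeptideSpec:
    """The 35-residue acetyl-capped, acid-terminated relay helix peptide."""
    return PeptideSpec(RELAY_HELIX_SEQUENCE, "acetyl", "carboxylic_acid")


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Ordered frames of labelled backbone coordinates in nm.

    ``coords`` has shape (n_frames, n_atoms, 3).  ``res_ids`` is 1-based for
    residues; the acetyl cap, if present, has residue id 0.  Atom ordering is
    identical across frames by construction.
    """

    coords: np.ndarray
    atom_names: list[str]
    res_ids: np.ndarray
    res_names: list[str]
    timestep_ps: float = 0.02
    spec: PeptideSpec | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError(
                f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        n_atoms = self.coords.shape[1]
        if not (len(self.atom_names) == len(self.res_ids) == len(self.res_names) == n_atoms):
            raise InvalidInputError("atom metadata length mismatch with coords")
        if not np.isfinite(self.coords).all():
            raise InvalidInputError("coordinates contain non-finite values")
        if self.timestep_ps <= 0:
            raise InvalidInputError("timestep_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, res_id: int, name: str) -> int:
        """Index of the atom ``name`` in residue ``res_id`` (−1 if absent)."""
        for k in range(self.n_atoms):
            if self.res_ids[k] == res_id and self.atom_names[k] == name:
                return k
        return -1

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass
class Spectrum1D:
    """Intensity on a strictly increasing frequency axis (cm⁻¹)."""

    frequency: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.frequency.shape != self.intensity.shape:
            raise InvalidInputError("frequency and intensity length mismatch")
        if self.frequency.size > 1 and not np.all(np.diff(self.frequency) > 0):
            raise InvalidInputError("frequency axis must be strictly increasing")
        if not np.isfinite(self.intensity).all():
            raise InvalidInputError("intensities must be finite")


@dataclass
class Spectrum2D:
    """Signed intensity on an (ω_τ, ω_m) grid at wait time T_w (ps).

    ``grid[i, j]`` is the intensity at ``omega_tau[i]``, ``omega_m[j]``.
    """

    omega_tau: np.ndarray
    omega_m: np.ndarray
    grid: np.ndarray
    t_wait_ps: float = 0.0
    component: str = "absorptive"

    def __post_init__(self) -> None:
        self.omega_tau = np.asarray(self.omega_tau, dtype=float)
        self.omega_m = np.asarray(self.omega_m, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (self.omega_tau.size, self.omega_m.size):
            raise InvalidInputError(
                f"grid shape {self.grid.shape} does not match axes "
                f"({self.omega_tau.size}, {self.omega_m.size})"
            )
        for ax in (self.omega_tau, self.omega_m):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise InvalidInputError("spectrum axes must be strictly increasing")
        if self.component not in ("rephasing", "nonrephasing", "absorptive"):
            raise InvalidInputError(f"unknown component {self.component!r}")


# ---------------------------------------------------------------------------
# Hamiltonian series
# ---------------------------------------------------------------------------


@dataclass
class HamiltonianSeries:
    """Per-frame N×N site-basis amide I Hamiltonians and transition dipoles.

    ``matrices`` has shape (n_frames, N, N) in cm⁻¹ (symmetric); ``dipoles``
    has shape (n_frames, N, 3) in debye.
    """

    matrices: np.ndarray
    dipoles: np.ndarray
    dt_ps: float = 0.02

    SYMMETRY_TOL = 1e-9
    FREQ_WINDOW = (1550.0, 1750.0)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise InvalidInputError("matrices must be (n_frames, N, N)")
        if self.dipoles.shape != (self.matrices.shape[0], self.matrices.shape[1], 3):
            raise InvalidInputError("dipoles must be (n_frames, N, 3)")
        asym = np.abs(self.matrices - np.swapaxes(self.matrices, 1, 2)).max()
        if asym > self.SYMMETRY_TOL:
            raise InvalidInputError(f"Hamiltonian asymmetry {asym:.2e} exceeds tolerance")
        if self.dt_ps <= 0:
            raise InvalidInputError("dt_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrices.shape[1]

    def validate_window(self, window: tuple[float, float] | None = None) -> None:
        """Check site frequencies lie in a physical amide I window."""
        lo, hi = window or self.FREQ_WINDOW
        diag = np.diagonal(self.matrices, axis1=1, axis2=2)
        if diag.min() < lo or diag.max() > hi:
            raise InvalidInputError(
                f"site frequencies outside [{lo}, {hi}] cm⁻¹: "
                f"range [{diag.min():.1f}, {diag.max():.1f}]"
            )


def as_static_series(
    matrix: np.ndarray, dipoles: np.ndarray, n_frames: int = 1, dt_ps: float = 0.02
) -> HamiltonianSeries:
    """Wrap a single Hamiltonian frame as a (repeated) static series."""
    matrix = np.asarray(matrix, dtype=float)
    dipoles = np.asarray(dipoles, dtype=float)
    return HamiltonianSeries(
        np.repeat(matrix[None], n_frames, axis=0),
        np.repeat(dipoles[None], n_frames, axis=0),
        dt_ps=dt_ps,
    )
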