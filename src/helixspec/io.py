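"""File formats shared by all pipeline stages.

Trajectories are multi-model PDB (coordinates converted nm↔Å at the
boundary; residue numbering 1-based, acetyl cap as residue 0).  Spectra and
tables are TSV with ``#`` header comments; free-energy surfaces use the
PLUMED-style whitespace-delimited grid layout (d1, d2, G columns).  All
writers are atomic (temp file + rename) and every output gets a JSON
provenance sidecar with the configuration hash, seed, and package version.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import __version__
from .core import (
    InvalidInputError,
    PeptideSpec,
    Spectrum1D,
    Spectrum2D,
    Trajectory,
)
from .conformation import FESGrid

NM_PER_ANGSTROM = 0.1


# ---------------------------------------------------------------------------
# Atomic writes and provenance
# ---------------------------------------------------------------------------


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_sidecar(path: str | Path, config: dict, seed: int | None = None) -> None:
    """JSON provenance sidecar (<path>.json): config hash, seed, version."""
    blob = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
    _atomic_write(str(path) + ".json", json.dumps(meta, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# Multi-model PDB trajectories
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames as a multi-model PDB (nm → Å)."""
    n_atoms = traj.n_atoms
    atoms = struc.AtomArray(n_atoms)
    atoms.coord = traj.coords[0] / NM_PER_ANGSTROM
    atoms.atom_name = np.asarray(traj.atom_names, dtype="U6")
    atoms.res_id = traj.res_ids
    atoms.res_name = np.asarray(traj.res_names, dtype="U5")
    atoms.chain_id = np.full(n_atoms, "A", dtype="U4")
    atoms.element = np.asarray(
        [n[0] if not n[0].isdigit() else n[1] for n in traj.atom_names], dtype="U2"
    )
    if traj.n_frames == 1:
        stack = atoms
    else:
        stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
        for cat in ("atom_name", "res_id", "res_name", "chain_id", "element"):
            stack.set_annotation(cat, atoms.get_annotation(cat))
        stack.coord = traj.coords / NM_PER_ANGSTROM
    pdb = PDBFile()
    pdb.set_structure(stack)
    fd, tmp = tempfile.mkstemp(dir=Path(path).parent or ".", suffix=".tmp")
    os.close(fd)
    try:
        pdb.write(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _check_pdb_structure(path: Path) -> None:
    """Reject truncated files: unbalanced MODEL/ENDMDL, reporting the line."""
    depth = 0
    last_model_line = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if depth != 0:
                    raise InvalidInputError(
                        f"{path}: nested MODEL at line {ln}"
                    )
                depth += 1
                last_model_line = ln
            elif rec == "ENDMDL":
                if depth != 1:
                    raise InvalidInputError(
                        f"{path}: ENDMDL without MODEL at line {ln}"
                    )
                depth -= 1
    if depth != 0:
        raise InvalidInputError(
            f"{path}: truncated file, MODEL at line {last_model_line} "
            "has no matching ENDMDL"
        )


def read_trajectory(
    path: str | Path,
    timestep_ps: float = 0.02,
    spec: PeptideSpec | None = None,
) -> Trajectory:
    """Read a multi-model PDB into a Trajectory (Å → nm)."""
    path = Path(path)
    _check_pdb_structure(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # pragma: no cover
        stack = struc.stack([stack])
    coords = stack.coord * NM_PER_ANGSTROM
    return Trajectory(
        coords=coords,
        atom_names=list(stack.atom_name),
        res_ids=np.asarray(stack.res_id, dtype=int),
        res_names=list(stack.res_name),
        timestep_ps=timestep_ps,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# TSV spectra and tables
# ---------------------------------------------------------------------------


def write_spectrum(s: Spectrum1D, path: str | Path) -> None:
    lines = ["# helixspec 1D spectrum",
             f"# metadata: {json.dumps(s.metadata, default=str)}",
             "# frequency_cm\tintensity"]
    lines += [f"{f:.6f}\t{v:.10e}" for f, v in zip(s.frequency, s.intensity)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> Spectrum1D:
    meta: dict = {}
    freqs, vals = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# metadata:"):
                    meta = json.loads(line.split(":", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InvalidInputError(f"{path}: malformed record at line {ln}")
            freqs.append(float(parts[0]))
            vals.append(float(parts[1]))
    if not freqs:
        raise InvalidInputError(f"{path}: no data rows")
    return Spectrum1D(np.asarray(freqs), np.asarray(vals), meta)


def write_spectrum2d(s: Spectrum2D, path: str | Path) -> None:
    """Long-format TSV: omega_tau, omega_m, value; metadata in comments."""
    lines = ["# helixspec 2D spectrum",
             f"# t_wait_ps: {s.t_wait_ps}",
             f"# component: {s.component}",
             "# omega_tau_cm\tomega_m_cm\tvalue"]
    for i, wt in enumerate(s.omega_tau):
        for j, wm in enumerate(s.omega_m):
            lines.append(f"{wt:.4f}\t{wm:.4f}\t{s.grid[i, j]:.10e}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_spectrum2d(path: str | Path) -> Spectrum2D:
    t_wait = 0.0
    component = "absorptive"
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# t_wait_ps:"):
                    t_wait = float(line.split(":", 1)[1])
                elif line.startswith("# component:"):
                    component = line.split(":", 1)[1].strip()
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InvalidInputError(f"{path}: malformed record at line {ln}")
            rows.append([float(p) for p in parts])
    if not rows:
        raise InvalidInputError(f"{path}: no data rows")
    arr = np.asarray(rows)
    wt = np.unique(arr[:, 0])
    wm = np.unique(arr[:, 1])
    if arr.shape[0] != wt.size * wm.size:
        raise InvalidInputError(f"{path}: incomplete 2D grid")
    grid = np.full((wt.size, wm.size), np.nan)
    it = np.searchsorted(wt, arr[:, 0])
    im = np.searchsorted(wm, arr[:, 1])
    grid[it, im] = arr[:, 2]
    return Spectrum2D(wt, wm, grid, t_wait_ps=t_wait, component=component)


def write_table(arr: np.ndarray, path: str | Path, columns: list[str],
                comment: str = "") -> None:
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("# " + "\t".join(columns))
    for row in np.atleast_2d(arr):
        lines.append("\t".join(f"{v:.10g}" for v in row))
    _atomic_write(path, "\n".join(lines) + "\n")


def read_table(path: str | Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([float(p) for p in line.split()])
            except ValueError:
                raise InvalidInputError(
                    f"{path}: malformed record at line {ln}"
                ) from None
    if not rows:
        raise InvalidInputError(f"{path}: no data rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InvalidInputError(f"{path}: ragged rows")
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# PLUMED-style free-energy grids
# ---------------------------------------------------------------------------


def write_fes(fes: FESGrid, path: str | Path) -> None:
    """PLUMED-style text grid: d1 d2 free_energy, d2 fastest-varying."""
    lines = ["#! FIELDS d1 d2 free_energy",
             f"#! SET temperature_k {fes.temperature_k}",
             f"#! SET offset {fes.offset_note}"]
    for i, x in enumerate(fes.d1):
        for j, y in enumerate(fes.d2):
            lines.append(f"{x: .6f} {y: .6f} {fes.free_energy[i, j]: .8e}")
        lines.append("")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_fes(path: str | Path) -> FESGrid:
    temperature = 298.15
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "temperature_k" in line:
                    temperature = float(line.split()[-1])
                continue
            parts = line.split()
            if len(parts) != 3:
                raise InvalidInputError(f"{path}: malformed record at line {ln}")
            rows.append([float(p) for p in parts])
    if not rows:
        raise InvalidInputError(f"{path}: no data rows")
    arr = np.asarray(rows)
    d1 = np.unique(arr[:, 0])
    d2 = np.unique(arr[:, 1])
    if arr.shape[0] != d1.size * d2.size:
        raise InvalidInputError(f"{path}: incomplete FES grid")
    grid = np.full((d1.size, d2.size), np.nan)
    i1 = np.searchsorted(d1, arr[:, 0])
    i2 = np.searchsorted(d2, arr[:, 1])
    grid[i1, i2] = arr[:, 2]
    return FESGrid(d1, d2, grid, temperature_k=temperature)
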