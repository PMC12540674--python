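"""Structures, trajectories and superposition primitives.

The in-memory model is deliberately minimal: a :class:`Structure` is an
ordered atom table plus an ``(n, 3)`` coordinate array in Angstrom, and a
:class:`Trajectory` is a stack of coordinate sets sharing one atom table.
PDB files (including multi-model files, which serve as the trajectory
interchange format) are read and written through biotite; a plain CSV
"xyz-table" dialect is accepted for synthetic data.

All RMSD/RMSF computations operate on an atom selection that defaults to
the C-alpha atoms, the conventional choice for backbone conformational
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_VDW_RADIUS, VDW_RADII
from .errors import DegeneracyError, FormatError, SelectionError

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "RMSDMatrix",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "kabsch_superpose",
    "rmsd_matrix",
    "rmsf",
]


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    res_name: str
    chain: str
    res_id: int
    element: str


@dataclass
class Structure:
    """An ordered atom table with coordinates in Angstrom."""

    atoms: list[Atom]
    coords: np.ndarray
    vdw_radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if self.vdw_radius is not None:
            self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
            if self.vdw_radius.shape != (len(self.atoms),):
                raise ValueError("vdw_radius length must equal atom count")
            if np.any(self.vdw_radius <= 0):
                raise ValueError("vdw_radius entries must be positive")

    def __len__(self) -> int:
        return len(self.atoms)

    def with_default_radii(
        self, overrides: dict[str, float] | None = None
    ) -> "Structure":
        """Return a copy with per-atom vdW radii filled from the element table."""
        table = dict(VDW_RADII)
        if overrides:
            table.update({k.upper(): v for k, v in overrides.items()})
        radii = np.array(
            [table.get(a.element.upper(), DEFAULT_VDW_RADIUS) for a in self.atoms]
        )
        return Structure(self.atoms, self.coords.copy(), radii)


@dataclass
class Trajectory:
    """Ordered snapshots of one atom table; frames are (n_frames, n_atoms, 3)."""

    atoms: list[Atom]
    frames: np.ndarray
    frame_times: np.ndarray | None = None  # ps
    selection: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{len(self.atoms)} atoms"
            )
        if self.selection is None:
            sel = [i for i, a in enumerate(self.atoms) if a.name == "CA"]
            if not sel:  # fall back to every atom (synthetic point clouds)
                sel = list(range(len(self.atoms)))
            self.selection = np.array(sel, dtype=int)
        else:
            self.selection = np.asarray(self.selection, dtype=int)
            if self.selection.size and (
                self.selection.min() < 0 or self.selection.max() >= len(self.atoms)
            ):
                raise SelectionError("selection indices out of range")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def selected(self) -> np.ndarray:
        """Coordinates of the selection, shape (n_frames, n_sel, 3)."""
        if self.selection.size == 0:
            raise SelectionError("empty atom selection")
        return self.frames[:, self.selection, :]

    def frame_structure(self, i: int, vdw_radius: np.ndarray | None = None) -> Structure:
        return Structure(self.atoms, self.frames[i].copy(), vdw_radius)


@dataclass
class RMSDMatrix:
    """Symmetric all-vs-all RMSD grid in Angstrom."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if np.any(v < 0):
            raise ValueError("RMSD matrix entries must be non-negative")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric within 1e-9")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("RMSD matrix diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_XYZ_STRUCTURE_COLUMNS = {"x", "y", "z"}


def _atoms_from_biotite(array) -> list[Atom]:
    serials = (
        array.atom_id
        if "atom_id" in array.get_annotation_categories()
        else np.arange(1, array.array_length() + 1)
    )
    return [
        Atom(
            serial=int(serials[i]),
            name=str(array.atom_name[i]),
            res_name=str(array.res_name[i]),
            chain=str(array.chain_id[i]),
            res_id=int(array.res_id[i]),
            element=str(array.element[i]),
        )
        for i in range(array.array_length())
    ]


def _biotite_from_atoms(atoms: Sequence[Atom], coords: np.ndarray):
    import biotite.structure as struc

    arr = struc.AtomArray(len(atoms))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.array([a.name for a in atoms])
    arr.res_name = np.array([a.res_name for a in atoms])
    arr.chain_id = np.array([a.chain for a in atoms])
    arr.res_id = np.array([a.res_id for a in atoms], dtype=int)
    arr.element = np.array([a.element for a in atoms])
    return arr


def _read_pdb_models(path: str | Path):
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(extra_fields=["atom_id"])
    except FileNotFoundError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return stack


def _read_xyz_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as CSV xyz-table: {exc}") from exc
    missing = _XYZ_STRUCTURE_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: xyz-table missing columns {sorted(missing)}")
    bad = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: line {line}: non-numeric coordinate")
    return df


def _atoms_from_xyz_table(df: pd.DataFrame, n: int) -> list[Atom]:
    name = df["name"] if "name" in df.columns else pd.Series(["CA"] * n)
    elem = df["element"] if "element" in df.columns else pd.Series(["C"] * n)
    resid = df["resid"] if "resid" in df.columns else pd.Series(range(1, n + 1))
    chain = df["chain"] if "chain" in df.columns else pd.Series(["A"] * n)
    return [
        Atom(
            serial=i + 1,
            name=str(name.iloc[i]),
            res_name="UNK",
            chain=str(chain.iloc[i]),
            res_id=int(resid.iloc[i]),
            element=str(elem.iloc[i]),
        )
        for i in range(n)
    ]


def read_structure(path: str | Path, dialect: str = "pdb") -> Structure:
    """Read a single structure from a PDB file or a CSV xyz-table.

    The xyz-table dialect requires columns ``x, y, z`` and accepts optional
    ``name, element, resid, chain, vdw_radius`` columns; atom order is
    preserved exactly as in the file.
    """
    if dialect == "pdb":
        stack = _read_pdb_models(path)
        atoms = _atoms_from_biotite(stack[0])
        # PDB text carries exactly 3 decimals; rounding removes float32 noise
        return Structure(atoms, np.round(np.asarray(stack.coord[0], dtype=float), 3))
    if dialect == "xyz-table":
        df = _read_xyz_table(path)
        if "frame" in df.columns:
            df = df[df["frame"] == df["frame"].iloc[0]].reset_index(drop=True)
        n = len(df)
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        radii = (
            df["vdw_radius"].to_numpy(dtype=float) if "vdw_radius" in df.columns else None
        )
        return Structure(_atoms_from_xyz_table(df, n), coords, radii)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_structure(s: Structure, path: str | Path, dialect: str = "pdb") -> None:
    """Write a structure; PDB output preserves coordinates to 3 decimals."""
    if len(s) == 0:
        raise ValueError("refusing to write an empty structure")
    if dialect == "pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile()
        pdb.set_structure(_biotite_from_atoms(s.atoms, np.round(s.coords, 3)))
        pdb.write(str(path))
        return
    if dialect == "xyz-table":
        df = pd.DataFrame(
            {
                "name": [a.name for a in s.atoms],
                "element": [a.element for a in s.atoms],
                "resid": [a.res_id for a in s.atoms],
                "chain": [a.chain for a in s.atoms],
                "x": s.coords[:, 0],
                "y": s.coords[:, 1],
                "z": s.coords[:, 2],
            }
        )
        if s.vdw_radius is not None:
            df["vdw_radius"] = s.vdw_radius
        df.to_csv(path, index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def read_trajectory(path: str | Path, dialect: str = "pdb") -> Trajectory:
    """Read a trajectory from a multi-model PDB or a (frame, atom, x, y, z) CSV."""
    if dialect == "pdb":
        stack = _read_pdb_models(path)
        atoms = _atoms_from_biotite(stack[0])
        return Trajectory(atoms, np.round(np.asarray(stack.coord, dtype=float), 3))
    if dialect == "xyz-table":
        df = _read_xyz_table(path)
        if "frame" not in df.columns or "atom" not in df.columns:
            raise FormatError(f"{path}: trajectory xyz-table needs frame and atom columns")
        frames_idx = sorted(df["frame"].unique())
        first = df[df["frame"] == frames_idx[0]].sort_values("atom")
        n_atoms = len(first)
        frames = np.empty((len(frames_idx), n_atoms, 3))
        for k, fi in enumerate(frames_idx):
            sub = df[df["frame"] == fi].sort_values("atom")
            if len(sub) != n_atoms:
                raise FormatError(
                    f"{path}: frame {fi} has {len(sub)} atoms, expected {n_atoms}"
                )
            frames[k] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        return Trajectory(_atoms_from_xyz_table(first.reset_index(drop=True), n_atoms), frames)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_trajectory(traj: Trajectory, path: str | Path, dialect: str = "pdb") -> None:
    if dialect == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        template = _biotite_from_atoms(traj.atoms, traj.frames[0])
        stack = struc.stack([template] * traj.n_frames)
        stack.coord = np.round(traj.frames, 3).astype(np.float32)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
        return
    if dialect == "xyz-table":
        rows = []
        for f in range(traj.n_frames):
            for i in range(len(traj.atoms)):
                rows.append(
                    (f, i, traj.frames[f, i, 0], traj.frames[f, i, 1], traj.frames[f, i, 2])
                )
        pd.DataFrame(rows, columns=["frame", "atom", "x", "y", "z"]).to_csv(
            path, index=False
        )
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Superposition / deviation primitives
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to the
    reference over all proper rigid motions (Kabsch algorithm; the
    reflection branch of the SVD is corrected so the rotation determinant
    is +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {P.shape}, {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegeneracyError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def superpose_frames(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose each frame onto a reference coordinate set."""
    out = np.empty_like(frames)
    for i in range(frames.shape[0]):
        R, t, _ = kabsch_superpose(frames[i], reference)
        out[i] = frames[i] @ R.T + t
    return out


def iterative_mean_superpose(
    frames: np.ndarray, n_iter: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose frames onto their converged mean structure.

    Returns ``(aligned_frames, mean_coords)``.  The mean is refined by the
    usual fixed-point iteration: align to the current mean, recompute it.
    """
    aligned = superpose_frames(frames, frames[0])
    for _ in range(n_iter):
        mean = aligned.mean(axis=0)
        aligned = superpose_frames(frames, mean)
    return aligned, aligned.mean(axis=0)


def rmsd_matrix(traj: Trajectory) -> RMSDMatrix:
    """All-vs-all C-alpha RMSD matrix over the trajectory selection."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for an RMSD matrix")
    X = traj.selected()
    n = traj.n_frames
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(X[i], X[j])
            m[i, j] = m[j, i] = r
    return RMSDMatrix(m)


def rmsf(traj: Trajectory) -> np.ndarray:
    """Per-selected-atom root-mean-square fluctuation about the mean structure."""
    if traj.n_frames < 2:
        raise DegeneracyError("RMSF is undefined for a single frame")
    X = traj.selected()
    aligned, mean = iterative_mean_superpose(X)
    dev2 = ((aligned - mean) ** 2).sum(axis=2)  # (n_frames, n_sel)
    return np.sqrt(dev2.mean(axis=0))
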