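import numpy as np
import pytest

from confswitch.structures import Atom, Structure, Trajectory


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent minimal-RMSD oracle via the quaternion key matrix.

    The optimal superposition RMSD is sqrt((G_A + G_B - 2*lam_max)/N) where
    lam_max is the largest eigenvalue of the 4x4 quaternion key matrix of
    the inner-product matrix M = A^T B (Horn's method).
    """
    A = mobile - mobile.mean(axis=0)
    B = reference - reference.mean(axis=0)
    n = A.shape[0]
    GA = (A**2).sum()
    GB = (B**2).sum()
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    val = max((GA + GB - 2.0 * lam_max) / n, 0.0)
    return float(np.sqrt(val))


def point_cloud_trajectory(frames: np.ndarray) -> Trajectory:
    """Wrap a (n_frames, n_atoms, 3) array as an all-CA trajectory."""
    n_atoms = frames.shape[1]
    atoms = [Atom(i + 1, "CA", "ALA", "A", i + 1, "C") for i in range(n_atoms)]
    return Trajectory(atoms, frames)


def simple_structure(coords: np.ndarray, radii=None) -> Structure:
    coords = np.atleast_2d(coords)
    # group atoms 10 per residue to stay within the 4-digit PDB residue field
    atoms = [Atom(i + 1, "C", "UNK", "A", i // 10 + 1, "C") for i in range(len(coords))]
    return Structure(atoms, coords, radii)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_atom_pdb(tmp_path):
    text = (
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C  \n"
        "ATOM      2  CB  ALA A   1       4.000   5.500   6.250  1.00  0.00           C  \n"
        "END\n"
    )
    p = tmp_path / "two_atoms.pdb"
    p.write_text(text)
    return p


def pdb_atom_line(serial: int, resid: int, x: float, y: float, z: float) -> str:
    return (
        f"ATOM  {serial:>5d}  CA  GLY A{resid:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C  "
    )


@pytest.fixture
def three_model_pdb(tmp_path):
    lines = []
    for m in range(1, 4):
        lines.append(f"MODEL     {m:4d}")
        lines.append(pdb_atom_line(1, 1, float(m), 0.0, 0.0))
        lines.append(pdb_atom_line(2, 2, 0.0, float(m + 1), 0.0))
        lines.append(pdb_atom_line(3, 3, 0.0, 0.0, float(m + 2)))
        lines.append("ENDMDL")
    lines.append("END")
    p = tmp_path / "traj.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p
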