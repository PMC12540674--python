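"""End-point binding free-energy algebra: MM/PBSA components, SIE scoring,
per-residue decomposition ranking, vacuum pair energies and a
Shrake-Rupley surface-area estimator.

The MM/PBSA enthalpy is the sum of vacuum electrostatics (ELE_IN), vacuum
van der Waals (VDW_IN), polar solvation from a Poisson-Boltzmann solver
(ELE_PB, consumed as input) and the nonpolar surface term (VDW_SA); the
binding free energy subtracts the normal-mode entropy term T*dS, also
consumed as input:

    dG = dH - T*dS,   dH = ELE_IN + VDW_IN + ELE_PB + VDW_SA.

The solvated interaction energy (SIE) score is the scaled linear
combination

    dG_bind = alpha * [E_c + dG_R_bind + E_vdw + gamma * dMSA] + C

with alpha the global entropy-loss scale, E_c the intermolecular Coulomb
energy at internal dielectric D_in, dG_R_bind the reaction-field energy
change, E_vdw the intermolecular van der Waals energy, dMSA the change in
molecular surface area (Angstrom^2) and C a calibration constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .constants import COULOMB_KCAL
from .errors import SchemaError
from .structures import Structure

__all__ = [
    "MMPBSARow",
    "SIEComponents",
    "SIEParams",
    "ResidueEnergyTable",
    "mmpbsa_delta",
    "binding_energy",
    "aggregate_snapshots",
    "sie_score",
    "rank_residue_contributions",
    "vacuum_interaction_energy",
    "sasa",
]

_COMPONENTS = ("ELE_IN", "VDW_IN", "ELE_PB", "VDW_SA")


@dataclass
class MMPBSARow:
    """One system's MM/PBSA terms in kcal/mol; fields may be absent (None)."""

    label: str
    ELE_IN: float | None = None
    VDW_IN: float | None = None
    ELE_PB: float | None = None
    VDW_SA: float | None = None
    H: float | None = None
    TdS: float | None = None

    def present(self) -> set[str]:
        return {
            f.name
            for f in fields(self)
            if f.name != "label" and getattr(self, f.name) is not None
        }

    def __post_init__(self) -> None:
        comps = [getattr(self, c) for c in _COMPONENTS]
        if self.H is not None and all(v is not None for v in comps):
            if abs(self.H - sum(comps)) > 0.02:
                raise ValueError(
                    f"{self.label}: H={self.H} inconsistent with component sum "
                    f"{sum(comps):.4f} (tolerance 0.02)"
                )


@dataclass
class SIEParams:
    """Calibrated SIE coefficients (defaults are the standard calibration)."""

    alpha: float = 0.1048
    D_in: float = 2.25
    rho: float = 1.1
    gamma: float = 0.0129  # kcal mol^-1 A^-2
    C: float = -2.89  # kcal/mol

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.D_in < 1:
            raise ValueError("D_in must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class SIEComponents:
    """Per-system SIE inputs; dMSA is in Angstrom^2, the rest kcal/mol."""

    label: str
    E_c: float
    dG_R_bind: float
    E_vdw: float
    dMSA: float

    def __post_init__(self) -> None:
        vals = (self.E_c, self.dG_R_bind, self.E_vdw, self.dMSA)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"{self.label}: non-finite SIE component")


@dataclass
class ResidueEnergyTable:
    """Per-residue decomposition rows (E_VDW, E_ELE, E_GB, E_GBSUR, total)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    _REQUIRED = ("residue", "E_VDW", "E_ELE", "E_GB", "E_GBSUR", "total")

    def __post_init__(self) -> None:
        missing = set(self._REQUIRED) - set(self.table.columns)
        if missing:
            raise SchemaError(f"residue table missing columns {sorted(missing)}")
        if len(self.table):
            s = self.table[["E_VDW", "E_ELE", "E_GB", "E_GBSUR"]].sum(axis=1)
            if (abs(self.table["total"] - s) > 0.02).any():
                raise ValueError("residue totals inconsistent with term sums")


def mmpbsa_delta(
    complex_row: MMPBSARow, receptor: MMPBSARow, ligand: MMPBSARow
) -> MMPBSARow:
    """Component-wise complex - receptor - ligand difference ("Delta" row)."""
    present = complex_row.present()
    if receptor.present() != present or ligand.present() != present:
        raise SchemaError(
            "complex/receptor/ligand rows must share the same set of present fields"
        )
    kwargs = {}
    for name in present:
        kwargs[name] = (
            getattr(complex_row, name) - getattr(receptor, name) - getattr(ligand, name)
        )
    return MMPBSARow(label="Delta", **kwargs)


def binding_energy(delta: MMPBSARow) -> tuple[float, float]:
    """Return (dH, dG) from a Delta row: dH = sum of the four interaction
    components, dG = dH - TdS."""
    missing = [c for c in (*_COMPONENTS, "TdS") if getattr(delta, c) is None]
    if missing:
        raise SchemaError(f"Delta row missing {missing}")
    dH = sum(getattr(delta, c) for c in _COMPONENTS)
    return dH, dH - delta.TdS


def aggregate_snapshots(rows: list[MMPBSARow], label: str) -> tuple[MMPBSARow, MMPBSARow]:
    """Mean and SD over per-snapshot rows (returned as two rows)."""
    if not rows:
        raise ValueError("no rows to aggregate")
    present = rows[0].present()
    if any(r.present() != present for r in rows):
        raise SchemaError("snapshot rows must share the same set of present fields")
    mean_kwargs, sd_kwargs = {}, {}
    for name in present:
        vals = np.array([getattr(r, name) for r in rows], dtype=float)
        mean_kwargs[name] = float(vals.mean())
        sd_kwargs[name] = float(vals.std(ddof=0)) if len(vals) > 1 else 0.0
    mean = MMPBSARow(label=label, **mean_kwargs)
    # the SD row is not a physical row; bypass the H-consistency check
    sd = MMPBSARow.__new__(MMPBSARow)
    sd.label = f"{label}_sd"
    for f in ("ELE_IN", "VDW_IN", "ELE_PB", "VDW_SA", "H", "TdS"):
        setattr(sd, f, sd_kwargs.get(f))
    return mean, sd


def sie_score(c: SIEComponents, p: SIEParams | None = None) -> float:
    """Solvated-interaction-energy binding free energy in kcal/mol."""
    p = p or SIEParams()
    return p.alpha * (c.E_c + c.dG_R_bind + c.E_vdw + p.gamma * c.dMSA) + p.C


def rank_residue_contributions(t: ResidueEnergyTable, n: int = 10) -> pd.DataFrame:
    """Top-``n`` residues by most favourable (lowest) total contribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(t.table) == 0:
        raise ValueError("residue table is empty")
    out = t.table.sort_values(["total", "residue"], kind="stable").head(n)
    return out.reset_index(drop=True)


def vacuum_interaction_energy(
    a: Structure,
    b: Structure,
    charges_a: np.ndarray,
    charges_b: np.ndarray,
    lj_a: np.ndarray,
    lj_b: np.ndarray,
    dielectric: float = 1.0,
) -> tuple[float, float]:
    """Intermolecular Coulomb and Lennard-Jones energies, no cutoff.

    ``lj_*`` are ``(n, 2)`` arrays of ``(Rmin/2, epsilon)`` per atom; pair
    parameters combine as ``Rmin_ij = Rmin_i/2 + Rmin_j/2`` and
    ``eps_ij = sqrt(eps_i * eps_j)``.
    """
    qa = np.asarray(charges_a, float)
    qb = np.asarray(charges_b, float)
    la = np.asarray(lj_a, float)
    lb = np.asarray(lj_b, float)
    if qa.shape[0] != len(a) or la.shape[0] != len(a):
        raise SchemaError("parameter tables must cover every atom of a")
    if qb.shape[0] != len(b) or lb.shape[0] != len(b):
        raise SchemaError("parameter tables must cover every atom of b")
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms (r < 1e-6 A)")
    e_ele = float((COULOMB_KCAL * qa[:, None] * qb[None, :] / (dielectric * r)).sum())
    rmin = la[:, 0][:, None] + lb[:, 0][None, :]
    eps = np.sqrt(la[:, 1][:, None] * lb[:, 1][None, :])
    ratio6 = (rmin / r) ** 6
    e_vdw = float((eps * (ratio6**2 - 2.0 * ratio6)).sum())
    return e_ele, e_vdw


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sasa(
    s: Structure, probe: float = 1.4, n_points: int = 960
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's vdW sphere is inflated by the probe radius and covered with
    ``n_points`` quasi-uniform test points; the accessible fraction is the
    share of points not buried inside any other inflated sphere.  Returns
    ``(total, per_atom)`` in Angstrom^2.
    """
    if s.vdw_radius is None:
        raise SchemaError("structure lacks vdW radii; call with_default_radii()")
    pts = _sphere_points(n_points)
    radii = s.vdw_radius + probe
    coords = s.coords
    n = len(s)
    per_atom = np.zeros(n)
    for i in range(n):
        surface = coords[i] + radii[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = ((surface - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return float(per_atom.sum()), per_atom
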