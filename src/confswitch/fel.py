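"""PCA of trajectory coordinates and Boltzmann-inversion free-energy landscapes.

Frames are superposed onto their mean structure, the Cartesian covariance
of the selected atoms is diagonalised (via scikit-learn's PCA), and the
first two principal components serve as reaction coordinates.  The
landscape is the Boltzmann inversion of the 2D projection histogram,

    dG(X) = -kB * T * ln P(X),

shifted so the lowest occupied bin sits at zero.  Empty bins are masked
rather than assigned an infinite free energy so that grids stay
serialisable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .errors import DegeneracyError, ParameterError
from .structures import Trajectory, iterative_mean_superpose

__all__ = ["PCAResult", "FELGrid", "Basin", "pca_project", "free_energy_landscape", "find_basins"]


@dataclass
class PCAResult:
    mean_coords: np.ndarray  # (n_sel, 3)
    components: np.ndarray  # (n_components, 3*n_sel), orthonormal rows
    variances: np.ndarray  # per-component variance, A^2
    projections: np.ndarray  # (n_frames, n_components), centred

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variances) > 1e-9):
            raise ValueError("variances must be non-increasing")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-8):
            raise ValueError("components must be orthonormal")


@dataclass
class FELGrid:
    """2D free-energy landscape over PC1/PC2 bins."""

    bin_edges: tuple[np.ndarray, np.ndarray]
    probability: np.ndarray  # (nx, ny), sums to 1 over occupied bins
    free_energy: np.ndarray  # kcal/mol, NaN on empty bins, min occupied = 0
    occupied: np.ndarray  # bool mask
    temperature: float
    kB: float = KB_KCAL

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: bin centres, probability, dG, occupancy mask."""
        cx = 0.5 * (self.bin_edges[0][:-1] + self.bin_edges[0][1:])
        cy = 0.5 * (self.bin_edges[1][:-1] + self.bin_edges[1][1:])
        xi, yi = np.meshgrid(np.arange(cx.size), np.arange(cy.size), indexing="ij")
        return pd.DataFrame(
            {
                "pc1": cx[xi.ravel()],
                "pc2": cy[yi.ravel()],
                "probability": self.probability.ravel(),
                "free_energy": self.free_energy.ravel(),
                "occupied": self.occupied.ravel(),
            }
        )


@dataclass
class Basin:
    minimum_bin: tuple[int, int]
    member_bins: list[tuple[int, int]]
    depth: float  # dG of rim minus dG of minimum, kcal/mol


def pca_project(traj: Trajectory, n_components: int = 2) -> PCAResult:
    """Principal components of superposed selected-atom coordinates.

    Mass-unweighted Cartesian covariance; projections are centred per
    component.  Raises on a static (zero-variance) trajectory.
    """
    from sklearn.decomposition import PCA

    if traj.n_frames < 3:
        raise ValueError("PCA needs at least 3 frames")
    aligned, mean = iterative_mean_superpose(traj.selected())
    flat = aligned.reshape(traj.n_frames, -1)
    if float(flat.var(axis=0).sum()) <= 1e-12:
        raise DegeneracyError("trajectory has zero coordinate variance")
    k = min(n_components, traj.n_frames - 1, flat.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    projections = pca.fit_transform(flat)
    return PCAResult(
        mean_coords=mean,
        components=pca.components_,
        variances=pca.explained_variance_,
        projections=projections,
    )


def free_energy_landscape(
    projections: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    bins: int | tuple[int, int] = 50,
    ranges=None,
) -> FELGrid:
    """Boltzmann inversion of the 2D histogram of PC1/PC2 projections."""
    if temperature <= 0:
        raise ParameterError(f"temperature must be positive, got {temperature}")
    proj = np.asarray(projections, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < 2:
        raise ValueError("projections must be (n_samples, >=2)")
    if proj.shape[0] < 1:
        raise ValueError("need at least one sample")
    hist, ex, ey = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins, range=ranges)
    prob = hist / hist.sum()
    occupied = prob > 0
    dG = np.full_like(prob, np.nan)
    with np.errstate(divide="ignore"):
        dG[occupied] = -KB_KCAL * temperature * np.log(prob[occupied])
    dG[occupied] -= dG[occupied].min()
    return FELGrid(
        bin_edges=(ex, ey),
        probability=prob,
        free_energy=dG,
        occupied=occupied,
        temperature=temperature,
    )


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def find_basins(grid: FELGrid, k: int = 3) -> list[Basin]:
    """Locate up to ``k`` free-energy basins on the landscape.

    A basin minimum is an occupied bin no 8-neighbour of which has strictly
    lower free energy; bins are assigned to basins by steepest descent.
    Plateau ties are broken toward the lowest bin index, so a uniformly
    occupied grid collapses into a single basin rooted at bin (0, 0).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if not grid.occupied.any():
        raise ValueError("grid has no occupied bins")
    dG = grid.free_energy
    nx, ny = dG.shape

    def descend(ij: tuple[int, int]) -> tuple[int, int]:
        # steepest-descent step; ties toward lowest (i, j)
        i, j = ij
        best = (dG[i, j], i, j)
        for di, dj in _NEIGHBOURS:
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and grid.occupied[a, b]:
                cand = (dG[a, b], a, b)
                if cand < best:
                    best = cand
        return (best[1], best[2])

    # follow descent paths to their fixed points
    root: dict[tuple[int, int], tuple[int, int]] = {}
    for i in range(nx):
        for j in range(ny):
            if not grid.occupied[i, j]:
                continue
            path = [(i, j)]
            cur = (i, j)
            while True:
                if cur in root:
                    cur = root[cur]
                    break
                nxt = descend(cur)
                if nxt == cur:
                    break
                path.append(nxt)
                cur = nxt
            for p in path:
                root[p] = cur

    minima = sorted(set(root.values()), key=lambda ij: (dG[ij], ij))
    basins = []
    for m in minima[:k]:
        members = sorted(p for p, r in root.items() if r == m)
        rim = max(dG[p] for p in members)
        basins.append(Basin(minimum_bin=m, member_bins=members, depth=float(rim - dG[m])))
    return basins
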