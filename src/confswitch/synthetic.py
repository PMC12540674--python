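"""Seeded generators for every input the analysis stages consume.

Each generator plants known ground truth (cluster labels, segment
free-energy differences, MM/PBSA deltas, analytic pore radii, an exact
potential behind umbrella histograms) so that the downstream estimators
can be validated by parameter recovery.  All randomness flows through an
explicit integer seed; no global state is touched.

The Gaussian work model is chosen deliberately: for final works
W ~ N(mu, sigma^2) the Jarzynski average has the closed form
dG = mu - beta*sigma^2/2, so planting dG targets amounts to shifting the
mean by the analytic bias.  Trajectory basins are isotropic Gaussian
jitter about distinct reference conformations; channel fixtures are
coaxial atom rings whose inscribed-sphere radius is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import AMINO_ACIDS, Mutant, MutationSite, enumerate_mutants
from .energetics import MMPBSARow
from .pmf import SegmentWork, UmbrellaWindow, WorkEnsemble
from .structures import Atom, Structure, Trajectory

__all__ = [
    "PlantedTrajectorySpec",
    "LangevinWorkSpec",
    "gen_multibasin_trajectory",
    "make_basin_centres",
    "gen_work_ensemble",
    "gen_mmpbsa_tables",
    "gen_channel_structure",
    "gen_umbrella_samples",
    "gen_screen_table",
    "KEY_SITES",
]


# ---------------------------------------------------------------------------
# Multi-basin trajectories
# ---------------------------------------------------------------------------


@dataclass
class PlantedTrajectorySpec:
    """Multi-basin trajectory recipe: frames are drawn per-basin from
    isotropic Gaussians about reference conformations."""

    centres: np.ndarray  # (n_basins, n_atoms, 3)
    occupancy: np.ndarray  # per-basin fraction, sums to 1
    sigma: float  # per-axis jitter, A
    frames: int
    seed: int

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.centres.ndim != 3 or self.centres.shape[2] != 3:
            raise ValueError("centres must be (n_basins, n_atoms, 3)")
        if self.occupancy.shape[0] != self.centres.shape[0]:
            raise ValueError("one occupancy per basin required")
        if abs(self.occupancy.sum() - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")
        if self.sigma < 0 or self.frames < 1:
            raise ValueError("sigma must be >= 0 and frames >= 1")


def make_basin_centres(
    n_basins: int, n_atoms: int, scale: float = 6.0, seed: int = 0
) -> np.ndarray:
    """Random reference conformations with pairwise RMSD of order ``scale``."""
    rng = np.random.default_rng(seed)
    return rng.normal(scale=scale / np.sqrt(2.0), size=(n_basins, n_atoms, 3))


def gen_multibasin_trajectory(
    spec: PlantedTrajectorySpec,
) -> tuple[Trajectory, np.ndarray]:
    """Draw frames per basin occupancy; returns the trajectory and the
    ground-truth basin label of every frame."""
    rng = np.random.default_rng(spec.seed)
    n_basins, n_atoms, _ = spec.centres.shape
    labels = rng.choice(n_basins, size=spec.frames, p=spec.occupancy)
    frames = spec.centres[labels] + rng.normal(
        scale=spec.sigma, size=(spec.frames, n_atoms, 3)
    )
    atoms = [Atom(i + 1, "CA", "ALA", "A", i + 1, "C") for i in range(n_atoms)]
    return Trajectory(atoms, frames), labels


# ---------------------------------------------------------------------------
# Nonequilibrium pulling work
# ---------------------------------------------------------------------------


@dataclass
class LangevinWorkSpec:
    """Segmented Gaussian work recipe.

    ``dG_targets`` are the planted per-segment free-energy changes; final
    works are drawn as N(dG + beta*sigma^2/2, sigma^2) so the Jarzynski
    average recovers the targets in expectation.  ``friction`` and
    ``noise_amp`` shape the monotone within-segment accumulation (they
    mimic the drag and fluctuation terms of an overdamped pulling
    equation) without affecting the planted endpoint statistics.
    """

    dG_targets: np.ndarray  # kcal/mol per segment
    sigma: np.ndarray | float = 0.5  # work SD per segment, kcal/mol
    friction: float = 1.0
    noise_amp: float = 0.2
    trajectories: int = 25
    points_per_segment: int = 21
    boundaries: np.ndarray | None = None  # xi values, len = n_segments + 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.dG_targets = np.atleast_1d(np.asarray(self.dG_targets, dtype=float))
        if self.dG_targets.size == 0:
            raise ValueError("need at least one segment")
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), self.dG_targets.shape
        ).copy()
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.trajectories < 1:
            raise ValueError("need at least one trajectory per segment")
        if self.boundaries is None:
            self.boundaries = np.arange(self.dG_targets.size + 1, dtype=float)
        else:
            self.boundaries = np.asarray(self.boundaries, dtype=float)
            if self.boundaries.size != self.dG_targets.size + 1:
                raise ValueError("boundaries must have n_segments + 1 entries")


def gen_work_ensemble(spec: LangevinWorkSpec, beta: float) -> WorkEnsemble:
    """Generate a segmented work ensemble with planted free-energy changes."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    rng = np.random.default_rng(spec.seed)
    segments = []
    for si, dG in enumerate(spec.dG_targets):
        sig = spec.sigma[si]
        mu = dG + beta * sig**2 / 2.0  # Gaussian-work Jarzynski identity
        finals = rng.normal(mu, sig, size=spec.trajectories) if sig > 0 else np.full(
            spec.trajectories, mu
        )
        xi = np.linspace(
            spec.boundaries[si], spec.boundaries[si + 1], spec.points_per_segment
        )
        # monotone accumulation: positive increments shaped by a drag-plus-
        # noise profile, rescaled to reach the final work exactly
        incr = np.abs(
            rng.normal(
                spec.friction, spec.noise_amp, size=(spec.trajectories, xi.size - 1)
            )
        )
        frac = np.cumsum(incr, axis=1)
        frac /= frac[:, -1][:, None]
        work = np.concatenate(
            [np.zeros((spec.trajectories, 1)), frac * finals[:, None]], axis=1
        )
        segments.append(SegmentWork(xi=xi, work=work))
    return WorkEnsemble(segments=segments, beta=beta)


# ---------------------------------------------------------------------------
# MM/PBSA component tables
# ---------------------------------------------------------------------------

# baseline per-system component means (kcal/mol) for a receptor of a few
# hundred residues with a CoA-ester-sized ligand; only the *delta* matters
# to downstream tests
_RECEPTOR_MEAN = {"ELE_IN": -7325.69, "VDW_IN": -964.62, "ELE_PB": -3044.21, "VDW_SA": 68.97}
_LIGAND_MEAN = {"ELE_IN": -512.76, "VDW_IN": -4.52, "ELE_PB": -107.70, "VDW_SA": 6.44}


def gen_mmpbsa_tables(
    seed: int,
    n_snapshots: int,
    planted_delta: dict[str, float],
    sds: dict[str, float] | None = None,
    planted_TdS: tuple[float, float, float] | None = None,
) -> dict[str, list[MMPBSARow]]:
    """Per-snapshot MM/PBSA rows for complex/receptor/ligand.

    The complex mean equals receptor + ligand + planted delta, so with
    zero noise the aggregated delta reproduces the plant exactly.
    ``planted_TdS`` optionally supplies (complex, receptor, ligand)
    entropy terms.  H is always the per-row component sum.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    rng = np.random.default_rng(seed)
    sds = sds or {}
    comps = ("ELE_IN", "VDW_IN", "ELE_PB", "VDW_SA")
    means = {
        "receptor": _RECEPTOR_MEAN,
        "ligand": _LIGAND_MEAN,
        "complex": {
            c: _RECEPTOR_MEAN[c] + _LIGAND_MEAN[c] + planted_delta[c] for c in comps
        },
    }
    tds = dict(zip(("complex", "receptor", "ligand"), planted_TdS or (0.0, 0.0, 0.0)))
    out: dict[str, list[MMPBSARow]] = {}
    for system, mean in means.items():
        rows = []
        for _ in range(n_snapshots):
            vals = {
                c: mean[c] + (rng.normal(0.0, sds[c]) if sds.get(c) else 0.0)
                for c in comps
            }
            rows.append(
                MMPBSARow(
                    label=system,
                    **vals,
                    H=sum(vals.values()),
                    TdS=tds[system],
                )
            )
        out[system] = rows
    return out


# ---------------------------------------------------------------------------
# Channel geometry
# ---------------------------------------------------------------------------


def gen_channel_structure(
    ring_radii: np.ndarray,
    stations: np.ndarray | None = None,
    atoms_per_ring: int = 24,
    vdw_radius: float = 1.5,
    seed: int = 0,
) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Coaxial atom rings along z realising a known pore-radius profile.

    Returns ``(structure, analytic_radius, blocked)`` where the analytic
    inscribed-sphere radius at each ring plane is ``ring_radius -
    vdw_radius`` (clamped at zero and flagged blocked when negative).
    Station spacing defaults to 4 A, wide enough that neighbouring rings
    do not undercut a ring's own clearance for tapers up to ~0.5 A per
    station.
    """
    ring_radii = np.asarray(ring_radii, dtype=float)
    if np.any(ring_radii <= 0):
        raise ValueError("ring radii must be positive")
    if stations is None:
        stations = 4.0 * np.arange(ring_radii.size, dtype=float)
    stations = np.asarray(stations, dtype=float)
    if stations.size != ring_radii.size:
        raise ValueError("one station per ring required")
    rng = np.random.default_rng(seed)
    coords = []
    atoms = []
    serial = 1
    for z, R in zip(stations, ring_radii):
        phase = rng.uniform(0, 2 * np.pi)  # decorrelate ring orientations
        for j in range(atoms_per_ring):
            th = phase + 2 * np.pi * j / atoms_per_ring
            coords.append((R * np.cos(th), R * np.sin(th), z))
            atoms.append(Atom(serial, "C", "RNG", "A", serial, "C"))
            serial += 1
    coords = np.asarray(coords)
    radii = np.full(len(atoms), vdw_radius)
    analytic = ring_radii - vdw_radius
    blocked = analytic < 0
    analytic = np.clip(analytic, 0.0, None)
    return Structure(atoms, coords, radii), analytic, blocked


# ---------------------------------------------------------------------------
# Umbrella-sampling windows
# ---------------------------------------------------------------------------


def gen_umbrella_samples(
    potential,
    centres: np.ndarray,
    spring: float,
    n_per_window: int,
    temperature: float,
    seed: int,
    xi_range: tuple[float, float] | None = None,
    n_bins: int = 100,
) -> list[UmbrellaWindow]:
    """Sample biased Boltzmann densities per window onto a shared bin grid.

    Sampling is grid-based inverse-CDF over a fine discretisation of the
    xi range (deterministic per seed), which is exact up to the bin width
    and avoids rejection-rate pathologies for stiff biases.
    """
    from .constants import beta as beta_of

    centres = np.asarray(centres, dtype=float)
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    beta = beta_of(temperature)
    if xi_range is None:
        pad = 3.0 / np.sqrt(beta * spring)
        xi_range = (float(centres.min() - pad), float(centres.max() + pad))
    # warn on coverage gaps: neighbouring centres further apart than ~4
    # bias SDs will leave a hole WHAM cannot bridge
    sd = 1.0 / np.sqrt(beta * spring)
    gaps = np.diff(np.sort(centres))
    if gaps.size and np.any(gaps > 4 * sd):
        import warnings

        warnings.warn("umbrella window centres leave coverage gaps")
    edges = np.linspace(xi_range[0], xi_range[1], n_bins + 1)
    fine = np.linspace(xi_range[0], xi_range[1], 4001)
    u_pot = np.asarray([potential(x) for x in fine], dtype=float)
    rng = np.random.default_rng(seed)
    windows = []
    for c in centres:
        logw = -beta * (u_pot + 0.5 * spring * (fine - c) ** 2)
        logw -= logw.max()
        p = np.exp(logw)
        p /= p.sum()
        idx = rng.choice(fine.size, size=n_per_window, p=p)
        dx = fine[1] - fine[0]
        samples = fine[idx] + rng.uniform(-dx / 2, dx / 2, size=n_per_window)
        counts, _ = np.histogram(samples, bins=edges)
        windows.append(
            UmbrellaWindow(centre=float(c), spring=spring, bin_edges=edges, counts=counts)
        )
    return windows


# ---------------------------------------------------------------------------
# Mutant-screen provider tables
# ---------------------------------------------------------------------------

#: The ten key substrate-recognition residues of the reference
#: methyltransferase (hydrogen-bonding: N170, D218, T42, Y188, N39, R186,
#: N174, R30; hydrophobic: K1, I40).
KEY_SITES: list[MutationSite] = [
    MutationSite(1, "K"),
    MutationSite(30, "R"),
    MutationSite(39, "N"),
    MutationSite(40, "I"),
    MutationSite(42, "T"),
    MutationSite(170, "N"),
    MutationSite(174, "N"),
    MutationSite(186, "R"),
    MutationSite(188, "Y"),
    MutationSite(218, "D"),
]

#: Per-site stability-pass counts and finalist substitutions planted by
#: :func:`gen_screen_table` (the screen's reference study conditions).
PLANTED_STABILITY_COUNTS: dict[int, int] = {1: 8, 39: 9, 40: 11, 42: 17, 174: 9, 218: 9}
PLANTED_FINALISTS: dict[int, tuple[str, float]] = {
    1: ("L", -6.24),
    39: ("G", -5.83),
    40: ("P", -6.43),
    42: ("N", -6.58),
    174: ("D", -7.44),
    218: ("V", -5.10),
}


def gen_screen_table(
    seed: int,
    sites: list[MutationSite] | None = None,
    fold_cut: float = 2.0,
    wt_dG: float = -10.17,
) -> list[Mutant]:
    """Enumerated mutants with planted provider values.

    Stability-passing substitutions per site follow
    :data:`PLANTED_STABILITY_COUNTS` (zero at the remaining sites); each
    passing site's finalist substitution receives its reference binding
    free energy from :data:`PLANTED_FINALISTS` and strictly maximises
    ``dG_bind`` at its site.  Which non-finalist substitutions pass
    stability is drawn per seed.
    """
    rng = np.random.default_rng(seed)
    mutants = enumerate_mutants(sites if sites is not None else list(KEY_SITES))
    by_site: dict[int, list[Mutant]] = {}
    for m in mutants:
        if not m.is_wildtype_reference:
            by_site.setdefault(m.site.res_id, []).append(m)
    for res_id, group in by_site.items():
        n_pass = PLANTED_STABILITY_COUNTS.get(res_id, 0)
        finalist = PLANTED_FINALISTS.get(res_id)
        targets = [m.target for m in group]
        chosen: set[str] = set()
        if n_pass:
            if finalist is not None:
                chosen.add(finalist[0])
            pool = [t for t in targets if t not in chosen]
            extra = rng.choice(len(pool), size=n_pass - len(chosen), replace=False)
            chosen.update(pool[i] for i in extra)
        for m in group:
            if m.target in chosen:
                m.ddG_fold = float(rng.uniform(-0.9 * fold_cut, 0.9 * fold_cut))
                if finalist is not None and m.target == finalist[0]:
                    m.dG_bind = finalist[1]
                else:
                    # strictly below the finalist's dG_bind at this site
                    hi = (finalist[1] if finalist else wt_dG + 4.0) - 0.3
                    m.dG_bind = float(rng.uniform(wt_dG + 0.7, hi))
            else:
                m.ddG_fold = float(rng.uniform(1.3 * fold_cut, 4.0 * fold_cut))
    return mutants
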