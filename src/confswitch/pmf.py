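"""Potential-of-mean-force estimation from nonequilibrium pulling work.

Adaptive steered MD partitions the reaction coordinate xi into segments;
within each segment an ensemble of pulling trajectories accumulates work
W(xi), and the segment free-energy change follows from the Jarzynski
equality

    dG_seg = -(1/beta) * ln < exp(-beta * W_final) >,

evaluated with a log-sum-exp reduction so large beta*W never underflows.
Segment estimates are summed ("stitched") into a continuous profile; the
within-segment shape is taken from the trajectory whose final work lies
closest to the segment's Jarzynski average (the standard ASMD contraction
rule for choosing the next segment's seed).

A one-dimensional WHAM estimator over umbrella-sampling windows is
provided as the complementary equilibrium route to the same profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, KB_KCAL, beta as beta_of
from .errors import ConvergenceError, ParameterError

__all__ = [
    "PullingSpec",
    "WorkEnsemble",
    "PMFProfile",
    "UmbrellaWindow",
    "guiding_energy_force",
    "jarzynski_segment",
    "asmd_stitch",
    "wham_1d",
]


@dataclass
class PullingSpec:
    """Harmonic guiding potential: spring k (kcal/mol/A^2), speed v (A/ns),
    unit pulling direction n, and initial attachment point X0 (A)."""

    k: float
    v: float
    n: np.ndarray
    X0: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.X0 = np.asarray(self.X0, dtype=float)
        if self.k <= 0:
            raise ParameterError("spring constant must be positive")
        if abs(np.linalg.norm(self.n) - 1.0) > 1e-9:
            raise ParameterError("pulling direction must be a unit vector")


@dataclass
class SegmentWork:
    """Work curves of one segment: xi grid plus one row per trajectory."""

    xi: np.ndarray  # (n_points,), increasing, xi[0] = left boundary
    work: np.ndarray  # (n_traj, n_points), work[:,0] == 0

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.work = np.atleast_2d(np.asarray(self.work, dtype=float))
        if self.work.shape[1] != self.xi.size:
            raise ValueError("work rows must match the xi grid")
        if np.any(np.abs(self.work[:, 0]) > 1e-9):
            raise ValueError("work must start at 0 at the segment's left boundary")

    @property
    def final_works(self) -> np.ndarray:
        return self.work[:, -1]


@dataclass
class WorkEnsemble:
    """Per-segment pulling-work ensembles along a partitioned coordinate."""

    segments: list[SegmentWork]
    beta: float  # mol/kcal

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("ensemble needs at least one segment")
        if self.beta <= 0:
            raise ParameterError("beta must be positive")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if abs(prev.xi[-1] - cur.xi[0]) > 1e-9:
                raise ValueError("segment boundaries must be continuous")

    @property
    def boundaries(self) -> np.ndarray:
        return np.array([s.xi[0] for s in self.segments] + [self.segments[-1].xi[-1]])


@dataclass
class PMFProfile:
    xi: np.ndarray
    dG: np.ndarray  # kcal/mol
    segment_dG: np.ndarray | None = None
    seed_indices: list[int] | None = None


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic bias centre/spring and a sample histogram
    over a bin grid shared by all windows."""

    centre: float  # A
    spring: float  # kcal/mol/A^2
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValueError("histogram needs non-negative counts, at least one positive")


def guiding_energy_force(
    spec: PullingSpec, t: float, X_t: np.ndarray
) -> tuple[float, np.ndarray]:
    """Harmonic guiding energy and restoring force at time ``t`` (ns).

    The spring connects the pulled centre to a point moving at speed ``v``
    along ``n``; the lag is ``v*t - (X_t - X0) . n``.  The force on the
    pulled particle has magnitude ``k * |lag|`` and points along ``n``
    toward the schedule point.
    """
    if t < 0:
        raise ParameterError("time must be non-negative")
    X_t = np.asarray(X_t, dtype=float)
    lag = spec.v * t - float((X_t - spec.X0) @ spec.n)
    U = 0.5 * spec.k * lag**2
    F = spec.k * lag * spec.n
    return float(U), F


def jarzynski_segment(works: np.ndarray, beta: float) -> float:
    """Jarzynski free-energy estimate from final work values of one segment."""
    w = np.asarray(works, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("empty work array")
    if beta <= 0:
        raise ParameterError("beta must be positive")
    # -(1/beta) ln( (1/N) sum exp(-beta W) ), stabilised
    return float(-(logsumexp(-beta * w) - np.log(w.size)) / beta)


def asmd_stitch(e: WorkEnsemble) -> PMFProfile:
    """Stitch per-segment Jarzynski estimates into one continuous PMF.

    The within-segment curve is the selected seed trajectory's work curve
    shifted so the profile is continuous; the seed is the trajectory whose
    final work is closest to the segment's Jarzynski average (lowest index
    on ties).
    """
    xi_all: list[np.ndarray] = []
    dg_all: list[np.ndarray] = []
    seg_dG = np.empty(len(e.segments))
    seeds: list[int] = []
    running = 0.0
    for si, seg in enumerate(e.segments):
        dG = jarzynski_segment(seg.final_works, e.beta)
        seg_dG[si] = dG
        gap = np.abs(seg.final_works - dG)
        seed = int(np.argmin(gap))
        seeds.append(seed)
        curve = seg.work[seed] + running
        if si == 0:
            xi_all.append(seg.xi)
            dg_all.append(curve)
        else:  # drop the duplicated boundary point
            xi_all.append(seg.xi[1:])
            dg_all.append(curve[1:])
        running += dG
        # pin the boundary to the cumulative Jarzynski value
        dg_all[-1][-1] = running
    return PMFProfile(
        xi=np.concatenate(xi_all),
        dG=np.concatenate(dg_all),
        segment_dG=seg_dG,
        seed_indices=seeds,
    )


def wham_1d(
    windows: list[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Self-consistent 1D WHAM over umbrella windows sharing one bin grid.

    Iterates the window free energies f_i and unbiased probabilities until
    ``max |delta f| < tol``; the PMF is ``-kB T ln p`` shifted to zero at
    its minimum.  Bins never visited by any window are dropped.
    """
    if not windows:
        raise ValueError("need at least one window")
    beta = beta_of(temperature)
    edges = windows[0].bin_edges
    for w in windows[1:]:
        if not np.allclose(w.bin_edges, edges):
            raise ValueError("all windows must share one bin grid")
    centres = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([w.counts for w in windows])  # (W, B)
    n_i = counts.sum(axis=1)  # samples per window
    total = counts.sum(axis=0)  # (B,)
    visited = total > 0
    if not visited.any():
        raise ValueError("no visited bins")
    # coverage check: every gap between visited bins should be bridged
    vis_idx = np.where(visited)[0]
    if np.any(np.diff(vis_idx) > 1):
        warnings.warn("umbrella windows leave unvisited gaps in the xi range")
    bias = 0.5 * np.array([w.spring for w in windows])[:, None] * (
        centres[None, :] - np.array([w.centre for w in windows])[:, None]
    ) ** 2  # (W, B)
    log_c = np.where(visited, np.log(np.maximum(total, 1)), -np.inf)
    f = np.zeros(len(windows))
    for _ in range(max_iter):
        # log p_b = log total_b - logsumexp_i [ log n_i + beta f_i - beta bias_ib ]
        log_den = logsumexp(
            np.log(n_i)[:, None] + beta * f[:, None] - beta * bias, axis=0
        )
        log_p = np.where(visited, log_c - log_den, -np.inf)
        log_p -= logsumexp(log_p[visited])
        new_f = -(1.0 / beta) * logsumexp(-beta * bias[:, visited] + log_p[None, visited], axis=1)
        new_f -= new_f[0]
        if np.max(np.abs(new_f - f)) < tol:
            f = new_f
            break
        f = new_f
    else:
        raise ConvergenceError(f"WHAM did not converge in {max_iter} iterations")
    pmf = -(1.0 / beta) * log_p[visited]
    pmf -= pmf.min()
    return PMFProfile(xi=centres[visited], dG=pmf)
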