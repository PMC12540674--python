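# Methods

This note documents the models, conventions and numerical choices behind
each stage of the toolkit, what the synthetic generators do and do not
emulate, and the known limitations.

Units throughout: lengths in Å, energies in kcal/mol, temperatures in K,
times in ns (ps for frame timestamps).  The Boltzmann constant is
k_B = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and the Coulomb conversion factor
332.0637 kcal·Å·mol⁻¹·e⁻²; the default temperature is 300 K.

## Structures and superposition

A `Structure` is a flat atom table plus an (n, 3) coordinate array; a
`Trajectory` shares one atom table across frames.  Multi-model PDB is
the trajectory interchange format (read/written through biotite); a CSV
xyz-table (`frame, atom, x, y, z`) is accepted for synthetic data.  PDB
text carries exactly three decimals, so coordinates are rounded to
3 decimals on write and after read — round-trip error is bounded by the
format, not by float32 storage.

Superposition is the Kabsch algorithm (SVD of the cross-covariance,
reflection branch corrected so det(R) = +1).  RMSD/RMSF/clustering/PCA
all operate on a selection defaulting to Cα atoms, mass-unweighted —
the conventional backbone choice; mass weighting changes little for
Cα-only selections and is deliberately not offered.  RMSF superposes
frames onto their converged mean structure (five fixed-point
iterations, ample for the fixtures used) before measuring per-atom
fluctuation.  Note that the rigid-body fit absorbs a 1/n share of any
single atom's displacement, so an isolated atom's RMSF converges to
σ√3 only when it is embedded among many anchor atoms.

## Conformational clustering

Greedy maximal-neighbour clustering: two snapshots are neighbours when
their pairwise RMSD is **at or below** the cutoff (inclusive, default
1.7 Å); the unassigned snapshot with the most unassigned neighbours is
extracted together with them, repeatedly.  Two tie rules make the
procedure fully deterministic: neighbour-count ties resolve to the
lowest snapshot index, and equal-sized clusters keep extraction order.
Each cluster's representative is its lowest-potential-energy member
(index tie-break again).

A caution documented here because it is easy to assume otherwise:
cluster count is **not** monotone in the cutoff.  Greedy extraction can
fragment the remainder, so raising the threshold occasionally increases
the number of clusters on realistic distance matrices.

## Free-energy landscapes

PCA is performed on superposed, flattened selection coordinates
(scikit-learn, full SVD); the first two components serve as reaction
coordinates.  The landscape is the Boltzmann inversion of the
normalised 2D histogram, shifted so the lowest occupied bin is zero.
Empty bins are masked (`NaN` in exports), never given +∞, so grids stay
serialisable; the default grid is 50×50 over the projection range.
Basins are local minima under 8-neighbour connectivity with
steepest-descent membership; plateau ties descend toward the lowest
bin index, so a perfectly uniform grid collapses into a single basin —
the appropriate reading of a landscape with no structure.

## Binding-energy algebra

MM/PBSA rows carry the four interaction components (vacuum
electrostatics ELE_IN, vacuum van der Waals VDW_IN, polar solvation
ELE_PB, nonpolar surface VDW_SA), the enthalpy H and the entropy term
TΔS.  ELE_PB, the reaction-field term of SIE and normal-mode TΔS are
*consumed as inputs* — no PB/BEM solver or normal-mode analysis is
included, these belong to upstream tooling.  The delta row is the
component-wise complex − receptor − ligand difference; ΔH is the sum of
the four components and ΔG = ΔH − TΔS, applied literally with TΔS
stored as printed (negative for the delta of the reference system).

Published per-system enthalpy totals are not the sum of the four
interaction components — they include bonded self-energies that cancel
only in the difference — so the row-level H-consistency check
(|H − Σcomponents| ≤ 0.02, the printed-rounding tolerance) is
meaningful for difference rows and the packaged reference table leaves
per-system H empty.  For the packaged CCoAOMT–CCoA table the computed
ΔG (−10.18) coincides with the experimental reference value rather than
the historically printed calculated one (−8.87); the formula is
computed, never the printed number.

SIE: ΔG_bind = α[E_c + ΔG^R_bind + E_vdw + γ·ΔMSA] + C with the
standard calibration α = 0.1048, D_in = 2.25, ρ = 1.1,
γ = 0.0129 kcal·mol⁻¹·Å⁻², C = −2.89 kcal/mol.  Five of the six
packaged mutant rows recombine to their published scores within 0.01;
the I40P row does not (it recombines to −7.79 against a printed −6.43)
and is treated as an upstream table inconsistency — the component data
are kept, the printed score is not asserted.

Vacuum pair energies use Lorentz–Berthelot-style combination (Rmin sum
of half-radii, geometric-mean ε), no cutoff, and refuse overlapping
atoms below 10⁻⁶ Å.  SASA is Shrake–Rupley with a deterministic
golden-spiral point set (default 960 points, probe 1.4 Å); per-atom
areas sum exactly to the total by construction.

## PMF estimation

The guiding potential is harmonic in the lag between the pulled centre
and a schedule point moving at speed v along the unit direction n:
U = ½k[vt − (X−X₀)·n]², F = k·lag·n.  Defaults mirror standard pulling
protocols (k = 2.5 kcal·mol⁻¹·Å⁻², v = 1 Å/ns).

Segment free energies follow the Jarzynski equality on final works,
evaluated with a log-sum-exp reduction (naïve exponential averaging
underflows once βW ≫ 1).  Segments are stitched by cumulative
summation; the within-segment shape comes from the trajectory whose
final work is closest to the segment's Jarzynski average (lowest index
on ties) — the standard ASMD contraction rule for re-seeding — with the
boundary value pinned to the cumulative estimate so the profile is
continuous and the total equals the sum of segment estimates exactly.
Finite ensembles carry the usual Jarzynski small-sample statistics: for
Gaussian work of SD σ and N tracks the total estimate has a bias of
order βσ²/2N per segment and an SD near σ√(N_seg)/√N, ≈0.25 kcal/mol
for the 5-segment × 25-track, σ = 0.5 reference protocol.

WHAM solves the standard self-consistent equations over windows sharing
one bin grid, in log space, to a window-free-energy tolerance of 10⁻⁶
(default, max 10⁵ iterations); never-visited bins are dropped and
unbridged gaps raise a coverage warning.  Both estimators are provided
because both routes (nonequilibrium work and equilibrium umbrella
sampling) are in common use for channel-entry PMFs; they agree within
sampling error on the planted double-well fixture.

## Pore profiling

At each station along a straight user-supplied axis, the profiler
maximises the clearance min_i(|p − x_i| − r_i) over centres p in the
perpendicular plane, restricted to a search disc (planar HOLE-style
variant; full 3D sphere wandering is out of scope).  Optimisation is a
vectorised coarse grid (default 0.5 Å) followed by pattern-search
refinement down to 0.02 Å; the clearance is piecewise-smooth and
concave near an interior optimum, so grid-then-refine is reliable
there.  Negative optima flag the station "blocked".  Two practical
cautions: keep the search disc smaller than the channel wall radius or
the optimiser will legitimately escape an open-sided pore, and remember
that a steep taper lets *neighbouring* rings govern a station's
clearance (for coaxial ring fixtures the own-ring value R − r_vdw is
exact only while (ΔR)² + Δz² ≥ R², which sets the generator's default
ring spacing of 4 Å against tapers up to ~0.5 Å per station).

## Mutant screening

Each key residue enumerates 19 substitutions plus one wild-type
reference entry (so ten sites give 200 entries; references are carried
through but excluded from verdict counts).  Stage 1 keeps
|ΔΔG_fold| ≤ 2 kcal/mol (inclusive), stage 2 keeps
ΔΔG_bind = ΔG_bind − ΔG_bind(wt) ≥ 2 kcal/mol (inclusive), with the
wild-type reference binding free energy defaulting to −10.17 kcal/mol
(configurable).  The finalist at each passing site is the mutant with
maximal ΔG_bind — the weakest binder, i.e. the most effective activity
reduction that still folds — with ties to the alphabetically first
target.  ΔΔG_fold and mutant ΔG_bind come from pluggable providers
(CSV tables, SIE scoring, or the synthetic generator); no structural
modelling of mutants is performed.

## Synthetic data: what it does and does not show

Every generator takes an explicit integer seed and is bit-reproducible;
none touches global RNG state.

* **Multi-basin trajectories** draw frames from isotropic Gaussians
  about distinct reference conformations.  This plants exact cluster
  labels and occupancies but has none of the kinetics, anisotropy or
  slow collective modes of real protein dynamics — recovery tests
  validate the clustering/FEL machinery, not its behaviour on subtle,
  overlapping conformational states.
* **Work ensembles** draw final works as N(ΔG + βσ²/2, σ²), the unique
  Gaussian consistent with the Jarzynski identity at the planted ΔG, so
  recovery targets are analytic.  The drag/noise parameters only shape
  the monotone within-segment accumulation.  Real pulling work is
  neither Gaussian nor monotone; the fixture validates the averaging
  and stitching algebra, not robustness to heavy-tailed work.
* **MM/PBSA tables** add independent Gaussian noise per component and
  system around means whose difference is the planted delta; real
  snapshot components are strongly correlated in time.
* **Channel fixtures** are coaxial atom rings with analytically known
  inscribed radii (see the taper caveat above).
* **Umbrella windows** are sampled by grid-based inverse-CDF from the
  exact biased Boltzmann density (deterministic per seed, exact up to
  the 4001-point discretisation), avoiding rejection-rate pathologies
  for stiff biases.
* **Screen provider tables** plant the reference per-site
  stability-pass counts (8/9/11/17/9/9 at K1/N39/I40/T42/N174/D218,
  zero at the other four sites) and give each passing site's finalist
  its published SIE binding free energy, strictly maximal at its site;
  which non-finalist substitutions pass is seed-dependent.

Problem sizes in the test suite and acceptance script (300–600-frame
trajectories of 20 pseudo-atoms, 5×25 work tracks, 12 windows × 5000
samples, 5–7-ring channels) are chosen so planted parameters are
recoverable at their stated tolerances with the estimators' known
sampling error; they are desk-scale stand-ins, not reproductions of
production simulation campaigns (10⁴-snapshot trajectories of a full
enzyme), whose headline observables depend on the original trajectories.

## Known limitations

* No PB/GB or boundary-element solver, no normal-mode entropy, no
  force-field parsing, no MD/docking engine: all such quantities are
  inputs.
* The pore axis is straight and user-supplied; no curved or adaptive
  axis.
* The screen handles single-point mutants only; no combinatorial
  multi-site designs.
* WHAM is 1D; no 2D umbrella unbiasing, no time-lagged (kinetic)
  embedding in the landscape analysis.
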