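"""Exhaustive single-point mutant enumeration and the dual free-energy screen
for low-activity enzyme candidates.

Each key residue is substituted by the 19 other canonical amino acids and
accompanied by one wild-type reference entry (20 entries per site).  The
screen keeps a mutant when

  1. its folding-stability change is small, ``|ddG_fold| <= fold_cut``
     (basic function preserved), and
  2. its binding free energy to the substrate is substantially weakened,
     ``ddG_bind = dG_bind(mutant) - dG_bind(wild type) >= bind_cut``.

Both thresholds are inclusive and default to 2 kcal/mol.  Per passing
site, the finalist is the mutant with the weakest binding (maximal
dG_bind); ties go to the alphabetically first target residue.  Folding
ddG and mutant dG_bind values come from pluggable providers (a CSV table,
SIE scoring over supplied components, or the synthetic generator) — no
structural modelling is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ProviderError

__all__ = [
    "AMINO_ACIDS",
    "MutationSite",
    "Mutant",
    "ScreenResult",
    "enumerate_mutants",
    "ddg_bind",
    "dual_criterion_screen",
    "mutant_sequences",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default wild-type binding free energy of the reference system (kcal/mol),
#: the experimentally anchored CCoAOMT-CCoA value.
DEFAULT_WT_DG_BIND = -10.17


@dataclass(frozen=True)
class MutationSite:
    res_id: int
    wild_type: str
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.wild_type not in AMINO_ACIDS:
            raise ValueError(f"wild type {self.wild_type!r} is not a canonical amino acid")


@dataclass
class Mutant:
    site: MutationSite
    target: str
    is_wildtype_reference: bool = False
    ddG_fold: float | None = None
    dG_bind: float | None = None
    ddG_bind: float | None = None

    def __post_init__(self) -> None:
        if self.target not in AMINO_ACIDS:
            raise ValueError(f"target {self.target!r} is not a canonical amino acid")

    @property
    def name(self) -> str:
        return f"{self.site.wild_type}{self.site.res_id}{self.target}"


@dataclass
class ScreenResult:
    mutants: list[Mutant]
    stability_pass: list[Mutant]
    affinity_pass: list[Mutant]
    finalists: list[Mutant]
    counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        stab = {id(m) for m in self.stability_pass}
        aff = {id(m) for m in self.affinity_pass}
        fin = {id(m) for m in self.finalists}
        rows = []
        for m in self.mutants:
            rows.append(
                {
                    "site": m.site.res_id,
                    "chain": m.site.chain,
                    "wt": m.site.wild_type,
                    "target": m.target,
                    "is_reference": m.is_wildtype_reference,
                    "ddG_fold": m.ddG_fold,
                    "dG_bind": m.dG_bind,
                    "ddG_bind": m.ddG_bind,
                    "stability_pass": id(m) in stab,
                    "affinity_pass": id(m) in aff,
                    "finalist": id(m) in fin,
                }
            )
        return pd.DataFrame(rows)


def enumerate_mutants(sites: list[MutationSite]) -> list[Mutant]:
    """All 19 substitutions plus one wild-type reference entry per site."""
    if not sites:
        raise ValueError("site list is empty")
    seen = set()
    for s in sites:
        key = (s.chain, s.res_id)
        if key in seen:
            raise ValueError(f"duplicate site {s.chain}{s.res_id}")
        seen.add(key)
    out: list[Mutant] = []
    for s in sites:
        out.append(Mutant(site=s, target=s.wild_type, is_wildtype_reference=True))
        for aa in AMINO_ACIDS:
            if aa != s.wild_type:
                out.append(Mutant(site=s, target=aa))
    return out


def ddg_bind(mut_dG: float, wt_dG: float) -> float:
    """Binding free-energy change of a mutant relative to wild type."""
    return mut_dG - wt_dG


def dual_criterion_screen(
    mutants: list[Mutant],
    fold_cut: float = 2.0,
    bind_cut: float = 2.0,
    wt_dG: float = DEFAULT_WT_DG_BIND,
) -> ScreenResult:
    """Two-stage screen: stability first, then weakened binding.

    Wild-type reference entries are carried through untouched and excluded
    from all verdict counts.  Stage 1 requires ``|ddG_fold| <= fold_cut``;
    stage 2 requires ``ddG_bind >= bind_cut`` (filled in from ``dG_bind``
    and ``wt_dG`` when absent).  Finalists are the per-site maximisers of
    ``dG_bind`` among affinity-passing mutants.
    """
    candidates = [m for m in mutants if not m.is_wildtype_reference]
    for m in candidates:
        if m.ddG_fold is None:
            raise ProviderError(f"{m.name}: no ddG_fold provided")
    stability = [m for m in candidates if abs(m.ddG_fold) <= fold_cut]
    for m in stability:
        if m.dG_bind is None:
            raise ProviderError(f"{m.name}: no dG_bind provided")
        if m.ddG_bind is None:
            m.ddG_bind = ddg_bind(m.dG_bind, wt_dG)
    affinity = [m for m in stability if m.ddG_bind >= bind_cut]
    finalists: list[Mutant] = []
    by_site: dict[tuple[str, int], list[Mutant]] = {}
    for m in affinity:
        by_site.setdefault((m.site.chain, m.site.res_id), []).append(m)
    for key in sorted(by_site):
        best = max(by_site[key], key=lambda m: (m.dG_bind, -ord(m.target)))
        # ties on dG_bind resolve to the alphabetically first target
        finalists.append(best)
    per_site_stability = {}
    for m in stability:
        per_site_stability[m.site.res_id] = per_site_stability.get(m.site.res_id, 0) + 1
    counts = {
        "enumerated": len(mutants),
        "candidates": len(candidates),
        "stability_pass": len(stability),
        "affinity_pass": len(affinity),
        "finalists": len(finalists),
        "stability_pass_per_site": per_site_stability,
    }
    return ScreenResult(
        mutants=mutants,
        stability_pass=stability,
        affinity_pass=affinity,
        finalists=finalists,
        counts=counts,
    )


def mutant_sequences(
    wild_type: str, finalists: list[Mutant], offset: int = 1
) -> dict[str, str]:
    """Apply each finalist's single substitution to the wild-type sequence.

    ``offset`` is the residue number of the first sequence position.
    Returns a mapping from mutant name (e.g. ``K1L``) to full sequence.
    """
    out: dict[str, str] = {}
    for m in finalists:
        pos = m.site.res_id - offset
        if pos < 0 or pos >= len(wild_type):
            raise ValueError(f"{m.name}: residue {m.site.res_id} outside sequence")
        if wild_type[pos] != m.site.wild_type:
            raise ValueError(
                f"{m.name}: sequence has {wild_type[pos]!r} at position "
                f"{m.site.res_id}, expected {m.site.wild_type!r}"
            )
        out[m.name] = wild_type[:pos] + m.target + wild_type[pos + 1 :]
    return out
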