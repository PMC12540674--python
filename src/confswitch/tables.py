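"""CSV schemas for energy tables, work ensembles, umbrella windows and
mutant tables, plus the packaged reference tables for the CCoAOMT-CCoA
system.

Schemas (all plain CSV with a header row):

* MM/PBSA rows:   label, ELE_IN, VDW_IN, ELE_PB, VDW_SA, H, TdS
* SIE rows:       label, E_c, dG_R_bind, E_vdw, dMSA [, dG_bind]
* Work ensemble:  segment, trajectory, xi, W
* Umbrella CSV:   window, centre, spring, bin_left, bin_right, count
* Mutant table:   site, chain, wt, target, is_reference, ddG_fold, dG_bind
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Mutant, MutationSite
from .energetics import MMPBSARow, SIEComponents
from .errors import SchemaError
from .pmf import SegmentWork, UmbrellaWindow, WorkEnsemble

__all__ = [
    "read_mmpbsa_rows",
    "write_mmpbsa_rows",
    "read_sie_rows",
    "read_work_ensemble",
    "write_work_ensemble",
    "read_umbrella_windows",
    "write_umbrella_windows",
    "read_mutant_table",
    "write_mutant_table",
    "reference_mmpbsa_rows",
    "reference_sie_rows",
]

_MMPBSA_COLS = ("ELE_IN", "VDW_IN", "ELE_PB", "VDW_SA", "H", "TdS")


def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{what} table missing columns {sorted(missing)}")


def read_mmpbsa_rows(path: str | Path) -> dict[str, MMPBSARow]:
    df = pd.read_csv(path)
    _require(df, ("label",), "MM/PBSA")
    rows: dict[str, MMPBSARow] = {}
    for _, rec in df.iterrows():
        kwargs = {
            c: (float(rec[c]) if c in df.columns and pd.notna(rec[c]) else None)
            for c in _MMPBSA_COLS
        }
        rows[str(rec["label"])] = MMPBSARow(label=str(rec["label"]), **kwargs)
    return rows


def write_mmpbsa_rows(rows: list[MMPBSARow], path: str | Path) -> None:
    recs = []
    for r in rows:
        recs.append({"label": r.label, **{c: getattr(r, c) for c in _MMPBSA_COLS}})
    pd.DataFrame(recs).to_csv(path, index=False)


def read_sie_rows(path: str | Path) -> dict[str, SIEComponents]:
    df = pd.read_csv(path)
    _require(df, ("label", "E_c", "dG_R_bind", "E_vdw", "dMSA"), "SIE")
    return {
        str(rec["label"]): SIEComponents(
            label=str(rec["label"]),
            E_c=float(rec["E_c"]),
            dG_R_bind=float(rec["dG_R_bind"]),
            E_vdw=float(rec["E_vdw"]),
            dMSA=float(rec["dMSA"]),
        )
        for _, rec in df.iterrows()
    }


def read_work_ensemble(path: str | Path, beta: float) -> WorkEnsemble:
    df = pd.read_csv(path)
    _require(df, ("segment", "trajectory", "xi", "W"), "work-ensemble")
    segments = []
    for seg_id in sorted(df["segment"].unique()):
        sub = df[df["segment"] == seg_id]
        xi = np.sort(sub["xi"].unique())
        trajs = sorted(sub["trajectory"].unique())
        work = np.empty((len(trajs), xi.size))
        for k, tr in enumerate(trajs):
            cur = sub[sub["trajectory"] == tr].sort_values("xi")
            if len(cur) != xi.size:
                raise SchemaError(
                    f"segment {seg_id} trajectory {tr}: xi grid mismatch"
                )
            work[k] = cur["W"].to_numpy()
        segments.append(SegmentWork(xi=xi, work=work))
    return WorkEnsemble(segments=segments, beta=beta)


def write_work_ensemble(e: WorkEnsemble, path: str | Path) -> None:
    recs = []
    for si, seg in enumerate(e.segments):
        for ti in range(seg.work.shape[0]):
            for xi, w in zip(seg.xi, seg.work[ti]):
                recs.append({"segment": si, "trajectory": ti, "xi": xi, "W": w})
    pd.DataFrame(recs).to_csv(path, index=False)


def read_umbrella_windows(path: str | Path) -> list[UmbrellaWindow]:
    df = pd.read_csv(path)
    _require(df, ("window", "centre", "spring", "bin_left", "bin_right", "count"), "umbrella")
    windows = []
    for wid in sorted(df["window"].unique()):
        sub = df[df["window"] == wid].sort_values("bin_left")
        edges = np.append(sub["bin_left"].to_numpy(), sub["bin_right"].iloc[-1])
        windows.append(
            UmbrellaWindow(
                centre=float(sub["centre"].iloc[0]),
                spring=float(sub["spring"].iloc[0]),
                bin_edges=edges,
                counts=sub["count"].to_numpy(dtype=float),
            )
        )
    return windows


def write_umbrella_windows(windows: list[UmbrellaWindow], path: str | Path) -> None:
    recs = []
    for wid, w in enumerate(windows):
        for b in range(w.counts.size):
            recs.append(
                {
                    "window": wid,
                    "centre": w.centre,
                    "spring": w.spring,
                    "bin_left": w.bin_edges[b],
                    "bin_right": w.bin_edges[b + 1],
                    "count": w.counts[b],
                }
            )
    pd.DataFrame(recs).to_csv(path, index=False)


def read_mutant_table(path: str | Path) -> list[Mutant]:
    df = pd.read_csv(path)
    _require(df, ("site", "wt", "target"), "mutant")
    out = []
    for _, rec in df.iterrows():
        site = MutationSite(
            res_id=int(rec["site"]),
            wild_type=str(rec["wt"]),
            chain=str(rec["chain"]) if "chain" in df.columns else "A",
        )
        out.append(
            Mutant(
                site=site,
                target=str(rec["target"]),
                is_wildtype_reference=bool(rec.get("is_reference", False)),
                ddG_fold=float(rec["ddG_fold"])
                if "ddG_fold" in df.columns and pd.notna(rec["ddG_fold"])
                else None,
                dG_bind=float(rec["dG_bind"])
                if "dG_bind" in df.columns and pd.notna(rec["dG_bind"])
                else None,
            )
        )
    return out


def write_mutant_table(mutants: list[Mutant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site": m.site.res_id,
                "chain": m.site.chain,
                "wt": m.site.wild_type,
                "target": m.target,
                "is_reference": m.is_wildtype_reference,
                "ddG_fold": m.ddG_fold,
                "dG_bind": m.dG_bind,
                "ddG_bind": m.ddG_bind,
            }
            for m in mutants
        ]
    ).to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("confswitch.data").joinpath(name)


def reference_mmpbsa_rows() -> dict[str, MMPBSARow]:
    """Published MM/PBSA component table for the CCoAOMT-CCoA system
    (complex, receptor and ligand rows; kcal/mol)."""
    with resources.as_file(_data_path("mmpbsa_ccoaomt_ccoa.csv")) as p:
        return read_mmpbsa_rows(p)


def reference_sie_rows() -> dict[str, SIEComponents]:
    """Published SIE component table for the six low-activity candidate
    mutants of CCoAOMT (kcal/mol; dMSA in A^2)."""
    with resources.as_file(_data_path("sie_mutants_ccoaomt.csv")) as p:
        return read_sie_rows(p)
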