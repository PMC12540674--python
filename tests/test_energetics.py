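"""MM/PBSA algebra, SIE scoring, decomposition ranking, pair energies, SASA."""

import numpy as np
import pandas as pd
import pytest

from confswitch.constants import COULOMB_KCAL
from confswitch.energetics import (
    MMPBSARow,
    ResidueEnergyTable,
    SIEComponents,
    SIEParams,
    aggregate_snapshots,
    binding_energy,
    mmpbsa_delta,
    rank_residue_contributions,
    sasa,
    sie_score,
    vacuum_interaction_energy,
)
from confswitch.errors import SchemaError
from confswitch.tables import reference_mmpbsa_rows, reference_sie_rows

from conftest import simple_structure


class TestMMPBSADelta:
    def test_reference_table_deltas(self):
        rows = reference_mmpbsa_rows()
        delta = mmpbsa_delta(rows["complex"], rows["receptor"], rows["ligand"])
        assert delta.ELE_IN == pytest.approx(-78.80, abs=0.02)
        assert delta.VDW_SA == pytest.approx(-7.36, abs=0.02)
        assert delta.VDW_IN == pytest.approx(-54.05, abs=0.02)
        assert delta.ELE_PB == pytest.approx(103.03, abs=0.02)
        assert delta.TdS == pytest.approx(-27.01, abs=0.02)

    def test_zero_delta_when_additive(self):
        rec = MMPBSARow("r", ELE_IN=-5.0, VDW_IN=1.0)
        lig = MMPBSARow("l", ELE_IN=-2.0, VDW_IN=0.5)
        com = MMPBSARow("c", ELE_IN=-7.0, VDW_IN=1.5)
        delta = mmpbsa_delta(com, rec, lig)
        assert delta.ELE_IN == 0.0 and delta.VDW_IN == 0.0

    def test_field_set_mismatch(self):
        with pytest.raises(SchemaError):
            mmpbsa_delta(
                MMPBSARow("c", ELE_IN=1.0),
                MMPBSARow("r", ELE_IN=1.0, VDW_IN=2.0),
                MMPBSARow("l", ELE_IN=1.0),
            )

    def test_linearity(self, rng):
        vals = rng.normal(size=(3, 4))
        def row(label, v, s=1.0):
            return MMPBSARow(label, ELE_IN=s * v[0], VDW_IN=s * v[1], ELE_PB=s * v[2], VDW_SA=s * v[3])
        d1 = mmpbsa_delta(row("c", vals[0]), row("r", vals[1]), row("l", vals[2]))
        d3 = mmpbsa_delta(row("c", vals[0], 3.0), row("r", vals[1], 3.0), row("l", vals[2], 3.0))
        for f in ("ELE_IN", "VDW_IN", "ELE_PB", "VDW_SA"):
            assert getattr(d3, f) == pytest.approx(3.0 * getattr(d1, f), abs=1e-9)

    def test_h_consistency_guard(self):
        with pytest.raises(ValueError):
            MMPBSARow("x", ELE_IN=1.0, VDW_IN=1.0, ELE_PB=1.0, VDW_SA=1.0, H=10.0)


class TestBindingEnergy:
    def test_reference_delta_dh_dg(self):
        rows = reference_mmpbsa_rows()
        delta = mmpbsa_delta(rows["complex"], rows["receptor"], rows["ligand"])
        dH, dG = binding_energy(delta)
        assert dH == pytest.approx(-37.18, abs=0.02)
        # dG = dH - TdS with TdS = -27.01: the enthalpy/entropy split gives
        # a net spontaneous binding free energy
        assert dG == pytest.approx(-10.17, abs=0.02)

    def test_explicit_components(self):
        delta = MMPBSARow("Delta", ELE_IN=-78.8, VDW_IN=-54.05, ELE_PB=103.03, VDW_SA=-7.36, TdS=-27.01)
        dH, dG = binding_energy(delta)
        assert dH == pytest.approx(-37.18, abs=1e-9)
        assert dG == pytest.approx(-10.17, abs=1e-9)

    def test_all_zero(self):
        delta = MMPBSARow("Delta", ELE_IN=0.0, VDW_IN=0.0, ELE_PB=0.0, VDW_SA=0.0, TdS=0.0)
        assert binding_energy(delta) == (0.0, 0.0)

    def test_missing_component(self):
        with pytest.raises(SchemaError):
            binding_energy(MMPBSARow("Delta", ELE_IN=1.0))


class TestAggregate:
    def test_mean_and_sd(self):
        rows = [MMPBSARow("s", ELE_IN=v) for v in (1.0, 2.0, 3.0)]
        mean, sd = aggregate_snapshots(rows, "sys")
        assert mean.ELE_IN == pytest.approx(2.0)
        assert sd.ELE_IN == pytest.approx(np.std([1, 2, 3]))

    def test_single_row_sd_zero(self):
        mean, sd = aggregate_snapshots([MMPBSARow("s", ELE_IN=5.0)], "sys")
        assert sd.ELE_IN == 0.0


class TestSIE:
    def test_reference_mutants(self):
        # the five self-consistent published rows recombine to the printed
        # binding free energies within 0.01 kcal/mol
        printed = {"K1L": -6.24, "N39G": -5.83, "T42N": -6.58, "N174D": -7.44, "D218V": -5.10}
        rows = reference_sie_rows()
        for label, expected in printed.items():
            assert sie_score(rows[label]) == pytest.approx(expected, abs=0.01)

    def test_zero_components_give_offset(self):
        c = SIEComponents("null", E_c=0.0, dG_R_bind=0.0, E_vdw=0.0, dMSA=0.0)
        assert sie_score(c) == pytest.approx(-2.89)

    def test_affine_slopes_by_finite_difference(self):
        p = SIEParams()
        base = SIEComponents("b", E_c=-10.0, dG_R_bind=5.0, E_vdw=-20.0, dMSA=-500.0)
        f0 = sie_score(base, p)
        for field_name, slope in (
            ("E_c", p.alpha),
            ("dG_R_bind", p.alpha),
            ("E_vdw", p.alpha),
            ("dMSA", p.alpha * p.gamma),
        ):
            kwargs = {f: getattr(base, f) for f in ("E_c", "dG_R_bind", "E_vdw", "dMSA")}
            kwargs[field_name] += 1.0
            bumped = SIEComponents("b", **kwargs)
            assert sie_score(bumped, p) - f0 == pytest.approx(slope, abs=1e-12)

    def test_non_finite_component_rejected(self):
        with pytest.raises(ValueError):
            SIEComponents("bad", E_c=np.nan, dG_R_bind=0.0, E_vdw=0.0, dMSA=0.0)


class TestResidueRanking:
    def make_table(self, totals):
        rng = np.random.default_rng(0)
        rows = []
        for i, tot in enumerate(totals):
            parts = rng.dirichlet(np.ones(4)) * tot
            rows.append(
                {
                    "residue": f"R{i}",
                    "E_VDW": parts[0],
                    "E_ELE": parts[1],
                    "E_GB": parts[2],
                    "E_GBSUR": parts[3],
                    "total": tot,
                }
            )
        return ResidueEnergyTable(pd.DataFrame(rows))

    def test_single_residue(self):
        t = self.make_table([-1.0])
        assert rank_residue_contributions(t, 5)["residue"].tolist() == ["R0"]

    def test_matches_argsort_oracle(self, rng):
        totals = rng.normal(size=20)
        t = self.make_table(totals)
        ranked = rank_residue_contributions(t, 10)["residue"].tolist()
        oracle = [f"R{i}" for i in np.argsort(totals, kind="stable")[:10]]
        assert ranked == oracle

    def test_n_clamped_to_table(self):
        t = self.make_table([-1.0, -2.0])
        assert len(rank_residue_contributions(t, 99)) == 2

    def test_empty_table_rejected(self):
        t = ResidueEnergyTable(
            pd.DataFrame(columns=["residue", "E_VDW", "E_ELE", "E_GB", "E_GBSUR", "total"])
        )
        with pytest.raises(ValueError):
            rank_residue_contributions(t)


class TestVacuumEnergies:
    def pair(self, r, q1=1.0, q2=-1.0, rmin_half=1.9, eps=0.1):
        a = simple_structure(np.array([[0.0, 0.0, 0.0]]))
        b = simple_structure(np.array([[r, 0.0, 0.0]]))
        lj = np.array([[rmin_half, eps]])
        return vacuum_interaction_energy(a, b, [q1], [q2], lj, lj)

    def test_coulomb_pair_hand_value(self):
        e_ele, _ = self.pair(3.0)
        assert e_ele == pytest.approx(-COULOMB_KCAL / 3.0, abs=1e-3)
        assert e_ele == pytest.approx(-110.688, abs=1e-3)

    def test_lj_minimum_identity(self):
        rmin_half, eps = 1.9, 0.25
        _, e_vdw = self.pair(2 * rmin_half, rmin_half=rmin_half, eps=eps)
        assert e_vdw == pytest.approx(-eps, abs=1e-12)

    def test_long_range_decay(self):
        e_ele, e_vdw = self.pair(1e3)
        assert abs(e_ele) <= 1e-3 * COULOMB_KCAL / 1e3 * 1e3  # 0.332 kcal/mol
        assert abs(e_ele) < 0.5 and abs(e_vdw) <= 1e-3

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            self.pair(1e-9)

    def test_parameter_coverage_checked(self):
        a = simple_structure(np.zeros((2, 3)))
        b = simple_structure(np.array([[3.0, 0.0, 0.0]]))
        with pytest.raises(SchemaError):
            vacuum_interaction_energy(a, b, [1.0], [1.0], np.ones((1, 2)), np.ones((1, 2)))


class TestSASA:
    def test_isolated_atom_sphere_area(self):
        s = simple_structure(np.zeros((1, 3)), radii=np.array([1.6]))
        total, per_atom = sasa(s)
        assert total == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)

    def test_distant_atoms_additive(self):
        s = simple_structure(
            np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]]), radii=np.array([1.6, 1.2])
        )
        total, per_atom = sasa(s)
        expected = 4 * np.pi * (3.0**2 + 2.6**2)
        assert total == pytest.approx(expected, rel=0.01)
        assert per_atom.sum() == pytest.approx(total)

    def test_two_sphere_overlap_cap_formula(self):
        # inflated radii R1 = R2 = 3.0, centre distance d = 4.0: each sphere
        # loses a cap of height h = R - d/2
        R, d = 3.0, 4.0
        s = simple_structure(
            np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), radii=np.array([1.6, 1.6])
        )
        total, _ = sasa(s, n_points=2000)
        h = R - d / 2
        expected = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)
        assert total == pytest.approx(expected, rel=0.02)

    def test_point_count_convergence(self, rng):
        coords = rng.uniform(0, 8, size=(20, 3))
        s = simple_structure(coords, radii=np.full(20, 1.7))
        t960, _ = sasa(s, n_points=960)
        t4000, _ = sasa(s, n_points=4000)
        assert abs(t960 - t4000) / t4000 <= 0.005

    def test_missing_radii_rejected(self):
        s = simple_structure(np.zeros((1, 3)))
        with pytest.raises(SchemaError):
            sasa(s)
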