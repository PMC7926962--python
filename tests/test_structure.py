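"""Superposition, reaction-coordinate measurements, state classification,
the key-residue rule and binding-mode analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import phmd
from phmd.structure import (
    CDRMap,
    StructureError,
    StructureModel,
    binding_modes,
    brrmsd,
    classify_states,
    d3_distance,
    extract_states,
    filter_states,
    kabsch_superpose,
    key_residue_pairs,
    load_example_state_table,
    superposed_rmsd,
)


def brute_force_rmsd_z(mobile, reference, step_deg=1.0):
    """Centroid superposition + 1-degree grid search over z rotations."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    best = math.inf
    for deg in np.arange(0.0, 360.0, step_deg):
        r = Rotation.from_euler("z", deg, degrees=True).as_matrix()
        rmsd = math.sqrt(np.mean(np.sum((mob @ r.T - ref) ** 2, axis=1)))
        best = min(best, rmsd)
    return best


def place_residue(records, chain, resseq, origin, resname="GLY"):
    for atom, element, off in (("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)), ("C", "C", (2.0, 1.2, 0))):
        records.append({
            "chain": chain, "resseq": resseq, "resname": resname, "atom_name": atom,
            "element": element, "x": origin[0] + off[0], "y": origin[1] + off[1], "z": origin[2] + off[2],
        })


class TestKabsch:
    def test_identity_and_pure_translation(self, rng):
        pts = rng.normal(size=(10, 3))
        _, _, r0 = kabsch_superpose(pts, pts)
        assert r0 == pytest.approx(0.0, abs=1e-9)
        rot, trans, r1 = kabsch_superpose(pts + np.array([5.0, 5.0, 5.0]), pts)
        assert r1 == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_rotation_is_proper(self, rng):
        mob = rng.normal(size=(6, 3))
        ref = rng.normal(size=(6, 3))
        rot, _, _ = kabsch_superpose(mob, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_rotation_grid(self):
        """Optimal RMSD of a perturbed, 90-degree-rotated planar 4-point set
        agrees with a 1-degree brute-force in-plane rotation search within
        1e-3 A (planar set + in-plane perturbation keep the optimum in the
        searched subgroup)."""
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [1.0, 1.0, 0]])
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        rng = np.random.default_rng(5)
        noise = rng.normal(0.0, 0.1, size=ref.shape)
        noise[:, 2] = 0.0
        mobile = ref @ rot90.T + noise + np.array([2.0, -1.0, 0.0])
        exact = superposed_rmsd(mobile, ref)
        brute = brute_force_rmsd_z(mobile, ref)
        assert exact <= brute + 1e-12
        assert abs(exact - brute) < 1e-3

    def test_rejects_mismatch_and_degenerate(self):
        with pytest.raises(StructureError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(StructureError):
            kabsch_superpose(line, line + 1.0)


class TestBRRMSD:
    def test_reference_frame_is_zero(self, mini_fab):
        assert phmd.minifab_brrmsd(mini_fab, mini_fab.reference) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_displacement_has_known_rmsd(self):
        """A displacement orthogonal to all rigid-body modes leaves the
        optimal superposition at identity; RMSD equals the displacement."""
        ref = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        delta = 0.05
        mobile = ref + np.array([[0, 0, delta], [0, 0, delta], [0, 0, -delta], [0, 0, -delta]])
        assert superposed_rmsd(mobile, ref) == pytest.approx(delta, rel=1e-3)

    def test_region_order_is_irrelevant(self, fab_complex):
        a = brrmsd(fab_complex, fab_complex, regions=("HCDR2", "HCDR3", "LCDR1", "LCDR2", "LCDR3"))
        b = brrmsd(fab_complex, fab_complex, regions=("LCDR3", "HCDR3", "LCDR2", "HCDR2", "LCDR1"))
        assert a == b == pytest.approx(0.0, abs=1e-9)

    @given(angle=st.floats(0.0, 2 * math.pi), shift=st.floats(-20.0, 20.0))
    def test_rigid_body_invariance(self, mini_fab, angle, shift):
        rot = Rotation.from_rotvec([0.3 * angle, angle, 0.1]).as_matrix()
        moved = mini_fab.reference @ rot.T + shift
        assert phmd.minifab_brrmsd(mini_fab, moved) == pytest.approx(0.0, abs=1e-7)
        assert phmd.minifab_d3(mini_fab, moved) == pytest.approx(
            phmd.minifab_d3(mini_fab), abs=1e-7)


class TestD3:
    def test_hand_value_from_region_centers(self):
        records = []
        cdr = CDRMap()
        # HCDR3 residues with single atoms at (0,0,0) and (2,0,0); LCDR3 at
        # (1,4,0) and (1,6,0) -> COMs (1,0,0) and (1,5,0), distance 5
        for resseq, pos in ((99, (0.0, 0, 0)), (100, (2.0, 0, 0))):
            records.append({"chain": "H", "resseq": resseq, "resname": "GLY", "atom_name": "CA",
                            "element": "C", "x": pos[0], "y": pos[1], "z": pos[2]})
        for resseq, pos in ((89, (1.0, 4.0, 0)), (90, (1.0, 6.0, 0))):
            records.append({"chain": "L", "resseq": resseq, "resname": "GLY", "atom_name": "CA",
                            "element": "C", "x": pos[0], "y": pos[1], "z": pos[2]})
        model = StructureModel.from_records(records)
        assert d3_distance(model, cdr) == pytest.approx(5.0)

    def test_identical_regions_give_zero(self, mini_fab):
        m = phmd.make_mini_fab(seed=1, loop_separation=10.0)
        coords = m.reference.copy()
        coords[m.loops["LCDR3-like"]] = coords[m.loops["HCDR3-like"]]
        assert phmd.minifab_d3(m, coords) == pytest.approx(0.0, abs=1e-12)


class TestStateTables:
    def test_ph74_table_filter_and_first_area(self):
        table = load_example_state_table(7.4)
        low = filter_states(table, pmf_cutoff=50.0)
        assert len(low) == 13
        area = filter_states(low, brrmsd_range=(1.0, 1.5), d3_range=(11.0, 13.0))
        assert len(area) == 5

    def test_ph74_classification_counts(self):
        low = filter_states(load_example_state_table(7.4), pmf_cutoff=50.0)
        counts = classify_states(low)
        assert counts.binder_like == 5

    def test_ph6_classification_counts(self):
        low = filter_states(load_example_state_table(6.0), pmf_cutoff=50.0)
        assert len(low) == 21  # printed rows, incl. the duplicated index
        assert classify_states(low).binder_like == 0

    def test_strict_pmf_cutoff(self):
        table = load_example_state_table(7.4)
        assert len(filter_states(table, pmf_cutoff=0.0)) == 0
        assert len(filter_states(table, pmf_cutoff=np.inf)) == len(table)

    def test_empty_table_classifies_to_zero(self):
        counts = classify_states(pd.DataFrame(columns=["brrmsd", "d3", "pmf"]))
        assert (counts.binder_like, counts.non_binder_like, counts.indeterminate) == (0, 0, 0)

    def test_extract_states_from_grid(self, rng):
        from phmd.reweighting import reweight_cumulant2

        df = pd.DataFrame({
            "rc1": rng.uniform(0.5, 3.5, 8000),
            "rc2": rng.uniform(10.0, 16.0, 8000),
            "dv": 0.0,
        })
        edges = (np.arange(0.0, 4.1, 0.5), np.arange(10.0, 17.0, 1.0))
        grid = reweight_cumulant2(df, edges)
        table = extract_states(grid, pmf_cutoff=50.0)
        assert set(table.columns) == {"brrmsd", "d3", "pmf"}
        assert (table["pmf"] < 50.0).all()
        assert (table["pmf"] >= 0.0).all()
        assert not table.duplicated(["brrmsd", "d3"]).any()
        assert len(extract_states(grid, pmf_cutoff=0.0)) == 0


class TestKeyResidueRule:
    def residue_grid(self):
        records = []
        place_residue(records, "H", 99, (0.0, 0.0, 0.0))       # HCDR3
        place_residue(records, "L", 89, (0.0, 8.0, 0.0))       # LCDR3, 8 A away
        place_residue(records, "L", 24, (0.0, 0.0, 10.0))      # LCDR1, exactly 10 A
        place_residue(records, "H", 100, (3.0, 0.0, 0.0))      # same region as 99
        place_residue(records, "H", 50, (40.0, 0.0, 0.0))      # HCDR2, far
        return StructureModel.from_records(records)

    def test_reports_pair_below_cutoff_only(self):
        pairs = key_residue_pairs(self.residue_grid())
        tagged = set(zip(pairs["region1"], pairs["region2"]))
        assert ("HCDR3", "LCDR3") in tagged or ("LCDR3", "HCDR3") in tagged
        # exactly 10.0 A is excluded (strict inequality)
        assert not any("LCDR1" in t for t in tagged)

    def test_same_region_pairs_never_reported(self):
        pairs = key_residue_pairs(self.residue_grid())
        assert not ((pairs["region1"] == pairs["region2"])).any()

    def test_monotone_in_cutoff(self):
        small = key_residue_pairs(self.residue_grid(), cutoff=9.0)
        large = key_residue_pairs(self.residue_grid(), cutoff=12.0)
        assert len(large) >= len(small)
        small_keys = set(map(tuple, small[["region1", "resseq1", "region2", "resseq2"]].to_numpy()))
        large_keys = set(map(tuple, large[["region1", "resseq1", "region2", "resseq2"]].to_numpy()))
        assert small_keys <= large_keys

    def test_rejects_nonpositive_cutoff(self):
        with pytest.raises(ValueError):
            key_residue_pairs(self.residue_grid(), cutoff=0.0)


class TestBindingModes:
    def test_far_antigen_yields_all_null(self):
        fab = phmd.make_fab_fixture(phmd.FabLayout(include_antigen=True, antigen_offset=50.0))
        for record in binding_modes(fab):
            assert record.is_null
            assert record.format() == "Null"

    def test_contact_above_cutoff_not_reported(self):
        # single-atom residues so the closest heavy-atom pair is exactly 4.5 A
        records = [
            {"chain": "H", "resseq": 103, "resname": "GLY", "atom_name": "CA",
             "element": "C", "x": 0.0, "y": 0.0, "z": 0.0},
            {"chain": "L", "resseq": 89, "resname": "GLY", "atom_name": "CA",
             "element": "C", "x": 0.0, "y": 30.0, "z": 0.0},
            {"chain": "A", "resseq": 1, "resname": "GLU", "atom_name": "CA",
             "element": "C", "x": 0.0, "y": -4.5, "z": 0.0},
        ]
        model = StructureModel.from_records(records)
        assert all(r.is_null for r in binding_modes(model))
        hit = binding_modes(model, contact_cutoff=5.0)
        assert any(not r.is_null for r in hit)

    def test_missing_chain_error_names_chain(self, fab_only):
        with pytest.raises(StructureError, match="chain A"):
            binding_modes(fab_only)
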