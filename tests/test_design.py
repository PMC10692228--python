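"""Design engine: enumeration, constraints, scores, sampling, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covbinder.design import (
    CovalentConstraint,
    DesignError,
    DesignTask,
    ModelRecord,
    UnsupportedNucleophileError,
    constraint_score,
    enumerate_positions,
    filter_complexes,
    interface_bb_rmsd,
    interface_score,
    make_covalent_constraints,
    mutate_ligand_cysteines_to_serine,
    sample_models,
    select_designs,
)
from covbinder.geometry import ca_distance
from covbinder.structure import AtomRecord, ResidueRecord, StructureComplex, select_residue

from conftest import ca_only_complex


class TestEnumerate:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_equals_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        cx = ca_only_complex(rng)
        target = ("A", int(rng.integers(1, 6)))
        got = enumerate_positions(cx, target, cutoff=14.0)
        target_res = select_residue(cx, *target)
        expected = sorted(
            r.seq_number
            for r in cx.ligand_residues
            if ca_distance(target_res, r) < 14.0
        )
        assert got == expected

    def test_toy_ground_truth(self, toy):
        cx, truth = toy
        assert enumerate_positions(cx, truth.target) == truth.within_cutoff_positions

    def test_strictly_less_than_cutoff(self):
        residues = [
            ResidueRecord("A", 1, "LYS", [AtomRecord("CA", "C", np.zeros(3))]),
            ResidueRecord("B", 1, "ALA", [AtomRecord("CA", "C", np.array([14.0, 0, 0]))]),
            ResidueRecord("B", 2, "ALA", [AtomRecord("CA", "C", np.array([13.999, 0, 0]))]),
        ]
        cx = StructureComplex(["A"], "B", residues)
        assert enumerate_positions(cx, ("A", 1)) == [2]


def _complex_with_ligand_ca(near_far_positions):
    """Receptor with a 'near' residue at origin and a 'far' residue at +30x;
    ligand CAs given as (distance-from-near, distance-from-far) pairs
    realized on the x axis."""
    residues = [
        ResidueRecord("A", 1, "LYS", [AtomRecord("CA", "C", np.zeros(3))]),
        ResidueRecord("A", 2, "CYS", [AtomRecord("CA", "C", np.array([30.0, 0, 0]))]),
    ]
    for i, (d_near, d_far) in enumerate(near_far_positions):
        # place on the x axis: x = d_near must satisfy 30 - x = d_far
        assert abs((30.0 - d_near) - d_far) < 1e-9
        residues.append(
            ResidueRecord("B", i + 1, "ALA", [AtomRecord("CA", "C", np.array([d_near, 0, 0]))])
        )
    return StructureComplex(["A"], "B", residues)


class TestFilterComplexes:
    NEAR = (("A", 1), 14.0)
    FAR = (("A", 2), 12.0)

    def test_near_and_clear_is_kept(self):
        cx = _complex_with_ligand_ca([(10.0, 20.0)])
        assert filter_complexes([cx], near=self.NEAR, far=self.FAR) == [cx]

    def test_too_close_to_far_ref_is_excluded(self):
        cx = _complex_with_ligand_ca([(10.0, 20.0), (19.0, 11.0)])
        assert filter_complexes([cx], near=self.NEAR, far=self.FAR) == []

    def test_far_boundary_is_inclusive_exclusion(self):
        # exactly 12.0 from the far reference fails the "> 12" requirement
        cx = _complex_with_ligand_ca([(10.0, 20.0), (18.0, 12.0)])
        assert filter_complexes([cx], near=self.NEAR, far=self.FAR) == []

    def test_nothing_near_is_excluded(self):
        cx = _complex_with_ligand_ca([(16.0, 14.0)])
        assert filter_complexes([cx], near=self.NEAR, far=self.FAR) == []


class TestConstraints:
    def test_lysine_target_pairs(self, toy):
        cx, truth = toy
        task = DesignTask(
            complex=cx, target=truth.target, position=truth.planted_position, n_models=1
        )
        c1, c2 = make_covalent_constraints(task)
        assert c1.real_atom[1] == "CZ" and c1.virtual_anchor[1] == "VCM"
        assert c2.real_atom[1] == "NZ" and c2.virtual_anchor[1] == "VNZ"
        assert c1.x0 == 0.0 and c1.sd == 0.3

    def test_cysteine_target_pairs(self, toy_cys):
        cx, truth = toy_cys
        task = DesignTask(
            complex=cx, target=truth.target, position=truth.planted_position, n_models=1
        )
        c1, c2 = make_covalent_constraints(task)
        assert c2.real_atom[1] == "SG"

    def test_non_nucleophile_target(self, toy):
        cx, truth = toy
        ala_num = truth.target[1] + 1  # neighbouring poly-ALA residue
        task = DesignTask(
            complex=cx, target=(truth.target[0], ala_num),
            position=truth.planted_position, n_models=1,
        )
        with pytest.raises(UnsupportedNucleophileError):
            make_covalent_constraints(task)


def _coords(*entries):
    return {key: np.asarray(pos, dtype=float) for key, pos in entries}


CST = [
    CovalentConstraint(((("B"), 1), "CZ"), ((("A"), 9), "VCM")),
    CovalentConstraint(((("A"), 9), "NZ"), ((("B"), 1), "VNZ")),
]


class TestConstraintScore:
    def test_ideal_adduct_is_zero(self):
        coords = _coords(
            (("B", 1, "CZ"), [0, 0, 0]), (("A", 9, "VCM"), [0, 0, 0]),
            (("A", 9, "NZ"), [5, 5, 5]), (("B", 1, "VNZ"), [5, 5, 5]),
        )
        assert constraint_score(coords, CST) == 0.0

    def test_single_pair_at_sd(self):
        coords = _coords(
            (("B", 1, "CZ"), [0.3, 0, 0]), (("A", 9, "VCM"), [0, 0, 0]),
            (("A", 9, "NZ"), [5, 5, 5]), (("B", 1, "VNZ"), [5, 5, 5]),
        )
        assert constraint_score(coords, CST) == pytest.approx(1.0)

    def test_both_pairs_at_sd_is_exactly_two(self):
        coords = _coords(
            (("B", 1, "CZ"), [0.3, 0, 0]), (("A", 9, "VCM"), [0, 0, 0]),
            (("A", 9, "NZ"), [0.3, 5, 5]), (("B", 1, "VNZ"), [0, 5, 5]),
        )
        score = constraint_score(coords, CST)
        assert score == pytest.approx(2.0)
        assert not score < 2.0  # the strict filter rejects the boundary

    def test_monotone_along_a_ray(self):
        previous = -1.0
        for d in np.linspace(0.0, 2.0, 21):
            coords = _coords(
                (("B", 1, "CZ"), [d, 0, 0]), (("A", 9, "VCM"), [0, 0, 0]),
                (("A", 9, "NZ"), [5, 5, 5]), (("B", 1, "VNZ"), [5, 5, 5]),
            )
            score = constraint_score(coords, CST)
            assert score > previous or (score == 0.0 and previous < 0)
            previous = score


def _pair_complex():
    residues = [
        ResidueRecord("A", 1, "ALA", [AtomRecord("CB", "C", np.zeros(3))]),
        ResidueRecord("B", 1, "ALA", [AtomRecord("CB", "C", np.array([3.4, 0, 0]))]),
    ]
    return StructureComplex(["A"], "B", residues)


class TestInterfaceScore:
    def test_empty_interface_is_zero(self):
        cx = _pair_complex()
        coords = {
            ("A", 1, "CB"): np.zeros(3),
            ("B", 1, "CB"): np.array([50.0, 0.0, 0.0]),
        }
        assert interface_score(coords, cx) == 0.0

    def test_single_cc_pair_at_radius_sum_is_minimum(self):
        cx = _pair_complex()
        coords = {
            ("A", 1, "CB"): np.zeros(3),
            ("B", 1, "CB"): np.array([3.4, 0.0, 0.0]),  # C radius 1.7 + 1.7
        }
        # closed form: eps * ((rmin/d)^12 - 2 (rmin/d)^6) at d = rmin -> -eps
        assert interface_score(coords, cx) == pytest.approx(-0.1, abs=1e-12)
        # any other separation scores higher
        for d in (3.0, 3.2, 3.8, 4.5):
            coords[("B", 1, "CB")] = np.array([d, 0.0, 0.0])
            assert interface_score(coords, cx) > -0.1

    def test_close_contact_capped_at_ten(self):
        cx = _pair_complex()
        coords = {
            ("A", 1, "CB"): np.zeros(3),
            ("B", 1, "CB"): np.array([0.5, 0.0, 0.0]),
        }
        assert interface_score(coords, cx) == pytest.approx(10.0)


class TestInterfaceBbRmsd:
    def test_model_equals_template(self, toy):
        cx, _ = toy
        coords = {
            (r.chain_id, r.seq_number, a.name): a.position
            for r in cx.residues
            for a in r.atoms
        }
        assert interface_bb_rmsd(coords, cx) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_ligand_shift_reads_as_its_magnitude(self, toy):
        cx, _ = toy
        shift = np.array([1.0, 0.0, 0.0])
        coords = {}
        for r in cx.residues:
            for a in r.atoms:
                pos = a.position + shift if r.chain_id == cx.ligand_chain else a.position
                coords[(r.chain_id, r.seq_number, a.name)] = pos
        assert interface_bb_rmsd(coords, cx) == pytest.approx(1.0, abs=1e-6)

    def test_single_displaced_interface_residue_hand_value(self, toy):
        cx, truth = toy
        # displace all four backbone atoms of one interface residue by 2 A
        target_pos = truth.within_cutoff_positions[0]
        coords = {}
        n_interface_bb = 0
        for r in cx.residues:
            for a in r.atoms:
                coords[(r.chain_id, r.seq_number, a.name)] = a.position
        from covbinder.design import EmptyInterfaceError  # noqa: F401

        rec_heavy = np.asarray(
            [a.position for r in cx.receptor_residues for a in r.heavy_atoms()]
        )
        interface = []
        for res in cx.ligand_residues:
            pts = np.asarray([a.position for a in res.heavy_atoms()])
            if ((pts[:, None, :] - rec_heavy[None, :, :]) ** 2).sum(-1).min() < 64.0:
                interface.append(res)
        res0 = interface[0]
        for name in ("N", "CA", "C", "O"):
            coords[(res0.chain_id, res0.seq_number, name)] = res0.atom_position(name) + np.array(
                [0.0, 0.0, 2.0]
            )
        n_interface_bb = sum(
            1 for r in interface for nm in ("N", "CA", "C", "O") if r.get_atom(nm)
        )
        got = interface_bb_rmsd(coords, cx)
        # receptor superposition is identity (receptor untouched), so
        # rmsd = sqrt(4 * 2^2 / n_backbone_atoms)
        expected = np.sqrt(4 * 4.0 / n_interface_bb)
        assert got == pytest.approx(expected, abs=1e-3)


class TestSampling:
    def test_seed_determinism_bitwise(self, toy):
        cx, truth = toy
        task = dict(complex=cx, target=truth.target, position=truth.planted_position,
                    stereo="MCR", n_models=4, seed=11)
        s1 = [(m.constraint_score, m.interface_score) for m in sample_models(DesignTask(**task))]
        s2 = [(m.constraint_score, m.interface_score) for m in sample_models(DesignTask(**task))]
        assert s1 == s2

    def test_stereoisomer_exhaustive(self, toy):
        cx, truth = toy
        task = DesignTask(complex=cx, target=truth.target, position=truth.planted_position,
                          stereo="both", n_models=3, seed=5)
        models = sample_models(task)
        tags = [m.stereo for m in models]
        assert tags.count("MCR") == 3 and tags.count("MCS") == 3

    def test_ideal_adduct_reachable(self, toy):
        cx, truth = toy
        task = DesignTask(complex=cx, target=truth.target, position=truth.planted_position,
                          stereo="both", n_models=20, seed=3)
        models = sample_models(task)
        assert min(m.constraint_score for m in models) < 2.0

    def test_unreachable_target_flagged_not_raised(self, toy):
        cx, truth = toy
        far = cx.copy()
        for r in far.ligand_residues:
            r.atoms = [a.moved_to(a.position + np.array([40.0, 0, 0])) for a in r.atoms]
        task = DesignTask(complex=far, target=truth.target, position=truth.planted_position,
                          stereo="MCR", n_models=2, seed=0)
        models = sample_models(task)
        assert all(m.unsatisfiable for m in models)

    def test_scores_invariant_under_rigid_transform(self, toy):
        from scipy.spatial.transform import Rotation

        cx, truth = toy
        rot = Rotation.from_euler("zyx", [17.0, -33.0, 120.0], degrees=True).as_matrix()
        shift = np.array([5.0, -8.0, 2.5])
        moved = cx.copy()
        for r in moved.residues:
            r.atoms = [a.moved_to(a.position @ rot.T + shift) for a in r.atoms]
        kw = dict(target=truth.target, position=truth.planted_position,
                  stereo="MCR", n_models=2, seed=4)
        ref = sample_models(DesignTask(complex=cx, **kw))
        got = sample_models(DesignTask(complex=moved, **kw))
        for a, b in zip(ref, got):
            assert b.constraint_score == pytest.approx(a.constraint_score, abs=1e-6)
            assert b.interface_score == pytest.approx(a.interface_score, abs=1e-6)


def _fake_model(idx, cst, iface, rmsd=0.0, stereo="MCR", position=1):
    return ModelRecord(
        coordinates={},
        constraint_score=cst,
        interface_score=iface,
        clash_score=0.0,
        interface_bb_rmsd=rmsd,
        stereo=stereo,
        model_index=idx,
        position=position,
    )


class TestSelect:
    def test_top10_with_exactly_three_passing(self):
        models = []
        # 3 models pass both filters, the rest fail the constraint filter
        for i in range(20):
            passing = i in (2, 5, 9)
            models.append(
                _fake_model(i, cst=0.5 if passing else 5.0, iface=float(i))
            )
        report = select_designs(models)
        assert len(report.entries) == 10
        assert report.n_passing == 3
        assert [e.model_index for e in report.entries] == list(range(10))

    def test_boundary_constraint_fails_strictly(self):
        report = select_designs([_fake_model(0, cst=2.0, iface=-1.0)])
        assert report.n_passing == 0

    def test_all_failing_report_nonempty(self):
        report = select_designs([_fake_model(i, cst=10.0, iface=float(i)) for i in range(4)])
        assert len(report.entries) == 4 and report.n_passing == 0

    def test_empty_input_raises(self):
        with pytest.raises(DesignError):
            select_designs([])

    def test_tie_break_by_constraint_then_index(self):
        models = [
            _fake_model(3, cst=1.5, iface=0.0),
            _fake_model(1, cst=0.5, iface=0.0),
            _fake_model(0, cst=0.5, iface=0.0),
        ]
        report = select_designs(models)
        assert [e.model_index for e in report.entries] == [0, 1, 3]


class TestCysToSer:
    def test_other_cysteines_become_serine(self, toy):
        cx, truth = toy
        mutated = cx.copy()
        # plant an extra cysteine elsewhere in the ligand
        other = [r for r in mutated.ligand_residues
                 if r.seq_number != truth.planted_position][0]
        other.name = "CYS"
        other.atoms = other.atoms + [AtomRecord("SG", "S", other.atom_position("CB") + 1.0)]
        out = mutate_ligand_cysteines_to_serine(mutated, keep_position=truth.planted_position)
        kept = select_residue(out, out.ligand_chain, truth.planted_position)
        converted = select_residue(out, out.ligand_chain, other.seq_number)
        assert kept.name == "CYS"
        assert converted.name == "SER"
        assert converted.get_atom("OG") is not None and converted.get_atom("SG") is None
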