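"""Superposition, interface definitions, I-RMSD, f_non-nat, SASA, CDR RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dockbench.fixtures import FixtureSpec, generate_toy_case
from dockbench.metrics import (
    CDRAnnotation,
    ResidueMap,
    cdr_rmsd,
    contacts,
    delta_asa,
    f_non_nat,
    framework_block_ranges,
    i_rmsd,
    interface_residues,
    kabsch_superpose,
    mapped_rmsd,
    sasa,
)
from dockbench.structure import AtomRecord, Chain, ChainRole, ComplexCase, Residue, StructureModel


def rigid(coords, angle_deg=0.0, axis=(0, 0, 1), shift=(0, 0, 0)):
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis, float))
    return rot.apply(coords) + np.asarray(shift, float)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    points = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.4, 1.2]])

    def test_identity_fit(self):
        sup = kabsch_superpose(self.points, self.points)
        assert sup.fit_rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self):
        moved = rigid(self.points, angle_deg=90, shift=(5, -3, 2))
        sup = kabsch_superpose(self.points, moved)
        assert sup.fit_rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.apply(moved), self.points, atol=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        sup = kabsch_superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_displaced_point_matches_numeric_optimizer(self):
        """One displaced point: our closed-form fit equals brute-force
        minimization over rotations (scipy align_vectors as independent
        route, refined against a random-search floor)."""
        b = self.points.copy()
        b[3] += (0.5, -0.2, 0.3)
        sup = kabsch_superpose(self.points, b)

        rot, rssd = Rotation.align_vectors(
            self.points - self.points.mean(0), b - b.mean(0)
        )
        oracle = rssd / np.sqrt(len(b))
        assert sup.fit_rmsd == pytest.approx(oracle, abs=1e-9)

        rng = np.random.default_rng(1)
        bc = b - b.mean(0)
        ac = self.points - self.points.mean(0)
        best = min(
            np.sqrt(np.mean(np.sum((Rotation.random(random_state=rng).apply(bc) - ac) ** 2, axis=1)))
            for _ in range(2000)
        )
        assert sup.fit_rmsd <= best + 1e-3

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(self.points[:2], self.points[:2])
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


# ---------------------------------------------------------------------------
# mapped RMSD
# ---------------------------------------------------------------------------

def test_mapped_rmsd_zero_on_self(unperturbed_toy):
    model = unperturbed_toy.case.bound
    rmap = ResidueMap.from_models(model, model)
    assert mapped_rmsd(model, model, rmap) == pytest.approx(0.0, abs=1e-9)


def test_mapped_rmsd_invariant_under_rigid_motion(unperturbed_toy):
    bound = unperturbed_toy.case.antibody_model()
    moved = bound.copy()
    for chain in moved.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = rigid(atom.coords, angle_deg=117, axis=(1, 2, 3), shift=(4, 5, 6))
    rmap = ResidueMap.from_models(bound, moved)
    assert mapped_rmsd(bound, moved, rmap) == pytest.approx(0.0, abs=1e-6)


def test_mapped_rmsd_hinge_matches_independent_optimizer(unperturbed_toy):
    """Half the chain rotated about a hinge: compare our value against a
    fit computed by scipy's independent rotation-alignment routine."""
    toy = generate_toy_case(FixtureSpec(perturbation="hinge_rotation", magnitude=25.0, seed=31))
    bound = toy.case.antibody_model()
    unbound = toy.case.unbound_antibody[0]
    rmap = ResidueMap.from_models(bound, unbound)
    ours = mapped_rmsd(bound, unbound, rmap)

    a = np.array([r.ca.coords for r in bound.chain("H").residues])
    b = np.array([r.ca.coords for r in unbound.chain("H").residues])
    rot, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
    assert ours == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-6)
    assert ours > 0.1


def test_mapped_rmsd_rejects_tiny_maps(unperturbed_toy):
    model = unperturbed_toy.case.bound
    full = ResidueMap.from_models(model, model)
    with pytest.raises(ValueError, match="empty"):
        mapped_rmsd(model, model, ResidueMap(pairs=[]))
    with pytest.raises(ValueError, match="at least 3"):
        mapped_rmsd(model, model, ResidueMap(pairs=full.pairs[:1]))


# ---------------------------------------------------------------------------
# interface residues and contacts
# ---------------------------------------------------------------------------

def _point_case(separation):
    def one_res_chain(cid, x, role):
        return Chain(id=cid, role=role, residues=[
            Residue(name="ALA", number=1,
                    atoms=[AtomRecord("CA", "C", np.array([x, 0.0, 0.0])),
                           AtomRecord("N", "N", np.array([x, 1.0, 0.0])),
                           AtomRecord("C", "C", np.array([x, 0.0, 1.0]))])
        ])
    model = StructureModel(id="pair", chains=[
        one_res_chain("H", 0.0, ChainRole.SINGLE_DOMAIN),
        one_res_chain("A", separation, ChainRole.ANTIGEN),
    ])
    return ComplexCase(case_id="pair", bound=model,
                       antibody_chain_ids=["H"], antigen_chain_ids=["A"])


def test_far_apart_chains_have_empty_interface_and_contacts():
    case = _point_case(60.0)
    iface = interface_residues(case)
    assert iface.antibody_side == set() and iface.antigen_side == set()
    assert len(contacts(case)) == 0


def test_cutoff_definition_on_single_residue_pair():
    case = _point_case(8.0)
    iface = interface_residues(case, cutoff=10.0)
    assert iface.antibody_side == {("H", 1, "")}
    assert iface.antigen_side == {("A", 1, "")}
    assert len(contacts(case, cutoff=5.0)) == 0  # 8 A apart: not a contact


def _brute_force_pairs(case, cutoff):
    out = set()
    for ab_cid in case.antibody_chain_ids:
        for ra in case.bound.chain(ab_cid).residues:
            for ag_cid in case.antigen_chain_ids:
                for rb in case.bound.chain(ag_cid).residues:
                    hit = any(
                        np.linalg.norm(x.coords - y.coords) <= cutoff
                        for x in ra.heavy_atoms()
                        for y in rb.heavy_atoms()
                    )
                    if hit:
                        out.add(((ab_cid, ra.number, ra.insertion_code),
                                 (ag_cid, rb.number, rb.insertion_code)))
    return out


@pytest.mark.parametrize("seed", [41, 42, 43])
def test_interface_and_contacts_equal_brute_force(seed):
    toy = generate_toy_case(FixtureSpec(n_antibody=25, n_antigen=25, seed=seed))
    case = toy.case
    expected10 = _brute_force_pairs(case, 10.0)
    iface = interface_residues(case, 10.0)
    assert iface.antibody_side == {p[0] for p in expected10}
    assert iface.antigen_side == {p[1] for p in expected10}
    expected5 = _brute_force_pairs(case, 5.0)
    assert contacts(case, 5.0).pairs == expected5


def test_contacts_are_subset_of_interface(shifted_toy):
    case = shifted_toy.case
    iface = interface_residues(case, 10.0)
    for ab_key, ag_key in contacts(case, 5.0).pairs:
        assert ab_key in iface.antibody_side
        assert ag_key in iface.antigen_side


def test_interface_requires_atoms_on_both_sides():
    case = _point_case(8.0)
    case.bound.chain("A").residues = []
    with pytest.raises(ValueError, match="no heavy atoms"):
        interface_residues(case)


# ---------------------------------------------------------------------------
# I-RMSD and f_non-nat
# ---------------------------------------------------------------------------

def test_i_rmsd_zero_when_unbound_equals_bound(unperturbed_toy):
    case = unperturbed_toy.case
    for side in ("antibody", "antigen", "combined"):
        assert i_rmsd(case, side) == pytest.approx(0.0, abs=1e-6)


def test_i_rmsd_matches_construction_magnitude(shifted_toy):
    case = shifted_toy.case
    expected = shifted_toy.expected
    assert i_rmsd(case, "antibody") == pytest.approx(expected["i_rmsd_antibody"], abs=1e-3)
    assert i_rmsd(case, "antigen") == pytest.approx(expected["i_rmsd_antigen"], abs=1e-3)
    assert i_rmsd(case, "combined") == pytest.approx(expected["i_rmsd_combined"], abs=1e-3)


def test_i_rmsd_is_side_local():
    toy = generate_toy_case(
        FixtureSpec(perturbation="rigid_shift", magnitude=2.0, perturb_side="antibody", seed=51)
    )
    assert i_rmsd(toy.case, "antigen") == pytest.approx(0.0, abs=1e-6)
    assert i_rmsd(toy.case, "antibody") == pytest.approx(2.0, abs=1e-3)
    combined = i_rmsd(toy.case, "combined")
    assert 0.0 < combined < 2.0
    assert combined == pytest.approx(toy.expected["i_rmsd_combined"], abs=1e-3)


def test_f_non_nat_zero_on_identical_conformations(unperturbed_toy):
    assert f_non_nat(unperturbed_toy.case) == 0.0


def test_f_non_nat_bounds_and_large_shift(shifted_toy):
    value = f_non_nat(shifted_toy.case)
    assert 0.0 < value <= 1.0


def test_f_non_nat_requires_native_contacts():
    case = _point_case(60.0)
    case.unbound_antibody = [case.antibody_model()]
    case.unbound_antigen = [case.antigen_model()]
    with pytest.raises(ValueError, match="no contacts"):
        f_non_nat(case)


def test_f_non_nat_matches_independent_recount(shifted_toy):
    """Dual route: recompute f_non-nat with scipy's rotation alignment and
    a brute-force O(N^2) contact scan, then compare with the pipeline."""
    case = shifted_toy.case
    native = _brute_force_pairs(case, 5.0)
    iface10 = _brute_force_pairs(case, 10.0)

    placed = {}
    for side, chain_ids, unbound in (
        ("ab", case.antibody_chain_ids, case.unbound_antibody[0]),
        ("ag", case.antigen_chain_ids, case.unbound_antigen[0]),
    ):
        keys = {p[0] for p in iface10} if side == "ab" else {p[1] for p in iface10}
        bound_ca, unbound_ca = [], []
        for key in sorted(keys):
            cid, num, icode = key
            res_b = case.bound.chain(cid).residue_by_id((num, icode))
            res_u = unbound.chain(cid).residue_by_id((num, icode))
            bound_ca.append(res_b.ca.coords)
            unbound_ca.append(res_u.ca.coords)
        bound_ca, unbound_ca = np.array(bound_ca), np.array(unbound_ca)
        rot, _ = Rotation.align_vectors(bound_ca - bound_ca.mean(0),
                                        unbound_ca - unbound_ca.mean(0))
        atoms = []
        for chain in unbound.chains:
            for res in chain.residues:
                for atom in res.heavy_atoms():
                    moved = rot.apply(atom.coords - unbound_ca.mean(0)) + bound_ca.mean(0)
                    atoms.append(((chain.id, res.number, res.insertion_code), moved))
        placed[side] = atoms

    model_pairs = {
        (ka, kb)
        for ka, xa in placed["ab"]
        for kb, xb in placed["ag"]
        if np.linalg.norm(xa - xb) <= 5.0
    }
    assert model_pairs, "shifted fixture should still form contacts"
    oracle = len(model_pairs - native) / len(model_pairs)
    assert f_non_nat(case) == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_single_atom_sasa_matches_sphere_area():
    from biotite.structure.info import vdw_radius_single

    model = StructureModel(id="c1", chains=[
        Chain(id="A", residues=[
            Residue(name="ALA", number=1,
                    atoms=[AtomRecord("CA", "C", np.zeros(3))])
        ])
    ])
    _, total = sasa(model, probe=1.4, n_points=960)
    r = vdw_radius_single("C") + 1.4
    analytic = 4 * np.pi * r**2
    assert total == pytest.approx(analytic, rel=0.01)


def test_overlapping_atoms_occlude_each_other():
    def single(x):
        return Residue(name="ALA", number=int(x) + 1,
                       atoms=[AtomRecord("CA", "C", np.array([x, 0.0, 0.0]))])

    apart = StructureModel(id="m", chains=[Chain(id="A", residues=[single(0), single(50)])])
    close = StructureModel(id="m", chains=[Chain(id="A", residues=[single(0), single(1)])])
    _, area_apart = sasa(apart)
    _, area_close = sasa(close)
    assert area_close < area_apart


def test_sasa_point_density_convergence(unperturbed_toy):
    model = unperturbed_toy.case.bound
    _, coarse = sasa(model, n_points=960)
    _, fine = sasa(model, n_points=1920)
    assert abs(fine - coarse) / fine < 0.005


def test_unknown_element_is_an_error():
    model = StructureModel(id="x", chains=[
        Chain(id="A", residues=[
            Residue(name="UNK", number=1,
                    atoms=[AtomRecord("Q1", "Xx", np.zeros(3))])
        ])
    ])
    with pytest.raises(ValueError, match="Xx"):
        sasa(model)


def test_delta_asa_vanishes_for_separated_chains():
    case = _point_case(60.0)
    assert abs(delta_asa(case, n_points=960)) < 1.0


def test_delta_asa_positive_for_contacting_fixture(unperturbed_toy):
    value = delta_asa(unperturbed_toy.case, n_points=480)
    assert value > 0
    # convergence against a higher point density
    fine = delta_asa(unperturbed_toy.case, n_points=1920)
    assert value == pytest.approx(fine, rel=0.02)


# ---------------------------------------------------------------------------
# CDR RMSD and framework blocks
# ---------------------------------------------------------------------------

def test_cdr_rmsd_zero_on_identical_structures(unperturbed_toy):
    values = cdr_rmsd(unperturbed_toy.case, unperturbed_toy.annotation)
    for v in values.values():
        assert v == pytest.approx(0.0, abs=1e-6)


def test_cdr3_translation_recovered_exactly():
    toy = generate_toy_case(FixtureSpec(perturbation="cdr_displacement", magnitude=2.0, seed=71))
    values = cdr_rmsd(toy.case, toy.annotation)
    assert values["H.CDR1"] == pytest.approx(0.0, abs=1e-3)
    assert values["H.CDR2"] == pytest.approx(0.0, abs=1e-3)
    assert values["H.CDR3"] == pytest.approx(2.0, abs=1e-3)


def test_missing_cdr_reported_none_others_computed(unperturbed_toy):
    case = unperturbed_toy.case
    annotation = CDRAnnotation(ranges={"H": {"CDR1": (10, 14), "CDR2": (25, 29),
                                             "CDR3": (200, 210)}})
    values = cdr_rmsd(case, annotation)
    assert values["H.CDR3"] is None
    assert values["H.CDR1"] == pytest.approx(0.0, abs=1e-6)


def test_cdr3_annotation_is_mandatory():
    with pytest.raises(ValueError, match="CDR3"):
        CDRAnnotation(ranges={"H": {"CDR1": (10, 14)}})


def test_framework_block_ranges():
    heavy = framework_block_ranges("heavy")
    light = framework_block_ranges(ChainRole.LIGHT)
    assert len(heavy) == 4 and heavy[0] == (6, 22) and heavy[-1] == (106, None)
    assert len(light) == 4 and light[0] == (7, 20) and light[-1] == (101, None)
    with pytest.raises(ValueError):
        framework_block_ranges("antigen")
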