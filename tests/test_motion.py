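"""Superposition, domain rotation, twist–swing split, displacements."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ribometrics.errors import DegenerateInputError, InsufficientPairsError
from ribometrics.model_io import AtomicModel, SelectionSpec
from ribometrics.motion import (displacement, domain_rotation, kabsch,
                                load_domain_definitions, min_distance,
                                pair_atoms, swivel_tilt_decompose,
                                twist_swing)
from ribometrics.synthetic import ToySpec, make_helix_model, make_two_domain_pair


def _rot(axis, deg):
    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(np.radians(deg) * axis / np.linalg.norm(axis))


# ------------------------------------------------------------------ pairing

def test_pair_atoms_identical_models_pair_everything():
    m = make_helix_model(12, "rna_P_trace")
    a, b, n = pair_atoms(m, m)
    assert n == 12
    np.testing.assert_allclose(a, b)


def test_pair_atoms_missing_residues_reduce_count():
    m = make_helix_model(12, "rna_P_trace")
    truncated = m.with_atoms([x for x in m if x.residue_number > 4])
    _, _, n = pair_atoms(m, truncated)
    assert n == 8


def test_pair_atoms_order_independent():
    """Shuffled atom order in model_b pairs the same atoms (brute-force check)."""
    m = make_helix_model(12, "rna_P_trace")
    rng = np.random.default_rng(5)
    order = rng.permutation(len(m.atoms))
    shuffled = m.with_atoms([m.atoms[i] for i in order])
    a1, b1, _ = pair_atoms(m, m)
    a2, b2, _ = pair_atoms(m, shuffled)
    np.testing.assert_allclose(a1, a2)
    np.testing.assert_allclose(b1, b2)


def test_pair_atoms_too_few_raises():
    m = make_helix_model(2, "rna_P_trace")
    with pytest.raises(InsufficientPairsError):
        pair_atoms(m, m)


# ------------------------------------------------------------------ kabsch

def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(20, 3))
    t = kabsch(pts, pts)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-10)
    assert t.angle_deg == pytest.approx(0.0, abs=1e-8)
    assert t.rmsd == pytest.approx(0.0, abs=1e-10)


def test_kabsch_recovers_applied_transform_exactly():
    pts = np.random.default_rng(1).normal(size=(30, 3))
    R = _rot([0, 0, 1], 30.0).as_matrix()
    moved = pts @ R.T + np.array([1.0, -2.0, 0.5])
    t = kabsch(pts, moved)  # maps moved back onto pts
    assert t.angle_deg == pytest.approx(30.0, abs=1e-9)
    assert abs(t.axis[2]) == pytest.approx(1.0, abs=1e-9)
    assert t.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(t.apply(moved), pts, atol=1e-9)


def test_kabsch_noisy_recovery_within_half_degree():
    rng = np.random.default_rng(2)
    pts = rng.normal(0.0, 10.0, (200, 3))
    R = _rot([1, 1, 0], 25.0).as_matrix()
    moved = pts @ R.T + rng.normal(0.0, 0.3, (200, 3))
    t = kabsch(pts, moved)
    assert abs(t.angle_deg - 25.0) < 0.5
    assert t.rmsd == pytest.approx(0.3 * np.sqrt(3), rel=0.3)


def test_kabsch_agrees_with_scipy_align_vectors():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(50, 3))
    b = rng.normal(size=(50, 3))
    t = kabsch(a, b)
    rot, _ = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
    np.testing.assert_allclose(t.rotation, rot.as_matrix(), atol=1e-8)


def test_kabsch_collinear_points_degenerate():
    line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
    with pytest.raises(DegenerateInputError):
        kabsch(line, line)


@given(seed=st.integers(0, 500))
@settings(max_examples=30, deadline=None)
def test_kabsch_exact_recovery_random_rotations(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(10, 3))
    R = Rotation.random(random_state=seed).as_matrix()
    tr = rng.normal(size=3)
    t = kabsch(pts, pts @ R.T + tr)
    np.testing.assert_allclose(t.rotation @ R, np.eye(3), atol=1e-8)


# ------------------------------------------------------- domain rotation

def test_domain_rotation_recovers_constructed_head_motion(toy_pair):
    a, b, truth = toy_pair
    rep = domain_rotation(a, b, truth.reference_selection,
                          truth.mobile_selection,
                          swivel_axis=truth.swivel_axis)
    assert rep.mobile_motion.angle_deg == pytest.approx(
        truth.mobile_motion.angle_deg, abs=1e-6)
    assert rep.body_alignment.rmsd == pytest.approx(0.0, abs=1e-8)
    assert rep.swivel_deg == pytest.approx(truth.swivel_deg, abs=1e-6)
    assert rep.tilt_deg == pytest.approx(truth.tilt_deg, abs=1e-6)


def test_domain_rotation_zero_motion_gives_zero_angles():
    a, b, truth = make_two_domain_pair(ToySpec(atoms_per_domain=20,
                                               swivel_deg=0.0, tilt_deg=0.0))
    rep = domain_rotation(a, b, truth.reference_selection, truth.mobile_selection)
    assert rep.mobile_motion.angle_deg == pytest.approx(0.0, abs=1e-7)
    assert rep.body_alignment.angle_deg == pytest.approx(0.0, abs=1e-7)


def test_domain_rotation_antisymmetric(toy_pair):
    a, b, truth = toy_pair
    fwd = domain_rotation(a, b, truth.reference_selection, truth.mobile_selection)
    rev = domain_rotation(b, a, truth.reference_selection, truth.mobile_selection)
    assert fwd.mobile_motion.angle_deg == pytest.approx(
        rev.mobile_motion.angle_deg, abs=1e-6)
    np.testing.assert_allclose(fwd.mobile_motion.axis,
                               -rev.mobile_motion.axis, atol=1e-6)


def test_domain_rotation_invariant_under_global_transform(toy_pair):
    a, b, truth = toy_pair
    R = _rot([1, 2, 3], 40.0).as_matrix()
    tr = np.array([5.0, 6.0, 7.0])
    rep0 = domain_rotation(a, b, truth.reference_selection, truth.mobile_selection)
    rep1 = domain_rotation(a.transformed(R, tr), b.transformed(R, tr),
                           truth.reference_selection, truth.mobile_selection)
    assert rep1.mobile_motion.angle_deg == pytest.approx(
        rep0.mobile_motion.angle_deg, abs=1e-6)


# ------------------------------------------------------- twist / swing

def test_pure_swivel_and_pure_tilt_decompose_cleanly():
    u = np.array([0.0, 0.0, 1.0])
    sw, ti = swivel_tilt_decompose(_rot(u, 10.0).as_matrix(), u)
    assert (sw, ti) == (pytest.approx(10.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))
    sw, ti = swivel_tilt_decompose(_rot([1, 0, 0], 7.0).as_matrix(), u)
    assert (sw, ti) == (pytest.approx(0.0, abs=1e-9), pytest.approx(7.0, abs=1e-9))
    sw, ti = swivel_tilt_decompose(np.eye(3), u)
    assert (sw, ti) == (0.0, 0.0)


@given(seed=st.integers(0, 500))
@settings(max_examples=40, deadline=None)
def test_twist_swing_recomposition_reproduces_rotation(seed):
    R = Rotation.random(random_state=seed).as_matrix()
    u = np.array([0.0, 0.0, 1.0])
    R_twist, R_swing = twist_swing(R, u)
    np.testing.assert_allclose(R_swing @ R_twist, R, atol=1e-6)
    # twist is about u; swing axis is orthogonal to u
    rv_t = Rotation.from_matrix(R_twist).as_rotvec()
    if np.linalg.norm(rv_t) > 1e-9:
        np.testing.assert_allclose(np.cross(rv_t, u), 0.0, atol=1e-8)
    rv_s = Rotation.from_matrix(R_swing).as_rotvec()
    if np.linalg.norm(rv_s) > 1e-9:
        assert abs(rv_s @ u) < 1e-8


# ------------------------------------------------------- displacements

def test_displacement_zero_for_identical_models():
    m = make_helix_model(15, "rna_P_trace")
    sel = SelectionSpec.make(residue_ranges=[(5, 10)])
    align = SelectionSpec.make(residue_ranges=[(1, 15)])
    assert displacement(m, m, sel, align, "mean") == pytest.approx(0.0, abs=1e-10)
    assert displacement(m, m, sel, align, "max") == pytest.approx(0.0, abs=1e-10)


def test_displacement_pure_translation_of_measured_part():
    a, b, truth = make_two_domain_pair(ToySpec(
        atoms_per_domain=20, swivel_deg=0.0, tilt_deg=0.0,
        head_translation=(3.0, 0.0, 4.0)))  # |t| = 5 Å
    d_mean = displacement(a, b, truth.mobile_selection, truth.reference_selection, "mean")
    d_max = displacement(a, b, truth.mobile_selection, truth.reference_selection, "max")
    assert d_mean == pytest.approx(5.0, abs=1e-9)
    assert d_max == pytest.approx(5.0, abs=1e-9)


def test_displacement_per_residue_matches_bruteforce(toy_pair):
    a, b, truth = toy_pair
    per = displacement(a, b, truth.mobile_selection, truth.reference_selection,
                       "per_residue")
    # independent distance oracle: reference untouched → alignment is identity
    pos_a = {x.residue_number: x.position for x in a}
    pos_b = {x.residue_number: x.position for x in b}
    n = 30
    for (chain, resnum), d in per.items():
        expected = np.linalg.norm(pos_a[resnum] - pos_b[resnum])
        assert d == pytest.approx(expected, abs=1e-8)
    assert len(per) == n


# ------------------------------------------------------- min distance

def test_min_distance_two_atoms_and_shared_atom():
    from conftest import make_protein_cluster
    m = make_protein_cluster([[0.0, 0.0, 0.0], [0.0, 0.0, 4.2]])
    s1 = SelectionSpec.make(residue_ranges=[(1, 1)])
    s2 = SelectionSpec.make(residue_ranges=[(2, 2)])
    assert min_distance(m, s1, s2) == pytest.approx(4.2)
    both = SelectionSpec.make(residue_ranges=[(1, 2)])
    assert min_distance(m, s1, both) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        min_distance(m, s1, SelectionSpec.make(residue_ranges=[(99, 99)]))


def test_min_distance_matches_exhaustive_scan(random_cluster):
    sel_a = SelectionSpec.make(residue_ranges=[(1, 15)])
    sel_b = SelectionSpec.make(residue_ranges=[(16, 30)])
    got = min_distance(random_cluster, sel_a, sel_b)
    pa = random_cluster.coordinates()[:15]
    pb = random_cluster.coordinates()[15:]
    brute = min(np.linalg.norm(x - y) for x in pa for y in pb)
    assert got == pytest.approx(brute, abs=1e-12)


# ------------------------------------------------------- domain config

def test_domain_definitions_load_and_are_disjoint():
    for scheme in ("Ecoli-16S", "Sac-16S"):
        doms = load_domain_definitions(scheme)
        assert set(doms) == {"head", "body"}
        head = doms["head"].selection.residue_ranges
        body = doms["body"].selection.residue_ranges
        head_set = {r for lo, hi in head for r in range(lo, hi + 1)}
        body_set = {r for lo, hi in body for r in range(lo, hi + 1)}
        assert not head_set & body_set
    # the Sac head boundaries sit 31 residues below the E. coli ones
    ec = load_domain_definitions("Ecoli-16S")["head"].selection.residue_ranges[0]
    sac = load_domain_definitions("Sac-16S")["head"].selection.residue_ranges[0]
    assert (ec[0] - sac[0], ec[1] - sac[1]) == (31, 31)
    with pytest.raises(KeyError):
        load_domain_definitions("Tth-16S")
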