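"""Geometry diagnostics: distances, dihedrals, role inference, Δ_length."""

from dataclasses import replace
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pkadirect import (
    AnalysisError,
    ReactionCenterMetrics,
    carboxyl_ring_dihedral,
    delta_length,
    distance,
    fold_dihedral,
    infer_roles,
    pair_average_dihedral,
    reaction_center_metrics,
)
from pkadirect.structures import AtomicStructure


def _random_rigid(rng):
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=10.0, size=3)


def test_distance_euclidean():
    s = AtomicStructure(elements=("H", "H"), coordinates=np.array([[0, 0, 0], [0, 0, 2.0]]))
    assert distance(s, 0, 1) == pytest.approx(2.0)


def test_distance_errors():
    s = AtomicStructure(elements=("H", "H"), coordinates=np.array([[0, 0, 0], [0, 0, 2.0]]))
    with pytest.raises(ValueError, match="range"):
        distance(s, 0, 5)
    with pytest.raises(ValueError, match="distinct"):
        distance(s, 1, 1)


def test_distance_brute_force_table(water_cluster):
    xyz = water_cluster.coordinates
    for i in range(water_cluster.n_atoms):
        for j in range(water_cluster.n_atoms):
            if i == j:
                continue
            brute = float(np.sqrt(((xyz[i] - xyz[j]) ** 2).sum()))
            assert distance(water_cluster, i, j) == pytest.approx(brute, abs=1e-12)


def test_distance_rigid_invariance(water_cluster):
    rng = np.random.default_rng(11)
    q, t = _random_rigid(rng)
    moved = water_cluster.transformed(q, t)
    for i, j in [(0, 3), (1, 8), (2, 5)]:
        assert distance(moved, i, j) == pytest.approx(distance(water_cluster, i, j), abs=1e-9)


def _toy_acid(theta_deg):
    """Benzoic-like fragment with the carboxyl plane rotated by theta
    about the ipso→carboxyl axis; built from an explicit rotation matrix
    so the expected folded dihedral is known exactly."""
    ipso = np.array([0.0, 0.0, 0.0])
    carboxyl = np.array([1.5, 0.0, 0.0])
    ortho = np.array([-0.7, 1.25, 0.0])
    carbonyl0 = carboxyl + np.array([0.65, 1.05, 0.0])  # in-plane C=O
    axis = np.array([1.0, 0.0, 0.0])
    th = np.deg2rad(theta_deg)
    k = axis
    v = carbonyl0 - carboxyl
    rot = (
        v * np.cos(th)
        + np.cross(k, v) * np.sin(th)
        + k * np.dot(k, v) * (1 - np.cos(th))
    )
    carbonyl = carboxyl + rot
    return AtomicStructure(
        elements=("C", "C", "C", "O"),
        coordinates=np.vstack([ortho, ipso, carboxyl, carbonyl]),
        roles={0: "ring_C_ortho", 1: "ring_C_ipso", 2: "carboxyl_C", 3: "carbonyl_O"},
    )


@pytest.mark.parametrize(
    "theta,expected",
    [(0.0, 0.0), (90.0, 90.0), (67.0, 67.0), (-67.0, 67.0), (135.0, 45.0), (180.0, 0.0)],
)
def test_dihedral_from_constructed_rotation(theta, expected):
    # the toy fragment starts with an in-plane C=O whose torsion is 180°,
    # which folds to 0; rotating by theta folds to |theta| mod the symmetry
    assert carboxyl_ring_dihedral(_toy_acid(theta)) == pytest.approx(expected, abs=1e-6)


def test_dihedral_rigid_invariance():
    rng = np.random.default_rng(3)
    s = _toy_acid(41.0)
    q, t = _random_rigid(rng)
    assert carboxyl_ring_dihedral(s.transformed(q, t)) == pytest.approx(
        carboxyl_ring_dihedral(s), abs=1e-9
    )


@given(st.floats(min_value=-720, max_value=720, allow_nan=False))
def test_fold_symmetry(theta):
    f = fold_dihedral
    assert 0.0 <= f(theta) <= 90.0
    assert f(theta) == pytest.approx(f(-theta), abs=1e-9)
    assert f(theta) == pytest.approx(f(180.0 - theta), abs=1e-9)


def test_pair_average():
    assert pair_average_dihedral(0, 0) == 0
    assert pair_average_dihedral(60, 74) == 67
    assert pair_average_dihedral(33.3, 33.3) == pytest.approx(33.3)
    with pytest.raises(ValueError):
        pair_average_dihedral(-1, 10)
    with pytest.raises(ValueError):
        pair_average_dihedral(10, 95)


def test_acid_template_metrics(acid_cluster):
    m = reaction_center_metrics(acid_cluster)
    assert m.kind == "acid"
    assert 0.95 <= m.lengths["c"] <= 1.05  # covalent O–H
    assert 1.6 <= m.lengths["a"] <= 2.2
    assert 1.6 <= m.lengths["b"] <= 2.2


def test_base_template_metrics(base_cluster):
    m = reaction_center_metrics(base_cluster)
    assert m.kind == "base"
    assert 1.6 <= m.lengths["a_prime"] <= 2.2
    assert 1.6 <= m.lengths["a_second"] <= 2.2


def test_metrics_without_waters_is_analysis_error(benzoic):
    from pkadirect import embed_3d

    with pytest.raises(AnalysisError, match="water_O"):
        reaction_center_metrics(embed_3d(benzoic))


def test_metrics_survive_role_stripping(acid_cluster):
    """Connectivity-based role inference reproduces the builder's labels."""
    stripped = replace(acid_cluster, roles={})
    inferred = reaction_center_metrics(stripped)
    direct = reaction_center_metrics(acid_cluster)
    assert inferred.kind == direct.kind
    for k in direct.lengths:
        assert inferred.lengths[k] == pytest.approx(direct.lengths[k], abs=1e-9)
    assert inferred.dihedral == pytest.approx(direct.dihedral, abs=1e-9)


def test_metrics_invariant_under_atom_reordering(base_cluster):
    rng = np.random.default_rng(5)
    perm = rng.permutation(base_cluster.n_atoms)
    inverse = {int(old): new for new, old in enumerate(perm)}
    shuffled = AtomicStructure(
        elements=tuple(base_cluster.elements[i] for i in perm),
        coordinates=base_cluster.coordinates[perm],
        charge=base_cluster.charge,
        multiplicity=base_cluster.multiplicity,
        roles={inverse[i]: r for i, r in base_cluster.roles.items()},
        label=base_cluster.label,
    )
    a = reaction_center_metrics(base_cluster)
    b = reaction_center_metrics(shuffled)
    assert sorted(a.lengths.values()) == pytest.approx(sorted(b.lengths.values()), abs=1e-9)
    assert a.dihedral == pytest.approx(b.dihedral, abs=1e-9)


def test_base_contact_assignment_matches_brute_force(base_cluster):
    s = base_cluster
    waters = {}
    for h in s.atoms_with_role("water_H"):
        o = min(s.atoms_with_role("water_O"), key=lambda o: distance(s, h, o))
        waters.setdefault(o, []).append(h)
    water_items = sorted(waters.items())
    o_carbox = [s.atoms_with_role("carboxylate_O1")[0], s.atoms_with_role("carboxylate_O2")[0]]
    best = min(
        (
            sum(
                min(distance(s, h, o_carbox[k]) for h in water_items[p[k]][1])
                for k in range(2)
            )
            for p in permutations(range(2))
        )
    )
    m = reaction_center_metrics(s)
    assert m.lengths["a_prime"] + m.lengths["a_second"] == pytest.approx(best, abs=1e-9)


def test_non_aromatic_input_is_analysis_error():
    # acetic acid + a water: carboxyl present, no ring
    s = AtomicStructure(
        elements=("C", "C", "O", "O", "H", "H", "H", "H", "O", "H", "H"),
        coordinates=np.array(
            [
                [0.0, 0.0, 0.0],      # CH3 C
                [1.5, 0.0, 0.0],      # carboxyl C
                [2.15, 1.05, 0.0],    # carbonyl O
                [2.15, -1.15, 0.0],   # hydroxyl O
                [3.12, -1.1, 0.0],    # acidic H
                [-0.5, 0.9, 0.2],
                [-0.5, -0.8, 0.5],
                [-0.2, -0.2, -1.0],
                [5.0, 0.0, 0.0],
                [5.5, 0.7, 0.3],
                [5.5, -0.7, 0.3],
            ]
        ),
    )
    with pytest.raises(AnalysisError, match="ring|aromatic"):
        carboxyl_ring_dihedral(s)


def _metrics(kind, **lengths):
    dihedral = lengths.pop("dihedral", 10.0)
    return ReactionCenterMetrics(kind=kind, lengths=lengths, dihedral=dihedral)


def test_delta_length_reference_is_zero_and_signs():
    metrics = {
        "CAM-B3LYP": {"Benzoic Acid": _metrics("acid", a=1.80, b=1.90, c=0.99)},
        "PBEPBE": {"Benzoic Acid": _metrics("acid", a=1.85, b=1.88, c=0.99)},
    }
    report = delta_length(metrics, "CAM-B3LYP")
    t = report.table
    ref_rows = t[t.functional == "CAM-B3LYP"]
    assert (ref_rows.delta == 0).all()
    a_row = t[(t.functional == "PBEPBE") & (t.label == "a")].iloc[0]
    assert a_row.delta == pytest.approx(+0.05)
    assert not report.outliers.shape[0]


def test_delta_length_flags_outliers():
    metrics = {
        "CAM-B3LYP": {"X": _metrics("base", a_prime=1.80, a_second=1.80)},
        "TPSSTPSS": {"X": _metrics("base", a_prime=2.10, a_second=1.82)},
    }
    report = delta_length(metrics, "CAM-B3LYP")
    flagged = report.outliers
    assert list(flagged.label) == ["a_prime"]
    assert flagged.iloc[0].delta == pytest.approx(0.30)


def test_delta_length_missing_reference_entry():
    metrics = {
        "CAM-B3LYP": {"X": _metrics("acid", a=1.8, b=1.9, c=1.0)},
        "PBEPBE": {"Y": _metrics("acid", a=1.8, b=1.9, c=1.0)},
    }
    with pytest.raises(AnalysisError, match="no entry"):
        delta_length(metrics, "CAM-B3LYP")
    with pytest.raises(AnalysisError, match="not present"):
        delta_length(metrics, "B3PW91")


def test_metrics_validation():
    with pytest.raises(ValueError, match="labels"):
        ReactionCenterMetrics(kind="acid", lengths={"a": 1.8}, dihedral=0.0)
    with pytest.raises(ValueError, match="dihedral"):
        ReactionCenterMetrics(kind="base", lengths={"a_prime": 1.8, "a_second": 1.8}, dihedral=120.0)
    with pytest.raises(ValueError, match="outside"):
        ReactionCenterMetrics(kind="base", lengths={"a_prime": 6.0, "a_second": 1.8}, dihedral=0.0)


def test_infer_roles_identifies_base(base_cluster):
    inferred = infer_roles(replace(base_cluster, roles={}))
    assert len(inferred.atoms_with_role("carboxylate_O1")) == 1
    assert len(inferred.atoms_with_role("water_O")) == 2
    assert not inferred.atoms_with_role("acidic_H")
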