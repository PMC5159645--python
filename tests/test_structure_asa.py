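"""Shrake–Rupley areas against closed-form sphere oracles, residue
aggregation, the missing-atom completeness rule, and normalization."""

import math

import numpy as np
import pytest

from rnasnap.structure_asa import (
    AsaConfig,
    AtomSet,
    aggregate_residue_asa,
    chain_residue_asa,
    completeness_mask,
    compute_atom_asa,
    denormalize_asa,
    load_chain,
    normalize_asa,
)

from conftest import make_pair

R_EXP = 1.9 + 0.75  # probe-expanded radius of the standard test atom


def two_sphere_exposed_area(d: float, R: float = R_EXP) -> float:
    """Closed form: exposed area per sphere for two equal overlapping
    spheres of radius R at centre distance d (spherical-cap subtraction)."""
    if d >= 2 * R:
        return 4 * math.pi * R**2
    return 4 * math.pi * R**2 - 2 * math.pi * R * (R - d / 2)


def test_isolated_sphere_matches_closed_form(single_atom):
    area = compute_atom_asa(single_atom)[0]
    exact = 4 * math.pi * R_EXP**2
    assert area == pytest.approx(exact, rel=0.02)


def test_distant_pair_has_no_occlusion():
    atoms = make_pair(d=2 * R_EXP + 0.5)
    areas = compute_atom_asa(atoms)
    exact = 4 * math.pi * R_EXP**2
    assert areas == pytest.approx([exact, exact], rel=0.02)


@pytest.mark.parametrize("d", np.arange(0.5, 2 * R_EXP + 0.25, 0.5).tolist())
def test_two_sphere_overlap_matches_cap_formula(d):
    areas = compute_atom_asa(make_pair(d=d))
    exact = two_sphere_exposed_area(d)
    assert areas == pytest.approx([exact, exact], rel=0.02)


def test_quadrature_converges_on_doubling(random_cluster):
    a1 = compute_atom_asa(random_cluster, AsaConfig(n_sphere_points=960))
    a2 = compute_atom_asa(random_cluster, AsaConfig(n_sphere_points=1920))
    # change below 1% of each atom's full sphere area (the exposed fraction);
    # nearly-buried atoms have arbitrarily small areas, so their own area is
    # not a usable scale
    sphere = 4 * math.pi * (random_cluster.radii + 0.75) ** 2
    assert np.all(np.abs(a1 - a2) / sphere < 0.01)


def test_adding_an_atom_never_increases_areas(random_cluster):
    before = compute_atom_asa(random_cluster)
    extra = AtomSet(
        names=random_cluster.names + ["CX"],
        elements=random_cluster.elements + ["C"],
        radii=np.append(random_cluster.radii, 1.7),
        coords=np.vstack([random_cluster.coords, [0.5, 0.5, 0.5]]),
        residue_index=np.append(random_cluster.residue_index, 0),
        residue_base=random_cluster.residue_base + ["A"],
    )
    after = compute_atom_asa(extra)[:-1]
    assert np.all(after <= before + 1e-9)


def test_rigid_motion_invariance(random_cluster):
    base = compute_atom_asa(random_cluster)
    rng = np.random.default_rng(7)
    # random rotation via QR, plus a translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = AtomSet(
        names=random_cluster.names,
        elements=random_cluster.elements,
        radii=random_cluster.radii,
        coords=random_cluster.coords @ q.T + np.array([10.0, -3.0, 5.0]),
        residue_index=random_cluster.residue_index,
        residue_base=random_cluster.residue_base,
    )
    rotated = compute_atom_asa(moved)
    # compared on the exposed-fraction scale: the point lattice is fixed in
    # space, so rotating the cluster re-samples the buried boundary
    sphere = 4 * math.pi * (random_cluster.radii + 0.75) ** 2
    assert np.all(np.abs(base - rotated) / sphere < 0.02)


def test_nonfinite_coordinate_rejected():
    with pytest.raises(ValueError, match="finite"):
        AtomSet(["C1'"], ["C"], np.array([1.9]), np.array([[np.nan, 0, 0]]),
                np.array([0]), ["A"])


def test_too_few_sphere_points_rejected():
    with pytest.raises(ValueError, match="n_sphere_points"):
        AsaConfig(n_sphere_points=10)


# --- aggregation -----------------------------------------------------------


def _toy_chain() -> AtomSet:
    """2 residues with 3 + 2 atoms, spread far apart (no occlusion)."""
    coords = np.array(
        [[0, 0, 0], [10, 0, 0], [0, 10, 0], [50, 0, 0], [50, 10, 0]], dtype=float
    )
    return AtomSet(
        names=["P", "O5'", "C1'", "P", "C1'"],
        elements=["P", "O", "C", "P", "C"],
        radii=np.array([1.8, 1.52, 1.7, 1.8, 1.7]),
        coords=coords,
        residue_index=np.array([0, 0, 0, 1, 1]),
        residue_base=["A", "A", "A", "G", "G"],
    )


def test_residue_asa_is_partial_sum_of_atom_areas():
    atoms = _toy_chain()
    areas = compute_atom_asa(atoms)
    residues = aggregate_residue_asa(areas, atoms)
    assert [r.residue_index for r in residues] == [0, 1]
    assert residues[0].asa == pytest.approx(areas[:3].sum())
    assert residues[1].asa == pytest.approx(areas[3:].sum())
    # total conservation to machine precision
    total = sum(r.asa for r in residues)
    assert total == pytest.approx(areas.sum(), rel=1e-12)
    # singleton sum case via a one-atom residue set
    assert residues[1].base == "G"


def test_aggregate_requires_one_area_per_atom():
    atoms = _toy_chain()
    with pytest.raises(ValueError, match="one area per atom"):
        aggregate_residue_asa(np.ones(3), atoms)


# --- completeness ----------------------------------------------------------


def test_all_complete_residues_all_valid():
    exp = [{"P", "C1'"}] * 5
    obs = [{"P", "C1'"}] * 5
    assert completeness_mask(obs, exp).all()


def test_interior_incomplete_residue_invalidates_neighbours():
    exp = [{"P", "C1'"}] * 6
    obs = [set(e) for e in exp]
    obs[3] = {"P"}  # missing C1'
    mask = completeness_mask(obs, exp)
    assert mask.tolist() == [True, True, False, False, False, True]


def test_terminal_incomplete_residue_invalidates_two_positions():
    exp = [{"P", "C1'"}] * 4
    obs = [set(e) for e in exp]
    obs[0] = {"P"}
    mask = completeness_mask(obs, exp)
    assert mask.tolist() == [False, False, True, True]


def test_unknown_base_marked_invalid():
    exp = [{"P"}, frozenset(), {"P"}]
    obs = [{"P"}, {"P"}, {"P"}]
    mask = completeness_mask(obs, exp)
    assert mask.tolist() == [False, False, False]  # neighbours dragged down too


# --- normalization ---------------------------------------------------------


@pytest.mark.parametrize(
    "asa,expected", [(400.0, 1.0), (0.0, 0.0), (137.0, 0.3425)]
)
def test_normalize_by_400(asa, expected):
    assert normalize_asa(asa) == pytest.approx(expected)


def test_normalize_round_trip_and_no_clipping_above_400():
    assert denormalize_asa(normalize_asa(513.2)) == pytest.approx(513.2)
    assert normalize_asa(500.0) > 1.0  # ground truth is not clipped


def test_negative_asa_rejected():
    with pytest.raises(ValueError):
        normalize_asa(-1.0)


# --- structure file round trip --------------------------------------------


def test_pdb_round_trip(tmp_path):
    from rnasnap.cli import _write_pdb
    from rnasnap.synthetic import SIMPLE_INVENTORY, make_synthetic_chain

    atoms, seq = make_synthetic_chain(seed=11, n_residues=5)
    path = str(tmp_path / "toy.pdb")
    _write_pdb(path, atoms)
    loaded = load_chain(path, "A")
    assert len(loaded) == len(atoms)
    assert loaded.residue_bases() == atoms.residue_bases()
    np.testing.assert_allclose(loaded.coords, atoms.coords, atol=1e-3)
    res = chain_residue_asa(
        loaded, inventory=SIMPLE_INVENTORY, first_residue_lacks_phosphate_ok=False
    )
    assert all(r.valid for r in res)
    assert all(r.asa > 0 for r in res)
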