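"""RMSD and COM clustering, significance filter, grouping, subunit occupancy."""

import numpy as np
import pytest

from sterolsites import (
    ResidueFingerprint,
    cluster_by_rmsd,
    com_cluster,
    filter_significant,
    group_by_fingerprint,
    make_pose_ensemble,
    pose_rmsd,
    subunit_occupancy,
    symmetric_points,
)
from sterolsites.core_model import PoseEnsemble, ResidueKey
from sterolsites.contacts import contact_fingerprint
from sterolsites.pose_clustering import PoseCluster
from sterolsites.synthetic_data import SiteSpec

from conftest import ensemble_from_coords, multi_atom_pose


def fp(*nums, chain="A"):
    return ResidueFingerprint(frozenset(ResidueKey(chain, n) for n in nums))


# --- pose_rmsd --------------------------------------------------------------


def test_rmsd_identity_and_translation():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(10, 3))
    a = multi_atom_pose(coords)
    assert pose_rmsd(a, a) == 0.0
    b = multi_atom_pose(coords + np.array([1.0, 0.0, 0.0]))
    assert pose_rmsd(a, b) == pytest.approx(1.0)  # rigid translation closed form


def test_rmsd_matches_direct_formula():
    rng = np.random.default_rng(42)
    ca, cb = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
    expected = np.sqrt(((ca - cb) ** 2).sum(axis=1).mean())
    assert pose_rmsd(multi_atom_pose(ca), multi_atom_pose(cb)) == pytest.approx(expected)


def test_rmsd_topology_mismatch():
    with pytest.raises(ValueError):
        pose_rmsd(multi_atom_pose(np.zeros((3, 3))), multi_atom_pose(np.zeros((4, 3))))


# --- cluster_by_rmsd --------------------------------------------------------


def base_coords(offset):
    base = np.zeros((4, 3))
    base[:, 0] = [0, 1, 2, 3]
    return base + np.asarray(offset)


def test_greedy_assignment_example():
    """A(−10), B(−9, 1 Å away), C(−8, 5 Å away) → {A,B} and {C}."""
    ens = ensemble_from_coords(
        [base_coords((0, 0, 0)), base_coords((0, 1, 0)), base_coords((0, 5, 0))],
        energies=[-10.0, -9.0, -8.0],
    )
    clusters = cluster_by_rmsd(ens, tolerance=2.0)
    assert [sorted(c.member_indices) for c in clusters] == [[0, 1], [2]]
    assert clusters[0].representative == 0


def test_singleton_and_degenerate():
    single = ensemble_from_coords([base_coords((0, 0, 0))], energies=[-5.0])
    (c,) = cluster_by_rmsd(single)
    assert c.size == 1 and c.fraction == 1.0
    same = ensemble_from_coords([base_coords((0, 0, 0))] * 5, energies=[-5.0] * 5)
    (c,) = cluster_by_rmsd(same)
    assert c.size == 5


def test_missing_energy_instructive_error():
    ens = ensemble_from_coords([base_coords((0, 0, 0))])
    with pytest.raises(ValueError, match="com_cluster"):
        cluster_by_rmsd(ens)


def test_partition_property():
    rng = np.random.default_rng(9)
    coords = [base_coords(rng.normal(scale=4.0, size=3)) for _ in range(40)]
    ens = ensemble_from_coords(coords, energies=list(rng.normal(-8, 1, size=40)))
    clusters = cluster_by_rmsd(ens)
    members = sorted(i for c in clusters for i in c.member_indices)
    assert members == list(range(40))  # every pose in exactly one cluster
    assert sum(c.size for c in clusters) == 40
    for c in clusters:
        rep_e = ens.poses[c.representative].energy
        assert all(rep_e <= ens.poses[i].energy for i in c.member_indices)


# --- filter_significant -----------------------------------------------------


def make_cluster(indices):
    return PoseCluster(member_indices=list(indices), representative=indices[0], size=len(indices), fraction=0.0)


def test_two_percent_of_300_means_six():
    five = make_cluster(list(range(5)))
    six = make_cluster(list(range(5, 11)))
    kept = filter_significant([five, six], ensemble_size=300)
    assert kept == [six]


def test_zero_fraction_keeps_all_and_empty_ok():
    c = make_cluster([0])
    assert filter_significant([c], 300, min_fraction=0.0) == [c]
    assert filter_significant([], 300) == []


# --- group_by_fingerprint ---------------------------------------------------


def test_grouping_identity_and_disjoint():
    c1, c2 = make_cluster([0]), make_cluster([1])
    same = group_by_fingerprint([c1, c2], [fp(1, 2, 3), fp(1, 2, 3)])
    assert len(same) == 1
    apart = group_by_fingerprint([c1, c2], [fp(1, 2, 3), fp(7, 8, 9)])
    assert len(apart) == 2


def test_single_linkage_transitive_closure():
    """i~j (0.6) and j~k (0.6) chain into one group although i~k is 0.2."""
    fpi = fp(1, 2, 3, 4, 10)
    fpj = fp(1, 2, 3, 4, 5)  # J(i,j) = 4/6 ≈ 0.67
    fpk = fp(2, 3, 4, 5, 6)  # J(j,k) = 4/6; J(i,k) = 3/7 ≈ 0.43
    clusters = [make_cluster([0]), make_cluster([1]), make_cluster([2])]
    groups = group_by_fingerprint(clusters, [fpi, fpj, fpk], threshold=0.5)
    assert len(groups) == 1
    assert groups[0].union_fingerprint.residues == (fpi.residues | fpj.residues | fpk.residues)


# --- com_cluster ------------------------------------------------------------


def com_ensemble(xs, lgfes):
    return ensemble_from_coords([base_coords((x, 0, 0)) for x in xs], lgfes=lgfes)


def test_lgfe_gate_applied_before_clustering():
    ens = com_ensemble([0.0, 1.0], lgfes=[-3.0, -5.0])
    clusters = com_cluster(ens)
    assert sum(c.size for c in clusters) == 1  # the −3.0 pose is dropped


def test_two_stage_worked_example():
    """COMs at x = 0, 2.5, 10 Å (all lgfe −5) → two final hotspots."""
    ens = com_ensemble([0.0, 2.5, 10.0], lgfes=[-5.0, -5.0, -5.0])
    clusters = com_cluster(ens)
    assert len(clusters) == 2
    assert sorted(len(c.member_indices) for c in clusters) == [1, 2]


def test_com_cluster_empty_and_errors():
    assert com_cluster(com_ensemble([0.0], lgfes=[-1.0])) == []
    with pytest.raises(ValueError):
        com_cluster(com_ensemble([0.0], lgfes=[None]))


def test_com_cluster_invariant_under_relabeling():
    rng = np.random.default_rng(3)
    xs = list(rng.normal(scale=6.0, size=20))
    lg = list(rng.normal(-6, 0.5, size=20))
    ens = com_ensemble(xs, lg)
    shuffled_order = list(rng.permutation(20))
    ens2 = PoseEnsemble(
        ligand_name="LIG", poses=[ens.poses[i] for i in shuffled_order]
    )
    reps1 = sorted(round(ens.poses[c.representative].com()[0], 6) for c in com_cluster(ens))
    reps2 = sorted(round(ens2.poses[c.representative].com()[0], 6) for c in com_cluster(ens2))
    assert reps1 == reps2  # depends only on coordinates and lgfe


def test_representative_is_lowest_lgfe():
    ens = com_ensemble([0.0, 0.5, 0.2], lgfes=[-4.0, -6.0, -5.0])
    (c,) = com_cluster(ens)
    assert c.representative == 1


# --- subunit_occupancy ------------------------------------------------------


def probe_ligand():
    from sterolsites import Atom, Pose

    return Pose(atoms=[Atom(1, "C1", "C", np.zeros(3))], label="probe")


def test_occupancy_counts_planted_chains(tetramer):
    """A site planted at all four symmetry-equivalent positions groups into
    one site with subunit occupancy 4."""
    structure, _ = tetramer
    anchor = structure.chains["A"][10].atoms[1].position  # a CA atom
    center = anchor * np.array([1.15, 1.15, 1.0])  # nudged outward, still in contact
    sites = [
        SiteSpec(center=tuple(c), n_poses=5, sigma=0.2)
        for c in symmetric_points(center, order=4)
    ]
    ensemble, _ = make_pose_ensemble(structure, sites, seed=2, ligand=probe_ligand())
    clusters = cluster_by_rmsd(ensemble, tolerance=2.0)
    fps = [contact_fingerprint(structure, ensemble.poses[c.representative]) for c in clusters]
    groups = group_by_fingerprint(clusters, fps)
    assert len(groups) == 1
    assert subunit_occupancy(groups[0], structure) == 4
    chains = {key.chain_id for key in groups[0].union_fingerprint.residues}
    assert chains == {"A", "B", "C", "D"}


def test_occupancy_single_chain_site(tetramer):
    structure, _ = tetramer
    center = structure.chains["A"][10].atoms[1].position
    ensemble, _ = make_pose_ensemble(structure, [SiteSpec(center=tuple(center), n_poses=4, sigma=0.3)], seed=4)
    clusters = cluster_by_rmsd(ensemble)
    fps = [contact_fingerprint(structure, ensemble.poses[c.representative]) for c in clusters]
    groups = group_by_fingerprint(clusters, fps)
    assert all(subunit_occupancy(g, structure) == 1 for g in groups)


def test_occupancy_never_exceeds_symmetry_order(tetramer):
    structure, _ = tetramer
    from sterolsites.pose_clustering import SiteGroup

    fps = [fp(440, 441, chain=c) for c in "ABCD"] * 2  # 8 member fingerprints
    union = frozenset().union(*(f.residues for f in fps))
    g = SiteGroup(
        cluster_ids=list(range(8)),
        union_fingerprint=ResidueFingerprint(union),
        cluster_fingerprints=fps,
        label="G1",
    )
    assert subunit_occupancy(g, structure) == 4


def test_occupancy_requires_fingerprints(tetramer):
    structure, _ = tetramer
    from sterolsites.pose_clustering import SiteGroup

    g = SiteGroup([], ResidueFingerprint(frozenset()), [], "G0")
    with pytest.raises(ValueError):
        subunit_occupancy(g, structure)
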