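"""Occupancy binning, Boltzmann GFE, OC, LGFE scoring, boxes, annealing MC."""

import math

import numpy as np
import pytest

from sterolsites import (
    KB,
    Atom,
    FragMapSet,
    GfeMap,
    GridSpec,
    MCSchedule,
    OccupancyMap,
    Pose,
    ProbeTrajectory,
    build_occupancy,
    default_fragmap_classes,
    default_sterol_classifier,
    make_probe_trajectory,
    mc_hotspot_sample,
    occupancy_to_gfe,
    overlap_coefficient,
    partition_boxes,
    read_dx,
    score_lgfe,
    sterol_ligand,
    write_dx,
)


def grid(dims=(4, 4, 4), spacing=1.0, origin=(0.0, 0.0, 0.0)):
    return GridSpec(origin=origin, spacing=spacing, dims=dims)


def traj_from_points(points, cls="generic_apolar", box=((0, 0, 0), (4, 4, 4))):
    frame = [(cls, np.asarray(p, float)) for p in points]
    return ProbeTrajectory(frames=[frame], box=box)


# --- occupancy binning ------------------------------------------------------


def test_single_point_single_voxel():
    occ = build_occupancy(traj_from_points([(1.5, 2.5, 3.5)]), "generic_apolar", grid())
    assert occ.counts.sum() == 1
    assert occ.counts[1, 2, 3] == 1


def test_boundary_point_goes_to_higher_voxel():
    occ = build_occupancy(traj_from_points([(2.0, 0.5, 0.5)]), "generic_apolar", grid())
    assert occ.counts[2, 0, 0] == 1
    assert occ.counts[1, 0, 0] == 0


def test_binning_matches_histogramdd_oracle():
    rng = np.random.default_rng(8)
    pts = rng.random((2000, 3)) * 4
    g = grid()
    occ = build_occupancy(traj_from_points(pts), "generic_apolar", g)
    expected, _ = np.histogramdd(pts, bins=(4, 4, 4), range=[(0, 4)] * 3)
    # np.histogramdd closes the last bin on the right; no point sits at 4.0
    assert np.array_equal(occ.counts, expected.astype(int))


def test_absent_class_warns_and_zeroes():
    occ = build_occupancy(traj_from_points([(1, 1, 1)]), "no_such_class", grid())
    assert occ.counts.sum() == 0


# --- Boltzmann transform ----------------------------------------------------


def test_uniform_occupancy_gives_zero_map():
    g = grid((2, 2, 2))
    occ = OccupancyMap(g, np.full((2, 2, 2), 7), n_frames=7, atom_class="x")
    gfe = occupancy_to_gfe(occ)
    assert np.allclose(gfe.values, 0.0)


def test_e_fold_enrichment_depth():
    """A voxel at e × bulk density has raw GFE −k_B·T ≈ −0.596 kcal/mol."""
    g = grid((3, 1, 1))
    counts = np.array([[[10]], [[10]], [[10]]], dtype=float)
    counts[1, 0, 0] = 10 * math.e
    occ = OccupancyMap(g, counts, n_frames=100, atom_class="x")
    bulk = counts.mean()
    gfe = occupancy_to_gfe(occ, temperature=300.0, bulk_density=bulk)
    # the zero-mean offset cancels in voxel differences: enriched − bulk-like
    raw_bulk_voxel = -KB * 300.0 * math.log(10 / bulk)
    diff = gfe.values[1, 0, 0] - gfe.values[0, 0, 0]
    assert diff == pytest.approx(-KB * 300.0 - 0.0, abs=1e-9)
    assert gfe.values[1, 0, 0] - gfe.values[2, 0, 0] == pytest.approx(-KB * 300.0, abs=1e-9)
    assert -KB * 300.0 == pytest.approx(-0.596, abs=0.001)


def test_empty_voxel_capped():
    g = grid((2, 1, 1))
    counts = np.array([[[8]], [[0]]], dtype=float)
    occ = OccupancyMap(g, counts, n_frames=8, atom_class="x")
    gfe = occupancy_to_gfe(occ, cap=3.0)
    # offset-free difference between the empty and occupied voxel is fixed
    raw_occupied = -KB * 300.0 * math.log(8 / 4)
    assert gfe.values[1, 0, 0] - gfe.values[0, 0, 0] == pytest.approx(3.0 - raw_occupied, abs=1e-9)


def test_zero_mean_invariant_random_maps():
    rng = np.random.default_rng(0)
    for _ in range(5):
        counts = rng.integers(0, 50, size=(6, 5, 4))
        occ = OccupancyMap(grid((6, 5, 4)), counts, n_frames=100, atom_class="x")
        if counts.sum() == 0:
            continue
        gfe = occupancy_to_gfe(occ)
        assert abs(gfe.values.mean()) < 1e-9


def test_all_zero_map_rejected():
    occ = OccupancyMap(grid((2, 2, 2)), np.zeros((2, 2, 2), int), n_frames=5, atom_class="x")
    with pytest.raises(ValueError):
        occupancy_to_gfe(occ)


# --- overlap coefficient ----------------------------------------------------


def occ_of(counts):
    counts = np.asarray(counts)
    return OccupancyMap(grid(counts.shape), counts, n_frames=10, atom_class="x")


def test_oc_identity_disjoint_and_hand_value():
    m = occ_of(np.arange(8).reshape(2, 2, 2))
    assert overlap_coefficient(m, m) == pytest.approx(1.0)
    a = np.zeros((2, 2, 2), int)
    b = np.zeros((2, 2, 2), int)
    a[0, 0, 0] = 5
    b[1, 1, 1] = 3
    assert overlap_coefficient(occ_of(a), occ_of(b)) == 0.0
    p = np.zeros((2, 1, 1), int)
    q = np.zeros((2, 1, 1), int)
    p[0] = 4  # p = (1, 0)
    q[:] = 2  # q = (0.5, 0.5)
    assert overlap_coefficient(occ_of(p), occ_of(q)) == pytest.approx(0.5)


def test_oc_symmetric_and_bounded():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = occ_of(rng.integers(0, 20, size=(3, 3, 3)))
        b = occ_of(rng.integers(0, 20, size=(3, 3, 3)))
        if a.counts.sum() == 0 or b.counts.sum() == 0:
            continue
        oc_ab = overlap_coefficient(a, b)
        assert oc_ab == pytest.approx(overlap_coefficient(b, a))
        assert 0.0 <= oc_ab <= 1.0


def test_oc_grid_mismatch_rejected():
    a = occ_of(np.ones((2, 2, 2), int))
    b = OccupancyMap(grid((2, 2, 2), origin=(1, 0, 0)), np.ones((2, 2, 2), int), 10, "x")
    with pytest.raises(ValueError):
        overlap_coefficient(a, b)


# --- LGFE -------------------------------------------------------------------


def fragmap_set(values_by_class, g):
    maps = {}
    for cls, vals in values_by_class.items():
        vals = np.asarray(vals, float)
        maps[cls] = GfeMap(g, vals - vals.mean(), temperature=300.0)
    classifier = {"C": "generic_apolar", "O": "generic_apolar", "N": "generic_apolar"}
    classifier = {k: v for k, v in classifier.items() if v in maps}
    return FragMapSet(maps=maps, classifier=classifier)


def test_lgfe_zero_field_and_additivity():
    g = grid((4, 4, 4))
    fset = fragmap_set({"generic_apolar": np.zeros((4, 4, 4))}, g)
    pose = Pose(atoms=[Atom(1, "C1", "C", np.array([1.2, 1.2, 1.2])), Atom(2, "C2", "C", np.array([2.5, 2.5, 2.5]))])
    assert score_lgfe(pose, fset) == 0.0

    vals = np.zeros((4, 4, 4))
    vals[1, 1, 1] = -1.2
    vals[2, 2, 2] = -0.8
    fset = fragmap_set({"generic_apolar": vals}, g)
    offset = (np.asarray(vals) - np.asarray(vals).mean())  # zero-mean map actually used
    expected = offset[1, 1, 1] + offset[2, 2, 2]
    assert score_lgfe(pose, fset) == pytest.approx(expected)
    # additivity over single-atom subposes
    parts = sum(
        score_lgfe(Pose(atoms=[a]), fset) for a in pose.atoms
    )
    assert score_lgfe(pose, fset) == pytest.approx(parts)


def test_lgfe_outside_grid_contributes_zero():
    g = grid((2, 2, 2))
    vals = np.array([[[-1.0, 1.0], [0.5, -0.5]], [[0.2, -0.2], [0.8, -0.8]]])
    fset = fragmap_set({"generic_apolar": vals}, g)
    inside = Pose(atoms=[Atom(1, "C1", "C", np.array([0.5, 0.5, 0.5]))])
    outside = Pose(atoms=[Atom(1, "C1", "C", np.array([50.0, 50.0, 50.0]))])
    both = Pose(atoms=inside.atoms + outside.atoms)
    assert score_lgfe(both, fset) == pytest.approx(score_lgfe(inside, fset))


def test_unclassifiable_atom_errors():
    g = grid((2, 2, 2))
    fset = fragmap_set({"generic_apolar": np.zeros((2, 2, 2))}, g)
    pose = Pose(atoms=[Atom(1, "XX1", "Xx", np.array([0.5, 0.5, 0.5]))])
    with pytest.raises(KeyError):
        score_lgfe(pose, fset)


def test_default_registry_has_14_classes_and_classifies_sterol():
    assert len(default_fragmap_classes()) == 14
    assert len(set(default_fragmap_classes())) == 14
    classifier = default_sterol_classifier()
    assert set(classifier.values()) <= set(default_fragmap_classes())
    g = grid((4, 4, 4))
    maps = {cls: GfeMap(g, np.zeros((4, 4, 4))) for cls in default_fragmap_classes()}
    fset = FragMapSet(maps=maps, classifier=classifier)
    lig = sterol_ligand()
    classes = {fset.classify(a) for a in lig.atoms}
    assert "generic_apolar" in classes  # ring carbons
    assert "methanol_oxygen" in classes  # the 3-hydroxyl oxygen


# --- boxes ------------------------------------------------------------------


def test_partition_boxes_covering():
    boxes = partition_boxes(((0, 0, 0), (28.28, 28.28, 28.28)), edge=14.14)
    assert len(boxes) == 8  # 2 per axis
    assert len(partition_boxes(((0, 0, 0), (5, 5, 5)), edge=14.14)) == 1
    lo = np.min([b[0] for b in boxes], axis=0)
    hi = np.max([b[1] for b in boxes], axis=0)
    assert np.all(lo <= 0) and np.all(hi >= 28.28)


# --- MC hotspot sampling ----------------------------------------------------


def single_atom_ligand():
    return Pose(atoms=[Atom(1, "C1", "C", np.zeros(3))], label="probe")


def gaussian_well_set(g, centers, depth=8.0, sigma=2.5, cls="generic_apolar"):
    xyz = g.centers()
    vals = np.zeros(g.dims)
    for c in centers:
        r2 = ((xyz - np.asarray(c)) ** 2).sum(axis=-1)
        vals -= depth * np.exp(-r2 / (2 * sigma ** 2))
    maps = {cls: GfeMap(g, vals - vals.mean() - (vals - vals.mean()).mean())}
    return FragMapSet(maps=maps, classifier={"C": cls})


def test_zero_step_schedule_returns_initial_placements():
    g = grid((8, 8, 8))
    fset = gaussian_well_set(g, [(4, 4, 4)])
    sched = MCSchedule(hot_steps=0, cool_steps=0, repeats=5)
    ens = mc_hotspot_sample(fset, single_atom_ligand(), ((0, 0, 0), (8, 8, 8)), sched, seed=3)
    assert len(ens) == 5
    again = mc_hotspot_sample(fset, single_atom_ligand(), ((0, 0, 0), (8, 8, 8)), sched, seed=3)
    for p, q in zip(ens.poses, again.poses):
        assert np.array_equal(p.coords(), q.coords())  # reproducible from seed
    # initial placements lie inside the box
    for p in ens.poses:
        assert np.all(p.com() >= 0) and np.all(p.com() <= 8)


def test_annealing_finds_single_deep_well():
    """≥ 90% of repeats end with COM within 2 Å of the planted well centre."""
    g = grid((12, 12, 12))
    center = (6.0, 6.0, 6.0)
    fset = gaussian_well_set(g, [center], depth=8.0, sigma=3.0)
    sched = MCSchedule(
        hot_steps=1000, cool_steps=800, max_translation=1.0, max_rotation=30.0, repeats=50
    )
    ens = mc_hotspot_sample(fset, single_atom_ligand(), ((0, 0, 0), (12, 12, 12)), sched, seed=12)
    dists = [np.linalg.norm(p.com() - center) for p in ens.poses]
    assert sum(d <= 2.0 for d in dists) >= 45


def test_zero_temperature_is_monotone():
    g = grid((10, 10, 10))
    fset = gaussian_well_set(g, [(5, 5, 5)], depth=6.0, sigma=2.0)
    lig = single_atom_ligand()
    sched0 = MCSchedule(hot_steps=0, cool_steps=0, repeats=20)
    start = mc_hotspot_sample(fset, lig, ((0, 0, 0), (10, 10, 10)), sched0, seed=4)
    cooled = mc_hotspot_sample(
        fset,
        lig,
        ((0, 0, 0), (10, 10, 10)),
        MCSchedule(hot_steps=0, cool_steps=500, t_start=0.0, t_end=0.0, max_translation=1.0, repeats=20),
        seed=4,
    )
    for p0, p1 in zip(start.poses, cooled.poses):
        assert p1.lgfe <= p0.lgfe + 1e-12


def test_box_outside_grid_rejected():
    g = grid((4, 4, 4))
    fset = gaussian_well_set(g, [(2, 2, 2)])
    with pytest.raises(ValueError):
        mc_hotspot_sample(fset, single_atom_ligand(), ((0, 0, 0), (40, 4, 4)), MCSchedule(repeats=1), seed=0)


# --- synthetic density recovery ---------------------------------------------


def test_gaussian_component_recovered():
    """GFE argmin within 1 voxel of the planted mean; depth within 15%."""
    mean = (10.0, 10.0, 10.0)
    traj, truth = make_probe_trajectory(
        components=[(mean, 1.0, 5, "benzene_carbon")],
        n_frames=5000,
        box=((0, 0, 0), (20, 20, 20)),
        background_weight=2,
        seed=31,
    )
    g = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(20, 20, 20))
    occ = build_occupancy(traj, "benzene_carbon", g)
    gfe = occupancy_to_gfe(occ)
    argmin = np.unravel_index(np.argmin(gfe.values), gfe.values.shape)
    mean_voxel = g.voxel_of(np.asarray(mean))[0]
    assert np.max(np.abs(np.asarray(argmin) - mean_voxel)) <= 1

    # raw depth vs the analytic −k_B·T·ln(peak/bulk)
    n_comp = 5 * 5000
    n_bg = 2 * 5000
    from scipy.stats import norm

    p_vox = (norm.cdf(0.5) - norm.cdf(-0.5)) ** 3
    peak = n_comp * p_vox + n_bg / g.dims[0] ** 3
    bulk = (n_comp + n_bg) / np.prod(g.dims)
    expected_raw = -KB * 300.0 * math.log(peak / bulk)
    counts = occ.counts.astype(float)
    raw_measured = -KB * 300.0 * math.log(counts[argmin] / counts.mean())
    assert raw_measured == pytest.approx(expected_raw, rel=0.15)


def test_half_trajectory_oc_above_threshold():
    from sterolsites import oc_convergence

    traj, _ = make_probe_trajectory(
        components=[((10.0, 10.0, 10.0), 1.0, 5, "benzene_carbon")],
        n_frames=5000,
        box=((0, 0, 0), (20, 20, 20)),
        background_weight=2,
        seed=31,
    )
    g = GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(20, 20, 20))
    oc, converged = oc_convergence(traj, "benzene_carbon", g, threshold=0.6)
    assert converged and oc > 0.6


# --- OpenDX round trip ------------------------------------------------------


def test_dx_round_trip(tmp_path):
    g = grid((3, 4, 5), spacing=0.5, origin=(1.0, -2.0, 3.0))
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(3, 4, 5))
    vals -= vals.mean()
    gfe = GfeMap(g, vals - vals.mean())
    path = tmp_path / "map.dx"
    write_dx(gfe, path)
    g2, vals2 = read_dx(path)
    assert g2.dims == g.dims
    assert np.allclose(g2.origin, g.origin)
    assert g2.spacing == pytest.approx(0.5)
    assert np.allclose(vals2, gfe.values, atol=1e-6)
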