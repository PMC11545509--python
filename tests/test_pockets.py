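import itertools

import numpy as np
import pytest

from pocketens.pockets import (
    AlphaSphere,
    GridPocket,
    OccupancyGrid,
    build_occupancy_grid,
    cluster_alpha_spheres,
    cut_channel_at_bottleneck,
    extract_grid_pocket,
    neighbors26,
    rasterize_spheres,
    select_active_site,
    voronoi_alpha_spheres,
)
from pocketens.structure_io import AtomRecord, Ensemble, HemeFrame, Snapshot, StructureError


def _cloud_snapshot(points, element="C"):
    atoms = [
        AtomRecord(i + 1, element, element, "CLD", i + 1, "A", np.asarray(p, float))
        for i, p in enumerate(points)
    ]
    return Snapshot(atoms=atoms, frame_index=1)


def _regular_tetrahedron(edge, center=(0.0, 0.0, 0.0)):
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    verts *= edge / (2 * np.sqrt(2))
    return verts + np.asarray(center)


def brute_force_alpha_spheres(points, r_min=2.9, r_max=16.0):
    """Independent oracle: all 4-point circumspheres with the empty-sphere
    check, the radius window and the convex-hull filter."""
    from scipy.spatial import Delaunay

    points = np.asarray(points, float)
    hull = Delaunay(points)
    found = []
    for combo in itertools.combinations(range(len(points)), 4):
        p = points[list(combo)]
        mat = 2.0 * (p[1:] - p[0])
        if abs(np.linalg.det(mat)) < 1e-10:
            continue
        rhs = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
        center = np.linalg.solve(mat, rhs)
        radius = np.linalg.norm(center - p[0])
        if not (r_min <= radius <= r_max):
            continue
        d = np.linalg.norm(points - center, axis=1)
        inside = d < radius - 1e-6
        if inside.any():
            continue
        if hull.find_simplex(center) < 0:
            continue
        found.append((center, radius))
    return found


# ---------------------------------------------------------------------------
# alpha spheres


def test_tetrahedron_circumsphere_closed_form():
    snap = _cloud_snapshot(_regular_tetrahedron(6.0))
    spheres = voronoi_alpha_spheres(snap)
    assert len(spheres) == 1
    expected = 6.0 * np.sqrt(3.0 / 8.0)
    assert spheres[0].radius == pytest.approx(expected, abs=1e-9)
    assert np.allclose(spheres[0].center, [0, 0, 0], atol=1e-9)


def test_small_tetrahedron_rejected_by_radius_floor():
    snap = _cloud_snapshot(_regular_tetrahedron(4.0))
    assert voronoi_alpha_spheres(snap) == []  # circumradius ≈ 2.449 < 2.9


def test_two_distant_tetrahedra_one_interior_sphere_each():
    pts = np.vstack(
        [_regular_tetrahedron(6.0), _regular_tetrahedron(6.0, center=(100.0, 0, 0))]
    )
    spheres = voronoi_alpha_spheres(_cloud_snapshot(pts))
    centers = np.array([s.center for s in spheres])
    oracle = brute_force_alpha_spheres(pts)
    assert len(spheres) == len(oracle) == 2
    assert sorted(np.round(centers[:, 0], 6)) == [0.0, 100.0]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_voronoi_route_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    points = rng.uniform(0, 14, size=(18, 3))
    spheres = voronoi_alpha_spheres(_cloud_snapshot(points))
    oracle = brute_force_alpha_spheres(points)
    assert len(spheres) == len(oracle)
    got = sorted((tuple(np.round(s.center, 5)), round(s.radius, 5)) for s in spheres)
    want = sorted((tuple(np.round(c, 5)), round(r, 5)) for c, r in oracle)
    assert got == want


@pytest.mark.parametrize("seed", [10, 11])
def test_alpha_sphere_invariants_on_random_clouds(seed):
    rng = np.random.default_rng(seed)
    points = rng.uniform(0, 20, size=(40, 3))
    spheres = voronoi_alpha_spheres(_cloud_snapshot(points))
    for s in spheres:
        assert 2.9 <= s.radius <= 16.0
        d = np.linalg.norm(points - s.center, axis=1)
        # tangent to its four contact atoms, no atom strictly inside
        contact_d = d[[i - 1 for i in s.contact_atoms]]
        assert np.allclose(contact_d, s.radius, atol=1e-6)
        assert (d > s.radius - 1e-6).all()


def test_degenerate_coplanar_cloud_is_an_error():
    pts = [(x, y, 0.0) for x in range(3) for y in range(3)]
    with pytest.raises(StructureError):
        voronoi_alpha_spheres(_cloud_snapshot(pts))


def test_apolar_flag_follows_contact_electronegativity():
    carbon = voronoi_alpha_spheres(_cloud_snapshot(_regular_tetrahedron(6.0), element="C"))
    oxygen = voronoi_alpha_spheres(_cloud_snapshot(_regular_tetrahedron(6.0), element="O"))
    assert carbon[0].apolar and not oxygen[0].apolar


# ---------------------------------------------------------------------------
# clustering


def _sphere(center, radius=1.0):
    return AlphaSphere(np.asarray(center, float), radius, (1, 2, 3, 4), (0, 1, 2, 3), True)


def test_spheres_within_cutoff_form_one_pocket():
    spheres = [_sphere((0, 0, 0)), _sphere((2, 0, 0)), _sphere((0, 2, 0))]
    pockets = cluster_alpha_spheres(spheres, link_cutoff=4.5, min_spheres=3)
    assert len(pockets) == 1 and len(pockets[0].spheres) == 3


def test_distant_spheres_split_and_min_spheres_filters():
    spheres = [_sphere((0, 0, 0)), _sphere((100, 0, 0))]
    assert len(cluster_alpha_spheres(spheres, min_spheres=1)) == 2
    assert cluster_alpha_spheres(spheres, min_spheres=2) == []


def test_single_linkage_chains_are_transitive():
    spheres = [_sphere((0, 0, 0)), _sphere((4, 0, 0)), _sphere((8, 0, 0))]
    pockets = cluster_alpha_spheres(spheres, link_cutoff=4.5, min_spheres=1)
    assert len(pockets) == 1


def test_overlapping_spheres_link_beyond_the_cutoff():
    # a big cavity sphere and a small corridor sphere share volume
    spheres = [_sphere((0, 0, 0), radius=6.0), _sphere((6, 0, 0), radius=3.0), _sphere((7, 0, 0), radius=3.0)]
    pockets = cluster_alpha_spheres(spheres, link_cutoff=4.5, min_spheres=1)
    assert len(pockets) == 1


def test_empty_input_gives_empty_output():
    assert cluster_alpha_spheres([]) == []


def test_pocket_pdb_export_stores_radius_in_bfactor(tmp_path):
    from pocketens.pockets import write_pocket_pdb

    pocket = _pocket([(1.0, 2.0, 3.0)])
    path = tmp_path / "pocket.pdb"
    write_pocket_pdb(pocket, path)
    line = path.read_text().splitlines()[0]
    assert line.startswith("HETATM") and "STP" in line
    assert float(line[60:66]) == pytest.approx(pocket.spheres[0].radius, abs=0.01)


# ---------------------------------------------------------------------------
# active-site selection


def _heme_at_origin():
    return HemeFrame(np.zeros(3), np.array([0, 0, -2.3]), np.array([0, 0, 1.0]))


def _pocket(centers):
    return cluster_alpha_spheres([_sphere(c) for c in centers], min_spheres=1)[0]


def test_distal_pocket_wins_over_proximal():
    distal = _pocket([(0, 0, 5)])
    proximal = _pocket([(0, 0, -5)])
    assert select_active_site([proximal, distal], _heme_at_origin()) is distal


def test_no_pocket_within_max_dist_returns_none():
    far = _pocket([(0, 0, 20)])
    assert select_active_site([far], _heme_at_origin(), max_dist=8.0) is None


def test_nearest_distal_pocket_wins():
    near = _pocket([(0, 0, 4)])
    farther = _pocket([(0, 0, 7)])
    assert select_active_site([farther, near], _heme_at_origin()) is near


# ---------------------------------------------------------------------------
# occupancy grid


def _tiny_ensemble(n):
    snap = _cloud_snapshot(_regular_tetrahedron(6.0))
    snaps = [snap.copy() for _ in range(n)]
    for i, s in enumerate(snaps, start=1):
        s.frame_index = i
    return Ensemble(reference=snap.copy(), snapshots=snaps, aligned=True)


def test_identical_pockets_give_unit_occupancy():
    ens = _tiny_ensemble(4)
    pocket = _pocket([(0, 0, 0)])
    grid = build_occupancy_grid(ens, [pocket] * 4, spacing=0.5)
    core = grid.point_to_flat(np.zeros(3))
    assert grid.occupancy.flat[core] == 1.0


def test_half_present_pocket_gives_half_occupancy():
    ens = _tiny_ensemble(4)
    pocket = _pocket([(0, 0, 0)])
    grid = build_occupancy_grid(ens, [pocket, None, pocket, None], spacing=0.5)
    core = grid.point_to_flat(np.zeros(3))
    assert grid.occupancy.flat[core] == 0.5


def test_occupancy_counts_are_conserved():
    ens = _tiny_ensemble(3)
    pockets = [_pocket([(0, 0, 0)]), _pocket([(1, 0, 0)]), None]
    grid = build_occupancy_grid(ens, pockets, spacing=0.5)
    total = sum(
        rasterize_spheres(grid, p.spheres).sum() for p in pockets if p is not None
    )
    assert grid.counts.sum() == total


def test_unaligned_ensemble_is_an_error():
    ens = _tiny_ensemble(2)
    ens.aligned = False
    with pytest.raises(StructureError):
        build_occupancy_grid(ens, [None, None])


# ---------------------------------------------------------------------------
# grid pocket extraction


def _grid_from_array(occ):
    occ = np.asarray(occ, float)
    return OccupancyGrid(
        origin=np.zeros(3), spacing=1.0, dims=occ.shape, counts=occ * 100, n_snapshots=100
    )


def _blob(grid_shape, center, radius):
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in grid_shape], indexing="ij")
    d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
    return d2 <= radius ** 2


def test_seeded_selection_picks_the_distal_blob():
    shape = (20, 20, 20)
    occ = np.zeros(shape)
    occ[_blob(shape, (10, 10, 14), 3)] = 0.8  # distal
    occ[_blob(shape, (10, 10, 4), 3)] = 0.9  # proximal
    grid = _grid_from_array(occ)
    heme = HemeFrame(np.array([9.5, 9.5, 9.5]), np.array([9.5, 9.5, 7.2]), np.array([0, 0, 1.0]))
    pocket = extract_grid_pocket(grid, 0.5, heme)
    centers = grid.voxel_center(np.array(sorted(pocket.voxel_ids)))
    assert centers[:, 2].min() > 9.5  # entirely on the distal side


def test_no_voxel_above_threshold_is_an_error():
    grid = _grid_from_array(np.full((8, 8, 8), 0.3))
    heme = HemeFrame(np.array([4.0, 4.0, 2.0]), np.array([4.0, 4.0, 0.0]), np.array([0, 0, 1.0]))
    with pytest.raises(StructureError, match="no persistent distal pocket"):
        extract_grid_pocket(grid, 0.5, heme)


def test_bridged_blobs_form_a_single_component():
    shape = (24, 12, 12)
    occ = np.zeros(shape)
    occ[_blob(shape, (6, 6, 6), 3)] = 0.8
    occ[_blob(shape, (16, 6, 6), 3)] = 0.8
    occ[6:17, 6, 6] = 0.7  # bridge
    grid = _grid_from_array(occ)
    heme = HemeFrame(np.array([6.0, 6.0, 2.0]), np.array([6.0, 6.0, 0.0]), np.array([0, 0, 1.0]))
    pocket = extract_grid_pocket(grid, 0.5, heme)
    centers = grid.voxel_center(np.array(sorted(pocket.voxel_ids)))
    assert centers[:, 0].max() > 16.0  # reaches the far blob


def test_raising_threshold_never_grows_the_pocket():
    rng = np.random.default_rng(5)
    shape = (16, 16, 16)
    occ = np.zeros(shape)
    occ[_blob(shape, (8, 8, 8), 5)] = rng.uniform(0.4, 1.0, size=int(_blob(shape, (8, 8, 8), 5).sum()))
    grid = _grid_from_array(occ)
    heme = HemeFrame(np.array([7.5, 7.5, 3.0]), np.array([7.5, 7.5, 1.0]), np.array([0, 0, 1.0]))
    previous = None
    for thr in (0.45, 0.6, 0.75, 0.9):
        try:
            pocket = extract_grid_pocket(grid, thr, heme)
        except StructureError:
            break
        if previous is not None:
            assert pocket.voxel_ids <= previous
        previous = pocket.voxel_ids


# ---------------------------------------------------------------------------
# bottleneck cutting


def _cavity_with_tubes(shape=(20, 20, 20), tubes=((0, 0, 1),)):
    """Ball cavity at the center plus 1-voxel tubes to the +face(s)."""
    occ = np.zeros(shape)
    cavity = _blob(shape, (10, 10, 10), 4)
    occ[cavity] = 1.0
    for direction in tubes:
        pos = np.array([10, 10, 10])
        while all(0 <= pos[d] < shape[d] for d in range(3)):
            occ[tuple(pos)] = 1.0
            pos = pos + np.array(direction)
    grid = _grid_from_array(occ)
    pocket_ids = set(int(v) for v in np.flatnonzero(occ.ravel() >= 0.5))
    # surface = everything strictly outside the occupied region, at the box shell
    surface = set()
    for v in np.flatnonzero(occ.ravel() < 0.5):
        idx = np.unravel_index(v, shape)
        if any(i in (0, shape[d] - 1) for d, i in enumerate(idx)):
            surface.add(int(v))
    core = int(np.ravel_multi_index((10, 10, 10), shape))
    return grid, GridPocket(pocket_ids, 0.5), surface, core, cavity


def test_sealed_cavity_is_returned_unchanged():
    grid, pocket, surface, core, _ = _cavity_with_tubes(tubes=())
    cut = cut_channel_at_bottleneck(pocket, grid, surface, core)
    assert cut.voxel_ids == pocket.voxel_ids and not cut.channel_cut


def test_single_tube_is_cut_back_to_the_cavity():
    grid, pocket, surface, core, cavity = _cavity_with_tubes()
    cut = cut_channel_at_bottleneck(pocket, grid, surface, core)
    assert cut.channel_cut
    removed = pocket.voxel_ids - cut.voxel_ids
    assert removed  # some of the tube is gone
    centers = grid.voxel_center(np.array(sorted(removed)))
    assert (centers[:, 2] > 14.0).all()  # only tube voxels beyond the cavity
    # the cavity body itself is intact
    cavity_ids = set(int(v) for v in np.flatnonzero(cavity.ravel()))
    assert cavity_ids <= cut.voxel_ids


def test_two_tubes_are_cut_independently():
    grid, pocket, surface, core, cavity = _cavity_with_tubes(tubes=((0, 0, 1), (0, 0, -1)))
    cut = cut_channel_at_bottleneck(pocket, grid, surface, core)
    assert cut.channel_cut
    removed = grid.voxel_center(np.array(sorted(pocket.voxel_ids - cut.voxel_ids)))
    assert (removed[:, 2] > 14.0).any() and (removed[:, 2] < 6.0).any()
    cavity_ids = set(int(v) for v in np.flatnonzero(cavity.ravel()))
    assert cavity_ids <= cut.voxel_ids
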