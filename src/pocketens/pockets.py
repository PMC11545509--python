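"""Alpha-sphere pocket detection and ensemble occupancy-grid pockets.

Two tracks mirror the single-structure / trajectory pocket tools of the
field:

* the *sphere track* detects cavities per snapshot by placing alpha
  spheres (spheres tangent to four atoms with no atom inside) at the
  Voronoi vertices of the heavy-atom centers, keeping radii within a
  [r_min, r_max] window, and single-linkage clustering them into pockets;
* the *grid track* rasterizes each snapshot's detected pocket space onto
  a common grid and records, per voxel, the fraction of snapshots in
  which it is part of the pocket (the occupancy), from which a persistent
  pocket is extracted at an occupancy threshold (default 50%).

Default radii are 2.9 Å (minimum) and 16.0 Å (maximum); alpha-sphere
radii are measured center-to-atom-center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree

from .elements import APOLAR_EN_CUTOFF, electronegativity
from .structure_io import Ensemble, HemeFrame, Snapshot, StructureError

__all__ = [
    "AlphaSphere",
    "SpherePocket",
    "OccupancyGrid",
    "GridPocket",
    "voronoi_alpha_spheres",
    "cluster_alpha_spheres",
    "select_active_site",
    "build_occupancy_grid",
    "rasterize_spheres",
    "extract_grid_pocket",
    "cut_channel_at_bottleneck",
    "neighbors26",
]

def write_pocket_pdb(pocket: "SpherePocket", path) -> None:
    """Export a sphere pocket as pseudo-atoms at alpha-sphere centers.

    One HETATM per sphere (residue STP), with the sphere radius stored in
    the B-factor column — the layout single-structure pocket tools use.
    """
    from pathlib import Path

    lines = []
    for i, sphere in enumerate(pocket.spheres, start=1):
        x, y, z = sphere.center
        lines.append(
            f"HETATM{i:>5} APOL STP A{1:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{sphere.radius:6.2f}           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


R_MIN_DEFAULT = 2.9
R_MAX_DEFAULT = 16.0
LINK_CUTOFF_DEFAULT = 4.5
MIN_SPHERES_DEFAULT = 3


@dataclass
class AlphaSphere:
    """Sphere tangent to four atoms with no atom center strictly inside."""

    center: np.ndarray
    radius: float
    contact_atoms: tuple[int, int, int, int]  # atom serials
    contact_indices: tuple[int, int, int, int]  # indices into the snapshot atom list
    apolar: bool


@dataclass
class SpherePocket:
    """Single-linkage cluster of alpha spheres from one snapshot."""

    spheres: list[AlphaSphere]
    snapshot_index: int
    centroid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.spheres:
            raise ValueError("SpherePocket must be non-empty")
        self.centroid = np.mean([s.center for s in self.spheres], axis=0)

    @property
    def sphere_ids(self) -> set[int]:
        return set(range(len(self.spheres)))

    def lining_atom_indices(self) -> set[int]:
        out: set[int] = set()
        for sphere in self.spheres:
            out.update(sphere.contact_indices)
        return out


@dataclass
class OccupancyGrid:
    """Regular grid of per-voxel pocket occupancy frequencies in [0, 1]."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    counts: np.ndarray  # int, per-voxel number of snapshots covering it
    n_snapshots: int

    @property
    def occupancy(self) -> np.ndarray:
        return self.counts / max(self.n_snapshots, 1)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_center(self, flat: np.ndarray | int) -> np.ndarray:
        idx = np.array(np.unravel_index(flat, self.dims)).T
        return self.origin + (idx + 0.5) * self.spacing

    def all_centers(self) -> np.ndarray:
        ii, jj, kk = np.meshgrid(*[np.arange(d) for d in self.dims], indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.origin + (idx + 0.5) * self.spacing

    def point_to_flat(self, point: np.ndarray) -> int | None:
        idx = np.floor((np.asarray(point) - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.dims)):
            return None
        return int(np.ravel_multi_index(tuple(idx), self.dims))


@dataclass
class GridPocket:
    """26-connected set of grid voxels above the occupancy threshold."""

    voxel_ids: set[int]
    threshold: float
    channel_cut: bool = False

    def volume(self, grid: OccupancyGrid) -> float:
        return len(self.voxel_ids) * grid.spacing ** 3


# ---------------------------------------------------------------------------
# Alpha spheres


def _circumspheres(points: np.ndarray, simplices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch circumcenters/radii of tetrahedra; returns (centers, radii, ok)."""
    p = points[simplices]  # (m, 4, 3)
    a = p[:, 0]
    rhs_pts = p[:, 1:] - a[:, None, :]  # (m, 3, 3)
    mat = 2.0 * rhs_pts
    sq = (p ** 2).sum(axis=2)
    rhs = sq[:, 1:] - sq[:, 0][:, None]
    # shift rhs for the translated frame: |pi|^2-|p0|^2 - 2 a.(pi-p0)
    rhs = rhs - 2.0 * np.einsum("mij,mj->mi", rhs_pts, a)
    det = np.linalg.det(mat)
    ok = np.abs(det) > 1e-10
    centers = np.full((len(simplices), 3), np.nan)
    if ok.any():
        centers[ok] = np.linalg.solve(mat[ok], rhs[ok][..., None])[..., 0] + a[ok]
    radii = np.linalg.norm(centers - a, axis=1)
    return centers, radii, ok


def voronoi_alpha_spheres(
    snapshot: Snapshot,
    r_min: float = R_MIN_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
    en_cutoff: float = APOLAR_EN_CUTOFF,
) -> list[AlphaSphere]:
    """Place alpha spheres at the Voronoi vertices of heavy-atom centers.

    Each Delaunay tetrahedron of the heavy atoms contributes one candidate
    sphere (center = circumcenter = Voronoi vertex, radius = distance to
    its four defining atoms).  Spheres with radius outside [r_min, r_max]
    or center outside the convex hull of the atoms are discarded.  A
    sphere is apolar when at least three of its four contact atoms have
    electronegativity below ``en_cutoff``.
    """
    heavy = snapshot.heavy_atoms()
    if len(heavy) < 4:
        raise StructureError("need at least 4 heavy atoms for alpha-sphere detection")
    points = np.array([a.coords for a in heavy])
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise StructureError(f"degenerate atom geometry: {exc}") from exc

    centers, radii, ok = _circumspheres(points, tri.simplices)
    keep = ok & (radii >= r_min) & (radii <= r_max)
    if keep.any():
        inside = tri.find_simplex(centers[keep]) >= 0
        keep_idx = np.flatnonzero(keep)[inside]
    else:
        keep_idx = np.array([], dtype=int)

    apolar_flags = np.array([electronegativity(a.element) < en_cutoff for a in heavy])
    heavy_serials = np.array([a.serial for a in heavy])
    heavy_snapshot_idx = np.array(
        [i for i, a in enumerate(snapshot.atoms) if a.element.upper() != "H"]
    )

    spheres: list[AlphaSphere] = []
    for si in keep_idx:
        simplex = tri.simplices[si]
        n_apolar = int(apolar_flags[simplex].sum())
        spheres.append(
            AlphaSphere(
                center=centers[si],
                radius=float(radii[si]),
                contact_atoms=tuple(int(s) for s in heavy_serials[simplex]),
                contact_indices=tuple(int(s) for s in heavy_snapshot_idx[simplex]),
                apolar=n_apolar >= 3,
            )
        )
    return spheres


def cluster_alpha_spheres(
    spheres: Sequence[AlphaSphere],
    link_cutoff: float = LINK_CUTOFF_DEFAULT,
    min_spheres: int = MIN_SPHERES_DEFAULT,
    snapshot_index: int = 0,
) -> list[SpherePocket]:
    """Single-linkage clustering of alpha spheres into pockets.

    Two spheres are linked when their centers are within ``link_cutoff``
    Å *or* when the spheres overlap (center distance below the sum of
    radii): a large cavity sphere and the smaller sphere of an attached
    corridor share interior volume and belong to one pocket even when
    their centers are far apart.  Connected components are pockets;
    clusters smaller than ``min_spheres`` are discarded.
    """
    if not spheres:
        return []
    centers = np.array([s.center for s in spheres])
    radii = np.array([s.radius for s in spheres])
    tree = cKDTree(centers)
    reach = max(link_cutoff, 2.0 * float(radii.max()))
    candidate = np.array(sorted(tree.query_pairs(reach)), dtype=int)
    if len(candidate):
        d = np.linalg.norm(centers[candidate[:, 0]] - centers[candidate[:, 1]], axis=1)
        linked = (d <= link_cutoff) | (d < radii[candidate[:, 0]] + radii[candidate[:, 1]])
        pairs = candidate[linked]
    else:
        pairs = candidate
    n = len(spheres)
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    pockets: list[SpherePocket] = []
    for comp in range(n_comp):
        members = [spheres[i] for i in np.flatnonzero(labels == comp)]
        if len(members) >= min_spheres:
            pockets.append(SpherePocket(spheres=members, snapshot_index=snapshot_index))
    return pockets


def select_active_site(
    pockets: Sequence[SpherePocket],
    heme: HemeFrame,
    max_dist: float = 8.0,
) -> SpherePocket | None:
    """Pick the pocket on the distal side of the heme iron nearest to Fe.

    A pocket qualifies if it contains a sphere whose center c satisfies
    (c − Fe)·distal_axis > 0 and |c − Fe| ≤ max_dist; among qualifying
    pockets the one whose closest such sphere is nearest Fe wins.  None
    when no pocket qualifies (a valid per-snapshot outcome).
    """
    best: SpherePocket | None = None
    best_dist = np.inf
    for pocket in pockets:
        centers = np.array([s.center for s in pocket.spheres])
        rel = centers - heme.fe_coord
        distal = rel @ heme.distal_axis > 0
        dist = np.linalg.norm(rel, axis=1)
        qualifying = distal & (dist <= max_dist)
        if qualifying.any():
            d = float(dist[qualifying].min())
            if d < best_dist:
                best, best_dist = pocket, d
    return best


# ---------------------------------------------------------------------------
# Occupancy grid


def rasterize_spheres(grid: OccupancyGrid, spheres: Iterable[AlphaSphere]) -> np.ndarray:
    """Boolean per-voxel mask: voxel center inside at least one sphere."""
    mask = np.zeros(grid.dims, dtype=bool)
    dims = np.array(grid.dims)
    for sphere in spheres:
        lo = np.floor((sphere.center - sphere.radius - grid.origin) / grid.spacing - 0.5).astype(int)
        hi = np.ceil((sphere.center + sphere.radius - grid.origin) / grid.spacing - 0.5).astype(int)
        lo = np.clip(lo, 0, dims - 1)
        hi = np.clip(hi, 0, dims - 1)
        ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1)
        centers = grid.origin + (idx + 0.5) * grid.spacing
        inside = ((centers - sphere.center) ** 2).sum(axis=-1) <= sphere.radius ** 2
        mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= inside
    return mask


def build_occupancy_grid(
    ensemble: Ensemble,
    per_snapshot_pockets: Sequence[SpherePocket | None],
    spacing: float = 1.0,
    margin: float = 2.0,
) -> OccupancyGrid:
    """Accumulate per-snapshot pocket space into an occupancy-frequency grid.

    The grid bounding box covers all pocket spheres plus ``margin`` Å; a
    voxel counts as occupied in a snapshot iff its center lies inside at
    least one alpha sphere of that snapshot's pocket.
    """
    if not ensemble.aligned:
        raise StructureError("ensemble must be aligned before building an occupancy grid")
    if len(per_snapshot_pockets) != len(ensemble.snapshots):
        raise ValueError("per_snapshot_pockets length must match ensemble size")

    all_spheres = [s for p in per_snapshot_pockets if p is not None for s in p.spheres]
    if not all_spheres:
        raise StructureError("no pocket spheres in any snapshot")
    centers = np.array([s.center for s in all_spheres])
    radii = np.array([s.radius for s in all_spheres])
    lo = (centers - radii[:, None]).min(axis=0) - margin
    hi = (centers + radii[:, None]).max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) for d in range(3))

    grid = OccupancyGrid(
        origin=lo,
        spacing=spacing,
        dims=dims,
        counts=np.zeros(dims, dtype=np.int32),
        n_snapshots=len(ensemble.snapshots),
    )
    for pocket in per_snapshot_pockets:
        if pocket is None:
            continue
        grid.counts += rasterize_spheres(grid, pocket.spheres)
    return grid


# ---------------------------------------------------------------------------
# Grid pocket extraction

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

_OFFSETS26 = np.array(
    [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
)


def neighbors26(flat: int, dims: tuple[int, int, int]) -> list[int]:
    """Flat indices of the 26-neighborhood of a voxel (bounds-checked)."""
    idx = np.array(np.unravel_index(flat, dims))
    nbr = idx + _OFFSETS26
    good = np.all((nbr >= 0) & (nbr < np.array(dims)), axis=1)
    return [int(f) for f in np.ravel_multi_index(nbr[good].T, dims)]


def extract_grid_pocket(
    grid: OccupancyGrid,
    threshold: float = 0.5,
    heme: HemeFrame | None = None,
    seed_offset: float = 4.0,
    max_dist: float = 8.0,
) -> GridPocket:
    """Threshold the grid and return the 26-connected distal-side component.

    The component containing (or nearest to, within ``max_dist``) the seed
    point Fe + ``seed_offset``·distal_axis is returned.  Threshold
    comparison is inclusive (≥), so "at least 50% frequency" keeps voxels
    at exactly 0.5.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    mask = grid.occupancy >= threshold
    if not mask.any():
        raise StructureError("no persistent distal pocket: no voxel reaches the threshold")
    labels, n_comp = ndimage.label(mask, structure=_STRUCT26)

    if heme is None:
        # no heme frame: return the largest component
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        target = int(np.argmax(sizes)) + 1
    else:
        seed = heme.fe_coord + seed_offset * heme.distal_axis
        seed_flat = grid.point_to_flat(seed)
        target = 0
        if seed_flat is not None:
            target = int(labels.flat[seed_flat])
        if target == 0:
            occupied = np.argwhere(labels > 0)
            centers = grid.origin + (occupied + 0.5) * grid.spacing
            dist = np.linalg.norm(centers - seed, axis=1)
            if dist.size and dist.min() <= max_dist:
                nearest = occupied[int(np.argmin(dist))]
                target = int(labels[tuple(nearest)])
        if target == 0:
            raise StructureError("no persistent distal pocket near the heme seed point")

    flat_ids = set(int(f) for f in np.flatnonzero(labels.ravel() == target))
    return GridPocket(voxel_ids=flat_ids, threshold=threshold, channel_cut=False)


# ---------------------------------------------------------------------------
# Bottleneck cutting


def _bfs_distances(start: set[int], members: set[int], dims: tuple[int, int, int]) -> dict[int, int]:
    dist = {v: 0 for v in start}
    frontier = list(start)
    d = 0
    while frontier:
        d += 1
        nxt: list[int] = []
        for v in frontier:
            for w in neighbors26(v, dims):
                if w in members and w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    return dist


def cut_channel_at_bottleneck(
    pocket: GridPocket,
    grid: OccupancyGrid,
    surface_voxels: set[int],
    core_voxel: int | None = None,
) -> GridPocket:
    """Cut surface-reaching channels off a grid pocket at their bottleneck.

    Voxels of the pocket that touch the solvent exterior are exit voxels.
    For each 26-connected exit group, grid-geodesic depth layers are
    grown inward from the exits; layer sizes follow the corridor
    cross-section until they swell into the pocket body, and the
    narrowest layer before that swell is the bottleneck.  Everything
    from the bottleneck outward is removed, and any part of the pocket
    disconnected from the core by the removal is dropped.  A sealed
    pocket is returned unchanged with ``channel_cut`` false.
    """
    members = set(pocket.voxel_ids)
    exits = {
        v for v in members if any(w in surface_voxels for w in neighbors26(v, grid.dims))
    }
    if not exits:
        return GridPocket(voxel_ids=members, threshold=pocket.threshold, channel_cut=False)

    if core_voxel is None or core_voxel not in members:
        # fall back: the voxel geodesically farthest from every exit
        dist_from_exits = _bfs_distances(exits, members, grid.dims)
        core_voxel = max(members, key=lambda v: dist_from_exits.get(v, -1))

    # group exits by 26-connectivity among themselves (one group per branch)
    remaining = set(exits)
    groups: list[set[int]] = []
    while remaining:
        seed = remaining.pop()
        group = {seed}
        stack = [seed]
        while stack:
            v = stack.pop()
            for w in neighbors26(v, grid.dims):
                if w in remaining:
                    remaining.remove(w)
                    group.add(w)
                    stack.append(w)
        groups.append(group)

    removed: set[int] = set()
    for group in groups:
        # geodesic depth from this branch's surface exits into the pocket:
        # layer sizes track the channel cross-section while the corridor
        # is traversed, then swell once the pocket body is reached — the
        # narrowest layer before that swell is the bottleneck
        depth = _bfs_distances(group, members, grid.dims)
        layers: dict[int, set[int]] = {}
        for v, d in depth.items():
            layers.setdefault(d, set()).add(v)
        ordered = sorted(layers)
        sizes = [len(layers[d]) for d in ordered]
        # first local minimum going inward: the throat where the corridor
        # is narrowest before layer sizes swell into the pocket body
        k_star = None
        for i in range(1, len(ordered) - 1):
            if sizes[i] < sizes[i + 1] and sizes[i] <= min(sizes[1 : i + 1]):
                k_star = ordered[i]
                break
        if k_star is None:
            continue
        if depth.get(core_voxel, np.inf) < k_star:
            continue  # never cut the pocket core away
        # the bottleneck layer becomes the pocket's new mouth; everything
        # on its surface side is removed
        removed |= {v for v, d in depth.items() if d < k_star}

    cut_layer = removed
    if not cut_layer:
        return GridPocket(voxel_ids=members, threshold=pocket.threshold, channel_cut=False)

    kept = members - cut_layer
    # retain only the component still containing the core
    comp: set[int] = set()
    if core_voxel in kept:
        comp = {core_voxel}
        stack = [core_voxel]
        while stack:
            v = stack.pop()
            for w in neighbors26(v, grid.dims):
                if w in kept and w not in comp:
                    comp.add(w)
                    stack.append(w)
    return GridPocket(voxel_ids=comp, threshold=pocket.threshold, channel_cut=True)
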