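"""Per-snapshot binding-site descriptors.

For each snapshot the pocket is characterized by its volume (union of
alpha spheres, or grid-restricted voxel count), the solvent-accessible
surface area of its lining atoms, a sphere-normalized shape factor, and
a hydrophobicity fraction (apolar / total SASA).  When both detection
tracks find a site, the track with the smaller volume is taken as the
active site and all descriptors are reported as a coherent set from that
track (the "min rule"): a smaller sphere-track volume means the grid
region split into several pockets, while a smaller grid-track volume
means the sphere track leaked through an open channel onto the surface.

The reported SASA covers pocket-lining atoms only and therefore does not
represent the full closed surface of the cavity, while the volume covers
the entire pocket; shape factors below 1 are possible and expected for
buried sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .elements import APOLAR_EN_CUTOFF, electronegativity, vdw_radius
from .pockets import AlphaSphere, GridPocket, OccupancyGrid, SpherePocket
from .structure_io import Snapshot

__all__ = [
    "SnapshotDescriptors",
    "sphere_union_volume",
    "voxel_volume",
    "pocket_sasa",
    "shape_factor",
    "hydrophobicity",
    "apply_min_rule",
    "fibonacci_sphere_points",
    "grid_track_snapshot_volume",
]

PROBE_RADIUS_DEFAULT = 1.4
SASA_POINTS_DEFAULT = 960


@dataclass
class SnapshotDescriptors:
    """Descriptor set for one snapshot after track reconciliation."""

    frame_index: int
    volume_sphere_track: float | None
    volume_grid_track: float | None
    volume: float
    source: str  # "sphere-track" | "grid-track" | "none"
    sasa_total: float
    sasa_apolar: float
    shape: float
    hydrophobicity: float
    site_found: bool
    open_channel_ids: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# Volume


def sphere_union_volume(
    spheres: Sequence[AlphaSphere],
    n_samples: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo volume (Å³) of a union of spheres.

    Uniform samples in the joint bounding box; volume = inside fraction ×
    box volume.  Reproducible for a fixed seed.
    """
    if not spheres:
        return 0.0
    centers = np.array([s.center for s in spheres])
    radii = np.array([s.radius for s in spheres])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    box_volume = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = np.zeros(n_samples, dtype=bool)
    r2 = radii ** 2
    chunk = max(1, 2_000_000 // max(len(centers), 1))
    for start in range(0, n_samples, chunk):
        block = samples[start : start + chunk]
        d2 = ((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        inside[start : start + chunk] = np.any(d2 <= r2[None, :], axis=1)
    return float(inside.mean() * box_volume)


def voxel_volume(voxel_ids: Iterable[int], spacing: float) -> float:
    """Volume (Å³) of a voxel set: count × spacing³."""
    return len(set(voxel_ids)) * spacing ** 3


def grid_track_snapshot_volume(
    grid: OccupancyGrid,
    grid_pocket: GridPocket,
    frame_mask: np.ndarray,
) -> float:
    """Per-snapshot grid-track volume: persistent-pocket voxels covered by
    this frame's own pocket space, times the voxel volume."""
    flat = frame_mask.ravel()
    covered = sum(1 for v in grid_pocket.voxel_ids if flat[v])
    return covered * grid.spacing ** 3


# ---------------------------------------------------------------------------
# SASA


def fibonacci_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def pocket_sasa(
    snapshot: Snapshot,
    pocket: SpherePocket | set[int],
    probe: float = PROBE_RADIUS_DEFAULT,
    n_points: int = SASA_POINTS_DEFAULT,
    en_cutoff: float = APOLAR_EN_CUTOFF,
    grid: OccupancyGrid | None = None,
    contact_scale: float = 2.0,
    voxel_contact_dist: float = 3.0,
) -> tuple[float, float]:
    """SASA (total, apolar) in Å² over pocket-lining atoms.

    Lining atoms are the alpha-sphere contact atoms of a sphere-track
    pocket, or (grid track) heavy atoms within ``voxel_contact_dist`` Å
    of a pocket voxel center.  Per-atom SASA uses a fixed deterministic
    sphere-point lattice; occlusion is tested against all heavy atoms of
    the snapshot.  A surface point is apolar iff at least three atoms of
    electronegativity below ``en_cutoff`` are in contact with it, where
    "in contact" means the point lies within (vdW + ``contact_scale`` ×
    probe) of the atom center.
    """
    heavy = snapshot.heavy_atoms()
    heavy_coords = np.array([a.coords for a in heavy]) if heavy else np.zeros((0, 3))
    heavy_vdw = np.array([a.vdw for a in heavy])
    heavy_apolar = np.array([electronegativity(a.element) < en_cutoff for a in heavy])
    heavy_index_of = {i: j for j, i in enumerate(
        i for i, a in enumerate(snapshot.atoms) if a.element.upper() != "H"
    )}

    if isinstance(pocket, SpherePocket):
        lining_snapshot_idx = pocket.lining_atom_indices()
    else:
        if grid is None:
            raise ValueError("grid is required for voxel-based lining selection")
        voxel_centers = grid.voxel_center(np.array(sorted(pocket), dtype=int))
        if voxel_centers.ndim == 1:
            voxel_centers = voxel_centers[None, :]
        tree = cKDTree(voxel_centers)
        lining_snapshot_idx = set()
        for i, a in enumerate(snapshot.atoms):
            if a.element.upper() == "H":
                continue
            if tree.query_ball_point(a.coords, r=voxel_contact_dist):
                lining_snapshot_idx.add(i)

    lining = sorted(heavy_index_of[i] for i in lining_snapshot_idx if i in heavy_index_of)
    if not lining:
        return 0.0, 0.0

    unit = fibonacci_sphere_points(n_points)
    occl_tree = cKDTree(heavy_coords)
    max_vdw = float(heavy_vdw.max())
    contact_radii = heavy_vdw + contact_scale * probe

    total = 0.0
    apolar = 0.0
    for j in lining:
        r = heavy_vdw[j] + probe
        pts = heavy_coords[j] + r * unit
        # occlusion: point inside any *other* atom's probe-extended sphere
        nbrs = occl_tree.query_ball_point(heavy_coords[j], r=r + max_vdw + probe)
        nbrs = [k for k in nbrs if k != j]
        accessible = np.ones(n_points, dtype=bool)
        if nbrs:
            nbr_coords = heavy_coords[nbrs]
            nbr_r = heavy_vdw[np.array(nbrs)] + probe
            d2 = ((pts[:, None, :] - nbr_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = ~np.any(d2 < (nbr_r ** 2)[None, :] - 1e-12, axis=1)
        n_acc = int(accessible.sum())
        if n_acc == 0:
            continue
        point_area = 4.0 * math.pi * r * r / n_points
        total += n_acc * point_area
        # apolar classification of the accessible points
        acc_pts = pts[accessible]
        cand = occl_tree.query_ball_point(heavy_coords[j], r=r + contact_radii.max())
        cand = np.array(cand, dtype=int)
        d2 = ((acc_pts[:, None, :] - heavy_coords[cand][None, :, :]) ** 2).sum(axis=2)
        in_contact = d2 <= (contact_radii[cand] ** 2)[None, :]
        n_apolar_contacts = (in_contact & heavy_apolar[cand][None, :]).sum(axis=1)
        apolar += int((n_apolar_contacts >= 3).sum()) * point_area
    return total, apolar


# ---------------------------------------------------------------------------
# Shape and hydrophobicity


def shape_factor(sasa_total: float, volume: float) -> float:
    """Sphere-normalized surface-to-volume ratio.

    Returns A / ((36π)^(1/3) · V^(2/3)); a perfect sphere scores exactly
    1, branched or irregular pockets score above 1.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    return float(sasa_total / ((36.0 * math.pi) ** (1.0 / 3.0) * volume ** (2.0 / 3.0)))


def hydrophobicity(sasa_apolar: float, sasa_total: float) -> float:
    """Apolar fraction of the pocket SASA (NaN when the total is zero)."""
    if sasa_apolar < 0 or sasa_total < 0:
        raise ValueError("SASA values must be non-negative")
    if sasa_apolar > sasa_total + 1e-9:
        raise ValueError("apolar SASA exceeds total SASA")
    if sasa_total == 0:
        return float("nan")
    return float(min(sasa_apolar / sasa_total, 1.0))


# ---------------------------------------------------------------------------
# Min rule


def apply_min_rule(
    frame_index: int,
    sphere_track: tuple[float, float, float] | None,
    grid_track: tuple[float, float, float] | None,
    open_channel_ids: tuple[int, ...] = (),
) -> SnapshotDescriptors:
    """Reconcile the two tracks: the smaller-volume track is the active site.

    Each track is a (volume, sasa_total, sasa_apolar) triple or None when
    the track found no site.  The chosen track supplies volume and SASA
    as a coherent set, from which shape and hydrophobicity follow.  Ties
    go to the sphere track.
    """
    if sphere_track is None and grid_track is None:
        return SnapshotDescriptors(
            frame_index=frame_index,
            volume_sphere_track=None,
            volume_grid_track=None,
            volume=0.0,
            source="none",
            sasa_total=0.0,
            sasa_apolar=0.0,
            shape=float("nan"),
            hydrophobicity=float("nan"),
            site_found=False,
            open_channel_ids=open_channel_ids,
        )

    v_sphere = sphere_track[0] if sphere_track is not None else None
    v_grid = grid_track[0] if grid_track is not None else None
    if sphere_track is not None and (grid_track is None or v_sphere <= v_grid):
        chosen, source = sphere_track, "sphere-track"
    else:
        chosen, source = grid_track, "grid-track"

    volume, sasa_total, sasa_apolar = chosen
    shape = shape_factor(sasa_total, volume) if volume > 0 else float("nan")
    return SnapshotDescriptors(
        frame_index=frame_index,
        volume_sphere_track=v_sphere,
        volume_grid_track=v_grid,
        volume=volume,
        source=source,
        sasa_total=sasa_total,
        sasa_apolar=sasa_apolar,
        shape=shape,
        hydrophobicity=hydrophobicity(sasa_apolar, sasa_total),
        site_found=True,
        open_channel_ids=open_channel_ids,
    )
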