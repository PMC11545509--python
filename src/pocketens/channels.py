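"""Channel detection, per-snapshot openness, accessibility and direction.

A channel is a connected corridor of pocket space leading from the
buried active site to the solvent exterior.  Channels are found on the
ensemble occupancy grid by thresholding at a descending ladder of
isovalues and testing 26-connectivity from the pocket core to the
surface; the largest isovalue at which a given surface exit stays
connected is that channel's opening frequency.  Accessibility — the
percentage of snapshots with at least one open channel — is a
per-snapshot property evaluated against each frame's own solvent
exterior, and can exceed any single channel's opening frequency.

Direction classes follow the conserved fold nomenclature: channels whose
flanking secondary-structure elements all belong to the membrane-facing
set (helices A, A′, B, B′, F′, G′ and the β-sheets) point toward the
membrane; mixed flanking points perpendicular to the N-terminal helix;
no membrane-set flanking points toward the cytosol.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .pockets import GridPocket, OccupancyGrid, neighbors26, _STRUCT26
from .structure_io import HemeFrame, Snapshot, SSEAnnotation

__all__ = [
    "ChannelPath",
    "blocked_mask",
    "frame_exterior_mask",
    "ensemble_exterior_mask",
    "detect_channels",
    "snapshot_open",
    "accessibility",
    "classify_direction",
    "flag_solvent_channel",
    "channel_lining_residues",
    "estimate_nterm_axis",
    "MEMBRANE_HELICES",
    "default_threshold_ladder",
]

MEMBRANE_HELICES = {"A", "A′", "B", "B′", "F′", "G′"}
_SHEET_RE = re.compile(r"^(β|beta|B?\d+-\d+$)", re.IGNORECASE)

DIRECTION_MEMBRANE = "membrane-directed"
DIRECTION_PERPENDICULAR = "perpendicular"
DIRECTION_CYTOSOLIC = "cytosolic"


@dataclass
class ChannelPath:
    """One surface exit of the active-site pocket space."""

    channel_id: int
    voxel_ids: tuple[int, ...]  # ordered core → surface
    exit_voxels: frozenset[int]
    exit_zone: frozenset[int]  # exit voxels dilated for per-frame matching
    opening_frequency: float
    lining_residues: list[tuple[str, int]] = dataclass_field(default_factory=list)
    flanking_sse: set[str] = dataclass_field(default_factory=set)
    direction_class: str | None = None
    is_solvent_channel: bool = False


def default_threshold_ladder(step: float = 0.05) -> np.ndarray:
    """Descending isovalue ladder 0.95 … 0.05 (default step 0.05)."""
    n = int(round((0.95 - 0.05) / step)) + 1
    return np.round(np.linspace(0.95, 0.05, n), 10)


# ---------------------------------------------------------------------------
# Solvent exterior


def blocked_mask(grid: OccupancyGrid, coords: np.ndarray, radii: np.ndarray, probe: float = 1.4) -> np.ndarray:
    """Voxels whose center lies within vdW+probe of any atom."""
    mask = np.zeros(grid.dims, dtype=bool)
    dims = np.array(grid.dims)
    for center, vdw in zip(coords, radii):
        r = vdw + probe
        lo = np.floor((center - r - grid.origin) / grid.spacing - 0.5).astype(int)
        hi = np.ceil((center + r - grid.origin) / grid.spacing - 0.5).astype(int)
        lo = np.clip(lo, 0, dims - 1)
        hi = np.clip(hi, 0, dims - 1)
        ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1)
        centers = grid.origin + (idx + 0.5) * grid.spacing
        inside = ((centers - center) ** 2).sum(axis=-1) <= r * r
        mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= inside
    return mask


def _exterior_from_free(free: np.ndarray, structure: np.ndarray | None = None) -> np.ndarray:
    """Flood fill: free-space components touching the grid boundary.

    Solvent percolation uses face (6-)connectivity by default — a probe
    cannot squeeze through a voxel corner contact."""
    if structure is None:
        structure = ndimage.generate_binary_structure(3, 1)
    labels, _ = ndimage.label(free, structure=structure)
    boundary_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    boundary_labels = boundary_labels[boundary_labels > 0]
    return np.isin(labels, boundary_labels)


def frame_exterior_mask(grid: OccupancyGrid, snapshot: Snapshot, probe: float = 1.4) -> np.ndarray:
    """Solvent exterior for one frame: flood fill outside its vdW+probe volume."""
    heavy = snapshot.heavy_atoms()
    coords = np.array([a.coords for a in heavy])
    radii = np.array([a.vdw for a in heavy])
    return _exterior_from_free(~blocked_mask(grid, coords, radii, probe))


def ensemble_exterior_mask(
    grid: OccupancyGrid,
    snapshots: Sequence[Snapshot],
    probe: float = 1.4,
    blocked_fraction: float = 0.5,
    corridor_cutoff: float | None = 0.05,
) -> np.ndarray:
    """Consensus solvent far-field over an aligned ensemble.

    A voxel counts as blocked when it lies inside the vdW+probe volume in
    at least ``blocked_fraction`` of the frames, or — with
    ``corridor_cutoff`` set — when its pocket occupancy reaches that
    cutoff (so the flood fill cannot run down a transiently open channel
    corridor and flag the pocket mouth itself as solvent).  The exterior
    is the flood fill from the grid boundary over the remaining voxels.
    """
    counts = np.zeros(grid.dims, dtype=np.int32)
    for snap in snapshots:
        heavy = snap.heavy_atoms()
        coords = np.array([a.coords for a in heavy])
        radii = np.array([a.vdw for a in heavy])
        counts += blocked_mask(grid, coords, radii, probe)
    blocked = counts >= blocked_fraction * len(snapshots)
    if corridor_cutoff is not None:
        blocked |= grid.occupancy >= corridor_cutoff
    return _exterior_from_free(~blocked)


# ---------------------------------------------------------------------------
# Channel detection


def _component_of(mask_flat: np.ndarray, seed: int, dims: tuple[int, int, int]) -> set[int]:
    if not mask_flat[seed]:
        return set()
    comp = {seed}
    stack = [seed]
    while stack:
        v = stack.pop()
        for w in neighbors26(v, dims):
            if mask_flat[w] and w not in comp:
                comp.add(w)
                stack.append(w)
    return comp


def _exit_voxels(comp: set[int], exterior_flat: np.ndarray, dims: tuple[int, int, int]) -> set[int]:
    return {v for v in comp if any(exterior_flat[w] for w in neighbors26(v, dims))}


def _cluster_voxels(voxels: set[int], dims: tuple[int, int, int]) -> list[set[int]]:
    remaining = set(voxels)
    groups: list[set[int]] = []
    while remaining:
        seed = remaining.pop()
        group = {seed}
        stack = [seed]
        while stack:
            v = stack.pop()
            for w in neighbors26(v, dims):
                if w in remaining:
                    remaining.remove(w)
                    group.add(w)
                    stack.append(w)
        groups.append(group)
    return groups


def _dilate(voxels: set[int], dims: tuple[int, int, int], steps: int = 2) -> set[int]:
    out = set(voxels)
    frontier = set(voxels)
    for _ in range(steps):
        new = set()
        for v in frontier:
            for w in neighbors26(v, dims):
                if w not in out:
                    new.add(w)
        out |= new
        frontier = new
    return out


def _shortest_path(
    mask_flat: np.ndarray, start: int, targets: set[int], dims: tuple[int, int, int]
) -> tuple[int, ...]:
    """BFS path (flat voxel ids) from start to the nearest target voxel."""
    prev: dict[int, int | None] = {start: None}
    frontier = [start]
    hit: int | None = start if start in targets else None
    while frontier and hit is None:
        nxt: list[int] = []
        for v in frontier:
            for w in neighbors26(v, dims):
                if mask_flat[w] and w not in prev:
                    prev[w] = v
                    if w in targets:
                        hit = w
                        break
                    nxt.append(w)
            if hit is not None:
                break
        frontier = nxt
    if hit is None:
        return (start,)
    path = [hit]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])  # type: ignore[arg-type]
    return tuple(reversed(path))


def detect_channels(
    grid: OccupancyGrid,
    pocket: GridPocket,
    surface: np.ndarray | set[int],
    core_voxel: int,
    threshold_ladder: np.ndarray | None = None,
    top_n: int = 3,
) -> list[ChannelPath]:
    """Detect surface-exit channels and their opening frequencies.

    The grid is thresholded at each ladder isovalue; distinct 26-connected
    surface-exit regions of the core component define channels, and a
    channel's opening frequency is the largest isovalue at which its exit
    stays connected to the core.  Channels are ranked by opening
    frequency; the ``top_n`` most frequently open are returned.
    """
    if threshold_ladder is None:
        threshold_ladder = default_threshold_ladder()
    ladder = np.sort(np.asarray(threshold_ladder, dtype=float))[::-1]

    if isinstance(surface, set):
        exterior_flat = np.zeros(grid.n_voxels, dtype=bool)
        exterior_flat[list(surface)] = True
    else:
        exterior_flat = np.asarray(surface).ravel().copy()

    occ_flat = grid.occupancy.ravel()
    f_min = ladder[-1]
    # the surface proper excludes corridor voxels: exits are where pocket
    # space at the lowest isovalue borders genuinely non-pocket solvent
    exterior_flat &= occ_flat < f_min
    comp_low = _component_of(occ_flat >= f_min, core_voxel, grid.dims)
    if not comp_low:
        return []
    exits_low = _exit_voxels(comp_low, exterior_flat, grid.dims)
    if not exits_low:
        return []
    clusters = _cluster_voxels(exits_low, grid.dims)

    channels: list[ChannelPath] = []
    for cluster in clusters:
        freq = None
        for f in ladder:
            comp = _component_of(occ_flat >= f, core_voxel, grid.dims)
            if comp & cluster:
                freq = float(f)
                break
        if freq is None:
            continue
        path_mask = occ_flat >= freq
        path = _shortest_path(path_mask, core_voxel, cluster, grid.dims)
        channels.append(
            ChannelPath(
                channel_id=0,
                voxel_ids=path,
                exit_voxels=frozenset(cluster),
                exit_zone=frozenset(_dilate(cluster, grid.dims, steps=2)),
                opening_frequency=freq,
            )
        )

    channels.sort(key=lambda c: -c.opening_frequency)
    channels = channels[:top_n]
    for rank, channel in enumerate(channels, start=1):
        channel.channel_id = rank
    return channels


# ---------------------------------------------------------------------------
# Per-snapshot openness


def snapshot_open(
    frame_mask: np.ndarray,
    channel: ChannelPath,
    frame_exterior: np.ndarray,
    grid: OccupancyGrid,
    core_voxel: int,
) -> bool:
    """True iff this frame's pocket space connects the core to the surface
    through the given channel's exit region."""
    comp = _component_of(frame_mask.ravel(), core_voxel, grid.dims)
    if not comp:
        return False
    exits = _exit_voxels(comp, frame_exterior.ravel(), grid.dims)
    return bool(exits & channel.exit_zone)


def frame_reaches_surface(
    frame_mask: np.ndarray,
    frame_exterior: np.ndarray,
    grid: OccupancyGrid,
    core_voxel: int,
) -> bool:
    """True iff the frame's pocket space connects the core to any surface exit."""
    comp = _component_of(frame_mask.ravel(), core_voxel, grid.dims)
    if not comp:
        return False
    return bool(_exit_voxels(comp, frame_exterior.ravel(), grid.dims))


def accessibility(per_frame_open_flags: np.ndarray) -> float:
    """Percentage of frames with at least one open channel.

    ``per_frame_open_flags`` is a (frames × channels) boolean matrix.
    """
    flags = np.asarray(per_frame_open_flags, dtype=bool)
    if flags.ndim == 1:
        flags = flags[:, None]
    if flags.shape[0] == 0:
        raise ValueError("at least one frame is required")
    return float(100.0 * flags.any(axis=1).mean())


# ---------------------------------------------------------------------------
# Direction classification


def _normalize_label(label: str) -> str:
    return label.strip().replace("'", "′").replace("’", "′")


def _is_sheet_label(label: str) -> bool:
    return bool(_SHEET_RE.match(label))


def classify_direction(flanking_sse: set[str]) -> str:
    """Direction class from the flanking SSE label set.

    All labels in the membrane set (helices A, A′, B, B′, F′, G′ and any
    β-sheet) → membrane-directed; some but not all → perpendicular;
    none → cytosolic.  An empty label set classifies as cytosolic with a
    warning.
    """
    labels = {_normalize_label(l) for l in flanking_sse if l.strip()}
    if not labels:
        warnings.warn("channel has no labeled flanking residues; classed as cytosolic")
        return DIRECTION_CYTOSOLIC
    in_membrane = {l for l in labels if l in MEMBRANE_HELICES or _is_sheet_label(l)}
    if in_membrane == labels:
        return DIRECTION_MEMBRANE
    if in_membrane:
        return DIRECTION_PERPENDICULAR
    return DIRECTION_CYTOSOLIC


def channel_lining_residues(
    channel: ChannelPath,
    snapshot: Snapshot,
    grid: OccupancyGrid,
    contact_dist: float = 4.0,
) -> list[tuple[str, int]]:
    """Residues with a heavy atom within ``contact_dist`` Å of the channel path."""
    centers = grid.voxel_center(np.array(channel.voxel_ids, dtype=int))
    if centers.ndim == 1:
        centers = centers[None, :]
    tree = cKDTree(centers)
    residues: set[tuple[str, int]] = set()
    for atom in snapshot.heavy_atoms():
        if tree.query_ball_point(atom.coords, r=contact_dist):
            residues.add((atom.chain, atom.residue_id))
    return sorted(residues)


def estimate_nterm_axis(snapshot: Snapshot, n_residues: int = 10) -> np.ndarray:
    """Unit vector from the protein centroid toward the first N-terminal residues.

    Used as the membrane direction when no axis is supplied: the
    N-terminal helix anchors the enzyme to the membrane, so the direction
    from the protein body toward it approximates "toward the membrane".
    """
    coords = snapshot.coords
    resids = sorted({(a.chain, a.residue_id) for a in snapshot.atoms if not a.is_hetero})
    first = set(resids[:n_residues])
    head = np.array([a.coords for a in snapshot.atoms if (a.chain, a.residue_id) in first])
    if len(head) == 0:
        raise ValueError("no residues available to estimate the N-terminal axis")
    axis = head.mean(axis=0) - coords.mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate N-terminal axis")
    return axis / norm


def flag_solvent_channel(
    channels: Sequence[ChannelPath],
    heme: HemeFrame,
    nterm_axis: np.ndarray,
    grid: OccupancyGrid,
    tol: float = 0.1,
) -> list[ChannelPath]:
    """Flag the channel exiting opposite the membrane as the solvent channel.

    Each channel's exit direction (from Fe to its exit-region centroid) is
    projected onto the membrane direction ``nterm_axis``; the channel with
    the most negative projection is flagged, provided the projection is
    below −``tol``.  A tie within ``tol`` flags none and warns.
    """
    if not channels:
        return list(channels)
    projections = []
    for channel in channels:
        exit_centers = grid.voxel_center(np.array(sorted(channel.exit_voxels), dtype=int))
        if exit_centers.ndim == 1:
            exit_centers = exit_centers[None, :]
        direction = exit_centers.mean(axis=0) - heme.fe_coord
        direction = direction / np.linalg.norm(direction)
        projections.append(float(direction @ nterm_axis))
    order = np.argsort(projections)
    best = int(order[0])
    for channel in channels:
        channel.is_solvent_channel = False
    if projections[best] >= -tol:
        return list(channels)
    if len(channels) > 1 and projections[int(order[1])] - projections[best] < tol:
        warnings.warn("solvent-channel assignment ambiguous (projection tie); none flagged")
        return list(channels)
    channels[best].is_solvent_channel = True
    return list(channels)
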