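"""End-to-end orchestration: ensembles in, descriptor tables and maps out.

The two detection tracks run side by side.  Per snapshot, alpha-sphere
pockets are detected and the heme-distal one selected; pooled over all
replicates, the per-snapshot pocket spaces build an occupancy grid from
which the persistent (≥50%) pocket is extracted and any surface-reaching
channel is cut at its bottleneck.  Each frame's volume/SASA pair is then
taken from the smaller-volume track (min rule), and channel openness and
accessibility are evaluated against each frame's own solvent exterior.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import channels as ch
from .descriptors import (
    SnapshotDescriptors,
    apply_min_rule,
    grid_track_snapshot_volume,
    pocket_sasa,
    sphere_union_volume,
)
from .pockets import (
    GridPocket,
    OccupancyGrid,
    SpherePocket,
    build_occupancy_grid,
    cluster_alpha_spheres,
    cut_channel_at_bottleneck,
    extract_grid_pocket,
    rasterize_spheres,
    select_active_site,
    voronoi_alpha_spheres,
)
from .stats import (
    EnzymeSummary,
    ReplicateSummary,
    categorize,
    summarize_enzyme,
    summarize_replicate,
)
from .structure_io import (
    Ensemble,
    HemeFrame,
    Snapshot,
    SSEAnnotation,
    StructureError,
    find_heme_frame,
    strip_nonprotein,
    superpose_ensemble,
)

__all__ = ["PipelineConfig", "EnzymeResult", "analyze_replicates", "write_outputs"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline with its default."""

    r_min: float = 2.9  # minimum alpha-sphere radius (Å)
    r_max: float = 16.0  # maximum alpha-sphere radius (Å)
    link_cutoff: float = 4.5  # single-linkage clustering cutoff (Å)
    min_spheres: int = 3  # smallest sphere cluster kept as a pocket
    site_max_dist: float = 8.0  # max sphere–Fe distance for the active site (Å)
    seed_offset: float = 4.0  # distal seed point offset above Fe (Å)
    grid_spacing: float = 1.0  # occupancy grid spacing (Å)
    grid_margin: float = 2.0  # bounding-box margin (Å)
    occupancy_threshold: float = 0.5  # persistent-pocket frequency (inclusive)
    probe: float = 1.4  # solvent probe radius (Å)
    mc_samples: int = 20_000  # Monte-Carlo samples per frame volume
    ladder_step: float = 0.05  # channel isovalue ladder step
    top_channels: int = 3  # channels retained, ranked by opening frequency
    seed: int = 0  # base seed for per-frame Monte-Carlo volumes
    keep_het: frozenset[str] = frozenset({"HEM"})
    # rasterize every detected pocket (not just the selected active site)
    # into the occupancy grid
    rasterize_all_pockets: bool = False


@dataclass
class ReplicateFrames:
    replicate_id: str
    descriptors: list[SnapshotDescriptors]
    open_any: list[bool]
    channel_open: np.ndarray  # frames × channels


@dataclass
class EnzymeResult:
    enzyme: str
    frames: pd.DataFrame
    replicate_summaries: list[ReplicateSummary]
    summary: EnzymeSummary
    categories: tuple[str, str, str, str, str]
    channels: list[ch.ChannelPath]
    accessibility_pct: float
    grid: OccupancyGrid
    grid_pocket: GridPocket
    heme: HemeFrame
    channel_open: np.ndarray | None = None  # frames × channels open/closed
    notes: list[str] = field(default_factory=list)


def _prepare(ensemble: Ensemble, config: PipelineConfig) -> Ensemble:
    stripped = [strip_nonprotein(s, set(config.keep_het)) for s in ensemble.snapshots]
    prepared = Ensemble(
        reference=strip_nonprotein(ensemble.reference, set(config.keep_het)),
        snapshots=stripped,
        replicate_id=ensemble.replicate_id,
        aligned=ensemble.aligned,
    )
    if not prepared.aligned:
        try:
            prepared, _ = superpose_ensemble(prepared)
        except StructureError:
            # no protein backbone (e.g. pseudo-atom fixtures): trust the
            # input frames to be pre-aligned
            warnings.warn(
                "no backbone available for superposition; assuming pre-aligned frames"
            )
            prepared.aligned = True
    return prepared


def _frame_seed(base: int, index: int) -> int:
    return (base * 1_000_003 + index) % (2 ** 31)


def analyze_replicates(
    ensembles: Sequence[Ensemble],
    enzyme: str = "enzyme",
    sse: SSEAnnotation | None = None,
    nterm_axis: np.ndarray | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> EnzymeResult:
    """Run the full two-track analysis over one enzyme's replicates."""
    if not ensembles:
        raise ValueError("at least one ensemble is required")
    prepared = [_prepare(e, config) for e in ensembles]
    heme = find_heme_frame(prepared[0].reference)

    # --- sphere track: per-snapshot active-site pockets -------------------
    all_snapshots: list[Snapshot] = []
    site_pockets: list[SpherePocket | None] = []
    grid_source: list[SpherePocket | None] = []
    replicate_of: list[str] = []
    for ens in prepared:
        for snap in ens.snapshots:
            frame_heme = find_heme_frame(snap)
            spheres = voronoi_alpha_spheres(snap, config.r_min, config.r_max)
            pockets = cluster_alpha_spheres(
                spheres, config.link_cutoff, config.min_spheres, snap.frame_index
            )
            site = select_active_site(pockets, frame_heme, config.site_max_dist)
            site_pockets.append(site)
            if config.rasterize_all_pockets and pockets:
                merged = SpherePocket(
                    spheres=[s for p in pockets for s in p.spheres],
                    snapshot_index=snap.frame_index,
                )
                grid_source.append(merged)
            else:
                grid_source.append(site)
            all_snapshots.append(snap)
            replicate_of.append(ens.replicate_id)

    pooled = Ensemble(
        reference=prepared[0].reference,
        snapshots=all_snapshots,
        replicate_id="pooled",
        aligned=True,
    )

    # --- grid track: pooled occupancy grid and persistent pocket ----------
    grid = build_occupancy_grid(
        pooled, grid_source, config.grid_spacing, config.grid_margin
    )
    seed_point = heme.fe_coord + config.seed_offset * heme.distal_axis
    core_voxel = grid.point_to_flat(seed_point)
    if core_voxel is None:
        raise StructureError("heme seed point falls outside the occupancy grid")

    exterior = ch.ensemble_exterior_mask(grid, all_snapshots, config.probe)
    surface_set = set(int(v) for v in np.flatnonzero(exterior.ravel()))
    raw_pocket = extract_grid_pocket(
        grid, config.occupancy_threshold, heme, config.seed_offset, config.site_max_dist
    )
    grid_pocket = cut_channel_at_bottleneck(raw_pocket, grid, surface_set, core_voxel)

    # --- channels on the ensemble grid ------------------------------------
    channel_paths = ch.detect_channels(
        grid,
        raw_pocket,
        exterior,
        core_voxel,
        ch.default_threshold_ladder(config.ladder_step),
        config.top_channels,
    )
    for channel in channel_paths:
        channel.lining_residues = ch.channel_lining_residues(
            channel, prepared[0].reference, grid
        )
        if sse is not None:
            channel.flanking_sse = sse.labels_for_residues(channel.lining_residues)
            channel.direction_class = ch.classify_direction(channel.flanking_sse)
    if channel_paths:
        try:
            axis = (
                nterm_axis
                if nterm_axis is not None
                else ch.estimate_nterm_axis(prepared[0].reference)
            )
            ch.flag_solvent_channel(channel_paths, heme, axis, grid)
        except ValueError:
            warnings.warn("could not estimate the N-terminal axis; solvent flag skipped")

    # --- per-frame descriptors and openness --------------------------------
    records: list[SnapshotDescriptors] = []
    open_any: list[bool] = []
    channel_open = np.zeros((len(all_snapshots), len(channel_paths)), dtype=bool)
    for idx, (snap, site) in enumerate(zip(all_snapshots, site_pockets)):
        if site is None:
            records.append(apply_min_rule(snap.frame_index, None, None))
            open_any.append(False)
            continue
        frame_mask = rasterize_spheres(grid, site.spheres)

        v_sphere = sphere_union_volume(
            site.spheres, config.mc_samples, _frame_seed(config.seed, idx)
        )
        sasa_s, sasa_s_ap = pocket_sasa(snap, site, config.probe)
        sphere_track = (v_sphere, sasa_s, sasa_s_ap)

        covered = {v for v in grid_pocket.voxel_ids if frame_mask.ravel()[v]}
        if covered:
            v_grid = grid_track_snapshot_volume(grid, grid_pocket, frame_mask)
            sasa_g, sasa_g_ap = pocket_sasa(snap, covered, config.probe, grid=grid)
            grid_track = (v_grid, sasa_g, sasa_g_ap)
        else:
            grid_track = None

        frame_ext = ch.frame_exterior_mask(grid, snap, config.probe)
        opens = tuple(
            c.channel_id
            for j, c in enumerate(channel_paths)
            if ch.snapshot_open(frame_mask, c, frame_ext, grid, core_voxel)
        )
        for j, c in enumerate(channel_paths):
            channel_open[idx, j] = c.channel_id in opens
        open_any.append(
            ch.frame_reaches_surface(frame_mask, frame_ext, grid, core_voxel)
        )
        records.append(apply_min_rule(snap.frame_index, sphere_track, grid_track, opens))

    accessibility_pct = ch.accessibility(np.array(open_any, dtype=bool))

    # --- statistics --------------------------------------------------------
    replicate_summaries: list[ReplicateSummary] = []
    for ens in prepared:
        rep_frames = [
            rec for rec, rep in zip(records, replicate_of) if rep == ens.replicate_id
        ]
        replicate_summaries.append(summarize_replicate(rep_frames, ens.replicate_id))
    summary = summarize_enzyme(replicate_summaries, accessibility_pct, enzyme)
    categories = categorize(summary).symbols()

    frames_df = pd.DataFrame(
        {
            "replicate": replicate_of,
            "frame": [r.frame_index for r in records],
            "volume_sphere": [r.volume_sphere_track for r in records],
            "volume_grid": [r.volume_grid_track for r in records],
            "volume": [r.volume for r in records],
            "source": [r.source for r in records],
            "sasa_total": [r.sasa_total for r in records],
            "sasa_apolar": [r.sasa_apolar for r in records],
            "shape": [r.shape for r in records],
            "hydrophobicity": [r.hydrophobicity for r in records],
            "site_found": [r.site_found for r in records],
            "open_channel_ids": [
                ";".join(map(str, r.open_channel_ids)) for r in records
            ],
            "open_any": open_any,
        }
    )

    notes: list[str] = []
    n_missing = sum(1 for r in records if not r.site_found)
    if n_missing:
        notes.append(f"{n_missing}/{len(records)} frames without a detected site")

    return EnzymeResult(
        enzyme=enzyme,
        frames=frames_df,
        replicate_summaries=replicate_summaries,
        summary=summary,
        categories=categories,
        channels=channel_paths,
        accessibility_pct=accessibility_pct,
        grid=grid,
        grid_pocket=grid_pocket,
        heme=heme,
        channel_open=channel_open,
        notes=notes,
    )


def write_outputs(result: EnzymeResult, out_dir: str | Path) -> None:
    """Write the standard output set: per-frame CSV, replicate CSV, enzyme
    summary JSON, category TSV, channel report JSON and the occupancy DX."""
    from .gridio import write_dx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.frames.to_csv(out / "descriptors.csv", index=False)
    pd.DataFrame([vars(r) for r in result.replicate_summaries]).to_csv(
        out / "replicates.csv", index=False
    )
    (out / "enzyme_summary.json").write_text(result.summary.to_json())
    header = "enzyme\tvolume\trange\tshape\thydrophobicity\taccessibility\n"
    (out / "categories.tsv").write_text(
        header + result.enzyme + "\t" + "\t".join(result.categories) + "\n"
    )
    report = [
        {
            "channel_id": c.channel_id,
            "opening_frequency": c.opening_frequency,
            "flanking_sse": sorted(c.flanking_sse),
            "direction_class": c.direction_class,
            "is_solvent_channel": c.is_solvent_channel,
            "n_lining_residues": len(c.lining_residues),
        }
        for c in result.channels
    ]
    (out / "channels.json").write_text(json.dumps(report, indent=2, ensure_ascii=False))
    if result.channel_open is not None and result.channels:
        open_df = pd.DataFrame(
            result.channel_open.astype(int),
            columns=[f"channel_{c.channel_id}" for c in result.channels],
        )
        open_df.insert(0, "frame", result.frames["frame"].to_numpy())
        open_df.to_csv(out / "channels_open.csv", index=False)
    write_dx(result.grid, out / "occupancy.dx")
    from .stats import export_violin_data

    per_rep: dict[str, list[float]] = {}
    for rep, vol, found in zip(
        result.frames["replicate"], result.frames["volume"], result.frames["site_found"]
    ):
        if found:
            per_rep.setdefault(rep, []).append(float(vol))
    export_violin_data(per_rep).to_csv(out / "violin_data.csv", index=False)
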