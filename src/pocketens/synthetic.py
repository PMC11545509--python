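"""Deterministic toy structures with analytically known cavities.

The generator builds hollow atomic "cages": three concentric Fibonacci
shells of pseudo-atoms enclosing a spherical cavity, optionally pierced
by an aperture (a cone about +z whose lid atoms swing to the antipodal
wall in open frames, keeping atom count and ordering constant across an
ensemble).  A minimal heme pseudo-group (Fe, four pyrrole-like
N and a cysteine SG below) sits low in the cavity so heme-seeded
active-site selection works end to end.

Because alpha-sphere radii are measured center-to-atom-center, the inner
shell's *atom centers* lie on the nominal cavity sphere: a cage of
``cavity_radius`` r yields a detected pocket whose analytic volume is
(4/3)πr³.  Every fixture is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .descriptors import fibonacci_sphere_points
from .structure_io import AtomRecord, Ensemble, Snapshot, write_ensemble_pdb

__all__ = [
    "CageSpec",
    "BreathingSchedule",
    "GroundTruth",
    "make_cage",
    "make_breathing_ensemble",
    "write_fixture",
]

@dataclass(frozen=True)
class CageSpec:
    """Geometry and composition of one cage fixture."""

    cavity_radius: float = 6.0
    shell_thickness: float = 1.8
    n_shell_atoms: int | None = None  # None → sized for ~2.0 Å lattice spacing
    aperture_half_angle: float = 0.0  # degrees; 0 = sealed
    apolar_fraction: float = 1.0
    include_heme: bool = True
    seed: int = 0

    def resolved_n_shell(self) -> int:
        if self.n_shell_atoms is not None:
            return self.n_shell_atoms
        per_layer = max(50, int(math.pi * self.cavity_radius ** 2))
        return 3 * per_layer


@dataclass(frozen=True)
class BreathingSchedule:
    """Per-frame openness and cavity radius for a breathing ensemble."""

    n_frames: int
    open_fraction: float
    radius_series: tuple[float, ...] | None = None
    seed: int = 0

    def open_flags(self) -> np.ndarray:
        k = int(round(self.open_fraction * self.n_frames))
        rng = np.random.default_rng(self.seed)
        flags = np.zeros(self.n_frames, dtype=bool)
        flags[rng.permutation(self.n_frames)[:k]] = True
        return flags


@dataclass
class GroundTruth:
    """What the generator knows about its own fixture."""

    analytic_cavity_volume: list[float]
    open_flags: list[bool]
    apolar_fraction: float
    cavity_radius: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "analytic_cavity_volume": self.analytic_cavity_volume,
                "open_flags": [bool(f) for f in self.open_flags],
                "apolar_fraction": self.apolar_fraction,
                "cavity_radius": self.cavity_radius,
            },
            indent=2,
        )


def _shell_points(spec: CageSpec, radius: float, n_override: int | None = None) -> np.ndarray:
    # three concentric layers: the innermost bounds the cavity, the outer
    # two thicken the wall so lining atoms have no free outward surface
    n = n_override if n_override is not None else spec.resolved_n_shell()
    per_layer = n // 3
    counts = [per_layer, per_layer, n - 2 * per_layer]
    rng = np.random.default_rng(spec.seed + 1)
    layers = []
    for layer, count in enumerate(counts):
        unit = fibonacci_sphere_points(count)
        theta = rng.uniform(0, 2 * math.pi) if layer else 0.0
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        layers.append((radius + layer * spec.shell_thickness) * (unit @ rot.T))
    return np.vstack(layers)


def _heme_positions(radius: float) -> dict[str, np.ndarray]:
    # the heme plugs the bottom pole of the shell: Fe sits on the inner
    # shell sphere so the cavity interior stays analytically empty
    fe = np.array([0.0, 0.0, -radius])
    nitrogens = [
        fe + np.array([1.2, 0.0, 0.0]),
        fe + np.array([-1.2, 0.0, 0.0]),
        fe + np.array([0.0, 1.2, 0.0]),
        fe + np.array([0.0, -1.2, 0.0]),
    ]
    sg = fe + np.array([0.0, 0.0, -2.3])
    return {"FE": fe, "N": nitrogens, "SG": sg}  # type: ignore[dict-item]


def _build_snapshot(
    spec: CageSpec,
    radius: float,
    open_frame: bool,
    frame_index: int,
    n_override: int | None = None,
) -> Snapshot:
    points = _shell_points(spec, radius, n_override)
    n = len(points)

    # element assignment fixed by the spec seed, shared across frames
    rng = np.random.default_rng(spec.seed)
    elements = np.where(rng.random(n) < spec.apolar_fraction, "C", "O")

    heme = _heme_positions(radius) if spec.include_heme else None

    # drop shell atoms clashing with the heme pseudo-group (<1.5 Å)
    if heme is not None:
        heme_coords = np.vstack([heme["FE"], *heme["N"], heme["SG"]])
        d = np.linalg.norm(points[:, None, :] - heme_coords[None, :, :], axis=2)
        keep = d.min(axis=1) >= 1.5
        points, elements = points[keep], elements[keep]

    # open frames move the aperture-cone lid out of the way
    if spec.aperture_half_angle > 0:
        unit = points / np.linalg.norm(points, axis=1, keepdims=True)
        in_cone = unit[:, 2] >= math.cos(math.radians(spec.aperture_half_angle))
        if open_frame:
            # open frames swing the lid to the antipode: lid atoms become
            # extra wall layers over the bottom pole, keeping atom count
            # and ordering identical while leaving the mouth open and the
            # atom cloud's convex hull essentially unchanged
            norms = np.linalg.norm(points, axis=1)
            points = points.copy()
            points[in_cone] = -unit[in_cone] * (norms[in_cone] + 3 * spec.shell_thickness)[:, None]

    # shell self-clash check (ignoring parked lid atoms)
    core = points[np.linalg.norm(points, axis=1) < radius + 2 * spec.shell_thickness + 1.0]
    if len(core) > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(core)
        pairs = tree.query_pairs(1.5)
        if pairs:
            raise ValueError(
                f"cage spec yields overlapping shell atoms closer than 1.5 Å "
                f"({len(pairs)} pairs); reduce n_shell_atoms or grow the cavity"
            )

    atoms: list[AtomRecord] = []
    serial = 0
    for i, (xyz, element) in enumerate(zip(points, elements), start=1):
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name=f"{element}1",
                element=str(element),
                residue_name="CAG",
                residue_id=i,
                chain="A",
                coords=xyz,
                is_hetero=False,
            )
        )
    if heme is not None:
        resid = len(points) + 1
        serial += 1
        atoms.append(AtomRecord(serial, "FE", "FE", "HEM", resid, "A", heme["FE"], True))
        for j, pos in enumerate(heme["N"], start=1):
            serial += 1
            atoms.append(AtomRecord(serial, f"N{j}", "N", "HEM", resid, "A", pos, True))
        serial += 1
        atoms.append(
            AtomRecord(serial, "SG", "S", "CYS", resid + 1, "A", heme["SG"], False)
        )
    return Snapshot(atoms=atoms, frame_index=frame_index)


def make_cage(spec: CageSpec) -> tuple[Snapshot, GroundTruth]:
    """Build one cage snapshot plus its analytic ground truth."""
    open_frame = spec.aperture_half_angle > 0
    snapshot = _build_snapshot(spec, spec.cavity_radius, open_frame, frame_index=1)
    truth = GroundTruth(
        analytic_cavity_volume=[4.0 / 3.0 * math.pi * spec.cavity_radius ** 3],
        open_flags=[open_frame],
        apolar_fraction=spec.apolar_fraction,
        cavity_radius=[spec.cavity_radius],
    )
    return snapshot, truth


def make_breathing_ensemble(
    spec: CageSpec, schedule: BreathingSchedule
) -> tuple[Ensemble, GroundTruth]:
    """Build an aligned ensemble of cages following the breathing schedule.

    The aperture is present exactly in the scheduled open frames; the
    cavity radius follows ``radius_series`` (default: constant).  Frames
    share atom count and ordering, so the ensemble is aligned by
    construction.
    """
    flags = schedule.open_flags()
    if schedule.radius_series is not None:
        radii: Sequence[float] = schedule.radius_series
        if len(radii) != schedule.n_frames:
            raise ValueError("radius_series length must equal n_frames")
    else:
        radii = [spec.cavity_radius] * schedule.n_frames

    # atom count must be identical across frames: size the shell lattice
    # for the smallest cavity in the series
    if spec.n_shell_atoms is not None:
        n_shell = spec.n_shell_atoms
    else:
        n_shell = 3 * max(50, int(math.pi * min(radii) ** 2))

    snapshots = [
        _build_snapshot(spec, radii[i], bool(flags[i]), frame_index=i + 1, n_override=n_shell)
        for i in range(schedule.n_frames)
    ]
    ensemble = Ensemble(
        reference=snapshots[0].copy(),
        snapshots=snapshots,
        replicate_id=f"synthetic-seed{schedule.seed}",
        aligned=True,
    )
    truth = GroundTruth(
        analytic_cavity_volume=[4.0 / 3.0 * math.pi * r ** 3 for r in radii],
        open_flags=[bool(f) for f in flags],
        apolar_fraction=spec.apolar_fraction,
        cavity_radius=list(radii),
    )
    return ensemble, truth


def write_fixture(
    spec: CageSpec, schedule: BreathingSchedule, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a multi-model PDB plus ground_truth.json; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ensemble, truth = make_breathing_ensemble(spec, schedule)
    pdb_path = out_dir / "ensemble.pdb"
    truth_path = out_dir / "ground_truth.json"
    write_ensemble_pdb(ensemble, pdb_path)
    truth_path.write_text(truth.to_json())
    return pdb_path, truth_path
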