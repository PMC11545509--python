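"""Reading, cleaning and superposing conformational ensembles.

An :class:`Ensemble` is an ordered collection of :class:`Snapshot` objects
(one per PDB MODEL) sharing atom count and ordering, plus a reference
snapshot onto whose backbone all frames can be least-squares superposed.
The heme reference frame (:class:`HemeFrame`) defines the distal axis —
the unit vector from the coordinating cysteine sulfur through the heme
iron — which seeds active-site pocket selection downstream.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .elements import vdw_radius

__all__ = [
    "AtomRecord",
    "Snapshot",
    "Ensemble",
    "SSEAnnotation",
    "HemeFrame",
    "StructureError",
    "read_ensemble",
    "write_ensemble_pdb",
    "strip_nonprotein",
    "superpose_ensemble",
    "find_heme_frame",
    "read_sse_annotation",
]

WATER_NAMES = {"HOH", "SOL", "WAT"}
ION_NAMES = {"NA", "CL", "K", "MG", "CA", "ZN"}
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
BACKBONE_NAMES = {"N", "CA", "C", "O"}
HEME_NAMES = {"HEM", "HEC"}


class StructureError(ValueError):
    """Raised when a structure violates an input contract."""


@dataclass
class AtomRecord:
    """One atom of one snapshot (coordinates in Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    coords: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial}: coords must be a finite 3-vector")

    @property
    def vdw(self) -> float:
        return vdw_radius(self.element)


@dataclass
class Snapshot:
    """One conformation: an ordered atom list plus frame metadata."""

    atoms: list[AtomRecord]
    frame_index: int = 1
    time_ps: float | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix (a fresh copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element.upper() != "H"]

    def backbone_indices(self) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_name.upper() in STANDARD_AA and a.name.upper() in BACKBONE_NAMES
        ]

    def copy(self) -> "Snapshot":
        return copy.deepcopy(self)


@dataclass
class Ensemble:
    """Aligned (or alignable) collection of snapshots from one replicate."""

    reference: Snapshot
    snapshots: list[Snapshot]
    replicate_id: str = "rep1"
    aligned: bool = False

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)


@dataclass
class SSEAnnotation:
    """Secondary-structure element ranges: (chain, start, end, label)."""

    entries: list[tuple[str, int, int, str]] = field(default_factory=list)

    def label_for(self, chain: str, residue_id: int) -> str | None:
        for ch, start, end, label in self.entries:
            if ch == chain and start <= residue_id <= end:
                return label
        return None

    def labels_for_residues(self, residues: Iterable[tuple[str, int]]) -> set[str]:
        """Distinct SSE labels covering the given (chain, residue_id) pairs."""
        found = set()
        for chain, resid in residues:
            label = self.label_for(chain, resid)
            if label is not None:
                found.add(label)
        return found


@dataclass
class HemeFrame:
    """Heme reference frame: Fe position and the distal (substrate) axis."""

    fe_coord: np.ndarray
    sg_coord: np.ndarray
    distal_axis: np.ndarray

    def __post_init__(self) -> None:
        self.fe_coord = np.asarray(self.fe_coord, dtype=float)
        self.sg_coord = np.asarray(self.sg_coord, dtype=float)
        self.distal_axis = np.asarray(self.distal_axis, dtype=float)
        norm = np.linalg.norm(self.distal_axis)
        if abs(norm - 1.0) > 1e-9:
            raise StructureError("distal_axis must be a unit vector")


# ---------------------------------------------------------------------------
# Reading / writing


def read_ensemble(path: str | Path, format: str = "multi-model-PDB") -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    One snapshot per MODEL record; the first model is the reference.  All
    models must share atom count and ordering.
    """
    if format != "multi-model-PDB":
        raise ValueError(f"unsupported format: {format}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise StructureError(f"{path}: no models found")

    snapshots: list[Snapshot] = []
    n_expected: int | None = None
    for model_idx, model in enumerate(structure, start=1):
        atoms: list[AtomRecord] = []
        serial = 0
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for atom in residue:
                    serial += 1
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            name=atom.name,
                            element=atom.element.name.upper(),
                            residue_name=residue.name,
                            residue_id=residue.seqid.num,
                            chain=chain.name,
                            coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            is_hetero=het,
                        )
                    )
        if n_expected is None:
            n_expected = len(atoms)
        elif len(atoms) != n_expected:
            raise StructureError(
                f"model {model_idx} atom count mismatch: expected {n_expected}, got {len(atoms)}"
            )
        snapshots.append(Snapshot(atoms=atoms, frame_index=model_idx))

    return Ensemble(reference=snapshots[0], snapshots=snapshots, aligned=False)


def write_ensemble_pdb(ensemble: Ensemble | Sequence[Snapshot], path: str | Path) -> None:
    """Write snapshots as a multi-model PDB file (MODEL/ENDMDL)."""
    snapshots = list(ensemble.snapshots) if isinstance(ensemble, Ensemble) else list(ensemble)
    structure = gemmi.Structure()
    structure.name = "pocketens"
    for snap in snapshots:
        model = gemmi.Model(snap.frame_index)
        chains: dict[str, gemmi.Chain] = {}
        for atom in snap.atoms:
            chain = chains.get(atom.chain)
            if chain is None:
                chain = gemmi.Chain(atom.chain)
                chains[atom.chain] = chain
            if len(chain) == 0 or chain[-1].seqid.num != atom.residue_id or chain[-1].name != atom.residue_name:
                residue = gemmi.Residue()
                residue.name = atom.residue_name
                residue.seqid = gemmi.SeqId(atom.residue_id, " ")
                residue.het_flag = "H" if atom.is_hetero else "A"
                chain.add_residue(residue)
            residue = chain[-1]
            gatom = gemmi.Atom()
            gatom.name = atom.name
            gatom.element = gemmi.Element(atom.element.capitalize())
            gatom.pos = gemmi.Position(*atom.coords)
            residue.add_atom(gatom)
        for chain in chains.values():
            model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    Path(path).write_text(structure.make_pdb_string())


# ---------------------------------------------------------------------------
# Cleaning


def _is_monoatomic_ion(residue_atoms: list[AtomRecord]) -> bool:
    if len(residue_atoms) != 1:
        return False
    atom = residue_atoms[0]
    return (
        atom.is_hetero
        and atom.residue_name.upper() in ION_NAMES
        and atom.element.upper() == atom.residue_name.upper()
    )


def strip_nonprotein(snapshot: Snapshot, keep_het: set[str] | None = None) -> Snapshot:
    """Remove solvent and monoatomic ions, keeping protein and ``keep_het``.

    Waters (HOH/SOL/WAT) and single-atom ion residues (NA, CL, K, MG, CA,
    ZN HETATM records with matching element) are dropped; hetero residues
    named in ``keep_het`` (default ``{"HEM"}``) are retained.
    """
    if keep_het is None:
        keep_het = {"HEM"}
    keep_het = {name.upper() for name in keep_het}

    # group consecutive atoms by residue identity
    groups: list[list[AtomRecord]] = []
    key = None
    for atom in snapshot.atoms:
        atom_key = (atom.chain, atom.residue_id, atom.residue_name)
        if atom_key != key:
            groups.append([])
            key = atom_key
        groups[-1].append(atom)

    kept: list[AtomRecord] = []
    for group in groups:
        resname = group[0].residue_name.upper()
        if resname in WATER_NAMES:
            continue
        if _is_monoatomic_ion(group):
            continue
        if group[0].is_hetero and resname not in keep_het and resname in HEME_NAMES:
            continue  # heme explicitly excluded from keep_het
        kept.append(group)  # type: ignore[arg-type]

    atoms = [copy.deepcopy(a) for group in kept for a in group]
    if not atoms:
        warnings.warn("strip_nonprotein produced an empty snapshot")
    return Snapshot(atoms=atoms, frame_index=snapshot.frame_index, time_ps=snapshot.time_ps)


# ---------------------------------------------------------------------------
# Superposition


def _kabsch_transform(ref: np.ndarray, mob: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    return rot, mob_c, ref_c


def superpose_ensemble(ensemble: Ensemble, selection: str = "backbone") -> tuple[Ensemble, list[float]]:
    """Least-squares superpose every snapshot onto the reference backbone.

    Returns a new aligned ensemble plus the per-snapshot backbone RMSD (Å)
    after fitting.  Backbone = N, CA, C, O atoms of standard residues.
    """
    if selection != "backbone":
        raise ValueError(f"unsupported selection: {selection}")
    idx = ensemble.reference.backbone_indices()
    if len(idx) < 3:
        raise StructureError("fewer than 3 backbone atoms available for superposition")
    ref_bb = ensemble.reference.coords[idx]

    new_snaps: list[Snapshot] = []
    rmsds: list[float] = []
    for snap in ensemble.snapshots:
        xyz = snap.coords
        mob_bb = xyz[idx]
        rot, mob_c, ref_c = _kabsch_transform(ref_bb, mob_bb)
        fitted = rot.apply(xyz - mob_c) + ref_c
        new_snap = snap.copy()
        new_snap.set_coords(fitted)
        new_snaps.append(new_snap)
        delta = fitted[idx] - ref_bb
        rmsds.append(float(np.sqrt((delta ** 2).sum(axis=1).mean())))

    return (
        Ensemble(
            reference=ensemble.reference.copy(),
            snapshots=new_snaps,
            replicate_id=ensemble.replicate_id,
            aligned=True,
        ),
        rmsds,
    )


# ---------------------------------------------------------------------------
# Heme frame


def find_heme_frame(snapshot: Snapshot, max_fe_sg_dist: float = 3.5) -> HemeFrame:
    """Locate the heme iron and its proximal cysteine SG; build the distal axis.

    The distal axis points from SG through Fe, i.e. toward the substrate
    side of the heme plane, opposite the coordinating cysteine.
    """
    heme_residues = {
        (a.chain, a.residue_id)
        for a in snapshot.atoms
        if a.residue_name.upper() in HEME_NAMES
    }
    if len(heme_residues) == 0:
        raise StructureError("no heme (HEM/HEC) residue found")
    if len(heme_residues) > 1:
        raise StructureError(f"multiple heme residues found: {sorted(heme_residues)}")

    fe_atoms = [
        a
        for a in snapshot.atoms
        if a.residue_name.upper() in HEME_NAMES and a.element.upper() == "FE"
    ]
    if not fe_atoms:
        raise StructureError("heme iron (FE) not found")
    fe = fe_atoms[0].coords

    sg_atoms = [
        a
        for a in snapshot.atoms
        if a.residue_name.upper() == "CYS" and a.name.upper() == "SG"
    ]
    candidates = [a for a in sg_atoms if np.linalg.norm(a.coords - fe) <= max_fe_sg_dist]
    if not candidates:
        raise StructureError("proximal cysteine not found")
    sg = min(candidates, key=lambda a: float(np.linalg.norm(a.coords - fe))).coords

    axis = fe - sg
    axis = axis / np.linalg.norm(axis)
    return HemeFrame(fe_coord=fe, sg_coord=sg, distal_axis=axis)


# ---------------------------------------------------------------------------
# SSE annotation


def read_sse_annotation(path: str | Path) -> SSEAnnotation:
    """Read a 4-column TSV (chain, start, end, label); '#' lines are comments.

    Ranges must not overlap within a chain.
    """
    entries: list[tuple[str, int, int, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        chain, start_s, end_s, label = parts
        start, end = int(start_s), int(end_s)
        if not label:
            raise ValueError(f"{path}:{lineno}: empty label")
        if end < start:
            raise ValueError(f"{path}:{lineno}: end < start")
        entries.append((chain, start, end, label))

    by_chain: dict[str, list[tuple[int, int, str]]] = {}
    for chain, start, end, label in entries:
        by_chain.setdefault(chain, []).append((start, end, label))
    for chain, ranges in by_chain.items():
        ranges = sorted(ranges)
        for (s1, e1, l1), (s2, e2, l2) in zip(ranges, ranges[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping SSE ranges on chain {chain}: "
                    f"{l1} [{s1},{e1}] overlaps {l2} [{s2},{e2}]"
                )
    return SSEAnnotation(entries=entries)
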