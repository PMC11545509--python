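import numpy as np
import pytest

from pocketens.structure_io import (
    AtomRecord,
    Ensemble,
    Snapshot,
    StructureError,
    find_heme_frame,
    read_ensemble,
    read_sse_annotation,
    strip_nonprotein,
    superpose_ensemble,
    write_ensemble_pdb,
)


def _atom(serial, name, element, resname, resid, coords, het=False, chain="A"):
    return AtomRecord(serial, name, element, resname, resid, chain, np.array(coords, float), het)


def _protein_snapshot(n_res=5, jitter=None, rng=None):
    """Tiny extended-chain polypeptide with N/CA/C/O backbone atoms."""
    atoms = []
    serial = 0
    offsets = {"N": (0.0, 0.0, 0.0), "CA": (1.4, 0.4, 0.0), "C": (2.4, -0.5, 0.3), "O": (2.5, -1.6, -0.2)}
    for i in range(n_res):
        for name, off in offsets.items():
            serial += 1
            xyz = np.array([3.6 * i, 0.0, 0.0]) + np.array(off)
            if jitter is not None:
                xyz = xyz + rng.normal(0, jitter, 3)
            atoms.append(_atom(serial, name, name[0], "ALA", i + 1, xyz))
    return Snapshot(atoms=atoms, frame_index=1)


# ---------------------------------------------------------------------------
# reading / writing


def test_multimodel_roundtrip_preserves_counts(tmp_path):
    snaps = [_protein_snapshot() for _ in range(3)]
    for i, s in enumerate(snaps, start=1):
        s.frame_index = i
    path = tmp_path / "toy.pdb"
    write_ensemble_pdb(snaps, path)
    ens = read_ensemble(path)
    assert len(ens.snapshots) == 3
    assert all(len(s.atoms) == len(snaps[0].atoms) for s in ens.snapshots)
    assert ens.reference is ens.snapshots[0]
    assert not ens.aligned


def test_single_model_reference(tmp_path):
    path = tmp_path / "one.pdb"
    write_ensemble_pdb([_protein_snapshot()], path)
    ens = read_ensemble(path)
    assert len(ens.snapshots) == 1
    assert ens.reference is ens.snapshots[0]


def test_model_atom_count_mismatch_is_an_error(tmp_path):
    lines = ["MODEL     1"]
    for i in range(10):
        lines.append(
            f"ATOM  {i+1:>5}  CA  ALA A{i+1:>4}    {float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
        )
    lines += ["ENDMDL", "MODEL     2"]
    for i in range(9):
        lines.append(
            f"ATOM  {i+1:>5}  CA  ALA A{i+1:>4}    {float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
        )
    lines += ["ENDMDL", "END"]
    path = tmp_path / "bad.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(StructureError, match="model 2 atom count mismatch"):
        read_ensemble(path)


# ---------------------------------------------------------------------------
# stripping


def _solvated_snapshot():
    atoms = list(_protein_snapshot().atoms)
    serial = len(atoms)
    for i in range(5):
        serial += 1
        atoms.append(_atom(serial, "O", "O", "HOH", 100 + i, (30.0 + i, 0, 0), het=True))
    for i in range(2):
        serial += 1
        atoms.append(_atom(serial, "NA", "NA", "NA", 200 + i, (40.0 + i, 0, 0), het=True))
    serial += 1
    atoms.append(_atom(serial, "FE", "FE", "HEM", 300, (5.0, 5.0, 0), het=True))
    return Snapshot(atoms=atoms, frame_index=1)


def test_strip_removes_solvent_and_ions_keeps_heme():
    snap = _solvated_snapshot()
    stripped = strip_nonprotein(snap)
    names = {a.residue_name for a in stripped.atoms}
    assert "HOH" not in names and "NA" not in names
    assert "HEM" in names and "ALA" in names


def test_strip_with_empty_keep_het_removes_heme():
    stripped = strip_nonprotein(_solvated_snapshot(), keep_het=set())
    assert all(a.residue_name != "HEM" for a in stripped.atoms)


def test_strip_is_idempotent_and_identity_without_solvent():
    clean = _protein_snapshot()
    once = strip_nonprotein(clean)
    assert [a.serial for a in once.atoms] == [a.serial for a in clean.atoms]
    twice = strip_nonprotein(strip_nonprotein(_solvated_snapshot()))
    assert [a.name for a in twice.atoms] == [a.name for a in strip_nonprotein(_solvated_snapshot()).atoms]


# ---------------------------------------------------------------------------
# superposition


def _ensemble_of(snapshots):
    return Ensemble(reference=snapshots[0].copy(), snapshots=snapshots, aligned=False)


def test_identical_copies_have_zero_rmsd():
    ref = _protein_snapshot()
    ens = _ensemble_of([ref.copy(), ref.copy()])
    aligned, rmsds = superpose_ensemble(ens)
    assert aligned.aligned
    assert all(r < 1e-9 for r in rmsds)


def test_rigid_motion_is_removed_by_fitting():
    ref = _protein_snapshot()
    moved = ref.copy()
    theta = np.pi / 2
    rot = np.array([[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    moved.set_coords(ref.coords @ rot.T + np.array([5.0, -3.0, 2.0]))
    _, rmsds = superpose_ensemble(_ensemble_of([ref.copy(), moved]))
    assert rmsds[1] < 1e-9


def test_gaussian_noise_rmsd_matches_closed_form(rng):
    # i.i.d. N(0, sigma^2) on each axis => fitted RMSD -> sigma * sqrt(3)
    sigma = 0.1
    ref = _protein_snapshot(n_res=150)
    noisy = ref.copy()
    noisy.set_coords(ref.coords + rng.normal(0, sigma, ref.coords.shape))
    _, rmsds = superpose_ensemble(_ensemble_of([ref.copy(), noisy]))
    assert abs(rmsds[1] - sigma * np.sqrt(3)) < 0.01


def test_superposition_preserves_internal_distances_and_is_idempotent(rng):
    ref = _protein_snapshot(n_res=20)
    moved = ref.copy()
    moved.set_coords(ref.coords + rng.normal(0, 0.3, ref.coords.shape))
    aligned, rmsds1 = superpose_ensemble(_ensemble_of([ref.copy(), moved]))
    before = moved.coords
    after = aligned.snapshots[1].coords
    d_before = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
    d_after = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
    assert np.abs(d_before - d_after).max() < 1e-9
    again, rmsds2 = superpose_ensemble(Ensemble(aligned.reference, aligned.snapshots, aligned=False))
    assert abs(rmsds1[1] - rmsds2[1]) < 1e-9


def test_too_few_backbone_atoms_is_an_error():
    hetero = Snapshot(atoms=[_atom(1, "FE", "FE", "HEM", 1, (0, 0, 0), het=True)])
    with pytest.raises(StructureError):
        superpose_ensemble(_ensemble_of([hetero, hetero.copy()]))


# ---------------------------------------------------------------------------
# heme frame


def _heme_snapshot(fe, sg):
    return Snapshot(
        atoms=[
            _atom(1, "FE", "FE", "HEM", 1, fe, het=True),
            _atom(2, "SG", "S", "CYS", 2, sg),
        ]
    )


def test_distal_axis_points_away_from_cysteine():
    frame = find_heme_frame(_heme_snapshot((0, 0, 0), (0, 0, -2.3)))
    assert np.allclose(frame.distal_axis, [0, 0, 1])


def test_distal_axis_is_translation_invariant():
    frame = find_heme_frame(_heme_snapshot((1, 1, 1), (1, 1, -1.3)))
    assert np.allclose(frame.distal_axis, [0, 0, 1])


def test_missing_proximal_cysteine_is_an_error():
    snap = _heme_snapshot((0, 0, 0), (0, 0, -5.0))  # SG too far
    with pytest.raises(StructureError, match="proximal cysteine not found"):
        find_heme_frame(snap)


def test_swapping_fe_and_sg_flips_the_axis():
    a = find_heme_frame(_heme_snapshot((0, 0, 1), (0, 0, -1)))
    b = find_heme_frame(_heme_snapshot((0, 0, -1), (0, 0, 1)))
    assert np.allclose(a.distal_axis, -b.distal_axis)


# ---------------------------------------------------------------------------
# SSE annotation


def test_sse_annotation_reads_ranges(tmp_path):
    path = tmp_path / "sse.tsv"
    path.write_text("# chain start end label\nA\t40\t55\tA′\nA\t60\t78\tB\n")
    ann = read_sse_annotation(path)
    assert len(ann.entries) == 2
    assert ann.label_for("A", 45) == "A′"
    assert ann.label_for("A", 59) is None


def test_empty_annotation_file(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("# nothing\n")
    ann = read_sse_annotation(path)
    assert ann.entries == []
    assert ann.label_for("A", 1) is None


def test_overlapping_ranges_are_an_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("A\t40\t55\tA\nA\t50\t60\tB\n")
    with pytest.raises(ValueError, match="overlap"):
        read_sse_annotation(path)
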