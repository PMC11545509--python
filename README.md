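# pocketens

Ensemble binding-pocket flexibility analysis for heme enzymes.

Cytochrome P450s and related heme enzymes bury their active site — the
cavity on the distal side of the heme iron, opposite the coordinating
cysteine thiolate — inside a highly flexible fold.  Which substrates an
isoform can accept depends less on any single structure than on the
*ensemble* of pocket conformations it samples: how big the pocket is,
how much its volume fluctuates, how spherical or branched it is, how
hydrophobic its lining is, and how often a channel to the protein
surface is open.  `pocketens` computes exactly these five descriptors
from an aligned conformational ensemble (e.g. MD snapshots), plus the
opening frequencies and direction classes of the access channels, and
condenses them into a categorical flexibility map suitable for
comparing many enzymes side by side.

## Method in brief

Two detection tracks run in parallel and are reconciled per snapshot:

* **sphere track** — alpha spheres (spheres tangent to four atoms with
  no atom inside, radii in [2.9, 16.0] Å) are placed at the Voronoi
  vertices of the heavy atoms of each snapshot, single-linkage
  clustered into pockets, and the pocket nearest the heme iron on its
  distal side is selected;
* **grid track** — the per-snapshot pocket spaces are rasterized onto a
  common grid; voxels inside the pocket in ≥ 50% of snapshots form the
  persistent pocket, with any surface-reaching corridor cut at its
  bottleneck.

Per snapshot the smaller-volume track wins (**min rule**): a smaller
sphere-track volume means the grid region split into several pockets;
a smaller grid-track volume means the sphere track leaked through an
open channel onto the surface.

The descriptors are: volume *V* (Monte-Carlo union of alpha spheres, or
voxel count); volume range max *V* − min *V* per replicate; shape
factor *A* / ((36π)^⅓ *V*^⅔), normalized so a perfect sphere scores 1;
hydrophobicity = apolar/total pocket SASA, where a surface point is
apolar iff ≥ 3 contacting atoms have Pauling electronegativity < 2.8;
and accessibility = % of snapshots with at least one open channel from
the active site to the surface.  Statistics are medians per replicate,
then mean ± sample SD across replicates; accessibility is pooled over
all frames.  See `docs/methods.md` for the full model description.

## Worked example

`examples/02_breathing_accessibility.py` builds a 25-frame synthetic
"breathing cage" — a hollow atomic shell with a 6 Å spherical cavity, a
minimal heme group, and an aperture that is open in exactly 64% of the
frames — and runs the full pipeline:

```
frames analyzed:       25
median volume:           852.0 Å³ (analytic cavity 904.8 Å³)
volume range:              3.0 Å³
shape factor:             0.56
hydrophobicity:           0.95
accessibility:            64.0 %  (scheduled 64%)
channel 1: open at the 60% isovalue  [solvent channel]
category symbols:      M ● ○ +++ H
```

The recovered median volume sits within 6% of the analytic cavity
volume (the bottleneck cut trims the pocket at the aperture throat);
accessibility recovers the scheduled open fraction exactly, while the
channel's opening frequency is quantized to the 0.05 isovalue ladder
(64% → 0.60).  The symbol string is the enzyme's row in the categorical
flexibility map (volume class, range class, shape class, hydrophobicity
class, accessibility class).

The other examples show single-structure pocket detection against a
known cavity volume (`01`), the category thresholds applied to
published human CYP reference rows including the surfaced CYP2A6
boundary discrepancy (`03`), and the file-based workflow through
multi-model PDB and the exported result tables (`04`).

A thin command-line interface wraps the same pipeline:

```sh
pocketens synth --preset breathing64 --frames 100 --out fixtures/
pocketens run --pdb fixtures/ensemble.pdb --out results/ --sse annotations.tsv
pocketens channels --pdb fixtures/ensemble.pdb
```

`run` writes `descriptors.csv` (one row per frame), `replicates.csv`,
`enzyme_summary.json`, `categories.tsv`, `channels.json`,
`occupancy.dx` (OpenDX, viewable in VMD/PyMOL) and `violin_data.csv`.

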