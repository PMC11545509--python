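# Methods

`pocketens` characterizes the flexibility of a buried, heme-proximal
binding pocket across a conformational ensemble.  The intended use case
is an ensemble of snapshots of a cytochrome-P450-like enzyme (from
molecular dynamics or any other source of aligned conformations), from
which five descriptors are computed — pocket volume, volume range,
shape factor, hydrophobicity and accessibility — together with the
opening frequencies and directions of the channels that connect the
pocket to the protein surface.

## Two detection tracks

**Sphere track (per snapshot).**  Alpha spheres are placed at the
Voronoi vertices of the heavy-atom centers: each Delaunay tetrahedron
contributes one candidate sphere (center = circumcenter, radius =
distance to its four defining atoms), which by construction contains no
atom center.  Spheres with radius outside [`r_min` = 2.9 Å, `r_max` =
16.0 Å] are discarded — the lower bound suppresses packing interstices,
the upper bound suppresses shallow surface depressions — as are spheres
whose center falls outside the convex hull of the atoms (exterior
Voronoi vertices).  Radii are measured center-to-atom-center; no
van-der-Waals correction is applied, and hydrogens are ignored
throughout.  Spheres are clustered into pockets by single linkage: two
spheres are linked when their centers are within `link_cutoff` = 4.5 Å
*or* when the spheres overlap (center distance below the sum of radii).
The overlap clause is needed because a large cavity sphere and the
smaller spheres of an attached corridor share interior volume while
their centers can be arbitrarily far apart; without it a single cavity
can fragment.  Clusters below `min_spheres` = 3 are dropped.  The
active site is the pocket containing a sphere on the distal side of the
heme iron — (c − Fe)·d̂ > 0 for the distal axis d̂ from the
coordinating cysteine SG through Fe — within `site_max_dist` = 8 Å of
Fe, nearest first.

**Grid track (ensemble).**  Each snapshot's selected pocket is
rasterized onto a common grid (spacing 1.0 Å, voxel-center-in-sphere
test); the per-voxel fraction of snapshots covering it is the
occupancy.  The persistent pocket is the 26-connected component of
voxels with occupancy ≥ 0.5 (inclusive) containing, or nearest to, the
seed point Fe + 4 Å·d̂.  If that pocket reaches the solvent surface,
the corridor is cut at its bottleneck: geodesic depth layers are grown
inward from each 26-connected group of surface-touching voxels; layer
sizes follow the corridor cross-section and swell once they reach the
pocket body, and the first local minimum of the layer-size profile is
taken as the bottleneck.  The bottleneck layer becomes the pocket's new
mouth; everything on its surface side is removed.  The layer-profile
rule is this package's own operational definition of "bottleneck"; it
reduces to the intuitive answer (remove the whole tube) for a narrow
corridor and cuts a wide funnel at its throat.

**Reconciliation (min rule).**  Per snapshot, the sphere-track volume
is the Monte-Carlo volume of the selected pocket's sphere union; the
grid-track volume is the volume of persistent-pocket voxels covered by
that snapshot's own pocket space.  The track with the smaller volume
supplies the snapshot's volume *and* its SASA as one coherent set.  The
rationale: a smaller sphere-track volume indicates the grid region
fragmented into several per-snapshot pockets (only the heme-distal one
is wanted), while a smaller grid-track volume indicates the sphere
track leaked through an open channel onto the protein surface.  Ties go
to the sphere track.  Whether surface areas should instead always come
from one fixed track is not determinable from first principles; the
same-track choice keeps each snapshot's A/V pair internally consistent.

## Descriptors

* **Volume** — Monte-Carlo integration over the sphere union (uniform
  samples in the joint bounding box; default 20 000 samples per frame,
  seeded per frame from the pipeline seed) or voxel count × spacing³ on
  the grid track.
* **SASA** — Shrake–Rupley-style sampling with a deterministic 960-point
  Fibonacci lattice per atom, probe 1.4 Å, over pocket-lining atoms
  only (alpha-sphere contact atoms, or heavy atoms within 3 Å of a
  pocket voxel on the grid track); occlusion is tested against all
  heavy atoms.  Because only lining atoms contribute, the reported area
  is not the closed surface of the cavity, while the volume covers the
  entire pocket — shape factors below 1 are therefore possible and no
  correction is applied.
* **Shape factor** — A / ((36π)^{1/3} V^{2/3}), the surface-to-volume
  ratio normalized so a perfect sphere scores exactly 1; higher values
  mean a more branched, irregular pocket.
* **Hydrophobicity** — apolar fraction of the pocket SASA.  A surface
  point is apolar iff at least three atoms with Pauling
  electronegativity below 2.8 are in contact with it, where "in
  contact" means the point lies within (vdW + 2 × probe) of the atom
  center.  The electronegativity table is Pauling (C 2.55, S 2.58,
  H 2.20, N 3.04, O 3.44, ...); both the table and the contact rule are
  overridable.
* **Accessibility** — the percentage of snapshots whose pocket space
  forms a 26-connected path from the active-site core to that
  snapshot's own solvent exterior (flood fill from the grid boundary
  over voxels outside the frame's vdW+probe volume, face-connected).

## Channels

Channels are read off the occupancy grid with a descending isovalue
ladder (0.95 … 0.05, step 0.05).  The solvent far-field is the
face-connected flood fill from the grid boundary over voxels that are
(a) blocked by atoms in fewer than half the frames and (b) below the
ladder floor in occupancy; clause (b) keeps the flood from running down
a transiently open corridor and labelling the pocket mouth itself as
solvent.  Exits are pocket-space voxels (at the ladder floor) bordering
the far-field; each 26-connected exit group is one channel, and its
opening frequency is the largest isovalue at which the core component
still reaches that exit group.  The three most frequently open channels
are retained.  Face connectivity for solvent (a probe cannot pass
through a voxel corner) versus 26-connectivity for pocket space is
deliberate and fixed.

Per-frame openness of a specific channel requires the frame's pocket
component to reach the frame's own exterior within that channel's exit
zone (exit voxels dilated by two).  Opening frequency is ladder-
quantized (a corridor open in 64% of frames reads 0.60) while
accessibility is exact; accessibility also dominates every single
channel's frequency, since any open channel makes the frame accessible.

Direction classes follow the conserved fold nomenclature: with M =
{helices A, A′, B, B′, F′, G′} ∪ {β-sheet labels}, a channel whose
flanking secondary-structure elements all lie in M is
*membrane-directed*, a mixed set is *perpendicular* (to the N-terminal
helix), none in M is *cytosolic*.  Flanking elements are the annotation
labels of residues with a heavy atom within 4 Å of the channel path;
annotations are consumed as a 4-column TSV and never computed here.
The channel whose exit direction has the most negative projection onto
the membrane axis (supplied, or estimated as the direction from the
protein centroid toward the first ten N-terminal residues) is flagged
as the solvent channel, provided the projection is below −0.1; ties
flag none.  Channel names from the published human-enzyme nomenclature
are *not* auto-assigned — channels are reported by their flanking
elements and direction class, and the mapping to named channels is left
to the user.

## Statistics and the flexibility map

Per replicate: median volume, shape and hydrophobicity over site-found
frames (even counts → midpoint), volume range = max − min.  Per enzyme:
mean of the per-replicate medians (and of the ranges) with the sample
standard deviation (ddof = 1) across replicates; accessibility is
pooled over all frames of all replicates, not averaged.  Frames without
a detected site are excluded from medians but reported as a site-found
fraction.

The categorical map bins each descriptor into three classes: volume
S < 800 ≤ M ≤ 950 < L (Å³); range ● < 1100 ≤ ●● ≤ 1300 < ●●●
(Å³); shape ○ < 0.94 ≤ ○○ ≤ 1.00 < ○○○; hydrophobicity
+ < 0.65 ≤ ++ ≤ 0.70 < +++; accessibility L < 40 ≤ M ≤ 55 < H (%).
Middle bins are closed intervals, so printed boundary values fall in
the middle bin.  A set of published human reference rows ships with the
package; `check_published_consistency()` maps their numeric values
through these thresholds and reports every symbol that disagrees with
the published map.  One reference enzyme (CYP2A6) sits exactly on the
800 Å³ volume boundary and below the 1100 Å³ range floor, so its
computed classes differ from its published row; this is surfaced as a
validation note rather than silently resolved.

## Synthetic fixtures

`pocketens.synthetic` generates hollow atomic cages: three concentric
Fibonacci-lattice shells (lattice spacing ≈ 2 Å, wall pitch 1.8 Å)
whose innermost atom centers lie on the nominal cavity sphere.  Because
alpha-sphere radii are center-to-center, the detected pocket volume of
a sealed cage matches (4/3)πr³ to within about 1%.  A minimal heme
pseudo-group (Fe plugging the bottom pole of the inner shell, four
pyrrole-like N, a cysteine SG below) makes heme-seeded selection work
without occupying cavity space; it is geometrically, not chemically,
meaningful.  An aperture is a cone about +z whose lid atoms swing to
the antipodal wall in open frames, keeping atom count and ordering
identical across frames.  The default open-cage aperture half-angle is
40° at cavity radius 6 Å (mouth clearance ≈ 3.9 Å): a detectable
channel must clear both the 2.9 Å alpha-sphere floor and the 3.1 Å
carbon vdW + probe solvent radius, which sets a lower bound on usable
apertures.  Shell composition is a seeded carbon/oxygen mixture
(`apolar_fraction`).

What the fixtures do and do not emulate: they provide cavities of known
volume, exact open/closed schedules and controlled polarity, so volume
recovery, accessibility, hydrophobicity limits and channel counting can
be checked against ground truth.  They are not protein-like — the wall
is three atom layers thin, there are no residues, rotamers or thermal
noise, and open frames within a schedule are geometrically identical.
Consequences worth knowing: the shape factor of a cage is not a
meaningful reference value (lining atoms of a thin wall expose area a
buried protein pocket would not), and surface points on bare
aperture-rim atoms of open frames can fall below the three-apolar-
contact rule, so the exact 1.0/0.0 hydrophobicity limits are asserted
on sealed cages.  Passing these tests demonstrates the machinery is
internally correct at desk scale; it does not demonstrate agreement
with measurements on real trajectories, which require cluster-scale
sampling (a 500 ns replicate sampled every 0.04 ns is 12 500 frames;
five replicates are 2.5 µs).

## Numerical choices and degenerate inputs

Occupancy thresholds compare inclusively (≥), so "at least 50%" keeps
voxels at exactly 0.5 — this matters for even-length alternating
schedules.  Monte-Carlo volume seeds derive deterministically from the
pipeline seed and the frame index.  Collinear/coplanar atom sets raise
a structure error from the Delaunay step; ensembles whose models differ
in atom count are rejected naming the first offending model; a missing
proximal cysteine (no SG within 3.5 Å of Fe) is an error, while a
snapshot without a detectable active site is a recorded, valid outcome.
Inputs lacking any protein backbone (pseudo-atom fixtures) skip
superposition with a warning and are trusted to be pre-aligned.
Multi-chain structures are used as given; callers wanting a monomer
should strip to it first.

Problem sizes in the shipped tests (ensembles of 2–100 frames of
300–400-atom cages) were chosen so the whole suite runs on a single CPU
in a few minutes while still exercising every pipeline stage end to
end.
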