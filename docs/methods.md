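# Methods

This note documents the models, algorithms and numerical choices behind
`emtracer`, a template-matching model-building pipeline for high-resolution
(≲3.5 Å) cryo-EM density maps. It is written for users who want to know what
the package computes and why, and what the synthetic test bed does and does
not demonstrate.

## Overview of the pipeline

The pipeline has two stages.

**Secondary-structure stage.** Short α-helix (6-residue) and β-strand
(4-residue) templates — each a standard coordinate segment plus a *mean map*
and a *correlation map* on a fine standard grid — are searched in the
working map, scored with a correlation-map-weighted Pearson CC, and refined
by simplex. The refined placements then calibrate the map's global voxel
size: a microscope magnification error mis-states every distance in the map,
and the placed templates, whose geometry is known in ångström, act as the
ruler.

**Cα stage.** A well-determined reference map/model pair provides training
data for an oriented density likelihood target. The reference map is first
put on the working map's amplitude scale by Guinier-curve (lnF vs d⁻²)
matching; per-offset density means and variances are then accumulated around
every interior Cα of the reference model. Chains are grown Cα-by-Cα from
both ends of the placed secondary structures, accepting the best-scoring
geometrically admissible candidate while its log-likelihood stays above an
adaptive threshold. Optionally, residue-type targets dock the target
sequence onto traced fragments and assign side-chain identities.

## Templates

Training segments are all sliding windows (step 1 residue) of annotated
helices/strands that superpose onto the ideal standard segment with
main-chain (N, Cα, C, O) RMSD < 0.5 Å. The map is sampled by third-order
(separable cubic-spline) interpolation on a standard grid of 0.5 Å spacing
covering the 15 Å ball around the standard segment's Cα centre of mass.
With samples `S[n, k]` (segment n, grid point k):

* mean map: `S_mean[k] = (1/n) Σ_n S[n, k]`;
* correlation map: grid points are binned by the distance `L[k]` to the
  nearest standard-segment atom into 30 groups of 0.5 Å (`i = floor(L/0.5)+1`,
  points with `L ≥ 15 Å` discarded); within each group the Pearson
  correlation of each segment's samples against the mean map is averaged
  over segments, and the group value is broadcast back to its points.

The correlation map estimates how *reproducible* density is at each distance
from the backbone, and is used as the per-point weight during scoring
(negative weights clamped to zero). The per-segment-then-averaged form of
the group correlation was chosen over a pooled variant; with the fixture's
training sets the two differ negligibly, and the per-segment form keeps each
training segment's contribution bounded.

Templates are trained by default on a dedicated clean structure (an isolated
helix plus a canonical 4-strand sheet, mixed sequences) standing in for a
well-determined experimental pair. Two fixture-design points matter and were
established empirically during development:

* **Mixed training sequences.** The mean map then carries an average
  side-chain sheath. A poly-alanine template is systematically "thinner"
  than real instances, and because the voxel-size scan compares template and
  map at 0.1% granularity, that radial mismatch translated into a measured
  ~+1% magnification bias.
* **Sheet-context strands.** An isolated 4-residue strand is nearly
  degenerate under axial sliding and scaling; most of a sheet's geometric
  information is the ~4.8 Å inter-strand spacing. Strand templates are
  therefore trained inside a sheet, and strand scoring uses a wider support
  (below) that reaches the neighbouring strands.

## Search and scoring

`fast_search` is a deliberately cheap pre-screen: a coarse orientation grid
(Fibonacci-sphere axis directions × spins, ~700 orientations) crossed with
every second voxel, scored by summing nearest-voxel map values at the
template's Cα/CB positions. Candidates are greedily peak-picked with a
minimum spacing. Precision comes from the next step, not from this one.

`weighted_cc` is the real objective: a weighted Pearson correlation between
the template mean map and the working map interpolated at the
pose-transformed standard-grid points, with weights `max(corr_map, 0)`.
Scoring is restricted to points within a per-kind distance of the standard
segment (helix 2 Å, strand 6 Å). The restriction matters: grid points far
from the segment belong to *neighbouring molecules*, and on the noise-free
synthetic maps their correlations stay high enough to pass any weight
threshold, dragging several-percent biases into the voxel-size scan. Helices
carry their scale information in their own 10 Å-periodic tube, so the tight
support suffices; strands need the wider support to see their sheet
neighbours.

`refine_pose` maximises the weighted CC by Nelder–Mead over a rotation
vector (about the current pose) and translation; standard coefficients,
convergence when the simplex's CC spread falls below `fatol` (1e-4 in
search, tighter in the voxel scan) or an iteration cap. Refinement never
returns a pose scoring below its start. Placements are then thresholded
(CC > 0.3), deduplicated (COM within 2 Å and axis within 15°), capped at the
top 20 per kind, and cross-kind arbitrated: a placement loses its claimed
region (5 Å around its COM) to any higher-CC placement of the other kind.
The cross-kind step exists because a helix template laid diagonally across a
sheet (or a strand along a helix) can clear the CC threshold on small maps
where true SSEs are few.

## Voxel-size refinement

The original voxel size `v_ori` is multiplied by each factor of the fixed
grid m ∈ {0.900, 0.901, …, 1.100} (201 values). Under a trial factor the
whole grid rescales about its origin, so each placement's translation is
multiplied by m (*offset compensation* — exact for the pose COM) and its
pose re-optimised at the trial scale before the weighted CC `CC[m, n]` is
recorded. The refined size is

    v_new = v_ori · argmax_m Σ_n CC[m, n]

per template kind, and the helix/strand estimates are combined by a weighted
average with weights equal to the number of "good" (CC > 0.3) placements of
each kind.

Two numerical points were decisive at small map sizes:

* **Per-factor refinement is translation-only, evaluated via anchors.**
  A uniform magnification never rotates features, so rotations stay at their
  (fully re-converged) native-scale values. Re-refining all six pose
  parameters at every factor lets the small strand template *absorb* the
  scale signal (a slight tilt mimics a changed sheet spacing), and running
  an optimiser 201 times per placement injects convergence noise larger than
  the CC peak's curvature (~1e-3). Instead, poses are re-optimised at anchor
  factors (every 0.010, warm-started marching outward from m = 1) and
  interpolated between anchors for the full 201-point profile. Warm starts
  are safe only because each anchor solve is run to convergence; an
  unconverged warm-started march accumulates optimisation progress along the
  scan and pushes the argmax toward the scan edges.
* **Reliability gating before combination.** The scan reports the
  dispersion (standard deviation) of the per-placement argmax factors. A
  kind whose individual placements disagree by much more than the sought
  precision carries no coherent scale signal; scans with dispersion > 0.015
  or a boundary argmax are excluded from the weighted average (if neither
  kind qualifies, both are used and the result is flagged). On the synthetic
  test bed, helix scans agree to ~1% while strand scans scatter by 2–6% —
  the strand's transverse signal is dominated by side-chain density that
  differs between sheets — so in practice the helix estimate carries the
  result there. The scan itself evaluates ~900 scoring points per pose with
  trilinear interpolation; the ~10 best placements per kind enter the scan.

`apply_voxel` writes the corrected voxel size into the header (isotropic)
and rescales the origin by the same ratio; the density array never moves.

## Reference-map scaling ("map simulation")

Both maps are mean-subtracted; Fourier amplitudes are radially averaged in
equal-width d⁻² shells (one shell per Fourier radius step of the box) with
the DC term excluded. The reference's amplitudes are multiplied per Fourier
voxel by `exp(lnF_work − lnF_ref)`, with the two curves linearly
interpolated in d⁻² between shell centres. For all components at resolution
coarser than 10 Å the correction is clamped to its value at the 10 Å shell:
the low-frequency terms describe the two molecules' different envelopes and
would otherwise be grossly over-weighted. Phases are untouched. Finally the
scaled map is low-pass filtered to the working resolution. Mean amplitude
(not RMS) per shell is used; with the mean-subtraction convention the
identity case (`reference = working`) reproduces the low-passed working map
to float precision.

## Likelihood targets and chain extension

The Cα target is defined on a fixed offset set (1 Å lattice clipped to a
4 Å ball, 257 offsets) expressed in a canonical frame built from the
Cα(i−1), Cα(i), Cα(i+1) triplet: z along Cα(i+1)−Cα(i−1), x toward the
triplet bisector. For every interior Cα of the reference model the scaled
reference map is sampled at the offsets and per-offset mean μ and variance
σ² accumulated (variance floored at 1e-6 of the map variance — purely to
guard constant-density offsets). A pose scores

    score = − Σ_j [ (ρ_j − μ_j)² / (2 σ²_j) + ½ ln σ²_j ] ,

with outside-map samples counted as zero density (a strong penalty wherever
the target expects signal). Per-residue-type targets are accumulated the
same way over residues of each type (minimum 3 examples).

Extension grows a trace from both ends of a seed (the Cαs of a placed
template, or an existing fragment). Candidates for the next Cα lie on
shells of radius 3.4/3.8/4.2 Å (60 Fibonacci directions each) around the
last Cα, subject to Cα(i−1)–Cα(i+1) ≥ 4.5 Å, map bounds, and a 3.0 Å
clash distance against everything built so far. Each candidate c is scored
by the likelihood of the triplet (prev, last, c) evaluated at the last Cα;
the best candidate is accepted while its score stays above an adaptive
threshold calibrated on the seed region (mean − 2·SD of the seed's interior
triplet scores). Produced fragments always satisfy the geometry invariants
(consecutive Cα in [3.0, 4.2] Å, non-consecutive pairs ≥ 3.0 Å), enforced
by construction and re-checked.

Fragment merging drops duplicates (> 40% of the shorter trace within 2 Å of
a higher-scoring one) and greedily joins end-to-end continuable fragments
(gap within bonding distance, geometry check passed). A residue budget
derived from the requested residue count (or molecular mass at 110 Da per
residue) caps the total, keeping the best-scoring fragments.

Sequence docking scores every alignment of the sequence along a fragment in
both directions as the mean per-position residue-type log-likelihood. The
best alignment is accepted when it beats the runner-up by more than 5% of
the spread (best − worst) of all alignment scores; log-likelihoods carry an
arbitrary additive offset, so a margin defined as a fraction of the best
score itself would depend on that offset, whereas the spread is
offset-invariant. Ambiguous fragments (poly-ALA stretches, fragments longer
than the sequence) stay unassigned and are emitted as poly-ALA.

Model quality against a ground-truth structure is reported as the fraction
of built Cαs within 1 Å and 2 Å of the nearest truth Cα, the RMSD over
those nearest-neighbour pairs, and (for the synthetic benchmarks) the
*coverage*: the fraction of truth Cαs with a built Cα within 2 Å.

## Synthetic test bed

All tests run on simulated data. Segments are built from ideal backbone
geometry (NeRF chain construction; helix φ/ψ = −57.8°/−47.0°, strand
−130°/125°), with schematic side chains: CB placed tetrahedrally plus a
short zig-zag of carbon pseudo-atoms whose count scales with the residue's
heavy-atom size. Maps are rendered as one normalised 3D Gaussian per atom
(weight proportional to atomic number; width σ² = B/(8π²) plus an
anti-alias term of (0.8·voxel)², which keeps the lattice sum equal to the
continuous integral to ~1e-8), low-pass filtered to the target resolution
with a cosine edge two Fourier pixels wide, with optional seeded Gaussian
noise.

The default structures are:

* a **toy protein** (74 residues: three 14-residue helices in a bundle and a
  canonical 4×8 sheet, mixed sequences) — the working-map stand-in;
* a **training protein** (120 residues, four helices and four strands,
  disjoint from the toy protein) — the reference-pair stand-in for
  likelihood training;
* the **template training structure** described above.

Default simulation conditions: 1.0 Å voxels, 2.5 Å resolution, B = 20 Å²,
no noise. Magnification errors are introduced by multiplying the header
voxel size by factors 0.95–1.05, reproducing how the error manifests in
practice (the data never move; the coordinates lie).

What the fixtures do *not* model: experimental noise statistics and CTF
effects, solvent/detergent density, resolution anisotropy and local
resolution variation, conformational heterogeneity, and real side-chain
rotamers. Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms — recovery of known magnification errors,
detection of known SSEs, likelihood discrimination, register recovery — not
performance on experimental maps. One consequence worked through above is
that the noise-free fixtures are in some ways *harder* than real data for
the voxel scan (deterministic context correlations defeat the
correlation-map weighting), which motivated the distance-restricted scoring
support.

Problem sizes were chosen to keep the full test suite and the acceptance
script in the minutes range on a single CPU: a ~60×40×40 Å box at 1 Å
voxels, ≤ 10 placements per kind in the scan, ~900–1500 scoring points per
pose. The method is unchanged at larger sizes; only the statistics improve.

## Known limitations

* Loop closure and topology assembly across gaps are out of scope; traced
  fragments are emitted as separate chains.
* Side-chain assignment is at residue-type level (no rotamer building), and
  the schematic fixture side chains can only demonstrate coarse (size-based)
  discrimination.
* Voxel-size refinement assumes an isotropic magnification error.
* Strand-based voxel estimates are unreliable on small maps (see the
  reliability gate); on maps with many sheets the gate admits them
  naturally.
* The MRC reader supports orthogonal (P1) cells only; non-cubic voxels are
  accepted with a warning but the voxel scan treats the size as isotropic.
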