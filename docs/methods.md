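# Methods

## Scope and data flow

`crosscoil` operates on three kinds of input: a cross-link table (residue
pairs with a high/low confidence class and a free-text provenance label), a
coordinate model in PDB format that may be *disjointed* — built from rigid
fragments with runs of unmodelled residues between them — and sequence-level
evidence (homologue alignments, secondary-structure prediction strings) for
break-point calling.  Everything downstream is deterministic given these
inputs; the only stochastic components are the synthetic-data generators and
the rigid-fragment optimizer, both of which take mandatory seeds.

## Coiled-coil generation

Strand Cα traces come from the Crick parameterization with defaults
r₀ = 5.0 Å, P = 140 Å, r₁ = 2.26 Å, h = 1.5 Å/residue and exact 3.5-residue
periodicity (the minor-helix phase advances 2·2π/7 per residue in the frame
that co-rotates with the superhelix, i.e. exactly two minor turns per
heptad).  The supercoil is left-handed; the minor helices are right-handed,
which for the strand running toward −z means its minor phase decreases with
residue index.  The a/d heptad positions face the superhelical axis: the
phase of residue 1 is chosen so that the midpoint of the a and d phases
points inward.  A `beclin_like` preset (P = 127 Å) mirrors the geometry of
the longest crystallographically resolved anti-parallel two-stranded coil
and serves as a second self-consistency point.

Backbone completion: N, C and O are placed at constant offsets from Cα in
an intrinsic per-residue frame (e₁ along Cαᵢ₋₁→Cαᵢ₊₁, e₂ toward the local
helix axis, e₃ = e₁×e₂).  The offsets are calibrated once from an ideal
straight α-helix built by sequential internal-coordinate (NeRF)
construction with φ = −57°, ψ = −47°, ω = 180° and standard bond
lengths/angles.  Cβ is placed by the ideal tetrahedral construction from
N/CA/C; glycine gets no Cβ but a virtual one is available on demand.
Because the frames are computed from the actual local Cα neighbourhood,
the same recipe serves straight and supercoiled traces and either strand
direction; the residual distortion from applying straight-helix offsets to
a gently supercoiled trace is well below PDB coordinate precision concerns
and does not create steric clashes (tested).

`register_offset` shifts strand B axially by offset × h, positive toward
strand A's C-terminus, so offset 7 ≈ 10.5 Å and offset 14 ≈ 21 Å.

## Geometry measurement

`measure` inverts the generator using one exact identity: because the minor
phase advances 4π per heptad, the mean of seven consecutive Cα positions
cancels the minor helix and lands on the local helix axis.  The measurement
pipeline is: (1) per-strand 7-residue moving averages → local helix
centres; (2) superhelical axis = first principal component of all centres;
(3) rise = |slope| of axial coordinate vs residue index per strand;
(4) pitch from the slope of the unwrapped azimuth of centres against axial
position (2π/|dθ/dz|); (5) radius = mean centre–axis distance, corrected
for the slight radial shrinkage the moving average causes (dividing by the
window mean of cos(kΩ), k = −3…3, ≈ 0.7 % at canonical parameters).  A
fragment measuring radius < 0.5 Å is treated as a straight helix and
reports infinite pitch.  Two full heptads per strand are required.

## Distance validation

*Euclidean*: Cα–Cα, accommodated at ≤ 30 Å.  The 30 Å cap is the empirical
27.4 Å BS3 reach plus modelling tolerance; both values are carried in
`ValidationThresholds` (the 27 Å nominal spacer length is documentation
only).

*Solvent-accessible-surface*: Cβ–Cβ shortest path through solvent.  The
algorithm voxelises a bounding box around the two endpoints (margin =
cutoff/2 + 2 voxels, which provably contains every path shorter than the
cutoff) at 1 Å spacing; a voxel is blocked when its centre lies within
vdW + 1.4 Å probe of any heavy atom (C 1.7, N 1.55, O 1.52, S 1.8 Å).
Atoms of the two endpoint residues do not block a 3 Å shell around their
own Cβ — the shell is fixed in physical units, not voxel counts, so grid
refinement cannot seal an endpoint inside its own residue's spheres.  The
shortest path runs over 26-connected free voxels with exact Euclidean edge
weights (Dijkstra; the sparse graph solve is delegated to scipy), plus the
snap distances from each Cβ to its nearest free voxel.  Discretisation
overestimates free-space distances by at most ~8 % (chamfer error of the
26-neighbourhood); the free-space test budgets 0.8 Å at 10 Å.  Paths
longer than the 40 Å calculation cutoff are `unreachable`, which — matching
the difference between the calculation and acceptance cut-offs — is
reported but never by itself fails a link whose Euclidean distance passes.

Status assignment: both endpoints modelled → accommodated/incompatible by
threshold; exactly one modelled → *implicit* (the model cannot contradict
the link); neither modelled → unmeasurable, with the sequence separation
recorded so that closely spaced unmodelled pairs can still be counted
implicitly compatible (gap ≤ 5 residues in the summary accounting).
The compatibility summary reports both the itemised explicit/implicit
counts and the complement of the incompatible links (total − incompatible),
since the two figures answer slightly different questions.

## Junction criterion and clashes

A junction passes when its endpoint Cα distance is ≤ n_omitted × 3.4 Å
+ 2.0 Å: 3.4 Å/residue is the extended (β-strand) per-residue span, and
2 Å is the upper end of the deliberate allowance acknowledging rigid
-fragment limitations; the per-residue metric (distance / n_omitted) is
reported for plotting against the 1.5 Å helical and 3.4 Å extended
reference rates.  Clash detection flags atom pairs of non-adjacent residues
closer than vdWᵢ + vdWⱼ − 0.6 Å, using a KD-tree with an all-pairs oracle
cross-check in the tests.

## Register inference and shift sensitivity

`scan_registers` rebuilds the pair at each candidate offset (default: the
heptad-preserving grid −21…+21 in steps of 7) and counts links with
Cα ≤ threshold; ties break toward the smaller |offset|, then the negative
one.  `shift_sensitivity` translates one strand of each coiled-coil unit
rigidly along the unit's principal axis by shift × 1.5 Å and reports the
fraction of previously satisfied links pushed over threshold (links already
broken are excluded from the denominator).  The rigid axial translation is
a declared choice — re-threading the sequence would be an alternative
reading.  Strands are paired into units either explicitly (two-segment
fragments) or, after a PDB round-trip has split strands into separate
chains, geometrically: nearest anti-parallel fragment (axis dot < −0.5)
within 15 Å; unpaired strands are skipped with a warning.

## Break-point heuristics

Five masks over the reference residues of a homologue alignment:
(i) runs of ≥ 5 alignment columns where ≥ 60 % of non-gap rows are polar
(D,E,K,R,N,Q,S,T,H); (ii) ≥ 3 secondary-structure methods predicting
non-helix (reported *not evaluable*, never false, when fewer than three
tracks are supplied); (iii) runs of ≥ 4 columns containing only hydrophobic
residues (A,V,I,L,M,F,W,Y,C); (iv) columns where Pro/Gly or gaps occur in
more than one third of rows; (v) heptad-phase disruption from a 21-residue
sliding window scored as hydrophobic fraction at the implied a/d positions
minus the hydrophobic fraction elsewhere, best of the seven phases — a
phase jump between adjacent windows (necessarily a non-multiple of 7) or a
score below 0.4 flags disruption.  The amino-acid sets, the 60 % dominance
margin and the 0.4 collapse threshold are configurable; the score is a
simplified stand-in for full position-specific coiled-coil profile
matrices, adequate for run/phase logic but not a probability model.  Calls
are maximal runs where ≥ 1 criterion fires, merged across gaps ≤ 2
residues; all evidence is reported rather than enforcing a precedence
between heuristics and automatic predictions.

## Rigid-fragment optimizer

Seeded simulated annealing over rigid-body fragment poses: moves are
rotations ≤ 5° about the fragment centroid plus translations ≤ 2 Å;
the objective is 10 × (broken links + soft distance excess) + 5 ×
(junction violations + soft excess) + inter-fragment Cα contacts < 3 Å
(a cheap steric proxy; full vdW clash scanning remains a separate check).
Geometric cooling; an input already at objective 0 is returned untouched;
the best-so-far trace is non-increasing by construction.  Atoms never move
within a fragment.

## Synthetic generators — what they emulate and what they do not

`make_dimer_scaffold` builds two SMC-like proteins, each folded back into
its own anti-parallel coiled-coil (an "up" strand, an unmodelled 5-residue
linker, a "down" strand), the two coils placed side by side at 15 Å
centre-to-centre — the rod-like arrangement the cross-link patterns imply
for the condensin SMC core.  Strands default to 70 residues (10 heptads):
long enough for stable geometric fits and realistic link statistics, small
enough that the full test suite runs in seconds.  Leucine occupies a/d;
surface positions (b,c,e,f,g) carry lysine at density 0.25 — only
outward-facing residues, since buried lysines cannot react with the
cross-linker — with the remaining surface drawn from polar residues
(deliberately excluding Ala/Gly/Pro so the sequence background cannot fake
hydrophobic runs or parsing signals).

`simulate_crosslinks` thresholds the Cα–Cα distance at the 27.4 Å empirical
reach and applies a detection probability (default 0.8) to reachable
lysine pairs; false positives are drawn uniformly from non-reachable pairs
(default rate 0, set explicitly in tests that need noise — no estimate
exists for the high-confidence class being emulated, so the default favours
a clean truth set).  This is a deliberate simplification of BS3 chemistry:
real capture depends on side-chain (NZ) geometry, solvent accessibility and
peptide detectability, none of which are modelled.  Consequently, passing
recovery tests demonstrate that the algorithms invert their own generative
model — register recovery, break-point recall and validation accounting are
internally sound — not that the noise statistics of a real CLMS experiment
are reproduced.

Break-point tasks substitute windows of an ideal repeat with Gly/Pro or
polar runs (keeping alignment columns intact; true insertions with gap
columns are not generated), build homologues by class-preserving point
substitution outside the conserved disruption windows, and emit
secondary-structure tracks as H with 5 % per-residue error and C across
disruptions.

All generators are pure functions of (spec, seed) using
`numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Numerical choices and degenerate inputs

* Residue numbering is 1-based everywhere and never renumbered on I/O;
  insertion codes are rejected, altlocs keep the first conformer.
* PDB round-trips are coordinate-stable at the format's 3-decimal
  precision; fragments are re-inferred from chains and numbering gaps, so a
  two-strand fragment becomes two single-strand fragments after a round
  trip (the geometric pairing above compensates where it matters).
* Unassigned residues (outside every declared segment) classify links as
  interdomain rather than erroring; self-pairs (identical endpoints) are
  forced intermolecular because a single chain cannot link a residue to
  itself.
* Sequence mismatches between a link table and the registry warn instead
  of failing: residue numbering conventions drift across database isoforms.
* The geometry fitter requires ≥ 2 heptads per strand; the heptad profile
  requires one full window (21 residues).

## Known limitations

* The published condensin coordinate model and its link table are
  user-supplied inputs; the statistics check against them runs only when
  the supplementary files are placed under `data/condensin/`.
* SAS distances are Cβ–Cβ over a 1 Å grid; no side-chain atoms beyond Cβ,
  no surface-area computation, no ensemble averaging.
* Criterion (v) uses the simplified windowed score, not full COILS/PCOILS
  profile matrices.
* The optimizer is a local annealer intended for refining nearly correct
  poses against dense restraints, not a global assembly search.
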