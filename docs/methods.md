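# Methods

This note records the models, parameters, and numerical choices behind the
pipeline, and what the synthetic fixtures do and do not establish.

## Base reference frames

Every geometric comparison operates on one frame per nucleotide: the
centroid of the base ring heavy atoms (9 for purines, 6 for pyrimidines)
and a proper rotation obtained by Kabsch-fitting an idealized planar base
onto the observed ring atoms.  The idealized geometries are standard
chemical reference data (planarized ideal coordinates of A, C, G, U ring
atoms plus C1′), stored canonically with the ring centroid at the origin
and the x-axis toward the glycosidic nitrogen, and re-centered exactly at
import so that synthesizing atoms from a frame and re-fitting recovers the
frame to machine precision.  Residues missing ring atoms, and modified
residues, yield no frame; they are reported, never silently dropped.  For
congruent planar point sets the proper-rotation fit is unique, so frames
are well defined; rotation angles between frames are computed as
`atan2(sin, cos)` of the relative rotation, which is well-conditioned over
the whole `[0, π]` range (plain `arccos` loses ~8 digits near 0 and would
dominate the discrepancy of near-identical loops).

## Geometric discrepancy

For matched frame lists of length `n ≥ 3`,

    D = (1/n) · sqrt( Σᵢ ‖T(cᵢ) − c′ᵢ‖² + Σᵢ (κ·θᵢ)² )   [Å per nucleotide]

with `T` the rigid transform minimizing the translational sum over base
centers, `θᵢ ∈ [0, π]` the residual orientation angle of base `i`, and
`κ` the angle weight in Å/radian.  `D` is symmetric in its arguments and
invariant under rigid motions of either input.

**Angle weight κ = 1.0 Å/rad (default).**  With realistic base geometry
this makes a single 180° glycosidic flip in an 8–12 nt loop cost
0.29–0.47 Å/nt: the angular term contributes π/n, and the translational
term reflects how far the ring centroid sits from the glycosidic axis
(≈1.1 Å for purines, hence a ≈2.2 Å centroid jump on flipping; nearly 0
for pyrimidines, whose 6-ring centroid lies almost on the axis).  The
acceptance script measures a mean of ≈0.38 Å/nt over mixed-base,
mixed-size replicates.  The match cutoff of 1.0 Å/nt therefore tolerates
single flips — desirable, since flips are frequently modeling artifacts —
while separating genuinely different geometries.  κ is configurable for
recalibration against other annotators' discrepancy conventions.

## Alignment search

A query's *core* is the set of its nucleotides making at least one true
(non-near) pair or stack with another loop nucleotide, plus the closing
nucleotides; the complement is the bulged bases.  Admissible alignments
are injective, cover the whole core, preserve 5′→3′ order per strand, and
map closing nucleotides onto closing nucleotides; internal loops may also
be matched with their two strands exchanged (rotated), but never
reflected, which would break chirality.  Pinning strand endpoints to
strand endpoints also enforces the flankSS-correspondence constraint: in a
maximal loop the only nucleotides making nested canonical cWW pairs are
the closing ones, so flankSS holds exactly between strand endpoints on
both sides.

The search enumerates per-strand monotone placements recursively and is
exact.  Partial mappings are pruned with a distance-matrix lower bound:
for any rigid `T`, `|d(qᵢ,qⱼ) − d(tᵢ,tⱼ)| ≤ ‖Tcᵢ − c′ᵢ‖ + ‖Tcⱼ − c′ⱼ‖`
implies `Σ‖Tcᵢ − c′ᵢ‖² ≥ Σᵢ<ⱼ (Δdᵢⱼ)² / (2n)`, a bound that only grows as
the mapping extends.  Ties between equal-discrepancy optima resolve to the
unrotated orientation first, then the lexicographically smallest target
index sequence, so results do not depend on enumeration order.  For
internal loops a pre-screen first checks whether the four closing
nucleotides alone superpose within the cutoff (identity or rotated
correspondence); on the fixture set the pre-screen never prunes a pair the
full search would have matched, and the relation is asserted by test.

Degenerate inputs: cores smaller than 3 leave the superposition
underdetermined and raise; the all-against-all driver records such pairs
as non-matches rather than aborting a whole release.

## Matching matrix and clustering

Entries merge the two directed searches: infinity if neither matched or
either direction was structurally incompatible, else the lower of the two
discrepancies; the diagonal is zero and symmetry is enforced structurally.
Motif groups are exact maximum cliques of the finite-entry graph, removed
iteratively.  Selection among maximal cliques uses the total order (size,
discrepancy sum, lexicographic id list); enumeration is Bron–Kerbosch per
connected component — exact, and fast because match graphs at the 1.0 Å/nt
cutoff decompose into small components.  The third, lexicographic
tie-break goes beyond the discrepancy-sum rule because symmetric synthetic
data can tie exactly; determinism must be total for byte-stable releases.
Greedy peeling can orphan instances whose best partners were absorbed by
an earlier clique; these end as singletons, a known and accepted property
of the scheme.

The consensus alignment of a clique is built as connected components over
(instance, nucleotide) nodes with edges from the member pairwise
alignments, added in order of increasing discrepancy; an alignment whose
edges would merge two nucleotides of one instance into one column is
discarded (highest-discrepancy first, by construction) and recorded on the
group.  Columns with a nucleotide in every instance are core columns;
columns covering a proper subset are insertions (bulges).  Column order
follows strand and 5′ position in the reference instance (lowest loop id),
with insertion columns anchored after their nearest preceding core
position.  If members matched in inconsistent strand orientations, the
group is flagged rather than silently re-oriented.

## Base-pair signatures

A consensus pair is a true pair annotated between two core columns in more
than half of the instances (majority family; ties lexicographic).  Tokens
are ordered by the strand-1 position of each pair's strand-1 partner and
rendered from the strand-1 side (`tSH` = strand-1 base uses the Sugar
edge).  Conserved unpaired core columns contribute `L` (strand 1, at their
own position) or `R` (strand 2, inserted between the two pairs whose
strand-2 partners bracket them — well defined because strand-2 partner
positions fall monotonically as pairs are read off).  Signatures begin and
end with the closing cWW tokens; hairpin signatures begin with their
single closing cWW.  Base triples (two consensus pairs sharing a strand-1
partner) are ordered by strand-2 partner and flagged in the diagnostics.

## Id versioning

Motif ids are `PREFIX_CCCCC.V` with a five-digit code drawn from a seeded
RNG and collision-checked against all recorded history (the code history
travels in release provenance).  Tracking rules, in order: identical
instance set → same id and version; overlap with one or two old groups
where some old group shares ≥ 2/3 of both set sizes → that code,
version + 1 (at most one old group can qualify, since two two-thirds
majorities cannot coexist — asserted at runtime); overlap with more than
two old groups → fresh code regardless of overlap; no overlap → fresh
code.  The two-thirds comparisons are done in integer arithmetic
(`3·shared ≥ 2·size`), so the 8-of-12/9 boundary case is exact.  HL and IL
releases are versioned independently; release ids (`major.minor`) are
operator-supplied, since the significance of a change is a human judgment.
Common names attached to a code propagate to its successors.

## Synthetic fixtures

The generator emulates the inputs the pipeline consumes in production:
single-chain constructs of A-form-like helices (rise 2.81 Å, twist 32.7°,
base centers 4 Å off axis) around loop regions with template-specific
geometry, plus the pair/stack annotations an annotator would emit.  The
shipped library holds five internal-loop templates (differing in interior
lengths 4–7, helix–helix gaps 5–18 Å, bend angles 0–160°, and lateral
offsets) and three hairpin templates (arcs of different radius, height,
and plane), with total loop sizes spanning 8–12 nt.  All inter-template
alignment discrepancies exceed 1.2 Å/nt (asserted by test), so clustering
ground truth is unambiguous at the 1.0 cutoff.  Instantiation jitters
centers with isotropic Gaussian noise σ and orientations with random
rotations of angle ~|N(0, σ/κ)|, balancing the two discrepancy terms; at
the default study condition σ = 0.2 Å, within-template pairs land around
0.1–0.3 Å/nt, matching the coherence observed for real motif groups.
Bulge insertion uses insertion codes (so every other residue identity is
untouched) and adds no interactions unless stacks or a near pair are
requested to trigger specific incompatibility criteria; base flips rotate
ring atoms 180° about the C1′→N1/N9 axis and are exact involutions.

What the fixtures do *not* emulate: physically realistic backbones and
sugar puckers, sequence-dependent geometry, annotation noise or
non-unanimity across instances, crystallographic disorder, and the scale
of a full structure database.  Passing tests therefore establish the
correctness of the pipeline's logic and calibration on well-posed inputs,
not classification accuracy on experimental structures.

## Problem sizes

The test suite and acceptance script run at desk scale by design: the
end-to-end recovery scenario uses 5 templates × 8 instances (40 internal
loops, ~1,500 directed alignments), the clique-exactness check uses 200
random graphs of ≤15 vertices against subset enumeration, and the flip
calibration uses 56 replicates.  The whole suite completes in a few
seconds on one CPU.

## Known limitations

- QA covers the two failure modes the method names (missing coordinates,
  modified nucleotides); the reason vocabulary is extensible, and further
  stages (e.g. symmetry-related clash checks) would slot into the same
  report structure.
- Junction loops are extracted and identified but not clustered; cycles of
  order four and five are detected and reported without ids.
- Alternate locations: the first altloc is taken, and the choice is not
  currently surfaced per residue.
- The mmCIF round trip is exact only to the format's coordinate precision
  (10⁻³ Å); in-memory pipelines are exact.
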