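# rna-motif-atlas

Automated classification of RNA 3D hairpin (HL) and internal loop (IL)
motifs, with versioned, trackable releases.

Recurrent RNA 3D motifs — sarcin–ricin, kink-turn, T-loop, and many motifs
with no common name — are loop regions that adopt the same spatial
arrangement of non-Watson–Crick base pairs in unrelated molecules.  This
package implements the full pipeline a motif atlas needs to classify them
automatically from 3D structures and their pairwise interaction
annotations:

1. **Loop extraction.**  Canonical cWW pairs (GC/AU/GU) that are nested in
   the secondary structure delimit loops via the *flankSS* relation: two
   same-chain nucleotides flank a single-stranded region when both make
   nested canonical cWW pairs and no nucleotide between them does.  HL,
   IL, and three-way junction (J3) loops are extracted (closing pairs are
   part of the loop), given stable ids such as `IL_1S72_001`, passed
   through quality assurance (modified nucleotides and unresolved
   coordinates are set aside), and deduplicated to representative chains.
2. **Geometric all-against-all alignment.**  Each base is reduced to a
   reference frame (ring-atom centroid + orientation fitted to an
   idealized base).  The discrepancy between two loops under an alignment
   is

       D = (1/n) * sqrt( Σᵢ ‖T(cᵢ) − c′ᵢ‖²  +  Σᵢ (κ·θᵢ)² )

   where `T` is the optimal rigid superposition of base centers, `θᵢ` the
   residual base-orientation angle, and `κ = 1.0 Å/rad`.  Two loops match
   when some admissible alignment — injective, 5′→3′ order-preserving per
   strand, closing nucleotides onto closing nucleotides, optionally with
   IL strands rotated — reaches `D ≤ 1.0 Å/nt`.  Bulged bases (no pair or
   stack into the loop) are excluded from query cores, so instances with
   different bulge counts can still match.
3. **Structural incompatibility.**  Aligned-but-incompatible pairs are
   severed: base pairs from different Leontis–Westhof families at
   corresponding positions, extra nucleotides that pair (true or near)
   into the loop, intercalating extras (two or more stacks), pairs aligned
   onto stacks, and — for hairpins — extras stacked on aligned bases or on
   each other.
4. **Clustering.**  The symmetric matching matrix (minimum of the two
   search directions; infinity for non-matches and severed pairs) defines
   a graph; motif groups are exact maximum cliques, peeled iteratively,
   with ties resolved by lowest discrepancy sum so the result is
   independent of instance order.  A consensus alignment per group defines
   its core nucleotides.
5. **Releases.**  Groups get ids like `IL_24982.1` (random five-digit code
   + version).  Between releases a group keeps its id when unchanged,
   increments its version when it shares at least two-thirds of the
   instances of both old and new group, and otherwise gets a fresh code.
   Groups without common names are labeled by their base-pair signature,
   e.g. `cWW-tSH-tHS-cWW`, with `L`/`R` marking conserved unpaired bases.

Inputs are mmCIF/PDB coordinates plus a small tabular dialect for base-pair
and stacking annotations (in production these come from an annotator such
as FR3D), so the pipeline is annotator-agnostic.  A synthetic-fixture
generator ships with the package: a library of well-separated loop
templates with known ground truth, so every stage is testable without
downloads.

## Worked example

```python
from motif_atlas import build_release
from motif_atlas.synthetic_fixtures import (template_library,
                                            instantiate_template,
                                            instance_loops)

library = template_library()
prepared = []
sid = 0
for name in ("il-straight", "il-bent70"):
    for replicate in range(4):
        sid += 1
        inst = instantiate_template(library[name], noise_sigma=0.2,
                                    seed=sid, structure_id=f"S{sid:03d}")
        prepared.extend(instance_loops(inst))

release = build_release(prepared, "IL", release_id="0.1", seed=1)
print(f"release {release.release_id}: {len(release.groups)} IL motif groups")
for g in release.groups:
    print(f"  {g.motif_id}  n={len(g.instances)}  "
          f"mean_discrepancy={g.draft.mean_discrepancy:.3f}  {g.signature}")
```

prints

```
release 0.1: 2 IL motif groups
  IL_52586.1  n=4  mean_discrepancy=0.165  cWW-L-R-R-L-cWW
  IL_56063.1  n=4  mean_discrepancy=0.171  cWW-tSH-L-R-L-cWW
```

Eight noisy instances of two geometrically distinct internal-loop
templates are classified into exactly two motif groups, one per template.
The mean intra-group discrepancies (~0.17 Å/nt) sit well below the
1.0 Å/nt match cutoff — coherent groups typically show 0.1–0.6 Å/nt — and
each group is labeled by its consensus base-pair signature (the second
template carries a tSH pair; conserved unpaired bases appear as `L`/`R`).

The same workflow is available from the shell:

```sh
motif-atlas simulate --template il-straight --n 4 --sigma 0.2 --out sim/
motif-atlas extract  --structure sim/S001.cif \
                     --annotations sim/S001.annotations.csv --out loops/
motif-atlas release  --inputs sim/ --loop-type IL --release-id 0.1 --out r1/
motif-atlas compare  --a r1/release.json --b r2/release.json
```

## Layout

| module | contents |
| --- | --- |
| `motif_atlas.structure_io` | coordinates (gemmi), annotation dialect, base reference frames, release serialization |
| `motif_atlas.loop_extraction` | nested pairs, flankSS, HL/IL/J3 extraction, loop ids, QA, chain deduplication |
| `motif_atlas.geometric_alignment` | discrepancy, query cores, pre-screen, exact pairwise alignment, all-against-all |
| `motif_atlas.compatibility` | the five incompatibility criteria |
| `motif_atlas.clustering` | matching matrix, exact maximum-clique peeling, consensus alignments |
| `motif_atlas.atlas_release` | base-pair signatures, id versioning, release assembly/comparison |
| `motif_atlas.synthetic_fixtures` | template library, noisy instantiation, bulges, base flips, release scenarios |
| `motif_atlas.cli` | `motif-atlas` command group |

See `docs/methods.md` for the model, parameter, and design notes.
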