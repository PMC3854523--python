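"""Synthetic structures and annotations with known ground truth.

The generator builds idealized single-chain constructs — helices with
A-form-like rise and twist, internal loops with template-specific bends
and interior placements, hairpins with template-specific arcs — together
with the base-pair/stacking annotations an annotator would emit for
them.  Atoms are synthesized from the base frames via the idealized base
geometries, so coordinate I/O, frame computation and discrepancy are
exercised jointly end to end.

The template library is fixed: every template is deterministic, and the
inter-template separation (minimum alignment discrepancy between zero-
noise instances of different templates, well above the 1.0 Å/nt match
cutoff) makes clustering ground truth unambiguous.  Instances add
isotropic Gaussian jitter to base centers and small random rotations to
orientations; bulged nucleotides and base flips can be introduced on top
to emulate the variation seen among homologous motif instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._geometry import rotation_about_axis, small_random_rotation
from .loop_extraction import (Loop, assign_loop_ids, extract_loops,
                              qa_filter, select_representative_chains)
from .geometric_alignment import PreparedLoop, prepare_loop
from .structure_io import (AnnotationSet, BaseFrame, Chain, NucleotideRef,
                           PairAnnotation, Residue, StackAnnotation,
                           Structure, atoms_from_frame, compute_base_frames,
                           glycosidic_nitrogen, is_canonical_pair,
                           ring_atom_names)

# A-form-like helix constants (recorded here as the generator's config)
RISE = 2.81          # Å per base pair step
TWIST = math.radians(32.7)
RADIUS = 4.0         # base-center distance from the helix axis, Å
STRAND_OFFSET = math.radians(150.0)
DEFAULT_KAPPA = 1.0  # Å/radian; couples orientation noise to center noise


def _rz(a: float) -> np.ndarray:
    return rotation_about_axis([0.0, 0.0, 1.0], a)


_FLIP_X = rotation_about_axis([1.0, 0.0, 0.0], math.pi)


def helix_frames(level: int) -> tuple[BaseFrame, BaseFrame]:
    """Frames of the two bases of helix pair ``level`` (0 = first pair)."""
    z = np.array([0.0, 0.0, level * RISE])
    A1 = _rz(level * TWIST)
    A2 = _rz(level * TWIST + STRAND_OFFSET)
    f1 = BaseFrame(A1 @ np.array([RADIUS, 0.0, 0.0]) + z, A1)
    f2 = BaseFrame(A2 @ np.array([RADIUS, 0.0, 0.0]) + z, A2 @ _FLIP_X)
    return f1, f2


@dataclass
class HelixLayout:
    """An ideal ``n_pairs`` helix: frames plus index-based annotations."""

    n_pairs: int
    strand1: list                      # BaseFrame, 5'->3'
    strand2: list                      # BaseFrame, 5'->3' (level n-1 .. 0)
    pairs: list                        # (i in strand1, j in strand2)
    stacks: list                       # ((strand, i), (strand, j))


def make_ideal_helix(n_pairs: int) -> HelixLayout:
    """A-form-like helix with canonical cWW pairs and sequential stacks."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    s1, s2 = [], []
    for level in range(n_pairs):
        f1, f2 = helix_frames(level)
        s1.append(f1)
        s2.append(f2)
    s2 = s2[::-1]                      # 5'->3' on the complementary strand
    pairs = [(i, n_pairs - 1 - i) for i in range(n_pairs)]
    stacks = []
    for i in range(n_pairs - 1):
        stacks.append(((1, i), (1, i + 1)))
        stacks.append(((2, i), (2, i + 1)))
    return HelixLayout(n_pairs, s1, s2, pairs, stacks)


# --------------------------------------------------------------------------
# Motif templates
# --------------------------------------------------------------------------

@dataclass
class MotifTemplate:
    """One idealized loop instance embedded in closing helices.

    ``sequence``/``frames`` describe the full single-chain construct;
    ``pairs``/``stacks`` are index-based annotations; ``loop_strands``
    lists the residue indices of the motif loop's strands (ground truth
    for extraction); ``interior`` lists flippable interior indices and
    ``bulge_sites`` the (strand, offset) insertion points."""

    name: str
    loop_type: str
    sequence: str
    frames: list
    pairs: list                        # (i, j, family, near)
    stacks: list                       # (i, j, face, near)
    loop_strands: list                 # list of list of residue indices
    interior: list                     # residue indices of loop interiors
    cap_strand: Optional[list] = None  # residue indices of the cap HL

    def size(self) -> int:
        return sum(len(s) for s in self.loop_strands)


_HELIX_N = 3          # closing helix length used throughout the library
_CAP_N = 4            # nucleotides in the hairpin cap of IL constructs


def _interp_frames(p0: np.ndarray, p1: np.ndarray, k: int,
                   rng: np.random.Generator, spread: float = 2.0) -> list:
    """``k`` frames along the segment p0 -> p1 with deterministic,
    template-specific lateral offsets and orientations."""
    out = []
    for j in range(1, k + 1):
        t = j / (k + 1)
        center = (1 - t) * p0 + t * p1 + rng.normal(0.0, spread, size=3)
        axis = rng.normal(size=3)
        angle = rng.uniform(0.0, math.pi)
        out.append(BaseFrame((center), rotation_about_axis(axis, angle)))
    return out


def _transform_frame(f: BaseFrame, R: np.ndarray, t: np.ndarray) -> BaseFrame:
    return BaseFrame(R @ f.center + t, R @ f.rotation)


_SEQ_CYCLE = "AUGC"


def _build_il_template(name: str, k1: int, k2: int, bend_axis, bend_angle,
                       extra_twist: float, seed: int,
                       noncanonical: Sequence[tuple] = (),
                       gap: float = 6.0,
                       lateral: tuple = (0.0, 0.0)) -> MotifTemplate:
    """Internal-loop construct: helixA + interior1 + helixB + cap +
    helixB' + interior2 + helixA'."""
    rng = np.random.default_rng(seed)
    hA = make_ideal_helix(_HELIX_N)
    hB_local = make_ideal_helix(_HELIX_N)

    R_t = rotation_about_axis(bend_axis, bend_angle) @ _rz(extra_twist)
    t_t = np.array([lateral[0], lateral[1],
                    (_HELIX_N - 1) * RISE + gap])

    def B(f: BaseFrame) -> BaseFrame:
        return _transform_frame(f, R_t, t_t)

    # cap frames in helixB local coordinates: arc over the helix top
    cap_local = []
    top = (_HELIX_N - 1) * RISE
    for j in range(_CAP_N):
        a = math.pi * (j + 1) / (_CAP_N + 1)
        center = np.array([3.5 * math.cos(a), 3.5 * math.sin(a),
                           top + 3.0 + 1.5 * math.sin(a)])
        cap_local.append(BaseFrame(center,
                                   _rz(a) @ rotation_about_axis(
                                       [0, 1, 0], 0.9)))

    frames: list = []
    seq: list = []
    idx: dict = {}

    def push(tag, frame, base):
        idx[tag] = len(frames)
        frames.append(frame)
        seq.append(base)

    for lv in range(_HELIX_N):                       # helixA strand 1
        push(("A1", lv), hA.strand1[lv], "G")
    p0 = hA.strand1[_HELIX_N - 1].center
    p1 = B(hB_local.strand1[0]).center
    for j, f in enumerate(_interp_frames(p0, p1, k1, rng)):
        push(("I1", j), f, _SEQ_CYCLE[j % 4])
    for lv in range(_HELIX_N):                       # helixB strand 1
        push(("B1", lv), B(hB_local.strand1[lv]), "G")
    for j, f in enumerate(cap_local):                # hairpin cap
        push(("CAP", j), B(f), _SEQ_CYCLE[(j + 1) % 4])
    for i, f in enumerate(hB_local.strand2):         # helixB strand 2
        push(("B2", _HELIX_N - 1 - i), B(f), "C")
    p2 = B(hB_local.strand2[-1]).center
    p3 = hA.strand2[0].center
    for j, f in enumerate(_interp_frames(p2, p3, k2, rng)):
        push(("I2", j), f, _SEQ_CYCLE[(j + 2) % 4])
    for i, f in enumerate(hA.strand2):               # helixA strand 2
        push(("A2", _HELIX_N - 1 - i), f, "C")

    pairs = []
    for lv in range(_HELIX_N):
        pairs.append((idx[("A1", lv)], idx[("A2", lv)], "cWW", False))
        pairs.append((idx[("B1", lv)], idx[("B2", lv)], "cWW", False))
    for (a, b, fam) in noncanonical:
        pairs.append((idx[a], idx[b], fam, False))

    stacks = []
    n = len(frames)
    helix_runs = [[idx[("A1", lv)] for lv in range(_HELIX_N)],
                  [idx[("B1", lv)] for lv in range(_HELIX_N)],
                  [idx[("B2", lv)] for lv in range(_HELIX_N - 1, -1, -1)],
                  [idx[("A2", lv)] for lv in range(_HELIX_N - 1, -1, -1)]]
    for run in helix_runs:
        for a, b in zip(run, run[1:]):
            stacks.append((a, b, "s35", False))
    # loop + cap regions: consecutive chain stacking keeps them in the core
    loop_runs = [
        [idx[("A1", _HELIX_N - 1)]] + [idx[("I1", j)] for j in range(k1)]
        + [idx[("B1", 0)]],
        [idx[("B2", 0)]] + [idx[("I2", j)] for j in range(k2)]
        + [idx[("A2", _HELIX_N - 1)]],
        [idx[("B1", _HELIX_N - 1)]] + [idx[("CAP", j)]
                                       for j in range(_CAP_N)]
        + [idx[("B2", _HELIX_N - 1)]],
    ]
    for run in loop_runs:
        for a, b in zip(run, run[1:]):
            stacks.append((a, b, "s35", False))

    loop_strands = [
        [idx[("A1", _HELIX_N - 1)]] + [idx[("I1", j)] for j in range(k1)]
        + [idx[("B1", 0)]],
        [idx[("B2", 0)]] + [idx[("I2", j)] for j in range(k2)]
        + [idx[("A2", _HELIX_N - 1)]],
    ]
    cap_strand = [idx[("B1", _HELIX_N - 1)]] + \
        [idx[("CAP", j)] for j in range(_CAP_N)] + \
        [idx[("B2", _HELIX_N - 1)]]
    interior = [idx[("I1", j)] for j in range(k1)] + \
        [idx[("I2", j)] for j in range(k2)]
    return MotifTemplate(name, "IL", "".join(seq), frames, pairs, stacks,
                         loop_strands, interior, cap_strand)


def _build_hl_template(name: str, k: int, arc_radius: float, lift: float,
                       tilt: float, seed: int,
                       offset: tuple = (0.0, 0.0)) -> MotifTemplate:
    """Hairpin construct: helix + ``k``-nucleotide loop arc."""
    rng = np.random.default_rng(seed)
    h = make_ideal_helix(_HELIX_N)
    frames, seq, idx = [], [], {}

    def push(tag, frame, base):
        idx[tag] = len(frames)
        frames.append(frame)
        seq.append(base)

    for lv in range(_HELIX_N):
        push(("S1", lv), h.strand1[lv], "G")
    top = (_HELIX_N - 1) * RISE
    for j in range(k):
        a = math.pi * (j + 1) / (k + 1)
        center = np.array([offset[0] + arc_radius * math.cos(a),
                           offset[1] + arc_radius * math.sin(a),
                           top + lift + 1.2 * math.sin(2 * a)])
        center = center + rng.normal(0.0, 0.8, size=3)
        rot = _rz(a) @ rotation_about_axis([0, 1, 0], tilt)
        push(("L", j), BaseFrame(center, rot), _SEQ_CYCLE[j % 4])
    for i, f in enumerate(h.strand2):
        push(("S2", _HELIX_N - 1 - i), f, "C")

    pairs = [(idx[("S1", lv)], idx[("S2", lv)], "cWW", False)
             for lv in range(_HELIX_N)]
    stacks = []
    runs = [[idx[("S1", lv)] for lv in range(_HELIX_N)],
            [idx[("S2", lv)] for lv in range(_HELIX_N - 1, -1, -1)],
            [idx[("S1", _HELIX_N - 1)]] + [idx[("L", j)] for j in range(k)]
            + [idx[("S2", _HELIX_N - 1)]]]
    for run in runs:
        for a, b in zip(run, run[1:]):
            stacks.append((a, b, "s35", False))
    loop_strands = [[idx[("S1", _HELIX_N - 1)]]
                    + [idx[("L", j)] for j in range(k)]
                    + [idx[("S2", _HELIX_N - 1)]]]
    interior = [idx[("L", j)] for j in range(k)]
    return MotifTemplate(name, "HL", "".join(seq), frames, pairs, stacks,
                         loop_strands, interior)


def template_library() -> dict:
    """The fixed library: five internal-loop and three hairpin templates.

    Bend axes/angles, twists and interior placements are chosen to keep
    all inter-template alignment discrepancies far above the 1.0 Å/nt
    cutoff; loop sizes span the typical 8-12 nt range."""
    lib = {}
    ils = [
        ("il-straight", 2, 2, [1, 0, 0], 0.0, 0.0, 101, (), 5.0, (0, 0)),
        ("il-bent70", 3, 2, [1, 0, 0], math.radians(70), 0.4, 102,
         ((("I1", 0), ("I2", 1), "tSH"),), 9.0, (5.0, -3.0)),
        ("il-bent140", 4, 3, [1, 0, 0], math.radians(140), 1.0, 103, (),
         14.0, (-6.0, 4.0)),
        ("il-bulge", 4, 0, [0, 1, 0], math.radians(70), 2.0, 104,
         ((("I1", 0), ("I1", 3), "tHS"),), 18.0, (8.0, 8.0)),
        ("il-twisted", 3, 3, [0, 1, 0], math.radians(160), 2.6, 105, (),
         11.0, (-9.0, -7.0)),
    ]
    for name, k1, k2, axis, angle, twist, seed, nc, gap, lat in ils:
        lib[name] = _build_il_template(name, k1, k2, axis, angle, twist,
                                       seed, nc, gap, lat)
    hls = [
        ("hl-arc6", 6, 4.5, 2.5, 0.7, 201, (0.0, 0.0)),
        ("hl-arc7", 7, 8.0, 7.0, 1.6, 202, (8.0, 3.0)),
        ("hl-arc8", 8, 3.0, 12.0, 2.6, 203, (-8.0, 5.0)),
    ]
    for name, k, radius, lift, tilt, seed, off in hls:
        lib[name] = _build_hl_template(name, k, radius, lift, tilt, seed,
                                       off)
    return lib


# --------------------------------------------------------------------------
# Instantiation
# --------------------------------------------------------------------------

@dataclass
class Instance:
    """One synthesized loop instance: structure + annotations + truth."""

    structure: Structure
    annotations: AnnotationSet
    template_name: str
    loop_type: str
    loop_strand_refs: list             # ground-truth strands (refs)
    interior_refs: list
    noise_sigma: float
    seed: int

    @property
    def structure_id(self) -> str:
        return self.structure.structure_id

    def chain_residues(self) -> list:
        return self.structure.chains[0].residues


def instantiate_template(template: MotifTemplate, noise_sigma: float = 0.0,
                         seed: int = 0, structure_id: str = "SYN1",
                         chain: str = "A") -> Instance:
    """Materialize a template as a structure + annotation set.

    Base centers are jittered by isotropic Gaussian noise of ``noise_sigma``
    (Å); orientations by small random rotations of angle ~
    ``noise_sigma / kappa`` radians, so both discrepancy terms carry
    comparable noise.  ``noise_sigma=0`` reproduces the template layout
    exactly."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    residues = []
    refs = []
    for i, (frame, base) in enumerate(zip(template.frames,
                                          template.sequence)):
        center = frame.center + rng.normal(0.0, noise_sigma, size=3)
        rot = small_random_rotation(rng, noise_sigma / DEFAULT_KAPPA) \
            @ frame.rotation
        noisy = BaseFrame(center, rot)
        ref = NucleotideRef(structure_id, 1, chain, i + 1, "", base)
        atoms = atoms_from_frame(base, noisy)
        # minimal backbone so the construct reads like a nucleotide chain
        atoms["P"] = noisy.rotation @ np.array([-2.0, 4.5, 1.0]) \
            + noisy.center
        residues.append(Residue(ref, base, atoms, True))
        refs.append(ref)
    structure = Structure(structure_id, [Chain(chain, residues)])

    annset = AnnotationSet(structure_id)
    for i, j, fam, near in template.pairs:
        canonical = is_canonical_pair(fam, refs[i].base, refs[j].base, near)
        annset.add_pair(PairAnnotation(refs[i], refs[j], fam, near,
                                       canonical))
    for i, j, face, near in template.stacks:
        annset.add_stack(StackAnnotation(refs[i], refs[j], face, near))

    strands = [[refs[i] for i in strand] for strand in template.loop_strands]
    interior = [refs[i] for i in template.interior]
    return Instance(structure, annset, template.name, template.loop_type,
                    strands, interior, noise_sigma, seed)


def instance_loops(instance: Instance,
                   representatives: Optional[dict] = None) -> list:
    """Run the extraction pipeline on an instance: extract, id, QA,
    deduplicate chains, and bundle with frames into PreparedLoops."""
    loops, _ = extract_loops(instance.structure, instance.annotations)
    loops = assign_loop_ids(loops, instance.structure_id)
    loops, _ = qa_filter(loops, instance.structure)
    loops = select_representative_chains(loops, instance.structure,
                                         representatives)
    frames, _ = compute_base_frames(instance.structure)
    return [prepare_loop(loop, frames, instance.annotations)
            for loop in loops]


def motif_loop(instance: Instance) -> Loop:
    """The ground-truth motif loop of an instance, as extracted."""
    wanted = {nt.key() for s in instance.loop_strand_refs for nt in s}
    for pl in instance_loops(instance):
        if {nt.key() for nt in pl.loop.nucleotides()} == wanted:
            return pl.loop
    raise LookupError(
        f"motif loop of {instance.template_name} not recovered")


def prepared_motif_loop(instance: Instance) -> PreparedLoop:
    wanted = {nt.key() for s in instance.loop_strand_refs for nt in s}
    for pl in instance_loops(instance):
        if {nt.key() for nt in pl.loop.nucleotides()} == wanted:
            return pl
    raise LookupError(
        f"motif loop of {instance.template_name} not recovered")


# --------------------------------------------------------------------------
# Structural perturbations
# --------------------------------------------------------------------------

_ICODES = "ABCDEFGH"


def add_bulge(instance: Instance, strand: int, position: int,
              base: str = "A", stack_count: int = 0,
              near_pair: bool = False, seed: int = 7) -> Instance:
    """Insert a bulged nucleotide after interior offset ``position`` of
    loop strand ``strand``.

    The inserted nucleotide makes no true pair or stack with the loop
    (so it is excluded from query cores and triggers no incompatibility)
    unless ``stack_count`` stack annotations to its chain neighbors are
    requested, or ``near_pair`` adds a near-cWW to a loop nucleotide.
    Insertion uses an insertion code, so all other residue identities
    are untouched."""
    strand_refs = instance.loop_strand_refs[strand]
    if not 0 <= position < len(strand_refs) - 1:
        raise ValueError("position outside strand interior")
    anchor = strand_refs[position]
    rng = np.random.default_rng(seed)

    residues = list(instance.chain_residues())
    ai = next(i for i, r in enumerate(residues)
              if r.ref.key() == anchor.key())
    used_icodes = {r.ref.insertion_code for r in residues
                   if r.ref.number == anchor.number}
    icode = next(c for c in _ICODES if c not in used_icodes)
    ref = NucleotideRef(instance.structure_id, 1, anchor.chain,
                        anchor.number, icode, base)

    nxt = residues[ai + 1]
    mid = (residues[ai].atoms["C1'"] + nxt.atoms["C1'"]) / 2.0
    offset = rng.normal(0.0, 1.0, size=3)
    offset = 5.0 * offset / np.linalg.norm(offset)
    frame = BaseFrame(mid + offset,
                      rotation_about_axis(rng.normal(size=3),
                                          rng.uniform(0, math.pi)))
    atoms = atoms_from_frame(base, frame)
    atoms["P"] = frame.rotation @ np.array([-2.0, 4.5, 1.0]) + frame.center
    residues.insert(ai + 1, Residue(ref, base, atoms, True))

    structure = Structure(instance.structure_id,
                          [Chain(anchor.chain, residues)])
    annset = AnnotationSet(instance.structure_id)
    for p in instance.annotations.pairs:
        annset.add_pair(p)
    for s in instance.annotations.stacks:
        annset.add_stack(s)
    neighbors = [residues[ai].ref, nxt.ref]
    for k in range(stack_count):
        annset.add_stack(StackAnnotation(ref, neighbors[k % 2], "s35",
                                         False))
    if near_pair:
        partner = strand_refs[-1]
        annset.add_pair(PairAnnotation(ref, partner, "cWW", near=True,
                                       canonical=False))

    new_strands = [list(s) for s in instance.loop_strand_refs]
    new_strands[strand] = (strand_refs[:position + 1] + [ref]
                           + strand_refs[position + 1:])
    return Instance(structure, annset, instance.template_name,
                    instance.loop_type, new_strands,
                    list(instance.interior_refs), instance.noise_sigma,
                    instance.seed)


def flip_base(instance: Instance, ref: NucleotideRef) -> Instance:
    """Rotate one base ~180° about its glycosidic bond (anti <-> syn).

    The rotation axis runs through C1' along the C1'->N1/N9 direction;
    only the base ring atoms of that residue move.  Applying the flip
    twice restores the original coordinates."""
    residues = []
    for res in instance.chain_residues():
        if res.ref.key() != ref.key():
            residues.append(res)
            continue
        ngly = glycosidic_nitrogen(res.name)
        c1 = res.atoms["C1'"]
        axis = res.atoms[ngly] - c1
        R = rotation_about_axis(axis, math.pi)
        atoms = dict(res.atoms)
        for name in ring_atom_names(res.name):
            atoms[name] = R @ (atoms[name] - c1) + c1
        residues.append(Residue(res.ref, res.name, atoms, res.is_rna))
    structure = Structure(instance.structure_id,
                          [Chain(instance.chain_residues()[0].ref.chain,
                                 residues)])
    return Instance(structure, instance.annotations,
                    instance.template_name, instance.loop_type,
                    [list(s) for s in instance.loop_strand_refs],
                    list(instance.interior_refs), instance.noise_sigma,
                    instance.seed)


# --------------------------------------------------------------------------
# Release scenarios
# --------------------------------------------------------------------------

@dataclass
class ReleaseScenario:
    """Inputs for successive releases plus the expected id history."""

    releases: list                     # list of list[Instance]
    expected: list                     # per release: {template: action}
    # action: "new" | "same" | "increment"


def make_release_scenario(spec: Sequence[dict], seed: int = 0,
                          noise_sigma: float = 0.15,
                          loop_type_filter: Optional[str] = None
                          ) -> ReleaseScenario:
    """Generate instance sets for successive releases.

    ``spec`` lists, per release, ``{template_name: instance_count}``.
    Replicates are stable across releases (replicate ``k`` of a template
    is the same structure in every release containing it), so the
    expected id history follows from the overlap rules applied to the
    template partition: identical instance sets -> same id; two-thirds
    overlap of both sets -> version increment; otherwise a fresh id."""
    lib = template_library()
    max_counts: dict = {}
    for entry in spec:
        for name, count in entry.items():
            max_counts[name] = max(max_counts.get(name, 0), count)

    cache: dict = {}
    serial = 0
    for name in sorted(max_counts):
        for k in range(max_counts[name]):
            serial += 1
            sid = f"S{serial:03d}"
            cache[(name, k)] = instantiate_template(
                lib[name], noise_sigma,
                seed=int(np.random.default_rng((seed, serial)).integers(
                    0, 2**31 - 1)),
                structure_id=sid)

    releases, expected = [], []
    prev_counts: dict = {}
    for entry in spec:
        insts = []
        actions = {}
        for name in sorted(entry):
            count = entry[name]
            insts.extend(cache[(name, k)] for k in range(count))
            old = prev_counts.get(name)
            if old is None:
                actions[name] = "new"
            elif old == count:
                actions[name] = "same"
            else:
                shared = min(old, count)
                if 3 * shared >= 2 * count and 3 * shared >= 2 * old:
                    actions[name] = "increment"
                else:
                    actions[name] = "new"
        releases.append(insts)
        expected.append(actions)
        prev_counts = dict(entry)
    return ReleaseScenario(releases, expected)
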