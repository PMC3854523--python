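"""Coordinates, pairwise-interaction annotations, and base reference frames.

This module owns the data model shared by the whole pipeline:

* :class:`NucleotideRef` — stable identity of one residue (author numbering,
  never a re-index), so loop identifiers survive re-parsing.
* :class:`Structure` / :class:`Residue` — a light in-memory model of an RNA
  3D structure read from mmCIF or PDB via :mod:`gemmi`.
* :class:`PairAnnotation` / :class:`StackAnnotation` / :class:`AnnotationSet`
  — Leontis–Westhof base-pair and base-stacking annotations with ``near``
  and ``canonical`` flags, read from a small tabular dialect so that any
  annotator (FR3D or otherwise) can feed the pipeline.
* :class:`BaseFrame` — base center plus orthonormal orientation matrix,
  obtained by Kabsch-fitting an idealized planar base onto the observed
  ring atoms.  All geometric comparisons operate on these frames.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from ._geometry import kabsch

# --------------------------------------------------------------------------
# Leontis-Westhof vocabulary
# --------------------------------------------------------------------------

#: The 12 Leontis-Westhof base-pair families in normalized edge order.
LW_FAMILIES = (
    "cWW", "tWW", "cWH", "tWH", "cWS", "tWS",
    "cHH", "tHH", "cHS", "tHS", "cSS", "tSS",
)

_EDGE_ORDER = {"W": 0, "H": 1, "S": 2}

#: Base combinations whose cWW pairs are canonical (helix-forming).
CANONICAL_COMBOS = frozenset({("G", "C"), ("C", "G"), ("A", "U"),
                              ("U", "A"), ("G", "U"), ("U", "G")})

STACK_FACES = ("s33", "s35", "s53", "s55")

STANDARD_BASES = frozenset({"A", "C", "G", "U"})


def reverse_family(family: str) -> str:
    """Edge-order reversal of a family code: ``cWH`` <-> ``cHW``; cWW fixed."""
    return family[0] + family[2] + family[1]


def normalize_family(family: str) -> tuple[str, bool]:
    """Return the normalized family code and whether the edge order was flipped.

    Accepts all 24 edge-ordered spellings (e.g. ``cHW`` is stored as ``cWH``
    with the two nucleotides swapped).  Raises ``ValueError`` for anything
    else.
    """
    if family in LW_FAMILIES:
        return family, False
    rev = reverse_family(family)
    if rev in LW_FAMILIES:
        return rev, True
    raise ValueError(f"unknown family {family!r}")


def reverse_face(face: str) -> str:
    """Stacking face-code reversal under nucleotide swap (s35 <-> s53)."""
    return "s" + face[2] + face[1]


# --------------------------------------------------------------------------
# Identity and annotation types
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class NucleotideRef:
    """Stable identity of one residue within one input structure.

    Equality and ordering use ``(structure_id, model, chain, number,
    insertion_code)``; the base letter is descriptive metadata only.
    """

    structure_id: str
    model: int
    chain: str
    number: int
    insertion_code: str = ""
    base: str = field(default="N", compare=False)

    def __post_init__(self) -> None:
        if self.model < 1:
            raise ValueError("model must be >= 1")

    @property
    def is_standard(self) -> bool:
        return self.base in STANDARD_BASES

    def key(self) -> tuple:
        return (self.structure_id, self.model, self.chain,
                self.number, self.insertion_code)

    def unit_id(self) -> str:
        """Compact textual form used in CSV/JSON output."""
        parts = [self.structure_id, str(self.model), self.chain,
                 self.base, str(self.number)]
        if self.insertion_code:
            parts.append(self.insertion_code)
        return "|".join(parts)

    @classmethod
    def from_unit_id(cls, text: str) -> "NucleotideRef":
        parts = text.split("|")
        if len(parts) not in (5, 6):
            raise ValueError(f"malformed unit id {text!r}")
        icode = parts[5] if len(parts) == 6 else ""
        return cls(parts[0], int(parts[1]), parts[2], int(parts[4]),
                   icode, parts[3])


@dataclass(frozen=True)
class PairAnnotation:
    """One base pair in a Leontis-Westhof family, oriented nt1 -> nt2."""

    nt1: NucleotideRef
    nt2: NucleotideRef
    family: str
    near: bool = False
    canonical: bool = False

    def reversed(self) -> "PairAnnotation":
        return PairAnnotation(self.nt2, self.nt1, reverse_family(self.family),
                              self.near, self.canonical)


@dataclass(frozen=True)
class StackAnnotation:
    """One base-stacking contact, oriented nt1 -> nt2."""

    nt1: NucleotideRef
    nt2: NucleotideRef
    face_code: str
    near: bool = False

    def reversed(self) -> "StackAnnotation":
        return StackAnnotation(self.nt2, self.nt1, reverse_face(self.face_code),
                               self.near)


def is_canonical_pair(family: str, base1: str, base2: str, near: bool) -> bool:
    """A canonical pair is a true (non-near) cWW between GC/AU/GU bases."""
    return (family == "cWW" and not near and (base1, base2) in CANONICAL_COMBOS)


class AnnotationSet:
    """All pairwise annotations of one structure, symmetric under swap."""

    def __init__(self, structure_id: str,
                 pairs: Iterable[PairAnnotation] = (),
                 stacks: Iterable[StackAnnotation] = ()) -> None:
        self.structure_id = structure_id
        self._pairs: dict[tuple, PairAnnotation] = {}
        self._stacks: dict[tuple, StackAnnotation] = {}
        self._by_nt_pairs: dict[tuple, list[PairAnnotation]] = {}
        self._by_nt_stacks: dict[tuple, list[StackAnnotation]] = {}
        for p in pairs:
            self.add_pair(p)
        for s in stacks:
            self.add_stack(s)

    # -- construction -----------------------------------------------------

    def add_pair(self, pair: PairAnnotation) -> None:
        a, b = pair.nt1.key(), pair.nt2.key()
        if a > b:
            pair = pair.reversed()
            a, b = b, a
        key = (a, b, pair.family)
        if key in self._pairs:
            return  # duplicate (unordered pair, family)
        self._pairs[key] = pair
        self._by_nt_pairs.setdefault(a, []).append(pair)
        self._by_nt_pairs.setdefault(b, []).append(pair.reversed())

    def add_stack(self, stack: StackAnnotation) -> None:
        a, b = stack.nt1.key(), stack.nt2.key()
        if a > b:
            stack = stack.reversed()
            a, b = b, a
        key = (a, b, stack.face_code)
        if key in self._stacks:
            return
        self._stacks[key] = stack
        self._by_nt_stacks.setdefault(a, []).append(stack)
        self._by_nt_stacks.setdefault(b, []).append(stack.reversed())

    # -- queries ----------------------------------------------------------

    @property
    def pairs(self) -> list[PairAnnotation]:
        return list(self._pairs.values())

    @property
    def stacks(self) -> list[StackAnnotation]:
        return list(self._stacks.values())

    def pairs_of(self, nt: NucleotideRef) -> list[PairAnnotation]:
        """All pairs involving ``nt``, oriented so that ``nt1 == nt``."""
        return list(self._by_nt_pairs.get(nt.key(), ()))

    def stacks_of(self, nt: NucleotideRef) -> list[StackAnnotation]:
        return list(self._by_nt_stacks.get(nt.key(), ()))

    def pairs_between(self, a: NucleotideRef, b: NucleotideRef
                      ) -> list[PairAnnotation]:
        """Pairs between ``a`` and ``b``, oriented a -> b."""
        return [p for p in self._by_nt_pairs.get(a.key(), ())
                if p.nt2.key() == b.key()]

    def stacks_between(self, a: NucleotideRef, b: NucleotideRef
                       ) -> list[StackAnnotation]:
        return [s for s in self._by_nt_stacks.get(a.key(), ())
                if s.nt2.key() == b.key()]

    def canonical_pairs(self) -> list[PairAnnotation]:
        return [p for p in self._pairs.values() if p.canonical]

    def true_pairs_between(self, a, b) -> list[PairAnnotation]:
        return [p for p in self.pairs_between(a, b) if not p.near]

    def true_stacks_between(self, a, b) -> list[StackAnnotation]:
        return [s for s in self.stacks_between(a, b) if not s.near]


# --------------------------------------------------------------------------
# Structure model
# --------------------------------------------------------------------------

@dataclass
class Residue:
    ref: NucleotideRef
    name: str                       # residue code as given in the file
    atoms: dict                     # atom name -> np.ndarray(3)
    is_rna: bool = True

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_BASES


@dataclass
class Chain:
    name: str
    residues: list
    is_rna: bool = True


class EmptyModelError(ValueError):
    """Raised when a structure contains no RNA residues."""


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class Structure:
    """Ordered chains of residues with author numbering preserved."""

    def __init__(self, structure_id: str, chains: Sequence[Chain],
                 model_number: int = 1) -> None:
        self.structure_id = structure_id
        self.model_number = model_number
        self.chains = list(chains)
        self._index = {r.ref.key(): r for c in self.chains for r in c.residues}

    def residue(self, ref: NucleotideRef) -> Residue:
        return self._index[ref.key()]

    def has_residue(self, ref: NucleotideRef) -> bool:
        return ref.key() in self._index

    def rna_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_rna]

    def rna_residues(self) -> list[Residue]:
        return [r for c in self.rna_chains() for r in c.residues if r.is_rna]

    def chain(self, name: str) -> Chain:
        for c in self.chains:
            if c.name == name:
                return c
        raise KeyError(name)

    def chain_sequence(self, name: str) -> str:
        return "".join(r.name if len(r.name) == 1 else f"({r.name})"
                       for r in self.chain(name).residues)


_RNA_NAMES_EXTRA = frozenset({
    # common modified ribonucleotides seen in rRNA/tRNA structures
    "PSU", "H2U", "1MA", "2MA", "5MC", "OMC", "OMG", "7MG", "M2G", "2MG",
    "1MG", "5MU", "4SU", "OMU", "UR3", "A2M", "MA6", "6MZ", "G7M",
})


def _looks_like_rna(name: str, atom_names: set) -> bool:
    if name in STANDARD_BASES or name in _RNA_NAMES_EXTRA:
        return True
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_nucleic_acid():
        # exclude deoxy: RNA carries an O2'
        return "O2'" in atom_names or name.startswith(("A", "C", "G", "U"))
    return "O2'" in atom_names and "C1'" in atom_names


def read_structure(path, model_policy: str = "first"):
    """Read an mmCIF or PDB file into one :class:`Structure` (or several).

    ``model_policy`` selects model handling: ``"first"`` returns the first
    model only (the conventional representative for NMR ensembles);
    ``"all"`` returns a list with one :class:`Structure` per model.

    Residues keep the file's author numbering and insertion codes; chain
    order and intra-chain order follow the file.  Non-RNA chains are
    retained but flagged.  Of alternate locations, the first is kept.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path} contains no models")
    structure_id = (st.name or path.stem).upper()[:4].ljust(4, "X")

    structures = []
    for mi, model in enumerate(st):
        model_number = getattr(model, "num", 0) or mi + 1
        chains = []
        for ch in model:
            residues = []
            any_rna = False
            for res in ch:
                atoms: dict = {}
                for atom in res:
                    if atom.name in atoms:
                        continue  # keep first altloc only
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z])
                is_rna = _looks_like_rna(res.name, set(atoms))
                any_rna = any_rna or is_rna
                icode = res.seqid.icode.strip()
                base = res.name if res.name in STANDARD_BASES else res.name
                ref = NucleotideRef(structure_id, model_number, ch.name,
                                    res.seqid.num, icode, base)
                residues.append(Residue(ref, res.name, atoms, is_rna))
            chains.append(Chain(ch.name, residues, is_rna=any_rna))
        structures.append(Structure(structure_id, chains, model_number))
        if model_policy == "first":
            break

    first = structures[0]
    if not first.rna_residues():
        raise EmptyModelError(f"{path} contains no RNA residues")
    return first if model_policy == "first" else structures


def write_structure(structure: Structure, path) -> None:
    """Write a :class:`Structure` as mmCIF (``.cif``) or PDB (``.pdb``)."""
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model(structure.model_number)
    for chain in structure.chains:
        gch = gemmi.Chain(chain.name)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.ref.number,
                                     res.ref.insertion_code or " ")
            for name, pos in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name.strip("0123456789'*")[:1]
                                             or "C")
                atom.pos = gemmi.Position(*map(float, pos))
            # occupancy defaults are fine for synthetic output
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# --------------------------------------------------------------------------
# Annotation CSV dialect
# --------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["chain1", "number1", "icode1", "chain2", "number2",
                      "icode2", "kind", "label", "near"]
# optional trailing columns: base1, base2 (used when no structure is attached)


@dataclass
class RejectedRow:
    line: int
    row: list
    reason: str


class AnnotationValidationError(ValueError):
    pass


def read_annotations(path, structure: Optional[Structure] = None,
                     structure_id: Optional[str] = None, model: int = 1
                     ) -> tuple[AnnotationSet, list]:
    """Read the annotation table; returns ``(AnnotationSet, rejected_rows)``.

    The table is comma- or tab-separated with header columns
    ``chain1,number1,icode1,chain2,number2,icode2,kind,label,near`` and
    optionally ``base1,base2``.  Symmetric closure is applied on load and
    the ``canonical`` flag is derived from the family, the base identities
    and the ``near`` flag.  Malformed rows are collected, not dropped
    silently.  When a structure is attached, every referenced residue must
    resolve in it.
    """
    path = Path(path)
    if structure is not None:
        structure_id = structure.structure_id
        model = structure.model_number
    if structure_id is None:
        raise ValueError("need a structure or an explicit structure_id")

    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(text.splitlines(), delimiter=delim)
    header = next(reader)
    header = [h.strip() for h in header]
    if header[:9] != ANNOTATION_COLUMNS:
        raise AnnotationValidationError(
            f"{path}: bad header {header[:9]!r}, expected {ANNOTATION_COLUMNS}")
    has_bases = header[9:11] == ["base1", "base2"]

    annset = AnnotationSet(structure_id)
    rejected: list[RejectedRow] = []

    def resolve(chain: str, number: str, icode: str, base: str
                ) -> NucleotideRef:
        ref = NucleotideRef(structure_id, model, chain, int(number),
                            icode.strip(), base or "N")
        if structure is not None:
            if not structure.has_residue(ref):
                raise AnnotationValidationError(
                    f"residue {chain} {number}{icode} not in structure")
            res = structure.residue(ref)
            ref = replace(ref, base=res.name)
        return ref

    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        row = [c.strip() for c in row]
        try:
            if len(row) < 9:
                raise ValueError("too few columns")
            b1 = row[9] if has_bases and len(row) > 9 else ""
            b2 = row[10] if has_bases and len(row) > 10 else ""
            nt1 = resolve(row[0], row[1], row[2], b1)
            nt2 = resolve(row[3], row[4], row[5], b2)
            kind, label, near_s = row[6], row[7], row[8]
            near = near_s == "1"
            if near_s not in ("0", "1"):
                raise ValueError(f"near must be 0 or 1, got {near_s!r}")
            if kind == "pair":
                family, flipped = normalize_family(label)
                if flipped:
                    nt1, nt2 = nt2, nt1
                canonical = is_canonical_pair(family, nt1.base, nt2.base, near)
                annset.add_pair(PairAnnotation(nt1, nt2, family, near,
                                               canonical))
            elif kind == "stack":
                if label not in STACK_FACES:
                    raise ValueError(f"unknown face code {label!r}")
                annset.add_stack(StackAnnotation(nt1, nt2, label, near))
            else:
                raise ValueError(f"unknown kind {kind!r}")
        except AnnotationValidationError:
            raise
        except (ValueError, KeyError) as exc:
            rejected.append(RejectedRow(lineno, row, str(exc)))
    return annset, rejected


def write_annotations(annset: AnnotationSet, path) -> None:
    """Write an :class:`AnnotationSet` in the dialect read back by
    :func:`read_annotations` (with base columns)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_COLUMNS + ["base1", "base2"])
        def row(nt1, nt2, kind, label, near):
            w.writerow([nt1.chain, nt1.number, nt1.insertion_code,
                        nt2.chain, nt2.number, nt2.insertion_code,
                        kind, label, int(near), nt1.base, nt2.base])
        for p in sorted(annset.pairs,
                        key=lambda p: (p.nt1.key(), p.nt2.key(), p.family)):
            row(p.nt1, p.nt2, "pair", p.family, p.near)
        for s in sorted(annset.stacks,
                        key=lambda s: (s.nt1.key(), s.nt2.key(), s.face_code)):
            row(s.nt1, s.nt2, "stack", s.face_code, s.near)


# --------------------------------------------------------------------------
# Base reference frames
# --------------------------------------------------------------------------

@dataclass
class BaseFrame:
    """Base center (Å) and orthonormal orientation (det +1)."""

    center: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        R = self.rotation
        if (np.abs(R @ R.T - np.eye(3)).max() > 1e-6
                or abs(np.linalg.det(R) - 1.0) > 1e-6):
            raise ValueError("rotation must be orthonormal with det +1")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "BaseFrame":
        return BaseFrame(R @ self.center + t, R @ self.rotation)


# Idealized planar base geometries in a canonical frame: ring centroid at
# the origin, x-axis toward the glycosidic nitrogen, z normal to the base
# plane.  Derived from the PDB Chemical Component Dictionary ideal
# coordinates, planarized.
PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

IDEAL_BASES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (1.9185, 0.0000, 0.0), "C8": (1.8935, -1.3626, 0.0),
        "N7": (0.6627, -1.7847, 0.0), "C5": (-0.1783, -0.7236, 0.0),
        "C6": (-1.5750, -0.5688, 0.0), "N1": (-2.0763, 0.6613, 0.0),
        "C2": (-1.2874, 1.7196, 0.0), "N3": (0.0251, 1.6240, 0.0),
        "C4": (0.6172, 0.4348, 0.0), "C1'": (3.1147, 0.8443, 0.0),
    },
    "G": {
        "N9": (1.9162, 0.0000, 0.0), "C8": (1.8986, -1.3644, 0.0),
        "N7": (0.6688, -1.7899, 0.0), "C5": (-0.1730, -0.7271, 0.0),
        "C6": (-1.5803, -0.5857, 0.0), "N1": (-2.0993, 0.6613, 0.0),
        "C2": (-1.2779, 1.7480, 0.0), "N3": (0.0305, 1.6303, 0.0),
        "C4": (0.6164, 0.4276, 0.0), "C1'": (3.1095, 0.8493, 0.0),
    },
    "C": {
        "N1": (1.3465, 0.0000, 0.0), "C2": (0.6665, 1.1594, 0.0),
        "N3": (-0.6658, 1.1759, 0.0), "C4": (-1.3562, 0.0434, 0.0),
        "C5": (-0.6724, -1.1896, 0.0), "C6": (0.6813, -1.1890, 0.0),
        "C1'": (2.8114, 0.0148, 0.0),
    },
    "U": {
        "N1": (1.3492, 0.0000, 0.0), "C2": (0.6797, 1.1647, 0.0),
        "N3": (-0.6669, 1.1885, 0.0), "C4": (-1.3666, 0.0358, 0.0),
        "C5": (-0.6729, -1.1970, 0.0), "C6": (0.6775, -1.1920, 0.0),
        "C1'": (2.8147, 0.0050, 0.0),
    },
}


# re-center exactly: the fitted frame's origin is the ring-atom centroid,
# so the stored template must have a centroid of exactly zero
for _base, _atoms in IDEAL_BASES.items():
    _names = PURINE_RING if _base in ("A", "G") else PYRIMIDINE_RING
    _cen = np.mean([_atoms[_n] for _n in _names], axis=0)
    for _n in list(_atoms):
        IDEAL_BASES[_base][_n] = tuple(np.asarray(_atoms[_n]) - _cen)


def ring_atom_names(base: str) -> tuple:
    return PURINE_RING if base in ("A", "G") else PYRIMIDINE_RING


def glycosidic_nitrogen(base: str) -> str:
    return "N9" if base in ("A", "G") else "N1"


def ideal_base_coords(base: str, atom_names: Sequence[str]) -> np.ndarray:
    tpl = IDEAL_BASES[base]
    return np.array([tpl[n] for n in atom_names])


@dataclass
class FrameFailure:
    ref: NucleotideRef
    reason: str


def residue_frame(residue: Residue) -> BaseFrame:
    """Frame of one standard residue from its base ring atoms.

    The center is the mean of the ring heavy atoms; the rotation is the
    proper Kabsch rotation taking the idealized base template into the
    observed coordinates.
    """
    base = residue.name
    names = ring_atom_names(base)
    missing = [n for n in names if n not in residue.atoms]
    if missing:
        raise KeyError(f"missing base atoms {missing}")
    obs = np.array([residue.atoms[n] for n in names])
    tpl = ideal_base_coords(base, names)
    R, _ = kabsch(tpl, obs)
    return BaseFrame(obs.mean(axis=0), R)


def compute_base_frames(structure: Structure
                        ) -> tuple[dict, list]:
    """Frames for every standard residue whose ring atoms are present.

    Returns ``(frames, failures)``; residues failing the precondition are
    omitted from the mapping and listed, never silently skipped.
    """
    frames: dict[NucleotideRef, BaseFrame] = {}
    failures: list[FrameFailure] = []
    for res in structure.rna_residues():
        if res.name not in STANDARD_BASES:
            failures.append(FrameFailure(res.ref,
                                         f"modified residue {res.name}"))
            continue
        try:
            frames[res.ref] = residue_frame(res)
        except KeyError as exc:
            failures.append(FrameFailure(res.ref, str(exc)))
    return frames, failures


def atoms_from_frame(base: str, frame: BaseFrame) -> dict:
    """Synthesize base ring + C1' atoms for a residue from its frame.

    Inverse of :func:`residue_frame`: reading these atoms back recovers
    ``frame`` exactly (up to floating point).
    """
    names = list(ring_atom_names(base)) + ["C1'"]
    tpl = ideal_base_coords(base, names)
    coords = tpl @ frame.rotation.T + frame.center
    return {n: coords[i] for i, n in enumerate(names)}


# --------------------------------------------------------------------------
# Release serialization (deterministic, byte-stable)
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:.6f}"


def write_release(release, outdir) -> dict:
    """Write an assembled release deterministically.

    Produces ``release.json`` (groups), ``matching_matrix.csv`` (loop ids
    as labels, ``inf`` for non-matches) and ``loops.fasta`` (one record per
    instance, id line = loop id; strands joined with ``*``).  Identical
    input yields byte-identical output.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    doc = release.to_json_dict()
    jpath = outdir / "release.json"
    jpath.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    paths["json"] = jpath

    matrix = getattr(release, "matrix", None)
    mpath = outdir / "matching_matrix.csv"
    with open(mpath, "w", newline="") as fh:
        w = csv.writer(fh)
        if matrix is None:
            w.writerow(["loop_id"])
        else:
            ids = list(matrix.ids)
            w.writerow(["loop_id"] + ids)
            for i, lid in enumerate(ids):
                w.writerow([lid] + [_fmt(v) for v in matrix.values[i]])
    paths["matrix"] = mpath

    sequences = getattr(release, "sequences", None) or {}
    fpath = outdir / "loops.fasta"
    with open(fpath, "w") as fh:
        for lid in sorted(sequences):
            fh.write(f">{lid}\n{sequences[lid]}\n")
    paths["fasta"] = fpath
    return paths
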