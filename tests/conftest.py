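"""Shared fixtures: dot-bracket toy structures and template instances."""

from __future__ import annotations

import numpy as np
import pytest

from motif_atlas._geometry import rotation_about_axis
from motif_atlas.structure_io import (AnnotationSet, BaseFrame, Chain,
                                      NucleotideRef, PairAnnotation,
                                      Residue, Structure,
                                      atoms_from_frame)
from motif_atlas.synthetic_fixtures import template_library

OPEN = {"(": ")", "[": "]", "{": "}"}
CLOSE = {v: k for k, v in OPEN.items()}


def toy_structure(*chain_specs: str, structure_id: str = "TOYS",
                  chain_names=None, with_atoms: bool = True):
    """Build a structure + cWW annotations from dot-bracket strings.

    ``()`` , ``[]`` and ``{}`` all denote canonical cWW pairs (crossing
    bracket types model pseudoknots); ``.`` is unpaired.  One string per
    chain; pairs may span chains (one shared bracket stack).  Paired
    positions become G/C, unpaired become A.  Atoms are synthesized on a
    straight-line layout so base frames are computable.
    """
    chain_names = chain_names or [chr(ord("A") + i)
                                  for i in range(len(chain_specs))]
    flat = []                           # (chain index, position, char)
    for ci, spec in enumerate(chain_specs):
        for pi, ch in enumerate(spec):
            flat.append((ci, pi, ch))

    stacks: dict = {b: [] for b in OPEN}
    pairs = []                          # ((ci, pi), (cj, pj))
    for ci, pi, ch in flat:
        if ch in OPEN:
            stacks[ch].append((ci, pi))
        elif ch in CLOSE:
            if not stacks[CLOSE[ch]]:
                raise ValueError("unbalanced brackets in toy spec")
            pairs.append((stacks[CLOSE[ch]].pop(), (ci, pi)))
        elif ch != ".":
            raise ValueError(f"bad character {ch!r}")
    if any(s for s in stacks.values()):
        raise ValueError("unbalanced brackets in toy spec")

    bases: dict = {}
    for (ci, pi), (cj, pj) in pairs:
        bases[(ci, pi)] = "G"
        bases[(cj, pj)] = "C"

    chains = []
    refs: dict = {}
    serial = 0
    for ci, spec in enumerate(chain_specs):
        residues = []
        for pi in range(len(spec)):
            base = bases.get((ci, pi), "A")
            ref = NucleotideRef(structure_id, 1, chain_names[ci], pi + 1,
                                "", base)
            refs[(ci, pi)] = ref
            atoms = {}
            if with_atoms:
                frame = BaseFrame([3.8 * serial, 0.0, 0.0], np.eye(3))
                atoms = atoms_from_frame(base, frame)
            residues.append(Residue(ref, base, atoms, True))
            serial += 1
        chains.append(Chain(chain_names[ci], residues))
    structure = Structure(structure_id, chains)

    annotations = AnnotationSet(structure_id)
    for a, b in pairs:
        annotations.add_pair(PairAnnotation(refs[a], refs[b], "cWW",
                                            near=False, canonical=True))
    return structure, annotations


@pytest.fixture(scope="session")
def library():
    return template_library()


@pytest.fixture(scope="session")
def il_template(library):
    return library["il-straight"]


@pytest.fixture(scope="session")
def hl_template(library):
    return library["hl-arc6"]


def random_frames(rng, n, spread=6.0):
    """Well-separated random base frames for discrepancy tests."""
    frames = []
    for _ in range(n):
        axis = rng.normal(size=3)
        frames.append(BaseFrame(rng.normal(0.0, spread, size=3),
                                rotation_about_axis(axis,
                                                    rng.uniform(0, np.pi))))
    return frames


def rigid_motion(rng):
    R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, np.pi))
    t = rng.normal(0.0, 10.0, size=3)
    return R, t
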