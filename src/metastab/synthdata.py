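"""Seeded generator of labelled synthetic molecules with planted functional groups.

Each molecule is a random scaffold (alkane chain, cyclohexane, benzene or
pyridine) with exactly one planted motif appended at a chemically valid
attachment point.  The clean label is 1 (stable) iff the motif belongs to
the stabilizing set (acetylene, trifluoromethyl, chlorophenyl) and 0 for the
destabilizing set (ester, amide, methoxy, hydroxyl); the emitted label is
flipped with probability ``noise``.  Because molecules are assembled from
string templates validated at import time, every emitted SMILES parses.

The generator also records ground truth: the motif name and the atom
indices of the planted group, which (by construction, RDKit preserves SMILES
atom order) are the last heavy atoms of each molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .chemio import LabelledDataset, MolGraph, parse_molecule

# motif SMILES are written so that appending them to any scaffold tail is valid
STABILIZING_MOTIFS = {
    "acetylene": "C#C",
    "trifluoromethyl": "C(F)(F)F",
    "chlorophenyl": "c1ccc(Cl)cc1",
}
DESTABILIZING_MOTIFS = {
    "ester": "C(=O)OC",
    "amide": "C(=O)N",
    "methoxy": "OC",
    "hydroxyl": "O",
}

_SCAFFOLDS = [
    "CC", "CCC", "CCCC", "CCCCC", "CCCCCC",   # alkane chains
    "C1CCCCC1",                                # cyclohexane
    "c1ccccc1",                                # benzene
    "c1ccncc1",                                # pyridine
]

_MOTIF_HEAVY_ATOMS = {
    "acetylene": 2, "trifluoromethyl": 4, "chlorophenyl": 7,
    "ester": 4, "amide": 3, "methoxy": 2, "hydroxyl": 1,
}


@dataclass
class SynthSpec:
    """Conditions of a synthetic dataset draw."""

    n: int = 2000
    positive_fraction: float = 0.64   # mirrors the 3784/5878 class balance of HLM-style data
    noise: float = 0.0                # label-flip probability
    seed: int = 0
    stabilizing: Dict[str, str] = field(default_factory=lambda: dict(STABILIZING_MOTIFS))
    destabilizing: Dict[str, str] = field(default_factory=lambda: dict(DESTABILIZING_MOTIFS))

    def __post_init__(self):
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise must be in [0, 0.5)")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        overlap = set(self.stabilizing) & set(self.destabilizing)
        if overlap or set(self.stabilizing.values()) & set(self.destabilizing.values()):
            raise ValueError("motif sets must be disjoint")
        if not self.stabilizing or not self.destabilizing:
            raise ValueError("both motif sets must be non-empty")


@dataclass
class GroundTruth:
    """Per-molecule provenance of the planted motif."""

    motif: str
    motif_smiles: str
    atom_indices: List[int]
    clean_label: int

    def to_dict(self):
        return {"motif": self.motif, "motif_smiles": self.motif_smiles,
                "atom_indices": self.atom_indices, "clean_label": self.clean_label}


def generate_dataset(spec: SynthSpec) -> Tuple[LabelledDataset, Dict[str, GroundTruth]]:
    """Draw a labelled synthetic dataset; returns (dataset, id -> ground truth)."""
    rng = np.random.default_rng(spec.seed)
    stab = sorted(spec.stabilizing.items())
    destab = sorted(spec.destabilizing.items())
    molecules, truth = [], {}
    for i in range(spec.n):
        positive = rng.random() < spec.positive_fraction
        name, motif = stab[rng.integers(len(stab))] if positive \
            else destab[rng.integers(len(destab))]
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        smiles = scaffold + motif
        mol_id = f"syn{i:05d}"
        mol = parse_molecule(smiles, mol_id=mol_id)
        n_motif = _MOTIF_HEAVY_ATOMS.get(name)
        if n_motif is None:  # user-supplied motif: count its heavy atoms once
            n_motif = parse_molecule(motif).num_atoms
        atom_idx = list(range(mol.num_atoms - n_motif, mol.num_atoms))
        clean = int(positive)
        label = clean ^ int(rng.random() < spec.noise)
        mol.label = label
        molecules.append(mol)
        truth[mol_id] = GroundTruth(name, motif, atom_idx, clean)
    ds = LabelledDataset(molecules, provenance=f"synthetic(seed={spec.seed})")
    return ds, truth


def fixture_graphs() -> Dict[str, MolGraph]:
    """Tiny hand-built graphs with scalar features, for oracle tests."""
    return {
        "path3": MolGraph(np.array([[1.0], [2.0], [3.0]]), [(0, 1), (1, 2)], 3),
        "singleton": MolGraph(np.array([[1.0]]), [], 1),
        "benzene": MolGraph(np.ones((6, 1)),
                            [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)], 6),
        "two_component": MolGraph(np.array([[1.0], [2.0], [3.0], [4.0]]),
                                  [(0, 1), (2, 3)], 4),
    }
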