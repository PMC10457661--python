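"""Chemistry I/O: SMILES tokenization, molecular graphs, fingerprints, datasets.

Molecules enter the package as SMILES strings.  Each one is kept in three
synchronized views: the raw string, its token sequence (for the sequence
encoder) and a heavy-atom graph with an 84-dimensional binary feature vector
per atom (for the graph encoder).  RDKit does all chemical parsing,
canonicalization and circular (Morgan/ECFP) fingerprinting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

RDLogger.DisableLog("rdApp.*")


class SmilesParseError(ValueError):
    """Raised for SMILES strings that cannot be tokenized or parsed."""


class ConfigError(ValueError):
    """Raised for malformed dataset files / missing columns."""


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_TWO_LETTER = ("Cl", "Br")


def tokenize_smiles(smiles: str) -> List[str]:
    """Split a SMILES string into atom/symbol tokens.

    Bracket atoms (``[nH]``, ``[O-]`` ...) and the two-letter organic-subset
    halogens ``Cl``/``Br`` are single tokens; every other character (ring
    digits, bonds, branch parentheses, ``%nn`` ring closures) is its own
    token.  Concatenating the tokens reproduces the input exactly.

    Raises
    ------
    SmilesParseError
        for unbalanced square brackets or parentheses, naming the offset.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    tokens: List[str] = []
    depth_stack: List[int] = []
    i, n = 0, len(smiles)
    while i < n:
        c = smiles[i]
        if c == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise SmilesParseError(f"unclosed '[' at offset {i}")
            tokens.append(smiles[i:j + 1])
            i = j + 1
        elif c == "]":
            raise SmilesParseError(f"unmatched ']' at offset {i}")
        elif c == "(":
            depth_stack.append(i)
            tokens.append(c)
            i += 1
        elif c == ")":
            if not depth_stack:
                raise SmilesParseError(f"unmatched ')' at offset {i}")
            depth_stack.pop()
            tokens.append(c)
            i += 1
        elif c == "%":
            tokens.append(smiles[i:i + 3])
            i += 3
        elif smiles[i:i + 2] in _TWO_LETTER:
            tokens.append(smiles[i:i + 2])
            i += 2
        else:
            tokens.append(c)
            i += 1
    if depth_stack:
        raise SmilesParseError(f"unclosed '(' at offset {depth_stack[-1]}")
    return tokens


_AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}
_ALIPHATIC_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}


def is_atom_token(token: str) -> bool:
    """True for tokens that denote an atom (bracket atoms or organic subset)."""
    return (token.startswith("[")
            or token in _ALIPHATIC_ORGANIC
            or token in _AROMATIC_ORGANIC)


# ---------------------------------------------------------------------------
# graphs and features
# ---------------------------------------------------------------------------

# 49 element symbols + trailing "unknown" slot = 50-way one-hot
ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "W", "Ru", "Nb", "Re", "Te", "Rh",
]
# one-hot block layout: symbol(50) + degree(11) + numHs(11) + implicit valence(11) + aromatic(1)
FEATURE_BLOCKS = [50, 11, 11, 11]
NUM_ATOM_FEATURES = sum(FEATURE_BLOCKS) + 1  # = 84


def _one_hot(value: int, size: int) -> np.ndarray:
    vec = np.zeros(size, dtype=np.float32)
    vec[min(value, size - 1)] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """84-dim binary feature vector: symbol, degree, #H, implicit valence, aromatic."""
    sym = atom.GetSymbol()
    sym_idx = ATOM_SYMBOLS.index(sym) if sym in ATOM_SYMBOLS else len(ATOM_SYMBOLS)
    parts = [
        _one_hot(sym_idx, 50),
        _one_hot(atom.GetDegree(), 11),
        _one_hot(atom.GetTotalNumHs(), 11),
        _one_hot(atom.GetImplicitValence(), 11),
        np.array([float(atom.GetIsAromatic())], dtype=np.float32),
    ]
    return np.concatenate(parts)


@dataclass
class MolGraph:
    """Undirected heavy-atom graph with per-node feature rows.

    Edges are stored once per unordered pair ``(u, v)`` with ``u < v`` and
    expanded to both directions at encode time.
    """

    node_features: np.ndarray          # N x d (d = 84 for chemistry-built graphs)
    edges: List[Tuple[int, int]]
    num_nodes: int

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if not (0 <= u < self.num_nodes and 0 <= v < self.num_nodes):
                raise ValueError(f"edge ({u},{v}) out of range for N={self.num_nodes}")

    def edge_index(self) -> np.ndarray:
        """2 x 2|E| directed edge index (both directions of every bond)."""
        if not self.edges:
            return np.zeros((2, 0), dtype=np.int64)
        e = np.asarray(self.edges, dtype=np.int64).T
        return np.concatenate([e, e[::-1]], axis=1)

    def neighbors(self) -> List[List[int]]:
        adj: List[List[int]] = [[] for _ in range(self.num_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def with_edges(self, edges: Sequence[Tuple[int, int]]) -> "MolGraph":
        """Copy of this graph with a different (subset) edge list."""
        return MolGraph(self.node_features, [tuple(sorted(e)) for e in edges],
                        self.num_nodes)


@dataclass
class Molecule:
    """A SMILES string with its token sequence, parsed graph and optional label."""

    smiles: str
    tokens: List[str]
    graph: MolGraph
    label: Optional[int] = None
    id: str = ""

    @property
    def num_atoms(self) -> int:
        return self.graph.num_nodes


def smiles_to_graph(smiles: str, mol_id: str = "") -> MolGraph:
    """Parse a SMILES into a :class:`MolGraph` (implicit-hydrogen heavy-atom graph)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        ident = f" (id={mol_id})" if mol_id else ""
        raise SmilesParseError(f"unparseable SMILES{ident}: {smiles!r}")
    feats = np.stack([atom_features(a) for a in mol.GetAtoms()])
    edges = [tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
             for b in mol.GetBonds()]
    return MolGraph(feats, edges, mol.GetNumAtoms())


def parse_molecule(smiles: str, label: Optional[int] = None, mol_id: str = "") -> Molecule:
    return Molecule(smiles=smiles, tokens=tokenize_smiles(smiles),
                    graph=smiles_to_graph(smiles, mol_id), label=label, id=mol_id)


# ---------------------------------------------------------------------------
# fingerprints and similarity
# ---------------------------------------------------------------------------

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _fingerprint(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return _MORGAN.GetFingerprint(mol)


def tanimoto_bits(a, b) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two on-bit index sets."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def ecfp_tanimoto(a, b) -> float:
    """ECFP4 (radius-2, 2048-bit circular fingerprint) Tanimoto similarity.

    Accepts SMILES strings or :class:`Molecule` objects; 1.0 for identical
    canonical molecules, 0.0 for disjoint on-bit sets.
    """
    sa = a.smiles if isinstance(a, Molecule) else a
    sb = b.smiles if isinstance(b, Molecule) else b
    return float(DataStructs.TanimotoSimilarity(_fingerprint(sa), _fingerprint(sb)))


def ecfp_matrix(smiles_list: Sequence[str]) -> np.ndarray:
    """n x 2048 binary fingerprint matrix."""
    out = np.zeros((len(smiles_list), 2048), dtype=np.uint8)
    for i, smi in enumerate(smiles_list):
        fp = _fingerprint(smi)
        out[i, list(fp.GetOnBits())] = 1
    return out


def tanimoto_matrix(bits: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity of a binary fingerprint matrix."""
    b = bits.astype(np.float64)
    inter = b @ b.T
    pop = b.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def similarity_bin(score: float) -> str:
    """Bin a Tanimoto score: <=0.5 dissimilar, (0.5, 0.7] moderately, >0.7 highly."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"similarity score out of [0,1]: {score}")
    if score <= 0.5:
        return "dissimilar"
    if score <= 0.7:
        return "moderately_similar"
    return "highly_similar"


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class LabelledDataset:
    molecules: List[Molecule]
    provenance: str = ""
    dedupe_report: Dict[str, int] = field(default_factory=dict)

    def __len__(self):
        return len(self.molecules)

    @property
    def smiles(self) -> List[str]:
        return [m.smiles for m in self.molecules]

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.label for m in self.molecules], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [m.id for m in self.molecules],
            "smiles": self.smiles,
            "label": self.labels,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_dedupe_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.dedupe_report, fh, indent=2)


def read_dataset(path, dedupe: bool = True, smiles_col: str = "smiles",
                 label_col: str = "label") -> LabelledDataset:
    """Load a delimited molecule table (CSV/TSV with header) into a dataset.

    Rows whose SMILES fail to parse are skipped and counted; with ``dedupe``
    later duplicates (by RDKit canonical SMILES) are dropped, first
    occurrence wins.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in (smiles_col, label_col):
        if col not in df.columns:
            raise ConfigError(f"missing column {col!r} in {path}")
    molecules: List[Molecule] = []
    seen: Dict[str, int] = {}
    n_failed = n_dup = 0
    for i, row in enumerate(df.itertuples(index=False)):
        smi = str(getattr(row, smiles_col))
        label = int(getattr(row, label_col))
        if label not in (0, 1):
            raise ConfigError(f"label must be 0/1, got {label} in row {i}")
        mol_id = str(getattr(row, "id", i)) if "id" in df.columns else str(i)
        try:
            can = canonical_smiles(smi)
            mol = parse_molecule(smi, label=label, mol_id=mol_id)
        except SmilesParseError:
            n_failed += 1
            continue
        if dedupe and can in seen:
            n_dup += 1
            continue
        seen[can] = len(molecules)
        molecules.append(mol)
    if not molecules:
        raise ConfigError(f"no valid molecules found in {path}")
    report = {"n_input": len(df), "n_kept": len(molecules),
              "n_parse_failures": n_failed, "n_duplicates_removed": n_dup}
    return LabelledDataset(molecules, provenance=str(path), dedupe_report=report)


def read_smi(path) -> List[str]:
    """Read an unlabelled .smi corpus: one SMILES per line, blank lines skipped."""
    with open(path) as fh:
        return [line.split()[0] for line in fh if line.strip()]
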