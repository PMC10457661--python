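"""Model interpretability: attention atom/bond weights and edge Shapley values.

Two complementary views of what drives a prediction:

* **Attention weights** — the sequence encoder's multihead attention is
  averaged over heads, mapped from SMILES tokens to atoms (non-atom tokens
  such as ring digits, bonds and branch parentheses carry no atom mass;
  their attention is renormalized over atom tokens) and turned into bond
  weights: the weight of a bond is the average of the weights of its two
  atoms.

* **Edge Shapley values** — each bond is treated as a player in a
  cooperative game whose value function f(S) is the model's sigmoid score
  with only the edge subset S present in the graph (node features and the
  sequence branch held fixed).  Values are estimated by Monte-Carlo
  permutation sampling, which satisfies the efficiency axiom
  sum(phi) = f(E) - f(empty) by construction; per-edge standard errors are
  reported.

The frequency report aggregates, over an evaluation set, the substructures
formed by high-Shapley bonds (threshold 0.2) together with their neighbor
bonds, canonicalized as fragment SMILES and counted separately for
predicted-stable and predicted-unstable molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import MolGraph, Molecule, is_atom_token, parse_molecule

Edge = Tuple[int, int]


class TokenAlignmentError(ValueError):
    """Raised when SMILES atom tokens cannot be aligned with graph atoms."""


# small named-group dictionary used only to annotate report rows
FUNCTIONAL_GROUP_SMARTS = {
    "phenyl ring": "c1ccccc1",
    "trifluoromethyl": "C(F)(F)F",
    "chlorobenzene": "Clc1ccccc1",
    "monofluorobenzene": "Fc1ccccc1",
    "acetylene": "C#C",
    "ester": "C(=O)OC",
    "amide": "C(=O)N",
    "carbonyl": "C=O",
    "ether": "COC",
    "hydroxyl": "[OX2H]",
    "methoxy": "OC",
    "primary amine": "[NX3;H2]",
    "thiophene": "c1ccsc1",
}


@dataclass
class Explanation:
    """Per-molecule importance scores."""

    molecule_id: str
    smiles: str
    atom_weights: np.ndarray                      # length N, nonneg, sums to 1
    bond_weights: Dict[Edge, float]               # mean of endpoint atom weights
    edge_shapley: Optional[Dict[Edge, float]] = None
    shapley_se: Optional[Dict[Edge, float]] = None
    score: Optional[float] = None                 # model sigmoid score
    predicted_label: Optional[int] = None
    extras: Dict = field(default_factory=dict)


def _atom_token_indices(tokens: Sequence[str]) -> List[int]:
    return [i for i, t in enumerate(tokens) if is_atom_token(t)]


def bond_weights_from_atoms(atom_weights: np.ndarray,
                            edges: Sequence[Edge]) -> Dict[Edge, float]:
    """Bond weight = average of its two atom weights."""
    return {tuple(sorted((u, v))): float((atom_weights[u] + atom_weights[v]) / 2.0)
            for u, v in edges}


def attention_explanation(model, molecule) -> Explanation:
    """Head-averaged attention mapped from tokens to atoms and bonds.

    Raises :class:`TokenAlignmentError` if the number of atom tokens does
    not match the number of heavy atoms in the parsed graph (e.g. explicit
    hydrogens merged away by sanitization).
    """
    mol = molecule if isinstance(molecule, Molecule) else parse_molecule(str(molecule))
    atom_idx = _atom_token_indices(mol.tokens)
    if len(atom_idx) != mol.graph.num_nodes:
        bad = next((t for t in mol.tokens if is_atom_token(t)), "?")
        raise TokenAlignmentError(
            f"{len(atom_idx)} atom tokens vs {mol.graph.num_nodes} graph atoms "
            f"for {mol.smiles!r} (first atom token {bad!r})")
    alphas, _ = model.sequence_attention(mol)
    token_w = np.mean(np.stack(alphas), axis=0)
    atom_w = token_w[atom_idx]
    total = atom_w.sum()
    if total <= 0:
        atom_w = np.full(len(atom_idx), 1.0 / len(atom_idx))
    else:
        atom_w = atom_w / total
    score = float(model.predict_proba([mol])[0, 1])
    return Explanation(
        molecule_id=mol.id, smiles=mol.smiles, atom_weights=atom_w,
        bond_weights=bond_weights_from_atoms(atom_w, mol.graph.edges),
        score=score, predicted_label=int(score >= 0.5))


# ---------------------------------------------------------------------------
# edge Shapley values
# ---------------------------------------------------------------------------

def shapley_values(graph: MolGraph,
                   value_fn: Callable[[Sequence[Sequence[Edge]]], np.ndarray],
                   n_samples: int = 1000, rng=None, chunk: int = 16):
    """Monte-Carlo permutation-sampling Shapley values for the edges of a graph.

    ``value_fn`` maps a list of edge subsets to an array of game values (it
    is called with batches so a model can score many coalitions at once).
    Returns ``(phi, se)`` dicts keyed by edge.  Each permutation contributes
    one marginal sample per edge, so the per-permutation totals telescope to
    f(E) - f(empty) and the efficiency axiom holds exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    edges = [tuple(sorted(e)) for e in graph.edges]
    m = len(edges)
    if m == 0:
        return {}, {}
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sums = np.zeros(m)
    sqsums = np.zeros(m)
    for start in range(0, n_samples, chunk):
        n_here = min(chunk, n_samples - start)
        perms = [rng.permutation(m) for _ in range(n_here)]
        subsets: List[List[Edge]] = []
        for perm in perms:
            subsets.append([])  # empty coalition
            acc: List[Edge] = []
            for j in perm:
                acc.append(edges[j])
                subsets.append(list(acc))
        values = np.asarray(value_fn(subsets), dtype=np.float64)
        k = 0
        for perm in perms:
            vals = values[k:k + m + 1]
            k += m + 1
            marg = np.diff(vals)
            sums[perm] += marg
            sqsums[perm] += marg ** 2
    phi = sums / n_samples
    var = np.maximum(sqsums / n_samples - phi ** 2, 0.0)
    se = np.sqrt(var / n_samples)
    return ({e: float(p) for e, p in zip(edges, phi)},
            {e: float(s) for e, s in zip(edges, se)})


def edge_shapley(model, molecule, n_samples: int = 1000, rng=None,
                 chunk: int = 16) -> Explanation:
    """Shapley value of every bond for one molecule under a trained model.

    The game value of a coalition is the model's sigmoid score with only
    those bonds present; the sequence-branch input is the intact molecule.
    """
    mol = molecule if isinstance(molecule, Molecule) else parse_molecule(str(molecule))
    if model.use_sequence:
        _, s_vec = model.sequence_attention(mol)
    else:
        s_vec = None

    def value_fn(subsets):
        variants = [mol.graph.with_edges(s) for s in subsets]
        return model.score_graph_variants(variants, s_vec)

    phi, se = shapley_values(mol.graph, value_fn, n_samples=n_samples,
                             rng=rng, chunk=chunk)
    score = float(value_fn([list(mol.graph.edges)])[0])
    n = mol.graph.num_nodes
    atom_w = np.full(n, 1.0 / n)
    return Explanation(
        molecule_id=mol.id, smiles=mol.smiles, atom_weights=atom_w,
        bond_weights=bond_weights_from_atoms(atom_w, mol.graph.edges),
        edge_shapley=phi, shapley_se=se, score=score,
        predicted_label=int(score >= 0.5))


# ---------------------------------------------------------------------------
# substructure frequency report
# ---------------------------------------------------------------------------

def _fragment_smiles(smiles: str, edge_set: Sequence[Edge]) -> Optional[str]:
    """Canonical SMILES of the fragment induced by a set of bonds."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    bond_ids, atoms = [], set()
    for u, v in edge_set:
        bond = mol.GetBondBetweenAtoms(int(u), int(v))
        if bond is None:
            continue
        bond_ids.append(bond.GetIdx())
        atoms.update((int(u), int(v)))
    if not bond_ids:
        return None
    try:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms),
                                        bondsToUse=bond_ids, canonical=True)
    except Exception:
        return None


def _name_fragment(frag_smiles: str) -> str:
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        frag = Chem.MolFromSmarts(frag_smiles)
    if frag is not None:
        for name, smarts in FUNCTIONAL_GROUP_SMARTS.items():
            patt = Chem.MolFromSmarts(smarts)
            if patt is not None and frag.HasSubstructMatch(patt):
                return name
    return ""


def group_frequency_report(explanations: Sequence[Explanation],
                           threshold: float = 0.2, top: int = 10) -> pd.DataFrame:
    """Frequency table of high-Shapley substructures, split by predicted class.

    For every molecule, each bond with a Shapley value above ``threshold``
    (a "main bond") together with its neighbor bonds defines a substructure
    instance; instances are canonicalized as fragment SMILES and counted.
    Percentages are per predicted class (stable / unstable).  Returns the
    top ``top`` rows per class.
    """
    counts: Dict[Tuple[int, str], int] = {}
    totals = {0: 0, 1: 0}
    for expl in explanations:
        if not expl.edge_shapley:
            continue
        cls = expl.predicted_label if expl.predicted_label is not None else 1
        edges = list(expl.edge_shapley)
        for e, phi in expl.edge_shapley.items():
            if phi <= threshold:
                continue
            group = {e}
            group.update(o for o in edges if o != e and set(o) & set(e))
            frag = _fragment_smiles(expl.smiles, sorted(group))
            if frag is None:
                continue
            totals[cls] += 1
            counts[(cls, frag)] = counts.get((cls, frag), 0) + 1
    rows = []
    for (cls, frag), cnt in counts.items():
        rows.append({
            "predicted_class": "stable" if cls == 1 else "unstable",
            "substructure": frag,
            "name": _name_fragment(frag),
            "count": cnt,
            "percentage": 100.0 * cnt / totals[cls],
        })
    df = pd.DataFrame(rows, columns=["predicted_class", "substructure", "name",
                                     "count", "percentage"])
    if df.empty:
        return df
    df = (df.sort_values(["predicted_class", "count"], ascending=[True, False])
            .groupby("predicted_class", group_keys=False).head(top)
            .reset_index(drop=True))
    return df
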