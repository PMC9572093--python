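"""Multilevel-neighborhood-of-atoms (MNA) descriptors and whole-molecule descriptors.

An MNA descriptor of level 0 is the atom's mark: its element symbol, prefixed
with ``-`` when the atom is acyclic, with any formal charge appended as a run
of ``+``/``-`` signs.  A level-k descriptor is ``label(atoms')`` where the
parenthesized body concatenates the level-(k-1) descriptors of the immediate
neighbors in lexicographic (byte) order, which makes the string canonical
under atom renumbering.

The three whole-molecule descriptors — topological length, topological
volume, lipophilicity — are heavy-atom-based: graph diameter in bonds, an
additive per-element volume sum, and an additive atomic-contribution logP
estimate.  The contribution tables are pluggable; bundled defaults are
van-der-Waals-like volumes (A^3) and a coarse element-level logP scheme.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chem_graph import Atom, MolecularGraph

#: fixed trailing columns of every descriptor matrix
WHOLE_MOLECULE_COLUMNS = ("topological_length", "topological_volume", "lipophilicity")

#: per-element atomic volume contributions, A^3 (van-der-Waals sphere volumes)
DEFAULT_VOLUME_CONTRIBUTIONS: dict[str, float] = {
    "C": 20.58, "N": 15.60, "O": 14.71, "S": 24.43, "P": 24.43,
    "F": 13.31, "Cl": 22.45, "Br": 26.52, "I": 32.52, "B": 17.88,
    "Si": 38.79, "Se": 28.73, "H": 7.24,
}

#: coarse element-level additive logP contributions (log units per atom);
#: hydrogens are folded into the heavy-atom values (contribution 0)
DEFAULT_LOGP_CONTRIBUTIONS: dict[str, float] = {
    "C": 0.36, "N": -0.60, "O": -0.40, "S": 0.25, "P": -0.50,
    "F": 0.22, "Cl": 0.65, "Br": 0.85, "I": 1.10, "B": 0.10,
    "Si": 0.30, "Se": 0.30,
}


class MNADescriptor(NamedTuple):
    """Canonical descriptor string plus its neighborhood level."""

    text: str
    level: int


def load_contribution_table(path) -> dict[str, float]:
    """Read an element -> contribution table from a JSON file."""
    with open(path) as fh:
        table = json.load(fh)
    return {str(k): float(v) for k, v in table.items()}


def atom_label(a: Atom) -> str:
    """Atom mark: element, ``-`` prefix when acyclic, charge as +/- runs."""
    label = a.element if a.in_ring else "-" + a.element
    if a.formal_charge > 0:
        label += "+" * a.formal_charge
    elif a.formal_charge < 0:
        label += "-" * (-a.formal_charge)
    return label


def mna_descriptors(g: MolecularGraph, max_level: int = 2) -> Counter:
    """Multiset of MNA descriptors over all atoms and levels 0..max_level."""
    if max_level < 0:
        raise ValueError(f"max_level must be >= 0, got {max_level}")
    adj = g.adjacency()
    current = {a.index: atom_label(a) for a in g.atoms}
    labels = {a.index: current[a.index] for a in g.atoms}
    out: Counter = Counter()
    for text in current.values():
        out[MNADescriptor(text, 0)] += 1
    for level in range(1, max_level + 1):
        nxt = {
            i: labels[i] + "(" + "".join(sorted(current[j] for j in adj[i])) + ")"
            for i in current
        }
        for text in nxt.values():
            out[MNADescriptor(text, level)] += 1
        current = nxt
    return out


def topological_length(g: MolecularGraph) -> int:
    """Heavy-atom graph diameter in bonds (0 for a single heavy atom)."""
    heavy = g.to_networkx(heavy_only=True)
    if heavy.number_of_nodes() == 0:
        return 0
    if not nx.is_connected(heavy):
        warnings.warn("disconnected heavy-atom graph; using largest component")
        comp = max(nx.connected_components(heavy), key=len)
        heavy = heavy.subgraph(comp)
    if heavy.number_of_nodes() == 1:
        return 0
    return nx.diameter(heavy)


def topological_volume(
    g: MolecularGraph, contributions: Optional[Mapping[str, float]] = None
) -> float:
    """Sum of per-heavy-atom volume contributions."""
    table = DEFAULT_VOLUME_CONTRIBUTIONS if contributions is None else contributions
    total = 0.0
    for a in g.atoms:
        if a.element == "H":
            continue
        if a.element not in table:
            raise ValueError(f"no volume contribution for element {a.element!r}")
        total += table[a.element]
    return total


def lipophilicity(
    g: MolecularGraph, scheme: Optional[Mapping[str, float]] = None
) -> float:
    """Additive atomic-contribution logP estimate.

    Hydrogens default to a zero contribution when the scheme omits them
    (their share is conventionally folded into the heavy-atom values); a
    heavy element missing from the scheme is an error.
    """
    table = DEFAULT_LOGP_CONTRIBUTIONS if scheme is None else scheme
    total = 0.0
    for a in g.atoms:
        if a.element == "H":
            total += table.get("H", 0.0)
            continue
        if a.element not in table:
            raise ValueError(f"no lipophilicity contribution for element {a.element!r}")
        total += table[a.element]
    return total


@dataclass
class DescriptorVector:
    """All descriptors for one compound."""

    mna_counts: Counter
    topo_length: int
    topo_volume: float
    lipophilicity: float
    id: Optional[str] = None


def compute_vector(
    g: MolecularGraph,
    level: int = 2,
    volume_table: Optional[Mapping[str, float]] = None,
    logp_table: Optional[Mapping[str, float]] = None,
) -> DescriptorVector:
    return DescriptorVector(
        mna_counts=mna_descriptors(g, level),
        topo_length=topological_length(g),
        topo_volume=topological_volume(g, volume_table),
        lipophilicity=lipophilicity(g, logp_table),
        id=g.id,
    )


@dataclass
class DescriptorMatrix:
    """ids x descriptors table; the last three columns are the whole-molecule values."""

    ids: list[str]
    vocabulary: list[str]
    values: pd.DataFrame
    unseen_fraction: Optional[pd.Series] = None
    n_dropped: int = 0

    @property
    def mna_columns(self) -> list[str]:
        return [c for c in self.vocabulary if c not in WHOLE_MOLECULE_COLUMNS]


def build_matrix(
    vectors: Sequence[DescriptorVector],
    vocabulary: Optional[Sequence[str]] = None,
) -> DescriptorMatrix:
    """Assemble descriptor vectors into a numeric matrix.

    Training mode (``vocabulary`` omitted): the MNA vocabulary is the union
    of observed descriptor texts, ordered by first occurrence with
    lexicographic order inside each compound.  Prediction mode: descriptors
    absent from the given vocabulary are dropped; the count-weighted fraction
    of dropped occurrences per compound is reported for applicability-domain
    checks.
    """
    if not vectors:
        raise ValueError("empty vector list")
    ids = [v.id if v.id is not None else f"mol{k + 1}" for k, v in enumerate(vectors)]

    if vocabulary is None:
        mna_vocab: list[str] = []
        seen: set[str] = set()
        for v in vectors:
            for key in sorted(d.text for d in v.mna_counts):
                if key not in seen:
                    seen.add(key)
                    mna_vocab.append(key)
        unseen = None
        n_dropped = 0
    else:
        mna_vocab = [c for c in vocabulary if c not in WHOLE_MOLECULE_COLUMNS]
        known = set(mna_vocab)
        fractions = []
        n_dropped = 0
        for v in vectors:
            total = sum(v.mna_counts.values())
            missing = sum(n for d, n in v.mna_counts.items() if d.text not in known)
            n_dropped += missing
            fractions.append(missing / total if total else 1.0)
        unseen = pd.Series(fractions, index=ids, name="unseen_fraction")
        if n_dropped:
            warnings.warn(f"{n_dropped} descriptor occurrences outside vocabulary dropped")

    columns = list(mna_vocab) + list(WHOLE_MOLECULE_COLUMNS)
    data = np.zeros((len(vectors), len(columns)))
    col_index = {c: k for k, c in enumerate(mna_vocab)}
    for r, v in enumerate(vectors):
        for d, n in v.mna_counts.items():
            k = col_index.get(d.text)
            if k is not None:
                data[r, k] += n
        data[r, -3] = v.topo_length
        data[r, -2] = v.topo_volume
        data[r, -1] = v.lipophilicity
    frame = pd.DataFrame(data, index=ids, columns=columns)
    return DescriptorMatrix(ids, columns, frame, unseen_fraction=unseen, n_dropped=n_dropped)


def matrix_for_graphs(
    graphs: Sequence[MolecularGraph],
    level: int = 2,
    vocabulary: Optional[Sequence[str]] = None,
    volume_table: Optional[Mapping[str, float]] = None,
    logp_table: Optional[Mapping[str, float]] = None,
) -> DescriptorMatrix:
    """One-call convenience: descriptor vectors then matrix."""
    vectors = [compute_vector(g, level, volume_table, logp_table) for g in graphs]
    return build_matrix(vectors, vocabulary)
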