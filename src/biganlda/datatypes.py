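"""Core data containers for the lncRNA-disease association pipeline.

The pipeline works on three primary inputs -- lncRNA nucleotide sequences,
a disease ontology (a DAG of parent->child "is-a" edges), and a binary
disease x lncRNA association matrix -- and derives square similarity
matrices and per-pair feature vectors from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SequenceSet",
    "DiseaseOntology",
    "AssociationMatrix",
    "SimilarityMatrix",
    "PairFeature",
]

#: Accepted nucleotide symbols after uppercasing.  U is folded onto T before
#: any distance computation (RNA/DNA normalisation).
SEQUENCE_ALPHABET = frozenset("ACGTU")

SYMMETRY_TOL = 1e-9


class InputError(ValueError):
    """Malformed user input (bad alphabet, empty sequence, degenerate matrix)."""


class LookupError_(KeyError):
    """An id was requested that the container does not hold."""


class AlignmentError(ValueError):
    """Two containers that must share an id universe do not."""


@dataclass
class SequenceSet:
    """Ordered map of lncRNA id -> nucleotide sequence.

    Sequences are uppercased and U is normalised to T on construction so that
    RNA and DNA spellings of the same transcript compare equal.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for lid, seq in self.entries.items():
            s = seq.upper().replace("U", "T")
            if not s:
                raise InputError(f"sequence for {lid!r} is empty")
            for pos, ch in enumerate(s):
                if ch not in "ACGT":
                    raise InputError(
                        f"sequence for {lid!r} has non-nucleotide symbol "
                        f"{ch!r} at position {pos}"
                    )
            cleaned[lid] = s
        self.entries = cleaned

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, lid: str) -> str:
        try:
            return self.entries[lid]
        except KeyError:
            raise LookupError_(f"unknown lncRNA id {lid!r}") from None


@dataclass
class DiseaseOntology:
    """Disease ontology as a DAG of (parent, child) edges.

    ``graph`` stores edges parent -> child; ancestors of a disease are the
    nodes that can reach it.  Diseases absent from the edge list may still be
    registered as isolated nodes (singleton DAGs).
    """

    graph: nx.DiGraph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "DiseaseOntology":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        g.add_nodes_from(extra_nodes)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise InputError(f"ontology contains a cycle: {cycle}")
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.in_degree(n) == 0}

    def ensure_node(self, disease_id: str) -> None:
        """Register a disease with no ontology placement as a singleton DAG."""
        self.graph.add_node(disease_id)

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.graph


@dataclass
class AssociationMatrix:
    """Binary nd x nl matrix of verified disease-lncRNA links.

    Rows are diseases, columns are lncRNAs; A[i, j] = 1 means the link between
    disease i and lncRNA j is experimentally verified.
    """

    values: np.ndarray
    disease_ids: list[str]
    lncrna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InputError("association matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise InputError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        nd, nl = self.values.shape
        if len(self.disease_ids) != nd or len(self.lncrna_ids) != nl:
            raise InputError("id list lengths do not match matrix shape")
        if len(set(self.disease_ids)) != nd or len(set(self.lncrna_ids)) != nl:
            raise InputError("duplicate ids in association matrix")
        self._d_index = {d: i for i, d in enumerate(self.disease_ids)}
        self._l_index = {l: j for j, l in enumerate(self.lncrna_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def disease_index(self, disease_id: str) -> int:
        try:
            return self._d_index[disease_id]
        except KeyError:
            raise LookupError_(f"unknown disease id {disease_id!r}") from None

    def lncrna_index(self, lncrna_id: str) -> int:
        try:
            return self._l_index[lncrna_id]
        except KeyError:
            raise LookupError_(f"unknown lncRNA id {lncrna_id!r}") from None

    def label(self, disease_id: str, lncrna_id: str) -> int:
        return int(self.values[self.disease_index(disease_id),
                               self.lncrna_index(lncrna_id)])

    def positive_pairs(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.values)
        return [(self.disease_ids[i], self.lncrna_ids[j])
                for i, j in zip(rows.tolist(), cols.tolist())]

    def masked(self, pairs: Sequence[tuple[str, str]]) -> "AssociationMatrix":
        """Copy with the given verified pairs zeroed (hidden) -- used per CV fold."""
        vals = self.values.copy()
        for d, l in pairs:
            vals[self.disease_index(d), self.lncrna_index(l)] = 0
        return AssociationMatrix(vals, list(self.disease_ids), list(self.lncrna_ids))


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1] and unit diagonal."""

    values: np.ndarray
    ids: list[str]
    kind: str = "generic"

    KINDS = (
        "sequence", "semantic", "gip_lncrna", "gip_disease",
        "integrated_lncrna", "integrated_disease", "generic",
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError("similarity matrix shape does not match id list")
        if self.kind not in self.KINDS:
            raise InputError(f"unknown similarity kind {self.kind!r}")
        self._index = {x: i for i, x in enumerate(self.ids)}
        self.validate()

    def validate(self) -> None:
        v = self.values
        if np.abs(v - v.T).max(initial=0.0) > SYMMETRY_TOL:
            raise InputError(f"{self.kind} similarity matrix is not symmetric")
        if v.size and np.abs(np.diag(v) - 1.0).max() > SYMMETRY_TOL:
            raise InputError(f"{self.kind} similarity diagonal is not 1")
        if v.size and (v.min() < -SYMMETRY_TOL or v.max() > 1 + SYMMETRY_TOL):
            raise InputError(f"{self.kind} similarity entries outside [0, 1]")

    def row(self, entity_id: str) -> np.ndarray:
        try:
            return self.values[self._index[entity_id]]
        except KeyError:
            raise LookupError_(f"unknown id {entity_id!r}") from None

    def entry(self, id_a: str, id_b: str) -> float:
        return float(self.row(id_a)[self._index[id_b]])


@dataclass
class PairFeature:
    """Feature vector for one (disease, lncRNA) pair.

    ``vector`` is the concatenation of the disease's integrated-similarity row
    (length nd) followed by the lncRNA's integrated-similarity row (length nl).
    """

    disease_id: str
    lncrna_id: str
    vector: np.ndarray
    label: int = field(default=0)

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.label not in (0, 1):
            raise InputError("pair label must be 0 or 1")
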