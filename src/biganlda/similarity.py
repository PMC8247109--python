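"""Similarity matrices and per-pair feature vectors.

Four base similarities feed the predictor:

* **sequence similarity** between lncRNAs: a weighted Levenshtein distance
  (substitution cost 2, insertion/deletion cost 1) rescaled to [0, 1] by the
  summed sequence lengths, ``L_sim = 1 - cost / (len_i + len_j)``;
* **semantic similarity** between diseases: each disease is represented by
  the DAG of its ontology ancestors, each ancestor carrying a semantic value
  that decays by a factor ``mu`` per generation, and two diseases are
  compared by the semantic mass of their shared ancestors relative to their
  total masses;
* **Gaussian interaction-profile (GIP) kernels** for both lncRNAs and
  diseases: a Gaussian kernel on the columns (resp. rows) of the binary
  association matrix, with bandwidth set to the reciprocal mean squared
  profile norm;
* the **integrated similarities** are the element-wise means of the
  sequence/semantic matrix and the corresponding GIP kernel.

A pair (disease d, lncRNA l) is described by concatenating d's integrated
disease-similarity row and l's integrated lncRNA-similarity row, a vector of
length nd + nl.
"""

from __future__ import annotations

from collections import deque
from typing import Sequence

import numpy as np

from .datatypes import (
    AlignmentError,
    AssociationMatrix,
    DiseaseOntology,
    InputError,
    PairFeature,
    SequenceSet,
    SimilarityMatrix,
)

__all__ = [
    "edit_cost",
    "sequence_similarity",
    "semantic_values",
    "semantic_similarity",
    "gip_kernel",
    "gip_similarities",
    "integrate",
    "build_pair_features",
]

DEFAULT_SUB_COST = 2.0
DEFAULT_INDEL_COST = 1.0
DEFAULT_MU = 0.5


# ---------------------------------------------------------------------------
# weighted edit distance
# ---------------------------------------------------------------------------

def _edit_cost_py(a: np.ndarray, b: np.ndarray, sub: float, indel: float) -> float:
    m, n = len(a), len(b)
    prev = np.arange(n + 1, dtype=np.float64) * indel
    curr = np.empty(n + 1, dtype=np.float64)
    for i in range(1, m + 1):
        curr[0] = i * indel
        ai = a[i - 1]
        for j in range(1, n + 1):
            c = prev[j - 1] + (0.0 if ai == b[j - 1] else sub)
            d = prev[j] + indel
            e = curr[j - 1] + indel
            curr[j] = min(c, d, e)
        prev, curr = curr, prev
    return float(prev[n])


try:  # numba gives C-speed DP for the O(nl^2) pairwise matrix
    from numba import njit

    _edit_cost_fast = njit(cache=True)(_edit_cost_py)
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    _edit_cost_fast = _edit_cost_py


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def edit_cost(
    s1: str,
    s2: str,
    sub_cost: float = DEFAULT_SUB_COST,
    indel_cost: float = DEFAULT_INDEL_COST,
) -> float:
    """Minimum cost to transform ``s1`` into ``s2`` under a weighted edit model.

    Substitution costs ``sub_cost`` (default 2) and insertion/deletion each
    cost ``indel_cost`` (default 1).  Symmetric; 0 iff the strings are equal
    after uppercasing and U->T normalisation.
    """
    if sub_cost < 0 or indel_cost < 0:
        raise InputError("edit costs must be non-negative")
    norm = []
    for name, s in (("s1", s1), ("s2", s2)):
        t = s.upper().replace("U", "T")
        for pos, ch in enumerate(t):
            if ch not in "ACGT":
                raise InputError(
                    f"{name} has non-nucleotide symbol {ch!r} at position {pos}"
                )
        norm.append(t)
    return _edit_cost_fast(_encode(norm[0]), _encode(norm[1]),
                           float(sub_cost), float(indel_cost))


def sequence_similarity(
    seqs: SequenceSet,
    sub_cost: float = DEFAULT_SUB_COST,
    indel_cost: float = DEFAULT_INDEL_COST,
) -> SimilarityMatrix:
    """Pairwise lncRNA sequence similarity ``1 - cost / (len_i + len_j)``."""
    ids = seqs.ids
    n = len(ids)
    enc = [_encode(seqs[i]) for i in ids]
    lens = np.array([len(e) for e in enc])
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = _edit_cost_fast(enc[i], enc[j], float(sub_cost), float(indel_cost))
            vals[i, j] = vals[j, i] = 1.0 - c / (lens[i] + lens[j])
    # cost <= indel*(len_i+len_j) guarantees [0,1]; clip numerical dust only
    np.clip(vals, 0.0, 1.0, out=vals)
    return SimilarityMatrix(vals, ids, kind="sequence")


# ---------------------------------------------------------------------------
# disease semantic similarity
# ---------------------------------------------------------------------------

def semantic_values(
    onto: DiseaseOntology, disease_id: str, mu: float = DEFAULT_MU
) -> dict[str, float]:
    """Semantic-value profile of ``disease_id`` over its ancestor DAG.

    The disease itself has value 1; an ancestor ``x`` contributes
    ``max over paths x->...->d of mu^path_length``, i.e. ``mu`` to the power
    of the shortest descending distance from ``x`` to the disease.
    """
    if not 0 < mu < 1:
        raise InputError("mu must lie strictly between 0 and 1")
    if disease_id not in onto:
        raise KeyError(f"disease {disease_id!r} not in ontology")
    # BFS upward over parent edges: depth = shortest path length down to d
    depths = {disease_id: 0}
    queue = deque([disease_id])
    g = onto.graph
    while queue:
        node = queue.popleft()
        for parent in g.predecessors(node):
            if parent not in depths:
                depths[parent] = depths[node] + 1
                queue.append(parent)
    return {node: mu ** k for node, k in depths.items()}


def semantic_similarity(
    onto: DiseaseOntology,
    disease_ids: Sequence[str],
    mu: float = DEFAULT_MU,
) -> SimilarityMatrix:
    """Pairwise disease semantic similarity from shared-ancestor semantic mass.

    Entry (i, j) is the sum of both diseases' semantic values over their
    shared DAG nodes, divided by the sum of their total semantic masses.
    Diseases with disjoint DAGs score 0.
    """
    profiles = [semantic_values(onto, d, mu) for d in disease_ids]
    totals = [sum(p.values()) for p in profiles]
    n = len(disease_ids)
    vals = np.ones((n, n))
    for i in range(n):
        pi = profiles[i]
        for j in range(i + 1, n):
            pj = profiles[j]
            shared = pi.keys() & pj.keys()
            if shared:
                num = sum(pi[x] + pj[x] for x in shared)
                vals[i, j] = vals[j, i] = num / (totals[i] + totals[j])
            else:
                vals[i, j] = vals[j, i] = 0.0
    return SimilarityMatrix(vals, list(disease_ids), kind="semantic")


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernel
# ---------------------------------------------------------------------------

def gip_kernel(
    profiles: np.ndarray, ids: Sequence[str], kind: str = "generic"
) -> SimilarityMatrix:
    """Gaussian kernel on binary interaction profiles (one profile per row).

    The bandwidth is data-driven: ``lambda = 1 / mean(||profile||^2)``, so the
    kernel is ``exp(-lambda * ||p_i - p_j||^2)``.  Requires at least one
    nonzero profile, otherwise the bandwidth is undefined.
    """
    p = np.asarray(profiles, dtype=float)
    if p.ndim != 2 or p.shape[0] != len(ids):
        raise InputError("profiles must be a 2-D array, one row per id")
    sq_norms = (p ** 2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise InputError(
            "all interaction profiles are zero: GIP bandwidth is undefined"
        )
    lam = 1.0 / mean_sq
    gram = p @ p.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.clip(d2, 0.0, None, out=d2)
    vals = np.exp(-lam * d2)
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(vals, list(ids), kind=kind)


def gip_similarities(
    assoc: AssociationMatrix,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """GIP kernels for lncRNAs (columns of A) and diseases (rows of A).

    Each kernel gets its own bandwidth from its own profiles.  Compute this
    from the *training* association matrix only when cross-validating, so the
    bandwidth never sees held-out links.
    """
    gkl = gip_kernel(assoc.values.T, assoc.lncrna_ids, kind="gip_lncrna")
    gkd = gip_kernel(assoc.values, assoc.disease_ids, kind="gip_disease")
    return gkl, gkd


# ---------------------------------------------------------------------------
# integration and feature construction
# ---------------------------------------------------------------------------

_INTEGRATED_KIND = {
    frozenset({"sequence", "gip_lncrna"}): "integrated_lncrna",
    frozenset({"semantic", "gip_disease"}): "integrated_disease",
}


def integrate(sim_a: SimilarityMatrix, sim_b: SimilarityMatrix) -> SimilarityMatrix:
    """Element-wise mean of two similarity matrices over the same id universe."""
    if sim_a.ids != sim_b.ids:
        diff = set(sim_a.ids) ^ set(sim_b.ids)
        raise AlignmentError(
            f"similarity matrices are not aligned; differing ids: {sorted(diff)}"
            if diff else "similarity matrices list the same ids in different order"
        )
    kind = _INTEGRATED_KIND.get(frozenset({sim_a.kind, sim_b.kind}), "generic")
    return SimilarityMatrix(
        (sim_a.values + sim_b.values) / 2.0, list(sim_a.ids), kind=kind
    )


def build_pair_features(
    ds: SimilarityMatrix,
    ls: SimilarityMatrix,
    assoc: AssociationMatrix,
    pairs: Sequence[tuple[str, str]],
) -> list[PairFeature]:
    """Feature vectors for the given (disease, lncRNA) pairs.

    Each vector is ``concat(Ds row of the disease, Ls row of the lncRNA)``,
    length nd + nl, with the label copied from the association matrix.
    """
    if ds.ids != assoc.disease_ids or ls.ids != assoc.lncrna_ids:
        raise AlignmentError(
            "similarity matrices not aligned with association matrix id order"
        )
    out = []
    for d, l in pairs:
        vec = np.concatenate([ds.row(d), ls.row(l)])
        out.append(PairFeature(d, l, vec, label=assoc.label(d, l)))
    return out


def all_pairs(assoc: AssociationMatrix) -> list[tuple[str, str]]:
    """Every (disease, lncRNA) pair, row-major — the nd x nl candidate grid."""
    return [(d, l) for d in assoc.disease_ids for l in assoc.lncrna_ids]
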