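"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain: FASTA for sequences, tab-separated text for
associations, ontology edges, similarity matrices and score tables, JSON for
reports.  TSV files are UTF-8; lines starting with ``#`` are comments; ids
must not contain tabs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    AssociationMatrix,
    DiseaseOntology,
    InputError,
    SequenceSet,
    SimilarityMatrix,
)

__all__ = [
    "read_fasta", "write_fasta",
    "read_associations", "write_associations",
    "read_ontology", "write_ontology",
    "read_similarity", "write_similarity",
    "read_scores", "write_scores",
]


def read_fasta(path: str | Path) -> SequenceSet:
    """Load lncRNA sequences; the id is the first whitespace token of the header."""
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in entries:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        entries[rec.id] = str(rec.seq)
    if not entries:
        raise InputError(f"no FASTA records found in {path}")
    return SequenceSet(entries)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=lid, description="")
               for lid, s in seqs.entries.items()]
    SeqIO.write(records, str(path), "fasta")


def _read_tsv(path: str | Path, ncols: int, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except Exception as exc:
        raise InputError(f"cannot parse {what} file {path}: {exc}") from exc
    if df.shape[1] != ncols:
        raise InputError(
            f"{what} file {path} has {df.shape[1]} columns, expected {ncols}"
        )
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 1
        raise InputError(f"{what} file {path}: missing field near line {line}")
    return df


def read_associations(
    path: str | Path,
    disease_ids: list[str] | None = None,
    lncrna_ids: list[str] | None = None,
) -> AssociationMatrix:
    """Read verified pairs (``disease_id<TAB>lncrna_id`` per line) into a matrix.

    Row/column orders default to first-appearance order of the ids in the
    file; pass explicit id lists to pin the ordering (e.g. to the FASTA).
    An optional ``disease_id\tlncrna_id`` header line is ignored.
    """
    df = _read_tsv(path, 2, "association")
    if list(df.iloc[0]) == ["disease_id", "lncrna_id"]:
        df = df.iloc[1:]
    if disease_ids is None:
        disease_ids = list(dict.fromkeys(df[0]))
    if lncrna_ids is None:
        lncrna_ids = list(dict.fromkeys(df[1]))
    values = np.zeros((len(disease_ids), len(lncrna_ids)), dtype=np.int8)
    d_idx = {d: i for i, d in enumerate(disease_ids)}
    l_idx = {l: j for j, l in enumerate(lncrna_ids)}
    for d, l in zip(df[0], df[1]):
        if d not in d_idx:
            raise InputError(f"association file {path}: unknown disease id {d!r}")
        if l not in l_idx:
            raise InputError(f"association file {path}: unknown lncRNA id {l!r}")
        values[d_idx[d], l_idx[l]] = 1
    return AssociationMatrix(values, disease_ids, lncrna_ids)


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tlncrna_id\n")
        for d, l in assoc.positive_pairs():
            fh.write(f"{d}\t{l}\n")


def read_ontology(
    path: str | Path, extra_nodes: list[str] | None = None
) -> DiseaseOntology:
    """Read ``parent_id<TAB>child_id`` edges into an ontology DAG."""
    df = _read_tsv(path, 2, "ontology")
    if list(df.iloc[0]) == ["parent_id", "child_id"]:
        df = df.iloc[1:]
    edges = list(zip(df[0], df[1]))
    return DiseaseOntology.from_edges(edges, extra_nodes or ())

def write_ontology(onto: DiseaseOntology, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("parent_id\tchild_id\n")
        for parent, child in onto.graph.edges:
            fh.write(f"{parent}\t{child}\n")


def read_similarity(path: str | Path, kind: str = "generic") -> SimilarityMatrix:
    """Read a square similarity TSV with id header row and id first column."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:
        raise InputError(f"cannot parse similarity file {path}: {exc}") from exc
    if list(df.index) != list(df.columns):
        raise InputError(f"similarity file {path}: row and column ids differ")
    return SimilarityMatrix(df.to_numpy(dtype=float), list(df.index), kind=kind)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["disease_id", "lncrna_id", "score", "known_flag"]
    if list(df.columns) != expected:
        raise InputError(f"score file {path}: expected columns {expected}")
    return df


def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
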