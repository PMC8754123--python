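"""Readers and writers for the pipeline's tab-separated tables and trees.

All tabular interchange is plain TSV with a header row; trees are Newick
(parsed with dendropy).  Readers validate structure and return pandas
DataFrames; ``read_gene_table`` additionally recomputes contig-local
ordinals so downstream neighborhood arithmetic never trusts input order.
"""

from __future__ import annotations

import os

import dendropy
import pandas as pd

from .model import (
    EVIDENCE_COLUMNS,
    EVIDENCE_SOURCES,
    GENE_TABLE_COLUMNS,
    AniMatrix,
    assign_ordinals,
)


def read_gene_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene table TSV and recompute per-contig ordinals."""
    genes = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "contig_id": str, "gene_uid": str})
    return assign_ordinals(genes)


def read_evidence_table(path: str | os.PathLike) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t", dtype={"gene_uid": str, "source": str, "accession": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    bad = set(hits["source"]) - EVIDENCE_SOURCES
    if bad:
        raise ValueError(f"unknown evidence sources: {sorted(bad)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-values in evidence table")
    return hits


def read_metadata_table(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in meta.columns:
        raise ValueError("metadata table must have a genome_id column")
    if "is_type_strain" in meta.columns:
        meta["is_type_strain"] = meta["is_type_strain"].map(
            {"1": True, "0": False, "True": True, "False": False}
        )
    if "habitat" in meta.columns:
        bad = set(meta["habitat"].dropna()) - {"animal", "non_animal", "unknown"}
        if bad:
            raise ValueError(f"unknown habitat labels: {sorted(bad)}")
    return meta


def read_qc_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"genome_id": str})


def read_ani_matrix(path: str | os.PathLike) -> AniMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return AniMatrix(frame)


def write_ani_matrix(ani: AniMatrix, path: str | os.PathLike) -> None:
    ani.frame.to_csv(path, sep="\t")


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    """Read a rooted Newick tree; duplicate leaf labels are rejected."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({x for x in labels if labels.count(x) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf labels: {dupes}")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calls(calls: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-genome SAC call table (one row per genome)."""
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | os.PathLike) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    if "sac_positive" in calls.columns:
        calls["sac_positive"] = calls["sac_positive"].astype(bool)
    return calls


def read_presence_profile(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column (label, 0/1) presence TSV into a dict."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    label_col, state_col = frame.columns[:2]
    states = frame[state_col].astype(int)
    if not states.isin([0, 1]).all():
        raise ValueError("presence profile states must be 0/1")
    return dict(zip(frame[label_col].astype(str), states))


def write_presence_profile(profile: dict[str, int], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"label": list(profile), "present": [int(v) for v in profile.values()]}
    ).to_csv(path, sep="\t", index=False)
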