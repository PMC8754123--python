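"""Core domain types, genome QC filtering, and ANI dereplication.

The pipeline operates on per-genome ordered gene tables: one row per CDS
with its contig and its *ordinal* — the 0-based rank of the CDS in its
contig's gene order.  Ordinals are the distance unit for all neighborhood
rules downstream ("within 10 ORFs").  Clusters never span contigs, because
ORF distance is undefined across a contig break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_TABLE_COLUMNS = ["genome_id", "contig_id", "gene_uid", "start", "end", "strand"]
EVIDENCE_COLUMNS = ["gene_uid", "source", "accession", "evalue", "identity_pct", "coverage_pct"]
EVIDENCE_SOURCES = frozenset({"pfam", "cdd", "blastp", "itseg", "isfinder", "cog"})

# QC thresholds: strict inequalities for completeness/contamination, the
# marker rule excludes genomes with *less than* 75% of the 138 markers
# (a genome at exactly 0.75 is kept).
QC_COMPLETENESS_MIN = 95.0
QC_CONTAMINATION_MAX = 5.0
QC_MARKER_FRACTION_MIN = 0.75

DEREPLICATION_ANI_THRESHOLD = 99.5


@dataclass(frozen=True)
class GeneRecord:
    """One CDS. Coordinates are 1-based inclusive; ordinal is contig-local."""

    genome_id: str
    contig_id: str
    gene_uid: str
    start: int
    end: int
    strand: str
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_uid}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_uid}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainHit:
    """A single domain/homology hit attached to a gene.

    ``source`` names the evidence channel (pfam, cdd, blastp, itseg,
    isfinder, cog); identity/coverage may be absent (NaN) for channels
    that do not report them.
    """

    gene_uid: str
    source: str
    accession: str
    evalue: float
    identity_pct: float = float("nan")
    coverage_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.source not in EVIDENCE_SOURCES:
            raise ValueError(f"unknown evidence source {self.source!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        for v in (self.identity_pct, self.coverage_pct):
            if not np.isnan(v) and not 0 <= v <= 100:
                raise ValueError("identity/coverage must lie in [0, 100]")


@dataclass(frozen=True)
class GenomeMeta:
    genome_id: str
    species: str = ""
    genus: str = ""
    family: str = ""
    order: str = ""
    class_: str = ""
    is_type_strain: bool = False
    habitat: str = "unknown"  # animal | non_animal | unknown

    def __post_init__(self) -> None:
        if self.habitat not in ("animal", "non_animal", "unknown"):
            raise ValueError(f"bad habitat {self.habitat!r}")


@dataclass(frozen=True)
class QcMetrics:
    genome_id: str
    completeness_pct: float
    contamination_pct: float
    marker_fraction: float


def assign_ordinals(genes: pd.DataFrame) -> pd.DataFrame:
    """Recompute contig-local ordinals from start coordinates.

    Rows are stably sorted by (genome, contig, start, end, gene_uid) and
    each contig's genes are numbered 0..n-1.  The result is independent of
    input row order.
    """
    missing = [c for c in GENE_TABLE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(genes[col]):
            coerced = pd.to_numeric(genes[col], errors="raise")
            if not np.allclose(coerced, coerced.astype(np.int64)):
                raise ValueError(f"non-integer coordinates in column {col!r}")
            genes = genes.assign(**{col: coerced.astype(np.int64)})
    dup = genes.groupby("genome_id")["gene_uid"].apply(lambda s: s[s.duplicated()])
    if len(dup):
        raise ValueError(f"duplicate gene_uid within genome: {sorted(set(dup))}")
    out = genes.sort_values(
        ["genome_id", "contig_id", "start", "end", "gene_uid"], kind="mergesort"
    ).reset_index(drop=True)
    out["ordinal"] = out.groupby(["genome_id", "contig_id"]).cumcount()
    return out


def qc_filter(metrics: pd.DataFrame) -> set[str]:
    """Keep genomes passing completeness/contamination/marker thresholds.

    Kept iff completeness > 95, contamination < 5 and marker_fraction
    >= 0.75.  Genomes with any missing metric are unevaluable: excluded
    with a warning.
    """
    required = ["genome_id", "completeness_pct", "contamination_pct", "marker_fraction"]
    missing_cols = [c for c in required if c not in metrics.columns]
    if missing_cols:
        raise ValueError(f"QC table missing columns: {missing_cols}")
    m = metrics[required]
    unevaluable = m[m.isna().any(axis=1)]["genome_id"]
    if len(unevaluable):
        warnings.warn(
            f"{len(unevaluable)} genome(s) with missing QC metrics excluded: "
            f"{sorted(unevaluable)[:5]}...",
            stacklevel=2,
        )
    ok = (
        (m["completeness_pct"] > QC_COMPLETENESS_MIN)
        & (m["contamination_pct"] < QC_CONTAMINATION_MAX)
        & (m["marker_fraction"] >= QC_MARKER_FRACTION_MIN)
    )
    return set(m.loc[ok.fillna(False), "genome_id"])


class AniMatrix:
    """Symmetric pairwise ANI percentage matrix keyed by genome_id."""

    def __init__(self, frame: pd.DataFrame, tol: float = 1e-6):
        if list(frame.index) != list(frame.columns):
            raise ValueError("ANI matrix index and columns must match")
        values = frame.to_numpy(dtype=float)
        if not np.allclose(values, values.T, atol=tol):
            raise ValueError("ANI matrix asymmetric beyond tolerance")
        if not np.allclose(np.diag(values), 100.0, atol=tol):
            raise ValueError("ANI matrix diagonal must be 100")
        self.frame = frame

    @property
    def genome_ids(self) -> list[str]:
        return list(self.frame.index)

    def ani(self, a: str, b: str) -> float:
        return float(self.frame.loc[a, b])


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def dereplicate(
    ani: AniMatrix,
    meta: pd.DataFrame,
    threshold: float = DEREPLICATION_ANI_THRESHOLD,
) -> set[str]:
    """Pick representative genomes at an ANI threshold.

    Type strains are always retained.  Non-type strains are single-linkage
    clustered within each genus at ANI >= threshold; the lexicographically
    smallest genome_id represents each cluster.
    """
    meta = meta.set_index("genome_id") if "genome_id" in meta.columns else meta
    missing = [g for g in ani.genome_ids if g not in meta.index]
    if missing:
        raise ValueError(f"genomes without metadata: {missing}")
    kept: set[str] = {g for g in ani.genome_ids if bool(meta.loc[g, "is_type_strain"])}
    nontype = [g for g in ani.genome_ids if g not in kept]
    for _, group in meta.loc[nontype].groupby("genus", sort=False):
        ids = sorted(group.index)
        uf = _UnionFind(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if ani.ani(a, b) >= threshold:
                    uf.union(a, b)
        reps: dict[str, str] = {}
        for g in ids:
            root = uf.find(g)
            if root not in reps or g < reps[root]:
                reps[root] = g
        kept.update(reps.values())
    return kept
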