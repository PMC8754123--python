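"""SAC gene role assignment from domain evidence.

A *role* is a functional label (nanA, nanK, nanE, transporter families,
regulator, ...) assigned to a CDS when its domain/homology hits pass the
thresholds of the shipped role map.  Core roles (nanA/K/E) require
confirmation from two independent channels (Pfam family plus conserved
domain), mirroring how putative SAC genes are called in practice; all
other roles accept any single passing pattern.

The role map lives in ``data/rolemap.yaml`` and is an editable config:
the rule engine is generic, the uncertain family->accession mapping is
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .model import EVIDENCE_SOURCES

CORE_ROLES = ("nanA", "nanK", "nanE")

TRANSPORTER_ROLES = (
    "transporter_ABC_ST3",
    "transporter_ABC_ST7",
    "transporter_ABC_partial",
    "transporter_MFS",
    "transporter_SSS",
)

ASSIGNMENT_COLUMNS = [
    "gene_uid",
    "role",
    "accessions",
    "best_evalue",
    "pfam_confirmed",
    "cdd_confirmed",
]


@dataclass(frozen=True)
class RolePattern:
    source: str
    accession: str  # "*" matches any accession from the source


@dataclass
class RoleMap:
    """Role -> evidence patterns plus per-source thresholds."""

    source_thresholds: dict[str, dict[str, float]]
    roles: dict[str, dict]

    @classmethod
    def from_dict(cls, raw: dict) -> "RoleMap":
        thresholds = raw.get("source_thresholds", {})
        roles: dict[str, dict] = {}
        for role, conf in raw["roles"].items():
            patterns = [RolePattern(p["source"], str(p["accession"])) for p in conf["patterns"]]
            if not patterns:
                raise ValueError(f"role {role} has no evidence patterns")
            for p in patterns:
                if p.source not in EVIDENCE_SOURCES:
                    raise ValueError(f"role {role}: unknown source {p.source!r}")
            roles[role] = {
                "patterns": patterns,
                "require_sources": tuple(conf.get("require_sources", ())),
                "thresholds": conf.get("thresholds", {}),
            }
        for src, th in thresholds.items():
            if src not in EVIDENCE_SOURCES:
                raise ValueError(f"unknown source {src!r} in source_thresholds")
            if any(v < 0 for v in th.values()):
                raise ValueError(f"negative threshold for source {src}")
        return cls(source_thresholds=thresholds, roles=roles)

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "RoleMap":
        ref = resources.files("nanclust.data").joinpath("rolemap.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    def thresholds_for(self, role: str, source: str) -> dict[str, float]:
        th = dict(self.source_thresholds.get(source, {}))
        th.update(self.roles[role]["thresholds"].get(source, {}))
        return th


def _passing_mask(hits: pd.DataFrame, th: dict[str, float]) -> np.ndarray:
    """Strict thresholds: evalue < max, identity > min, coverage > min."""
    ok = np.ones(len(hits), dtype=bool)
    if "evalue_max" in th:
        ok &= hits["evalue"].to_numpy() < th["evalue_max"]
    if "identity_min" in th:
        ident = hits["identity_pct"].to_numpy(dtype=float)
        ok &= ~np.isnan(ident) & (ident > th["identity_min"])
    if "coverage_min" in th:
        cov = hits["coverage_pct"].to_numpy(dtype=float)
        ok &= ~np.isnan(cov) & (cov > th["coverage_min"])
    return ok


def assign_roles(
    genes: pd.DataFrame, hits: pd.DataFrame, rolemap: RoleMap | None = None
) -> pd.DataFrame:
    """Assign SAC roles to genes from their evidence hits.

    Returns one row per (gene_uid, role) with supporting accessions, the
    best (smallest) passing e-value and per-channel confirmation flags.
    Output is sorted by (gene_uid, role) and is a pure function of its
    inputs.
    """
    rolemap = rolemap or RoleMap.default()
    known = set(genes["gene_uid"])
    unknown = set(hits["gene_uid"]) - known
    if unknown:
        raise ValueError(f"evidence references unknown gene_uids: {sorted(unknown)[:5]}")

    rows = []
    for role, conf in rolemap.roles.items():
        passing_by_source: dict[str, pd.DataFrame] = {}
        for pat in conf["patterns"]:
            sub = hits[hits["source"] == pat.source]
            if pat.accession != "*":
                sub = sub[sub["accession"] == pat.accession]
            if sub.empty:
                continue
            sub = sub[_passing_mask(sub, rolemap.thresholds_for(role, pat.source))]
            if sub.empty:
                continue
            passing_by_source.setdefault(pat.source, [])
            passing_by_source[pat.source].append(sub)
        if not passing_by_source:
            continue
        per_source = {
            src: pd.concat(frames, ignore_index=True) for src, frames in passing_by_source.items()
        }
        required = conf["require_sources"]
        if required:
            if not set(required) <= set(per_source):
                continue
            gene_sets = [set(per_source[src]["gene_uid"]) for src in required]
            eligible = set.intersection(*gene_sets)
        else:
            eligible = set().union(*(set(f["gene_uid"]) for f in per_source.values()))
        if not eligible:
            continue
        allhits = pd.concat(per_source.values(), ignore_index=True)
        allhits = allhits[allhits["gene_uid"].isin(eligible)]
        for gene_uid, grp in allhits.groupby("gene_uid"):
            rows.append(
                {
                    "gene_uid": gene_uid,
                    "role": role,
                    "accessions": ",".join(sorted(set(grp["accession"]))),
                    "best_evalue": float(grp["evalue"].min()),
                    "pfam_confirmed": bool((grp["source"] == "pfam").any()),
                    "cdd_confirmed": bool((grp["source"] == "cdd").any()),
                }
            )
    out = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    return out.sort_values(["gene_uid", "role"], kind="mergesort").reset_index(drop=True)


def classify_sialidase(assignments: pd.DataFrame) -> pd.DataFrame:
    """Split sialidase genes into IT-sialidases and hydrolytic sialidases.

    A sialidase is an IT-sialidase iff the same gene also carries a
    passing segmented RgNanH-type domain hit (role it_sialidase_segment);
    segment hits on non-sialidase genes are ignored with a warning.
    """
    out = assignments.copy()
    out["sialidase_subtype"] = pd.NA
    sial_genes = set(out.loc[out["role"] == "sialidase", "gene_uid"])
    seg_genes = set(out.loc[out["role"] == "it_sialidase_segment", "gene_uid"])
    orphan = seg_genes - sial_genes
    if orphan:
        warnings.warn(
            f"IT-sialidase segment evidence on non-sialidase gene(s), ignored: "
            f"{sorted(orphan)[:5]}",
            stacklevel=2,
        )
    is_sial = out["role"] == "sialidase"
    out.loc[is_sial, "sialidase_subtype"] = [
        "IT" if g in seg_genes else "hydrolytic" for g in out.loc[is_sial, "gene_uid"]
    ]
    return out


def copy_numbers(genes: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-genome, per-role gene copy counts (genomes with zero copies
    of a role get an explicit 0)."""
    merged = assignments.merge(genes[["gene_uid", "genome_id"]], on="gene_uid")
    counts = (
        merged.groupby(["genome_id", "role"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(sorted(set(genes["genome_id"])), fill_value=0)
    counts.index.name = "genome_id"
    return counts.astype(int)


def copy_number_summary(counts: pd.DataFrame, role: str) -> dict | None:
    """Median and quartiles of a role's copy number over positive genomes.

    Genomes lacking the role entirely are excluded (only genomes that
    contain the gene are considered); returns None when no genome is
    positive.
    """
    if role not in counts.columns:
        return None
    positives = counts[role][counts[role] > 0].to_numpy()
    if len(positives) == 0:
        return None
    q1, med, q3 = np.percentile(positives, [25, 50, 75])
    return {"n_positive": int(len(positives)), "q1": float(q1), "median": float(med), "q3": float(q3)}
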