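"""Detection, typing and context annotation of nan gene clusters.

A genome is called SAC-positive when it carries a *nan* cluster under one
of two paradigms:

* **canonical** — nanA, nanK and nanE co-occur on one contig with all
  three genes inside an 11-ORF window (max ordinal − min ordinal <= 10);
* **bacteroidetes** — nanA and nanE-II lie within 10 ORFs of each other
  on one contig and the genome also carries rokA anywhere.

Ordinal (ORF-rank) distance is the only metric; clusters never span
contigs.  Detected clusters are then typed (consecutive vs inconsecutive
core arrangement) and annotated with the transporter system, regulator
COGs, and pathway/mobility context flags found in and around the core
span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .roles import CORE_ROLES, TRANSPORTER_ROLES

CLUSTER_FLAGS = (
    "sialidase_in_cluster",
    "it_sialidase_in_cluster",
    "nanOx_in_cluster",
    "nanOx_in_genome",
    "nagA_in_cluster",
    "nagB_in_cluster",
    "IS_near",
    "mobilome_near",
    "contig_boundary",
)


@dataclass(frozen=True)
class DetectionParams:
    """Neighborhood-rule tunables.

    max_span: ordinal window for the core genes (10 -> 11 consecutive ORFs).
    rule: 'max_span' (all core genes inside one window, order-independent)
        or 'chain' (each gap between ordinal-sorted core genes <= max_span).
    flank: ordinals beyond the core span searched for transporters,
        IS/mobilome and extra core copies.
    regulator_flank: ordinals beyond the span searched for regulators.
    boundary_dist: a span within this many ordinals of a contig end is
        flagged as potentially truncated.
    """

    max_span: int = 10
    rule: str = "max_span"
    flank: int = 5
    regulator_flank: int = 3
    boundary_dist: int = 10

    def __post_init__(self):
        if self.rule not in ("max_span", "chain"):
            raise ValueError(f"unknown window rule {self.rule!r}")
        if self.max_span < 0 or self.flank < 0 or self.regulator_flank < 0:
            raise ValueError("window parameters must be non-negative")


@dataclass
class NanCluster:
    genome_id: str
    contig_id: str
    paradigm: str  # canonical | bacteroidetes
    core_genes: dict[str, list[tuple[str, int]]]  # role -> [(gene_uid, ordinal)]
    span: tuple[int, int]
    structure: str | None = None  # consecutive | inconsecutive (canonical only)
    transporters: list[tuple[str, str]] = field(default_factory=list)
    regulator_cogs: list[str] = field(default_factory=list)
    flags: dict[str, bool] = field(default_factory=dict)
    extra_core_copies: dict[str, int] = field(default_factory=dict)

    @property
    def core_uids(self) -> frozenset[str]:
        return frozenset(u for lst in self.core_genes.values() for u, _ in lst)


def _triple_ok(ordinals: list[int], params: DetectionParams) -> bool:
    s = sorted(ordinals)
    if params.rule == "chain":
        return all(b - a <= params.max_span for a, b in zip(s, s[1:]))
    return s[-1] - s[0] <= params.max_span


def _role_positions(contig_genes: pd.DataFrame, assignments: pd.DataFrame) -> dict[str, list]:
    """role -> ordinal-sorted [(ordinal, gene_uid)] for one contig."""
    merged = assignments.merge(
        contig_genes[["gene_uid", "ordinal"]], on="gene_uid", how="inner"
    )
    out: dict[str, list] = {}
    for role, grp in merged.groupby("role"):
        out[role] = sorted(zip(grp["ordinal"], grp["gene_uid"]))
    return out


def _match_core(
    anchor: tuple[int, str],
    partners: dict[str, list],
    params: DetectionParams,
) -> dict[str, tuple[str, int]] | None:
    """Match an anchor core gene to its nearest partners under the window rule.

    ``partners`` maps role -> candidate (ordinal, uid) list.  Candidates
    are restricted to combinations whose full set of ordinals satisfies
    the window rule; among those, each partner role is resolved greedily
    in turn by (|ordinal − anchor|, ordinal).  Returns role -> (uid,
    ordinal), or None when no combination passes.
    """
    e_ord = anchor[0]
    roles = list(partners)
    chosen: dict[str, tuple[str, int]] = {}

    def feasible(fixed: list[int], remaining: list[str]) -> bool:
        if not remaining:
            return _triple_ok(fixed, params)
        role = remaining[0]
        return any(
            feasible(fixed + [o], remaining[1:]) for o, _ in partners[role]
        )

    fixed_ords = [e_ord]
    for i, role in enumerate(roles):
        best = None
        for o, uid in partners[role]:
            if not feasible(fixed_ords + [o], roles[i + 1 :]):
                continue
            key = (abs(o - e_ord), o)
            if best is None or key < best[0]:
                best = (key, (uid, o))
        if best is None:
            return None
        chosen[role] = best[1]
        fixed_ords.append(best[1][1])
    return chosen


def _merge_clusters(clusters: list[NanCluster]) -> list[NanCluster]:
    """Merge clusters sharing any core gene; span = min/max over cores."""
    if not clusters:
        return []
    parent = list(range(len(clusters)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if clusters[i].core_uids & clusters[j].core_uids:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[NanCluster]] = {}
    for i, c in enumerate(clusters):
        groups.setdefault(find(i), []).append(c)
    merged = []
    for members in groups.values():
        core: dict[str, dict[str, int]] = {}
        for c in members:
            for role, lst in c.core_genes.items():
                core.setdefault(role, {})
                for uid, o in lst:
                    core[role][uid] = o
        core_lists = {role: sorted((o, u) for u, o in d.items()) for role, d in core.items()}
        ords = [o for lst in core_lists.values() for o, _ in lst]
        merged.append(
            NanCluster(
                genome_id=members[0].genome_id,
                contig_id=members[0].contig_id,
                paradigm=members[0].paradigm,
                core_genes={r: [(u, o) for o, u in lst] for r, lst in core_lists.items()},
                span=(min(ords), max(ords)),
            )
        )
    return sorted(merged, key=lambda c: (c.contig_id, c.span))


def find_canonical_clusters(
    genes: pd.DataFrame,
    assignments: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
) -> list[NanCluster]:
    """Find canonical nanA/K/E clusters in one genome's gene table.

    Every nanE gene is matched to the nearest nanA and nanK compatible
    with the window rule; clusters sharing any core gene are merged.
    """
    out: list[NanCluster] = []
    for contig_id, contig_genes in genes.groupby("contig_id", sort=True):
        pos = _role_positions(contig_genes, assignments)
        if not all(r in pos for r in CORE_ROLES):
            continue
        genome_id = contig_genes["genome_id"].iloc[0]
        for e_ord, e_uid in pos["nanE"]:
            match = _match_core(
                (e_ord, e_uid), {"nanA": pos["nanA"], "nanK": pos["nanK"]}, params
            )
            if match is None:
                continue
            core = {
                "nanA": [(match["nanA"][0], match["nanA"][1])],
                "nanK": [(match["nanK"][0], match["nanK"][1])],
                "nanE": [(e_uid, e_ord)],
            }
            ords = [o for lst in core.values() for _, o in lst]
            out.append(
                NanCluster(genome_id, contig_id, "canonical", core, (min(ords), max(ords)))
            )
    return _merge_clusters(out)


def find_bacteroidetes_clusters(
    genes: pd.DataFrame,
    assignments: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
) -> list[NanCluster]:
    """Find bacteroidetes-paradigm clusters (clustered nanA + nanE-II,
    rokA required anywhere in the genome but not in-window)."""
    roles_present = set(assignments["role"])
    if "rokA" not in roles_present:
        return []
    out: list[NanCluster] = []
    for contig_id, contig_genes in genes.groupby("contig_id", sort=True):
        pos = _role_positions(contig_genes, assignments)
        if "nanA" not in pos or "nanE_II" not in pos:
            continue
        genome_id = contig_genes["genome_id"].iloc[0]
        for e_ord, e_uid in pos["nanE_II"]:
            match = _match_core((e_ord, e_uid), {"nanA": pos["nanA"]}, params)
            if match is None:
                continue
            core = {"nanA": [match["nanA"]], "nanE_II": [(e_uid, e_ord)]}
            ords = [o for lst in core.values() for _, o in lst]
            out.append(
                NanCluster(genome_id, contig_id, "bacteroidetes", core, (min(ords), max(ords)))
            )
    return _merge_clusters(out)


def classify_structure(cluster: NanCluster) -> str:
    """Canonical clusters are 'consecutive' iff the core ordinals occupy
    an interval of length 2 ({m, m+1, m+2}, any role order)."""
    if cluster.paradigm != "canonical":
        raise ValueError("structure typing applies to canonical clusters only")
    ords = sorted({o for lst in cluster.core_genes.values() for _, o in lst})
    if len(ords) == 3 and ords[2] - ords[0] == 2:
        return "consecutive"
    return "inconsecutive"


def _transporter_families(roles_in_flank: set[str]) -> list[tuple[str, str]]:
    """Map transporter roles found near a cluster to (superfamily, ST)."""
    fams: list[tuple[str, str]] = []
    full_abc = bool({"transporter_ABC_ST3", "transporter_ABC_ST7"} & roles_in_flank)
    if "transporter_ABC_ST3" in roles_in_flank:
        fams.append(("ABC", "ST3"))
    if "transporter_ABC_ST7" in roles_in_flank:
        fams.append(("ABC", "ST7"))
    if "transporter_MFS" in roles_in_flank:
        # with a full ABC system also present the MFS family is reported
        # but its ST family cannot be resolved
        fams.append(("MFS", "ND" if full_abc else "ST1"))
    if "transporter_SSS" in roles_in_flank:
        fams.append(("SSS", "ST5"))
    if "transporter_ABC_partial" in roles_in_flank and not full_abc:
        fams.append(("ABC_partial", "ND"))
    return fams


def annotate_context(
    cluster: NanCluster,
    genes: pd.DataFrame,
    assignments: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
) -> NanCluster:
    """Attach transporter/regulator/context annotation to a cluster.

    Transporters, IS/mobilome and extra core copies are searched within
    the core span and up to ``params.flank`` ordinals beyond it;
    regulators within ``params.regulator_flank``; the pathway-context
    flags (sialidase, nanOx, nagA/B) are in-span only, with nanOx also
    flagged genome-wide.
    """
    contig_genes = genes[genes["contig_id"] == cluster.contig_id]
    merged = assignments.merge(contig_genes[["gene_uid", "ordinal"]], on="gene_uid")
    lo, hi = cluster.span
    f_lo, f_hi = lo - params.flank, hi + params.flank
    r_lo, r_hi = lo - params.regulator_flank, hi + params.regulator_flank

    in_span = merged[(merged["ordinal"] >= lo) & (merged["ordinal"] <= hi)]
    in_flank = merged[(merged["ordinal"] >= f_lo) & (merged["ordinal"] <= f_hi)]
    in_reg = merged[(merged["ordinal"] >= r_lo) & (merged["ordinal"] <= r_hi)]

    span_roles = set(in_span["role"])
    flank_roles = set(in_flank["role"])
    cluster.transporters = _transporter_families(
        flank_roles & set(TRANSPORTER_ROLES)
    )
    reg = in_reg[in_reg["role"] == "regulator"]
    cluster.regulator_cogs = sorted(
        {a for accs in reg["accessions"] for a in accs.split(",")}
    )

    if "sialidase_subtype" in merged.columns:
        it_in_span = (
            (in_span["role"] == "sialidase") & (in_span["sialidase_subtype"] == "IT")
        ).any()
    else:
        it_in_span = False
    n_contig = len(contig_genes)
    boundary = lo <= params.boundary_dist or (n_contig - 1 - hi) <= params.boundary_dist
    cluster.flags = {
        "sialidase_in_cluster": "sialidase" in span_roles,
        "it_sialidase_in_cluster": bool(it_in_span),
        "nanOx_in_cluster": "nanOx" in span_roles,
        "nanOx_in_genome": "nanOx" in set(assignments["role"]),
        "nagA_in_cluster": "nagA" in span_roles,
        "nagB_in_cluster": "nagB" in span_roles,
        "IS_near": "IS" in flank_roles,
        "mobilome_near": "mobilome" in flank_roles,
        "contig_boundary": bool(boundary),
    }

    core_uids = cluster.core_uids
    core_roles = set(cluster.core_genes)
    extra = in_flank[
        in_flank["role"].isin(core_roles) & ~in_flank["gene_uid"].isin(core_uids)
    ]
    cluster.extra_core_copies = extra.groupby("role").size().to_dict()
    if cluster.paradigm == "canonical":
        cluster.structure = classify_structure(cluster)
    return cluster


@dataclass
class SacCall:
    genome_id: str
    sac_positive: bool
    paradigms: tuple[str, ...]
    clusters: list[NanCluster]
    role_counts: dict[str, int]


def call_genome(
    genes: pd.DataFrame,
    assignments: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
) -> SacCall:
    """Full SAC verdict for one genome: detect both paradigms, annotate
    every cluster, and tally per-role copy numbers."""
    genome_id = genes["genome_id"].iloc[0]
    clusters = find_canonical_clusters(genes, assignments, params)
    clusters += find_bacteroidetes_clusters(genes, assignments, params)
    clusters = [annotate_context(c, genes, assignments, params) for c in clusters]
    counts = assignments.groupby("role").size().to_dict()
    return SacCall(
        genome_id=genome_id,
        sac_positive=bool(clusters),
        paradigms=tuple(sorted({c.paradigm for c in clusters})),
        clusters=sorted(clusters, key=lambda c: (c.contig_id, c.span)),
        role_counts={k: int(v) for k, v in counts.items()},
    )


def call_genomes(
    genes: pd.DataFrame,
    assignments: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run call_genome over every genome in a gene table.

    Returns (calls, clusters): one row per genome with the verdict and
    per-role copy-number columns (``count_<role>``), and one row per
    detected cluster with its typing, transporters, regulators and 0/1
    context-flag columns.
    """
    gene2genome = genes[["gene_uid", "genome_id"]]
    assign_by_genome = {
        gid: grp.drop(columns="genome_id")
        for gid, grp in assignments.merge(gene2genome, on="gene_uid").groupby("genome_id")
    }
    empty_assign = assignments.iloc[0:0]
    call_rows, cluster_rows = [], []
    all_roles = sorted(set(assignments["role"]))
    for genome_id, ggenes in genes.groupby("genome_id", sort=True):
        sub = assign_by_genome.get(genome_id, empty_assign)
        call = call_genome(ggenes, sub, params)
        row = {
            "genome_id": genome_id,
            "sac_positive": call.sac_positive,
            "n_clusters": len(call.clusters),
            "paradigms": ",".join(call.paradigms),
        }
        for role in all_roles:
            row[f"count_{role}"] = call.role_counts.get(role, 0)
        call_rows.append(row)
        for c in call.clusters:
            crow = {
                "genome_id": c.genome_id,
                "contig_id": c.contig_id,
                "paradigm": c.paradigm,
                "span_min": c.span[0],
                "span_max": c.span[1],
                "structure": c.structure or "",
                "core_genes": ";".join(
                    f"{role}:{uid}@{o}"
                    for role in sorted(c.core_genes)
                    for uid, o in c.core_genes[role]
                ),
                "transporters": ";".join(f"{f}:{st}" for f, st in c.transporters) or "none",
                "regulator_cogs": ";".join(c.regulator_cogs),
                "extra_core_copies": ";".join(
                    f"{r}:{n}" for r, n in sorted(c.extra_core_copies.items())
                ),
            }
            for flag in CLUSTER_FLAGS:
                crow[flag] = int(c.flags.get(flag, False))
            cluster_rows.append(crow)
    calls = pd.DataFrame(call_rows)
    clusters_frame = pd.DataFrame(
        cluster_rows,
        columns=[
            "genome_id", "contig_id", "paradigm", "span_min", "span_max",
            "structure", "core_genes", "transporters", "regulator_cogs",
            "extra_core_copies", *CLUSTER_FLAGS,
        ],
    )
    return calls, clusters_frame
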