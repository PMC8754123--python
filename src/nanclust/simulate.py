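"""Seed-reproducible synthetic datasets with known ground truth.

The generator emulates the statistical structure of a large
actinobacterial genome survey: ordered gene tables with *planted* nan
clusters at a configurable prevalence, near-universal decoy nanA/nanK
homologs scattered outside clusters (nanE is the rare, informative gene),
domain-evidence tables in which planted roles pass the calling thresholds
and decoy evidence fails them by construction, taxon and habitat labels
skewed by cluster presence, and a random species tree with an optional
simulated gain/loss history of the cluster.

It emits exactly the tables the readers consume, plus a TruthTable
against which detection output can be compared exactly.  No nucleotide or
protein sequence is simulated — evidence is generated at the hit-table
level, which is the level at which the pipeline operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .clusters import CLUSTER_FLAGS

CORE_COMPLEMENT = {
    "nanA": {"nanK", "nanE", "nanE_II"},
    "nanK": {"nanA", "nanE"},
    "nanE": {"nanA", "nanK"},
    "nanE_II": {"nanA"},
}
DECOY_MIN_DIST = 11  # > max_span: a decoy can never complete a window

_ROLE_EVIDENCE = {
    # role -> list of (source, accession); values drawn at emission time
    "nanA": [("pfam", "PF00701"), ("cdd", "cd00954")],
    "nanK": [("pfam", "PF00480"), ("cdd", "cd24069")],
    "nanE": [("pfam", "PF04131"), ("cdd", "cd04729")],
    "nanE_II": [("blastp", "NANE2_REF")],
    "rokA": [("blastp", "ROKA_REF")],
    "nanOx": [("blastp", "NANOX_REF")],
    "nagA": [("pfam", "PF01979")],
    "nagB": [("pfam", "PF01182")],
    "sialidase": [("pfam", "PF13088")],
    "it_sialidase_segment": [("itseg", "RgNanH_seg")],
    "transporter_ABC_ST3": [("pfam", "PF00496")],
    "transporter_ABC_ST7": [("pfam", "PF01547")],
    "transporter_ABC_partial": [("pfam", "PF00528")],
    "transporter_MFS": [("pfam", "PF07690")],
    "transporter_SSS": [("pfam", "PF00474")],
    "IS": [("isfinder", "ISAb1")],
    "mobilome": [("cog", "X")],
}

COUNTED_ROLES = ("nanA", "nanK", "nanE", "nanE_II", "rokA", "nanOx", "sialidase")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic survey.

    Defaults emulate the reference survey's reported structure: ~13%
    species-level cluster prevalence, a small bacteroidetes-paradigm
    minority, ~79% consecutive core arrangement, an ABC(ST3)-dominated
    transporter mix, near-universal scattered nanA/nanK decoys, and
    habitat odds skewed toward animal hosts among positives.
    """

    n_orders: int = 4
    genera_per_order: int = 4
    species_per_genus: int = 4
    contigs_per_genome: int = 2
    genes_per_contig_mean: int = 50
    genes_per_contig_min: int = 30
    cluster_prevalence: float = 0.13
    bacteroidetes_fraction: float = 0.01
    consecutive_fraction: float = 0.79
    # transporter system mix among positive genomes
    transporter_mix: tuple = (
        ("ABC_ST3", 0.80),
        ("ABC_ST7", 0.025),
        ("MFS", 0.07),
        ("ABC_MFS", 0.015),
        ("SSS", 0.035),
        ("none", 0.055),
    )
    p_regulator: float = 0.95
    p_sialidase_cluster: float = 0.32
    p_it_given_sialidase: float = 0.15
    p_nanox_cluster: float = 0.02
    p_naga_cluster: float = 0.28
    p_nagb_cluster: float = 0.48
    p_is_near: float = 0.95
    p_mobilome_near: float = 0.10
    p_extra_nanA: float = 0.03
    decoy_nanA_rate: float = 0.99
    decoy_nanK_rate: float = 0.97
    decoy_sialidase_rate: float = 0.30
    background_rokA_rate: float = 0.85
    background_nanox_rate: float = 0.17
    near_miss_rate: float = 0.50  # genomes given failing right-accession evidence
    p_animal_given_positive: float = 0.59
    p_animal_given_negative: float = 0.27
    p_unknown_habitat: float = 0.02
    mean_branch_length: float = 0.1
    gain_rate: float = 0.3
    loss_rate: float = 0.1
    root_state: int = 0
    presence_from_history: bool = False
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return self.n_orders * self.genera_per_order * self.species_per_genus

    def __post_init__(self):
        probs = [
            self.cluster_prevalence, self.bacteroidetes_fraction,
            self.consecutive_fraction, self.p_regulator, self.p_sialidase_cluster,
            self.p_it_given_sialidase, self.p_nanox_cluster, self.p_naga_cluster,
            self.p_nagb_cluster, self.p_is_near, self.p_mobilome_near,
            self.p_extra_nanA, self.decoy_nanA_rate, self.decoy_nanK_rate,
            self.decoy_sialidase_rate, self.background_rokA_rate,
            self.background_nanox_rate, self.near_miss_rate,
            self.p_animal_given_positive, self.p_animal_given_negative,
            self.p_unknown_habitat,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(w for _, w in self.transporter_mix) - 1.0) > 1e-9:
            raise ValueError("transporter_mix weights must sum to 1")
        if self.genes_per_contig_min < 25:
            raise ValueError("contigs must hold at least 25 genes to fit a cluster")


@dataclass
class TruthTable:
    genomes: pd.DataFrame  # one row per genome with all planted-cluster fields
    branch_events: pd.DataFrame | None = None  # only in history mode


@dataclass
class SyntheticDataset:
    genes: pd.DataFrame
    evidence: pd.DataFrame
    meta: pd.DataFrame
    tree: dendropy.Tree
    newick: str
    profile: dict[str, int]
    truth: TruthTable
    config: SimConfig


def _evalue(rng, lo=12, hi=40) -> float:
    return float(10.0 ** -rng.uniform(lo, hi))


def _emit_hits(rows: list, uid: str, role: str, rng) -> None:
    for source, accession in _ROLE_EVIDENCE[role]:
        if source in ("pfam", "cdd", "itseg"):
            rows.append((uid, source, accession, _evalue(rng), np.nan, np.nan))
        elif source == "blastp":
            rows.append(
                (uid, source, accession, _evalue(rng, 6, 30),
                 round(rng.uniform(35, 90), 1), np.nan)
            )
        elif source == "isfinder":
            rows.append((uid, source, accession, _evalue(rng, 6, 30), np.nan, np.nan))
        elif source == "cog":
            rows.append(
                (uid, source, accession, _evalue(rng, 6, 30),
                 round(rng.uniform(55, 95), 1), round(rng.uniform(60, 98), 1))
            )


def _emit_regulator(rows: list, uid: str, cog_id: str, rng) -> None:
    rows.append(
        (uid, "cog", cog_id, _evalue(rng, 6, 30),
         round(rng.uniform(55, 95), 1), round(rng.uniform(60, 98), 1))
    )


def _emit_near_miss(rows: list, uid: str, rng) -> None:
    """Right accession, failing threshold — or wrong accession entirely."""
    kind = rng.integers(0, 4)
    if kind == 0:  # pfam core accession, e-value 10x above cutoff
        rows.append((uid, "pfam", "PF04131", 1e-9, np.nan, np.nan))
    elif kind == 1:  # passes pfam but lacks the confirming cdd channel
        rows.append((uid, "pfam", "PF00701", _evalue(rng), np.nan, np.nan))
    elif kind == 2:  # blastp identity below cutoff
        rows.append((uid, "blastp", "NANOX_REF", 1e-8, 25.0, np.nan))
    else:  # strong hit to an accession no role recognises
        rows.append((uid, "pfam", "PF99999", 1e-30, np.nan, np.nan))


class _GenomeBuilder:
    """Lays out one genome: contigs, planted cluster, decoys, evidence."""

    def __init__(self, genome_id: str, cfg: SimConfig, rng: np.random.Generator):
        self.genome_id = genome_id
        self.cfg = cfg
        self.rng = rng
        self.n_genes = [
            max(cfg.genes_per_contig_min, int(rng.poisson(cfg.genes_per_contig_mean)))
            for _ in range(cfg.contigs_per_genome)
        ]
        # contig -> ordinal -> role
        self.roles: list[dict[int, str]] = [{} for _ in self.n_genes]
        # planted-cluster flank window per contig; decoys stay out of it so
        # planted truth and detected annotation cannot disagree
        self.forbidden: dict[int, tuple[int, int]] = {}
        self.it_genes: set[tuple[int, int]] = set()
        self.regulator_cog: dict[tuple[int, int], str] = {}
        self.truth: dict = {"genome_id": genome_id, "sac_positive": False}

    # -- core-gene geometry ------------------------------------------------
    def _core_positions(self, contig: int) -> list[tuple[int, str]]:
        return [
            (o, r) for o, r in self.roles[contig].items()
            if r in CORE_COMPLEMENT
        ]

    def _decoy_ok(self, contig: int, pos: int, role: str) -> bool:
        if pos in self.roles[contig]:
            return False
        if contig in self.forbidden:
            lo, hi = self.forbidden[contig]
            if lo <= pos <= hi:
                return False
        if role in CORE_COMPLEMENT:
            for o, r in self._core_positions(contig):
                if r in CORE_COMPLEMENT[role] and abs(o - pos) < DECOY_MIN_DIST:
                    return False
        return True

    def _place_decoy(self, role: str, required: bool = False) -> bool:
        for _ in range(40):
            contig = int(self.rng.integers(0, len(self.n_genes)))
            pos = int(self.rng.integers(0, self.n_genes[contig]))
            if self._decoy_ok(contig, pos, role):
                self.roles[contig][pos] = role
                return True
        if required:  # deterministic fallback scan
            for contig in range(len(self.n_genes)):
                for pos in range(self.n_genes[contig]):
                    if self._decoy_ok(contig, pos, role):
                        self.roles[contig][pos] = role
                        return True
        return False

    # -- cluster planting --------------------------------------------------
    def plant_cluster(self, paradigm: str) -> None:
        cfg, rng = self.cfg, self.rng
        contig = int(rng.integers(0, len(self.n_genes)))
        consecutive = False
        if paradigm == "canonical":
            consecutive = rng.random() < cfg.consecutive_fraction
            if consecutive:
                w = 3
                core_offsets = [0, 1, 2]
            else:
                w = int(rng.integers(4, 12))  # span 3..10
                core_offsets = [0, int(rng.integers(1, w - 1)), w - 1]
            core_roles = list(rng.permutation(["nanA", "nanK", "nanE"]))
        else:
            gap = int(rng.integers(1, 11))
            w = gap + 1
            core_offsets = [0, gap]
            core_roles = list(rng.permutation(["nanA", "nanE_II"]))

        margin = 6  # flank(5) + 1 so every context slot stays on the contig
        anchor = int(rng.integers(margin, self.n_genes[contig] - w - margin + 1))
        span = (anchor, anchor + w - 1)
        self.forbidden[contig] = (span[0] - 5, span[1] + 5)
        for off, role in zip(core_offsets, core_roles):
            self.roles[contig][anchor + off] = role

        interior = [anchor + o for o in range(w) if o not in core_offsets]
        rng.shuffle(interior)
        flank: list[int] = []
        for d in range(1, 6):
            flank += [span[1] + d, span[0] - d]
        flank_near = [p for p in flank if abs(p - span[0]) <= 3 or abs(p - span[1]) <= 3]

        def take(slots: list[int]) -> int | None:
            while slots:
                p = slots.pop(0)
                if p not in self.roles[contig]:
                    return p
            return None

        truth = self.truth
        truth.update(
            {
                "sac_positive": True,
                "paradigm": paradigm,
                "contig_id": f"{self.genome_id}_c{contig + 1}",
                "span_min": span[0],
                "span_max": span[1],
                "structure": (
                    ("consecutive" if consecutive else "inconsecutive")
                    if paradigm == "canonical" else ""
                ),
            }
        )
        flags = {f: False for f in CLUSTER_FLAGS}

        # transporter system
        fam = rng.choice(
            [f for f, _ in cfg.transporter_mix],
            p=[p for _, p in cfg.transporter_mix],
        )
        tr_roles: list[str] = []
        if fam in ("ABC_ST3", "ABC_MFS"):
            tr_roles += ["transporter_ABC_ST3", "transporter_ABC_partial"]
        if fam == "ABC_ST7":
            tr_roles += ["transporter_ABC_ST7", "transporter_ABC_partial"]
        if fam in ("MFS", "ABC_MFS"):
            tr_roles.append("transporter_MFS")
        if fam == "SSS":
            tr_roles.append("transporter_SSS")
        truth_transporters = {
            "ABC_ST3": "ABC:ST3",
            "ABC_ST7": "ABC:ST7",
            "MFS": "MFS:ST1",
            "ABC_MFS": "ABC:ST3;MFS:ND",
            "SSS": "SSS:ST5",
            "none": "none",
        }[fam]
        slots = interior + flank
        for r in tr_roles:
            p = take(slots)
            if p is not None:
                self.roles[contig][p] = r
        truth["transporters"] = truth_transporters

        # regulator within 3 ORFs of the span
        truth["regulator_cogs"] = ""
        if rng.random() < cfg.p_regulator:
            cog = str(rng.choice(["COG2186", "COG2186", "COG2186", "COG1349", "COG2207"]))
            near = [p for p in interior if p not in self.roles[contig]] + list(flank_near)
            p = take(near)
            if p is not None:
                self.roles[contig][p] = "regulator"
                self.regulator_cog[(contig, p)] = cog
                truth["regulator_cogs"] = cog

        # pathway context: in-span placement sets the in-cluster flag,
        # flank placement does not
        def place_context(role: str, prob: float, flag: str | None):
            if rng.random() >= prob:
                return None
            p = take(slots)
            if p is None:
                return None
            self.roles[contig][p] = role
            in_span = span[0] <= p <= span[1]
            if flag and in_span:
                flags[flag] = True
            return contig, p

        sial = place_context("sialidase", cfg.p_sialidase_cluster, "sialidase_in_cluster")
        if sial and rng.random() < cfg.p_it_given_sialidase:
            self.it_genes.add(sial)
            if flags["sialidase_in_cluster"]:
                flags["it_sialidase_in_cluster"] = True
        nanox = place_context("nanOx", cfg.p_nanox_cluster, "nanOx_in_cluster")
        place_context("nagA", cfg.p_naga_cluster, "nagA_in_cluster")
        place_context("nagB", cfg.p_nagb_cluster, "nagB_in_cluster")
        if nanox:
            flags["nanOx_in_genome"] = True

        if rng.random() < cfg.p_is_near:
            p = take(slots)
            if p is not None:
                self.roles[contig][p] = "IS"
                flags["IS_near"] = True
        if rng.random() < cfg.p_mobilome_near:
            p = take(slots)
            if p is not None:
                self.roles[contig][p] = "mobilome"
                flags["mobilome_near"] = True

        # extra nanA copy next to the cluster, never nearer to the
        # cluster's nanE/nanE_II than the core nanA (so the core match is
        # unambiguous)
        truth["extra_nanA"] = 0
        if paradigm == "canonical" and rng.random() < cfg.p_extra_nanA:
            e_ord = next(o for o, r in self._core_positions(contig) if r == "nanE")
            a_ord = next(o for o, r in self._core_positions(contig) if r == "nanA")
            for p in flank:
                if p in self.roles[contig]:
                    continue
                if abs(p - e_ord) > abs(a_ord - e_ord):
                    self.roles[contig][p] = "nanA"
                    truth["extra_nanA"] = 1
                    break

        if paradigm == "bacteroidetes":
            self._place_decoy("rokA", required=True)
            truth["has_rokA"] = True

        n_contig = self.n_genes[contig]
        flags["contig_boundary"] = span[0] <= 10 or (n_contig - 1 - span[1]) <= 10
        truth.update(flags)

    # -- background content ------------------------------------------------
    def plant_background(self) -> None:
        cfg, rng = self.cfg, self.rng
        if rng.random() < cfg.decoy_nanA_rate:
            self._place_decoy("nanA")
        if rng.random() < cfg.decoy_nanK_rate:
            self._place_decoy("nanK")
        if rng.random() < cfg.decoy_sialidase_rate:
            self._place_decoy("sialidase")
        if self.truth.get("paradigm") != "bacteroidetes":
            if rng.random() < cfg.background_rokA_rate:
                if self._place_decoy("rokA"):
                    self.truth["has_rokA"] = True
        if rng.random() < cfg.background_nanox_rate:
            if self._place_decoy("nanOx"):
                self.truth["nanOx_in_genome"] = True

    # -- emission ----------------------------------------------------------
    def emit(self, gene_rows: list, hit_rows: list) -> dict:
        cfg, rng = self.cfg, self.rng
        counts = dict.fromkeys(COUNTED_ROLES, 0)
        for contig, n in enumerate(self.n_genes):
            contig_id = f"{self.genome_id}_c{contig + 1}"
            pos = 1
            for o in range(n):
                uid = f"{self.genome_id}_c{contig + 1}_g{o:04d}"
                length = int(rng.integers(300, 3000))
                gene_rows.append(
                    (
                        self.genome_id, contig_id, uid, pos, pos + length - 1,
                        "+" if rng.random() < 0.5 else "-",
                    )
                )
                pos += length + int(rng.integers(1, 200))
                role = self.roles[contig].get(o)
                if role is None:
                    if rng.random() < 0.02 * cfg.near_miss_rate:
                        _emit_near_miss(hit_rows, uid, rng)
                    continue
                if role == "regulator":
                    _emit_regulator(hit_rows, uid, self.regulator_cog[(contig, o)], rng)
                    continue
                _emit_hits(hit_rows, uid, role, rng)
                if (contig, o) in self.it_genes:
                    _emit_hits(hit_rows, uid, "it_sialidase_segment", rng)
                if role in counts:
                    counts[role] += 1
        truth = dict(self.truth)
        for r in COUNTED_ROLES:
            truth[f"count_{r}"] = counts[r]
        truth.setdefault("nanOx_in_genome", counts["nanOx"] > 0)
        truth.setdefault("has_rokA", counts["rokA"] > 0)
        return truth


def _random_tree_newick(labels: list[str], rng: np.random.Generator, mean_bl: float) -> str:
    labels = list(labels)
    rng.shuffle(labels)

    def bl() -> str:
        return f"{rng.exponential(mean_bl):.6f}"

    def build(part: list[str]) -> str:
        if len(part) == 1:
            return f"{part[0]}:{bl()}"
        k = int(rng.integers(1, len(part)))
        return f"({build(part[:k])},{build(part[k:])}):{bl()}"

    return build(labels) + ";"


def simulate_gainloss_history(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    root_state: int = 0,
    seed: int = 0,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Two-state Markov gain/loss process down a tree.

    Each branch evolves the 0/1 state by exponential waiting times
    (rates: gain for 0→1, loss for 1→0) over its length (1.0 when branch
    lengths are absent); a branch whose end state differs from its start
    state records one effective gain or loss event.  Returns the tip
    profile and a per-branch event table.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    state: dict = {tree.seed_node: int(root_state)}
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        s = state[node.parent_node]
        start = s
        length = node.edge.length if node.edge.length is not None else 1.0
        t = 0.0
        while True:
            rate = gain_rate if s == 0 else loss_rate
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= length:
                break
            s = 1 - s
        state[node] = s
        event = "none"
        if start == 0 and s == 1:
            event = "gain"
        elif start == 1 and s == 0:
            event = "loss"
        label = node.taxon.label if node.is_leaf() else None
        rows.append(
            {
                "child": label,
                "is_leaf": node.is_leaf(),
                "start_state": start,
                "end_state": s,
                "event": event,
            }
        )
    profile = {
        leaf.taxon.label: state[leaf] for leaf in tree.leaf_node_iter()
    }
    return profile, pd.DataFrame(rows)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic survey under the configured conditions.

    Deterministic for a given config (same seed → identical tables).
    Independent RNG streams feed the genome tables, the habitat labels,
    the tree and the optional gain/loss history, so adding one output
    never perturbs the others.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_genomes, rng_habitat, rng_tree, rng_presence = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    species = []
    for o in range(config.n_orders):
        for g in range(config.genera_per_order):
            for s in range(config.species_per_genus):
                species.append(
                    {
                        "order": f"O{o + 1:02d}",
                        "genus": f"O{o + 1:02d}_G{g + 1:02d}",
                        "species": f"O{o + 1:02d}_G{g + 1:02d}_S{s + 1:02d}",
                    }
                )

    newick = _random_tree_newick(
        [sp["species"] for sp in species], rng_tree, config.mean_branch_length
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True

    branch_events = None
    if config.presence_from_history:
        hist_profile, branch_events = simulate_gainloss_history(
            tree,
            config.gain_rate,
            config.loss_rate,
            config.root_state,
            seed=int(rng_presence.integers(0, 2**31 - 1)),
        )
        positive = {sp["species"]: bool(hist_profile[sp["species"]]) for sp in species}
    else:
        positive = {
            sp["species"]: bool(rng_presence.random() < config.cluster_prevalence)
            for sp in species
        }

    gene_rows: list = []
    hit_rows: list = []
    truth_rows: list = []
    meta_rows: list = []
    for i, sp in enumerate(species):
        genome_id = f"G{i + 1:05d}"
        builder = _GenomeBuilder(genome_id, config, rng_genomes)
        if positive[sp["species"]]:
            paradigm = (
                "bacteroidetes"
                if rng_genomes.random() < config.bacteroidetes_fraction
                else "canonical"
            )
            builder.plant_cluster(paradigm)
        builder.plant_background()
        truth_rows.append(builder.emit(gene_rows, hit_rows))

        p_animal = (
            config.p_animal_given_positive
            if positive[sp["species"]]
            else config.p_animal_given_negative
        )
        u = rng_habitat.random()
        if rng_habitat.random() < config.p_unknown_habitat:
            habitat = "unknown"
        else:
            habitat = "animal" if u < p_animal else "non_animal"
        meta_rows.append(
            {
                "genome_id": genome_id,
                "species": sp["species"],
                "genus": sp["genus"],
                "family": sp["genus"],
                "order": sp["order"],
                "class_": "SimClass",
                "is_type_strain": True,
                "habitat": habitat,
            }
        )

    genes = pd.DataFrame(
        gene_rows, columns=["genome_id", "contig_id", "gene_uid", "start", "end", "strand"]
    )
    from .model import assign_ordinals

    genes = assign_ordinals(genes)
    evidence = pd.DataFrame(
        hit_rows,
        columns=["gene_uid", "source", "accession", "evalue", "identity_pct", "coverage_pct"],
    )
    meta = pd.DataFrame(meta_rows)
    profile = {sp["species"]: int(positive[sp["species"]]) for sp in species}
    truth = TruthTable(
        genomes=pd.DataFrame(truth_rows), branch_events=branch_events
    )
    return SyntheticDataset(
        genes=genes,
        evidence=evidence,
        meta=meta,
        tree=tree,
        newick=newick,
        profile=profile,
        truth=truth,
        config=config,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every table of a synthetic dataset to a directory; returns
    the name -> path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def emit(name, writer):
        path = os.path.join(outdir, name)
        writer(path)
        paths[name] = path

    emit("genes.tsv", lambda p: ds.genes.to_csv(p, sep="\t", index=False))
    emit("evidence.tsv", lambda p: ds.evidence.to_csv(p, sep="\t", index=False))
    emit("metadata.tsv", lambda p: ds.meta.to_csv(p, sep="\t", index=False))
    emit("tree.nwk", lambda p: open(p, "w").write(ds.newick + "\n"))
    emit(
        "profile.tsv",
        lambda p: pd.DataFrame(
            {"label": list(ds.profile), "present": list(ds.profile.values())}
        ).to_csv(p, sep="\t", index=False),
    )
    emit("truth_genomes.tsv", lambda p: ds.truth.genomes.to_csv(p, sep="\t", index=False))
    if ds.truth.branch_events is not None:
        emit(
            "truth_branch_events.tsv",
            lambda p: ds.truth.branch_events.to_csv(p, sep="\t", index=False),
        )
    return paths


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
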