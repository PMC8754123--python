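# Methods

This note records the models, rules and numerical choices behind
`nanclust`, and what its synthetic benchmarks do and do not demonstrate.

## Units and coordinates

All neighborhood reasoning uses the **ordinal** of a CDS: its 0-based
rank in the gene order of its contig, recomputed from start coordinates
on input (stable sort by start, end, then gene id). ORF distance is the
difference of ordinals; it is undefined across contigs, so clusters never
span a contig break. Input coordinates are 1-based inclusive (GFF
convention) but are used only to derive ordinals.

## Genome QC and dereplication

A genome passes QC iff completeness > 95%, contamination < 5% and it
carries at least 75% of the 138 actinobacterial marker genes. The first
two bounds are strict and the marker bound is inclusive, a literal
reading of the underlying rules ("more than", "less than", "filter out
… less than 75%"); boundary cases are pinned in tests. Genomes with a
missing metric are unevaluable and excluded with a warning.

Dereplication keeps every type strain unconditionally and clusters
non-type strains within each genus by single linkage at ANI ≥ 99.5%,
keeping the lexicographically smallest genome id of each cluster. This
deliberately replaces the two-stage greedy scoring of dedicated
dereplication tools with a deterministic rule: determinism matters more
here than replicating any particular tool's representative choice.
Whether clustering should be genus-restricted or global is genuinely
ambiguous; we restrict to genera, which can only keep more genomes.

## Role calling

Roles are assigned from externally produced hit tables (Pfam, CDD,
BLASTP against reference proteins, COG, ISFinder, IT-sialidase segment
model); the package never runs a homology search. Thresholds are strict:
a hit passes iff e-value < cutoff, identity > cutoff and coverage >
cutoff where a channel defines them. Defaults: Pfam/CDD 1e-10; BLASTP
1e-5 with identity > 30% (no coverage bound); COG 1e-5 with identity and
coverage > 50%; ISFinder 1e-5. Core roles (nanA/K/E) require at least
one passing pattern from *both* the Pfam and the CDD channel; all other
roles accept any single passing pattern. A gene may carry several roles
if each passes independently.

The role → accession map ships as `data/rolemap.yaml`. The transporter
and regulator accessions (PF00496, PF01547, PF00528, COG2186, COG1349,
COG1481, COG2207, COG categories K and X) are the standard ones for this
pathway; the per-enzyme Pfam/CDD families are a reconstruction from
widely cited assignments and are explicitly marked editable — the rule
engine is fixed, the uncertain mapping is data. Whether CDD confirmation
should apply beyond the core genes is an open choice; we require it for
core roles only, since those alone decide the SAC verdict.

Role assignment is monotone (adding a passing hit never removes a role;
tightening a threshold never adds one) and a pure function of its
inputs; both properties are tested.

## Cluster detection

**Window rule.** "Within 10 ORFs of each other" is read as
max − min ordinal ≤ 10 over the core genes — all inside a window of 11
consecutive ORFs — rather than a pairwise-chain rule. The max-span
reading is order-independent and matches the "within 10 consecutive
ORFs" phrasing of the bacteroidetes rule. Both semantics are available
(`DetectionParams.rule = "max_span" | "chain"`); max-span is the
default.

**Matching.** For every nanE (anchor), candidate (nanA, nanK) partners
are restricted to combinations whose full ordinal set satisfies the
window rule; among those the nanA is chosen by smallest (|Δordinal|,
ordinal), then the nanK likewise. Restricting *before* choosing matters:
unconstrained nearest-neighbor matching can pick a nanA and nanK on
opposite sides of the anchor whose joint span exceeds the window even
though a valid triple exists, breaking equivalence with plain triple
enumeration. With the constraint, the detector is provably
verdict-equivalent to brute-force enumeration, which the acceptance
suite verifies on 1,000 random genomes. Ties resolve to the lower
ordinal. Clusters sharing a core gene are merged (within a paradigm; a
gene may serve both paradigm definitions without collapsing the calls),
so no two reported same-paradigm clusters share a core gene, and
multiple disjoint clusters per genome are allowed.

**Typing and context.** A canonical cluster is *consecutive* iff its
core ordinals occupy an interval of length 2 ({m, m+1, m+2}, any role
order), else *inconsecutive*. Transporters, IS/mobilome and extra core
copies are searched in the core span and up to 5 ordinals beyond it;
regulators up to 3 ordinals beyond (the stated regulator rule); the
5-ordinal flank is our operationalisation of "around the cluster", which
is not quantified for the other features — it is configurable and all
flank-sensitive behavior is pinned in tests. Pathway flags (sialidase,
IT-sialidase, NanOx, NagA, NagB) are in-span only; NanOx is additionally
flagged genome-wide because anhydro-SAC capability does not require the
oxidoreductase to sit inside the cluster. Transporter ST mapping:
SBP_bac_5 → ABC/ST3, SBP_bac_1 → ABC/ST7, MFS → ST1 unless a full ABC
system is also present (then the MFS family is reported with ST = ND),
SSS → ST5, a PF00528 permease without a substrate-binding protein →
partial ABC, ST = ND. A span within 10 ordinals of a contig end is
flagged as a possible truncation.

## Taxon statistics

Rates are percentages rounded **half-up** to two decimals, computed in
exact decimal arithmetic from integer counts (no printed reference rate
is a .xx5 tie, so the rounding mode is unobservable there; half-up is
fixed for determinism). A taxon with fewer than five members reports the
literal string `ND` instead of a rate. Species-level statistics use type
strains (one per species) as the unit. Per-rank tables carry a Total row
whose counts are the column sums; total-consistency is a tested
invariant.

The habitat association is a two-sided Fisher exact test on the 2×2
animal/non-animal × positive/negative table, point-probability
convention: p is the sum of hypergeometric probabilities ≤ the observed
table's probability, with a (1 + 1e-7) relative guard against
floating-point ties. It is computed from log-pmfs via logsumexp, exact
to ~1e-14 relative against rational enumeration, safe for counts up to
1e5, returns exactly 1.0 when the whole support is included, and clamps
underflow so p stays in (0, 1]. Genomes with unknown habitat are
excluded and counted separately. A zero margin yields p = 1 with a
warning.

## Wagner parsimony

Ancestral presence/absence is reconstructed by Sankoff dynamic
programming: bottom-up per-node state costs with transition costs
gain_cost (0→1) and loss_cost (1→0), default 1:1, both configurable;
multifurcations are handled natively. The returned cost is the global
minimum and always equals gain_cost·gains + loss_cost·losses. Minimum
reconstructions are often non-unique, so the tie policy is explicit:
during top-down traceback a child prefers its parent's state (no change
on the incoming branch), and a root tie resolves to absence (state 0) by
default — the conservative prior for a patchily distributed accessory
cluster — with the preference configurable and the number of ties
reported. Terminal-branch events are the "species-level" totals.

An exhaustive enumerator over internal states (≤ 20 internal nodes)
serves as the oracle; the DP matches it on batteries of random trees
with mixed costs. Event counts from the survey-scale reference analysis
(hundreds of gains, tens of losses over ~2,000 species) depend on the
full species tree and are not reproduced here; the parsimony stage is
validated by oracle equivalence, the complement/cost-swap symmetry, and
the lower-bound property below.

## Synthetic surveys

`generate_dataset` emulates the statistical structure of the reference
survey rather than its sequences: ordered gene tables (default 2 contigs
of ~50 genes per genome — enough to hold a cluster plus flanks and
distant decoys, small enough to run thousands of genomes in seconds),
planted clusters at 13% species prevalence, ~1% bacteroidetes paradigm,
79% consecutive arrangement, an ABC(ST3)-dominated transporter mix with
minority ST7/MFS/SSS/mixed/none systems, regulator presence 95%
(FadR-type dominant), sialidase-in-cluster 32% with 15% IT-sialidase,
NanOx 2% in-cluster and 17% genome background, NagA/NagB 28%/48%, IS
95%, mobilome 10%, occasional extra nanA copies beside the cluster, and
near-universal scattered decoy nanA (99%) and nanK (97%) with background
rokA (85%) — all following the reference survey's reported proportions,
chosen once as the study conditions of the benchmark.

Decoy core genes are placed > 10 ordinals from any complementary core
gene and outside planted flank windows, so planted truth is recoverable
exactly by construction; evidence for planted roles passes thresholds
while decoy evidence fails by construction (right accession at 10× the
e-value cutoff, sub-threshold identity, passing Pfam without the
confirming CDD channel, or an accession no role recognises), so the
threshold logic — not just pattern matching — is exercised. Habitat
labels are drawn conditionally on cluster presence (59% animal among
positives vs 27% among negatives, 2% unknown). Independent RNG streams
(spawned from one seed) feed the genome tables, habitat labels, tree and
history, so adding an output never perturbs the others; identical seeds
give byte-identical files.

Presence has two modes. By default each species is positive i.i.d. with
the configured prevalence (so prevalence-recovery and the 0%/100% edge
cases are exact); with `presence_from_history=True`, presence is instead
the tip state of a two-state Markov gain/loss process simulated down the
tree, and the truth table then includes per-branch events consistent
with the tips. The two cannot hold simultaneously, so the mode is
explicit. In history mode at most the net state change per branch is
recorded as one effective event, which makes the parsimony lower bound
(inferred events ≤ true effective events under 1:1 costs) hold with
certainty — the true history is itself a feasible assignment.

What passing synthetic benchmarks shows: the rule engine, window
geometry, annotation, statistics and reconstruction are implemented
exactly as specified, at survey scale. What it does not show: robustness
to real annotation noise — fragmented assemblies, chimeric contigs,
mis-predicted ORFs, borderline homology — because decoys are adversarial
only in the dimensions the rules measure, and no sequence-level error
model is simulated.

## Known limitations

* The per-enzyme Pfam/CDD accessions in the shipped role map are a
  reconstruction; real deployments should pin their own mapping.
* Survey-scale reference quantities that require the original genome
  set (genome-wide copy-number distributions, the concatenated-protein
  phylogeny and its clades, absolute gain/loss counts) are out of reach
  by design; the package reproduces the printed rate arithmetic and
  validates the algorithms by oracle equivalence instead.
* Dereplication is a deterministic stand-in rule, not a reimplementation
  of any specific tool's scoring.
* The Fisher test underflows to the smallest positive float for
  astronomically significant tables; the reported p is then a floor, not
  an exact value.
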