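"""Independent brute-force oracles used only by the test suite.

These re-derive verdicts from first principles (full enumeration, exact
rational arithmetic) without touching the library's own search or DP
code paths.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pandas as pd


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom) for k in support}
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


def _merge_shared(items: list[tuple[frozenset, str, str]]) -> list[tuple[frozenset, str, str]]:
    """Union groups of (uid-set, contig, paradigm) sharing any uid.

    Merging is within one paradigm: a gene may serve both the canonical
    and the bacteroidetes definition without collapsing the two calls.
    """
    merged: list[tuple[set, str, str]] = []
    for uids, contig, paradigm in items:
        hits = [g for g in merged if g[1:] == (contig, paradigm) and g[0] & uids]
        for g in hits:
            merged.remove(g)
        combined = set(uids)
        for g in hits:
            combined |= g[0]
        merged.append((combined, contig, paradigm))
    return [(frozenset(u), c, p) for u, c, p in merged]


def enumerate_clusters(
    genes: pd.DataFrame, assignments: pd.DataFrame, max_span: int = 10
) -> tuple[bool, list[tuple[str, int, int]]]:
    """Verdict and merged cluster spans by full triple/pair enumeration.

    Canonical: every (nanA, nanK, nanE) triple on one contig with
    max − min ordinal <= max_span; per nanE the winning triple minimises
    (|a − e|, a, |k − e|, k).  Bacteroidetes: (nanA, nanE_II) pairs within
    max_span when rokA occurs anywhere.  Winning units sharing a gene are
    merged; spans cover the merged core genes.
    """
    merged = assignments.merge(genes[["gene_uid", "contig_id", "ordinal"]], on="gene_uid")
    has_rokA = bool((merged["role"] == "rokA").any())
    units: list[tuple[frozenset, str, str]] = []
    ords: dict[str, int] = dict(zip(merged["gene_uid"], merged["ordinal"]))
    for contig, grp in merged.groupby("contig_id"):
        by = {
            r: sorted(zip(g["ordinal"], g["gene_uid"]))
            for r, g in grp.groupby("role")
        }
        for e_o, e_u in by.get("nanE", []):
            best = None
            for a_o, a_u in by.get("nanA", []):
                for k_o, k_u in by.get("nanK", []):
                    if max(a_o, k_o, e_o) - min(a_o, k_o, e_o) <= max_span:
                        key = (abs(a_o - e_o), a_o, abs(k_o - e_o), k_o)
                        if best is None or key < best[0]:
                            best = (key, frozenset({a_u, k_u, e_u}))
            if best:
                units.append((best[1], contig, "canonical"))
        if has_rokA:
            for e_o, e_u in by.get("nanE_II", []):
                best = None
                for a_o, a_u in by.get("nanA", []):
                    if abs(a_o - e_o) <= max_span:
                        key = (abs(a_o - e_o), a_o)
                        if best is None or key < best[0]:
                            best = (key, frozenset({a_u, e_u}))
                if best:
                    units.append((best[1], contig, "bacteroidetes"))
    clusters = _merge_shared(units)
    spans = sorted(
        (contig, min(ords[u] for u in uids), max(ords[u] for u in uids))
        for uids, contig, _ in clusters
    )
    return bool(spans), spans
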