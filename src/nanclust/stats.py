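"""Per-taxon positive rates, habitat association, and Fisher's exact test.

Positive rates are reported at two units: all strains, and type strains
only (one type strain per species, so type-strain rates are species
rates).  A taxon's rate is reported as ``ND`` (no data) when it has fewer
than five members; otherwise rates are percentages rounded half-up to two
decimals.

``data/actinobacteria_order_counts.tsv`` ships the per-order strain and
SAC-positive counts from the reference survey of 7,180 high-quality,
non-redundant actinobacterial genomes (1,969 type strains); the rate
engine recomputes every rate from those raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

ND = "ND"
MIN_COUNT_FOR_RATE = 5
RANKS = ("class", "order", "family", "genus", "species")


def round_half_up_pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100*numerator/denominator rounded half-up, computed exactly."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def rate_or_nd(n_positive: int, n_total: int, min_count: int = MIN_COUNT_FOR_RATE):
    """Rounded percentage, or ND when the group has < min_count members."""
    if n_total < min_count:
        return ND
    return round_half_up_pct(n_positive, n_total)


def load_reference_order_counts() -> pd.DataFrame:
    """Per-order strain/type-strain counts of the reference actinobacterial
    survey (44 orders, 7,180 strains, 1,969 type strains)."""
    ref = resources.files("nanclust.data").joinpath("actinobacteria_order_counts.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def rate_table(
    counts: pd.DataFrame,
    taxon_col: str = "taxon",
    min_count: int = MIN_COUNT_FOR_RATE,
    include_total: bool = True,
) -> pd.DataFrame:
    """Compute rate columns from a (taxon, n, n_positive) count table.

    Adds ``rate`` (float percent or the string ND) and, when requested, a
    Total row aggregated over all taxa (the Total rate is always computed,
    whatever its n).
    """
    out = counts.copy()
    if (out["n_positive"] > out["n"]).any() or (out["n_positive"] < 0).any():
        raise ValueError("need 0 <= n_positive <= n")
    out["rate"] = [
        rate_or_nd(p, n, min_count) for p, n in zip(out["n_positive"], out["n"])
    ]
    if include_total:
        total = {
            taxon_col: "Total",
            "n": int(out["n"].sum()),
            "n_positive": int(out["n_positive"].sum()),
        }
        total["rate"] = round_half_up_pct(total["n_positive"], total["n"])
        out = pd.concat([out, pd.DataFrame([total])], ignore_index=True)
    return out


def _check_rank(rank: str) -> str:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    return "class_" if rank == "class" else rank


def positive_rates(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    rank: str = "order",
    type_strains_only: bool = False,
    min_count: int = MIN_COUNT_FOR_RATE,
) -> pd.DataFrame:
    """Per-taxon SAC-positive rates at a taxonomic rank, plus a Total row."""
    col = rank if rank in meta.columns else _check_rank(rank)
    _check_rank(rank)
    merged = calls[["genome_id", "sac_positive"]].merge(meta, on="genome_id", how="left")
    if merged[col].isna().any():
        missing = merged.loc[merged[col].isna(), "genome_id"].tolist()
        raise ValueError(f"genomes without {rank} metadata: {missing[:5]}")
    if type_strains_only:
        merged = merged[merged["is_type_strain"].astype(bool)]
    grouped = merged.groupby(col, sort=True)["sac_positive"]
    counts = pd.DataFrame(
        {
            "taxon": list(grouped.size().index),
            "n": grouped.size().to_numpy(),
            "n_positive": grouped.sum().astype(int).to_numpy(),
        }
    )
    out = rate_table(counts, min_count=min_count)
    out.insert(1, "rank", rank)
    return out


def gene_presence_rates(
    role: str,
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    type_strains_only: bool = True,
) -> dict:
    """Fraction of (type-strain) genomes carrying >=1 copy of a role
    anywhere in the genome — clustering is not required."""
    col = f"count_{role}"
    if col not in calls.columns:
        raise ValueError(f"unknown role {role!r} (no column {col})")
    merged = calls[["genome_id", col]].merge(meta, on="genome_id", how="left")
    if type_strains_only:
        merged = merged[merged["is_type_strain"].astype(bool)]
    n = len(merged)
    n_pos = int((merged[col] >= 1).sum())
    return {"role": role, "n": n, "n_positive": n_pos, "rate": rate_or_nd(n_pos, n)}


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    Point-probability method with fixed margins: p is the sum of
    hypergeometric probabilities not exceeding the observed table's
    probability (with a (1 + 1e-7) relative guard against floating-point
    ties).  Computed in log space, safe for counts up to ~1e5.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        warnings.warn("degenerate 2x2 table (zero margin): p = 1", stacklevel=2)
        return 1.0
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    logpmf = hypergeom.logpmf(support, n, r1, c1)
    log_obs = hypergeom.logpmf(a, n, r1, c1)
    keep = logpmf <= log_obs + np.log1p(1e-7)
    if keep.all():
        return 1.0
    p = float(np.exp(logsumexp(logpmf[keep])))
    # keep p in (0, 1]: an extreme table may underflow float64
    p = max(p, np.nextafter(0.0, 1.0))
    return min(p, 1.0)


@dataclass
class ContingencyResult:
    """2x2 habitat-by-SAC-status contingency analysis."""

    n_animal_positive: int
    n_animal_negative: int
    n_non_animal_positive: int
    n_non_animal_negative: int
    rate_animal: float
    rate_non_animal: float
    p_value: float
    n_unknown_habitat: int = 0

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.n_animal_positive, self.n_animal_negative],
            [self.n_non_animal_positive, self.n_non_animal_negative],
        ]


def contingency_from_counts(
    n_animal_positive: int,
    n_animal_negative: int,
    n_non_animal_positive: int,
    n_non_animal_negative: int,
    n_unknown: int = 0,
) -> ContingencyResult:
    return ContingencyResult(
        n_animal_positive=n_animal_positive,
        n_animal_negative=n_animal_negative,
        n_non_animal_positive=n_non_animal_positive,
        n_non_animal_negative=n_non_animal_negative,
        rate_animal=round_half_up_pct(
            n_animal_positive, n_animal_positive + n_animal_negative
        ),
        rate_non_animal=round_half_up_pct(
            n_non_animal_positive, n_non_animal_positive + n_non_animal_negative
        ),
        p_value=fisher_exact_2x2(
            n_animal_positive,
            n_animal_negative,
            n_non_animal_positive,
            n_non_animal_negative,
        ),
        n_unknown_habitat=n_unknown,
    )


def habitat_association(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    type_strains_only: bool = True,
) -> ContingencyResult:
    """Test whether SAC-positive species are enriched among animal
    host-associated species (two-sided Fisher's exact test).

    Genomes with unknown habitat are excluded and counted separately.
    """
    merged = calls[["genome_id", "sac_positive"]].merge(meta, on="genome_id", how="left")
    if type_strains_only:
        merged = merged[merged["is_type_strain"].astype(bool)]
    unknown = int((merged["habitat"] == "unknown").sum() + merged["habitat"].isna().sum())
    merged = merged[merged["habitat"].isin(["animal", "non_animal"])]
    pos = merged["sac_positive"].astype(bool)
    animal = merged["habitat"] == "animal"
    return contingency_from_counts(
        int((animal & pos).sum()),
        int((animal & ~pos).sum()),
        int((~animal & pos).sum()),
        int((~animal & ~pos).sum()),
        n_unknown=unknown,
    )


def subset_fraction(
    numerator: Callable[[pd.DataFrame], pd.Series],
    denominator: Callable[[pd.DataFrame], pd.Series],
    calls: pd.DataFrame,
    meta: pd.DataFrame,
):
    """Percentage of a denominator subset satisfying a numerator predicate.

    Both predicates map the calls⋈meta frame to boolean masks; the
    numerator must select within the denominator.  Returns the rounded
    percent, or ND for an empty denominator.
    """
    merged = calls.merge(meta, on="genome_id", how="left")
    den = denominator(merged).astype(bool)
    num = numerator(merged).astype(bool)
    if (num & ~den).any():
        raise ValueError("numerator predicate selects rows outside the denominator")
    n_den = int(den.sum())
    if n_den == 0:
        return ND
    return round_half_up_pct(int(num.sum()), n_den)
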