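"""Shared builders for hand-laid-out genomes and role assignments."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_genome(
    layout: dict[str, dict[int, str]],
    genome_id: str = "G1",
    contig_len: int | dict[str, int] = 40,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a gene table plus a role-assignment table from a sketch.

    ``layout`` maps contig_id -> {ordinal: role}.  Every contig is filled
    with filler genes up to its length; coordinates are synthesised from
    the ordinal so re-sorting reproduces the sketch.
    """
    gene_rows, assign_rows = [], []
    for contig_id, roles in layout.items():
        n = contig_len[contig_id] if isinstance(contig_len, dict) else contig_len
        n = max(n, max(roles, default=0) + 1)
        for o in range(n):
            uid = f"{genome_id}_{contig_id}_{o:03d}"
            gene_rows.append(
                (genome_id, contig_id, uid, o * 1000 + 1, o * 1000 + 900, "+")
            )
            role = roles.get(o)
            if role is not None:
                for r in role.split("+"):  # "sialidase+it" style combos
                    assign_rows.append(
                        {
                            "gene_uid": uid,
                            "role": r,
                            "accessions": "TEST",
                            "best_evalue": 1e-30,
                            "pfam_confirmed": True,
                            "cdd_confirmed": True,
                            "sialidase_subtype": pd.NA,
                        }
                    )
    genes = pd.DataFrame(
        gene_rows, columns=["genome_id", "contig_id", "gene_uid", "start", "end", "strand"]
    )
    genes["ordinal"] = genes.groupby(["genome_id", "contig_id"]).cumcount()
    assignments = pd.DataFrame(
        assign_rows,
        columns=[
            "gene_uid", "role", "accessions", "best_evalue",
            "pfam_confirmed", "cdd_confirmed", "sialidase_subtype",
        ],
    )
    return genes, assignments


def random_role_genome(
    rng: np.random.Generator, genome_id: str = "R1"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A genome with core roles scattered uniformly at random (no planting
    constraints), for detector-vs-enumeration equivalence checks."""
    n_contigs = int(rng.integers(1, 3))
    layout: dict[str, dict[int, str]] = {}
    for c in range(n_contigs):
        n = int(rng.integers(25, 60))
        roles: dict[int, str] = {}
        for role, hi in (("nanA", 5), ("nanK", 4), ("nanE", 3), ("nanE_II", 2), ("rokA", 2)):
            for _ in range(int(rng.integers(0, hi))):
                roles[int(rng.integers(0, n))] = role
        layout[f"c{c + 1}"] = roles
    return make_genome(layout, genome_id=genome_id)


@pytest.fixture
def simple_cluster_genome():
    """One canonical consecutive cluster at ordinals 5..7 plus context."""
    genes, assignments = make_genome(
        {
            "c1": {
                5: "nanA", 6: "nanK", 7: "nanE",
                9: "transporter_ABC_ST3",
                3: "regulator",
            },
            "c2": {2: "nanA"},
        }
    )
    return genes, assignments
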