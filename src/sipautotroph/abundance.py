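"""Length-normalized gene abundance and MAG relative abundance.

The gene catalog (unigene) abundance of gene *k* in a library is its
mapped-read count divided by gene length, renormalized over the catalog:

    G_k = (r_k / L_k) / sum_i (r_i / L_i)

so the G values sum to 1 and are invariant to sequencing depth. Gene
length units cancel; lengths are stored in nucleotides. MAG relative
abundance is the simpler proportion of uniquely mapped, correctly
paired reads out of all reads in a metagenome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "MagMappingRecord",
    "normalize_gene_abundance",
    "mag_relative_abundance",
    "aggregate_by_taxon",
    "RANKS",
]

# standard seven-rank taxonomy path order for GeneRecord.taxon_path
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class GeneRecord:
    """A catalog gene with its mapped reads, length, and optional taxonomy.

    ``taxon_path`` lists names from kingdom downward; missing ranks are
    "unclassified". ``g_norm`` is filled by :func:`normalize_gene_abundance`.
    """

    gene_id: str
    mapped_reads: float
    length: int
    taxon_path: tuple[str, ...] = ()
    g_norm: float | None = None

    def __post_init__(self) -> None:
        if self.mapped_reads < 0:
            raise ValueError(f"mapped_reads must be >= 0, got {self.mapped_reads}")
        if self.length <= 0:
            raise ValueError(f"gene length must be positive, got {self.length}")

    def rank_name(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        i = RANKS.index(rank)
        if i < len(self.taxon_path) and self.taxon_path[i]:
            return self.taxon_path[i]
        return "unclassified"


@dataclass(frozen=True)
class MagMappingRecord:
    mag_id: str
    unique_paired_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.unique_paired_reads <= self.total_reads:
            raise ValueError(
                "unique_paired_reads must lie in [0, total_reads], got "
                f"{self.unique_paired_reads} of {self.total_reads}"
            )


def normalize_gene_abundance(records: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Fill ``g_norm`` with the length-normalized relative abundance.

    G_k = (r_k/L_k) / sum_i (r_i/L_i); zero-read genes get G_k = 0 and
    the filled values sum to 1. Raises if every gene has zero reads.
    """
    if not records:
        raise ValueError("no gene records given")
    rates = np.array([r.mapped_reads / r.length for r in records], dtype=float)
    total = rates.sum()
    if total == 0:
        raise ValueError("all genes have zero mapped reads; nothing to normalize")
    g = rates / total
    return [replace(r, g_norm=float(v)) for r, v in zip(records, g)]


def mag_relative_abundance(rec: MagMappingRecord) -> float:
    """Proportion of uniquely mapped, correctly paired reads in a metagenome."""
    if rec.total_reads == 0:
        raise ValueError("total_reads must be positive")
    return rec.unique_paired_reads / rec.total_reads


def aggregate_by_taxon(
    records: Sequence[GeneRecord],
    rank: str,
    exclude_unclassified: bool = False,
    renormalize: bool = False,
) -> pd.Series:
    """Sum normalized gene abundances per taxon at the given rank.

    Records must already carry ``g_norm``. With ``exclude_unclassified``
    genes unresolved at the kingdom level are dropped entirely (the
    convention used when summarizing read taxonomy); with
    ``renormalize`` the included taxa are rescaled to sum to 1.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    totals: dict[str, float] = {}
    for rec in records:
        if rec.g_norm is None:
            raise ValueError(f"gene {rec.gene_id} has no g_norm; normalize first")
        if exclude_unclassified and rec.rank_name("kingdom") == "unclassified":
            continue
        name = rec.rank_name(rank)
        totals[name] = totals.get(name, 0.0) + rec.g_norm
    out = pd.Series(totals, name=f"g_norm_{rank}").sort_values(ascending=False)
    if renormalize and out.sum() > 0:
        out = out / out.sum()
    return out
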