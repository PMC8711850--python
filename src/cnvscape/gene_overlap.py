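"""Intersection of CNVs with gene models and overlap aggregates.

Overlap is interval intersection in half-open coordinates on the same
scaffold; strand is ignored (CNVs are unstranded dosage events).  Means of
genes-per-CNV are taken over ALL CNVs of a type, zeros included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cnvscape.sv_io import CNVTable, GeneModel, GenomeIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapRow:
    locus_id: str
    svtype: str
    gene_ids: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class OverlapAggregates:
    n_cnvs_overlapping: int
    fraction_overlapping: float
    n_distinct_genes: int
    n_pairs: int
    mean_genes_per_cnv_by_type: dict[str, float]
    max_genes_per_cnv_by_type: dict[str, int]


@dataclass(frozen=True)
class OverlapTable:
    rows: tuple[OverlapRow, ...]  # one row per CNV, zero-overlap included
    aggregates: OverlapAggregates


def overlap_cnv_genes(
    table: CNVTable,
    genes: list[GeneModel],
    min_overlap_bp: int = 1,
    genome: GenomeIndex | None = None,
) -> OverlapTable:
    """Find (CNV, gene) interval overlaps of at least ``min_overlap_bp``.

    Genes on scaffolds absent from ``genome`` (when given) are skipped with
    a warning.  Returns one row per CNV plus catalog-level aggregates.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    usable: list[GeneModel] = []
    for g in genes:
        if genome is not None and g.scaffold not in genome:
            logger.warning("gene %s on unknown scaffold %s: skipped", g.gene_id, g.scaffold)
            continue
        usable.append(g)

    by_scaffold: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for scaffold in {g.scaffold for g in usable}:
        sub = sorted(
            (g for g in usable if g.scaffold == scaffold), key=lambda g: (g.start, g.end)
        )
        by_scaffold[scaffold] = (
            np.array([g.start for g in sub], dtype=np.int64),
            np.array([g.end for g in sub], dtype=np.int64),
            [g.gene_id for g in sub],
        )

    rows: list[OverlapRow] = []
    for r in table.records:
        hit_ids: tuple[str, ...] = ()
        entry = by_scaffold.get(r.scaffold)
        if entry is not None:
            gstarts, gends, gids = entry
            shared = np.minimum(r.end, gends) - np.maximum(r.start, gstarts)
            mask = shared >= min_overlap_bp
            hit_ids = tuple(gids[i] for i in np.flatnonzero(mask))
        rows.append(OverlapRow(locus_id=r.locus_id, svtype=r.svtype, gene_ids=hit_ids))

    agg = overlap_summary(rows, len(table.records))
    return OverlapTable(rows=tuple(rows), aggregates=agg)


def overlap_summary(rows: list[OverlapRow], n_total: int) -> OverlapAggregates:
    """Aggregate overlap rows over the whole catalog.

    Per-type means include zero-overlap CNVs; the distinct-gene count is a
    set cardinality across all rows, while ``n_pairs`` counts every
    (CNV, gene) pair once.
    """
    n_overlapping = sum(1 for r in rows if r.n_genes > 0)
    distinct: set[str] = set()
    n_pairs = 0
    for r in rows:
        distinct.update(r.gene_ids)
        n_pairs += r.n_genes
    means: dict[str, float] = {}
    maxes: dict[str, int] = {}
    for svtype in ("DEL", "DUP"):
        counts = [r.n_genes for r in rows if r.svtype == svtype]
        means[svtype] = float(np.mean(counts)) if counts else 0.0
        maxes[svtype] = max(counts) if counts else 0
    return OverlapAggregates(
        n_cnvs_overlapping=n_overlapping,
        fraction_overlapping=n_overlapping / n_total if n_total else 0.0,
        n_distinct_genes=len(distinct),
        n_pairs=n_pairs,
        mean_genes_per_cnv_by_type=means,
        max_genes_per_cnv_by_type=maxes,
    )
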