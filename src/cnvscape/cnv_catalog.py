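"""Locus filtering and catalog-level summary statistics.

A "carrier" is a sample with alternate-allele dosage >= 1 at a locus; locus
frequency is carrier frequency (carriers / non-missing samples) by default,
with an allele-frequency mode available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from cnvscape.sv_io import MISSING, CNVTable, GenomeIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CatalogSummary:
    n_total: int
    n_del: int
    n_dup: int
    mean_length: float
    per_sample_counts: dict[str, int]
    mean_per_sample: float
    min_per_sample: int
    max_per_sample: int
    mean_locus_frequency: float
    covered_bp: int
    coverage_fraction: float
    n_scaffolds_with_cnv: int

    def as_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_del": self.n_del,
            "n_dup": self.n_dup,
            "mean_length": self.mean_length,
            "mean_per_sample": self.mean_per_sample,
            "min_per_sample": self.min_per_sample,
            "max_per_sample": self.max_per_sample,
            "mean_locus_frequency": self.mean_locus_frequency,
            "covered_bp": self.covered_bp,
            "coverage_fraction": self.coverage_fraction,
            "n_scaffolds_with_cnv": self.n_scaffolds_with_cnv,
        }
        return d


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_sided: float
    mean_a: float
    mean_b: float


def filter_cnvs(
    table: CNVTable, min_length: int = 1000, min_carriers: int = 2
) -> CNVTable:
    """Keep records with length >= ``min_length`` and >= ``min_carriers``
    carrier samples.

    Singleton loci (one carrier) and reference-only loci (zero carriers)
    are removed with the defaults.  Idempotent.
    """
    if min_length < 1:
        raise ValueError(f"min_length must be >= 1, got {min_length}")
    if min_carriers < 0:
        raise ValueError(f"min_carriers must be >= 0, got {min_carriers}")
    kept = [
        r
        for r in table.records
        if r.length >= min_length and r.n_carriers() >= min_carriers
    ]
    return CNVTable(records=kept, samples=table.samples, groups=table.groups)


def per_sample_counts(
    table: CNVTable,
) -> tuple[dict[str, int], float, int, int]:
    """Per-sample number of loci carried (dosage >= 1; MISSING not counted).

    Returns ``(counts, mean, min, max)``.
    """
    m = table.dosage_matrix()  # samples x loci
    carried = (m >= 1).sum(axis=1)
    counts = {s: int(c) for s, c in zip(table.samples, carried)}
    if len(counts) == 0:
        return counts, float("nan"), 0, 0
    vals = list(counts.values())
    return counts, float(np.mean(vals)), int(min(vals)), int(max(vals))


def locus_frequencies(
    table: CNVTable, mode: str = "carrier"
) -> tuple[np.ndarray, float]:
    """Per-locus frequency and its mean over loci.

    ``mode='carrier'``: carriers / non-missing samples (default).
    ``mode='allele'``: alternate-allele dosage sum / (2 x non-missing).
    Loci with zero non-missing samples are excluded with a warning.
    """
    if mode not in ("carrier", "allele"):
        raise ValueError(f"unknown frequency mode {mode!r}")
    freqs: list[float] = []
    n_dropped = 0
    for r in table.records:
        called = [g for g in r.genotypes if g != MISSING]
        if not called:
            n_dropped += 1
            continue
        if mode == "carrier":
            freqs.append(sum(1 for g in called if g >= 1) / len(called))
        else:
            freqs.append(sum(called) / (2 * len(called)))
    if n_dropped:
        logger.warning("%d loci with zero non-missing samples excluded", n_dropped)
    arr = np.asarray(freqs, dtype=float)
    mean = float(arr.mean()) if arr.size else float("nan")
    return arr, mean


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals on one scaffold."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    total += cur_end - cur_start
    return total


def genome_coverage(table: CNVTable, genome: GenomeIndex) -> tuple[int, float]:
    """Base pairs covered by the union of CNV intervals, and the fraction of
    the assembly covered (overlapping records counted once)."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for r in table.records:
        by_scaffold.setdefault(r.scaffold, []).append((r.start, r.end))
    covered = sum(_union_length(ivs) for ivs in by_scaffold.values())
    return covered, covered / genome.total_length


def length_comparison(lengths_a: list[int], lengths_b: list[int]) -> WelchResult:
    """Welch unequal-variance t-test on two length samples.

    t > 0 when mean(a) > mean(b); call with a = duplications and
    b = deletions so a positive t reads "deletions are smaller".
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p_two_sided=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def summarize_catalog(table: CNVTable, genome: GenomeIndex) -> CatalogSummary:
    """Assemble the catalog-level summary (counts, lengths, per-sample
    burden, locus frequency, genome coverage, scaffolds hit)."""
    n_del = sum(1 for r in table.records if r.svtype == "DEL")
    n_dup = sum(1 for r in table.records if r.svtype == "DUP")
    lengths = [r.length for r in table.records]
    counts, mean_ps, min_ps, max_ps = per_sample_counts(table)
    _, mean_freq = locus_frequencies(table)
    covered, fraction = genome_coverage(table, genome)
    return CatalogSummary(
        n_total=len(table.records),
        n_del=n_del,
        n_dup=n_dup,
        mean_length=float(np.mean(lengths)) if lengths else math.nan,
        per_sample_counts=counts,
        mean_per_sample=mean_ps if lengths or counts else math.nan,
        min_per_sample=min_ps,
        max_per_sample=max_ps,
        mean_locus_frequency=mean_freq,
        covered_bp=covered,
        coverage_fraction=fraction,
        n_scaffolds_with_cnv=len({r.scaffold for r in table.records}),
    )
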