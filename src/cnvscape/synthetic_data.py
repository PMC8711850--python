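"""Truth-known synthetic fixtures: genome, gene models and a multi-sample
CNV catalog with clustered (hotspot) placement and two groups differing in
carrier frequency at planted loci.

Every artifact is a pure function of (params, seed).  Defaults are scaled
to desk size while keeping the catalog's qualitative structure: deletions
outnumber duplications ~6:1, lengths are heavy-tailed above 1 kb, a share
of loci cluster inside planted hotspots, and planted divergent loci carry a
fixed between-group carrier-frequency difference.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from cnvscape.sv_io import (
    MISSING,
    CNVRecord,
    CNVTable,
    GeneModel,
    GenomeIndex,
    write_genome_tsv,
    write_gff3,
    write_groups_tsv,
    write_vcf,
)

logger = logging.getLogger(__name__)

#: Annotation vocabulary for simulated gene products (reporting realism).
ANNOTATION_VOCABULARY = (
    "response to cold",
    "visual perception",
    "sensory perception of sound",
    "musculoskeletal movement",
    "regulation of heart rate",
    "innate immune response",
    "defense response to bacterium",
    "fatty acid metabolism",
    "muscle contraction",
    "cardiac muscle hypertrophy",
    "locomotory behavior",
    "retina development",
    "social behavior",
    "regulation of appetite",
    "response to UV",
    "regulation of circadian sleep/wake cycle",
    "skin barrier establishment",
    "heart development",
)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for the synthetic CNV catalog generator."""

    scaffold_lengths: tuple[int, ...] = (500_000_000, 400_000_000, 300_000_000)
    n_samples_per_group: int = 10
    group_labels: tuple[str, str] = ("sedentary", "migratory")
    n_loci: int = 500
    del_fraction: float = 0.863  # deletions dominate ~6:1
    length_median: float = 2_000.0  # log-normal median, bp
    length_sigma: float = 1.0
    hotspot_count: int = 5
    hotspot_width: int = 6_000_000
    hotspot_placement_weight: float = 0.6
    hotspot_min_gap: int = 20_000_000
    hotspot_edge_margin: int = 2_000_000
    bg_freq_alpha: float = 0.9
    bg_freq_beta: float = 12.0
    freq_clip: tuple[float, float] = (0.10, 0.95)
    n_divergent: int = 10
    delta_freq: float = 0.6
    divergent_base_freq: tuple[float, float] = (0.28, 0.35)
    missing_rate: float = 0.02
    n_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "del_fraction",
            "hotspot_placement_weight",
            "missing_rate",
            "delta_freq",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.scaffold_lengths) == 0:
            raise ValueError("at least one scaffold required")
        if self.n_loci < 0 or self.n_divergent < 0:
            raise ValueError("n_loci and n_divergent must be >= 0")
        if self.n_divergent > self.n_loci:
            raise ValueError("n_divergent cannot exceed n_loci")
        lo, hi = self.freq_clip
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("freq_clip must satisfy 0 < lo < hi < 1")
        dlo, dhi = self.divergent_base_freq
        if not (0.0 < dlo <= dhi < 1.0):
            raise ValueError("divergent_base_freq must satisfy 0 < lo <= hi < 1")
        if dhi + self.delta_freq > 1.0:
            raise ValueError("delta_freq not achievable given divergent_base_freq")


@dataclass(frozen=True)
class SyntheticTruth:
    hotspot_intervals: tuple[tuple[str, int, int], ...]
    divergent_locus_ids: tuple[str, ...]
    group_freqs: dict[str, tuple[float, float]]  # locus -> (freq_g1, freq_g2)
    group_labels: tuple[str, str]


def simulate_genome(params: SimulationParams, seed: int | None = None) -> GenomeIndex:
    """Build the GenomeIndex from the configured scaffold lengths."""
    del seed  # lengths are taken verbatim; kept for API symmetry
    names = tuple(f"scaffold_{i + 1}" for i in range(len(params.scaffold_lengths)))
    return GenomeIndex(names=names, lengths=tuple(params.scaffold_lengths))


def simulate_gene_models(
    genome: GenomeIndex, n_genes: int, seed: int
) -> list[GeneModel]:
    """Place non-overlapping 1-50 kb genes uniformly over the genome."""
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = np.array(genome.lengths, dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.names}
    genes: list[GeneModel] = []
    attempts = 0
    while len(genes) < n_genes and attempts < n_genes * 200 + 1000:
        attempts += 1
        si = rng.choice(len(genome.names), p=lengths / lengths.sum())
        scaffold = genome.names[si]
        glen = int(rng.integers(1_000, 50_001))
        max_start = genome.lengths[si] - glen
        if max_start <= 0:
            continue
        start = int(rng.integers(0, max_start))
        end = start + glen
        if any(s < end and start < e for s, e in placed[scaffold]):
            continue
        placed[scaffold].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        annot = ANNOTATION_VOCABULARY[int(rng.integers(0, len(ANNOTATION_VOCABULARY)))]
        genes.append(
            GeneModel(
                gene_id=f"gene_{len(genes) + 1:05d}",
                scaffold=scaffold,
                start=start,
                end=end,
                strand=strand,
                annotation=annot,
            )
        )
    if len(genes) < n_genes:
        logger.warning("placed only %d/%d genes without overlap", len(genes), n_genes)
    genes.sort(key=lambda g: (genome.rank(g.scaffold), g.start))
    return genes


def _place_hotspots(
    genome: GenomeIndex, params: SimulationParams, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    width = params.hotspot_width
    margin = params.hotspot_edge_margin
    eligible = [
        i
        for i, length in enumerate(genome.lengths)
        if length >= width + 2 * margin
    ]
    if params.hotspot_count > 0 and not eligible:
        raise ValueError(
            f"no scaffold can hold a {width} bp hotspot with {margin} bp margins"
        )
    lengths = np.array([genome.lengths[i] for i in eligible], dtype=float)
    placed: list[tuple[str, int, int]] = []
    tries = 0
    while len(placed) < params.hotspot_count:
        tries += 1
        if tries > 10_000:
            raise ValueError("cannot place hotspots with the requested gap/width")
        si = eligible[int(rng.choice(len(eligible), p=lengths / lengths.sum()))]
        scaffold = genome.names[si]
        start = int(rng.integers(margin, genome.lengths[si] - margin - width + 1))
        end = start + width
        ok = all(
            not (scaffold == s and start - params.hotspot_min_gap < e
                 and s_start < end + params.hotspot_min_gap)
            for s, s_start, e in placed
        )
        if ok:
            placed.append((scaffold, start, end))
    placed.sort(key=lambda h: (genome.rank(h[0]), h[1]))
    return placed


def _draw_length(
    params: SimulationParams, scaffold_len: int, rng: np.random.Generator
) -> int:
    mu = math.log(params.length_median)
    for _ in range(100):
        length = int(round(rng.lognormal(mu, params.length_sigma)))
        if 1_000 <= length <= scaffold_len:
            return length
    return max(1_000, min(int(round(params.length_median)), scaffold_len))


def _draw_genotypes(
    freqs_per_sample: np.ndarray,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Diploid dosages under Hardy-Weinberg from per-sample carrier freqs.

    Redraws until at least two non-missing carriers exist, so generated
    catalogs survive the singleton filter unchanged.
    """
    n = freqs_per_sample.size
    allele = 1.0 - np.sqrt(1.0 - freqs_per_sample)
    for _ in range(500):
        dosages = rng.binomial(2, allele)
        missing = rng.random(n) < missing_rate
        g = np.where(missing, MISSING, dosages)
        if int(np.sum(g >= 1)) >= 2:
            return g.astype(np.int64)
    # pathological frequency: force two carriers deterministically
    g = np.where(rng.random(n) < missing_rate, MISSING, rng.binomial(2, allele))
    idx = rng.choice(n, size=2, replace=False)
    g[idx] = 1
    return g.astype(np.int64)


def simulate_cnv_catalog(
    genome: GenomeIndex, params: SimulationParams
) -> tuple[CNVTable, SyntheticTruth]:
    """Generate the genotyped CNV catalog and its ground truth."""
    rng = np.random.default_rng(params.seed)
    g1, g2 = params.group_labels
    n_per = params.n_samples_per_group
    samples = tuple(
        [f"{g1}_{i + 1:02d}" for i in range(n_per)]
        + [f"{g2}_{i + 1:02d}" for i in range(n_per)]
    )
    groups = {s: (g1 if i < n_per else g2) for i, s in enumerate(samples)}

    hotspots = (
        _place_hotspots(genome, params, rng) if params.hotspot_count > 0 else []
    )
    n_hot = int(round(params.hotspot_placement_weight * params.n_loci)) if hotspots else 0

    scaffold_lengths = np.array(genome.lengths, dtype=float)
    p_scaffold = scaffold_lengths / scaffold_lengths.sum()

    divergent_set = set(
        rng.choice(params.n_loci, size=params.n_divergent, replace=False).tolist()
    ) if params.n_divergent else set()

    lo, hi = params.freq_clip
    draft = []  # (scaffold_rank, start, end, svtype, genotypes, is_div, fA, fB)
    for i in range(params.n_loci):
        if i < n_hot:
            hs = hotspots[int(rng.integers(0, len(hotspots)))]
            scaffold, h_start, h_end = hs
            mid = float(rng.uniform(h_start, h_end))
        else:
            si = int(rng.choice(len(genome.names), p=p_scaffold))
            scaffold = genome.names[si]
            mid = float(rng.uniform(0, genome.lengths[si]))
        slen = genome.length_of(scaffold)
        length = _draw_length(params, slen, rng)
        start = int(round(mid - length / 2))
        start = max(0, min(start, slen - length))
        end = start + length

        svtype = "DEL" if rng.random() < params.del_fraction else "DUP"

        if i in divergent_set:
            dlo, dhi = params.divergent_base_freq
            f_a = float(rng.uniform(dlo, dhi))
            f_b = min(f_a + params.delta_freq, 1.0)
        else:
            f = float(rng.beta(params.bg_freq_alpha, params.bg_freq_beta))
            f_a = f_b = float(np.clip(f, lo, hi))
        freqs = np.array([f_a] * n_per + [f_b] * n_per, dtype=float)
        genotypes = _draw_genotypes(freqs, params.missing_rate, rng)
        draft.append(
            (genome.rank(scaffold), scaffold, start, end, svtype, genotypes,
             i in divergent_set, f_a, f_b)
        )

    draft.sort(key=lambda d: (d[0], d[2], d[3]))
    records: list[CNVRecord] = []
    divergent_ids: list[str] = []
    group_freqs: dict[str, tuple[float, float]] = {}
    for j, (_, scaffold, start, end, svtype, genotypes, is_div, f_a, f_b) in enumerate(
        draft
    ):
        locus_id = f"cnv_{j + 1:05d}"
        records.append(
            CNVRecord(
                locus_id=locus_id,
                scaffold=scaffold,
                start=start,
                end=end,
                svtype=svtype,
                genotypes=tuple(int(g) for g in genotypes),
            )
        )
        group_freqs[locus_id] = (f_a, f_b)
        if is_div:
            divergent_ids.append(locus_id)

    table = CNVTable(records=records, samples=samples, groups=groups)
    truth = SyntheticTruth(
        hotspot_intervals=tuple(hotspots),
        divergent_locus_ids=tuple(divergent_ids),
        group_freqs=group_freqs,
        group_labels=params.group_labels,
    )
    return table, truth


def make_fixture_bundle(params: SimulationParams, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture bundle (VCF, GFF3, genome TSV, groups TSV,
    truth JSON) and return the paths; byte-identical for identical params."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(params)
    table, truth = simulate_cnv_catalog(genome, params)
    genes = simulate_gene_models(genome, params.n_genes, params.seed + 1_000_003)

    paths = {
        "vcf": out / "cnv.vcf",
        "gff3": out / "genes.gff3",
        "genome": out / "genome.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(table, genome, paths["vcf"])
    write_gff3(genes, paths["gff3"])
    write_genome_tsv(genome, paths["genome"])
    write_groups_tsv(table.groups or {}, paths["groups"])
    truth_json = {
        "hotspot_intervals": [list(h) for h in truth.hotspot_intervals],
        "divergent_locus_ids": list(truth.divergent_locus_ids),
        "group_freqs": {k: list(v) for k, v in truth.group_freqs.items()},
        "group_labels": list(truth.group_labels),
        "params": dataclasses.asdict(params),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
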