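"""I/O for the standard formats the pipeline touches.

All coordinates are 0-based half-open internally.  Conversion happens only
at format boundaries: VCF and GFF3 are 1-based inclusive on disk, BED is
0-based half-open (identity with the internal convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing (./.) genotype.
MISSING: int = -1

_CNV_SVTYPES = ("DEL", "DUP")


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered scaffold names and lengths defining a concatenated coordinate
    system (scaffolds laid end to end in file order)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(self.names) == 0:
            raise ValueError("GenomeIndex needs at least one scaffold")
        seen: set[str] = set()
        for name, length in zip(self.names, self.lengths):
            if name in seen:
                raise ValueError(f"duplicate scaffold name: {name!r}")
            seen.add(name)
            if length <= 0:
                raise ValueError(f"non-positive length for scaffold {name!r}: {length}")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @property
    def offsets(self) -> dict[str, int]:
        """Cumulative start of each scaffold in the concatenated genome."""
        out: dict[str, int] = {}
        acc = 0
        for name, length in zip(self.names, self.lengths):
            out[name] = acc
            acc += length
        return out

    def __contains__(self, name: str) -> bool:
        return name in self.offsets

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def rank(self, name: str) -> int:
        """Position of a scaffold in the genome order (for sorting)."""
        return self.names.index(name)


@dataclass(frozen=True)
class CNVRecord:
    """A single CNV locus with per-sample diploid alternate-allele dosages.

    ``genotypes[i]`` is 0, 1 or 2 for sample ``i``, or :data:`MISSING`.
    """

    locus_id: str
    scaffold: str
    start: int
    end: int
    svtype: str
    genotypes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"record {self.locus_id}: end ({self.end}) <= start ({self.start})"
            )
        if self.svtype not in _CNV_SVTYPES:
            raise ValueError(f"record {self.locus_id}: svtype {self.svtype!r}")
        for g in self.genotypes:
            if g not in (0, 1, 2, MISSING):
                raise ValueError(f"record {self.locus_id}: bad dosage {g}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def n_carriers(self) -> int:
        return sum(1 for g in self.genotypes if g >= 1)

    def n_called(self) -> int:
        return sum(1 for g in self.genotypes if g != MISSING)


@dataclass
class CNVTable:
    """A multi-sample CNV catalog sharing one sample ordering."""

    records: list[CNVRecord]
    samples: tuple[str, ...]
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [r.locus_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("locus_ids are not unique")
        for r in self.records:
            if len(r.genotypes) != len(self.samples):
                raise ValueError(
                    f"record {r.locus_id}: {len(r.genotypes)} genotypes for "
                    f"{len(self.samples)} samples"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def locus_ids(self) -> list[str]:
        return [r.locus_id for r in self.records]

    def dosage_matrix(self) -> np.ndarray:
        """samples x loci int matrix with :data:`MISSING` for no-calls."""
        if not self.records:
            return np.zeros((len(self.samples), 0), dtype=np.int8)
        return np.array([r.genotypes for r in self.records], dtype=np.int8).T


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Readers


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Read scaffold names/lengths from a FASTA ``.fai`` or 2-column TSV.

    Dialect is auto-detected by column count; only the first two columns
    (name, length) are used either way.  Scaffolds keep file order.
    """
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            name = cols[0]
            try:
                length = int(cols[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {cols[1]!r}"
                ) from None
            names.append(name)
            lengths.append(length)
    return GenomeIndex(tuple(names), tuple(lengths))


def _dosage_from_gt(alleles: Sequence[int], alt_index: int) -> int:
    if len(alleles) == 0 or alleles[0] < 0:
        return MISSING
    return sum(1 for a in alleles if a == alt_index)


def read_sv_vcf(path: str | Path, genome: GenomeIndex) -> CNVTable:
    """Read a LUMPY/svtyper-dialect SV VCF into a :class:`CNVTable`.

    Only DEL/DUP rows are kept; other SVTYPEs (INV, BND, INS, ...) are
    counted and skipped.  1-based inclusive POS/END become 0-based
    half-open [POS-1, END).  Multi-allelic rows are split per ALT with
    suffixed locus ids.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    records: list[CNVRecord] = []
    skipped: dict[str, int] = {}
    n_row = 0
    for variant in vcf:
        n_row += 1
        svtype = variant.INFO.get("SVTYPE")
        if svtype not in _CNV_SVTYPES:
            skipped[str(svtype)] = skipped.get(str(svtype), 0) + 1
            continue
        if variant.CHROM not in genome:
            raise ValueError(
                f"record at {variant.CHROM}:{variant.POS} on scaffold absent "
                f"from the genome index"
            )
        pos = variant.POS  # 1-based
        end = variant.INFO.get("END")
        if end is None:
            raise ValueError(f"record at {variant.CHROM}:{pos}: no END in INFO")
        end = int(end)
        rid = variant.ID if variant.ID not in (None, ".") else f"cnv_{n_row}"
        if end <= pos - 1:
            raise ValueError(f"record {rid}: END ({end}) <= POS ({pos})")
        n_alts = max(1, len(variant.ALT))
        gts = variant.genotypes  # [a0, a1, phased] per sample
        for alt_i in range(n_alts):
            locus_id = rid if n_alts == 1 else f"{rid}_{alt_i + 1}"
            dosages = tuple(
                _dosage_from_gt(gt[:-1], alt_i + 1) for gt in gts
            )
            records.append(
                CNVRecord(
                    locus_id=locus_id,
                    scaffold=variant.CHROM,
                    start=pos - 1,
                    end=end,
                    svtype=svtype,
                    genotypes=dosages,
                )
            )
    if skipped:
        logger.info(
            "skipped non-CNV rows: %s",
            ", ".join(f"{k}={v}" for k, v in sorted(skipped.items())),
        )
    return CNVTable(records=records, samples=samples)


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(
    path: str | Path, feature_types: Iterable[str] = ("gene",)
) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Rows whose type is in ``feature_types`` are kept; coordinates convert
    from 1-based inclusive to 0-based half-open.  A missing ID attribute
    yields a synthesized ``gene_<line>`` id and a warning.
    """
    wanted = set(feature_types)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            if cols[2] not in wanted:
                continue
            attrs = _parse_gff_attributes(cols[8])
            gene_id = attrs.get("ID")
            if gene_id is None:
                gene_id = f"gene_{lineno}"
                logger.warning("%s:%d: no ID attribute, using %s", path, lineno, gene_id)
            annotation = attrs.get("product", attrs.get("Note", ""))
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    scaffold=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in ("+", "-") else ".",
                    annotation=annotation,
                )
            )
    return genes


def read_groups_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column sample -> group TSV (header optional)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                continue
            if cols[0].lower() in ("sample", "sample_id", "individual"):
                continue
            groups[cols[0]] = cols[1]
    return groups


# ---------------------------------------------------------------------------
# Writers


def write_bed(
    intervals: Iterable[tuple],
    path: str | Path,
    genome: GenomeIndex | None = None,
) -> None:
    """Write intervals as BED (0-based half-open, no conversion needed).

    Each interval is ``(scaffold, start, end[, name[, score]])``.  Output is
    sorted by genome order (if given, else scaffold name), then start.
    """
    rows = [tuple(iv) for iv in intervals]
    if genome is not None:
        order = {name: i for i, name in enumerate(genome.names)}
        rows.sort(key=lambda r: (order.get(r[0], len(order)), r[1], r[2]))
    else:
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: CNVTable, genome: GenomeIndex, path: str | Path) -> None:
    """Write a CNVTable as a minimal svtyper-dialect VCF 4.2 (plain text).

    Deterministic output: no timestamps, records in genome order then start.
    """
    order = {name: i for i, name in enumerate(genome.names)}
    records = sorted(
        table.records, key=lambda r: (order[r.scaffold], r.start, r.locus_id)
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in zip(genome.names, genome.lengths):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">\n'
        )
        fh.write(
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">\n'
        )
        fh.write(
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for r in records:
            svlen = r.length if r.svtype == "DUP" else -r.length
            info = f"SVTYPE={r.svtype};END={r.end};SVLEN={svlen}"
            gts = "\t".join(_GT_BY_DOSAGE[g] for g in r.genotypes)
            fh.write(
                f"{r.scaffold}\t{r.start + 1}\t{r.locus_id}\tN\t<{r.svtype}>\t"
                f".\t.\t{info}\tGT\t{gts}\n"
            )


def write_genome_tsv(genome: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.names, genome.lengths):
            fh.write(f"{name}\t{length}\n")


def write_groups_tsv(groups: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.annotation:
                attrs += f";product={g.annotation}"
            fh.write(
                f"{g.scaffold}\tcnvscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
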