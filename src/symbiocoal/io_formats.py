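"""Readers, writers and site-level filters for the on-disk formats the pipeline touches.

All on-disk coordinates are 1-based inclusive (pileup/VCF convention). Columns
containing gaps or N in a multi-sample alignment are excluded from the variant
catalogue, and diversity denominators downstream use the usable (non-excluded)
length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class AlignmentError(ValueError):
    """Records in a multi-FASTA do not form a rectangular alignment."""


class FormatError(ValueError):
    """A file is structurally unusable (empty, truncated, malformed token)."""


@dataclass(frozen=True)
class SiteRecord:
    """One VCF-style site with the quantities the consensus filters act on.

    ``quality_by_depth`` is the QD ratio, ``fisher_strand`` the phred-scaled
    strand-bias score (FS), ``genotype_quality`` the nominal GQ and
    ``mq0_reads`` the count of mapping-quality-zero reads at the site.
    """

    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    quality_by_depth: float | None = None
    fisher_strand: float | None = None
    genotype_quality: float | None = None
    mq0_reads: int | None = None
    allele_number: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.mq0_reads is not None and self.mq0_reads < 0:
            raise ValueError("mq0_reads must be >= 0")
        if self.genotype_quality is not None and self.genotype_quality < 0:
            raise ValueError("genotype_quality must be >= 0")


@dataclass
class HaplotypeAlignment:
    """Equal-length haplotype/consensus sequences with optional host labels."""

    sample_ids: list[str]
    sequences: list[str]
    host_ids: list[str] | None = None
    genome_length: int = 0
    variant_positions: list[int] = field(default_factory=list)
    excluded_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.genome_length == 0:
            self.genome_length = len(self.sequences[0])
        if not self.variant_positions and not self.excluded_positions:
            self.variant_positions, self.excluded_positions = _scan_columns(self.sequences)
        if any(
            a >= b for a, b in zip(self.variant_positions, self.variant_positions[1:])
        ):
            raise AlignmentError("variant_positions must be strictly increasing")
        if self.variant_positions and not (
            1 <= self.variant_positions[0] and self.variant_positions[-1] <= self.genome_length
        ):
            raise AlignmentError("variant_positions out of [1, genome_length]")

    @property
    def n_samples(self) -> int:
        return len(self.sequences)

    @property
    def usable_length(self) -> int:
        """Genome length minus columns excluded for gaps/ambiguity."""
        return self.genome_length - len(self.excluded_positions)

    def column(self, position: int) -> str:
        """Alignment column at a 1-based position, one character per sample."""
        i = position - 1
        return "".join(s[i] for s in self.sequences)


def _scan_columns(sequences: Sequence[str]) -> tuple[list[int], list[int]]:
    variant, excluded = [], []
    for i in range(len(sequences[0])):
        col = {s[i] for s in sequences}
        if col - _VALID_BASES:
            excluded.append(i + 1)
        elif len(col) > 1:
            variant.append(i + 1)
    return variant, excluded


def read_fasta_alignment(
    path: str | Path, host_map: Mapping[str, str] | None = None
) -> HaplotypeAlignment:
    """Read a multi-FASTA into a :class:`HaplotypeAlignment`.

    Sequences are upper-cased; gap characters are preserved but their columns
    are excluded from ``variant_positions``. ``host_map`` optionally assigns a
    host label per sample id.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    hosts = [host_map[i] for i in ids] if host_map is not None else None
    return HaplotypeAlignment(sample_ids=ids, sequences=seqs, host_ids=hosts)


def write_fasta_alignment(aln: HaplotypeAlignment, path: str | Path) -> None:
    """Write an alignment as FASTA wrapped at 80 columns."""
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.sample_ids, aln.sequences)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

@dataclass
class PileupColumn:
    """One decoded 6-column mpileup line."""

    chrom: str
    position: int
    ref_base: str
    depth: int
    base_calls: str          # decoded to one character per read: .,ACGTacgt*
    base_qualities: str
    has_indel: bool = False  # an indel token (+n/-n) or deletion placeholder seen here

    def __post_init__(self) -> None:
        if self.depth != len(self.base_calls):
            raise FormatError(
                f"pileup column {self.position}: depth {self.depth} != "
                f"{len(self.base_calls)} decoded calls"
            )
        if len(self.base_qualities) != len(self.base_calls):
            raise FormatError(
                f"pileup column {self.position}: quality string length mismatch"
            )

    def allele_counts(self) -> dict[str, int]:
        """Counts of reference ('.') vs each alternate base, strand-collapsed."""
        counts: dict[str, int] = {}
        for c in self.base_calls:
            key = "." if c in ".," else c.upper()
            counts[key] = counts.get(key, 0) + 1
        return counts


_INDEL_RE = re.compile(r"[+-](\d+)")


def decode_pileup_bases(raw: str, position: int | None = None) -> tuple[str, bool]:
    """Decode an mpileup base string to one character per aligned read.

    Read-start markers (``^`` plus one mapping-quality character) and read-end
    markers (``$``) are consumed; indel tokens (``+n``/``-n`` plus n bases) are
    consumed and flag the column as indel-bearing. Returns
    ``(decoded_calls, has_indel)``.
    """
    out: list[str] = []
    has_indel = False
    i, n = 0, len(raw)
    while i < n:
        c = raw[i]
        if c == "^":
            i += 2  # mapping-quality char after ^ consumed and discarded
        elif c == "$":
            i += 1
        elif c in "+-":
            m = _INDEL_RE.match(raw, i)
            if m is None:
                where = f" at position {position}" if position else ""
                raise FormatError(f"malformed indel length token{where}: {raw[i:i+6]!r}")
            length = int(m.group(1))
            i = m.end() + length
            has_indel = True
        else:
            if c == "*":
                has_indel = True
            out.append(c)
            i += 1
    return "".join(out), has_indel


def parse_pileup(path: str | Path) -> list[PileupColumn]:
    """Parse a 6-column samtools mpileup text file."""
    columns: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"line {lineno}: expected 6 pileup columns")
            chrom, pos, ref, depth, bases, quals = parts[:6]
            try:
                decoded, has_indel = decode_pileup_bases(bases, int(pos))
            except FormatError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            columns.append(
                PileupColumn(
                    chrom=chrom,
                    position=int(pos),
                    ref_base=ref.upper(),
                    depth=int(depth),
                    base_calls=decoded,
                    base_qualities=quals,
                    has_indel=has_indel,
                )
            )
    return columns


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    """Serialize columns back to 6-column pileup text (decoded base strings)."""
    with open(path, "w") as fh:
        for col in columns:
            fh.write(
                f"{col.chrom}\t{col.position}\t{col.ref_base}\t{col.depth}\t"
                f"{col.base_calls}\t{col.base_qualities}\n"
            )


# ---------------------------------------------------------------------------
# VCF-style site filtering
# ---------------------------------------------------------------------------

#: thresholds for consensus genotyping: QD >= 2, FS <= 60, GQ >= 20, MQ0 <= 5
GENOTYPING_THRESHOLDS = {"qd_min": 2.0, "fs_max": 60.0, "gq_min": 20.0, "mq0_max": 5}
#: the relaxed screen used before four-gamete analysis: biallelic SNPs, GQ >= 10
FOURGAMETE_GQ_MIN = 10.0


def filter_consensus_sites(
    records: Iterable[SiteRecord], mode: str = "genotyping"
) -> list[SiteRecord]:
    """Apply the per-site threshold filter in either of its two modes.

    ``genotyping`` keeps records with quality/depth >= 2, Fisher strand <= 60,
    genotype quality >= 20 and at most 5 mapping-quality-zero reads.
    ``fourgamete`` keeps biallelic single-nucleotide records with genotype
    quality >= 10. Records missing a required field are dropped with a counted
    warning rather than raising.
    """
    if mode not in ("genotyping", "fourgamete"):
        raise ValueError(f"unknown filter mode {mode!r}")
    kept: list[SiteRecord] = []
    n_missing = 0
    for rec in records:
        if mode == "genotyping":
            fields = (
                rec.quality_by_depth,
                rec.fisher_strand,
                rec.genotype_quality,
                rec.mq0_reads,
            )
            if any(f is None for f in fields):
                n_missing += 1
                continue
            if (
                rec.quality_by_depth >= GENOTYPING_THRESHOLDS["qd_min"]
                and rec.fisher_strand <= GENOTYPING_THRESHOLDS["fs_max"]
                and rec.genotype_quality >= GENOTYPING_THRESHOLDS["gq_min"]
                and rec.mq0_reads <= GENOTYPING_THRESHOLDS["mq0_max"]
            ):
                kept.append(rec)
        else:
            if rec.genotype_quality is None:
                n_missing += 1
                continue
            biallelic_snv = (
                len(rec.alt_alleles) == 1
                and len(rec.ref_allele) == 1
                and len(rec.alt_alleles[0]) == 1
            )
            if biallelic_snv and rec.genotype_quality >= FOURGAMETE_GQ_MIN:
                kept.append(rec)
    if n_missing:
        logger.warning("filter_consensus_sites: %d records dropped for missing fields", n_missing)
    return kept


def read_vcf_sites(path: str | Path) -> list[SiteRecord]:
    """Ingest SiteRecords from a VCF (INFO QD/FS/MQ0/AN; FORMAT GQ).

    Unknown INFO keys are ignored. GQ is taken as the minimum over samples when
    several are present, the conservative per-site reading.
    """
    import pysam

    records: list[SiteRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gq: float | None = None
            gqs = [
                s["GQ"]
                for s in rec.samples.values()
                if "GQ" in s and s["GQ"] is not None
            ]
            if gqs:
                gq = float(min(gqs))
            info = rec.info
            records.append(
                SiteRecord(
                    position=rec.pos,
                    ref_allele=rec.ref or "",
                    alt_alleles=tuple(a for a in (rec.alts or ()) if a is not None),
                    quality_by_depth=_maybe_float(info.get("QD")),
                    fisher_strand=_maybe_float(info.get("FS")),
                    genotype_quality=gq,
                    mq0_reads=_maybe_int(info.get("MQ0")),
                    allele_number=_maybe_int(info.get("AN")),
                )
            )
    return records


def _maybe_float(v) -> float | None:
    if v is None:
        return None
    if isinstance(v, tuple):
        v = v[0]
    return float(v)


def _maybe_int(v) -> int | None:
    if v is None:
        return None
    if isinstance(v, tuple):
        v = v[0]
    return int(v)


def write_vcf_sites(
    records: Sequence[SiteRecord], path: str | Path, contig: str = "ref", contig_length: int | None = None
) -> None:
    """Write SiteRecords as a minimal single-sample VCF v4.2 text file."""
    length = contig_length or (max((r.position for r in records), default=1))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=MQ0,Number=1,Type=Integer,Description="MQ0 read count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample0\n")
        for r in records:
            info_parts = []
            if r.quality_by_depth is not None:
                info_parts.append(f"QD={r.quality_by_depth:g}")
            if r.fisher_strand is not None:
                info_parts.append(f"FS={r.fisher_strand:g}")
            if r.mq0_reads is not None:
                info_parts.append(f"MQ0={r.mq0_reads}")
            if r.allele_number is not None:
                info_parts.append(f"AN={r.allele_number}")
            info = ";".join(info_parts) or "."
            gq = int(r.genotype_quality) if r.genotype_quality is not None else "."
            alt = ",".join(r.alt_alleles) or "."
            fh.write(
                f"{contig}\t{r.position}\t.\t{r.ref_allele}\t{alt}\t.\t.\t{info}\tGQ\t{gq}\n"
            )
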