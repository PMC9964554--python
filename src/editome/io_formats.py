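"""Readers and writers for the formats the pipeline touches.

Coordinates are 1-based inclusive everywhere inside the package (GTF/VCF
native); the only 0-based conversion happens when writing BED.  Pileup
counts are in forward-reference orientation and strand-agnostic.
"""
from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._utils import BASES

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True, slots=True)
class PileupRecord:
    """Per-position base tally for one sample and one source (DNA or RNA)."""

    chrom: str
    pos: int  # 1-based
    sample_id: str
    source: str  # "DNA" | "RNA"
    counts_a: int
    counts_c: int
    counts_g: int
    counts_t: int
    mean_qual: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.source not in ("DNA", "RNA"):
            raise ValueError(f"source must be DNA or RNA, got {self.source!r}")
        for b, n in zip(BASES, (self.counts_a, self.counts_c, self.counts_g, self.counts_t)):
            if n < 0:
                raise ValueError(f"negative count for {b} at {self.chrom}:{self.pos}")

    @property
    def coverage(self) -> int:
        return self.counts_a + self.counts_c + self.counts_g + self.counts_t

    def count(self, base: str) -> int:
        return {
            "A": self.counts_a,
            "C": self.counts_c,
            "G": self.counts_g,
            "T": self.counts_t,
        }[base]

    def base_counts(self) -> dict[str, int]:
        return {b: self.count(b) for b in BASES}


@dataclasses.dataclass(slots=True)
class Transcript:
    """One transcript model; all intervals 1-based inclusive, sorted."""

    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    utr5: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    utr3: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    cds_incomplete: bool = False  # CDS length not a multiple of 3 (flagged, kept)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclasses.dataclass(slots=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    biotype: str = "protein_coding"
    gene_name: str | None = None
    transcripts: list[Transcript] = dataclasses.field(default_factory=list)

    @property
    def start(self) -> int:
        """Gene-body start: leftmost exon base over all transcripts."""
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclasses.dataclass(slots=True)
class VariantSet:
    """Known SNP positions and INDEL intervals used to mask candidates."""

    snps: set[tuple[str, int]] = dataclasses.field(default_factory=set)
    indels: set[tuple[str, int, int]] = dataclasses.field(default_factory=set)

    def covers(self, chrom: str, pos: int) -> bool:
        if (chrom, pos) in self.snps:
            return True
        return any(c == chrom and s <= pos <= e for c, s, e in self.indels)


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into ``{name: uppercase sequence}``.

    The key is the header token before the first whitespace.  Duplicate
    records and empty files are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# GTF (Ensembl dialect)
# --------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;')

_GTF_FEATURES = {"gene", "transcript", "exon", "CDS", "five_prime_utr", "three_prime_utr"}


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    Intervals are kept 1-based inclusive exactly as written.  UTRs are
    pass-through: they are stored only when annotated, never inferred.
    CDS totals that are not multiples of 3 are flagged on the transcript,
    not rejected.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_field = fields[:9]
            if feature not in _GTF_FEATURES:
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attr_field)
            start_i, end_i = int(start), int(end)

            if feature == "gene":
                gid = attrs["gene_id"]
                genes[gid] = GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    biotype=attrs.get("gene_biotype", "other"),
                    gene_name=attrs.get("gene_name"),
                )
            elif feature == "transcript":
                tid = attrs["transcript_id"]
                transcripts[tid] = Transcript(transcript_id=tid, exons=[])
                tx_gene[tid] = attrs["gene_id"]
            else:
                tid = attrs.get("transcript_id")
                if tid is None or tid not in transcripts:
                    raise ValueError(
                        f"{path}:{lineno}: {feature} without parent transcript"
                    )
                tx = transcripts[tid]
                iv = (start_i, end_i)
                if feature == "exon":
                    tx.exons.append(iv)
                elif feature == "CDS":
                    tx.cds.append(iv)
                elif feature == "five_prime_utr":
                    tx.utr5.append(iv)
                else:
                    tx.utr3.append(iv)

    for tid, tx in transcripts.items():
        gid = tx_gene[tid]
        if gid not in genes:
            raise ValueError(f"transcript {tid} references unknown gene {gid}")
        for name in ("exons", "cds", "utr5", "utr3"):
            getattr(tx, name).sort()
        _validate_transcript(tx)
        tx.cds_incomplete = bool(tx.cds) and tx.cds_length % 3 != 0
        genes[gid].transcripts.append(tx)

    return [g for g in genes.values() if g.transcripts]


def _validate_transcript(tx: Transcript) -> None:
    if not tx.exons:
        raise ValueError(f"transcript {tx.transcript_id} has no exons")
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping exons in transcript {tx.transcript_id}")
    for kind in ("cds", "utr5", "utr3"):
        for s, e in getattr(tx, kind):
            if not any(es <= s and e <= ee for es, ee in tx.exons):
                raise ValueError(
                    f"{kind} interval {s}-{e} of {tx.transcript_id} not contained in an exon"
                )


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene models as Ensembl-dialect GTF (round-trips through read_gtf)."""

    def attrs(gene: GeneModel, tid: str | None = None) -> str:
        parts = [f'gene_id "{gene.gene_id}"']
        if tid:
            parts.append(f'transcript_id "{tid}"')
        parts.append(f'gene_biotype "{gene.biotype}"')
        if gene.gene_name:
            parts.append(f'gene_name "{gene.gene_name}"')
        return "; ".join(parts) + ";"

    with open(path, "w") as fh:
        for g in genes:
            row = [g.chrom, "editome", "gene", str(g.start), str(g.end), ".", g.strand, "."]
            fh.write("\t".join(row + [attrs(g)]) + "\n")
            for tx in g.transcripts:
                row = [g.chrom, "editome", "transcript", str(tx.start), str(tx.end), ".", g.strand, "."]
                fh.write("\t".join(row + [attrs(g, tx.transcript_id)]) + "\n")
                for feature, ivs in (
                    ("exon", tx.exons),
                    ("CDS", tx.cds),
                    ("five_prime_utr", tx.utr5),
                    ("three_prime_utr", tx.utr3),
                ):
                    for s, e in ivs:
                        row = [g.chrom, "editome", feature, str(s), str(e), ".", g.strand, "."]
                        fh.write("\t".join(row + [attrs(g, tx.transcript_id)]) + "\n")


# --------------------------------------------------------------------------
# VCF (positions only)
# --------------------------------------------------------------------------


def read_vcf_positions(path: str | Path) -> VariantSet:
    """Extract SNP positions and INDEL intervals from a VCF v4.x file.

    A SNP has REF and ALT both of length 1; anything else spans
    ``(POS, POS + max(len(REF), len(ALT)) - 1)``.  Multiallelic lines
    contribute one entry per ALT allele.
    """
    out = VariantSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: malformed VCF line (<5 columns)")
            chrom, pos_s, _vid, ref, alt_field = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer POS {pos_s!r}") from None
            if pos < 1 or not ref:
                raise ValueError(f"{path}:{lineno}: malformed VCF line")
            for alt in alt_field.split(","):
                if alt in (".", "") or alt.startswith("<"):
                    continue
                if len(ref) == 1 and len(alt) == 1:
                    out.snps.add((chrom, pos))
                else:
                    out.indels.add((chrom, pos, pos + max(len(ref), len(alt)) - 1))
    return out


def write_vcf(snps: Iterable[tuple[str, int, str, str, str]], path: str | Path) -> None:
    """Write a minimal VCF v4.2 of SNPs: (chrom, pos, ref, alt, genotype)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GT,Number=1,Type=String,Description="Planted genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, gt in snps:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tGT={gt}\n")


# --------------------------------------------------------------------------
# pileup TSV dialect
# --------------------------------------------------------------------------

PILEUP_HEADER = ["chrom", "pos", "sample", "source", "A", "C", "G", "T", "mean_qual"]


def write_pileup_tsv(records: Iterable[PileupRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.sample_id}\t{r.source}\t"
                f"{r.counts_a}\t{r.counts_c}\t{r.counts_g}\t{r.counts_t}\t{r.mean_qual!r}\n"
            )


def read_pileup_tsv(path: str | Path) -> list[PileupRecord]:
    records: list[PileupRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PILEUP_HEADER:
            raise ValueError(f"{path}: unexpected pileup header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            try:
                records.append(
                    PileupRecord(
                        chrom=f[0],
                        pos=int(f[1]),
                        sample_id=f[2],
                        source=f[3],
                        counts_a=int(f[4]),
                        counts_c=int(f[5]),
                        counts_g=int(f[6]),
                        counts_t=int(f[7]),
                        mean_qual=float(f[8]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


# --------------------------------------------------------------------------
# BED output
# --------------------------------------------------------------------------


def write_sites_bed(sites: Iterable, path: str | Path) -> None:
    """Write sites as BED6: 0-based half-open, name = canonical class.

    Accepts any objects exposing chrom, pos, canonical_class and
    resolved_strand; an ambiguous strand is emitted as ".".
    """
    with open(path, "w") as fh:
        for s in sites:
            strand = s.resolved_strand if s.resolved_strand in ("+", "-") else "."
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.canonical_class}\t.\t{strand}\n")


# --------------------------------------------------------------------------
# samtools mpileup conversion
# --------------------------------------------------------------------------


def _parse_mpileup_bases(bases: str, ref: str) -> dict[str, int]:
    counts = dict.fromkeys(BASES, 0)
    ref = ref.upper()
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":  # read start: next char is mapping quality
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":  # indel: length digits then sequence
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            i = j + int(bases[i + 1 : j])
            continue
        if c in ".,":
            if ref in counts:
                counts[ref] += 1
        elif c.upper() in counts:
            counts[c.upper()] += 1
        i += 1
    return counts


def convert_mpileup(path: str | Path, sample_id: str, source: str) -> list[PileupRecord]:
    """Convert `samtools mpileup` text output to pileup records.

    Expects the default 6-column layout (chrom, pos, ref, depth, bases,
    quals).  Read-level filters (unknown-base and low-quality fractions)
    are upstream responsibility and are not re-applied here.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 mpileup columns")
            chrom, pos, ref, _depth, bases, quals = f[:6]
            counts = _parse_mpileup_bases(bases, ref)
            mean_qual = (
                sum(ord(q) - 33 for q in quals) / len(quals) if quals and quals != "*" else 0.0
            )
            records.append(
                PileupRecord(
                    chrom=chrom,
                    pos=int(pos),
                    sample_id=sample_id,
                    source=source,
                    counts_a=counts["A"],
                    counts_c=counts["C"],
                    counts_g=counts["G"],
                    counts_t=counts["T"],
                    mean_qual=round(mean_qual, 2),
                )
            )
    return records
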