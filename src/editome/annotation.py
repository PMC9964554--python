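"""Strand resolution, canonical classification and feature assignment.

Libraries here are unstranded, so the editing class of a raw base change
can only be resolved through the strand of the hosting gene: A>G in a
plus-strand gene and T>C in a minus-strand gene are both A-to-I; C>T in a
plus-strand gene and G>A in a minus-strand gene are both C-to-U.  Sites
without a host gene, or hosted by genes on both strands, stay ambiguous.
"""
from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from ._utils import BASES, percent
from .detection import EditingObservation, SiteCall
from .io_formats import GeneModel, Transcript

A_TO_I = "A-to-I"
C_TO_U = "C-to-U"
OTHER = "other"
AMBIGUOUS = "ambiguous"

FEATURES = ("CDS", "5'UTR", "3'UTR", "exon_other", "intron", "intergenic")
_FEATURE_RANK = {f: i for i, f in enumerate(FEATURES)}


@dataclasses.dataclass(slots=True)
class GenomicSite:
    """A unique edited genomic position with resolved strand, class and feature."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    resolved_strand: str = "*"  # "+" | "-" | "*"
    canonical_class: str = AMBIGUOUS
    feature: str = "intergenic"
    host_genes: list[str] = dataclasses.field(default_factory=list)
    host_transcripts: list[str] = dataclasses.field(default_factory=list)
    biotype: str | None = None
    n_samples: int = 0
    mean_level: float = float("nan")

    @property
    def raw_type(self) -> str:
        return self.ref_base + self.alt_base

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def classify_on_strand(ref_base: str, alt_base: str, strand: str) -> str:
    """Canonical class of a raw base change assuming the gene strand is known."""
    raw = ref_base + alt_base
    if (raw, strand) in (("AG", "+"), ("TC", "-")):
        return A_TO_I
    if (raw, strand) in (("CT", "+"), ("GA", "-")):
        return C_TO_U
    return OTHER


def resolve_class(
    ref_base: str, alt_base: str, host_gene_strands: Iterable[str]
) -> tuple[str, str]:
    """Resolve (canonical_class, strand) from the strands of hosting genes.

    With a single host strand the strand-collapse rule applies directly.
    With no host gene or hosts on both strands the strand is "*" and the
    class is ambiguous unless the raw type resolves identically on both
    strands (which only happens for non-canonical changes, mapped to
    "other").
    """
    for b in (ref_base, alt_base):
        if b not in BASES:
            raise ValueError(f"invalid base {b!r}")
    if ref_base == alt_base:
        raise ValueError("ref and alt bases must differ")
    strands = set(host_gene_strands)
    if not strands <= {"+", "-"}:
        raise ValueError(f"invalid strand in {strands}")
    if len(strands) == 1:
        strand = strands.pop()
        return classify_on_strand(ref_base, alt_base, strand), strand
    on_plus = classify_on_strand(ref_base, alt_base, "+")
    on_minus = classify_on_strand(ref_base, alt_base, "-")
    return (on_plus if on_plus == on_minus else AMBIGUOUS), "*"


class GeneIndex:
    """Gene-body interval lookup (min exon start to max exon end per gene)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = defaultdict(list)
        for g in genes:
            self._by_chrom[g.chrom].append((g.start, g.end, g))
        for entries in self._by_chrom.values():
            entries.sort(key=lambda t: t[:2])

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        return [g for s, e, g in self._by_chrom.get(chrom, []) if s <= pos <= e]


def _transcript_feature(pos: int, tx: Transcript) -> str | None:
    """Feature of a position within one transcript, or None if outside its span."""
    if not (tx.start <= pos <= tx.end):
        return None
    if any(s <= pos <= e for s, e in tx.cds):
        return "CDS"
    if any(s <= pos <= e for s, e in tx.utr5):
        return "5'UTR"
    if any(s <= pos <= e for s, e in tx.utr3):
        return "3'UTR"
    if any(s <= pos <= e for s, e in tx.exons):
        return "exon_other"
    return "intron"


def assign_feature(
    chrom: str, pos: int, host_genes: Sequence[GeneModel]
) -> tuple[str, list[str]]:
    """Highest-precedence feature over all hosting transcripts.

    Precedence: CDS > 5'UTR > 3'UTR > exon_other > intron; a site inside a
    gene body but outside every transcript span falls back to intron; no
    host gene at all means intergenic.
    """
    if not host_genes:
        return "intergenic", []
    best = "intron"
    hosting_tx: list[str] = []
    for gene in host_genes:
        for tx in gene.transcripts:
            feat = _transcript_feature(pos, tx)
            if feat is None:
                continue
            hosting_tx.append(tx.transcript_id)
            if _FEATURE_RANK[feat] < _FEATURE_RANK[best]:
                best = feat
    return best, hosting_tx


def annotate_sites(
    site_calls: Sequence[SiteCall], genes: Sequence[GeneModel]
) -> list[GenomicSite]:
    """Attach strand, canonical class, feature and host genes to site calls."""
    index = GeneIndex(genes)
    annotated: list[GenomicSite] = []
    for call in site_calls:
        hosts = index.overlapping(call.chrom, call.pos)
        cls, strand = resolve_class(call.ref_base, call.alt_base, {g.strand for g in hosts})
        feature, host_tx = assign_feature(call.chrom, call.pos, hosts)
        biotypes = sorted({g.biotype for g in hosts})
        annotated.append(
            GenomicSite(
                chrom=call.chrom,
                pos=call.pos,
                ref_base=call.ref_base,
                alt_base=call.alt_base,
                resolved_strand=strand,
                canonical_class=cls,
                feature=feature,
                host_genes=[g.gene_id for g in hosts],
                host_transcripts=host_tx,
                biotype=";".join(biotypes) if biotypes else None,
                n_samples=call.n_samples,
                mean_level=call.mean_level,
            )
        )
    return annotated


def combine_raw_type_shares(raw_shares: dict[str, float], ndigits: int = 2) -> dict[str, float]:
    """Collapse per-raw-type percentage shares into canonical class shares.

    AG and TC fold into A-to-I, CT and GA into C-to-U; everything else is
    pooled into "other".
    """
    from ._utils import round_half_up

    a = raw_shares.get("AG", 0.0) + raw_shares.get("TC", 0.0)
    c = raw_shares.get("CT", 0.0) + raw_shares.get("GA", 0.0)
    rest = sum(v for k, v in raw_shares.items() if k not in ("AG", "TC", "CT", "GA"))
    return {
        A_TO_I: round_half_up(a, ndigits),
        C_TO_U: round_half_up(c, ndigits),
        OTHER: round_half_up(rest, ndigits),
    }


def class_count_summary(
    sites: Sequence[GenomicSite],
    observations: Sequence[EditingObservation] | None = None,
) -> dict:
    """Counts and percentages by raw type, canonical class and strand.

    Percentages use the non-redundant site total as denominator.  When
    observations are supplied, the per-sample median count of each raw
    type is also reported together with its share of the median total.
    """
    total = len(sites)
    raw_counts = Counter(s.raw_type for s in sites)
    class_counts = Counter(s.canonical_class for s in sites)
    strand_counts = Counter(s.resolved_strand for s in sites)
    summary = {
        "n_sites": total,
        "raw_type_counts": dict(sorted(raw_counts.items())),
        "class_counts": dict(sorted(class_counts.items())),
        "strand_counts": {k: strand_counts.get(k, 0) for k in ("+", "-", "*")},
        "class_pct": {k: percent(v, total) for k, v in sorted(class_counts.items())},
        "strand_pct": {k: percent(strand_counts.get(k, 0), total) for k in ("+", "-", "*")},
    }
    if observations is not None:
        per_sample: dict[str, Counter] = defaultdict(Counter)
        for o in observations:
            per_sample[o.sample_id][o.raw_type] += 1
        raw_types = sorted({rt for c in per_sample.values() for rt in c})
        medians = {}
        for rt in raw_types:
            counts = sorted(c.get(rt, 0) for c in per_sample.values())
            n = len(counts)
            medians[rt] = (
                counts[n // 2] if n % 2 else (counts[n // 2 - 1] + counts[n // 2]) / 2
            )
        median_total = sum(medians.values())
        summary["median_raw_type_counts"] = medians
        summary["median_raw_type_shares"] = {
            rt: percent(v, median_total) for rt, v in medians.items()
        }
    return summary
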