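"""Sequence-context, recoding, clustering and splice-proximity analyses."""
from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._utils import BASES, percent, revcomp
from .annotation import A_TO_I, C_TO_U, GenomicSite
from .io_formats import GeneModel, Transcript


@dataclasses.dataclass(slots=True)
class RecodingResult:
    """Effect of one editing event on one transcript's coding sequence."""

    transcript_id: str
    codon_number: int  # 1-based
    codon_pos: int  # 1 | 2 | 3
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str
    synonymous: bool
    canonical_class: str = ""
    chrom: str = ""
    pos: int = 0


# --------------------------------------------------------------------------
# flanking sequence context
# --------------------------------------------------------------------------


def extract_flank(
    genome: Mapping[str, str], chrom: str, pos: int, resolved_strand: str, k: int = 10
) -> str:
    """2k+1 bp window centred on the site, in edited-strand orientation.

    Minus-strand sites return the reverse complement of the plus-strand
    window, so the centre base reads as the edited base (A or C).  Windows
    running off a chromosome end are padded with N.
    """
    if resolved_strand not in ("+", "-"):
        raise ValueError("cannot extract a flank for an ambiguous-strand site")
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {chrom}:{pos} outside chromosome")
    lo, hi = pos - 1 - k, pos + k  # 0-based half-open
    window = "N" * max(0, -lo) + seq[max(0, lo) : hi] + "N" * max(0, hi - len(seq))
    return revcomp(window) if resolved_strand == "-" else window


def flank_frequency(flanks: Iterable[str], k: int = 10) -> pd.DataFrame:
    """Per-position base frequencies of centred flanks: 4 x (2k+1) matrix.

    Rows are A/C/G/T, columns are offsets -k..+k.  N bases contribute
    nothing; each column with any contributing base sums to 1.
    """
    width = 2 * k + 1
    counts = np.zeros((4, width), dtype=float)
    for flank in flanks:
        if len(flank) != width:
            raise ValueError(f"flank length {len(flank)} != {width}")
        for j, base in enumerate(flank.upper()):
            if base in BASES:
                counts[BASES.index(base), j] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(freqs, index=list(BASES), columns=range(-k, k + 1))


# --------------------------------------------------------------------------
# codon position and recoding
# --------------------------------------------------------------------------


def cds_offset(pos: int, transcript: Transcript, strand: str) -> int:
    """0-based offset of a genomic position within the spliced CDS.

    Counts from the start codon in transcript orientation: plus-strand
    transcripts count from the leftmost CDS base, minus-strand from the
    rightmost.
    """
    blocks = transcript.cds
    if not any(s <= pos <= e for s, e in blocks):
        raise ValueError(f"position {pos} is not inside the CDS of {transcript.transcript_id}")
    if strand == "+":
        offset = 0
        for s, e in blocks:
            if pos > e:
                offset += e - s + 1
            else:
                return offset + pos - s
    else:
        offset = 0
        for s, e in reversed(blocks):
            if pos < s:
                offset += e - s + 1
            else:
                return offset + e - pos
    raise AssertionError("unreachable")


def codon_index(offset: int) -> tuple[int, int]:
    """Map a 0-based CDS offset to (codon_number, codon_pos), both 1-based."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    return offset // 3 + 1, offset % 3 + 1


def recode(ref_codon: str, codon_pos: int, canonical_class: str) -> RecodingResult:
    """Apply A>G (A-to-I) or C>T (C-to-U) at a codon position and translate.

    The codon is sense-strand oriented; its base at ``codon_pos`` must be
    compatible with the class.
    """
    ref_codon = ref_codon.upper()
    if len(ref_codon) != 3 or any(b not in BASES for b in ref_codon):
        raise ValueError(f"invalid codon {ref_codon!r}")
    if codon_pos not in (1, 2, 3):
        raise ValueError("codon_pos must be 1, 2 or 3")
    expected, substituted = {A_TO_I: ("A", "G"), C_TO_U: ("C", "T")}.get(
        canonical_class, (None, None)
    )
    if expected is None:
        raise ValueError(f"cannot recode class {canonical_class!r}")
    if ref_codon[codon_pos - 1] != expected:
        raise ValueError(
            f"codon {ref_codon} position {codon_pos} is {ref_codon[codon_pos - 1]}, "
            f"incompatible with {canonical_class}"
        )
    edited = ref_codon[: codon_pos - 1] + substituted + ref_codon[codon_pos:]
    ref_aa = str(Seq(ref_codon).translate())
    edited_aa = str(Seq(edited).translate())
    return RecodingResult(
        transcript_id="",
        codon_number=0,
        codon_pos=codon_pos,
        ref_codon=ref_codon,
        edited_codon=edited,
        ref_aa=ref_aa,
        edited_aa=edited_aa,
        synonymous=ref_aa == edited_aa,
        canonical_class=canonical_class,
    )


def cds_sequence(genome: Mapping[str, str], chrom: str, transcript: Transcript, strand: str) -> str:
    """Spliced CDS sequence in transcript orientation."""
    seq = "".join(genome[chrom][s - 1 : e] for s, e in transcript.cds)
    return revcomp(seq) if strand == "-" else seq


def recode_site(
    genome: Mapping[str, str],
    site: GenomicSite,
    gene: GeneModel,
    transcript: Transcript,
) -> RecodingResult:
    """Full recoding result for a site inside a transcript's CDS."""
    offset = cds_offset(site.pos, transcript, gene.strand)
    codon_number, codon_pos = codon_index(offset)
    cds = cds_sequence(genome, gene.chrom, transcript, gene.strand)
    codon = cds[(codon_number - 1) * 3 : codon_number * 3]
    result = recode(codon, codon_pos, site.canonical_class)
    result.transcript_id = transcript.transcript_id
    result.codon_number = codon_number
    result.chrom = site.chrom
    result.pos = site.pos
    return result


def recoding_summary(results: Sequence[RecodingResult]) -> dict:
    """Amino-acid substitution matrices per class and nonsynonymous fractions.

    A site hit in several transcripts contributes one row per transcript;
    the caller decides any site-level collapsing.
    """
    by_class: dict[str, pd.DataFrame] = {}
    fractions: dict[str, dict] = {}
    groups: dict[str, list[RecodingResult]] = defaultdict(list)
    for r in results:
        groups[r.canonical_class].append(r)
    for cls, rows in sorted(groups.items()):
        aa_pairs = pd.crosstab(
            pd.Series([r.ref_aa for r in rows], name="ref_aa"),
            pd.Series([r.edited_aa for r in rows], name="edited_aa"),
        )
        by_class[cls] = aa_pairs
        n_nonsyn = sum(1 for r in rows if not r.synonymous)
        fractions[cls] = {
            "n_total": len(rows),
            "n_nonsynonymous": n_nonsyn,
            "pct_nonsynonymous": percent(n_nonsyn, len(rows), 1),
        }
    return {"aa_matrix": by_class, "nonsynonymous": fractions}


# --------------------------------------------------------------------------
# clustering and splice proximity
# --------------------------------------------------------------------------


def nearest_site_distances(sites: Sequence[GenomicSite]) -> list[float]:
    """Distance from each site to its nearest other site on the same chromosome.

    Sites alone on their chromosome get NaN.  Order of the result matches
    the input order.
    """
    if not sites:
        raise ValueError("no sites provided")
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for s in sites:
        by_chrom[s.chrom].append(s.pos)
    sorted_pos = {c: sorted(ps) for c, ps in by_chrom.items()}
    out: list[float] = []
    for s in sites:
        positions = sorted_pos[s.chrom]
        if len(positions) < 2:
            out.append(math.nan)
            continue
        i = positions.index(s.pos)
        candidates = []
        if i > 0:
            candidates.append(s.pos - positions[i - 1])
        if i + 1 < len(positions):
            candidates.append(positions[i + 1] - s.pos)
        # duplicated positions give distance 0 via either neighbour
        out.append(float(min(candidates)))
    return out


def clustering_summary(sites: Sequence[GenomicSite], threshold: int = 20) -> dict:
    """Fraction of sites whose nearest neighbour is closer than ``threshold`` bp."""
    distances = nearest_site_distances(sites)
    finite = [d for d in distances if not math.isnan(d)]
    n_close = sum(1 for d in finite if d < threshold)
    return {
        "n_sites": len(sites),
        "n_with_neighbor": len(finite),
        "n_below_threshold": n_close,
        "pct_below_threshold": percent(n_close, len(sites)),
        "threshold": threshold,
    }


def exon_boundary_distance(pos: int, transcript: Transcript) -> int:
    """Minimum distance from an exonic position to its exon's start or end."""
    for s, e in transcript.exons:
        if s <= pos <= e:
            return min(pos - s, e - pos)
    raise ValueError(f"position {pos} is not exonic in {transcript.transcript_id}")


def site_exon_boundary_distances(
    site: GenomicSite, genes: Mapping[str, GeneModel]
) -> dict[str, int]:
    """Per-transcript exon-boundary distances for every hosting transcript."""
    out: dict[str, int] = {}
    for gid in site.host_genes:
        gene = genes.get(gid)
        if gene is None:
            continue
        for tx in gene.transcripts:
            if any(s <= site.pos <= e for s, e in tx.exons):
                out[tx.transcript_id] = exon_boundary_distance(site.pos, tx)
    return out


def splice_candidate_filter(
    distances: Mapping[tuple[str, int], float], max_dist: int
) -> list[tuple[str, int]]:
    """Sites whose exon-boundary distance is at most ``max_dist`` bp."""
    return sorted(k for k, d in distances.items() if not math.isnan(d) and d <= max_dist)
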