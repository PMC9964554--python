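"""Candidate editing-site calling and the filter cascade.

Detection compares matched DNA and RNA pileups point by point: the DNA
majority base defines the reference at each position, and every RNA base
disagreeing with it becomes a candidate observation.  Observations then
pass per-sample primary filters, a known-variant mask, and cohort-level
filters that aggregate across samples into non-redundant sites.
"""
from __future__ import annotations

import dataclasses
import logging
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from ._utils import BASES, percent
from .io_formats import PileupRecord, VariantSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True, slots=True)
class EditingObservation:
    """One candidate editing event: one site in one sample."""

    chrom: str
    pos: int
    sample_id: str
    ref_base: str
    alt_base: str
    rna_cov: int
    rna_alt_count: int
    rna_alt_freq: float  # the editing level
    dna_cov: int
    dna_ref_freq: float
    dna_alt_count: int
    mean_qual: float = 0.0
    multiallelic: bool = False

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def raw_type(self) -> str:
        return self.ref_base + self.alt_base


@dataclasses.dataclass(slots=True)
class FilterConfig:
    """Thresholds of the per-sample and cohort filter cascade."""

    min_rna_cov: int = 10
    min_dna_cov: int = 5
    min_alt_reads: int = 2
    max_dna_alt_reads: int = 0
    min_rna_alt_freq: float = 0.01
    min_dna_ref_freq: float = 0.95
    exclude_multiallelic: bool = True
    min_samples: int = 3
    drop_all_ones: bool = True
    autosomes_only: bool = True
    autosome_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.min_rna_cov < 0 or self.min_dna_cov < 0 or self.min_alt_reads < 0:
            raise ValueError("coverage/read thresholds must be non-negative")
        if not (0.0 <= self.min_rna_alt_freq <= 1.0 and 0.0 <= self.min_dna_ref_freq <= 1.0):
            raise ValueError("frequency thresholds must be in [0, 1]")


@dataclasses.dataclass(slots=True)
class SiteCall:
    """A non-redundant site surviving the cohort filters."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    n_samples: int
    mean_level: float

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def compute_editing_level(alt_count: int, coverage: int) -> float:
    """Editing level = fraction of RNA reads carrying the edited base."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= alt_count <= coverage:
        raise ValueError("alt_count must lie in [0, coverage]")
    return alt_count / coverage


def _majority_base(record: PileupRecord) -> str:
    counts = record.base_counts()
    return max(BASES, key=lambda b: (counts[b], -BASES.index(b)))


def _check_sorted(records: Iterable[PileupRecord], label: str):
    last = None
    for rec in records:
        key = (rec.chrom, rec.pos)
        if last is not None and key < last:
            raise ValueError(f"{label} pileup stream is not sorted at {rec.chrom}:{rec.pos}")
        last = key
        yield rec


def call_candidates(
    dna_records: Iterable[PileupRecord],
    rna_records: Iterable[PileupRecord],
    sample_id: str | None = None,
    min_alt_reads: int = 2,
) -> list[EditingObservation]:
    """Pair sorted DNA/RNA pileups and emit one observation per RNA mismatch base.

    The DNA majority base defines ``ref_base``.  Positions whose RNA bases
    all agree with the reference produce nothing.  A position with two or
    more distinct alt bases each supported by ``min_alt_reads`` reads is
    flagged multiallelic on every observation it emits.
    """
    dna_by_pos: dict[tuple[str, int], PileupRecord] = {
        (r.chrom, r.pos): r for r in _check_sorted(dna_records, "DNA")
    }
    observations: list[EditingObservation] = []
    for rna in _check_sorted(rna_records, "RNA"):
        dna = dna_by_pos.get((rna.chrom, rna.pos))
        if dna is None or dna.coverage == 0 or rna.coverage == 0:
            continue
        ref = _majority_base(dna)
        dna_ref_freq = dna.count(ref) / dna.coverage
        alt_bases = [b for b in BASES if b != ref and rna.count(b) > 0]
        if not alt_bases:
            continue
        multi = sum(1 for b in alt_bases if rna.count(b) >= min_alt_reads) >= 2
        sid = sample_id if sample_id is not None else rna.sample_id
        for alt in alt_bases:
            observations.append(
                EditingObservation(
                    chrom=rna.chrom,
                    pos=rna.pos,
                    sample_id=sid,
                    ref_base=ref,
                    alt_base=alt,
                    rna_cov=rna.coverage,
                    rna_alt_count=rna.count(alt),
                    rna_alt_freq=compute_editing_level(rna.count(alt), rna.coverage),
                    dna_cov=dna.coverage,
                    dna_ref_freq=dna_ref_freq,
                    dna_alt_count=dna.count(alt),
                    mean_qual=rna.mean_qual,
                    multiallelic=multi,
                )
            )
    return observations


# Primary filter rules checked in order; the first violation is reported.
_PRIMARY_RULES = (
    ("min_rna_cov", lambda o, c: o.rna_cov >= c.min_rna_cov),
    ("min_dna_cov", lambda o, c: o.dna_cov >= c.min_dna_cov),
    ("min_alt_reads", lambda o, c: o.rna_alt_count >= c.min_alt_reads),
    ("dna_variant", lambda o, c: o.dna_alt_count <= c.max_dna_alt_reads),
    ("min_rna_alt_freq", lambda o, c: o.rna_alt_freq >= c.min_rna_alt_freq),
    ("min_dna_ref_freq", lambda o, c: o.dna_ref_freq >= c.min_dna_ref_freq),
    ("multiallelic", lambda o, c: not (c.exclude_multiallelic and o.multiallelic)),
)


def apply_primary_filters(obs: EditingObservation, cfg: FilterConfig) -> str | None:
    """Return None if the observation passes, else the name of the first failed rule."""
    for name, rule in _PRIMARY_RULES:
        if not rule(obs, cfg):
            return name
    return None


def filter_observations(
    observations: Iterable[EditingObservation], cfg: FilterConfig
) -> tuple[list[EditingObservation], Counter]:
    """Apply the primary filters to a batch; returns survivors and failure tallies."""
    passed: list[EditingObservation] = []
    reasons: Counter = Counter()
    for obs in observations:
        reason = apply_primary_filters(obs, cfg)
        if reason is None:
            passed.append(obs)
        else:
            reasons[reason] += 1
            logger.debug("filtered %s:%d %s (%s)", obs.chrom, obs.pos, obs.sample_id, reason)
    return passed, reasons


def mask_known_variants(
    observations: Iterable[EditingObservation], variants: VariantSet
) -> list[EditingObservation]:
    """Drop observations at known SNP positions or inside known INDEL intervals."""
    return [o for o in observations if not variants.covers(o.chrom, o.pos)]


def apply_cohort_filters(
    observations: Sequence[EditingObservation], cfg: FilterConfig
) -> tuple[list[EditingObservation], list[SiteCall]]:
    """Aggregate per-sample observations into non-redundant sites.

    A site survives iff it is detected in at least ``min_samples`` distinct
    samples, its editing level is not 1 in every detected sample, and its
    chromosome is in ``autosome_names`` (when ``autosomes_only``).  The
    surviving observation set is all observations at surviving sites.
    """
    if cfg.autosomes_only and not cfg.autosome_names:
        raise ValueError("autosome_names must be provided when autosomes_only is set")
    autosomes = set(cfg.autosome_names or ())

    by_site: dict[tuple[str, int], list[EditingObservation]] = defaultdict(list)
    for obs in observations:
        by_site[obs.site].append(obs)

    hq_obs: list[EditingObservation] = []
    sites: list[SiteCall] = []
    for (chrom, pos) in sorted(by_site):
        group = by_site[(chrom, pos)]
        n_samples = len({o.sample_id for o in group})
        if n_samples < cfg.min_samples:
            continue
        if cfg.drop_all_ones and all(o.rna_alt_freq == 1.0 for o in group):
            continue
        if cfg.autosomes_only and chrom not in autosomes:
            continue
        ref, alt = Counter((o.ref_base, o.alt_base) for o in group).most_common(1)[0][0]
        mean_level = sum(o.rna_alt_freq for o in group) / len(group)
        sites.append(SiteCall(chrom, pos, ref, alt, n_samples, mean_level))
        hq_obs.extend(sorted(group, key=lambda o: o.sample_id))
    return hq_obs, sites


def level_summary(observations: Sequence[EditingObservation]) -> dict:
    """Editing-level distribution of observations plus per-site sample support.

    Fractions use the observation count as denominator; the support
    histogram counts non-redundant sites by how many samples detected them.
    """
    n = len(observations)
    n_gt_05 = sum(1 for o in observations if o.rna_alt_freq > 0.5)
    n_gt_095 = sum(1 for o in observations if o.rna_alt_freq > 0.95)
    n_eq_1 = sum(1 for o in observations if o.rna_alt_freq == 1.0)
    support: dict[tuple[str, int], set] = defaultdict(set)
    for o in observations:
        support[o.site].add(o.sample_id)
    hist = Counter(len(s) for s in support.values())
    return {
        "n_observations": n,
        "n_sites": len(support),
        "n_level_gt_05": n_gt_05,
        "n_level_gt_095": n_gt_095,
        "n_level_eq_1": n_eq_1,
        "pct_level_gt_05": percent(n_gt_05, n),
        "pct_level_gt_095": percent(n_gt_095, n),
        "pct_level_eq_1": percent(n_eq_1, n),
        "support_histogram": dict(sorted(hist.items())),
    }
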