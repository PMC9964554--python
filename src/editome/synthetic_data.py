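"""Synthetic genome, annotation, pileups and expression with planted truth.

The generator emulates the study design the analysis assumes: two
populations x four tissues x five individuals, planted A-to-I and C-to-U
sites with per-sample editing levels, germline SNPs present in both DNA
and RNA, uniform sequencing error, and negative-binomial expression
counts whose rank correlation with designated sites' editing levels is
induced through a shared Gaussian latent factor.

Pileups are emitted at informative positions only (planted sites, planted
SNPs and a configurable number of background gene-body positions) rather
than genome-wide, which keeps outputs desk-scale while still exercising
every filter, including false-positive opportunities from sequencing
error.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._utils import BASES, substream
from .annotation import A_TO_I, C_TO_U
from .io_formats import GeneModel, PileupRecord, Transcript

_EDIT_RULES = {
    # class -> {gene strand: (ref base, alt base)} in forward-reference orientation
    A_TO_I: {"+": ("A", "G"), "-": ("T", "C")},
    C_TO_U: {"+": ("C", "T"), "-": ("G", "A")},
}


@dataclasses.dataclass
class SimConfig:
    """All knobs of the simulator; the seed fixes every output byte-for-byte."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 60_000
    n_genes: int = 20
    n_a_to_i: int = 40
    n_c_to_u: int = 20
    n_snps: int = 30
    n_tissue_specific: int = 0
    n_population_specific: int = 0
    n_population_differential: int = 0
    differential_delta: float = 0.3
    dna_depth_mean: float = 30.0
    rna_depth_mean: float = 50.0
    depth_dispersion: float | None = 10.0  # NB size parameter; None = Poisson
    base_error_rate: float = 0.002
    level_alpha: float = 2.0
    level_beta: float = 2.0
    level_min: float = 0.0
    populations: tuple[str, ...] = ("TBG", "IMG")
    tissues: tuple[str, ...] = ("heart", "lung", "kidney", "muscle")
    n_individuals: int = 5
    n_correlated_sites: int = 0
    expression_rho: float = 0.7
    expression_mean: float = 200.0
    expression_dispersion: float = 5.0
    n_background_positions: int = 400
    cds_site_fraction: float = 0.7
    catalyzer_names: tuple[str, ...] = (
        "ADAR",
        "ADARB1",
        "ADARB2",
        "APOBEC1",
        "APOBEC2",
        "APOBEC4",
    )

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "level_min", "cds_site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dna_depth_mean < 0 or self.rna_depth_mean < 0:
            raise ValueError("depth means must be non-negative")
        if not -1.0 <= self.expression_rho <= 1.0:
            raise ValueError("expression_rho must be in [-1, 1]")
        if self.level_alpha <= 0 or self.level_beta <= 0:
            raise ValueError("editing level Beta parameters must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("populations", "tissues", "catalyzer_names"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- sample bookkeeping -------------------------------------------------

    def dna_samples(self) -> list[str]:
        return [
            f"{pop}{i + 1}" for pop in self.populations for i in range(self.n_individuals)
        ]

    def rna_samples(self) -> list[str]:
        return [
            f"{pop}{i + 1}_{tissue}"
            for pop in self.populations
            for i in range(self.n_individuals)
            for tissue in self.tissues
        ]

    def sample_metadata(self) -> pd.DataFrame:
        rows = []
        for pop in self.populations:
            for i in range(self.n_individuals):
                for tissue in self.tissues:
                    rows.append(
                        {
                            "sample": f"{pop}{i + 1}_{tissue}",
                            "population": pop,
                            "tissue": tissue,
                            "individual": f"{pop}{i + 1}",
                            "dna_sample": f"{pop}{i + 1}",
                        }
                    )
        return pd.DataFrame(rows).set_index("sample")


@dataclasses.dataclass(slots=True)
class PlantedSite:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    true_class: str
    host_gene: str
    label: str  # none | tissue_specific:<tissue> | population_specific:<pop> | population_differential
    levels: dict[str, float]  # RNA sample id -> true editing level
    target_gene: str | None = None  # gene whose expression the levels track


@dataclasses.dataclass
class TruthTable:
    """Ground truth of planted SNPs and editing sites."""

    snps: list[tuple[str, int, str, str, str]]  # chrom, pos, ref, alt, het|hom
    sites: list[PlantedSite]
    expression_u: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        snp_pos = {(c, p) for c, p, *_ in self.snps}
        site_pos = {(s.chrom, s.pos) for s in self.sites}
        if snp_pos & site_pos:
            raise ValueError("planted SNP and editing positions must be disjoint")

    def site_positions(self) -> set[tuple[str, int]]:
        return {(s.chrom, s.pos) for s in self.sites}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            row = {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "true_class": s.true_class,
                "host_gene": s.host_gene,
                "label": s.label,
                "target_gene": s.target_gene or "",
            }
            row.update(s.levels)
            rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# reference generation
# --------------------------------------------------------------------------


def _spliced_to_genomic(
    exons: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Map a 0-based half-open window on the ascending spliced axis to genomic intervals."""
    out = []
    acc = 0
    for s, e in exons:
        length = e - s + 1
        a, b = max(lo, acc), min(hi, acc + length)
        if a < b:
            out.append((s + (a - acc), s + (b - acc) - 1))
        acc += length
    return out


def _make_gene(
    idx: int, chrom: str, start: int, rng: np.random.Generator, config: SimConfig
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    protein_coding = rng.random() >= 0.15
    n_exons = int(rng.integers(2, 5))
    exon_lens = rng.integers(150, 400, n_exons)
    intron_lens = rng.integers(60, 300, max(n_exons - 1, 0))
    exons = []
    cursor = start
    for i, ln in enumerate(exon_lens):
        exons.append((cursor, cursor + int(ln) - 1))
        cursor += int(ln)
        if i < len(intron_lens):
            cursor += int(intron_lens[i])
    spliced_len = int(exon_lens.sum())

    gene_id = f"SYNG{idx:05d}"
    name = (
        config.catalyzer_names[idx] if idx < len(config.catalyzer_names) else None
    )
    tx_id = f"SYNT{idx:05d}"
    if not protein_coding:
        tx = Transcript(transcript_id=tx_id, exons=exons)
        return GeneModel(gene_id, chrom, strand, "lincRNA", name, [tx])

    left_utr = int(rng.integers(20, 80))
    right_utr = int(rng.integers(20, 80))
    cds_len = spliced_len - left_utr - right_utr
    cds_len -= cds_len % 3
    right_utr = spliced_len - left_utr - cds_len
    cds = _spliced_to_genomic(exons, left_utr, left_utr + cds_len)
    utr_left = _spliced_to_genomic(exons, 0, left_utr)
    utr_right = _spliced_to_genomic(exons, left_utr + cds_len, spliced_len)
    utr5, utr3 = (utr_left, utr_right) if strand == "+" else (utr_right, utr_left)
    tx = Transcript(transcript_id=tx_id, exons=exons, cds=cds, utr5=utr5, utr3=utr3)
    return GeneModel(gene_id, chrom, strand, "protein_coding", name, [tx])


def generate_reference(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus an internally consistent annotation on both strands."""
    rng = substream(config.seed, "reference")
    genome = {
        f"chr{i + 1}": "".join(rng.choice(list(BASES), size=config.chrom_length))
        for i in range(config.n_chrom)
    }
    genes: list[GeneModel] = []
    cursors = {c: 200 for c in genome}
    chroms = list(genome)
    for idx in range(config.n_genes):
        chrom = chroms[idx % len(chroms)]
        gap = int(rng.integers(200, 800))
        gene = _make_gene(idx, chrom, cursors[chrom] + gap, rng, config)
        if gene.end > config.chrom_length - 200:
            raise ValueError(
                f"requested {config.n_genes} genes do not fit chromosomes of "
                f"length {config.chrom_length}"
            )
        cursors[chrom] = gene.end
        genes.append(gene)
    return genome, genes


# --------------------------------------------------------------------------
# truth planting
# --------------------------------------------------------------------------


def _eligible_positions(
    genome: Mapping[str, str], gene: GeneModel, wanted_base: str
) -> tuple[list[int], list[int]]:
    """(CDS positions, other exonic positions) of the gene holding wanted_base."""
    seq = genome[gene.chrom]
    cds_pos, exon_pos = [], []
    for tx in gene.transcripts:
        cds_ivs = tx.cds
        for s, e in tx.exons:
            for p in range(s, e + 1):
                if seq[p - 1] != wanted_base:
                    continue
                if any(cs <= p <= ce for cs, ce in cds_ivs):
                    cds_pos.append(p)
                else:
                    exon_pos.append(p)
    return cds_pos, exon_pos


def _draw_levels(
    rng: np.random.Generator, config: SimConfig, n: int
) -> np.ndarray:
    raw = rng.beta(config.level_alpha, config.level_beta, size=n)
    return config.level_min + (1.0 - config.level_min) * raw


def plant_truth(
    config: SimConfig, genome: Mapping[str, str], genes: Sequence[GeneModel]
) -> TruthTable:
    """Plant SNPs and editing sites with design labels and per-sample levels."""
    rng = substream(config.seed, "truth")
    rna_samples = config.rna_samples()
    used: set[tuple[str, int]] = set()

    # -- editing sites ------------------------------------------------------
    site_specs: list[tuple[str, int, str, str, str, str]] = []
    for cls, n_wanted in ((A_TO_I, config.n_a_to_i), (C_TO_U, config.n_c_to_u)):
        cds_pool: list[tuple[GeneModel, int]] = []
        exon_pool: list[tuple[GeneModel, int]] = []
        for gene in genes:
            ref, _alt = _EDIT_RULES[cls][gene.strand]
            cds_pos, exon_pos = _eligible_positions(genome, gene, ref)
            cds_pool.extend((gene, p) for p in cds_pos)
            exon_pool.extend((gene, p) for p in exon_pos)
        cds_pool = [cds_pool[int(i)] for i in rng.permutation(len(cds_pool))]
        exon_pool = [exon_pool[int(i)] for i in rng.permutation(len(exon_pool))]
        placed = 0
        while placed < n_wanted:
            if not cds_pool and not exon_pool:
                raise ValueError(
                    f"not enough eligible bases to plant {n_wanted} {cls} sites"
                )
            use_cds = bool(cds_pool) and (
                not exon_pool or rng.random() < config.cds_site_fraction
            )
            gene, pos = (cds_pool if use_cds else exon_pool).pop()
            if (gene.chrom, pos) in used:
                continue
            ref, alt = _EDIT_RULES[cls][gene.strand]
            used.add((gene.chrom, pos))
            site_specs.append((gene.chrom, pos, ref, alt, cls, gene.gene_id))
            placed += 1

    order = rng.permutation(len(site_specs))
    site_specs = [site_specs[int(i)] for i in order]

    # design labels, assigned in blocks over the shuffled specs
    labels: list[str] = []
    for j in range(config.n_tissue_specific):
        labels.append(f"tissue_specific:{config.tissues[j % len(config.tissues)]}")
    for j in range(config.n_population_specific):
        labels.append(f"population_specific:{config.populations[j % len(config.populations)]}")
    labels.extend(["population_differential"] * config.n_population_differential)
    if len(labels) > len(site_specs):
        raise ValueError("more design labels requested than planted sites")
    labels.extend(["none"] * (len(site_specs) - len(labels)))

    # latent expression factors for correlation targets
    expression_u: dict[str, dict[str, float]] = {}
    gene_z: dict[str, np.ndarray] = {}
    catalyzers = [g.gene_id for g in genes if g.gene_name in config.catalyzer_names]
    n_corr = min(config.n_correlated_sites, labels.count("none"))
    if n_corr and not catalyzers:
        raise ValueError("correlated sites requested but no catalyzer genes generated")
    for gid in catalyzers:
        z = rng.standard_normal(len(rna_samples))
        gene_z[gid] = z
        expression_u[gid] = {
            s: float(stats.norm.cdf(v)) for s, v in zip(rna_samples, z)
        }
    r = 2.0 * math.sin(math.pi * config.expression_rho / 6.0)  # Spearman -> Pearson copula

    sites: list[PlantedSite] = []
    none_seen = 0
    for (chrom, pos, ref, alt, cls, host), label in zip(site_specs, labels):
        target: str | None = None
        if label == "none" and none_seen < n_corr:
            target = catalyzers[none_seen % len(catalyzers)]
            none_seen += 1
            eps = rng.standard_normal(len(rna_samples))
            z1 = r * gene_z[target] + math.sqrt(max(0.0, 1.0 - r * r)) * eps
            raw = stats.beta.ppf(stats.norm.cdf(z1), config.level_alpha, config.level_beta)
            base = config.level_min + (1.0 - config.level_min) * raw
        else:
            base = _draw_levels(rng, config, len(rna_samples))
        levels = dict(zip(rna_samples, base.astype(float)))

        if label.startswith("tissue_specific:"):
            tissue = label.split(":", 1)[1]
            levels = {s: (lv if s.endswith(f"_{tissue}") else 0.0) for s, lv in levels.items()}
        elif label.startswith("population_specific:"):
            pop = label.split(":", 1)[1]
            levels = {s: (lv if s.startswith(pop) else 0.0) for s, lv in levels.items()}
        elif label == "population_differential":
            high = config.populations[0]
            levels = {
                s: (min(1.0, lv + config.differential_delta) if s.startswith(high) else lv)
                for s, lv in levels.items()
            }
        sites.append(
            PlantedSite(chrom, pos, ref, alt, cls, host, label, levels, target)
        )

    # -- germline SNPs inside gene bodies so RNA covers them ----------------
    snps: list[tuple[str, int, str, str, str]] = []
    attempts = 0
    while len(snps) < config.n_snps and attempts < config.n_snps * 50:
        attempts += 1
        gene = genes[int(rng.integers(len(genes)))]
        pos = int(rng.integers(gene.start, gene.end + 1))
        if (gene.chrom, pos) in used:
            continue
        ref = genome[gene.chrom][pos - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        genotype = "het" if rng.random() < 0.5 else "hom"
        used.add((gene.chrom, pos))
        snps.append((gene.chrom, pos, ref, alt, genotype))
    if len(snps) < config.n_snps:
        raise ValueError("could not place the requested number of SNPs")

    return TruthTable(snps=snps, sites=sites, expression_u=expression_u)


# --------------------------------------------------------------------------
# pileup and expression simulation
# --------------------------------------------------------------------------


def _depth(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _base_probs(ref: str, alt: str | None, dose: float, error: float) -> np.ndarray:
    """Multinomial base probabilities for a mixture of ref and alt alleles."""
    probs = np.zeros(4)
    alleles = [(ref, 1.0 - dose)] if alt is None else [(ref, 1.0 - dose), (alt, dose)]
    for allele, weight in alleles:
        for j, b in enumerate(BASES):
            probs[j] += weight * ((1.0 - error) if b == allele else error / 3.0)
    return probs


def simulate_pileups(
    truth: TruthTable,
    config: SimConfig,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
) -> tuple[list[PileupRecord], list[PileupRecord], pd.DataFrame]:
    """Generate DNA/RNA pileup records and the gene expression count matrix.

    DNA is homozygous reference away from planted SNPs; planted SNPs carry
    their genotype dose in both DNA and RNA so the DNA-based filters (not
    only the VCF mask) must remove them.  RNA alternative-base counts
    follow the per-sample true editing level under uniform sequencing
    error.
    """
    rng = substream(config.seed, "pileups")
    e = config.base_error_rate

    snp_at = {(c, p): (ref, alt, gt) for c, p, ref, alt, gt in truth.snps}
    site_at = {(s.chrom, s.pos): s for s in truth.sites}

    positions: list[tuple[str, int]] = sorted(set(snp_at) | set(site_at))
    taken = set(positions)
    background: list[tuple[str, int]] = []
    attempts = 0
    while len(background) < config.n_background_positions and attempts < config.n_background_positions * 50:
        attempts += 1
        gene = genes[int(rng.integers(len(genes)))] if genes else None
        if gene is None:
            break
        pos = int(rng.integers(gene.start, gene.end + 1))
        if (gene.chrom, pos) in taken:
            continue
        taken.add((gene.chrom, pos))
        background.append((gene.chrom, pos))
    positions = sorted(taken)

    dna_records: list[PileupRecord] = []
    rna_records: list[PileupRecord] = []
    rna_samples = config.rna_samples()
    dna_samples = config.dna_samples()
    dose_of_gt = {"het": 0.5, "hom": 1.0}

    for chrom, pos in positions:
        ref = genome[chrom][pos - 1]
        snp = snp_at.get((chrom, pos))
        site = site_at.get((chrom, pos))
        for sid in dna_samples:
            depth = _depth(rng, config.dna_depth_mean, config.depth_dispersion)
            if snp is not None:
                probs = _base_probs(snp[0], snp[1], dose_of_gt[snp[2]], e)
            else:
                probs = _base_probs(ref, None, 0.0, e)
            counts = rng.multinomial(depth, probs) if depth else np.zeros(4, dtype=int)
            dna_records.append(
                PileupRecord(chrom, pos, sid, "DNA", *map(int, counts), mean_qual=37.0)
            )
        for sid in rna_samples:
            depth = _depth(rng, config.rna_depth_mean, config.depth_dispersion)
            if snp is not None:
                probs = _base_probs(snp[0], snp[1], dose_of_gt[snp[2]], e)
            elif site is not None:
                probs = _base_probs(site.ref_base, site.alt_base, site.levels[sid], e)
            else:
                probs = _base_probs(ref, None, 0.0, e)
            counts = rng.multinomial(depth, probs) if depth else np.zeros(4, dtype=int)
            rna_records.append(
                PileupRecord(chrom, pos, sid, "RNA", *map(int, counts), mean_qual=37.0)
            )

    expression = _simulate_expression(truth, config, genes)
    return dna_records, rna_records, expression


def _simulate_expression(
    truth: TruthTable, config: SimConfig, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Negative-binomial counts per gene x RNA sample; genes with a latent
    factor in the truth table are generated through its Gaussian copula."""
    rng = substream(config.seed, "expression")
    samples = config.rna_samples()
    k = config.expression_dispersion
    rows = {}
    for gene in genes:
        mean = float(rng.lognormal(math.log(config.expression_mean), 0.5))
        p = k / (k + mean)
        u_map = truth.expression_u.get(gene.gene_id)
        if u_map is not None:
            u = np.array([u_map[s] for s in samples])
            counts = stats.nbinom.ppf(u, k, p).astype(int)
        else:
            counts = rng.negative_binomial(k, p, size=len(samples))
        rows[gene.gene_id] = counts
    return pd.DataFrame(rows, index=samples).T


# --------------------------------------------------------------------------
# recovery evaluation
# --------------------------------------------------------------------------

_CONFUSION_CLASSES = (A_TO_I, C_TO_U, "other")


@dataclasses.dataclass
class RecoveryResult:
    precision: float  # NaN when nothing was called
    recall: float
    n_tp: int
    n_fp: int
    n_fn: int
    confusion: pd.DataFrame  # true class x called class, over true positives


def evaluate_recovery(called_sites: Sequence, truth: TruthTable) -> RecoveryResult:
    """Precision/recall of called positions against the planted truth,
    plus the class-confusion table over recovered sites."""
    called: dict[tuple[str, int], str] = {}
    for s in called_sites:
        if isinstance(s, tuple):
            key, cls = (s[0], s[1]), "other"
        else:
            key = (s.chrom, s.pos)
            cls = getattr(s, "canonical_class", "other")
        called[key] = cls if cls in (A_TO_I, C_TO_U) else "other"

    true_class = {(s.chrom, s.pos): s.true_class for s in truth.sites}
    tp = set(called) & set(true_class)
    fp = set(called) - set(true_class)
    fn = set(true_class) - set(called)

    confusion = pd.DataFrame(
        0, index=list(_CONFUSION_CLASSES), columns=list(_CONFUSION_CLASSES), dtype=int
    )
    for key in tp:
        confusion.loc[true_class[key], called[key]] += 1

    precision = len(tp) / len(called) if called else math.nan
    recall = len(tp) / len(true_class) if true_class else math.nan
    return RecoveryResult(
        precision=precision,
        recall=recall,
        n_tp=len(tp),
        n_fp=len(fp),
        n_fn=len(fn),
        confusion=confusion,
    )
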