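"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (enumeration,
frozen tables, single-pass brute force) and must stay independent of the
package code paths it checks.
"""
from __future__ import annotations

from itertools import combinations

BASES = ("A", "C", "G", "T")

# Standard genetic code, frozen by hand ('*' = stop).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def wilcoxon_exact_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by complete enumeration of rank assignments.

    Assumes no ties across the pooled sample.
    """
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    observed = sum(ranks[v] for v in x)
    all_ranks = list(range(1, len(pooled) + 1))
    mean = nx * (len(pooled) + 1) / 2
    total = 0
    extreme = 0
    for combo in combinations(all_ranks, nx):
        total += 1
        if abs(sum(combo) - mean) >= abs(observed - mean) - 1e-12:
            extreme += 1
    return extreme / total


def bh_step_up(p_values):
    """BH adjusted p-values via the literal min-over-larger-ranks definition."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    for rank_pos, i in enumerate(indexed, start=1):
        candidates = []
        for later_pos in range(rank_pos, m + 1):
            j = indexed[later_pos - 1]
            candidates.append(p_values[j] * m / later_pos)
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def spearman_rho_ranks(x, y) -> float:
    """Spearman rho via average ranks and the Pearson formula on ranks."""

    def avg_ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def brute_force_survivors(dna, rna, variants_snps, variants_indels, cfg):
    """Single-pass reference of the whole filter cascade.

    dna/rna: {(sample, chrom, pos): {base: count}} (RNA keyed by RNA sample,
    DNA by the same sample id for this oracle's purposes).
    Returns (surviving observation keys, surviving site set) where an
    observation key is (sample, chrom, pos, alt).
    """
    passing = []
    for (sample, chrom, pos), rcounts in rna.items():
        dcounts = dna.get((sample, chrom, pos))
        if dcounts is None:
            continue
        dcov = sum(dcounts.values())
        rcov = sum(rcounts.values())
        if dcov == 0 or rcov == 0:
            continue
        ref = max(BASES, key=lambda b: (dcounts.get(b, 0), -BASES.index(b)))
        alts = [b for b in BASES if b != ref and rcounts.get(b, 0) > 0]
        n_supported = sum(1 for b in alts if rcounts[b] >= cfg.min_alt_reads)
        for alt in alts:
            ok = (
                rcov >= cfg.min_rna_cov
                and dcov >= cfg.min_dna_cov
                and rcounts[alt] >= cfg.min_alt_reads
                and dcounts.get(alt, 0) <= cfg.max_dna_alt_reads
                and rcounts[alt] / rcov >= cfg.min_rna_alt_freq
                and dcounts.get(ref, 0) / dcov >= cfg.min_dna_ref_freq
                and not (cfg.exclude_multiallelic and n_supported >= 2)
            )
            if not ok:
                continue
            if (chrom, pos) in variants_snps:
                continue
            if any(c == chrom and s <= pos <= e for c, s, e in variants_indels):
                continue
            passing.append((sample, chrom, pos, alt, rcounts[alt] / rcov))

    by_site = {}
    for sample, chrom, pos, alt, level in passing:
        by_site.setdefault((chrom, pos), []).append((sample, level))
    sites = set()
    for (chrom, pos), group in by_site.items():
        n_samples = len({s for s, _ in group})
        if n_samples < cfg.min_samples:
            continue
        if cfg.drop_all_ones and all(level == 1.0 for _, level in group):
            continue
        if cfg.autosomes_only and chrom not in set(cfg.autosome_names or ()):
            continue
        sites.add((chrom, pos))
    obs_keys = {
        (sample, chrom, pos, alt)
        for sample, chrom, pos, alt, _ in passing
        if (chrom, pos) in sites
    }
    return obs_keys, sites
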