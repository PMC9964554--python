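"""Cross-sample editing matrices, specificity calling and statistics.

"Detected" throughout this module means: present in the high-quality
observation set after all detection filters.  Missing matrix cells are
NaN and are dropped pairwise by every statistic.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import percent
from .detection import EditingObservation

REQUIRED_METADATA = ("population", "tissue", "individual")


@dataclasses.dataclass
class EditingMatrix:
    """Sites x samples editing levels with per-sample metadata.

    ``levels`` rows are indexed "chrom:pos" and ordered by (chrom, pos);
    ``meta`` is indexed by sample id with population/tissue/individual
    columns covering every matrix column.
    """

    levels: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.levels.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in REQUIRED_METADATA:
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.meta["tissue"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.meta["population"].unique())

    def samples_of(self, tissue: str | None = None, population: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        if tissue is not None:
            mask &= self.meta["tissue"] == tissue
        if population is not None:
            mask &= self.meta["population"] == population
        return [s for s in self.meta.index[mask] if s in self.levels.columns]

    def detected(self, site: str, samples: Sequence[str]) -> pd.Series:
        row = self.levels.loc[site, samples]
        return row.dropna()


def build_matrix(
    observations: Sequence[EditingObservation], metadata: pd.DataFrame
) -> EditingMatrix:
    """Pivot filtered observations into a sites x samples level matrix."""
    seen: set[tuple[str, int, str]] = set()
    for o in observations:
        key = (o.chrom, o.pos, o.sample_id)
        if key in seen:
            raise ValueError(f"duplicate observation for {o.chrom}:{o.pos} in {o.sample_id}")
        seen.add(key)
    sites = sorted({(o.chrom, o.pos) for o in observations})
    index = [f"{c}:{p}" for c, p in sites]
    samples = list(metadata.index)
    levels = pd.DataFrame(np.nan, index=index, columns=samples, dtype=float)
    for o in observations:
        if o.sample_id not in metadata.index:
            raise ValueError(f"sample {o.sample_id!r} has no metadata")
        levels.loc[f"{o.chrom}:{o.pos}", o.sample_id] = o.rna_alt_freq
    return EditingMatrix(levels=levels, meta=metadata)


# --------------------------------------------------------------------------
# expression normalization
# --------------------------------------------------------------------------


def rpkm(count: float, gene_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of gene per million library reads."""
    if gene_length_bp <= 0 or library_size <= 0:
        raise ValueError("gene length and library size must be positive")
    return count / ((gene_length_bp / 1e3) * (library_size / 1e6))


def cpm(count: float, library_size: float) -> float:
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (library_size / 1e6)


def rpkm_matrix(counts: pd.DataFrame, gene_lengths: Mapping[str, float]) -> pd.DataFrame:
    lengths = pd.Series({g: gene_lengths[g] for g in counts.index}, dtype=float)
    lib = counts.sum(axis=0)
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def cpm_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.div(counts.sum(axis=0) / 1e6, axis=1)


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------


def spearman_correlation(levels: Sequence[float], expression: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with average ranks for ties; p from the t-approximation.

    Pairs where the editing level is missing (NaN) are dropped; fewer than
    4 complete pairs yields (NaN, NaN).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(expression, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 4:
        return math.nan, math.nan
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlate_with_catalyzers(
    matrix: EditingMatrix,
    expression: pd.DataFrame,
    catalyzer_genes: Iterable[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Correlate each site's levels with each catalyzing gene's expression.

    Returns a long table (site, gene, n, rho, p, significant) and a summary
    with the fraction of sites having at least one significant catalyzer,
    split by correlation sign.
    """
    rows = []
    for gene in catalyzer_genes:
        if gene not in expression.index:
            warnings.warn(f"catalyzer gene {gene!r} absent from expression matrix; skipped")
            continue
        expr = expression.loc[gene]
        common = [s for s in matrix.levels.columns if s in expr.index]
        for site in matrix.levels.index:
            lv = matrix.levels.loc[site, common]
            n = int(lv.notna().sum())
            rho, p = spearman_correlation(lv.to_numpy(), expr[common].to_numpy())
            rows.append(
                {
                    "site": site,
                    "gene": gene,
                    "n": n,
                    "rho": rho,
                    "p": p,
                    "significant": bool(p < alpha) if not math.isnan(p) else False,
                }
            )
    table = pd.DataFrame(rows, columns=["site", "gene", "n", "rho", "p", "significant"])
    sig = table[table["significant"].astype(bool)]
    sig_sites = set(sig["site"])
    pos_sites = set(sig[sig["rho"] > 0]["site"])
    n_sites = matrix.levels.shape[0]
    summary = {
        "n_sites": n_sites,
        "n_significant_sites": len(sig_sites),
        "pct_significant_sites": percent(len(sig_sites), n_sites, 1),
        "pct_positive_of_significant": percent(len(pos_sites), len(sig_sites), 1),
    }
    return table, summary


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided rank-sum test: exact when both groups are small and tie-free,
    otherwise the normal approximation with tie and continuity corrections."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def anova_tissue_levels(matrix: EditingMatrix, min_per_group: int = 2) -> pd.DataFrame:
    """Per-site one-way ANOVA of detected editing levels across tissues.

    Sites with fewer than two tissues holding at least ``min_per_group``
    detected values get NaN.
    """
    rows = []
    for site in matrix.levels.index:
        groups = []
        for tissue in matrix.tissues:
            vals = matrix.detected(site, matrix.samples_of(tissue=tissue)).to_numpy()
            if len(vals) >= min_per_group:
                groups.append(vals)
        if len(groups) < 2:
            rows.append({"site": site, "F": math.nan, "p": math.nan})
            continue
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            rows.append({"site": site, "F": 0.0, "p": 1.0})
            continue
        f, p = stats.f_oneway(*groups)
        rows.append({"site": site, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows).set_index("site")


# --------------------------------------------------------------------------
# specificity calling
# --------------------------------------------------------------------------


def call_tses(matrix: EditingMatrix, min_support: int = 3) -> pd.DataFrame:
    """Tissue-specific sites: detected in >= min_support samples of exactly
    one tissue and zero samples of every other tissue."""
    rows = []
    for site in matrix.levels.index:
        counts = {
            t: int(matrix.detected(site, matrix.samples_of(tissue=t)).size)
            for t in matrix.tissues
        }
        nonzero = [t for t, n in counts.items() if n > 0]
        if len(nonzero) == 1 and counts[nonzero[0]] >= min_support:
            rows.append({"site": site, "tissue": nonzero[0], "n_detected": counts[nonzero[0]]})
    return pd.DataFrame(rows, columns=["site", "tissue", "n_detected"])


def call_pses(matrix: EditingMatrix, tissue: str, min_support: int = 3) -> pd.DataFrame:
    """Population-specific sites within one tissue: detected in >= min_support
    samples of one population and in none of the other."""
    pops = matrix.populations
    if len(pops) != 2:
        raise ValueError("population-specific calling requires exactly two populations")
    rows = []
    for site in matrix.levels.index:
        counts = {
            p: int(matrix.detected(site, matrix.samples_of(tissue=tissue, population=p)).size)
            for p in pops
        }
        for p, other in (pops, pops[::-1]):
            if counts[p] >= min_support and counts[other] == 0:
                rows.append(
                    {"site": site, "population": p, "tissue": tissue, "n_detected": counts[p]}
                )
    return pd.DataFrame(rows, columns=["site", "population", "tissue", "n_detected"])


def call_pdes(matrix: EditingMatrix, tissue: str, alpha: float = 0.05, min_support: int = 3) -> pd.DataFrame:
    """Population-differential sites within one tissue.

    Sites detected in >= min_support samples per population are tested with
    the two-sided rank-sum test; p-values are BH-adjusted across all tested
    sites in the tissue and called significant below ``alpha``.
    """
    pops = matrix.populations
    if len(pops) != 2:
        raise ValueError("population-differential calling requires exactly two populations")
    rows = []
    for site in matrix.levels.index:
        a = matrix.detected(site, matrix.samples_of(tissue=tissue, population=pops[0]))
        b = matrix.detected(site, matrix.samples_of(tissue=tissue, population=pops[1]))
        if len(a) < min_support or len(b) < min_support:
            continue
        stat, p = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
        rows.append(
            {
                "site": site,
                "tissue": tissue,
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "statistic": stat,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["site", "tissue", "n_a", "n_b", "mean_a", "mean_b", "statistic", "p"]
    )
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def shared_site_summary(matrix: EditingMatrix, axis: str = "tissue") -> dict:
    """Partition sites by the number of groups (tissues or populations) they
    are detected in; reports exact-k counts and shared vs exclusive tallies."""
    if axis not in ("tissue", "population"):
        raise ValueError("axis must be 'tissue' or 'population'")
    groups = matrix.tissues if axis == "tissue" else matrix.populations
    k_counts: dict[int, int] = {k: 0 for k in range(1, len(groups) + 1)}
    per_group_exclusive = {g: 0 for g in groups}
    for site in matrix.levels.index:
        detected_in = [
            g
            for g in groups
            if matrix.detected(site, matrix.samples_of(**{axis: g})).size > 0
        ]
        k = len(detected_in)
        if k == 0:
            continue
        k_counts[k] += 1
        if k == 1:
            per_group_exclusive[detected_in[0]] += 1
    total = sum(k_counts.values())
    return {
        "axis": axis,
        "n_sites_detected": total,
        "counts_by_group_number": k_counts,
        "exclusive_by_group": per_group_exclusive,
        "pct_by_group_number": {k: percent(v, total, 1) for k, v in k_counts.items()},
    }
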