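import math

import numpy as np
import pandas as pd
import pytest

from editome import comparative as comp
from editome.detection import EditingObservation

from _oracles import bh_step_up, spearman_rho_ranks, wilcoxon_exact_two_sided
from conftest import matrix_from_levels


def mk_obs(chrom, pos, sample, level):
    return EditingObservation(
        chrom=chrom, pos=pos, sample_id=sample, ref_base="A", alt_base="G",
        rna_cov=20, rna_alt_count=int(level * 20), rna_alt_freq=level,
        dna_cov=20, dna_ref_freq=1.0, dna_alt_count=0,
    )


# ---------------------------------------------------------- matrix


def test_build_matrix(meta_frame):
    observations = [
        mk_obs("chr1", 100, "TBG1_kidney", 0.5),
        mk_obs("chr1", 100, "TBG2_kidney", 0.4),
        mk_obs("chr2", 50, "IMG1_lung", 0.9),
    ]
    m = comp.build_matrix(observations, meta_frame)
    assert list(m.levels.index) == ["chr1:100", "chr2:50"]  # (chrom, pos) order
    assert m.levels.loc["chr1:100", "TBG1_kidney"] == 0.5
    assert math.isnan(m.levels.loc["chr1:100", "IMG1_lung"])
    assert m.levels.notna().sum().sum() == 3


def test_build_matrix_duplicate_errors(meta_frame):
    observations = [mk_obs("chr1", 1, "TBG1_kidney", 0.5)] * 2
    with pytest.raises(ValueError, match="duplicate"):
        comp.build_matrix(observations, meta_frame)


def test_build_matrix_unknown_sample_errors(meta_frame):
    with pytest.raises(ValueError):
        comp.build_matrix([mk_obs("chr1", 1, "NOPE", 0.5)], meta_frame)


def test_metadata_must_cover_columns(meta_frame):
    levels = pd.DataFrame([[0.1]], index=["chr1:1"], columns=["ghost_sample"])
    with pytest.raises(ValueError, match="metadata"):
        comp.EditingMatrix(levels=levels, meta=meta_frame)


# ---------------------------------------------------------- normalization


def test_rpkm_and_cpm():
    assert comp.rpkm(10, 1000, 1e6) == pytest.approx(10.0)
    assert comp.rpkm(0, 500, 2e6) == 0.0
    assert comp.rpkm(3, 1500, 3e6) == pytest.approx(2 / 3)
    assert comp.cpm(10, 2e6) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        comp.rpkm(1, 0, 1e6)
    with pytest.raises(ValueError):
        comp.cpm(1, 0)


def test_matrix_normalizations():
    counts = pd.DataFrame({"s1": [10, 90], "s2": [40, 160]}, index=["g1", "g2"])
    c = comp.cpm_matrix(counts)
    assert c.loc["g1", "s1"] == pytest.approx(1e5)
    r = comp.rpkm_matrix(counts, {"g1": 1000, "g2": 2000})
    assert r.loc["g1", "s1"] == pytest.approx(10 / (1 * 100 / 1e6))


# ---------------------------------------------------------- spearman


def test_spearman_monotone():
    rho, p = comp.spearman_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert rho == pytest.approx(1.0) and p < 0.05
    rho, _ = comp.spearman_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
    assert rho == pytest.approx(-1.0)


def test_spearman_with_ties_matches_rank_oracle():
    x, y = [1, 2, 3, 4, 5], [5, 6, 7, 8, 7]
    rho, _ = comp.spearman_correlation(x, y)
    assert rho == pytest.approx(spearman_rho_ranks(x, y))


def test_spearman_small_n_is_nan():
    rho, p = comp.spearman_correlation([1, 2, 3], [1, 2, 3])
    assert math.isnan(rho) and math.isnan(p)


def test_spearman_drops_missing_pairs():
    rho, _ = comp.spearman_correlation([1, np.nan, 2, 3, 4, 5], [9, 0, 20, 30, 40, 50])
    assert rho == pytest.approx(1.0)


# ---------------------------------------------------------- wilcoxon


def test_wilcoxon_small_exact():
    _, p = comp.wilcoxon_rank_sum([1, 2], [3, 4])
    assert p == pytest.approx(1 / 3)


def test_wilcoxon_identical_groups():
    _, p = comp.wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0])
    assert p == 1.0


def test_wilcoxon_complete_separation_5v5():
    _, p = comp.wilcoxon_rank_sum([0.1] * 5, [0.9] * 5)
    # ties within groups force the approximation; exact value with distinct
    # values is 2/252
    x = [0.10, 0.11, 0.12, 0.13, 0.14]
    y = [0.90, 0.91, 0.92, 0.93, 0.94]
    _, p_exact = comp.wilcoxon_rank_sum(x, y)
    assert p_exact == pytest.approx(2 / 252)


def test_wilcoxon_exact_matches_enumeration(rng):
    for _ in range(10):
        nx, ny = int(rng.integers(2, 5)), int(rng.integers(2, 6))
        pooled = rng.permutation(np.arange(1, nx + ny + 1)).astype(float)
        x, y = pooled[:nx], pooled[nx:]
        _, p = comp.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(wilcoxon_exact_two_sided(x, y))


def test_wilcoxon_asymptotic_close_to_exact_at_6v6(rng):
    x = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
    y = np.array([4.0, 5.0, 6.0, 10.0, 11.0, 12.0])
    exact = wilcoxon_exact_two_sided(x, y)
    from scipy import stats

    approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    assert abs(approx - exact) < 0.01


# ---------------------------------------------------------- BH


def test_bh_single_and_hand_example():
    assert comp.bh_adjust([0.03]).tolist() == [0.03]
    assert comp.bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])


def test_bh_matches_oracle_random(rng):
    for _ in range(20):
        p = rng.uniform(0, 1, size=int(rng.integers(1, 50)))
        assert comp.bh_adjust(p).tolist() == pytest.approx(bh_step_up(p.tolist()))


def test_bh_properties(rng):
    p = rng.uniform(0, 1, size=30)
    adj = comp.bh_adjust(p)
    assert np.all(adj >= p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in raw ranks
    with pytest.raises(ValueError):
        comp.bh_adjust([1.2])


# ---------------------------------------------------------- ANOVA


def test_anova_identical_groups(meta_frame):
    m = matrix_from_levels(
        {"chr1:1": {s: 0.5 for s in meta_frame.index}}, meta_frame
    )
    res = comp.anova_tissue_levels(m)
    assert res.loc["chr1:1", "F"] == 0.0 and res.loc["chr1:1", "p"] == 1.0


def test_anova_hand_computed_fixture():
    meta = pd.DataFrame(
        {
            "population": ["P"] * 6,
            "tissue": ["t1", "t1", "t2", "t2", "t3", "t3"],
            "individual": [f"i{k}" for k in range(6)],
        },
        index=[f"s{k}" for k in range(6)],
    )
    m = matrix_from_levels(
        {"chr1:1": dict(zip(meta.index, [1.0, 2.0, 2.0, 3.0, 5.0, 6.0]))}, meta
    )
    res = comp.anova_tissue_levels(m)
    # SSB/dfB = 17.3333/2, SSW/dfW = 1.5/3 -> F = 17.3333
    assert res.loc["chr1:1", "F"] == pytest.approx(17.3333, rel=1e-4)


def test_anova_power_on_planted_shift(rng):
    n = 20
    meta = pd.DataFrame(
        {
            "population": ["P"] * (2 * n),
            "tissue": ["t1"] * n + ["t2"] * n,
            "individual": [f"i{k}" for k in range(2 * n)],
        },
        index=[f"s{k}" for k in range(2 * n)],
    )
    levels = np.concatenate([rng.normal(0.3, 0.05, n), rng.normal(0.6, 0.05, n)])
    m = matrix_from_levels({"chr1:1": dict(zip(meta.index, levels))}, meta)
    assert comp.anova_tissue_levels(m).loc["chr1:1", "p"] < 1e-3


def test_anova_insufficient_groups(meta_frame):
    m = matrix_from_levels({"chr1:1": {"TBG1_kidney": 0.5, "TBG2_kidney": 0.6}}, meta_frame)
    assert math.isnan(comp.anova_tissue_levels(m).loc["chr1:1", "p"])


# ---------------------------------------------------------- specificity calls


def _design_meta():
    rows = []
    for pop in ("TBG", "IMG"):
        for i in range(1, 6):
            for tissue in ("heart", "kidney", "lung", "muscle"):
                rows.append(
                    {
                        "sample": f"{pop}{i}_{tissue}",
                        "population": pop,
                        "tissue": tissue,
                        "individual": f"{pop}{i}",
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def test_call_tses():
    meta = _design_meta()
    kidney4 = {f"TBG{i}_kidney": 0.5 for i in range(1, 5)}
    kidney4_lung1 = dict(kidney4, IMG1_lung=0.5)
    kidney2 = {f"TBG{i}_kidney": 0.5 for i in (1, 2)}
    m = matrix_from_levels(
        {"chr1:1": kidney4, "chr1:2": kidney4_lung1, "chr1:3": kidney2}, meta
    )
    tses = comp.call_tses(m, min_support=3)
    assert tses["site"].tolist() == ["chr1:1"]
    assert tses["tissue"].tolist() == ["kidney"]


def test_call_pses():
    meta = _design_meta()
    m = matrix_from_levels(
        {
            "chr1:1": {f"IMG{i}_kidney": 0.5 for i in (1, 2, 3)},
            "chr1:2": dict({f"IMG{i}_kidney": 0.5 for i in (1, 2, 3)}, TBG1_kidney=0.4),
            "chr1:3": {f"IMG{i}_kidney": 0.5 for i in (1, 2)},
        },
        meta,
    )
    pses = comp.call_pses(m, "kidney", min_support=3)
    assert pses["site"].tolist() == ["chr1:1"]
    assert pses["population"].tolist() == ["IMG"]


def test_call_pdes():
    meta = _design_meta()
    same = {f"{p}{i}_kidney": 0.5 for p in ("TBG", "IMG") for i in range(1, 6)}
    split = {f"TBG{i}_kidney": 0.1 + i * 0.001 for i in range(1, 6)}
    split.update({f"IMG{i}_kidney": 0.9 + i * 0.001 for i in range(1, 6)})
    m = matrix_from_levels({"chr1:1": same, "chr1:2": split}, meta)
    pdes = comp.call_pdes(m, "kidney")
    by_site = pdes.set_index("site")
    assert by_site.loc["chr1:1", "p"] == 1.0 and not by_site.loc["chr1:1", "significant"]
    assert by_site.loc["chr1:2", "p"] == pytest.approx(2 / 252)
    # BH over 2 tests: 0.0079 * 2 / 1 = 0.0159 < 0.05
    assert bool(by_site.loc["chr1:2", "significant"])


def test_pdes_requires_min_support():
    meta = _design_meta()
    m = matrix_from_levels(
        {"chr1:1": {f"TBG{i}_kidney": 0.5 for i in (1, 2)}}, meta
    )
    assert len(comp.call_pdes(m, "kidney")) == 0


def test_pses_not_tested_as_pdes():
    """A population-specific site lacks support in the other group, so the
    pDES caller must skip it."""
    meta = _design_meta()
    m = matrix_from_levels(
        {"chr1:1": {f"IMG{i}_kidney": 0.5 for i in (1, 2, 3, 4)}}, meta
    )
    pses = comp.call_pses(m, "kidney")
    pdes = comp.call_pdes(m, "kidney")
    assert pses["site"].tolist() == ["chr1:1"] and len(pdes) == 0


def test_shared_site_summary():
    meta = _design_meta()
    shared = {f"{p}1_{t}": 0.5 for p in ("TBG", "IMG") for t in ("heart", "kidney", "lung", "muscle")}
    exclusive = {"TBG1_heart": 0.5}
    m = matrix_from_levels({"chr1:1": shared, "chr1:2": exclusive}, meta)
    s = comp.shared_site_summary(m, axis="tissue")
    assert s["counts_by_group_number"] == {1: 1, 2: 0, 3: 0, 4: 1}
    assert sum(s["counts_by_group_number"].values()) == s["n_sites_detected"]
    p = comp.shared_site_summary(m, axis="population")
    assert p["counts_by_group_number"] == {1: 1, 2: 1}
    assert sum(p["pct_by_group_number"].values()) == pytest.approx(100.0, abs=0.1)


def test_correlate_with_catalyzers_recovers_planted(rng):
    meta = _design_meta()
    n = len(meta)
    expr_target = rng.normal(100, 10, n)
    levels = 0.5 + 0.004 * (expr_target - 100) + rng.normal(0, 0.005, n)
    m = matrix_from_levels({"chr1:1": dict(zip(meta.index, levels))}, meta)
    expression = pd.DataFrame(
        {s: [expr_target[i], rng.normal(50, 5)] for i, s in enumerate(meta.index)},
        index=["CATA", "UNRELATED"],
    )
    table, summary = comp.correlate_with_catalyzers(m, expression, ["CATA"])
    row = table.iloc[0]
    assert row["significant"] and row["rho"] > 0.8
    assert summary["n_significant_sites"] == 1


def test_correlate_missing_catalyzer_warns(meta_frame):
    m = matrix_from_levels({"chr1:1": {"TBG1_kidney": 0.5}}, meta_frame)
    expression = pd.DataFrame({s: [1.0] for s in meta_frame.index}, index=["G"])
    with pytest.warns(UserWarning, match="absent"):
        table, _ = comp.correlate_with_catalyzers(m, expression, ["MISSING"])
    assert len(table) == 0
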