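import dataclasses
import math
import random

import pytest

from editome import detection as det
from editome.io_formats import VariantSet

from _oracles import brute_force_survivors
from conftest import make_pileup


def obs(**kwargs):
    """Observation builder with passing defaults."""
    defaults = dict(
        chrom="chr1", pos=100, sample_id="S1", ref_base="A", alt_base="G",
        rna_cov=20, rna_alt_count=5, rna_alt_freq=0.25, dna_cov=20,
        dna_ref_freq=1.0, dna_alt_count=0, mean_qual=30.0, multiallelic=False,
    )
    defaults.update(kwargs)
    return det.EditingObservation(**defaults)


# ---------------------------------------------------------- editing level


@pytest.mark.parametrize(
    "alt,cov,expected", [(5, 10, 0.5), (0, 10, 0.0), (10, 10, 1.0)]
)
def test_compute_editing_level(alt, cov, expected):
    assert det.compute_editing_level(alt, cov) == expected


def test_compute_editing_level_zero_coverage_errors():
    with pytest.raises(ValueError):
        det.compute_editing_level(0, 0)


# ---------------------------------------------------------- candidate calling


def test_call_candidates_simple_mismatch():
    dna = [make_pileup("chr1", 100, "S1", "DNA", {"A": 20})]
    rna = [make_pileup("chr1", 100, "S1", "RNA", {"A": 5, "G": 5})]
    (o,) = det.call_candidates(dna, rna)
    assert (o.ref_base, o.alt_base) == ("A", "G")
    assert o.rna_alt_freq == 0.5 and o.rna_cov == 10
    assert o.dna_ref_freq == 1.0 and o.dna_alt_count == 0


def test_call_candidates_no_mismatch_emits_nothing():
    dna = [make_pileup("chr1", 100, "S1", "DNA", {"A": 20})]
    rna = [make_pileup("chr1", 100, "S1", "RNA", {"A": 10})]
    assert det.call_candidates(dna, rna) == []


def test_call_candidates_het_snp_gets_low_dna_ref_freq():
    dna = [make_pileup("chr1", 100, "S1", "DNA", {"A": 10, "G": 10})]
    rna = [make_pileup("chr1", 100, "S1", "RNA", {"G": 10})]
    (o,) = det.call_candidates(dna, rna)
    assert o.ref_base == "A" and o.dna_ref_freq == 0.5 and o.dna_alt_count == 10


def test_call_candidates_multiallelic_flag():
    dna = [make_pileup("chr1", 100, "S1", "DNA", {"A": 20})]
    rna = [make_pileup("chr1", 100, "S1", "RNA", {"A": 4, "G": 3, "C": 3})]
    observations = det.call_candidates(dna, rna)
    assert len(observations) == 2 and all(o.multiallelic for o in observations)
    # one supported alt plus a single stray read: not multiallelic
    rna2 = [make_pileup("chr1", 100, "S1", "RNA", {"A": 4, "G": 5, "C": 1})]
    assert not any(o.multiallelic for o in det.call_candidates(dna, rna2))


def test_call_candidates_unsorted_errors():
    dna = [
        make_pileup("chr1", 200, "S1", "DNA", {"A": 20}),
        make_pileup("chr1", 100, "S1", "DNA", {"A": 20}),
    ]
    with pytest.raises(ValueError, match="not sorted"):
        det.call_candidates(dna, [])


# ---------------------------------------------------------- primary filters


def test_primary_filter_order_and_boundaries():
    cfg = det.FilterConfig()
    assert det.apply_primary_filters(obs(rna_cov=9), cfg) == "min_rna_cov"
    assert det.apply_primary_filters(obs(dna_cov=4), cfg) == "min_dna_cov"
    assert det.apply_primary_filters(obs(rna_alt_count=1, rna_alt_freq=0.05), cfg) == "min_alt_reads"
    assert det.apply_primary_filters(obs(dna_alt_count=1), cfg) == "dna_variant"
    assert det.apply_primary_filters(obs(rna_cov=300, rna_alt_count=2, rna_alt_freq=2 / 300), cfg) == "min_rna_alt_freq"
    assert det.apply_primary_filters(obs(dna_ref_freq=0.94), cfg) == "min_dna_ref_freq"
    assert det.apply_primary_filters(obs(multiallelic=True), cfg) == "multiallelic"


def test_primary_filter_first_violation_wins():
    cfg = det.FilterConfig()
    failing_everything = obs(
        rna_cov=5, dna_cov=2, rna_alt_count=1, dna_alt_count=3,
        rna_alt_freq=0.001, dna_ref_freq=0.5, multiallelic=True,
    )
    assert det.apply_primary_filters(failing_everything, cfg) == "min_rna_cov"


def test_primary_filter_exact_boundary_passes():
    cfg = det.FilterConfig()
    boundary = obs(
        rna_cov=10, dna_cov=5, rna_alt_count=2, dna_alt_count=0,
        rna_alt_freq=2 / 10, dna_ref_freq=0.95, multiallelic=False,
    )
    assert det.apply_primary_filters(boundary, cfg) is None
    tight = obs(rna_cov=200, rna_alt_count=2, rna_alt_freq=0.01, dna_ref_freq=0.95)
    assert det.apply_primary_filters(tight, cfg) is None


# ---------------------------------------------------------- variant mask


def test_mask_known_variants():
    variants = VariantSet(snps={("chr1", 100)}, indels={("chr1", 200, 205)})
    kept = det.mask_known_variants(
        [obs(pos=100), obs(pos=203), obs(pos=206), obs(pos=199)], variants
    )
    assert [o.pos for o in kept] == [206, 199]


def test_mask_empty_variantset_is_identity():
    observations = [obs(pos=p) for p in (1, 2, 3)]
    assert det.mask_known_variants(observations, VariantSet()) == observations


# ---------------------------------------------------------- cohort filters


def _cfg(**kw):
    kw.setdefault("autosome_names", ("chr1", "chr2"))
    return det.FilterConfig(**kw)


def test_cohort_min_samples():
    observations = [obs(sample_id=s) for s in ("S1", "S2")]
    hq, sites = det.apply_cohort_filters(observations, _cfg())
    assert sites == [] and hq == []
    observations.append(obs(sample_id="S3"))
    hq, sites = det.apply_cohort_filters(observations, _cfg())
    assert len(sites) == 1 and sites[0].n_samples == 3 and len(hq) == 3


def test_cohort_all_ones_dropped_but_not_partial():
    all_ones = [
        obs(sample_id=s, rna_alt_count=10, rna_cov=10, rna_alt_freq=1.0)
        for s in ("S1", "S2", "S3")
    ]
    _, sites = det.apply_cohort_filters(all_ones, _cfg())
    assert sites == []
    mixed = all_ones[:2] + [obs(sample_id="S3", rna_alt_freq=0.9)]
    _, sites = det.apply_cohort_filters(mixed, _cfg())
    assert len(sites) == 1


def test_cohort_sex_chromosome_dropped():
    observations = [obs(chrom="chrX", sample_id=s) for s in ("S1", "S2", "S3")]
    _, sites = det.apply_cohort_filters(observations, _cfg())
    assert sites == []


def test_cohort_requires_autosome_names():
    with pytest.raises(ValueError, match="autosome_names"):
        det.apply_cohort_filters([obs()], det.FilterConfig())


def test_cohort_order_independence():
    observations = [
        obs(pos=p, sample_id=s)
        for p in (100, 200, 300)
        for s in ("S1", "S2", "S3", "S4")
    ]
    _, sites_fwd = det.apply_cohort_filters(observations, _cfg())
    shuffled = observations[:]
    random.Random(5).shuffle(shuffled)
    _, sites_rev = det.apply_cohort_filters(shuffled, _cfg())
    assert [s.site for s in sites_fwd] == [s.site for s in sites_rev]


# ---------------------------------------------------------- level summary


def test_level_summary_trivial():
    observations = [
        obs(sample_id=f"S{i}", rna_alt_freq=f, rna_alt_count=int(f * 10), rna_cov=10)
        for i, f in enumerate((0.4, 0.6, 1.0))
    ]
    s = det.level_summary(observations)
    assert s["n_level_gt_05"] == 2 and s["n_level_gt_095"] == 1 and s["n_level_eq_1"] == 1
    assert s["pct_level_gt_05"] == pytest.approx(66.67)


def test_level_summary_empty():
    s = det.level_summary([])
    assert s["n_observations"] == 0
    assert math.isnan(s["pct_level_gt_05"])


def test_level_summary_support_histogram():
    observations = [obs(pos=100, sample_id=s) for s in ("S1", "S2")] + [
        obs(pos=200, sample_id="S1")
    ]
    s = det.level_summary(observations)
    assert s["support_histogram"] == {1: 1, 2: 1}


# ---------------------------------------------------------- properties


def _random_observations(rng, n=300):
    out = []
    for _ in range(n):
        rna_cov = int(rng.integers(1, 40))
        alt = int(rng.integers(0, rna_cov + 1))
        dna_cov = int(rng.integers(0, 40))
        dna_alt = int(rng.integers(0, 4))
        dna_ref = max(dna_cov - dna_alt, 0)
        out.append(
            obs(
                chrom=f"chr{int(rng.integers(1, 3))}",
                pos=int(rng.integers(1, 40)),
                sample_id=f"S{int(rng.integers(1, 7))}",
                rna_cov=rna_cov,
                rna_alt_count=alt,
                rna_alt_freq=alt / rna_cov,
                dna_cov=dna_cov,
                dna_ref_freq=dna_ref / dna_cov if dna_cov else 0.0,
                dna_alt_count=dna_alt,
                multiallelic=bool(rng.random() < 0.1),
            )
        )
    return out


def test_filter_monotonicity(rng):
    """Tightening any threshold never increases the passing count."""
    observations = _random_observations(rng)
    base_cfg = _cfg()
    base_n = len(det.filter_observations(observations, base_cfg)[0])
    tighter = [
        {"min_rna_cov": base_cfg.min_rna_cov + 5},
        {"min_dna_cov": base_cfg.min_dna_cov + 5},
        {"min_alt_reads": base_cfg.min_alt_reads + 2},
        {"min_rna_alt_freq": 0.2},
        {"min_dna_ref_freq": 0.99},
    ]
    for change in tighter:
        n = len(det.filter_observations(observations, _cfg(**change))[0])
        assert n <= base_n, change


def test_pipeline_equals_brute_force_oracle(rng):
    """Package survivors equal a single-pass independent re-implementation."""
    cfg = _cfg()
    samples = [f"S{i}" for i in range(4)]
    dna_map, rna_map = {}, {}
    dna_records, rna_records = {s: [] for s in samples}, {s: [] for s in samples}
    for pos in range(1, 81):
        for s in samples:
            dcounts = {
                "A": int(rng.integers(0, 25)), "C": int(rng.integers(0, 3)),
                "G": int(rng.integers(0, 3)), "T": 0,
            }
            rcounts = {
                "A": int(rng.integers(0, 25)), "C": int(rng.integers(0, 6)),
                "G": int(rng.integers(0, 6)), "T": int(rng.integers(0, 2)),
            }
            dna_map[(s, "chr1", pos)] = dcounts
            rna_map[(s, "chr1", pos)] = rcounts
            dna_records[s].append(make_pileup("chr1", pos, s, "DNA", dcounts))
            rna_records[s].append(make_pileup("chr1", pos, s, "RNA", rcounts))

    variants = VariantSet(snps={("chr1", 5)}, indels={("chr1", 10, 12)})
    pooled = []
    for s in samples:
        cands = det.call_candidates(dna_records[s], rna_records[s], min_alt_reads=cfg.min_alt_reads)
        passed, _ = det.filter_observations(cands, cfg)
        pooled.extend(passed)
    pooled = det.mask_known_variants(pooled, variants)
    hq, sites = det.apply_cohort_filters(pooled, cfg)

    oracle_obs, oracle_sites = brute_force_survivors(
        dna_map, rna_map, variants.snps, variants.indels, cfg
    )
    assert {s.site for s in sites} == oracle_sites
    assert {(o.sample_id, o.chrom, o.pos, o.alt_base) for o in hq} == oracle_obs


def test_filter_config_defaults_match_contract():
    cfg = det.FilterConfig()
    assert dataclasses.astuple(cfg)[:6] == (10, 5, 2, 0, 0.01, 0.95)
    assert cfg.exclude_multiallelic and cfg.min_samples == 3
    assert cfg.drop_all_ones and cfg.autosomes_only
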