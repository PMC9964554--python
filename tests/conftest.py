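import numpy as np
import pandas as pd
import pytest

from editome.io_formats import GeneModel, PileupRecord, Transcript
from editome.synthetic_data import SimConfig, generate_reference, plant_truth, simulate_pileups


@pytest.fixture
def toy_genes():
    """Two genes on chr1 (one per strand) and one on chr2."""
    plus = GeneModel(
        gene_id="G1",
        chrom="chr1",
        strand="+",
        biotype="protein_coding",
        transcripts=[
            Transcript(
                transcript_id="T1",
                exons=[(100, 200), (300, 400)],
                cds=[(150, 200), (300, 350)],
                utr5=[(100, 149)],
                utr3=[(351, 400)],
            )
        ],
    )
    minus = GeneModel(
        gene_id="G2",
        chrom="chr1",
        strand="-",
        biotype="lincRNA",
        transcripts=[Transcript(transcript_id="T2", exons=[(600, 700), (800, 900)])],
    )
    other = GeneModel(
        gene_id="G3",
        chrom="chr2",
        strand="+",
        biotype="protein_coding",
        transcripts=[Transcript(transcript_id="T3", exons=[(50, 250)], cds=[(101, 220)])],
    )
    return [plus, minus, other]


def make_pileup(chrom, pos, sample, source, counts, qual=30.0):
    return PileupRecord(
        chrom=chrom,
        pos=pos,
        sample_id=sample,
        source=source,
        counts_a=counts.get("A", 0),
        counts_c=counts.get("C", 0),
        counts_g=counts.get("G", 0),
        counts_t=counts.get("T", 0),
        mean_qual=qual,
    )


@pytest.fixture
def small_sim_config():
    return SimConfig(
        seed=11,
        n_chrom=2,
        chrom_length=40_000,
        n_genes=10,
        n_a_to_i=20,
        n_c_to_u=10,
        n_snps=12,
        n_background_positions=60,
        dna_depth_mean=25.0,
        rna_depth_mean=40.0,
        base_error_rate=0.002,
        level_min=0.1,
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One small simulated dataset shared across read-only tests."""
    cfg = SimConfig(
        seed=7,
        n_chrom=2,
        chrom_length=40_000,
        n_genes=10,
        n_a_to_i=20,
        n_c_to_u=10,
        n_snps=12,
        n_background_positions=60,
        level_min=0.1,
        n_correlated_sites=6,
    )
    genome, genes = generate_reference(cfg)
    truth = plant_truth(cfg, genome, genes)
    dna, rna, expression = simulate_pileups(truth, cfg, genome, genes)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "dna": dna,
        "rna": rna,
        "expression": expression,
    }


@pytest.fixture
def meta_frame():
    """Metadata for a 2-population x 2-tissue x 2-individual toy design."""
    rows = []
    for pop in ("TBG", "IMG"):
        for i in (1, 2):
            for tissue in ("kidney", "lung"):
                rows.append(
                    {
                        "sample": f"{pop}{i}_{tissue}",
                        "population": pop,
                        "tissue": tissue,
                        "individual": f"{pop}{i}",
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def matrix_from_levels(levels_by_site, meta):
    """Build an EditingMatrix directly from {site: {sample: level}}."""
    from editome.comparative import EditingMatrix

    frame = pd.DataFrame(levels_by_site).T.reindex(columns=meta.index)
    frame.index.name = "site"
    return EditingMatrix(levels=frame.astype(float), meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
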