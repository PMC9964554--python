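# editome

RNA editing site detection, classification and comparative analysis from
matched per-sample DNA/RNA pileups.

The pipeline compares DNA and RNA base counts point by point, applies a
per-sample filter cascade (RNA coverage ≥ 10, DNA coverage ≥ 5, edited
reads ≥ 2, zero DNA variant reads, RNA variant fraction ≥ 0.01, DNA
reference fraction ≥ 0.95, no multiallelic positions), masks known
SNPs/INDELs, then applies cohort filters (≥ 3 supporting samples, not
fully edited in every sample, autosomes only).  Because poly(A) libraries
are unstranded, canonical classes are resolved through the hosting gene's
strand: A>G on plus-strand genes and T>C on minus-strand genes are A-to-I;
C>T / G>A are C-to-U; sites without a host gene, or with hosts on both
strands, stay ambiguous.  Downstream analyses cover flanking-sequence
preference, codon-level recoding, site clustering, exon-boundary (splice)
proximity, tissue-specific (tSES), population-specific (pSES) and
population-differential (pDES, Wilcoxon + Benjamini-Hochberg) calling,
and Spearman correlation of editing levels with catalyzing-gene
expression (CPM/RPKM normalization included).

A synthetic-data module generates a toy genome, Ensembl-dialect GTF, VCF,
multi-sample pileups and expression counts with planted SNPs and editing
sites (2 populations × 4 tissues × 5 individuals by default), so the whole
pipeline is testable without sequencing data.

## Command line

```sh
# simulate a dataset (YAML holds SimConfig fields; seed fixes all bytes)
editome simulate --config sim.yaml --seed 1 --outdir out/

# detection + filter cascade
editome detect --dna-pileup out/dna_pileup.tsv --rna-pileup out/rna_pileup.tsv \
    --samples out/samples.tsv --vcf out/variants.vcf --autosomes chr1,chr2 \
    --out detected/

# strand/class/feature annotation
editome annotate --sites detected/sites.tsv --gtf out/annotation.gtf --out annotated/

# full pipeline from one config (simulate -> detect -> annotate ->
# characterize -> compare; writes summary.json)
editome run --config pipeline.yaml

# utilities
editome convert-mpileup --mpileup sample.mpileup --sample S1 --source RNA --out s1.tsv
editome validate-inputs --genome g.fa --gtf a.gtf --vcf v.vcf --pileup p.tsv
```

A minimal pipeline config:

```yaml
seed: 1
outdir: run1
simulate:
  n_genes: 20
  n_a_to_i: 40
  n_c_to_u: 20
  n_snps: 30
  level_min: 0.1
filters:
  min_samples: 3
thresholds:
  splice_max_dist: 5
  min_support: 3
```

Pileup TSV dialect (1-based positions, forward-reference counts):
`chrom  pos  sample  source  A  C  G  T  mean_qual` with source `DNA` or
`RNA`.  Coordinates are 1-based inclusive everywhere; only BED output is
0-based half-open.

## Layout

- `src/editome/io_formats.py` — FASTA/GTF/VCF/BED/pileup/mpileup I/O
- `src/editome/synthetic_data.py` — simulator + recovery evaluation
- `src/editome/detection.py` — candidate calling and filter cascade
- `src/editome/annotation.py` — strand resolution, classes, features
- `src/editome/characterization.py` — flanks, recoding, clustering, splicing
- `src/editome/comparative.py` — matrices, tSES/pSES/pDES, statistics
- `src/editome/pipeline.py`, `src/editome/cli.py` — orchestration and CLI
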