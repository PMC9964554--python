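"""End-to-end orchestration: simulate -> detect -> annotate -> characterize -> compare.

Each stage persists its artifacts under the output directory and the run
finishes with a machine-readable ``summary.json``.  A failing stage
aborts the run with the stage name attached; artifacts written by earlier
stages are retained.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotation, characterization, comparative, detection, io_formats, synthetic_data
from ._utils import percent

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class Thresholds:
    splice_max_dist: int = 5
    cluster_threshold: int = 20
    correlation_alpha: float = 0.05
    bh_alpha: float = 0.05
    min_support: int = 3
    flank_k: int = 10


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "editome_out"
    simulate: synthetic_data.SimConfig | None = None
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    filters: detection.FilterConfig = dataclasses.field(default_factory=detection.FilterConfig)
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls(
            seed=int(data.get("seed", 0)),
            outdir=str(data.get("outdir", "editome_out")),
            inputs=dict(data.get("inputs", {})),
        )
        if "simulate" in data and data["simulate"] is not None:
            sim = dict(data["simulate"])
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = synthetic_data.SimConfig.from_dict(sim)
        if "filters" in data:
            f = dict(data["filters"])
            if "autosome_names" in f and f["autosome_names"] is not None:
                f["autosome_names"] = tuple(f["autosome_names"])
            cfg.filters = detection.FilterConfig(**f)
        if "thresholds" in data:
            cfg.thresholds = Thresholds(**data["thresholds"])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out: dict[str, Any] = {
            "seed": self.seed,
            "outdir": self.outdir,
            "inputs": self.inputs,
            "filters": dataclasses.asdict(self.filters),
            "thresholds": dataclasses.asdict(self.thresholds),
        }
        if self.simulate is not None:
            out["simulate"] = dataclasses.asdict(self.simulate)
        if out["filters"]["autosome_names"] is not None:
            out["filters"]["autosome_names"] = list(out["filters"]["autosome_names"])
        if self.simulate is not None:
            for key in ("populations", "tissues", "catalyzer_names"):
                out["simulate"][key] = list(out["simulate"][key])
        return out


OBS_COLUMNS = [
    "chrom", "pos", "sample_id", "ref_base", "alt_base", "rna_cov", "rna_alt_count",
    "rna_alt_freq", "dna_cov", "dna_ref_freq", "dna_alt_count", "mean_qual", "multiallelic",
]


def observations_to_frame(observations) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(o, c) for c in OBS_COLUMNS} for o in observations], columns=OBS_COLUMNS
    )


def frame_to_observations(frame: pd.DataFrame) -> list[detection.EditingObservation]:
    return [
        detection.EditingObservation(
            chrom=str(r.chrom), pos=int(r.pos), sample_id=str(r.sample_id),
            ref_base=str(r.ref_base), alt_base=str(r.alt_base), rna_cov=int(r.rna_cov),
            rna_alt_count=int(r.rna_alt_count), rna_alt_freq=float(r.rna_alt_freq),
            dna_cov=int(r.dna_cov), dna_ref_freq=float(r.dna_ref_freq),
            dna_alt_count=int(r.dna_alt_count), mean_qual=float(r.mean_qual),
            multiallelic=bool(r.multiallelic),
        )
        for r in frame.itertuples(index=False)
    ]


def run_simulate(config: PipelineConfig, outdir: Path) -> None:
    sim = config.simulate
    assert sim is not None
    genome, genes = synthetic_data.generate_reference(sim)
    truth = synthetic_data.plant_truth(sim, genome, genes)
    dna, rna, expression = synthetic_data.simulate_pileups(truth, sim, genome, genes)
    io_formats.write_fasta(genome, outdir / "genome.fa")
    io_formats.write_gtf(genes, outdir / "annotation.gtf")
    io_formats.write_vcf(
        [(c, p, ref, alt, gt) for c, p, ref, alt, gt in truth.snps], outdir / "variants.vcf"
    )
    io_formats.write_pileup_tsv(dna, outdir / "dna_pileup.tsv")
    io_formats.write_pileup_tsv(rna, outdir / "rna_pileup.tsv")
    expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    sim.sample_metadata().to_csv(outdir / "samples.tsv", sep="\t")
    config.inputs = {
        "genome": str(outdir / "genome.fa"),
        "gtf": str(outdir / "annotation.gtf"),
        "vcf": str(outdir / "variants.vcf"),
        "dna_pileup": str(outdir / "dna_pileup.tsv"),
        "rna_pileup": str(outdir / "rna_pileup.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "expression": str(outdir / "expression.tsv"),
    }
    if config.filters.autosomes_only and not config.filters.autosome_names:
        config.filters.autosome_names = tuple(sorted(genome))


def run_detect(config: PipelineConfig, outdir: Path):
    meta = pd.read_csv(config.inputs["samples"], sep="\t", index_col=0)
    dna_records = io_formats.read_pileup_tsv(config.inputs["dna_pileup"])
    rna_records = io_formats.read_pileup_tsv(config.inputs["rna_pileup"])
    variants = (
        io_formats.read_vcf_positions(config.inputs["vcf"])
        if config.inputs.get("vcf")
        else io_formats.VariantSet()
    )
    dna_by_sample: dict[str, list] = {}
    for r in dna_records:
        dna_by_sample.setdefault(r.sample_id, []).append(r)
    rna_by_sample: dict[str, list] = {}
    for r in rna_records:
        rna_by_sample.setdefault(r.sample_id, []).append(r)

    all_passed = []
    for sample_id in meta.index:
        rna = rna_by_sample.get(sample_id, [])
        dna_sample = (
            meta.loc[sample_id, "dna_sample"] if "dna_sample" in meta.columns else sample_id
        )
        dna = dna_by_sample.get(dna_sample, [])
        dna.sort(key=lambda r: (r.chrom, r.pos))
        rna.sort(key=lambda r: (r.chrom, r.pos))
        candidates = detection.call_candidates(
            dna, rna, sample_id=sample_id, min_alt_reads=config.filters.min_alt_reads
        )
        passed, reasons = detection.filter_observations(candidates, config.filters)
        logger.info(
            "sample %s: %d candidates, %d passed primary filters (%s)",
            sample_id, len(candidates), len(passed), dict(reasons),
        )
        all_passed.extend(passed)

    masked = detection.mask_known_variants(all_passed, variants)
    hq_obs, site_calls = detection.apply_cohort_filters(masked, config.filters)

    observations_to_frame(hq_obs).to_csv(outdir / "observations.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(s) for s in site_calls],
        columns=["chrom", "pos", "ref_base", "alt_base", "n_samples", "mean_level"],
    ).to_csv(outdir / "sites.tsv", sep="\t", index=False)
    return hq_obs, site_calls, meta


def run_annotate(config: PipelineConfig, outdir: Path, site_calls):
    genes = io_formats.read_gtf(config.inputs["gtf"])
    sites = annotation.annotate_sites(site_calls, genes)
    frame = pd.DataFrame(
        [
            {
                "chrom": s.chrom, "pos": s.pos, "ref_base": s.ref_base, "alt_base": s.alt_base,
                "raw_type": s.raw_type, "canonical_class": s.canonical_class,
                "resolved_strand": s.resolved_strand, "feature": s.feature,
                "host_genes": ";".join(s.host_genes), "biotype": s.biotype or "",
                "n_samples": s.n_samples, "mean_level": s.mean_level,
            }
            for s in sites
        ]
    )
    frame.to_csv(outdir / "annotated_sites.tsv", sep="\t", index=False)
    io_formats.write_sites_bed(sites, outdir / "sites.bed")
    return sites, genes


def run_characterize(config: PipelineConfig, outdir: Path, sites, genes, genome):
    th = config.thresholds
    gene_map = {g.gene_id: g for g in genes}

    for cls in (annotation.A_TO_I, annotation.C_TO_U):
        flanks = [
            characterization.extract_flank(genome, s.chrom, s.pos, s.resolved_strand, th.flank_k)
            for s in sites
            if s.canonical_class == cls and s.resolved_strand in ("+", "-")
        ]
        matrix = characterization.flank_frequency(flanks, th.flank_k)
        name = "a_to_i" if cls == annotation.A_TO_I else "c_to_u"
        matrix.T.to_csv(outdir / f"flank_{name}.tsv", sep="\t", index_label="offset")

    recoding: list[characterization.RecodingResult] = []
    for s in sites:
        if s.canonical_class not in (annotation.A_TO_I, annotation.C_TO_U):
            continue
        for gid in s.host_genes:
            gene = gene_map[gid]
            for tx in gene.transcripts:
                if any(cs <= s.pos <= ce for cs, ce in tx.cds):
                    recoding.append(characterization.recode_site(genome, s, gene, tx))
    pd.DataFrame([dataclasses.asdict(r) for r in recoding]).to_csv(
        outdir / "recoding.tsv", sep="\t", index=False
    )

    distances = characterization.nearest_site_distances(sites) if sites else []
    pd.DataFrame(
        {"chrom": [s.chrom for s in sites], "pos": [s.pos for s in sites], "nearest": distances}
    ).to_csv(outdir / "nearest_distances.tsv", sep="\t", index=False)

    boundary: dict[tuple[str, int], float] = {}
    for s in sites:
        per_tx = characterization.site_exon_boundary_distances(s, gene_map)
        if per_tx:
            boundary[s.site] = min(per_tx.values())
    pd.DataFrame(
        [{"chrom": c, "pos": p, "min_exon_boundary_dist": d} for (c, p), d in sorted(boundary.items())]
    ).to_csv(outdir / "exon_boundary_distances.tsv", sep="\t", index=False)
    splice = characterization.splice_candidate_filter(boundary, th.splice_max_dist)

    return {
        "recoding": recoding,
        "cluster_summary": characterization.clustering_summary(sites, th.cluster_threshold)
        if sites
        else {},
        "n_splice_candidates": len(splice),
    }


def run_compare(config: PipelineConfig, outdir: Path, hq_obs, meta, genes):
    th = config.thresholds
    matrix = comparative.build_matrix(hq_obs, meta)
    matrix.levels.to_csv(outdir / "editing_matrix.tsv", sep="\t", index_label="site")

    tses = comparative.call_tses(matrix, th.min_support)
    tses.to_csv(outdir / "tses.tsv", sep="\t", index=False)

    pses_frames, pdes_frames = [], []
    for tissue in matrix.tissues:
        pses_frames.append(comparative.call_pses(matrix, tissue, th.min_support))
        pdes_frames.append(
            comparative.call_pdes(matrix, tissue, th.bh_alpha, th.min_support)
        )
    pses = pd.concat(pses_frames, ignore_index=True) if pses_frames else pd.DataFrame()
    pdes = pd.concat(pdes_frames, ignore_index=True) if pdes_frames else pd.DataFrame()
    pses.to_csv(outdir / "pses.tsv", sep="\t", index=False)
    pdes.to_csv(outdir / "pdes.tsv", sep="\t", index=False)

    correlation_summary = {}
    expr_path = config.inputs.get("expression")
    if expr_path:
        expression = pd.read_csv(expr_path, sep="\t", index_col=0)
        name_to_id = {g.gene_name: g.gene_id for g in genes if g.gene_name}
        catalyzer_ids = [gid for gid in name_to_id.values() if gid in expression.index]
        if catalyzer_ids:
            table, correlation_summary = comparative.correlate_with_catalyzers(
                matrix, expression, catalyzer_ids, th.correlation_alpha
            )
            table.to_csv(outdir / "catalyzer_correlations.tsv", sep="\t", index=False)

    n_pdes_sig = int(pdes["significant"].sum()) if "significant" in pdes else 0
    return {
        "matrix_shape": list(matrix.levels.shape),
        "n_tses": int(len(tses)),
        "n_pses": int(len(pses)),
        "n_pdes_tested": int(len(pdes)),
        "n_pdes_significant": n_pdes_sig,
        "shared_by_tissue": comparative.shared_site_summary(matrix, "tissue"),
        "shared_by_population": comparative.shared_site_summary(matrix, "population"),
        "catalyzer_correlation": correlation_summary,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order and write summary.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if config.simulate is not None:
            run_simulate(config, outdir)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        stage = "detect"
        for key in ("dna_pileup", "rna_pileup", "samples"):
            if not config.inputs.get(key) or not Path(config.inputs[key]).exists():
                raise FileNotFoundError(f"missing required input {key!r}")
        hq_obs, site_calls, meta = run_detect(config, outdir)

        stage = "annotate"
        if not config.inputs.get("gtf") or not Path(config.inputs["gtf"]).exists():
            raise FileNotFoundError("missing required input 'gtf'")
        sites, genes = run_annotate(config, outdir, site_calls)

        stage = "characterize"
        genome = io_formats.read_fasta(config.inputs["genome"])
        char = run_characterize(config, outdir, sites, genes, genome)

        stage = "compare"
        comp = run_compare(config, outdir, hq_obs, meta, genes)

        stage = "summarize"
        level = detection.level_summary(hq_obs)
        classes = annotation.class_count_summary(sites, hq_obs)
        nonsyn = characterization.recoding_summary(char["recoding"])["nonsynonymous"]
        summary = {
            "n_observations": level["n_observations"],
            "n_sites": level["n_sites"],
            "level_summary": {k: v for k, v in level.items() if k != "support_histogram"},
            "support_histogram": level["support_histogram"],
            "class_summary": classes,
            "cluster_summary": char["cluster_summary"],
            "n_splice_candidates": char["n_splice_candidates"],
            "nonsynonymous": nonsyn,
            "comparative": comp,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        return summary
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rethrown with stage context
        raise StageError(stage, exc) from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    return obj
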