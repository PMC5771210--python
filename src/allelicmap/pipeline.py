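"""End-to-end driver: simulate -> filter -> annotate -> intersect.

Two entry points:

* :func:`run_study` — the in-memory allelic mapping experiment: generate a
  toy genome, two (or more) independently mutagenized allelic populations
  sharing one causal gene with distinct lesions, bulk-sequence the selected
  homozygous mutants, run the filter cascade and effect annotation per
  population, and intersect the candidate genes.
* :func:`run_pipeline` — the same with all artifacts written to disk
  (FASTA/GFF3/VCF/TSV plus a run manifest with checksums), or, when
  ``simulate`` is off, driven from user-supplied variant files.

One seed feeds a tree of named substreams (genome, background, then
mutagenesis / meiosis / sequencing per population), so each stage is
independently reproducible and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as amio
from .analysis import (
    CandidateSet,
    IntersectionResult,
    build_candidate_set,
    intersect_candidates,
    plot_ratio_profile,
    snp_ratio_profile,
)
from .annotation import AnnotatedVariant, EffectAnnotator, filter_large_effect
from .filtering import (
    BackgroundPanel,
    FilterConfig,
    FilterReport,
    VariantCall,
    calls_from_table,
    run_filter_cascade,
)
from .genome import GeneModel, ToyGenome, generate_reference
from .simulate import (
    InducedMutationSet,
    PoolSeqParams,
    Snv,
    generate_parental_background,
    induce_ems_mutations,
    pick_large_effect_site,
    pool_and_sequence,
    select_homozygous_mutants,
    simulate_f2,
)

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Flat run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str | None = None
    simulate: bool = True

    # --- simulation (study conditions) ---
    n_chrom: int = Field(5, ge=1)
    chrom_length_bp: int = Field(150_000, ge=10_000)
    gc_content: float = Field(0.44, gt=0.0, lt=1.0)
    n_genes: int = Field(100, ge=1)
    cm_per_chromosome: float = Field(100.0, ge=0.0)
    n_populations: int = Field(2, ge=2)
    n_mutations_per_line: int = Field(147, ge=1)
    ems_fraction: float = Field(0.95, ge=0.0, le=1.0)
    n_background_snps: int = Field(400, ge=0)
    n_f2_plants: int = Field(160, ge=1)
    n_pooled: int = Field(20, ge=1)
    mean_depth: float = Field(15.0, gt=0.0)
    seq_error: float = Field(0.0, ge=0.0, lt=0.5)
    causal_gene: str | None = None

    # --- filtering / annotation ---
    min_depth: int = Field(5, ge=1)
    max_depth: int = Field(100, ge=1)
    ratio_cutoff: float = Field(1.0, gt=0.0, le=1.0)
    af_threshold: float = Field(0.05, ge=0.0, le=1.0)
    ems_only: bool = True
    include_start_stop_loss: bool = False
    intersect_before_effect: bool = False
    make_plot: bool = False

    # --- file-driven mode (simulate = false) ---
    reference_fasta: str | None = None
    gff3: str | None = None
    bulk_vcfs: list[str] = Field(default_factory=list)
    parent_vcf: str | None = None
    af_panel: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if not self.simulate:
            missing = [
                name
                for name, val in [
                    ("reference_fasta", self.reference_fasta),
                    ("gff3", self.gff3),
                ]
                if not val
            ]
            if len(self.bulk_vcfs) < 2:
                missing.append("bulk_vcfs (need >= 2)")
            if missing:
                raise ValueError(f"file-driven mode requires: {', '.join(missing)}")
            for p in [self.reference_fasta, self.gff3, self.parent_vcf,
                      self.af_panel, *self.bulk_vcfs]:
                if p and not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            self.min_depth, self.max_depth, self.ratio_cutoff,
            self.af_threshold, self.ems_only,
        )


@dataclass
class PopulationResult:
    """Everything produced for one bulked F2 population."""

    population_id: str
    mutations: InducedMutationSet | None
    causal_snv: Snv | None
    variant_table: pd.DataFrame  # truth-labelled in simulate mode
    candidates: list[VariantCall]
    report: FilterReport
    annotations: list[AnnotatedVariant]  # annotations of the cascade survivors
    candidate_set: CandidateSet


@dataclass
class StudyResult:
    genome: ToyGenome
    genes: list[GeneModel]
    causal_gene_id: str | None
    background: list[Snv]
    panel_table: pd.DataFrame
    populations: list[PopulationResult]
    intersection: IntersectionResult


def _study_rngs(seed: int, n_pop: int):
    root = np.random.SeedSequence(seed)
    genome_ss, background_ss, pops_ss = root.spawn(3)
    pop_streams = []
    for child in pops_ss.spawn(n_pop):
        mut, meiosis, seq = child.spawn(3)
        pop_streams.append(
            {
                "mutagenesis": np.random.default_rng(mut),
                "meiosis": np.random.default_rng(meiosis),
                "sequencing": np.random.default_rng(seq),
            }
        )
    return np.random.default_rng(genome_ss), np.random.default_rng(background_ss), pop_streams


def run_study(config: PipelineConfig) -> StudyResult:
    """Simulate and analyse an allelic bulked-segregant experiment in memory."""
    genome_rng, background_rng, pop_streams = _study_rngs(config.seed, config.n_populations)

    genome, genes = generate_reference(
        rng=genome_rng,
        n_chrom=config.n_chrom,
        chrom_length_bp=config.chrom_length_bp,
        gc_content=config.gc_content,
        n_genes=config.n_genes,
        cm_per_chromosome=config.cm_per_chromosome,
    )
    by_id = {g.gene_id: g for g in genes}
    if config.causal_gene is not None:
        if config.causal_gene not in by_id:
            raise ValueError(f"causal_gene {config.causal_gene!r} not among generated genes")
        causal_gene = by_id[config.causal_gene]
    else:
        causal_gene = genes[int(genome_rng.integers(0, len(genes)))]
    logger.info("causal gene: %s (%s:%d-%d)", causal_gene.gene_id, causal_gene.chrom,
                causal_gene.start, causal_gene.end)

    background, panel_table = generate_parental_background(
        genome, config.n_background_snps, rng=background_rng
    )
    background_positions = {(s.chrom, s.pos) for s in background}
    panel = BackgroundPanel(
        parental=frozenset(s.key for s in background),
        population_af={
            (r.chrom, int(r.pos), r.ref, r.alt): float(r.af)
            for r in panel_table.itertuples(index=False)
        },
    )

    annotator = EffectAnnotator(genome, genes)
    fcfg = config.filter_config()
    params = PoolSeqParams(config.n_pooled, config.mean_depth, config.seq_error)

    populations: list[PopulationResult] = []
    used_causal_positions: set[tuple[str, int]] = set()
    for i, streams in enumerate(pop_streams, 1):
        pop_id = f"pop{i}"
        causal_snv = pick_large_effect_site(
            genome, causal_gene, rng=streams["mutagenesis"],
            avoid=background_positions | used_causal_positions,
        )
        used_causal_positions.add((causal_snv.chrom, causal_snv.pos))
        mutations = induce_ems_mutations(
            genome,
            config.n_mutations_per_line - 1,
            ems_fraction=config.ems_fraction,
            rng=streams["mutagenesis"],
            line_id=pop_id,
            avoid=background_positions | {(causal_snv.chrom, causal_snv.pos)},
        ).with_mutation(causal_snv)

        f2 = simulate_f2(
            genome, mutations, (causal_snv.chrom, causal_snv.pos),
            config.n_f2_plants, rng=streams["meiosis"],
        )
        selected = select_homozygous_mutants(f2, config.n_pooled)
        table = pool_and_sequence(selected, params, background, rng=streams["sequencing"])

        calls = calls_from_table(table)
        candidates, report = run_filter_cascade(calls, fcfg, panel)
        annotations = annotator.annotate_all(candidates)
        genic = [a for a in annotations if a.gene_id is not None]
        if config.intersect_before_effect:
            selected_annotations = genic
        else:
            selected_annotations = filter_large_effect(genic, config.include_start_stop_loss)
        populations.append(
            PopulationResult(
                pop_id, mutations, causal_snv, table, candidates, report,
                annotations, build_candidate_set(pop_id, selected_annotations),
            )
        )
        logger.info(
            "%s: %d raw variants -> %d cascade survivors -> %d candidate genes",
            pop_id, len(calls), len(candidates), len(populations[-1].candidate_set.genes),
        )

    intersection = intersect_candidates([p.candidate_set for p in populations])
    logger.info("intersection: %s", sorted(intersection.gene_ids()) or "(empty)")
    return StudyResult(
        genome, genes, causal_gene.gene_id, background, panel_table,
        populations, intersection,
    )


def _analyse_from_files(config: PipelineConfig) -> StudyResult:
    """Filter/annotate/intersect user-supplied variant tables."""
    genome = ToyGenome.from_sequences(amio.read_fasta(config.reference_fasta))
    genes = amio.read_gff3(config.gff3)
    panel = amio.load_background_panel(config.parent_vcf, config.af_panel)
    panel_table = pd.DataFrame(
        [(c, p, r, a, af) for (c, p, r, a), af in sorted(panel.population_af.items())],
        columns=["chrom", "pos", "ref", "alt", "af"],
    )
    annotator = EffectAnnotator(genome, genes)
    fcfg = config.filter_config()
    populations = []
    for i, vcf in enumerate(config.bulk_vcfs, 1):
        pop_id = f"pop{i}"
        calls = amio.read_vcf(vcf)
        table = pd.DataFrame(
            [(v.chrom, v.pos, v.ref, v.alt, v.total_depth, v.alt_depth) for v in calls],
            columns=["chrom", "pos", "ref", "alt", "total_depth", "alt_depth"],
        )
        candidates, report = run_filter_cascade(calls, fcfg, panel)
        annotations = annotator.annotate_all(candidates)
        genic = [a for a in annotations if a.gene_id is not None]
        if not config.intersect_before_effect:
            genic = filter_large_effect(genic, config.include_start_stop_loss)
        populations.append(
            PopulationResult(pop_id, None, None, table, candidates, report,
                             annotations, build_candidate_set(pop_id, genic))
        )
    intersection = intersect_candidates([p.candidate_set for p in populations])
    return StudyResult(genome, genes, None, [], panel_table, populations, intersection)


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, checksums, per-stage counts."""

    config: dict
    version: str
    files: dict[str, str]  # relative path -> sha256
    filter_reports: dict[str, list[dict]]
    intersection_genes: list[str]
    distinct_positions: dict[str, bool]
    causal_gene: str | None = None
    causal_lesions: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _annotations_frame(annotations: list[AnnotatedVariant], calls: list[VariantCall]):
    depth = {c.key: (c.total_depth, c.alt_depth) for c in calls}
    rows = []
    for a in annotations:
        dp, ao = depth.get(a.key, (np.nan, np.nan))
        rows.append((a.chrom, a.pos, a.ref, a.alt, dp, ao,
                     a.gene_id or "", a.effect.value, a.protein_change_str or ""))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "total_depth", "alt_depth",
                 "gene_id", "effect", "protein_change"],
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline and write every artifact plus a manifest."""
    if not config.out_dir:
        raise ValueError("run_pipeline requires out_dir")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result = run_study(config) if config.simulate else _analyse_from_files(config)
    genome, genes = result.genome, result.genes
    contigs = {c.name: c.length_bp for c in genome.chromosomes}

    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    if config.simulate:
        emit("reference.fa", lambda p: amio.write_fasta(genome, p))
        emit("genes.gff3", lambda p: amio.write_gff3(genes, p))
        parent_df = pd.DataFrame(
            [(s.chrom, s.pos, s.ref, s.alt, 30, 30) for s in result.background],
            columns=["chrom", "pos", "ref", "alt", "total_depth", "alt_depth"],
        )
        emit("parent.vcf", lambda p: amio.write_vcf(parent_df, p, contigs))
        emit("af_panel.tsv", lambda p: amio.write_af_panel(result.panel_table, p))

    for pop in result.populations:
        pid = pop.population_id
        if config.simulate:
            emit(f"{pid}.bulk.vcf", lambda p, t=pop.variant_table: amio.write_vcf(t, p, contigs))
            emit(f"{pid}.truth.tsv", lambda p, t=pop.variant_table: amio.write_table(t, p))
        emit(f"{pid}.filter_report.tsv",
             lambda p, r=pop.report: amio.write_table(r.to_frame(), p))
        cand_df = pd.DataFrame(
            [(v.chrom, v.pos, v.ref, v.alt, v.total_depth, v.alt_depth)
             for v in pop.candidates],
            columns=["chrom", "pos", "ref", "alt", "total_depth", "alt_depth"],
        )
        emit(f"{pid}.candidates.vcf", lambda p, d=cand_df: amio.write_vcf(d, p, contigs))
        ann_df = _annotations_frame(pop.annotations, pop.candidates)
        emit(f"{pid}.candidates.tsv", lambda p, d=ann_df: amio.write_table(d, p))
        causal = (pop.causal_snv.chrom, pop.causal_snv.pos) if pop.causal_snv else None
        profile = snp_ratio_profile(
            pop.variant_table, genome if config.simulate else None, causal
        )
        emit(f"{pid}.ratio_profile.tsv", lambda p, d=profile: amio.write_table(d, p))
        if config.make_plot:
            emit(f"{pid}.ratio_profile.png", lambda p, d=profile: plot_ratio_profile(d, p))

    emit("intersection.tsv",
         lambda p: amio.write_table(result.intersection.summary(), p))

    lines = [
        f"populations analysed: {len(result.populations)}",
        f"genes in every population: {sorted(result.intersection.gene_ids()) or 'none'}",
    ]
    if config.simulate:
        lines.append(f"simulated causal gene: {result.causal_gene_id}")
        hit = result.causal_gene_id in result.intersection.gene_ids()
        lines.append(f"causal gene recovered: {'yes' if hit else 'NO'}")
    emit("summary.txt", lambda p: p.write_text("\n".join(lines) + "\n"))

    from . import __version__

    manifest = RunManifest(
        config=config.model_dump(),
        version=__version__,
        files={p.name: amio.sha256_file(p) for p in written},
        filter_reports={
            pop.population_id: [dataclasses.asdict(s) for s in pop.report.stages]
            for pop in result.populations
        },
        intersection_genes=sorted(result.intersection.gene_ids()),
        distinct_positions=dict(result.intersection.distinct_positions),
        causal_gene=result.causal_gene_id,
        causal_lesions={
            pop.population_id: f"{pop.causal_snv.chrom}:{pop.causal_snv.pos}"
            for pop in result.populations
            if pop.causal_snv is not None
        },
    )
    manifest.to_json(out / "manifest.json")
    return manifest
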