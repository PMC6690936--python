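"""End-to-end pipeline: simulate/ingest -> coverage filter -> deconvolve ->
embed -> census comparison, behind one validated configuration.

Configuration is a YAML or JSON file validated by pydantic models; every run
writes its resolved configuration and a structured JSON report (validated
against the shipped report schema) next to the results. Logging goes to
stderr so stdout stays clean for piping. Identical configuration and seed
yield an identical report, apart from the timestamp field.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, Field

from . import census as census_mod
from . import deconvolution as deconv
from . import embedding as emb
from . import readmodel
from . import synthetic

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config", "report_schema"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "coverage", "deconvolve", "embed", "census")


class SimulateSettings(BaseModel):
    n_samples: int = 2
    n_haplotypes: int = 4
    variants_per_haplotype: int = 5
    genome_length: int = 2000
    proportions: Optional[list[list[float]]] = None  # per sample; default uniform
    coverage: float = 50.0
    read_length: int = 150
    error_rate: float = 0.005


class EMSettings(BaseModel):
    alpha: float = 1.0
    tol: float = 1e-4
    max_iter: int = 1000
    min_prop: float = 0.01
    min_reads: int = 2
    low_coverage_mode: bool = False


class EmbeddingSettings(BaseModel):
    k: int = 2
    bootstrap_replicates: int = 1000
    ambiguity_fraction: float = 0.25


class CensusSettings(BaseModel):
    census_tsv: str
    freq_table_tsv: str
    category_map_tsv: str


class PipelineConfig(BaseModel):
    """Fully serializable run configuration."""

    out_dir: str
    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(STAGES[1:]))
    reference_fasta: Optional[str] = None
    reference_id: Optional[str] = None
    genome_length: Optional[int] = None
    phylotree: Optional[str] = None
    haplogroup_labels: list[str] = Field(default_factory=list)
    sam_files: list[str] = Field(default_factory=list)
    pool_id: Optional[str] = None
    min_mean_coverage: float = 10.0
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    em: EMSettings = Field(default_factory=EMSettings)
    embedding: EmbeddingSettings = Field(default_factory=EmbeddingSettings)
    census: Optional[CensusSettings] = None

    def model_post_init(self, __context: Any) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")


class SampleReport(BaseModel):
    sample_id: str
    n_reads: int
    mean_coverage: float
    passed_coverage_filter: Optional[bool] = None


class CompositionReport(BaseModel):
    sample_id: str
    proportions: dict[str, float]
    contributors: list[str]
    haplogroups: dict[str, float]
    final_loglik: float
    n_iterations: int


class EmbeddingReport(BaseModel):
    sample_ids: list[str]
    projections: list[list[float]]
    explained_variance_ratio: list[float]
    tree_newick: Optional[str] = None
    bootstrap_support: dict[str, float] = Field(default_factory=dict)


class CensusReport(BaseModel):
    census_ancestry: dict[str, float]
    sewage_ancestry: dict[str, dict[str, float]]
    total_variation_distance: dict[str, float]


class RunReport(BaseModel):
    """Schema of the pipeline's JSON report."""

    timestamp: str
    config: dict[str, Any]
    stages_run: list[str]
    samples: list[SampleReport] = Field(default_factory=list)
    compositions: list[CompositionReport] = Field(default_factory=list)
    embedding: Optional[EmbeddingReport] = None
    census: Optional[CensusReport] = None


def report_schema() -> dict:
    """JSON schema of the run report (shipped via pydantic)."""
    return RunReport.model_json_schema()


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return PipelineConfig.model_validate(data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages in order and write the report.

    Writes ``report.json``, ``resolved_config.json`` and
    ``report.schema.json`` into ``config.out_dir``. Raises
    :class:`StageError` naming the failing stage on any error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in config.stages]
    report = RunReport(
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        config=config.model_dump(),
        stages_run=stages,
    )

    sam_files = list(config.sam_files)
    db = None
    reference = None
    reference_id = config.reference_id

    if "simulate" in stages:
        try:
            sam_files, db, reference, reference_id = _stage_simulate(config, out_dir)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError("simulate", exc) from exc
        logger.info("simulate: wrote %d SAM files to %s", len(sam_files), out_dir)

    if db is None and config.phylotree is not None:
        from .phylotree import load_phylotree

        if config.genome_length is None:
            raise StageError("deconvolve", ValueError("genome_length required with phylotree"))
        db = load_phylotree(
            config.phylotree,
            config.genome_length,
            haplogroup_labels=config.haplogroup_labels,
        )
    if reference is None and config.reference_fasta is not None:
        records = synthetic.read_fasta(config.reference_fasta)
        if reference_id is None:
            reference_id, reference = next(iter(records.items()))
        else:
            reference = records[reference_id]

    genome_length = config.genome_length or (db.genome_length if db else None)
    if genome_length is None and reference is not None:
        genome_length = len(reference)
    if genome_length is None:
        raise StageError("coverage", ValueError("genome_length could not be resolved"))
    if reference_id is None:
        reference_id = "reference"

    samples = []
    for sam in sam_files:
        try:
            samples.append(readmodel.read_sam(sam, reference_id, genome_length))
        except Exception as exc:  # noqa: BLE001
            raise StageError("coverage", exc) from exc
    if config.pool_id and samples:
        samples = [readmodel.pool_samples(samples, config.pool_id)]

    retained = samples
    if "coverage" in stages:
        for sample in samples:
            profile = readmodel.coverage_profile(sample)
            report.samples.append(
                SampleReport(
                    sample_id=sample.sample_id,
                    n_reads=sample.n_reads,
                    mean_coverage=profile.mean,
                    passed_coverage_filter=profile.mean >= config.min_mean_coverage,
                )
            )
        retained = readmodel.filter_by_coverage(samples, config.min_mean_coverage)
        logger.info("coverage: %d of %d samples retained", len(retained), len(samples))

    compositions: dict[str, deconv.HaplogroupComposition] = {}
    if "deconvolve" in stages:
        if db is None or reference is None:
            raise StageError(
                "deconvolve", ValueError("deconvolve needs a phylotree and reference")
            )
        em_config = deconv.EMConfig(seed=config.seed, **config.em.model_dump())
        for sample in retained:
            try:
                estimate = deconv.deconvolve(sample, db, reference, em_config)
            except Exception as exc:  # noqa: BLE001
                raise StageError("deconvolve", exc) from exc
            groups = deconv.aggregate_haplogroups(estimate, db)
            compositions[sample.sample_id] = groups
            report.compositions.append(
                CompositionReport(
                    sample_id=sample.sample_id,
                    proportions=estimate.as_dict(),
                    contributors=list(estimate.contributors),
                    haplogroups=dict(groups.fractions),
                    final_loglik=estimate.loglik_trace[-1],
                    n_iterations=len(estimate.loglik_trace),
                )
            )
        logger.info("deconvolve: %d samples decomposed", len(report.compositions))

    if "embed" in stages:
        if reference is None:
            raise StageError("embed", ValueError("embed needs a reference sequence"))
        try:
            dominant = [
                emb.consensus(
                    emb.base_counts(s), reference, mode="dominant", sample_id=s.sample_id
                )
                for s in retained
            ]
            embedding_report = EmbeddingReport(
                sample_ids=[c.sample_id for c in dominant],
                projections=[],
                explained_variance_ratio=[],
            )
            if len(dominant) >= 2:
                k = min(config.embedding.k, len(dominant) - 1)
                result = emb.pca(emb.one_hot_encode(dominant), k=k)
                embedding_report.projections = result.projections.tolist()
                embedding_report.explained_variance_ratio = (
                    result.explained_variance_ratio.tolist()
                )
            if len(dominant) >= 3:
                ambiguous = [
                    emb.consensus(
                        emb.base_counts(s),
                        reference,
                        mode="ambiguity",
                        ambiguity_fraction=config.embedding.ambiguity_fraction,
                        sample_id=s.sample_id,
                    )
                    for s in retained
                ]
                embedding_report.tree_newick = emb.nj_tree(ambiguous)
                support = emb.bootstrap_support(
                    ambiguous,
                    replicates=config.embedding.bootstrap_replicates,
                    seed=config.seed,
                )
                embedding_report.bootstrap_support = {
                    "|".join(sorted(part)): value for part, value in support.items()
                }
            report.embedding = embedding_report
        except Exception as exc:  # noqa: BLE001
            raise StageError("embed", exc) from exc
        logger.info("embed: %d samples embedded", len(retained))

    if "census" in stages and config.census is not None:
        try:
            census_comp = census_mod.load_census(config.census.census_tsv)
            freq_table = census_mod.load_frequency_table(config.census.freq_table_tsv)
            category_map = census_mod.load_category_map(config.census.category_map_tsv)
            census_ancestry = census_mod.census_to_ancestry(census_comp, freq_table)
            sewage_ancestry = {}
            distances = {}
            for sample_id, groups in compositions.items():
                rolled = census_mod.haplogroups_to_ancestry(groups, category_map)
                sewage_ancestry[sample_id] = dict(rolled.fractions)
                distances[sample_id] = census_mod.compare_compositions(
                    census_ancestry, rolled
                )
            report.census = CensusReport(
                census_ancestry=dict(census_ancestry.fractions),
                sewage_ancestry=sewage_ancestry,
                total_variation_distance=distances,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("census", exc) from exc
        logger.info("census: compared %d samples", len(compositions))

    # validate against the shipped schema (pydantic revalidation) and persist
    RunReport.model_validate(report.model_dump())
    (out_dir / "report.schema.json").write_text(
        json.dumps(report_schema(), indent=2, sort_keys=True), encoding="utf-8"
    )
    (out_dir / "resolved_config.json").write_text(
        json.dumps(config.model_dump(), indent=2, sort_keys=True), encoding="utf-8"
    )
    (out_dir / "report.json").write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True), encoding="utf-8"
    )
    return report


def _stage_simulate(config: PipelineConfig, out_dir: Path):
    sim = config.simulate
    reference, db = synthetic.simulate_phylotree(
        sim.n_haplotypes,
        sim.variants_per_haplotype,
        sim.genome_length,
        seed=config.seed,
    )
    synthetic.write_fasta({db.reference_id: reference}, out_dir / "sim_reference.fasta")
    from .phylotree import save_phylotree

    save_phylotree(db, out_dir / "sim_phylotree.tsv")
    n = sim.n_samples
    if sim.proportions is None:
        uniform = [1.0 / sim.n_haplotypes] * sim.n_haplotypes
        per_sample = [uniform] * n
    else:
        per_sample = sim.proportions
        if len(per_sample) != n:
            raise ValueError("simulate.proportions must list one vector per sample")
    sam_files = []
    for i, props in enumerate(per_sample):
        sam_path = out_dir / f"sim_sample{i + 1}.sam"
        synthetic.simulate_mixture_reads(
            reference,
            db,
            props,
            sim.coverage,
            read_length=sim.read_length,
            error_rate=sim.error_rate,
            seed=config.seed + 1 + i,
            sample_id=f"sim_sample{i + 1}",
            out_sam=sam_path,
        )
        sam_files.append(str(sam_path))
    return sam_files, db, reference, db.reference_id
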