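"""End-to-end pipeline: simulate/load -> QC -> databases -> censuses -> call.

A :class:`PipelineConfig` (typically loaded from YAML) carries the
per-stage parameter blocks and one global seed; :func:`run_pipeline`
executes the stages in order, writes every intermediate artifact plus a
resolved-config copy next to the outputs, and returns the fitted
:class:`~hybridcensus.parentage.ParentageResults`.  Reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as hio
from .fragdb import build_database
from .hitcensus import AlignmentParams, census_reads, mito_census, quality_filter
from .parentage import ParentageModel, ParentageResults
from .simdata import (
    GeneTreeForestSpec,
    SimulationConfig,
    make_hybrid,
    simulate_gene_trees,
    simulate_parent_genomes,
    simulate_reads,
)
from .treecensus import sister_census

log = logging.getLogger("hybridcensus")

FOCAL_TIP = "hybrid"
OUTGROUP_TIP = "outgroup"


def coverage_estimate(n_reads: float, mean_len: float, genome_size: float) -> float:
    """Fold sequencing coverage: n_reads * mean_len / genome_size."""
    if n_reads <= 0 or mean_len <= 0 or genome_size <= 0:
        raise ValueError("all coverage inputs must be positive")
    return n_reads * mean_len / genome_size


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    align: AlignmentParams = field(default_factory=AlignmentParams)
    fragment_length: int = 100
    n_sample_fragments: int | None = None  # None = keep all tiles
    min_phred: int = 30
    min_len: int = 30
    max_masked: int = 30
    alpha: float = 0.001
    dam_threshold: float = 0.99
    n_eff: int | None = 150
    n_gene_trees: int = 1000
    genomes_dir: str | None = None  # load real assemblies instead of simulating

    @property
    def seed(self) -> int:
        return self.sim.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "species" in sim_raw:
            sim_raw["species"] = [tuple(x) for x in sim_raw["species"]]
        align_raw = raw.pop("align", {})
        return cls(
            sim=SimulationConfig(**sim_raw),
            align=AlignmentParams(**align_raw),
            **raw,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"].pop("tree_forest_spec", None)
        return d


def default_forest_spec(config: PipelineConfig) -> GeneTreeForestSpec:
    """Gene-tree forest matching the simulated study system.

    The focal tip's singleton sister is the sire with probability 0.45 and
    the dam with probability 0.34 (conditional on a singleton sister);
    about 27% of trees get a multi-leaf sister; the residual singleton
    mass is spread over the decoy species.
    """
    sim = config.sim
    non_singleton = 2153 / 8063
    singleton_mass = 1.0 - non_singleton
    mixture = {sim.sire: 0.45 * singleton_mass, sim.dam: 0.34 * singleton_mass}
    decoys = [n for n, _ in sim.species if n not in (sim.dam, sim.sire)]
    rest = singleton_mass - sum(mixture.values())
    for d in decoys:
        mixture[d] = rest / len(decoys)
    taxa = [FOCAL_TIP, OUTGROUP_TIP] + [n for n, _ in sim.species]
    return GeneTreeForestSpec(
        n_trees=config.n_gene_trees,
        taxa=taxa,
        focal=FOCAL_TIP,
        outgroup=OUTGROUP_TIP,
        sister_mixture=mixture,
        non_singleton_fraction=non_singleton,
        seed=sim.seed,
    )


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> ParentageResults:
    """Execute every stage, writing artifacts and a resolved-config copy."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str)
    )
    sim = config.sim
    stage = "init"
    try:
        stage = "simulate genomes"
        t0 = _stage(stage)
        if config.genomes_dir is not None:
            if not Path(config.genomes_dir).is_dir():
                raise FileNotFoundError(f"genomes dir {config.genomes_dir} not found")
            genome_map = hio.read_genomes(config.genomes_dir)
            from .simdata import GenomeSet

            genomes = GenomeSet(genome_map, [], next(iter(genome_map.values())).mito, sim.seed)
        else:
            genomes = simulate_parent_genomes(sim)
            hio.write_genomes(genomes, outdir / "genomes")
        log.info("genomes ready (%.1fs)", time.perf_counter() - t0)

        stage = "hybrid + reads"
        t0 = _stage(stage)
        hybrid = make_hybrid(genomes, sim)
        reads = simulate_reads(hybrid, sim)
        hio.write_fastq(reads, outdir / "reads.fastq")
        hio.write_origin_manifest(reads, outdir / "reads.origins.tsv")
        log.info("%d reads simulated (%.1fs)", len(reads), time.perf_counter() - t0)

        stage = "quality filter"
        t0 = _stage(stage)
        min_phred = config.min_phred
        if config.genomes_dir is None and sim.error_rate > 0:
            # simulated reads carry one constant quality encoding the mean
            # error rate; trimming above it would discard every base, so
            # the threshold is clamped to keep QC a structural pass-through
            q_sim = min(40, round(-10 * math.log10(sim.error_rate)))
            if q_sim < min_phred:
                log.info(
                    "clamping min_phred %d -> %d (simulated constant quality)",
                    min_phred,
                    q_sim,
                )
                min_phred = q_sim
        reads_qc = quality_filter(
            reads, min_phred, config.min_len, config.max_masked
        )
        log.info(
            "%d/%d reads retained (%.1fs)",
            len(reads_qc),
            len(reads),
            time.perf_counter() - t0,
        )

        stage = "build databases"
        t0 = _stage(stage)
        nuc_db = build_database(
            genomes,
            fragment_length=config.fragment_length,
            n_sample=config.n_sample_fragments,
            seed=sim.seed,
            k=config.align.seed_k,
        )
        nuc_db.write_fasta(outdir / "nuclear_db.fasta")
        mito_db = build_database(
            genomes,
            fragment_length=config.fragment_length,
            seed=sim.seed,
            k=config.align.seed_k,
            mito=True,
        )
        mito_db.write_fasta(outdir / "mito_db.fasta")
        log.info(
            "nuclear db %d fragments, mito db %d fragments (%.1fs)",
            len(nuc_db),
            len(mito_db),
            time.perf_counter() - t0,
        )

        stage = "nuclear census"
        t0 = _stage(stage)
        nuc = census_reads(reads_qc, nuc_db, config.align)
        _write_census_tsv(nuc, outdir / "nuclear_census.tsv")
        log.info("nuclear census done (%.1fs)", time.perf_counter() - t0)

        stage = "mito census"
        t0 = _stage(stage)
        mito = mito_census(reads_qc, mito_db, config.align)
        _write_census_tsv(mito, outdir / "mito_census.tsv")
        log.info("mito census done (%.1fs)", time.perf_counter() - t0)

        stage = "gene-tree census"
        t0 = _stage(stage)
        spec = sim.tree_forest_spec or default_forest_spec(config)
        forest = simulate_gene_trees(spec)
        hio.write_newick_forest(forest, outdir / "gene_trees.nwk")
        trees = sister_census(forest, spec.focal, spec.outgroup)
        log.info("tree census done (%.1fs)", time.perf_counter() - t0)

        stage = "parentage call"
        t0 = _stage(stage)
        model = ParentageModel(
            nuc,
            mito=mito,
            trees=trees,
            alpha=config.alpha,
            dam_threshold=config.dam_threshold,
            n_eff=config.n_eff,
        )
        results = model.fit()
        (outdir / "parentage_call.json").write_text(results.to_json() + "\n")
        (outdir / "parentage_summary.txt").write_text(results.summary() + "\n")
        log.info("call: %s (%.1fs)", results.generation, time.perf_counter() - t0)
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_census_tsv(census, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tcount\tproportion\n")
        props = census.proportions
        for sp in sorted(census.counts):
            fh.write(f"{sp}\t{census.counts[sp]}\t{props[sp]:.6f}\n")
        fh.write(f"#n_assigned\t{census.n_assigned}\t\n")
        fh.write(f"#n_tie_discarded\t{census.n_tie_discarded}\t\n")
        fh.write(f"#n_no_hit\t{census.n_no_hit}\t\n")
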