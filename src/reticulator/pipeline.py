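"""End-to-end orchestration: simulate -> amplicon -> haplotype -> genotype ->
parentage -> traits, with a fixture shortcut.

Stages run in order, each writing plain-file artifacts into the output
directory and logging input/output counts. Identical config + seed gives
byte-identical TSV/JSON outputs (timestamps only ever appear in the log).
On a stage failure the run aborts with the failing stage named and a
MANIFEST noting the incomplete state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import amplicon as amp
from . import haplotypes as hap
from . import parentage as par
from . import simulate as sim
from . import traits as tr
from .genotypes import Genotype, genotype_table, write_genotype_table
from .io import (
    AlleleCall,
    load_fixture,
    read_allele_calls,
    read_sample_table,
    write_allele_calls,
)

logger = logging.getLogger("reticulator")


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run."""

    mode: str = "fixture"  # fixture | simulated | files
    outdir: str = "reticulator_out"
    seed: int | None = None
    # amplicon stage
    min_reads: int = amp.DEFAULT_MIN_READS
    identity_threshold: float = 0.99
    # haplotyping stage
    min_samples: int = 2
    group_method: str = "distance_cluster"  # or provided_map / prefix
    group_threshold: float = 0.02
    # simulation stage
    n_parents: int = 7
    n_diploid_events: int = 10
    n_triploid_events: int = 10
    depth: float = 300.0
    error_rate: float = 0.0
    samples_per_event: int = 2
    parent_samples: int = 2
    within_group_divergence: int = 0
    # files mode inputs
    sample_table: str | None = None
    allele_calls: str | None = None

    def validate(self) -> None:
        if self.mode not in ("fixture", "simulated", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not 0.5 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0.5, 1]")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if not 0 < self.group_threshold < 0.5:
            raise ValueError("group_threshold must be in (0, 0.5)")
        if self.mode == "simulated":
            if self.seed is None:
                raise ValueError("seed is mandatory in simulated mode")
            if self.n_parents < 2:
                raise ValueError("need at least two parents")
            if self.depth <= 0:
                raise ValueError("depth must be positive")
            if not 0 <= self.error_rate < 1:
                raise ValueError("error_rate must be in [0, 1)")
            if self.samples_per_event < 1 or self.parent_samples < 1:
                raise ValueError("samples per genotype must be >= 1")
        if self.mode == "files":
            if not self.sample_table or not self.allele_calls:
                raise ValueError("files mode needs sample_table and allele_calls")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in
                               cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Aggregated result of a pipeline run."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "stages": self.stages,
                "summary": self.summary,
                "recovery": self.recovery,
                "artifacts": {k: str(v) for k, v in self.artifacts.items()},
            },
            indent=2,
            sort_keys=True,
        )


def default_events(
    n_parents: int, n_diploid: int, n_triploid: int, seed: int
) -> list[sim.HybridEvent]:
    """A deterministic roster of hybridization events between distinct
    parents: diploid events from reduced x reduced gametes, triploid events
    from an unreduced gamete on one side (alternating maternal/paternal,
    mirroring both directions seen in nature)."""
    rng = np.random.default_rng(seed)
    events: list[sim.HybridEvent] = []
    for i in range(n_diploid + n_triploid):
        mat, pat = rng.choice(n_parents, size=2, replace=False)
        if i < n_diploid:
            events.append(sim.HybridEvent(f"P{mat + 1}", f"P{pat + 1}"))
        else:
            unreduced_maternal = i % 2 == 0
            events.append(
                sim.HybridEvent(
                    f"P{mat + 1}",
                    f"P{pat + 1}",
                    maternal_gamete="unreduced" if unreduced_maternal else "reduced",
                    paternal_gamete="reduced" if unreduced_maternal else "unreduced",
                )
            )
    return events


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [logging.StreamHandler()]
    outdir.mkdir(parents=True, exist_ok=True)
    file_handler = logging.FileHandler(outdir / "run.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(file_handler)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the configured pipeline; returns the aggregated report.

    The report is also written to ``<outdir>/report.json``; each stage
    leaves its artifact files in the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    _setup_logging(outdir)
    report = RunReport(config=asdict(config))
    completed: list[str] = []

    def stage(name: str):
        def decorator(fn):
            def wrapped(*args, **kwargs):
                try:
                    result = fn(*args, **kwargs)
                except Exception as exc:
                    manifest = {
                        "completed_stages": completed,
                        "failed_stage": name,
                        "error": str(exc),
                    }
                    (outdir / "MANIFEST.json").write_text(
                        json.dumps(manifest, indent=2)
                    )
                    raise StageFailure(name, exc) from exc
                completed.append(name)
                return result

            return wrapped

        return decorator

    truth: sim.SimulationTruth | None = None
    panel: sim.ParentalPanel | None = None

    if config.mode == "fixture":

        @stage("load_fixture")
        def _load():
            fixture = load_fixture()
            records = par.records_from_fixture(fixture)
            logger.info("load_fixture: %d rows -> %d genotype records",
                        len(fixture.table), len(records))
            report.stages.append(
                {"stage": "load_fixture", "rows": len(fixture.table),
                 "records": len(records)}
            )
            return fixture, records

        fixture, records = _load()
        group_of = par.allele_group
        characters = fixture.characters

    elif config.mode == "simulated":

        @stage("simulate")
        def _simulate():
            panel = sim.simulate_parental_panel(
                config.n_parents,
                seed=config.seed,
                within_group_divergence=config.within_group_divergence,
            )
            events = default_events(
                config.n_parents, config.n_diploid_events,
                config.n_triploid_events, config.seed + 1,
            )
            samples, truth = sim.simulate_hybridization(
                panel, events, seed=config.seed + 2,
                samples_per_event=config.samples_per_event,
                parent_samples=config.parent_samples,
            )
            barcodes = sim.make_barcodes(
                [s.sample_id for s in samples], seed=config.seed + 3
            )
            primers = sim.default_locus_primers(
                [l.locus_id for l in panel.nuclear_loci]
            )
            reads = sim.simulate_reads(
                samples, config.depth, config.error_rate, barcodes,
                seed=config.seed + 4, primers=primers,
            )
            sim.write_simulation(samples, truth, outdir / "sim", reads, barcodes)
            logger.info("simulate: %d samples, %d reads", len(samples), len(reads))
            report.stages.append(
                {"stage": "simulate", "samples": len(samples),
                 "events": len(events), "reads": len(reads)}
            )
            return panel, samples, truth, barcodes, primers, reads

        panel, sim_samples, truth, barcodes, primers, reads = _simulate()

        @stage("amplicon")
        def _amplicon():
            assigned, unassigned = amp.demultiplex(reads, barcodes)
            retained: dict[tuple[str, str], list[amp.ReadCluster]] = {}
            ploidy_of = {s.sample_id: s.ploidy for s in sim_samples}
            for sample_id, sample_reads in assigned.items():
                for locus in panel.nuclear_loci:
                    fwd, rev = primers[locus.locus_id]
                    trimmed, _dropped = amp.trim_primers(sample_reads, fwd, rev)
                    clusters = amp.cluster_reads(
                        trimmed, config.identity_threshold,
                        sample_id=sample_id, locus_id=locus.locus_id,
                    )
                    kept = amp.retain_clusters(
                        clusters, ploidy_of[sample_id], config.min_reads
                    )
                    if kept:
                        retained[(sample_id, locus.locus_id)] = kept
            logger.info(
                "amplicon: %d reads assigned, %d unassigned, %d sample-locus "
                "allele sets", sum(len(v) for v in assigned.values()),
                len(unassigned), len(retained),
            )
            report.stages.append(
                {"stage": "amplicon",
                 "assigned": sum(len(v) for v in assigned.values()),
                 "unassigned": len(unassigned)}
            )
            return retained

        retained = _amplicon()

        @stage("haplotype")
        def _haplotype():
            calls: list[AlleleCall] = []
            label_seq: dict[str, dict[str, str]] = {}
            for locus in panel.nuclear_loci:
                records_in = []
                for (sample_id, locus_id), clusters in sorted(retained.items()):
                    if locus_id != locus.locus_id:
                        continue
                    for rank, cluster in enumerate(clusters):
                        records_in.append(
                            (f"{sample_id}|{locus_id}|{rank}|{cluster.read_count}",
                             cluster.consensus)
                        )
                table = hap.collapse_haplotypes(
                    records_in, locus.locus_id, prefix=locus.locus_id[0]
                )
                label_seq[locus.locus_id] = table.label_to_sequence
                for rec_id, label in table.assignments.items():
                    sample_id, locus_id, _rank, count = rec_id.split("|")
                    calls.append(
                        AlleleCall(sample_id, locus_id, label,
                                   read_support=int(count), source="ngs")
                    )
            # chloroplast marker: direct sequences, no amplicon stage
            cp_records = [
                (s.sample_id, s.cp_sequence) for s in sim_samples
            ]
            cp_table = hap.collapse_haplotypes(cp_records, "cpDNA", prefix="cp")
            cp_by_sample = dict(cp_table.assignments)

            calls, dropped = hap.filter_rare_alleles(calls, config.min_samples)
            write_allele_calls(calls, outdir / "allele_calls.tsv")
            logger.info("haplotype: %d calls kept, %d alleles dropped as rare",
                        len(calls), len(dropped))
            report.stages.append(
                {"stage": "haplotype", "calls": len(calls),
                 "rare_dropped": len(dropped)}
            )
            return calls, label_seq, cp_by_sample

        calls, label_seq, cp_by_sample = _haplotype()

        @stage("genotype")
        def _genotype():
            meta = [s.as_sample() for s in sim_samples]
            genotypes = genotype_table(meta, calls)
            by_sample: dict[str, dict[str, Genotype]] = {}
            for g in genotypes:
                by_sample.setdefault(g.sample_id, {})[g.locus_id] = g
            records = par.build_genotype_records(meta, by_sample, cp_by_sample)
            modes = {s.sample_id: s.reproductive_mode for s in meta}
            write_genotype_table(genotypes, modes, outdir / "genotypes.tsv")
            logger.info("genotype: %d genotypes, %d records",
                        len(genotypes), len(records))
            report.stages.append(
                {"stage": "genotype", "genotypes": len(genotypes),
                 "records": len(records)}
            )
            return records

        records = _genotype()

        primary = panel.nuclear_loci[0].locus_id
        alleles_primary = sorted(label_seq[primary])
        groups = hap.assign_groups(
            alleles_primary, "distance_cluster", config.group_threshold,
            sequences=label_seq[primary],
        )
        group_of = groups.group_of
        characters = None

    else:  # files mode

        @stage("load_files")
        def _load_files():
            samples = read_sample_table(config.sample_table)
            calls = read_allele_calls(config.allele_calls)
            cp_by_sample = {
                c.sample_id: c.allele_label
                for c in calls if c.locus_id == "cpDNA"
            }
            nuclear_calls = [c for c in calls if c.locus_id != "cpDNA"]
            nuclear_calls, dropped = hap.filter_rare_alleles(
                nuclear_calls, config.min_samples
            )
            genotypes = genotype_table(samples, nuclear_calls)
            by_sample: dict[str, dict[str, Genotype]] = {}
            for g in genotypes:
                by_sample.setdefault(g.sample_id, {})[g.locus_id] = g
            records = par.build_genotype_records(samples, by_sample, cp_by_sample)
            logger.info("load_files: %d samples -> %d records",
                        len(samples), len(records))
            report.stages.append(
                {"stage": "load_files", "samples": len(samples),
                 "records": len(records), "rare_dropped": len(dropped)}
            )
            return records

        records = _load_files()
        group_of = par.allele_group
        loci_present = {l for rec in records for l in rec.genotypes}
        primary_locus = (par.PRIMARY_LOCUS if par.PRIMARY_LOCUS in loci_present
                         else sorted(loci_present)[0])
        characters = None

    primary_locus = (
        par.PRIMARY_LOCUS if config.mode != "simulated"
        else panel.nuclear_loci[0].locus_id
    )
    if config.mode == "files":
        loci_present = {l for rec in records for l in rec.genotypes}
        if primary_locus not in loci_present:
            primary_locus = sorted(loci_present)[0]

    @stage("parentage")
    def _parentage():
        statuses, matrix, maternal, registry, formulas = par.infer_all(
            records, group_of, primary_locus
        )
        graph = par.build_reticulogram(formulas, records, statuses, primary_locus)
        summary = par.summarize(records, statuses, formulas, primary_locus)
        par.write_formulas(formulas, outdir / "formulas.tsv")
        par.write_gml(graph, outdir / "network.gml")
        par.write_dot(graph, outdir / "network.dot")
        (outdir / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True)
        )
        logger.info(
            "parentage: %d genotypes = %d parental + %d hybrid (%d parental taxa)",
            summary.total_genotypes, summary.parental_genotypes,
            summary.hybrid_genotypes, summary.n_parental_taxa,
        )
        report.stages.append({"stage": "parentage", **summary.to_dict()})
        return statuses, maternal, formulas, summary

    statuses, maternal, formulas, summary = _parentage()
    report.summary = summary.to_dict()
    report.artifacts.update(
        {name: outdir / name for name in
         ("formulas.tsv", "network.gml", "network.dot", "summary.json")}
    )

    if config.mode == "fixture" and characters is not None:

        @stage("traits")
        def _traits():
            sample_alleles = {
                sid: rec.distinct_alleles(primary_locus)
                for rec in records for sid in rec.sample_ids
                if rec.distinct_alleles(primary_locus)
            }
            rows = tr.associate_states(characters, sample_alleles, "allele")
            rows += tr.associate_states(characters, sample_alleles, "group")
            tr.write_associations(rows, outdir / "associations.tsv")
            logger.info("traits: %d association rows", len(rows))
            report.stages.append({"stage": "traits", "rows": len(rows)})

        _traits()
        report.artifacts["associations.tsv"] = outdir / "associations.tsv"

    if truth is not None:

        @stage("evaluate")
        def _evaluate():
            recovery = evaluate_recovery(
                records, statuses, formulas, maternal, truth, panel,
                group_of, primary_locus,
            )
            logger.info(
                "evaluate: parent-pair recovery %.3f, maternal-group recovery %.3f",
                recovery["parent_pair_recovery"],
                recovery["maternal_group_recovery"],
            )
            report.stages.append({"stage": "evaluate", **recovery})
            return recovery

        report.recovery = _evaluate()

    (outdir / "report.json").write_text(report.to_json())
    report.artifacts["report.json"] = outdir / "report.json"
    return report


def evaluate_recovery(
    records: Sequence[par.GenotypeRecord],
    statuses: Mapping[str, str],
    formulas: Sequence[par.HybridFormula],
    maternal: Mapping[str, par.MaternalCall],
    truth: sim.SimulationTruth,
    panel: sim.ParentalPanel,
    group_of,
    locus: str,
) -> dict:
    """Fraction of true (maternal, paternal) pairs and maternal groups
    recovered for the simulated hybrid genotypes."""
    formula_by_taxon: dict[str, list[par.HybridFormula]] = {}
    for formula in formulas:
        formula_by_taxon.setdefault(formula.taxon, []).append(formula)

    # True group of each parent = group of its (first) primary-locus allele.
    parent_group: dict[str, str] = {}
    for rec in records:
        if statuses.get(rec.record_id) == par.PARENTAL:
            alleles = rec.distinct_alleles(locus)
            if alleles:
                parent_group[rec.taxon] = group_of(alleles[0])

    pair_hits = pair_total = 0
    group_hits = group_total = 0
    for child_taxon, (true_mat, true_pat) in truth.parent_pairs.items():
        child_formulas = formula_by_taxon.get(child_taxon, [])
        pair_total += 1
        if any(
            f.maternal_taxa == {true_mat} and f.paternal_taxa == {true_pat}
            for f in child_formulas
        ):
            pair_hits += 1
        group_total += 1
        expected_group = parent_group.get(true_mat)
        if expected_group is not None and any(
            f.maternal_groups == {expected_group} for f in child_formulas
        ):
            group_hits += 1

    return {
        "parent_pair_recovery": pair_hits / pair_total if pair_total else 1.0,
        "maternal_group_recovery": group_hits / group_total if group_total else 1.0,
        "n_true_hybrids": pair_total,
    }
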