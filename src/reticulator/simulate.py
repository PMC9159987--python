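"""Forward simulator of reticulate evolution with apogamy.

The model is deliberately minimal: parental taxa diverge on a star phylogeny
from a shared random ancestral sequence per locus, accumulating independent
private substitutions (uniform choice among the three alternative bases).
Hybrid samples carry the union of the alleles contributed by a maternal and
a paternal gamete — reduced (one copy) or unreduced (the full somatic
complement) — with the chloroplast marker inherited strictly maternally.
Sexual offspring produce 64 spores per sporangium, apogamous offspring 32.
No backcrossing, introgression, recombination or selection is simulated.

All randomness flows through a single explicitly threaded ``numpy``
generator, so a seed fixes every output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .amplicon import Read, revcomp
from .io import Sample, write_fasta, write_fastq, write_sample_table

BASES = np.array(list("ACGT"))

#: Default amplicon primers used when none are supplied (arbitrary but fixed).
DEFAULT_FORWARD_PRIMER = "ACATTCAAGGAGCAGCTTCAGC"
DEFAULT_REVERSE_PRIMER = "CATCCTCATCGTCCGACATGGT"


@dataclass(frozen=True)
class LocusConfig:
    """One marker in the simulated panel.

    ``inheritance`` is ``maternal`` for the chloroplast marker (the
    concatenated rbcL+matK stand-in) or ``biparental`` for a nuclear locus;
    ``mutation_rate`` is substitutions per site on each parental branch.
    """

    locus_id: str
    inheritance: str
    length: int
    mutation_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.inheritance not in ("maternal", "biparental"):
            raise ValueError(f"bad inheritance {self.inheritance!r}")
        if self.length <= 0:
            raise ValueError(f"locus {self.locus_id!r}: length must be positive")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError(f"locus {self.locus_id!r}: mutation_rate not in [0, 1]")


def default_loci() -> list[LocusConfig]:
    """The default three-marker panel (lengths follow the study's datasets:
    2184 bp chloroplast, 493 and 397 bp nuclear)."""
    return [
        LocusConfig("cpDNA", "maternal", 2184),
        LocusConfig("Knox3", "biparental", 493),
        LocusConfig("IBR3", "biparental", 397),
    ]


def _check_loci(loci: Sequence[LocusConfig]) -> None:
    maternal = [l for l in loci if l.inheritance == "maternal"]
    if len(maternal) != 1:
        raise ValueError("exactly one maternal locus is required per panel")


@dataclass
class ParentalPanel:
    """Diploid parental taxa with private alleles per locus."""

    taxa: list[str]
    loci: list[LocusConfig]
    #: (taxon, locus_id) -> tuple of allele sequences (1 = homozygous).
    allele_sequences: dict[tuple[str, str], tuple[str, ...]]
    #: allele sequence label "taxon.locus.i" -> lineage group label.
    group_map: dict[str, str]

    @property
    def maternal_locus(self) -> LocusConfig:
        return next(l for l in self.loci if l.inheritance == "maternal")

    @property
    def nuclear_loci(self) -> list[LocusConfig]:
        return [l for l in self.loci if l.inheritance == "biparental"]

    def cp_haplotype(self, taxon: str) -> str:
        return self.allele_sequences[(taxon, self.maternal_locus.locus_id)][0]


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_sub`` substitutions at distinct positions, each to a
    uniformly chosen different base."""
    out = seq.copy()
    if n_sub == 0:
        return out
    positions = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for pos in positions:
        alternatives = BASES[BASES != out[pos]]
        out[pos] = rng.choice(alternatives)
    return out


def simulate_parental_panel(
    n_taxa: int,
    loci: Sequence[LocusConfig] | None = None,
    seed: int = 0,
    within_group_divergence: int = 0,
) -> ParentalPanel:
    """Simulate diploid parental taxa on a star phylogeny.

    Each taxon receives binomial(length, mutation_rate) private substitutions
    from a shared ancestral sequence per locus. With
    ``within_group_divergence`` > 0, each taxon carries two nuclear alleles
    separated by that many substitutions (heterozygous within its own
    lineage group); otherwise parents are strictly homozygous. Group labels
    are one letter per taxon (A, B, C, ...).
    """
    if n_taxa < 2:
        raise ValueError("need at least two parents")
    loci = list(loci) if loci is not None else default_loci()
    _check_loci(loci)
    rng = np.random.default_rng(seed)

    taxa = [f"P{i + 1}" for i in range(n_taxa)]
    ancestral = {
        locus.locus_id: rng.choice(BASES, size=locus.length) for locus in loci
    }

    allele_sequences: dict[tuple[str, str], tuple[str, ...]] = {}
    group_map: dict[str, str] = {}
    from .haplotypes import _group_letter

    for t_idx, taxon in enumerate(taxa):
        group = _group_letter(t_idx)
        for locus in loci:
            n_sub = int(rng.binomial(locus.length, locus.mutation_rate))
            primary = _mutate(ancestral[locus.locus_id], n_sub, rng)
            seqs = ["".join(primary)]
            if locus.inheritance == "biparental" and within_group_divergence > 0:
                second = _mutate(primary, within_group_divergence, rng)
                seqs.append("".join(second))
            allele_sequences[(taxon, locus.locus_id)] = tuple(seqs)
            if locus.inheritance == "biparental":
                for i in range(len(seqs)):
                    group_map[f"{taxon}.{locus.locus_id}.{i}"] = group
    return ParentalPanel(taxa, loci, allele_sequences, group_map)


@dataclass(frozen=True)
class HybridEvent:
    """One hybridization: a maternal and a paternal gamete meeting."""

    maternal_taxon: str
    paternal_taxon: str
    maternal_gamete: str = "reduced"   # reduced | unreduced
    paternal_gamete: str = "reduced"
    child_mode: str = "apogamous"      # sexual | apogamous

    def __post_init__(self) -> None:
        for g in (self.maternal_gamete, self.paternal_gamete):
            if g not in ("reduced", "unreduced"):
                raise ValueError(f"bad gamete type {g!r}")
        if self.child_mode not in ("sexual", "apogamous"):
            raise ValueError(f"bad child mode {self.child_mode!r}")

    @property
    def child_ploidy(self) -> int:
        return (2 if self.maternal_gamete == "unreduced" else 1) + (
            2 if self.paternal_gamete == "unreduced" else 1
        )


@dataclass
class SimSample:
    """One simulated plant with its true allele sequences."""

    sample_id: str
    taxon_name: str
    ploidy: int
    spore_count: int
    mode: str
    #: locus_id -> tuple of allele sequences (with multiplicity).
    alleles: dict[str, tuple[str, ...]]
    cp_sequence: str

    def as_sample(self) -> Sample:
        return Sample(
            sample_id=self.sample_id,
            taxon_name=self.taxon_name,
            ploidy=self.ploidy,
            spore_count=self.spore_count,
            reproductive_mode=self.mode,
        )


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside simulated samples."""

    #: child taxon label -> (maternal_taxon, paternal_taxon)
    parent_pairs: dict[str, tuple[str, str]]
    #: child taxon label -> list of child sample ids
    child_samples: dict[str, list[str]]
    #: (child taxon, locus_id, allele sequence) -> source parental taxon
    allele_origin: dict[tuple[str, str, str], str]
    events: list[HybridEvent] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "parent_pairs": self.parent_pairs,
            "child_samples": self.child_samples,
            "allele_origin": [
                {"child": c, "locus": l, "sequence": s, "source": src}
                for (c, l, s), src in self.allele_origin.items()
            ],
            "events": [vars(e) for e in self.events],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _gamete(
    panel: ParentalPanel, taxon: str, locus_id: str, unreduced: bool,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    copies = panel.allele_sequences[(taxon, locus_id)]
    somatic = copies * 2 if len(copies) == 1 else copies  # diploid complement
    if unreduced:
        return tuple(somatic)
    return (somatic[int(rng.integers(len(somatic)))],)


def simulate_hybridization(
    panel: ParentalPanel,
    events: Sequence[HybridEvent],
    seed: int = 0,
    samples_per_event: int = 2,
    parent_samples: int = 2,
) -> tuple[list[SimSample], SimulationTruth]:
    """Generate parental and hybrid samples for a list of hybridization
    events, plus the ground-truth record.

    Each parental taxon contributes ``parent_samples`` samples (sexual if
    homozygous-by-construction parents are treated as sexual diploids, which
    they are here) and each event ``samples_per_event`` clonal child samples.
    Children carry the union of gamete alleles; cpDNA follows the maternal
    taxon; spore count is 64 for sexual children and 32 for apogamous ones.
    """
    rng = np.random.default_rng(seed)
    for event in events:
        for taxon in (event.maternal_taxon, event.paternal_taxon):
            if taxon not in panel.taxa:
                raise ValueError(f"unknown taxon {taxon!r} in hybrid event")
        if event.child_ploidy not in (2, 3):
            raise ValueError(
                f"gamete combination yields ploidy {event.child_ploidy}, "
                "only 2 or 3 supported"
            )

    cp_locus = panel.maternal_locus.locus_id
    samples: list[SimSample] = []
    for taxon in panel.taxa:
        for k in range(parent_samples):
            alleles = {
                locus.locus_id: tuple(
                    sorted(
                        panel.allele_sequences[(taxon, locus.locus_id)] * 2
                        if len(panel.allele_sequences[(taxon, locus.locus_id)]) == 1
                        else panel.allele_sequences[(taxon, locus.locus_id)]
                    )
                )
                for locus in panel.nuclear_loci
            }
            samples.append(
                SimSample(
                    sample_id=f"{taxon}_s{k + 1}",
                    taxon_name=taxon,
                    ploidy=2,
                    spore_count=64,
                    mode="sexual",
                    alleles=alleles,
                    cp_sequence=panel.cp_haplotype(taxon),
                )
            )

    truth = SimulationTruth({}, {}, {}, list(events))
    for e_idx, event in enumerate(events):
        child_taxon = f"H{e_idx + 1}_{event.maternal_taxon}x{event.paternal_taxon}"
        truth.parent_pairs[child_taxon] = (event.maternal_taxon, event.paternal_taxon)
        truth.child_samples[child_taxon] = []

        child_alleles: dict[str, tuple[str, ...]] = {}
        for locus in panel.nuclear_loci:
            maternal = _gamete(
                panel, event.maternal_taxon, locus.locus_id,
                event.maternal_gamete == "unreduced", rng,
            )
            paternal = _gamete(
                panel, event.paternal_taxon, locus.locus_id,
                event.paternal_gamete == "unreduced", rng,
            )
            child_alleles[locus.locus_id] = tuple(sorted(maternal + paternal))
            for seq in set(maternal):
                truth.allele_origin[(child_taxon, locus.locus_id, seq)] = (
                    event.maternal_taxon
                )
            for seq in set(paternal):
                truth.allele_origin.setdefault(
                    (child_taxon, locus.locus_id, seq), event.paternal_taxon
                )

        spores = 64 if event.child_mode == "sexual" else 32
        for k in range(samples_per_event):
            sample_id = f"{child_taxon}_s{k + 1}"
            truth.child_samples[child_taxon].append(sample_id)
            samples.append(
                SimSample(
                    sample_id=sample_id,
                    taxon_name=child_taxon,
                    ploidy=event.child_ploidy,
                    spore_count=spores,
                    mode="sexual" if event.child_mode == "sexual" else "apogamous",
                    alleles=dict(child_alleles),
                    cp_sequence=panel.cp_haplotype(event.maternal_taxon),
                )
            )
    return samples, truth


def make_barcodes(sample_ids: Sequence[str], seed: int = 0) -> dict[str, str]:
    """Unique random 8-base barcodes, one per sample."""
    rng = np.random.default_rng(seed)
    barcodes: dict[str, str] = {}
    used: set[str] = set()
    for sample_id in sample_ids:
        while True:
            bc = "".join(rng.choice(BASES, size=8))
            if bc not in used:
                used.add(bc)
                barcodes[sample_id] = bc
                break
    return barcodes


def default_locus_primers(locus_ids: Iterable[str]) -> dict[str, tuple[str, str]]:
    """A deterministic, distinct 20-mer primer pair per locus (amplicon
    pools are separated by primer identity downstream)."""
    import zlib

    primers = {}
    for locus_id in locus_ids:
        rng = np.random.default_rng(zlib.crc32(locus_id.encode()))
        primers[locus_id] = (
            "".join(rng.choice(BASES, size=20)),
            "".join(rng.choice(BASES, size=20)),
        )
    return primers


def simulate_reads(
    samples: Sequence[SimSample],
    depth: float,
    error_rate: float,
    barcode_map: Mapping[str, str],
    seed: int = 0,
    loci: Sequence[str] | None = None,
    forward_primer: str = DEFAULT_FORWARD_PRIMER,
    reverse_primer: str = DEFAULT_REVERSE_PRIMER,
    primers: Mapping[str, tuple[str, str]] | None = None,
) -> list[Read]:
    """Simulate merged amplicon reads for the nuclear loci.

    Each distinct allele of a sample yields a Poisson(``depth``) cluster of
    reads of the form barcode + forward primer + allele + revcomp(reverse
    primer), with independent per-base substitution errors at ``error_rate``
    applied to the allele insert (barcode and primers are synthesised, not
    sequenced through the same error process in this simple model).

    ``primers`` optionally gives a distinct (forward, reverse) pair per
    locus (how pooled amplicons are told apart downstream); otherwise the
    single ``forward_primer``/``reverse_primer`` pair is used for all loci.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    _checked = dict(barcode_map)
    from .amplicon import _check_barcodes

    _check_barcodes(_checked)
    rng = np.random.default_rng(seed)

    reads: list[Read] = []
    for sample in samples:
        if sample.sample_id not in barcode_map:
            raise ValueError(f"no barcode for sample {sample.sample_id!r}")
        barcode = barcode_map[sample.sample_id]
        for locus_id in sorted(sample.alleles):
            if loci is not None and locus_id not in loci:
                continue
            fwd, rev = (
                primers[locus_id] if primers is not None
                else (forward_primer, reverse_primer)
            )
            for a_idx, allele in enumerate(
                sorted(set(sample.alleles[locus_id]))
            ):
                n_reads = int(rng.poisson(depth))
                insert = np.array(list(allele))
                for r in range(n_reads):
                    if error_rate > 0:
                        errs = rng.random(len(insert)) < error_rate
                        seq = insert.copy()
                        for pos in np.nonzero(errs)[0]:
                            seq[pos] = rng.choice(BASES[BASES != seq[pos]])
                        body = "".join(seq)
                    else:
                        body = allele
                    reads.append(
                        Read(
                            read_id=f"{sample.sample_id}|{locus_id}|{a_idx}|{r}",
                            sequence=barcode + fwd + body + revcomp(rev),
                        )
                    )
    return reads


# ---------------------------------------------------------------------------
# Writers


def write_simulation(
    samples: Sequence[SimSample],
    truth: SimulationTruth,
    outdir: str | Path,
    reads: Sequence[Read] | None = None,
    barcode_map: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write samples (TSV), allele sequences (FASTA), reads (FASTQ),
    barcodes (TSV) and truth (JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["samples"] = outdir / "samples.tsv"
    write_sample_table([s.as_sample() for s in samples], paths["samples"])

    fasta_records = []
    for sample in samples:
        for locus_id in sorted(sample.alleles):
            for a_idx, allele in enumerate(sorted(set(sample.alleles[locus_id]))):
                fasta_records.append(
                    (f"{sample.sample_id}|{locus_id}|{a_idx}", allele)
                )
        fasta_records.append((f"{sample.sample_id}|cpDNA|0", sample.cp_sequence))
    paths["alleles"] = outdir / "alleles.fasta"
    write_fasta(fasta_records, paths["alleles"])

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(truth.to_json())

    if reads is not None:
        paths["reads"] = outdir / "reads.fastq"
        write_fastq([(r.read_id, r.sequence) for r in reads], paths["reads"])
    if barcode_map is not None:
        paths["barcodes"] = outdir / "barcodes.tsv"
        with paths["barcodes"].open("w") as fh:
            fh.write("sample_id\tbarcode\n")
            for sample_id, barcode in barcode_map.items():
                fh.write(f"{sample_id}\t{barcode}\n")
    return paths
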