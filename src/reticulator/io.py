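"""Readers and writers for the tabular and sequence formats used throughout.

All readers are strict: unknown values stay explicitly unknown and malformed
input raises instead of being coerced. Sequence IO goes through Biopython.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = "-"

#: IUPAC nucleotide codes plus gap, the only characters accepted in FASTA IO.
IUPAC_NT = set("ACGTURYSWKMBDHVN-")

PLOIDY_LEVELS = (2, 3)
HABITATS = ("open", "semi_shade", "shade", "unknown")
ELEVATION_CLASSES = ("low", "high", "both", "unknown")
MODES = ("sexual", "apogamous", "unknown")


@dataclass(frozen=True)
class Sample:
    """One collected plant.

    ``ploidy`` and ``spore_count`` are ``None`` when not determined;
    ``reproductive_mode`` is carried explicitly because curated tables report
    the mode directly while freshly collected material reports spore counts.
    """

    sample_id: str
    taxon_name: str
    matches_type: bool = False
    ploidy: int | None = None
    spore_count: int | None = None
    reproductive_mode: str = "unknown"
    habitat: str = "unknown"
    elevation_class: str = "unknown"
    region: str = ""

    def __post_init__(self) -> None:
        if self.ploidy is not None and self.ploidy not in PLOIDY_LEVELS:
            raise ValueError(
                f"sample {self.sample_id!r}: ploidy must be one of "
                f"{PLOIDY_LEVELS} or unknown, got {self.ploidy!r}"
            )
        if self.spore_count is not None and self.spore_count <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: spore_count must be positive"
            )
        if self.reproductive_mode not in MODES:
            raise ValueError(
                f"sample {self.sample_id!r}: bad reproductive mode "
                f"{self.reproductive_mode!r}"
            )
        if self.habitat not in HABITATS:
            raise ValueError(f"sample {self.sample_id!r}: bad habitat {self.habitat!r}")
        if self.elevation_class not in ELEVATION_CLASSES:
            raise ValueError(
                f"sample {self.sample_id!r}: bad elevation class "
                f"{self.elevation_class!r}"
            )


@dataclass(frozen=True)
class AlleleCall:
    """A single allele observed in one sample at one locus."""

    sample_id: str
    locus_id: str
    allele_label: str
    group_label: str | None = None
    read_support: int | None = None
    source: str = "fixture"  # sanger | ngs | fixture


class CharacterMatrix:
    """Per-sample morphological/habitat character states.

    Wraps a DataFrame (index = sample_id, one column per character) plus the
    ordered state list of each character. Missing scores are ``None``.
    """

    def __init__(self, states: pd.DataFrame, state_lists: Mapping[str, list[str]]):
        self.states = states
        self.state_lists = {c: list(v) for c, v in state_lists.items()}
        for char in states.columns:
            if char not in self.state_lists:
                raise ValueError(f"character {char!r} has no state list")
            allowed = set(self.state_lists[char])
            observed = set(states[char].dropna())
            bad = observed - allowed
            if bad:
                raise ValueError(
                    f"character {char!r}: states {sorted(bad)} not in its state list"
                )

    @property
    def characters(self) -> list[str]:
        return list(self.states.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states.index)


def _parse_bool_flag(value: str) -> bool:
    return value.strip().upper() == "Y"


def _parse_ploidy(value: str) -> int | None:
    value = value.strip().lower()
    if value in ("", MISSING, "unknown"):
        return None
    value = value.rstrip("x")
    return int(value)


def read_sample_table(path: str | Path) -> list[Sample]:
    """Read a sample metadata TSV into :class:`Sample` records.

    Required columns: ``sample_id``, ``taxon_name``. Optional columns:
    ``matches_type``, ``ploidy``, ``spore_count``, ``reproductive_mode``,
    ``habitat``, ``elevation_class``, ``region``. Unknowns are written as
    ``-`` (or left empty) and preserved as unknown.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for required in ("sample_id", "taxon_name"):
            if required not in header:
                raise ValueError(f"{path.name}: missing required column {required!r}")
        rows = list(reader)

    ids = [r["sample_id"] for r in rows]
    duplicates = sorted({s for s in ids if ids.count(s) > 1})
    if duplicates:
        raise ValueError(f"{path.name}: duplicate sample_id values: {duplicates}")

    def get(row: dict, key: str, default: str = MISSING) -> str:
        value = (row.get(key) or "").strip()
        return value if value else default

    samples = []
    for row in rows:
        spore = get(row, "spore_count")
        mode = get(row, "reproductive_mode", "unknown")
        samples.append(
            Sample(
                sample_id=row["sample_id"].strip(),
                taxon_name=row["taxon_name"].strip(),
                matches_type=_parse_bool_flag(get(row, "matches_type", "")),
                ploidy=_parse_ploidy(get(row, "ploidy")),
                spore_count=None if spore in (MISSING, "unknown") else int(spore),
                reproductive_mode="unknown" if mode == MISSING else mode,
                habitat=get(row, "habitat", "unknown").replace(MISSING, "unknown"),
                elevation_class=get(row, "elevation_class", "unknown").replace(
                    MISSING, "unknown"
                ),
                region=get(row, "region", ""),
            )
        )
    return samples


def write_sample_table(samples: Iterable[Sample], path: str | Path) -> None:
    path = Path(path)
    columns = [
        "sample_id", "taxon_name", "matches_type", "ploidy", "spore_count",
        "reproductive_mode", "habitat", "elevation_class", "region",
    ]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for s in samples:
            writer.writerow([
                s.sample_id, s.taxon_name, "Y" if s.matches_type else "-",
                s.ploidy if s.ploidy is not None else MISSING,
                s.spore_count if s.spore_count is not None else MISSING,
                s.reproductive_mode, s.habitat, s.elevation_class, s.region,
            ])


def read_allele_calls(path: str | Path) -> list[AlleleCall]:
    """Read an allele-call TSV (sample_id, locus_id, allele_label and
    optionally group_label, read_support, source)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for required in ("sample_id", "locus_id", "allele_label"):
            if required not in header:
                raise ValueError(f"{path.name}: missing required column {required!r}")
        calls = []
        seen = set()
        for row in reader:
            key = (row["sample_id"], row["locus_id"], row["allele_label"])
            if key in seen:
                raise ValueError(f"{path.name}: duplicate allele call {key}")
            seen.add(key)
            support = (row.get("read_support") or "").strip()
            group = (row.get("group_label") or "").strip()
            calls.append(
                AlleleCall(
                    sample_id=row["sample_id"],
                    locus_id=row["locus_id"],
                    allele_label=row["allele_label"],
                    group_label=group or None,
                    read_support=int(support) if support and support != MISSING else None,
                    source=(row.get("source") or "ngs").strip() or "ngs",
                )
            )
    return calls


def write_allele_calls(calls: Iterable[AlleleCall], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample_id", "locus_id", "allele_label", "group_label",
             "read_support", "source"]
        )
        for c in calls:
            writer.writerow([
                c.sample_id, c.locus_id, c.allele_label,
                c.group_label or MISSING,
                c.read_support if c.read_support is not None else MISSING,
                c.source,
            ])


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def validate_sequence(seq: str, record_id: str = "?") -> None:
    """Raise if ``seq`` contains a non-IUPAC nucleotide character.

    The error names the 1-based position of the first offending character.
    """
    for pos, char in enumerate(seq.upper(), start=1):
        if char not in IUPAC_NT:
            raise ValueError(
                f"record {record_id!r}: non-IUPAC character {char!r} at position {pos}"
            )


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs to FASTA, validating the alphabet."""
    seq_records = []
    for rec_id, seq in records:
        validate_sequence(seq, rec_id)
        seq_records.append(SeqRecord(Seq(seq), id=rec_id, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        validate_sequence(seq, rec.id)
        records.append((rec.id, seq))
    return records


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs to FASTQ with uniform qualities."""
    seq_records = []
    for rec_id, seq in records:
        validate_sequence(seq, rec_id)
        sr = SeqRecord(Seq(seq), id=rec_id, description="")
        sr.letter_annotations["phred_quality"] = [40] * len(seq)
        seq_records.append(sr)
    SeqIO.write(seq_records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Packaged fixture

FIXTURE_LOCI = ("Knox3", "IBR3")
ALLELE_RE = re.compile(r"([A-Z]+)(\d+)")


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("reticulator.fixtures").joinpath(name)))


@dataclass
class FixtureData:
    """The packaged genotype table and companion character matrix."""

    table: pd.DataFrame
    samples: list[Sample] = field(default_factory=list)
    allele_calls: list[AlleleCall] = field(default_factory=list)
    characters: CharacterMatrix | None = None


def parse_allele_string(genotype: str) -> tuple[list[str], bool]:
    """Split a printed genotype string into allele labels and the "*" flag.

    ``"A1A6D7" -> (["A1", "A6", "D7"], False)``;
    ``"A1D7*" -> (["A1", "D7"], True)``. Returns ``([], False)`` for missing.
    """
    genotype = genotype.strip()
    if genotype in ("", MISSING):
        return [], False
    unassorted = genotype.endswith("*")
    body = genotype.rstrip("*")
    alleles = ["".join(m) for m in ALLELE_RE.findall(body)]
    if "".join(alleles) != body:
        raise ValueError(f"cannot parse genotype string {genotype!r}")
    return alleles, unassorted


def allele_group(label: str) -> str:
    """Lineage group of an allele label: its leading letter block (A7 -> A)."""
    m = ALLELE_RE.fullmatch(label)
    if not m:
        raise ValueError(f"bad allele label {label!r}")
    return m.group(1)


_MODE_MAP = {"sex": "sexual", "apo": "apogamous", MISSING: "unknown"}
_ELEV_MAP = {"l": "low", "h": "high", "both": "both", MISSING: "unknown"}


def load_fixture() -> FixtureData:
    """Load the packaged genotype table (one row per multilocus genotype).

    Resolves the published table's conventions: "-" is missing data, "*" marks
    unassorted alleles (kept as a genotype-level flag), primed haplotype
    labels (cf', ca') are distinct haplotypes. Habitat is known from the
    source only at taxon level (*P. minor* in the open, *P. latipinna* in
    shade, *P. fauriei* in semi-shade); other taxa stay unknown.
    """
    table = pd.read_csv(_fixture_path("table1.tsv"), sep="\t", dtype=str).fillna(MISSING)

    taxon_habitat = {
        "P. minor": "open",
        "P. latipinna": "shade",
        "P. fauriei": "semi_shade",
    }

    samples: list[Sample] = []
    calls: list[AlleleCall] = []
    for _, row in table.iterrows():
        mode = _MODE_MAP[row["mode"]]
        samples.append(
            Sample(
                sample_id=row["sample_id"],
                taxon_name=row["taxon"],
                matches_type=_parse_bool_flag(row["matches_type"]),
                ploidy=_parse_ploidy(row["ploidy"]),
                spore_count={"sexual": 64, "apogamous": 32}.get(mode),
                reproductive_mode=mode,
                habitat=taxon_habitat.get(row["taxon"], "unknown"),
                elevation_class=_ELEV_MAP[row["elevation"]],
                region=row["region"],
            )
        )
        for locus, column in (("Knox3", "knox3"), ("IBR3", "ibr3")):
            alleles, _ = parse_allele_string(row[column])
            for label in sorted(set(alleles)):
                calls.append(
                    AlleleCall(
                        sample_id=row["sample_id"],
                        locus_id=locus,
                        allele_label=label,
                        group_label=allele_group(label),
                        source="fixture",
                    )
                )

    characters = load_fixture_characters()
    return FixtureData(table=table, samples=samples, allele_calls=calls,
                       characters=characters)


def load_fixture_characters() -> CharacterMatrix:
    """The reconstructed morphology/habitat matrix (see fixture PROVENANCE)."""
    df = pd.read_csv(_fixture_path("characters.tsv"), sep="\t", dtype=str)
    df = df.set_index("sample_id")
    state_lists = {
        "stipe_color": ["stramineous_or_green", "red_brown"],
        "venation": ["free", "triangular", "areolate"],
        "elevation_range": ["low", "high"],
    }
    return CharacterMatrix(df, state_lists)


def fixture_provenance() -> str:
    """The transcription notes shipped with the fixture."""
    return _fixture_path("PROVENANCE.md").read_text()
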