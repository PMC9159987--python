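"""Parental-taxon identification, maternal-lineage inference, hybrid-formula
assignment, the hybridization network (reticulogram), and summary counts.

The unit of bookkeeping is the *genotype record*: one distinct combination of
(taxon, nuclear genotype per locus, chloroplast haplotype), carried by one or
more samples. Parentage itself runs on a single primary nuclear locus.

Classification logic, in outline:

* a record is **parental** when it has a chloroplast haplotype and nuclear
  data and is either homozygous, or a diploid (or ploidy-unknown)
  heterozygote whose alleles all belong to one lineage group and that is
  either sexual or *anchored* — sharing an allele with a homozygous diploid
  record of the same taxon and carrying a haplotype seen among that taxon's
  homozygotes. Anchoring separates within-taxon allelic variation (e.g. a
  segregating sexual lineage) from cryptic hybrids between related lineages
  of the same group; everything else, including records lacking nuclear
  data, is treated as being of hybrid origin.
* the **maternal group** of a haplotype is decided by a cascade: the single
  group carried by its parental carriers; failing that, the group(s) present
  in every carrier; failing that, all co-occurring groups, flagged ambiguous.
* **parents** are attributed per allele: the taxon homozygous (or parental)
  for that exact allele; when no parental taxon carries the allele, the
  attribution falls back to the group only if exactly one parental taxon
  owns that group, and otherwise remains an undiscovered ("unknown")
  lineage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .genotypes import Genotype, parse_genotype_string
from .io import MISSING, FixtureData, allele_group

#: Primary nuclear locus used for parentage unless overridden.
PRIMARY_LOCUS = "Knox3"

PARENTAL = "parental"
HYBRID = "hybrid"
UNRESOLVED = "unresolved"


@dataclass
class GenotypeRecord:
    """One distinct multilocus genotype with its carrier samples."""

    record_id: str
    taxon: str
    sample_ids: tuple[str, ...]
    genotypes: dict[str, Genotype]
    cp_haplotype: str | None
    ploidy: int | None
    mode: str = "unknown"
    matches_type: bool = False
    habitat: str = "unknown"
    elevation_class: str = "unknown"

    def genotype_string(self, locus: str) -> str | None:
        g = self.genotypes.get(locus)
        return g.canonical_string if g is not None else None

    def distinct_alleles(self, locus: str) -> tuple[str, ...]:
        g = self.genotypes.get(locus)
        return g.distinct_alleles if g is not None else ()

    def unit(self, locus: str) -> tuple[str, str]:
        """The (taxon, genotype string) unit used to count 'hybrid taxa'."""
        return (self.taxon, self.genotype_string(locus) or MISSING)


def records_from_fixture(fixture: FixtureData) -> list[GenotypeRecord]:
    """One record per row of the packaged genotype table."""
    records = []
    for _, row in fixture.table.iterrows():
        genotypes = {}
        for locus, column in (("Knox3", "knox3"), ("IBR3", "ibr3")):
            g = parse_genotype_string(row[column], row["sample_id"], locus)
            if g is not None:
                genotypes[locus] = g
        cp = row["cp_haplotype"]
        ploidy = row["ploidy"]
        records.append(
            GenotypeRecord(
                record_id=row["sample_id"],
                taxon=row["taxon"],
                sample_ids=(row["sample_id"],),
                genotypes=genotypes,
                cp_haplotype=None if cp == MISSING else cp,
                ploidy=None if ploidy == MISSING else int(ploidy),
                mode={"sex": "sexual", "apo": "apogamous"}.get(row["mode"], "unknown"),
                matches_type=row["matches_type"] == "Y",
                elevation_class={"l": "low", "h": "high", "both": "both"}.get(
                    row["elevation"], "unknown"
                ),
            )
        )
    return records


def build_genotype_records(
    samples: Sequence,
    genotypes_by_sample: Mapping[str, dict[str, Genotype]],
    cp_by_sample: Mapping[str, str | None],
) -> list[GenotypeRecord]:
    """Deduplicate samples into genotype records.

    Samples sharing taxon, every per-locus genotype string and chloroplast
    haplotype collapse into one record (the first sample id, in input order,
    names the record).
    """
    records: dict[tuple, GenotypeRecord] = {}
    for sample in samples:
        genotypes = genotypes_by_sample.get(sample.sample_id, {})
        key = (
            sample.taxon_name,
            tuple(sorted(
                (locus, g.canonical_string) for locus, g in genotypes.items()
            )),
            cp_by_sample.get(sample.sample_id),
        )
        if key in records:
            rec = records[key]
            rec.sample_ids = rec.sample_ids + (sample.sample_id,)
        else:
            records[key] = GenotypeRecord(
                record_id=sample.sample_id,
                taxon=sample.taxon_name,
                sample_ids=(sample.sample_id,),
                genotypes=dict(genotypes),
                cp_haplotype=cp_by_sample.get(sample.sample_id),
                ploidy=sample.ploidy,
                mode=sample.reproductive_mode,
                matches_type=sample.matches_type,
                habitat=sample.habitat,
                elevation_class=sample.elevation_class,
            )
    return list(records.values())


# ---------------------------------------------------------------------------
# Parental classification


def identify_parental_genotypes(
    records: Sequence[GenotypeRecord],
    group_of: Callable[[str], str] = allele_group,
    locus: str = PRIMARY_LOCUS,
) -> dict[str, str]:
    """Classify every record as parental or of hybrid origin.

    See the module docstring for the rule. Returns record_id -> status.
    """
    # Anchors: homozygous records with a cp haplotype, per taxon.
    homozygous_cp: dict[str, set[str]] = {}
    diploid_anchor_alleles: dict[str, set[str]] = {}
    for rec in records:
        distinct = rec.distinct_alleles(locus)
        if len(distinct) == 1 and rec.cp_haplotype is not None:
            homozygous_cp.setdefault(rec.taxon, set()).add(rec.cp_haplotype)
            if rec.ploidy == 2:
                diploid_anchor_alleles.setdefault(rec.taxon, set()).add(distinct[0])

    statuses: dict[str, str] = {}
    for rec in records:
        distinct = set(rec.distinct_alleles(locus))
        if not distinct or rec.cp_haplotype is None:
            statuses[rec.record_id] = HYBRID
            continue
        if len(distinct) == 1:
            statuses[rec.record_id] = PARENTAL
            continue
        groups = {group_of(a) for a in distinct}
        if len(groups) == 1 and rec.ploidy in (2, None):
            anchored = bool(
                distinct & diploid_anchor_alleles.get(rec.taxon, set())
            ) and rec.cp_haplotype in homozygous_cp.get(rec.taxon, set())
            if rec.mode == "sexual" or anchored:
                statuses[rec.record_id] = PARENTAL
                continue
        statuses[rec.record_id] = HYBRID
    return statuses


# ---------------------------------------------------------------------------
# Maternal-lineage inference


@dataclass
class CooccurrenceMatrix:
    """Counts of (cp haplotype, nuclear group) co-occurrence across records."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    parental_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    #: cp haplotype -> group sets of each carrier record with nuclear data.
    carrier_groups: dict[str, list[frozenset[str]]] = field(default_factory=dict)
    #: cp haplotype -> alleles carried by its parental-status carriers.
    parental_alleles: dict[str, set[str]] = field(default_factory=dict)

    @property
    def haplotypes(self) -> list[str]:
        return sorted(self.counts)


def build_cooccurrence(
    records: Sequence[GenotypeRecord],
    statuses: Mapping[str, str],
    group_of: Callable[[str], str] = allele_group,
    locus: str = PRIMARY_LOCUS,
) -> CooccurrenceMatrix:
    """Count each (record, distinct group) incidence per cp haplotype.

    Records without a cp haplotype are skipped; records with a haplotype but
    no nuclear data register the haplotype with an empty group set.
    """
    matrix = CooccurrenceMatrix()
    for rec in records:
        cp = rec.cp_haplotype
        if cp is None:
            continue
        groups = frozenset(group_of(a) for a in rec.distinct_alleles(locus))
        matrix.counts.setdefault(cp, {})
        matrix.parental_counts.setdefault(cp, {})
        matrix.carrier_groups.setdefault(cp, [])
        matrix.parental_alleles.setdefault(cp, set())
        if groups:
            matrix.carrier_groups[cp].append(groups)
        if statuses.get(rec.record_id) == PARENTAL:
            matrix.parental_alleles[cp].update(rec.distinct_alleles(locus))
        for group in groups:
            matrix.counts[cp][group] = matrix.counts[cp].get(group, 0) + 1
            if statuses.get(rec.record_id) == PARENTAL:
                matrix.parental_counts[cp][group] = (
                    matrix.parental_counts[cp].get(group, 0) + 1
                )
    return matrix


@dataclass(frozen=True)
class MaternalCall:
    """Inferred maternal lineage group(s) for one cp haplotype.

    ``parental_alleles`` lists the alleles seen in the haplotype's
    parental-status carriers; when a hybrid genotype holds several alleles
    of the maternal group (an intra-group hybrid), those pin which allele
    is the maternal one.
    """

    haplotype: str
    groups: frozenset[str]
    basis: str  # parental | universal | ambiguous
    parental_alleles: frozenset[str] = frozenset()

    @property
    def ambiguous(self) -> bool:
        return self.basis == "ambiguous" or len(self.groups) != 1


def infer_maternal_group(cp_haplotype: str, matrix: CooccurrenceMatrix) -> MaternalCall:
    """Decide the maternal nuclear group for a chloroplast haplotype.

    Cascade: (1) the unique group among parental carriers; (2) the group(s)
    present in *every* carrier of the haplotype; (3) all co-occurring
    groups, flagged ambiguous.
    """
    if cp_haplotype not in matrix.counts:
        raise KeyError(f"haplotype {cp_haplotype!r} not present in matrix")

    anchors = frozenset(matrix.parental_alleles.get(cp_haplotype, set()))
    parental_groups = {
        g for g, n in matrix.parental_counts[cp_haplotype].items() if n > 0
    }
    if len(parental_groups) == 1:
        return MaternalCall(cp_haplotype, frozenset(parental_groups),
                            "parental", anchors)

    carrier_sets = matrix.carrier_groups.get(cp_haplotype, [])
    if carrier_sets:
        universal = frozenset.intersection(*carrier_sets)
        if universal:
            return MaternalCall(cp_haplotype, universal, "universal", anchors)

    all_groups = frozenset(
        g for g, n in matrix.counts[cp_haplotype].items() if n > 0
    )
    return MaternalCall(cp_haplotype, all_groups, "ambiguous", anchors)


# ---------------------------------------------------------------------------
# Parentage assignment


UNKNOWN_TAXON = "unknown"


def unknown_lineage(allele: str) -> str:
    """Placeholder name for an undiscovered parental lineage."""
    return f"{UNKNOWN_TAXON}[{allele}]"


def is_unknown(taxon: str) -> bool:
    return taxon == UNKNOWN_TAXON or taxon.startswith(f"{UNKNOWN_TAXON}[")


@dataclass
class ParentalRegistry:
    """Maps alleles and groups to the parental taxa carrying them."""

    allele_to_taxa: dict[str, set[str]] = field(default_factory=dict)
    group_to_taxa: dict[str, set[str]] = field(default_factory=dict)

    def taxa_for_allele(self, allele: str, group: str) -> tuple[set[str], bool]:
        """Parental taxa attributable to one allele.

        Returns (taxa, group_level): exact carriers when known; otherwise the
        single taxon owning the allele's group (group-level attribution), or
        an undiscovered-lineage placeholder.
        """
        exact = self.allele_to_taxa.get(allele, set())
        if exact:
            return set(exact), False
        owners = self.group_to_taxa.get(group, set())
        if len(owners) == 1:
            return set(owners), True
        return {unknown_lineage(allele)}, False


def build_parental_registry(
    records: Sequence[GenotypeRecord],
    statuses: Mapping[str, str],
    group_of: Callable[[str], str] = allele_group,
    locus: str = PRIMARY_LOCUS,
) -> ParentalRegistry:
    registry = ParentalRegistry()
    for rec in records:
        if statuses.get(rec.record_id) != PARENTAL:
            continue
        for allele in rec.distinct_alleles(locus):
            registry.allele_to_taxa.setdefault(allele, set()).add(rec.taxon)
            registry.group_to_taxa.setdefault(group_of(allele), set()).add(rec.taxon)
    return registry


@dataclass
class HybridFormula:
    """Inferred parentage of one hybrid genotype record."""

    record_id: str
    taxon: str
    genotype_string: str | None
    cp_haplotype: str | None
    status: str
    maternal_taxa: frozenset[str] = frozenset()
    paternal_taxa: frozenset[str] = frozenset()
    maternal_alleles: frozenset[str] = frozenset()
    paternal_alleles: frozenset[str] = frozenset()
    maternal_groups: frozenset[str] = frozenset()
    ambiguous: bool = False
    notes: str = ""

    @property
    def parent_taxa(self) -> frozenset[str]:
        return self.maternal_taxa | self.paternal_taxa

    @property
    def formula_string(self) -> str:
        """Human-readable '<maternal> x <paternal>' with ambiguity sets
        joined by 'or' and undiscovered lineages printed as 'unknown'."""
        def side(taxa: frozenset[str]) -> str:
            if not taxa:
                return "?"
            shown = sorted({UNKNOWN_TAXON if is_unknown(t) else t for t in taxa})
            return " or ".join(shown)

        return f"{side(self.maternal_taxa)} x {side(self.paternal_taxa)}"


def assign_parentage(
    record: GenotypeRecord,
    maternal_call: MaternalCall | None,
    registry: ParentalRegistry,
    group_of: Callable[[str], str] = allele_group,
    locus: str = PRIMARY_LOCUS,
) -> HybridFormula:
    """Derive the hybrid formula for one hybrid-status record.

    The maternal side collects the genotype's alleles belonging to the
    inferred maternal group(s) (two alleles when an unreduced maternal
    gamete contributed); the paternal side takes the rest. Parents are the
    parental taxa registered for those alleles; unresolved cases (no
    chloroplast data, or a maternal group absent from the genotype) are
    flagged rather than guessed.
    """
    distinct = record.distinct_alleles(locus)
    base = dict(
        record_id=record.record_id,
        taxon=record.taxon,
        genotype_string=record.genotype_string(locus),
        cp_haplotype=record.cp_haplotype,
    )
    if not distinct:
        return HybridFormula(**base, status=UNRESOLVED, notes="no nuclear data")
    if maternal_call is None:
        # No cpDNA: parents can still be listed, but no maternal/paternal split.
        taxa: set[str] = set()
        for allele in distinct:
            found, _ = registry.taxa_for_allele(allele, group_of(allele))
            taxa |= found
        return HybridFormula(
            **base,
            status=UNRESOLVED,
            paternal_taxa=frozenset(taxa),
            paternal_alleles=frozenset(distinct),
            notes="no cpDNA haplotype; contributing lineages listed as unsided",
        )

    maternal_alleles = frozenset(
        a for a in distinct if group_of(a) in maternal_call.groups
    )
    # Intra-group hybrids carry several maternal-group alleles; the alleles
    # of the haplotype's own parental carriers pin the maternal one(s).
    refined = maternal_alleles & maternal_call.parental_alleles
    if refined and refined != maternal_alleles:
        maternal_alleles = refined
    if not maternal_alleles:
        return HybridFormula(
            **base,
            status=UNRESOLVED,
            maternal_groups=maternal_call.groups,
            notes=(
                f"maternal group(s) {sorted(maternal_call.groups)} not "
                "represented in the genotype"
            ),
        )
    paternal_alleles = frozenset(distinct) - maternal_alleles

    ambiguous = maternal_call.ambiguous
    maternal_taxa: set[str] = set()
    for allele in sorted(maternal_alleles):
        found, group_level = registry.taxa_for_allele(allele, group_of(allele))
        maternal_taxa |= found
        ambiguous = ambiguous or group_level or len(found) > 1
    paternal_taxa: set[str] = set()
    for allele in sorted(paternal_alleles):
        found, group_level = registry.taxa_for_allele(allele, group_of(allele))
        paternal_taxa |= found
        ambiguous = ambiguous or group_level

    notes = ""
    if maternal_call.ambiguous:
        notes = (
            f"maternal group ambiguous ({maternal_call.basis}: "
            f"{sorted(maternal_call.groups)})"
        )
    return HybridFormula(
        **base,
        status=HYBRID,
        maternal_taxa=frozenset(maternal_taxa),
        paternal_taxa=frozenset(paternal_taxa),
        maternal_alleles=maternal_alleles,
        paternal_alleles=paternal_alleles,
        maternal_groups=maternal_call.groups,
        ambiguous=ambiguous,
        notes=notes,
    )


def infer_all(
    records: Sequence[GenotypeRecord],
    group_of: Callable[[str], str] = allele_group,
    locus: str = PRIMARY_LOCUS,
) -> tuple[dict[str, str], CooccurrenceMatrix, dict[str, MaternalCall],
           ParentalRegistry, list[HybridFormula]]:
    """Run the full inference chain on a set of genotype records."""
    statuses = identify_parental_genotypes(records, group_of, locus)
    matrix = build_cooccurrence(records, statuses, group_of, locus)
    maternal = {h: infer_maternal_group(h, matrix) for h in matrix.haplotypes}
    registry = build_parental_registry(records, statuses, group_of, locus)
    formulas = [
        assign_parentage(rec, maternal.get(rec.cp_haplotype), registry,
                         group_of, locus)
        for rec in records
        if statuses[rec.record_id] == HYBRID
    ]
    return statuses, matrix, maternal, registry, formulas


# ---------------------------------------------------------------------------
# Reticulogram


def build_reticulogram(
    formulas: Sequence[HybridFormula],
    records: Sequence[GenotypeRecord],
    statuses: Mapping[str, str],
    locus: str = PRIMARY_LOCUS,
) -> nx.MultiDiGraph:
    """Directed hybridization network.

    Nodes are distinct (taxon, genotype string) units — one per parental or
    hybrid genotype — plus dashed placeholder nodes for undiscovered
    lineages. Edges run parent -> hybrid, typed maternal or paternal;
    ambiguity sets expand to parallel edges flagged ``ambiguous``. A hybrid
    node missing either parent side carries ``incomplete=True``.
    """
    graph = nx.MultiDiGraph()
    by_id = {rec.record_id: rec for rec in records}

    def node_id(taxon: str, genotype: str | None) -> str:
        return f"{taxon}|{genotype or MISSING}"

    parental_node_of_taxon: dict[str, list[str]] = {}
    for rec in records:
        nid = node_id(rec.taxon, rec.genotype_string(locus))
        status = statuses.get(rec.record_id, HYBRID)
        if nid not in graph:
            graph.add_node(
                nid,
                taxon=rec.taxon,
                genotype=rec.genotype_string(locus) or MISSING,
                status=status,
                ploidy=rec.ploidy if rec.ploidy is not None else 0,
                mode=rec.mode,
                habitat=rec.habitat,
                elevation=rec.elevation_class,
                dashed=False,
            )
        if status == PARENTAL:
            parental_node_of_taxon.setdefault(rec.taxon, []).append(nid)

    def parent_node(taxon: str) -> str:
        if is_unknown(taxon):
            if taxon not in graph:
                graph.add_node(
                    taxon, taxon=taxon, genotype=MISSING, status=PARENTAL,
                    ploidy=0, mode="unknown", habitat="unknown",
                    elevation="unknown", dashed=True,
                )
            return taxon
        nodes = parental_node_of_taxon.get(taxon)
        return nodes[0] if nodes else taxon

    for formula in formulas:
        rec = by_id[formula.record_id]
        child = node_id(rec.taxon, rec.genotype_string(locus))
        for role, taxa in (("maternal", formula.maternal_taxa),
                           ("paternal", formula.paternal_taxa)):
            for taxon in sorted(taxa):
                graph.add_edge(
                    parent_node(taxon), child, type=role,
                    ambiguous=formula.ambiguous or len(taxa) > 1,
                )
        incomplete = not formula.maternal_taxa or not formula.paternal_taxa
        graph.nodes[child]["incomplete"] = incomplete
    return graph


def write_gml(graph: nx.MultiDiGraph, path: str | Path) -> None:
    nx.write_gml(graph, str(path))


def write_dot(graph: nx.MultiDiGraph, path: str | Path) -> None:
    """Minimal DOT export with maternal edges red, paternal blue, and
    dashed outlines for undiscovered lineages."""
    lines = ["digraph reticulogram {"]
    for node, data in graph.nodes(data=True):
        attrs = [f'label="{node}"']
        if data.get("dashed"):
            attrs.append("style=dashed")
        shape = {2: "ellipse", 3: "triangle"}.get(data.get("ploidy"), "box")
        attrs.append(f"shape={shape}")
        lines.append(f'  "{node}" [{", ".join(attrs)}];')
    for u, v, data in graph.edges(data=True):
        color = "red" if data.get("type") == "maternal" else "blue"
        style = ", style=dashed" if data.get("ambiguous") else ""
        lines.append(f'  "{u}" -> "{v}" [color={color}{style}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Summary counts


ROLE_DEFINITIONS = ("maternal", "paternal", "either")


@dataclass
class Summary:
    total_genotypes: int
    parental_genotypes: int
    hybrid_genotypes: int
    parental_taxa: list[str]
    #: taxon -> {role definition -> number of distinct hybrid units}
    hybrids_per_parental_taxon: dict[str, dict[str, int]]

    @property
    def n_parental_taxa(self) -> int:
        return len(self.parental_taxa)

    def to_dict(self) -> dict:
        return {
            "total_genotypes": self.total_genotypes,
            "parental_genotypes": self.parental_genotypes,
            "hybrid_genotypes": self.hybrid_genotypes,
            "n_parental_taxa": self.n_parental_taxa,
            "parental_taxa": self.parental_taxa,
            "hybrids_per_parental_taxon": self.hybrids_per_parental_taxon,
        }


def summarize(
    records: Sequence[GenotypeRecord],
    statuses: Mapping[str, str],
    formulas: Sequence[HybridFormula],
    locus: str = PRIMARY_LOCUS,
) -> Summary:
    """Headline bookkeeping of the inference.

    Genotype counts are over records; the per-parental-taxon hybrid counts
    are over distinct (taxon, genotype string) hybrid units, reported under
    all three role definitions (parent as maternal, as paternal, in either
    role) because the appropriate definition depends on the question asked.
    """
    by_id = {rec.record_id: rec for rec in records}
    total = len(records)
    parental = sum(1 for rec in records if statuses[rec.record_id] == PARENTAL)
    hybrid = total - parental
    parental_taxa = sorted(
        {rec.taxon for rec in records if statuses[rec.record_id] == PARENTAL}
    )

    role_units: dict[str, dict[str, set]] = {
        role: {} for role in ROLE_DEFINITIONS
    }
    for formula in formulas:
        unit = by_id[formula.record_id].unit(locus)
        role_taxa = {
            "maternal": formula.maternal_taxa,
            "paternal": formula.paternal_taxa,
            "either": formula.parent_taxa,
        }
        for role, taxa in role_taxa.items():
            for taxon in taxa:
                if is_unknown(taxon):
                    continue
                role_units[role].setdefault(taxon, set()).add(unit)

    per_taxon: dict[str, dict[str, int]] = {}
    for taxon in sorted({t for role in role_units.values() for t in role}):
        per_taxon[taxon] = {
            role: len(role_units[role].get(taxon, set()))
            for role in ROLE_DEFINITIONS
        }
    return Summary(total, parental, hybrid, parental_taxa, per_taxon)


def write_formulas(formulas: Iterable[HybridFormula], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "record_id", "taxon", "genotype", "cp_haplotype", "status",
            "formula", "maternal_taxa", "paternal_taxa", "maternal_alleles",
            "paternal_alleles", "ambiguous", "notes",
        ])
        for f in formulas:
            writer.writerow([
                f.record_id, f.taxon, f.genotype_string or MISSING,
                f.cp_haplotype or MISSING, f.status, f.formula_string,
                ";".join(sorted(f.maternal_taxa)) or MISSING,
                ";".join(sorted(f.paternal_taxa)) or MISSING,
                ";".join(sorted(f.maternal_alleles)) or MISSING,
                ";".join(sorted(f.paternal_alleles)) or MISSING,
                str(f.ambiguous).lower(), f.notes,
            ])
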