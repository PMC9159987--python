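"""Ploidy-aware genotype assembly and reproductive-mode classification.

A genotype is the multiset of allele labels observed for one sample at one
locus, constrained by the sample's ploidy. When fewer distinct alleles are
observed than the ploidy allows, the exact dosage cannot be asserted and the
genotype carries an "unassorted" flag, printed as a trailing ``*``
(``A1D7*`` = a triploid showing two distinct alleles). Homozygous completion
(one allele in a diploid -> doubled, ``A7`` -> ``A7A7``) is applied only for
diploids; a triploid is never completed to a triple homozygote.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import MISSING, AlleleCall, Sample, parse_allele_string

_LABEL_RE = re.compile(r"([A-Za-z]+)(\d+)")


def allele_sort_key(label: str) -> tuple[str, int]:
    """Sort key: letter prefix alphabetically, then numeric value (A2 < A11)."""
    m = _LABEL_RE.fullmatch(label)
    if not m:
        return (label, 0)
    return (m.group(1), int(m.group(2)))


@dataclass(frozen=True)
class Genotype:
    """Allele multiset of one sample at one locus.

    ``unassorted`` is True when dosage cannot be asserted, False when the
    allele count matches the ploidy (or was completed), and None when the
    ploidy itself is unknown.
    """

    sample_id: str
    locus_id: str
    alleles: tuple[str, ...]
    unassorted: bool | None

    @property
    def distinct_alleles(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.alleles:
            seen.setdefault(a)
        return tuple(seen)

    @property
    def canonical_string(self) -> str:
        s = "".join(self.alleles)
        return s + "*" if self.unassorted else s


def infer_reproductive_mode(spore_count: int | None) -> str:
    """Classify reproductive mode from the spores-per-sporangium count.

    Sexual plants of this group produce 64 spores per sporangium; apogamous
    plants produce 32 or fewer. Counts strictly between 32 and 64, or above
    64, do not fit either mode and map to ``unknown``.
    """
    if spore_count is None:
        return "unknown"
    if spore_count <= 0:
        raise ValueError(f"spore count must be positive, got {spore_count}")
    if spore_count == 64:
        return "sexual"
    if spore_count <= 32:
        return "apogamous"
    return "unknown"


def assemble_genotype(
    sample_id: str,
    locus_id: str,
    alleles: Iterable[str],
    ploidy: int | None,
    homozygous_completion: bool = True,
) -> Genotype:
    """Build the canonical genotype for one sample at one locus.

    ``alleles`` are the distinct allele labels retained for the sample.
    With known ploidy, observing more distinct alleles than the ploidy is an
    error (contamination or a wrong ploidy call). Observing exactly ploidy
    alleles gives a plain heterozygous genotype; observing one allele in a
    diploid doubles it when ``homozygous_completion`` is on; every other
    shortfall sets the unassorted flag.
    """
    distinct = sorted(set(alleles), key=allele_sort_key)
    if not distinct:
        raise ValueError(f"{sample_id}/{locus_id}: need at least one allele")

    if ploidy is None:
        return Genotype(sample_id, locus_id, tuple(distinct), unassorted=None)

    if len(distinct) > ploidy:
        raise ValueError(
            f"{sample_id}/{locus_id}: allele count exceeds ploidy "
            f"({len(distinct)} alleles, ploidy {ploidy})"
        )
    if len(distinct) == ploidy:
        return Genotype(sample_id, locus_id, tuple(distinct), unassorted=False)
    if len(distinct) == 1 and ploidy == 2 and homozygous_completion:
        return Genotype(sample_id, locus_id, tuple(distinct * 2), unassorted=False)
    return Genotype(sample_id, locus_id, tuple(distinct), unassorted=True)


def parse_genotype_string(
    genotype: str, sample_id: str = "?", locus_id: str = "?"
) -> Genotype | None:
    """Parse a printed genotype string (``A1A6D7``, ``A1D7*``) verbatim.

    Unlike :func:`assemble_genotype` this preserves printed dosage (e.g. a
    curated triple homozygote ``F7F7F7``) instead of re-deriving it. Returns
    None for a missing genotype.
    """
    alleles, unassorted = parse_allele_string(genotype)
    if not alleles:
        return None
    ordered = sorted(alleles, key=allele_sort_key)
    return Genotype(sample_id, locus_id, tuple(ordered), unassorted)


def genotype_table(
    samples: Sequence[Sample],
    calls: Iterable[AlleleCall],
    homozygous_completion: bool = True,
) -> list[Genotype]:
    """Assemble one genotype per sample x locus holding at least one call.

    Samples with no call at a locus are simply absent from the result for
    that locus (missing data, not an empty genotype). Assembly errors are
    re-raised with the sample context attached.
    """
    ploidy_of = {s.sample_id: s.ploidy for s in samples}
    by_sample_locus: dict[tuple[str, str], list[str]] = {}
    for call in calls:
        if call.sample_id not in ploidy_of:
            raise ValueError(f"allele call for unknown sample {call.sample_id!r}")
        by_sample_locus.setdefault((call.sample_id, call.locus_id), []).append(
            call.allele_label
        )

    genotypes = []
    for (sample_id, locus_id), alleles in sorted(by_sample_locus.items()):
        genotypes.append(
            assemble_genotype(
                sample_id,
                locus_id,
                alleles,
                ploidy_of[sample_id],
                homozygous_completion=homozygous_completion,
            )
        )
    return genotypes


def write_genotype_table(
    genotypes: Iterable[Genotype],
    modes: Mapping[str, str],
    path,
) -> None:
    """Write a genotype TSV: sample, locus, canonical string, flags, mode."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "locus_id", "genotype", "unassorted", "mode"])
        for g in genotypes:
            flag = MISSING if g.unassorted is None else str(g.unassorted).lower()
            writer.writerow(
                [g.sample_id, g.locus_id, g.canonical_string, flag,
                 modes.get(g.sample_id, "unknown")]
            )
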