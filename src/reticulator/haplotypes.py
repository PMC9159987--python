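"""Collapsing aligned sequences into labelled haplotypes / allele types,
lineage-group assignment, and the rare-allele filter.

Haplotype collapsing is an exact-identity partition of equal-length (aligned)
sequences; labels are assigned in order of first appearance, so reruns on the
same input are label-stable. Group assignment either passes through a
provided allele-to-group map or single-links alleles on pairwise p-distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AlleleCall

GAP_CHARS = set("-")


@dataclass
class HaplotypeTable:
    """Partition of input sequences into labelled haplotypes for one locus."""

    locus_id: str
    label_to_sequence: dict[str, str]
    assignments: dict[str, str]  # input sequence id -> haplotype label
    prefix: str = "h"

    @property
    def labels(self) -> list[str]:
        return list(self.label_to_sequence)

    def members(self, label: str) -> list[str]:
        return [sid for sid, lab in self.assignments.items() if lab == label]


def _retained_columns(seqs: Sequence[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    has_gap = np.isin(arr, list(GAP_CHARS)).any(axis=0)
    return ~has_gap


def collapse_haplotypes(
    records: Sequence[tuple[str, str]],
    locus_id: str = "locus",
    gap_policy: str = "sites_with_gaps_excluded",
    prefix: str = "h",
) -> HaplotypeTable:
    """Partition aligned sequences into haplotypes by exact identity.

    ``gap_policy="sites_with_gaps_excluded"`` drops every alignment column
    containing a gap in any sequence before comparing (gaps treated as
    missing data); ``"gaps_as_missing"`` keeps all columns and lets a gap
    match any base, assigning each sequence greedily to the first existing
    haplotype it is compatible with (deterministic in input order).

    Labels are ``<prefix><k>`` numbered from 1 in order of first appearance.
    """
    if gap_policy not in ("sites_with_gaps_excluded", "gaps_as_missing"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if not records:
        return HaplotypeTable(locus_id, {}, {}, prefix)

    ids = [rid for rid, _ in records]
    seqs = [s.upper() for _, s in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"{locus_id}: sequences must be aligned to equal length, got {sorted(lengths)}"
        )

    if gap_policy == "sites_with_gaps_excluded":
        keep = _retained_columns(seqs)
        keys = ["".join(np.array(list(s))[keep]) for s in seqs]
        label_of_key: dict[str, str] = {}
        label_to_seq: dict[str, str] = {}
        assignments: dict[str, str] = {}
        for rid, seq, key in zip(ids, seqs, keys):
            if key not in label_of_key:
                label_of_key[key] = f"{prefix}{len(label_of_key) + 1}"
                label_to_seq[label_of_key[key]] = seq
            assignments[rid] = label_of_key[key]
        return HaplotypeTable(locus_id, label_to_seq, assignments, prefix)

    # gaps_as_missing: greedy first-fit with gap as wildcard
    def compatible(a: str, b: str) -> bool:
        return all(x == y or x in GAP_CHARS or y in GAP_CHARS for x, y in zip(a, b))

    label_to_seq = {}
    assignments = {}
    for rid, seq in zip(ids, seqs):
        for label, rep in label_to_seq.items():
            if compatible(seq, rep):
                assignments[rid] = label
                break
        else:
            label = f"{prefix}{len(label_to_seq) + 1}"
            label_to_seq[label] = seq
            assignments[rid] = label
    return HaplotypeTable(locus_id, label_to_seq, assignments, prefix)


@dataclass
class GroupAssignment:
    """Total map from allele label to lineage-group label."""

    groups: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, allele: str) -> str:
        return self.groups[allele]

    def group_of(self, allele: str) -> str:
        return self.groups[allele]


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("p-distance requires equal-length sequences")
    if not a:
        return 0.0
    return sum(x != y for x, y in zip(a, b)) / len(a)


def _single_linkage(items: list[str], linked) -> list[list[str]]:
    """Connected components under a symmetric predicate, input-order stable."""
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if linked(items[i], items[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[str]] = {}
    for i, item in enumerate(items):
        clusters.setdefault(find(i), []).append(item)
    return [clusters[root] for root in sorted(clusters)]


def assign_groups(
    alleles: Sequence[str],
    method: str = "provided_map",
    threshold: float = 0.05,
    provided_map: Mapping[str, str] | None = None,
    sequences: Mapping[str, str] | None = None,
) -> GroupAssignment:
    """Map every allele to a lineage group.

    ``provided_map`` passes a curated map through after checking it covers
    every allele. ``distance_cluster`` single-links allele representative
    sequences at p-distance <= ``threshold`` and names groups by descending
    cluster size (ties broken by the lexicographically smallest member):
    A, B, C, ...
    """
    alleles = list(alleles)
    if method == "provided_map":
        if provided_map is None:
            raise ValueError("provided_map method requires a map")
        missing = sorted(a for a in alleles if a not in provided_map)
        if missing:
            raise ValueError(f"alleles not covered by provided map: {missing}")
        return GroupAssignment({a: provided_map[a] for a in alleles})

    if method != "distance_cluster":
        raise ValueError(f"unknown grouping method {method!r}")
    if sequences is None:
        raise ValueError("distance_cluster requires allele sequences")
    missing = sorted(a for a in alleles if a not in sequences)
    if missing:
        raise ValueError(f"no sequence for alleles: {missing}")

    clusters = _single_linkage(
        alleles, lambda a, b: p_distance(sequences[a], sequences[b]) <= threshold
    )
    clusters.sort(key=lambda c: (-len(c), sorted(c)[0]))
    groups: dict[str, str] = {}
    for rank, cluster in enumerate(clusters):
        letter = _group_letter(rank)
        for allele in cluster:
            groups[allele] = letter
    return GroupAssignment(groups)


def _group_letter(rank: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    name = ""
    rank += 1
    while rank:
        rank, rem = divmod(rank - 1, 26)
        name = letters[rem] + name
    return name


def filter_rare_alleles(
    calls: Iterable[AlleleCall], min_samples: int = 2
) -> tuple[list[AlleleCall], list[dict]]:
    """Drop alleles observed in fewer than ``min_samples`` distinct samples.

    Singleton alleles in amplicon data are likely residual errors. Returns
    the retained calls (input order preserved) and a report of dropped
    alleles with their carriers. Idempotent.
    """
    calls = list(calls)
    carriers: dict[tuple[str, str], set[str]] = {}
    for call in calls:
        carriers.setdefault((call.locus_id, call.allele_label), set()).add(
            call.sample_id
        )

    kept, dropped = [], []
    reported = set()
    for call in calls:
        key = (call.locus_id, call.allele_label)
        if len(carriers[key]) >= min_samples:
            kept.append(call)
        elif key not in reported:
            reported.add(key)
            dropped.append(
                {
                    "locus_id": call.locus_id,
                    "allele_label": call.allele_label,
                    "carriers": sorted(carriers[key]),
                }
            )
    return kept, dropped
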