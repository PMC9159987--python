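"""Barcoded amplicon processing: demultiplexing, primer trimming, read
clustering, and the ploidy-aware cluster-retention rule.

The retention rule keeps the three highest-count clusters for diploid
samples, four for triploid or ploidy-unknown samples, and then removes any
retained cluster backed by fewer than 100 original reads. Clustering is
single-linkage over pairwise identity on equal-length reads (reads are
binned by length first; indel-tolerant alignment is deliberately not
implemented — see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Default minimum original-read support for a retained cluster.
DEFAULT_MIN_READS = 100

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str


@dataclass
class ReadCluster:
    """A cluster of near-identical reads from one sample at one locus."""

    sample_id: str
    locus_id: str
    consensus: str
    read_count: int
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.read_count != len(self.member_ids) or self.read_count < 1:
            raise ValueError("read_count must equal the number of member reads (>= 1)")


def _check_barcodes(barcode_map: Mapping[str, str]) -> None:
    for sample, barcode in barcode_map.items():
        if len(barcode) != 8:
            raise ValueError(f"barcode for {sample!r} is not 8 bases: {barcode!r}")
    seen: dict[str, str] = {}
    for sample, barcode in barcode_map.items():
        if barcode in seen:
            raise ValueError(
                f"duplicate barcode {barcode!r} for samples {seen[barcode]!r} and {sample!r}"
            )
        seen[barcode] = sample


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[Read],
    barcode_map: Mapping[str, str],
    max_mismatches: int = 0,
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Assign reads to samples by their leading 8-base barcode.

    A read is assigned iff its first 8 bases match exactly one barcode within
    ``max_mismatches`` (default exact); the barcode is stripped from assigned
    reads. Assigned plus unassigned reads always partition the input.
    """
    _check_barcodes(barcode_map)
    assigned: dict[str, list[Read]] = {sample: [] for sample in barcode_map}
    unassigned: list[Read] = []
    for read in reads:
        prefix = read.sequence[:8]
        hits = [
            sample
            for sample, barcode in barcode_map.items()
            if len(prefix) == 8 and _hamming(prefix, barcode) <= max_mismatches
        ]
        if len(hits) == 1:
            assigned[hits[0]].append(Read(read.read_id, read.sequence[8:]))
        else:
            unassigned.append(read)
    return assigned, unassigned


def trim_primers(
    reads: Iterable[Read],
    forward_primer: str,
    reverse_primer: str,
    max_mismatches: int = 0,
) -> tuple[list[Read], int]:
    """Strip primers from merged reads of the form F + insert + revcomp(R).

    Reads whose ends do not match both primers within ``max_mismatches``
    (or that are shorter than the two primers) are dropped; the count of
    dropped reads is returned alongside the trimmed reads.
    """
    if not forward_primer or not reverse_primer:
        raise ValueError("primers must be non-empty")
    fwd = forward_primer.upper()
    rev_rc = revcomp(reverse_primer)
    trimmed: list[Read] = []
    dropped = 0
    for read in reads:
        seq = read.sequence
        if len(seq) < len(fwd) + len(rev_rc):
            dropped += 1
            continue
        if (
            _hamming(seq[: len(fwd)], fwd) <= max_mismatches
            and _hamming(seq[len(seq) - len(rev_rc):], rev_rc) <= max_mismatches
        ):
            trimmed.append(Read(read.read_id, seq[len(fwd): len(seq) - len(rev_rc)]))
        else:
            dropped += 1
    return trimmed, dropped


def _consensus(seqs: Sequence[str], weights: Sequence[int]) -> str:
    """Per-column majority, ties to the lexicographically smallest base."""
    arr = np.array([list(s) for s in seqs])
    out = []
    for col in arr.T:
        counts: dict[str, int] = {}
        for base, weight in zip(col, weights):
            counts[base] = counts.get(base, 0) + int(weight)
        top = max(counts.values())
        out.append(min(b for b, c in counts.items() if c == top))
    return "".join(out)


def cluster_reads(
    reads: Sequence[Read],
    identity_threshold: float = 0.99,
    sample_id: str = "?",
    locus_id: str = "?",
) -> list[ReadCluster]:
    """Single-linkage clustering of same-locus reads by pairwise identity.

    Reads are binned by length (identity is defined on equal-length pairs);
    within a bin, identical reads are deduplicated and unique sequences are
    single-linked at identity >= ``identity_threshold``. The consensus is the
    weighted per-column majority with ties to the smallest base. Clusters are
    returned sorted by read count descending, then consensus lexicographic.
    """
    if not 0.5 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0.5, 1]")
    if not reads:
        return []

    by_length: dict[int, list[Read]] = {}
    for read in reads:
        by_length.setdefault(len(read.sequence), []).append(read)

    clusters: list[ReadCluster] = []
    for length in sorted(by_length):
        bin_reads = by_length[length]
        uniq: dict[str, list[str]] = {}
        for read in bin_reads:
            uniq.setdefault(read.sequence.upper(), []).append(read.read_id)
        seqs = list(uniq)
        n = len(seqs)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        if length > 0:
            # identity >= t  <=>  mismatches <= (1-t)*L; epsilon guards the
            # float representation of (1-t) (e.g. 1-0.9 is slightly < 0.1)
            max_diff = int(np.floor((1 - identity_threshold) * length + 1e-9))
            arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, length)
            for i in range(n):
                diffs = (arr[i + 1:] != arr[i]).sum(axis=1)
                for off in np.nonzero(diffs <= max_diff)[0]:
                    j = i + 1 + int(off)
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)

        groups: dict[int, list[str]] = {}
        for i, seq in enumerate(seqs):
            groups.setdefault(find(i), []).append(seq)
        for member_seqs in groups.values():
            ids = tuple(rid for seq in member_seqs for rid in uniq[seq])
            weights = [len(uniq[seq]) for seq in member_seqs]
            clusters.append(
                ReadCluster(
                    sample_id=sample_id,
                    locus_id=locus_id,
                    consensus=_consensus(member_seqs, weights),
                    read_count=len(ids),
                    member_ids=ids,
                )
            )

    clusters.sort(key=lambda c: (-c.read_count, c.consensus))
    return clusters


def retain_clusters(
    clusters: Sequence[ReadCluster],
    ploidy: int | None,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[ReadCluster]:
    """Apply the ploidy-aware retention rule.

    Keep the top-3 clusters for a diploid sample, the top-4 for a triploid
    or ploidy-unknown sample (input must be sorted as produced by
    :func:`cluster_reads`; equal-count ties at the boundary therefore keep
    the lexicographically smaller consensus), then drop any retained cluster
    with fewer than ``min_reads`` original reads. Order is preserved.
    """
    top_k = 3 if ploidy == 2 else 4
    retained = list(clusters[:top_k])
    return [c for c in retained if c.read_count >= min_reads]


def merge_read_pair(forward: str, reverse: str, min_overlap: int = 10) -> str | None:
    """Exact-overlap merge of a read pair (reverse read given as sequenced).

    Scans for the longest suffix of the forward read equal to a prefix of the
    reverse-complemented reverse read. Returns the merged sequence, or None
    when no exact overlap of at least ``min_overlap`` exists.
    """
    rev = revcomp(reverse)
    best = None
    for overlap in range(min(len(forward), len(rev)), min_overlap - 1, -1):
        if forward[-overlap:] == rev[:overlap]:
            best = forward + rev[overlap:]
            break
    return best


def find_chimeric_clusters(clusters: Sequence[ReadCluster]) -> list[int]:
    """Indices of clusters whose consensus is a left/right mosaic of two
    larger clusters (a simple breakpoint check standing in for full chimera
    detection).
    """
    flagged = []
    for idx, cluster in enumerate(clusters):
        seq = cluster.consensus
        bigger = [c for c in clusters if c.read_count > cluster.read_count
                  and len(c.consensus) == len(seq)]
        found = False
        for a in bigger:
            if found:
                break
            for b in bigger:
                if a is b or found:
                    continue
                for k in range(1, len(seq)):
                    if (
                        seq == a.consensus[:k] + b.consensus[k:]
                        and seq != a.consensus
                        and seq != b.consensus
                    ):
                        flagged.append(idx)
                        found = True
                        break
    return flagged
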