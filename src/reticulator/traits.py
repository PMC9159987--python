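"""Mining allele-trait associations: which alleles (or lineage groups) are
carried by all — and only — the samples exhibiting a character state.

For each (character, state), the *lenient* set is the intersection of the
carriers' allele sets (alleles present in every sample showing the state);
the *strict* set removes any allele also carried by a sample of a different
state. A state whose strict set is empty is reported as undetermined — the
association, if any, is one of absence (the complement report lists the
opposing states' strict alleles as "except" candidates). Associations are
hypotheses for follow-up, not statistical tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .io import CharacterMatrix, allele_group


@dataclass
class StateAssociation:
    """Association candidates for one character state."""

    character: str
    state: str
    granularity: str  # allele | group
    strict: frozenset[str]
    lenient: frozenset[str]
    n_state_samples: int
    n_other_samples: int
    undetermined: bool = False
    #: strict alleles of the opposing states ("except X" reading).
    complement: frozenset[str] = field(default_factory=frozenset)


def associate_states(
    matrix: CharacterMatrix,
    genotypes: Mapping[str, Iterable[str]],
    granularity: str = "allele",
    group_of: Callable[[str], str] = allele_group,
) -> list[StateAssociation]:
    """Mine state-to-allele associations over a character matrix.

    ``genotypes`` maps sample_id to its allele labels (any iterable). With
    ``granularity="group"`` alleles are replaced by their lineage groups
    before mining, reproducing group-level statements such as "triangular
    costal veins go with the F group". Samples with a missing score are
    excluded per character; a scored sample without a genotype is an error.
    Output is independent of sample order.
    """
    if granularity not in ("allele", "group"):
        raise ValueError(f"bad granularity {granularity!r}")

    carriers: dict[str, frozenset[str]] = {}
    for sample_id in matrix.sample_ids:
        if sample_id not in genotypes:
            raise ValueError(f"sample {sample_id!r} in character matrix has no genotype")
        alleles = frozenset(genotypes[sample_id])
        if granularity == "group":
            alleles = frozenset(group_of(a) for a in alleles)
        carriers[sample_id] = alleles

    associations: list[StateAssociation] = []
    for character in matrix.characters:
        scored = matrix.states[character].dropna()
        by_state: dict[str, list[str]] = {}
        for sample_id in sorted(scored.index):
            by_state.setdefault(scored[sample_id], []).append(sample_id)
        if len(by_state) < 2:
            # no contrast available: every state is undetermined
            for state in matrix.state_lists[character]:
                if state in by_state:
                    associations.append(
                        StateAssociation(
                            character, state, granularity,
                            strict=frozenset(), lenient=frozenset(),
                            n_state_samples=len(by_state[state]),
                            n_other_samples=0, undetermined=True,
                        )
                    )
            continue

        strict_by_state: dict[str, frozenset[str]] = {}
        lenient_by_state: dict[str, frozenset[str]] = {}
        for state in matrix.state_lists[character]:
            if state not in by_state:
                continue
            in_state = by_state[state]
            others = [s for st, ss in by_state.items() if st != state for s in ss]
            lenient = frozenset.intersection(
                *(carriers[s] for s in in_state)
            )
            elsewhere = frozenset().union(*(carriers[s] for s in others)) if others else frozenset()
            strict = lenient - elsewhere
            # self-audit: strict alleles really are universal in-state and
            # absent elsewhere
            for allele in strict:
                assert all(allele in carriers[s] for s in in_state)
                assert all(allele not in carriers[s] for s in others)
            strict_by_state[state] = strict
            lenient_by_state[state] = lenient

        for state, strict in strict_by_state.items():
            others_strict = frozenset().union(
                *(v for st, v in strict_by_state.items() if st != state)
            ) if len(strict_by_state) > 1 else frozenset()
            associations.append(
                StateAssociation(
                    character, state, granularity,
                    strict=strict,
                    lenient=lenient_by_state[state],
                    n_state_samples=len(by_state[state]),
                    n_other_samples=sum(
                        len(ss) for st, ss in by_state.items() if st != state
                    ),
                    undetermined=not strict,
                    complement=others_strict,
                )
            )
    return associations


def write_associations(
    associations: Iterable[StateAssociation], path: str | Path
) -> None:
    """TSV report mirroring the published table's shape: one row per
    (character, state) with its associated alleles or an 'except' note."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "character", "state", "granularity", "alleles", "lenient_alleles",
            "n_state_samples", "n_other_samples",
        ])
        for a in associations:
            if a.strict:
                shown = ", ".join(sorted(a.strict))
            elif a.complement:
                shown = "Except " + ", ".join(sorted(a.complement))
            else:
                shown = "Undetermined"
            writer.writerow([
                a.character, a.state, a.granularity, shown,
                ", ".join(sorted(a.lenient)), a.n_state_samples,
                a.n_other_samples,
            ])
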