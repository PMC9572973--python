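"""Consolidation of candidate sets across reagents and mobile phases.

Within one mobile phase a compound is a *consolidated match* only if it
survives the cascades of both derivatisation databases (NP-PEG and VSA):
strict set intersection. Across the two mobile phases, a compound found
in both database sets is *double identified*; a compound found in only
one set is still reported — bands that separate cleanly in one solvent
system can overlap in the other, so a single-set identification is a
valid finding, not noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping

__all__ = ["ConsolidatedMatches", "consolidate_pair", "cross_solvent_report"]


def consolidate_pair(matches_a: Iterable[int], matches_b: Iterable[int]) -> frozenset[int]:
    """Consolidated matches for one mobile phase: the intersection of the
    survivor sets of its two derivatisation views."""
    return frozenset(matches_a) & frozenset(matches_b)


@dataclass(frozen=True)
class ConsolidatedMatches:
    """Cross-solvent identification report.

    ``presence`` maps each compound code to the set of result labels it
    appeared in; ``double_identified`` and ``single_identified`` partition
    the union of both result sets.
    """

    labels: tuple[str, str]
    presence: Mapping[int, frozenset[str]]
    double_identified: frozenset[int]
    single_identified: frozenset[int]


def cross_solvent_report(result_mpa: AbstractSet[int], result_mpb: AbstractSet[int],
                         labels: tuple[str, str] = ("MPA", "MPB")) -> ConsolidatedMatches:
    """Combine the identified sets of the two mobile-phase database sets."""
    mpa, mpb = frozenset(result_mpa), frozenset(result_mpb)
    presence = {
        code: frozenset(label for label, group in zip(labels, (mpa, mpb)) if code in group)
        for code in mpa | mpb
    }
    return ConsolidatedMatches(
        labels=labels,
        presence=presence,
        double_identified=mpa & mpb,
        single_identified=mpa ^ mpb,
    )
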