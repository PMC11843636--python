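"""Novelty classification of positive preferred-term signals.

A statistically positive PT is only interesting as a *novel* signal if
it cannot be attributed to (in precedence order): the underlying disease
course, erroneous/ambiguous reporting usage, the drug's label, or the
pivotal trial's adverse-event listing.  Each positive PT receives
exactly one status from configurable, case-insensitive term lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .disproportionality import SignalStats

STATUS_NOVEL = "novel"
STATUS_KNOWN_INSERT = "known_insert"
STATUS_KNOWN_TRIAL = "known_trial"
STATUS_EXCLUDED_DISEASE = "excluded_disease"
STATUS_EXCLUDED_AMBIGUOUS = "excluded_ambiguous"

#: Exclusion rules in default precedence order (clinical-irrelevance
#: exclusions dominate label/trial knowledge).
DEFAULT_RULE_ORDER = (STATUS_EXCLUDED_DISEASE, STATUS_EXCLUDED_AMBIGUOUS,
                      STATUS_KNOWN_INSERT, STATUS_KNOWN_TRIAL)


@dataclass(frozen=True)
class ExclusionLists:
    """The four PT lists driving novelty classification.

    Matching is case-insensitive; lists may overlap (precedence order
    decides).
    """

    disease_related: frozenset[str] = frozenset()
    ambiguous: frozenset[str] = frozenset()
    known_insert: frozenset[str] = frozenset()
    known_trial: frozenset[str] = frozenset()

    def _folded(self, status: str) -> frozenset[str]:
        attr = {
            STATUS_EXCLUDED_DISEASE: self.disease_related,
            STATUS_EXCLUDED_AMBIGUOUS: self.ambiguous,
            STATUS_KNOWN_INSERT: self.known_insert,
            STATUS_KNOWN_TRIAL: self.known_trial,
        }[status]
        return frozenset(t.casefold() for t in attr)


@dataclass(frozen=True)
class ClassifiedSignal:
    """A positive PT signal together with its novelty status."""

    stats: SignalStats
    status: str

    @property
    def term(self) -> str:
        return self.stats.term


def classify_signals(positive_pts: Iterable[SignalStats],
                     ex: ExclusionLists,
                     rule_order: Sequence[str] = DEFAULT_RULE_ORDER,
                     ) -> tuple[list[ClassifiedSignal], dict[str, int]]:
    """Assign each positive PT signal its unique novelty status.

    The first rule in ``rule_order`` whose list contains the term (case-
    insensitively) wins; terms matching no list are ``novel``.  Returns
    the annotated signals plus per-status counts (statuses with zero
    hits included, so the counts always partition the input).
    """
    folded = {status: ex._folded(status) for status in rule_order}
    counts = {status: 0 for status in (*rule_order, STATUS_NOVEL)}
    classified: list[ClassifiedSignal] = []
    for stats in positive_pts:
        term_cf = stats.term.casefold()
        status = next((s for s in rule_order if term_cf in folded[s]),
                      STATUS_NOVEL)
        counts[status] += 1
        classified.append(ClassifiedSignal(stats=stats, status=status))
    return classified, counts
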