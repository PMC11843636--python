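"""Clinical-priority scoring of positive disproportionality signals.

Each positive preferred term is scored 0/1/2 on five dimensions and the
total (0–10) is banded weak (0–4), moderate (5–7) or strong (8–10):

====================  =====================  ==================  ===========
dimension             2 points               1 point             0 points
====================  =====================  ==================  ===========
target events (a)     > 50                   10–50               < 10
ROR CI lower bound    > 5                    2–5                 1–2
mortality proportion  > 50%                  25–50%              < 25%
IME / DME membership  DME                    IME                 neither
plausibility          on the drug label      in the phase III    no prior
                                             trial               report
====================  =====================  ==================  ===========

The printed band edges overlap; this implementation closes them as
``[10, 50] → 1``, ``[2, 5] → 1`` and ``[0.25, 0.5] → 1``, with the
2-point band strictly above.  When a term satisfies several levels of a
dimension (e.g. appears on both the IME and DME lists) the highest score
applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .disproportionality import SignalStats
from .faers_ingest import AEReport, OutcomeClass
from .novel_signals import (STATUS_KNOWN_INSERT, STATUS_KNOWN_TRIAL,
                            STATUS_NOVEL)

BAND_WEAK = "weak"
BAND_MODERATE = "moderate"
BAND_STRONG = "strong"


@dataclass(frozen=True)
class EventSeverityLists:
    """EMA-style Important / Designated Medical Event term lists
    (user-supplied; matching is case-insensitive)."""

    ime_terms: frozenset[str] = frozenset()
    dme_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "_ime_cf",
                           frozenset(t.casefold() for t in self.ime_terms))
        object.__setattr__(self, "_dme_cf",
                           frozenset(t.casefold() for t in self.dme_terms))


@dataclass(frozen=True)
class PriorityAssessment:
    """Five dimension scores, total and band for one positive PT."""

    term: str
    s_events: int
    s_ror: int
    s_mortality: int
    s_ime_dme: int
    s_plausibility: int
    total: int
    band: str
    mortality_proportion: float


def score_events(a: int) -> int:
    """Target-event count dimension: >50 → 2, 10–50 → 1, <10 → 0."""
    if a > 50:
        return 2
    return 1 if a >= 10 else 0


def score_ror_lower(ci_low: float) -> int:
    """ROR lower-CI dimension: >5 → 2, [2,5] → 1, [1,2) → 0.

    A positive signal always has a lower bound above 1, so values ≤ 1
    indicate a non-positive input and raise ``ValueError``.
    """
    if ci_low <= 1:
        raise ValueError(f"ROR CI lower bound {ci_low} is not from a "
                         "positive signal (must exceed 1)")
    if ci_low > 5:
        return 2
    return 1 if ci_low >= 2 else 0


def score_mortality(p: float) -> int:
    """Mortality-proportion dimension: >0.5 → 2, [0.25,0.5] → 1, else 0."""
    if not 0 <= p <= 1:
        raise ValueError(f"mortality proportion must be in [0, 1], got {p}")
    if p > 0.5:
        return 2
    return 1 if p >= 0.25 else 0


def score_ime_dme(term: str, lists: EventSeverityLists) -> int:
    """Severity-list dimension: DME → 2, IME → 1, neither → 0 (a term on
    both lists takes the higher score)."""
    term_cf = term.casefold()
    if term_cf in lists._dme_cf:  # type: ignore[attr-defined]
        return 2
    return 1 if term_cf in lists._ime_cf else 0  # type: ignore[attr-defined]


def score_plausibility(status: str) -> int:
    """Plausibility dimension from novelty status: drug label → 2,
    phase III trial → 1, novel (no prior documentation) → 0."""
    mapping = {STATUS_KNOWN_INSERT: 2, STATUS_KNOWN_TRIAL: 1, STATUS_NOVEL: 0}
    if status not in mapping:
        raise ValueError(f"no plausibility score for status {status!r} "
                         "(disease/ambiguous exclusions are not scored)")
    return mapping[status]


def band_for_total(total: int) -> str:
    """Map a 0–10 total to its priority band."""
    if not 0 <= total <= 10:
        raise ValueError(f"total must be in [0, 10], got {total}")
    if total >= 8:
        return BAND_STRONG
    return BAND_MODERATE if total >= 5 else BAND_WEAK


def mortality_proportion(term: str, target_reports: Iterable[AEReport]) -> float:
    """Fraction of target reports mentioning ``term`` whose outcome is
    death.  Terms never mentioned yield 0."""
    term_cf = term.casefold()
    mentioning = died = 0
    for report in target_reports:
        if any(pt.casefold() == term_cf for pt in report.events):
            mentioning += 1
            died += report.outcome is OutcomeClass.DEATH
    return died / mentioning if mentioning else 0.0


def assess(stats: SignalStats, mortality: float,
           lists: EventSeverityLists, status: str) -> PriorityAssessment:
    """Score one positive PT on all five dimensions and band the total."""
    if stats.ror_ci_low is None:
        raise ValueError(f"{stats.term}: ROR CI undefined, cannot score")
    scores = (
        score_events(stats.table.a),
        score_ror_lower(stats.ror_ci_low),
        score_mortality(mortality),
        score_ime_dme(stats.term, lists),
        score_plausibility(status),
    )
    total = sum(scores)
    return PriorityAssessment(
        term=stats.term,
        s_events=scores[0], s_ror=scores[1], s_mortality=scores[2],
        s_ime_dme=scores[3], s_plausibility=scores[4],
        total=total, band=band_for_total(total),
        mortality_proportion=mortality,
    )
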