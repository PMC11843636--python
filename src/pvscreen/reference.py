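"""Shipped reference data: published sparsentan/IgAN screening tables and
default term lists.

The package bundles, as plain CSV, the published disproportionality
results for sparsentan as primary-suspect drug in the IgA-nephropathy
cohort of FAERS 2023 (24 system-organ-class rows and 30 preferred-term
rows, each with its 2x2 counts and the printed ROR, 95% CI, PRR and
chi-square), the corresponding clinical-priority scores, and small
default term lists (label/trial adverse events reconstructed from the
published per-term annotations; illustrative disease-related, ambiguous
and IME/DME excerpts).  These serve as golden fixtures and as defaults
for the novel-signal and priority stages; they are not a substitute for
user-supplied MedDRA, EMA or label data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path)


def load_soc_reference() -> pd.DataFrame:
    """24 SOC-level rows: a, b, c, d, printed statistics, flag pattern."""
    return _read_csv("soc_reference.csv")


def load_pt_reference() -> pd.DataFrame:
    """30 positive PT rows: counts, printed statistics and the published
    annotation (``novel`` / ``insert`` / ``trial``)."""
    return _read_csv("pt_reference.csv")


def load_priority_reference() -> pd.DataFrame:
    """Published per-dimension priority scores, totals and bands for the
    30 positive preferred terms."""
    return _read_csv("priority_reference.csv")


def load_pt_soc_map() -> dict[str, str]:
    """Toy MedDRA-like PT→SOC mapping covering the 30 reference PTs."""
    ref = load_pt_reference()
    return dict(zip(ref["pt"], ref["soc"]))


def load_term_list(name_or_path) -> frozenset[str]:
    """Read a one-PT-per-line term list; ``#`` comments and blanks ignored.

    ``name_or_path`` may be a shipped list name (e.g. ``known_insert_pts``)
    or a filesystem path.
    """
    from pathlib import Path

    candidate = _DATA / f"{name_or_path}.txt"
    if not str(name_or_path).endswith(".txt") and candidate.is_file():
        text = candidate.read_text()
    else:
        text = Path(name_or_path).read_text()
    terms = (line.strip() for line in text.splitlines())
    return frozenset(t for t in terms if t and not t.startswith("#"))


def default_exclusion_lists():
    """ExclusionLists built from the shipped default term lists."""
    from .novel_signals import ExclusionLists

    return ExclusionLists(
        disease_related=load_term_list("disease_related_pts"),
        ambiguous=load_term_list("ambiguous_pts"),
        known_insert=load_term_list("known_insert_pts"),
        known_trial=load_term_list("known_trial_pts"),
    )


def default_severity_lists():
    """EventSeverityLists built from the shipped IME/DME excerpts."""
    from .priority import EventSeverityLists

    return EventSeverityLists(
        ime_terms=load_term_list("ime_pts"),
        dme_terms=load_term_list("dme_pts"),
    )
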