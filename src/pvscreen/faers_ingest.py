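"""Parsing, deduplication and cohort selection for FAERS-style reports.

A spontaneous-report quarter arrives as four linked tables (DEMO, DRUG,
REAC, OUTC) keyed by ``primaryid`` (one row per report *version*) and
``caseid`` (one value per underlying case).  This module assembles those
tables into one :class:`AEReport` per report version, collapses versions
to one record per case using the FDA-recommended rules — keep the most
recent ``FDA_DT``; on ties keep the higher ``PRIMARYID`` — and splits the
indication cohort into target-drug reports (drug of interest as primary
suspect) and comparator reports (every other report with the same
indication).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dialect import TABLE_COLUMNS, TABLE_NAMES, read_table

logger = logging.getLogger("pvscreen")

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

SEX_FEMALE = "female"
SEX_MALE = "male"
SEX_UNKNOWN = "unknown"

_SEX_CODES = {"F": SEX_FEMALE, "M": SEX_MALE}

#: Conversion from FAERS age-unit codes to years.
_AGE_UNIT_YEARS = {
    "DEC": 10.0, "YR": 1.0, "MON": 1.0 / 12.0, "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0,
}

_MAX_PLAUSIBLE_AGE = 120.0


class OutcomeClass(enum.IntEnum):
    """Report outcome, ordered by severity (higher value = more severe).

    Death takes precedence over a life-threatening event, which takes
    precedence over disability, hospitalization, other important medical
    events, and an unknown outcome, in that order.
    """

    UNKNOWN = 0
    OTHER_IME = 1
    HOSPITALIZATION = 2
    DISABILITY = 3
    LIFE_THREATENING = 4
    DEATH = 5


#: FAERS OUTC_COD values for the outcome classes the analysis retains.
OUTCOME_CODES: dict[str, OutcomeClass] = {
    "DE": OutcomeClass.DEATH,
    "LT": OutcomeClass.LIFE_THREATENING,
    "DS": OutcomeClass.DISABILITY,
    "HO": OutcomeClass.HOSPITALIZATION,
    "OT": OutcomeClass.OTHER_IME,
}


def worst_outcome(codes: Iterable[str]) -> OutcomeClass:
    """Most severe outcome among FAERS ``OUTC_COD`` values.

    Empty input yields :attr:`OutcomeClass.UNKNOWN`.  An unrecognized
    code raises ``ValueError`` naming the code.
    """
    worst = OutcomeClass.UNKNOWN
    for code in codes:
        key = code.strip().upper()
        if not key:
            continue
        if key not in OUTCOME_CODES:
            raise ValueError(f"unrecognized outcome code: {code!r}")
        worst = max(worst, OUTCOME_CODES[key])
    return worst


def parse_age(age: str | float | None, age_cod: str | None) -> float | None:
    """Normalize a FAERS (age, unit-code) pair to years.

    Missing, unparsable or implausible (> 120 y) values map to ``None``
    (unknown).  An empty unit code is treated as years, FAERS's dominant
    convention.
    """
    if age is None:
        return None
    text = str(age).strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    unit = (age_cod or "YR").strip().upper() or "YR"
    factor = _AGE_UNIT_YEARS.get(unit)
    if factor is None or value < 0:
        return None
    years = value * factor
    return years if years <= _MAX_PLAUSIBLE_AGE else None


@dataclass(frozen=True)
class DrugMention:
    """One drug row of a report: reported name, FAERS role code, and the
    indication text attached to that drug (may be unknown)."""

    name_as_reported: str
    role: str
    indication: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"invalid FAERS role code: {self.role!r}")


@dataclass(frozen=True)
class AEReport:
    """One (deduplicated) spontaneous adverse-event report."""

    caseid: int
    primaryid: int
    fda_dt: int
    sex: str = SEX_UNKNOWN
    age_years: float | None = None
    drugs: tuple[DrugMention, ...] = ()
    events: frozenset[str] = frozenset()
    outcome: OutcomeClass = OutcomeClass.UNKNOWN


def _normalize_name(name: str) -> str:
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class DrugQuery:
    """Name-based drug matcher: case-insensitive exact match, after
    whitespace normalization, against any synonym (generic, brand,
    development codes)."""

    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValueError("drug query needs at least one synonym")
        object.__setattr__(self, "_normalized",
                           frozenset(_normalize_name(s) for s in self.synonyms))

    def matches(self, name: str) -> bool:
        return _normalize_name(name) in self._normalized  # type: ignore[attr-defined]


@dataclass
class Cohort:
    """Analysis cohort split into target and comparator reports."""

    target: list[AEReport]
    comparator: list[AEReport]

    @property
    def all_reports(self) -> list[AEReport]:
        return self.target + self.comparator

    def __len__(self) -> int:
        return len(self.target) + len(self.comparator)


@dataclass
class RawQuarter:
    """Parsed (still string-typed) quarter tables plus per-table counts
    of malformed lines encountered while reading."""

    tables: dict[str, pd.DataFrame]
    malformed: dict[str, int] = field(default_factory=dict)


def parse_quarter(directory: str | Path,
                  filenames: Mapping[str, str] | None = None) -> RawQuarter:
    """Read the DEMO/DRUG/REAC/OUTC tables of one quarter directory.

    ``filenames`` overrides the default ``<TABLE>.txt`` naming.  Malformed
    lines are counted per table (and logged), never silently dropped.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    malformed: dict[str, int] = {}
    for name in TABLE_NAMES:
        fname = (filenames or {}).get(name, f"{name}.txt")
        frame, bad = read_table(directory / fname, required=TABLE_COLUMNS[name])
        tables[name] = frame
        malformed[name] = bad
        logger.info("parsed %s: %d records, %d malformed line(s)",
                    fname, len(frame), bad)
    return RawQuarter(tables=tables, malformed=malformed)


def combine_quarters(quarters: Sequence[RawQuarter]) -> RawQuarter:
    """Concatenate several parsed quarters into one raw collection."""
    tables = {
        name: pd.concat([q.tables[name] for q in quarters], ignore_index=True)
        for name in TABLE_NAMES
    }
    malformed = {name: sum(q.malformed.get(name, 0) for q in quarters)
                 for name in TABLE_NAMES}
    return RawQuarter(tables=tables, malformed=malformed)


def build_reports(raw: RawQuarter) -> list[AEReport]:
    """Assemble one :class:`AEReport` per DEMO row (i.e. per report
    version) by joining DRUG, REAC and OUTC on ``primaryid``.

    DEMO rows whose key fields fail integer coercion are logged and
    skipped; orphan DRUG/REAC/OUTC rows (no DEMO parent) are ignored.
    """
    demo = raw.tables["DEMO"]
    by_pid_drugs: dict[str, list[DrugMention]] = {}
    for row in raw.tables["DRUG"].itertuples(index=False):
        indication = getattr(row, "indi_pt", "") or None
        try:
            mention = DrugMention(name_as_reported=row.drugname,
                                  role=row.role_cod.strip().upper(),
                                  indication=indication)
        except ValueError:
            logger.warning("primaryid %s: bad role code %r, drug row skipped",
                           row.primaryid, row.role_cod)
            continue
        by_pid_drugs.setdefault(row.primaryid, []).append(mention)

    by_pid_events: dict[str, set[str]] = {}
    for row in raw.tables["REAC"].itertuples(index=False):
        by_pid_events.setdefault(row.primaryid, set()).add(row.pt.strip())

    by_pid_outcomes: dict[str, list[str]] = {}
    for row in raw.tables["OUTC"].itertuples(index=False):
        by_pid_outcomes.setdefault(row.primaryid, []).append(row.outc_cod)

    reports: list[AEReport] = []
    for row in demo.itertuples(index=False):
        try:
            caseid = int(row.caseid)
            primaryid = int(row.primaryid)
            fda_dt = int(row.fda_dt)
        except (TypeError, ValueError):
            logger.warning("DEMO row with unparsable keys skipped: %r", row)
            continue
        reports.append(AEReport(
            caseid=caseid,
            primaryid=primaryid,
            fda_dt=fda_dt,
            sex=_SEX_CODES.get(str(row.sex).strip().upper(), SEX_UNKNOWN),
            age_years=parse_age(row.age, row.age_cod),
            drugs=tuple(by_pid_drugs.get(row.primaryid, [])),
            events=frozenset(by_pid_events.get(row.primaryid, set())),
            outcome=worst_outcome(by_pid_outcomes.get(row.primaryid, [])),
        ))
    return reports


def deduplicate(reports: Iterable[AEReport]) -> list[AEReport]:
    """Collapse report versions to one record per case.

    The survivor of each ``caseid`` maximizes ``(fda_dt, primaryid)``
    lexicographically: most recent receipt date first, highest version
    identifier on date ties.  Output order follows first appearance of
    each case, so the result is independent of input ordering up to that
    canonical order; the operation is idempotent.
    """
    best: dict[int, AEReport] = {}
    for report in reports:
        incumbent = best.get(report.caseid)
        if (incumbent is None
                or (report.fda_dt, report.primaryid)
                > (incumbent.fda_dt, incumbent.primaryid)):
            best[report.caseid] = report
    return sorted(best.values(), key=lambda r: r.caseid)


def _matches_indication(report: AEReport, terms_cf: tuple[str, ...]) -> bool:
    # a report belongs to the indication cohort if ANY drug mention
    # carries a matching indication (FAERS indications attach per drug)
    for drug in report.drugs:
        if drug.indication:
            hay = drug.indication.casefold()
            if any(term in hay for term in terms_cf):
                return True
    return False


def select_cohort(reports: Iterable[AEReport],
                  drug_query: DrugQuery,
                  indication_terms: Sequence[str],
                  role_filter: frozenset[str] = frozenset({"PS"}),
                  date_window: tuple[int, int] | None = None) -> Cohort:
    """Split deduplicated reports into target and comparator sets.

    Target: indication-cohort reports with at least one drug matching
    ``drug_query`` in a role in ``role_filter`` (default: primary suspect
    only).  Comparator: remaining indication-cohort reports.  Reports
    outside the indication cohort — or outside ``date_window``
    (inclusive ``fda_dt`` bounds), when given — fall in neither set.

    Indication matching is case-insensitive substring over
    ``indication_terms``.  A report with several matching role entries
    (a data error seen in practice) counts as target if any matches; such
    reports are noted in the log.
    """
    if not indication_terms:
        raise ValueError("indication_terms must be non-empty")
    terms_cf = tuple(t.casefold() for t in indication_terms)
    target: list[AEReport] = []
    comparator: list[AEReport] = []
    for report in reports:
        if date_window is not None:
            lo, hi = date_window
            if not (lo <= report.fda_dt <= hi):
                continue
        if not _matches_indication(report, terms_cf):
            continue
        matching = [d for d in report.drugs
                    if d.role in role_filter and drug_query.matches(d.name_as_reported)]
        if matching:
            if len(matching) > 1:
                logger.info("case %s: %d matching %s entries, treated as target",
                            report.caseid, len(matching), "/".join(sorted(role_filter)))
            target.append(report)
        else:
            comparator.append(report)
    logger.info("cohort selected: %d target, %d comparator reports",
                len(target), len(comparator))
    return Cohort(target=target, comparator=comparator)
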