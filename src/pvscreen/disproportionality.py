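"""2x2 disproportionality statistics: ROR, PRR, chi-square, signal flags.

For each adverse-event term (MedDRA preferred term or system organ
class), reports are cross-classified against the comparator to give the
2x2 table::

                       term present   term absent
    target drug             a             b
    comparator drugs        c             d

The counting unit is the (report, distinct term) pair, so the margins
``a+b`` (target) and ``c+d`` (comparator) are the total pair counts at
that level and are shared by every term.  Two classical frequentist
screening statistics are computed:

* reporting odds ratio  ``ROR = ad/(bc)`` with a Woolf (log-normal) 95%
  confidence interval ``exp(ln ROR ± z·sqrt(1/a+1/b+1/c+1/d))``;
* proportional reporting ratio ``PRR = [a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-square ``N(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)]`` (no
  continuity correction).

A term is ROR-positive when ``a ≥ min_a`` and the CI lower bound exceeds
1; PRR-positive when ``a ≥ min_a``, ``PRR ≥ 2`` and ``χ² ≥ 4`` (the Evans
criteria); a dual-algorithm signal satisfies both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

from .faers_ingest import AEReport, Cohort

#: Two-sided 95% normal quantile as conventionally used in this
#: literature (1.96, not the fuller-precision 1.959964 — the published
#: tables this package reproduces round with 1.96).
Z_95 = 1.96

#: Sentinel system organ class for preferred terms absent from the map.
UNMAPPED_SOC = "Unmapped system organ class"

Level = Literal["SOC", "PT"]
_LEVEL_ORDER = {"SOC": 0, "PT": 1}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention of the reference
    tables; Python's built-in ``round`` is half-to-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of (report, term) pairs for one term."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool) or value < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, "
                                 f"got {value!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class RorResult(NamedTuple):
    """ROR point estimate and 95% CI; fields are ``None`` when the
    corresponding quantity is undefined (zero cell)."""

    ror: float | None
    ci_low: float | None
    ci_high: float | None


class PrrResult(NamedTuple):
    """PRR point estimate and Pearson chi-square; ``None`` = undefined."""

    prr: float | None
    chi2: float | None


def ror_with_ci(t: ContingencyTable, z: float = Z_95) -> RorResult:
    """Reporting odds ratio ``ad/(bc)`` with the Woolf log-normal CI.

    The point estimate requires ``b > 0`` and ``c > 0``; the CI
    additionally requires all four cells positive.  Undefined quantities
    come back as explicit ``None`` fields rather than silent NaN.
    """
    if t.b == 0 or t.c == 0:
        return RorResult(None, None, None)
    ror = (t.a * t.d) / (t.b * t.c)
    if t.a == 0 or t.d == 0:
        return RorResult(ror, None, None)
    half_width = z * math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_ror = math.log(ror)
    return RorResult(ror, math.exp(log_ror - half_width),
                     math.exp(log_ror + half_width))


def prr_with_chi2(t: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio and Pearson chi-square (no
    continuity correction).

    The PRR requires both row margins positive and ``c > 0``; the
    chi-square requires all four margins positive.
    """
    if t.a + t.b == 0 or t.c + t.d == 0 or t.c == 0:
        return PrrResult(None, None)
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    if t.a + t.c == 0 or t.b + t.d == 0:
        return PrrResult(prr, None)
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    den = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    return PrrResult(prr, num / den)


@dataclass(frozen=True)
class ThresholdConfig:
    """Dual-algorithm positivity thresholds (defaults: Evans criteria)."""

    min_a: int = 3
    ror_ci_low_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0

    def __post_init__(self) -> None:
        if min(self.min_a, self.ror_ci_low_gt, self.prr_min, self.chi2_min) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class SignalStats:
    """Disproportionality result for one term at one level."""

    term: str
    level: Level
    table: ContingencyTable
    ror: float | None = None
    ror_ci_low: float | None = None
    ror_ci_high: float | None = None
    prr: float | None = None
    chi2: float | None = None
    ror_positive: bool = False
    prr_positive: bool = False
    positive_both: bool = False


def compute_stats(term: str, level: Level, table: ContingencyTable,
                  z: float = Z_95) -> SignalStats:
    """ROR/CI and PRR/chi-square for one table, flags left unset."""
    ror = ror_with_ci(table, z=z)
    prr = prr_with_chi2(table)
    return SignalStats(term=term, level=level, table=table,
                       ror=ror.ror, ror_ci_low=ror.ci_low,
                       ror_ci_high=ror.ci_high,
                       prr=prr.prr, chi2=prr.chi2)


def flag_signal(stats: SignalStats, th: ThresholdConfig) -> SignalStats:
    """Apply the dual-algorithm positivity thresholds.

    ROR-positive: ``a ≥ min_a`` and CI lower bound ``> ror_ci_low_gt``.
    PRR-positive: ``a ≥ min_a``, ``PRR ≥ prr_min`` and ``χ² ≥ chi2_min``.
    Undefined statistics never satisfy a threshold.
    """
    a_ok = stats.table.a >= th.min_a
    ror_pos = bool(a_ok and stats.ror_ci_low is not None
                   and stats.ror_ci_low > th.ror_ci_low_gt)
    prr_pos = bool(a_ok and stats.prr is not None and stats.chi2 is not None
                   and stats.prr >= th.prr_min and stats.chi2 >= th.chi2_min)
    return replace(stats, ror_positive=ror_pos, prr_positive=prr_pos,
                   positive_both=ror_pos and prr_pos)


def _soc_for(pt: str, pt_to_soc: Mapping[str, str]) -> str:
    return pt_to_soc.get(pt) or pt_to_soc.get(pt.casefold(), UNMAPPED_SOC)


def term_pairs(reports: Iterable[AEReport], pt_to_soc: Mapping[str, str],
               level: Level) -> tuple[dict[str, int], int]:
    """Count (report, distinct term) pairs at the requested level.

    At PT level a report contributes one pair per distinct preferred
    term; at SOC level one pair per distinct mapped organ class (two PTs
    of one report sharing a SOC yield a single SOC pair).  PTs missing
    from ``pt_to_soc`` fall under a sentinel class.  Returns the per-term
    counts and the margin (total pairs).
    """
    lookup = {k.casefold(): v for k, v in pt_to_soc.items()}
    counts: dict[str, int] = {}
    margin = 0
    empty = True
    for report in reports:
        empty = False
        if level == "PT":
            terms = set(report.events)
        elif level == "SOC":
            terms = {_soc_for(pt, lookup) for pt in report.events}
        else:
            raise ValueError(f"unknown level: {level!r}")
        margin += len(terms)
        for term in terms:
            counts[term] = counts.get(term, 0) + 1
    if empty:
        raise ValueError("empty report collection")
    return counts, margin


def run_screen(cohort: Cohort, pt_to_soc: Mapping[str, str],
               th: ThresholdConfig | None = None,
               levels: Sequence[Level] = ("SOC", "PT"),
               z: float = Z_95) -> list[SignalStats]:
    """Full dual-algorithm screen of a cohort at SOC and PT level.

    Emits one flagged :class:`SignalStats` per term observed in the
    *target* set, ordered by level (SOC before PT), then descending
    ``a``, then term name.
    """
    if not cohort.target:
        raise ValueError("cohort has no target reports")
    th = th or ThresholdConfig()
    results: list[SignalStats] = []
    for level in levels:
        target_counts, target_margin = term_pairs(cohort.target, pt_to_soc, level)
        if cohort.comparator:
            comp_counts, comp_margin = term_pairs(cohort.comparator, pt_to_soc, level)
        else:
            comp_counts, comp_margin = {}, 0
        for term, a in target_counts.items():
            c = comp_counts.get(term, 0)
            table = ContingencyTable(a=a, b=target_margin - a,
                                     c=c, d=comp_margin - c)
            results.append(flag_signal(compute_stats(term, level, table, z=z), th))
    results.sort(key=lambda s: (_LEVEL_ORDER[s.level], -s.table.a, s.term))
    return results


def stats_to_frame(stats: Sequence[SignalStats]):
    """Tabulate screen results as a DataFrame in output-column order."""
    import pandas as pd

    columns = ["term", "level", "a", "b", "c", "d", "ror", "ror_ci_low",
               "ror_ci_high", "prr", "chi2", "ror_positive", "prr_positive",
               "positive_both"]
    if not stats:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([{
        "term": s.term, "level": s.level,
        "a": s.table.a, "b": s.table.b, "c": s.table.c, "d": s.table.d,
        "ror": s.ror, "ror_ci_low": s.ror_ci_low, "ror_ci_high": s.ror_ci_high,
        "prr": s.prr, "chi2": s.chi2,
        "ror_positive": s.ror_positive, "prr_positive": s.prr_positive,
        "positive_both": s.positive_both,
    } for s in stats])
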