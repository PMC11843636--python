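"""Sex- and age-stratified re-screening and cross-stratum comparison.

The disproportionality screen is re-run independently inside each
stratum (each stratum keeps its own target/comparator margins), and for
preferred terms positive in both strata the strata are compared with a
ratio of stratum RORs whose CI combines the two Woolf log-variances:
``exp(ln(ROR_A/ROR_B) ± z·sqrt(V_A + V_B))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .disproportionality import (SignalStats, ThresholdConfig, Z_95,
                                 run_screen)
from .faers_ingest import AEReport, Cohort, SEX_FEMALE, SEX_MALE

logger = logging.getLogger("pvscreen")

_Member = Callable[[AEReport], bool]


def _age_known(report: AEReport) -> bool:
    return report.age_years is not None


@dataclass(frozen=True)
class SubgroupSpec:
    """Named, disjoint strata over one demographic dimension.

    The two stock specs mirror common pharmacovigilance practice: sex
    (female vs male, unknown excluded) and age split at 45 years
    (18–45 inclusive vs over 45; under-18 and unknown excluded).
    """

    dimension: str
    strata: Mapping[str, _Member] = field(hash=False)

    @staticmethod
    def by_sex() -> "SubgroupSpec":
        return SubgroupSpec("sex", {
            "female": lambda r: r.sex == SEX_FEMALE,
            "male": lambda r: r.sex == SEX_MALE,
        })

    @staticmethod
    def by_age(split: float = 45.0, adult_min: float = 18.0) -> "SubgroupSpec":
        return SubgroupSpec("age", {
            f"{adult_min:g}-{split:g}":
                lambda r: _age_known(r) and adult_min <= r.age_years <= split,
            f">{split:g}":
                lambda r: _age_known(r) and r.age_years > split,
        })


@dataclass
class StratifiedScreen:
    """Per-stratum screen results plus the count of cohort reports that
    belonged to no stratum (unknown or out-of-range)."""

    spec: SubgroupSpec
    results: dict[str, list[SignalStats]]
    excluded: int


def stratify_and_screen(cohort: Cohort, spec: SubgroupSpec,
                        pt_to_soc: Mapping[str, str],
                        th: ThresholdConfig | None = None,
                        levels: Sequence[str] = ("PT",)) -> StratifiedScreen:
    """Run the screen independently within each stratum.

    A stratum with no target reports yields an empty result list with a
    warning rather than failing.  Reports matching no stratum are
    excluded and counted.
    """
    results: dict[str, list[SignalStats]] = {}
    claimed: set[int] = set()
    for name, member in spec.strata.items():
        sub = Cohort(target=[r for r in cohort.target if member(r)],
                     comparator=[r for r in cohort.comparator if member(r)])
        claimed.update(id(r) for r in sub.target + sub.comparator)
        if not sub.target:
            logger.warning("stratum %s=%s: no target reports, empty screen",
                           spec.dimension, name)
            results[name] = []
            continue
        results[name] = run_screen(sub, pt_to_soc, th, levels=levels)
    excluded = sum(1 for r in cohort.all_reports if id(r) not in claimed)
    logger.info("subgroup %s: %d report(s) outside all strata",
                spec.dimension, excluded)
    return StratifiedScreen(spec=spec, results=results, excluded=excluded)


@dataclass(frozen=True)
class SubgroupComparison:
    """Cross-stratum contrast for one shared positive PT."""

    term: str
    stratum_a: str
    stratum_b: str
    stats_a: SignalStats
    stats_b: SignalStats
    ratio: float
    ci_low: float
    ci_high: float
    higher_risk_stratum: str


def _log_variance(s: SignalStats) -> float:
    t = s.table
    if min(t.a, t.b, t.c, t.d) == 0:
        raise ValueError(f"{s.term}: zero cell, ROR variance undefined")
    return 1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d


def compare_shared(stats_a: SignalStats, stats_b: SignalStats,
                   stratum_a: str = "A", stratum_b: str = "B",
                   z: float = Z_95) -> SubgroupComparison:
    """Ratio of stratum RORs with a combined-variance Woolf CI.

    Defined only for a term positive in both strata; swapping the strata
    inverts the ratio.  The higher-risk stratum is the one with the
    larger ROR.
    """
    if stats_a.term != stats_b.term:
        raise ValueError("cannot compare different terms: "
                         f"{stats_a.term!r} vs {stats_b.term!r}")
    if stats_a.ror is None or stats_b.ror is None or stats_b.ror == 0:
        raise ValueError(f"{stats_a.term}: undefined ROR in a stratum")
    ratio = stats_a.ror / stats_b.ror
    half = z * math.sqrt(_log_variance(stats_a) + _log_variance(stats_b))
    log_ratio = math.log(ratio)
    return SubgroupComparison(
        term=stats_a.term, stratum_a=stratum_a, stratum_b=stratum_b,
        stats_a=stats_a, stats_b=stats_b, ratio=ratio,
        ci_low=math.exp(log_ratio - half), ci_high=math.exp(log_ratio + half),
        higher_risk_stratum=stratum_a if stats_a.ror >= stats_b.ror else stratum_b,
    )


def compare_all_shared(screen: StratifiedScreen,
                       z: float = Z_95) -> list[SubgroupComparison]:
    """Compare every PT that is dual-algorithm positive in both strata
    of a two-stratum screen, in descending target-count order."""
    names = list(screen.results)
    if len(names) != 2:
        raise ValueError("cross-stratum comparison needs exactly two strata")
    name_a, name_b = names
    pos_a = {s.term: s for s in screen.results[name_a] if s.positive_both}
    pos_b = {s.term: s for s in screen.results[name_b] if s.positive_both}
    shared = sorted(pos_a.keys() & pos_b.keys(),
                    key=lambda t: (-pos_a[t].table.a, t))
    return [compare_shared(pos_a[t], pos_b[t], name_a, name_b, z=z)
            for t in shared]
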