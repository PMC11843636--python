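"""End-to-end orchestration: ingest → screen → novelty → priority →
subgroups, with a demographics summary, CSV outputs and a JSON manifest.

Every stage logs a funnel count (raw rows in → deduplicated → cohort)
and any stage failure aborts with the stage name and the counts so far.
Given identical inputs the non-log outputs are byte-identical across
reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import reference
from .disproportionality import (SignalStats, ThresholdConfig,
                                 round_half_away, run_screen, stats_to_frame)
from .faers_ingest import (AEReport, Cohort, DrugQuery, OutcomeClass,
                           build_reports, combine_quarters, deduplicate,
                           parse_quarter)
from .novel_signals import ExclusionLists, classify_signals
from .priority import EventSeverityLists, assess, mortality_proportion
from .subgroups import SubgroupSpec, compare_all_shared, stratify_and_screen
from .synthetic_faers import TARGET_SYNONYMS

logger = logging.getLogger("pvscreen")

DEFAULT_INDICATION_TERMS = ("IgA nephropathy", "Immunoglobulin A nephropathy")

_OUTCOME_LABELS = {
    OutcomeClass.DEATH: "Death",
    OutcomeClass.LIFE_THREATENING: "Life-threatening",
    OutcomeClass.DISABILITY: "Disability",
    OutcomeClass.HOSPITALIZATION: "Hospitalization",
    OutcomeClass.OTHER_IME: "Other important medical event",
    OutcomeClass.UNKNOWN: "Unknown",
}


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    quarter_dirs: list[Path]
    output_dir: Path
    drug_synonyms: tuple[str, ...] = TARGET_SYNONYMS
    indication_terms: tuple[str, ...] = DEFAULT_INDICATION_TERMS
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    pt_soc_map: Mapping[str, str] | None = None
    exclusion_lists: ExclusionLists | None = None
    severity_lists: EventSeverityLists | None = None
    date_window: tuple[int, int] | None = None
    age_split: float = 45.0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        lists = raw.get("exclusion_lists")
        exclusions = ExclusionLists(
            **{k: reference.load_term_list(v) for k, v in lists.items()}
        ) if lists else None
        sev = raw.get("severity_lists")
        severity = EventSeverityLists(
            **{k: reference.load_term_list(v) for k, v in sev.items()}
        ) if sev else None
        pt_map = None
        if raw.get("pt_soc_map"):
            frame = pd.read_csv(raw["pt_soc_map"])
            pt_map = dict(zip(frame["pt"], frame["soc"]))
        return PipelineConfig(
            quarter_dirs=[Path(p) for p in raw["quarter_dirs"]],
            output_dir=Path(raw["output_dir"]),
            drug_synonyms=tuple(raw.get("drug_synonyms", TARGET_SYNONYMS)),
            indication_terms=tuple(raw.get("indication_terms",
                                           DEFAULT_INDICATION_TERMS)),
            thresholds=ThresholdConfig(**raw.get("thresholds", {})),
            pt_soc_map=pt_map,
            exclusion_lists=exclusions,
            severity_lists=severity,
            date_window=tuple(raw["date_window"]) if raw.get("date_window") else None,
            age_split=float(raw.get("age_split", 45.0)),
        )


def summarize_demographics(cohort_reports: Sequence[AEReport]) -> pd.DataFrame:
    """Counts and percentages by sex, age band and worst outcome,
    including explicit Unknown categories.

    Percentages are count/total×100 rounded half-away-from-zero to two
    decimals; an empty cohort yields an empty table.
    """
    rows: list[tuple[str, str, int]] = []
    total = len(cohort_reports)
    if total == 0:
        return pd.DataFrame(columns=["dimension", "category", "count", "percent"])

    def tally(dimension: str, labels: list[str], values: list[str]) -> None:
        counts = {label: 0 for label in labels}
        for v in values:
            counts[v] += 1
        rows.extend((dimension, label, count) for label, count in counts.items())

    tally("sex", ["Female", "Male", "Unknown"],
          [r.sex.capitalize() for r in cohort_reports])

    def age_band(r: AEReport) -> str:
        if r.age_years is None:
            return "Unknown"
        if r.age_years < 18:
            return "<18 years"
        if r.age_years <= 45:
            return "18-45 years"
        return ">45 years"

    tally("age", ["<18 years", "18-45 years", ">45 years", "Unknown"],
          [age_band(r) for r in cohort_reports])
    tally("outcome", [_OUTCOME_LABELS[o] for o in sorted(OutcomeClass, reverse=True)],
          [_OUTCOME_LABELS[r.outcome] for r in cohort_reports])

    frame = pd.DataFrame(rows, columns=["dimension", "category", "count"])
    frame["percent"] = [round_half_away(c / total * 100, 2) for c in frame["count"]]
    return frame


@dataclass
class PipelineResult:
    """In-memory bundle of one run's outputs."""

    cohort: Cohort
    demographics: pd.DataFrame
    screen: list[SignalStats]
    novel_table: pd.DataFrame
    priority_table: pd.DataFrame
    subgroup_tables: dict[str, pd.DataFrame]
    comparison_tables: dict[str, pd.DataFrame]
    funnel: dict[str, int]


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full screen and write the output bundle.

    Outputs (CSV unless noted): ``demographics``, ``soc_table``,
    ``pt_table``, ``novel_signals``, ``priority``, per-stratum subgroup
    tables, cross-stratum comparisons, and a JSON ``manifest`` with the
    record-count funnel.
    """
    funnel: dict[str, int] = {}
    stage = "ingest"
    try:
        quarters = [parse_quarter(d) for d in config.quarter_dirs]
        raw = combine_quarters(quarters)
        funnel["raw_demo_rows"] = len(raw.tables["DEMO"])
        funnel["malformed_lines"] = sum(raw.malformed.values())
        reports = build_reports(raw)
        funnel["report_versions"] = len(reports)

        stage = "deduplicate"
        unique = deduplicate(reports)
        funnel["deduplicated_reports"] = len(unique)

        stage = "cohort"
        cohort = select_cohort_stage(unique, config)
        funnel["cohort_reports"] = len(cohort)
        funnel["target_reports"] = len(cohort.target)
        funnel["comparator_reports"] = len(cohort.comparator)

        stage = "demographics"
        demographics = summarize_demographics(cohort.target)

        stage = "screen"
        pt_map = dict(config.pt_soc_map) if config.pt_soc_map \
            else reference.load_pt_soc_map()
        screen = run_screen(cohort, pt_map, config.thresholds)
        positive_pts = [s for s in screen
                        if s.level == "PT" and s.positive_both]
        funnel["positive_pts"] = len(positive_pts)

        stage = "novel_signals"
        exclusions = config.exclusion_lists or reference.default_exclusion_lists()
        classified, status_counts = classify_signals(positive_pts, exclusions)
        funnel["novel_pts"] = status_counts["novel"]
        novel_table = stats_to_frame([c.stats for c in classified])
        novel_table.insert(2, "status", [c.status for c in classified])

        stage = "priority"
        severity = config.severity_lists or reference.default_severity_lists()
        scored = [c for c in classified
                  if c.status in ("novel", "known_insert", "known_trial")]
        assessments = [
            assess(c.stats,
                   mortality_proportion(c.stats.term, cohort.target),
                   severity, c.status)
            for c in scored
        ]
        assessments.sort(key=lambda p: (p.total, p.term))
        priority_table = pd.DataFrame([{
            "term": p.term, "s_events": p.s_events, "s_ror": p.s_ror,
            "s_mortality": p.s_mortality, "s_ime_dme": p.s_ime_dme,
            "s_plausibility": p.s_plausibility, "total": p.total,
            "band": p.band, "mortality_proportion": p.mortality_proportion,
        } for p in assessments])

        stage = "subgroups"
        subgroup_tables: dict[str, pd.DataFrame] = {}
        comparison_tables: dict[str, pd.DataFrame] = {}
        for spec in (SubgroupSpec.by_sex(), SubgroupSpec.by_age(config.age_split)):
            strat = stratify_and_screen(cohort, spec, pt_map, config.thresholds)
            for name, stats in strat.results.items():
                subgroup_tables[f"{spec.dimension}_{name}"] = stats_to_frame(stats)
            comparisons = compare_all_shared(strat)
            comparison_tables[spec.dimension] = pd.DataFrame([{
                "term": c.term,
                "stratum_a": c.stratum_a, "stratum_b": c.stratum_b,
                "ror_a": c.stats_a.ror, "ror_b": c.stats_b.ror,
                "ratio": c.ratio, "ci_low": c.ci_low, "ci_high": c.ci_high,
                "higher_risk_stratum": c.higher_risk_stratum,
            } for c in comparisons])
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {stage!r} (funnel so far: {funnel})"
        ) from exc

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(demographics, out / "demographics.csv")
    screen_frame = stats_to_frame(screen)
    _write_csv(screen_frame[screen_frame["level"] == "SOC"], out / "soc_table.csv")
    _write_csv(screen_frame[screen_frame["level"] == "PT"], out / "pt_table.csv")
    _write_csv(novel_table, out / "novel_signals.csv")
    _write_csv(priority_table, out / "priority.csv")
    for name, frame in subgroup_tables.items():
        _write_csv(frame, out / f"subgroup_{name}.csv")
    for name, frame in comparison_tables.items():
        _write_csv(frame, out / f"comparison_{name}.csv")
    manifest = {"funnel": funnel,
                "thresholds": vars(config.thresholds),
                "outputs": sorted(p.name for p in out.glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", funnel)
    return PipelineResult(cohort=cohort, demographics=demographics,
                          screen=screen, novel_table=novel_table,
                          priority_table=priority_table,
                          subgroup_tables=subgroup_tables,
                          comparison_tables=comparison_tables, funnel=funnel)


def select_cohort_stage(unique: list[AEReport], config: PipelineConfig) -> Cohort:
    from .faers_ingest import select_cohort

    return select_cohort(unique, DrugQuery(synonyms=config.drug_synonyms),
                         config.indication_terms,
                         date_window=config.date_window)
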