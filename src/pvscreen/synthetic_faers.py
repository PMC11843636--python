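"""Synthetic FAERS-style quarter generator with injected signals.

Emulates the raw inputs of a spontaneous-report safety analysis without
any database download: a cohort of reports, each carrying case/version
keys, demographics, drug mentions with FAERS role codes and name
synonyms, one or more event preferred terms, and a worst-outcome code.
A configurable signal table inflates the reporting rate of chosen
drug–event pairs by a known relative reporting ratio, giving downstream
stages a ground truth to recover.

Generative model, per report:

* the primary-suspect drug is the target drug with probability
  ``target_drug_share`` (one of its name synonyms chosen at random),
  otherwise a comparator drug;
* the number of distinct event PTs is zero-truncated Poisson with
  configurable mean; PTs are drawn without replacement, comparator
  reports from ``baseline_pt_probs`` and target reports from the
  baseline reweighted by the per-PT relative reporting ratio
  (renormalized);
* sex, age band and worst outcome are categorical draws that include
  explicit "unknown" masses, mirroring real reporting gaps;
* with probability ``duplicate_rate`` a case is filed twice with a
  higher version key and a later (or equal) receipt date, exercising
  the deduplication rules.

Default parameters reproduce the scale of the sparsentan/IgAN study
conditions: 2,196 cohort reports of which a ≈ 0.23 share name the target
drug as primary suspect, ~3 events per report, and the demographic and
outcome mixes of that cohort.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import reference
from .dialect import DELIMITER, write_table

TARGET_SYNONYMS = ("SPARSENTAN", "FILSPARI", "DEARA", "PS-433540", "RE-021")

_COMPARATOR_DRUGS = (
    "LISINOPRIL", "IRBESARTAN", "LOSARTAN", "DAPAGLIFLOZIN", "PREDNISONE",
    "TACROLIMUS", "BUDESONIDE", "MYCOPHENOLATE MOFETIL", "RAMIPRIL",
    "EMPAGLIFLOZIN",
)

_COHORT_INDICATIONS = ("IgA nephropathy", "IGA NEPHROPATHY",
                       "Immunoglobulin A nephropathy")
_OTHER_INDICATION = "Hypertension"

#: Common background PTs (beyond the 30 reference signal PTs) with their
#: system organ classes, giving the default dictionary realistic breadth.
_BACKGROUND_PTS: tuple[tuple[str, str], ...] = (
    ("Headache", "Nervous system disorders"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Vomiting", "Gastrointestinal disorders"),
    ("Rash", "Skin and subcutaneous tissue disorders"),
    ("Alopecia", "Skin and subcutaneous tissue disorders"),
    ("Pyrexia", "General disorders and administration site conditions"),
    ("Malaise", "General disorders and administration site conditions"),
    ("Asthenia", "General disorders and administration site conditions"),
    ("Cough", "Respiratory, thoracic and mediastinal disorders"),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders"),
    ("Back pain", "Musculoskeletal and connective tissue disorders"),
    ("Muscle spasms", "Musculoskeletal and connective tissue disorders"),
    ("Insomnia", "Psychiatric disorders"),
    ("Anxiety", "Psychiatric disorders"),
    ("Depression", "Psychiatric disorders"),
    ("Urinary tract infection", "Infections and infestations"),
    ("Pneumonia", "Infections and infestations"),
    ("Hyperkalaemia", "Metabolism and nutrition disorders"),
    ("Decreased appetite", "Metabolism and nutrition disorders"),
    ("Palpitations", "Cardiac disorders"),
    ("Vision blurred", "Eye disorders"),
    ("Tinnitus", "Ear and labyrinth disorders"),
    ("Weight decreased", "Investigations"),
    ("Blood pressure increased", "Investigations"),
    ("Renal impairment", "Renal and urinary disorders"),
    ("Pollakiuria", "Renal and urinary disorders"),
    ("Hypertension", "Vascular disorders"),
    ("Flushing", "Vascular disorders"),
    ("Contusion", "Injury, poisoning and procedural complications"),
    ("Fall", "Injury, poisoning and procedural complications"),
)


def default_pt_dictionary() -> list[tuple[str, str]]:
    """The 30 reference signal PTs plus 30 common background PTs."""
    ref = reference.load_pt_reference()
    return list(zip(ref["pt"], ref["soc"])) + list(_BACKGROUND_PTS)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic report database.

    ``baseline_pt_probs`` is the per-draw PT probability vector for
    comparator reports (must sum to 1); ``signal_table`` maps PT names
    to relative reporting ratios ≥ 0 applied to target-drug reports.
    ``events_per_report_mean`` is the mean of the zero-truncated Poisson
    event count.  Demographic distributions carry explicit ``unknown``
    masses.  ``non_cohort_share`` is the probability that a *non-target*
    report belongs to a different indication entirely (exercising cohort
    selection).
    """

    n_reports: int = 2196
    target_drug_share: float = 504 / 2196
    pt_dictionary: list[tuple[str, str]] = field(default_factory=default_pt_dictionary)
    baseline_pt_probs: Sequence[float] | None = None
    signal_table: list[tuple[str, float]] = field(default_factory=list)
    events_per_report_mean: float = 3.0
    sex_probs: Mapping[str, float] = field(default_factory=lambda: {
        "F": 0.4345, "M": 0.5496, "UNK": 0.0159})
    age_distribution: Mapping[str, float] = field(default_factory=lambda: {
        "<18": 0.0040, "18-45": 0.3333, ">45": 0.4067, "unknown": 0.2560})
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: {
        "HO": 0.0258, "OT": 0.0615, "unknown": 0.9127})
    duplicate_rate: float = 0.05
    non_cohort_share: float = 0.0
    concomitant_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError(f"n_reports must be positive, got {self.n_reports}")
        if not 0 <= self.target_drug_share <= 1:
            raise ValueError("target_drug_share must be a probability")
        if self.baseline_pt_probs is None:
            p = np.full(len(self.pt_dictionary), 1 / len(self.pt_dictionary))
            self.baseline_pt_probs = p
        probs = np.asarray(self.baseline_pt_probs, dtype=float)
        if len(probs) != len(self.pt_dictionary):
            raise ValueError("baseline_pt_probs length must match pt_dictionary")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"baseline_pt_probs sums to {probs.sum()!r}, not 1")
        names = {name for name, _ in self.pt_dictionary}
        for pt, ratio in self.signal_table:
            if pt not in names:
                raise ValueError(f"signal PT {pt!r} not in pt_dictionary")
            if ratio < 0:
                raise ValueError(f"signal ratio for {pt!r} must be >= 0")
        if self.events_per_report_mean < 1:
            raise ValueError("events_per_report_mean must be >= 1")
        for dist in (self.sex_probs, self.age_distribution, self.outcome_probs):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"distribution {dict(dist)} sums to {total}, not 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated database: the injected per-PT
    relative reporting ratios (exactly 1 for PTs without an injected
    signal) and the cases intentionally emitted twice."""

    ratios: dict[str, float]
    socs: dict[str, str]
    duplicated_caseids: frozenset[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pt": list(self.ratios),
            "soc": [self.socs[pt] for pt in self.ratios],
            "ratio": list(self.ratios.values()),
        })


def _truncated_poisson_rate(mean: float) -> float:
    """Rate λ such that the zero-truncated Poisson mean λ/(1−e^−λ)
    equals ``mean``; mean 1 degenerates to all-ones counts (λ→0)."""
    if mean <= 1 + 1e-9:
        return 0.0
    return brentq(lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-9, mean)


def _sample_event_counts(rng: np.random.Generator, n: int, mean: float,
                         n_pts: int) -> np.ndarray:
    lam = _truncated_poisson_rate(mean)
    if lam == 0.0:
        return np.ones(n, dtype=np.int64)
    counts = rng.poisson(lam, size=n)
    zero = counts == 0
    while zero.any():  # rejection step realizes the zero truncation
        counts[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = counts == 0
    return np.minimum(counts, n_pts)


def _categorical(rng: np.random.Generator, dist: Mapping[str, float],
                 n: int) -> np.ndarray:
    labels = np.array(list(dist), dtype=object)
    return labels[rng.choice(len(labels), size=n, p=list(dist.values()))]


_BASE_DATE = datetime.date(2023, 1, 1)
_LAST_ORD = datetime.date(2023, 12, 31).toordinal() - _BASE_DATE.toordinal()


def _fda_dt(day_offsets: np.ndarray) -> list[str]:
    return [(_BASE_DATE + datetime.timedelta(days=int(o))).strftime("%Y%m%d")
            for o in day_offsets]


def generate_raw_tables(config: GeneratorConfig
                        ) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate one quarter's DEMO/DRUG/REAC/OUTC tables plus ground
    truth.  Output is deterministic in ``config`` (including its seed):
    identical configs give byte-identical serialized tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    pt_names = [name for name, _ in config.pt_dictionary]
    socs = dict(config.pt_dictionary)
    base = np.asarray(config.baseline_pt_probs, dtype=float)
    ratios = np.ones(len(pt_names))
    for pt, ratio in config.signal_table:
        ratios[pt_names.index(pt)] = ratio
    target_p = base * ratios
    if target_p.sum() == 0:
        raise ValueError("signal_table zeroes out every PT probability")
    target_p = target_p / target_p.sum()

    is_target = rng.random(n) < config.target_drug_share
    non_cohort = ~is_target & (rng.random(n) < config.non_cohort_share)

    counts = _sample_event_counts(rng, n, config.events_per_report_mean,
                                  len(pt_names))
    # Weighted sampling without replacement, vectorized across reports
    # via exponential sort keys (Efraimidis–Spirakis): the k smallest
    # values of Exp(1)/p_i are exactly a sequential weighted draw.  Rows
    # use the target or baseline weight vector as appropriate.
    weights = np.where(is_target[:, None], target_p[None, :], base[None, :])
    keys = rng.exponential(size=(n, len(pt_names)))
    with np.errstate(divide="ignore"):
        keys /= weights
    kmax = int(counts.max())
    part = (np.argpartition(keys, kmax - 1, axis=1)[:, :kmax]
            if kmax < len(pt_names) else np.argsort(keys, axis=1))
    order = np.argsort(np.take_along_axis(keys, part, axis=1), axis=1)
    ranked = np.take_along_axis(part, order, axis=1)

    sex = _categorical(rng, config.sex_probs, n)
    age_band = _categorical(rng, config.age_distribution, n)
    ages = np.empty(n, dtype=object)
    ages[age_band == "<18"] = rng.integers(2, 18, size=int((age_band == "<18").sum()))
    ages[age_band == "18-45"] = rng.integers(18, 46, size=int((age_band == "18-45").sum()))
    ages[age_band == ">45"] = rng.integers(46, 91, size=int((age_band == ">45").sum()))
    ages[age_band == "unknown"] = ""
    outcome = _categorical(rng, config.outcome_probs, n)
    day_offsets = rng.integers(0, _LAST_ORD + 1, size=n)
    ps_synonym = rng.integers(0, len(TARGET_SYNONYMS), size=n)
    comp_drug = rng.integers(0, len(_COMPARATOR_DRUGS), size=n)
    indi_pick = rng.integers(0, len(_COHORT_INDICATIONS), size=n)
    has_conc = rng.random(n) < config.concomitant_prob
    conc_drug = rng.integers(0, len(_COMPARATOR_DRUGS), size=n)
    conc_is_target = rng.random(n) < 0.05  # target as mere concomitant
    duplicated = rng.random(n) < config.duplicate_rate
    dup_gap = rng.integers(1, 91, size=n)

    caseids = 230000001 + np.arange(n)
    fda = _fda_dt(day_offsets)

    demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []

    def emit(i: int, version: int, fda_dt: str) -> None:
        caseid = int(caseids[i])
        pid = caseid * 10 + version
        demo_rows.append((pid, caseid, version, fda_dt, ages[i], "YR",
                          sex[i], "US"))
        if is_target[i]:
            ps_name = TARGET_SYNONYMS[ps_synonym[i]]
        else:
            ps_name = _COMPARATOR_DRUGS[comp_drug[i]]
        indication = (_OTHER_INDICATION if non_cohort[i]
                      else _COHORT_INDICATIONS[indi_pick[i]])
        drug_rows.append((pid, caseid, 1, "PS", ps_name, indication))
        if has_conc[i]:
            name = (TARGET_SYNONYMS[0] if conc_is_target[i] and not is_target[i]
                    else _COMPARATOR_DRUGS[conc_drug[i]])
            drug_rows.append((pid, caseid, 2, "C", name, ""))
        for j in ranked[i, :counts[i]]:
            reac_rows.append((pid, caseid, pt_names[j]))
        if outcome[i] != "unknown":
            outc_rows.append((pid, caseid, outcome[i]))

    for i in range(n):
        emit(i, 1, fda[i])
    for i in np.flatnonzero(duplicated):  # re-filed versions, appended last
        later = min(int(day_offsets[i]) + int(dup_gap[i]), _LAST_ORD)
        emit(int(i), 2, _fda_dt(np.array([later]))[0])

    tables = {
        "DEMO": pd.DataFrame(demo_rows, columns=[
            "primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod",
            "sex", "occr_country"]),
        "DRUG": pd.DataFrame(drug_rows, columns=[
            "primaryid", "caseid", "drug_seq", "role_cod", "drugname",
            "indi_pt"]),
        "REAC": pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"]),
        "OUTC": pd.DataFrame(outc_rows, columns=["primaryid", "caseid",
                                                 "outc_cod"]),
    }
    for name, frame in tables.items():
        if frame.astype(str).apply(
                lambda col: col.str.contains(DELIMITER, regex=False)).any().any():
            raise ValueError(f"{name}: generated value contains {DELIMITER!r}")
    truth = SyntheticTruth(
        ratios={pt: float(ratios[k]) for k, pt in enumerate(pt_names)},
        socs=socs,
        duplicated_caseids=frozenset(int(caseids[i])
                                     for i in np.flatnonzero(duplicated)),
    )
    return tables, truth


def generate_cohort(config: GeneratorConfig,
                    indication_terms: Sequence[str] = ("IgA nephropathy",
                                                       "Immunoglobulin A nephropathy"),
                    ):
    """Generate, assemble, deduplicate and cohort-select in memory.

    Convenience path for simulation studies that do not need the
    serialized quarter files; returns ``(Cohort, SyntheticTruth)``.
    """
    from .faers_ingest import (DrugQuery, RawQuarter, build_reports,
                               deduplicate, select_cohort)

    tables, truth = generate_raw_tables(config)
    raw = RawQuarter(tables={k: v.astype(str) for k, v in tables.items()})
    reports = deduplicate(build_reports(raw))
    cohort = select_cohort(reports, DrugQuery(synonyms=TARGET_SYNONYMS),
                           indication_terms)
    return cohort, truth


def write_quarter(tables: Mapping[str, pd.DataFrame], directory: str | Path,
                  truth: SyntheticTruth | None = None) -> dict[str, Path]:
    """Serialize generated tables (and optionally the ground truth) into
    ``directory``; returns the written paths keyed by table name."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: write_table(frame, directory / f"{name}.txt")
             for name, frame in tables.items()}
    if truth is not None:
        truth_path = directory / "truth.csv"
        truth.to_frame().to_csv(truth_path, index=False)
        paths["truth"] = truth_path
    return paths
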