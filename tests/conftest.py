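"""Shared fixtures: reference tables, report factories, study-scale
generator configurations."""

from __future__ import annotations

import numpy as np
import pytest

from pvscreen import (AEReport, DrugMention, GeneratorConfig, OutcomeClass,
                      default_pt_dictionary, reference)

IGAN = "IgA nephropathy"


def make_report(caseid=1, primaryid=None, fda_dt=20230601, sex="female",
                age=40.0, events=(), ps_drug="SPARSENTAN", role="PS",
                indication=IGAN, outcome=OutcomeClass.UNKNOWN,
                extra_drugs=()) -> AEReport:
    """Handcrafted report with sensible defaults for unit tests."""
    drugs = (DrugMention(ps_drug, role, indication),) + tuple(extra_drugs)
    return AEReport(caseid=caseid,
                    primaryid=primaryid if primaryid is not None else caseid * 10 + 1,
                    fda_dt=fda_dt, sex=sex, age_years=age, drugs=drugs,
                    events=frozenset(events), outcome=outcome)


@pytest.fixture(scope="session")
def soc_reference():
    return reference.load_soc_reference()


@pytest.fixture(scope="session")
def pt_reference():
    return reference.load_pt_reference()


@pytest.fixture(scope="session")
def priority_reference():
    return reference.load_priority_reference()


@pytest.fixture(scope="session")
def pt_soc_map():
    return reference.load_pt_soc_map()


def power_config(seed: int, ratio: float = 5.0,
                 signal_pt: str = "Tinnitus") -> GeneratorConfig:
    """Study-scale generator config with one injected drug–event signal.

    2,196 cohort reports, a 504/2,196 target share and ~3 events per
    report mirror the reference cohort; the signal PT's baseline
    per-draw probability of 0.004 puts its expected target count near 30
    when the injected relative reporting ratio is 5.
    """
    pts = default_pt_dictionary()
    names = [name for name, _ in pts]
    probs = np.full(len(pts), (1 - 0.004) / (len(pts) - 1))
    probs[names.index(signal_pt)] = 0.004
    probs = probs / probs.sum()
    return GeneratorConfig(
        n_reports=2196, target_drug_share=504 / 2196,
        pt_dictionary=pts, baseline_pt_probs=probs,
        signal_table=[(signal_pt, ratio)] if ratio != 1.0 else [],
        seed=seed,
    )


def null_config(seed: int, n_pts: int = 1000,
                n_reports: int = 20000) -> GeneratorConfig:
    """Global-null config: many PTs, no injected signal."""
    pts = [(f"Background term {i:04d}", f"Background class {i % 20:02d}")
           for i in range(n_pts)]
    return GeneratorConfig(n_reports=n_reports, target_drug_share=0.23,
                           pt_dictionary=pts, duplicate_rate=0.0, seed=seed)
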