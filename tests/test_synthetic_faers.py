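"""Generator tests: determinism, dialect round-trip, conservation, and
statistical fidelity of the injected signal structure."""

from __future__ import annotations

import numpy as np
import pytest

from pvscreen import (GeneratorConfig, RawQuarter, build_reports,
                      generate_raw_tables, parse_quarter, write_quarter)

from conftest import power_config


def small_config(**kw) -> GeneratorConfig:
    defaults = dict(n_reports=300, duplicate_rate=0.0, seed=11)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestConfigValidation:
    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_reports=0)

    def test_signal_pt_must_be_in_dictionary(self):
        with pytest.raises(ValueError, match="not in pt_dictionary"):
            GeneratorConfig(signal_table=[("No such term", 5.0)])

    def test_baseline_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            GeneratorConfig(pt_dictionary=[("A", "S"), ("B", "S")],
                            baseline_pt_probs=[0.5, 0.4])

    def test_truth_ratios_default_to_one(self):
        _, truth = generate_raw_tables(small_config(
            signal_table=[("Tinnitus", 5.0)]))
        assert truth.ratios["Tinnitus"] == 5.0
        others = {pt: r for pt, r in truth.ratios.items() if pt != "Tinnitus"}
        assert set(others.values()) == {1.0}


class TestStructure:
    def test_no_duplication_means_distinct_caseids(self):
        tables, truth = generate_raw_tables(small_config())
        assert tables["DEMO"]["caseid"].nunique() == 300
        assert truth.duplicated_caseids == frozenset()

    def test_duplicates_share_caseid_differ_in_keys(self):
        tables, truth = generate_raw_tables(small_config(duplicate_rate=0.3))
        demo = tables["DEMO"]
        assert truth.duplicated_caseids
        for caseid in truth.duplicated_caseids:
            versions = demo[demo["caseid"] == caseid]
            assert len(versions) == 2
            assert versions["primaryid"].nunique() == 2

    def test_reac_keys_exist_in_demo(self):
        tables, _ = generate_raw_tables(small_config())
        assert set(tables["REAC"]["primaryid"]) <= set(tables["DEMO"]["primaryid"])

    def test_event_conservation(self):
        """REAC rows equal the summed per-report event counts, and every
        report lists each PT at most once."""
        tables, _ = generate_raw_tables(small_config(duplicate_rate=0.2))
        reac = tables["REAC"]
        per_report = reac.groupby("primaryid")["pt"].agg(["count", "nunique"])
        assert (per_report["count"] == per_report["nunique"]).all()
        assert per_report["count"].sum() == len(reac)
        assert per_report["count"].min() >= 1

    def test_seeded_determinism(self, tmp_path):
        a, _ = generate_raw_tables(small_config(duplicate_rate=0.1))
        b, _ = generate_raw_tables(small_config(duplicate_rate=0.1))
        pa = write_quarter(a, tmp_path / "a")
        pb = write_quarter(b, tmp_path / "b")
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes()

    def test_different_seed_different_output(self):
        a, _ = generate_raw_tables(small_config(seed=1))
        b, _ = generate_raw_tables(small_config(seed=2))
        assert not a["REAC"].equals(b["REAC"])


class TestDialectRoundTrip:
    def test_round_trip_identical(self, tmp_path):
        tables, truth = generate_raw_tables(small_config(duplicate_rate=0.1))
        write_quarter(tables, tmp_path, truth=truth)
        raw = parse_quarter(tmp_path)
        assert sum(raw.malformed.values()) == 0
        for name, original in tables.items():
            assert raw.tables[name].equals(original.astype(str))

    def test_round_trip_record_count_through_reports(self, tmp_path):
        tables, _ = generate_raw_tables(small_config())
        write_quarter(tables, tmp_path)
        reports = build_reports(parse_quarter(tmp_path))
        assert len(reports) == len(tables["DEMO"])

    def test_embedded_delimiter_rejected(self, tmp_path):
        tables, _ = generate_raw_tables(small_config(n_reports=5))
        tables["DRUG"].loc[0, "drugname"] = "BAD$NAME"
        with pytest.raises(ValueError, match="delimiter"):
            write_quarter(tables, tmp_path)


def _reporting_fractions(config: GeneratorConfig):
    """Per-PT fraction of reports mentioning each PT, split by PS drug."""
    tables, _ = generate_raw_tables(config)
    raw = RawQuarter(tables={k: v.astype(str) for k, v in tables.items()})
    reports = build_reports(raw)
    from pvscreen import TARGET_SYNONYMS, DrugQuery
    query = DrugQuery(TARGET_SYNONYMS)
    groups = {"target": [], "comparator": []}
    for r in reports:
        ps = [d for d in r.drugs if d.role == "PS"]
        key = "target" if any(query.matches(d.name_as_reported) for d in ps) \
            else "comparator"
        groups[key].append(r)
    pts = [name for name, _ in config.pt_dictionary]
    out = {}
    for key, members in groups.items():
        n = len(members)
        out[key] = {pt: sum(pt in r.events for r in members) / n for pt in pts}, n
    return out


class TestSignalFidelity:
    def test_null_config_balances_target_and_comparator(self):
        """With all ratios 1, per-PT reporting fractions for target vs
        comparator reports agree within 3 binomial standard errors."""
        config = GeneratorConfig(n_reports=50_000, duplicate_rate=0.0, seed=101)
        fracs = _reporting_fractions(config)
        (ft, nt), (fc, nc) = fracs["target"], fracs["comparator"]
        for pt in ft:
            pooled = (ft[pt] * nt + fc[pt] * nc) / (nt + nc)
            se = np.sqrt(pooled * (1 - pooled) * (1 / nt + 1 / nc))
            assert abs(ft[pt] - fc[pt]) <= 3 * se, pt

    def test_injected_ratio_recovered(self):
        """A PT injected at relative reporting ratio 5 shows an empirical
        target:comparator fraction ratio within [4, 6] at n=50,000."""
        config = power_config(seed=202, ratio=5.0)
        config.n_reports = 50_000
        config.duplicate_rate = 0.0
        fracs = _reporting_fractions(config)
        (ft, _), (fc, _) = fracs["target"], fracs["comparator"]
        assert 4.0 <= ft["Tinnitus"] / fc["Tinnitus"] <= 6.0
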