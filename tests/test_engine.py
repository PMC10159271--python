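"""Engine: sentinel rules, sampling, classification, resampling contracts."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from vcgsim.engine import (
    OutcomeCategory,
    Scenario,
    classify_outcome,
    run_resampling,
    sample_vcg,
    select_sentinels,
    sentinel_filter,
)
from vcgsim.store import AnimalRecord, HCDPool, Measurement
from vcgsim.synthetic import LegacyStudy, generate_legacy_study, legacy_group_specs


def _animal(sid, bw, ca, study="S1", anesth="isoflurane", year=2018):
    return AnimalRecord(
        subject_id=sid,
        study_id=study,
        initial_body_weight=bw,
        anesthetic=anesth,
        study_start_year=year,
        measurements={"CA": Measurement(ca, "mmol/L", 28)},
    )


def _weight_ranked_control(n=10):
    # subject ids encode the body-weight rank for readable assertions
    return [_animal(f"R{r:02d}", 100.0 + 10 * r, 2.5 + 0.01 * r) for r in range(1, n + 1)]


class TestSelectSentinels:
    def test_keep_five_takes_extremes_and_middle(self):
        sel = select_sentinels(_weight_ranked_control(), 5)
        assert sel.kept_ids == ("R01", "R02", "R05", "R09", "R10")

    def test_keep_four_takes_extremes_only(self):
        sel = select_sentinels(_weight_ranked_control(), 4)
        assert sel.kept_ids == ("R01", "R02", "R09", "R10")

    def test_keep_two(self):
        sel = select_sentinels(_weight_ranked_control(), 2)
        assert sel.kept_ids == ("R01", "R10")

    def test_keep_all_and_keep_none(self):
        control = _weight_ranked_control()
        all_sel = select_sentinels(control, 10)
        assert set(all_sel.kept_ids) == {a.subject_id for a in control}
        assert all_sel.replaced == ()
        none_sel = select_sentinels(control, 0)
        assert none_sel.kept == () and len(none_sel.replaced) == 10
        assert none_sel.range_low is None

    def test_partition_is_exact(self):
        control = _weight_ranked_control()
        sel = select_sentinels(control, 5)
        assert set(sel.kept_ids) | set(sel.replaced_ids) == {a.subject_id for a in control}
        assert set(sel.kept_ids) & set(sel.replaced_ids) == set()

    def test_more_than_group_size_errors(self):
        with pytest.raises(ValueError):
            select_sentinels(_weight_ranked_control(), 11)

    def test_range_from_two_values(self):
        animals = [_animal("A", 100.0, 2.51), _animal("B", 200.0, 2.63)]
        sel = select_sentinels(animals, 2)
        sd = np.std([2.51, 2.63], ddof=1)  # 0.0849
        assert sel.range_low == pytest.approx(2.57 - 2 * sd)
        assert sel.range_high == pytest.approx(2.57 + 2 * sd)


class TestSentinelFilter:
    def test_zero_width_range_keeps_exact_matches_only(self):
        sentinels = [_animal("S1", 100, 2.5), _animal("S2", 200, 2.5)]
        sel = select_sentinels(sentinels, 2)
        pool = HCDPool(records=[_animal(f"P{i}", 150, v, study="H")
                                for i, v in enumerate([2.5, 2.5, 2.51, 2.49])])
        out = sentinel_filter(pool, sel)
        assert sorted(r.value("CA") for r in out.records) == [2.5, 2.5]

    def test_matches_brute_force_range_check(self):
        rng = np.random.default_rng(11)
        pool = HCDPool(records=[_animal(f"P{i}", 150, float(v), study="H")
                                for i, v in enumerate(rng.normal(2.6, 0.15, size=20))])
        sel = select_sentinels(_weight_ranked_control(), 5)
        out = sentinel_filter(pool, sel)
        lo, hi = sel.range_low, sel.range_high
        expected = [r for r in pool.records if lo <= r.value("CA") <= hi]
        assert out.records == expected

    def test_undefined_range_errors_with_guidance(self):
        sel = select_sentinels(_weight_ranked_control(), 1)
        with pytest.raises(ValueError, match="disable"):
            sentinel_filter(HCDPool(records=[]), sel)


class TestSampleVcg:
    def _pool(self, n=5):
        return HCDPool(records=[_animal(f"P{i}", 150, 2.5 + i * 0.01, study="H")
                                for i in range(n)])

    def test_exhaustive_draw_returns_whole_pool(self):
        pool = self._pool(5)
        out = sample_vcg(pool, 5, ("CA",), np.random.default_rng(0))
        assert sorted(a.subject_id for a in out) == sorted(r.subject_id for r in pool.records)

    def test_infeasible_draw_reports_eligible_count(self):
        with pytest.raises(ValueError, match="5"):
            sample_vcg(self._pool(5), 6, ("CA",), np.random.default_rng(0))

    def test_draws_never_repeat_a_subject(self):
        pool = self._pool(8)
        rng = np.random.default_rng(1)
        for _ in range(200):
            ids = [a.subject_id for a in sample_vcg(pool, 4, ("CA",), rng)]
            assert len(set(ids)) == 4

    def test_selection_is_uniform(self):
        pool = self._pool(5)
        rng = np.random.default_rng(2)
        counts = {r.subject_id: 0 for r in pool.records}
        n_draws = 10_000
        for _ in range(n_draws):
            counts[sample_vcg(pool, 1, ("CA",), rng)[0].subject_id] += 1
        chi2 = sum((c - n_draws / 5) ** 2 / (n_draws / 5) for c in counts.values())
        assert sps.chi2.sf(chi2, 4) > 0.001

    def test_animals_lacking_an_endpoint_are_ineligible(self):
        pool = self._pool(5)
        out_of_scope = AnimalRecord(subject_id="NOCA", study_id="H")
        pool = HCDPool(records=pool.records + [out_of_scope])
        with pytest.raises(ValueError):
            sample_vcg(pool, 6, ("CA",), np.random.default_rng(0))


class TestClassification:
    def test_exhaustive_mapping(self):
        cases = {
            (False, "none", False, "none"): OutcomeCategory.CONSISTENT_NONSIGNIFICANT,
            (False, "increase", False, "decrease"): OutcomeCategory.CONSISTENT_NONSIGNIFICANT,
            (False, "none", True, "increase"): OutcomeCategory.INCONSISTENT_SIGNIFICANT,
            (False, "decrease", True, "decrease"): OutcomeCategory.INCONSISTENT_SIGNIFICANT,
            (True, "increase", False, "increase"): OutcomeCategory.INCONSISTENT_NONSIGNIFICANT,
            (True, "decrease", False, "none"): OutcomeCategory.INCONSISTENT_NONSIGNIFICANT,
            (True, "increase", True, "increase"): OutcomeCategory.CONSISTENT_SIGNIFICANT,
            (True, "increase", True, "decrease"): OutcomeCategory.INVERTED_SIGNIFICANT,
        }
        for (os_, od, vs, vd), expected in cases.items():
            assert classify_outcome(os_, od, vs, vd) is expected

    def test_inverted_significance_example(self):
        got = classify_outcome(True, "increase", True, "decrease")
        assert got is OutcomeCategory.INVERTED_SIGNIFICANT
        assert not got.consistent


def _identity_pool(study: LegacyStudy) -> HCDPool:
    # historical animals carrying exactly the control values
    records = [
        AnimalRecord(
            subject_id=f"HCD-{a.subject_id}",
            study_id="HCDX",
            initial_body_weight=a.initial_body_weight,
            anesthetic="isoflurane",
            study_start_year=2018,
            measurements=dict(a.measurements),
        )
        for a in study.control_animals
    ]
    return HCDPool(records=records)


class TestRunResampling:
    def test_identity_pool_reproduces_everything(self, legacy_study):
        pool = _identity_pool(legacy_study)
        scenario = Scenario(name="identity", iterations=25, seed=7)
        report = run_resampling(legacy_study, pool, scenario)
        for group in report.dose_labels:
            assert report.reproducibility_percent(group) == 100.0

    def test_category_counts_sum_to_iterations(self, legacy_study, default_pool):
        scenario = Scenario(name="1a", iterations=40, seed=3)
        report = run_resampling(legacy_study, default_pool, scenario)
        for group in report.dose_labels:
            assert sum(report.counts["CA"][group].values()) == 40

    def test_constant_control_group_size_and_distinct_subjects(self, legacy_study, default_pool):
        scenario = Scenario(
            name="1c", n_keep_sentinels=5, sentinel_range_filter=True,
            iterations=30, seed=5,
        )
        report = run_resampling(legacy_study, default_pool, scenario)
        kept = set(report.sentinel_selection.kept_ids)
        for entry in report.iteration_log:
            ids = entry["subject_ids"]
            assert len(ids) == 10
            assert len(set(ids)) == 10
            assert kept <= set(ids)

    def test_same_seed_byte_identical_reports(self, legacy_study, default_pool):
        scenario = Scenario(name="rep", iterations=30, seed=21)
        a = run_resampling(legacy_study, default_pool, scenario)
        b = run_resampling(legacy_study, default_pool, scenario)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(b.to_dict(), sort_keys=True)

    def test_different_seed_changes_draws(self, legacy_study, default_pool):
        a = run_resampling(legacy_study, default_pool, Scenario(iterations=5, seed=1))
        b = run_resampling(legacy_study, default_pool, Scenario(iterations=5, seed=2))
        assert a.iteration_log[0]["subject_ids"] != b.iteration_log[0]["subject_ids"]

    def test_anesthetic_match_improves_high_dose_reproducibility(self, legacy_study, default_pool):
        agnostic = run_resampling(
            legacy_study, default_pool, Scenario(name="1a", iterations=200, seed=9)
        )
        matched = run_resampling(
            legacy_study, default_pool,
            Scenario(name="2a", pool_anesthetic_filter="match_study",
                     iterations=200, seed=9),
        )
        assert (
            matched.reproducibility_percent("DG3")
            > agnostic.reproducibility_percent("DG3")
        )

    def test_anesthetic_filter_excludes_unknown_and_mismatched(self, legacy_study, default_pool):
        from vcgsim.store import attach_metadata

        # strip metadata from one study so its animals become 'unknown'
        known = {
            r.study_id: r.anesthetic
            for r in default_pool.records
            if r.study_id != "HCD001"
        }
        pool = attach_metadata(default_pool, known)
        report = run_resampling(
            legacy_study, pool,
            Scenario(pool_anesthetic_filter="match_study", iterations=5, seed=0),
        )
        entry = report.pool_provenance[-1]
        iso = sum(1 for r in pool.records if r.anesthetic == "isoflurane")
        assert entry.n_after == iso

    def test_monte_carlo_stability_of_agnostic_estimate(self, legacy_study, default_pool):
        short = run_resampling(
            legacy_study, default_pool, Scenario(name="1a", iterations=500, seed=13)
        )
        long = run_resampling(
            legacy_study, default_pool, Scenario(name="1a", iterations=5000, seed=14)
        )
        assert short.reproducibility_percent("DG1") == pytest.approx(
            long.reproducibility_percent("DG1"), abs=3.0
        )

    def test_pool_too_small_reports_eligible_count(self, legacy_study):
        tiny = HCDPool(records=_identity_pool(legacy_study).records[:4])
        with pytest.raises(ValueError, match="4 eligible"):
            run_resampling(legacy_study, tiny, Scenario(iterations=2, seed=0))

    def test_sentinel_count_above_group_size_errors(self, legacy_study, default_pool):
        with pytest.raises(ValueError, match="exceeds"):
            run_resampling(
                legacy_study, default_pool,
                Scenario(n_keep_sentinels=11, iterations=1, seed=0),
            )

    def test_multi_endpoint_runs_share_the_drawn_animals(self, default_pool):
        # give the fixture phosphate dose-group values too
        study = generate_legacy_study(legacy_group_specs(), seed=2)
        rng = np.random.default_rng(0)
        for a in study.control_animals:
            a.measurements["PHOS"] = Measurement(float(rng.normal(2.05, 0.15)), "mmol/L", 28)
        study.dose_values["PHOS"] = {
            lab: rng.normal(2.1, 0.15, size=10) for lab in study.dose_labels
        }
        report = run_resampling(
            study, default_pool,
            Scenario(iterations=10, seed=4, endpoints=("CA", "PHOS")),
        )
        assert set(report.counts) == {"CA", "PHOS"}
        for group in report.dose_labels:
            assert sum(report.counts["PHOS"][group].values()) == 10
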