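"""Downregulation filter, BH correction, correlation, t tests and survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy import stats as sps

from isomirkit import (
    bh_adjust,
    compare_groups,
    correlate_isoforms,
    downregulated_genes,
    load_patient_table,
    logrank_statistic,
    quartile_survival,
)
from isomirkit.simulate import CohortConfig, simulate_cohort, simulate_de_table
from isomirkit.stats import quartile_groups


def bh_brute_force(p):
    """Step-up definition: sort, scale by m/rank, cummin from the largest."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


class TestBhAdjust:
    def test_hand_computed_example(self):
        # 0.04*4/4=0.04 caps every smaller rank by the step-up cummin
        result = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert result == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for size in (3, 17, 256, 10_000):
            p = rng.random(size)
            assert bh_adjust(p) == pytest.approx(bh_brute_force(p))

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(100)
        assert np.all(bh_adjust(p) >= p)
        assert np.all(bh_adjust(p) <= 1.0)


def _de_rows(entries):
    """entries: (gene, line, condition, ratio, p)"""
    return pd.DataFrame(
        entries, columns=["gene_id", "cell_line", "condition", "ratio", "p"]
    )


class TestDownregulatedGenes:
    def test_hit_below_both_thresholds_included(self):
        rows = []
        for line in ("A", "B"):
            rows.append(("g1", line, "isomir", 0.64, 1e-8))
            for i in range(2, 30):  # null background keeps BH from inflating g1
                rows.append((f"g{i}", line, "isomir", 1.0, 0.9))
        result = downregulated_genes(_de_rows(rows), ["A", "B"])
        assert result.gene_sets["isomir"] == {"g1"}

    def test_ratio_boundary_is_strict(self):
        rows = []
        for line in ("A", "B"):
            ratio = 0.66 if line == "A" else 0.5
            rows.append(("g1", line, "isomir", ratio, 1e-8))
        result = downregulated_genes(_de_rows(rows), ["A", "B"])
        assert result.gene_sets["isomir"] == frozenset()

    def test_exact_065_excluded(self):
        rows = [("g1", line, "isomir", 0.65, 1e-8) for line in ("A", "B")]
        result = downregulated_genes(_de_rows(rows), ["A", "B"])
        assert result.gene_sets["isomir"] == frozenset()

    def test_missing_gene_in_required_line_raises(self):
        rows = [("g1", "A", "isomir", 0.5, 1e-8)]
        with pytest.raises(ValueError, match="g1"):
            downregulated_genes(_de_rows(rows), ["A", "B"])

    def test_planted_venn_counts_recovered(self, rng):
        table, truth = simulate_de_table(
            rng, n_genes=500, planted={"canonical": 10, "isomir": 30, "shared": 4}
        )
        result = downregulated_genes(table, ["LineA", "LineB"])
        assert result.venn == {
            "canonical_specific": 10,
            "isomir_specific": 30,
            "shared": 4,
        }
        assert result.gene_sets["isomir"] == truth["isomir"] | truth["shared"]
        assert result.gene_sets["canonical"] == truth["canonical"] | truth["shared"]

    def test_zero_planted_hits_empty_sets(self, rng):
        table, _ = simulate_de_table(rng, n_genes=100, planted={})
        result = downregulated_genes(table, ["LineA", "LineB"])
        assert all(not genes for genes in result.gene_sets.values())

    def test_boundary_planted_ratio_0649_included(self):
        rows = []
        for line in ("A", "B"):
            rows.append(("g1", line, "isomir", 0.649, 1e-8))
            for i in range(2, 20):
                rows.append((f"g{i}", line, "isomir", 1.1, 0.8))
        result = downregulated_genes(_de_rows(rows), ["A", "B"])
        assert "g1" in result.gene_sets["isomir"]

    def test_sanity_bound_with_thresholds_relaxed(self):
        rows = []
        for line in ("A",):
            rows.append(("down", line, "isomir", 0.9, 0.001))
            rows.append(("up", line, "isomir", 1.1, 0.001))
        result = downregulated_genes(
            _de_rows(rows), ["A"], fold_threshold=1.0, alpha=1.0
        )
        assert result.gene_sets["isomir"] == {"down"}

    def test_replicate_schema_computes_ratio_and_p(self):
        rows = []
        for line in ("A", "B"):
            for rep, value in enumerate([100.0, 102.0, 98.0]):
                rows.append(("g1", line, "control", rep, value))
            for rep, value in enumerate([50.0, 51.0, 49.0]):
                rows.append(("g1", line, "isomir", rep, value))
        table = pd.DataFrame(
            rows, columns=["gene_id", "cell_line", "condition", "replicate", "expression"]
        )
        result = downregulated_genes(table, ["A", "B"])
        assert result.gene_sets["isomir"] == {"g1"}


class TestCorrelation:
    def test_identical_vectors_r_one(self):
        frame = pd.DataFrame({"mir_rpm": [1.0, 2, 3, 4], "isomir_rpm": [1.0, 2, 3, 4]})
        r, p, n = correlate_isoforms(frame)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_constant_vector_raises(self):
        frame = pd.DataFrame({"mir_rpm": [1.0, 1, 1], "isomir_rpm": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="constant"):
            correlate_isoforms(frame)

    def test_missing_values_dropped(self):
        frame = pd.DataFrame(
            {"mir_rpm": [1.0, 2, 3, np.nan], "isomir_rpm": [1.1, 2.2, 2.9, 4]}
        )
        _, _, n = correlate_isoforms(frame)
        assert n == 3

    def test_spearman_option(self):
        frame = pd.DataFrame({"mir_rpm": [1.0, 2, 3, 4], "isomir_rpm": [1.0, 4, 9, 16]})
        r, _, _ = correlate_isoforms(frame, method="spearman")
        assert r == pytest.approx(1.0)

    def test_single_cohort_recovers_target(self, rng):
        config = CohortConfig(n_patients=616, target_correlation=0.85, er_effect_size=0.0)
        patients, _ = simulate_cohort(config, rng)
        r, p, n = correlate_isoforms(patients)
        assert n == 616
        assert p < 0.001
        # Fisher-z 95% CI around the target at this n is about +/- 0.03
        z = np.arctanh(0.85)
        half = 1.96 / np.sqrt(616 - 3)
        assert np.tanh(z - 3 * half) < r < np.tanh(z + 3 * half)


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        frame = pd.DataFrame(
            {
                "er_status": ["negative"] * 3 + ["positive"] * 3,
                "isomir_rpm": [1.0, 2, 3, 1, 2, 3],
            }
        )
        result = compare_groups(frame, "er_status", "isomir_rpm")
        assert result["t_statistic"] == pytest.approx(0.0)
        assert result["p_value"] == pytest.approx(1.0)

    def test_hand_sized_example_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        frame = pd.DataFrame(
            {"metastasis": ["yes"] * 3 + ["no"] * 3, "mir_rpm": a + b}
        )
        result = compare_groups(frame, "metastasis", "mir_rpm", groups=("yes", "no"))
        sp = np.sqrt(((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2) * (2 / 3))
        expected_t = (np.mean(a) - np.mean(b)) / sp
        assert result["t_statistic"] == pytest.approx(expected_t)
        assert result["higher_in"] == "no"

    def test_power_with_unit_effect(self, rng):
        rejections = 0
        for _ in range(100):
            frame = pd.DataFrame(
                {
                    "er_status": ["negative"] * 50 + ["positive"] * 50,
                    "isomir_rpm": np.concatenate(
                        [rng.normal(1.0, 1.0, 50), rng.normal(0.0, 1.0, 50)]
                    ),
                }
            )
            if compare_groups(frame, "er_status", "isomir_rpm")["p_value"] < 0.05:
                rejections += 1
        assert rejections >= 99

    def test_unknowns_dropped_and_small_group_raises(self):
        frame = pd.DataFrame(
            {"er_status": ["negative", "unknown", "positive", "positive"],
             "isomir_rpm": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups(frame, "er_status", "isomir_rpm")


def _survival_frame(times, events, expressions):
    n = len(times)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "mir_rpm": expressions,
            "isomir_rpm": expressions,
            "survival_time": times,
            "event": ["death" if e else "censored" for e in events],
        }
    )


class TestQuartileSurvival:
    def test_quartile_groups_disjoint_and_sized(self, rng):
        expr = pd.Series(rng.lognormal(5, 1, 200),
                         index=[f"P{i}" for i in range(200)])
        groups = quartile_groups(expr)
        assert not groups.high & groups.low
        assert abs(len(groups.high) - 50) <= 2
        assert abs(len(groups.low) - 50) <= 2
        assert len(groups.high) + len(groups.low) + len(groups.excluded) == 200

    def test_identical_groups_give_null_statistic(self):
        # low quartile and high quartile carry identical survival experience
        times = [10, 20, 30, 40] * 2 + [5, 6, 7, 8]
        events = [1, 0, 1, 1] * 2 + [0, 0, 0, 0]
        expr = [1, 1, 1, 1, 100, 100, 100, 100, 50, 50, 50, 50]
        result = quartile_survival(_survival_frame(times, events, expr))
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_all_censored_warns_with_zero_statistic(self):
        times = list(range(1, 13))
        events = [0] * 12
        expr = list(range(12))
        result = quartile_survival(_survival_frame(times, events, expr))
        assert result.statistic == 0.0
        assert result.warning is not None

    def test_statistic_matches_lifelines_oracle(self, rng):
        time = rng.exponential(100, 80)
        event = rng.random(80) < 0.7
        group = rng.random(80) < 0.5
        ours = logrank_statistic(time, event, group)
        theirs = lifelines_logrank(
            time[group], time[~group], event[group], event[~group]
        )
        assert ours == pytest.approx(theirs.test_statistic, rel=1e-9)

    def test_statistic_invariant_to_group_relabeling(self, rng):
        time = rng.exponential(100, 60)
        event = rng.random(60) < 0.6
        group = rng.random(60) < 0.5
        assert logrank_statistic(time, event, group) == pytest.approx(
            logrank_statistic(time, event, ~group)
        )

    def test_km_without_censoring_is_empirical_survival(self):
        times = [10.0, 20, 30, 40, 50, 60, 70, 80]
        events = [1] * 8
        expr = [1, 2, 3, 4, 5, 6, 7, 8]
        result = quartile_survival(_survival_frame(times, events, expr))
        for curve in result.km_curves.values():
            observed_times = curve.index[1:]
            n = len(observed_times)
            for i, t in enumerate(observed_times, start=1):
                assert curve.loc[t].iloc[0] == pytest.approx(1 - i / n)

    def test_power_under_hazard_ratio_two(self, rng):
        # two planted groups of 100 (n = 200), exponential with hazard ratio 2
        rejections = 0
        group = np.repeat([True, False], 100)
        for _ in range(100):
            hazard = np.where(group, 2.0 / 1000, 1.0 / 1000)
            time = rng.exponential(1.0 / hazard)
            censor = rng.exponential(1000 / 0.25)  # ~20% censoring
            event = time <= censor
            observed = np.minimum(time, censor)
            statistic = logrank_statistic(observed, event, group)
            if sps.chi2.sf(statistic, df=1) < 0.05:
                rejections += 1
        assert rejections >= 90

    def test_quartile_survival_detects_planted_hazard_ratio(self, rng):
        # the full quartile pipeline on one seeded cohort with a strong effect
        config = CohortConfig(
            n_patients=400, hazard_ratio_high_vs_low=0.5,
            censoring_rate=0.2, er_effect_size=0.0,
        )
        patients, _ = simulate_cohort(config, rng)
        result = quartile_survival(patients, fit_km=False)
        assert result.p_value < 0.05

    def test_too_few_patients_raises(self):
        frame = _survival_frame([1, 2, 3], [1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match=">= 8"):
            quartile_survival(frame)


class TestPatientTableLoading:
    def test_column_mapping_and_event_codes(self, tmp_path):
        # synthetic table in a deposit-style layout with its own headers
        path = tmp_path / "clinical_synthetic.tsv"
        path.write_text(
            "barcode\tmiR140_reads\tisomiR140_reads\tER\tdist_met\tdays\tvital\n"
            "T1\t100.5\t150.2\tpositive\tno\t2000\t1\n"
            "T2\t80.0\t90.0\tnegative\tyes\t1500\t0\n"
        )
        frame = load_patient_table(
            path,
            column_map={
                "patient_id": "barcode",
                "mir_rpm": "miR140_reads",
                "isomir_rpm": "isomiR140_reads",
                "er_status": "ER",
                "metastasis": "dist_met",
                "survival_time": "days",
                "event": "vital",
            },
            event_codes={"1": "death", "0": "censored"},
        )
        assert list(frame.columns) == [
            "patient_id", "mir_rpm", "isomir_rpm", "er_status",
            "metastasis", "survival_time", "event",
        ]
        assert frame.loc[0, "event"] == "death"
        assert frame.loc[1, "metastasis"] == "yes"

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("patient_id\tmir_rpm\nX\t1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_patient_table(path)
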