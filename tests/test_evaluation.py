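import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrsynth import (
    DataTable,
    correlation_preservation_rate,
    evaluate,
    export_distribution_data,
    jaccard_categories,
    ks_statistic,
)
from ehrsynth.schema import ColumnKind, ColumnSpec, TableSchema


def brute_force_ks(x, y):
    """Independent oracle: sup over pooled points of |ECDF_x - ECDF_y|."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    points = np.concatenate([x, y])
    best = 0.0
    for p in points:
        fx = (x <= p).mean()
        fy = (y <= p).mean()
        best = max(best, abs(fx - fy))
    return best


class TestKSStatistic:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(size=37)
        assert ks_statistic(x, x) == 0.0

    def test_disjoint_supports_give_one(self):
        assert ks_statistic([1, 2], [3, 4]) == 1.0

    def test_hand_example(self):
        assert ks_statistic([1, 2], [1, 3]) == pytest.approx(0.5)

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            n, m = rng.integers(1, 30, size=2)
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            if rng.random() < 0.3:  # force ties across samples
                y = np.concatenate([y, rng.choice(x, size=min(3, n))])
            assert ks_statistic(x, y) == pytest.approx(
                brute_force_ks(x, y), abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_in_arguments(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=11), r.normal(size=7)
        assert ks_statistic(x, y) == ks_statistic(y, x)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])


class TestJaccard:
    def test_identical_sets_give_one(self):
        assert jaccard_categories(["a", "b", "a"], ["b", "a"]) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert jaccard_categories(["a"], ["b"]) == 0.0

    def test_partial_overlap_one_third(self):
        assert jaccard_categories(["a", "b"], ["b", "c"]) == pytest.approx(1 / 3)

    def test_symmetric(self):
        a, b = ["a", "b", "c"], ["b", "d"]
        assert jaccard_categories(a, b) == jaccard_categories(b, a)

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            jaccard_categories([], ["a"])


def three_col_tables(shift_pair=False):
    schema = TableSchema(
        tuple(ColumnSpec(c, ColumnKind.CONTINUOUS) for c in ("x", "y", "z"))
    )
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    real = pd.DataFrame(
        {"x": x, "y": x + 0.1 * rng.normal(size=200), "z": rng.normal(size=200)}
    )
    synth = real.copy()
    if shift_pair:
        synth["y"] = -real["y"]  # flips corr(x, y) from ~+1 to ~-1
    return (
        DataTable(schema=schema, frame=real),
        DataTable(schema=schema, frame=synth),
    )


class TestCorrelationPreservation:
    def test_identical_tables_give_100_percent(self):
        real, synth = three_col_tables()
        assert correlation_preservation_rate(real, synth, tau=0.1) == 100.0

    def test_tau_at_maximum_gap_gives_100_percent(self):
        real, synth = three_col_tables(shift_pair=True)
        assert correlation_preservation_rate(real, synth, tau=2.0) == 100.0

    def test_single_broken_pair_out_of_three(self):
        real, synth = three_col_tables(shift_pair=True)
        # flipping y breaks (x,y); (x,z) and (y,z) are both near-zero corr
        # but (y,z) flips sign too: only (x,z) is guaranteed preserved at
        # small tau, so use tau=0.2 where |delta| is tiny for the z pairs
        rate = correlation_preservation_rate(real, synth, tau=0.2)
        assert rate == pytest.approx(100 * 2 / 3, abs=1e-9)

    def test_monotone_in_tau(self):
        real, synth = three_col_tables(shift_pair=True)
        taus = [0.0, 0.1, 0.5, 1.0, 2.0]
        rates = [correlation_preservation_rate(real, synth, tau=t) for t in taus]
        assert rates == sorted(rates)

    def test_constant_column_excluded_with_warning(self):
        real, synth = three_col_tables()
        real.frame["z"] = 1.0
        synth.frame["z"] = 1.0
        with pytest.warns(UserWarning, match="constant column"):
            rate = correlation_preservation_rate(real, synth, tau=0.1)
        assert rate == 100.0


class TestEvaluate:
    def test_self_comparison_is_perfect(self, cohort_table):
        report = evaluate(cohort_table, cohort_table)
        assert all(v == 0.0 for v in report.ks.values())
        assert all(v == 1.0 for v in report.jaccard.values())
        assert report.preservation_rate == 100.0

    def test_mean_ks_is_mean_of_entries(self, cohort_table):
        other, _ = __import__("ehrsynth").generate_reference_cohort(seed=1)
        report = evaluate(cohort_table, other)
        assert report.mean_ks == pytest.approx(
            np.mean(list(report.ks.values())), abs=1e-12
        )

    def test_column_order_matches_schema(self, cohort_table):
        report = evaluate(cohort_table, cohort_table)
        assert list(report.ks) == [c.name for c in cohort_table.schema.continuous]
        assert list(report.jaccard) == [
            c.name for c in cohort_table.schema.categorical
        ]

    def test_schema_mismatch_rejected(self, cohort_table):
        real, _ = three_col_tables()
        with pytest.raises(ValueError):
            evaluate(cohort_table, real)

    def test_report_json_round_trip(self, cohort_table, tmp_path):
        import json

        report = evaluate(cohort_table, cohort_table)
        path = tmp_path / "report.json"
        report.save_json(path)
        with open(path) as fh:
            d = json.load(fh)
        assert d["mean_ks"] == report.mean_ks
        assert d["tau"] == 0.1


class TestExportDistributionData:
    def test_cdf_files_are_monotone_and_end_at_one(self, cohort_table, tmp_path):
        other, _ = __import__("ehrsynth").generate_reference_cohort(seed=9)
        files = export_distribution_data(cohort_table, other, tmp_path)
        cdfs = [f for f in files if f.name.startswith("cdf_")]
        assert len(cdfs) == cohort_table.schema.k
        for f in cdfs:
            df = pd.read_csv(f)
            for col in ("real_cdf", "synth_cdf"):
                assert (df[col].diff().dropna() >= 0).all()
                assert df[col].iloc[-1] == 1.0

    def test_category_counts_sum_to_n(self, cohort_table, tmp_path):
        other, _ = __import__("ehrsynth").generate_reference_cohort(seed=9)
        files = export_distribution_data(cohort_table, other, tmp_path)
        freqs = [f for f in files if f.name.startswith("freq_")]
        assert len(freqs) == cohort_table.schema.l
        for f in freqs:
            df = pd.read_csv(f)
            assert df["real_count"].sum() == cohort_table.n
            assert df["synth_count"].sum() == other.n

    def test_empty_synth_rejected(self, cohort_table, tmp_path):
        empty = DataTable(schema=cohort_table.schema)
        with pytest.raises(ValueError):
            export_distribution_data(cohort_table, empty, tmp_path)
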