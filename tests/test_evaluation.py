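"""Dataset clustering/splitting, metric suite, cross-validation, benchmark."""

import io

import numpy as np
import pandas as pd
import pytest

from isopoint.evaluation import (
    EvaluationReport,
    LabelledDataset,
    benchmark,
    cluster_and_average,
    cross_validate,
    metrics,
    split_dataset,
)
from isopoint.synthetic import GeneratorConfig, generate_pi_dataset


def _ds(seqs, values):
    return LabelledDataset(
        records=pd.DataFrame(
            {"id": [f"s{i}" for i in range(len(seqs))],
             "sequence": seqs, "value": values}
        )
    )


class TestClusterAndAverage:
    def test_duplicates_merged_with_mean_label(self):
        ds = cluster_and_average(_ds(["ACDK", "ACDK"], [5.0, 6.0]))
        assert len(ds) == 1
        assert ds.values[0] == pytest.approx(5.5)

    def test_all_distinct_unchanged(self):
        ds = cluster_and_average(_ds(["ACDK", "GGGG", "KKKK"], [5.0, 6.0, 9.0]))
        assert len(ds) == 3
        np.testing.assert_array_equal(ds.values, [5.0, 6.0, 9.0])

    def test_merge_counts_sum_to_original_n(self):
        ds = cluster_and_average(
            _ds(["A", "A", "B", "C", "C", "C"], [1, 2, 3, 4, 5, 6])
        )
        assert ds.records["merged_n"].sum() == 6

    def test_idempotence(self):
        once = cluster_and_average(_ds(["ACDK", "ACDK", "GG"], [5.0, 6.0, 7.0]))
        twice = cluster_and_average(once)
        pd.testing.assert_frame_equal(
            once.records[["sequence", "value"]].reset_index(drop=True),
            twice.records[["sequence", "value"]].reset_index(drop=True),
        )

    def test_pka_clustering_keyed_by_sequence_and_position(self):
        records = pd.DataFrame({
            "id": ["p", "p", "p"],
            "sequence": ["ACDK", "ACDK", "ACDK"],
            "value": [3.5, 4.5, 10.0],
            "position": [3, 3, 4],
            "residue": ["D", "D", "K"],
        })
        ds = cluster_and_average(LabelledDataset(records=records, kind="pKa"))
        assert len(ds) == 2
        merged = ds.records.set_index("position")["value"]
        assert merged[3] == pytest.approx(4.0)


class TestSplitDataset:
    def test_75_25_sizes(self):
        ds = generate_pi_dataset(GeneratorConfig(n=100, seed=1))
        train, test = split_dataset(ds, 0.25, seed=0)
        assert (len(train), len(test)) == (75, 25)
        assert train.split == "train75" and test.split == "test25"

    def test_disjoint_and_exhaustive(self):
        ds = generate_pi_dataset(GeneratorConfig(n=57, seed=2))
        train, test = split_dataset(ds, 0.25, seed=3)
        ids = set(train.records["id"]) | set(test.records["id"])
        assert len(ids) == 57
        assert not set(train.records["id"]) & set(test.records["id"])

    def test_seed_reproducible(self):
        ds = generate_pi_dataset(GeneratorConfig(n=40, seed=4))
        a = split_dataset(ds, 0.25, seed=9)[1]
        b = split_dataset(ds, 0.25, seed=9)[1]
        assert list(a.records["id"]) == list(b.records["id"])

    def test_too_small_rejected(self):
        ds = generate_pi_dataset(GeneratorConfig(n=3, seed=5))
        with pytest.raises(ValueError, match="small"):
            split_dataset(ds)


class TestMetrics:
    def test_perfect_prediction(self):
        rep = metrics([5.0, 6.0, 7.0], [5.0, 6.0, 7.0], 0.5)
        assert rep.rmse == 0 and rep.mae == 0 and rep.outliers == 0
        assert rep.r2_pearson == pytest.approx(1.0)

    def test_outlier_uses_strict_inequality(self):
        # errors 0.4 and 0.6 at threshold 0.5: exactly one outlier; an error
        # of exactly 0.5 is NOT an outlier.
        rep = metrics([5.4, 6.6], [5.0, 6.0], 0.5)
        assert rep.outliers == 1
        rep2 = metrics([5.5, 6.5], [5.0, 6.0], 0.5)
        assert rep2.outliers == 0

    def test_five_point_hand_computed_example(self):
        predicted = np.array([5.1, 6.4, 7.0, 4.8, 9.2])
        experimental = np.array([5.0, 6.0, 7.5, 5.0, 8.8])
        errors = predicted - experimental
        # Independent spreadsheet-style arithmetic, fully written out.
        exp_rmse = (sum(e * e for e in errors) / 5) ** 0.5
        exp_mae = sum(abs(e) for e in errors) / 5
        mx, my = predicted.mean(), experimental.mean()
        sxy = float(np.sum((predicted - mx) * (experimental - my)))
        sxx = float(np.sum((predicted - mx) ** 2))
        syy = float(np.sum((experimental - my) ** 2))
        exp_r2 = (sxy / (sxx * syy) ** 0.5) ** 2
        rep = metrics(predicted, experimental, 0.25)
        assert rep.rmse == pytest.approx(exp_rmse, abs=1e-12)
        assert rep.mae == pytest.approx(exp_mae, abs=1e-12)
        assert rep.r2_pearson == pytest.approx(exp_r2, abs=1e-12)
        assert rep.outliers == int(sum(abs(e) > 0.25 for e in errors))

    def test_rmse_at_least_mae(self, random_peptides):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(2, 12, 15)
            y_hat = y + rng.normal(0, 0.5, 15)
            rep = metrics(y_hat, y, 0.5)
            assert rep.rmse >= rep.mae >= 0

    def test_determination_can_go_negative(self):
        y = np.array([4.0, 5.0, 6.0, 7.0])
        rep = metrics(y[::-1], y, 0.5)
        assert rep.r2_determination < 0
        assert rep.r2_pearson >= 0

    def test_zero_variance_experimental_warns_nan(self):
        with pytest.warns(UserWarning, match="variance"):
            rep = metrics([5.0, 6.0], [7.0, 7.0], 0.5)
        assert np.isnan(rep.r2_pearson)

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError, match="RMSE"):
            EvaluationReport("m", rmse=0.1, mae=0.5, r2_pearson=1.0,
                             r2_determination=1.0, outliers=0, threshold=0.5, n=2)


class _ConstantModel:
    def __init__(self, value=None):
        self.value = value

    def fit(self, dataset):
        if self.value is None:
            self.value = float(np.mean(dataset.values))

    def predict(self, dataset):
        return np.full(len(dataset), self.value)


class TestCrossValidate:
    def test_folds_partition_indices(self):
        ds = generate_pi_dataset(GeneratorConfig(n=53, seed=6))
        per_fold, pooled = cross_validate(_ConstantModel, ds, folds=10, seed=0)
        assert len(per_fold) == 10
        assert pooled.n == 53

    def test_constant_model_pooled_rmse_is_sd_around_constant(self):
        ds = generate_pi_dataset(GeneratorConfig(n=60, seed=7))
        c = 7.0
        _, pooled = cross_validate(lambda: _ConstantModel(c), ds, folds=5, seed=1)
        expected = float(np.sqrt(np.mean((ds.values - c) ** 2)))
        assert pooled.rmse == pytest.approx(expected, abs=1e-12)

    def test_fold_assignment_seed_determinism(self):
        ds = generate_pi_dataset(GeneratorConfig(n=30, seed=8))
        a = cross_validate(_ConstantModel, ds, folds=3, seed=5)[0]
        b = cross_validate(_ConstantModel, ds, folds=3, seed=5)[0]
        assert [r.n for r in a] == [r.n for r in b]
        assert [r.rmse for r in a] == [r.rmse for r in b]

    def test_more_folds_than_records_rejected(self):
        ds = generate_pi_dataset(GeneratorConfig(n=5, seed=9))
        with pytest.raises(ValueError, match="folds"):
            cross_validate(_ConstantModel, ds, folds=10)


class TestBenchmark:
    def test_table_layout_and_ordering(self):
        ds = generate_pi_dataset(GeneratorConfig(n=40, seed=10))
        table = benchmark(["EMBOSS", "Dawson", "IPC_peptide"], ds, 0.25)
        assert list(table.columns) == [
            "method", "rmse", "mae", "r2_pearson", "r2_determination",
            "outliers", "n", "valid",
        ]
        rmse = table["rmse"].to_numpy()
        assert np.all(np.diff(rmse) >= 0)
        # Labels were generated from IPC_peptide, which must therefore win.
        assert table.iloc[0]["method"] == "IPC_peptide"

    def test_identical_methods_identical_reports(self):
        ds = generate_pi_dataset(GeneratorConfig(n=30, seed=11))
        from isopoint.charge import get_pka_set, isoelectric_point
        from isopoint.seqio import PolypeptideSequence

        fn = lambda s: isoelectric_point(PolypeptideSequence("q", s),
                                         get_pka_set("EMBOSS"))
        table = benchmark({"a": fn, "b": fn}, ds, 0.5)
        a = table[table["method"] == "a"].iloc[0]
        b = table[table["method"] == "b"].iloc[0]
        assert a["rmse"] == b["rmse"] and a["outliers"] == b["outliers"]

    def test_failing_method_marked_invalid_others_unaffected(self):
        ds = generate_pi_dataset(GeneratorConfig(n=30, seed=12))

        def boom(s):
            raise RuntimeError("no")

        from isopoint.charge import get_pka_set, isoelectric_point
        from isopoint.seqio import PolypeptideSequence

        ok = lambda s: isoelectric_point(PolypeptideSequence("q", s),
                                         get_pka_set("EMBOSS"))
        with pytest.warns(UserWarning, match="failed"):
            table = benchmark({"ok": ok, "bad": boom}, ds, 0.5)
        assert not table[table["method"] == "bad"]["valid"].iloc[0]
        assert table[table["method"] == "ok"]["valid"].iloc[0]

    def test_unknown_method_name_rejected(self):
        ds = generate_pi_dataset(GeneratorConfig(n=30, seed=13))
        with pytest.raises(KeyError, match="nope"):
            benchmark(["nope"], ds)


class TestTsvRoundTrip:
    def test_pi_dataset_round_trip(self):
        ds = generate_pi_dataset(GeneratorConfig(n=20, seed=14))
        buf = io.StringIO()
        ds.to_tsv(buf)
        buf.seek(0)
        back = LabelledDataset.from_tsv(buf)
        assert back.kind == "pI"
        pd.testing.assert_frame_equal(
            ds.records[["id", "sequence", "value"]], back.records
        )

    def test_pka_dataset_kind_inferred(self):
        from isopoint.synthetic import generate_pka_dataset

        ds = generate_pka_dataset(GeneratorConfig(n=3, seed=15))
        buf = io.StringIO()
        ds.to_tsv(buf)
        buf.seek(0)
        back = LabelledDataset.from_tsv(buf)
        assert back.kind == "pKa"
        assert len(back) == len(ds)
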