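import numpy as np
import pandas as pd
import pytest

from symptomnet.data_prep import (
    CUDIT_SCALES,
    SIMULTANEOUS_USE_SCALE,
    SymptomData,
    dichotomize_cudit,
    infer_cluster_labels,
    prepare_matrix,
    reliability,
    select_simultaneous_users,
    spearman_brown,
)
from symptomnet.errors import DataError


class TestSelectSimultaneousUsers:
    def test_never_excluded(self):
        assert select_simultaneous_users(["never"]).tolist() == [False]

    def test_hardly_ever_included(self):
        assert select_simultaneous_users(["hardly ever"]).tolist() == [True]

    def test_almost_always_included(self):
        assert select_simultaneous_users(["almost always"]).tolist() == [True]

    def test_full_scale_cutoff(self):
        mask = select_simultaneous_users(list(SIMULTANEOUS_USE_SCALE))
        assert mask.tolist() == [False, True, True, True, True, True]

    def test_missing_excluded(self):
        mask = select_simultaneous_users(["often", None, float("nan"), "NA"])
        assert mask.tolist() == [True, False, False, False]

    def test_unknown_category_named(self):
        with pytest.raises(DataError, match="sometimes"):
            select_simultaneous_users(["sometimes"])


class TestDichotomizeCudit:
    def test_item3_never_is_absence(self):
        assert dichotomize_cudit(3, "never") == 0

    @pytest.mark.parametrize("item", range(3, 11))
    def test_items_3_to_10_anything_above_never(self, item):
        scale = CUDIT_SCALES[item]
        assert [dichotomize_cudit(item, ans) for ans in scale] == [0, 1, 1, 1, 1]

    def test_item1_lowest_category_absence(self):
        assert dichotomize_cudit(1, "less than a month") == 0
        assert dichotomize_cudit(1, "monthly") == 1

    def test_item2_lowest_category_absence(self):
        assert dichotomize_cudit(2, "one or two h") == 0
        for answer in CUDIT_SCALES[2][1:]:
            assert dichotomize_cudit(2, answer) == 1

    def test_off_scale_answer_rejected(self):
        with pytest.raises(DataError, match="weekly.*item 2|not on the scale"):
            dichotomize_cudit(2, "weekly")

    def test_bad_item_id(self):
        with pytest.raises(DataError):
            dichotomize_cudit(11, "never")


class TestPrepareMatrix:
    def _frame(self, matrix, labels=None):
        labels = labels or [f"A{i + 1}" for i in range(np.shape(matrix)[1])]
        return pd.DataFrame(matrix, columns=labels)

    def test_complete_mixed_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(60, 4))
        m[0] = [0, 1, 0, 1]
        m[1] = [1, 0, 1, 0]
        data, log = prepare_matrix(self._frame(m), min_rows=10)
        assert np.array_equal(data.matrix, m)
        assert log["n_dropped_rows"] == 0
        assert log["dropped_columns"] == []

    def test_all_ones_column_dropped_and_logged(self):
        m = np.array([[1, 0, 1], [1, 1, 0]] * 30)
        data, log = prepare_matrix(self._frame(m), min_rows=10)
        assert data.symptom_labels == ["A2", "A3"]
        assert log["dropped_columns"][0]["label"] == "A1"
        assert "endorsed by all" in log["dropped_columns"][0]["reason"]

    def test_all_zeros_column_dropped(self):
        m = np.array([[0, 0, 1], [0, 1, 0]] * 30)
        data, log = prepare_matrix(self._frame(m), min_rows=10)
        assert data.symptom_labels == ["A2", "A3"]
        assert "endorsed by no" in log["dropped_columns"][0]["reason"]

    def test_rows_with_missing_listwise_deleted(self):
        m = np.array([[0.0, 1], [1, 0], [np.nan, 1], [1, 1], [0, 0]] * 20)
        data, log = prepare_matrix(self._frame(m), min_rows=10)
        assert log["n_dropped_rows"] == 20
        assert data.n == 80

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, size=(80, 5)).astype(float)
        m[rng.random(m.shape) < 0.05] = np.nan
        m[:, 2] = 1.0  # degenerate column
        once, _ = prepare_matrix(self._frame(m), min_rows=10)
        twice, log2 = prepare_matrix(once.to_frame(), min_rows=10)
        assert np.array_equal(once.matrix, twice.matrix)
        assert log2["n_dropped_rows"] == 0 and log2["dropped_columns"] == []

    def test_dropping_degenerate_column_preserves_rates(self):
        rng = np.random.default_rng(2)
        m = rng.integers(0, 2, size=(100, 4)).astype(float)
        m[0] = [0, 1, 0, 1]
        with_deg = np.column_stack([m, np.ones(100)])
        frame = pd.DataFrame(with_deg, columns=["A1", "A2", "A3", "A4", "A5"])
        data, _ = prepare_matrix(frame, min_rows=10)
        base, _ = prepare_matrix(self._frame(m), min_rows=10)
        assert np.allclose(data.endorsement_rates(), base.endorsement_rates())

    def test_too_few_columns_error(self):
        m = np.column_stack([np.ones(60), np.zeros(60), np.r_[np.zeros(30), np.ones(30)]])
        with pytest.raises(DataError, match="fewer than 2"):
            prepare_matrix(self._frame(m), min_rows=10)

    def test_min_rows_error(self):
        m = np.array([[0, 1], [1, 0]] * 10)
        with pytest.raises(DataError, match="below the minimum"):
            prepare_matrix(self._frame(m), min_rows=50)

    def test_non_binary_entry_rejected(self):
        m = np.array([[0, 2.0], [1, 0]] * 30)
        with pytest.raises(DataError, match="expected 0, 1 or missing"):
            prepare_matrix(self._frame(m), min_rows=10)

    def test_na_string_recognized_via_csv(self, tmp_path):
        path = tmp_path / "d.csv"
        rows = ["A1,C1"] + ["0,1", "1,NA", "1,0", ","] * 20
        path.write_text("\n".join(rows), encoding="utf-8")
        from symptomnet.data_prep import read_symptom_csv

        data, log = prepare_matrix(read_symptom_csv(path), min_rows=10)
        assert log["n_dropped_rows"] == 40
        assert data.cluster_labels == ["alcohol", "cannabis"]


class TestSymptomData:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(DataError, match="unique"):
            SymptomData(np.zeros((2, 2), dtype=np.int8), ["A1", "A1"], ["alcohol"] * 2)

    def test_cluster_inference(self):
        assert infer_cluster_labels(["A1", "C2"]) == ["alcohol", "cannabis"]
        with pytest.raises(DataError):
            infer_cluster_labels(["X1"])

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        data = SymptomData(
            rng.integers(0, 2, (20, 3)), ["A1", "A2", "C1"],
            ["alcohol", "alcohol", "cannabis"],
        )
        path = tmp_path / "data.csv"
        data.to_csv(path)
        back = SymptomData.from_frame(pd.read_csv(path))
        assert np.array_equal(back.matrix, data.matrix)
        assert back.cluster_labels == data.cluster_labels


class TestReliability:
    def test_parallel_items_kr20_is_one(self):
        col = np.array([0, 1] * 30)
        matrix = np.column_stack([col] * 5)
        report = reliability(matrix, split_seed=0)
        assert report.kr20 == pytest.approx(1.0, abs=1e-12)

    def test_sample_independent_items_kr20_zero(self):
        # all four (x1, x2) combinations equally often -> sample covariance 0,
        # so the total variance equals the sum of the item variances exactly
        matrix = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 10)
        report = reliability(matrix, split_seed=0)
        assert report.kr20 == pytest.approx(0.0, abs=1e-12)

    def test_spearman_brown_formula(self):
        assert spearman_brown(0.6) == pytest.approx(0.75, abs=1e-15)

    def test_kr20_matches_direct_oracle(self):
        rng = np.random.default_rng(4)
        matrix = rng.integers(0, 2, size=(40, 6))
        while np.var(matrix.sum(axis=1)) == 0:
            matrix = rng.integers(0, 2, size=(40, 6))
        report = reliability(matrix, split_seed=1)
        # independent direct-formula computation
        k = 6
        p_i = matrix.mean(axis=0)
        sigma2 = np.var(matrix.sum(axis=1))
        expected = k / (k - 1) * (1 - np.sum(p_i * (1 - p_i)) / sigma2)
        assert report.kr20 == pytest.approx(expected, abs=1e-12)

    def test_split_halves_partition_items(self):
        rng = np.random.default_rng(5)
        matrix = rng.integers(0, 2, size=(50, 7))
        report = reliability(matrix, split_seed=3)
        first, second = report.split
        assert sorted(first + second) == list(range(7))
        assert abs(len(first) - len(second)) <= 1

    def test_split_seed_reproducible(self):
        rng = np.random.default_rng(6)
        matrix = rng.integers(0, 2, size=(50, 6))
        a = reliability(matrix, split_seed=11)
        b = reliability(matrix, split_seed=11)
        assert a.split == b.split and a.split_half == b.split_half

    def test_zero_total_variance_error(self):
        matrix = np.array([[0, 1], [0, 1], [0, 1]])
        with pytest.raises(DataError, match="variance"):
            reliability(matrix, split_seed=0)


class TestRawResponses:
    def test_screen_and_dichotomize_end_to_end(self):
        from symptomnet.data_prep import RawResponses

        answers = ["never", "often", "almost always", None]
        aud = pd.DataFrame(np.array([[0, 1], [1, 0], [1, 1], [0, 0]]))
        # columns map positionally to CUDIT items 1 and 2
        cudit = pd.DataFrame(
            {
                "q1": ["monthly", "less than a month", "weekly", "monthly"],
                "q2": ["one or two h", "one or two h", "five or six h", "one or two h"],
            }
        )
        raw = RawResponses(answers, cudit, aud)
        frame = raw.to_binary_frame()
        # rows 1 and 2 pass the screen
        assert list(frame.columns) == ["A1", "A2", "C1", "C2"]
        assert frame.shape == (2, 4)
        assert frame["C1"].tolist() == [0, 1]
        assert frame["C2"].tolist() == [0, 1]

    def test_missing_item_stays_missing(self):
        from symptomnet.data_prep import RawResponses

        raw = RawResponses(
            ["often", "seldom"],
            pd.DataFrame({"q1": ["monthly", None]}),
            pd.DataFrame(np.array([[1], [0]])),
        )
        frame = raw.to_binary_frame()
        assert frame["C1"].isna().tolist() == [False, True]
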