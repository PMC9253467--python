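"""Grid building, exclusions, splits and normalization of the datasets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from leukotransit.sweep_dataset import (
    CANONICAL_IMPACTION_PAIRS,
    PAPER_COMPAT_AR_VALUES,
    STUDY_AR_VALUES,
    STUDY_RE_VALUES,
    SampleTable,
    build_grid,
    exclude_impaction,
    make_motion_table,
    make_time_table,
    split_dataset,
    toy_surface_table,
)


class TestGrid:
    def test_study_grid_counts(self):
        assert len(STUDY_RE_VALUES) == 11 and len(STUDY_AR_VALUES) == 10
        assert len(build_grid(STUDY_RE_VALUES, STUDY_AR_VALUES)) == 110

    def test_compat_grid_reaches_121_minus_6(self):
        grid = build_grid(STUDY_RE_VALUES, PAPER_COMPAT_AR_VALUES)
        assert len(grid) == 121
        kept = exclude_impaction(grid, pairs=CANONICAL_IMPACTION_PAIRS)
        assert len(kept) == 115

    def test_toy_grid_re_major_order(self):
        grid = build_grid([0.2, 0.1], [0.5, 0.9])
        assert grid.cases() == [(0.1, 0.5), (0.1, 0.9), (0.2, 0.5), (0.2, 0.9)]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_grid([0.1, 0.1], [0.5])

    def test_empty_exclusion_is_identity(self):
        grid = build_grid([0.1, 0.2], [0.5, 0.9])
        assert exclude_impaction(grid, pairs=[]).cases() == grid.cases()

    def test_unknown_pair_rejected(self):
        grid = build_grid([0.1, 0.2], [0.5, 0.9])
        with pytest.raises(ValueError, match="not in grid"):
            exclude_impaction(grid, pairs=[(0.3, 0.5)])

    def test_excluding_everything_rejected(self):
        grid = build_grid([0.1], [0.5])
        with pytest.raises(ValueError, match="unusable"):
            exclude_impaction(grid, pairs=[(0.1, 0.5)])

    def test_exclusion_from_outcomes_frame(self):
        grid = build_grid([0.1, 0.2], [0.5, 0.9])
        outcomes = pd.DataFrame(
            {"Re": [0.1, 0.1, 0.2, 0.2], "AR": [0.5, 0.9, 0.5, 0.9],
             "outcome": ["impaction", "transit", "transit", "transit"]}
        )
        assert exclude_impaction(grid, outcomes=outcomes).cases() == [
            (0.1, 0.9), (0.2, 0.5), (0.2, 0.9)
        ]


class TestSplit:
    def test_115_at_60_20_20(self):
        labels = split_dataset(115, (0.6, 0.2, 0.2), seed=0)
        counts = pd.Series(labels).value_counts()
        assert counts["train"] == 69 and counts["val"] == 23 and counts["test"] == 23

    def test_all_train(self):
        assert set(split_dataset(10, (1.0, 0.0, 0.0), seed=0)) == {"train"}

    def test_two_seeds_differ_same_counts(self):
        a = split_dataset(50, seed=1)
        b = split_dataset(50, seed=2)
        assert not np.array_equal(a, b)
        assert pd.Series(a).value_counts().to_dict() == pd.Series(b).value_counts().to_dict()

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            split_dataset(10, (0.5, 0.2, 0.2), seed=0)
        with pytest.raises(ValueError):
            split_dataset(10, (1.2, -0.1, -0.1), seed=0)

    def test_assignment_keyed_to_identity_not_arrival_order(self):
        # shuffling the rows leaves each (Re, AR)'s split label unchanged
        df = toy_surface_table(5, 5, seed=7).df
        shuffled = df.drop(columns="split").sample(frac=1.0, random_state=0)
        table2 = SampleTable.from_frame(shuffled, ["Re", "AR"], "transit_time", seed=7)
        merged = df.merge(table2.df, on=["Re", "AR"], suffixes=("_a", "_b"))
        assert (merged["split_a"] == merged["split_b"]).all()


class TestNormalization:
    @given(st.floats(-1e3, 1e3), st.floats(1e-3, 1e3))
    def test_round_trip(self, lo, width):
        table = toy_surface_table(4, 4, seed=0)
        table.norm["transit_time"] = (lo, lo + width)
        x = np.linspace(lo, lo + width, 11)
        back = table.denormalize_column(table.normalize_column(x, "transit_time"), "transit_time")
        assert np.allclose(back, x, rtol=1e-12, atol=1e-12 * width)

    def test_normalized_training_range(self):
        table = toy_surface_table(6, 6, seed=1)
        X, Y = table.normalized_arrays("train")
        assert X.min() >= -1 - 1e-12 and X.max() <= 1 + 1e-12
        assert Y.min() >= -1 - 1e-12 and Y.max() <= 1 + 1e-12

    def test_norm_fitted_on_training_split_only(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
        df["split"] = ["train"] * 5 + ["val"] * 3 + ["test"] * 2  # extremes not in train
        table = SampleTable(df, ["x"], "y")
        assert table.norm["x"] == (0.0, 4.0)  # max of training rows, not 9
        assert table.norm["y"] == (0.0, 4.0)

    def test_degenerate_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        df["split"] = "train"
        with pytest.raises(ValueError, match="degenerate"):
            SampleTable(df, ["x"], "y")


class TestTimeTable:
    def _summaries(self, n=8):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "Re": np.linspace(0.1, 0.2, n),
                "AR": np.linspace(0.5, 0.95, n),
                "outcome": "transit",
                "transit_time": rng.uniform(0.005, 0.05, n),
            }
        )

    def test_row_count_preserved(self):
        table = make_time_table(self._summaries(8), seed=0)
        assert len(table) == 8
        assert table.input_columns == ["Re", "AR"]
        assert table.target_column == "transit_time"

    def test_impaction_row_rejected(self):
        df = self._summaries(5)
        df.loc[2, "outcome"] = "impaction"
        with pytest.raises(ValueError, match="exclude impaction"):
            make_time_table(df)

    def test_single_row_rejected_with_actionable_message(self):
        with pytest.raises(ValueError, match="at least two"):
            make_time_table(self._summaries(1))


class _FakeTraj:
    def __init__(self, Re, AR, n, seed=0):
        rng = np.random.default_rng(seed)
        self.Re, self.AR = Re, AR
        self.displacement = np.cumsum(rng.uniform(0.1, 1.0, n)) * 1e-6
        self._data = {
            "R_max": 5e-6 + 1e-7 * rng.standard_normal(n),
            "V_y": rng.uniform(0, 4e-3, n),
            "F_l": rng.standard_normal(n) * 1e-5,
            "F_d": rng.standard_normal(n) * 1e-6,
        }

    def series(self, name):
        return self._data[name]


class TestMotionTable:
    def test_one_row_per_stored_sample(self):
        trajs = [_FakeTraj(0.1, 0.8, 17), _FakeTraj(0.2, 0.6, 23)]
        table = make_motion_table(trajs, "R_max", seed=0)
        assert len(table) == 40
        assert table.input_columns == ["Re", "AR", "displacement"]

    def test_displacement_nondecreasing_within_case(self):
        trajs = [_FakeTraj(0.1, 0.8, 30), _FakeTraj(0.2, 0.6, 30, seed=1)]
        table = make_motion_table(trajs, "V_y", seed=0)
        for _, block in table.df.groupby(["Re", "AR"]):
            assert np.all(np.diff(block["displacement"].to_numpy()) >= 0)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="unknown target"):
            make_motion_table([_FakeTraj(0.1, 0.8, 5)], "pressure")


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        table = toy_surface_table(5, 5, seed=3)
        path = tmp_path / "table.csv"
        table.save(path)
        loaded = SampleTable.load(path)
        pd.testing.assert_frame_equal(loaded.df, table.df)
        assert loaded.norm == table.norm
        assert loaded.seed == table.seed
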