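import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazecnn.preprocess import (
    assemble,
    exclude_participants,
    exclusion_from_proportions,
    fill_missing,
    pad_or_truncate,
    preprocess_dataset,
)


class TestFillMissing:
    def test_missing_cells_become_central_fixation(self, geometry):
        trace = np.array([[np.nan, 1.0], [100.0, np.nan], [np.nan, np.nan]])
        out = fill_missing(trace, geometry)
        np.testing.assert_array_equal(out[:, 0], [1279.5, 100.0, 1279.5])
        np.testing.assert_array_equal(out[:, 1], [1.0, 719.5, 719.5])

    def test_fully_observed_trace_unchanged(self, geometry):
        trace = np.arange(10.0).reshape(5, 2)
        np.testing.assert_array_equal(fill_missing(trace, geometry), trace)

    def test_fully_missing_trace_becomes_constant_fixation(self, geometry):
        out = fill_missing(np.full((5, 2), np.nan), geometry)
        np.testing.assert_array_equal(out, np.tile([1279.5, 719.5], (5, 1)))


class TestPadOrTruncate:
    def test_short_trace_padded_with_fixation(self, geometry):
        out = pad_or_truncate(np.ones((550, 2)), 600, geometry)
        assert out.shape == (600, 2)
        np.testing.assert_array_equal(out[550:], np.tile([1279.5, 719.5], (50, 1)))
        np.testing.assert_array_equal(out[:550], np.ones((550, 2)))

    def test_exact_length_unchanged(self, geometry):
        trace = np.random.default_rng(0).normal(size=(600, 2))
        np.testing.assert_array_equal(pad_or_truncate(trace, 600, geometry), trace)

    def test_long_trace_truncated(self, geometry):
        trace = np.arange(603 * 2, dtype=float).reshape(603, 2)
        out = pad_or_truncate(trace, 600, geometry)
        np.testing.assert_array_equal(out, trace[:600])

    def test_nonpositive_length_rejected(self, geometry):
        with pytest.raises(ValueError):
            pad_or_truncate(np.ones((10, 2)), 0, geometry)

    @given(n=st.integers(0, 700))
    @settings(max_examples=25, deadline=None)
    def test_output_always_fixed_length_and_finite(self, geometry, n):
        rng = np.random.default_rng(n)
        trace = rng.normal(1000, 100, size=(n, 2))
        trace[rng.random(trace.shape) < 0.2] = np.nan
        out = pad_or_truncate(fill_missing(trace, geometry), 600, geometry)
        assert out.shape == (600, 2)
        assert np.isfinite(out).all()

    def test_fill_and_pad_commute_on_observed_traces(self, geometry):
        trace = np.random.default_rng(1).normal(1000, 50, size=(400, 2))
        a = pad_or_truncate(fill_missing(trace, geometry), 600, geometry)
        b = fill_missing(pad_or_truncate(trace, 600, geometry), geometry)
        np.testing.assert_array_equal(a, b)


class TestAssemble:
    def _trials(self, n, rng):
        return pd.DataFrame(
            {
                "participant_id": ["p1"] * n,
                "trial_index": np.arange(1, n + 1),
                "target_location": rng.integers(0, 6, n),
                "distractor_location": [np.nan] * n,
                "rt_ms": 500.0,
                "n_recorded_samples": 10,
            }
        )

    def test_tensor_shape_and_feature_order(self):
        rng = np.random.default_rng(0)
        traces = [rng.normal(size=(600, 2)) for _ in range(2)]
        tm, labels = assemble(traces, self._trials(2, rng), semantics="target")
        assert tm.values.shape == (2, 2, 600)
        np.testing.assert_array_equal(tm.values[0, 0], traces[0][:, 0])  # x first
        np.testing.assert_array_equal(tm.values[0, 1], traces[0][:, 1])

    def test_labels_follow_semantics_column(self):
        rng = np.random.default_rng(0)
        trials = self._trials(1, rng)
        trials.loc[0, "target_location"] = 4
        _, labels = assemble([np.zeros((600, 2))], trials, semantics="target")
        assert labels.tolist() == [4]

    def test_label_order_tracks_tensor_rows_on_shuffled_input(self):
        rng = np.random.default_rng(3)
        trials = self._trials(5, rng).sample(frac=1.0, random_state=1).reset_index(drop=True)
        traces = [np.full((10, 2), float(i)) for i in trials["trial_index"]]
        tm, labels = assemble(traces, trials, semantics="target")
        for row, (key, lab) in enumerate(zip(tm.trial_order, labels)):
            i = trials.index[trials["trial_index"] == key[1]][0]
            assert tm.values[row, 0, 0] == float(trials.loc[i, "trial_index"])
            assert lab == trials.loc[i, "target_location"]

    def test_distractor_semantics_requires_present_rows(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="subset"):
            assemble([np.zeros((10, 2))], self._trials(1, rng), semantics="distractor")

    def test_preprocess_dataset_full_window(self, small_dataset):
        tm, labels = preprocess_dataset(small_dataset, semantics="target")
        assert tm.values.shape == (len(small_dataset.trials), 2, 600)
        assert np.isfinite(tm.values).all()
        assert set(labels) <= set(range(6))


class TestExclusion:
    def test_excess_missing_participant_flagged(self):
        props = {f"p{i}": 0.1 for i in range(9)}
        props["p9"] = 0.9
        rep = exclusion_from_proportions(props)
        vals = np.array(list(props.values()))
        assert rep.mean == pytest.approx(vals.mean())
        assert rep.sd == pytest.approx(vals.std(ddof=1))
        assert rep.threshold == pytest.approx(vals.mean() + 2 * vals.std(ddof=1))
        assert rep.threshold == pytest.approx(0.686, abs=1e-4)
        assert rep.excluded == ["p9"]

    def test_identical_proportions_exclude_nobody(self):
        rep = exclusion_from_proportions({f"p{i}": 0.1 for i in range(5)})
        assert rep.sd == 0.0 and rep.threshold == pytest.approx(0.1)
        assert rep.excluded == []

    def test_spread_below_threshold_excludes_nobody(self):
        rep = exclusion_from_proportions({"a": 0.10, "b": 0.12, "c": 0.14, "d": 0.16})
        assert rep.excluded == []

    def test_invariant_to_participant_ordering(self):
        rng = np.random.default_rng(7)
        props = {f"p{i}": float(v) for i, v in enumerate(rng.random(12))}
        rep1 = exclusion_from_proportions(props)
        shuffled = {k: props[k] for k in reversed(list(props))}
        rep2 = exclusion_from_proportions(shuffled)
        assert set(rep1.excluded) == set(rep2.excluded)
        assert rep1.threshold == pytest.approx(rep2.threshold)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            exclusion_from_proportions({"p0": 0.1})

    def test_dataset_path_counts_missing_samples_only_while_recorded(self, three_trial_dataset):
        rep = exclude_participants(three_trial_dataset)
        # p1: trial 1 has 2/3 rows with a missing coordinate, trial 2 none
        assert rep.proportions["p1"] == pytest.approx(np.mean([2 / 3, 0.0]))
        assert rep.proportions["p2"] == pytest.approx(1.0)
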