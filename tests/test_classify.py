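"""Dataset assembly, splitting, greedy selection, trees, and evaluation."""

import numpy as np
import pandas as pd
import pytest

from fibroegm.classify import (
    EvalReport,
    SplitSpec,
    TASK_COLUMNS,
    assemble_dataset,
    evaluate,
    greedy_select,
    height_sweep,
    repeated_holdout,
    split,
    train_tree,
)
from fibroegm.errors import DataError, ParameterError
from fibroegm.features import FEATURE_NAMES


def make_table(n_per_class=60, effect=3.0, seed=0, noise_features=False):
    """Synthetic two-class feature table; `duration` carries the signal."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, shift in (("non-fibrotic", 0.0), ("fibrotic", effect)):
        for _ in range(n_per_class):
            f = {name: rng.normal() for name in FEATURE_NAMES}
            if not noise_features:
                f["duration"] += shift
            rows.append(
                dict(
                    binary_label=label,
                    density_class="none" if label == "non-fibrotic" else "60",
                    transmurality_class="none" if label == "non-fibrotic" else "2",
                    provenance="simulated",
                    **f,
                )
            )
    return pd.DataFrame(rows)


class TestAssembleDataset:
    def test_concatenation_row_count(self):
        sim = make_table(10)
        sub = make_table(5)
        sub = sub[sub.binary_label == "non-fibrotic"].assign(
            provenance="control-substitute"
        )
        out = assemble_dataset(sim, sub)
        assert len(out) == len(sim) + len(sub)
        assert set(out.provenance) == {"simulated", "control-substitute"}

    def test_no_substitutes_is_valid(self):
        sim = make_table(10)
        assert len(assemble_dataset(sim, None)) == len(sim)

    def test_fibrotic_substitute_rejected(self):
        sim = make_table(10)
        bad = make_table(5)  # contains fibrotic rows
        with pytest.raises(DataError):
            assemble_dataset(sim, bad)


class TestSplit:
    def test_70_15_15_sizes_on_balanced_100(self):
        df = make_table(50)  # 100 rows, 2 balanced classes
        train, val, test = split(df, SplitSpec(seed=0), "binary")
        assert (len(train), len(val), len(test)) == (70, 15, 15)

    def test_every_class_in_every_subset(self):
        df = make_table(5)
        for subset in split(df, SplitSpec(seed=1), "binary"):
            assert set(subset.binary_label) == {"fibrotic", "non-fibrotic"}

    def test_deterministic_under_seed(self):
        df = make_table(30)
        a = split(df, SplitSpec(seed=4), "binary")
        b = split(df, SplitSpec(seed=4), "binary")
        for x, y in zip(a, b):
            assert list(x.index) == list(y.index)

    def test_partition_is_exact(self):
        df = make_table(30)
        train, val, test = split(df, SplitSpec(seed=2), "binary")
        idx = sorted(list(train.index) + list(val.index) + list(test.index))
        assert idx == sorted(df.index)

    def test_tiny_class_rejected(self):
        df = make_table(10)
        df = pd.concat([df[df.binary_label == "non-fibrotic"],
                        df[df.binary_label == "fibrotic"].head(2)])
        with pytest.raises(DataError):
            split(df, SplitSpec(seed=0), "binary")


class TestGreedySelect:
    def test_perfectly_separating_feature_selected_first(self):
        df = make_table(60, effect=10.0)
        train, val, _ = split(df, SplitSpec(seed=0), "binary")
        feats = greedy_select(train, val, "binary")
        assert feats[0] == "duration"
        assert len(feats) <= 2

    def test_duplicated_feature_pruned_by_correlation(self):
        df = make_table(60, effect=10.0)
        df["p2p"] = df["duration"] * 2.0 + 1.0  # corr = 1 with duration
        train, val, _ = split(df, SplitSpec(seed=0), "binary")
        feats = greedy_select(train, val, "binary")
        assert not {"duration", "p2p"}.issubset(set(feats))

    def test_pure_noise_features_stop_early_near_chance(self):
        df = make_table(60, noise_features=True, seed=3)
        train, val, _ = split(df, SplitSpec(seed=0), "binary")
        feats = greedy_select(train, val, "binary")
        assert len(feats) <= 2

    def test_selected_features_obey_correlation_bound(self):
        df = make_table(80, effect=2.0, seed=5)
        train, val, _ = split(df, SplitSpec(seed=0), "binary")
        feats = greedy_select(train, val, "binary")
        corr = train[list(FEATURE_NAMES)].corr().abs()
        for i, a in enumerate(feats):
            for b in feats[i + 1 :]:
                assert corr.loc[a, b] <= 0.6 + 1e-12


class TestTrainAndEvaluate:
    def test_threshold_separable_data_depth_one(self):
        df = make_table(30, effect=50.0)
        model = train_tree(df, ["duration"], "binary")
        assert model.tree.get_depth() == 1
        _, metrics = evaluate(model, df)
        assert metrics["accuracy"] == 100.0

    def test_conflicting_duplicate_rows_do_not_crash(self):
        df = make_table(30, effect=0.0, seed=7)
        df[list(FEATURE_NAMES)] = 1.0  # identical rows, conflicting labels
        model = train_tree(df, list(FEATURE_NAMES), "binary")
        _, metrics = evaluate(model, df)
        assert metrics["accuracy"] < 100.0

    def test_single_class_training_rejected(self):
        df = make_table(30)
        with pytest.raises(DataError):
            train_tree(df[df.binary_label == "fibrotic"], ["duration"], "binary")

    def test_hand_computed_confusion_metrics(self):
        # truth rows: 10 non-fibrotic (8 right), 10 fibrotic (9 right)
        classes = ["fibrotic", "non-fibrotic"]
        df = make_table(30, effect=50.0)
        model = train_tree(df, ["duration"], "binary")

        class Stub:
            features = ["duration"]
            task = "binary"
            seed = 0

            class tree:
                classes_ = np.array(classes)

                @staticmethod
                def predict(X):
                    return np.array(pred)

        truth = ["non-fibrotic"] * 10 + ["fibrotic"] * 10
        pred = (["non-fibrotic"] * 8 + ["fibrotic"] * 2
                + ["fibrotic"] * 9 + ["non-fibrotic"] * 1)
        test = pd.DataFrame({"binary_label": truth, "duration": 0.0})
        cm, metrics = evaluate(Stub(), test, classes=["non-fibrotic", "fibrotic"])
        assert cm.tolist() == [[8, 2], [1, 9]]
        assert metrics["accuracy"] == pytest.approx(85.0)
        assert metrics["sensitivity"] == pytest.approx(90.0)
        assert metrics["specificity"] == pytest.approx(80.0)

    def test_deterministic_tree_under_seed(self):
        df = make_table(50, effect=1.0, seed=2)
        a = train_tree(df, list(FEATURE_NAMES), "binary", seed=3)
        b = train_tree(df, list(FEATURE_NAMES), "binary", seed=3)
        assert np.array_equal(a.tree.tree_.feature, b.tree.tree_.feature)
        assert np.array_equal(a.tree.tree_.threshold, b.tree.tree_.threshold)


class TestRepeatedHoldout:
    def test_separable_dataset_reaches_perfect_accuracy(self):
        df = make_table(40, effect=50.0)
        rep = repeated_holdout(df, "binary", n_realizations=3, base_seed=0)
        assert rep.accuracy_mean == 100.0
        assert rep.accuracy_se == 0.0

    def test_label_permutation_gives_chance_level(self):
        df = make_table(60, effect=50.0, seed=11)
        rng = np.random.default_rng(0)
        for col in ("binary_label", "density_class", "transmurality_class"):
            df[col] = rng.permutation(df[col].to_numpy())
        # permuting labels jointly breaks the label-consistency invariant;
        # restore it by reassigning the dependent columns from binary
        df["density_class"] = np.where(df.binary_label == "fibrotic", "60", "none")
        df["transmurality_class"] = np.where(
            df.binary_label == "fibrotic", "2", "none")
        rep = repeated_holdout(df, "binary", n_realizations=20, base_seed=0)
        se = max(rep.accuracy_se, 1.0)
        assert abs(rep.accuracy_mean - 50.0) < 3 * se + 5.0

    def test_validation_test_agreement(self):
        df = make_table(60, effect=3.0, seed=4)
        rep = repeated_holdout(df, "binary", n_realizations=20, base_seed=1)
        gap = abs(rep.validation_accuracy_mean - rep.accuracy_mean)
        assert gap < 3 * (rep.accuracy_se * np.sqrt(2)) + 5.0


class TestHeightSweep:
    def test_height_zero_equals_standard_test_accuracy(self):
        df = make_table(40, effect=50.0)
        model = train_tree(df, ["duration"], "binary")
        _, metrics = evaluate(model, df)
        table = height_sweep(model, {0.0: df, 1.0: df})
        assert table.accuracy.iloc[0] == pytest.approx(metrics["accuracy"])

    def test_heights_must_start_at_zero_ascending(self):
        df = make_table(10, effect=50.0)
        model = train_tree(df, ["duration"], "binary")
        with pytest.raises(ParameterError):
            height_sweep(model, {1.0: df, 0.0: df})
        with pytest.raises(ParameterError):
            height_sweep(model, {-1.0: df, 0.0: df})
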