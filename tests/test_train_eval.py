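"""Split protocol, early stopping, metrics vs brute-force oracles, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from sarcoseg import networks as nw
from sarcoseg import train_eval as te
from sarcoseg.errors import ValidationError


def brute_force_confusion(pred, gt):
    tp = fp = tn = fn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            if pred[r, c] and gt[r, c]:
                tp += 1
            elif pred[r, c] and not gt[r, c]:
                fp += 1
            elif not pred[r, c] and gt[r, c]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def brute_force_hausdorff(a, b, percentile, spacing):
    pa = np.argwhere(a) * np.asarray(spacing)
    pb = np.argwhere(b) * np.asarray(spacing)
    d = cdist(pa, pb)
    d_ab = np.percentile(d.min(axis=1), percentile)
    d_ba = np.percentile(d.min(axis=0), percentile)
    return max(d_ab, d_ba)


class TestPatientSplit:
    def make_manifest(self, n_patients, slices=4):
        return pd.DataFrame(
            {
                "patient": np.repeat([f"p{i:03d}" for i in range(n_patients)], slices),
                "slice_index": list(range(slices)) * n_patients,
            }
        )

    def test_45_patients_split_36_9(self):
        manifest = self.make_manifest(45)
        train_m, test_m = te.patient_split(manifest, 0.8, seed=0)
        assert train_m["patient"].nunique() == 36
        assert test_m["patient"].nunique() == 9

    def test_split_is_deterministic_disjoint_exhaustive(self):
        manifest = self.make_manifest(11)
        t1, s1 = te.patient_split(manifest, 0.8, seed=5)
        t2, s2 = te.patient_split(manifest, 0.8, seed=5)
        assert set(t1["patient"]) == set(t2["patient"])
        train_p, test_p = set(t1["patient"]), set(s1["patient"])
        assert not train_p & test_p
        assert train_p | test_p == set(manifest["patient"])
        assert len(t1) + len(s1) == len(manifest)
        t3, _ = te.patient_split(manifest, 0.8, seed=6)
        # a different seed may (and here does) select different patients
        assert set(t3["patient"]) != train_p

    def test_single_patient_cannot_be_split(self):
        with pytest.raises(ValidationError):
            te.patient_split(self.make_manifest(1), 0.8, seed=0)


class TestEarlyStopping:
    def test_improving_losses_run_to_max_epochs(self):
        losses = list(-np.arange(50, dtype=float))
        assert te.run_early_stopping(losses, patience=10, max_epochs=30) == 30

    def test_constant_losses_stop_after_patience_past_first(self):
        losses = [1.0] * 50
        assert te.run_early_stopping(losses, patience=10, max_epochs=100) == 11

    def test_late_improvement_resets_patience(self):
        losses = [1.0, 0.9] + [0.95] * 5 + [0.8] + [0.9] * 20
        # improvement at epoch 8 resets; then 10 flat epochs stop at 18
        assert te.run_early_stopping(losses, patience=10, max_epochs=100) == 18


class TestTrainLoop:
    def test_tiny_run_is_bit_reproducible(self, tumor_slices):
        def run():
            model = nw.build_model(
                nw.ModelConfig(variant="ours", base_channels=4), seed=0
            )
            cfg = te.TrainConfig(learning_rate=1e-3, max_epochs=2,
                                 early_stop_patience=1, batch_size=4, seed=0)
            _, history = te.train(model, tumor_slices, cfg)
            return history

        h1, h2 = run(), run()
        pd.testing.assert_frame_equal(h1, h2)
        assert np.array_equal(h1["train_loss"].values, h2["train_loss"].values)

    def test_training_loss_decreases(self, tumor_slices):
        model = nw.build_model(nw.ModelConfig(variant="ours", base_channels=4), seed=1)
        cfg = te.TrainConfig(learning_rate=1e-3, max_epochs=6,
                             early_stop_patience=5, batch_size=4, seed=1)
        _, history = te.train(model, tumor_slices, cfg)
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]


class TestConfusionAndRates:
    def test_perfect_prediction(self):
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[:2, :5] = 1
        c = te.confusion_counts(gt, gt)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)
        assert te.dice_score(c) == 1.0
        assert te.sensitivity(c) == 1.0
        assert te.specificity(c) == 1.0
        assert te.accuracy(c) == 1.0

    def test_total_disagreement(self):
        gt = np.zeros((4, 4), dtype=np.uint8)
        gt[:2] = 1
        c = te.confusion_counts(1 - gt, gt)
        assert c.tp == 0 and c.tn == 0
        assert c.total == 16

    def test_hand_arithmetic_fixtures(self):
        c = te.ConfusionCounts(tp=3, fp=2, tn=4, fn=1)
        assert te.dice_score(c) == pytest.approx(6 / 9)
        assert te.accuracy(c) == pytest.approx(7 / 10)
        c2 = te.ConfusionCounts(tp=5, fp=0, tn=0, fn=5)
        assert te.sensitivity(c2) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pred = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
            gt = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
            c = te.confusion_counts(pred, gt)
            assert (c.tp, c.fp, c.tn, c.fn) == brute_force_confusion(pred, gt)

    def test_dice_precision_sensitivity_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            c = te.ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            precision = c.tp / (c.tp + c.fp)
            sens = te.sensitivity(c)
            assert te.dice_score(c) == pytest.approx(
                2 * precision * sens / (precision + sens)
            )

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValidationError):
            te.confusion_counts(np.full((4, 4), 2), np.zeros((4, 4)))

    def test_undefined_rates_return_none(self):
        c = te.ConfusionCounts(tp=0, fp=0, tn=10, fn=0)
        assert te.sensitivity(c) is None
        assert te.dice_score(c) is None


class TestHausdorff:
    def test_identical_masks_have_zero_distance(self):
        m = np.zeros((12, 12), dtype=np.uint8)
        m[3:6, 4:9] = 1
        assert te.hausdorff(m, m, 95) == 0.0
        assert te.hausdorff(m, m, 100) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros((6, 6), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert te.hausdorff(a, b, 100) == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[0, 2] = 1
        assert te.hausdorff(a, b, 100, (1.0, 2.5)) == pytest.approx(5.0)

    def test_symmetry_and_empty_flag(self):
        rng = np.random.default_rng(9)
        a = (rng.uniform(size=(12, 12)) > 0.7).astype(np.uint8)
        b = (rng.uniform(size=(12, 12)) > 0.7).astype(np.uint8)
        assert te.hausdorff(a, b, 95) == te.hausdorff(b, a, 95)
        assert te.hausdorff(a, np.zeros_like(a), 95) is None

    @pytest.mark.parametrize("percentile", [95, 100])
    def test_matches_all_pairs_oracle(self, percentile):
        rng = np.random.default_rng(10)
        for _ in range(50):
            a = (rng.uniform(size=(12, 12)) > 0.75).astype(np.uint8)
            b = (rng.uniform(size=(12, 12)) > 0.75).astype(np.uint8)
            if not a.any() or not b.any():
                continue
            ours = te.hausdorff(a, b, percentile)
            oracle = brute_force_hausdorff(a, b, percentile, (1.0, 1.0))
            assert ours == pytest.approx(oracle, abs=1e-9)


class TestEvaluate:
    def test_ground_truth_against_itself_is_perfect(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[4:9, 5:12] = 1
        m = te._slice_metrics(gt, gt, (1.0, 1.0))
        assert m["Dice"] == 1.0 and m["Hausdorff95"] == 0.0 and m["Acc"] == 1.0

    def test_all_background_predictor_rates(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[2:5, 2:5] = 1
        m = te._slice_metrics(np.zeros_like(gt), gt, (1.0, 1.0))
        assert m["Sensitivity"] == 0.0
        assert m["Specificity"] == 1.0
        assert m["Hausdorff95"] is None

    def test_report_columns_and_undefined_bookkeeping(self, tumor_slices):
        model = nw.build_model(nw.ModelConfig(variant="sunet", base_channels=4), seed=2)
        report = te.evaluate({"SUNet": model}, tumor_slices, (2.0, 2.0))
        assert list(report.table.columns) == [
            "Model", "Acc", "Dice", "Sensitivity", "Specificity", "Hausdorff95",
        ]
        assert report.table["Model"].tolist() == ["SUNet"]
        assert set(report.per_patient["Model"]) == {"SUNet"}
        assert (report.undefined_counts.drop(columns="Model").values >= 0).all()
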