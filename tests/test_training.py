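import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vhfold.model_core import ModelConfig, build_model
from vhfold.training import (TrainConfig, evaluate_loss, kfold_cv, loss_ca,
                             loss_mse, loss_total, train, transfer_retrain)

TINY = dataclasses.replace(ModelConfig.small(0), resnet1_channels=8,
                           mid_channels=8, resnet1_blocks=1, head_channels=(8, 15))
FAST = TrainConfig(seed=0, batch_size=4, ca_average=True)


def example_arrays(n_res=10, seed=0):
    rng = np.random.default_rng(seed)
    y = np.zeros((140, 15))
    y[:n_res] = rng.normal(0, 5, (n_res, 15))
    mask = np.zeros(140)
    mask[:n_res] = 1
    cb = mask.copy()
    return y, mask, cb


def straight_ca_chain(n, spacing, n_res=140):
    y = np.zeros((n_res, 15))
    y[:n, 3] = np.arange(n) * spacing  # CA x-components
    return y


class TestLossMSE:
    def test_zero_when_equal(self):
        y, mask, cb = example_arrays()
        assert loss_mse(y, y, mask, cb) == 0.0

    def test_single_residue_uniform_displacement(self):
        y, mask, cb = example_arrays(n_res=1)
        yhat = y.copy()
        for j in range(5):
            yhat[0, 3 * j] += 3.0  # every atom displaced by (3, 0, 0)
        assert np.isclose(loss_mse(y, yhat, mask, cb), 9.0)

    def test_uniform_unit_shift_gives_squared_rmsd_one(self):
        y, mask, cb = example_arrays()
        yhat = y.copy()
        yhat[:, 0::3] += 1.0
        assert np.isclose(loss_mse(y, yhat, mask, cb), 1.0)

    def test_cb_gating(self):
        y, mask, cb = example_arrays(n_res=2)
        cb = cb.copy()
        cb[1] = 0.0
        yhat = y.copy()
        yhat[1, 12] += 100.0  # displaced CB of a glycine-like residue
        assert loss_mse(y, yhat, mask, cb) == 0.0

    def test_empty_mask_raises(self):
        y, _, _ = example_arrays()
        with pytest.raises(ValueError):
            loss_mse(y, y, np.zeros(140), np.zeros(140))


class TestLossCA:
    def test_ideal_spacing_is_zero(self):
        yhat = straight_ca_chain(10, 3.8)
        mask = np.zeros(140)
        mask[:10] = 1
        assert np.isclose(loss_ca(yhat, mask), 0.0, atol=1e-12)

    def test_two_residues_off_by_one(self):
        yhat = straight_ca_chain(2, 4.8)
        mask = np.zeros(140)
        mask[:2] = 1
        assert np.isclose(loss_ca(yhat, mask), 1.0)

    def test_sum_over_pairs(self):
        yhat = np.zeros((140, 15))
        yhat[0, 3], yhat[1, 3], yhat[2, 3] = 0.0, 3.8, 6.6  # spacings 3.8, 2.8
        mask = np.zeros(140)
        mask[:3] = 1
        assert np.isclose(loss_ca(yhat, mask), 1.0)
        assert np.isclose(loss_ca(yhat, mask, average=True), 0.5)

    def test_too_few_residues(self):
        mask = np.zeros(140)
        mask[0] = 1
        with pytest.raises(ValueError):
            loss_ca(np.zeros((140, 15)), mask)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        yhat = np.zeros((140, 15))
        yhat[:12] = rng.normal(0, 4, (12, 15))
        mask = np.zeros(140)
        mask[:12] = 1
        base = loss_ca(yhat, mask)
        rot = Rotation.random(random_state=1).as_matrix()
        moved = yhat.copy()
        moved[:12, 3:6] = yhat[:12, 3:6] @ rot.T + np.array([4.0, -2.0, 9.0])
        assert np.isclose(loss_ca(moved, mask), base)


class TestLossTotal:
    def test_zero_iff_equal_with_ideal_spacing(self):
        y = straight_ca_chain(10, 3.8)
        mask = np.zeros(140)
        mask[:10] = 1
        cb = mask.copy()
        bd = loss_total(y, y, mask, cb)
        assert bd.total == pytest.approx(0.0, abs=1e-20)

    def test_ground_truth_prediction_leaves_ca_term(self):
        y, mask, cb = example_arrays()
        bd = loss_total(y, y, mask, cb)
        assert bd.mse_term == 0.0
        assert np.isclose(bd.ca_term, loss_ca(y, mask))

    def test_breakdown_is_exact_sum(self):
        y, mask, cb = example_arrays()
        yhat = y + 0.3
        bd = loss_total(y, yhat, mask, cb)
        assert bd.total == bd.mse_term + bd.ca_term

    def test_mse_not_invariant_under_rigid_motion(self):
        y, mask, cb = example_arrays()
        moved = y.copy()
        moved[:, 0::3] += 5.0
        assert loss_mse(y, moved, mask, cb) > 0.0


class TestTrainLoop:
    def test_history_deterministic_and_checkpoint_rule(self, family_examples):
        ex = family_examples[:8]
        m1 = build_model(TINY)
        m1, h1 = train(m1, ex[:6], ex[6:], FAST, max_epochs=3)
        m2 = build_model(TINY)
        m2, h2 = train(m2, ex[:6], ex[6:], FAST, max_epochs=3)
        assert h1.equals(h2)
        restored = evaluate_loss(m1, ex[6:], ca_average=True).total
        assert restored <= h1["val_loss"].min() + 1e-9

    def test_training_reduces_loss(self, family_examples):
        ex = family_examples[:8]
        model = build_model(ModelConfig.small(0))
        model, h = train(model, ex[:6], ex[6:], FAST, max_epochs=12)
        assert h["val_loss"].min() < h["val_loss"].iloc[0]

    def test_empty_sets_rejected(self, family_examples):
        with pytest.raises(ValueError):
            train(build_model(TINY), [], family_examples[:2], FAST)


class TestKFold:
    def test_folds_disjoint_and_report_shape(self, family_examples):
        ex = family_examples[:8]
        report = kfold_cv(ex, lambda f: build_model(TINY), FAST, k=2, max_epochs=1)
        assert len(report) == 3  # 2 folds + summary row
        assert report["n_val"].iloc[:2].sum() == len(ex)

    def test_stratified_counts_respected(self, family_examples, family_records):
        ex = family_examples[:8]
        labels = {r.record_id: ("even" if r.family % 2 == 0 else "odd")
                  for r in family_records[:8]}
        spec = {"labels": labels, "counts": {"even": 1, "odd": 1}}
        report = kfold_cv(ex, lambda f: build_model(TINY), FAST, k=2,
                          fold_spec=spec, max_epochs=1)
        assert all(report["n_val"].iloc[:2] == 2)
        with pytest.raises(ValueError):
            kfold_cv(ex, lambda f: build_model(TINY), FAST, k=2,
                     fold_spec={"labels": labels, "counts": {"even": 10}},
                     max_epochs=1)


class TestTransfer:
    def test_transfer_on_same_data_never_worse(self, family_examples):
        ex = family_examples[:8]
        model = build_model(TINY)
        model, h = train(model, ex[:6], ex[6:], FAST, max_epochs=3)
        before = evaluate_loss(model, ex[6:], ca_average=True).total
        retrained, _ = transfer_retrain(model, ex[:6], ex[6:], FAST, max_epochs=2)
        after = evaluate_loss(retrained, ex[6:], ca_average=True).total
        assert after <= before + 1e-9

    def test_epochs_capped_at_transfer_limit(self, family_examples):
        ex = family_examples[:8]
        config = dataclasses.replace(FAST, transfer_max_epochs=2)
        model = build_model(TINY)
        _, history = transfer_retrain(model, ex[:6], ex[6:], config, max_epochs=50)
        assert len(history) == 2
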