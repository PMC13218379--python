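"""Dual-branch assembly: forward contracts, loss decomposition,
training mechanics, prediction round trips."""

import numpy as np
import pytest

from cads import cads_model, synthdata
from cads.cads_model import (DualPrediction, TrainConfig, forward, loss,
                             predict, train)


class TestForward:
    def test_branch_parameter_copy_identity(self, tiny_dataset, tiny_config):
        """With Ft's parameters set to Fc's and both branches fed the
        causal profile, the two outputs coincide exactly."""
        model = cads_model.DualBranchModel(tiny_config, 1,
                                           tiny_dataset.gene_ids,
                                           tiny_dataset.drugs)
        # route Gc to both branches by making the masks equal (alpha=0.5)
        model.mask_encoder.W.W.data[:] = 0.0
        fc_params = model.Fc.parameters()
        for pt, pc in zip(model.Ft.parameters(), fc_params):
            pt.data = pc.data.copy()
        C_all = np.stack([p.C for p in tiny_dataset.profiles])
        Yc, Yt = model.forward_batch(C_all, np.array([0, 1]),
                                     np.array([0, 1]), np.array([2, 3]))
        assert np.allclose(Yc.data, Yt.data)

    def test_branches_have_disjoint_parameters(self, tiny_trained):
        model = tiny_trained.model
        ids_c = {id(p) for p in model.Fc.parameters()}
        ids_t = {id(p) for p in model.Ft.parameters()}
        assert not ids_c & ids_t

    def test_batch_size_invariance(self, tiny_trained, tiny_dataset):
        ex = tiny_dataset.examples[:33]
        big = forward(tiny_trained.model, tiny_dataset, ex)
        ones = [forward(tiny_trained.model, tiny_dataset, [e]) for e in ex]
        assert np.allclose(big.Yc, np.concatenate([o.Yc for o in ones]),
                           atol=1e-10)

    def test_forward_deterministic(self, tiny_trained, tiny_dataset):
        ex = tiny_dataset.examples[:5]
        a = forward(tiny_trained.model, tiny_dataset, ex)
        b = forward(tiny_trained.model, tiny_dataset, ex)
        assert np.array_equal(a.Yc, b.Yc) and np.array_equal(a.Yt, b.Yt)

    def test_unknown_entity_raises_lookup_error(self, tiny_trained, tiny_dataset):
        bad = synthdata.SynergyExample("nope", "drug002", "cell0001",
                                       "s_score", 0.0)
        with pytest.raises(KeyError):
            forward(tiny_trained.model, tiny_dataset, [bad])


class TestLoss:
    def test_perfect_fit_zero_loss(self):
        pred = DualPrediction(Yc=np.array([1.0, -1.0]), Yt=np.zeros(2),
                              y_hat=np.zeros(2))
        total, rep = loss(pred, np.array([1.0, -1.0]))
        assert rep.L == 0.0

    def test_unit_error_unit_loss(self):
        pred = DualPrediction(Yc=np.array([1.0, 2.0]), Yt=np.zeros(2),
                              y_hat=np.zeros(2))
        total, rep = loss(pred, np.array([0.0, 1.0]))
        assert rep.L == pytest.approx(1.0)
        assert rep.L_causal == pytest.approx(1.0)
        assert rep.L_trivial == 0.0

    def test_matches_scalar_oracle(self, rng):
        Yc = rng.normal(size=16)
        Yt = rng.normal(size=16)
        y = rng.normal(size=16)
        _, rep = loss(DualPrediction(Yc=Yc, Yt=Yt, y_hat=Yc), y)
        assert rep.L_causal == pytest.approx(np.mean((Yc - y) ** 2), abs=1e-7)
        assert rep.L_trivial == pytest.approx(np.mean(Yt**2), abs=1e-7)
        assert rep.L == pytest.approx(rep.L_causal + rep.L_trivial, abs=1e-7)

    def test_non_finite_labels_rejected(self):
        pred = DualPrediction(Yc=np.zeros(2), Yt=np.zeros(2), y_hat=np.zeros(2))
        with pytest.raises(ValueError):
            loss(pred, np.array([np.nan, 0.0]))


class TestTraining:
    def test_same_seed_identical_history(self, tiny_dataset, tiny_config):
        a = train(tiny_dataset, tiny_config)
        b = train(tiny_dataset, tiny_config)
        assert [h["train_loss"] for h in a.history] == \
               [h["train_loss"] for h in b.history]

    def test_trivial_branch_shrinks_toward_zero(self, tiny_dataset):
        cfg = TrainConfig(epochs=8, batch_size=64, hidden=(32, 16),
                          d_model=16, d_g=8, seed=7,
                          mask_finetune_epochs=0)
        model0 = cads_model.DualBranchModel(cfg, 1, tiny_dataset.gene_ids,
                                            tiny_dataset.drugs)
        ex = tiny_dataset.examples[:100]
        before = np.abs(forward(model0, tiny_dataset, ex).Yt).mean()
        trained = train(tiny_dataset, cfg)
        after = np.abs(forward(trained.model, tiny_dataset, ex).Yt).mean()
        assert after < before

    def test_empty_training_split_rejected(self, tiny_dataset, tiny_config):
        with pytest.raises(ValueError):
            train(tiny_dataset, tiny_config, train_idx=np.array([], dtype=int))

    def test_leave_cell_out_split_separates_cells(self, tiny_dataset):
        cfg = TrainConfig(epochs=1, batch_size=64, hidden=(8,), d_model=8,
                          d_g=4, seed=3, split_mode="leave_cell_out",
                          mask_finetune_epochs=5, mask_refine_reps=2)
        tm = train(tiny_dataset, cfg)
        ex = tiny_dataset.examples
        cells = lambda idx: {ex[i].cell_id for i in idx}  # noqa: E731
        assert not cells(tm.split["train"]) & cells(tm.split["test"])
        assert not cells(tm.split["val"]) & cells(tm.split["test"])


class TestPredict:
    def test_standardization_round_trip(self, tiny_dataset):
        std = tiny_dataset.standardization
        y = np.array([e.y for e in tiny_dataset.examples])
        assert np.abs(std.apply(std.invert(y)) - y).max() < 1e-9

    def test_predictions_finite_and_destandardized(self, tiny_trained,
                                                   tiny_dataset):
        ex = tiny_dataset.examples[:20]
        pred = predict(tiny_trained, tiny_dataset, ex)
        assert np.isfinite(pred.y_hat).all()
        std = tiny_trained.standardization
        assert np.allclose(pred.y_hat, std.invert(pred.Yc))

    def test_gene_panel_mismatch_rejected(self, tiny_trained):
        other = synthdata.simulate(n_cells=4, n_genes=10, k_causal=2,
                                   n_drugs=4, n_examples=10, seed=1)
        with pytest.raises(ValueError):
            predict(tiny_trained, other, other.examples[:1])


class TestBackbones:
    @pytest.mark.parametrize("backbone", ["graph", "xattn"])
    def test_alternative_backbones_train_and_predict(self, backbone):
        ds = synthdata.simulate(n_cells=6, n_genes=14, k_causal=3, n_drugs=5,
                                n_examples=60, seed=4)
        cfg = TrainConfig(backbone=backbone, epochs=2, batch_size=32,
                          hidden=(16,), d_model=16, d_g=4, n_heads=2, seed=4,
                          mask_finetune_epochs=5, mask_refine_reps=2)
        tm = train(ds, cfg)
        pred = predict(tm, ds, ds.examples[:8])
        assert np.isfinite(pred.y_hat).all()
        assert np.isfinite(pred.Yt).all()
        assert (np.abs(pred.Yc) <= 1).all()

    def test_single_branch_baseline_has_zero_trivial_output(self):
        ds = synthdata.simulate(n_cells=6, n_genes=14, k_causal=3, n_drugs=5,
                                n_examples=60, seed=4)
        cfg = TrainConfig(epochs=2, batch_size=32, hidden=(16,), d_model=16,
                          d_g=4, seed=4, use_cads=False,
                          mask_finetune_epochs=0)
        tm = train(ds, cfg)
        pred = predict(tm, ds, ds.examples[:8])
        assert np.array_equal(pred.Yt, np.zeros(8))


class TestMaskScheduleVariants:
    @pytest.mark.parametrize("kw", [
        {"mask_update": "epoch"},
        {"mask_refine_split": "cells"},
    ])
    def test_alternative_mask_schedules_train(self, tiny_dataset, kw):
        cfg = TrainConfig(epochs=2, batch_size=64, hidden=(16,), d_model=8,
                          d_g=4, seed=9, mask_finetune_epochs=5,
                          mask_refine_reps=2, **kw)
        tm = train(tiny_dataset, cfg)
        pred = predict(tm, tiny_dataset, tiny_dataset.examples[:5])
        assert np.isfinite(pred.y_hat).all()
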