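"""Assembled model: loss, thresholding, gradients, training behaviour."""

import numpy as np
import pytest

from csrec.autodiff import Tensor
from csrec.cohort_io import (CodeLevel, Cohort, Visit, Vocabulary,
                             encode_patient)
from csrec.graph_builder import SymmetricAdjacency
from csrec.recommender import (CSRecModel, ModelConfig, bce_loss,
                               load_checkpoint, recommend, save_checkpoint,
                               train)


def tiny_vocab(n_diag=4, n_proc=2, n_med=3):
    return Vocabulary(
        diag_index={f"d{i}": i for i in range(n_diag)},
        proc_index={f"p{i}": i for i in range(n_proc)},
        med_index={f"m{i}": i for i in range(n_med)},
    )


def tiny_patient(vocab, rng, n_visits=2):
    visits = []
    for t in range(n_visits):
        diags = rng.choice(list(vocab.diag_index), 2, replace=False)
        procs = rng.choice(list(vocab.proc_index), 1, replace=False)
        meds = rng.choice(list(vocab.med_index), rng.integers(1, 3),
                          replace=False)
        visits.append(Visit("s0", t, frozenset(diags), frozenset(procs),
                            frozenset(meds)))
    return visits


def tiny_model(vocab, seed=0, **kw):
    cfg = ModelConfig(embed_dim=4, heads=2, seed=seed, **kw)
    ddi = SymmetricAdjacency(np.zeros((vocab.n_med, vocab.n_med)))
    return CSRecModel(vocab, ddi, cfg), cfg


class TestBceLoss:
    def test_closed_form_at_half(self):
        T, M = 3, 5
        probs = Tensor(np.full((T, M), 0.5))
        loss = bce_loss(probs, np.zeros((T, M)))
        assert loss.item() == pytest.approx(T * M * np.log(2), rel=1e-12)

    def test_perfect_prediction_near_zero(self):
        y = np.array([[1.0, 0, 1], [0, 1, 0]])
        loss = bce_loss(Tensor(y), y)
        assert 0 <= loss.item() < 1e-5

    def test_matches_elementwise_oracle(self, rng):
        p = rng.uniform(0.05, 0.95, size=(3, 4))
        y = (rng.random((3, 4)) < 0.5).astype(float)
        expect = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert bce_loss(Tensor(p), y).item() == pytest.approx(expect, abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(Tensor(np.zeros((2, 3))), np.zeros((3, 2)))


class TestRecommend:
    def test_strict_inequality_at_threshold(self):
        assert recommend(np.array([0.5]), 0.5) == set()

    def test_all_above(self):
        assert recommend(np.full(4, 1 - 1e-9), 0.5) == {0, 1, 2, 3}

    def test_matches_filter_oracle(self, rng):
        for _ in range(100):
            p = rng.random(8)
            thr = float(rng.uniform(0.1, 0.9))
            assert recommend(p, thr) == {i for i in range(8) if p[i] > thr}

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            recommend(np.array([0.2]), 1.5)


class TestForward:
    def test_probs_in_unit_interval(self, rng):
        vocab = tiny_vocab()
        model, _ = tiny_model(vocab)
        encs = encode_patient(tiny_patient(vocab, rng), vocab)
        out = model.forward(encs, 1)
        assert out.probs.shape == (3,)
        assert np.all((out.probs > 0) & (out.probs < 1))
        assert out.recommended == {i for i in range(3)
                                   if out.probs[i] > model.config.threshold}

    def test_full_equals_wo_c_when_no_graph_edges(self, rng):
        """With no procedures and no medication history every graph is
        empty, so the full path must coincide with the no-collaboration
        ablation exactly."""
        vocab = tiny_vocab()
        visits = [Visit("s", 0, frozenset({"d0", "d1"}), frozenset(),
                        frozenset()),
                  Visit("s", 1, frozenset({"d2"}), frozenset(), frozenset())]
        encs = encode_patient(visits, vocab)
        model_full, _ = tiny_model(vocab, variant="full")
        model_woc, _ = tiny_model(vocab, variant="WO_C")
        p_full = model_full.forward(encs, 1).probs
        p_woc = model_woc.forward(encs, 1).probs
        assert np.allclose(p_full, p_woc, atol=1e-12)

    def test_stage2_cache_changes_nothing(self, rng):
        vocab = tiny_vocab()
        model, _ = tiny_model(vocab)
        encs = encode_patient(tiny_patient(vocab, rng, 3), vocab)
        direct = model.forward_tensor(encs, 2).data
        cached = model.forward_tensor(encs, 2, model._stage2_cache(encs)).data
        assert np.allclose(direct, cached, atol=1e-12)

    @pytest.mark.parametrize("variant", ["WO_S", "GAT_GCN", "WO_DM", "WO_PM",
                                         "WO_DP", "WO_MM"])
    def test_variants_run(self, variant, rng):
        vocab = tiny_vocab()
        model, _ = tiny_model(vocab, variant=variant)
        encs = encode_patient(tiny_patient(vocab, rng, 2), vocab)
        out = model.forward(encs, 1)
        assert np.all(np.isfinite(out.probs))


def test_gradients_match_finite_differences(rng):
    """Analytic gradients of loss∘forward on a d=4, |M|=3 model."""
    vocab = tiny_vocab()
    model, _ = tiny_model(vocab)
    encs = encode_patient(tiny_patient(vocab, rng, 2), vocab)

    def loss_value():
        return model.patient_loss(encs).item()

    model.zero_grad()
    loss = model.patient_loss(encs)
    loss.backward()
    eps = 1e-5
    checked = 0
    for name, p in model.parameters():
        if p.grad is None:
            continue
        flat = p.data.ravel()
        gflat = p.grad.ravel()
        idxs = rng.choice(flat.size, size=min(3, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            hi = loss_value()
            flat[i] = orig - eps
            lo = loss_value()
            flat[i] = orig
            num = (hi - lo) / (2 * eps)
            # relative error with a floor so near-zero gradients are
            # compared absolutely at the same tolerance
            denom = max(abs(num) + abs(gflat[i]), 1e-4)
            assert abs(num - gflat[i]) / denom < 1e-4, (name, i)
            checked += 1
    assert checked > 20


def small_cohort(vocab, rng, n=6, n_visits=2):
    patients = []
    for s in range(n):
        visits = [Visit(f"s{s}", t, *map(frozenset, (
            rng.choice(list(vocab.diag_index), 2, replace=False),
            rng.choice(list(vocab.proc_index), 1, replace=False),
            rng.choice(list(vocab.med_index), 2, replace=False))))
            for t in range(n_visits)]
        patients.append((f"s{s}", visits))
    return Cohort(patients=patients, level=CodeLevel.ATC04)


class TestTraining:
    def test_deterministic_reports(self, rng):
        vocab = tiny_vocab()
        cohort = small_cohort(vocab, rng)
        reports = []
        for _ in range(2):
            model, cfg = tiny_model(vocab, max_epochs=3, patience=3)
            reports.append(train(model, cohort, None, cfg).to_json())
        assert reports[0] == reports[1]

    def test_loss_decreases_on_overfit_fixture(self, rng):
        vocab = tiny_vocab()
        cohort = small_cohort(vocab, rng)
        model, cfg = tiny_model(vocab, max_epochs=10, patience=10,
                                learning_rate=3e-2)
        report = train(model, cohort, None, cfg)
        losses = [e["train_loss"] for e in report.epochs]
        assert losses[-1] < 0.5 * losses[0]

    def test_early_stopping_patience_one(self, rng):
        vocab = tiny_vocab()
        cohort = small_cohort(vocab, rng)
        model, cfg = tiny_model(vocab, max_epochs=50, patience=1,
                                learning_rate=0.0)
        # zero learning rate: the validation metric can never improve after
        # the first epoch, so training must stop after one extra epoch
        report = train(model, cohort, None, cfg)
        assert len(report.epochs) == 2
        assert "no validation improvement" in report.stopping_reason

    def test_divergence_detected(self, rng):
        vocab = tiny_vocab()
        cohort = small_cohort(vocab, rng)
        model, cfg = tiny_model(vocab, max_epochs=2, patience=2)
        model.out.W.data[:] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            train(model, cohort, None, cfg)


def test_checkpoint_round_trip(tmp_path, rng):
    vocab = tiny_vocab()
    model, _ = tiny_model(vocab, seed=7)
    encs = encode_patient(tiny_patient(vocab, rng, 2), vocab)
    before = model.forward(encs, 1).probs
    path = tmp_path / "model.ckpt"
    save_checkpoint(model, path)
    again = load_checkpoint(path)
    after = again.forward(encs, 1).probs
    assert np.allclose(before, after, atol=0)
    assert again.config == model.config
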