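import numpy as np
import pytest
from sklearn.model_selection import cross_val_score

from pathdx.model import SequenceModelConfig
from pathdx.model.albert import load_checkpoint, save_checkpoint
from pathdx.pathways import CLS_ID, MASK_ID, N_SPECIAL, Pathway, Vocabulary
from pathdx.training import (
    TrainPlan,
    featurize_counts,
    finetune,
    make_mlm_example,
    plan_steps,
    pretrain,
    train_lr_baseline,
)


class TestMLMCorruption:
    def test_cls_never_selected(self):
        seq = np.array([CLS_ID, 7])
        for seed in range(200):
            ex = make_mlm_example(seq, np.random.default_rng(seed), vocab_size=30)
            assert not ex.selection_mask[0]

    def test_zero_maskable_positions_gives_empty_selection(self):
        seq = np.array([CLS_ID, 0, 0])
        ex = make_mlm_example(seq, np.random.default_rng(0), vocab_size=30)
        assert not ex.selection_mask.any()
        assert np.array_equal(ex.input_ids, seq)

    def test_targets_are_original_ids(self, rng):
        seq = np.concatenate([[CLS_ID], rng.integers(4, 30, size=100)])
        ex = make_mlm_example(seq, rng, vocab_size=30)
        assert np.array_equal(ex.target_ids, seq)
        # unselected positions pass through uncorrupted
        assert np.array_equal(ex.input_ids[~ex.selection_mask], seq[~ex.selection_mask])

    def test_random_replacements_are_group_tokens(self, rng):
        seq = np.concatenate([[CLS_ID], rng.integers(4, 30, size=5000)])
        ex = make_mlm_example(seq, rng, vocab_size=30)
        corrupted = ex.input_ids[ex.selection_mask]
        assert (corrupted[corrupted != MASK_ID] >= N_SPECIAL).all()

    def test_corruption_marginals(self, rng):
        """~12% of maskable positions become [MASK], ~1.5% random."""
        n = 60_000
        seq = np.concatenate([[CLS_ID], rng.integers(4, 454, size=n)])
        ex = make_mlm_example(seq, rng, vocab_size=454)
        maskable = slice(1, None)
        masked = (ex.input_ids[maskable] == MASK_ID).mean()
        randomised = (
            ex.selection_mask[maskable]
            & (ex.input_ids[maskable] != MASK_ID)
            & (ex.input_ids[maskable] != ex.target_ids[maskable])
        ).mean()
        assert masked == pytest.approx(0.12, abs=0.01)
        assert randomised == pytest.approx(0.015, abs=0.005)


class TestPlanSteps:
    @pytest.mark.parametrize(
        "n,epochs,batch,expected",
        [(13029, 60, 2, 390_870), (8, 1, 8, 1), (7, 1, 2, 3)],
    )
    def test_step_counts(self, n, epochs, batch, expected):
        assert plan_steps(n, epochs, batch) == expected

    def test_zero_batch_errors(self):
        with pytest.raises(ValueError):
            plan_steps(10, 1, 0)

    def test_plan_defaults_mirror_finetune_schedule(self):
        plan = TrainPlan()
        assert (plan.batch_size, plan.epochs) == (8, 4)
        assert plan.planned_steps(13029) == 13029 * 4 // 8


class TestFeaturize:
    @pytest.fixture()
    def vocab(self):
        return Vocabulary.from_groups(["A", "B", "C"])

    def test_counts(self, vocab):
        vec = featurize_counts(["A", "A", "B"], vocab)
        assert vec.tolist() == [2.0, 1.0, 0.0]

    def test_empty_pathway_zero_vector(self, vocab):
        assert featurize_counts([], vocab).sum() == 0

    def test_sum_conserves_token_count(self, vocab, rng):
        tokens = [["A", "B", "C"][i] for i in rng.integers(0, 3, size=57)]
        assert featurize_counts(tokens, vocab).sum() == 57

    def test_binary_mode(self, vocab):
        vec = featurize_counts(["A", "A", "B"], vocab, binary=True)
        assert vec.tolist() == [1.0, 1.0, 0.0]


class TestLRBaseline:
    def test_separable_data_fits_perfectly_at_low_regularisation(self, rng):
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y, 3.0, -3.0)  # wide margin
        clf = train_lr_baseline(X, y, C=1e6)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_label_permutation_gives_chance_auroc(self, rng):
        X = rng.normal(size=(400, 20))
        y = rng.permutation([0] * 200 + [1] * 200)
        clf = train_lr_baseline(X[:10], y[:10], C=1.0)  # model class only
        aucs = cross_val_score(clf, X, y, cv=5, scoring="roc_auc")
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 1] > 0).astype(int)
        a = train_lr_baseline(X, y, seed=3, C=1.0)
        b = train_lr_baseline(X, y, seed=3, C=1.0)
        assert np.array_equal(a.coef_, b.coef_)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            train_lr_baseline(np.zeros((10, 3)), [0, 1] * 5)
        with pytest.raises(ValueError):
            train_lr_baseline(np.random.default_rng(0).normal(size=(10, 3)), [1] * 10)


@pytest.fixture(scope="module")
def toy_sequences():
    rng = np.random.default_rng(5)
    seqs = [
        np.concatenate([[CLS_ID], rng.integers(4, 30, size=int(rng.integers(8, 16)))])
        for _ in range(200)
    ]
    # planted signal: label-1 sequences end with token 4 then 5
    labels = rng.integers(0, 2, size=200)
    for s, y in zip(seqs, labels):
        if y:
            s[-2:] = [4, 5]
        else:
            s[-2:] = [5, 4]
    return seqs, labels


class TestPretrain:
    def test_loss_decreases_and_checkpoint_roundtrips(self, toy_sequences, tmp_path):
        seqs, _ = toy_sequences
        cfg = SequenceModelConfig.desk(vocab_size=30, max_len=32)
        res = pretrain(seqs, cfg, TrainPlan(batch_size=32, epochs=5,
                                            learning_rate=1e-3, seed=0))
        assert res.smoothed_trace[-1] < res.smoothed_trace[0]
        # analytic baseline: uniform-init loss ~ ln(V)
        assert res.loss_trace[0] == pytest.approx(np.log(30), rel=0.05)
        save_checkpoint(res.model, tmp_path / "m")
        again = load_checkpoint(tmp_path / "m")
        ids = np.array([seqs[0]])
        assert np.array_equal(
            res.model.forward(ids).cls.data, again.forward(ids).cls.data
        )

    def test_non_finite_loss_aborts_with_diagnostics(self, toy_sequences):
        from pathdx.model import SequenceModel

        seqs, _ = toy_sequences
        cfg = SequenceModelConfig.desk(vocab_size=30, max_len=32)
        broken = SequenceModel(cfg, seed=0)
        broken.params["tok_emb"].data[:] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            pretrain(seqs[:64], cfg,
                     TrainPlan(batch_size=32, epochs=1, learning_rate=1e-3, seed=0),
                     model=broken)


class TestFinetune:
    def test_identical_seeds_give_identical_selected_model(self, toy_sequences):
        seqs, labels = toy_sequences
        cfg = SequenceModelConfig.desk(vocab_size=30, max_len=32)
        pre = pretrain(seqs[:64], cfg, TrainPlan(batch_size=32, epochs=1,
                                                 learning_rate=1e-3, seed=0))
        plan = TrainPlan(batch_size=32, epochs=1, learning_rate=5e-4,
                         seed=9, restarts=2)
        a = finetune(seqs[:160], labels[:160], pre.model, plan,
                     seqs[160:], labels[160:])
        b = finetune(seqs[:160], labels[:160], pre.model, plan,
                     seqs[160:], labels[160:])
        assert a.best_restart == b.best_restart
        for k in a.model.params:
            assert np.array_equal(a.model.params[k].data, b.model.params[k].data)
        assert a.report == b.report

    def test_report_records_plan_and_restarts(self, toy_sequences):
        seqs, labels = toy_sequences
        cfg = SequenceModelConfig.desk(vocab_size=30, max_len=32)
        pre = pretrain(seqs[:64], cfg, TrainPlan(batch_size=32, epochs=1,
                                                 learning_rate=1e-3, seed=0))
        plan = TrainPlan(batch_size=8, epochs=4, learning_rate=5e-4,
                         seed=1, restarts=2)
        res = finetune(seqs[:120], labels[:120], pre.model, plan,
                       seqs[120:160], labels[120:160])
        assert len(res.report) == 2
        assert {r["batch_size"] for r in res.report} == {8}
        assert {r["epochs"] for r in res.report} == {4}
        assert res.best_restart == max(
            res.report, key=lambda r: r["eval_auroc"]
        )["restart"]

    def test_single_class_training_set_errors(self, toy_sequences):
        seqs, _ = toy_sequences
        cfg = SequenceModelConfig.desk(vocab_size=30, max_len=32)
        pre = pretrain(seqs[:64], cfg, TrainPlan(batch_size=32, epochs=1,
                                                 learning_rate=1e-3, seed=0))
        with pytest.raises(ValueError, match="both classes"):
            finetune(seqs[:40], [1] * 40, pre.model, TrainPlan(), seqs[:5], [1] * 5)
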