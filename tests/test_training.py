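"""Schedule closed forms, the MLL metric, losses and orchestration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mode import (ATRModel, ModelConfig, SummaryModel, Template,
                  build_vocabulary, generate_corpus, split_corpus)
from mode.sps import sps_generate
from mode.training import (TaskMetrics, TrainConfig, evaluate, lr_at_epoch,
                           mll_score, run_schedule, task_loss, train_task)


def small_model_cfg(vocab, **kw):
    defaults = dict(n=10, L=1, vocab=vocab, templated=True, dropout=0.0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestSchedule:
    def test_initial_learning_rate(self):
        assert lr_at_epoch(0, TrainConfig()) == 0.01

    def test_first_decay_step_closed_form(self):
        # lr_1 = 0.8 * 0.01 * 0.01^(0.01 / 40.01)
        want = 0.8 * 0.01 * 0.01 ** (0.01 / 40.01)
        got = lr_at_epoch(1, TrainConfig(epoch_max=40))
        np.testing.assert_allclose(got, want, rtol=1e-12)
        np.testing.assert_allclose(got, 0.0079908, atol=5e-8)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(1, 60))
    def test_strictly_decreasing(self, epoch_max):
        cfg = TrainConfig(epoch_max=epoch_max)
        rates = [lr_at_epoch(i, cfg) for i in range(epoch_max + 1)]
        assert all(b < a for a, b in zip(rates, rates[1:]))

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(-1, TrainConfig())


class TestMLL:
    @pytest.mark.parametrize("loss,expected", [
        (1.0, 0.0),
        (float(np.exp(-2.0)), 2.0),
        (0.1, 2.302585),
    ])
    def test_values(self, loss, expected):
        np.testing.assert_allclose(mll_score(loss), expected, atol=1e-6)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            mll_score(bad)

    def test_inverse_identity(self):
        for loss in np.linspace(0.05, 2.0, 9):
            np.testing.assert_allclose(np.exp(-mll_score(loss)), loss,
                                       rtol=1e-12)


class TestTaskLoss:
    def test_severity_exact_predictions_give_zero_mse(self, tiny_corpus,
                                                      tiny_vocab, monkeypatch):
        from mode.autodiff import Tensor

        class Oracle:
            task = "severity"
            def forward(self, F, I, training=False):
                return Tensor(np.array([r.severity / 5.0
                                        for r in batch]))
        batch = tiny_corpus[:6]
        loss = task_loss("severity", batch, Oracle(), flags=True)
        assert float(loss.data) == 0.0

    def test_unknown_task_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match="unknown task"):
            task_loss("diagnosis", tiny_corpus[:2], None, flags=True)


class TestTrainTask:
    def test_zero_epochs_leave_template_untouched(self, tiny_corpus, tiny_cfg,
                                                  tiny_vocab):
        tpl = Template.create(2, 16, 16, seed=3)
        model = SummaryModel(small_model_cfg(len(tiny_vocab)), tpl, seed=0)
        before = tpl.values.data.copy()
        cfg = TrainConfig(initial_lr=1e-3, batch_size=8, seed=0)
        train_task("summary", (tiny_corpus[:8], []), tpl, cfg, model=model,
                   epochs=0)
        np.testing.assert_array_equal(tpl.values.data, before)

    def test_training_summary_changes_future_atr_weights(self, tiny_corpus,
                                                         tiny_vocab):
        """Sharing propagation: one summary step moves the template, so an
        ATR weight generated afterwards (kernels untouched) changes too."""
        tpl = Template.create(2, 16, 16, seed=3)
        cfg = small_model_cfg(len(tiny_vocab))
        summary = SummaryModel(cfg, tpl, seed=0)
        atr = ATRModel(cfg, tpl, seed=1)
        binding = atr.dec[0][0].Wq.weight.binding
        w_before = sps_generate(tpl, binding.kernel).data.copy()
        k_before = binding.kernel.values.data.copy()
        tcfg = TrainConfig(initial_lr=1e-3, batch_size=8, seed=0)
        train_task("summary", (tiny_corpus[:8], []), tpl, tcfg, model=summary,
                   epochs=1)
        np.testing.assert_array_equal(binding.kernel.values.data, k_before)
        w_after = sps_generate(tpl, binding.kernel).data
        assert np.abs(w_after - w_before).max() > 0

    def test_dev_mll_logged_per_epoch(self, tiny_corpus, tiny_vocab):
        tpl = Template.create(2, 16, 16, seed=3)
        model = SummaryModel(small_model_cfg(len(tiny_vocab)), tpl, seed=0)
        cfg = TrainConfig(initial_lr=1e-3, batch_size=8, seed=0)
        metrics = train_task("summary", (tiny_corpus[:8], tiny_corpus[8:12]),
                             tpl, cfg, model=model, epochs=2)
        assert len(metrics.train_losses) == 2
        assert len(metrics.dev_mll) == 2


class TestEvaluate:
    def test_deterministic_and_inverse_consistent(self, tiny_corpus,
                                                  tiny_vocab):
        tpl = Template.create(2, 16, 16, seed=3)
        model = SummaryModel(small_model_cfg(len(tiny_vocab), dropout=0.4),
                             tpl, seed=0)
        m1 = evaluate(model, tiny_corpus[:6], flags=True)
        m2 = evaluate(model, tiny_corpus[:6], flags=True)
        assert m1 == m2
        loss = float(task_loss("summary", tiny_corpus[:6], model,
                               flags=True).data)
        np.testing.assert_allclose(np.exp(-m1), loss, rtol=1e-9)


class TestRunSchedule:
    def _splits(self, tiny_corpus, tiny_cfg):
        return split_corpus(tiny_corpus, tiny_cfg)

    def test_mode_none_creates_only_atr_bindings(self, tiny_corpus, tiny_cfg,
                                                 tiny_vocab):
        tpl = Template.create(2, 16, 16, seed=3)
        cfg = TrainConfig(initial_lr=1e-3, batch_size=8, aux="none",
                          epochs_atr=1, seed=0)
        run_schedule(cfg, self._splits(tiny_corpus, tiny_cfg),
                     small_model_cfg(len(tiny_vocab)), tpl)
        assert tpl.bindings
        assert all(mid.startswith("atr.") for mid in tpl.bindings)

    def test_independent_phases_each_move_the_template(self, tiny_corpus,
                                                       tiny_cfg, tiny_vocab):
        tpl = Template.create(2, 16, 16, seed=3)
        checksums = [tpl.checksum()]
        cfg = TrainConfig(initial_lr=1e-3, batch_size=8, aux="both",
                          schedule="independent", epochs_summary=1,
                          epochs_severity=1, epochs_atr=1, seed=0)

        def log(**kw):
            checksums.append(tpl.checksum())

        out = run_schedule(cfg, self._splits(tiny_corpus, tiny_cfg),
                           small_model_cfg(len(tiny_vocab)), tpl, log=log)
        assert len(set(checksums)) == len(checksums)
        assert out["metrics"]["atr"].test_mll is not None
        assert out["metrics"]["atr"].param_report is not None

    def test_collaborative_zero_weight_freezes_that_task(self, tiny_corpus,
                                                         tiny_cfg, tiny_vocab):
        """With lambda_summary = 0 the summed loss carries no summary
        gradient, so summary-only parameters must not move."""
        tpl = Template.create(2, 16, 16, seed=3)
        cfg = TrainConfig(initial_lr=1e-3, batch_size=8, aux="both",
                          schedule="collaborative", epochs_atr=1,
                          loss_weights=(0.0, 1.0, 1.0), seed=0)
        out = run_schedule(cfg, self._splits(tiny_corpus, tiny_cfg),
                           small_model_cfg(len(tiny_vocab)), tpl)
        summary_model = out["models"]["summary"]
        atr_model = out["models"]["atr"]
        fresh_summary = SummaryModel(small_model_cfg(len(tiny_vocab)),
                                     Template.create(2, 16, 16, seed=3),
                                     seed=cfg.seed + 0)
        np.testing.assert_array_equal(summary_model.embed.table.data,
                                      fresh_summary.embed.table.data)
        fresh_atr_embed = ATRModel(small_model_cfg(len(tiny_vocab)),
                                   Template.create(2, 16, 16, seed=99),
                                   seed=cfg.seed + 2).embed.table.data
        assert np.abs(atr_model.embed.table.data - fresh_atr_embed).max() > 0

    def test_collaborative_records_all_tasks(self, tiny_corpus, tiny_cfg,
                                             tiny_vocab):
        tpl = Template.create(2, 16, 16, seed=3)
        cfg = TrainConfig(initial_lr=1e-3, batch_size=8, aux="both",
                          schedule="collaborative", epochs_atr=2, seed=0)
        out = run_schedule(cfg, self._splits(tiny_corpus, tiny_cfg),
                           small_model_cfg(len(tiny_vocab)), tpl)
        for task in ("summary", "severity", "atr"):
            assert len(out["metrics"][task].train_losses) == 2

    def test_unknown_mode_rejected(self, tiny_corpus, tiny_cfg, tiny_vocab):
        cfg = TrainConfig(aux="everything")
        with pytest.raises(ValueError, match="aux"):
            run_schedule(cfg, self._splits(tiny_corpus, tiny_cfg),
                         small_model_cfg(len(tiny_vocab)),
                         Template.create(2, 16, 16, seed=3))
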