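"""Model core: forward contract, parameter accounting, embeddings, gradients."""

import numpy as np
import pytest

import plantlm as plm
from plantlm.model import InvalidConfigError, TaskHeadSpec, parameter_accounting

TINY = dict(vocab_size=13, max_tokens=32, embed_dim=16, num_layers=2,
            num_heads=2, mlp_hidden=64)


@pytest.fixture(scope="module")
def tiny_model():
    return plm.build_model(plm.make_config(**TINY), seed=1)


def _random_batch(seed=0, b=2, t=32, v=9):
    rng = np.random.default_rng(seed)
    ids = rng.integers(0, v, (b, t))
    spec = np.zeros((b, t), bool)
    spec[:, 0] = True
    ids[:, 0] = 13 - 2  # CLS
    return ids, spec


class TestForward:
    def test_logit_shape_contract(self, tiny_model):
        ids, spec = _random_batch()
        assert tiny_model.logits(ids, spec).shape == (2, 32, 13)

    def test_same_seed_gives_bit_identical_logits(self):
        ids, spec = _random_batch()
        a = plm.build_model(plm.make_config(**TINY), seed=7).logits(ids, spec)
        b = plm.build_model(plm.make_config(**TINY), seed=7).logits(ids, spec)
        assert np.array_equal(a, b)

    def test_uniform_logits_cross_entropy_is_log_vocab(self, vocab):
        from plantlm.pretrain import MaskingPlan, mlm_loss
        logits = np.zeros((10, 4105))
        plan = MaskingPlan(selected=np.arange(5), action=np.zeros(5, int),
                           labels=np.arange(5))
        assert mlm_loss(logits, plan) == pytest.approx(np.log(4105), abs=1e-9)
        assert np.log(4105) == pytest.approx(8.32, abs=0.01)

    def test_permutation_sensitivity(self, tiny_model):
        ids, spec = _random_batch(seed=3)
        base = tiny_model.logits(ids, spec)
        perm = ids.copy()
        perm[:, 1:] = perm[:, 1:][:, ::-1]
        assert not np.allclose(base[:, 0], tiny_model.logits(perm, spec)[:, 0])

    def test_config_invariants_enforced(self):
        with pytest.raises(InvalidConfigError):
            plm.ModelConfig(vocab_size=13, max_tokens=8, embed_dim=10,
                            num_layers=1, num_heads=3)


class TestParameterAccounting:
    @pytest.mark.parametrize("cfg_kwargs", [
        TINY,
        dict(vocab_size=13, max_tokens=8, embed_dim=8, num_layers=1, num_heads=1),
        dict(vocab_size=29, max_tokens=16, embed_dim=12, num_layers=3, num_heads=2),
        dict(vocab_size=13, max_tokens=8, embed_dim=8, num_layers=2, num_heads=4,
             mlp_hidden=10),
        dict(vocab_size=40, max_tokens=12, embed_dim=20, num_layers=4, num_heads=5),
    ])
    @pytest.mark.parametrize("mode,k", [("pretrain", 0), ("ia3_frozen", 0),
                                        ("ia3_unfreeze_last_k", 1)])
    def test_symbolic_counts_match_allocated_model(self, cfg_kwargs, mode, k):
        cfg = plm.make_config(**cfg_kwargs)
        head = TaskHeadSpec("single_regression") if mode != "pretrain" else None
        acc = parameter_accounting(cfg, mode, head=head, unfreeze_last_k=k)
        model = plm.build_model(cfg, seed=0)
        if mode != "pretrain":
            model.attach_ia3()
            model.attach_head(head)
        total, trainable = model.actual_param_counts(mode, unfreeze_last_k=k)
        assert acc.total_params == total
        assert acc.trainable_params == trainable
        assert sum(acc.breakdown.values()) == acc.total_params

    def test_ia3_adapter_count_formula(self):
        cfg = plm.make_config(**TINY)
        acc = parameter_accounting(cfg, "ia3_frozen")
        assert acc.trainable_params == 2 * (16 + 16 + 64) == 192

    def test_pretrain_mode_everything_trainable(self):
        acc = parameter_accounting(plm.make_config(**TINY), "pretrain")
        assert acc.trainable_params == acc.total_params

    def test_paper_scale_ia3_fraction_below_one_percent(self):
        acc = parameter_accounting(plm.make_config("paper_1b"), "ia3_frozen",
                                   head=TaskHeadSpec("single_regression"))
        assert acc.trainable_fraction <= 0.01
        assert acc.total_params > 1e9  # the billion-parameter preset

    def test_unknown_tuning_mode_rejected(self):
        with pytest.raises(InvalidConfigError):
            parameter_accounting(plm.make_config(**TINY), "lora")


class TestEmbeddings:
    def test_identical_input_identical_embeddings(self, tiny_model, tiny_vocab):
        ts = plm.encode_for_model("ACGTAG", tiny_vocab, 16)
        a = tiny_model.embed(ts, layers=[2]).pooled[2]
        b = tiny_model.embed(ts, layers=[2]).pooled[2]
        assert np.array_equal(a, b)

    def test_pooled_vector_is_mean_of_position_vectors(self, tiny_model, tiny_vocab):
        ts = plm.encode_for_model("ACG", tiny_vocab, 8)
        stack = tiny_model.embed(ts, layers=[1])
        nonspec = ~ts.is_special
        manual = stack.raw[1][0][nonspec].mean(axis=0)
        np.testing.assert_allclose(stack.pooled[1][0], manual, rtol=1e-6)

    def test_layer_zero_is_post_positional_input(self, tiny_model, tiny_vocab):
        ts = plm.encode_for_model("ACG", tiny_vocab, 8)
        raw0 = tiny_model.embed(ts, layers=[0]).raw[0][0]
        expected = (tiny_model.params["tok_emb"][ts.ids]
                    + tiny_model.params["pos_emb"][:8])
        np.testing.assert_allclose(raw0, expected, rtol=1e-6)

    def test_invalid_layer_rejected(self, tiny_model, tiny_vocab):
        ts = plm.encode_for_model("ACG", tiny_vocab, 8)
        with pytest.raises(InvalidConfigError):
            tiny_model.embed(ts, layers=[5])


class TestGradients:
    """Finite-difference verification of the hand-written backprop."""

    def _check(self, lossfn, model, names, rng, tol=2e-4):
        _, grads = lossfn()
        for name in names:
            flat = model.params[name].reshape(-1)
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, old = 1e-5, flat[i]
                flat[i] = old + eps
                up, _ = lossfn()
                flat[i] = old - eps
                down, _ = lossfn()
                flat[i] = old
                numeric = (up - down) / (2 * eps)
                analytic = grads[name].reshape(-1)[i]
                assert abs(numeric - analytic) <= tol * max(1e-3, abs(numeric) + abs(analytic))

    @pytest.fixture()
    def grad_model(self):
        cfg = plm.make_config(vocab_size=13, max_tokens=10, embed_dim=8,
                              num_layers=2, num_heads=2, mlp_hidden=12)
        m = plm.build_model(cfg, seed=3, dtype=np.float64)
        m.attach_ia3()
        m.attach_head(TaskHeadSpec("binary_classification"), seed=4)
        rng = np.random.default_rng(5)
        for n in m.params:  # move adapters off the identity, widen attention
            if ".ia3_" in n:
                m.params[n] = 1.0 + 0.1 * rng.normal(size=m.params[n].shape)
            if n.endswith(("wq", "wk")):
                m.params[n] *= 20
        return m, rng

    def test_mlm_gradients_match_finite_differences(self, grad_model):
        m, rng = grad_model
        ids = rng.integers(0, 9, (3, 10))
        spec = np.zeros((3, 10), bool)
        spec[:, 0] = True
        spec[:, 8:] = True
        ids[:, 0], ids[:, 8:] = 11, 9  # CLS, PAD
        sel = np.zeros((3, 10), bool)
        sel[:, 2] = True
        sel[1, 5] = True
        lab = rng.integers(0, 9, (3, 10))
        names = ["tok_emb", "pos_emb", "b0.wq", "b0.wk", "b1.wv", "b0.ia3_k",
                 "b1.ia3_v", "b0.ia3_m", "b1.ln1.g", "b0.w1", "b1.wo", "lm.w",
                 "lnf.g", "b0.ln2.b"]
        self._check(lambda: m.mlm_loss_and_grads(ids, spec, sel, lab), m, names, rng)

    def test_head_gradients_match_finite_differences(self, grad_model):
        m, rng = grad_model
        ids = rng.integers(0, 9, (3, 10))
        spec = np.zeros((3, 10), bool)
        spec[:, 0] = True
        ids[:, 0] = 11
        targets = rng.random((3, 1))
        names = ["head.w", "head.b", "b0.ia3_k", "b1.ia3_m", "b0.wq", "tok_emb"]
        self._check(lambda: m.head_loss_and_grads(ids, spec, targets), m, names, rng)

    def test_detection_head_gradients_match_finite_differences(self):
        cfg = plm.make_config(vocab_size=13, max_tokens=10, embed_dim=8,
                              num_layers=1, num_heads=2, mlp_hidden=12)
        m = plm.build_model(cfg, seed=3, dtype=np.float64)
        m.attach_head(TaskHeadSpec("binary_classification", pooling="detection"),
                      seed=4)
        rng = np.random.default_rng(6)
        m.params["head.w"] *= 50  # non-uniform soft-max pooling weights
        ids = rng.integers(0, 9, (2, 10))
        spec = np.zeros((2, 10), bool)
        spec[:, 0] = True
        spec[:, 8:] = True
        ids[:, 0], ids[:, 8:] = 11, 9
        targets = rng.random((2, 1))
        self._check(lambda: m.head_loss_and_grads(ids, spec, targets), m,
                    ["head.w", "head.b", "tok_emb", "b0.w1"], rng)

    def test_frozen_backbone_untouched_by_ia3_update(self, grad_model):
        m, rng = grad_model
        ids = rng.integers(0, 9, (2, 10))
        spec = np.zeros((2, 10), bool)
        spec[:, 0] = True
        ids[:, 0] = 11
        targets = rng.random((2, 1))
        before = {n: v.copy() for n, v in m.params.items()}
        opt = plm.Adam(m.trainable_names("ia3_frozen"))
        for _ in range(3):
            _, grads = m.head_loss_and_grads(ids, spec, targets)
            opt.step(m.params, grads, 1e-2)
        for n, v in m.params.items():
            if ".ia3_" in n or n.startswith("head."):
                assert not np.array_equal(v, before[n])
            else:
                assert np.array_equal(v, before[n]), n
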