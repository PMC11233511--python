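"""Encoder-only transformer with an MLM head, implemented in NumPy.

The model follows the standard pre-layer-norm encoder block — layer norm,
multi-head self-attention, layer norm, MLP — with learned positional
embeddings and a final layer norm before the language-model projection.
Forward and backward passes are written out explicitly (verified against
finite differences in the test suite), which keeps the package free of any
deep-learning framework dependency and makes every gradient path auditable.

IA3 parameter-efficient fine-tuning inserts multiplicative rescaling vectors
on the attention keys, attention values, and MLP intermediate activations of
every block. At their all-ones initialization the adapted model is exactly
the base model; under the frozen-backbone tuning mode only these vectors and
the task head receive gradient updates.

Parameter accounting is symbolic (no tensors allocated), so the billion-
parameter preset can be audited on a laptop.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import erf

from .tokenizer import TokenSequence

_LN_EPS = 1e-5
_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class InvalidConfigError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    max_tokens: int
    embed_dim: int
    num_layers: int
    num_heads: int
    mlp_hidden: int | None = None
    learned_positional_embeddings: bool = True

    def __post_init__(self):
        if self.mlp_hidden is None:
            # default MLP expansion ratio of 4x, the transformer convention
            object.__setattr__(self, "mlp_hidden", 4 * self.embed_dim)
        if self.embed_dim % self.num_heads != 0:
            raise InvalidConfigError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}")
        for name in ("vocab_size", "max_tokens", "embed_dim", "num_layers", "num_heads"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be positive")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads


#: Named presets. ``paper_1b`` documents the published architecture
#: (4105-token vocabulary, 1025-token input, 1500-dim embeddings, 40 blocks);
#: its MLP width and head count are approximate since they are not printed in
#: the main text.
PRESETS: dict[str, dict] = {
    "tiny": dict(vocab_size=4105, max_tokens=64, embed_dim=64,
                 num_layers=2, num_heads=4, mlp_hidden=256),
    "small": dict(vocab_size=4105, max_tokens=256, embed_dim=128,
                  num_layers=4, num_heads=8, mlp_hidden=512),
    "paper_1b": dict(vocab_size=4105, max_tokens=1025, embed_dim=1500,
                     num_layers=40, num_heads=20, mlp_hidden=6000),
}


def make_config(preset: str | None = None, **overrides) -> ModelConfig:
    kwargs = dict(PRESETS[preset]) if preset else {}
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


# ---------------------------------------------------------------------------
# symbolic parameter accounting


@dataclass
class ParameterAccounting:
    total_params: int
    trainable_params: int
    breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def trainable_fraction(self) -> float:
        return self.trainable_params / self.total_params


TUNING_MODES = ("pretrain", "ia3_frozen", "ia3_unfreeze_last_k")


def parameter_accounting(config: ModelConfig, tuning_mode: str = "pretrain",
                         head: "TaskHeadSpec | None" = None,
                         unfreeze_last_k: int = 0) -> ParameterAccounting:
    """Count total and trainable parameters symbolically.

    In ``pretrain`` mode the LM head is part of the model and everything is
    trainable. In the IA3 modes the LM head is replaced by the task head;
    total = backbone + IA3 vectors + head, trainable = IA3 vectors + head
    (+ the last ``unfreeze_last_k`` blocks if requested).
    """
    if tuning_mode not in TUNING_MODES:
        raise InvalidConfigError(f"unknown tuning mode {tuning_mode!r}")
    if tuning_mode == "ia3_unfreeze_last_k" and unfreeze_last_k > config.num_layers:
        raise InvalidConfigError("unfreeze_last_k exceeds num_layers")
    D, F, L, V, T = (config.embed_dim, config.mlp_hidden, config.num_layers,
                     config.vocab_size, config.max_tokens)
    emb = V * D + (T * D if config.learned_positional_embeddings else 0)
    attn_per_block = 4 * (D * D + D)
    norm_per_block = 2 * (2 * D)
    mlp_per_block = D * F + F + F * D + D
    block = attn_per_block + norm_per_block + mlp_per_block
    final_norm = 2 * D
    lm_head = D * V + V
    ia3_per_block = 2 * D + F
    head_params = head.num_params(D) if head is not None else 0

    breakdown = {
        "embeddings": emb,
        "attention_blocks": L * (attn_per_block + norm_per_block),
        "mlp_blocks": L * mlp_per_block,
        "final_norm": final_norm,
    }
    if tuning_mode == "pretrain":
        breakdown["lm_head"] = lm_head
        total = emb + L * block + final_norm + lm_head
        trainable = total
    else:
        breakdown["ia3_vectors"] = L * ia3_per_block
        breakdown["task_head"] = head_params
        total = emb + L * block + final_norm + L * ia3_per_block + head_params
        trainable = L * ia3_per_block + head_params
        if tuning_mode == "ia3_unfreeze_last_k":
            trainable += unfreeze_last_k * block
    assert sum(breakdown.values()) == total
    return ParameterAccounting(total_params=total, trainable_params=trainable,
                               breakdown=breakdown)


@dataclass(frozen=True)
class TaskHeadSpec:
    """Task head on the final hidden states.

    ``pooling='mean'`` is a linear map on the mean over non-special
    positions — the natural readout for dense targets such as expression.
    ``pooling='detection'`` scores every adjacent pair of non-special
    positions with a width-2 convolution and aggregates by log-sum-exp
    (a soft maximum): the multiple-instance readout for presence tasks,
    where the label is carried by a short local signal anywhere in the
    window rather than by the whole sequence.
    """

    kind: str  # binary_classification | multi_label_classification |
               # single_regression | multi_regression
    num_outputs: int = 1
    pooling: str = "mean"  # mean | detection
    #: residual-stream depth the head reads from; None = final layer norm
    #: output, an integer taps the output of that attention block
    layer: int | None = None

    def __post_init__(self):
        kinds = ("binary_classification", "multi_label_classification",
                 "single_regression", "multi_regression")
        if self.kind not in kinds:
            raise InvalidConfigError(f"unknown task kind {self.kind!r}")
        if self.pooling not in ("mean", "detection"):
            raise InvalidConfigError(f"unknown head pooling {self.pooling!r}")
        if self.num_outputs < 1:
            raise InvalidConfigError("num_outputs must be >= 1")
        if self.num_outputs > 1 and self.kind in ("binary_classification",
                                                  "single_regression"):
            raise InvalidConfigError(f"{self.kind} requires num_outputs == 1")

    @property
    def is_classification(self) -> bool:
        return self.kind.endswith("classification")

    def num_params(self, embed_dim: int) -> int:
        width = 2 * embed_dim if self.pooling == "detection" else embed_dim
        return width * self.num_outputs + self.num_outputs


# ---------------------------------------------------------------------------
# numerics


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    invstd = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * invstd
    return xhat * g + b, (xhat, invstd)


def _layernorm_bwd(dy, g, cache):
    xhat, invstd = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = invstd * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def _gelu_grad(x):
    return 0.5 * (1.0 + erf(x * _INV_SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def _softmax(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class TransformerLM:
    """Seed-deterministic encoder-only transformer with explicit backprop."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.has_ia3 = False
        self.head_spec: TaskHeadSpec | None = None
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        D, F, V, T = config.embed_dim, config.mlp_hidden, config.vocab_size, config.max_tokens
        init = lambda *shape: rng.normal(0.0, 0.02, size=shape).astype(dtype)
        self.params["tok_emb"] = init(V, D)
        if config.learned_positional_embeddings:
            self.params["pos_emb"] = init(T, D)
        for i in range(config.num_layers):
            p = f"b{i}."
            self.params[p + "ln1.g"] = np.ones(D, dtype)
            self.params[p + "ln1.b"] = np.zeros(D, dtype)
            for w in ("wq", "wk", "wv", "wo"):
                self.params[p + w] = init(D, D)
                self.params[p + w + "_b"] = np.zeros(D, dtype)
            self.params[p + "ln2.g"] = np.ones(D, dtype)
            self.params[p + "ln2.b"] = np.zeros(D, dtype)
            self.params[p + "w1"] = init(D, F)
            self.params[p + "w1_b"] = np.zeros(F, dtype)
            self.params[p + "w2"] = init(F, D)
            self.params[p + "w2_b"] = np.zeros(D, dtype)
        self.params["lnf.g"] = np.ones(D, dtype)
        self.params["lnf.b"] = np.zeros(D, dtype)
        self.params["lm.w"] = init(D, V)
        self.params["lm.b"] = np.zeros(V, dtype)

    # -- structure -------------------------------------------------------

    def attach_ia3(self) -> None:
        """Add all-ones rescaling vectors (keys, values, MLP intermediate)."""
        if self.has_ia3:
            return
        D, F = self.config.embed_dim, self.config.mlp_hidden
        for i in range(self.config.num_layers):
            self.params[f"b{i}.ia3_k"] = np.ones(D, self.dtype)
            self.params[f"b{i}.ia3_v"] = np.ones(D, self.dtype)
            self.params[f"b{i}.ia3_m"] = np.ones(F, self.dtype)
        self.has_ia3 = True

    def attach_head(self, head: TaskHeadSpec, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        D = self.config.embed_dim
        width = 2 * D if head.pooling == "detection" else D
        self.params["head.w"] = rng.normal(0.0, 0.02, (width, head.num_outputs)).astype(self.dtype)
        self.params["head.b"] = np.zeros(head.num_outputs, self.dtype)
        self.head_spec = head

    def trainable_names(self, tuning_mode: str, unfreeze_last_k: int = 0) -> list[str]:
        if tuning_mode not in TUNING_MODES:
            raise InvalidConfigError(f"unknown tuning mode {tuning_mode!r}")
        if tuning_mode == "pretrain":
            return list(self.params)
        if unfreeze_last_k > self.config.num_layers:
            raise InvalidConfigError("unfreeze_last_k exceeds num_layers")
        names = [n for n in self.params
                 if ".ia3_" in n or n.startswith("head.")]
        if tuning_mode == "ia3_unfreeze_last_k":
            first = self.config.num_layers - unfreeze_last_k
            for n in self.params:
                if n.startswith("b") and "." in n and ".ia3_" not in n:
                    layer = int(n[1:n.index(".")])
                    if layer >= first:
                        names.append(n)
        return names

    def actual_param_counts(self, tuning_mode: str = "pretrain",
                            unfreeze_last_k: int = 0) -> tuple[int, int]:
        """Oracle for the symbolic accounting: sizes of allocated arrays."""
        skip = {"lm.w", "lm.b"} if tuning_mode != "pretrain" else set()
        total = sum(v.size for n, v in self.params.items() if n not in skip)
        trainable = sum(self.params[n].size
                        for n in self.trainable_names(tuning_mode, unfreeze_last_k)
                        if n not in skip)
        return total, trainable

    # -- forward ---------------------------------------------------------

    def _forward(self, ids: np.ndarray, pad_mask: np.ndarray | None,
                 keep_cache: bool = False):
        cfg = self.config
        P = self.params
        B, T = ids.shape
        H, dh = cfg.num_heads, cfg.head_dim
        scale = 1.0 / math.sqrt(dh)
        x = P["tok_emb"][ids]
        if cfg.learned_positional_embeddings:
            x = x + P["pos_emb"][:T]
        if pad_mask is not None and pad_mask.any():
            bias = np.where(pad_mask[:, None, None, :], -1e9, 0.0).astype(x.dtype)
        else:
            bias = None
        cache = {"ids": ids, "pad_mask": pad_mask, "blocks": [], "x_layers": [x]}
        for i in range(cfg.num_layers):
            p = f"b{i}."
            a1, ln1c = _layernorm_fwd(x, P[p + "ln1.g"], P[p + "ln1.b"])
            q = a1 @ P[p + "wq"] + P[p + "wq_b"]
            k_pre = a1 @ P[p + "wk"] + P[p + "wk_b"]
            v_pre = a1 @ P[p + "wv"] + P[p + "wv_b"]
            if self.has_ia3:
                k = k_pre * P[p + "ia3_k"]
                v = v_pre * P[p + "ia3_v"]
            else:
                k, v = k_pre, v_pre
            qh = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            kh = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            vh = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            s = np.matmul(qh, kh.transpose(0, 1, 3, 2)) * scale
            if bias is not None:
                s = s + bias
            probs = _softmax(s)
            oh = np.matmul(probs, vh)
            o = oh.transpose(0, 2, 1, 3).reshape(B, T, cfg.embed_dim)
            x_mid = x + o @ P[p + "wo"] + P[p + "wo_b"]
            a2, ln2c = _layernorm_fwd(x_mid, P[p + "ln2.g"], P[p + "ln2.b"])
            m_pre = a2 @ P[p + "w1"] + P[p + "w1_b"]
            m_act = _gelu(m_pre)
            m = m_act * P[p + "ia3_m"] if self.has_ia3 else m_act
            x = x_mid + m @ P[p + "w2"] + P[p + "w2_b"]
            if keep_cache:
                cache["blocks"].append(dict(
                    a1=a1, ln1c=ln1c, q=q, k_pre=k_pre, v_pre=v_pre, k=k,
                    probs=probs, o=o, x_mid=x_mid, a2=a2, ln2c=ln2c,
                    m_pre=m_pre, m_act=m_act, m=m, vh=vh))
            cache["x_layers"].append(x)
        h, lnfc = _layernorm_fwd(x, P["lnf.g"], P["lnf.b"])
        cache["h"] = h
        cache["lnfc"] = lnfc
        return cache

    def logits(self, ids: np.ndarray, is_special: np.ndarray | None = None) -> np.ndarray:
        """MLM logits over the vocabulary at every position; (B, T, V)."""
        ids, pad_mask = self._prep(ids, is_special)
        c = self._forward(ids, pad_mask)
        return c["h"] @ self.params["lm.w"] + self.params["lm.b"]

    def _prep(self, ids, is_special):
        ids = np.atleast_2d(np.asarray(ids))
        if is_special is None:
            pad_mask = None
        else:
            is_special = np.atleast_2d(np.asarray(is_special))
            # only PAD is excluded from attention keys; CLS attends normally
            pad_mask = (ids == self._pad_id_guess()) & is_special
        return ids, pad_mask

    def _pad_id_guess(self) -> int:
        # vocabulary layout: [... kmers, standalone x5, PAD, MASK, CLS, UNK]
        return self.config.vocab_size - 4

    # -- embeddings ------------------------------------------------------

    def embed(self, sequences: "TokenSequence | Sequence[TokenSequence]",
              layers: Sequence[int] | None = None) -> "EmbeddingStack":
        """Per-layer token embeddings and mean pooling over non-special positions.

        Layer 0 is the post-positional-embedding input representation; layer
        ``i`` (1 <= i < num_layers) is the residual stream after block ``i``;
        layer ``num_layers`` is the final layer-normalized hidden state.
        """
        seqs = [sequences] if isinstance(sequences, TokenSequence) else list(sequences)
        ids = np.stack([s.ids for s in seqs])
        is_special = np.stack([s.is_special for s in seqs])
        if (~is_special).sum() == 0:
            raise DegenerateInputError("no non-special positions to embed")
        L = self.config.num_layers
        layers = list(range(L + 1)) if layers is None else list(layers)
        for l in layers:
            if not 0 <= l <= L:
                raise InvalidConfigError(f"layer index {l} outside [0, {L}]")
        _, pad_mask = self._prep(ids, is_special)
        c = self._forward(ids, pad_mask)
        nonspec = (~is_special).astype(c["h"].dtype)
        denom = nonspec.sum(axis=1, keepdims=True)
        raw, pooled = {}, {}
        for l in layers:
            mat = c["h"] if l == L else c["x_layers"][l]
            raw[l] = mat
            pooled[l] = (mat * nonspec[:, :, None]).sum(axis=1) / denom
        return EmbeddingStack(raw=raw, pooled=pooled)

    # -- heads and losses ------------------------------------------------

    def predict(self, ids: np.ndarray, is_special: np.ndarray) -> np.ndarray:
        """Task-head output on the final hidden states.

        Classification heads return probabilities (sigmoid); regression heads
        return raw values. Shape (B, num_outputs).
        """
        if self.head_spec is None:
            raise InvalidConfigError("no task head attached")
        ids, pad_mask = self._prep(ids, is_special)
        c = self._forward(ids, pad_mask)
        h = self._head_input(c)
        y, _ = self._head_forward(h, np.atleast_2d(is_special))
        if self.head_spec.is_classification:
            y = 1.0 / (1.0 + np.exp(-y))
        return y

    def _head_input(self, cache):
        layer = self.head_spec.layer
        if layer is None:
            return cache["h"]
        if not 0 <= layer <= self.config.num_layers:
            raise InvalidConfigError(f"head layer {layer} outside model depth")
        return cache["x_layers"][layer]

    @staticmethod
    def _pool(h, is_special):
        nonspec = (~is_special).astype(h.dtype)
        return (h * nonspec[:, :, None]).sum(axis=1) / nonspec.sum(axis=1, keepdims=True)

    def _head_forward(self, h, is_special):
        """Raw head output (pre-activation) plus a cache for the backward pass."""
        W, b = self.params["head.w"], self.params["head.b"]
        if self.head_spec.pooling == "detection":
            nonspec = ~is_special
            pair_valid = nonspec[:, :-1] & nonspec[:, 1:]  # (B, T-1)
            if not pair_valid.any(axis=1).all():
                raise DegenerateInputError(
                    "detection head needs >= 2 adjacent non-special positions")
            pairs = np.concatenate([h[:, :-1], h[:, 1:]], axis=2)  # (B,T-1,2D)
            s = pairs @ W + b
            s = np.where(pair_valid[:, :, None], s, -np.inf)
            m = s.max(axis=1, keepdims=True)
            e = np.exp(s - m)
            e = np.where(np.isfinite(s), e, 0.0)
            z = e.sum(axis=1, keepdims=True)
            y = (m + np.log(z))[:, 0, :]
            return y, {"pairs": pairs, "softmax": e / z}
        nonspec = (~is_special).astype(h.dtype)
        denom = nonspec.sum(axis=1, keepdims=True)
        pooled = (h * nonspec[:, :, None]).sum(axis=1) / denom
        return pooled @ W + b, {"pooled": pooled, "nonspec": nonspec, "denom": denom}

    def _head_backward(self, dy, h, hcache, grads):
        """Gradient w.r.t. the final hidden states plus head weight grads."""
        W = self.params["head.w"]
        if self.head_spec.pooling == "detection":
            pairs, p = hcache["pairs"], hcache["softmax"]
            ds = p * dy[:, None, :]                       # (B,T-1,O)
            B, Tm1, twoD = pairs.shape
            grads["head.w"] = pairs.reshape(-1, twoD).T @ ds.reshape(-1, dy.shape[1])
            grads["head.b"] = dy.sum(axis=0)
            dpairs = ds @ W.T
            D = twoD // 2
            dh = np.zeros_like(h)
            dh[:, :-1] += dpairs[:, :, :D]
            dh[:, 1:] += dpairs[:, :, D:]
            return dh
        pooled, nonspec, denom = hcache["pooled"], hcache["nonspec"], hcache["denom"]
        grads["head.w"] = pooled.T @ dy
        grads["head.b"] = dy.sum(axis=0)
        dpooled = dy @ W.T
        return (dpooled[:, None, :] * nonspec[:, :, None]) / denom[:, :, None]

    def mlm_loss_and_grads(self, ids, is_special, sel_mask, labels):
        """Masked-token cross-entropy and gradients for all parameters.

        ``sel_mask`` (B, T) marks the selected positions; ``labels`` (B, T)
        holds the original token ids there (ignored elsewhere).
        """
        ids, pad_mask = self._prep(ids, is_special)
        c = self._forward(ids, pad_mask, keep_cache=True)
        h = c["h"]
        B, T, D = h.shape
        V = self.config.vocab_size
        logits = h @ self.params["lm.w"] + self.params["lm.b"]
        n_sel = int(sel_mask.sum())
        if n_sel == 0:
            return 0.0, {n: np.zeros_like(v) for n, v in self.params.items()}
        z = logits - logits.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        loss = -logp[sel_mask, labels[sel_mask]].mean()
        dlogits = np.exp(logp)
        oh = np.zeros_like(dlogits)
        oh[sel_mask, labels[sel_mask]] = 1.0
        dlogits = (dlogits - oh) * sel_mask[:, :, None] / n_sel
        grads = {}
        hf = h.reshape(-1, D)
        dlf = dlogits.reshape(-1, V)
        grads["lm.w"] = hf.T @ dlf
        grads["lm.b"] = dlf.sum(axis=0)
        dh = dlogits @ self.params["lm.w"].T
        self._backward(c, dh, grads)
        return float(loss), grads

    def head_loss_and_grads(self, ids, is_special, targets):
        """Task-head loss (BCE for classification, MSE for regression) + grads."""
        if self.head_spec is None:
            raise InvalidConfigError("no task head attached")
        ids, pad_mask = self._prep(ids, is_special)
        is_special = np.atleast_2d(is_special)
        targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
        c = self._forward(ids, pad_mask, keep_cache=True)
        h = self._head_input(c)
        y, hcache = self._head_forward(h, is_special)
        n = y.size
        if self.head_spec.is_classification:
            # numerically stable BCE-with-logits
            loss = float(np.mean(np.maximum(y, 0) - y * targets + np.log1p(np.exp(-np.abs(y)))))
            dy = (1.0 / (1.0 + np.exp(-y)) - targets) / n
        else:
            diff = y - targets
            loss = float(np.mean(diff * diff))
            dy = 2.0 * diff / n
        dy = dy.astype(h.dtype)
        grads = {}
        dh = self._head_backward(dy, h, hcache, grads)
        self._backward(c, dh, grads, head_layer=self.head_spec.layer)
        return loss, grads

    # -- backward --------------------------------------------------------

    def _backward(self, cache, dh, grads, head_layer: int | None = None):
        """Backprop from the head's read-out point through the blocks below it.

        ``head_layer=None`` starts at the final layer norm (the MLM path and
        default head); an integer starts at that block's residual output, so
        blocks above it receive no gradient."""
        cfg = self.config
        P = self.params
        B, T, D = dh.shape
        H, dhd = cfg.num_heads, cfg.head_dim
        scale = 1.0 / math.sqrt(dhd)
        if head_layer is None:
            dx, dg, db = _layernorm_bwd(dh, P["lnf.g"], cache["lnfc"])
            grads["lnf.g"], grads["lnf.b"] = dg, db
            n_blocks = cfg.num_layers
        else:
            dx = dh
            n_blocks = head_layer
        for i in reversed(range(n_blocks)):
            p = f"b{i}."
            bc = cache["blocks"][i]
            # MLP branch: x = x_mid + m @ w2 + b2
            mf = bc["m"].reshape(-1, cfg.mlp_hidden)
            dxf = dx.reshape(-1, D)
            grads[p + "w2"] = mf.T @ dxf
            grads[p + "w2_b"] = dxf.sum(axis=0)
            dm = dx @ P[p + "w2"].T
            if self.has_ia3:
                grads[p + "ia3_m"] = (dm * bc["m_act"]).sum(axis=(0, 1))
                dm_act = dm * P[p + "ia3_m"]
            else:
                dm_act = dm
            dm_pre = dm_act * _gelu_grad(bc["m_pre"])
            a2f = bc["a2"].reshape(-1, D)
            dmpf = dm_pre.reshape(-1, cfg.mlp_hidden)
            grads[p + "w1"] = a2f.T @ dmpf
            grads[p + "w1_b"] = dmpf.sum(axis=0)
            da2 = dm_pre @ P[p + "w1"].T
            dx_mid_ln, dg2, db2 = _layernorm_bwd(da2, P[p + "ln2.g"], bc["ln2c"])
            grads[p + "ln2.g"], grads[p + "ln2.b"] = dg2, db2
            dx_mid = dx + dx_mid_ln
            # attention branch: x_mid = x_in + o @ wo + bo
            of = bc["o"].reshape(-1, D)
            dxmf = dx_mid.reshape(-1, D)
            grads[p + "wo"] = of.T @ dxmf
            grads[p + "wo_b"] = dxmf.sum(axis=0)
            do = dx_mid @ P[p + "wo"].T
            doh = do.reshape(B, T, H, dhd).transpose(0, 2, 1, 3)
            probs, vh = bc["probs"], bc["vh"]
            dprobs = np.matmul(doh, vh.transpose(0, 1, 3, 2))
            dvh = np.matmul(probs.transpose(0, 1, 3, 2), doh)
            ds = probs * (dprobs - (dprobs * probs).sum(axis=-1, keepdims=True))
            qh = bc["q"].reshape(B, T, H, dhd).transpose(0, 2, 1, 3)
            kh = bc["k"].reshape(B, T, H, dhd).transpose(0, 2, 1, 3)
            dqh = np.matmul(ds, kh) * scale
            dkh = np.matmul(ds.transpose(0, 1, 3, 2), qh) * scale
            dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, D)
            dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, D)
            dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, D)
            if self.has_ia3:
                grads[p + "ia3_k"] = (dk * bc["k_pre"]).sum(axis=(0, 1))
                grads[p + "ia3_v"] = (dv * bc["v_pre"]).sum(axis=(0, 1))
                dk = dk * P[p + "ia3_k"]
                dv = dv * P[p + "ia3_v"]
            a1f = bc["a1"].reshape(-1, D)
            grads[p + "wq"] = a1f.T @ dq.reshape(-1, D)
            grads[p + "wq_b"] = dq.reshape(-1, D).sum(axis=0)
            grads[p + "wk"] = a1f.T @ dk.reshape(-1, D)
            grads[p + "wk_b"] = dk.reshape(-1, D).sum(axis=0)
            grads[p + "wv"] = a1f.T @ dv.reshape(-1, D)
            grads[p + "wv_b"] = dv.reshape(-1, D).sum(axis=0)
            da1 = dq @ P[p + "wq"].T + dk @ P[p + "wk"].T + dv @ P[p + "wv"].T
            dx_in_ln, dg1, db1 = _layernorm_bwd(da1, P[p + "ln1.g"], bc["ln1c"])
            grads[p + "ln1.g"], grads[p + "ln1.b"] = dg1, db1
            dx = dx_mid + dx_in_ln
        ids = cache["ids"]
        dtok = np.zeros_like(P["tok_emb"])
        np.add.at(dtok, ids, dx)
        grads["tok_emb"] = dtok
        if cfg.learned_positional_embeddings:
            dpos = np.zeros_like(P["pos_emb"])
            dpos[:T] = dx.sum(axis=0)
            grads["pos_emb"] = dpos
        for name, v in self.params.items():
            grads.setdefault(name, np.zeros_like(v))
        return grads

    # -- checkpointing ---------------------------------------------------

    def save(self, ckpt_dir: str) -> None:
        os.makedirs(ckpt_dir, exist_ok=True)
        meta = {"config": asdict(self.config), "has_ia3": self.has_ia3,
                "head": asdict(self.head_spec) if self.head_spec else None}
        with open(os.path.join(ckpt_dir, "config.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        np.savez(os.path.join(ckpt_dir, "weights.npz"), **self.params)

    @classmethod
    def load(cls, ckpt_dir: str) -> "TransformerLM":
        with open(os.path.join(ckpt_dir, "config.json")) as fh:
            meta = json.load(fh)
        model = cls(ModelConfig(**meta["config"]))
        if meta["has_ia3"]:
            model.attach_ia3()
        if meta.get("head"):
            model.attach_head(TaskHeadSpec(**meta["head"]))
        with np.load(os.path.join(ckpt_dir, "weights.npz")) as npz:
            model.params = {k: npz[k] for k in npz.files}
        return model


@dataclass
class EmbeddingStack:
    """Per-layer token embeddings plus mean-pooled vectors per layer."""

    raw: dict[int, np.ndarray]     # layer -> (B, T, D)
    pooled: dict[int, np.ndarray]  # layer -> (B, D)


def build_model(config: ModelConfig, seed: int = 0, dtype=np.float32) -> TransformerLM:
    return TransformerLM(config, seed=seed, dtype=dtype)


class Adam:
    """Adam optimizer restricted to a declared set of trainable parameters."""

    def __init__(self, trainable: Sequence[str], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.trainable = list(trainable)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for n in self.trainable:
            g = grads[n].astype(np.float64)
            m = self.m.setdefault(n, np.zeros(g.shape))
            v = self.v.setdefault(n, np.zeros(g.shape))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            params[n] = (params[n] - lr * (m / c1) /
                         (np.sqrt(v / c2) + self.eps)).astype(params[n].dtype)
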