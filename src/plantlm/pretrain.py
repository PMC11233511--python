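"""Masked-language-model pre-training on genomic chunks.

Genomes are split into fixed-length chunks (default 6100 nt) whose
consecutive windows share the first and last 50 nt. As augmentation, each
epoch re-tokenizes every chunk from a random start offset in [0, 100].
The objective selects 15% of the non-special tokens; of those, 80% are
replaced by the mask token, 10% by a random different vocabulary token, and
10% are kept unchanged — cross-entropy is computed at the selected positions
only. The learning rate warms up linearly from 5e-5 to 1e-4 over 64k steps
and then decays (default inverse-square-root); these defaults document the
published training recipe, while desk-scale runs pass a scaled-down config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .model import Adam, TransformerLM
from .tokenizer import TokenSequence, TokenVocabulary, encode_for_model

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    pass


@dataclass
class GenomeChunk:
    chromosome: str
    start: int  # 0-based half-open
    end: int
    sequence: str

    def __post_init__(self):
        assert len(self.sequence) == self.end - self.start


def _iter_chromosomes(genome) -> Iterator[tuple[str, str]]:
    """Accept a {name: sequence} dict, a pyfaidx.Fasta, or a FASTA path."""
    if isinstance(genome, dict):
        yield from genome.items()
        return
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        import pyfaidx
        fa = pyfaidx.Fasta(str(genome))
        for name in fa.keys():
            yield name, str(fa[name][:])
        return
    # pyfaidx.Fasta-like object
    for name in genome.keys():
        yield name, str(genome[name][:])


def chunk_genome(genome, chunk_length: int = 6100,
                 overlap: int = 50) -> Iterator[GenomeChunk]:
    """Tile each chromosome with windows of ``chunk_length`` overlapping by
    ``overlap``; stride = chunk_length - overlap. Chunking stops once a
    window reaches the chromosome end, so every base is covered at least
    once and non-tail overlapping bases belong to exactly two chunks."""
    if chunk_length <= 2 * overlap:
        raise ValueError("chunk_length must exceed 2*overlap")
    stride = chunk_length - overlap
    for name, seq in _iter_chromosomes(genome):
        n = len(seq)
        if n <= overlap:
            logger.warning("chromosome %s shorter than overlap; one whole chunk", name)
            yield GenomeChunk(name, 0, n, seq)
            continue
        start = 0
        while True:
            end = min(start + chunk_length, n)
            yield GenomeChunk(name, start, end, seq[start:end])
            if end >= n:
                break
            start += stride


def sample_augmented_window(chunk: GenomeChunk, offset_range: tuple[int, int] = (0, 100),
                            rng: np.random.Generator | int | None = None) -> str:
    """Drop a random prefix of 0..100 nt before tokenization (per-epoch augmentation)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo, hi = offset_range
    if len(chunk.sequence) <= hi:
        raise ValueError(f"chunk of {len(chunk.sequence)} nt shorter than max offset {hi}")
    offset = int(rng.integers(lo, hi + 1))
    return chunk.sequence[offset:]


@dataclass
class MaskingPlan:
    """Selected positions, their corruption actions, and the MLM labels."""

    selected: np.ndarray              # position indices, per flattened sequence
    action: np.ndarray                # 0=mask, 1=random, 2=keep, per selected
    labels: np.ndarray                # original token id per selected position
    rng_seed: int | None = None

    ACTION_MASK, ACTION_RANDOM, ACTION_KEEP = 0, 1, 2


def make_masking_plan(tokens: TokenSequence, vocab: TokenVocabulary,
                      select_rate: float = 0.15, mask_frac: float = 0.8,
                      random_frac: float = 0.1, keep_frac: float = 0.1,
                      rng: np.random.Generator | int | None = None,
                      exact_counts: bool = False) -> tuple[MaskingPlan, TokenSequence]:
    """Select non-special positions and corrupt them for the MLM objective.

    Selection is independent Bernoulli at ``select_rate`` by default
    (``exact_counts=True`` draws exactly round(rate*n) positions). Random
    replacement draws uniformly from non-special tokens excluding the
    original. CLS and PAD are never touched.
    """
    if abs(mask_frac + random_frac + keep_frac - 1.0) > 1e-9:
        raise ValueError("mask/random/keep fractions must sum to 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    candidates = np.flatnonzero(~tokens.is_special)
    if candidates.size == 0:
        raise DegenerateInputError("all positions are special; nothing to mask")
    if exact_counts:
        n_sel = int(round(select_rate * candidates.size))
        selected = np.sort(rng.choice(candidates, size=n_sel, replace=False))
    else:
        selected = candidates[rng.random(candidates.size) < select_rate]
    action = rng.choice(3, size=selected.size, p=(mask_frac, random_frac, keep_frac))
    labels = tokens.ids[selected].copy()
    corrupted = tokens.ids.copy()
    corrupted[selected[action == MaskingPlan.ACTION_MASK]] = vocab.mask_id
    rand_pos = selected[action == MaskingPlan.ACTION_RANDOM]
    if rand_pos.size:
        pool = vocab.nonspecial_ids
        draws = pool[rng.integers(0, pool.size, size=rand_pos.size)]
        # redraw collisions with the original token
        clash = draws == corrupted[rand_pos]
        while clash.any():
            draws[clash] = pool[rng.integers(0, pool.size, size=int(clash.sum()))]
            clash = draws == tokens.ids[rand_pos]
        corrupted[rand_pos] = draws
    out = TokenSequence(ids=corrupted, is_special=tokens.is_special.copy(),
                        source_span=tokens.source_span)
    plan = MaskingPlan(selected=selected, action=action, labels=labels, rng_seed=seed)
    return plan, out


def mlm_loss(logits: np.ndarray, plan: MaskingPlan) -> float:
    """Mean cross-entropy over the selected positions only."""
    logits = np.asarray(logits)
    if logits.ndim == 3:
        logits = logits[0]
    if plan.selected.size == 0:
        logger.warning("empty masking selection; loss defined as 0")
        return 0.0
    sub = logits[plan.selected]
    z = sub - sub.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    return float(-logp[np.arange(plan.selected.size), plan.labels].mean())


@dataclass
class ScheduleConfig:
    """Adam learning-rate schedule; defaults document the published recipe."""

    warmup_steps: int = 64_000
    init_lr: float = 0.00005
    peak_lr: float = 0.0001
    decay_exponent: float = 0.5
    total_steps: int = 315_000
    beta1: float = 0.9
    beta2: float = 0.999
    effective_batch_tokens: int = 1_500_000

    def __post_init__(self):
        if self.init_lr > self.peak_lr:
            raise ValueError("init_lr must be <= peak_lr")
        if self.warmup_steps >= self.total_steps:
            raise ValueError("warmup_steps must be < total_steps")


def lr_schedule(step: int, cfg: ScheduleConfig) -> float:
    """Linear warmup to peak_lr, then (warmup/step)^decay_exponent decay."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if step <= cfg.warmup_steps:
        frac = step / cfg.warmup_steps if cfg.warmup_steps else 1.0
        return cfg.init_lr + (cfg.peak_lr - cfg.init_lr) * frac
    return cfg.peak_lr * (cfg.warmup_steps / step) ** cfg.decay_exponent


def tokens_seen(cfg: ScheduleConfig, steps: int) -> int:
    """Total training tokens = effective batch tokens x update steps."""
    return cfg.effective_batch_tokens * steps


@dataclass
class LossTrace:
    records: list[tuple[int, float, float]] = field(default_factory=list)  # (step, lr, loss)

    def append(self, step: int, lr: float, loss: float):
        self.records.append((step, lr, loss))

    @property
    def losses(self) -> list[float]:
        return [r[2] for r in self.records]

    def save(self, path):
        with open(path, "w") as fh:
            fh.write("step\tlr\tloss\n")
            for step, lr, loss in self.records:
                fh.write(f"{step}\t{lr:.8g}\t{loss:.8g}\n")


def pretrain(model: TransformerLM, corpus: Sequence[GenomeChunk] | Iterable[GenomeChunk],
             vocab: TokenVocabulary, cfg: ScheduleConfig, steps: int,
             seed: int = 0, batch_size: int = 8,
             offset_range: tuple[int, int] = (0, 100),
             select_rate: float = 0.15) -> LossTrace:
    """Desk-scale MLM pre-training loop (Adam, seed-deterministic).

    Each step samples ``batch_size`` chunks with replacement, applies the
    start-offset augmentation, encodes to the model's input length (over-long
    tokenizations right-truncate), masks, and takes one Adam update at the
    scheduled learning rate.
    """
    chunks = list(corpus)
    if not chunks:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(seed)
    opt = Adam(model.trainable_names("pretrain"), beta1=cfg.beta1, beta2=cfg.beta2)
    trace = LossTrace()
    max_tokens = model.config.max_tokens
    for step in range(steps):
        idx = rng.integers(0, len(chunks), size=batch_size)
        batch_ids, batch_spec, batch_sel, batch_lab = [], [], [], []
        for j in idx:
            window = sample_augmented_window(chunks[j], offset_range, rng)
            ts = encode_for_model(window, vocab, max_tokens)
            plan, corrupted = make_masking_plan(ts, vocab, select_rate=select_rate, rng=rng)
            sel = np.zeros(max_tokens, dtype=bool)
            sel[plan.selected] = True
            lab = np.zeros(max_tokens, dtype=np.int64)
            lab[plan.selected] = plan.labels
            batch_ids.append(corrupted.ids)
            batch_spec.append(corrupted.is_special)
            batch_sel.append(sel)
            batch_lab.append(lab)
        ids = np.stack(batch_ids)
        spec = np.stack(batch_spec)
        loss, grads = model.mlm_loss_and_grads(ids, spec, np.stack(batch_sel),
                                               np.stack(batch_lab))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"pre-training diverged at step {step}: loss={loss!r} "
                f"(lr={lr_schedule(step, cfg):.3g})")
        lr = lr_schedule(step, cfg)
        opt.step(model.params, grads, lr)
        trace.append(step, lr, loss)
    return trace
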