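"""In silico saturation mutagenesis and random-token importance profiling.

Saturation mutagenesis substitutes every position of a scanned region to all
three alternative bases and records the log-fold change
LFC = log2(P1 / P0), where P0 is the model's (strictly positive) output on
the original sequence and P1 on the mutant. For classification tasks P is
the positive-class probability; for regression on log2(x+1)-scale targets
the predictions are mapped back to the linear scale (2**y - 1) before the
ratio, since a log of a ratio of log-values is not meaningful.

Token importance replaces each token with a random different non-special
token and records the absolute prediction difference, averaged over output
dimensions (e.g. tissues) and over sequences.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import TransformerLM
from .tokenizer import TokenVocabulary, encode_for_model

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


class UndefinedLfcError(ValueError):
    pass


def classifier_predict_fn(model: TransformerLM, vocab: TokenVocabulary,
                          output_index: int = 0) -> Callable[[Sequence[str]], np.ndarray]:
    """Positive-class probability of a fine-tuned classification head."""

    def predict(seqs: Sequence[str]) -> np.ndarray:
        enc = [encode_for_model(s, vocab, model.config.max_tokens) for s in seqs]
        ids = np.stack([e.ids for e in enc])
        spec = np.stack([e.is_special for e in enc])
        return model.predict(ids, spec)[:, output_index]

    return predict


def regression_predict_fn(model: TransformerLM, vocab: TokenVocabulary,
                          output_index: int = 0,
                          invert_log2: bool = True) -> Callable[[Sequence[str]], np.ndarray]:
    """Regression output mapped to the linear scale (2**y - 1) by default."""

    def predict(seqs: Sequence[str]) -> np.ndarray:
        enc = [encode_for_model(s, vocab, model.config.max_tokens) for s in seqs]
        ids = np.stack([e.ids for e in enc])
        spec = np.stack([e.is_special for e in enc])
        y = model.predict(ids, spec)[:, output_index]
        return np.power(2.0, y) - 1.0 if invert_log2 else y

    return predict


def saturation_lfc(predict_fn: Callable[[Sequence[str]], np.ndarray], sequence: str,
                   region: tuple[int, int] | None = None, sequence_id: str = "seq",
                   batch_size: int = 64) -> pd.DataFrame:
    """LFC table over a scanned sub-region (0-based half-open; whole sequence
    by default): 3 rows per position — one per alternative base — with
    columns (sequence_id, position [1-based within the region], ref, alt, lfc).
    """
    start, end = region if region is not None else (0, len(sequence))
    if not (0 <= start < end <= len(sequence)):
        raise ValueError(f"region [{start}, {end}) outside sequence of {len(sequence)} nt")
    p0 = float(predict_fn([sequence])[0])
    if p0 <= 0:
        raise UndefinedLfcError(f"P0 = {p0} for {sequence_id}; LFC undefined")
    mutants, meta = [], []
    for pos in range(start, end):
        ref = sequence[pos].upper()
        for alt in BASES:
            if alt == ref:
                continue
            mutants.append(sequence[:pos] + alt + sequence[pos + 1:])
            meta.append((pos - start + 1, ref, alt))
    p1 = np.concatenate([np.asarray(predict_fn(mutants[i:i + batch_size]), dtype=float)
                         for i in range(0, len(mutants), batch_size)])
    if (p1 <= 0).any():
        raise UndefinedLfcError(f"non-positive mutant prediction for {sequence_id}")
    lfc = np.log2(p1 / p0)
    return pd.DataFrame({"sequence_id": sequence_id,
                         "position": [m[0] for m in meta],
                         "ref": [m[1] for m in meta],
                         "alt": [m[2] for m in meta],
                         "lfc": lfc})


def position_summary(ism: pd.DataFrame) -> pd.DataFrame:
    """Per-position maximum |LFC| (sequence-logo letter heights) plus the
    extreme (position, alt, lfc) record at each position."""
    if ism.empty:
        raise ValueError("empty LFC table")
    idx = ism.groupby("position")["lfc"].apply(lambda s: s.abs().idxmax())
    ext = ism.loc[idx.values, ["position", "ref", "alt", "lfc"]].copy()
    ext["height"] = ext["lfc"].abs()
    return ext.sort_values("position").reset_index(drop=True)


def lfc_quantile_threshold(lfc_values: np.ndarray, quantile: float = 1e-4) -> float:
    """Lower-tail LFC threshold (default the 0.01% quantile) for calling
    strongly-affecting mutations from a pooled LFC collection."""
    return float(np.quantile(np.asarray(lfc_values, dtype=float), quantile))


def token_importance(model: TransformerLM, vocab: TokenVocabulary,
                     sequences: Sequence[str], n_sequences: int = 100,
                     seed: int = 0, batch_size: int = 64) -> np.ndarray:
    """Mean absolute prediction difference under random-token replacement.

    Each non-special token position is replaced (one at a time) by a
    uniformly drawn different non-special token; the profile averages
    |prediction(original) - prediction(perturbed)| over output dimensions and
    over up to ``n_sequences`` sequences. All sequences must tokenize to the
    same position count.
    """
    rng = np.random.default_rng(seed)
    seqs = list(sequences)[:n_sequences]
    pool = vocab.nonspecial_ids
    profile = None
    for seq in seqs:
        ts = encode_for_model(seq, vocab, model.config.max_tokens)
        positions = np.flatnonzero(~ts.is_special)
        if profile is None:
            profile = np.zeros(positions.size)
        elif positions.size != profile.size:
            raise ValueError("sequences tokenize to different position counts")
        base = model.predict(ts.ids[None, :], ts.is_special[None, :])[0]
        perturbed = np.tile(ts.ids, (positions.size, 1))
        for row, p in enumerate(positions):
            new = int(pool[rng.integers(0, pool.size)])
            while new == ts.ids[p]:
                new = int(pool[rng.integers(0, pool.size)])
            perturbed[row, p] = new
        spec = np.tile(ts.is_special, (positions.size, 1))
        preds = np.concatenate([
            model.predict(perturbed[i:i + batch_size], spec[i:i + batch_size])
            for i in range(0, positions.size, batch_size)])
        profile += np.abs(preds - base[None, :]).mean(axis=1)
    if profile is None:
        raise ValueError("no sequences supplied")
    return profile / len(seqs)
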