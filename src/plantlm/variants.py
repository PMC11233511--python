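"""Zero-shot variant-effect scoring and enrichment statistics.

For a bi-allelic SNP, a window (6000 bp by default) is centered on the
variant and two sequences are built, one per allele. Five scores compare
them: the L1 and L2 distances, cosine similarity, and dot product between
mean-pooled per-layer embeddings, plus a loss-based log-likelihood ratio
(LLR) — the log probability of the token carrying the alternate allele minus
that of the reference token, read from the MLM head with the variant token
masked. Since the two windows differ only inside the masked token, one
masked forward pass serves both alleles and LLR is exactly antisymmetric
under allele swap.

Enrichment statistics mirror the evaluation style used for such scores:
missense/synonymous count ratios by frequency bin with chromosome-level
bootstrap intervals, and odds ratios across score quantiles with
Haldane-Anscombe-corrected normal-approximation intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import load_genome
from .model import TransformerLM
from .tokenizer import TokenVocabulary, encode_for_model, token_ids, token_spans, tokenize

logger = logging.getLogger(__name__)

#: default minor-allele-frequency bins: (<0.1%, 0.1-1%, 1-5%, >5%)
DEFAULT_FREQUENCY_BINS = ((0.0, 0.001), (0.001, 0.01), (0.01, 0.05), (0.05, 1.0))


class ReferenceMismatchError(ValueError):
    pass


@dataclass
class VariantRecord:
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    minor_allele_frequency: float | None = None
    functional_class: str | None = None  # missense | synonymous | coding | noncoding | other
    group: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chromosome}:{self.position}")


def read_variant_table(path) -> list[VariantRecord]:
    """TSV with columns chrom, pos, ref, alt [, maf, class, group]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(VariantRecord(
            chromosome=str(row[0]), position=int(row[1]), ref=str(row[2]),
            alt=str(row[3]),
            minor_allele_frequency=float(row[4]) if len(row) > 4 and pd.notna(row[4]) else None,
            functional_class=str(row[5]) if len(row) > 5 and pd.notna(row[5]) else None,
            group=str(row[6]) if len(row) > 6 and pd.notna(row[6]) else None))
    return out


def read_vcf(path) -> list[VariantRecord]:
    """Bi-allelic SNP records from a VCF; multi-allelic or indel records skipped."""
    from cyvcf2 import VCF
    out = []
    for v in VCF(str(path)):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        out.append(VariantRecord(chromosome=v.CHROM, position=v.POS,
                                 ref=v.REF, alt=v.ALT[0],
                                 minor_allele_frequency=v.INFO.get("AF")))
    return out


def variant_windows(genome, variant: VariantRecord,
                    window: int = 6000) -> tuple[str, str, int]:
    """Reference and alternate sequences centered on the SNP.

    The variant sits at 1-based window position window//2 + 1. Near a
    chromosome edge the window is clipped with a warning. Returns
    (ref_seq, alt_seq, variant position within the window, 1-based)."""
    chroms = load_genome(genome)
    seq = chroms[variant.chromosome]
    pos = variant.position
    if seq[pos - 1].upper() != variant.ref.upper():
        raise ReferenceMismatchError(
            f"reference mismatch at {variant.chromosome}:{pos}: genome has "
            f"{seq[pos - 1]!r}, variant says {variant.ref!r}")
    up, down = window // 2, window - window // 2 - 1
    lo = pos - 1 - up
    hi = pos + down
    if lo < 0 or hi > len(seq):
        logger.warning("window clipped at %s:%d", variant.chromosome, pos)
        up = min(up, pos - 1)
        down = min(down, len(seq) - pos)
        lo, hi = pos - 1 - up, pos + down
    ref_seq = seq[lo:hi]
    center = up + 1  # 1-based within the window
    alt_seq = ref_seq[:center - 1] + variant.alt + ref_seq[center:]
    return ref_seq, alt_seq, center


@dataclass
class ZeroShotScores:
    llr: float
    per_layer: dict[int, dict[str, float]] = field(default_factory=dict)
    flagged: bool = False  # variant fell in a standalone-token region

    def score(self, name: str, layer: int) -> float:
        return self.per_layer[layer][name]


def zero_shot_scores(model: TransformerLM, vocab: TokenVocabulary,
                     ref_seq: str, alt_seq: str, variant_offset: int,
                     layers=None) -> ZeroShotScores:
    """Embedding-distance scores and the masked-token LLR for one variant.

    ``variant_offset`` is the 0-based position of the variant within the
    window. Both sequences must tokenize to the same length (guaranteed for
    a SNP, which never changes the greedy token boundaries).
    """
    if len(ref_seq) != len(alt_seq):
        raise ValueError("ref and alt sequences must have equal length")
    max_tokens = model.config.max_tokens
    layers = [model.config.num_layers] if layers is None else list(layers)

    # embedding scores between pooled per-layer representations
    ts_ref = encode_for_model(ref_seq, vocab, max_tokens)
    ts_alt = encode_for_model(alt_seq, vocab, max_tokens)
    if ts_ref.n_nonspecial != ts_alt.n_nonspecial:
        raise ValueError("ref and alt tokenizations differ in length")
    stack = model.embed([ts_ref, ts_alt], layers=layers)
    per_layer = {}
    for l in layers:
        r, a = stack.pooled[l][0].astype(np.float64), stack.pooled[l][1].astype(np.float64)
        norms = np.linalg.norm(r) * np.linalg.norm(a)
        per_layer[l] = {
            "l1": float(np.abs(r - a).sum()),
            "l2": float(np.linalg.norm(r - a)),
            "cosine_similarity": float(r @ a / norms) if norms > 0 else np.nan,
            "dot_product": float(r @ a),
        }

    # LLR via single-token masking at the variant-containing token
    spans = token_spans(ref_seq, vocab)
    tok_idx = next(i for i, (s, e) in enumerate(spans)
                   if s <= variant_offset < e)
    flagged = (spans[tok_idx][1] - spans[tok_idx][0]) < vocab.kmer_size
    ref_tok_id = int(token_ids(ref_seq, vocab)[tok_idx])
    alt_tok_id = int(token_ids(alt_seq, vocab)[tok_idx])
    masked = encode_for_model(ref_seq, vocab, max_tokens)
    model_pos = tok_idx + 1  # CLS offset
    if model_pos >= max_tokens:
        raise ValueError("variant token truncated away; enlarge max_tokens")
    masked.ids[model_pos] = vocab.mask_id
    logits = model.logits(masked.ids[None, :], masked.is_special[None, :])[0, model_pos]
    z = logits.astype(np.float64)
    z = z - z.max()
    logp = z - np.log(np.exp(z).sum())
    llr = float(logp[alt_tok_id] - logp[ref_tok_id])
    return ZeroShotScores(llr=llr, per_layer=per_layer, flagged=flagged)


def score_variants(model: TransformerLM, vocab: TokenVocabulary, genome,
                   variants, window: int = 6000, layers=None) -> pd.DataFrame:
    rows = []
    for v in variants:
        ref_seq, alt_seq, center = variant_windows(genome, v, window)
        sc = zero_shot_scores(model, vocab, ref_seq, alt_seq, center - 1, layers)
        row = {"chromosome": v.chromosome, "position": v.position,
               "ref": v.ref, "alt": v.alt, "llr": sc.llr, "flagged": sc.flagged}
        for l, d in sc.per_layer.items():
            for name, val in d.items():
                row[f"{name}_layer{l}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment statistics


def missense_synonymous_ratio(variants, frequency_bins=DEFAULT_FREQUENCY_BINS,
                              n_bootstrap: int = 100, seed: int = 0) -> pd.DataFrame:
    """Missense/synonymous count ratio per frequency bin with a 95%
    chromosome-level bootstrap percentile interval (chromosomes resampled
    with replacement ``n_bootstrap`` times)."""
    recs = [v for v in variants if v.functional_class in ("missense", "synonymous")
            and v.minor_allele_frequency is not None]
    chroms = sorted({v.chromosome for v in recs})
    rng = np.random.default_rng(seed)

    def bin_of(maf):
        for i, (lo, hi) in enumerate(frequency_bins):
            if lo <= maf < hi or (hi == frequency_bins[-1][1] and maf == hi):
                return i
        return None

    def ratios(subset_chroms: list[str]) -> list[float]:
        counts = {i: [0, 0] for i in range(len(frequency_bins))}
        mult = pd.Series(subset_chroms).value_counts()
        for v in recs:
            if v.chromosome not in mult.index:
                continue
            b = bin_of(v.minor_allele_frequency)
            if b is None:
                continue
            w = int(mult[v.chromosome])
            counts[b][0 if v.functional_class == "missense" else 1] += w
        return [counts[i][0] / counts[i][1] if counts[i][1] > 0 else np.nan
                for i in range(len(frequency_bins))]

    point = ratios(chroms)
    boot = np.array([ratios(list(rng.choice(chroms, size=len(chroms), replace=True)))
                     for _ in range(n_bootstrap)], dtype=float)
    rows = []
    for i, (lo, hi) in enumerate(frequency_bins):
        col = boot[:, i]
        ok = np.isfinite(col)
        rows.append({
            "bin_low": lo, "bin_high": hi, "ratio": point[i],
            "ci_low": float(np.percentile(col[ok], 2.5)) if ok.any() else np.nan,
            "ci_high": float(np.percentile(col[ok], 97.5)) if ok.any() else np.nan,
        })
    return pd.DataFrame(rows)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """OR = (a/b)/(c/d) with a 95% CI from the log-OR normal approximation;
    Haldane-Anscombe 0.5 correction applied when any cell is zero."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ / b_) / (c_ / d_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return float(or_), float(np.exp(np.log(or_) - 1.96 * se)), float(np.exp(np.log(or_) + 1.96 * se))


def quantile_odds_ratios(scores: np.ndarray, group_a: np.ndarray,
                         group_b: np.ndarray,
                         quantiles=(0.01, 0.05, 0.1, 0.25, 0.5)) -> pd.DataFrame:
    """Enrichment of group_a vs group_b below each pooled-score quantile.

    Per quantile q: threshold = q-quantile of the pooled scores, 2x2 table of
    membership x (score <= threshold), OR with 95% CI. Degenerate quantiles
    (threshold separates nothing) are skipped with a note.
    """
    scores = np.asarray(scores, dtype=float)
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if (group_a & group_b).any():
        raise ValueError("groups must be disjoint")
    if not group_a.any() or not group_b.any():
        raise ValueError("both groups must be non-empty")
    pooled = scores[group_a | group_b]
    rows = []
    for q in quantiles:
        thr = float(np.quantile(pooled, q))
        below = scores <= thr
        if below[group_a | group_b].all() or not below[group_a | group_b].any():
            rows.append({"quantile": q, "threshold": thr, "note": "degenerate",
                         "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "a": np.nan, "b": np.nan, "c": np.nan, "d": np.nan})
            continue
        a = int((group_a & below).sum())
        b = int((group_a & ~below).sum())
        c = int((group_b & below).sum())
        d = int((group_b & ~below).sum())
        or_, lo, hi = odds_ratio_2x2(a, b, c, d)
        rows.append({"quantile": q, "threshold": thr, "note": "",
                     "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                     "a": a, "b": b, "c": c, "d": d})
    return pd.DataFrame(rows)
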