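"""Benchmark dataset construction: window extraction, negative-set
generation, labeling, count normalization, and leakage-free splits.

These are the construction rules behind the plant genomic benchmark tasks:
400-bp polyadenylation windows with the site at position 301 and shifted
negatives, length- and GC-matched lncRNA/mRNA pairs, 1000-bp chromatin
windows labeled by central-200-bp open-chromatin overlap, 6000-bp
promoter-proximal windows around the TSS, median-of-ratios count
normalization with log2(x+1), and gene-family / chromosome-holdout splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import GenomicInterval, gc_content, load_fasta_records, load_genome, read_bed, revcomp

logger = logging.getLogger(__name__)


@dataclass
class PgbExample:
    id: str
    sequence: str
    targets: float | int | np.ndarray
    split: str | None = None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# polyadenylation


def extract_apa_positives(genome, pac_sites,
                          upstream: int = 300, downstream: int = 100) -> tuple[list[PgbExample], dict]:
    """400-bp windows around annotated poly(A) sites; site at 1-based window
    position 301 (300 nt upstream + the site + 99 nt downstream).

    Minus-strand sites are reverse-complemented so upstream is leftward in
    the emitted sequence. Sites closer than ``upstream`` to the chromosome
    start or ``downstream`` to the end are skipped and counted.
    """
    chroms = load_genome(genome)
    sites = read_bed(pac_sites)
    out, skipped = [], 0
    for n, iv in enumerate(sites):
        seq = chroms[iv.chromosome]
        pos = iv.start + 1  # 1-based site position (single-base BED record)
        window = _apa_window(seq, pos, iv.strand, upstream, downstream)
        if window is None:
            skipped += 1
            continue
        out.append(PgbExample(
            id=f"apa_pos_{n}", sequence=window, targets=1,
            provenance={"chromosome": iv.chromosome, "site_pos": pos,
                        "strand": iv.strand}))
    report = {"n_positives": len(out), "n_skipped_boundary": skipped}
    return out, report


def _apa_window(seq: str, pos: int, strand: str, upstream: int,
                downstream: int) -> str | None:
    """Strand-aware 0-based window slice; None if it leaves the chromosome."""
    if strand == "-":
        lo, hi = pos - downstream, pos + upstream  # 0-based half-open
    else:
        lo, hi = pos - upstream - 1, pos + downstream - 1
    if lo < 0 or hi > len(seq):
        return None
    window = seq[lo:hi]
    return revcomp(window) if strand == "-" else window


def make_apa_negatives(positives: Sequence[PgbExample], genome,
                       shift_min: int = 1, shift_max: int = 50, ratio: int = 2,
                       seed: int = 0, upstream: int = 300, downstream: int = 100,
                       max_retries: int = 20) -> list[PgbExample]:
    """Per positive, ``ratio`` negatives re-extracted around a site shifted by
    a uniform magnitude in [shift_min, shift_max] with uniform sign."""
    if not positives:
        raise ValueError("positives must be non-empty")
    chroms = load_genome(genome)
    rng = np.random.default_rng(seed)
    out = []
    for pos_ex in positives:
        chrom = pos_ex.provenance["chromosome"]
        site = pos_ex.provenance["site_pos"]
        strand = pos_ex.provenance["strand"]
        seq = chroms[chrom]
        for j in range(ratio):
            for _ in range(max_retries):
                mag = int(rng.integers(shift_min, shift_max + 1))
                sign = 1 if rng.random() < 0.5 else -1
                shifted = site + sign * mag
                window = _apa_window(seq, shifted, strand, upstream, downstream)
                if window is not None:
                    out.append(PgbExample(
                        id=f"{pos_ex.id}_neg{j}", sequence=window, targets=0,
                        provenance={"chromosome": chrom, "site_pos": site,
                                    "strand": strand, "shift": sign * mag,
                                    "matched_positive": pos_ex.id}))
                    break
            else:
                logger.warning("could not place negative for %s; skipped", pos_ex.id)
    return out


# ---------------------------------------------------------------------------
# lncRNA / mRNA matching


def match_lncrna_negatives(lncrnas, mrnas, length_tolerance: int = 100,
                           gc_tolerance: float = 1.0, max_length: int = 6000,
                           seed: int = 0) -> tuple[list[tuple[str, str]], list[str]]:
    """Match each lncRNA to a distinct mRNA of similar length (within 100 bp)
    and GC content (within 1 percentage point).

    Sequences longer than ``max_length`` are removed first. Matching is
    greedy over a seeded random order of the lncRNAs, without mRNA reuse.
    Returns (matched id pairs, unmatched lncRNA ids).
    """
    lnc = {k: v for k, v in load_fasta_records(lncrnas).items() if len(v) <= max_length}
    mrna = {k: v for k, v in load_fasta_records(mrnas).items() if len(v) <= max_length}
    mrna_stats = {k: (len(v), gc_content(v)) for k, v in mrna.items()}
    rng = np.random.default_rng(seed)
    order = list(lnc)
    rng.shuffle(order)
    used: set[str] = set()
    pairs, unmatched = [], []
    for lid in order:
        llen, lgc = len(lnc[lid]), gc_content(lnc[lid])
        candidates = [mid for mid, (mlen, mgc) in mrna_stats.items()
                      if mid not in used
                      and abs(mlen - llen) <= length_tolerance
                      and abs(mgc - lgc) <= gc_tolerance]
        if not candidates:
            unmatched.append(lid)
            continue
        chosen = candidates[int(rng.integers(0, len(candidates)))]
        used.add(chosen)
        pairs.append((lid, chosen))
    return pairs, unmatched


# ---------------------------------------------------------------------------
# chromatin windows


def label_chromatin_windows(windows: Sequence[GenomicInterval], ocrs,
                            center_length: int = 200) -> list[PgbExample]:
    """Label 1000-bp windows by open-chromatin overlap of the central 200 bp.

    A window is positive for a track iff the union of that track's OCRs
    covers strictly more than half of the central 200-bp sub-interval
    (> 100 bp). ``ocrs`` is either a single interval list (one label) or a
    {track_name: intervals} dict (multi-label vector, tracks in sorted name
    order)."""
    if isinstance(ocrs, dict):
        tracks = {name: read_bed(v) for name, v in sorted(ocrs.items())}
    else:
        tracks = {"track0": read_bed(ocrs)}
    out = []
    for n, w in enumerate(windows):
        if len(w) != 1000:
            raise ValueError(f"window {n} is {len(w)} bp; expected exactly 1000")
        flank = (1000 - center_length) // 2
        c_start, c_end = w.start + flank, w.start + flank + center_length
        labels = []
        for intervals in tracks.values():
            covered = np.zeros(center_length, dtype=bool)
            for ocr in intervals:
                if ocr.chromosome != w.chromosome:
                    continue
                lo = max(c_start, ocr.start)
                hi = min(c_end, ocr.end)
                if lo < hi:
                    covered[lo - c_start:hi - c_start] = True
            labels.append(int(covered.sum() > center_length // 2))
        target = labels[0] if len(tracks) == 1 else np.array(labels)
        out.append(PgbExample(id=f"chromatin_{n}", sequence="", targets=target,
                              provenance={"chromosome": w.chromosome,
                                          "start": w.start, "end": w.end}))
    return out


# ---------------------------------------------------------------------------
# promoter-proximal windows


#: sliding upstream/downstream variants around the TSS (all 6000 bp total)
PROMOTER_WINDOW_VARIANTS = ((5000, 1000), (4000, 2000), (3000, 3000),
                            (2000, 4000), (1000, 5000))


def _gff_tss(gff, featuretype: str = "gene"):
    """Yield (gene_id, chromosome, tss 1-based, strand) from a GFF3 source."""
    if isinstance(gff, list):  # pre-parsed (id, chrom, tss, strand) tuples
        yield from gff
        return
    import gffutils
    db = gffutils.create_db(str(gff), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    for feat in db.features_of_type(featuretype):
        tss = feat.start if feat.strand != "-" else feat.end
        yield feat.id, feat.seqid, tss, feat.strand


def extract_promoter_window(genome, gff, upstream: int = 5000,
                            downstream: int = 1000,
                            featuretype: str = "gene") -> tuple[list[PgbExample], dict]:
    """Promoter-proximal windows: ``upstream`` bp before to ``downstream`` bp
    after the TSS (6000 bp at defaults), oriented 5'->3' with respect to the
    gene; minus-strand genes are reverse-complemented. Boundary-clipped genes
    are skipped and counted."""
    chroms = load_genome(genome)
    out, skipped = [], 0
    for gene_id, chrom, tss, strand in _gff_tss(gff, featuretype):
        if chrom not in chroms:
            raise KeyError(f"chromosome {chrom!r} missing from the genome FASTA")
        seq = chroms[chrom]
        if strand == "-":
            g_start, g_end = tss - downstream + 1, tss + upstream  # 1-based inclusive
        else:
            g_start, g_end = tss - upstream, tss + downstream - 1
        if g_start < 1 or g_end > len(seq):
            skipped += 1
            continue
        window = seq[g_start - 1:g_end]
        if strand == "-":
            window = revcomp(window)
        out.append(PgbExample(
            id=str(gene_id), sequence=window, targets=np.nan,
            provenance={"chromosome": chrom, "tss": tss, "strand": strand,
                        "genomic_span": (g_start, g_end)}))
    return out, {"n_windows": len(out), "n_skipped_boundary": skipped}


# ---------------------------------------------------------------------------
# expression normalization


def normalize_expression(counts: pd.DataFrame,
                         sample_to_tissue: dict[str, str]) -> pd.DataFrame:
    """Median-of-ratios size-factor normalization, replicate averaging per
    tissue, then log2(x + 1).

    Size factors: per sample, the median over genes (restricted to genes
    with all-positive counts) of count / geometric-mean-across-samples.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts have undefined size factors: {bad}")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_geo = np.log(counts.loc[positive]).mean(axis=1)
    ratios = np.log(counts.loc[positive]).sub(log_geo, axis=0)
    factors = np.exp(ratios.median(axis=0))
    normalized = counts.div(factors, axis=1)
    tissues = sorted(set(sample_to_tissue.values()))
    per_tissue = {}
    for t in tissues:
        cols = [s for s in counts.columns if sample_to_tissue[s] == t]
        per_tissue[t] = normalized[cols].mean(axis=1)
    mat = pd.DataFrame(per_tissue)
    return np.log2(mat + 1.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors alone (exposed for auditing)."""
    positive = (counts > 0).all(axis=1)
    log_geo = np.log(counts.loc[positive]).mean(axis=1)
    return np.exp(np.log(counts.loc[positive]).sub(log_geo, axis=0).median(axis=0))


# ---------------------------------------------------------------------------
# gene families and splits


@dataclass
class GeneFamilyAssignment:
    gene_to_family: dict[str, int]
    families: dict[int, list[str]]


def kmer_jaccard_edges(sequences: dict[str, str], k: int = 4,
                       min_score: float = 0.0) -> list[tuple[str, str, float]]:
    """Pluggable pairwise-similarity provider: shared-k-mer Jaccard index."""
    kmer_sets = {g: {s[i:i + k] for i in range(len(s) - k + 1)}
                 for g, s in sequences.items()}
    genes = sorted(kmer_sets)
    edges = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            inter = len(kmer_sets[a] & kmer_sets[b])
            union = len(kmer_sets[a] | kmer_sets[b])
            score = inter / union if union else 0.0
            if score >= min_score:
                edges.append((a, b, score))
    return edges


def assign_gene_families(similarity_edges: Sequence[tuple[str, str, float]],
                         threshold: float,
                         genes: Sequence[str] | None = None) -> GeneFamilyAssignment:
    """Families are connected components of the graph of gene pairs whose
    similarity meets the threshold; unconnected genes form singleton families."""
    best: dict[tuple[str, str], float] = {}
    all_genes = set(genes or [])
    for a, b, score in similarity_edges:
        all_genes.update((a, b))
        key = (a, b) if a <= b else (b, a)
        best[key] = max(best.get(key, -np.inf), score)
    g = nx.Graph()
    g.add_nodes_from(sorted(all_genes))
    g.add_edges_from(k for k, s in best.items() if s >= threshold)
    gene_to_family, families = {}, {}
    for fam_id, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        families[fam_id] = sorted(comp)
        for gene in comp:
            gene_to_family[gene] = fam_id
    return GeneFamilyAssignment(gene_to_family=gene_to_family, families=families)


def make_splits(examples: Sequence[PgbExample], mode: str,
                families: GeneFamilyAssignment | None = None,
                test_fraction: float = 0.2,
                holdout_chromosomes: Sequence[str] = (),
                seed: int = 0) -> pd.DataFrame:
    """Leakage-free train/test manifest.

    ``gene_family`` mode assigns whole families to the test set in a seeded
    random order until the test fraction is as close as possible to the
    target; a family larger than the whole test budget goes to train with a
    warning. ``chromosome_holdout`` mode sends every example whose provenance
    chromosome is in ``holdout_chromosomes`` to the test set.
    """
    ids = [e.id for e in examples]
    if mode == "gene_family":
        if families is None:
            raise ValueError("gene_family mode requires a GeneFamilyAssignment")
        rng = np.random.default_rng(seed)
        by_family: dict[int, list[str]] = {}
        for e in examples:
            fam = families.gene_to_family[e.id]
            by_family.setdefault(fam, []).append(e.id)
        target = test_fraction * len(examples)
        fam_ids = list(by_family)
        rng.shuffle(fam_ids)
        test_ids: set[str] = set()
        for fam in fam_ids:
            size = len(by_family[fam])
            if size > target and not test_ids:
                logger.warning("family %d (%d genes) exceeds the test budget; -> train",
                               fam, size)
                continue
            if abs(len(test_ids) + size - target) <= abs(len(test_ids) - target):
                test_ids.update(by_family[fam])
            if len(test_ids) >= target:
                break
        split = ["test" if i in test_ids else "train" for i in ids]
    elif mode == "chromosome_holdout":
        holdout = set(holdout_chromosomes)
        split = ["test" if e.provenance.get("chromosome") in holdout else "train"
                 for e in examples]
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    manifest = pd.DataFrame({"id": ids, "split": split})
    audit_splits(manifest, examples, families)
    return manifest


def audit_splits(manifest: pd.DataFrame, examples: Sequence[PgbExample],
                 families: GeneFamilyAssignment | None = None) -> None:
    """Raise if any id appears in several splits or a family straddles splits."""
    dup = manifest.groupby("id")["split"].nunique()
    if (dup > 1).any():
        raise ValueError(f"ids in multiple splits: {dup[dup > 1].index.tolist()}")
    if families is not None:
        split_of = dict(zip(manifest["id"], manifest["split"]))
        fam_splits: dict[int, set] = {}
        for gene, fam in families.gene_to_family.items():
            if gene in split_of:
                fam_splits.setdefault(fam, set()).add(split_of[gene])
        straddling = [f for f, s in fam_splits.items() if len(s) > 1]
        if straddling:
            raise ValueError(f"families straddling splits: {straddling}")
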