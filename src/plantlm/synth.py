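"""Synthetic genomes, annotations, labeled tasks, and variant panels with
known planted structure.

Everything downstream — tokenization, pre-training, benchmark construction,
fine-tuning, variant scoring, mutagenesis — is testable against these
generators because the ground truth (motif placements, gene models, site
positions, variant classes) is recorded exactly and every label is a
deterministic function of the planted structure. Outputs round-trip through
standard FASTA/GFF3/BED readers. The generators emulate sequence composition
and planted regulatory signal only; they do not attempt realistic
evolutionary structure, so benchmark numbers on them speak to the machinery,
not to real-genome difficulty.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io import GenomicInterval, write_bed, write_fasta
from .variants import VariantRecord

BASES = np.array(list("ACGT"))

#: fixed 18-bp consensus used as the default planted regulatory motif; its
#: length guarantees >= 2 full hexamer tokens inside the motif under every
#: tokenization frame
DEFAULT_MOTIF = "TGACGTCATCGATCGTAC"


class SpecError(ValueError):
    pass


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    tss: int      # 1-based
    strand: str
    cds_start: int  # 1-based inclusive
    cds_end: int


@dataclass
class SyntheticGenomeSpec:
    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str = DEFAULT_MOTIF
    motifs_per_chromosome: int = 100
    #: 'random' scatters motifs at non-overlapping random positions;
    #: 'tiled' fills each chromosome with motif copies separated by short
    #: random spacers (a motif-rich, largely predictable sequence)
    motif_layout: str = "random"
    spacer_range: tuple[int, int] = (2, 8)
    genes_per_chromosome: int = 20
    pac_sites_per_chromosome: int = 20
    ocrs_per_chromosome: int = 20
    ocr_length: int = 300
    n_run_rate: float = 0.0   # expected N-runs per chromosome
    n_run_length: int = 10
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise SpecError("base composition must sum to 1")
        if len(self.motif) >= self.chromosome_length:
            raise SpecError("motif longer than chromosome")


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    motif_intervals: list[GenomicInterval]
    genes: list[GeneModel]
    pac_sites: list[GenomicInterval]
    ocrs: list[GenomicInterval]
    spec: SyntheticGenomeSpec

    def motif_positions(self, chromosome: str) -> list[tuple[int, int]]:
        return [(iv.start, iv.end) for iv in self.motif_intervals
                if iv.chromosome == chromosome]


def _random_seq(rng, length, composition) -> np.ndarray:
    return rng.choice(BASES, size=length, p=composition)


def generate_genome(spec: SyntheticGenomeSpec, out_dir: str | None = None) -> SyntheticGenome:
    """Background sequence with planted motifs, gene models, poly(A) sites,
    open-chromatin intervals and optional N-runs; byte-identical for a fixed
    (spec, seed). When ``out_dir`` is given, writes genome.fa, genes.gff3,
    pac.bed, ocr.bed and a motifs.tsv ground-truth manifest."""
    rng = np.random.default_rng(spec.seed)
    L, m = spec.chromosome_length, len(spec.motif)
    chroms: dict[str, str] = {}
    motif_ivs: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    pacs: list[GenomicInterval] = []
    ocrs: list[GenomicInterval] = []
    for c in range(spec.n_chromosomes):
        name = f"chr{c + 1}"
        arr = _random_seq(rng, L, spec.base_composition)
        if spec.motif_layout == "tiled":
            # motif-rich layout: motif copies separated by short random spacers
            lo, hi = spec.spacer_range
            pos = int(rng.integers(lo, hi + 1))
            while pos + m <= L:
                arr[pos:pos + m] = list(spec.motif)
                motif_ivs.append(GenomicInterval(name, pos, pos + m))
                pos += m + int(rng.integers(lo, hi + 1))
        elif spec.motif_layout == "random":
            # scatter non-overlapping motif copies (rejection over placements)
            taken: list[tuple[int, int]] = []
            placed = 0
            attempts = 0
            while placed < spec.motifs_per_chromosome:
                attempts += 1
                if attempts > 50 * spec.motifs_per_chromosome:
                    raise SpecError("cannot place motifs without overlap; reduce density")
                start = int(rng.integers(0, L - m))
                if any(start < e and start + m > s for s, e in taken):
                    continue
                arr[start:start + m] = list(spec.motif)
                taken.append((start, start + m))
                motif_ivs.append(GenomicInterval(name, start, start + m))
                placed += 1
        else:
            raise SpecError(f"unknown motif layout {spec.motif_layout!r}")
        # N-runs
        n_runs = rng.poisson(spec.n_run_rate)
        for _ in range(n_runs):
            start = int(rng.integers(0, L - spec.n_run_length))
            arr[start:start + spec.n_run_length] = "N"
        seq = "".join(arr)
        chroms[name] = seq
        # gene models: TSS away from edges, short CDS downstream of the TSS
        margin = min(6000, L // 3)
        for g in range(spec.genes_per_chromosome):
            tss = int(rng.integers(margin, L - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            cds_len = int(rng.integers(300, 1500))
            if strand == "+":
                cds = (tss + 50, min(tss + 50 + cds_len, L))
            else:
                cds = (max(tss - 50 - cds_len, 1), tss - 50)
            genes.append(GeneModel(f"{name}_g{g}", name, tss, strand, cds[0], cds[1]))
        for s in range(spec.pac_sites_per_chromosome):
            pos = int(rng.integers(400, L - 400))
            strand = "+" if rng.random() < 0.5 else "-"
            pacs.append(GenomicInterval(name, pos, pos + 1, strand))
        for o in range(spec.ocrs_per_chromosome):
            start = int(rng.integers(0, L - spec.ocr_length))
            ocrs.append(GenomicInterval(name, start, start + spec.ocr_length))
    genome = SyntheticGenome(chromosomes=chroms, motif_intervals=motif_ivs,
                             genes=genes, pac_sites=pacs, ocrs=ocrs, spec=spec)
    if out_dir is not None:
        write_genome(genome, out_dir)
    return genome


def write_genome(genome: SyntheticGenome, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(genome.chromosomes, os.path.join(out_dir, "genome.fa"))
    with open(os.path.join(out_dir, "genes.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            lo = min(g.tss, g.cds_start, g.cds_end)
            hi = max(g.tss, g.cds_start, g.cds_end)
            fh.write(f"{g.chromosome}\tsynth\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.chromosome}\tsynth\tCDS\t{min(g.cds_start, g.cds_end)}\t"
                     f"{max(g.cds_start, g.cds_end)}\t.\t{g.strand}\t0\t"
                     f"ID={g.gene_id}.cds;Parent={g.gene_id}\n")
    write_bed(genome.pac_sites, os.path.join(out_dir, "pac.bed"))
    write_bed(genome.ocrs, os.path.join(out_dir, "ocr.bed"))
    with open(os.path.join(out_dir, "motifs.tsv"), "w") as fh:
        fh.write("chromosome\tstart\tend\tmotif\n")
        for iv in genome.motif_intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{genome.spec.motif}\n")


# ---------------------------------------------------------------------------
# planted motif classification task


@dataclass
class PlantedExample:
    id: str
    sequence: str
    label: int
    split: str
    motif_offset: int | None = None  # 0-based offset of the planted motif


@dataclass
class PlantedTask:
    examples: list[PlantedExample]
    motif: str
    window: int

    def split(self, name):
        return [e for e in self.examples if e.split == name]


def _contains(seq: str, motif: str) -> bool:
    from .io import revcomp
    return motif in seq or revcomp(motif) in seq


def generate_motif_task(genome: SyntheticGenome | None, motif: str = DEFAULT_MOTIF,
                        n_pos: int = 500, n_neg: int = 500, window: int = 200,
                        seed: int = 0,
                        composition=(0.25, 0.25, 0.25, 0.25),
                        split_fractions=(0.7, 0.15, 0.15)) -> PlantedTask:
    """Balanced binary task whose label is exactly 'window contains the motif'.

    Positives embed one motif copy at a uniform offset into a motif-free
    background window; negatives are rejection-sampled motif-free windows
    from the same background, so the GC distributions of the two classes
    match by construction (verified to within 2 percentage points in tests).
    Backgrounds are drawn from the genome's base composition when a genome
    is supplied, else from ``composition``.
    """
    if len(motif) >= window:
        raise SpecError("motif must be shorter than the window")
    comp = genome.spec.base_composition if genome is not None else composition
    rng = np.random.default_rng(seed)

    def background() -> str:
        for _ in range(100):
            s = "".join(_random_seq(rng, window, comp))
            if not _contains(s, motif):
                return s
        raise SpecError("motif too frequent in background to exclude")

    examples = []
    splits = ["train", "validation", "test"]
    probs = np.array(split_fractions) / sum(split_fractions)
    for i in range(n_pos):
        s = background()
        off = int(rng.integers(0, window - len(motif) + 1))
        s = s[:off] + motif + s[off + len(motif):]
        examples.append(PlantedExample(f"pos_{i}", s, 1,
                                       splits[int(rng.choice(3, p=probs))], off))
    for i in range(n_neg):
        examples.append(PlantedExample(f"neg_{i}", background(), 0,
                                       splits[int(rng.choice(3, p=probs))]))
    return PlantedTask(examples=examples, motif=motif, window=window)


# ---------------------------------------------------------------------------
# variant panel


def generate_variant_panel(genome: SyntheticGenome, n_variants: int = 200,
                           seed: int = 0,
                           disrupting_maf=(0.5, 20.0),
                           neutral_maf=(2.0, 5.0)) -> list[VariantRecord]:
    """Half motif-disrupting (inside a planted motif, consensus base
    changed), half neutral (background position outside every motif), with
    synthetic allele frequencies drawn so disrupting variants are rarer:
    MAF ~ Beta(0.5, 20) for disrupting vs Beta(2, 5) for neutral.

    functional_class records the ground truth ('motif_disrupting' /
    'neutral').
    """
    rng = np.random.default_rng(seed)
    n_disrupt = n_variants // 2
    motif_positions = [(iv.chromosome, p) for iv in genome.motif_intervals
                       for p in range(iv.start, iv.end)]
    if len(motif_positions) < n_disrupt:
        n_disrupt = len(motif_positions)
    in_motif = {(c, p) for c, p in motif_positions}
    out = []
    picks = rng.choice(len(motif_positions), size=n_disrupt, replace=False)
    for i in picks:
        chrom, p = motif_positions[int(i)]
        ref = genome.chromosomes[chrom][p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        out.append(VariantRecord(
            chromosome=chrom, position=p + 1, ref=ref, alt=alt,
            minor_allele_frequency=float(rng.beta(*disrupting_maf)),
            functional_class="motif_disrupting"))
    n_neutral = n_variants - n_disrupt
    chrom_names = sorted(genome.chromosomes)
    made = 0
    while made < n_neutral:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        p = int(rng.integers(0, len(genome.chromosomes[chrom])))
        if (chrom, p) in in_motif:
            continue
        ref = genome.chromosomes[chrom][p]
        if ref == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        out.append(VariantRecord(
            chromosome=chrom, position=p + 1, ref=ref, alt=alt,
            minor_allele_frequency=float(rng.beta(*neutral_maf)),
            functional_class="neutral"))
        made += 1
    return out


def write_variant_table(variants, path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\tref\talt\tmaf\tclass\n")
        for v in variants:
            fh.write(f"{v.chromosome}\t{v.position}\t{v.ref}\t{v.alt}\t"
                     f"{v.minor_allele_frequency}\t{v.functional_class}\n")
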