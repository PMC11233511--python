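"""Light wrappers over standard-format readers/writers used across modules.

Coordinate conventions: BED is 0-based half-open, GFF3 is 1-based inclusive,
and positions inside emitted windows are 1-based unless stated otherwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC percentage over A/C/G/T bases only (N excluded entirely)."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (s.count("G") + s.count("C")) / acgt


def load_genome(genome) -> dict[str, str]:
    """Accept {name: seq}, a FASTA path, or a pyfaidx.Fasta; return a dict."""
    if isinstance(genome, dict):
        return genome
    if isinstance(genome, (str, os.PathLike)):
        import pyfaidx
        fa = pyfaidx.Fasta(str(genome))
        return {name: str(fa[name][:]) for name in fa.keys()}
    return {name: str(genome[name][:]) for name in genome.keys()}


def load_fasta_records(path_or_dict) -> dict[str, str]:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path_or_dict), "fasta")}


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


@dataclass
class GenomicInterval:
    """BED-convention carrier: 0-based half-open, strand in {+,-,.}."""

    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(bed) -> list[GenomicInterval]:
    """Parse a BED path/DataFrame into intervals; unstranded records become '+'."""
    if isinstance(bed, list):
        return bed
    if isinstance(bed, pd.DataFrame):
        df = bed
    else:
        try:
            df = pd.read_csv(bed, sep="\t", header=None, comment="#")
        except Exception as exc:
            raise ValueError(f"malformed BED file {bed}: {exc}") from exc
    out = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else "+"
            out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed BED record at line {lineno}: {exc}") from exc
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
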