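"""Light genome summaries: FASTA parsing, length, GC content, GC skew.

GC skew, (G - C) / (G + C) in sliding windows, changes sign near the
replication origin and terminus of many circular genomes; here it is
computed over 0-based half-open windows, wrapping around the end of the
sequence only for records flagged circular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .errors import InputError

__all__ = [
    "GenomeRecord",
    "GenomeSummary",
    "read_fasta",
    "summarize",
    "gc_skew",
    "write_skew_bed",
]

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    identifier: str
    sequence: str  # uppercase ACGTN
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"record {self.identifier!r} has an empty sequence")
        seq = self.sequence.upper()
        bad = next((i for i, ch in enumerate(seq) if ch not in VALID_BASES), None)
        if bad is not None:
            raise InputError(
                f"record {self.identifier!r}: invalid character {seq[bad]!r} "
                f"at position {bad} (0-based)"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "GenomeRecord":
        comp = str.maketrans("ACGTN", "TGCAN")
        return GenomeRecord(
            identifier=self.identifier,
            sequence=self.sequence.translate(comp)[::-1],
            circular=self.circular,
        )


@dataclass(frozen=True)
class GenomeSummary:
    identifier: str
    length_bp: int
    gc_fraction: float
    gc_percent: int  # nearest-integer display value
    n_count: int
    base_counts: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "identifier": self.identifier,
                "length_bp": self.length_bp,
                "gc_fraction": self.gc_fraction,
                "gc_percent": self.gc_percent,
                "n_count": self.n_count,
                "base_counts": self.base_counts,
            },
            indent=2,
        )


def read_fasta(path, circular: bool = False) -> list[GenomeRecord]:
    """Parse a FASTA file into validated genome records.

    Sequences are uppercased; characters outside {A,C,G,T,N} raise an
    input error reporting the record and offending position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return [
        GenomeRecord(identifier=rec.id, sequence=str(rec.seq), circular=circular)
        for rec in records
    ]


def summarize(g: GenomeRecord) -> GenomeSummary:
    """Length and base composition of a genome.

    GC fraction is (G + C) / (A + C + G + T); ambiguous N bases are
    excluded from the denominator and reported separately.
    """
    seq = g.sequence
    counts = {base: seq.count(base) for base in "ACGTN"}
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if acgt == 0:
        raise InputError(f"record {g.identifier!r} is all-N; GC content undefined")
    gc = (counts["G"] + counts["C"]) / acgt
    return GenomeSummary(
        identifier=g.identifier,
        length_bp=len(seq),
        gc_fraction=gc,
        gc_percent=int(round(gc * 100)),
        n_count=counts["N"],
        base_counts=counts,
    )


def gc_skew(g: GenomeRecord, window: int, step: int | None = None) -> list[tuple[int, float]]:
    """Sliding-window GC skew profile, (G - C) / (G + C) per window.

    Windows are 0-based half-open intervals [start, start + window)
    reported by their start.  For circular records, windows wrap past
    the end so every start in range(0, length, step) is covered; for
    linear records the last start is length - window.  Windows without
    any G or C yield NaN.
    """
    if step is None:
        step = window
    L = len(g)
    if window > L:
        raise InputError(f"window {window} exceeds sequence length {L}")
    if window < 1 or step < 1:
        raise InputError("window and step must be >= 1")
    seq = g.sequence
    if g.circular:
        starts = range(0, L, step)
        padded = seq + seq[: window - 1]
    else:
        starts = range(0, L - window + 1, step)
        padded = seq
    profile: list[tuple[int, float]] = []
    for s in starts:
        win = padded[s : s + window]
        gg = win.count("G")
        cc = win.count("C")
        skew = np.nan if gg + cc == 0 else (gg - cc) / (gg + cc)
        profile.append((s, skew))
    return profile


def write_skew_bed(g: GenomeRecord, profile, path) -> None:
    """Write a skew profile as BED-like text: record, start, skew."""
    with open(path, "w") as fh:
        for start, skew in profile:
            fh.write(f"{g.identifier}\t{start}\t{skew:.6g}\n")
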