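"""Shared sequence primitives: records, intervals, encoding, FASTA/TSV I/O."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

# A=0 C=1 G=2 T=3; anything else (incl. N) = 4 and never matches.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA to uint8 codes (A0 C1 G2 T3, other 4). Lowercase accepted."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval", slack: int = 0) -> bool:
        return other.start >= self.start - slack and other.end <= self.end + slack

    def intersection_len(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Merge intervals whose separation is <= ``gap``; result sorted."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.start <= last.end + gap:
            if iv.end > last.end:
                out[-1] = Interval(last.start, iv.end)
        else:
            out.append(iv)
    return out


def union_length(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: a replicon of an assembly, or a query locus."""

    id: str
    description: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Element:
    """Annotated sequence element on a query locus (promoter box, RBS, ORF...)."""

    name: str
    interval: Interval
    reference: str


@dataclass(frozen=True)
class QueryLocus:
    """Annotated reference locus used as the homology-search query.

    ``toxin_segment`` spans the toxin transcript (5' UTR + ORF), ``antitoxin_segment``
    the antitoxin gene and ``utr_segment`` the toxin 5' UTR, all on the stored strand.
    """

    name: str
    sequence: str
    elements: tuple[Element, ...]
    toxin_segment: Interval
    antitoxin_segment: Interval
    utr_segment: Interval

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for el in self.elements:
            if el.interval.end > n:
                raise ValueError(f"element {el.name} outside sequence")
            if self.sequence[el.interval.start:el.interval.end] != el.reference:
                raise ValueError(f"element {el.name} reference mismatch")
        for iv in (self.toxin_segment, self.antitoxin_segment, self.utr_segment):
            if iv.end > n:
                raise ValueError("segment outside sequence")
        if self.toxin_segment.overlaps(self.antitoxin_segment):
            raise ValueError("toxin and antitoxin segments overlap")

    def element(self, name: str) -> Element | None:
        for el in self.elements:
            if el.name == name:
                return el
        return None

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(self.name, self.name, self.sequence)


# ---------------------------------------------------------------------------
# FASTA / annotation-table I/O

def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.description if rec.description else rec.id
            header = desc if desc.startswith(rec.id) else f"{rec.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [SequenceRecord(r.id, r.description, str(r.seq).upper())
            for r in SeqIO.parse(str(path), "fasta")]


_SEGMENT_NAMES = ("toxin_segment", "antitoxin_segment", "utr_segment")


def write_elements_tsv(loci: Sequence[QueryLocus], path: str | Path) -> None:
    """Element-annotation table: locus, element, start, end (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("locus\telement\tstart\tend\n")
        for q in loci:
            for el in q.elements:
                fh.write(f"{q.name}\t{el.name}\t{el.interval.start}\t{el.interval.end}\n")
            for seg in _SEGMENT_NAMES:
                iv: Interval = getattr(q, seg)
                fh.write(f"{q.name}\t{seg}\t{iv.start}\t{iv.end}\n")


def read_query_loci(fasta_path: str | Path, elements_path: str | Path) -> list[QueryLocus]:
    """Assemble QueryLocus objects from a FASTA + element-annotation TSV pair."""
    import pandas as pd

    seqs = {r.id: r.seq for r in read_fasta(fasta_path)}
    tab = pd.read_csv(elements_path, sep="\t")
    loci = []
    for name, grp in tab.groupby("locus", sort=True):
        if name not in seqs:
            raise ValueError(f"locus {name!r} in element table but not in FASTA")
        seq = seqs[name]
        elements = []
        segments: dict[str, Interval] = {}
        for row in grp.itertuples():
            iv = Interval(int(row.start), int(row.end))
            if row.element in _SEGMENT_NAMES:
                segments[row.element] = iv
            else:
                elements.append(Element(row.element, iv, seq[iv.start:iv.end]))
        missing = [s for s in _SEGMENT_NAMES if s not in segments]
        if missing:
            raise ValueError(f"locus {name!r} missing segment rows: {missing}")
        loci.append(QueryLocus(str(name), seq, tuple(elements),
                               segments["toxin_segment"],
                               segments["antitoxin_segment"],
                               segments["utr_segment"]))
    return loci


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
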