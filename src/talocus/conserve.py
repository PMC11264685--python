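"""Element-level conservation, consensus matrices and protein variant tables."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import log2
from typing import Iterable, Sequence

from ._seq import Element, Interval
from .align import AlignmentHit

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY*"

# IUPAC ambiguity code for each non-empty subset of {A,C,G,T}
_IUPAC = {frozenset(k): v for k, v in {
    "A": "A", "C": "C", "G": "G", "T": "T", "AC": "M", "AG": "R", "AT": "W",
    "CG": "S", "CT": "Y", "GT": "K", "ACG": "V", "ACT": "H", "AGT": "D",
    "CGT": "B", "ACGT": "N"}.items()}

# standard genetic code, written out so translation is independent of any
# library implementation (tests cross-check against one)
_T = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
CODON_TABLE = {a + b + c: _AA[16 * i + 4 * j + k]
               for i, a in enumerate(_T) for j, b in enumerate(_T)
               for k, c in enumerate(_T)}


@dataclass(frozen=True)
class ElementObservation:
    """Subject residues mapped from one query element through one alignment."""

    element_name: str
    assembly_id: str
    observed: str
    matches_reference: bool
    has_indel: bool = False


def _map_element_detail(hit: AlignmentHit, interval: Interval) -> tuple[str, bool] | None:
    if not (hit.query_interval.start <= interval.start and
            interval.end <= hit.query_interval.end):
        return None
    out = []
    has_indel = False
    qpos = hit.query_interval.start
    for qc, sc in zip(hit.aligned_query, hit.aligned_subject):
        if qc == "-":
            # insertion in the subject, placed between query positions
            if interval.start < qpos < interval.end:
                has_indel = True
                out.append(sc)
        else:
            if interval.start <= qpos < interval.end:
                if sc == "-":
                    has_indel = True
                else:
                    out.append(sc)
            qpos += 1
    return "".join(out), has_indel


def map_element(hit: AlignmentHit, element_interval: Interval) -> str | None:
    """Subject string aligned to a query interval, gaps removed.

    Returns None when the element is not fully inside the hit's query span.
    The observed string differs in length from the element only when the
    alignment has indels inside it.
    """
    detail = _map_element_detail(hit, element_interval)
    return None if detail is None else detail[0]


def observe_element(hit: AlignmentHit, element: Element,
                    assembly_id: str = "") -> ElementObservation | None:
    detail = _map_element_detail(hit, element.interval)
    if detail is None:
        return None
    observed, has_indel = detail
    return ElementObservation(element.name, assembly_id, observed,
                              matches_reference=(observed == element.reference
                                                 and not has_indel),
                              has_indel=has_indel)


def element_identity(observations: Sequence[ElementObservation] | Sequence[str],
                     reference: str) -> tuple[float, list[tuple[str, float]]]:
    """Fraction of observations identical to the reference, plus ranked variants.

    Variants are ranked by frequency, ties broken lexicographically.
    """
    if not observations:
        raise ValueError("no observations")
    strings = [o.observed if isinstance(o, ElementObservation) else o
               for o in observations]
    n = len(strings)
    identical = sum(1 for s in strings if s == reference)
    counts = Counter(strings)
    table = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return identical / n, [(s, c / n) for s, c in table]


@dataclass
class ConsensusMatrix:
    """Per-column symbol counts, consensus string and information content."""

    alphabet: str
    counts: list[dict[str, int]]
    n_sequences: int
    consensus: str
    information: list[float]
    masked: list[bool]

    def to_rows(self) -> list[dict]:
        rows = []
        for i, col in enumerate(self.counts):
            row = {"position": i}
            for sym in self.alphabet:
                row[sym] = col.get(sym, 0)
            row["gap"] = col.get("-", 0)
            row["bits"] = round(self.information[i], 6)
            row["consensus"] = self.consensus[i]
            rows.append(row)
        return rows


def build_consensus(sequences: Sequence[str], alphabet: str = "nt", *,
                    small_sample_correction: bool = False,
                    gap_mask_fraction: float = 0.5) -> ConsensusMatrix:
    """Column counts, modal consensus and information content R_i.

    R_i = log2(|alphabet|) - H_i with H_i the Shannon entropy of the non-gap
    symbol frequencies in column i.  Gap symbols are excluded from the
    entropy; columns with more than ``gap_mask_fraction`` gaps are flagged
    masked.  Ties for the modal symbol give the IUPAC ambiguity code
    (nucleotide) or 'X' (protein).
    """
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    symbols = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    bits_max = log2(len(symbols)) if alphabet != "nt" else 2.0
    counts: list[dict[str, int]] = []
    consensus = []
    information = []
    masked = []
    n = len(sequences)
    for i in range(length):
        col = Counter(s[i].upper() for s in sequences)
        counts.append(dict(col))
        n_gap = col.get("-", 0)
        masked.append(n_gap > gap_mask_fraction * n)
        core = {sym: c for sym, c in col.items() if sym in symbols}
        n_core = sum(core.values())
        if n_core == 0:
            consensus.append("-" if n_gap else "N" if alphabet == "nt" else "X")
            information.append(0.0)
            continue
        h = -sum((c / n_core) * log2(c / n_core) for c in core.values())
        r = bits_max - h
        if small_sample_correction:
            # standard small-sample entropy correction e_n = (|A|-1)/(2 ln2 n)
            r -= (len(symbols) - 1) / (2 * 0.6931471805599453 * n_core)
        information.append(max(0.0, r))
        top = max(core.values())
        modal = sorted(sym for sym, c in core.items() if c == top)
        if len(modal) == 1:
            consensus.append(modal[0])
        elif alphabet == "nt":
            consensus.append(_IUPAC[frozenset(modal)])
        else:
            consensus.append("X")
    return ConsensusMatrix(symbols, counts, n, "".join(consensus), information, masked)


@dataclass(frozen=True)
class Translation:
    protein: str
    truncated: bool        # internal stop codon before the final codon
    partial_codon: bool    # trailing bases not forming a full codon (trimmed)


def translate_orf(dna: str, table: dict[str, str] | None = None) -> Translation:
    """Standard-code translation; the terminal stop is stripped.

    Codons containing N translate to 'X'; other non-DNA symbols raise.  An
    internal stop truncates the protein and flags the result.
    """
    table = table or CODON_TABLE
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA symbols: {sorted(bad)}")
    partial = len(dna) % 3 != 0
    aa = []
    truncated = False
    n_codons = len(dna) // 3
    for ci in range(n_codons):
        codon = dna[3 * ci:3 * ci + 3]
        sym = "X" if "N" in codon else table[codon]
        if sym == "*":
            truncated = ci < n_codons - 1
            break
        aa.append(sym)
    return Translation("".join(aa), truncated, partial)


@dataclass(frozen=True)
class VariantRow:
    label: str
    protein: str
    count: int
    frequency: float


@dataclass
class ProteinVariantTable:
    reference: str
    rows: list[VariantRow]

    def frequency(self, label: str) -> float:
        for r in self.rows:
            if r.label == label:
                return r.frequency
        return 0.0


def variant_label(protein: str, reference: str) -> str:
    """Substitution-style label relative to the reference, e.g. N2S."""
    if protein == reference:
        return "reference"
    subs = [f"{r}{i + 1}{a}" for i, (r, a) in enumerate(zip(reference, protein))
            if r != a]
    return "+".join(subs)


def protein_variants(proteins: Sequence[str], reference: str) -> ProteinVariantTable:
    """Frequency table of full-length protein variants vs a reference.

    All inputs must equal the reference length (truncated/partial ORFs are
    excluded upstream).  Rows are ranked by frequency, ties lexicographic.
    """
    if not proteins:
        raise ValueError("no proteins")
    if any(len(p) != len(reference) for p in proteins):
        raise ValueError("all proteins must match the reference length")
    n = len(proteins)
    counts = Counter(proteins)
    rows = [VariantRow(variant_label(p, reference), p, c, c / n)
            for p, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return ProteinVariantTable(reference, rows)
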