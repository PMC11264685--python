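"""Synthetic pan-genomes with planted toxin-antitoxin loci and truth tables.

Every downstream stage (search, locus calling, conservation, pairing, group
statistics) is exercised against genomes produced here, so plants are tracked
in a truth table and all randomness flows from one master seed with
per-assembly substreams (``default_rng([seed, assembly_index])``).

Coordinates are 0-based half-open; the plus strand of the stored string is the
reference frame.  Planted fragments overwrite the background in place, so
truth intervals are exact replicon coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import (Element, Interval, QueryLocus, SequenceRecord, revcomp,
                   write_elements_tsv, write_fasta)

CATEGORIES = ("full", "interrupted", "antitoxin_only", "toxin_only", "absent")
BASES = np.array(list("ACGT"))

DEFAULT_UTR_STUB = 28       # antitoxin-only loci keep 27-29 nt of the toxin UTR
DEFAULT_SPACER = 1200       # insertion length for interrupted loci
DEFAULT_MIN_SPACING = 4000  # distance between planted locus starts


class LayoutError(ValueError):
    """Planted fragment does not fit, or overlaps a previous plant."""


@dataclass(frozen=True)
class LocusTemplate:
    """Annotated reference locus used both for planting and as a query."""

    name: str
    sequence: str
    elements: tuple[Element, ...]
    toxin_segment: Interval
    antitoxin_segment: Interval
    utr_segment: Interval

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for el in self.elements:
            if not (0 <= el.interval.start and el.interval.end <= n):
                raise ValueError(f"element {el.name} outside template")
            if self.sequence[el.interval.start:el.interval.end] != el.reference:
                raise ValueError(f"element {el.name} reference string mismatch")
        if self.toxin_segment.overlaps(self.antitoxin_segment):
            raise ValueError("toxin and antitoxin segments overlap")

    def element(self, name: str) -> Element | None:
        for el in self.elements:
            if el.name == name:
                return el
        return None

    def as_query(self) -> QueryLocus:
        return QueryLocus(self.name, self.sequence, self.elements,
                          self.toxin_segment, self.antitoxin_segment,
                          self.utr_segment)


@dataclass(frozen=True)
class PlantSpec:
    """How one assembly's loci for a system are planted."""

    category: str
    copies: float = 1.0
    on_plasmid: bool = False
    mutation_rate: float = 0.0
    variant_edits: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.copies < 0 or round(self.copies * 2) != self.copies * 2:
            raise ValueError("copies must be a non-negative multiple of 0.5")
        if self.category == "absent" and self.copies != 0:
            raise ValueError("absent requires copies = 0")
        if self.category != "absent" and self.copies == 0:
            raise ValueError("non-absent categories require copies > 0")
        if self.category in ("antitoxin_only", "toxin_only") and \
                round(self.copies / 0.5) != self.copies / 0.5:
            raise ValueError("orphan categories count 0.5 per instance")
        if not 0.0 <= self.mutation_rate <= 0.2:
            raise ValueError("mutation_rate must be in [0, 0.2]")

    def instances(self) -> list[str]:
        """Expand to a list of per-instance categories."""
        if self.category == "absent":
            return []
        if self.category in ("antitoxin_only", "toxin_only"):
            return [self.category] * int(round(self.copies / 0.5))
        n_full = int(self.copies)
        out = [self.category] * n_full
        if round(self.copies - n_full, 1) == 0.5:
            out.append("antitoxin_only")
        return out


@dataclass
class TruthRecord:
    """One planted locus instance (or metadata for the plant)."""

    category: str
    start: int
    end: int
    strand: str
    template_name: str
    copy_units: float
    assembly_id: str = ""
    strain_name: str = ""
    replicon_id: str = ""
    replicon_type: str = "chromosome"


@dataclass(frozen=True)
class MetadataModel:
    """Finite label vocabularies plus an optional planted copy-number effect.

    ``copy_effect = (pathotype_label, effect_in_copies)`` adds that many full
    copies (fractional part as a Bernoulli extra) to assemblies of the group,
    creating a recoverable group-mean signal for the statistics stage.
    """

    pathotypes: tuple[tuple[str, float], ...] = (
        ("intestinal disease", 0.30), ("extraintestinal disease", 0.25),
        ("healthy", 0.30), ("lab", 0.15))
    geographies: tuple[tuple[str, float], ...] = (
        ("north_america", 0.40), ("europe", 0.30), ("asia", 0.30))
    copy_effect: tuple[str, float] | None = None

    def draw(self, rng: np.random.Generator) -> tuple[str, str, str]:
        p_labels = [t[0] for t in self.pathotypes]
        p_probs = np.array([t[1] for t in self.pathotypes], dtype=float)
        g_labels = [t[0] for t in self.geographies]
        g_probs = np.array([t[1] for t in self.geographies], dtype=float)
        pathotype = p_labels[rng.choice(len(p_labels), p=p_probs / p_probs.sum())]
        geography = g_labels[rng.choice(len(g_labels), p=g_probs / g_probs.sum())]
        source = "laboratory" if pathotype == "lab" else "environmental"
        return pathotype, geography, source


# ---------------------------------------------------------------------------
# primitives

def generate_background(length: int, gc: float, seed) -> str:
    """Random DNA with expected GC fraction ``gc``; reproducible for a seed."""
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator,
                    protected: Sequence[Interval] = ()) -> str:
    """I.i.d. substitutions (to a different base) outside protected intervals."""
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for iv in protected:
        hit[iv.start:iv.end] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _build_fragment(template: LocusTemplate, category: str, rng: np.random.Generator,
                    mutation_rate: float, variant_edits, protect_elements: bool,
                    spacer_len: int, utr_stub: int) -> str:
    """Template fragment for one planted instance, in template orientation."""
    seq = template.sequence
    if variant_edits:
        arr = list(seq)
        for pos, base in variant_edits:
            arr[pos] = base
        seq = "".join(arr)
    protected = [el.interval for el in template.elements] if protect_elements else []
    seq = mutate_sequence(seq, mutation_rate, rng, protected)

    a, utr = template.antitoxin_segment, template.utr_segment
    if category == "full":
        return seq
    if category == "interrupted":
        cut = template.toxin_segment.start + len(utr) // 2
        spacer = generate_background(spacer_len, 0.5, rng)
        return seq[:cut] + spacer + seq[cut:]
    if category == "antitoxin_only":
        if not 0 <= utr_stub <= len(utr):
            raise ValueError("utr_stub outside the UTR")
        return seq[a.start:a.end] + seq[utr.start:utr.start + utr_stub]
    if category == "toxin_only":
        t = template.toxin_segment
        return seq[t.start:t.end]
    raise ValueError(f"cannot build fragment for category {category!r}")


_COPY_UNITS = {"full": 1.0, "interrupted": 1.0,
               "antitoxin_only": 0.5, "toxin_only": 0.5}


def plant_locus(background: str, template: LocusTemplate, spec: PlantSpec,
                position: int, seed, *, category: str | None = None,
                protect_elements: bool = True, spacer_len: int = DEFAULT_SPACER,
                utr_stub: int = DEFAULT_UTR_STUB) -> tuple[str, TruthRecord]:
    """Overwrite ``background`` at ``position`` with one locus instance.

    ``category`` overrides ``spec.category`` for multi-instance specs (a
    1.5-copy spec plants one full and one antitoxin-only instance).  Strand is
    a seeded coin flip; the truth interval is the exact replicon slice.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cat = category or spec.category
    if cat == "absent":
        raise ValueError("cannot plant an absent locus")
    frag = _build_fragment(template, cat, rng, spec.mutation_rate,
                           spec.variant_edits, protect_elements, spacer_len, utr_stub)
    if position < 0 or position + len(frag) > len(background):
        raise LayoutError(
            f"fragment [{position}, {position + len(frag)}) does not fit "
            f"replicon of length {len(background)}")
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        frag = revcomp(frag)
    new_seq = background[:position] + frag + background[position + len(frag):]
    rec = TruthRecord(category=cat, start=position, end=position + len(frag),
                      strand=strand, template_name=template.name,
                      copy_units=_COPY_UNITS[cat])
    return new_seq, rec


# ---------------------------------------------------------------------------
# default locus template

_CODONS_NO_STOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]


def make_template(name: str, seed, *, antitoxin_len: int = 90, utr_len: int = 70,
                  orf_codons: int = 29, orf_edits: Mapping[int, str] | None = None) -> LocusTemplate:
    """Deterministic synthetic locus: promoter, antitoxin, toxin 5' UTR + ORF.

    Layout: [promoter 40][antitoxin][UTR][ORF incl stop][flank 30].  The
    antitoxin carries a 20-nt exact antisense copy of the UTR pairing target
    (which spans the toxin RBS), so planted pairs are repression-competent.
    ``orf_edits`` maps codon index (0-based, codon 0 = start) to a replacement
    codon, for building protein variants.
    """
    rng = np.random.default_rng(seed)
    promoter = generate_background(40, 0.5, rng)
    antitoxin = generate_background(antitoxin_len, 0.5, rng)
    utr = generate_background(utr_len, 0.5, rng)
    codons = [_CODONS_NO_STOP[i] for i in rng.integers(0, len(_CODONS_NO_STOP),
                                                       orf_codons - 1)]
    if orf_edits:
        for ci, codon in orf_edits.items():
            codons[ci - 1] = codon
    orf = "ATG" + "".join(codons) + "TAA"
    flank = generate_background(30, 0.5, rng)

    minus35, minus10 = "TTGACA", "TATAAT"
    tfbox = generate_background(16, 0.5, rng)
    promoter = minus35 + tfbox + promoter[22:25] + minus10 + promoter[31:]
    assert len(promoter) == 40

    a0 = 40
    a1 = a0 + antitoxin_len
    u0, u1 = a1, a1 + utr_len
    o0, o1 = u1, u1 + len(orf)

    # pairing target: last 20 nt of the UTR (offset utr_len-20), covering the RBS
    pt_lo, pt_hi = utr_len - 25, utr_len - 5
    rbs = "AGGAGG"
    utr = utr[:pt_hi - 8] + rbs + utr[pt_hi - 2:]
    target = utr[pt_lo:pt_hi]
    # stamp the antisense copy into the antitoxin interior
    at_off = 25
    antitoxin = antitoxin[:at_off] + revcomp(target) + antitoxin[at_off + 20:]

    seq = promoter + antitoxin + utr + orf + flank
    eap_lo, eap_hi = u0 + 15, u0 + 35
    elements = (
        Element("minus35", Interval(0, 6), minus35),
        Element("tfbox", Interval(6, 22), tfbox),
        Element("minus10", Interval(25, 31), minus10),
        Element("eap", Interval(eap_lo, eap_hi), seq[eap_lo:eap_hi]),
        Element("rbs", Interval(u0 + pt_hi - 8, u0 + pt_hi - 2), rbs),
        Element("pairing_target", Interval(u0 + pt_lo, u0 + pt_hi), target),
        Element("orf", Interval(o0, o1), orf),
    )
    return LocusTemplate(name, seq, elements, Interval(u0, o1),
                         Interval(a0, a1), Interval(u0, u1))


def default_templates(seed: int = 20_17) -> list[LocusTemplate]:
    """One reference template per simulated system."""
    return [make_template("ta1", seed)]


def default_mix() -> dict[PlantSpec, float]:
    """Category mix loosely shaped like the observed copy-number spectrum."""
    return {
        PlantSpec("full", 1.0): 0.30,
        PlantSpec("full", 2.0): 0.25,
        PlantSpec("full", 1.5): 0.05,
        PlantSpec("interrupted", 1.0): 0.08,
        PlantSpec("antitoxin_only", 0.5): 0.22,
        PlantSpec("full", 2.0, on_plasmid=True): 0.04,
        PlantSpec("absent", 0.0): 0.06,
    }


# ---------------------------------------------------------------------------
# pan-genome generation

@dataclass
class Pangenome:
    out_dir: Path
    genome_paths: list[Path]
    truth_path: Path
    metadata_path: Path
    queries_path: Path
    elements_path: Path
    truth: pd.DataFrame
    metadata: pd.DataFrame


def _choose_spec(mix: Mapping[PlantSpec, float], rng: np.random.Generator) -> PlantSpec:
    specs = list(mix.keys())
    probs = np.array(list(mix.values()), dtype=float)
    if probs.sum() <= 0 or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("category mix must sum to 1")
    return specs[rng.choice(len(specs), p=probs / probs.sum())]


def generate_pangenome(n: int, category_mix: Mapping[PlantSpec, float],
                       metadata_model: MetadataModel | None,
                       templates: Sequence[LocusTemplate], seed: int,
                       out_dir: str | Path, *, chrom_len: int = 30_000,
                       plasmid_len: int = 8_000, gc: float = 0.5,
                       duplicate_rate: float = 0.0, dh5a_mode: bool = False,
                       min_spacing: int = DEFAULT_MIN_SPACING,
                       utr_stub: int = DEFAULT_UTR_STUB,
                       protect_elements: bool = True) -> Pangenome:
    """Write ``n`` assemblies (FASTA), a truth TSV and a metadata TSV.

    Each assembly has one chromosome and 0-2 plasmids; plasmid records carry
    the word "plasmid" in their description.  ``duplicate_rate`` re-uses a
    previous assembly's strain name and plant spec (identical copy number);
    ``dh5a_mode`` forces the first three assemblies to share the name
    "DH5alpha" with copy numbers 0.5 / 0.5 / 2 to exercise deduplication.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not templates:
        raise ValueError("empty template list")
    metadata_model = metadata_model or MetadataModel()
    out_dir = Path(out_dir)
    genomes_dir = out_dir / "genomes"
    genomes_dir.mkdir(parents=True, exist_ok=True)

    if dh5a_mode and n < 3:
        raise ValueError("dh5a_mode requires n >= 3")

    truth_rows: list[dict] = []
    meta_rows: list[dict] = []
    genome_paths: list[Path] = []
    chosen: list[tuple[str, dict[str, PlantSpec]]] = []  # (strain, spec per template)

    for i in range(n):
        rng = np.random.default_rng([seed, i])
        aid = f"ASM{i:04d}"
        specs: dict[str, PlantSpec] = {}
        if dh5a_mode and i < 3:
            strain = "DH5alpha"
            forced = (PlantSpec("antitoxin_only", 0.5), PlantSpec("antitoxin_only", 0.5),
                      PlantSpec("full", 2.0))[i]
            for t in templates:
                specs[t.name] = forced
        elif i > 0 and rng.random() < duplicate_rate:
            strain, specs = chosen[int(rng.integers(0, i))]
        else:
            strain = f"strain{i:04d}"
            for t in templates:
                specs[t.name] = _choose_spec(category_mix, rng)
        chosen.append((strain, specs))

        pathotype, geography, source = metadata_model.draw(rng)

        extra_full = 0
        if metadata_model.copy_effect is not None:
            group, effect = metadata_model.copy_effect
            if pathotype == group:
                extra_full = int(effect) + (1 if rng.random() < effect - int(effect) else 0)

        n_plasmids = int(rng.integers(0, 3))
        if any(s.on_plasmid for s in specs.values()):
            n_plasmids = max(1, n_plasmids)
        replicons: dict[str, str] = {
            f"{aid}_chr": generate_background(chrom_len, gc, rng)}
        for k in range(n_plasmids):
            replicons[f"{aid}_p{k + 1}"] = generate_background(plasmid_len, gc, rng)

        next_pos = {rid: 2_000 for rid in replicons}
        for t in templates:
            spec = specs[t.name]
            cats = spec.instances() + ["full"] * extra_full
            for cat in cats:
                rid = f"{aid}_p1" if spec.on_plasmid else f"{aid}_chr"
                pos = next_pos[rid] + int(rng.integers(0, 200))
                new_seq, rec = plant_locus(replicons[rid], t, spec, pos, rng,
                                           category=cat, utr_stub=utr_stub,
                                           protect_elements=protect_elements)
                replicons[rid] = new_seq
                next_pos[rid] = rec.end + min_spacing
                rec.assembly_id, rec.strain_name, rec.replicon_id = aid, strain, rid
                rec.replicon_type = "plasmid" if rid.endswith(tuple("123")) and "_p" in rid \
                    else "chromosome"
                truth_rows.append({
                    "assembly_id": aid, "strain_name": strain, "replicon_id": rid,
                    "replicon_type": rec.replicon_type, "category": rec.category,
                    "start": rec.start, "end": rec.end, "strand": rec.strand,
                    "template_name": rec.template_name})

        records = []
        for rid, s in replicons.items():
            if "_p" in rid:
                desc = f"{rid} {strain} plasmid {rid.split('_')[-1]}, complete sequence"
            else:
                desc = f"{rid} {strain} chromosome, complete genome"
            records.append(SequenceRecord(rid, desc, s))
        path = genomes_dir / f"{aid}.fasta"
        write_fasta(records, path)
        genome_paths.append(path)
        meta_rows.append({"assembly_id": aid, "strain_name": strain,
                          "source_category": source, "pathotype": pathotype,
                          "geography": geography})

    truth = pd.DataFrame(truth_rows, columns=[
        "assembly_id", "strain_name", "replicon_id", "replicon_type", "category",
        "start", "end", "strand", "template_name"])
    metadata = pd.DataFrame(meta_rows)
    truth_path = out_dir / "truth.tsv"
    metadata_path = out_dir / "metadata.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    metadata.to_csv(metadata_path, sep="\t", index=False)

    queries_path = out_dir / "queries.fasta"
    elements_path = out_dir / "elements.tsv"
    write_fasta([t.as_query().as_record() for t in templates], queries_path)
    write_elements_tsv([t.as_query() for t in templates], elements_path)

    return Pangenome(out_dir, genome_paths, truth_path, metadata_path,
                     queries_path, elements_path, truth, metadata)


def truth_copy_numbers(truth: pd.DataFrame, metadata: pd.DataFrame,
                       template_name: str) -> pd.Series:
    """Per-assembly planted copy number for one system (0 when absent)."""
    sub = truth[truth.template_name == template_name]
    per_asm = sub.category.map(_COPY_UNITS).groupby(sub.assembly_id).sum()
    return per_asm.reindex(metadata.assembly_id, fill_value=0.0)
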