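"""From alignment hits to locus calls and per-assembly copy numbers.

Copy units: a full or interrupted toxin+antitoxin locus counts 1.0; an orphan
antitoxin or orphan toxin counts 0.5; profiles that fit no category are
reported as "partial" and excluded from copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._seq import Interval, QueryLocus, SequenceRecord, merge_intervals, union_length
from .align import AlignmentHit, ScoringScheme, search

COPY_UNITS = {"full": 1.0, "interrupted": 1.0,
              "antitoxin_only": 0.5, "toxin_only": 0.5, "partial": 0.0}

TYPE_PRECEDENCE = {"O": 0, "P": 1, "Q": 2}


@dataclass
class CoverageProfile:
    """One genomic cluster of hits for a single query, with query coverage."""

    query_id: str
    subject_id: str
    strand: str
    interval: Interval                    # cluster footprint on the subject
    segments: tuple[Interval, ...]        # merged covered query segments
    collinear: bool
    max_gap_in_subject: int
    best_bit_score: float
    hits: tuple[AlignmentHit, ...] = field(repr=False, default=())

    @property
    def covered_length(self) -> int:
        return union_length(self.segments)

    @property
    def span(self) -> Interval:
        return Interval(min(s.start for s in self.segments),
                        max(s.end for s in self.segments))


@dataclass(frozen=True)
class LocusCall:
    assembly_id: str
    replicon_id: str
    category: str                         # full/interrupted/antitoxin_only/toxin_only/partial
    copy_units: float
    locus_type: str = "unassigned"
    on_plasmid: bool = False
    best_bit_score: float = 0.0
    interval: Interval = Interval(0, 0)
    strand: str = "+"
    query_id: str = ""
    profile: CoverageProfile | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.category not in COPY_UNITS:
            raise ValueError(f"unknown category {self.category!r}")
        if self.copy_units != COPY_UNITS[self.category]:
            raise ValueError("copy_units inconsistent with category")


@dataclass
class AssemblyReport:
    assembly_id: str
    strain_name: str
    calls: dict[str, list[LocusCall]] = field(default_factory=dict)
    partials: dict[str, list[LocusCall]] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def copy_number(self, system: str) -> float:
        return sum(c.copy_units for c in self.calls.get(system, []))

    def copy_vector(self) -> tuple[tuple[str, float], ...]:
        return tuple(sorted((s, self.copy_number(s)) for s in self.calls))


# ---------------------------------------------------------------------------

def cluster_hits(hits: Sequence[AlignmentHit], max_gap: int = 2000, *,
                 merge_subject_gap: int = 100, merge_query_gap: int = 50,
                 min_hit_bits: float = 50.0) -> list[CoverageProfile]:
    """Group hits into genomic clusters and project query coverage.

    Hits on the same subject and strand whose footprints are within
    ``max_gap`` form one cluster.  When a cluster contains any hit of at
    least ``min_hit_bits``, weaker co-clustered hits (chance word matches in
    the flanks) are ignored; clusters made only of weak hits are kept intact
    so they can be reported as partial matches.

    Within a cluster, hits merge into one covered query segment only when
    near-contiguous in both query and subject (gaps below the merge
    thresholds); larger gaps leave separate segments, which is what the
    classifier uses to call interruptions.
    """
    if not hits:
        return []
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError("cluster_hits expects hits for a single query")
    by_key: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        by_key.setdefault((h.subject_id, h.strand), []).append(h)

    profiles = []
    for (sid, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.subject_interval.start)
        clusters: list[list[AlignmentHit]] = [[group[0]]]
        for h in group[1:]:
            if h.subject_interval.start - clusters[-1][-1].subject_interval.end <= max_gap:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cl in clusters:
            strong = [h for h in cl if h.bit_score >= min_hit_bits]
            if strong:
                cl = strong
            # subject-order collinearity (reading order flips on the minus strand)
            s_ordered = cl if strand == "+" else cl[::-1]
            collinear = all(s_ordered[k].query_interval.start <=
                            s_ordered[k + 1].query_interval.start
                            for k in range(len(s_ordered) - 1))
            max_sgap = 0
            for prev, nxt in zip(s_ordered, s_ordered[1:]):
                if strand == "+":
                    sgap = nxt.subject_interval.start - prev.subject_interval.end
                else:
                    sgap = prev.subject_interval.start - nxt.subject_interval.end
                max_sgap = max(max_sgap, sgap)
            # covered query segments, built in query order
            q_ordered = sorted(cl, key=lambda h: (h.query_interval.start,
                                                  h.query_interval.end))
            segments: list[Interval] = [q_ordered[0].query_interval]
            prev_h = q_ordered[0]
            for nxt in q_ordered[1:]:
                cur = segments[-1]
                if nxt.query_interval.end <= cur.end:
                    continue  # adds no new query coverage
                if strand == "+":
                    sgap = nxt.subject_interval.start - prev_h.subject_interval.end
                else:
                    sgap = prev_h.subject_interval.start - nxt.subject_interval.end
                qgap = nxt.query_interval.start - cur.end
                if abs(sgap) < merge_subject_gap and qgap < merge_query_gap:
                    segments[-1] = Interval(cur.start, nxt.query_interval.end)
                else:
                    start = max(nxt.query_interval.start, cur.end)
                    segments.append(Interval(start, nxt.query_interval.end))
                prev_h = nxt
            profiles.append(CoverageProfile(
                query_id=cl[0].query_id, subject_id=sid, strand=strand,
                interval=Interval(min(h.subject_interval.start for h in cl),
                                  max(h.subject_interval.end for h in cl)),
                segments=tuple(segments),
                collinear=collinear, max_gap_in_subject=max_sgap,
                best_bit_score=max(h.bit_score for h in cl), hits=tuple(cl)))
    return profiles


def filter_spurious(profiles: Sequence[CoverageProfile],
                    query: QueryLocus | None = None, min_span: int = 60,
                    terminator_blacklist: Interval | None = None, *,
                    containment_slack: int = 20) -> list[CoverageProfile]:
    """Drop short terminator-region matches and palindromic echo clusters.

    A profile is removed when (a) its covered query segments all lie inside
    ``terminator_blacklist`` and span less than ``min_span`` nt, or (b) it is
    an opposite-strand cluster contained within the genomic footprint of a
    larger retained cluster on the same subject (a self-palindromic match,
    never an extra copy).
    """
    kept: list[CoverageProfile] = []
    order = sorted(profiles, key=lambda p: (-p.covered_length, p.subject_id,
                                            p.interval.start))
    for p in order:
        if terminator_blacklist is not None:
            span = p.span
            if terminator_blacklist.contains(span) and len(span) < min_span:
                continue
        contained = any(
            k.subject_id == p.subject_id and k.strand != p.strand and
            k.interval.contains(p.interval, slack=containment_slack) and
            k.covered_length >= p.covered_length
            for k in kept)
        if contained:
            continue
        kept.append(p)
    kept.sort(key=lambda p: (p.subject_id, p.interval.start))
    return kept


def classify_locus(profile: CoverageProfile, query: QueryLocus,
                   full_cov: float = 0.95, utr_slack: int = 30, *,
                   edge_slop: int = 25, max_internal_deletion: int = 300,
                   segment_cov: float = 0.8, assembly_id: str = "",
                   on_plasmid: bool = False) -> LocusCall:
    """Assign full / interrupted / antitoxin_only / toxin_only / partial.

    ``edge_slop`` tolerates a few residues of chance extension past a planted
    fragment boundary when testing confinement to the antitoxin or toxin
    segment.
    """
    if profile.query_id != query.name:
        raise ValueError(f"profile query {profile.query_id!r} != {query.name!r}")
    qlen = len(query.sequence)
    segs = profile.segments
    covered = profile.covered_length
    span = profile.span

    category = "partial"
    if len(segs) == 1 and profile.collinear and covered >= full_cov * qlen:
        category = "full"
    elif (len(segs) >= 2 and profile.collinear and
          len(span) >= full_cov * qlen and
          covered >= full_cov * qlen - max_internal_deletion):
        category = "interrupted"
    else:
        anti, tox, utr = (query.antitoxin_segment, query.toxin_segment,
                          query.utr_segment)
        orf_el = query.element("orf")
        orf_iv = orf_el.interval if orf_el else Interval(utr.end, tox.end)
        pair_el = query.element("pairing_target")
        anti_zone = Interval(max(0, anti.start - edge_slop),
                             min(qlen, utr.start + utr_slack + edge_slop))
        tox_zone = Interval(max(0, tox.start - edge_slop),
                            min(qlen, tox.end + edge_slop))
        in_anti = all(anti_zone.contains(s) for s in segs)
        no_toxin = all(not s.overlaps(orf_iv) for s in segs) and (
            pair_el is None or all(not s.overlaps(pair_el.interval) for s in segs))
        anti_cov = sum(s.intersection_len(anti) for s in segs)
        if in_anti and no_toxin and anti_cov >= segment_cov * len(anti):
            category = "antitoxin_only"
        else:
            in_tox = all(tox_zone.contains(s) for s in segs)
            no_anti = all(not s.overlaps(anti) for s in segs)
            tox_cov = sum(s.intersection_len(tox) for s in segs)
            if in_tox and no_anti and tox_cov >= segment_cov * len(tox):
                category = "toxin_only"

    return LocusCall(assembly_id=assembly_id, replicon_id=profile.subject_id,
                     category=category, copy_units=COPY_UNITS[category],
                     on_plasmid=on_plasmid, best_bit_score=profile.best_bit_score,
                     interval=profile.interval, strand=profile.strand,
                     query_id=profile.query_id, profile=profile)


DEFAULT_TYPE_THRESHOLDS = {"full": 650.0, "O": 280.0, "P": 250.0}


def assign_locus_type(call: LocusCall, scores_by_query: Mapping[str, float],
                      thresholds: Mapping[str, float] | None = None) -> LocusCall:
    """Type a locus (O/P/Q) from its bit scores against the typed queries.

    Full and interrupted loci take the highest-scoring query exceeding the
    "full" threshold (ties broken O > P > Q).  Antitoxin-only loci use the
    per-type antitoxin cutoffs: type O first, then P, else unassigned.
    """
    th = dict(DEFAULT_TYPE_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    locus_type = "unassigned"
    if call.category in ("full", "interrupted"):
        winners = [(s, TYPE_PRECEDENCE.get(t, 99), t)
                   for t, s in scores_by_query.items() if s > th["full"]]
        if winners:
            winners.sort(key=lambda w: (-w[0], w[1], w[2]))
            locus_type = winners[0][2]
    elif call.category == "antitoxin_only":
        if scores_by_query.get("O", float("-inf")) > th["O"]:
            locus_type = "O"
        elif scores_by_query.get("P", float("-inf")) > th["P"]:
            locus_type = "P"
    return replace(call, locus_type=locus_type)


def detect_plasmid(subject_description: str) -> bool:
    """True iff the record description marks an extrachromosomal replicon."""
    d = subject_description.lower()
    return "plasmid" in d or "extrachromosomal" in d


def set_categorize(full_hits: set[str], toxin_hits: set[str],
                   antitoxin_hits: set[str],
                   all_ids: Iterable[str] | None = None) -> dict[str, str]:
    """Set-difference categorization of assemblies from three hit lists.

    Assemblies hit by the full-locus query but not the antitoxin query are
    toxin-only; hit by the full query but not the toxin query are
    antitoxin-only; in all three are paired; in none are absent.  An assembly
    hit by a single-gene query but not the full-locus query is an anomaly.
    """
    universe = set(all_ids) if all_ids is not None else \
        full_hits | toxin_hits | antitoxin_hits
    out = {}
    for aid in universe:
        f, t, a = aid in full_hits, aid in toxin_hits, aid in antitoxin_hits
        if (t or a) and not f:
            out[aid] = "anomaly"
        elif f and t and a:
            out[aid] = "paired"
        elif f and t:
            out[aid] = "toxin_only"
        elif f and a:
            out[aid] = "antitoxin_only"
        elif f:
            out[aid] = "anomaly"
        else:
            out[aid] = "absent"
    return out


def dedupe_assemblies(reports: Sequence[AssemblyReport]
                      ) -> tuple[list[AssemblyReport], list[AssemblyReport]]:
    """Keep one representative per (strain name, copy-number vector).

    Assemblies with an empty strain name are never deduplicated.  Within a
    name group, the representative of each distinct copy-number vector is the
    lexicographically first assembly id; all others are removed.
    """
    by_name: dict[str, list[AssemblyReport]] = {}
    for r in reports:
        by_name.setdefault(r.strain_name, []).append(r)
    kept, removed = [], []
    for name, group in by_name.items():
        if not name:
            kept.extend(group)
            continue
        seen: dict[tuple, str] = {}
        for r in sorted(group, key=lambda r: r.assembly_id):
            vec = r.copy_vector()
            if vec in seen:
                removed.append(r)
            else:
                seen[vec] = r.assembly_id
                kept.append(r)
    kept.sort(key=lambda r: r.assembly_id)
    removed.sort(key=lambda r: r.assembly_id)
    return kept, removed


# ---------------------------------------------------------------------------
# per-assembly driver

def analyze_assembly(replicons: Sequence[SequenceRecord], query: QueryLocus,
                     scheme: ScoringScheme | None = None, *,
                     assembly_id: str = "", evalue_cutoff: float = 10.0,
                     max_targets: int = 10000, max_gap: int = 2000,
                     full_cov: float = 0.95, utr_slack: int = 30,
                     min_span: int = 60,
                     terminator_blacklist: Interval | None = None
                     ) -> tuple[list[LocusCall], list[LocusCall]]:
    """Search one assembly with one query and return (counted, partial) calls."""
    hits = search(query.as_record(), replicons, scheme,
                  evalue_cutoff=evalue_cutoff, max_targets=max_targets)
    profiles = filter_spurious(cluster_hits(hits, max_gap=max_gap), query,
                               min_span=min_span,
                               terminator_blacklist=terminator_blacklist)
    desc = {r.id: r.description for r in replicons}
    counted, partial = [], []
    for p in profiles:
        call = classify_locus(p, query, full_cov=full_cov, utr_slack=utr_slack,
                              assembly_id=assembly_id,
                              on_plasmid=detect_plasmid(desc.get(p.subject_id, "")))
        (partial if call.category == "partial" else counted).append(call)
    return counted, partial
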