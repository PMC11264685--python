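import numpy as np
import pytest

from talocus._seq import Interval, SequenceRecord, read_fasta, revcomp
from talocus.align import AlignmentHit
from talocus.loci import (AssemblyReport, LocusCall, analyze_assembly,
                          assign_locus_type, classify_locus, cluster_hits,
                          dedupe_assemblies, detect_plasmid, filter_spurious,
                          set_categorize)
from talocus.synthio import (PlantSpec, default_mix, generate_pangenome,
                             plant_locus, truth_copy_numbers)
from tests.conftest import random_dna


def make_hit(qs, qe, ss, se, strand="+", bits=500.0, subject="chr", query="ta1"):
    n = qe - qs
    s = "A" * n
    return AlignmentHit(query_id=query, subject_id=subject,
                        query_interval=Interval(qs, qe),
                        subject_interval=Interval(ss, se), strand=strand,
                        aligned_query=s, aligned_subject=s, raw_score=2 * n,
                        bit_score=bits, evalue=1e-10,
                        percent_identity=100.0, query_coverage=n / 320)


class TestClusterHits:
    def test_single_hit_single_profile(self):
        profiles = cluster_hits([make_hit(0, 320, 5000, 5320)])
        assert len(profiles) == 1
        assert profiles[0].segments == (Interval(0, 320),)
        assert profiles[0].collinear

    def test_split_hits_two_segments_collinear(self):
        # a 1,200-nt subject insertion between two fragments
        hits = [make_hit(0, 165, 5000, 5165), make_hit(165, 320, 6365, 6520)]
        profiles = cluster_hits(hits)
        assert len(profiles) == 1
        p = profiles[0]
        assert len(p.segments) == 2
        assert p.collinear
        assert p.max_gap_in_subject == 1200

    def test_distant_loci_two_profiles(self):
        hits = [make_hit(0, 320, 5000, 5320), make_hit(0, 320, 55_000, 55_320)]
        assert len(cluster_hits(hits)) == 2

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            cluster_hits([make_hit(0, 10, 0, 10, query="a"),
                          make_hit(0, 10, 0, 10, query="b")])

    def test_weak_co_clustered_hits_ignored(self):
        hits = [make_hit(0, 320, 5000, 5320, bits=600.0),
                make_hit(100, 112, 6000, 6012, bits=22.0)]
        p = cluster_hits(hits)[0]
        assert p.segments == (Interval(0, 320),)

    def test_weak_only_cluster_kept(self):
        p = cluster_hits([make_hit(10, 25, 9000, 9015, bits=22.0)])[0]
        assert p.segments == (Interval(10, 25),)


class TestFilterSpurious:
    def test_short_terminator_match_removed(self, query):
        blacklist = Interval(100, 130)  # 3' end of the antitoxin, say
        junk = cluster_hits([make_hit(103, 128, 9000, 9025, bits=60.0)])
        kept = filter_spurious(junk, query, min_span=60,
                               terminator_blacklist=blacklist)
        assert kept == []

    def test_full_profile_retained(self, query):
        full = cluster_hits([make_hit(0, 320, 5000, 5320)])
        kept = filter_spurious(full, query, terminator_blacklist=Interval(100, 130))
        assert len(kept) == 1

    def test_palindromic_opposite_strand_match_removed(self, query):
        counted = make_hit(0, 320, 5000, 5320, strand="+", bits=600.0)
        echo = make_hit(175, 195, 5060, 5080, strand="-", bits=40.0)
        profiles = cluster_hits([counted, echo])
        kept = filter_spurious(profiles, query)
        assert len(kept) == 1
        assert kept[0].strand == "+"

    def test_long_match_in_blacklist_kept(self, query):
        profiles = cluster_hits([make_hit(100, 180, 9000, 9080, bits=150.0)])
        kept = filter_spurious(profiles, query, min_span=60,
                               terminator_blacklist=Interval(90, 190))
        assert len(kept) == 1


class TestClassifyLocus:
    def _profile(self, hits):
        return cluster_hits(hits)[0]

    def test_noise_free_full(self, query):
        call = classify_locus(self._profile([make_hit(0, 320, 5000, 5320)]), query)
        assert call.category == "full" and call.copy_units == 1.0

    def test_antitoxin_with_28nt_stub(self, query):
        a = query.antitoxin_segment
        call = classify_locus(
            self._profile([make_hit(a.start, a.end + 28, 5000,
                                    5000 + len(a) + 28, bits=220.0)]), query)
        assert call.category == "antitoxin_only" and call.copy_units == 0.5

    def test_interrupted_split(self, query):
        hits = [make_hit(0, 165, 5000, 5165, bits=300.0),
                make_hit(165, 320, 6365, 6520, bits=290.0)]
        call = classify_locus(self._profile(hits), query)
        assert call.category == "interrupted" and call.copy_units == 1.0

    def test_toxin_only(self, query):
        t = query.toxin_segment
        call = classify_locus(
            self._profile([make_hit(t.start, t.end, 5000, 5000 + len(t),
                                    bits=300.0)]), query)
        assert call.category == "toxin_only" and call.copy_units == 0.5

    def test_low_coverage_is_partial(self, query):
        call = classify_locus(self._profile([make_hit(0, 100, 5000, 5100)]), query)
        assert call.category == "partial" and call.copy_units == 0.0

    def test_query_mismatch_rejected(self, query):
        p = self._profile([make_hit(0, 320, 0, 320, query="other")])
        with pytest.raises(ValueError):
            classify_locus(p, query)


class TestAssignLocusType:
    def _full_call(self):
        return LocusCall("a", "chr", "full", 1.0)

    def test_full_above_650(self):
        call = assign_locus_type(self._full_call(), {"O": 700.0, "P": 400.0})
        assert call.locus_type == "O"

    def test_antitoxin_only_fallback_to_p(self):
        call = LocusCall("a", "chr", "antitoxin_only", 0.5)
        typed = assign_locus_type(call, {"O": 260.0, "P": 260.0})
        assert typed.locus_type == "P"

    def test_below_thresholds_unassigned(self):
        typed = assign_locus_type(self._full_call(), {"O": 500.0, "P": 400.0})
        assert typed.locus_type == "unassigned"

    def test_tie_broken_by_precedence(self):
        typed = assign_locus_type(self._full_call(), {"P": 700.0, "O": 700.0})
        assert typed.locus_type == "O"


class TestDetectPlasmid:
    @pytest.mark.parametrize("desc,expect", [
        ("Escherichia coli strain X plasmid p11A_p2, complete sequence", True),
        ("strain Y extrachromosomal element", True),
        ("chromosome, complete genome", False),
        ("PLASMID pFoo", True),
    ])
    def test_examples(self, desc, expect):
        assert detect_plasmid(desc) is expect


class TestSetCategorize:
    def test_toxin_only_rule(self):
        cats = set_categorize({"a"}, {"a"}, set())
        assert cats["a"] == "toxin_only"

    def test_paired(self):
        cats = set_categorize({"a"}, {"a"}, {"a"})
        assert cats["a"] == "paired"

    def test_antitoxin_without_full_is_anomaly(self):
        cats = set_categorize(set(), set(), {"a"})
        assert cats["a"] == "anomaly"

    def test_absent_from_universe(self):
        cats = set_categorize(set(), set(), set(), all_ids=["a", "b"])
        assert cats == {"a": "absent", "b": "absent"}


def _report(aid, name, copies):
    r = AssemblyReport(aid, name)
    r.calls["sys"] = [LocusCall(aid, "chr", "full", 1.0)] * int(copies) + \
        ([LocusCall(aid, "chr", "antitoxin_only", 0.5)]
         if copies % 1 else [])
    return r


class TestDedupe:
    def test_dh5alpha_fixture(self):
        reports = [_report("A3", "DH5alpha", 2.0), _report("A1", "DH5alpha", 0.5),
                   _report("A2", "DH5alpha", 0.5)]
        kept, removed = dedupe_assemblies(reports)
        assert len(kept) == 2 and len(removed) == 1
        assert sorted(r.copy_number("sys") for r in kept) == [0.5, 2.0]
        assert removed[0].assembly_id == "A2"  # A1 kept as first of the 0.5 pair

    def test_five_identical_keep_one(self):
        reports = [_report(f"A{i}", "K12", 1.0) for i in range(5)]
        kept, removed = dedupe_assemblies(reports)
        assert len(kept) == 1 and len(removed) == 4

    def test_unique_names_untouched(self):
        reports = [_report(f"A{i}", f"s{i}", 1.0) for i in range(4)]
        kept, removed = dedupe_assemblies(reports)
        assert len(kept) == 4 and removed == []

    def test_idempotent(self):
        reports = [_report(f"A{i}", "K12", 1.0) for i in range(5)] + \
            [_report("B0", "DH5alpha", 0.5)]
        once, _ = dedupe_assemblies(reports)
        twice, removed = dedupe_assemblies(once)
        assert [r.assembly_id for r in twice] == [r.assembly_id for r in once]
        assert removed == []

    def test_unnamed_never_deduped(self):
        reports = [_report("A1", "", 1.0), _report("A2", "", 1.0)]
        kept, removed = dedupe_assemblies(reports)
        assert len(kept) == 2


class TestRoundTrip:
    def test_noise_free_recovery(self, noise_free_pangenome, template, scheme):
        pg = noise_free_pangenome
        truth_cn = truth_copy_numbers(pg.truth, pg.metadata, template.name)
        q = template.as_query()
        for i, path in enumerate(pg.genome_paths):
            aid = path.stem
            counted, _ = analyze_assembly(read_fasta(path), q, scheme,
                                          assembly_id=aid)
            assert sum(c.copy_units for c in counted) == truth_cn[aid]
            truth_cats = sorted(
                pg.truth[pg.truth.assembly_id == aid].category)
            assert sorted(c.category for c in counted) == truth_cats

    def test_interrupted_round_trip(self, template, scheme):
        from talocus.synthio import generate_background

        bg = generate_background(10_000, 0.5, 40)
        new, rec = plant_locus(bg, template, PlantSpec("interrupted", 1.0),
                               3000, seed=41)
        counted, _ = analyze_assembly(
            [SequenceRecord("chr", "chromosome", new)], template.as_query(),
            scheme, assembly_id="x")
        assert [c.category for c in counted] == ["interrupted"]

    def test_plasmid_flag_round_trip(self, template, scheme):
        from talocus.synthio import generate_background

        plasmid = generate_background(8000, 0.5, 42)
        new, rec = plant_locus(plasmid, template, PlantSpec("full", 1.0),
                               3000, seed=43)
        counted, _ = analyze_assembly(
            [SequenceRecord("p1", "p1 plasmid pX, complete sequence", new)],
            template.as_query(), scheme, assembly_id="x")
        assert [c.category for c in counted] == ["full"]
        assert counted[0].on_plasmid
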