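import numpy as np
import pytest

from talocus._seq import Interval, revcomp
from talocus.synthio import (LayoutError, MetadataModel, PlantSpec,
                             default_mix, default_templates,
                             generate_background, generate_pangenome,
                             make_template, mutate_sequence, plant_locus,
                             truth_copy_numbers)


class TestGenerateBackground:
    def test_deterministic(self):
        assert generate_background(1000, 0.5, 7) == generate_background(1000, 0.5, 7)

    def test_length_and_alphabet(self):
        s = generate_background(1000, 0.5, 7)
        assert len(s) == 1000 and set(s) <= set("ACGT")

    def test_gc_limit_case(self):
        s = generate_background(10, 1.0 - 1e-12, 3)
        assert set(s) <= set("GC")

    def test_gc_within_binomial_expectation(self):
        # binomial oracle: observed GC count within 3 SD of n*gc
        n, gc = 100_000, 0.5
        s = generate_background(n, gc, 1)
        observed = sum(c in "GC" for c in s)
        sd = (n * gc * (1 - gc)) ** 0.5
        assert abs(observed - n * gc) < 3 * sd

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-5, 0.5), (10, 0.0),
                                           (10, 1.0), (10, 1.5)])
    def test_invalid_inputs(self, length, gc):
        with pytest.raises(ValueError):
            generate_background(length, gc, 1)


class TestPlantSpec:
    def test_absent_requires_zero_copies(self):
        with pytest.raises(ValueError):
            PlantSpec("absent", 1.0)

    def test_copies_must_be_half_multiples(self):
        with pytest.raises(ValueError):
            PlantSpec("full", 0.7)

    def test_orphan_counts_half_per_instance(self):
        assert PlantSpec("antitoxin_only", 1.0).instances() == \
            ["antitoxin_only", "antitoxin_only"]

    def test_one_and_a_half_copies(self):
        assert PlantSpec("full", 1.5).instances() == ["full", "antitoxin_only"]

    def test_mutation_rate_bounds(self):
        with pytest.raises(ValueError):
            PlantSpec("full", 1.0, mutation_rate=0.5)


class TestTemplate:
    def test_elements_match_sequence(self, template):
        for el in template.elements:
            assert template.sequence[el.interval.start:el.interval.end] == el.reference

    def test_segments_disjoint(self, template):
        assert not template.toxin_segment.overlaps(template.antitoxin_segment)

    def test_antitoxin_pairs_with_utr_target(self, template):
        pt = template.element("pairing_target")
        anti = template.sequence[template.antitoxin_segment.start:
                                 template.antitoxin_segment.end]
        assert revcomp(pt.reference) in anti

    def test_orf_translates_cleanly(self, template):
        from talocus.conserve import translate_orf

        orf = template.element("orf")
        tr = translate_orf(orf.reference)
        assert not tr.truncated and len(tr.protein) == 29


class TestPlantLocus:
    def test_full_noise_free_identity(self, template):
        bg = generate_background(5000, 0.5, 2)
        spec = PlantSpec("full", 1.0)
        new, rec = plant_locus(bg, template, spec, 1000, seed=5)
        planted = new[rec.start:rec.end]
        if rec.strand == "-":
            planted = revcomp(planted)
        assert planted == template.sequence
        assert rec.category == "full" and rec.copy_units == 1.0

    def test_antitoxin_only_length(self, template):
        bg = generate_background(5000, 0.5, 2)
        new, rec = plant_locus(bg, template, PlantSpec("antitoxin_only", 0.5),
                               1000, seed=5, utr_stub=28)
        assert rec.end - rec.start == len(template.antitoxin_segment) + 28
        assert rec.copy_units == 0.5

    def test_interrupted_adds_spacer(self, template):
        bg = generate_background(8000, 0.5, 2)
        new, rec = plant_locus(bg, template, PlantSpec("interrupted", 1.0),
                               1000, seed=5, spacer_len=1200)
        assert rec.end - rec.start == len(template.sequence) + 1200

    def test_toxin_only_length(self, template):
        bg = generate_background(5000, 0.5, 2)
        new, rec = plant_locus(bg, template, PlantSpec("toxin_only", 0.5),
                               1000, seed=5)
        assert rec.end - rec.start == len(template.toxin_segment)

    def test_out_of_bounds_raises(self, template):
        bg = generate_background(200, 0.5, 2)
        with pytest.raises(LayoutError):
            plant_locus(bg, template, PlantSpec("full", 1.0), 100, seed=5)

    def test_mutations_protect_elements(self, template):
        bg = generate_background(5000, 0.5, 2)
        spec = PlantSpec("full", 1.0, mutation_rate=0.2)
        new, rec = plant_locus(bg, template, spec, 1000, seed=5)
        planted = new[rec.start:rec.end]
        if rec.strand == "-":
            planted = revcomp(planted)
        for el in template.elements:
            assert planted[el.interval.start:el.interval.end] == el.reference
        assert planted != template.sequence  # mutations landed elsewhere

    def test_variant_edit_applied(self, template):
        orf = template.element("orf")
        pos = orf.interval.start + 4  # second codon, middle base
        new_base = "G" if template.sequence[pos] != "G" else "C"
        spec = PlantSpec("full", 1.0, variant_edits=((pos, new_base),))
        bg = generate_background(5000, 0.5, 2)
        new, rec = plant_locus(bg, template, spec, 1000, seed=5)
        planted = new[rec.start:rec.end]
        if rec.strand == "-":
            planted = revcomp(planted)
        assert planted[pos] == new_base


class TestMutateSequence:
    def test_rate_zero_is_identity(self):
        s = generate_background(500, 0.5, 1)
        assert mutate_sequence(s, 0.0, np.random.default_rng(1)) == s

    def test_calibrated_rate(self):
        s = generate_background(20_000, 0.5, 1)
        out = mutate_sequence(s, 0.1, np.random.default_rng(2))
        n_diff = sum(a != b for a, b in zip(s, out))
        sd = (20_000 * 0.1 * 0.9) ** 0.5
        assert abs(n_diff - 2000) < 4 * sd

    def test_protected_interval_untouched(self):
        s = generate_background(1000, 0.5, 1)
        out = mutate_sequence(s, 0.2, np.random.default_rng(3),
                              protected=[Interval(100, 200)])
        assert out[100:200] == s[100:200]


class TestPangenome:
    def test_single_full_plant(self, template, tmp_path):
        pg = generate_pangenome(1, {PlantSpec("full", 1.0): 1.0}, None,
                                [template], seed=4, out_dir=tmp_path)
        assert len(pg.truth) == 1
        assert pg.truth.iloc[0].category == "full"

    def test_byte_identical_for_same_seed(self, template, tmp_path):
        a = generate_pangenome(4, default_mix(), None, [template], seed=9,
                               out_dir=tmp_path / "a")
        b = generate_pangenome(4, default_mix(), None, [template], seed=9,
                               out_dir=tmp_path / "b")
        for pa, pb in zip(a.genome_paths, b.genome_paths):
            assert pa.read_bytes() == pb.read_bytes()
        assert a.truth_path.read_bytes() == b.truth_path.read_bytes()
        assert a.metadata_path.read_bytes() == b.metadata_path.read_bytes()

    def test_invalid_mix_rejected(self, template, tmp_path):
        with pytest.raises(ValueError):
            generate_pangenome(2, {PlantSpec("full", 1.0): 0.5}, None,
                               [template], seed=1, out_dir=tmp_path)

    def test_empty_templates_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_pangenome(2, {PlantSpec("full", 1.0): 1.0}, None, [],
                               seed=1, out_dir=tmp_path)

    def test_plasmid_records_carry_keyword(self, template, tmp_path):
        pg = generate_pangenome(
            3, {PlantSpec("full", 1.0, on_plasmid=True): 1.0}, None,
            [template], seed=6, out_dir=tmp_path)
        for path in pg.genome_paths:
            text = path.read_text()
            assert "plasmid" in text
        assert (pg.truth.replicon_type == "plasmid").all()

    def test_metadata_vocabulary(self, template, tmp_path):
        pg = generate_pangenome(40, default_mix(), MetadataModel(), [template],
                                seed=13, out_dir=tmp_path)
        vocab = {t[0] for t in MetadataModel().pathotypes}
        assert set(pg.metadata.pathotype) <= vocab
        assert "intestinal disease" in vocab and "healthy" in vocab

    def test_duplicates_share_copy_number(self, template, tmp_path):
        pg = generate_pangenome(30, default_mix(), None, [template], seed=21,
                                out_dir=tmp_path, duplicate_rate=0.5)
        cn = truth_copy_numbers(pg.truth, pg.metadata, template.name)
        by_name = pg.metadata.set_index("assembly_id").strain_name
        for name, grp in cn.groupby(by_name):
            assert grp.nunique() == 1
        assert by_name.duplicated().any()

    def test_dh5a_mode_conflicting_copies(self, template, tmp_path):
        pg = generate_pangenome(5, default_mix(), None, [template], seed=2,
                                out_dir=tmp_path, dh5a_mode=True)
        meta = pg.metadata.set_index("assembly_id")
        dh5a = meta[meta.strain_name == "DH5alpha"].index
        cn = truth_copy_numbers(pg.truth, pg.metadata, template.name)
        assert sorted(cn[a] for a in dh5a) == [0.5, 0.5, 2.0]

    def test_copy_effect_shifts_group_mean(self, template, tmp_path):
        model = MetadataModel(copy_effect=("intestinal disease", 1.0))
        pg = generate_pangenome(60, default_mix(), model, [template], seed=17,
                                out_dir=tmp_path)
        cn = truth_copy_numbers(pg.truth, pg.metadata, template.name)
        patho = pg.metadata.set_index("assembly_id").pathotype
        target = cn[patho == "intestinal disease"].mean()
        others = cn[patho != "intestinal disease"].mean()
        assert target > others + 0.5

    def test_truth_accounting_matches_instances(self, template, tmp_path):
        mix = {PlantSpec("full", 2.0): 0.5, PlantSpec("antitoxin_only", 0.5): 0.5}
        pg = generate_pangenome(10, mix, None, [template], seed=3,
                                out_dir=tmp_path)
        cn = truth_copy_numbers(pg.truth, pg.metadata, template.name)
        assert set(cn) - {0.5, 2.0} == set()
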