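import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import fisher_exact

import mosaicenrich as me
from mosaicenrich import HeteroplasmyCall, MitoAnnotation, MitoClass, MitoRecord
from mosaicenrich.errors import (
    DataIntegrityError,
    DegenerateInputError,
    InvalidInputError,
)
from mosaicenrich.mito_heteroplasmy import MitoClassifier, counts_by_class


def hcall(vaf, mother=None, father=None, **kw):
    base = dict(sample_id="s", pos_1based=100, ref="A", alt="G", depth=700)
    base.update(kw)
    return HeteroplasmyCall(vaf=vaf, mother_vaf=mother, father_vaf=father, **base)


def oracle_classify(annotation, reference, pos, alt):
    """Independent site classifier: interval logic plus whole-CDS translation
    (vertebrate mitochondrial table) with adenine completion of partial
    terminal codons."""
    overlapping = [r for r in annotation.records
                   if r.start_1based <= pos <= r.end_1based]
    if not overlapping:
        return MitoClass.INTERGENIC
    if any(r.type == "tRNA" for r in overlapping):
        return MitoClass.TRNA
    if any(r.type == "rRNA" for r in overlapping):
        return MitoClass.RRNA
    by_gene = {}
    for r in annotation.records:
        if r.type == "protein":
            by_gene.setdefault(r.gene_id, []).append(r)
    for r in overlapping:
        recs = by_gene[r.gene_id]
        positions = [p for rec in recs for p in range(rec.start_1based, rec.end_1based + 1)]
        seq = "".join(reference[p - 1] for p in positions)
        i = positions.index(pos)
        mut = seq[:i] + alt + seq[i + 1 :]
        if recs[0].strand == "-":
            seq = str(Seq(seq).reverse_complement())
            mut = str(Seq(mut).reverse_complement())
        pad = "A" * ((-len(seq)) % 3)
        aa_ref = str(Seq(seq + pad).translate(table=2))
        aa_mut = str(Seq(mut + pad).translate(table=2))
        if aa_ref != aa_mut:
            return MitoClass.NON_SYNONYMOUS
    return MitoClass.SYNONYMOUS


class TestClassification:
    def test_known_trna_positions(self, mito_rcrs):
        fx = mito_rcrs
        for pos, gene in ((3243, "MT-TL1"), (625, "MT-TF"), (12257, "MT-TS2"),
                          (5703, "MT-TN")):
            ref = fx.reference[pos - 1]
            alt = "A" if ref != "A" else "G"
            assert me.classify_mito_snv(fx.annotation, fx.reference, pos, ref, alt) \
                is MitoClass.TRNA
            rec = next(r for r in fx.annotation.records if r.gene_id == gene)
            assert rec.start_1based <= pos <= rec.end_1based

    def test_rrna_position(self, mito_rcrs):
        fx = mito_rcrs
        pos = 1000  # inside MT-RNR1
        ref = fx.reference[pos - 1]
        alt = "C" if ref != "C" else "T"
        assert me.classify_mito_snv(fx.annotation, fx.reference, pos, ref, alt) \
            is MitoClass.RRNA

    def test_stop_gain_in_protein_is_non_synonymous(self, mito_rcrs):
        fx = mito_rcrs
        clf = MitoClassifier(fx.annotation, fx.reference)
        co3 = next(r for r in fx.annotation.records if r.gene_id == "MT-CO3")
        found = None
        for pos in range(co3.start_1based + 3, co3.end_1based - 3):
            ref = fx.reference[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                off = pos - co3.start_1based
                ci = off // 3
                codon = fx.reference[co3.start_1based - 1 + 3 * ci:
                                     co3.start_1based - 1 + 3 * ci + 3]
                mut = codon[: off % 3] + alt + codon[off % 3 + 1 :]
                if str(Seq(mut).translate(table=2)) == "*":
                    found = (pos, ref, alt)
                    break
            if found:
                break
        assert found, "no stop-creating substitution in the fixture CO3 gene"
        pos, ref, alt = found
        assert clf.classify(pos, ref, alt) is MitoClass.NON_SYNONYMOUS

    def test_vertebrate_code_specifics(self):
        # protein: ATG TGG CGA ATT TAA — TGG>TGA is Trp>Trp (synonymous under
        # the mitochondrial code), CGA>AGA is a stop gain (Arg > stop)
        genome = "TTTT" + "ATGTGGCGAATTTAA" + "TTTT"
        ann = MitoAnnotation(genome_length=len(genome),
                             records=[MitoRecord("P", 5, 19, "+", "protein")])
        clf = MitoClassifier(ann, genome)
        # TGG -> TGA at the third base of codon 2 (1-based position 10)
        assert genome[9] == "G"
        assert clf.classify(10, "G", "A") is MitoClass.SYNONYMOUS
        # CGA -> AGA at the first base of codon 3 (position 11)
        assert genome[10] == "C"
        assert clf.classify(11, "C", "A") is MitoClass.NON_SYNONYMOUS
        # ATT -> ATA is Ile > Met under table 2 (position 16)
        assert clf.classify(16, "T", "A") is MitoClass.NON_SYNONYMOUS

    def test_intergenic_and_reference_mismatch(self, mito_toy):
        fx = mito_toy
        ref = fx.reference[0]
        alt = "A" if ref != "A" else "C"
        assert me.classify_mito_snv(fx.annotation, fx.reference, 1, ref, alt) \
            is MitoClass.INTERGENIC
        with pytest.raises(DataIntegrityError):
            wrong = "A" if fx.reference[150] != "A" else "C"
            me.classify_mito_snv(fx.annotation, fx.reference, 151, wrong,
                                 "G" if wrong != "G" else "T")

    @pytest.mark.parametrize("style", ["toy", "rcrs_like"])
    def test_agrees_with_translation_oracle_everywhere(self, style, request):
        fx = request.getfixturevalue("mito_toy" if style == "toy" else "mito_rcrs")
        clf = MitoClassifier(fx.annotation, fx.reference)
        rng = np.random.default_rng(4)
        genic = fx.annotation.genic_positions()
        sample = genic if style == "toy" else rng.choice(genic, size=400, replace=False)
        for pos in sample:
            pos = int(pos)
            ref = fx.reference[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                assert clf.classify(pos, ref, alt) is \
                    oracle_classify(fx.annotation, fx.reference, pos, alt), (pos, ref, alt)

    def test_origin_crossing_gene_matches_rotated_genome(self):
        """A protein gene split across the origin classifies exactly like the
        same gene on a genome rotated so it is contiguous."""
        rng = np.random.default_rng(6)
        from mosaicenrich.synthetic_data import _mito_orf, _random_seq

        orf = _mito_orf(rng, 150, 0.45)
        filler = _random_seq(rng, 250, 0.45)
        L = 400
        # split layout: last 50 bases of the genome, then the first 100
        genome_split = orf[50:150] + filler[:250] + orf[:50]
        ann_split = MitoAnnotation(
            genome_length=L,
            records=[MitoRecord("P", 351, 400, "+", "protein"),
                     MitoRecord("P", 1, 100, "+", "protein")],
        )
        genome_rot = orf + filler
        ann_rot = MitoAnnotation(genome_length=L,
                                 records=[MitoRecord("P", 1, 150, "+", "protein")])
        clf_split = MitoClassifier(ann_split, genome_split)
        clf_rot = MitoClassifier(ann_rot, genome_rot)
        # map: offsets 0..49 -> positions 351..400; offsets 50..149 -> 1..100
        for off in range(150):
            p_split = 351 + off if off < 50 else off - 50 + 1
            p_rot = off + 1
            ref = genome_rot[off]
            assert genome_split[p_split - 1] == ref
            for alt in "ACGT":
                if alt == ref:
                    continue
                assert clf_split.classify(p_split, ref, alt) is \
                    clf_rot.classify(p_rot, ref, alt), (off, ref, alt)


class TestEnumerateGenicSnvs:
    def test_toy_conservation_and_length_shares(self, mito_toy):
        fx = mito_toy
        ex = me.enumerate_genic_snvs(fx.annotation, fx.reference)
        assert ex.total == 1110  # 3 x (70 tRNA + 300 protein)
        assert ex.class_totals[MitoClass.TRNA] == 210
        assert ex.class_totals[MitoClass.TRNA] / ex.total == 210 / 1110
        assert ex.class_totals[MitoClass.SYNONYMOUS] \
            + ex.class_totals[MitoClass.NON_SYNONYMOUS] == 900

    def test_rcrs_like_totals_conserved(self, mito_rcrs):
        fx = mito_rcrs
        ex = me.enumerate_genic_snvs(fx.annotation, fx.reference)
        n_genic = len(fx.annotation.genic_positions())
        assert ex.total == 3 * n_genic
        trna_len = sum(r.length for r in fx.annotation.records if r.type == "tRNA")
        rrna_len = sum(r.length for r in fx.annotation.records if r.type == "rRNA")
        assert ex.class_totals[MitoClass.TRNA] == 3 * trna_len
        assert ex.class_totals[MitoClass.RRNA] == 3 * rrna_len

    def test_exclusion_regions_respected(self, mito_toy):
        fx = mito_toy
        # exclude the whole tRNA (BED 0-based half-open over positions 101-170)
        ex = me.enumerate_genic_snvs(fx.annotation, fx.reference, [("MT", 100, 170)])
        assert ex.class_totals[MitoClass.TRNA] == 0
        assert ex.total == 900


class TestPartitionHetHom:
    def test_thresholds(self):
        calls = [hcall(0.005), hcall(0.12), hcall(0.99)]
        part = me.partition_het_hom(calls, 0.01, 0.95)
        assert [c.status for c in part.heteroplasmic] == ["heteroplasmic"]
        assert part.heteroplasmic[0].vaf == 0.12
        assert part.homoplasmic[0].vaf == 0.99
        assert part.discarded[0][1] == "below_het_min_vaf"

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        calls = [hcall(float(v)) for v in rng.uniform(0, 1, size=100)]
        part = me.partition_het_hom(calls)
        assert len(part.heteroplasmic) + len(part.homoplasmic) + len(part.discarded) == 100

    def test_bad_thresholds(self):
        with pytest.raises(InvalidInputError):
            me.partition_het_hom([], 0.5, 0.5)


class TestClassProportionCompare:
    def test_identical_composition_is_null(self):
        counts = {MitoClass.TRNA: 5, MitoClass.SYNONYMOUS: 15}
        e = me.class_proportion_compare(counts, counts, MitoClass.TRNA)
        assert e.fold == 1.0
        assert e.p == 1.0

    def test_against_scipy(self):
        a = {MitoClass.TRNA: 7, MitoClass.SYNONYMOUS: 10, MitoClass.NON_SYNONYMOUS: 16}
        b = {MitoClass.TRNA: 75, MitoClass.SYNONYMOUS: 400, MitoClass.NON_SYNONYMOUS: 525}
        e = me.class_proportion_compare(a, b, MitoClass.TRNA)
        assert e.target_a == 7 and e.total_a == 33
        assert e.target_b == 75 and e.total_b == 1000
        expected = fisher_exact([[7, 26], [75, 925]])[1]
        assert e.p == pytest.approx(expected, rel=1e-9)
        assert e.fold == pytest.approx((7 / 33) / (75 / 1000))

    def test_empty_set_rejected(self):
        with pytest.raises(DegenerateInputError):
            me.class_proportion_compare({}, {MitoClass.TRNA: 1}, MitoClass.TRNA)

    def test_table_covers_all_four_classes(self, mito_rcrs):
        fx = mito_rcrs
        ex = me.enumerate_genic_snvs(fx.annotation, fx.reference)
        observed = {MitoClass.TRNA: 7, MitoClass.RRNA: 4,
                    MitoClass.SYNONYMOUS: 8, MitoClass.NON_SYNONYMOUS: 14}
        df = me.class_proportion_table(observed, ex.class_totals)
        assert set(df["class"]) == {"tRNA", "rRNA", "synonymous", "non_synonymous"}
        assert (df["count_a"].sum(), df["total_a"].iloc[0]) == (33, 33)


class TestCarrierFrequencyCompare:
    def test_population_screen_values(self):
        r1 = me.carrier_frequency_compare(2, 231, 10, 7720)
        assert float(f"{r1.freq1:.3g}") == 0.00866
        assert float(f"{r1.fet_p:.3g}") == 0.0464
        r2 = me.carrier_frequency_compare(2, 231, 57, 56383)
        assert float(f"{r2.fet_p:.3g}") == 0.0247

    def test_textbook_convention(self):
        r = me.carrier_frequency_compare(2, 231, 10, 7720,
                                         convention="carriers_vs_noncarriers")
        expected = fisher_exact([[2, 229], [10, 7710]])[1]
        assert r.fet_p == pytest.approx(expected, rel=1e-9)

    def test_equal_frequencies_give_p_one(self):
        r = me.carrier_frequency_compare(1, 100, 10, 1000)
        assert r.fet_p == 1.0

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            me.carrier_frequency_compare(0, 0, 1, 10)


class TestNumtFlag:
    def test_transmitted_constant_fraction_is_suspect(self):
        flag = me.flag_numt_suspect(hcall(0.05, mother=0.05, father=0.05))
        assert flag.status == "suspect"

    def test_absent_from_parents_not_suspect(self):
        flag = me.flag_numt_suspect(hcall(0.05, mother=0.0, father=0.0))
        assert flag.status == "not_suspect"
        assert flag.maternally_inherited is False

    def test_low_level_maternal_carrier(self):
        flag = me.flag_numt_suspect(hcall(0.06, mother=0.02, father=0.0))
        assert flag.status == "not_suspect"
        assert flag.maternally_inherited is True

    def test_missing_parents_not_evaluable(self):
        flag = me.flag_numt_suspect(hcall(0.05))
        assert flag.status == "not_evaluable"
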