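import numpy as np
import pytest
from Bio.Seq import Seq

import mosaicenrich as me
from mosaicenrich.errors import (
    BoundaryError,
    DataIntegrityError,
    InvalidInputError,
)
from mosaicenrich.mutation_model import (
    BASES,
    ConsequenceClass,
    GeneModel,
    N_CATEGORIES,
    TrinucleotideSubstitution,
    consequence_from_code,
)


class TestTrinucleotideCategory:
    def test_purine_centre_is_reverse_complement_normalised(self):
        # central A>G in context TAC maps to central T>C in context GTA
        cat = me.trinucleotide_category({"c": "TTACG"}, "c", 3, "A", "G")
        assert cat == TrinucleotideSubstitution("GTA", "C")
        assert cat.context[1] in "CT"

    def test_examples(self):
        assert me.trinucleotide_category({"c": "TACAT"}, "c", 3, "C", "T") == \
            TrinucleotideSubstitution("ACA", "T")
        # A[A>G]C normalises to G[T>C]T
        assert me.trinucleotide_category({"c": "TAACT"}, "c", 3, "A", "G") == \
            TrinucleotideSubstitution("GTT", "C")
        # TCG centre already pyrimidine: unchanged
        assert me.trinucleotide_category({"c": "ATCGA"}, "c", 3, "C", "T") == \
            TrinucleotideSubstitution("TCG", "T")

    def test_normalisation_idempotent_under_reverse_complement(self):
        rng = np.random.default_rng(3)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=40))
        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        for pos in range(2, n):  # 1-based, interior
            ref = seq[pos - 1]
            for alt in BASES:
                if alt == ref:
                    continue
                fwd = me.trinucleotide_category({"c": seq}, "c", pos, ref, alt)
                mirrored = n - pos + 1
                rc_ref = str(Seq(ref).complement())
                rc_alt = str(Seq(alt).complement())
                rev = me.trinucleotide_category({"c": rc}, "c", mirrored, rc_ref, rc_alt)
                assert fwd == rev

    def test_category_census_matches_hand_enumeration(self):
        # every interior position of a 12-mer, all three alternates
        seq = "ACGTTGCAACGT"
        counts = np.zeros(N_CATEGORIES)
        for pos in range(2, len(seq)):
            ref = seq[pos - 1]
            for alt in BASES:
                if alt == ref:
                    continue
                counts[me.trinucleotide_category({"c": seq}, "c", pos, ref, alt).index] += 1
        assert counts.sum() == 3 * (len(seq) - 2)
        # independent mini-oracle: string-level normalisation
        oracle = np.zeros(N_CATEGORIES)
        for i in range(1, len(seq) - 1):
            ctx, ref = seq[i - 1 : i + 2], seq[i]
            for alt in BASES:
                if alt == ref:
                    continue
                c, a = ctx, alt
                if c[1] in "AG":
                    c = str(Seq(c).reverse_complement())
                    a = str(Seq(a).complement())
                oracle[TrinucleotideSubstitution(c, a).index] += 1
        assert np.array_equal(counts, oracle)

    def test_errors(self):
        with pytest.raises(DataIntegrityError):
            me.trinucleotide_category({"c": "AACAA"}, "c", 3, "G", "T")
        with pytest.raises(BoundaryError):
            me.trinucleotide_category({"c": "CACAA"}, "c", 1, "C", "T")
        with pytest.raises(InvalidInputError):
            me.trinucleotide_category({"c": "AACAA"}, "c", 3, "C", "C")

    def test_index_round_trip(self):
        for i in range(N_CATEGORIES):
            assert TrinucleotideSubstitution.from_index(i).index == i


class TestBuildSpectrum:
    def test_empty_is_zero_vector(self):
        ref = {"c": "ACGTACGT"}
        spec = me.build_spectrum([], ref)
        assert spec.total == 0

    def test_single_variant_one_hot(self):
        ref = {"c": "AACAA"}
        spec = me.build_spectrum([("c", 3, "C", "T")], ref)
        assert spec.total == 1
        assert spec.counts.max() == 1

    def test_conserves_accepted_snv_count(self, toy_universe):
        reference, _ = toy_universe
        rng = np.random.default_rng(5)
        seq = reference["chr1"]
        variants = []
        for _ in range(40):
            pos = int(rng.integers(2, len(seq)))
            ref = seq[pos - 1]
            alt = BASES[(BASES.index(ref) + 1) % 4]
            variants.append(("chr1", pos, ref, alt))
        spec96 = me.build_spectrum(variants, reference, "trinuc96")
        spec6 = me.build_spectrum(variants, reference, "subst6")
        assert spec96.total == 40
        assert spec6.total == 40
        # the 6-type spectrum is the 96-type spectrum folded over contexts
        folded = spec96.counts.reshape(6, 16).sum(axis=1)
        assert np.array_equal(folded, spec6.counts)

    def test_non_snv_skipped_with_tally(self):
        ref = {"c": "AACAA"}
        spec = me.build_spectrum([("c", 3, "C", "T"), ("c", 3, "CA", "C")], ref)
        assert spec.total == 1
        assert spec.n_skipped == 1


def brute_force_consequence(reference, model, chrom, pos_1based, alt):
    """Independent oracle: rebuild the whole CDS with the substituted base and
    compare the Biopython translations."""
    if model.chrom != chrom:
        return None
    p0 = pos_1based - 1
    if len(model.cds_intervals) > 1 and p0 in set(model.splice_positions().tolist()):
        return ConsequenceClass.CANONICAL_SPLICE
    if not any(s <= p0 < e for s, e in model.cds_intervals):
        return None
    seq = reference[model.chrom]
    cds_parts, mut_parts = [], []
    for s, e in model.cds_intervals:
        part = seq[s:e]
        if s <= p0 < e:
            i = p0 - s
            part_mut = part[:i] + alt + part[i + 1 :]
        else:
            part_mut = part
        cds_parts.append(part)
        mut_parts.append(part_mut)
    cds, mut = "".join(cds_parts), "".join(mut_parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
        mut = str(Seq(mut).reverse_complement())
    n3 = len(cds) - len(cds) % 3
    aa_ref = str(Seq(cds[:n3]).translate(table=1))
    aa_alt = str(Seq(mut[:n3]).translate(table=1))
    if aa_ref == aa_alt:
        # the change may sit in the untranslated tail codon
        changed = cds != mut
        return ConsequenceClass.SYNONYMOUS if changed else None
    diff = [(r, a) for r, a in zip(aa_ref, aa_alt) if r != a]
    r, a = diff[0]
    if a == "*":
        return ConsequenceClass.NONSENSE
    return ConsequenceClass.MISSENSE


class TestAnnotateConsequence:
    @pytest.fixture()
    def tiny_gene(self):
        # chr: TT | ATG AAA TGG TAA | TT  (CDS = [2, 14))
        reference = {"c": "TTATGAAATGGTAATT"}
        model = GeneModel("g", "c", "+", ((2, 14),))
        return reference, model

    def test_synonymous_third_position(self, tiny_gene):
        reference, model = tiny_gene
        # AAA -> AAG (Lys -> Lys) at 1-based position 8
        assert me.annotate_consequence(reference, [model], "c", 8, "A", "G") \
            is ConsequenceClass.SYNONYMOUS

    def test_stop_gain(self, tiny_gene):
        reference, model = tiny_gene
        # TGG -> TGA at 1-based position 11
        assert me.annotate_consequence(reference, [model], "c", 11, "G", "A") \
            is ConsequenceClass.NONSENSE

    def test_noncoding_outside_cds(self, tiny_gene):
        reference, model = tiny_gene
        assert me.annotate_consequence(reference, [model], "c", 1, "T", "A") \
            is ConsequenceClass.NONCODING

    def test_splice_dinucleotides_of_multi_interval_model(self):
        # two CDS intervals separated by an 8-bp intron
        rng = np.random.default_rng(9)
        intron = "GTAAGCAG"
        seq = "TT" + "ATGAAA" + intron + "TGGTAA" + "TT"
        model = GeneModel("g", "c", "+", ((2, 8), (16, 22)))
        reference = {"c": seq}
        for p0 in (8, 9, 14, 15):  # 0-based splice dinucleotides
            ref = seq[p0]
            alt = "A" if ref != "A" else "C"
            assert me.annotate_consequence(reference, [model], "c", p0 + 1, ref, alt) \
                is ConsequenceClass.CANONICAL_SPLICE
        # the spliced codons still annotate normally: AAA -> AAG synonymous
        assert me.annotate_consequence(reference, [model], "c", 8, "A", "G") \
            is ConsequenceClass.SYNONYMOUS

    def test_agrees_with_translation_oracle_on_random_genes(self):
        reference, models = me.make_toy_reference(5, 12, 0.1, seed=21)
        seq = reference["chr1"]
        for model in models:
            for p0 in model.cds_positions():
                pos = int(p0) + 1
                ref = seq[p0]
                for alt in BASES:
                    if alt == ref:
                        continue
                    got = me.annotate_consequence(reference, [model], "chr1", pos, ref, alt)
                    expected = brute_force_consequence(reference, model, "chr1", pos, alt)
                    assert got is expected, (model.gene_id, pos, ref, alt)

    def test_overlapping_models_resolve_by_severity(self):
        # same CDS twice, shifted frame: take the more severe call
        seq = "TTATGAAATGGTAATT"
        m1 = GeneModel("g1", "c", "+", ((2, 14),))
        m2 = GeneModel("g2", "c", "+", ((5, 14),))  # frame-shifted overlap
        reference = {"c": seq}
        got = me.annotate_consequence(reference, [m1, m2], "c", 11, "G", "A")
        c1 = me.annotate_consequence(reference, [m1], "c", 11, "G", "A")
        c2 = me.annotate_consequence(reference, [m2], "c", 11, "G", "A")
        severity = [ConsequenceClass.NONSENSE, ConsequenceClass.CANONICAL_SPLICE,
                    ConsequenceClass.MISSENSE, ConsequenceClass.SYNONYMOUS,
                    ConsequenceClass.NONCODING]
        assert got is min((c1, c2), key=severity.index)


class TestSiteIndex:
    def test_single_gene_inventory(self):
        # 9-bp CDS flanked by spacers: 27 (position, alternate) entries
        seq = "TTTT" + "ATGAAATAA" + "TTTT"
        model = GeneModel("g", "c", "+", ((4, 13),))
        idx = me.build_site_index({"c": seq}, [model])
        assert len(idx) == 27
        assert idx.n_edge_excluded == 0

    def test_two_identical_genes_double_the_counts(self):
        orf = "ATGAAATGGCCCTAA"
        seq1 = "TTTT" + orf + "TTTT"
        seq2 = "TTTT" + orf + "TTTT" + orf + "TTTT"
        m1 = [GeneModel("a", "c", "+", ((4, 19),))]
        m2 = [
            GeneModel("a", "c", "+", ((4, 19),)),
            GeneModel("b", "c", "+", ((23, 38),)),
        ]
        t1 = me.build_site_index({"c": seq1}, m1).totals()
        t2 = me.build_site_index({"c": seq2}, m2).totals()
        assert set(t1) == set(t2)
        assert all(t2[k] == 2 * t1[k] for k in t1)

    def test_partition_and_conservation(self, toy_universe, toy_index):
        reference, models = toy_universe
        n_positions = sum(m.cds_length for m in models)
        assert len(toy_index) + toy_index.n_edge_excluded == 3 * n_positions
        # no (pos, alt) under two keys
        key = toy_index.pos.astype(np.int64) * 4 + toy_index.alt
        assert len(np.unique(key)) == len(key)

    def test_index_classes_match_scalar_annotation(self, toy_universe, toy_index):
        reference, models = toy_universe
        seq = reference["chr1"]
        rng = np.random.default_rng(2)
        for i in rng.integers(0, len(toy_index), size=60):
            pos = int(toy_index.pos[i]) + 1
            alt = BASES[int(toy_index.alt[i])]
            got = consequence_from_code(int(toy_index.cls[i]))
            expected = me.annotate_consequence(reference, models, "chr1", pos, seq[pos - 1], alt)
            assert got is expected


def test_gene_model_validation():
    with pytest.raises(InvalidInputError):
        GeneModel("g", "c", "*", ((0, 3),))
    with pytest.raises(InvalidInputError):
        GeneModel("g", "c", "+", ((5, 3),))
    with pytest.raises(InvalidInputError):
        GeneModel("g", "c", "+", ((0, 6), (3, 9)))


def test_rate_table_flat_with_cpg():
    table = me.MutationRateTable.flat_with_cpg(10.0)
    boosted = [
        i for i in range(N_CATEGORIES)
        if table.rates[i] == 10.0
    ]
    # exactly the 4 NCG contexts with C>T
    cats = [TrinucleotideSubstitution.from_index(i) for i in boosted]
    assert len(cats) == 4
    assert all(c.context[1:] == "CG" and c.alt == "T" for c in cats)
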