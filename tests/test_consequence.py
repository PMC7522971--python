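"""Genomic->CDS projection, frameshift translation and impact tiers.

The prediction engine is cross-checked against an independent brute-force
translator (own codon table, own edit splicing, own stop scan) on hundreds
of random CDS x edit combinations.
"""

from __future__ import annotations

import random

import pytest

from minkmap.consequence import (
    ProjectionSignal,
    annotate_variant,
    classify_impact,
    first_affected_codon,
    predict_consequence,
    project_to_cds,
    utr3_sequence,
)
from minkmap.fixtures import rab38_surrogate_fixture
from minkmap.genebuild import cds_deletion_variant, cds_duplication_variant
from minkmap.hgvs import CodingVariant, parse_hgvs_c
from minkmap.models import ReferenceSequences, TranscriptModel, Variant

# --- independent oracle ----------------------------------------------------

_ORACLE_AA = {}
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    _ORACLE_AA[_a + _b + _c] = _AMINO[_i]


def oracle_apply(v: CodingVariant, cds: str) -> str:
    s, e = v.cds_start - 1, v.cds_end
    if v.kind in ("substitution", "delins"):
        return cds[:s] + v.inserted_seq + cds[e:]
    if v.kind == "deletion":
        return cds[:s] + cds[e:]
    if v.kind == "duplication":
        return cds[:e] + cds[s:e] + cds[e:]
    return cds[:e] + v.inserted_seq + cds[e:]  # insertion after cds_end


def oracle_first_stop(seq: str):
    """(stop codon index, protein) by naive codon-by-codon scan."""
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _ORACLE_AA[seq[i:i + 3]]
        if aa == "*":
            return i // 3 + 1, "".join(protein)
        protein.append(aa)
    return None, "".join(protein)


def random_cds(rng: random.Random, n_codons: int) -> str:
    sense = [c for c, aa in _ORACLE_AA.items() if aa != "*"]
    stops = [c for c, aa in _ORACLE_AA.items() if aa == "*"]
    return "ATG" + "".join(rng.choice(sense) for _ in range(n_codons - 2)) + rng.choice(stops)


def random_edit(rng: random.Random, cds: str) -> CodingVariant:
    cds_len = len(cds)
    kind = rng.choice(["substitution", "deletion", "duplication", "insertion", "delins"])
    if kind == "substitution":
        pos = rng.randint(1, cds_len)
        ref = cds[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return CodingVariant(kind, pos, pos, alt, ref_seq=ref)
    if kind == "insertion":
        pos = rng.randint(1, cds_len - 1)
        n = rng.randint(1, 7)
        return CodingVariant(kind, pos, pos,
                             "".join(rng.choice("ACGT") for _ in range(n)))
    start = rng.randint(1, cds_len - 1)
    end = min(cds_len, start + rng.randint(0, 7))
    if kind == "deletion":
        return CodingVariant(kind, start, end)
    if kind == "duplication":
        return CodingVariant(kind, start, end)
    n = rng.randint(1, 7)
    return CodingVariant("delins", start, end,
                         "".join(rng.choice("ACGT") for _ in range(n)))


# --- first_affected_codon --------------------------------------------------


@pytest.mark.parametrize(
    "text,codon",
    [
        ("c.574_589del", 192),
        ("c.20_21dup", 8),
        ("c.1A>T", 1),
        ("c.3del", 1),
        ("c.4del", 2),
        ("c.3_4insAA", 2),
        ("c.6_8delinsG", 2),
    ],
)
def test_first_affected_codon(text, codon):
    assert first_affected_codon(parse_hgvs_c(text)) == codon


# --- prediction on the surrogate transcript --------------------------------


class TestSurrogatePredictions:
    def test_deletion_reads_through_reference_stop(self):
        cds, utr3, sites = rab38_surrogate_fixture()
        v = CodingVariant("deletion", *sites["del_site"])
        rec = predict_consequence(v, cds, utr3)
        assert rec.type == "frameshift" and rec.impact == "HIGH"
        assert rec.first_affected_codon == 192
        assert rec.wt_stop_codon_index == 212
        assert rec.wt_protein_len == 211
        assert rec.mut_stop_codon_index > rec.wt_stop_codon_index

    def test_duplication_truncates_early(self):
        cds, utr3, sites = rab38_surrogate_fixture()
        v = CodingVariant("duplication", *sites["dup_site"])
        rec = predict_consequence(v, cds, utr3)
        assert rec.type == "frameshift"
        assert rec.first_affected_codon == 8
        assert rec.mut_stop_codon_index == 15
        assert rec.mut_protein_len == 14

    def test_stop_loss_extension_enlarges_protein(self):
        """Reading through the stop extends the protein by >= 30%."""
        cds, utr3, sites = rab38_surrogate_fixture()
        rec = predict_consequence(CodingVariant("deletion", *sites["del_site"]),
                                  cds, utr3)
        assert rec.percent_length_change >= 30.0


# --- hand-translatable cases -----------------------------------------------

TOY_CDS = "ATGAAATAA"


class TestPredictSmallCases:
    def test_stop_gain(self):
        rec = predict_consequence(parse_hgvs_c("c.4A>T"), TOY_CDS)
        assert rec.type == "stop_gain" and rec.impact == "HIGH"
        assert rec.mut_protein_len == 1

    def test_start_loss(self):
        rec = predict_consequence(parse_hgvs_c("c.1A>G"), TOY_CDS)
        assert rec.type == "start_loss" and rec.impact == "HIGH"

    def test_synonymous(self):
        rec = predict_consequence(parse_hgvs_c("c.6A>G"), TOY_CDS)  # AAA->AAG
        assert rec.type == "synonymous" and rec.impact == "LOW"

    def test_missense(self):
        rec = predict_consequence(parse_hgvs_c("c.4A>G"), TOY_CDS)  # Lys->Glu
        assert rec.type == "missense" and rec.impact == "MODERATE"

    def test_inframe_deletion(self):
        rec = predict_consequence(parse_hgvs_c("c.4_6del"), TOY_CDS)
        assert rec.type == "inframe_indel" and rec.impact == "MODERATE"
        assert rec.mut_protein_len == 1

    def test_stop_loss_by_substitution(self):
        rec = predict_consequence(parse_hgvs_c("c.8A>C"), TOY_CDS, utr3="AAATGA")
        assert rec.type == "stop_loss"
        assert rec.mut_stop_codon_index == 5

    def test_no_stop_found(self):
        rec = predict_consequence(parse_hgvs_c("c.5del"), TOY_CDS, utr3="AAAA")
        assert rec.type == "no_stop_found" and rec.impact == "HIGH"
        assert rec.mut_stop_codon_index is None

    def test_frameshift_iff_net_length_not_multiple_of_3(self):
        for text, fs in [
            ("c.4del", True), ("c.4_6del", False), ("c.4_5del", True),
            ("c.4_5insAAA", False), ("c.4_5insAA", True),
            ("c.5_6dup", True), ("c.4_6dup", False),
            ("c.4_5delinsGGG", True), ("c.4A>G", False),
        ]:
            v = parse_hgvs_c(text)
            assert v.is_frameshift == fs, text


# --- oracle equivalence ----------------------------------------------------


def test_oracle_equivalence_500_random_trials():
    """predict_consequence agrees with the independent translator."""
    rng = random.Random(42)
    for trial in range(500):
        n_codons = rng.randint(20, 100)
        cds = random_cds(rng, n_codons)
        utr3 = "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 120)))
        v = random_edit(rng, cds)
        rec = predict_consequence(v, cds, utr3)

        mutant = oracle_apply(v, cds)
        stop_idx, protein = oracle_first_stop(mutant + utr3)
        if mutant[:3] != "ATG":
            assert rec.type == "start_loss", (trial, v)
            continue
        if stop_idx is None:
            assert rec.type == "no_stop_found", (trial, v)
            continue
        assert rec.mut_stop_codon_index == stop_idx, (trial, v)
        assert rec.mut_protein_len == len(protein)
        net = v.inserted_len - v.deleted_len
        assert (rec.type == "frameshift") == (
            net % 3 != 0 and rec.type not in ("no_stop_found",)
        ), (trial, v, rec.type)


# --- projection ------------------------------------------------------------


class TestProjection:
    def test_plus_strand_deletion_maps_and_3prime_shifts(self, toy_plus):
        ref, model = toy_plus
        # delete two G's of the CDS GGG homopolymer (genomic 20-22, anchored)
        v = Variant("chrP", 20, "GGG", "G")
        cv = project_to_cds(v, model, ref)
        assert cv.kind == "deletion"
        assert (cv.cds_start, cv.cds_end) == (11, 12)

    def test_minus_strand_mirror_gives_identical_coding_variant(
        self, toy_plus, toy_minus
    ):
        ref_p, model_p = toy_plus
        ref_m, model_m = toy_minus
        for site in [(11, 12), (4, 6), (15, 16)]:
            vp = cds_deletion_variant(model_p, ref_p, *site)
            vm = cds_deletion_variant(model_m, ref_m, *site)
            cp = project_to_cds(vp, model_p, ref_p)
            cm = project_to_cds(vm, model_m, ref_m)
            assert cp == cm, site

    def test_insertion_matching_preceding_segment_becomes_duplication(
        self, toy_plus
    ):
        ref, model = toy_plus
        # insert TT inside the CDS TTT run: shifts 3' and matches the
        # preceding two bases -> duplication
        v = Variant("chrP", 23, "T", "TTT")
        cv = project_to_cds(v, model, ref)
        assert cv.kind == "duplication"
        assert (cv.cds_start, cv.cds_end) == (15, 16)

    def test_insertion_not_matching_context_stays_insertion(self, toy_plus):
        ref, model = toy_plus
        v = Variant("chrP", 23, "T", "TCA")
        cv = project_to_cds(v, model, ref)
        assert cv.kind == "insertion"

    def test_variant_outside_cds_is_modifier(self, toy_plus):
        ref, model = toy_plus
        sig = project_to_cds(Variant("chrP", 3, "T", "A"), model, ref)
        assert isinstance(sig, ProjectionSignal) and sig.kind == "non_coding"
        rec = annotate_variant(Variant("chrP", 3, "T", "A"), model, ref)
        assert rec.impact == "MODIFIER"

    def test_deletion_spanning_splice_boundary_is_high(self):
        genome = "GGGGG" + "ATGAA" + "CCCCC" + "ATAA" + "GGGG"
        ref = ReferenceSequences()
        ref["chr1"] = genome
        model = TranscriptModel(
            "g1", "g1.t1", "chr1", "+",
            exons=[(5, 10), (15, 19)], cds_intervals=[(5, 10), (15, 19)],
        )
        v = Variant("chr1", 9, "AACCC", "A")  # exon1 tail into the intron
        sig = project_to_cds(v, model, ref)
        assert isinstance(sig, ProjectionSignal) and sig.kind == "splice_region"
        rec = annotate_variant(v, model, ref)
        assert rec.impact == "HIGH" and rec.mut_stop_codon_index is None

    def test_strand_symmetry_of_full_annotation(self, toy_plus, toy_minus):
        """Identical consequence arithmetic through either strand."""
        ref_p, model_p = toy_plus
        ref_m, model_m = toy_minus
        for maker, site in [
            (cds_deletion_variant, (4, 5)),
            (cds_deletion_variant, (4, 6)),
            (cds_duplication_variant, (5, 6)),
        ]:
            vp = maker(model_p, ref_p, *site)
            vm = maker(model_m, ref_m, *site)
            rp = annotate_variant(vp, model_p, ref_p, genomic_flank=0)
            rm = annotate_variant(vm, model_m, ref_m, genomic_flank=0)
            for attr in ("type", "impact", "first_affected_codon",
                         "wt_stop_codon_index", "mut_stop_codon_index",
                         "wt_protein_len", "mut_protein_len"):
                assert getattr(rp, attr) == getattr(rm, attr), (maker, site, attr)

    def test_utr3_sequence_both_strands(self, toy_plus, toy_minus):
        ref_p, model_p = toy_plus
        ref_m, model_m = toy_minus
        assert utr3_sequence(model_p, ref_p) == utr3_sequence(model_m, ref_m)


def test_impact_tiers():
    assert classify_impact("frameshift") == "HIGH"
    assert classify_impact("splice_region") == "HIGH"
    assert classify_impact("no_stop_found") == "HIGH"
    assert classify_impact("missense") == "MODERATE"
    assert classify_impact("inframe_indel") == "MODERATE"
    assert classify_impact("synonymous") == "LOW"
    assert classify_impact("non_coding") == "MODIFIER"
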