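"""Committed in-repo fixtures: the RAB38 surrogate transcript and the
published genotyping table.

The surrogate CDS is a fixed 636-nt sequence (633 coding nt + TAA) encoding
211 residues with the stop at codon 212, standing in for the real mink
RAB38 transcript, which is not redistributable here. It is engineered so
that the two published mutations reproduce the published position
arithmetic: deleting c.574-589 (16 nt) shifts the frame at codon 192, reads
through the reference stop at 212 and terminates at codon 277 in former
3'-UTR territory; duplicating c.20-21 ("CT") shifts the frame at codon 8
with a premature stop at codon 15.

``table1_fixture`` transcribes the published genotyping table: 35 minks of
eight colour phenotypes genotyped at both mutations.
"""

from __future__ import annotations

import random

from .genebuild import assemble_gene, cds_deletion_variant, cds_duplication_variant
from .models import (
    CohortGenotypes,
    GenotypeCall,
    ReferenceSequences,
    Role,
    Sample,
    TranscriptModel,
    Variant,
)

RAB38_SURROGATE_CDS = (
    "ATGCGATACTGTCGGAAGCCTGAACTTCGCTTCTCATCTCTGATGCCGGCCTTATTCATC"
    "GAAAGACAGAGATACACGGCTTCCCAATTCGAGGTCTCCGCGTTAAGCCATACGGTGACA"
    "TTATGCGGTCCCCTGGATACGCCGCGTCCAGCTGGATTCATCGATCTGCTATGGGACCAA"
    "AATTCCTTCGATTTCAAAACCGTGTCTCGCGTCTCGTCAGGGGGAAAAGCTCTTTCGTGG"
    "CCCATTGTGCCAGTCTGGACAATATTCGCAATGATTTCCAGCTCCGAGCTAACCACCCCA"
    "TGTGAATTGCTTACGCATGATCAGGTCACTGATCCCTCGTTGGAGATCTCCGCGGATGCC"
    "CAGCTAACCGCGTCCCGACCAGCAATTCAGAGTATATCGAGTAAGGCTGGGCAACTGACA"
    "ACCGGTTACAGATGTAGCTTGAAGTCTACCTTAGTATTGTCTGAGGGTCGCTCTGTCGAC"
    "CACGACTCCATTTGCATCTTAGGTGCCTCGTTTCGGGCCCACCTACTTGGGGGCGTATTC"
    "TCACCGACCCCAGCTACTCTTGCCGGACCCTGCATAATTAACGTGCACACTGTCATGCCT"
    "TCAAGGCCCCGTTCGAATACGTCAAGCTGCGTATAA"
)

RAB38_SURROGATE_UTR3 = (
    "CAAGTCGGCAGGATTCTTGGAGGCGGGTACAAACACTGGAATAGCGTCTGCAACTCGCAC"
    "CCCTTCTACTAAGGCGAACATAAGTGTCACTCTGATCGTGTCCAATTTGGGTAACGAGCG"
    "TGCTACGTCTCAAACAATGACAGGCCATCCGCGTAGTAATGAACTCAAGGCGACGGTACG"
    "CATACAACCGTTAGTGCTGTCTTTATTCTAACCACCGGATCATTGGTGCATAGAGCCTGG"
)

DEL_SITE = (574, 589)  # 16 nt deletion site, CDS coordinates
DUP_SITE = (20, 21)    # 2 nt ("CT") duplication site

SURROGATE_GENE_ID = "RAB38S"
SURROGATE_CONTIG = "ctg7"


def rab38_surrogate_fixture() -> tuple[str, str, dict[str, tuple[int, int]]]:
    """The surrogate CDS, its 3' UTR, and the two mutation sites."""
    return (
        RAB38_SURROGATE_CDS,
        RAB38_SURROGATE_UTR3,
        {"del_site": DEL_SITE, "dup_site": DUP_SITE},
    )


def rab38_surrogate_gene() -> tuple[
    ReferenceSequences, TranscriptModel, Variant, Variant
]:
    """The surrogate embedded as a minus-strand three-exon gene.

    Mirrors the real gene's architecture: the duplication site lies in
    exon 1, the deletion site in exon 3, and exon 1 sits at the higher
    genomic coordinate (the gene is on the minus strand). Returns the
    reference, the transcript model, and the two mutations as VCF-style
    genomic variants (ids ``RAB38S_3del`` and ``RAB38S_1dup``).
    """
    rng = random.Random(20200928)

    def bases(n: int) -> str:
        return "".join(rng.choice("ACGT") for _ in range(n))

    cds, utr3 = RAB38_SURROGATE_CDS, RAB38_SURROGATE_UTR3
    utr5 = bases(50)
    exon_seqs = [utr5 + cds[:100], cds[100:500], cds[500:] + utr3]
    intron_seqs = [bases(200), bases(200)]
    flank = bases(100)
    offset = len(flank)
    piece, model = assemble_gene(
        SURROGATE_GENE_ID, f"{SURROGATE_GENE_ID}.t1", SURROGATE_CONTIG, "-",
        offset, exon_seqs, intron_seqs,
        cds_spliced_range=(len(utr5), len(utr5) + len(cds)),
    )
    genome = flank + piece + bases(100)
    reference = ReferenceSequences()
    reference[SURROGATE_CONTIG] = genome
    del_variant = cds_deletion_variant(
        model, reference, *DEL_SITE, variant_id="RAB38S_3del"
    )
    dup_variant = cds_duplication_variant(
        model, reference, *DUP_SITE, variant_id="RAB38S_1dup"
    )
    return reference, model, del_variant, dup_variant


# ---------------------------------------------------------------------------
# Published genotyping table
#
# Rows: (symbol, phenotype, genotype at the 1dup site, genotype at the 3del
# site, number of samples). Genotype strings use the published rendering.

TABLE1_ROWS: list[tuple[str, str, str, str, int]] = [
    ("m/m", "Moyle", "+/+", "del/del", 1),
    ("m/m", "Moyle", "+/dup", "+/del", 2),
    ("a/a m/m", "Lavender", "+/dup", "+/del", 1),
    ("a/a m/m p/p", "Violet", "dup/dup", "+/+", 1),
    ("a/a m/m p/p", "Violet", "+/dup", "+/del", 1),
    ("a/a m/m p/p", "Violet", "+/+", "del/del", 2),
    ("+/+", "Standard dark brown", "+/+", "+/+", 17),
    ("p/p", "Silverblue", "+/+", "+/+", 2),
    ("S^H/+ p/p", "Shadow silverblue", "+/+", "+/+", 1),
    ("b/b", "Royal pastel", "+/+", "+/+", 5),
    ("b/b", "Royal pastel", "+/+", "+/del", 1),
    ("S/+ a/a p/p", "Cross sapphire", "+/+", "+/+", 1),
]

CASE_PHENOTYPES = frozenset({"Moyle", "Lavender", "Violet"})

#: Nominal depth attached to the genotyped calls so they pass depth filters;
#: these genotypes were confirmed by targeted resequencing, not shallow WGS.
TABLE1_DEPTH = 30


def _parse_gt(text: str) -> GenotypeCall:
    alleles = tuple(0 if a == "+" else 1 for a in text.split("/"))
    return GenotypeCall(alleles[0], alleles[1], depth=TABLE1_DEPTH)


def table1_fixture() -> tuple[CohortGenotypes, list[Sample]]:
    """The published genotype table as a 2-site x 35-sample cohort.

    Sites are the surrogate gene's genomic variants; sample roles assign
    the brown-dilute phenotypes (Moyle, Lavender, Violet) as cases and all
    other phenotypes as controls.
    """
    _, _, del_variant, dup_variant = rab38_surrogate_gene()
    samples: list[Sample] = []
    dup_calls: list[GenotypeCall] = []
    del_calls: list[GenotypeCall] = []
    counter: dict[str, int] = {}
    for _symbol, phenotype, gt_dup, gt_del, n in TABLE1_ROWS:
        for _ in range(n):
            counter[phenotype] = counter.get(phenotype, 0) + 1
            slug = phenotype.lower().replace(" ", "_")
            role = Role.CASE if phenotype in CASE_PHENOTYPES else Role.CONTROL
            samples.append(
                Sample(f"{slug}_{counter[phenotype]:02d}", phenotype, role)
            )
            dup_calls.append(_parse_gt(gt_dup))
            del_calls.append(_parse_gt(gt_del))
    cohort = CohortGenotypes(
        [del_variant, dup_variant], samples, [del_calls, dup_calls]
    )
    return cohort, samples
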