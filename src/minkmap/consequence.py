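"""Coding-consequence prediction for sequence-resolved variants.

Given a transcript model and a reference, a VCF-style variant is projected
into CDS coordinates (strand-aware, anchor base stripped, indels 3'-shifted
per HGVS), the edit is applied to the CDS string, and the mutant reading
frame is translated codon-by-codon from the original start codon, scanning
for the first stop and continuing into the 3' UTR when a frameshift reads
through the reference stop. Impact tiers mirror the classic annotation
ontology: frameshift/stop/start/splice disruptions are HIGH, missense and
in-frame indels MODERATE, synonymous LOW, non-coding MODIFIER.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from Bio.Seq import Seq

from .hgvs import CodingVariant, format_hgvs_c
from .models import (
    STOP_CODONS,
    ReferenceSequences,
    TranscriptModel,
    Variant,
    reverse_complement,
)

HIGH_IMPACT_TYPES = frozenset(
    {"frameshift", "stop_gain", "stop_loss", "start_loss", "splice_region",
     "no_stop_found"}
)
MODERATE_IMPACT_TYPES = frozenset({"missense", "inframe_indel"})


@dataclass(frozen=True)
class ProjectionSignal:
    """Non-CDS outcome of a projection: the variant misses or straddles the CDS."""

    kind: str  # "non_coding" | "splice_region"
    reason: str


@dataclass
class ConsequenceRecord:
    """Result of consequence prediction for one variant on one transcript.

    Codon indices are 1-based protein positions; protein lengths exclude the
    stop. ``mut_stop_codon_index`` is ``None`` when the mutant frame runs
    out of sequence without a stop (``no_stop_found``) and for records with
    no protein arithmetic (splice/non-coding/start-loss).
    """

    type: str
    impact: str = ""
    first_affected_codon: Optional[int] = None
    wt_stop_codon_index: Optional[int] = None
    mut_stop_codon_index: Optional[int] = None
    wt_protein_len: Optional[int] = None
    mut_protein_len: Optional[int] = None
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    variant: Optional[Variant] = None
    coding_variant: Optional[CodingVariant] = None

    def __post_init__(self) -> None:
        if not self.impact:
            self.impact = classify_impact(self)

    @property
    def hgvs_c(self) -> Optional[str]:
        if self.coding_variant is None:
            return None
        return format_hgvs_c(self.coding_variant)

    @property
    def protein_summary(self) -> str:
        """Compact p.-style summary (``p.192fs*86`` for frameshifts)."""
        if self.type in ("frameshift", "no_stop_found"):
            if self.mut_stop_codon_index is not None:
                offset = self.mut_stop_codon_index - self.first_affected_codon + 1
                return f"p.{self.first_affected_codon}fs*{offset}"
            return f"p.{self.first_affected_codon}fs*?"
        if self.type == "start_loss":
            return "p.1?"
        if self.first_affected_codon is not None:
            return f"p.{self.first_affected_codon}{self.type}"
        return self.type

    @property
    def percent_length_change(self) -> Optional[float]:
        """Percent protein-length change relative to wild type."""
        if self.mut_protein_len is None or not self.wt_protein_len:
            return None
        return 100.0 * (self.mut_protein_len - self.wt_protein_len) / self.wt_protein_len


def classify_impact(record_or_type: Union[ConsequenceRecord, str]) -> str:
    ctype = (
        record_or_type if isinstance(record_or_type, str) else record_or_type.type
    )
    if ctype in HIGH_IMPACT_TYPES:
        return "HIGH"
    if ctype in MODERATE_IMPACT_TYPES:
        return "MODERATE"
    if ctype == "synonymous":
        return "LOW"
    return "MODIFIER"


def first_affected_codon(v: CodingVariant) -> int:
    """1-based codon containing the first edited CDS base.

    For insertions and duplications the insertion point lies after
    ``cds_end``, so the first codon whose sequence changes is the codon of
    ``cds_end + 1``. The codon is reported even when its residue happens to
    be preserved by the edit.
    """
    if v.kind in ("insertion", "duplication"):
        return v.cds_end // 3 + 1
    return (v.cds_start - 1) // 3 + 1


# ---------------------------------------------------------------------------
# genomic -> CDS projection


def _trim(ref: str, alt: str) -> tuple[str, str, int]:
    """Minimal representation: strip shared suffix then prefix.

    Returns (ref_core, alt_core, offset of first differing base).
    """
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
        len(ref) > 1 or len(alt) > 1
    ):
        ref, alt = ref[:-1], alt[:-1]
    off = 0
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0] and (
        len(ref) > 1 or len(alt) > 1
    ):
        ref, alt = ref[1:], alt[1:]
        off += 1
    if ref == alt:  # identical after trimming: no edit left
        raise ValueError("variant REF and ALT are identical after trimming")
    if ref and alt and (len(ref) > 1 or len(alt) > 1) and (
        ref[0] == alt[0] or ref[-1] == alt[-1]
    ):
        # fully trimmed representation has neither shared end
        pass
    return ref, alt, off


def _shift3_deletion(cds: str, start0: int, length: int) -> int:
    """Slide a deletion window right while the sequence is unchanged."""
    while start0 + length < len(cds) and cds[start0] == cds[start0 + length]:
        start0 += 1
    return start0


def _shift3_insertion(cds: str, after0: int, seq: str) -> tuple[int, str]:
    """Slide an insertion right while the result is unchanged.

    ``after0`` is the 0-based index the sequence is inserted before (i.e.
    after 1-based CDS position ``after0``).
    """
    while after0 < len(cds) and cds[after0] == seq[0]:
        seq = seq[1:] + seq[0]
        after0 += 1
    return after0, seq


def project_to_cds(
    variant: Variant,
    transcript: TranscriptModel,
    reference: ReferenceSequences,
) -> Union[CodingVariant, ProjectionSignal]:
    """Project a genomic variant into 1-based CDS coordinates.

    The shared VCF anchor base is stripped, coordinates are mapped through
    the exon structure (alleles reverse-complemented for minus-strand
    transcripts), and the resulting indel is 3'-shifted within the CDS to
    its most-3' equivalent position. Insertions whose sequence equals the
    immediately preceding CDS segment are reported as duplications.

    Returns a :class:`ProjectionSignal` instead of raising when the variant
    lies outside the CDS (``non_coding``) or straddles a CDS/intron boundary
    (``splice_region``).
    """
    pos_list = transcript.cds_genomic_positions()
    g2c = {g: i for i, g in enumerate(pos_list)}  # genomic -> 0-based CDS index
    cds = transcript.spliced_cds(reference)
    minus = transcript.strand == "-"

    ref_core, alt_core, off = _trim(variant.ref, variant.alt)
    g0 = variant.pos - 1 + off  # 0-based genomic index of first changed base

    if ref_core:  # substitution / deletion / delins
        affected = range(g0, g0 + len(ref_core))
        inside = [g in g2c for g in affected]
        if not any(inside):
            return ProjectionSignal("non_coding", f"{variant} outside CDS")
        if not all(inside):
            return ProjectionSignal(
                "splice_region", f"{variant} spans a CDS boundary"
            )
        idxs = [g2c[g] for g in affected]
        step = -1 if minus else 1
        if any(b - a != step for a, b in zip(idxs, idxs[1:])):
            return ProjectionSignal(
                "splice_region", f"{variant} spans a splice junction"
            )
        s0 = min(idxs)
        r = reverse_complement(ref_core) if minus else ref_core
        a = reverse_complement(alt_core) if minus else alt_core
        if cds[s0:s0 + len(r)] != r:
            raise ValueError(
                f"{variant}: REF does not match reference CDS at c.{s0 + 1} "
                f"(expected {cds[s0:s0 + len(r)]!r}, got {r!r})"
            )
        if not alt_core:  # deletion, 3'-shift
            s0 = _shift3_deletion(cds, s0, len(r))
            return CodingVariant(
                "deletion", s0 + 1, s0 + len(r),
                ref_seq=cds[s0:s0 + len(r)], gene=transcript.gene_id,
            )
        if len(r) == 1 and len(a) == 1:
            return CodingVariant("substitution", s0 + 1, s0 + 1, a, ref_seq=r,
                                 gene=transcript.gene_id)
        return CodingVariant("delins", s0 + 1, s0 + len(r), a, ref_seq=r,
                             gene=transcript.gene_id)

    # pure insertion between g_left and g_right
    g_left, g_right = g0 - 1, g0
    in_left, in_right = g_left in g2c, g_right in g2c
    if not (in_left or in_right):
        return ProjectionSignal("non_coding", f"{variant} outside CDS")
    if not (in_left and in_right):
        # one flank in CDS: insertion at a CDS/UTR edge within the same exon
        # changes no codon; at an intron edge it is a splice signal
        same_exon = any(
            s <= g_left and g_right < e for s, e in transcript.exons
        )
        if same_exon:
            return ProjectionSignal("non_coding", f"{variant} at CDS/UTR edge")
        return ProjectionSignal("splice_region", f"{variant} at a splice edge")
    i, j = g2c[g_left], g2c[g_right]
    if abs(i - j) != 1:
        return ProjectionSignal("splice_region", f"{variant} spans a splice junction")
    seq = reverse_complement(alt_core) if minus else alt_core
    after0 = min(i, j) + 1  # insert before this 0-based CDS index
    after0, seq = _shift3_insertion(cds, after0, seq)
    L = len(seq)
    if after0 >= L and cds[after0 - L:after0] == seq:
        return CodingVariant("duplication", after0 - L + 1, after0, seq,
                             gene=transcript.gene_id)
    return CodingVariant("insertion", after0, after0, seq,
                         gene=transcript.gene_id)


# ---------------------------------------------------------------------------
# translation and consequence


def _apply_edit(v: CodingVariant, cds: str) -> str:
    s, e = v.cds_start, v.cds_end
    if e > len(cds):
        raise ValueError(f"{format_hgvs_c(v)} extends past CDS length {len(cds)}")
    if v.kind in ("substitution", "deletion", "delins"):
        if v.ref_seq is not None and cds[s - 1:e] != v.ref_seq:
            raise ValueError(
                f"{format_hgvs_c(v)}: reference mismatch (CDS has {cds[s - 1:e]!r})"
            )
        return cds[:s - 1] + v.inserted_seq + cds[e:]
    if v.kind == "duplication":
        seg = cds[s - 1:e]
        if v.inserted_seq and v.inserted_seq != seg:
            raise ValueError(
                f"{format_hgvs_c(v)}: duplicated sequence {v.inserted_seq!r} "
                f"differs from reference segment {seg!r}"
            )
        return cds[:e] + seg + cds[e:]
    # insertion after cds_end
    return cds[:e] + v.inserted_seq + cds[e:]


def _first_stop(seq: str) -> Optional[int]:
    """1-based index of the first in-frame stop codon, scanning from base 1."""
    usable = seq[: len(seq) // 3 * 3]
    protein = str(Seq(usable).translate())
    idx = protein.find("*")
    return idx + 1 if idx >= 0 else None


def predict_consequence(
    v: CodingVariant,
    cds: str,
    utr3: str = "",
    **record_fields,
) -> ConsequenceRecord:
    """Apply a CDS edit and classify its effect on the encoded protein.

    ``cds`` must be a complete CDS (multiple of 3, terminal stop codon).
    The mutant sequence is translated from the original start codon and
    scanned codon-by-codon for the first stop, continuing into ``utr3``
    when the edited CDS has none (frameshifts past the reference stop).
    """
    cds = cds.upper()
    utr3 = utr3.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError(f"CDS does not end in a stop codon ({cds[-3:]!r})")
    if v.cds_end > len(cds):
        raise ValueError(
            f"{format_hgvs_c(v)} lies outside the {len(cds)} nt CDS"
        )

    wt_stop = len(cds) // 3
    wt_len = wt_stop - 1
    base = dict(
        first_affected_codon=first_affected_codon(v),
        wt_stop_codon_index=wt_stop,
        wt_protein_len=wt_len,
        coding_variant=v,
        **record_fields,
    )

    mutant = _apply_edit(v, cds)
    if mutant[:3] != "ATG":
        return ConsequenceRecord(type="start_loss", first_affected_codon=1,
                                 wt_stop_codon_index=wt_stop, wt_protein_len=wt_len,
                                 coding_variant=v, **record_fields)

    mut_stop = _first_stop(mutant + utr3)
    net = v.net_length_change

    if mut_stop is None:
        return ConsequenceRecord(type="no_stop_found", **base)
    base.update(mut_stop_codon_index=mut_stop, mut_protein_len=mut_stop - 1)

    if net % 3 != 0:
        return ConsequenceRecord(type="frameshift", **base)

    expected_stop = (len(cds) + net) // 3
    if mut_stop < expected_stop:
        return ConsequenceRecord(type="stop_gain", **base)
    if mut_stop > expected_stop:
        return ConsequenceRecord(type="stop_loss", **base)
    if net != 0:
        return ConsequenceRecord(type="inframe_indel", **base)
    wt_protein = str(Seq(cds[:-3]).translate())
    mut_protein = str(Seq(mutant[: 3 * (mut_stop - 1)]).translate())
    ctype = "synonymous" if mut_protein == wt_protein else "missense"
    return ConsequenceRecord(type=ctype, **base)


def utr3_sequence(
    transcript: TranscriptModel,
    reference: ReferenceSequences,
    genomic_flank: int = 0,
) -> str:
    """Exonic sequence 3' of the CDS, optionally extended past the transcript.

    ``genomic_flank`` appends up to that many genomic bases beyond the
    transcript end (strand-aware) so that frameshift stop scans can run
    past a short annotated UTR.
    """
    chrom_seq = reference[transcript.chrom]
    exon_pos = [p for s, e in transcript.exons for p in range(s, e)]
    if transcript.strand == "-":
        exon_pos = exon_pos[::-1]
    cds_pos = set(
        p for s, e in transcript.cds_intervals for p in range(s, e)
    )
    last_cds_i = max(i for i, p in enumerate(exon_pos) if p in cds_pos)
    tail = exon_pos[last_cds_i + 1:]
    if transcript.strand == "+":
        utr = "".join(chrom_seq[p] for p in tail)
        end = transcript.span[1]
        utr += chrom_seq[end:end + genomic_flank]
    else:
        utr = "".join(
            reverse_complement(chrom_seq[p]) for p in tail
        )
        start = transcript.span[0]
        utr += reverse_complement(chrom_seq[max(0, start - genomic_flank):start])
    return utr


def annotate_variant(
    variant: Variant,
    transcript: TranscriptModel,
    reference: ReferenceSequences,
    genomic_flank: int = 600,
) -> ConsequenceRecord:
    """Full projection + prediction for one variant on one transcript."""
    ids = dict(gene_id=transcript.gene_id, transcript_id=transcript.transcript_id,
               variant=variant)
    projected = project_to_cds(variant, transcript, reference)
    if isinstance(projected, ProjectionSignal):
        return ConsequenceRecord(type=projected.kind, **ids)
    cds = transcript.spliced_cds(reference)
    utr3 = utr3_sequence(transcript, reference, genomic_flank=genomic_flank)
    return predict_consequence(projected, cds, utr3, **ids)
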