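"""Assembly of synthetic gene models and planted variants.

These helpers lay out a transcript (UTR5 + CDS + UTR3 split across exons,
introns between) on a contig on either strand, producing the genomic
sequence piece together with a :class:`TranscriptModel` whose intervals are
already in genomic coordinates. They also express CDS-level edits (the
planted causal deletions/duplications) as VCF-style anchored genomic
variants, which is how they appear to the pipeline.
"""

from __future__ import annotations

from .models import ReferenceSequences, TranscriptModel, Variant, reverse_complement


def assemble_gene(
    gene_id: str,
    transcript_id: str,
    chrom: str,
    strand: str,
    offset: int,
    exon_seqs: list[str],
    intron_seqs: list[str],
    cds_spliced_range: tuple[int, int],
) -> tuple[str, TranscriptModel]:
    """Build the genomic sequence piece and model for one transcript.

    ``exon_seqs`` are in transcript (5'->3') order; ``cds_spliced_range``
    is the 0-based half-open CDS range in spliced-transcript coordinates.
    Returns the plus-strand genomic sequence starting at ``offset`` and the
    transcript model with genomic-sorted intervals.
    """
    if len(intron_seqs) != len(exon_seqs) - 1:
        raise ValueError("need exactly one intron between consecutive exons")
    cs, ce = cds_spliced_range
    spliced_len = sum(len(e) for e in exon_seqs)
    if not 0 <= cs < ce <= spliced_len:
        raise ValueError(f"CDS range {cds_spliced_range} outside spliced transcript")

    # walk pieces in transcript order, tracking unspliced + spliced offsets
    pre_parts: list[str] = []
    exon_tx: list[tuple[int, int, int]] = []  # (unspliced start, unspliced end, spliced start)
    u = s = 0
    for k, exon in enumerate(exon_seqs):
        exon_tx.append((u, u + len(exon), s))
        pre_parts.append(exon)
        u += len(exon)
        s += len(exon)
        if k < len(intron_seqs):
            pre_parts.append(intron_seqs[k])
            u += len(intron_seqs[k])
    pre_mrna = "".join(pre_parts)
    L = len(pre_mrna)

    def to_genomic(a: int, b: int) -> tuple[int, int]:
        """Map an unspliced pre-mRNA interval to genomic coordinates."""
        if strand == "+":
            return offset + a, offset + b
        return offset + L - b, offset + L - a

    exons_g = []
    cds_g = []
    for ua, ub, sa in exon_tx:
        exons_g.append(to_genomic(ua, ub))
        lo = max(cs, sa)
        hi = min(ce, sa + (ub - ua))
        if lo < hi:  # CDS overlap with this exon, in unspliced coords
            cds_g.append(to_genomic(ua + (lo - sa), ua + (hi - sa)))
    piece = pre_mrna if strand == "+" else reverse_complement(pre_mrna)
    model = TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=sorted(exons_g),
        cds_intervals=sorted(cds_g),
    )
    return piece, model


def _contiguous_runs(pos_list: list[int], strand: str) -> list[tuple[int, int]]:
    """0-based CDS-index runs whose genomic positions are contiguous."""
    step = -1 if strand == "-" else 1
    runs = []
    start = 0
    for i in range(1, len(pos_list)):
        if pos_list[i] - pos_list[i - 1] != step:
            runs.append((start, i))
            start = i
    runs.append((start, len(pos_list)))
    return runs


def pick_intraexon_range(
    transcript: TranscriptModel, length: int, prefer_start: int
) -> tuple[int, int]:
    """A 1-based CDS range of ``length`` lying in one exon, near ``prefer_start``.

    The range (plus one upstream anchor base) must be genomically
    contiguous so it can be expressed as a single VCF indel.
    """
    pos_list = transcript.cds_genomic_positions()
    runs = _contiguous_runs(pos_list, transcript.strand)
    best = None
    for a, b in runs:
        # keep one base upstream in-run for the VCF anchor
        lo, hi = a + 1, b - length  # 0-based candidate starts
        if lo > hi:
            continue
        cand = min(max(prefer_start - 1, lo), hi)
        score = abs(cand - (prefer_start - 1))
        if best is None or score < best[0]:
            best = (score, cand)
    if best is None:
        raise ValueError(
            f"no exon of {transcript.transcript_id} can host a {length} nt edit"
        )
    start0 = best[1]
    return start0 + 1, start0 + length


def cds_deletion_variant(
    transcript: TranscriptModel,
    reference: ReferenceSequences,
    cds_start: int,
    cds_end: int,
    variant_id: str | None = None,
) -> Variant:
    """Express deletion of CDS ``cds_start..cds_end`` as an anchored VCF variant."""
    pos_list = transcript.cds_genomic_positions()
    gs = pos_list[cds_start - 1:cds_end]
    lo, hi = min(gs), max(gs)
    if hi - lo != len(gs) - 1:
        raise ValueError(
            f"CDS {cds_start}..{cds_end} of {transcript.transcript_id} spans an intron"
        )
    seq = reference[transcript.chrom]
    anchor = lo - 1
    return Variant(
        transcript.chrom, anchor + 1, seq[anchor:hi + 1], seq[anchor],
        id=variant_id,
    )


def cds_duplication_variant(
    transcript: TranscriptModel,
    reference: ReferenceSequences,
    cds_start: int,
    cds_end: int,
    variant_id: str | None = None,
) -> Variant:
    """Express duplication of CDS ``cds_start..cds_end`` as an anchored VCF variant.

    The copy is inserted 3' of ``cds_end`` in transcript orientation; the
    VCF record anchors on the genomically-left flanking base.
    """
    pos_list = transcript.cds_genomic_positions()
    seq = reference[transcript.chrom]
    segment_g = pos_list[cds_start - 1:cds_end]
    if max(segment_g) - min(segment_g) != len(segment_g) - 1:
        raise ValueError("duplicated segment spans an intron")
    segment = "".join(seq[p] for p in sorted(segment_g))  # plus-strand spelling
    if transcript.strand == "+":
        anchor = pos_list[cds_end - 1]  # last segment base; copy goes after it
    else:
        anchor = min(segment_g) - 1  # genomic left flank: copy precedes the block
    if anchor + 1 + len(segment) > len(seq):
        raise ValueError("duplication anchor too close to contig end")
    return Variant(
        transcript.chrom, anchor + 1, seq[anchor], seq[anchor] + segment,
        id=variant_id,
    )
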