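"""Readers and writers for the standard formats the pipeline touches.

VCF is parsed with pysam; multi-allelic records are decomposed into
biallelic :class:`~minkmap.models.Variant` records at the boundary so that
everything downstream can assume allele indices 0/1. GFF3 is parsed with
gffutils (in-memory db) and validated against the reference. Sample roles
come from a separate tab-separated sample sheet because VCF has no standard
phenotype field.
"""

from __future__ import annotations

import csv
import logging
from typing import Iterable, Optional

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

from .models import (
    STOP_CODONS,
    CohortGenotypes,
    GenotypeCall,
    ReferenceSequences,
    Role,
    Sample,
    TranscriptModel,
    Variant,
)

logger = logging.getLogger(__name__)

SAMPLE_SHEET_HEADER = ("sample_id", "phenotype", "role")


class VcfParseError(ValueError):
    """Malformed VCF content (header, genotype string, duplicate sample)."""


class Gff3ValidationError(ValueError):
    """Gene model inconsistent with the reference or structurally invalid."""


class SampleSheetError(ValueError):
    """Malformed sample sheet."""


# ---------------------------------------------------------------------------
# VCF


def _is_symbolic(alt: Optional[str]) -> bool:
    if alt is None:
        return True
    return alt == "*" or any(c in alt for c in "<>[].") or not set(alt) <= set("ACGTacgt")


def _header_line_count(path: str) -> int:
    n = 0
    opener = pysam.BGZFile if str(path).endswith(".gz") else open
    with opener(path, "rb" if str(path).endswith(".gz") else "r") as fh:
        for raw in fh:
            line = raw.decode() if isinstance(raw, bytes) else raw
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def _check_duplicate_samples(path: str) -> None:
    """Report duplicate sample ids by name before htslib rejects the file."""
    gz = path.endswith(".gz")
    fh = pysam.BGZFile(path, "rb") if gz else open(path)
    with fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.decode() if isinstance(raw, bytes) else raw
            if line.startswith("#CHROM"):
                ids = line.rstrip("\n").split("\t")[9:]
                dupes = sorted({s for s in ids if ids.count(s) > 1})
                if dupes:
                    raise VcfParseError(
                        f"{path}: line {line_no}: duplicate sample id(s) {dupes}"
                    )
                return
            if not line.startswith("#"):
                return


def read_vcf(path: str, samples: Optional[list[Sample]] = None) -> CohortGenotypes:
    """Read a multi-sample VCF into a :class:`CohortGenotypes`.

    Multi-allelic records are decomposed into one biallelic record per ALT,
    remapping each sample's genotype (the decomposed ALT keeps index 1,
    every other allele maps to 0) so that per-sample non-REF allele counts
    are conserved across the decomposition. Symbolic ALTs (``<DEL>``,
    breakends, ``*``) are skipped with a warning.

    Parameters
    ----------
    path
        Plain or bgzip-compressed VCF v4.x with GT (and optionally DP)
        FORMAT fields.
    samples
        Optional sample metadata (from :func:`read_sample_sheet`) to attach
        by sample id; samples absent from the sheet stay unassigned.
    """
    _check_duplicate_samples(str(path))
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    with vcf:
        sample_ids = list(vcf.header.samples)
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise VcfParseError(f"{path}: duplicate sample id(s) {dupes} in header")
        n_header = _header_line_count(str(path))
        variants: list[Variant] = []
        rows: list[list[GenotypeCall]] = []
        record_no = 0
        records = iter(vcf)
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise VcfParseError(
                    f"{path}: parse error at line {n_header + record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            line_no = n_header + record_no
            alts = rec.alts or ()
            for alt_idx, alt in enumerate(alts, start=1):
                if _is_symbolic(alt):
                    logger.warning(
                        "%s line %d: skipping symbolic ALT %r at %s:%d",
                        path, line_no, alt, rec.chrom, rec.pos,
                    )
                    continue
                try:
                    variant = Variant(rec.chrom, rec.pos, rec.ref.upper(), alt.upper(),
                                      id=rec.id)
                except ValueError as exc:
                    raise VcfParseError(f"{path}: line {line_no}: {exc}") from exc
                row = []
                for sid in sample_ids:
                    call = rec.samples[sid]
                    gt = call.get("GT", (None, None))
                    if gt is None:
                        gt = (None, None)
                    if len(gt) == 1:  # haploid call: treat second allele missing
                        gt = (gt[0], None)
                    if len(gt) != 2:
                        raise VcfParseError(
                            f"{path}: line {line_no}: sample {sid} has ploidy "
                            f"{len(gt)}, only diploid GT is supported"
                        )
                    mapped = tuple(
                        None if a is None else (1 if a == alt_idx else 0) for a in gt
                    )
                    dp = call.get("DP")
                    row.append(
                        GenotypeCall(mapped[0], mapped[1], depth=dp,
                                     phased=bool(call.phased))
                    )
                variants.append(variant)
                rows.append(row)
    cohort_samples = [Sample(sid) for sid in sample_ids]
    cohort = CohortGenotypes(variants, cohort_samples, rows)
    if samples is not None:
        cohort = cohort.with_samples(samples)
    return cohort


def write_vcf(cohort: CohortGenotypes, path: str) -> None:
    """Write a cohort as VCF v4.2 with GT and DP FORMAT fields.

    Round-trips through :func:`read_vcf`: missing depth is emitted as "."
    and missing genotypes as "./.".
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    for chrom in sorted({v.chrom for v in cohort.variants}):
        header.contigs.add(chrom)
    for s in cohort.samples:
        header.add_sample(s.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in enumerate(cohort.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos + len(v.ref) - 1,
                alleles=(v.ref, v.alt), id=v.id,
            )
            for j, s in enumerate(cohort.samples):
                call = cohort.calls[i][j]
                rec.samples[j]["GT"] = (call.allele_a, call.allele_b)
                rec.samples[j].phased = call.phased
                if call.depth is not None:
                    rec.samples[j]["DP"] = call.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> ReferenceSequences:
    ref = ReferenceSequences()
    for record in SeqIO.parse(str(path), "fasta"):
        ref[record.id] = str(record.seq)
    return ref


def write_fasta(reference: ReferenceSequences, path: str, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def _validate_cds(model: TranscriptModel, reference: ReferenceSequences,
                  strict: bool) -> None:
    if model.cds_length % 3 != 0:
        raise Gff3ValidationError(
            f"transcript {model.transcript_id}: CDS length {model.cds_length} "
            f"is not divisible by 3"
        )
    if model.chrom not in reference:
        raise Gff3ValidationError(
            f"transcript {model.transcript_id}: sequence {model.chrom!r} "
            f"not in reference"
        )
    cds = model.spliced_cds(reference)
    problems = []
    if not cds.startswith("ATG"):
        problems.append(f"CDS does not start with ATG (found {cds[:3]!r})")
    if cds[-3:] not in STOP_CODONS:
        problems.append(f"CDS does not end with a stop codon (found {cds[-3:]!r})")
    if any(c in STOP_CODONS for c in
           (cds[i:i + 3] for i in range(0, len(cds) - 3, 3))):
        problems.append("internal stop codon in CDS")
    if problems:
        msg = f"transcript {model.transcript_id}: " + "; ".join(problems)
        if strict:
            raise Gff3ValidationError(msg)
        logger.warning(msg)


def read_gff3(path: str, reference: ReferenceSequences,
              strict: bool = True) -> list[TranscriptModel]:
    """Read gene models from GFF3 and validate CDS against the reference.

    Requires gene/mRNA/exon/CDS features linked by Parent attributes.
    Intervals are converted from GFF3 1-based closed to internal 0-based
    half-open. With ``strict=False`` start/stop-codon mismatches are
    downgraded to warnings (CDS length must still be a multiple of 3).
    """
    try:
        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="create_unique", keep_order=True)
    except Exception as exc:
        raise Gff3ValidationError(f"{path}: cannot parse GFF3: {exc}") from exc
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not set(parents) & mrna_ids:
            raise Gff3ValidationError(
                f"orphan CDS feature at {cds.seqid}:{cds.start}-{cds.end} "
                f"(Parent={parents or None})"
            )
    models = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        gene_ids = mrna.attributes.get("Parent", [mrna.id])
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="exon")
        )
        cds_ivs = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="CDS")
        )
        if not exons:
            exons = cds_ivs
        model = TranscriptModel(
            gene_id=gene_ids[0],
            transcript_id=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds_intervals=cds_ivs,
        )
        if cds_ivs:
            _validate_cds(model, reference, strict)
        models.append(model)
    return models


def write_gff3(transcripts: Iterable[TranscriptModel], path: str) -> None:
    """Write gene/mRNA/exon/CDS features (1-based closed) for the models."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(by_gene):
            ts = by_gene[gene_id]
            chrom, strand = ts[0].chrom, ts[0].strand
            g_start = min(t.span[0] for t in ts)
            g_end = max(t.span[1] for t in ts)
            fh.write(
                f"{chrom}\tminkmap\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}"
                f"\t.\tID={gene_id}\n"
            )
            for t in sorted(ts, key=lambda t: t.transcript_id):
                s, e = t.span
                fh.write(
                    f"{chrom}\tminkmap\tmRNA\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for k, (xs, xe) in enumerate(t.exons, 1):
                    fh.write(
                        f"{chrom}\tminkmap\texon\t{xs + 1}\t{xe}\t.\t{t.strand}"
                        f"\t.\tID={t.transcript_id}.exon{k};Parent={t.transcript_id}\n"
                    )
                # CDS phase: offset of the first complete codon in each piece
                pieces = t.cds_intervals if t.strand == "+" else t.cds_intervals[::-1]
                consumed = 0
                phases = {}
                for (cs, ce) in pieces:
                    phases[(cs, ce)] = (3 - consumed % 3) % 3
                    consumed += ce - cs
                for k, (cs, ce) in enumerate(t.cds_intervals, 1):
                    fh.write(
                        f"{chrom}\tminkmap\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}"
                        f"\t{phases[(cs, ce)]}\t"
                        f"ID={t.transcript_id}.cds{k};Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Sample sheet


def read_sample_sheet(path: str) -> list[Sample]:
    """Read a TSV with header ``sample_id<TAB>phenotype<TAB>role``."""
    samples = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SampleSheetError(f"{path}: empty sample sheet") from None
        if tuple(h.strip() for h in header) != SAMPLE_SHEET_HEADER:
            raise SampleSheetError(
                f"{path}: expected header {SAMPLE_SHEET_HEADER}, got {tuple(header)}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise SampleSheetError(
                    f"{path}: line {line_no}: expected 3 columns, got {len(row)}"
                )
            sid, phenotype, role = (c.strip() for c in row)
            try:
                samples.append(Sample(sid, phenotype, Role(role)))
            except ValueError:
                raise SampleSheetError(
                    f"{path}: line {line_no}: role must be one of "
                    f"{[r.value for r in Role]}, got {role!r}"
                ) from None
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise SampleSheetError(f"{path}: duplicate sample ids")
    return samples


def write_sample_sheet(samples: Iterable[Sample], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SAMPLE_SHEET_HEADER)
        for s in samples:
            writer.writerow([s.sample_id, s.phenotype_label, s.role.value])
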