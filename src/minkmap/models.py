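"""Core domain types for cohort genotype data and gene models.

Coordinate conventions
----------------------
Genomic coordinates are 0-based half-open internally; VCF and GFF3 I/O
convert at the boundary (both formats are 1-based). CDS ("c.") and protein
("p.") coordinates are 1-based, following HGVS.

A :class:`Variant` keeps the VCF-style anchored representation (1-based
``pos`` of the first REF base, shared leading base for indels) because that
is what callers emit and what the segregation filter matches on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

VALID_BASES = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class GenotypeClass(str, Enum):
    """Exhaustive classification of a biallelic genotype call."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True, order=True)
class Variant:
    """A biallelic sequence variant in VCF-style representation.

    ``pos`` is the 1-based genomic position of the first REF base. Multi-
    allelic records are decomposed into one ``Variant`` per ALT on read, so
    ``alt`` is always a single allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele in variant {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            bad = set(allele) - VALID_BASES
            if bad:
                raise ValueError(
                    f"non-ACGT characters {sorted(bad)} in variant "
                    f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"
                )
        if self.ref == self.alt:
            raise ValueError(f"REF equals ALT at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive genomic position of the last REF base."""
        return self.pos + len(self.ref) - 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid genotype at one variant.

    Allele indices are 0 (REF) or 1 (ALT); ``None`` marks a missing allele.
    ``depth`` is the DP value, ``None`` when DP was absent or "." — depth
    filters treat an absent depth as failing.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    depth: Optional[int] = None
    phased: bool = False

    def __post_init__(self) -> None:
        for a in (self.allele_a, self.allele_b):
            if a is not None and a not in (0, 1):
                raise ValueError(f"allele index must be 0, 1 or missing, got {a}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None or self.allele_b is None

    def classify(self) -> GenotypeClass:
        if self.is_missing:
            return GenotypeClass.MISSING
        n_alt = self.allele_a + self.allele_b  # type: ignore[operator]
        return (GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT)[n_alt]


MISSING_CALL = GenotypeCall(None, None, None)


class Role(str, Enum):
    CASE = "case"
    CONTROL = "control"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Sample:
    """A cohort member with its phenotype label and case/control role."""

    sample_id: str
    phenotype_label: str = ""
    role: Role = Role.UNASSIGNED


class CohortGenotypes:
    """Variants x samples genotype matrix with phenotype metadata.

    Variants are kept sorted by (chrom, pos, ref, alt); sample order is
    preserved from the input. ``calls[i][j]`` is the call for variant ``i``
    in sample ``j``.
    """

    def __init__(
        self,
        variants: list[Variant],
        samples: list[Sample],
        calls: list[list[GenotypeCall]],
    ) -> None:
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if len(calls) != len(variants):
            raise ValueError(
                f"calls has {len(calls)} rows for {len(variants)} variants"
            )
        for i, row in enumerate(calls):
            if len(row) != len(samples):
                raise ValueError(
                    f"row {i} has {len(row)} calls for {len(samples)} samples"
                )
        order = sorted(range(len(variants)), key=lambda i: variants[i].key)
        self.variants = [variants[i] for i in order]
        self.samples = list(samples)
        self.calls = [calls[i] for i in order]
        self._sample_index = {s.sample_id: j for j, s in enumerate(self.samples)}
        self._variant_index = {v.key: i for i, v in enumerate(self.variants)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def variant_index(self, variant: Variant) -> int:
        try:
            return self._variant_index[variant.key]
        except KeyError:
            raise KeyError(f"variant {variant} not in cohort") from None

    def call(self, variant: Variant, sample_id: str) -> GenotypeCall:
        return self.calls[self.variant_index(variant)][self.sample_index(sample_id)]

    def samples_with_role(self, role: Role) -> list[Sample]:
        return [s for s in self.samples if s.role == role]

    def with_samples(self, samples: list[Sample]) -> "CohortGenotypes":
        """Return a copy with sample metadata replaced (matched by id)."""
        by_id = {s.sample_id: s for s in samples}
        new = [by_id.get(s.sample_id, s) for s in self.samples]
        return CohortGenotypes(self.variants, new, self.calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortGenotypes):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and self.calls == other.calls
        )

    def __repr__(self) -> str:
        return (
            f"CohortGenotypes({self.n_variants} variants x "
            f"{self.n_samples} samples)"
        )


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` and ``cds_intervals`` are lists of 0-based half-open genomic
    intervals, sorted by genomic coordinate regardless of strand. The CDS
    includes the stop codon.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds_intervals", self.cds_intervals)):
            prev_end = -1
            for start, end in ivs:
                if start >= end:
                    raise ValueError(
                        f"{self.transcript_id}: empty/inverted {name} interval "
                        f"({start}, {end})"
                    )
                if start < prev_end:
                    raise ValueError(
                        f"{self.transcript_id}: {name} overlap or unsorted at "
                        f"({start}, {end})"
                    )
                prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open genomic span of the transcript."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in 5'->3' transcript order."""
        positions = [p for s, e in self.cds_intervals for p in range(s, e)]
        return positions[::-1] if self.strand == "-" else positions

    def spliced_cds(self, reference: "ReferenceSequences") -> str:
        seq = "".join(
            reference[self.chrom][s:e] for s, e in self.cds_intervals
        )
        return reverse_complement(seq) if self.strand == "-" else seq


class ReferenceSequences(dict):
    """Mapping of sequence name -> uppercase nucleotide string."""

    def __setitem__(self, name: str, seq: str) -> None:
        seq = seq.upper()
        bad = set(seq) - (VALID_BASES | {"N"})
        if bad:
            raise ValueError(f"sequence {name!r} has invalid characters {sorted(bad)}")
        super().__setitem__(name, seq)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
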