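"""Recessive case/control discovery filter.

Selects genes in which every affected sample carries two mutant alleles —
homozygous for one variant or heterozygous for at least two variants of the
same gene (putative compound heterozygote, unphased at this stage) — while
no unaffected sample shows the same biallelic pattern over the implicated
variants. Genotypes only count when supported by read depth strictly
greater than the configured threshold; exclusion by a control requires
affirmative evidence, so missing or shallow control genotypes never rescue
nor kill a gene.

Compound-heterozygous candidates are deliberately unphased here: any two
heterozygous variants in a gene qualify, and cis configurations are weeded
out downstream by the phase module (mirroring how such candidates are
confirmed experimentally by allele-specific amplicons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import (
    CohortGenotypes,
    GenotypeCall,
    GenotypeClass,
    Role,
    TranscriptModel,
    Variant,
)


class ConfigurationError(ValueError):
    """Cohort lacks cases or controls, or parameters are invalid."""


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the recessive discovery filter.

    ``min_depth_exclusive`` is an exclusive bound: a call passes when
    ``DP > min_depth_exclusive`` (DP >= 3 at the default of 2). With
    ``require_called_in_all_cases=False``, a case without supporting
    evidence is skipped unless it has a usable (called, depth-passing)
    genotype at one of the candidate variants implicated by the other
    cases; this tolerates shallow per-case coverage at the cost of weaker
    evidence.
    """

    min_depth_exclusive: int = 2
    require_called_in_all_cases: bool = True

    def __post_init__(self) -> None:
        if self.min_depth_exclusive < 0:
            raise ConfigurationError(
                f"min_depth_exclusive must be >= 0, got {self.min_depth_exclusive}"
            )


@dataclass
class CandidateGene:
    gene_id: str
    mode: str  # "homozygous" | "compound_het" | "mixed"
    variants: list[Variant]
    per_case_evidence: dict[str, str] = field(default_factory=dict)


@dataclass
class CandidateSet:
    entries: list[CandidateGene] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def genotype_class(call: GenotypeCall) -> GenotypeClass:
    """Classify a call as hom_ref / het / hom_alt / missing."""
    return call.classify()


def passes_depth(call: GenotypeCall, params: FilterParams) -> bool:
    """True iff depth is present and strictly greater than the threshold."""
    return call.depth is not None and call.depth > params.min_depth_exclusive


def gene_spans(
    transcripts: list[TranscriptModel],
) -> dict[str, tuple[str, int, int]]:
    """Per-gene (chrom, start, end) footprint, 0-based half-open.

    A gene's footprint is the union span of all its transcripts, introns
    included: the discovery filter is run genome-wide before annotation, so
    intronic (potential splice) variants are not silently dropped.
    """
    spans: dict[str, tuple[str, int, int]] = {}
    for t in transcripts:
        s, e = t.span
        if t.gene_id in spans:
            chrom, s0, e0 = spans[t.gene_id]
            if chrom != t.chrom:
                raise ConfigurationError(
                    f"gene {t.gene_id} has transcripts on multiple sequences"
                )
            spans[t.gene_id] = (chrom, min(s0, s), max(e0, e))
        else:
            spans[t.gene_id] = (t.chrom, s, e)
    return spans


def variants_in_gene(
    cohort: CohortGenotypes, span: tuple[str, int, int]
) -> list[int]:
    chrom, start, end = span
    return [
        i for i, v in enumerate(cohort.variants)
        if v.chrom == chrom and start < v.pos <= end  # v.pos is 1-based
    ]


def compound_het_groups(
    cohort: CohortGenotypes,
    sample_id: str,
    transcripts: list[TranscriptModel],
    params: FilterParams = FilterParams(),
) -> dict[str, list[Variant]]:
    """Genes in which a sample is depth-passing heterozygous at >= 2 variants."""
    j = cohort.sample_index(sample_id)
    groups: dict[str, list[Variant]] = {}
    for gene_id, span in sorted(gene_spans(transcripts).items()):
        hets = [
            cohort.variants[i]
            for i in variants_in_gene(cohort, span)
            if cohort.calls[i][j].classify() is GenotypeClass.HET
            and passes_depth(cohort.calls[i][j], params)
        ]
        if len(hets) >= 2:
            groups[gene_id] = hets
    return groups


def _case_support(
    cohort: CohortGenotypes,
    j: int,
    var_idxs: list[int],
    params: FilterParams,
) -> tuple[str | None, list[int]]:
    """How (if at all) sample ``j`` satisfies the biallelic rule in a gene.

    Returns (rule, supporting variant indices); rule is "homozygous",
    "compound_het" or None.
    """
    homs = [
        i for i in var_idxs
        if cohort.calls[i][j].classify() is GenotypeClass.HOM_ALT
        and passes_depth(cohort.calls[i][j], params)
    ]
    if homs:
        return "homozygous", homs
    hets = [
        i for i in var_idxs
        if cohort.calls[i][j].classify() is GenotypeClass.HET
        and passes_depth(cohort.calls[i][j], params)
    ]
    if len(hets) >= 2:
        return "compound_het", hets
    return None, []


def recessive_candidates(
    cohort: CohortGenotypes,
    transcripts: list[TranscriptModel],
    params: FilterParams = FilterParams(),
) -> CandidateSet:
    """Genes whose genotype pattern segregates with a recessive model.

    A gene is a candidate iff (A) every case is depth-passing homozygous
    for at least one of its variants or carries a depth-passing
    compound-het group in it, and (B) no control is homozygous at any
    implicated variant nor compound-het over the implicated variants.
    Controls that are heterozygous carriers at a single variant do not
    exclude a gene — a carrier is neither homozygous nor compound
    heterozygous.
    """
    cases = cohort.samples_with_role(Role.CASE)
    controls = cohort.samples_with_role(Role.CONTROL)
    if not cases or not controls:
        raise ConfigurationError(
            f"need >= 1 case and >= 1 control (got {len(cases)} cases, "
            f"{len(controls)} controls)"
        )
    result = CandidateSet()
    for gene_id, span in sorted(gene_spans(transcripts).items()):
        var_idxs = variants_in_gene(cohort, span)
        if not var_idxs:
            continue
        evidence: dict[str, str] = {}
        implicated: set[int] = set()
        ok = True
        unsupported: list[int] = []
        for s in cases:
            j = cohort.sample_index(s.sample_id)
            rule, support = _case_support(cohort, j, var_idxs, params)
            if rule is None:
                if params.require_called_in_all_cases:
                    ok = False
                    break
                unsupported.append(j)
                continue
            evidence[s.sample_id] = rule
            implicated.update(support)
        if not ok or not evidence:
            continue
        # relaxed mode: a case without supporting evidence is skipped unless
        # it has a usable genotype at an implicated variant (an affirmative
        # call at a candidate site that fails to fit the model)
        if any(
            not cohort.calls[i][j].is_missing
            and passes_depth(cohort.calls[i][j], params)
            for j in unsupported
            for i in implicated
        ):
            continue
        for s in controls:
            j = cohort.sample_index(s.sample_id)
            hom = any(
                cohort.calls[i][j].classify() is GenotypeClass.HOM_ALT
                and passes_depth(cohort.calls[i][j], params)
                for i in implicated
            )
            hets = sum(
                1 for i in implicated
                if cohort.calls[i][j].classify() is GenotypeClass.HET
                and passes_depth(cohort.calls[i][j], params)
            )
            if hom or hets >= 2:
                ok = False
                break
        if not ok:
            continue
        rules = set(evidence.values())
        mode = rules.pop() if len(rules) == 1 else "mixed"
        result.entries.append(
            CandidateGene(
                gene_id=gene_id,
                mode=mode,
                variants=sorted(
                    (cohort.variants[i] for i in implicated),
                    key=lambda v: v.key,
                ),
                per_case_evidence=evidence,
            )
        )
    return result


def homozygous_site_candidates(
    cohort: CohortGenotypes,
    params: FilterParams = FilterParams(),
) -> list[Variant]:
    """Gene-agnostic per-variant filter (homozygous-only rule).

    A variant passes iff every case is depth-passing homozygous ALT (or,
    with relaxed calling, has no usable call) and no control is.
    """
    cases = cohort.samples_with_role(Role.CASE)
    controls = cohort.samples_with_role(Role.CONTROL)
    if not cases or not controls:
        raise ConfigurationError("need >= 1 case and >= 1 control")
    out = []
    for i, v in enumerate(cohort.variants):
        case_ok = True
        any_hom = False
        for s in cases:
            call = cohort.calls[i][cohort.sample_index(s.sample_id)]
            if call.classify() is GenotypeClass.HOM_ALT and passes_depth(call, params):
                any_hom = True
            elif params.require_called_in_all_cases or (
                not call.is_missing and passes_depth(call, params)
            ):
                case_ok = False
                break
        if not case_ok or not any_hom:
            continue
        if any(
            cohort.calls[i][cohort.sample_index(s.sample_id)].classify()
            is GenotypeClass.HOM_ALT
            and passes_depth(cohort.calls[i][cohort.sample_index(s.sample_id)], params)
            for s in controls
        ):
            continue
        out.append(v)
    return out
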