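"""End-to-end pipeline: simulate -> filter -> annotate -> phase -> report.

Each stage logs one structured line with its input/output counts so the
funnel from raw variants to candidate genes is inspectable. All stages
round-trip through the on-disk formats (VCF/FASTA/GFF3/TSV) rather than
passing objects directly, so a pipeline run also exercises the I/O layer
end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as mio
from .consequence import ConsequenceRecord, annotate_variant
from .models import CohortGenotypes, TranscriptModel
from .phase import PhaseCall, infer_phase, read_observations, write_observations
from .report import ConcordanceSummary, GenotypeTable, concordance_with_recessive_model, genotype_table
from .segregation import CandidateSet, FilterParams, passes_depth, recessive_candidates
from .simulate import SimulationParams, TruthRecord, simulate_cohort, simulate_reference

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    candidates: CandidateSet
    consequences: list[ConsequenceRecord]
    phase_calls: dict[tuple[str, str], PhaseCall]
    table: Optional[GenotypeTable]
    concordance: Optional[ConcordanceSummary]
    truth: Optional[TruthRecord] = None
    confirmed_genes: list[str] = field(default_factory=list)


def write_candidates_tsv(
    candidates: CandidateSet, cohort: CohortGenotypes, path: str
) -> None:
    with open(path, "w") as fh:
        sample_ids = [s.sample_id for s in cohort.samples]
        fh.write(
            "gene_id\tmode\tchrom\tpos\tref\talt\t"
            + "\t".join(sample_ids) + "\n"
        )
        for entry in candidates:
            for v in entry.variants:
                i = cohort.variant_index(v)
                classes = [
                    cohort.calls[i][j].classify().value
                    for j in range(cohort.n_samples)
                ]
                fh.write(
                    f"{entry.gene_id}\t{entry.mode}\t{v.chrom}\t{v.pos}\t"
                    f"{v.ref}\t{v.alt}\t" + "\t".join(classes) + "\n"
                )


def write_consequences_tsv(records: list[ConsequenceRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\ttranscript\thgvs_c\tprotein\ttype\timpact\twt_len\tmut_len\n"
        )
        for r in records:
            fh.write(
                "\t".join(
                    str(x) if x is not None else "."
                    for x in (
                        r.gene_id, r.transcript_id, r.hgvs_c, r.protein_summary,
                        r.type, r.impact, r.wt_protein_len, r.mut_protein_len,
                    )
                ) + "\n"
            )


def annotate_candidates(
    candidates: CandidateSet,
    transcripts: list[TranscriptModel],
    reference,
) -> list[ConsequenceRecord]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    records = []
    for entry in candidates:
        for v in entry.variants:
            for t in by_gene.get(entry.gene_id, []):
                records.append(annotate_variant(v, t, reference))
    return records


def phase_candidates(
    candidates: CandidateSet,
    cohort: CohortGenotypes,
    observations: dict[tuple[str, str], list],
    noise_fraction: float = 0.05,
) -> dict[tuple[str, str], PhaseCall]:
    """Phase every double-het case over each candidate gene's variant pair."""
    calls: dict[tuple[str, str], PhaseCall] = {}
    for entry in candidates:
        for sample_id, rule in entry.per_case_evidence.items():
            if rule != "compound_het":
                continue
            obs = observations.get((sample_id, entry.gene_id))
            if not obs:
                continue
            # the amplicon design fixes the site pair: anchor and partner
            sites = {}
            for o in obs:
                sites[o.anchor_site.key] = o.anchor_site
                sites[o.observed_site.key] = o.observed_site
            if len(sites) != 2:
                continue
            site_a, site_b = sites.values()
            calls[(sample_id, entry.gene_id)] = infer_phase(
                obs, site_a, site_b, noise_fraction=noise_fraction
            )
    return calls


def confirmed_candidate_genes(
    candidates: CandidateSet,
    phase_calls: dict[tuple[str, str], PhaseCall],
) -> list[str]:
    """Candidate genes whose compound-het evidence (if any) phases trans.

    A gene is rejected when every compound-het case with a phase call comes
    back cis; ambiguous or missing calls leave the gene standing (phase can
    only refute, not establish, at this stage).
    """
    confirmed = []
    for entry in candidates:
        ch_calls = [
            phase_calls[(sid, entry.gene_id)]
            for sid, rule in entry.per_case_evidence.items()
            if rule == "compound_het" and (sid, entry.gene_id) in phase_calls
        ]
        if ch_calls and all(c.configuration == "cis" for c in ch_calls):
            continue
        confirmed.append(entry.gene_id)
    return confirmed


def run_pipeline(
    params: SimulationParams,
    outdir: str,
    seed: Optional[int] = None,
    filter_params: FilterParams = FilterParams(),
    noise_fraction: float = 0.05,
) -> PipelineResult:
    """Simulate a cohort into ``outdir`` and run discovery end to end."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = params.seed if seed is None else seed

    reference, transcripts = simulate_reference(params, seed)
    cohort, samples, truth, amplicons = simulate_cohort(
        params, reference, transcripts, seed
    )
    mio.write_fasta(reference, out / "ref.fa")
    mio.write_gff3(transcripts, out / "genes.gff3")
    mio.write_vcf(cohort, out / "cohort.vcf")
    mio.write_sample_sheet(samples, out / "samples.tsv")
    write_observations(amplicons, out / "amplicons.tsv")
    (out / "truth.json").write_text(truth.to_json())
    logger.info(
        "simulate: genes=%d variants=%d samples=%d causal_gene=%s",
        len(transcripts), cohort.n_variants, cohort.n_samples,
        truth.causal_gene_id,
    )

    reference = mio.read_fasta(out / "ref.fa")
    transcripts = mio.read_gff3(out / "genes.gff3", reference)
    cohort = mio.read_vcf(out / "cohort.vcf",
                          samples=mio.read_sample_sheet(out / "samples.tsv"))
    observations = read_observations(out / "amplicons.tsv")

    n_depth_pass = sum(
        1 for row in cohort.calls for c in row if passes_depth(c, filter_params)
    )
    candidates = recessive_candidates(cohort, transcripts, filter_params)
    logger.info(
        "filter: variants_in=%d depth_passing_calls=%d genes_tested=%d "
        "candidates=%d",
        cohort.n_variants, n_depth_pass,
        len({t.gene_id for t in transcripts}), len(candidates),
    )
    write_candidates_tsv(candidates, cohort, out / "candidates.tsv")

    consequences = annotate_candidates(candidates, transcripts, reference)
    logger.info(
        "annotate: candidate_variants=%d records=%d high_impact=%d",
        sum(len(e.variants) for e in candidates), len(consequences),
        sum(1 for r in consequences if r.impact == "HIGH"),
    )
    write_consequences_tsv(consequences, out / "consequences.tsv")

    phase_calls = phase_candidates(candidates, cohort, observations,
                                   noise_fraction)
    logger.info(
        "phase: double_het_calls=%d trans=%d cis=%d ambiguous=%d",
        len(phase_calls),
        *(sum(1 for c in phase_calls.values() if c.configuration == k)
          for k in ("trans", "cis", "ambiguous")),
    )
    confirmed = confirmed_candidate_genes(candidates, phase_calls)

    table = concordance = None
    if truth.causal_variants:
        table = genotype_table(cohort, truth.causal_variants)
        concordance = concordance_with_recessive_model(table, {"affected"})
        logger.info(
            "report: biallelic_cases=%d wildtype_controls=%d "
            "carrier_controls=%d discordant=%d",
            concordance.n_biallelic_cases, concordance.n_wildtype_controls,
            concordance.n_carrier_controls, concordance.n_discordant,
        )
    _write_report(out / "report.txt", candidates, confirmed, phase_calls,
                  table, concordance)
    return PipelineResult(
        candidates=candidates, consequences=consequences,
        phase_calls=phase_calls, table=table, concordance=concordance,
        truth=truth, confirmed_genes=confirmed,
    )


def _write_report(
    path,
    candidates: CandidateSet,
    confirmed: list[str],
    phase_calls,
    table: Optional[GenotypeTable],
    concordance: Optional[ConcordanceSummary],
) -> None:
    lines = ["candidate genes (recessive filter):"]
    if not candidates.entries:
        lines.append("  none")
    for e in candidates:
        status = "confirmed" if e.gene_id in confirmed else "rejected (cis)"
        lines.append(
            f"  {e.gene_id}\tmode={e.mode}\tvariants={len(e.variants)}\t{status}"
        )
    if phase_calls:
        lines.append("phase calls:")
        for (sid, gene), call in sorted(phase_calls.items()):
            lines.append(f"  {sid}\t{gene}\t{call.configuration}")
    if table is not None:
        lines.append("genotype table:")
        lines.append(table.to_dataframe().to_string(index=False))
    if concordance is not None:
        lines.append(
            "concordance: "
            f"biallelic_cases={concordance.n_biallelic_cases} "
            f"wildtype_controls={concordance.n_wildtype_controls} "
            f"carrier_controls={concordance.n_carrier_controls} "
            f"discordant={concordance.n_discordant}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
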