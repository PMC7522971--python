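"""Genotype tabulation and recessive-model concordance summaries.

Produces the classic two-site genotyping table (phenotype x genotype pair
with sample counts) and a concordance summary against a recessive model:
affected samples should carry two mutant alleles (homozygous at one site or
heterozygous at both, trans pending phase confirmation), unaffected samples
at most one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .models import CohortGenotypes, GenotypeClass, Variant


class ReportError(ValueError):
    """Requested site absent from the cohort or table malformed."""


@dataclass
class GenotypeTable:
    sites: list[Variant]
    site_labels: list[str]
    #: (phenotype_label, genotype at site 1, genotype at site 2, n_samples)
    rows: list[tuple[str, str, str, int]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return sum(r[-1] for r in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "phenotype",
                f"genotype_{self.site_labels[0]}",
                f"genotype_{self.site_labels[1]}",
                "n_samples",
            ],
        )


@dataclass
class ConcordanceSummary:
    n_biallelic_cases: int = 0
    n_wildtype_controls: int = 0
    n_carrier_controls: int = 0
    n_discordant: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_biallelic_cases + self.n_wildtype_controls
            + self.n_carrier_controls + self.n_discordant
        )


def _allele_label(variant: Variant, explicit: Optional[str]) -> str:
    if explicit:
        return explicit
    vid = variant.id or ""
    for tag in ("del", "dup", "ins"):
        if tag in vid:
            return tag
    return "alt"


def _render(cls: GenotypeClass, label: str) -> str:
    return {
        GenotypeClass.HOM_REF: "+/+",
        GenotypeClass.HET: f"+/{label}",
        GenotypeClass.HOM_ALT: f"{label}/{label}",
        GenotypeClass.MISSING: "./.",
    }[cls]


def genotype_table(
    cohort: CohortGenotypes,
    sites: list[Variant],
    site_labels: Optional[list[str]] = None,
) -> GenotypeTable:
    """Tabulate samples by (phenotype, genotype pair) at two sites.

    Genotypes are rendered ``+/+``, ``+/<label>``, ``<label>/<label>``; the
    label defaults to a tag inferred from the variant id (``del``/``dup``)
    or ``alt``. Rows are sorted by phenotype then genotypes; every sample
    is counted exactly once.
    """
    if len(sites) != 2:
        raise ReportError(f"expected 2 sites, got {len(sites)}")
    try:
        idx = [cohort.variant_index(s) for s in sites]
    except KeyError as exc:
        raise ReportError(str(exc)) from exc
    labels = [
        _allele_label(s, site_labels[k] if site_labels else None)
        for k, s in enumerate(sites)
    ]
    counts: dict[tuple[str, str, str], int] = {}
    for j, sample in enumerate(cohort.samples):
        gts = tuple(
            _render(cohort.calls[i][j].classify(), labels[k])
            for k, i in enumerate(idx)
        )
        key = (sample.phenotype_label, *gts)
        counts[key] = counts.get(key, 0) + 1
    rows = [(*key, n) for key, n in sorted(counts.items())]
    return GenotypeTable(sites=list(sites), site_labels=labels, rows=rows)


def _mutant_alleles(gt: str, label: str) -> Optional[int]:
    if gt == "./.":
        return None
    return sum(1 for a in gt.split("/") if a == label)


def concordance_with_recessive_model(
    table: GenotypeTable, case_phenotypes: Iterable[str]
) -> ConcordanceSummary:
    """Score a two-site genotype table against a recessive model.

    A sample is biallelic iff homozygous mutant at either site or
    heterozygous at both (trans assumed pending phase confirmation).
    Controls with exactly one mutant allele are carriers and remain
    concordant; discordant samples are cases lacking two mutant alleles
    and controls carrying two.
    """
    cases = set(case_phenotypes)
    out = ConcordanceSummary()
    for phenotype, gt1, gt2, n in table.rows:
        m1 = _mutant_alleles(gt1, table.site_labels[0])
        m2 = _mutant_alleles(gt2, table.site_labels[1])
        a1 = m1 or 0
        a2 = m2 or 0
        biallelic = a1 == 2 or a2 == 2 or (a1 >= 1 and a2 >= 1)
        if phenotype in cases:
            if biallelic:
                out.n_biallelic_cases += n
            else:
                out.n_discordant += n
        else:
            if biallelic:
                out.n_discordant += n
            elif a1 + a2 == 1:
                out.n_carrier_controls += n
            else:
                out.n_wildtype_controls += n
    return out
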