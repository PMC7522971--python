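"""Shared fixtures: toy transcripts and random-cohort builders."""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

from minkmap.models import (
    CohortGenotypes,
    GenotypeCall,
    ReferenceSequences,
    Role,
    Sample,
    TranscriptModel,
    Variant,
    reverse_complement,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_plus():
    """Single-exon plus-strand transcript: CDS ATG AAA CCC GGG TTT TAA.

    CDS occupies genomic 0-based [10, 28) on a 60 nt contig; 10 nt of
    leading sequence and a trailing 3' tail usable as UTR.
    """
    cds = "ATGAAACCCGGGTTTTAA"
    genome = "GATTACAGAT" + cds + "ACGTACGTACGTACGTACGTACGTACGTACGT"
    ref = ReferenceSequences()
    ref["chrP"] = genome
    model = TranscriptModel(
        gene_id="toyP", transcript_id="toyP.t1", chrom="chrP", strand="+",
        exons=[(10, 28 + 12)], cds_intervals=[(10, 28)],
    )
    return ref, model


@pytest.fixture
def toy_minus(toy_plus):
    """Mirror of ``toy_plus`` on the minus strand of the revcomp contig."""
    ref_p, model_p = toy_plus
    genome = ref_p["chrP"]
    L = len(genome)
    ref = ReferenceSequences()
    ref["chrM"] = reverse_complement(genome)

    def flip(iv):
        s, e = iv
        return (L - e, L - s)

    model = TranscriptModel(
        gene_id="toyM", transcript_id="toyM.t1", chrom="chrM", strand="-",
        exons=sorted(flip(iv) for iv in model_p.exons),
        cds_intervals=sorted(flip(iv) for iv in model_p.cds_intervals),
    )
    return ref, model


def random_cohort(rng: random.Random, n_variants=None, n_samples=None) -> CohortGenotypes:
    """A random cohort for round-trip and counting properties."""
    n_variants = rng.randint(0, 8) if n_variants is None else n_variants
    n_samples = rng.randint(1, 5) if n_samples is None else n_samples
    positions = rng.sample(range(1, 10_000), n_variants)
    variants = []
    for k, pos in enumerate(sorted(positions)):
        ref = rng.choice(["A", "C", "G", "T", "AT", "ACT"])
        alt = rng.choice([b for b in ["A", "C", "G", "T", "TG"] if b != ref])
        variants.append(Variant("chr1", pos, ref, alt, id=f"v{k}" if rng.random() < 0.5 else None))
    samples = [
        Sample(f"s{j}", rng.choice(["affected", "unaffected", ""]),
               rng.choice(list(Role)))
        for j in range(n_samples)
    ]
    calls = []
    for _ in range(n_variants):
        row = []
        for _ in range(n_samples):
            if rng.random() < 0.1:
                row.append(GenotypeCall(None, None, None))
            else:
                a, b = rng.choice([(0, 0), (0, 1), (1, 0), (1, 1)])
                dp = rng.choice([None, 0, 2, 3, 15, 40])
                row.append(GenotypeCall(a, b, depth=dp, phased=rng.random() < 0.2))
        calls.append(row)
    return CohortGenotypes(variants, samples, calls)
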