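"""Synthetic cohort generator with a planted recessive causal gene.

Emulates the statistical structure of a small case/control resequencing
study: a reference genome with a handful of multi-exon genes on mixed
strands, one gene carrying a pair of loss-of-function candidate mutations
(a short duplication early in the CDS and a 16-nt deletion late in it),
affected samples carrying two mutant alleles each (homozygous or compound
heterozygous in trans), unaffected samples carrying at most one, and rare
background variation whose genotype frequencies are independent of
case/control status. Per-genotype read depths follow a Poisson model and
genotypes can be masked missing at a configurable rate.

Default cohort composition mirrors the study design this emulates: two
affected genomes against six unaffected ones, mean depth near the cohort
mean of that study's eight genomes, and a control carrier rate of about one
carrier among 27 unaffected animals. Background allele frequencies default
to a rare spectrum (0.1-1%) so that background genotype patterns mimicking
recessive segregation in two cases are themselves rare and the planted gene
is, by design, the expected unique survivor of the filter; commoner
background variation can be dialled in via ``background_af_range``.

A single integer seed drives everything; it is split into named substreams
(reference, variants, genotypes, depth, missingness, amplicons) so
changing one knob does not scramble unrelated draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genebuild import (
    assemble_gene,
    cds_deletion_variant,
    cds_duplication_variant,
    pick_intraexon_range,
)
from .models import (
    STOP_CODONS,
    CohortGenotypes,
    GenotypeCall,
    MISSING_CALL,
    ReferenceSequences,
    Role,
    Sample,
    TranscriptModel,
    Variant,
)
from .phase import AmpliconObservation

CAUSAL_CONFIGS = ("hom_del", "hom_dup", "compound_het", "mixed_per_case")

_STREAMS = {
    "reference": 1, "variants": 2, "genotypes": 3,
    "depth": 4, "missingness": 5, "amplicons": 6,
}


class ParameterError(ValueError):
    """Simulation parameters are invalid or mutually infeasible."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    if seed < 0:
        raise ParameterError(f"seed must be non-negative, got {seed}")
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[stream]]))


@dataclass(frozen=True)
class SimulationParams:
    """Study-design knobs of the synthetic cohort.

    ``depth_mean`` is the Poisson mean of per-genotype read depth (the
    cohort mean coverage). ``carrier_rate_in_controls`` is the probability
    that an unaffected sample carries a single causal allele.
    ``causal_config`` fixes the mechanism per case: ``mixed_per_case``
    cycles hom-deletion, hom-duplication, compound-het across cases.
    ``missing_rate`` masks genotypes independently of everything else;
    the default is 0 because at these depths true no-calls are rare —
    raise it to stress the filter. ``n_cis_decoys`` plants, in that many
    non-causal genes, a cis double-het pair in the first case: such genes
    survive the unphased discovery filter and must be rejected by phase
    inference, not by the filter.
    """

    n_genes: int = 5
    n_background_variants: int = 70
    n_cases: int = 2
    n_controls: int = 6
    causal_config: str = "mixed_per_case"
    carrier_rate_in_controls: float = 0.04
    depth_mean: float = 11.0
    missing_rate: float = 0.0
    seed: int = 0
    background_af_range: tuple[float, float] = (0.001, 0.01)
    n_cis_decoys: int = 0
    amplicon_reads: int = 200
    amplicon_noise: float = 0.01

    def __post_init__(self) -> None:
        for name in ("carrier_rate_in_controls", "missing_rate", "amplicon_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ParameterError("need n_cases >= 1 and n_controls >= 1")
        if self.causal_config not in CAUSAL_CONFIGS:
            raise ParameterError(
                f"causal_config must be one of {CAUSAL_CONFIGS}, "
                f"got {self.causal_config!r}"
            )
        if self.depth_mean <= 0:
            raise ParameterError("depth_mean must be positive")
        if self.n_genes < 0 or self.n_background_variants < 0:
            raise ParameterError("counts must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort."""

    causal_gene_id: Optional[str]
    causal_variants: list[Variant]
    #: sample_id -> {variant str -> (allele_a, allele_b)} before masking
    genotypes: dict[str, dict[str, tuple[int, int]]]
    #: sample_id -> {gene_id -> "cis" | "trans"} for double-het variant pairs
    phase: dict[str, dict[str, str]]
    decoy_gene_ids: list[str] = field(default_factory=list)
    decoy_variants: dict[str, list[Variant]] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, Variant):
                return str(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)


# ---------------------------------------------------------------------------
# reference simulation

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(body) + stop


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_reference(
    params: SimulationParams, seed: Optional[int] = None
) -> tuple[ReferenceSequences, list[TranscriptModel]]:
    """Random single-contig genome with multi-exon genes on mixed strands.

    Deterministic given (params, seed): the same inputs produce the same
    sequences byte-for-byte. Each gene has a valid CDS (ATG start, stop
    end, length a multiple of 3) and a 3' UTR long enough for frameshift
    stop scans.
    """
    rng = _rng(params.seed if seed is None else seed, "reference")
    chrom = "ctg1"
    pieces: list[str] = [_random_bases(rng, 100)]
    cursor = 100
    transcripts: list[TranscriptModel] = []
    for g in range(params.n_genes):
        n_codons = int(rng.integers(50, 101))
        cds = _random_cds(rng, n_codons)
        utr5 = _random_bases(rng, int(rng.integers(10, 31)))
        utr3 = _random_bases(rng, int(rng.integers(150, 221)))
        spliced = utr5 + cds + utr3
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, len(spliced)), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), len(spliced)]
        exon_seqs = [spliced[a:b] for a, b in zip(bounds, bounds[1:])]
        intron_seqs = [
            _random_bases(rng, int(rng.integers(60, 121)))
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{g + 1:03d}"
        piece, model = assemble_gene(
            gene_id, f"{gene_id}.t1", chrom, strand, cursor,
            exon_seqs, intron_seqs,
            cds_spliced_range=(len(utr5), len(utr5) + len(cds)),
        )
        pieces.append(piece)
        cursor += len(piece)
        gap = _random_bases(rng, int(rng.integers(80, 151)))
        pieces.append(gap)
        cursor += len(gap)
        transcripts.append(model)
    reference = ReferenceSequences()
    reference[chrom] = "".join(pieces)
    return reference, transcripts


# ---------------------------------------------------------------------------
# cohort simulation

DELETION_LENGTH = 16
DUPLICATION_LENGTH = 2


def _causal_sites(
    transcript: TranscriptModel, reference: ReferenceSequences
) -> tuple[Variant, Variant]:
    """Plant the two causal mutations in one gene.

    A short duplication early in the CDS and a frameshifting deletion about
    two-thirds of the way in, each within a single exon.
    """
    cds_len = transcript.cds_length
    dup_s, dup_e = pick_intraexon_range(transcript, DUPLICATION_LENGTH, 20)
    del_s, del_e = pick_intraexon_range(
        transcript, DELETION_LENGTH, (cds_len * 2) // 3
    )
    gid = transcript.gene_id
    dup = cds_duplication_variant(transcript, reference, dup_s, dup_e,
                                  variant_id=f"{gid}_dup")
    dele = cds_deletion_variant(transcript, reference, del_s, del_e,
                                variant_id=f"{gid}_del")
    return dele, dup


def _case_mechanism(config: str, case_index: int) -> str:
    if config == "mixed_per_case":
        return ("hom_del", "hom_dup", "compound_het")[case_index % 3]
    return config


def simulate_amplicons(
    site_a: Variant,
    site_b: Variant,
    truth_phase: str,
    rng: np.random.Generator,
    n_reads: int = 200,
    noise: float = 0.01,
) -> list[AmpliconObservation]:
    """Allele-specific amplicon read counts for one double-het sample.

    Two anchor classes at ``site_b`` (one per allele); each read reports
    the partner allele on the anchored haplotype, flipped with probability
    ``noise`` (allele dropout / mispriming).
    """
    obs = []
    for anchor_allele in ("alt", "ref"):
        if truth_phase == "trans":
            true_obs = "ref" if anchor_allele == "alt" else "alt"
        else:
            true_obs = "alt" if anchor_allele == "alt" else "ref"
        flips = int(rng.binomial(n_reads, noise))
        counts = {true_obs: n_reads - flips,
                  ("ref" if true_obs == "alt" else "alt"): flips}
        for observed, n in counts.items():
            if n > 0:
                obs.append(
                    AmpliconObservation(
                        anchor_site=site_b, anchor_allele=anchor_allele,
                        observed_site=site_a, observed_allele=observed,
                        read_support=n,
                    )
                )
    return obs


def simulate_cohort(
    params: SimulationParams,
    reference: ReferenceSequences,
    transcripts: list[TranscriptModel],
    seed: Optional[int] = None,
) -> tuple[
    CohortGenotypes, list[Sample], TruthRecord,
    dict[tuple[str, str], list[AmpliconObservation]],
]:
    """Plant a recessive causal gene and draw a case/control cohort.

    Returns the cohort (with depth and missingness applied), the sample
    sheet, the ground truth (pre-masking genotypes and phase), and
    allele-specific amplicon observations keyed by (sample_id, gene_id)
    for every sample heterozygous at both variants of a planted pair.
    """
    seed = params.seed if seed is None else seed
    vrng = _rng(seed, "variants")
    grng = _rng(seed, "genotypes")
    drng = _rng(seed, "depth")
    mrng = _rng(seed, "missingness")
    arng = _rng(seed, "amplicons")

    samples = [
        *(Sample(f"case_{i + 1:02d}", "affected", Role.CASE)
          for i in range(params.n_cases)),
        *(Sample(f"ctrl_{i + 1:02d}", "unaffected", Role.CONTROL)
          for i in range(params.n_controls)),
    ]
    n = len(samples)
    chrom = next(iter(reference))
    genome = reference[chrom]

    eligible = [t for t in transcripts if t.cds_length >= 90]
    causal_variants: list[Variant] = []
    truth_gt: dict[str, dict[str, tuple[int, int]]] = {
        s.sample_id: {} for s in samples
    }
    truth_phase: dict[str, dict[str, str]] = {}
    causal_gene: Optional[str] = None
    decoy_genes: list[str] = []
    decoy_variants: dict[str, list[Variant]] = {}
    rows: list[tuple[Variant, list[tuple[Optional[int], Optional[int]]]]] = []

    if transcripts:
        if not eligible:
            raise ParameterError(
                "no gene has a CDS long enough to host the causal variant pair"
            )
        causal_tx = eligible[int(vrng.integers(len(eligible)))]
        causal_gene = causal_tx.gene_id
        del_v, dup_v = _causal_sites(causal_tx, reference)
        causal_variants = [del_v, dup_v]

        del_gts: list[tuple[int, int]] = []
        dup_gts: list[tuple[int, int]] = []
        for i, s in enumerate(samples):
            if s.role == Role.CASE:
                mech = _case_mechanism(params.causal_config, i)
                if mech == "hom_del":
                    dgt, pgt = (1, 1), (0, 0)
                elif mech == "hom_dup":
                    dgt, pgt = (0, 0), (1, 1)
                else:
                    dgt, pgt = (0, 1), (1, 0)  # trans by construction
                    truth_phase.setdefault(s.sample_id, {})[causal_gene] = "trans"
            else:
                dgt = pgt = (0, 0)
                if grng.random() < params.carrier_rate_in_controls:
                    if grng.random() < 0.5:
                        dgt = (0, 1)
                    else:
                        pgt = (0, 1)
            del_gts.append(dgt)
            dup_gts.append(pgt)
            truth_gt[s.sample_id][str(del_v)] = dgt
            truth_gt[s.sample_id][str(dup_v)] = pgt
        rows.append((del_v, del_gts))
        rows.append((dup_v, dup_gts))

        # cis decoys: a non-causal gene where every case is het at two SNVs
        # on the same haplotype — survives the unphased filter, refuted by
        # phase inference
        others = [t for t in transcripts if t.gene_id != causal_gene]
        if params.n_cis_decoys > len(others):
            raise ParameterError(
                f"{params.n_cis_decoys} cis decoys requested but only "
                f"{len(others)} non-causal genes exist"
            )
        for t in others[: params.n_cis_decoys]:
            pos_list = t.cds_genomic_positions()
            p1, p2 = sorted((pos_list[10], pos_list[40]))
            pair = []
            for k, p in enumerate((p1, p2)):
                ref_base = genome[p]
                alt_base = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
                pair.append(
                    Variant(chrom, p + 1, ref_base, alt_base,
                            id=f"{t.gene_id}_decoy{k + 1}")
                )
            decoy_genes.append(t.gene_id)
            decoy_variants[t.gene_id] = pair
            for v in pair:
                gts = []
                for s in samples:
                    gt = (0, 1) if s.role == Role.CASE else (0, 0)
                    gts.append(gt)
                    truth_gt[s.sample_id][str(v)] = gt
                rows.append((v, gts))
            for s in samples:
                if s.role == Role.CASE:
                    truth_phase.setdefault(s.sample_id, {})[t.gene_id] = "cis"

    # background SNVs, genotype frequencies independent of status
    blocked = set()
    for v, _ in rows:
        blocked.update(range(v.pos - 1, v.pos - 1 + len(v.ref) + 1))
    candidates = np.array(
        [p for p in range(len(genome)) if p not in blocked and genome[p] != "N"]
    )
    n_bg = min(params.n_background_variants, len(candidates))
    positions = sorted(
        int(p) for p in vrng.choice(candidates, size=n_bg, replace=False)
    )
    lo, hi = params.background_af_range
    for k, p in enumerate(positions):
        ref_base = genome[p]
        alt_base = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
        v = Variant(chrom, p + 1, ref_base, alt_base, id=f"bg{k + 1:04d}")
        af = lo + (hi - lo) * vrng.random()
        gts = []
        for s in samples:
            n_alt = int(grng.binomial(2, af))
            gt = ((0, 0), (0, 1), (1, 1))[n_alt]
            gts.append(gt)
            truth_gt[s.sample_id][str(v)] = gt
        rows.append((v, gts))

    # depth and missingness
    variants = [v for v, _ in rows]
    calls = []
    for v, gts in rows:
        depths = drng.poisson(params.depth_mean, size=n)
        row = []
        for j, gt in enumerate(gts):
            if params.missing_rate > 0 and mrng.random() < params.missing_rate:
                row.append(MISSING_CALL)
            else:
                row.append(GenotypeCall(gt[0], gt[1], depth=int(depths[j])))
        calls.append(row)

    cohort = CohortGenotypes(variants, samples, calls)
    truth = TruthRecord(
        causal_gene_id=causal_gene,
        causal_variants=causal_variants,
        genotypes=truth_gt,
        phase=truth_phase,
        decoy_gene_ids=decoy_genes,
        decoy_variants=decoy_variants,
    )

    amplicons: dict[tuple[str, str], list[AmpliconObservation]] = {}
    pairs = [(causal_gene, tuple(causal_variants))] if causal_variants else []
    pairs += [(g, tuple(pv)) for g, pv in decoy_variants.items()]
    for s in samples:
        for gene_id, (site_a, site_b) in pairs:
            g = truth_gt[s.sample_id]
            if g.get(str(site_a)) in ((0, 1), (1, 0)) and (
                g.get(str(site_b)) in ((0, 1), (1, 0))
            ):
                phase = truth_phase.get(s.sample_id, {}).get(gene_id, "trans")
                amplicons[(s.sample_id, gene_id)] = simulate_amplicons(
                    site_a, site_b, phase, arng,
                    n_reads=params.amplicon_reads,
                    noise=params.amplicon_noise,
                )
    return cohort, samples, truth, amplicons
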