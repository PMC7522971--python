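"""Cis/trans phase inference from allele-specific amplicon observations.

Models the allele-specific RT-PCR design: a primer anchored on one allele
of one variant amplifies only the haplotype carrying that allele, and the
amplicon reveals which allele of the partner variant rides on the same
chromosome. An anchor on the ALT allele observing REF at the partner site
means the two mutant alleles sit on different chromosomes (trans) — the
configuration a recessive compound heterozygote requires; observing ALT
means cis.

The experimental readout is generalized to counted observations with a
noise threshold so mixed or contaminated amplicon pools give an explicit
``ambiguous`` call rather than a coin flip.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field

from .models import Variant


class PhaseError(ValueError):
    """Observations unusable for phasing the requested site pair."""


@dataclass(frozen=True)
class AmpliconObservation:
    """Reads from one allele-specific amplicon class.

    ``anchor_allele`` / ``observed_allele`` are "ref" or "alt";
    ``read_support`` is the number of reads (or traces) in this class.
    """

    anchor_site: Variant
    anchor_allele: str
    observed_site: Variant
    observed_allele: str
    read_support: int = 1

    def __post_init__(self) -> None:
        for a in (self.anchor_allele, self.observed_allele):
            if a not in ("ref", "alt"):
                raise ValueError(f"allele must be 'ref' or 'alt', got {a!r}")
        if self.anchor_site.key == self.observed_site.key:
            raise ValueError("anchor and observed site must differ")
        if self.read_support <= 0:
            raise ValueError(f"read_support must be positive, got {self.read_support}")


@dataclass
class PhaseCall:
    configuration: str  # "cis" | "trans" | "ambiguous"
    evidence: list[AmpliconObservation] = field(default_factory=list)
    low_confidence: bool = False
    reason: str = ""


def _class_vote(anchor_allele: str, observed_allele: str) -> str:
    """Phase implied by a consistent (anchor, observed) class.

    An ALT-anchored amplicon reads the haplotype carrying the mutant
    anchor; a REF-anchored amplicon reads the other haplotype, so its
    implication flips.
    """
    if anchor_allele == "alt":
        return "cis" if observed_allele == "alt" else "trans"
    return "trans" if observed_allele == "alt" else "cis"


def infer_phase(
    observations: list[AmpliconObservation],
    site_a: Variant,
    site_b: Variant,
    noise_fraction: float = 0.05,
) -> PhaseCall:
    """Call the cis/trans configuration of two heterozygous variants.

    Observations are grouped by (anchor site, anchor allele); within each
    class the majority observed allele casts that class's vote, and a
    class whose minority fraction exceeds ``noise_fraction`` poisons the
    call (``ambiguous``). Votes from all classes must agree; a call backed
    by a single anchor class is returned with ``low_confidence=True``.
    """
    if not 0 <= noise_fraction < 0.5:
        raise PhaseError(f"noise_fraction must be in [0, 0.5), got {noise_fraction}")
    if not observations:
        raise PhaseError("no observations")
    keys = {site_a.key, site_b.key}
    classes: dict[tuple, dict[str, int]] = defaultdict(lambda: {"ref": 0, "alt": 0})
    for obs in observations:
        if obs.anchor_site.key not in keys or obs.observed_site.key not in keys:
            raise PhaseError(
                f"observation anchored at {obs.anchor_site} does not link "
                f"{site_a} and {site_b}"
            )
        classes[(obs.anchor_site.key, obs.anchor_allele)][
            obs.observed_allele
        ] += obs.read_support

    votes = set()
    for (anchor_key, anchor_allele), counts in classes.items():
        total = counts["ref"] + counts["alt"]
        majority = "alt" if counts["alt"] > counts["ref"] else "ref"
        if counts["ref"] == counts["alt"]:
            return PhaseCall("ambiguous", list(observations),
                             reason=f"tied counts in {anchor_allele}-anchored class")
        minority = min(counts.values()) / total
        if minority > noise_fraction:
            return PhaseCall(
                "ambiguous", list(observations),
                reason=(
                    f"minority fraction {minority:.3f} exceeds noise threshold "
                    f"{noise_fraction} in {anchor_allele}-anchored class"
                ),
            )
        votes.add(_class_vote(anchor_allele, majority))

    if len(votes) != 1:
        return PhaseCall("ambiguous", list(observations),
                         reason="anchor classes disagree")
    single_class = len(classes) == 1
    return PhaseCall(
        votes.pop(),
        list(observations),
        low_confidence=single_class,
        reason="single anchor class" if single_class else "",
    )


# ---------------------------------------------------------------------------
# observation TSV interface

OBS_COLUMNS = (
    "sample_id", "gene_id", "anchor_site", "anchor_allele",
    "observed_site", "observed_allele", "read_support",
)


def parse_site(text: str) -> Variant:
    """Parse a ``chrom:pos:ref:alt`` site descriptor."""
    parts = text.split(":")
    if len(parts) != 4:
        raise PhaseError(f"site {text!r} is not chrom:pos:ref:alt")
    chrom, pos, ref, alt = parts
    return Variant(chrom, int(pos), ref.upper(), alt.upper())


def _site_str(v: Variant) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


def write_observations(
    groups: dict[tuple[str, str], list[AmpliconObservation]], path: str
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(OBS_COLUMNS)
        for (sample_id, gene_id), observations in sorted(groups.items()):
            for o in observations:
                w.writerow([
                    sample_id, gene_id, _site_str(o.anchor_site),
                    o.anchor_allele, _site_str(o.observed_site),
                    o.observed_allele, o.read_support,
                ])


def read_observations(
    path: str,
) -> dict[tuple[str, str], list[AmpliconObservation]]:
    groups: dict[tuple[str, str], list[AmpliconObservation]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if tuple(reader.fieldnames or ()) != OBS_COLUMNS:
            raise PhaseError(
                f"{path}: expected columns {OBS_COLUMNS}, got {reader.fieldnames}"
            )
        for row in reader:
            obs = AmpliconObservation(
                anchor_site=parse_site(row["anchor_site"]),
                anchor_allele=row["anchor_allele"],
                observed_site=parse_site(row["observed_site"]),
                observed_allele=row["observed_allele"],
                read_support=int(row["read_support"]),
            )
            groups.setdefault((row["sample_id"], row["gene_id"]), []).append(obs)
    return groups
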