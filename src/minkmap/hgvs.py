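"""HGVS coding-DNA (c.) variant representation, parsing and formatting.

Supports the subset of HGVS needed for CDS-level consequence prediction:
substitutions, deletions, duplications, insertions and delins, all with
plain CDS coordinates (position 1 = the A of ATG). Intron-offset notation
(``c.88+2T>G``) is out of dialect and rejected explicitly.

Ranges accept both the standard underscore separator (``c.574_589del``) and
a hyphen between two plain integers (``c.574-589del``), a dialect that
occurs in the wild; the hyphen form is never emitted. A hyphenated
"range" whose second coordinate is not greater than the first is taken for
an intron offset and rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

KINDS = ("substitution", "deletion", "duplication", "insertion", "delins")


class HgvsParseError(ValueError):
    """Text is not parseable in the supported HGVS c. dialect."""


@dataclass(frozen=True)
class CodingVariant:
    """An edit in 1-based CDS coordinates.

    For deletions/delins/substitutions, ``cds_start..cds_end`` (inclusive)
    is the replaced reference segment. For duplications it is the segment
    being duplicated (the copy is inserted after ``cds_end``). For plain
    insertions ``cds_start == cds_end`` is the base after which
    ``inserted_seq`` is inserted.

    ``inserted_seq`` may be empty for a duplication parsed from text without
    an explicit sequence; :meth:`inserted_len` accounts for that.
    ``ref_seq`` optionally records the deleted/substituted reference bases.
    """

    kind: str
    cds_start: int
    cds_end: int
    inserted_seq: str = ""
    ref_seq: Optional[str] = None
    gene: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not 1 <= self.cds_start <= self.cds_end:
            raise ValueError(
                f"invalid CDS range {self.cds_start}..{self.cds_end}"
            )
        span = self.cds_end - self.cds_start + 1
        if self.kind == "substitution":
            if span != 1 or len(self.inserted_seq) != 1:
                raise ValueError("substitution must replace a single base")
            if self.ref_seq is None or len(self.ref_seq) != 1:
                raise ValueError("substitution requires a single REF base")
            if self.ref_seq == self.inserted_seq:
                raise ValueError("substitution REF equals ALT")
        elif self.kind == "deletion":
            if self.inserted_seq:
                raise ValueError("deletion carries no inserted sequence")
            if self.ref_seq is not None and len(self.ref_seq) != span:
                raise ValueError(
                    f"deleted sequence length {len(self.ref_seq)} does not "
                    f"match range {self.cds_start}_{self.cds_end}"
                )
        elif self.kind == "duplication":
            if self.inserted_seq and len(self.inserted_seq) != span:
                raise ValueError(
                    f"duplicated sequence length {len(self.inserted_seq)} does "
                    f"not match range {self.cds_start}_{self.cds_end}"
                )
        elif self.kind == "insertion":
            if self.cds_start != self.cds_end:
                raise ValueError("insertion point must be a single position")
            if not self.inserted_seq:
                raise ValueError("insertion requires a sequence")
        elif self.kind == "delins":
            if not self.inserted_seq:
                raise ValueError("delins requires an inserted sequence")

    @property
    def deleted_len(self) -> int:
        """Number of reference CDS bases removed by the edit."""
        if self.kind in ("deletion", "delins", "substitution"):
            return self.cds_end - self.cds_start + 1
        return 0

    @property
    def inserted_len(self) -> int:
        """Number of bases added by the edit."""
        if self.kind == "duplication":
            return self.cds_end - self.cds_start + 1
        return len(self.inserted_seq)

    @property
    def net_length_change(self) -> int:
        return self.inserted_len - self.deleted_len

    @property
    def is_frameshift(self) -> bool:
        return self.net_length_change % 3 != 0


_HGVS_RE = re.compile(
    r"^(?:(?P<gene>[A-Za-z0-9_.()-]+):)?"
    r"c\.(?P<start>\d+)(?:(?P<sep>[_-])(?P<end>\d+))?(?P<rest>.*)$"
)
_SEQ = r"[ACGTacgt]+"


def parse_hgvs_c(text: str) -> CodingVariant:
    """Parse an HGVS c. description into a :class:`CodingVariant`.

    Raises :class:`HgvsParseError` for intron-offset notation, unknown edit
    types, or an explicit sequence whose length contradicts the range.
    """
    text = text.strip()
    m = _HGVS_RE.match(text)
    if m is None:
        if re.search(r"c\.\d+[+]", text) or re.search(r"c\.[*-]", text):
            raise HgvsParseError(
                f"{text!r}: intron/UTR-offset positions are not supported"
            )
        raise HgvsParseError(f"{text!r}: not a recognized HGVS c. description")
    gene = m.group("gene")
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    rest = m.group("rest")
    if re.match(r"^[+-]\d", rest):
        raise HgvsParseError(f"{text!r}: intron-offset positions are not supported")
    if m.group("sep") == "-" and end <= start:
        # "c.88-2..." is an intron offset, not a (degenerate) range
        raise HgvsParseError(f"{text!r}: intron-offset positions are not supported")
    if end < start:
        raise HgvsParseError(f"{text!r}: range end {end} before start {start}")
    span = end - start + 1

    sub = re.fullmatch(rf"(?P<ref>{_SEQ})>(?P<alt>{_SEQ})", rest)
    if sub:
        ref, alt = sub.group("ref").upper(), sub.group("alt").upper()
        if m.group("end") is not None or len(ref) != 1 or len(alt) != 1:
            raise HgvsParseError(
                f"{text!r}: only single-base substitutions are supported"
            )
        try:
            return CodingVariant("substitution", start, end, alt, ref_seq=ref,
                                 gene=gene)
        except ValueError as exc:
            raise HgvsParseError(f"{text!r}: {exc}") from exc

    delins = re.fullmatch(rf"delins(?P<seq>{_SEQ})", rest)
    if delins:
        return CodingVariant("delins", start, end,
                             delins.group("seq").upper(), gene=gene)

    dele = re.fullmatch(rf"del(?P<seq>{_SEQ})?", rest)
    if dele:
        seq = (dele.group("seq") or "").upper() or None
        if seq is not None and len(seq) != span:
            raise HgvsParseError(
                f"{text!r}: deleted sequence {seq} has length {len(seq)}, "
                f"range spans {span}"
            )
        return CodingVariant("deletion", start, end, ref_seq=seq, gene=gene)

    dup = re.fullmatch(rf"dup(?P<seq>{_SEQ})?", rest)
    if dup:
        seq = (dup.group("seq") or "").upper()
        if seq and len(seq) != span:
            raise HgvsParseError(
                f"{text!r}: duplicated sequence {seq} has length {len(seq)}, "
                f"range spans {span}"
            )
        return CodingVariant("duplication", start, end, seq, gene=gene)

    ins = re.fullmatch(rf"ins(?P<seq>{_SEQ})", rest)
    if ins:
        if end != start + 1:
            raise HgvsParseError(
                f"{text!r}: insertion requires flanking positions n_n+1"
            )
        return CodingVariant("insertion", start, start,
                             ins.group("seq").upper(), gene=gene)

    raise HgvsParseError(f"{text!r}: unsupported edit {rest!r}")


def format_hgvs_c(v: CodingVariant, with_gene: bool = False) -> str:
    """Format a :class:`CodingVariant` in standard HGVS (underscore ranges).

    ``parse_hgvs_c(format_hgvs_c(v)) == v`` holds for every valid variant.
    """
    prefix = f"{v.gene}:" if with_gene and v.gene else ""
    if v.kind == "substitution":
        return f"{prefix}c.{v.cds_start}{v.ref_seq}>{v.inserted_seq}"
    if v.cds_start == v.cds_end:
        rng = str(v.cds_start)
    else:
        rng = f"{v.cds_start}_{v.cds_end}"
    if v.kind == "deletion":
        return f"{prefix}c.{rng}del{v.ref_seq or ''}"
    if v.kind == "duplication":
        return f"{prefix}c.{rng}dup{v.inserted_seq}"
    if v.kind == "insertion":
        return f"{prefix}c.{v.cds_start}_{v.cds_start + 1}ins{v.inserted_seq}"
    return f"{prefix}c.{rng}delins{v.inserted_seq}"
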