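"""Pipe-delimited TE locus identifiers.

A TE copy is identified by a six-field, pipe-delimited string such as

    chr4|134162050|134163888|MuLV-int:ERV1:LTR|68|+

with fields chromosome, 0-based start, end (half-open), a colon-joined
subfamily:family:class triple, an integer score, and the strand.  The
identifier doubles as the BED name field of the TE annotation, so it
must survive a parse/format round trip byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TEID", "TEIDError", "parse_te_id", "format_te_id"]


class TEIDError(ValueError):
    """Raised when a TE identifier string cannot be parsed."""


@dataclass(frozen=True, slots=True)
class TEID:
    chrom: str
    start: int
    end: int
    subfamily: str
    family: str
    te_class: str
    score: int
    strand: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_te_id(self)


def parse_te_id(text: str) -> TEID:
    """Parse a pipe-delimited TE identifier into its typed fields.

    Raises :class:`TEIDError` naming the offending field on malformed
    input (wrong field count, non-integer coordinates, start >= end,
    bad strand, malformed subfamily:family:class triple).
    """
    fields = text.split("|")
    if len(fields) != 6:
        raise TEIDError(
            f"expected 6 pipe-delimited fields, got {len(fields)}: {text!r}"
        )
    chrom, start_s, end_s, triple, score_s, strand = fields
    if not chrom:
        raise TEIDError(f"empty chromosome field in {text!r}")
    try:
        start = int(start_s)
    except ValueError:
        raise TEIDError(f"non-integer start {start_s!r} in {text!r}") from None
    try:
        end = int(end_s)
    except ValueError:
        raise TEIDError(f"non-integer end {end_s!r} in {text!r}") from None
    if start < 0:
        raise TEIDError(f"negative start {start} in {text!r}")
    if start >= end:
        raise TEIDError(f"start {start} >= end {end} in {text!r}")
    parts = triple.split(":")
    if len(parts) != 3 or not all(parts):
        raise TEIDError(
            f"family field {triple!r} is not subfamily:family:class in {text!r}"
        )
    subfamily, family, te_class = parts
    try:
        score = int(score_s)
    except ValueError:
        raise TEIDError(f"non-integer score {score_s!r} in {text!r}") from None
    if strand not in ("+", "-"):
        raise TEIDError(f"bad strand {strand!r} in {text!r}")
    return TEID(chrom, start, end, subfamily, family, te_class, score, strand)


def format_te_id(te: TEID) -> str:
    """Inverse of :func:`parse_te_id`."""
    return (
        f"{te.chrom}|{te.start}|{te.end}|"
        f"{te.subfamily}:{te.family}:{te.te_class}|{te.score}|{te.strand}"
    )
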