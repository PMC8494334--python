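"""Transposition-competence screen: six-frame translation and length gates.

A TE copy can only mobilize autonomously if (i) some reading frame
still encodes an uninterrupted protein (no stop codon in the
full-length translation) and (ii) the copy is long enough to carry the
machinery its class requires: roughly >= 6 kb for LINEs, >= 4 kb for
LTR elements, >= 900 bp for DNA transposons.  SINEs are non-autonomous
by definition (they borrow the LINE machinery), so they are never
competence candidates regardless of their reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from telocus.synth import revcomp

__all__ = [
    "CompetenceResult",
    "LENGTH_GATES",
    "six_frame",
    "has_stop_free_frame",
    "competence",
]

# lower bounds of the class-specific full-length ranges
LENGTH_GATES = {"LINE": 6000, "DNA": 900, "LTR": 4000}

_ALPHABET = frozenset("ACGTN")


@dataclass(slots=True)
class CompetenceResult:
    te_id: str
    te_class: str
    length: int
    has_stop_free_frame: bool
    length_ok: bool
    autonomous: bool
    verdict: str  # competent-candidate | non-competent | non-autonomous


def _translate(seq: str) -> str:
    trimmed = seq[: len(seq) - len(seq) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate())


def six_frame(seq: str) -> list[str]:
    """Translations of frames +1,+2,+3,-1,-2,-3 (standard code).

    Trailing partial codons are dropped; stops render as ``*`` and
    N-containing codons as ``X``.  Raises on characters outside ACGTN.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"non-ACGTN characters: {sorted(bad)}")
    rc = revcomp(s)
    return [_translate(s[i:]) for i in range(3)] + [_translate(rc[i:]) for i in range(3)]


def has_stop_free_frame(seq: str, all_frames: bool = False) -> bool:
    """Whether the copy could encode an uninterrupted protein.

    Default: true iff at least one of the six full-length frame
    translations contains no stop.  ``all_frames`` switches to the
    stricter requirement that every frame be stop-free.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    frames = six_frame(seq)
    if all_frames:
        return all("*" not in f for f in frames)
    return any("*" not in f for f in frames)


def competence(
    te_class: str,
    seq: str,
    te_id: str = "",
    all_frames: bool = False,
) -> CompetenceResult:
    """Class-gated competence verdict for one TE copy."""
    cls = te_class.upper()
    if cls not in ("LINE", "SINE", "LTR", "DNA"):
        raise ValueError(f"unknown TE class {te_class!r}")
    stop_free = has_stop_free_frame(seq, all_frames=all_frames)
    autonomous = cls != "SINE"
    length_ok = len(seq) >= LENGTH_GATES[cls] if cls in LENGTH_GATES else False
    if not autonomous:
        verdict = "non-autonomous"
    elif stop_free and length_ok:
        verdict = "competent-candidate"
    else:
        verdict = "non-competent"
    return CompetenceResult(
        te_id=te_id,
        te_class=cls,
        length=len(seq),
        has_stop_free_frame=stop_free,
        length_ok=length_ok,
        autonomous=autonomous,
        verdict=verdict,
    )
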