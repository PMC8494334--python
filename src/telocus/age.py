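"""TE age: Kimura 2-parameter divergence and young/old enrichment testing.

The age of a TE copy is proxied by its substitution distance from the
subfamily consensus sequence.  The Kimura 2-parameter (K2P) model
distinguishes transitions (A<->G, C<->T, proportion P) from
transversions (proportion Q):

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

expressed here in percent.  Copies at most 10% diverged are labelled
``young`` (recently active, and the hardest to quantify at the locus
level because their copies cross-map); the rest are ``old``.  Whether
young copies are over-represented among differentially expressed TEs is
assessed with a two-sample test of given proportions (chi-square on the
2x2 table, Yates continuity correction on by default, mirroring R's
``prop.test``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "SaturationError",
    "AgeLabel",
    "kimura2p",
    "label_age",
    "proportion_test",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """K2P distance is undefined: substitutions have saturated."""


@dataclass(frozen=True, slots=True)
class AgeLabel:
    te_id: str
    divergence_pct: float
    label: str  # "young" | "old"


def kimura2p(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter divergence (percent) between aligned sequences.

    The sequences must be equal length (a gap-free alignment).  Positions
    where either sequence has a non-ACGT character are excluded from the
    comparison.  Raises :class:`SaturationError` when the log arguments
    are non-positive and ``ValueError`` on length mismatch or when no
    comparable position remains.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    a = seq_a.upper()
    b = seq_b.upper()
    n = 0
    ts = 0
    tv = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable (ACGT/ACGT) positions")
    p = ts / n
    q = tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated divergence: P={p:.4f}, Q={q:.4f}"
        )
    return float(-0.5 * np.log(w1 * np.sqrt(w2)) * 100.0)


def label_age(divergence_pct: float, threshold: float = 10.0, te_id: str = "") -> AgeLabel:
    """Label a copy ``young`` iff its divergence is <= ``threshold`` percent."""
    if divergence_pct < 0:
        raise ValueError(f"negative divergence {divergence_pct}")
    label = "young" if divergence_pct <= threshold else "old"
    return AgeLabel(te_id=te_id, divergence_pct=float(divergence_pct), label=label)


class ProportionTestResult(NamedTuple):
    chi2: float
    pvalue: float
    p1: float
    p2: float


def proportion_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> ProportionTestResult:
    """Two-sample test of given proportions (df=1 chi-square on the 2x2 table).

    ``k1/n1`` is the young fraction among differentially expressed TEs,
    ``k2/n2`` among all TEs (or any two binomial samples).  The Yates
    continuity correction is applied by default, matching R's
    ``prop.test`` defaults.
    """
    for k, n, name in ((k1, n1, "sample 1"), (k2, n2, "sample 2")):
        if n <= 0:
            raise ValueError(f"{name}: n must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"{name}: k={k} outside [0, n={n}]")
    p1 = k1 / n1
    p2 = k2 / n2
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    # chi2_contingency cannot handle a zero marginal (e.g. k1 = k2 = 0);
    # the proportions are then identical and the test is degenerate.
    if (table.sum(axis=0) == 0).any():
        return ProportionTestResult(0.0, 1.0, p1, p2)
    chi2, pvalue, _, _ = stats.chi2_contingency(table, correction=continuity)
    return ProportionTestResult(float(chi2), float(pvalue), p1, p2)
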