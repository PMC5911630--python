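"""Composite hazard-ratio scoring of gene sets.

The screen summarises each gene's prognostic weight by combining the
hazard ratio of its high- vs low-expression group with the survival
p-value.  For a set of ``n`` genes with hazard ratios ``HR_i`` and
p-values ``p_i`` the composite score is

    score = 100 / n * sum_i (HR_i - 1) * (-log10 p_i)

A protective marker (HR < 1) contributes negatively, so the score is
signed.  Scores above 300 are classified as significant targeting value;
300 itself is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GeneScore",
    "hr_score",
    "classify_score",
    "score_gene",
    "round_score",
    "SIGNIFICANCE_THRESHOLD",
]

SIGNIFICANCE_THRESHOLD = 300.0

#: smallest p-value accepted without an explicit floor; below this the
#: -log10 term is numerically meaningless on printed inputs
_P_MIN = 1e-300


@dataclass(frozen=True)
class GeneScore:
    """Score record for one gene: the (HR, p) inputs, the composite
    score and its classification against the >300 threshold."""

    gene: str
    hr: float
    p: float
    score: float
    significant: bool

    @property
    def score_display(self) -> float:
        """Score rounded half-away-from-zero to one decimal, the
        precision at which scores are reported."""
        return round_score(self.score)


def round_score(score: float, decimals: int = 1) -> float:
    """Round half-away-from-zero (1282.35 -> 1282.4, -60.75 -> -60.8).

    Python's built-in ``round`` uses banker's rounding, which would turn
    half-values toward even digits; reported scores use the arithmetic
    convention instead.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(score) * factor + 0.5), score) / factor


def _validate_pair(hr: float, p: float, p_floor: float | None) -> float:
    if not (hr > 0) or not math.isfinite(hr):
        raise ValueError(f"hazard ratio must be a finite positive number, got {hr!r}")
    if not math.isfinite(p) or p > 1:
        raise ValueError(f"p-value must lie in (0, 1], got {p!r}")
    if p <= 0:
        raise ValueError(
            "p-value must be strictly positive (a zero p gives an infinite "
            "score); supply p_floor to clamp underflowed p-values explicitly"
        )
    if p_floor is not None:
        if p_floor <= 0:
            raise ValueError("p_floor must be positive")
        p = max(p, p_floor)
    elif p < _P_MIN:
        raise ValueError(
            f"p-value {p!r} is below {_P_MIN}; pass p_floor to clamp it explicitly"
        )
    return p


def hr_score(
    pairs: Iterable[tuple[float, float]] | Sequence[tuple[float, float]],
    *,
    absolute: bool = False,
    p_floor: float | None = None,
) -> float:
    """Composite score of a gene set from its (hazard ratio, p-value) pairs.

    Parameters
    ----------
    pairs
        One ``(hr, p)`` pair per gene in the set.  Must be non-empty;
        every ``hr`` must be positive and every ``p`` in ``(0, 1]``.
    absolute
        If True use ``|HR - 1|`` instead of the signed ``HR - 1``.  The
        signed form is the default: it is the variant under which every
        reported score, including the negative ones for protective
        markers, is reproducible.
    p_floor
        Optional lower clamp for p-values (underflow guard).  Without
        it, p-values below 1e-300 are rejected rather than silently
        floored.

    Returns
    -------
    float
        ``100 / n * sum (HR_i - 1) * (-log10 p_i)`` at full precision.
        Use :func:`round_score` for the one-decimal reporting form.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("gene set must contain at least one (hr, p) pair")
    total = 0.0
    for hr, p in pairs:
        p = _validate_pair(hr, p, p_floor)
        delta = abs(hr - 1.0) if absolute else hr - 1.0
        total += delta * (-math.log10(p))
    return 100.0 * total / len(pairs)


def classify_score(score: float) -> bool:
    """True iff the score exceeds the targeting-value threshold (strictly
    greater than 300; 300 itself is not significant)."""
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    return score > SIGNIFICANCE_THRESHOLD


def score_gene(
    gene: str,
    hr: float,
    p: float,
    *,
    absolute: bool = False,
    p_floor: float | None = None,
) -> GeneScore:
    """Score a single gene and classify it (convenience wrapper)."""
    score = hr_score([(hr, p)], absolute=absolute, p_floor=p_floor)
    return GeneScore(gene=gene, hr=hr, p=p, score=score, significant=classify_score(score))
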