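"""IUPAC consensus-motif counting in promoter windows.

Counts all (possibly overlapping) matches of a degenerate consensus
pattern on the forward strand and, optionally, the reverse complement.
Consensus matching rather than position-weight-matrix scoring keeps the
scan deterministic; an ambiguous base N in the *sequence* matches only a
pattern position that is itself N.

Coordinates are 0-based half-open throughout; a promoter window is
expressed as [TSS-1500, TSS) on the annotated strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .simulate import IUPAC_CODES, _validate_iupac

__all__ = ["MotifSpec", "PromoterWindow", "MotifMatches", "count_motifs", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A named transcription-factor binding consensus, e.g.
    ``MotifSpec("CEBPA", "TTNNGNAAT", both_strands=True)``."""

    name: str
    pattern: str
    both_strands: bool = True

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        object.__setattr__(self, "pattern", _validate_iupac(self.pattern))


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter sequence window with its source coordinates.

    ``start``/``end`` are 0-based half-open on the source record;
    ``strand`` records the orientation the window was extracted from.
    """

    sequence: str
    start: int = 0
    end: int | None = None
    strand: str = "+"

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("promoter window must be non-empty")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter window contains non-ACGTN characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if self.end is None:
            object.__setattr__(self, "end", self.start + len(seq))


@dataclass(frozen=True)
class MotifMatches:
    """Scan result: total count plus 0-based window positions per strand."""

    motif: str
    count: int
    forward_positions: tuple[int, ...] = ()
    reverse_positions: tuple[int, ...] = ()

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.forward_positions + self.reverse_positions))


def _iupac_regex(pattern: str) -> re.Pattern:
    # sequence N matches nothing except a pattern N, so degenerate
    # classes deliberately exclude N except for the N code itself
    parts = []
    for ch in pattern:
        allowed = IUPAC_CODES[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead makes overlapping matches countable
    return re.compile(f"(?=({''.join(parts)}))")


def count_motifs(window: PromoterWindow | str, spec: MotifSpec) -> MotifMatches:
    """All matches of a consensus motif in a promoter window.

    Forward-strand matches are positions where the pattern itself
    matches; reverse-strand matches (when ``spec.both_strands``) are
    positions where the pattern's reverse complement matches, reported
    as the match start on the forward coordinates of the window.
    Overlapping occurrences all count.
    """
    if isinstance(window, str):
        window = PromoterWindow(window)
    seq = window.sequence
    fwd = tuple(m.start() for m in _iupac_regex(spec.pattern).finditer(seq))
    rev: tuple[int, ...] = ()
    if spec.both_strands:
        rc_pattern = reverse_complement(spec.pattern)
        rev = tuple(m.start() for m in _iupac_regex(rc_pattern).finditer(seq))
    return MotifMatches(
        motif=spec.name,
        count=len(fwd) + len(rev),
        forward_positions=fwd,
        reverse_positions=rev,
    )
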