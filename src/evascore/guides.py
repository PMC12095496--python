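"""Guide (spacer) records, validation, and simple sequence features.

Position convention: spacer positions are numbered 1..20 with position 20
immediately 5' of the PAM (PAM-proximal) and position 1 PAM-distal. The
blunt Cas9 cut falls between positions 17 and 18. Genomic intervals are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SPACER_LENGTH = 20
_DNA = set("ACGT")


class GuideValidationError(ValueError):
    """Raised when a spacer or PAM fails validation."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T) spelling."""
    if not isinstance(seq, str):
        raise GuideValidationError(f"sequence must be a string, got {type(seq)!r}")
    return seq.strip().upper().replace("U", "T")


def validate_spacer(spacer: str) -> str:
    """Return the normalized 20-nt spacer or raise :class:`GuideValidationError`."""
    s = normalize_sequence(spacer)
    if len(s) != SPACER_LENGTH:
        raise GuideValidationError(
            f"spacer must be exactly {SPACER_LENGTH} nt, got {len(s)}: {s!r}"
        )
    bad = set(s) - _DNA
    if bad:
        raise GuideValidationError(f"invalid characters in spacer {s!r}: {sorted(bad)}")
    return s


def validate_pam(pam: str) -> str:
    s = normalize_sequence(pam)
    if len(s) != 3 or (set(s) - _DNA):
        raise GuideValidationError(f"PAM must be a 3-nt DNA string, got {pam!r}")
    return s


@dataclass
class GuideRecord:
    """A 20-nt SpCas9 spacer with PAM context and optional genomic interval.

    The interval, when present, covers the 20-nt protospacer (not the PAM)
    in 0-based half-open coordinates on ``chrom``; ``strand`` is '+' when
    the protospacer reads 5'->3' on the forward genome strand.
    """

    id: str
    spacer: str
    pam: str = "NGG"
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    enzyme: str = "cas9"

    def __post_init__(self) -> None:
        self.spacer = validate_spacer(self.spacer)
        if self.pam != "NGG":  # "NGG" accepted as the unresolved placeholder
            self.pam = validate_pam(self.pam)
        if self.strand not in (None, "+", "-"):
            raise GuideValidationError(f"strand must be '+'/'-', got {self.strand!r}")
        if (self.start is None) != (self.end is None):
            raise GuideValidationError("start and end must be given together")
        if self.start is not None and self.end - self.start != SPACER_LENGTH:
            raise GuideValidationError(
                f"interval {self.start}-{self.end} does not span {SPACER_LENGTH} nt"
            )

    @property
    def cut_position(self) -> Optional[int]:
        """0-based genomic index of the base immediately 3' of the blunt cut
        on the protospacer strand (between spacer positions 17 and 18)."""
        if self.start is None:
            return None
        if self.strand == "-":
            return self.start + 2
        return self.start + 17

    def base_at(self, position: int) -> str:
        """Spacer base at 1-based position (1 = PAM-distal, 20 = PAM-proximal)."""
        if not 1 <= position <= SPACER_LENGTH:
            raise GuideValidationError(f"position must be 1..{SPACER_LENGTH}")
        return self.spacer[position - 1]


def count_ga(spacer: str) -> int:
    """Number of 'GA' dinucleotides in the spacer (overlapping window scan).

    For the two-letter motif GA overlapping occurrences cannot share a G,
    so this equals the non-overlapping count.
    """
    s = validate_spacer(spacer)
    return sum(1 for i in range(SPACER_LENGTH - 1) if s[i] == "G" and s[i + 1] == "A")


def position_flags(spacer: str) -> tuple[bool, bool]:
    """(g17, c20): G at position 17 (5' of the cut) and C at position 20
    (immediately before the PAM), both activity-penalizing."""
    s = validate_spacer(spacer)
    return s[16] == "G", s[19] == "C"


_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return normalize_sequence(seq).translate(_COMP)[::-1]
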