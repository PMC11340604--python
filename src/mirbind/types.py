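"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open, in transcript-local (UTR) space.
Sequences are RNA, 5'->3', uppercase over {A, C, G, U}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

RNA_ALPHABET = frozenset("ACGU")

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

SITE_LENGTHS = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert DNA thymine to uracil (idempotent)."""
    return sequence.strip().upper().replace("T", "U")


def validate_rna(sequence: str, *, name: str = "sequence") -> str:
    seq = normalize_rna(sequence)
    for i, base in enumerate(seq):
        if base not in RNA_ALPHABET:
            raise ValueError(
                f"illegal character {base!r} at position {i} in {name}"
            )
    return seq


def complement_rna(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA with a miRBase-style identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_rna(self.sequence, name=self.id))
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.id!r} is shorter than 8 nt; seed positions 2-8 undefined"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptUTR:
    """A 3'-UTR sequence keyed by an ENST-style transcript identifier."""

    transcript_id: str
    sequence: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_rna(self.sequence, name=self.transcript_id)
        )
        if not self.sequence:
            raise ValueError(f"transcript {self.transcript_id!r} has an empty UTR")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ConservationTrack:
    """Per-base conservation scores in transcript coordinates.

    Missing positions are NaN; the vector length must equal the UTR length.
    """

    transcript_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class SNPAnnotation:
    transcript_id: str
    position: int
    disease_related: bool


@dataclass(frozen=True)
class CandidateSite:
    """A canonical seed-match site located on a 3'-UTR.

    ``start``/``end`` delimit the site itself; ``core_start`` is the offset of
    the 6-nt seed core (complement of miRNA positions 2-7).  ``target_region``
    is the UTR subsequence from ``region_start`` covering the site plus a
    flank, clipped at UTR boundaries.
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    site_type: str
    core_start: int
    target_region: str
    region_start: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != SITE_LENGTHS[self.site_type]:
            raise ValueError(
                f"site span {self.end - self.start} inconsistent with {self.site_type}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """UTR index of the target base opposite miRNA position 1."""
        return self.core_start + 6
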