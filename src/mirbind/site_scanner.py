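"""Enumerate canonical seed-match sites in a 3'-UTR.

Reading the UTR 5'->3', let M6 be the reverse complement of miRNA positions
2-7 and M7 the reverse complement of positions 2-8.  At a 6mer-core offset i
(the UTR position where an M6 match begins):

* 8mer      — M7 matches at i-1 and the base at i+6 is A
* 7mer-m8   — M7 matches at i-1 and the base at i+6 is not A (or absent)
* 7mer-A1   — M6 matches, base at i+6 is A, and no M7 match at i-1
* 6mer      — M6 matches with neither extension

Each core offset yields at most one site, of the maximal class.  Watson-Crick
complementarity only; G:U wobble does not count as a seed match.  Context
bases cut off by UTR boundaries cannot contribute to a larger class.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from mirbind.types import (
    CandidateSite,
    MiRNA,
    TranscriptUTR,
    complement_rna,
    reverse_complement,
)

DEFAULT_FLANK = 20


def seed(mirna: MiRNA) -> str:
    """Seed region: miRNA positions 2-8 (1-based from the 5' end), length 7."""
    if len(mirna.sequence) < 8:
        raise ValueError(f"miRNA {mirna.id!r} shorter than 8 nt")
    return mirna.sequence[1:8]


def _classify(
    mirna_seq: str, utr_seq: str, core_offset: int
) -> Optional[Tuple[str, int, int]]:
    """Return (site_type, start, end) for the maximal class at a core offset."""
    i = core_offset
    if i < 0 or i + 6 > len(utr_seq):
        return None
    m6 = reverse_complement(mirna_seq[1:7])
    if utr_seq[i:i + 6] != m6:
        return None
    has_m8 = i >= 1 and utr_seq[i - 1] == complement_rna(mirna_seq[7])
    has_a1 = i + 6 < len(utr_seq) and utr_seq[i + 6] == "A"
    if has_m8 and has_a1:
        return "8mer", i - 1, i + 7
    if has_m8:
        return "7mer-m8", i - 1, i + 6
    if has_a1:
        return "7mer-A1", i, i + 7
    return "6mer", i, i + 6


def classify_site_type(
    mirna: MiRNA, utr: TranscriptUTR, core_offset: int
) -> Optional[str]:
    """Site type of the maximal class whose 6mer core starts at ``core_offset``."""
    if core_offset < 0 or core_offset >= len(utr):
        raise IndexError(f"core offset {core_offset} outside UTR bounds")
    hit = _classify(mirna.sequence, utr.sequence, core_offset)
    return hit[0] if hit else None


def make_site(
    mirna: MiRNA,
    utr: TranscriptUTR,
    site_type: str,
    start: int,
    end: int,
    core_start: int,
    flank: int = DEFAULT_FLANK,
) -> CandidateSite:
    region_start = max(0, start - flank)
    region_end = min(len(utr), end + flank)
    return CandidateSite(
        mirna_id=mirna.id,
        transcript_id=utr.transcript_id,
        start=start,
        end=end,
        site_type=site_type,
        core_start=core_start,
        target_region=utr.sequence[region_start:region_end],
        region_start=region_start,
    )


def scan_candidate_sites(
    mirna: MiRNA, utr: TranscriptUTR, flank: int = DEFAULT_FLANK
) -> List[CandidateSite]:
    """All canonical sites for one miRNA on one UTR, sorted by start."""
    sites: List[CandidateSite] = []
    useq = utr.sequence
    mseq = mirna.sequence
    for i in range(len(useq) - 5):
        hit = _classify(mseq, useq, i)
        if hit is None:
            continue
        site_type, start, end = hit
        sites.append(make_site(mirna, utr, site_type, start, end, i, flank=flank))
    sites.sort(key=lambda s: (s.start, s.end))
    return sites
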