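"""Built-in duplex hybridization energy via nearest-neighbor stacking.

The miRNA is aligned antiparallel to the target so that miRNA position 1
faces the target base at ``anchor`` (0-based index in the target string) and
position k faces ``anchor - (k - 1)``.  Watson-Crick pairs only; the energy is
the sum of stack free energies over consecutive paired positions.  Stacking
parameters are standard RNA/RNA nearest-neighbor values at 37 degrees C
(kcal/mol); every stack term is negative, so adding a pair can only lower the
total.  An external tool backend can be substituted where available.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import List, Optional, Tuple

_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}

# 5'->3' dinucleotide on the miRNA strand, both positions Watson-Crick paired.
NN_STACK = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


def paired_mask(mirna_seq: str, target_seq: str, anchor: int) -> List[bool]:
    """Per-miRNA-position Watson-Crick pairing mask for a fixed alignment."""
    mask = []
    for k in range(1, len(mirna_seq) + 1):
        t = anchor - (k - 1)
        mask.append(
            0 <= t < len(target_seq)
            and _WC[mirna_seq[k - 1]] == target_seq[t]
        )
    return mask


def _stack_energy(mirna_seq: str, mask: List[bool], lo: int = 0, hi: Optional[int] = None) -> float:
    """Sum stack terms over consecutive paired positions in [lo, hi) (0-based)."""
    hi = len(mask) if hi is None else hi
    total = 0.0
    for k in range(lo, min(hi, len(mask)) - 1):
        if mask[k] and mask[k + 1]:
            total += NN_STACK[mirna_seq[k:k + 2]]
    return total


@dataclass(frozen=True)
class DuplexProfile:
    energy: float
    seed_energy: float
    energy_per_pair: float
    paired_count: int


def best_anchor(mirna_seq: str, target_seq: str) -> int:
    """Alignment anchor maximizing paired-base count (ties: lowest energy)."""
    best = None
    for anchor in range(len(target_seq) + len(mirna_seq) - 1):
        mask = paired_mask(mirna_seq, target_seq, anchor)
        count = sum(mask)
        energy = _stack_energy(mirna_seq, mask)
        key = (-count, energy, anchor)
        if best is None or key < best[0]:
            best = (key, anchor)
    return best[1]


def duplex_profile(
    mirna_seq: str, target_seq: str, anchor: Optional[int] = None
) -> DuplexProfile:
    """Energy, seed-region energy, per-pair energy, and paired-base count.

    With ``anchor=None`` the maximal complementary alignment is used, as found
    by sliding the miRNA along the target.
    """
    if not mirna_seq or not target_seq:
        raise ValueError("sequences must be non-empty")
    if anchor is None:
        anchor = best_anchor(mirna_seq, target_seq)
    mask = paired_mask(mirna_seq, target_seq, anchor)
    energy = _stack_energy(mirna_seq, mask)
    seed_energy = _stack_energy(mirna_seq, mask, 0, 8)
    count = sum(mask)
    return DuplexProfile(
        energy=energy,
        seed_energy=seed_energy,
        energy_per_pair=energy / count if count else 0.0,
        paired_count=count,
    )


def duplex_energy(
    mirna_seq: str,
    target_seq: str,
    backend: str = "builtin",
    anchor: Optional[int] = None,
) -> float:
    """Hybridization energy in kcal/mol (lower = more stable)."""
    if backend == "builtin":
        return duplex_profile(mirna_seq, target_seq, anchor=anchor).energy
    if backend == "intarna":
        exe = shutil.which("IntaRNA")
        if exe is None:
            raise RuntimeError(
                "IntaRNA executable not found; use backend='builtin' instead"
            )
        out = subprocess.run(
            [exe, "-q", mirna_seq, "-t", target_seq, "--outMode=C", "--outCsvCols=E"],
            capture_output=True, text=True, check=True,
        )
        lines = [l for l in out.stdout.splitlines() if l.strip()]
        return float(lines[-1]) if len(lines) > 1 else 0.0
    raise ValueError(f"unknown energy backend {backend!r}")
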