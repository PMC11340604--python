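"""The seven feature families computed per candidate site.

Family cardinalities: 4 site-type + 4 binding-stability + 13 accessibility +
7 3'-supplementary + 16 conservation + 18 SNP + 92 sequence descriptors = 154.
Missing inputs (no conservation track, region too short for a k-mer family)
yield NaN, never silent zeros.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from mirbind.features.energy import duplex_profile, paired_mask
from mirbind.features.fold import NussinovFoldBackend
from mirbind.types import CandidateSite, ConservationTrack, MiRNA, SITE_TYPES

NT = "ACGU"
DINUCS = ["".join(p) for p in itertools.product(NT, repeat=2)]
TRINUCS = ["".join(p) for p in itertools.product(NT, repeat=3)]

SITE_TYPE_NAMES = [f"st_{t.replace('-', '_')}" for t in SITE_TYPES]
STABILITY_NAMES = ["stab_energy", "stab_seed_energy", "stab_energy_per_pair",
                   "stab_paired_count"]
ACCESSIBILITY_NAMES = [
    "acc_dist5", "acc_dist3", "acc_dist_min", "acc_rel_pos", "acc_utr_len",
    "acc_au_flank5", "acc_au_flank3", "acc_au_site", "acc_open_energy",
    "acc_unpaired_site", "acc_unpaired_win10", "acc_gc_region",
    "acc_flank_clipped",
]
SUPPLEMENTARY_NAMES = [
    "supp_pairs_13_16", "supp_pairs_12_17", "supp_run_12_17",
    "supp_ge3_13_16", "supp_pairs_3p_half", "supp_wobble_13_16",
    "supp_best_offset",
]
_CONS_REGIONS = ["core", "site", "flank5", "flank3"]
_CONS_STATS = ["mean", "min", "max", "fracthr"]
CONSERVATION_NAMES = [f"cons_{r}_{s}" for r in _CONS_REGIONS for s in _CONS_STATS]
SNP_NAMES = (
    [f"snp_any_p{i}" for i in range(1, 9)]
    + [f"snp_dis_p{i}" for i in range(1, 9)]
    + ["snp_count", "snp_dis_count"]
)
DESCRIPTOR_NAMES = (
    [f"desc_nt_{b}" for b in NT]
    + [f"desc_di_{d}" for d in DINUCS]
    + [f"desc_tri_{t}" for t in TRINUCS]
    + ["desc_z1", "desc_z2", "desc_z3", "desc_gc", "desc_au", "desc_purine",
       "desc_len", "desc_maxrun"]
)


def site_type_features(site: CandidateSite) -> Dict[str, float]:
    """One-hot over {6mer, 7mer-A1, 7mer-m8, 8mer}."""
    return {
        name: float(site.site_type == t)
        for name, t in zip(SITE_TYPE_NAMES, SITE_TYPES)
    }


def stability_features(mirna: MiRNA, site: CandidateSite) -> Dict[str, float]:
    anchor = site.anchor - site.region_start
    prof = duplex_profile(mirna.sequence, site.target_region, anchor=anchor)
    return {
        "stab_energy": prof.energy,
        "stab_seed_energy": prof.seed_energy,
        "stab_energy_per_pair": prof.energy_per_pair,
        "stab_paired_count": float(prof.paired_count),
    }


def _au_fraction(seq: str) -> float:
    if not seq:
        return np.nan
    return sum(b in "AU" for b in seq) / len(seq)


def accessibility_features(
    utr_seq: str,
    site: CandidateSite,
    fold_backend: Optional[NussinovFoldBackend],
    flank: int = 30,
    window: int = 10,
) -> Dict[str, float]:
    L = len(utr_seq)
    dist5 = site.start
    dist3 = L - site.end
    span = L - site.length
    rel = dist5 / span if span > 0 else 0.0
    f5 = utr_seq[max(0, site.start - flank):site.start]
    f3 = utr_seq[site.end:site.end + flank]
    clipped = float(len(f5) < flank or len(f3) < flank)
    region = site.target_region
    gc_region = sum(b in "GC" for b in region) / len(region)
    if fold_backend is not None:
        opening, unpaired, wlo = fold_backend.analyze(utr_seq, site.start, site.end)
        site_prof = unpaired[site.start - wlo:site.end - wlo]
        wa = max(0, site.start - window) - wlo
        wb = min(L, site.end + window) - wlo
        win_prof = unpaired[wa:wb]
        unp_site = float(np.mean(site_prof))
        unp_win = float(np.mean(win_prof))
    else:
        opening = unp_site = unp_win = np.nan
    return {
        "acc_dist5": float(dist5),
        "acc_dist3": float(dist3),
        "acc_dist_min": float(min(dist5, dist3)),
        "acc_rel_pos": rel,
        "acc_utr_len": float(L),
        "acc_au_flank5": _au_fraction(f5),
        "acc_au_flank3": _au_fraction(f3),
        "acc_au_site": _au_fraction(utr_seq[site.start:site.end]),
        "acc_open_energy": opening,
        "acc_unpaired_site": unp_site,
        "acc_unpaired_win10": unp_win,
        "acc_gc_region": gc_region,
        "acc_flank_clipped": clipped,
    }


_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE = {("G", "U"), ("U", "G")}


def _pairs_at_offset(mirna_seq: str, utr_seq: str, anchor: int, shift: int) -> List[bool]:
    """WC-pair mask per miRNA position for a target window slid by ``shift``."""
    mask = []
    for k in range(1, len(mirna_seq) + 1):
        t = anchor - (k - 1) + shift
        mask.append(0 <= t < len(utr_seq) and _WC[mirna_seq[k - 1]] == utr_seq[t])
    return mask


def supplementary_pairing_features(
    mirna: MiRNA, utr_seq: str, site: CandidateSite
) -> Dict[str, float]:
    mseq = mirna.sequence
    anchor = site.anchor
    mask = _pairs_at_offset(mseq, utr_seq, anchor, 0)

    def count(lo: int, hi: int, m: List[bool]) -> int:
        return sum(m[lo - 1:hi])  # positions are 1-based inclusive

    c13_16 = count(13, 16, mask)
    c12_17 = count(12, 17, mask)
    window = mask[11:17]
    run = best = 0
    for v in window:
        run = run + 1 if v else 0
        best = max(best, run)
    c3p = count(9, len(mseq), mask)
    wobble = 0
    for k in range(13, 17):
        t = anchor - (k - 1)
        if 0 <= t < len(utr_seq) and k <= len(mseq):
            if (mseq[k - 1], utr_seq[t]) in _WOBBLE:
                wobble += 1
    best_shift, best_count = 0, -1
    for shift in (0, -1, 1, -2, 2):
        c = count(13, 16, _pairs_at_offset(mseq, utr_seq, anchor, shift))
        if c > best_count:
            best_shift, best_count = abs(shift), c
    return {
        "supp_pairs_13_16": float(c13_16),
        "supp_pairs_12_17": float(c12_17),
        "supp_run_12_17": float(best),
        "supp_ge3_13_16": float(c13_16 >= 3),
        "supp_pairs_3p_half": float(c3p),
        "supp_wobble_13_16": float(wobble),
        "supp_best_offset": float(best_shift),
    }


def _region_stats(scores: np.ndarray, threshold: float) -> List[float]:
    covered = scores[~np.isnan(scores)] if scores.size else np.array([])
    if covered.size == 0:
        return [np.nan] * 4
    return [
        float(covered.mean()),
        float(covered.min()),
        float(covered.max()),
        float((covered > threshold).mean()),
    ]


def conservation_features(
    track: Optional[ConservationTrack],
    site: CandidateSite,
    flank: int = 30,
    threshold: float = 0.5,
) -> Dict[str, float]:
    if track is None:
        return {name: np.nan for name in CONSERVATION_NAMES}
    s = track.scores
    regions = {
        "core": s[site.core_start:site.core_start + 6],
        "site": s[site.start:site.end],
        "flank5": s[max(0, site.start - flank):site.start],
        "flank3": s[site.end:site.end + flank],
    }
    out: Dict[str, float] = {}
    for rname, vec in regions.items():
        for sname, value in zip(_CONS_STATS, _region_stats(np.asarray(vec), threshold)):
            out[f"cons_{rname}_{sname}"] = value
    return out


def snp_features(snp_table: Optional[pd.DataFrame], site: CandidateSite) -> Dict[str, float]:
    """Per-position indicators over the 3'-most eight site bases, plus counts.

    Site position p (1..8) maps to UTR index ``end - 8 + (p - 1)``; positions
    falling before the site start (6/7mer sites) are missing.
    """
    out: Dict[str, float] = {}
    if snp_table is None:
        snp_table = pd.DataFrame(columns=["transcript_id", "position", "disease_related"])
    rows = snp_table[snp_table["transcript_id"] == site.transcript_id] if len(snp_table) else snp_table
    positions = set()
    disease_positions = set()
    for _, row in rows.iterrows():
        positions.add(int(row["position"]))
        if bool(row["disease_related"]):
            disease_positions.add(int(row["position"]))
    total = sum(1 for p in positions if site.start <= p < site.end)
    dis_total = sum(1 for p in disease_positions if site.start <= p < site.end)
    for p in range(1, 9):
        idx = site.end - 8 + (p - 1)
        if idx < site.start:
            out[f"snp_any_p{p}"] = np.nan
            out[f"snp_dis_p{p}"] = np.nan
        else:
            out[f"snp_any_p{p}"] = float(idx in positions)
            out[f"snp_dis_p{p}"] = float(idx in disease_positions)
    out["snp_count"] = float(total)
    out["snp_dis_count"] = float(dis_total)
    return out


def _kmer_freqs(seq: str, k: int, alphabet: List[str]) -> Dict[str, float]:
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        return {mer: np.nan for mer in alphabet}
    counts = {mer: 0 for mer in alphabet}
    for i in range(n_windows):
        counts[seq[i:i + k]] += 1
    return {mer: c / n_windows for mer, c in counts.items()}


def descriptor_features(region: str) -> Dict[str, float]:
    """92 sequence descriptors of the target region.

    k-mer composition for k in {1,2,3} (frequencies over all windows), the
    three Z-curve components, GC/AU content, purine fraction, length, and the
    longest homopolymer run.
    """
    if not region:
        raise ValueError("target region must be non-empty")
    out: Dict[str, float] = {}
    for b, v in _kmer_freqs(region, 1, list(NT)).items():
        out[f"desc_nt_{b}"] = v
    for d, v in _kmer_freqs(region, 2, DINUCS).items():
        out[f"desc_di_{d}"] = v
    for t, v in _kmer_freqs(region, 3, TRINUCS).items():
        out[f"desc_tri_{t}"] = v
    n = len(region)
    counts = {b: region.count(b) for b in NT}
    out["desc_z1"] = (counts["A"] + counts["G"] - counts["C"] - counts["U"]) / n
    out["desc_z2"] = (counts["A"] + counts["C"] - counts["G"] - counts["U"]) / n
    out["desc_z3"] = (counts["A"] + counts["U"] - counts["G"] - counts["C"]) / n
    out["desc_gc"] = (counts["G"] + counts["C"]) / n
    out["desc_au"] = (counts["A"] + counts["U"]) / n
    out["desc_purine"] = (counts["A"] + counts["G"]) / n
    out["desc_len"] = float(n)
    run = best = 1
    for a, b in zip(region, region[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    out["desc_maxrun"] = float(best if n else 0)
    return out
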