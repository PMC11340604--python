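"""Synthetic corpora with implanted canonical sites and controllable signal.

A corpus bundles random miRNAs, random-background 3'-UTRs carrying implanted
seed-match sites of chosen types, conservation tracks elevated over the
signal implants, sparse SNP annotations, a validated-pair list, and an
expression table in which transcripts bearing signal implants are repressed.

Signal implants ("positives") optionally carry a GC-enriched local context
and a complementary 3'-supplementary region; decoy implants and chance
seed matches arising in the background form the negative pool, mimicking
candidate sites that crosslinking data failed to verify.  A configurable
fraction of signal implants is withheld from the positive list and placed in
the validated-pair list instead, so the negative filter has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from mirbind.datasets import filter_negatives, undersample_balance
from mirbind.features.registry import FeatureRegistry, featurize_many, META_COLUMNS
from mirbind.sequence_io import (
    ResourceBundle,
    write_conservation,
    write_expression,
    write_fasta,
    write_snp_table,
)
from mirbind.site_scanner import _classify, scan_candidate_sites
from mirbind.types import (
    ConservationTrack,
    MiRNA,
    SNPAnnotation,
    TranscriptUTR,
    complement_rna,
    reverse_complement,
    SITE_TYPES,
)

NT = np.array(list("ACGU"))

DEFAULT_TYPE_MIX = {"6mer": 0.2, "7mer-A1": 0.25, "7mer-m8": 0.25, "8mer": 0.3}


@dataclass
class CorpusConfig:
    n_mirnas: int = 5
    n_transcripts: int = 50
    utr_length_range: Tuple[int, int] = (150, 300)
    implant_rate: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )  # expected signal implants per transcript, per site type
    decoy_rate: float = 1.0       # expected signal-free implants per transcript
    energy_bias: float = 0.15     # GC enrichment of signal-implant context
    supp_rate: float = 0.6        # P(signal implant gets 3'-supplementary match)
    conservation_signal: float = 0.5
    snp_density: float = 0.002
    repression_link: float = 0.9
    holdout_rate: float = 0.1     # signal implants routed to the validated list
    excluded_rate: float = 0.1    # unaffected pairs drawn in the excluded range
    max_unaffected_per_mirna: Optional[int] = None
    two_transcript_gene_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("decoy_rate", "energy_bias", "supp_rate", "snp_density",
                     "repression_link", "holdout_rate", "excluded_rate",
                     "two_transcript_gene_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 and name != "decoy_rate":
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.utr_length_range) < 60:
            raise ValueError("UTRs shorter than 60 nt cannot host implant contexts")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Corpus:
    config: CorpusConfig
    resources: ResourceBundle
    manifest: pd.DataFrame  # mirna_id, transcript_id, core_start, start, end,
    #                         site_type, signal, held_out

    def positive_keys(self) -> Set[Tuple[str, str, int]]:
        rows = self.manifest[self.manifest["signal"] & ~self.manifest["held_out"]]
        return set(zip(rows["mirna_id"], rows["transcript_id"], rows["core_start"]))


def _random_seq(rng: np.random.Generator, length: int, p: Optional[np.ndarray] = None) -> str:
    return "".join(rng.choice(NT, size=length, p=p))


def _gc_biased_probs(bias: float) -> np.ndarray:
    return np.array([0.25 - bias, 0.25 + bias, 0.25 + bias, 0.25 - bias])


def _random_mirnas(rng: np.random.Generator, n: int) -> List[MiRNA]:
    mirnas: List[MiRNA] = []
    seeds_seen: Set[str] = set()
    while len(mirnas) < n:
        seq = _random_seq(rng, 22)
        if seq[1:8] in seeds_seen:
            continue
        seeds_seen.add(seq[1:8])
        mirnas.append(MiRNA(id=f"syn-miR-{len(mirnas) + 1}", sequence=seq))
    return mirnas


def _implant(
    utr: List[str],
    mirna: MiRNA,
    core: int,
    site_type: str,
    rng: np.random.Generator,
    signal: bool,
    config: CorpusConfig,
) -> Optional[Tuple[int, int]]:
    """Write one canonical site into the UTR; returns (start, end) or None."""
    mseq = mirna.sequence
    if signal and config.energy_bias > 0:
        p = _gc_biased_probs(config.energy_bias)
        lo, hi = max(0, core - 20), min(len(utr), core + 26)
        utr[lo:hi] = list(_random_seq(rng, hi - lo, p))
    utr[core:core + 6] = list(reverse_complement(mseq[1:7]))
    m8_base = complement_rna(mseq[7])
    non_a = rng.choice([b for b in "CGU"])
    non_m8 = rng.choice([b for b in "ACGU" if b != m8_base])
    if site_type in ("8mer", "7mer-m8"):
        utr[core - 1] = m8_base
    else:
        utr[core - 1] = non_m8
    if site_type in ("8mer", "7mer-A1"):
        utr[core + 6] = "A"
    else:
        utr[core + 6] = non_a
    if signal and rng.random() < config.supp_rate:
        anchor = core + 6
        for k in range(13, 17):  # complement of miRNA positions 13-16
            t = anchor - (k - 1)
            if 0 <= t < len(utr):
                utr[t] = complement_rna(mseq[k - 1])
    hit = _classify(mseq, "".join(utr), core)
    if hit is None or hit[0] != site_type:
        return None
    return hit[1], hit[2]


def generate_corpus(config: CorpusConfig) -> Corpus:
    """Build a full in-memory corpus, deterministic in ``config.seed``."""
    for t in config.implant_rate:
        if t not in SITE_TYPES:
            raise ValueError(f"unknown site type {t!r} in implant_rate")
    min_len = min(config.utr_length_range)
    if min_len < 40:
        raise ValueError("UTR too short for implants")
    rng = np.random.default_rng(config.seed)
    mirnas = _random_mirnas(rng, config.n_mirnas)

    utrs: List[TranscriptUTR] = []
    manifest_rows: List[dict] = []
    conservation: Dict[str, ConservationTrack] = {}
    snps: List[SNPAnnotation] = []

    gene_counter = 0
    t_index = 0
    while t_index < config.n_transcripts:
        gene_counter += 1
        gene_id = f"GENE{gene_counter}"
        n_iso = 2 if rng.random() < config.two_transcript_gene_rate else 1
        n_iso = min(n_iso, config.n_transcripts - t_index)
        for _ in range(n_iso):
            t_index += 1
            tid = f"ENST{t_index:08d}"
            length = int(rng.integers(*config.utr_length_range))
            utr = list(_random_seq(rng, length))
            occupied: List[Tuple[int, int]] = []

            def place(site_type: str, signal: bool) -> None:
                for _attempt in range(20):
                    core = int(rng.integers(21, length - 27))
                    if any(abs(core - c) < 34 for c, _ in occupied):
                        continue
                    mirna = mirnas[int(rng.integers(len(mirnas)))]
                    span = _implant(utr, mirna, core, site_type, rng, signal, config)
                    if span is None:
                        continue
                    occupied.append((core, mirna.id))
                    manifest_rows.append({
                        "mirna_id": mirna.id, "transcript_id": tid,
                        "core_start": core, "start": span[0], "end": span[1],
                        "site_type": site_type, "signal": signal,
                        "held_out": False,
                    })
                    return

            for site_type, rate in config.implant_rate.items():
                for _ in range(rng.poisson(rate)):
                    place(site_type, signal=True)
            type_names = list(config.implant_rate) or list(SITE_TYPES)
            for _ in range(rng.poisson(config.decoy_rate)):
                place(type_names[int(rng.integers(len(type_names)))], signal=False)

            utrs.append(TranscriptUTR(tid, "".join(utr), gene_id=gene_id))

            scores = rng.uniform(0.0, 0.4, size=length)
            for row in manifest_rows:
                if row["transcript_id"] == tid and row["signal"]:
                    lo = max(0, row["start"] - 3)
                    hi = min(length, row["end"] + 3)
                    scores[lo:hi] = np.clip(
                        scores[lo:hi] + config.conservation_signal, 0.0, 1.0
                    )
            conservation[tid] = ConservationTrack(tid, scores)

            n_snps = rng.binomial(length, config.snp_density)
            for pos in sorted(rng.choice(length, size=n_snps, replace=False).tolist()):
                snps.append(SNPAnnotation(tid, int(pos), bool(rng.random() < 0.3)))

    manifest = pd.DataFrame(
        manifest_rows,
        columns=["mirna_id", "transcript_id", "core_start", "start", "end",
                 "site_type", "signal", "held_out"],
    )

    gene_of = {u.transcript_id: u.gene_id for u in utrs}
    validated: Set[Tuple[str, str]] = set()
    if len(manifest):
        signal_idx = manifest.index[manifest["signal"]].to_numpy()
        n_hold = int(round(config.holdout_rate * len(signal_idx)))
        if n_hold:
            held = rng.choice(signal_idx, size=n_hold, replace=False)
            manifest.loc[held, "held_out"] = True
            for _, row in manifest.loc[held].iterrows():
                validated.add((row["mirna_id"], gene_of[row["transcript_id"]]))

    # Expression: gene-level, driven by signal implants on the longest isoform.
    longest: Dict[str, TranscriptUTR] = {}
    for u in utrs:
        cur = longest.get(u.gene_id)
        if cur is None or (-len(u), u.transcript_id) < (-len(cur), cur.transcript_id):
            longest[u.gene_id] = u
    implanted_pairs: Set[Tuple[str, str]] = set(
        (r["mirna_id"], gene_of[r["transcript_id"]])
        for _, r in manifest[manifest["signal"]].iterrows()
    )
    expr_rows: List[dict] = []
    for mirna in mirnas:
        unaffected_genes: List[str] = []
        for gene_id, utr in sorted(longest.items()):
            if (mirna.id, gene_id) in implanted_pairs:
                if rng.random() < config.repression_link:
                    value = rng.uniform(0.20, 0.60)
                else:
                    value = rng.uniform(1.00, 1.10)
                expr_rows.append({"mirna_id": mirna.id, "gene_id": gene_id,
                                  "relative_expression": round(value, 4)})
            else:
                unaffected_genes.append(gene_id)
        if config.max_unaffected_per_mirna is not None:
            k = min(config.max_unaffected_per_mirna, len(unaffected_genes))
            chosen = rng.choice(unaffected_genes, size=k, replace=False).tolist()
        else:
            chosen = unaffected_genes
        for gene_id in chosen:
            if rng.random() < config.excluded_rate:
                value = rng.uniform(0.65, 0.95)
            else:
                value = rng.uniform(1.00, 1.10)
            expr_rows.append({"mirna_id": mirna.id, "gene_id": gene_id,
                              "relative_expression": round(value, 4)})

    resources = ResourceBundle(
        mirnas=mirnas,
        utrs=utrs,
        conservation=conservation,
        snps=pd.DataFrame(
            [(s.transcript_id, s.position, s.disease_related) for s in snps],
            columns=["transcript_id", "position", "disease_related"],
        ),
        validated_pairs=validated,
        expression=pd.DataFrame(
            expr_rows, columns=["mirna_id", "gene_id", "relative_expression"]
        ),
    )
    return Corpus(config=config, resources=resources, manifest=manifest)


def write_corpus(corpus: Corpus, outdir) -> Dict[str, Path]:
    """Write the corpus in the exact plain-text formats sequence_io reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirnas": outdir / "mirnas.fasta",
        "utrs": outdir / "utrs.fasta",
        "conservation": outdir / "conservation.tsv",
        "snps": outdir / "snps.tsv",
        "pairs": outdir / "validated_pairs.tsv",
        "expression": outdir / "expression.tsv",
        "manifest": outdir / "ground_truth.tsv",
    }
    res = corpus.resources
    write_fasta(res.mirnas, paths["mirnas"])
    write_fasta(res.utrs, paths["utrs"])
    write_conservation(res.conservation, paths["conservation"])
    snp_objs = [
        SNPAnnotation(r.transcript_id, int(r.position), bool(r.disease_related))
        for r in res.snps.itertuples()
    ]
    write_snp_table(snp_objs, paths["snps"])
    with open(paths["pairs"], "w") as fh:
        for mirna_id, gene_id in sorted(res.validated_pairs):
            fh.write(f"{mirna_id}\t{gene_id}\n")
    write_expression(res.expression, paths["expression"])
    corpus.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths


def assemble_ts_dataset(
    corpus: Corpus,
    registry: FeatureRegistry,
    seed: int = 0,
    balance: bool = True,
) -> pd.DataFrame:
    """Scan, featurize, and label every candidate site in the corpus.

    Signal implants not withheld are positives; all other scanned sites are
    candidate negatives, filtered against the validated-pair list and
    (optionally) under-sampled to a 1:1 class balance.
    """
    res = corpus.resources
    sites = []
    for mirna in res.mirnas:
        for utr in res.utrs:
            sites.extend(scan_candidate_sites(mirna, utr, flank=registry.config.flank))
    feats = featurize_many(sites, res, registry)
    core_starts = []
    for site in sites:
        core_starts.append(site.core_start)
    feats.insert(len(META_COLUMNS), "core_start", core_starts)
    pos_keys = corpus.positive_keys()
    is_pos = [
        (m, t, c) in pos_keys
        for m, t, c in zip(feats["mirna_id"], feats["transcript_id"], feats["core_start"])
    ]
    feats["label"] = np.asarray(is_pos, dtype=int)
    positives = feats[feats["label"] == 1]
    negatives, _removed = filter_negatives(
        feats[feats["label"] == 0], res.validated_pairs
    )
    if not balance:
        return pd.concat([positives, negatives], ignore_index=True)
    return undersample_balance(positives, negatives, seed=seed)


def ground_truth_eval(
    manifest: pd.DataFrame, predictions: Sequence
) -> Dict[str, object]:
    """Per-type recall of implanted sites plus the chance-site rate.

    ``predictions`` are CandidateSite objects (e.g. the scanner's output over
    the whole corpus).
    """
    pred_keys = set()
    pred_tids = set()
    for s in predictions:
        pred_keys.add((s.mirna_id, s.transcript_id, s.core_start, s.site_type))
        pred_tids.add(s.transcript_id)
    if len(manifest) and pred_tids and not (
        set(manifest["transcript_id"]) & pred_tids
    ):
        raise ValueError("predictions do not cover any manifest transcript")
    recall: Dict[str, float] = {}
    for site_type in SITE_TYPES:
        sub = manifest[manifest["site_type"] == site_type]
        if len(sub) == 0:
            recall[site_type] = float("nan")
            continue
        hits = sum(
            (r.mirna_id, r.transcript_id, r.core_start, r.site_type) in pred_keys
            for r in sub.itertuples()
        )
        recall[site_type] = hits / len(sub)
    implanted = set(
        (r.mirna_id, r.transcript_id, r.core_start) for r in manifest.itertuples()
    )
    chance = sum(
        1 for s in predictions
        if (s.mirna_id, s.transcript_id, s.core_start) not in implanted
    )
    return {
        "recall_by_type": recall,
        "n_predictions": len(pred_keys),
        "n_chance_sites": chance,
    }


def informative_features(config: CorpusConfig, registry: FeatureRegistry) -> Set[str]:
    """Feature names expected to carry signal given the corpus dials.

    Conservation uplift marks the conservation family; GC-context bias marks
    the stability family, the composition-driven descriptors, and the
    composition-driven accessibility features; supplementary implants mark
    the 3'-supplementary family.  Site-type indicators are always included
    because chance negatives skew heavily toward 6mers.
    """
    names = set(registry.feature_names)
    out: Set[str] = set()
    out |= {n for n in names if n.startswith("st_")}
    if config.conservation_signal > 0:
        out |= {n for n in names if n.startswith("cons_")}
    if config.energy_bias > 0:
        out |= {n for n in names if n.startswith("stab_") or n.startswith("desc_")}
        out |= {n for n in names if n in (
            "acc_au_flank5", "acc_au_flank3", "acc_au_site", "acc_gc_region",
            "acc_open_energy", "acc_unpaired_site", "acc_unpaired_win10",
        )}
    if config.supp_rate > 0:
        out |= {n for n in names if n.startswith("supp_")}
    return out
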