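"""Transcript-level repression model over aggregated site probabilities.

For each (miRNA, gene) pair all canonical sites on the gene's longest
transcript are scored by the site-level model; the four aggregation
features — sum of probabilities plus the top three — feed the repression
classifier.  Absent top-k entries are NaN, not zero: no site is not the same
as a site of probability zero.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from mirbind.datasets import LABEL_COLUMN
from mirbind.features.registry import FeatureRegistry, featurize_many
from mirbind.models.ts import ModelBundle, predict_sites, train_ts
from mirbind.sequence_io import ResourceBundle
from mirbind.site_scanner import scan_candidate_sites

TM_FEATURES = ["sum_p", "top1", "top2", "top3"]


def aggregate_site_probs(
    probabilities: Sequence[float],
) -> Tuple[float, float, float, float]:
    """(sum, top1, top2, top3); missing entries are NaN, empty input sums to 0."""
    probs = [float(p) for p in probabilities]
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    ordered = sorted(probs, reverse=True)
    top = ordered[:3] + [math.nan] * (3 - len(ordered))
    return (float(sum(probs)), top[0], top[1], top[2])


def build_tm_dataset(
    ts_bundle: ModelBundle,
    resources: ResourceBundle,
    tm_labels: pd.DataFrame,
    registry: FeatureRegistry,
    flank: Optional[int] = None,
) -> pd.DataFrame:
    """Aggregation features for every labelled (miRNA, gene) pair.

    Pairs whose gene resolves to no transcript are skipped (and counted in
    the ``skipped`` attribute of the returned frame).
    """
    flank = registry.config.flank if flank is None else flank
    rows: List[dict] = []
    skipped: List[Tuple[str, str]] = []
    for _, rec in tm_labels.iterrows():
        mirna_id, gene_id = rec["mirna_id"], rec["gene_id"]
        try:
            mirna = resources.mirna_by_id(mirna_id)
            utr = resources.utr_for_gene(gene_id)
        except KeyError:
            skipped.append((mirna_id, gene_id))
            continue
        sites = scan_candidate_sites(mirna, utr, flank=flank)
        if sites:
            feats = featurize_many(sites, resources, registry)
            probs = predict_sites(ts_bundle, feats)
        else:
            probs = np.empty(0)
        sum_p, top1, top2, top3 = aggregate_site_probs(probs.tolist())
        rows.append({
            "mirna_id": mirna_id,
            "gene_id": gene_id,
            "transcript_id": utr.transcript_id,
            "n_sites": len(sites),
            "sum_p": sum_p,
            "top1": top1,
            "top2": top2,
            "top3": top3,
            LABEL_COLUMN: int(rec[LABEL_COLUMN]),
        })
    out = pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "transcript_id", "n_sites"]
        + TM_FEATURES + [LABEL_COLUMN],
    )
    out.attrs["skipped"] = skipped
    return out


def train_tm(
    tm_dataset: pd.DataFrame,
    model_config: Optional[Dict] = None,
    seed: int = 0,
    monotone: bool = False,
    features: Sequence[str] = tuple(TM_FEATURES),
) -> ModelBundle:
    """Train the repression classifier on the aggregation features."""
    labels = set(tm_dataset[LABEL_COLUMN].unique().tolist())
    if labels != {0, 1}:
        raise ValueError("both labels must be present")
    monotonic = [1] * len(features) if monotone else None
    return train_ts(
        tm_dataset, list(features), model_config=model_config, seed=seed,
        monotonic_cst=monotonic,
    )


def predict_tm(bundle: ModelBundle, examples: pd.DataFrame) -> np.ndarray:
    """Interaction confidence per (miRNA, transcript) example."""
    return predict_sites(bundle, examples)
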