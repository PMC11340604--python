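"""Assembly of labelled site-level (TS) and transcript-level (TM) datasets.

Positives come from verified site interactions; candidate negatives are
filtered against a validated-pair list (any candidate whose (miRNA, gene)
pair is validated is removed) and then balanced 1:1 by random under-sampling.
TM labels derive from relative expression versus an untransfected control:
<= 0.60 is repressed (positive), [1.00, 1.10] unaffected (negative),
everything else excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"


@dataclass(frozen=True)
class TMLabelConfig:
    repression_max: float = 0.60
    unaffected_low: float = 1.00
    unaffected_high: float = 1.10

    def __post_init__(self) -> None:
        if not self.repression_max < self.unaffected_low:
            raise ValueError("repression bound must lie below the unaffected range")


def filter_negatives(
    candidate_negatives: pd.DataFrame,
    validated_pairs: Set[Tuple[str, str]],
) -> Tuple[pd.DataFrame, int]:
    """Drop candidates whose (mirna_id, gene_id) pair is validated.

    Returns the surviving rows (order preserved) and the removal count.
    """
    if candidate_negatives.empty:
        return candidate_negatives, 0
    keys = list(zip(candidate_negatives["mirna_id"], candidate_negatives["gene_id"]))
    keep = [k not in validated_pairs for k in keys]
    kept = candidate_negatives[keep]
    return kept, int(len(candidate_negatives) - len(kept))


def undersample_balance(
    positives: pd.DataFrame, negatives: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """1:1 balanced dataset by uniform under-sampling of the majority class."""
    if positives.empty or negatives.empty:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    minority, majority, flip = positives, negatives, False
    if len(positives) > len(negatives):
        minority, majority, flip = negatives, positives, True
    idx = rng.choice(len(majority), size=len(minority), replace=False)
    sampled = majority.iloc[np.sort(idx)]
    parts = (sampled, minority) if flip else (minority, sampled)
    return pd.concat(parts, ignore_index=True)


def label_tm_from_expression(
    records: pd.DataFrame, config: TMLabelConfig = TMLabelConfig()
) -> pd.DataFrame:
    """Label (mirna_id, gene_id) pairs from relative expression; drop the rest."""
    expr = records["relative_expression"].to_numpy(dtype=float)
    if (expr < 0).any():
        bad = records.iloc[int(np.argmax(expr < 0))]
        raise ValueError(
            f"negative expression for ({bad['mirna_id']}, {bad['gene_id']})"
        )
    positive = expr <= config.repression_max
    negative = (expr >= config.unaffected_low) & (expr <= config.unaffected_high)
    out = records.loc[positive | negative, ["mirna_id", "gene_id"]].copy()
    out[LABEL_COLUMN] = positive[positive | negative].astype(int)
    return out.reset_index(drop=True)


def split_blind_test(
    dataset: pd.DataFrame, fraction: float = 0.2, seed: int = 0,
    stratified: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive (train, blind) split, stratified by label."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    blind_idx: List[int] = []
    if stratified:
        groups: Iterable[np.ndarray] = (
            np.flatnonzero(dataset[LABEL_COLUMN].to_numpy() == lab)
            for lab in sorted(dataset[LABEL_COLUMN].unique())
        )
    else:
        groups = [np.arange(len(dataset))]
    for idx in groups:
        n_blind = int(round(len(idx) * fraction))
        if n_blind == 0 or n_blind == len(idx):
            raise ValueError("fraction leaves a class empty on one side")
        blind_idx.extend(rng.choice(idx, size=n_blind, replace=False).tolist())
    mask = np.zeros(len(dataset), dtype=bool)
    mask[blind_idx] = True
    return dataset[~mask].reset_index(drop=True), dataset[mask].reset_index(drop=True)


def split_by_entity(
    dataset: pd.DataFrame, entity: str, fraction: float = 0.3, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out whole miRNAs and/or transcripts so test entities are unseen.

    ``entity`` is one of ``mirna``, ``transcript``, ``both``.
    """
    if entity not in ("mirna", "transcript", "both"):
        raise ValueError(f"unknown entity mode {entity!r}")
    rng = np.random.default_rng(seed)

    def held_out(column: str) -> Set[str]:
        ids = sorted(dataset[column].unique())
        n = int(round(len(ids) * fraction))
        if n == 0 or n == len(ids):
            raise ValueError(f"too few distinct {column} values to split")
        return set(rng.choice(ids, size=n, replace=False).tolist())

    test_mask = np.zeros(len(dataset), dtype=bool)
    if entity in ("mirna", "both"):
        held = held_out("mirna_id")
        test_mask |= dataset["mirna_id"].isin(held).to_numpy()
    if entity in ("transcript", "both"):
        held = held_out("transcript_id")
        test_mask |= dataset["transcript_id"].isin(held).to_numpy()
    train = dataset[~test_mask].reset_index(drop=True)
    test = dataset[test_mask].reset_index(drop=True)
    if entity == "both":
        # drop train rows touching any held-out entity on either axis
        bad_m = set(test["mirna_id"]) & set(train["mirna_id"])
        bad_t = set(test["transcript_id"]) & set(train["transcript_id"])
        test = test[
            ~(test["mirna_id"].isin(bad_m) | test["transcript_id"].isin(bad_t))
        ].reset_index(drop=True)
    return train, test
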