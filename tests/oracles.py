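"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own helpers: complements, metrics,
and aggregations are recomputed from first principles so the dual-route
checks stay meaningful.
"""

import itertools
import math

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def oracle_scan(mirna_seq: str, utr_seq: str):
    """All canonical sites by testing each of the four definitions at every
    UTR offset; returns a sorted list of (site_type, start, end)."""
    m6 = "".join(_COMP[b] for b in mirna_seq[1:7])[::-1]
    m7 = "".join(_COMP[b] for b in mirna_seq[1:8])[::-1]
    m8_comp = _COMP[mirna_seq[7]]
    L = len(utr_seq)
    hits = []
    for s in range(L):
        # 8mer: M7 then A
        if utr_seq[s:s + 7] == m7 and s + 7 < L and utr_seq[s + 7] == "A":
            hits.append(("8mer", s, s + 8))
        # 7mer-m8: M7 not followed by A (or boundary)
        elif utr_seq[s:s + 7] == m7 and (s + 7 >= L or utr_seq[s + 7] != "A"):
            hits.append(("7mer-m8", s, s + 7))
        # 7mer-A1: M6 then A, no m8 extension
        if (
            utr_seq[s:s + 6] == m6
            and s + 6 < L
            and utr_seq[s + 6] == "A"
            and (s == 0 or utr_seq[s - 1] != m8_comp)
        ):
            hits.append(("7mer-A1", s, s + 7))
        # 6mer: M6 with neither extension
        if (
            utr_seq[s:s + 6] == m6
            and (s == 0 or utr_seq[s - 1] != m8_comp)
            and (s + 6 >= L or utr_seq[s + 6] != "A")
        ):
            hits.append(("6mer", s, s + 6))
    return sorted(hits, key=lambda h: (h[1], h[2]))


def oracle_confusion_metrics(tp, fp, tn, fn):
    """Threshold metrics recomputed naively from confusion counts."""
    def div(a, b):
        return a / b if b else 0.0

    precision = div(tp, tp + fp)
    recall = div(tp, tp + fn)
    specificity = div(tn, tn + fp)
    f1 = div(2 * precision * recall, precision + recall)
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "mcc": mcc,
        "bacc": (recall + specificity) / 2,
    }


def oracle_auc(y_true, scores):
    """AUC by counting concordant score pairs, half credit for ties."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    if not pos or not neg:
        return math.nan
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))


def oracle_aggregate(probs):
    """Sort-and-sum aggregation: (sum, top1, top2, top3) with NaN padding."""
    ordered = sorted(probs, reverse=True) + [math.nan] * 3
    return (sum(probs), ordered[0], ordered[1], ordered[2])
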