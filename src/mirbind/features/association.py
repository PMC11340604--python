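"""Per-feature association with the binary class label.

Continuous features use the two-sided Mann-Whitney U rank-sum test; binary
indicator features use a chi-square contingency test.  Constant or
undecidable features are flagged non-informative rather than erroring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _is_indicator(values: np.ndarray) -> bool:
    uniq = set(np.unique(values[~np.isnan(values)]).tolist())
    return uniq <= {0.0, 1.0}


def feature_class_association(
    feature_matrix: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Statistic + p-value table, sorted by p-value (non-informative last)."""
    y = np.asarray(labels).astype(int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    records = []
    for name in feature_matrix.columns:
        x = feature_matrix[name].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        x_ok, y_ok = x[ok], y[ok]
        record = {"feature": name, "test": None, "statistic": np.nan,
                  "pvalue": np.nan, "informative": False}
        if len(np.unique(x_ok)) < 2 or len(set(y_ok.tolist())) < 2:
            record["test"] = "constant"
        elif _is_indicator(x_ok):
            table = pd.crosstab(x_ok, y_ok).to_numpy()
            if table.shape == (2, 2) and table.sum(axis=1).min() > 0:
                chi2, p, _, _ = stats.chi2_contingency(table)
                record.update(test="chi2", statistic=chi2, pvalue=p, informative=True)
            else:
                record["test"] = "degenerate"
        else:
            a, b = x_ok[y_ok == 1], x_ok[y_ok == 0]
            if len(a) >= 2 and len(b) >= 2:
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                record.update(test="mannwhitneyu", statistic=u, pvalue=p,
                              informative=True)
            else:
                record["test"] = "degenerate"
        records.append(record)
    out = pd.DataFrame(records)
    return out.sort_values(
        by=["informative", "pvalue"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
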