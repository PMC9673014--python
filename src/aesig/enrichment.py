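"""SOC-category enrichment of AE signatures.

For a SOC (system organ class) category with m member AEs and signature v,
the category's m probabilities in signature v are rank-tested (one-sided,
"greater") against the same m AEs' probabilities pooled across the other
k - 1 signatures.  The companion effect size is

    ES = (mean(w_v) - mean(w_v^c)) / sd(w_v^c)

with the sample (n-1) standard deviation of the pooled vector.

Raw p-values are reported (with a Benjamini-Hochberg column emitted for
reference but not used for the default significance flag).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# exact Mann-Whitney null when the pooled sample is this small and tie-free
_EXACT_LIMIT = 12


def _category_vectors(W: pd.DataFrame, mapping: dict, category: str, v):
    members = [ae for ae in W.index if mapping.get(ae) == category]
    if not members:
        raise ValueError(f"category {category!r} has no member AEs in W")
    if v not in W.columns:
        raise KeyError(f"signature {v!r} not in W columns")
    a = W.loc[members, v].to_numpy(dtype=float)
    others = [c for c in W.columns if c != v]
    b = W.loc[members, others].to_numpy(dtype=float).ravel()
    return a, b


def wilcoxon_category_test(W: pd.DataFrame, mapping: dict, category: str,
                           v) -> float:
    """One-sided (greater) two-sample rank test p-value.

    Uses the exact Mann-Whitney null when the pooled sample is small
    (m * k <= 12) and tie-free, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a, b = _category_vectors(W, mapping, category, v)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_LIMIT and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def effect_size(W: pd.DataFrame, mapping: dict, category: str, v) -> float:
    """Standardized mean difference of category probabilities in signature v
    versus the same AEs pooled over the other signatures."""
    a, b = _category_vectors(W, mapping, category, v)
    if b.size < 2:
        raise ValueError("pooled vector too short for a standard deviation")
    diff = a.mean() - b.mean()
    sd = b.std(ddof=1)
    if sd == 0:
        if diff == 0:
            return 0.0
        warnings.warn("pooled standard deviation is zero; "
                      "effect size reported as signed infinity")
        return float(np.sign(diff) * np.inf)
    return float(diff / sd)


def enrichment_table(W: pd.DataFrame, mapping: dict,
                     alpha: float = 0.05) -> pd.DataFrame:
    """p and ES for every (category, signature) pair, sorted by p."""
    missing = [ae for ae in W.index if ae not in mapping]
    if missing:
        raise ValueError(
            f"{len(missing)} AE(s) missing from the SOC mapping, "
            f"e.g. {missing[:3]}")
    categories = sorted(set(mapping[ae] for ae in W.index))
    rows = []
    for cat in categories:
        m = sum(mapping[ae] == cat for ae in W.index)
        for v in W.columns:
            rows.append({
                "category": cat, "signature": v, "m": m,
                "p": wilcoxon_category_test(W, mapping, cat, v),
                "ES": effect_size(W, mapping, cat, v),
            })
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["p"] <= alpha
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)
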