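"""Per-block univariate feature screening.

Wilcoxon rank-sum (Mann-Whitney U) with Benjamini-Hochberg FDR for
metabolite/lipid blocks, a two-sided Welch t-test with BH for
relative-abundance tables, top-k selection and the row-normalized
heatmap matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import (
    PIPELINE_STATES,
    OmicsBlock,
    PipelineOrderError,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

#: at or below this smaller-group size (and without ties) the exact
#: Mann-Whitney null distribution is used instead of the normal
#: approximation
EXACT_MAX_N = 8


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} min(1, m * p_(j) / j)`` on the sorted p's,
    mapped back to input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _split_groups(block: OmicsBlock, metadata: SampleMetadata,
                  factor: str, levels: tuple[str, str]):
    if metadata.sample_ids != block.sample_ids:
        raise ValueError("metadata and block sample ids/order disagree; align first")
    m1 = metadata.mask(factor, levels[0])
    m2 = metadata.mask(factor, levels[1])
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError(
            f"both levels need >= 2 samples (got {int(m1.sum())} and {int(m2.sum())})"
        )
    return block.matrix[m1], block.matrix[m2]


def wilcoxon_screen(
    block: OmicsBlock,
    metadata: SampleMetadata,
    factor: str,
    levels: tuple[str, str],
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature with BH q-values.

    The exact null distribution is used when the smaller group has at
    most :data:`EXACT_MAX_N` samples and the feature has no ties;
    otherwise the tie-corrected, continuity-corrected normal
    approximation.  ``direction`` is the sign of (mean of ``levels[1]``
    minus mean of ``levels[0]``) on the tested scale.
    """
    if block.state_index < PIPELINE_STATES.index("imputed"):
        raise PipelineOrderError(
            f"wilcoxon_screen needs state 'imputed' or later, got {block.state!r}"
        )
    x1, x2 = _split_groups(block, metadata, factor, levels)
    rows = []
    for j, fid in enumerate(block.feature_ids):
        a, b = x1[:, j], x2[:, j]
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (min(a.size, b.size) <= EXACT_MAX_N
                             and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        mean1, mean2 = float(a.mean()), float(b.mean())
        rows.append({
            "feature_id": fid,
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "method": method,
            "direction": int(np.sign(mean2 - mean1)),
            f"mean_{levels[0]}": mean1,
            f"mean_{levels[1]}": mean2,
        })
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def welch_screen(
    block: OmicsBlock,
    metadata: SampleMetadata,
    factor: str,
    levels: tuple[str, str],
) -> pd.DataFrame:
    """Two-sided Welch t-test (Satterthwaite df) per feature with BH q.

    Degenerate features (zero variance in both groups) get p = 1 when
    the means are equal and p = 0 otherwise, flagged in ``degenerate``.
    """
    x1, x2 = _split_groups(block, metadata, factor, levels)
    rows = []
    for j, fid in enumerate(block.feature_ids):
        a, b = x1[:, j], x2[:, j]
        mean1, mean2 = float(a.mean()), float(b.mean())
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        degenerate = v1 == 0 and v2 == 0
        if degenerate:
            if mean1 == mean2:
                t, p, df = 0.0, 1.0, float("nan")
            else:
                t, p, df = np.inf * np.sign(mean2 - mean1), 0.0, float("nan")
            logger.warning("welch_screen: feature %r has zero variance in both "
                           "groups", fid)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append({
            "feature_id": fid,
            "statistic": t,
            "p": p,
            "df": df,
            "degenerate": degenerate,
            "direction": int(np.sign(mean2 - mean1)),
            f"mean_{levels[0]}": mean1,
            f"mean_{levels[1]}": mean2,
        })
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def top_k_heatmap_matrix(
    table: pd.DataFrame,
    block: OmicsBlock,
    k: int = 50,
    alpha: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    """Row-normalized matrix of the top-``k`` features passing ``alpha``.

    Features with (raw) p < alpha are ranked by p ascending and
    truncated to ``k``; with ``use_q=True`` the BH q is used instead.
    Each row is scaled to zero mean / unit variance across samples and
    rows are ordered by average-linkage hierarchical clustering on
    Euclidean distance.  Returns an empty frame (with a warning) when
    nothing passes.
    """
    crit = "q" if use_q else "p"
    passed = table[table[crit] < alpha].sort_values(
        [crit, "feature_id"], kind="stable")
    selected = list(passed["feature_id"].iloc[:k])
    if not selected:
        logger.warning("top_k_heatmap_matrix: no feature passes %s < %g",
                       crit, alpha)
        return pd.DataFrame(columns=list(block.sample_ids))

    index = {f: j for j, f in enumerate(block.feature_ids)}
    sub = block.matrix[:, [index[f] for f in selected]].T  # features x samples
    sub = sub - sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    sub /= sd

    if sub.shape[0] > 2:
        link = hierarchy.linkage(pdist(sub, metric="euclidean"),
                                 method="average")
        order = hierarchy.leaves_list(
            hierarchy.optimal_leaf_ordering(link, pdist(sub)))
    else:
        order = np.arange(sub.shape[0])
    return pd.DataFrame(sub[order], index=[selected[i] for i in order],
                        columns=list(block.sample_ids))
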