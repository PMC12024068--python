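"""Per-block preprocessing chain.

Order: prevalence filter -> per-sample median normalization ->
uniform-random imputation of censored entries -> log10 -> autoscaling.
Each step checks the block's processing state, so calling a step out of
order raises :class:`~mbfuse.data_model.PipelineOrderError`.
"""

from __future__ import annotations

import logging

import numpy as np

from .data_model import OmicsBlock

logger = logging.getLogger(__name__)


def filter_features(block: OmicsBlock, min_prevalence: float = 0.5) -> OmicsBlock:
    """Keep features observed (non-missing, non-zero) in at least
    ``min_prevalence`` of samples (boundary inclusive).

    ``min_prevalence=0`` keeps every feature.  Dropping all features is
    a hard error.
    """
    block.require_state("raw")
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must lie in [0, 1]")
    mat = block.matrix
    observed = np.isfinite(mat) & (mat != 0)
    prevalence = observed.mean(axis=0)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise ValueError(
            f"block {block.name!r}: every feature dropped at "
            f"min_prevalence={min_prevalence}"
        )
    dropped = [f for f, k in zip(block.feature_ids, keep) if not k]
    if dropped:
        logger.info("filter_features(%s): dropped %d features: %s",
                    block.name, len(dropped), ", ".join(dropped[:20]))
    kept_ids = [f for f, k in zip(block.feature_ids, keep) if k]
    return block.advance("filtered", matrix=mat[:, keep], feature_ids=kept_ids)


def median_normalize(block: OmicsBlock, mode: str = "positive") -> OmicsBlock:
    """Divide each sample row by its median intensity.

    ``mode="positive"`` (default) takes the median over positive
    non-missing entries, so zeros from detection-limit censoring do not
    drag the normalizer down; ``mode="all"`` uses all non-missing
    entries.  Zeros stay zero and missing stays missing.
    """
    block.require_state("filtered")
    if mode not in ("positive", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    mat = block.matrix.copy()
    medians = np.empty(block.n_samples)
    for i, sid in enumerate(block.sample_ids):
        row = mat[i]
        vals = row[np.isfinite(row) & (row > 0)] if mode == "positive" \
            else row[np.isfinite(row)]
        if vals.size == 0 or (mode == "all" and np.median(vals) <= 0):
            raise ValueError(
                f"sample {sid!r} has no positive entries; cannot median-normalize"
            )
        medians[i] = np.median(vals)
    mat /= medians[:, None]
    return block.advance("median_normalized", matrix=mat)


def impute(block: OmicsBlock, seed: int) -> OmicsBlock:
    """Replace each missing or zero entry of column *j* by ``u * m_j / 5``
    with ``u ~ Uniform(0, 1]`` and ``m_j`` the column's smallest non-zero
    value.  Deterministic for a fixed seed; the output is strictly
    positive everywhere.
    """
    block.require_state("median_normalized")
    rng = np.random.default_rng(seed)
    mat = block.matrix.copy()
    for j, fid in enumerate(block.feature_ids):
        col = mat[:, j]
        positive = col[np.isfinite(col) & (col > 0)]
        needs = ~np.isfinite(col) | (col == 0)
        if positive.size == 0:
            raise ValueError(
                f"column {fid!r} has no non-zero entries; run filter_features first"
            )
        if needs.any():
            # 1 - random() lies in (0, 1]: imputed values stay strictly
            # positive so the log step downstream never sees zero.
            u = 1.0 - rng.random(int(needs.sum()))
            mat[needs, j] = u * (positive.min() / 5.0)
    return block.advance("imputed", matrix=mat)


def log10_transform(block: OmicsBlock) -> OmicsBlock:
    """Entrywise base-10 logarithm; requires strictly positive input."""
    block.require_state("imputed")
    mat = block.matrix
    if not np.isfinite(mat).all() or (mat <= 0).any():
        raise ValueError(
            f"block {block.name!r} contains non-positive or missing entries; "
            "impute before log-transforming"
        )
    return block.advance("log10", matrix=np.log10(mat))


def autoscale(block: OmicsBlock) -> OmicsBlock:
    """Center each column to mean zero and scale to unit variance (n-1).

    Constant columns are centered and left at zero with a warning.
    """
    block.require_state("log10", "epo")
    mat = block.matrix.copy()
    mat -= mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        names = [f for f, c in zip(block.feature_ids, constant) if c]
        logger.warning("autoscale(%s): constant columns left at zero: %s",
                       block.name, ", ".join(names[:20]))
    sd[constant] = 1.0
    mat /= sd
    return block.advance("autoscaled", matrix=mat)


def preprocess_block(
    block: OmicsBlock,
    seed: int,
    min_prevalence: float = 0.5,
    median_mode: str = "positive",
) -> OmicsBlock:
    """Run filter -> median_normalize -> impute on a raw block."""
    out = filter_features(block, min_prevalence=min_prevalence)
    out = median_normalize(out, mode=median_mode)
    return impute(out, seed=seed)
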