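"""External Parameter Orthogonalization.

Estimates a detrimental-variation subspace from an interference matrix
(by default, grand-mean-centered class means of a user-named nuisance
factor) and projects block data onto its orthogonal complement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import OmicsBlock, SampleMetadata


@dataclass(frozen=True)
class EpoModel:
    """Loadings spanning the detrimental subspace and the projector they induce.

    ``loadings`` is features x k with orthonormal columns; the implied
    corrector is ``P = I - V V^T``.
    """

    n_components: int
    loadings: np.ndarray
    feature_ids: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        V = np.asarray(self.loadings, dtype=float)
        object.__setattr__(self, "loadings", V)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if V.shape != (len(self.feature_ids), self.n_components):
            raise ValueError(
                f"loadings shape {V.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {self.n_components} components"
            )
        if self.n_components:
            gram = V.T @ V
            if not np.allclose(gram, np.eye(self.n_components), atol=1e-10):
                raise ValueError("EPO loadings are not orthonormal")


def fit_epo(D: np.ndarray, k: int, feature_ids=None, source: str = "") -> EpoModel:
    """Fit the detrimental subspace as the first ``k`` right singular
    vectors of the column-centered interference matrix ``D``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise ValueError("interference matrix must be 2-D")
    if feature_ids is None:
        feature_ids = tuple(f"f{j}" for j in range(D.shape[1]))
    if k < 0:
        raise ValueError("k must be non-negative")
    centered = D - D.mean(axis=0)
    if k == 0:
        return EpoModel(0, np.zeros((D.shape[1], 0)), tuple(feature_ids), source)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(centered.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if k > rank:
        raise ValueError(
            f"requested k={k} detrimental components but the centered "
            f"interference matrix has rank {rank}"
        )
    return EpoModel(k, vt[:k].T, tuple(feature_ids), source)


def build_interference_matrix(
    block: OmicsBlock, metadata: SampleMetadata, nuisance_factor: str
) -> np.ndarray:
    """Level-mean interference matrix: one row per nuisance level, each
    row that level's feature means, centered on the grand level mean.
    """
    block.require_state("log10")
    levels = metadata.levels(nuisance_factor)
    if len(levels) < 2:
        raise ValueError(
            f"nuisance factor {nuisance_factor!r} has {len(levels)} level(s); "
            "need at least 2"
        )
    rows = []
    for level in levels:
        mask = metadata.mask(nuisance_factor, level)
        if not mask.any():
            raise ValueError(f"nuisance level {level!r} has no samples")
        rows.append(block.matrix[mask].mean(axis=0))
    D = np.vstack(rows)
    return D - D.mean(axis=0)


def apply_epo(block: OmicsBlock, model: EpoModel) -> OmicsBlock:
    """Project the block onto the orthogonal complement of the
    detrimental subspace: ``X <- X (I - V V^T)``.
    """
    block.require_state("log10")
    if block.feature_ids != model.feature_ids:
        raise ValueError(
            f"block {block.name!r} features do not match the EPO model "
            f"({block.n_features} vs {len(model.feature_ids)})"
        )
    V = model.loadings
    corrected = block.matrix - (block.matrix @ V) @ V.T if model.n_components \
        else block.matrix.copy()
    return block.advance("epo", matrix=corrected)


def save_epo_model(model: EpoModel, prefix: str | Path) -> None:
    """Serialize to ``<prefix>_loadings.csv`` + ``<prefix>.json``."""
    prefix = Path(prefix)
    cols = [f"epo{c + 1}" for c in range(model.n_components)]
    pd.DataFrame(model.loadings, index=list(model.feature_ids), columns=cols) \
        .to_csv(prefix.with_name(prefix.name + "_loadings.csv"))
    meta = {"n_components": model.n_components, "source": model.source}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_epo_model(prefix: str | Path) -> EpoModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_name(prefix.name + "_loadings.csv"), index_col=0)
    return EpoModel(
        n_components=int(meta["n_components"]),
        loadings=df.to_numpy(),
        feature_ids=tuple(df.index.astype(str)),
        source=meta.get("source", ""),
    )
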