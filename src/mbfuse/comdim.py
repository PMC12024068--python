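"""ComDim / CCSWA multiblock fusion.

Per-block Frobenius normalization followed by iterative extraction of
common components.  For each component the algorithm alternates between
the dominant eigenvector of the salience-weighted sum of block
association matrices and the salience update ``lambda_b = q' W_b q``,
then deflates every block and moves to the next component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MultiblockDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentConvergence:
    component: int
    n_iter: int
    final_delta: float
    converged: bool
    objective: tuple[float, ...]  # sum_b lambda_b^2 per iteration


@dataclass(frozen=True)
class ComDimResult:
    """Fitted common components.

    Attributes
    ----------
    scores
        samples x n_components.  By default columns carry
        ``sqrt(eigenvalue)`` scaling; ``unit_scores`` holds the
        unit-norm variants.
    saliences
        blocks x n_components, non-negative block weights.
    block_loadings
        block name -> features x n_components array (``X_b' q``).
    explained
        Per component, fraction of the total fused sum of squares
        removed by its deflation.
    """

    scores: np.ndarray
    unit_scores: np.ndarray
    eigenvalues: np.ndarray
    saliences: np.ndarray
    block_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    block_loadings: dict[str, np.ndarray]
    block_feature_ids: dict[str, tuple[str, ...]]
    explained: np.ndarray
    convergence: tuple[ComponentConvergence, ...] = field(default_factory=tuple)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"CC{c + 1}" for c in range(self.n_components)]
        df = pd.DataFrame(self.scores, index=list(self.sample_ids), columns=cols)
        df.index.name = "sample_id"
        return df


def frobenius_scale(dataset: MultiblockDataset) -> MultiblockDataset:
    """Divide each block by its Frobenius norm so every block carries
    unit total variance into the fusion.
    """
    scaled = []
    for b in dataset.blocks:
        b.require_state("autoscaled")
        norm = float(np.linalg.norm(b.matrix))
        if norm == 0:
            raise ValueError(f"block {b.name!r} has zero Frobenius norm")
        scaled.append(b.advance("block_scaled", matrix=b.matrix / norm))
    return dataset.with_blocks(scaled)


def _dominant_eigpair(W: np.ndarray) -> tuple[float, np.ndarray]:
    # dense symmetric solve: sample counts are tens, exactness over speed
    vals, vecs = np.linalg.eigh(W)
    return float(vals[-1]), vecs[:, -1]


def _fix_sign(q: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(q)))
    return q if q[i] >= 0 else -q


def fit_comdim(
    dataset: MultiblockDataset,
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ComDimResult:
    """Extract ``n_components`` common components with per-block saliences.

    Blocks must be in state ``block_scaled``.  Non-convergence within
    ``max_iter`` is recorded per component, not fatal.
    """
    for b in dataset.blocks:
        b.require_state("block_scaled")
    n = len(dataset.sample_ids)
    if not 1 <= n_components <= n - 1:
        raise ValueError(
            f"n_components must lie in [1, {n - 1}] for {n} samples"
        )

    names = dataset.block_names
    X = {b.name: b.matrix.copy() for b in dataset.blocks}
    total_ss = sum(float(np.sum(x * x)) for x in X.values())

    scores = np.zeros((n, n_components))
    unit_scores = np.zeros((n, n_components))
    eigenvalues = np.zeros(n_components)
    saliences = np.zeros((len(names), n_components))
    loadings = {name: np.zeros((X[name].shape[1], n_components)) for name in names}
    explained = np.zeros(n_components)
    convergence: list[ComponentConvergence] = []

    for c in range(n_components):
        W = {name: X[name] @ X[name].T for name in names}
        lam = np.ones(len(names))
        objective: list[float] = []
        delta = np.inf
        q = np.zeros(n)
        eig = 0.0
        for it in range(1, max_iter + 1):
            W_global = np.zeros((n, n))
            for lb, name in zip(lam, names):
                W_global += lb * W[name]
            eig, q = _dominant_eigpair(W_global)
            new_lam = np.array([float(q @ W[name] @ q) for name in names])
            objective.append(float(np.sum(new_lam ** 2)))
            delta = float(np.max(np.abs(new_lam - lam)))
            lam = new_lam
            if delta < tol:
                break
        converged = delta < tol
        if not converged:
            logger.warning("component %d: no convergence after %d iterations "
                           "(delta=%.3e)", c + 1, max_iter, delta)
        q = _fix_sign(q / np.linalg.norm(q))
        # variance of the (unweighted) fused data along q: sum_b q'W_b q
        eig = float(np.sum(lam))

        unit_scores[:, c] = q
        eigenvalues[c] = eig
        scores[:, c] = q * np.sqrt(max(eig, 0.0))
        saliences[:, c] = lam

        removed = 0.0
        for name in names:
            before = float(np.sum(X[name] ** 2))
            loadings[name][:, c] = X[name].T @ q
            X[name] -= np.outer(q, q @ X[name])
            removed += before - float(np.sum(X[name] ** 2))
        explained[c] = removed / total_ss if total_ss else 0.0
        convergence.append(ComponentConvergence(
            component=c + 1, n_iter=len(objective), final_delta=delta,
            converged=converged, objective=tuple(objective),
        ))

    return ComDimResult(
        scores=scores,
        unit_scores=unit_scores,
        eigenvalues=eigenvalues,
        saliences=saliences,
        block_names=names,
        sample_ids=dataset.sample_ids,
        block_loadings=loadings,
        block_feature_ids={b.name: b.feature_ids for b in dataset.blocks},
        explained=explained,
        convergence=tuple(convergence),
    )


def salience_table(result: ComDimResult) -> pd.DataFrame:
    """Blocks x components salience table with a trailing
    ``explained_fraction`` row.
    """
    cols = [f"CC{c + 1}" for c in range(result.n_components)]
    df = pd.DataFrame(result.saliences, index=list(result.block_names), columns=cols)
    df.loc["explained_fraction"] = result.explained
    df.index.name = "block"
    return df
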