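"""Synthetic multiblock generator with ground truth.

Emulates a four-block MS study design: log-normal intensity scales,
one shared latent factor with per-block signal strengths, a planted
nuisance direction, a two-factor group design with unbalanced small
groups, and value-dependent (limit-of-detection) censoring to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .comdim import ComDimResult
from .data_model import MultiblockDataset, OmicsBlock, SampleMetadata


@dataclass(frozen=True)
class BlockSpec:
    """Per-block simulation parameters."""

    name: str
    n_features: int = 60
    shared_signal: float = 1.0    # strength of the shared latent score
    nuisance_strength: float = 0.0
    noise_sd: float = 0.3
    affected_fraction: float = 0.25  # fraction of features loading on the signal


@dataclass(frozen=True)
class SimConfig:
    """Simulation design.

    Default group sizes (3, 4, 8, 8) over genotype x treatment mirror a
    small unbalanced in-vivo design so degenerate-small-n code paths
    (exact rank tests, the n >= 3 ellipse rule) get exercised.
    """

    group_sizes: tuple[int, int, int, int] = (3, 4, 8, 8)
    group_factor: str = "genotype"
    group_levels: tuple[str, str] = ("AKR", "SAMP")
    nuisance_factor: str = "treatment"
    nuisance_levels: tuple[str, str] = ("vehicle", "RED")
    blocks: tuple[BlockSpec, ...] = (
        BlockSpec("metabolomics_pos", 80, 1.0, 0.5, 0.3),
        BlockSpec("metabolomics_neg", 70, 0.8, 0.5, 0.3),
        BlockSpec("lipidomics_pos", 90, 0.6, 0.5, 0.3),
        BlockSpec("lipidomics_neg", 60, 0.4, 0.5, 0.3),
    )
    group_effect: float = 2.0
    censor_quantile: float = 0.1
    intensity_location: float = 4.0  # log10 scale of typical intensities
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 4 or any(g < 1 for g in self.group_sizes):
            raise ValueError("group_sizes must be 4 positive counts "
                             "(genotype x treatment cells)")
        if not 0.0 <= self.censor_quantile <= 0.5:
            raise ValueError("censor_quantile must lie in [0, 0.5]")
        for b in self.blocks:
            if b.n_features < 1:
                raise ValueError(f"block {b.name!r}: n_features must be >= 1")
            if min(b.shared_signal, b.nuisance_strength, b.noise_sd) < 0:
                raise ValueError(f"block {b.name!r}: strengths must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery evaluation."""

    shared_score: np.ndarray            # t, per sample
    nuisance_score: np.ndarray          # u, per sample (+-1 coding)
    shared_strengths: dict[str, float]  # s_b per block
    loadings: dict[str, np.ndarray]     # p_b per block
    nuisance_loadings: dict[str, np.ndarray]
    affected: dict[str, tuple[str, ...]]  # truly signal-carrying features
    sample_ids: tuple[str, ...]


def simulate(config: SimConfig) -> tuple[MultiblockDataset, GroundTruth]:
    """Generate a raw multiblock dataset plus its ground truth.

    Per block: ``log10 intensity = loc + s_b * t p_b' + nu_b * u r_b'
    + noise``, exponentiated, then the lowest ``censor_quantile`` of
    each column set to exactly zero.  Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    g1, g2 = config.group_levels
    t1, t2 = config.nuisance_levels
    cells = [(g1, t1), (g1, t2), (g2, t1), (g2, t2)]

    genotype: list[str] = []
    treatment: list[str] = []
    for (g, tr), size in zip(cells, config.group_sizes):
        genotype += [g] * size
        treatment += [tr] * size
    n = len(genotype)
    sample_ids = tuple(f"S{i + 1:03d}" for i in range(n))
    metadata = SampleMetadata(
        sample_ids=sample_ids,
        factors={config.group_factor: tuple(genotype),
                 config.nuisance_factor: tuple(treatment)},
    )

    group_code = np.array([1.0 if g == g2 else -1.0 for g in genotype])
    t = config.group_effect / 2.0 * group_code + rng.standard_normal(n)
    u = np.array([1.0 if tr == t2 else -1.0 for tr in treatment])

    blocks: list[OmicsBlock] = []
    loadings: dict[str, np.ndarray] = {}
    nuis_loadings: dict[str, np.ndarray] = {}
    affected: dict[str, tuple[str, ...]] = {}
    strengths: dict[str, float] = {}
    for spec in config.blocks:
        p = spec.n_features
        fids = tuple(f"{spec.name}_f{j + 1:04d}" for j in range(p))

        n_hit = max(1, int(round(spec.affected_fraction * p)))
        hit = rng.choice(p, size=n_hit, replace=False)
        pb = np.zeros(p)
        pb[hit] = rng.choice([-1.0, 1.0], size=n_hit) * rng.uniform(0.5, 1.0, n_hit)
        pb /= np.linalg.norm(pb)

        rb = rng.standard_normal(p)
        rb -= (rb @ pb) * pb  # nuisance direction orthogonal to the signal
        rb /= np.linalg.norm(rb)

        log_int = (
            config.intensity_location
            + spec.shared_signal * np.outer(t, pb)
            + spec.nuisance_strength * np.outer(u, rb)
            + spec.noise_sd * rng.standard_normal((n, p))
        )
        intensity = 10.0 ** log_int
        if config.censor_quantile > 0:
            cutoff = np.quantile(intensity, config.censor_quantile, axis=0)
            intensity = np.where(intensity <= cutoff, 0.0, intensity)

        blocks.append(OmicsBlock(name=spec.name, matrix=intensity,
                                 sample_ids=sample_ids, feature_ids=fids))
        loadings[spec.name] = pb
        nuis_loadings[spec.name] = rb
        strengths[spec.name] = spec.shared_signal
        affected[spec.name] = tuple(fids[j] for j in sorted(hit)) \
            if spec.shared_signal > 0 else ()

    dataset = MultiblockDataset(blocks=tuple(blocks), metadata=metadata)
    truth = GroundTruth(
        shared_score=t, nuisance_score=u, shared_strengths=strengths,
        loadings=loadings, nuisance_loadings=nuis_loadings,
        affected=affected, sample_ids=sample_ids,
    )
    return dataset, truth


def truth_eval(result, truth: GroundTruth,
               univariate_table=None, block_name: str | None = None,
               q_threshold: float = 0.05) -> dict:
    """Compare a fitted result against the planted ground truth.

    For a :class:`ComDimResult`: |corr(component-1 scores, t)| and the
    Kendall tau between component-1 saliences and the planted per-block
    strengths.  With a univariate table and block name: sensitivity and
    false-discovery proportion of the q < threshold screen against the
    truly affected feature set.
    """
    metrics: dict = {}
    if isinstance(result, ComDimResult):
        if result.sample_ids != truth.sample_ids:
            raise ValueError("result and ground truth sample ids do not match")
        r = np.corrcoef(result.scores[:, 0], truth.shared_score)[0, 1]
        metrics["score_correlation"] = float(abs(r))
        s = [truth.shared_strengths[b] for b in result.block_names]
        tau = stats.kendalltau(result.saliences[:, 0], s).statistic
        metrics["salience_kendall_tau"] = float(tau)
    elif isinstance(result, np.ndarray):
        if result.shape != truth.shared_score.shape:
            raise ValueError("score vector length does not match ground truth")
        r = np.corrcoef(result, truth.shared_score)[0, 1]
        metrics["score_correlation"] = float(abs(r))

    if univariate_table is not None:
        if block_name is None or block_name not in truth.affected:
            raise ValueError("block_name required (and must match the "
                             "simulation) to score a univariate table")
        true_set = set(truth.affected[block_name])
        called = set(
            univariate_table.loc[univariate_table["q"] < q_threshold,
                                 "feature_id"]
        )
        metrics["n_discoveries"] = len(called)
        metrics["sensitivity"] = (
            len(called & true_set) / len(true_set) if true_set else float("nan")
        )
        metrics["fdp"] = (
            len(called - true_set) / len(called) if called else float("nan")
        )
    return metrics
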