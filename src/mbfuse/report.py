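"""Score plots with per-class Hotelling T² confidence ellipses."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse
from scipy import stats

from .comdim import ComDimResult
from .data_model import SampleMetadata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EllipseSpec:
    """A 2-D Hotelling T² confidence ellipse for one class.

    ``semi_axes`` are (major, minor); ``angle`` is the major axis angle
    in radians.
    """

    label: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float
    confidence: float
    n: int


def hotelling_critical(n: int, confidence: float) -> float:
    """Squared Mahalanobis radius c² = 2(n-1)/(n-2) · F_{2,n-2}(confidence).

    F-based small-sample scaling; the χ² asymptotic under-covers for the
    tiny class sizes this targets.
    """
    if n < 3:
        raise ValueError("need n >= 3 for a T² ellipse")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    return 2.0 * (n - 1) / (n - 2) * stats.f.ppf(confidence, 2, n - 2)


def hotelling_ellipse(scores: np.ndarray, confidence: float = 0.98,
                      label: str = "") -> EllipseSpec:
    """Fit a T² confidence ellipse to one class's 2-column scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    n = scores.shape[0]
    c2 = hotelling_critical(n, confidence)
    center = scores.mean(axis=0)
    S = np.cov(scores, rowvar=False)
    if np.linalg.det(S) <= 0 or not np.all(np.isfinite(S)):
        raise ValueError(
            f"singular score covariance for class {label!r}; scores are "
            "collinear — add jitter or more samples"
        )
    evals, evecs = np.linalg.eigh(S)  # ascending
    c = np.sqrt(c2)
    major, minor = c * np.sqrt(evals[1]), c * np.sqrt(evals[0])
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    return EllipseSpec(
        label=label,
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(major), float(minor)),
        angle=angle,
        confidence=float(confidence),
        n=n,
    )


def points_inside(scores: np.ndarray, spec_scores: np.ndarray,
                  confidence: float) -> np.ndarray:
    """Boolean mask of which ``scores`` fall inside the T² ellipse fitted
    on ``spec_scores`` — the defining Mahalanobis inequality, used for
    coverage checks.
    """
    spec_scores = np.asarray(spec_scores, dtype=float)
    c2 = hotelling_critical(spec_scores.shape[0], confidence)
    center = spec_scores.mean(axis=0)
    Sinv = np.linalg.inv(np.cov(spec_scores, rowvar=False))
    d = np.asarray(scores, dtype=float) - center
    return np.einsum("ij,jk,ik->i", d, Sinv, d) <= c2


def score_plot(
    result: ComDimResult,
    metadata: SampleMetadata,
    class_factor: str,
    confidence: float = 0.98,
    components: tuple[int, int] = (0, 1),
    path: str | Path | None = None,
):
    """2-D score scatter with one T² ellipse per class level.

    Classes with fewer than 3 samples get their points drawn but the
    ellipse skipped with a warning.  Returns ``(figure, [EllipseSpec])``.
    """
    if result.n_components < 2:
        raise ValueError("score_plot needs at least 2 fitted components")
    ci, cj = components
    xy = result.scores[:, [ci, cj]]
    levels = metadata.levels(class_factor)
    cmap = plt.get_cmap("tab10")

    fig, ax = plt.subplots(figsize=(6, 5))
    specs: list[EllipseSpec] = []
    for idx, level in enumerate(levels):
        mask = metadata.mask(class_factor, level)
        pts = xy[mask]
        color = cmap(idx % 10)
        ax.scatter(pts[:, 0], pts[:, 1], s=30, color=color, label=level,
                   edgecolors="k", linewidths=0.4, zorder=3)
        if pts.shape[0] < 3:
            logger.warning("score_plot: class %r has n=%d < 3, ellipse skipped",
                           level, pts.shape[0])
            continue
        spec = hotelling_ellipse(pts, confidence=confidence, label=level)
        specs.append(spec)
        ax.add_patch(Ellipse(
            spec.center, width=2 * spec.semi_axes[0],
            height=2 * spec.semi_axes[1], angle=np.degrees(spec.angle),
            facecolor=color, alpha=0.15, edgecolor=color, lw=1.2,
        ))
    ax.set_xlabel(f"CC{ci + 1} ({100 * result.explained[ci]:.1f}%)")
    ax.set_ylabel(f"CC{cj + 1} ({100 * result.explained[cj]:.1f}%)")
    ax.legend(frameon=False)
    ax.axhline(0, color="0.8", lw=0.6, zorder=0)
    ax.axvline(0, color="0.8", lw=0.6, zorder=0)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150, metadata=_figure_metadata(path))
    return fig, specs


def _figure_metadata(path: str | Path) -> dict | None:
    # strip timestamps so reruns are byte-identical
    suffix = Path(path).suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    return None


def write_ellipses(specs: list[EllipseSpec], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(s) for s in specs], indent=2))
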