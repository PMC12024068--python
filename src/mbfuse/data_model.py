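"""Domain types and I/O for multiblock feature tables.

An :class:`OmicsBlock` is one platform's samples x features intensity
matrix.  Missing values are carried as NaN and are distinct from exact
zeros until imputation.  Blocks progress through an ordered processing
state machine; each processing operation checks and advances the state
so that stages cannot run out of order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Orderered processing states.  Transitions may skip states but never
#: move backwards.
PIPELINE_STATES = (
    "raw",
    "filtered",
    "median_normalized",
    "imputed",
    "log10",
    "epo",
    "autoscaled",
    "block_scaled",
)

#: Cell contents parsed as missing (in addition to empty cells).
MISSING_SENTINELS = ("NA", "NaN", "nan", "na", "N/A", "")


class PipelineOrderError(RuntimeError):
    """Raised when a processing operation is applied out of order."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class OmicsBlock:
    """One samples x features intensity table with processing state.

    Parameters
    ----------
    name
        Block identifier, e.g. ``"lipidomics_pos"``.
    matrix
        Float array of shape ``(n_samples, n_features)``.  NaN encodes
        missing; raw intensities must otherwise be non-negative.
    sample_ids, feature_ids
        Unique string identifiers for rows / columns.
    state
        Current processing state, one of :data:`PIPELINE_STATES`.
    """

    name: str
    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    state: str = "raw"

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if mat.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"block {self.name!r}: matrix shape {mat.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.state not in PIPELINE_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "raw":
            finite = mat[np.isfinite(mat)]
            if finite.size and finite.min() < 0:
                raise ValueError(f"block {self.name!r}: raw intensities must be >= 0")

    # -- state machine -------------------------------------------------

    @property
    def state_index(self) -> int:
        return PIPELINE_STATES.index(self.state)

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise PipelineOrderError(
                f"block {self.name!r} is in state {self.state!r}; "
                f"operation requires state in {allowed}"
            )

    def advance(self, new_state: str, matrix: np.ndarray | None = None,
                feature_ids: Sequence[str] | None = None) -> "OmicsBlock":
        """Return a copy advanced to ``new_state`` (forward-only)."""
        if PIPELINE_STATES.index(new_state) <= self.state_index:
            raise PipelineOrderError(
                f"cannot move block {self.name!r} from {self.state!r} to {new_state!r}: "
                "pipeline states only advance"
            )
        kwargs: dict = {"state": new_state}
        if matrix is not None:
            kwargs["matrix"] = matrix
        if feature_ids is not None:
            kwargs["feature_ids"] = tuple(feature_ids)
        return replace(self, **kwargs)

    # -- convenience ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.sample_ids),
                            columns=list(self.feature_ids))


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample categorical factors (genotype, age, treatment, ...)."""

    sample_ids: tuple[str, ...]
    factors: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.sample_ids, "sample")
        factors = {k: tuple(str(v) for v in vals) for k, vals in self.factors.items()}
        for name, vals in factors.items():
            if len(vals) != len(self.sample_ids):
                raise ValueError(
                    f"factor {name!r} has {len(vals)} values for "
                    f"{len(self.sample_ids)} samples"
                )
        object.__setattr__(self, "factors", factors)

    def levels(self, factor: str) -> tuple[str, ...]:
        vals = self.factor_values(factor)
        out: list[str] = []
        for v in vals:
            if v not in out:
                out.append(v)
        return tuple(out)

    def factor_values(self, factor: str) -> tuple[str, ...]:
        if factor not in self.factors:
            raise KeyError(f"unknown factor {factor!r}; have {sorted(self.factors)}")
        return self.factors[factor]

    def mask(self, factor: str, level: str) -> np.ndarray:
        vals = self.factor_values(factor)
        if level not in vals:
            raise ValueError(f"level {level!r} absent from factor {factor!r}")
        return np.array([v == level for v in vals])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [index[s] for s in sample_ids]
        return SampleMetadata(
            sample_ids=tuple(sample_ids),
            factors={k: tuple(v[i] for i in idx) for k, v in self.factors.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(dict(self.factors), index=list(self.sample_ids))
        df.index.name = "sample_id"
        return df


@dataclass(frozen=True)
class MultiblockDataset:
    """Blocks sharing one identically ordered sample index plus metadata."""

    blocks: tuple[OmicsBlock, ...]
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        names = [b.name for b in self.blocks]
        _check_unique(names, "block")
        ref = self.metadata.sample_ids
        for b in self.blocks:
            if b.sample_ids != ref:
                raise ValueError(
                    f"block {b.name!r} sample order disagrees with metadata"
                )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.metadata.sample_ids

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks)

    def block(self, name: str) -> OmicsBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")

    def with_blocks(self, blocks: Sequence[OmicsBlock]) -> "MultiblockDataset":
        return MultiblockDataset(blocks=tuple(blocks), metadata=self.metadata)


# ---------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------

def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_feature_table(
    path: str | Path,
    orientation: str = "samples_in_rows",
    name: str | None = None,
    delimiter: str | None = None,
) -> OmicsBlock:
    """Read a delimited feature table into a raw :class:`OmicsBlock`.

    Empty cells, ``NA`` and ``NaN`` parse as missing; exact zeros are
    preserved as zeros.  Duplicated ids or non-numeric body cells are
    hard errors.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)

    # pandas silently renames duplicated header ids; check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for h in header:
        if h in seen:
            raise ValueError(f"duplicate column id in {path.name}: {h!r}")
        seen.add(h)

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate row id in {path.name}: {dup[0]!r}")

    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j, col in enumerate(df.columns):
        for i, row in enumerate(df.index):
            cell = raw[i, j].strip() if isinstance(raw[i, j], str) else raw[i, j]
            if cell in MISSING_SENTINELS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {row!r}, column {col!r} "
                    f"in {path.name}"
                ) from None

    if orientation == "features_in_rows":
        values = values.T
        sample_ids, feature_ids = tuple(df.columns), tuple(df.index)
    else:
        sample_ids, feature_ids = tuple(df.index), tuple(df.columns)

    return OmicsBlock(
        name=name or path.stem,
        matrix=values,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
    )


def write_feature_table(
    block: OmicsBlock,
    path: str | Path,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
) -> None:
    """Write a block to CSV/TSV.  Missing entries are written as empty cells."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = block.to_frame()
    if orientation == "features_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=sep, na_rep="")


def read_metadata(path: str | Path, delimiter: str | None = None) -> SampleMetadata:
    """Read a metadata table (header ``sample_id`` + factor columns)."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    first = df.columns[0]
    if first != "sample_id":
        logger.warning("metadata first column is %r, expected 'sample_id'", first)
    sample_ids = tuple(df[first].astype(str))
    factors = {c: tuple(df[c].astype(str)) for c in df.columns[1:]}
    return SampleMetadata(sample_ids=sample_ids, factors=factors)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------

def align(blocks: Sequence[OmicsBlock], metadata: SampleMetadata) -> MultiblockDataset:
    """Align blocks onto the shared sample set, in metadata order.

    Samples missing from any block are dropped with a logged warning.
    An empty intersection is a hard error.
    """
    common = set(metadata.sample_ids)
    for b in blocks:
        common &= set(b.sample_ids)
    if not common:
        raise ValueError("no sample id is shared by every block and the metadata")

    kept = [s for s in metadata.sample_ids if s in common]
    dropped = sorted(
        (set(metadata.sample_ids) | {s for b in blocks for s in b.sample_ids}) - common
    )
    if dropped:
        logger.warning("align: dropping samples absent from some block: %s",
                       ", ".join(dropped))

    aligned = []
    for b in blocks:
        index = {s: i for i, s in enumerate(b.sample_ids)}
        idx = [index[s] for s in kept]
        aligned.append(replace(b, matrix=b.matrix[idx], sample_ids=tuple(kept)))
    return MultiblockDataset(blocks=tuple(aligned), metadata=metadata.subset(kept))
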