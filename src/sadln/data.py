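"""Multi-omics data containers and delimited-text I/O.

The central container is :class:`OmicsDataset`: an ordered collection of
per-omics feature blocks (copy number, mRNA, miRNA, DNA methylation, ...)
measured on the same samples, row-aligned by sample identifier. Survival
times and clinical covariates live in a separate :class:`ClinicalTable`
that aligns to a dataset by identifier, never by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsBlock",
    "OmicsDataset",
    "ClinicalTable",
    "AlignmentError",
    "read_omics",
    "read_clinical",
    "zscore_blocks",
]


class AlignmentError(ValueError):
    """Raised when sample identifiers cannot be aligned across inputs."""


@dataclass
class OmicsBlock:
    """One omics layer: an ``N x D`` numeric matrix plus feature names."""

    name: str
    values: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"block {self.name!r}: values must be 2-D")
        n, d = self.values.shape
        if d < 1 or n < 2:
            raise ValueError(f"block {self.name!r}: need N >= 2 samples and D >= 1 features, got {n} x {d}")
        if len(self.feature_ids) != d:
            raise ValueError(f"block {self.name!r}: {len(self.feature_ids)} feature ids for {d} columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"block {self.name!r}: non-finite or missing entries are not allowed")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class OmicsDataset:
    """Ordered omics blocks sharing one sample axis.

    Every block has exactly ``N`` rows in identical sample order; row ``i``
    of every block refers to ``sample_ids[i]``.
    """

    blocks: list[OmicsBlock]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("dataset needs at least one omics block")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        n = len(self.sample_ids)
        for b in self.blocks:
            if b.n_samples != n:
                raise AlignmentError(f"block {b.name!r} has {b.n_samples} rows, expected {n}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_widths(self) -> list[int]:
        return [b.n_features for b in self.blocks]

    def as_matrices(self) -> list[np.ndarray]:
        return [b.values for b in self.blocks]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.as_matrices(), axis=1)

    def to_tsv(self, paths: list[str], sep: str = "\t") -> None:
        """Write one delimited file per block (rows = samples)."""
        if len(paths) != self.n_blocks:
            raise ValueError("need one output path per block")
        for block, path in zip(self.blocks, paths):
            df = pd.DataFrame(block.values, index=self.sample_ids, columns=block.feature_ids)
            df.index.name = "sample_id"
            df.to_csv(path, sep=sep)


@dataclass
class ClinicalTable:
    """Survival outcome plus optional clinical covariates per sample.

    ``labels`` columns may contain missing entries; ``survival_time`` and
    ``event`` may not.
    """

    sample_ids: list[str]
    survival_time: np.ndarray
    event: np.ndarray
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.survival_time = np.asarray(self.survival_time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.survival_time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("survival_time and event must have one entry per sample")
        if np.any(self.survival_time < 0):
            raise ValueError("survival_time must be nonnegative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event must be 0 or 1")
        if len(self.labels) and len(self.labels) != n:
            raise ValueError("labels must have one row per sample")

    def aligned_to(self, sample_ids: list[str]) -> "ClinicalTable":
        """Reorder/subset to the given sample identifiers."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise AlignmentError(f"{len(missing)} samples absent from clinical table, e.g. {missing[:3]}")
        idx = [pos[s] for s in sample_ids]
        labels = self.labels.iloc[idx].reset_index(drop=True) if len(self.labels) else pd.DataFrame()
        return ClinicalTable(list(sample_ids), self.survival_time[idx], self.event[idx], labels)

    def to_tsv(self, path: str, sep: str = "\t") -> None:
        df = pd.DataFrame({"sample_id": self.sample_ids, "time": self.survival_time, "event": self.event})
        for col in self.labels.columns:
            df[col] = self.labels[col].to_numpy()
        df.to_csv(path, sep=sep, index=False)


def _read_matrix(path: str, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float, np.number)))]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"non-numeric cell in {path}: row {row!r}, column {col!r}")
    if df.isna().any().any():
        rc = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in {path}: row {df.index[rc[0]]!r}, column {df.columns[rc[1]]!r}"
        )
    return df


def read_omics(paths: list[str], sep: str = "\t", names: list[str] | None = None) -> OmicsDataset:
    """Read per-omics delimited matrices and row-align them by sample ID.

    Each file must have a header row of feature IDs and a first column of
    sample IDs. Blocks are aligned on the intersection of sample IDs across
    files, preserving the order of the first file; dropped samples are
    logged.
    """
    if not paths:
        raise ValueError("no input files given")
    frames = [_read_matrix(p, sep) for p in paths]
    if names is None:
        names = [f"omics{i + 1}" for i in range(len(paths))]

    common = set(frames[0].index)
    for df in frames[1:]:
        common &= set(df.index)
    if not common:
        raise AlignmentError("no sample IDs shared by all input files")
    order = [s for s in frames[0].index if s in common]

    for path, df in zip(paths, frames):
        dropped = sorted(set(df.index) - common)
        if dropped:
            logger.info("read_omics: dropped %d samples from %s (e.g. %s)", len(dropped), path, dropped[:3])

    blocks = [
        OmicsBlock(name, df.loc[order].to_numpy(dtype=float), [str(c) for c in df.columns])
        for name, df in zip(names, frames)
    ]
    return OmicsDataset(blocks, [str(s) for s in order])


def read_clinical(path: str, sep: str = "\t") -> ClinicalTable:
    """Read a clinical TSV with required columns sample_id, time, event."""
    df = pd.read_csv(path, sep=sep)
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} lacks required column {col!r}")
    label_cols = [c for c in df.columns if c not in ("sample_id", "time", "event")]
    return ClinicalTable(
        [str(s) for s in df["sample_id"]],
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
        df[label_cols].reset_index(drop=True),
    )


def zscore_blocks(data: OmicsDataset) -> OmicsDataset:
    """Standardize every feature column to mean 0, unit variance.

    Uses the population (1/N) variance. Constant columns map to all-zeros
    rather than NaN so nothing non-finite reaches the network.
    """
    blocks = []
    for b in data.blocks:
        mu = b.values.mean(axis=0)
        sd = b.values.std(axis=0)  # ddof=0
        centered = b.values - mu
        out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
        blocks.append(OmicsBlock(b.name, out, list(b.feature_ids)))
    return OmicsDataset(blocks, list(data.sample_ids))
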