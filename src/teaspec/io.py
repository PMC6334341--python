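"""Spectral block containers, preprocessing, and matrix-augmentation fusion.

A :class:`SpectralBlock` holds one instrument's sample x wavenumber absorbance
matrix together with its wavenumber axis, stored in acquisition (descending)
order.  Blocks from different instruments are combined by low-level data
fusion: horizontal concatenation of the variable blocks ("matrix
augmentation"), optionally after a per-block scaling that balances the raw
magnitude difference between mid- and near-infrared absorbances.

Blocks are serialized as plain CSV: header row = wavenumbers, one row per
sample, index column = sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MIR_TAG = "MIR"
NIR_TAG = "NIR"

FUSION_SCALINGS = ("none", "blockwise-autoscale", "blockwise-unit-norm")
PREPROCESS_METHODS = ("none", "mean-center", "autoscale", "SNV")


@dataclass
class SpectralBlock:
    """One instrument's absorbance matrix plus its wavenumber axis.

    Parameters
    ----------
    tag:
        Block label, conventionally ``"MIR"`` or ``"NIR"``.
    wavenumbers:
        Strictly descending axis in cm^-1 (acquisition order).
    matrix:
        samples x variables absorbance, columns aligned with `wavenumbers`.
    """

    tag: str
    wavenumbers: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be two-dimensional (samples x variables)")
        if self.matrix.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"axis length {self.wavenumbers.size} does not match "
                f"matrix column count {self.matrix.shape[1]}"
            )
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) < 0):
            raise ValueError("wavenumber axis must be strictly descending")
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("block contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FusedMatrix:
    """Matrix-augmented (horizontally concatenated) multi-block matrix.

    ``column_tags``/``column_wavenumbers`` record each column's source block
    and original wavenumber so selected intervals can be reported back in
    instrument coordinates.
    """

    matrix: np.ndarray
    column_tags: np.ndarray
    column_wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.column_tags = np.asarray(self.column_tags)
        self.column_wavenumbers = np.asarray(self.column_wavenumbers, dtype=float)
        if not (self.matrix.shape[1] == self.column_tags.size == self.column_wavenumbers.size):
            raise ValueError("column_map length must equal fused column count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    @property
    def column_map(self) -> list[tuple[str, float]]:
        return list(zip(self.column_tags.tolist(), self.column_wavenumbers.tolist()))

    def block_columns(self, tag: str) -> np.ndarray:
        """Boolean mask of the columns originating from `tag`."""
        return self.column_tags == tag


def _autoscale_columns(matrix: np.ndarray, wavenumbers: np.ndarray, tag: str) -> np.ndarray:
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ValueError(
            f"zero-variance column under autoscale: {tag} {wavenumbers[zero[0]]:.2f} cm^-1"
        )
    return (matrix - mean) / sd


def fuse_blocks(blocks: list[SpectralBlock], scaling: str = "blockwise-autoscale") -> FusedMatrix:
    """Fuse blocks by matrix augmentation, in the order given.

    ``scaling`` is applied independently within each block before
    concatenation: ``"none"`` reproduces plain augmentation,
    ``"blockwise-autoscale"`` autoscales every column (mean 0, sd 1),
    ``"blockwise-unit-norm"`` divides the block by its Frobenius norm.
    """
    if scaling not in FUSION_SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}; choose from {FUSION_SCALINGS}")
    if not blocks:
        raise ValueError("need at least one block")
    tags = [b.tag for b in blocks]
    if len(set(tags)) != len(tags):
        raise ValueError(f"duplicate block tags: {tags}")
    n = blocks[0].n_samples
    for b in blocks:
        if b.n_samples != n:
            raise ValueError(
                f"row-count mismatch: block {b.tag} has {b.n_samples} samples, expected {n}"
            )
    parts = []
    for b in blocks:
        if scaling == "none":
            parts.append(b.matrix)
        elif scaling == "blockwise-autoscale":
            parts.append(_autoscale_columns(b.matrix, b.wavenumbers, b.tag))
        else:
            norm = np.linalg.norm(b.matrix)
            if norm == 0:
                raise ValueError(f"block {b.tag} is all zero; cannot unit-norm scale")
            parts.append(b.matrix / norm)
    return FusedMatrix(
        matrix=np.hstack(parts),
        column_tags=np.concatenate([np.full(b.n_variables, b.tag, dtype=object) for b in blocks]),
        column_wavenumbers=np.concatenate([b.wavenumbers for b in blocks]),
    )


def preprocess(block: SpectralBlock, method: str = "none") -> SpectralBlock:
    """Return a preprocessed copy of `block`; the axis is unchanged.

    ``mean-center`` and ``autoscale`` operate per column, ``SNV`` (standard
    normal variate) per row (each spectrum centered and scaled by its own
    standard deviation).
    """
    if method not in PREPROCESS_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {PREPROCESS_METHODS}")
    if method == "none":
        matrix = block.matrix.copy()
    elif method in ("mean-center", "autoscale"):
        if block.n_samples < 2:
            raise ValueError("need at least 2 samples for centering/scaling")
        if method == "mean-center":
            matrix = block.matrix - block.matrix.mean(axis=0)
        else:
            matrix = _autoscale_columns(block.matrix, block.wavenumbers, block.tag)
    else:  # SNV
        mean = block.matrix.mean(axis=1, keepdims=True)
        sd = block.matrix.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            row = int(np.flatnonzero(sd[:, 0] == 0)[0])
            raise ValueError(f"SNV undefined for constant spectrum (row {row})")
        matrix = (block.matrix - mean) / sd
    return SpectralBlock(tag=block.tag, wavenumbers=block.wavenumbers.copy(), matrix=matrix)


def write_block(block: SpectralBlock, path: str | Path, sample_ids: list[str] | None = None) -> None:
    """Write a block as CSV (header = wavenumbers, one row per sample)."""
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(block.n_samples)]
    df = pd.DataFrame(block.matrix, index=sample_ids, columns=block.wavenumbers)
    df.index.name = "sample_id"
    # 17 significant digits guarantee exact float64 round-trip through text
    df.to_csv(path, float_format="%.17g")


def read_block(path: str | Path, tag: str) -> SpectralBlock:
    """Read a block CSV written by :func:`write_block`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    wavenumbers = np.asarray([float(c) for c in df.columns])
    return SpectralBlock(tag=tag, wavenumbers=wavenumbers, matrix=df.to_numpy(dtype=float))
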