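"""Moving-window PLS (MWPLS) variable selection.

A fixed-width window slides along the wavenumber axis; at every position a
local PLS model of the response on the window's columns is fitted for
1..max_lv latent variables and the calibration sum of squared residuals
(SSR) is recorded.  Windows whose minimum SSR falls below a quantile
threshold mark informative regions; overlapping marked windows are merged
into wavenumber intervals.

When the input is a fused multi-block matrix, windows never straddle a
block boundary: a window spanning the MIR/NIR seam would mix two
instruments' variables and has no physical meaning, so positions are
enumerated within each contiguous block segment separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW_WIDTH = 60
DEFAULT_SSR_QUANTILE = 0.1
DEFAULT_LV_CAP = 5


@dataclass
class ResidueMap:
    """Per-window SSR profiles ("residue lines").

    ``ssr[k, a-1]`` is the calibration SSR of the window starting at column
    ``starts[k]`` fitted with ``a`` latent variables.
    """

    window_width: int
    starts: np.ndarray
    center_wavenumbers: np.ndarray
    ssr: np.ndarray
    window_tags: np.ndarray
    column_wavenumbers: np.ndarray
    column_tags: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.starts.size

    @property
    def max_lv(self) -> int:
        return self.ssr.shape[1]


@dataclass
class SelectedIntervals:
    """Merged informative intervals, reported as (high, low) cm^-1 per block.

    ``column_mask`` flags the selected columns of the matrix the residue
    map was computed on, ready to subset model inputs.
    """

    intervals: list[tuple[float, float, str]]
    column_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.intervals)

    def for_block(self, tag: str) -> list[tuple[float, float, str]]:
        return [iv for iv in self.intervals if iv[2] == tag]


def _batched_pls1_ssr(Xw: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """Calibration SSR for a batch of windows.

    `Xw` has shape (batch, n_samples, width).  Runs PLS1-NIPALS on all
    windows simultaneously; windows whose residual rank is exhausted keep
    their last SSR value (monotone non-increasing by construction).
    """
    B, n, w = Xw.shape
    Xc = Xw - Xw.mean(axis=1, keepdims=True)
    yc = np.broadcast_to(y - y.mean(), (B, n)).copy()
    ssr = np.empty((B, max_lv))
    tiny = 1e-30
    for a in range(max_lv):
        wv = np.einsum("bnw,bn->bw", Xc, yc)
        nw = np.linalg.norm(wv, axis=1)
        ok = nw > tiny
        wv = np.where(ok[:, None], wv / np.where(ok, nw, 1.0)[:, None], 0.0)
        t = np.einsum("bnw,bw->bn", Xc, wv)
        tt = (t * t).sum(axis=1)
        ok &= tt > tiny
        safe_tt = np.where(ok, tt, 1.0)
        p = np.einsum("bnw,bn->bw", Xc, t) / safe_tt[:, None]
        q = (yc * t).sum(axis=1) / safe_tt
        upd = ok[:, None]
        Xc -= np.where(upd[..., None], t[:, :, None] * p[:, None, :], 0.0)
        yc -= np.where(upd, q[:, None] * t, 0.0)
        ssr[:, a] = (yc * yc).sum(axis=1)
    return ssr


def residue_lines(
    X: np.ndarray,
    y: np.ndarray,
    wavenumbers: np.ndarray,
    window_width: int = DEFAULT_WINDOW_WIDTH,
    max_lv: int = DEFAULT_LV_CAP,
    column_tags: np.ndarray | None = None,
    chunk_size: int = 256,
) -> ResidueMap:
    """Compute the MWPLS residue map of `y` on `X`.

    `column_tags` (one tag per column) restricts windows to contiguous
    same-tag segments; with ``None`` all columns form one segment.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if wavenumbers.size != p:
        raise ValueError("wavenumbers length must equal the column count")
    if window_width > p:
        raise ValueError(f"window width {window_width} exceeds variable count {p}")
    if max_lv >= window_width:
        raise ValueError("max_lv must be smaller than the window width")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if column_tags is None:
        column_tags = np.full(p, "ALL", dtype=object)
    else:
        column_tags = np.asarray(column_tags)
        if column_tags.size != p:
            raise ValueError("column_tags length must equal the column count")

    # contiguous same-tag segments
    boundaries = [0] + (np.flatnonzero(column_tags[1:] != column_tags[:-1]) + 1).tolist() + [p]
    starts: list[int] = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi - lo >= window_width:
            starts.extend(range(lo, hi - window_width + 1))
    starts_arr = np.asarray(starts, dtype=int)
    if starts_arr.size == 0:
        raise ValueError("no block segment is wide enough for the window")

    ssr = np.empty((starts_arr.size, max_lv))
    windows = np.lib.stride_tricks.sliding_window_view(X, window_width, axis=1)
    for k0 in range(0, starts_arr.size, chunk_size):
        batch = starts_arr[k0 : k0 + chunk_size]
        Xw = np.ascontiguousarray(windows[:, batch, :].transpose(1, 0, 2))
        ssr[k0 : k0 + chunk_size] = _batched_pls1_ssr(Xw, y, max_lv)

    centers = wavenumbers[starts_arr + (window_width - 1) // 2]
    return ResidueMap(
        window_width=window_width,
        starts=starts_arr,
        center_wavenumbers=centers,
        ssr=ssr,
        window_tags=column_tags[starts_arr],
        column_wavenumbers=wavenumbers,
        column_tags=column_tags,
    )


def select_intervals(
    rmap: ResidueMap,
    ssr_quantile: float = DEFAULT_SSR_QUANTILE,
    lv_cap: int | None = None,
) -> SelectedIntervals:
    """Extract informative intervals from a residue map.

    Windows whose minimum SSR over 1..lv_cap latent variables falls at or
    below the `ssr_quantile` quantile of the window minima are marked;
    the columns they cover are merged into per-block intervals reported as
    (high cm^-1, low cm^-1, block tag).
    """
    if not 0 < ssr_quantile <= 1:
        raise ValueError("ssr_quantile must lie in (0, 1]")
    lv_cap = rmap.max_lv if lv_cap is None else min(lv_cap, rmap.max_lv)
    if lv_cap < 1:
        raise ValueError("lv_cap must be >= 1")
    minima = rmap.ssr[:, :lv_cap].min(axis=1)
    threshold = np.quantile(minima, ssr_quantile)
    marked = minima <= threshold
    if not marked.any():
        warnings.warn("no window below the SSR threshold; empty selection", stacklevel=2)
        return SelectedIntervals(
            intervals=[], column_mask=np.zeros(rmap.column_wavenumbers.size, dtype=bool)
        )

    p = rmap.column_wavenumbers.size
    mask = np.zeros(p, dtype=bool)
    for start in rmap.starts[marked]:
        mask[start : start + rmap.window_width] = True

    intervals: list[tuple[float, float, str]] = []
    i = 0
    while i < p:
        if mask[i]:
            j = i
            while (
                j + 1 < p
                and mask[j + 1]
                and rmap.column_tags[j + 1] == rmap.column_tags[i]
            ):
                j += 1
            intervals.append(
                (
                    float(rmap.column_wavenumbers[i]),
                    float(rmap.column_wavenumbers[j]),
                    str(rmap.column_tags[i]),
                )
            )
            i = j + 1
        else:
            i += 1
    return SelectedIntervals(intervals=intervals, column_mask=mask)
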