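"""Sample-set partitioning: stratified random split and DUPLEX.

Two schemes are used in the study design this package reconstructs:

* a stratified random 88/32 training/prediction split for classification,
  with fixed per-class training counts;
* a deterministic DUPLEX (Snee) split of the 120 samples into
  calibration (60) / validation (30) / prediction (30) sets for
  calibration, realized as two sequential DUPLEX passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

# Per-class training-set sizes of the 88/32 classification split
# (12 classes x 10 samples; the remaining 32 samples form the prediction set).
STUDY_TRAIN_COUNTS = (9, 6, 8, 8, 6, 8, 5, 8, 7, 8, 8, 7)

# Calibration / validation (monitoring) / prediction sizes of the DUPLEX split.
STUDY_DUPLEX_SIZES = (60, 30, 30)

TRAIN, TEST = "train", "test"
CALIBRATION, VALIDATION, PREDICTION = "calibration", "validation", "prediction"


@dataclass
class SplitPlan:
    """Role assignment for every sample.

    ``roles`` is an object array of role names; ``provenance`` records the
    scheme that produced the plan.
    """

    roles: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.roles = np.asarray(self.roles, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.roles.size

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    def counts(self) -> dict[str, int]:
        values, counts = np.unique(self.roles.astype(str), return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def to_frame(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        if sample_ids is None:
            sample_ids = [f"S{i + 1:03d}" for i in range(self.n_samples)]
        return pd.DataFrame({"sample_id": sample_ids, "role": self.roles.astype(str)})

    def to_csv(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        self.to_frame(sample_ids).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "file") -> "SplitPlan":
        df = pd.read_csv(path)
        return cls(roles=df["role"].to_numpy(dtype=object), provenance=provenance)


def stratified_split(
    labels: np.ndarray, train_counts, seed: int | None = None
) -> SplitPlan:
    """Stratified random train/test split with exact per-class train counts.

    `train_counts` gives the training-set size for class 1, 2, ... in label
    order; the remaining samples of each class go to the test set.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    train_counts = list(train_counts)
    if len(train_counts) != classes.size:
        raise ValueError(
            f"got {len(train_counts)} per-class counts for {classes.size} classes"
        )
    rng = np.random.default_rng(seed)
    roles = np.empty(labels.size, dtype=object)
    for cls, count in zip(classes, train_counts):
        members = np.flatnonzero(labels == cls)
        if count > members.size:
            raise ValueError(
                f"class {cls}: requested {count} training samples, only {members.size} available"
            )
        chosen = rng.permutation(members)[:count]
        roles[members] = TEST
        roles[chosen] = TRAIN
    return SplitPlan(roles=roles, provenance="stratified-random")


def _farthest_pair(dist: np.ndarray, candidates: list[int]) -> tuple[int, int]:
    """Mutually farthest pair among `candidates`; ties break to the
    lexicographically smallest index pair (row-major argmax)."""
    sub = dist[np.ix_(candidates, candidates)].copy()
    np.fill_diagonal(sub, -np.inf)  # a point is never paired with itself
    flat = int(np.argmax(sub))
    i, j = divmod(flat, sub.shape[1])
    a, b = candidates[i], candidates[j]
    return (a, b) if a <= b else (b, a)


def _assign_next(dist: np.ndarray, members: list[int], candidates: list[int]) -> int:
    """Candidate with the largest min-distance to `members`; candidates are
    in ascending index order, so ties break to the lowest sample index."""
    dmin = dist[np.ix_(candidates, members)].min(axis=1)
    return candidates[int(np.argmax(dmin))]


def _duplex_two_way(dist: np.ndarray, candidates: list[int], n_a: int, n_b: int):
    """Classical DUPLEX assignment of `candidates` into sets of sizes
    (`n_a`, `n_b`): seed each set with a mutually farthest pair, then
    alternate max-min-distance assignment until the quotas are met."""
    if n_a + n_b != len(candidates):
        raise ValueError("sizes must sum to the candidate count")
    remaining = sorted(candidates)
    sets: list[list[int]] = [[], []]
    quotas = (n_a, n_b)
    for s in range(2):
        take = min(2, quotas[s], len(remaining))
        if take == 2:
            a, b = _farthest_pair(dist, remaining)
            sets[s] = [a, b]
        elif take == 1:
            # quota of one: take the lower-index member of the farthest pair
            sets[s] = [_farthest_pair(dist, remaining)[0]] if len(remaining) > 1 else [remaining[0]]
        for idx in sets[s]:
            remaining.remove(idx)
    while remaining:
        progressed = False
        for s in range(2):
            if len(sets[s]) < quotas[s] and remaining:
                nxt = _assign_next(dist, sets[s], remaining)
                sets[s].append(nxt)
                remaining.remove(nxt)
                progressed = True
        if not progressed:  # pragma: no cover - defensive
            raise RuntimeError("DUPLEX assignment stalled")
    return sorted(sets[0]), sorted(sets[1])


def duplex_split(X: np.ndarray, sizes: tuple[int, int, int]) -> SplitPlan:
    """Three-way DUPLEX split on Euclidean distances between rows of `X`.

    Stage 1 separates the calibration set from the rest; stage 2 runs
    DUPLEX again within the remainder to split validation from prediction.
    Fully deterministic; distance ties break to the lowest sample index.
    """
    X = np.asarray(X, dtype=float)
    n_cal, n_val, n_pred = sizes
    n = X.shape[0]
    if n_cal + n_val + n_pred != n:
        raise ValueError(f"sizes {sizes} do not sum to the sample count {n}")
    if n_cal < 2:
        raise ValueError("calibration set must have at least 2 samples")
    dist = squareform(pdist(X, metric="euclidean"))
    cal, rest = _duplex_two_way(dist, list(range(n)), n_cal, n_val + n_pred)
    val, pred = _duplex_two_way(dist, rest, n_val, n_pred)
    roles = np.empty(n, dtype=object)
    roles[cal] = CALIBRATION
    roles[val] = VALIDATION
    roles[pred] = PREDICTION
    return SplitPlan(roles=roles, provenance="duplex")
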