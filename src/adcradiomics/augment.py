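"""Feature-space oversampling of the 4-feature signature and the 75/25 split.

The selected features are oversampled to a balanced dataset (default 200
samples, 100 per class) by within-class pairwise linear interpolation: each
synthetic sample is a convex combination ``x_i + lam * (x_j - x_i)`` of an
original and one of its k nearest same-class neighbours, with ``lam`` drawn
uniformly from [0.05, 0.95] so originals are never duplicated.  All
originals are retained.  A Gaussian-jitter alternative is available.

Splitting is stratified with exact class balance (200 -> 150 train / 50
test).  Two assignment rules exist: plain stratified random (default) and
the SVM margin rule, where a pilot linear SVM is fitted on the full set and
the samples nearest its boundary are forced into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_N_TARGET = 200
DEFAULT_TRAIN_FRAC = 0.75
LAMBDA_RANGE = (0.05, 0.95)
K_NEIGHBOURS = 5


@dataclass
class AugmentedSet:
    """Balanced oversampled feature set with per-row provenance."""

    samples: np.ndarray  # (n, 4)
    labels: np.ndarray  # (n,) binary
    provenance: list[str]  # "original:<i>" or "synthetic-from(<i>,<j>)"
    seed: int
    method: str = "interpolate"

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=2)
        if counts[0] != counts[1]:
            raise ValueError(f"augmented set must be balanced, got {counts.tolist()}")
        if len(self.provenance) != len(self.samples):
            raise ValueError("provenance must cover every row")

    @property
    def n_original(self) -> int:
        return sum(1 for p in self.provenance if p.startswith("original"))


def augment(
    samples: np.ndarray,
    labels: Sequence[int],
    *,
    n_target: int = DEFAULT_N_TARGET,
    seed: int = 0,
    method: str = "interpolate",
    k_neighbours: int = K_NEIGHBOURS,
    jitter_scale: float = 0.05,
) -> AugmentedSet:
    """Oversample to ``n_target`` samples, equally split between classes.

    Originals are always retained; synthetic rows lie strictly inside the
    segment between two same-class originals (interpolation method) or are
    Gaussian perturbations of originals (jitter method).
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("samples must be a 2D array matching labels")
    if n_target < len(X):
        raise ValueError(f"n_target {n_target} smaller than original n {len(X)}")
    if n_target % 2:
        raise ValueError("n_target must be even for exact class balance")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 original rows")
    per_class = n_target // 2
    if counts.max() > per_class:
        raise ValueError(f"class count {counts.max()} exceeds per-class target {per_class}")
    if method == "interpolate" and counts.min() < 5:
        raise ValueError("interpolation oversampling needs >= 5 rows per class")

    rng = np.random.default_rng(seed)
    out_X, out_y, prov = [], [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        Xc = X[idx]
        out_X.append(Xc)
        out_y.append(np.full(len(idx), cls))
        prov.extend(f"original:{i}" for i in idx)
        n_syn = per_class - len(idx)
        if n_syn == 0:
            continue
        if method == "interpolate":
            k = min(k_neighbours, len(idx) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, neigh = nn.kneighbors(Xc)  # first column is the point itself
            src = rng.integers(0, len(idx), size=n_syn)
            pick = rng.integers(1, k + 1, size=n_syn)
            dst = neigh[src, pick]
            lam = rng.uniform(*LAMBDA_RANGE, size=n_syn)
            syn = Xc[src] + lam[:, None] * (Xc[dst] - Xc[src])
            prov.extend(
                f"synthetic-from({idx[s]},{idx[d]})" for s, d in zip(src, dst)
            )
        elif method == "jitter":
            scale = X.std(axis=0) * jitter_scale
            src = rng.integers(0, len(idx), size=n_syn)
            syn = Xc[src] + rng.normal(0.0, scale, size=(n_syn, X.shape[1]))
            prov.extend(f"synthetic-from({idx[s]})" for s in src)
        else:
            raise ValueError(f"unknown augmentation method {method!r}")
        out_X.append(syn)
        out_y.append(np.full(n_syn, cls))
    return AugmentedSet(
        np.vstack(out_X), np.concatenate(out_y).astype(int), prov, seed, method
    )


@dataclass
class SplitSet:
    """Stratified train/test partition of an (augmented) feature set."""

    train_X: np.ndarray
    train_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray
    rule: str
    seed: int
    train_idx: np.ndarray = field(default=None)
    test_idx: np.ndarray = field(default=None)

    @property
    def n_train(self) -> int:
        return len(self.train_y)

    @property
    def n_test(self) -> int:
        return len(self.test_y)


def _per_class_quota(counts: np.ndarray, train_frac: float) -> np.ndarray:
    quota = counts * train_frac
    rounded = np.round(quota).astype(int)
    if not np.allclose(quota, rounded):
        logger.warning(
            "train fraction %g not exact for class counts %s; using %s",
            train_frac, counts.tolist(), rounded.tolist(),
        )
    return rounded


def split(
    samples: np.ndarray | AugmentedSet,
    labels: Sequence[int] | None = None,
    *,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    rule: str = "random",
    seed: int = 0,
) -> SplitSet:
    """Partition samples into train/test with exact per-class proportions.

    ``rule="random"`` is a stratified random assignment.  ``rule="margin"``
    fits a pilot linear SVM on everything and, per class, sends the samples
    with the smallest ``|decision value|`` (margin-adjacent) to training
    until the quota fills; the remainder is the held-out test set.
    """
    if isinstance(samples, AugmentedSet):
        X, y = samples.samples, samples.labels
    else:
        X = np.asarray(samples, dtype=float)
        y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    quotas = _per_class_quota(counts, train_frac)
    rng = np.random.default_rng(seed)

    if rule == "random":
        order_key = rng.random(len(y))
    elif rule == "margin":
        pilot = SVC(kernel="linear", C=1.0, max_iter=200_000)
        pilot.fit(X, y)
        order_key = np.abs(pilot.decision_function(X))  # small = near boundary
    else:
        raise ValueError(f"unknown split rule {rule!r}")

    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = idx[np.argsort(order_key[idx], kind="stable")]
        train_idx.extend(idx[: quotas[cls]])
        test_idx.extend(idx[quotas[cls] :])
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.sort(np.asarray(test_idx))
    return SplitSet(
        X[train_idx], y[train_idx], X[test_idx], y[test_idx],
        rule, seed, train_idx, test_idx,
    )
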