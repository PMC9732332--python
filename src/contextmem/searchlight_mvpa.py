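"""Sphere-wise leave-one-run-out context decoding and top-K voxel selection.

A linear c-SVC (cost 1, libsvm solver) is trained at every in-mask center on
the voxels within a Euclidean sphere (default radius 4, in voxel units).
Cross-validation leaves one scanner run out at a time: training folds are
label-balanced by seeded subsampling of the overrepresented class, test folds
use all valid trials of the held-out run, and fold accuracies are averaged
into a per-voxel accuracy map.  The K best voxels form the feature mask for
the downstream template analysis (ties at the cutoff break by ascending
linear voxel index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SearchlightConfig",
    "sphere_offsets",
    "sphere_indices",
    "balance_labels",
    "crossval_accuracy",
    "run_searchlight",
    "top_k_mask",
]


@dataclass(frozen=True)
class SearchlightConfig:
    radius_voxels: float = 4.0
    svm_cost: float = 1.0
    top_k: int = 2000
    balance_seed: int = 0
    n_balance_repeats: int = 1  # re-balancing repetitions per fold, averaged

    def __post_init__(self) -> None:
        if self.radius_voxels <= 0:
            raise ValueError("radius must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")
        if self.n_balance_repeats < 1:
            raise ValueError("n_balance_repeats must be at least 1")


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets with squared Euclidean norm <= radius**2, (n, 3)."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def sphere_indices(
    center: tuple[int, int, int],
    radius: float,
    shape: tuple[int, int, int],
    brain_mask: np.ndarray,
) -> np.ndarray:
    """Flat indices of in-mask voxels within ``radius`` of ``center``."""
    center = tuple(int(c) for c in center)
    if not brain_mask[center]:
        raise ValueError(f"center {center} lies outside the brain mask")
    coords = np.asarray(center) + sphere_offsets(radius)
    inside = np.all((coords >= 0) & (coords < np.asarray(shape)), axis=1)
    coords = coords[inside]
    flat = np.ravel_multi_index(coords.T, shape)
    return flat[brain_mask.ravel()[flat]]


def balance_labels(labels: np.ndarray, seed_or_rng) -> np.ndarray:
    """Indices of a label-balanced subset (overrepresented class subsampled).

    The underrepresented class is kept whole; subsampling is seeded and
    reproducible.  Returns sorted positional indices into ``labels``.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() == 0:
        raise ValueError("degenerate labels: need two non-empty classes")
    n_keep = counts.min()
    keep: list[np.ndarray] = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if count > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def _fold_plan(labels, run_ids, config):
    """Per-fold (train-indices, test-indices) with training-fold balancing.

    Computed once per searchlight because balancing depends only on labels
    and runs, never on the sphere's voxels.
    """
    rng = np.random.default_rng(config.balance_seed)
    labels = np.asarray(labels)
    run_ids = np.asarray(run_ids)
    folds = []
    for held in np.unique(run_ids):
        test = np.flatnonzero(run_ids == held)
        train = np.flatnonzero(run_ids != held)
        plans = []
        for _ in range(config.n_balance_repeats):
            try:
                sub = balance_labels(labels[train], rng)
            except ValueError:
                continue
            plans.append(train[sub])
        if not plans:
            warnings.warn(f"fold for run {held} skipped: a class is empty after balancing")
            continue
        folds.append((plans, test))
    return folds


def crossval_accuracy(patterns, labels, run_ids, config: SearchlightConfig | None = None) -> float:
    """Mean leave-one-run-out accuracy of the linear SVM on one voxel set.

    Returns NaN when every fold had to be skipped (a class missing from the
    training data), which marks the sphere's center voxel undefined.
    """
    config = config or SearchlightConfig()
    X = np.asarray(patterns, dtype=np.float64)
    y = np.asarray(labels)
    if len(np.unique(run_ids)) < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out")
    folds = _fold_plan(y, run_ids, config)
    return _accuracy_from_folds(X, y, folds, config.svm_cost)


def _accuracy_from_folds(X, y, folds, cost) -> float:
    accs = []
    for plans, test in folds:
        fold_accs = []
        for train in plans:
            clf = SVC(kernel="linear", C=cost)
            clf.fit(X[train], y[train])
            fold_accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
        accs.append(float(np.mean(fold_accs)))
    return float(np.mean(accs)) if accs else float("nan")


def run_searchlight(
    patterns,
    labels,
    run_ids,
    brain_mask: np.ndarray,
    config: SearchlightConfig | None = None,
) -> np.ndarray:
    """Accuracy map: sphere-wise cross-validated accuracy at every in-mask center.

    ``patterns`` is the (trials x in-mask voxels) matrix of valid imagery
    patterns in canonical voxel order.  Returns a 3D float map, NaN outside
    the brain mask; deterministic given data and ``config.balance_seed``.
    """
    config = config or SearchlightConfig()
    X = np.asarray(patterns, dtype=np.float64)
    y = np.asarray(labels)
    run_ids = np.asarray(run_ids)
    if not brain_mask.any():
        raise ValueError("empty brain mask")
    if len(np.unique(y)) < 2:
        raise ValueError("need two contexts represented")
    if len(np.unique(run_ids)) < 2:
        raise ValueError("need at least 2 runs")
    shape = brain_mask.shape
    mask_flat = brain_mask.ravel()
    # column j of `patterns` is the j-th in-mask voxel; map flat index -> column
    col_of = np.full(mask_flat.size, -1, dtype=np.int64)
    col_of[np.flatnonzero(mask_flat)] = np.arange(int(mask_flat.sum()))
    if X.shape[1] != int(mask_flat.sum()):
        raise ValueError("pattern width must equal the number of in-mask voxels")

    folds = _fold_plan(y, run_ids, config)
    offsets = sphere_offsets(config.radius_voxels)
    shape_arr = np.asarray(shape)

    acc_map = np.full(shape, np.nan)
    centers = np.argwhere(brain_mask)
    for center in centers:
        coords = center + offsets
        inside = np.all((coords >= 0) & (coords < shape_arr), axis=1)
        flat = np.ravel_multi_index(coords[inside].T, shape)
        cols = col_of[flat]
        cols = cols[cols >= 0]
        acc_map[tuple(center)] = _accuracy_from_folds(
            X[:, cols], y, folds, config.svm_cost
        )
    return acc_map


def top_k_mask(accuracy_map: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k highest-accuracy voxels (cutoff ties break by
    ascending linear voxel index)."""
    flat = accuracy_map.ravel()
    defined = np.flatnonzero(~np.isnan(flat))
    if defined.size < k:
        raise ValueError("mask too small")
    # sort by (-accuracy, linear index): stable deterministic tie-break
    order = np.lexsort((defined, -flat[defined]))
    chosen = defined[order[:k]]
    mask = np.zeros(flat.size, dtype=bool)
    mask[chosen] = True
    return mask.reshape(accuracy_map.shape)
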