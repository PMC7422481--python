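"""Synthetic source/target domain pairs with controlled shift and noise.

Emulates the transfer-learning evaluation protocol without any external
download: class-conditional Gaussian features (unit covariance, class means
mutually 2 apart), a source domain with ample labels, and a target domain
that is either drawn from the same distributions, mean-shifted, or has two
class distributions swapped.  A separate operation adds white Gaussian
noise to the source features only, mimicking a corrupted source domain.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "DomainPair",
    "make_domain_pair",
    "add_source_noise",
    "save_dataset",
    "load_dataset",
]


@dataclass
class LabeledDataset:
    """A feature matrix X (N x d) with one class label per row."""

    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels disagree on sample count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class DomainPair:
    """A source dataset plus a train/test-split target dataset.

    ``shift_kind`` records how the target distribution relates to the
    source: "identical", "mean_shift" (class means displaced by
    ``shift_magnitude``), "class_swap" (two class distributions exchanged),
    or "cross_set" for pairs assembled from real data with differing
    class provenance.
    """

    source: LabeledDataset
    target_train: LabeledDataset
    target_test: LabeledDataset
    shift_kind: str
    shift_magnitude: float
    seed: int


def _class_means(C: int, d: int) -> np.ndarray:
    # sqrt(2) * e_i: pairwise Euclidean distance exactly 2
    if d < C:
        raise ValueError(f"need d >= C to place {C} separated class means in {d} dims")
    M = np.zeros((C, d))
    M[np.arange(C), np.arange(C)] = np.sqrt(2.0)
    return M


def _sample_classes(
    rng: np.random.Generator, means: np.ndarray, n_per_class: int
) -> LabeledDataset:
    C, d = means.shape
    X = np.vstack(
        [rng.standard_normal((n_per_class, d)) + means[c] for c in range(C)]
    )
    labels = np.repeat(np.arange(C), n_per_class)
    return LabeledDataset(X=X, labels=labels)


def make_domain_pair(
    C: int = 2,
    d: int = 8,
    n_source_per_class: int = 75,
    n_target_per_class: int = 25,
    shift_kind: str = "identical",
    shift_magnitude: float = 1.0,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> DomainPair:
    """Draw a source/target domain pair of Gaussian class clouds.

    Source samples come from N(mu_c, I); target samples come from the same
    distributions ("identical"), from means displaced by ``shift_magnitude``
    in an independent random direction per class ("mean_shift"), or from
    distributions with the first two class means exchanged ("class_swap").
    The target is split per class into train and test, with
    ``floor(test_fraction * n)`` test samples per class; splits are disjoint
    and the whole pair is a pure function of ``seed``.
    """
    if C < 2:
        raise ValueError(f"need at least 2 classes, got {C}")
    if n_source_per_class < 1 or n_target_per_class < 1:
        raise ValueError("per-class counts must be >= 1")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    if shift_kind not in ("identical", "mean_shift", "class_swap"):
        raise ValueError(f"unknown shift_kind {shift_kind!r}")
    if shift_magnitude < 0:
        raise ValueError("shift_magnitude must be >= 0")

    rng = np.random.default_rng(seed)
    means = _class_means(C, d)

    target_means = means.copy()
    if shift_kind == "mean_shift":
        directions = rng.standard_normal((C, d))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        target_means = means + shift_magnitude * directions
    elif shift_kind == "class_swap":
        target_means[[0, 1]] = target_means[[1, 0]]

    source = _sample_classes(rng, means, n_source_per_class)
    target = _sample_classes(rng, target_means, n_target_per_class)

    # per-class disjoint train/test split of the target
    n_test = int(np.floor(test_fraction * n_target_per_class))
    if n_test < 1 or n_test >= n_target_per_class:
        raise ValueError(
            f"test_fraction {test_fraction} leaves an empty train or test split "
            f"at {n_target_per_class} target samples per class"
        )
    train_idx, test_idx = [], []
    for c in range(C):
        members = np.flatnonzero(target.labels == c)
        perm = rng.permutation(members)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)

    return DomainPair(
        source=source,
        target_train=LabeledDataset(target.X[train_idx], target.labels[train_idx]),
        target_test=LabeledDataset(target.X[test_idx], target.labels[test_idx]),
        shift_kind=shift_kind,
        shift_magnitude=float(shift_magnitude) if shift_kind == "mean_shift" else 0.0,
        seed=seed,
    )


def add_source_noise(
    pair: DomainPair,
    noise_level: float,
    seed: int = 0,
    mode: str = "relative_sigma",
) -> DomainPair:
    """Return a copy of the pair with white Gaussian noise on the source only.

    ``mode="relative_sigma"`` (default) adds independent zero-mean Gaussian
    noise to every source sample with per-feature standard deviation
    ``noise_level * sigma_j``, where sigma_j is the source standard
    deviation of feature j — the signal-relative reading of "x% white
    Gaussian noise".  ``mode="sample_fraction"`` instead corrupts a random
    ``noise_level`` fraction of source samples with unit-sigma_j noise.
    Labels and the target splits are untouched.
    """
    if noise_level < 0:
        raise ValueError(f"noise_level must be >= 0, got {noise_level}")
    out = copy.deepcopy(pair)
    if noise_level == 0:
        return out
    rng = np.random.default_rng(seed)
    X = out.source.X
    sigma = X.std(axis=0, ddof=0)
    if mode == "relative_sigma":
        X += rng.standard_normal(X.shape) * (noise_level * sigma)[None, :]
    elif mode == "sample_fraction":
        if noise_level > 1:
            raise ValueError("sample_fraction mode needs noise_level in [0, 1]")
        n_noisy = int(round(noise_level * X.shape[0]))
        rows = rng.choice(X.shape[0], size=n_noisy, replace=False)
        X[rows] += rng.standard_normal((n_noisy, X.shape[1])) * sigma[None, :]
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    return out


# --- delimited-text I/O ------------------------------------------------------
# Header row; feature columns then a final "label" column.

def save_dataset(ds: LabeledDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.X, columns=[f"f{j}" for j in range(ds.n_features)])
    df["label"] = ds.labels
    df.to_csv(path, sep="\t", index=False)


def load_dataset(path: str | Path) -> LabeledDataset:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    labels = df["label"].to_numpy()
    X = df.drop(columns="label").to_numpy(dtype=float)
    return LabeledDataset(X=X, labels=labels)
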