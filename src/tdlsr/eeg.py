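"""Reading Bonn-style single-channel EEG segments and turning them into features.

The Bonn epilepsy corpus distributes five sets (A-E) of 100 single-channel
EEG segments each, as plain ASCII files with one sample value per line
(4097 samples at 173.61 Hz, ~23.6 s).  This module parses that dialect
(tolerating comma/whitespace-separated variants), extracts fixed-length
feature vectors, and assembles source/target domain pairs following the
75/25 source/target and 80/20 train/test protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import periodogram

from .synthetic import DomainPair, LabeledDataset

__all__ = [
    "EEGSegment",
    "read_bonn_segment",
    "extract_features",
    "build_subdataset",
    "BONN_SAMPLING_RATE_HZ",
    "CLASSICAL_BANDS_HZ",
]

BONN_SAMPLING_RATE_HZ = 173.61
BONN_SEGMENT_LENGTH = 4097

# delta, theta, alpha, beta, gamma
CLASSICAL_BANDS_HZ = ((0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 60.0))


@dataclass
class EEGSegment:
    """One single-channel EEG recording segment."""

    samples: np.ndarray
    sampling_rate_hz: float = BONN_SAMPLING_RATE_HZ
    set_label: str = ""
    segment_id: str = ""
    length_warning: bool = field(default=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("EEG segment has no samples")
        if not np.isfinite(self.samples).all():
            raise ValueError("EEG segment contains non-finite samples")
        if self.samples.size != BONN_SEGMENT_LENGTH:
            self.length_warning = True


def read_bonn_segment(path: str | Path, set_label: str = "") -> EEGSegment:
    """Parse one ASCII segment file (one value per line; separators tolerated).

    Raises a ``ValueError`` naming the offending line if a token is not
    numeric, and on empty files.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            for token in line.replace(",", " ").split():
                try:
                    values.append(float(token))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {token!r} on line {lineno}"
                    ) from None
    if not values:
        raise ValueError(f"{path}: empty segment file")
    return EEGSegment(
        samples=np.asarray(values),
        set_label=set_label,
        segment_id=path.stem,
    )


def extract_features(
    segment: EEGSegment,
    scheme: str = "band_power",
    bands: Sequence[tuple[float, float]] = CLASSICAL_BANDS_HZ,
    n_bins: int = 16,
) -> np.ndarray:
    """Fixed-length feature vector for one segment.

    ``band_power``: log mean periodogram power in each frequency band
    (default: the five classical EEG bands delta..gamma), length
    ``len(bands)``.  ``raw_downsample``: the signal averaged over
    ``n_bins`` consecutive equal-width bins.  Features are meant to be
    z-scored per dataset downstream.
    """
    x = segment.samples
    if scheme == "band_power":
        nyquist = segment.sampling_rate_hz / 2.0
        for lo, hi in bands:
            if hi > nyquist:
                raise ValueError(
                    f"band ({lo}, {hi}) Hz exceeds Nyquist frequency {nyquist:.2f} Hz"
                )
        freqs, power = periodogram(x, fs=segment.sampling_rate_hz)
        out = np.empty(len(bands))
        for k, (lo, hi) in enumerate(bands):
            mask = (freqs >= lo) & (freqs < hi)
            out[k] = np.log(np.mean(power[mask]) + 1e-300)
        return out
    if scheme == "raw_downsample":
        edges = np.linspace(0, x.size, n_bins + 1).astype(int)
        return np.asarray(
            [x[edges[k]: edges[k + 1]].mean() for k in range(n_bins)]
        )
    raise ValueError(f"unknown feature scheme {scheme!r}")


def build_subdataset(
    segments_by_set: Mapping[str, Sequence[EEGSegment]],
    recipe: str,
    target_recipe: str | None = None,
    source_fraction: float = 0.75,
    test_fraction: float = 0.2,
    seed: int = 0,
    scheme: str = "band_power",
    **feature_params,
) -> DomainPair:
    """Assemble a source/target domain pair from sets of EEG segments.

    ``recipe`` names the source sets by letter (e.g. ``"AE"``); ``target_recipe``
    defaults to the same letters.  Each involved set is shuffled once and
    split ``floor(source_fraction * n)`` / remainder; the source domain takes
    the large part of its recipe's sets, the target domain the small part of
    its recipe's sets, so no segment appears in both even when the recipes
    share a letter.  The target is then split per class into train and test
    (``floor(test_fraction * n)`` test segments).  Classes are positional:
    the i-th letter of each recipe maps to class i, which is how source and
    target classes correspond when the letters differ.  Features are z-scored
    with the mean/std of the source and target-train segments only.
    """
    target_recipe = recipe if target_recipe is None else target_recipe
    if len(recipe) != len(target_recipe):
        raise ValueError(
            f"source recipe {recipe!r} and target recipe {target_recipe!r} "
            "must name the same number of classes"
        )
    for letter in set(recipe + target_recipe):
        if letter not in segments_by_set:
            raise ValueError(f"no segments provided for set {letter!r}")

    rng = np.random.default_rng(seed)
    # one shuffled 75/25 split per distinct set letter
    splits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for letter in sorted(set(recipe + target_recipe)):
        n = len(segments_by_set[letter])
        n_src = int(np.floor(source_fraction * n))
        if n_src < 1 or n - n_src < 1:
            raise ValueError(
                f"set {letter!r} has too few segments ({n}) to split "
                f"{source_fraction:.0%}/{1 - source_fraction:.0%}"
            )
        perm = rng.permutation(n)
        splits[letter] = (perm[:n_src], perm[n_src:])

    def featurize(letter: str, indices: np.ndarray, cls: int):
        segs = segments_by_set[letter]
        X = np.vstack(
            [extract_features(segs[i], scheme=scheme, **feature_params) for i in indices]
        )
        return X, np.full(len(indices), cls, dtype=int)

    src_X, src_y = zip(*(featurize(s, splits[s][0], c) for c, s in enumerate(recipe)))
    source = LabeledDataset(np.vstack(src_X), np.concatenate(src_y))

    tr_X, tr_y, te_X, te_y = [], [], [], []
    for cls, letter in enumerate(target_recipe):
        tgt_idx = splits[letter][1]
        n_test = int(np.floor(test_fraction * len(tgt_idx)))
        if n_test < 1 or n_test >= len(tgt_idx):
            raise ValueError(
                f"set {letter!r}: {len(tgt_idx)} target segments cannot be split "
                f"{1 - test_fraction:.0%}/{test_fraction:.0%} train/test"
            )
        perm = rng.permutation(tgt_idx)
        X_te, y_te = featurize(letter, perm[:n_test], cls)
        X_tr, y_tr = featurize(letter, perm[n_test:], cls)
        tr_X.append(X_tr); tr_y.append(y_tr)
        te_X.append(X_te); te_y.append(y_te)
    target_train = LabeledDataset(np.vstack(tr_X), np.concatenate(tr_y))
    target_test = LabeledDataset(np.vstack(te_X), np.concatenate(te_y))

    # z-score with statistics from data available at fit time (never test)
    fit_X = np.vstack([source.X, target_train.X])
    mu = fit_X.mean(axis=0)
    sd = fit_X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    for ds in (source, target_train, target_test):
        ds.X = (ds.X - mu) / sd

    return DomainPair(
        source=source,
        target_train=target_train,
        target_test=target_test,
        shift_kind="identical" if recipe == target_recipe else "cross_set",
        shift_magnitude=0.0,
        seed=seed,
    )
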