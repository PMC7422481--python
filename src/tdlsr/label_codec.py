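"""Binary label matrices and the relaxed (epsilon-dragged) regression targets.

Multiclass least-squares classifiers regress features onto a binary label
matrix ``Y`` (one-hot rows).  Discriminative LSR additionally builds a sign
matrix ``B`` (+1 at the true class, -1 elsewhere) and drags each target
outward by a nonnegative slack ``W``: the relaxed target is ``Y + B o W``
(``o`` = Hadamard product), pushing true-class scores above 1 and
false-class scores below 0, which enlarges inter-class margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "InvalidLabelSetError",
    "LabelEncoding",
    "encode_labels",
    "relaxed_targets",
    "decode_scores",
]


class InvalidLabelSetError(ValueError):
    """Raised when a label sequence cannot support multiclass encoding."""


@dataclass(frozen=True)
class LabelEncoding:
    """One-hot label matrix ``Y`` and sign matrix ``B`` for N samples.

    Attributes
    ----------
    class_index_map
        Ordered mapping from original label value to column index 0..C-1.
        Columns are ordered by sorted original label value.
    Y
        (N, C) matrix; each row has exactly one 1, zeros elsewhere.
    B
        (N, C) matrix with ``B = 2Y - 1``: +1 at the true class, -1 elsewhere.
    """

    class_index_map: dict[Any, int]
    Y: np.ndarray = field(repr=False)
    B: np.ndarray = field(repr=False)

    @property
    def C(self) -> int:
        """Number of classes (columns of Y)."""
        return self.Y.shape[1]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]


def encode_labels(labels: Sequence[Any]) -> LabelEncoding:
    """Build the binary label matrix Y and sign matrix B from class labels.

    Columns are assigned to the distinct labels in sorted order, making the
    encoding deterministic for any hashable, orderable label type.

    Raises
    ------
    InvalidLabelSetError
        If fewer than two distinct labels are present.
    """
    labels = list(labels)
    if len(labels) == 0:
        raise InvalidLabelSetError("empty label sequence")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise InvalidLabelSetError(
            f"need at least 2 distinct labels, got {len(classes)}"
        )
    cmap = {c: j for j, c in enumerate(classes)}
    N, C = len(labels), len(classes)
    Y = np.zeros((N, C))
    Y[np.arange(N), [cmap[v] for v in labels]] = 1.0
    B = 2.0 * Y - 1.0
    return LabelEncoding(class_index_map=cmap, Y=Y, B=B)


def relaxed_targets(encoding: LabelEncoding, W: np.ndarray) -> np.ndarray:
    """Dragged targets ``L = Y + B o W`` for a nonnegative slack matrix W.

    True-class entries of L are >= 1 and false-class entries <= 0, so the
    relaxation can only move targets away from the decision boundary.
    """
    W = np.asarray(W, dtype=float)
    if W.shape != encoding.Y.shape:
        raise ValueError(
            f"slack matrix shape {W.shape} != label matrix shape {encoding.Y.shape}"
        )
    if np.any(W < 0):
        raise ValueError("slack matrix W must be elementwise nonnegative")
    return encoding.Y + encoding.B * W


def decode_scores(
    scores: np.ndarray, class_index_map: Mapping[Any, int]
) -> np.ndarray:
    """Map rows of a score matrix back to original labels by argmax.

    Ties are broken toward the lowest column index (numpy argmax semantics),
    i.e. toward the smallest original label under the sorted column order.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    C = len(class_index_map)
    if scores.shape[1] != C:
        raise ValueError(
            f"score matrix has {scores.shape[1]} columns, class map has {C}"
        )
    inverse = [None] * C
    for label, j in class_index_map.items():
        inverse[j] = label
    cols = np.argmax(scores, axis=1)
    return np.asarray([inverse[j] for j in cols])
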