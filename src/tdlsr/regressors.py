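"""Least-squares classifiers: LSR, DLSR (epsilon-dragging) and transfer DLSR.

Three nested models over a feature matrix ``X`` (N x d) and one-hot targets
``Y`` (N x C):

* ridge LSR,   min_Z   ||XZ - Y||_F^2 + lam ||Z||_F^2;
* DLSR,        min_{Z,p,W>=0} ||XZ + e p^T - (Y + B o W)||_F^2 + lam ||Z||_F^2,
  solved by alternating two closed-form steps: a centered ridge solve for
  (Z, p) given the dragged targets L = Y + B o W, and the elementwise clamp
  W = max(B o G, 0) with G = XZ + e p^T - Y;
* transfer DLSR (TDLSR), which adds eta ||Z - Z_s||_F^2 to the DLSR
  objective, shrinking the target-domain coefficients toward a coefficient
  matrix Z_s learned on a source domain.  At eta = 0 it coincides with DLSR
  step for step.

The (Z, p) solve eliminates the offset p through the centering matrix
H = I - e e^T / N:  Z = (X^T H X + (lam + eta) I)^{-1} (X^T H L + eta Z_s)
and p = (L^T e - Z^T X^T e) / N.  H is applied implicitly by removing
column means; the normal matrix is symmetric positive definite for lam > 0
and is solved by a Cholesky-backed routine, never explicit inversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import scipy.linalg

from .label_codec import LabelEncoding, decode_scores, encode_labels

__all__ = [
    "IncompatibleDomainsError",
    "RegressionModel",
    "FitTrace",
    "SourceKnowledge",
    "centering_matrix",
    "solve_lsr",
    "fit_lsr",
    "dlsr_update_Zp",
    "dlsr_update_W",
    "fit_dlsr",
    "tdlsr_update_Z",
    "fit_tdlsr",
    "extract_source_knowledge",
    "predict",
    "save_model",
    "load_model",
]

DEFAULT_MAX_ITER = 50
DEFAULT_TOL = 1e-6


class IncompatibleDomainsError(ValueError):
    """Source knowledge does not match the target problem's classes/shape."""


@dataclass
class RegressionModel:
    """A fitted linear classifier: scores(X) = X Z + e p^T.

    ``Z`` is (d, C), ``p`` is (C,).  ``eta`` is 0 for non-transfer models.
    """

    Z: np.ndarray
    p: np.ndarray
    class_index_map: dict[Any, int] | None
    lam: float
    eta: float = 0.0
    model_kind: str = "lsr"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.model_kind != "tdlsr" and self.eta != 0.0:
            raise ValueError("eta must be 0 for non-transfer models")

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.Z.shape[0]:
            raise ValueError(
                f"feature matrix with {X.shape[-1] if X.ndim == 2 else '?'} "
                f"columns does not match model dimension {self.Z.shape[0]}"
            )
        return X @ self.Z + self.p[None, :]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


@dataclass
class FitTrace:
    """Objective value after each completed alternating iteration."""

    objective_values: list[float]
    converged: bool
    n_iterations: int


@dataclass
class SourceKnowledge:
    """Coefficient matrix learned on a source domain, ready to transfer.

    Only Z is transferred; the offset p is relearned on the target domain.
    """

    Z_s: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)
    class_index_map: dict[Any, int] | None = None

    def __post_init__(self) -> None:
        self.Z_s = np.asarray(self.Z_s, dtype=float)


def centering_matrix(N: int) -> np.ndarray:
    """The projector H = I_N - e e^T / N onto zero-mean N-vectors."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    return np.eye(N) - np.full((N, N), 1.0 / N)


def _check_Xy(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"row mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite entries in input")
    return X, Y


def solve_lsr(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    class_index_map: dict[Any, int] | None = None,
) -> RegressionModel:
    """Closed-form ridge regression onto a label matrix (no offset).

    Solves (X^T X + lam I) Z = X^T Y; lam > 0 guarantees the system is
    symmetric positive definite.
    """
    X, Y = _check_Xy(X, Y)
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    d = X.shape[1]
    A = X.T @ X + lam * np.eye(d)
    Z = scipy.linalg.solve(A, X.T @ Y, assume_a="pos")
    return RegressionModel(
        Z=Z,
        p=np.zeros(Y.shape[1]),
        class_index_map=class_index_map,
        lam=lam,
        model_kind="lsr",
    )


def fit_lsr(X: np.ndarray, labels: Sequence[Any], lam: float) -> RegressionModel:
    """Convenience wrapper: encode labels then apply the LSR closed form."""
    enc = encode_labels(labels)
    return solve_lsr(X, enc.Y, lam, class_index_map=enc.class_index_map)


def _centered_solve(
    X: np.ndarray,
    L: np.ndarray,
    lam: float,
    eta: float = 0.0,
    Z_s: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly optimal (Z, p) for ||XZ + e p^T - L||^2 + lam||Z||^2 [+ eta||Z-Z_s||^2].

    Centering X and L absorbs p; for eta = 0 the arithmetic is identical to
    the plain DLSR update, so the eta = 0 reduction holds bitwise.
    """
    d = X.shape[1]
    x_mean = X.mean(axis=0)
    l_mean = L.mean(axis=0)
    Xc = X - x_mean
    Lc = L - l_mean
    A = Xc.T @ Xc + (lam + eta) * np.eye(d)
    rhs = Xc.T @ Lc
    if eta != 0.0:
        if Z_s is None:
            raise ValueError("eta > 0 requires a source coefficient matrix")
        rhs = rhs + eta * Z_s
    Z = scipy.linalg.solve(A, rhs, assume_a="pos")
    p = l_mean - Z.T @ x_mean
    return Z, p


def dlsr_update_Zp(
    X: np.ndarray, L: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (Z, p) minimizing ||XZ + e p^T - L||_F^2 + lam ||Z||_F^2."""
    X, L = _check_Xy(X, L)
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    return _centered_solve(X, L, lam)


def dlsr_update_W(
    X: np.ndarray,
    Z: np.ndarray,
    p: np.ndarray,
    Y: np.ndarray,
    B: np.ndarray,
) -> np.ndarray:
    """Optimal nonnegative slack W = max(B o G, 0), G = XZ + e p^T - Y.

    The Frobenius objective ||G - B o W||^2 separates per entry; since
    B_ij^2 = 1 each scalar problem is (B_ij G_ij - W_ij)^2 clamped at 0.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    p = np.asarray(p, dtype=float)
    Y = np.asarray(Y, dtype=float)
    B = np.asarray(B, dtype=float)
    if Y.shape != B.shape:
        raise ValueError(f"Y shape {Y.shape} != B shape {B.shape}")
    G = X @ Z + p[None, :] - Y
    if G.shape != Y.shape:
        raise ValueError(f"score shape {G.shape} != label shape {Y.shape}")
    return np.maximum(B * G, 0.0)


def _dragging_objective(
    X: np.ndarray,
    Z: np.ndarray,
    p: np.ndarray,
    Y: np.ndarray,
    B: np.ndarray,
    W: np.ndarray,
    lam: float,
    eta: float = 0.0,
    Z_s: np.ndarray | None = None,
) -> float:
    R = X @ Z + p[None, :] - (Y + B * W)
    J = float(np.sum(R * R) + lam * np.sum(Z * Z))
    if eta != 0.0:
        D = Z - Z_s
        J += float(eta * np.sum(D * D))
    return J


def _fit_dragging(
    X: np.ndarray,
    labels: Sequence[Any],
    lam: float,
    eta: float,
    Z_s: np.ndarray | None,
    max_iter: int,
    tol: float,
    model_kind: str,
) -> tuple[RegressionModel, FitTrace]:
    enc = encode_labels(labels)
    X, Y = _check_Xy(X, enc.Y)
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    B = enc.B
    W = np.zeros_like(Y)  # iteration 1 is then plain ridge on Y
    objective_values: list[float] = []
    converged = False
    Z = np.zeros((X.shape[1], Y.shape[1]))
    p = np.zeros(Y.shape[1])
    for _ in range(max_iter):
        L = Y + B * W
        Z, p = _centered_solve(X, L, lam, eta=eta, Z_s=Z_s)
        W = dlsr_update_W(X, Z, p, Y, B)
        J = _dragging_objective(X, Z, p, Y, B, W, lam, eta=eta, Z_s=Z_s)
        if objective_values:
            prev = objective_values[-1]
            if abs(prev - J) / max(1.0, prev) < tol:
                objective_values.append(J)
                converged = True
                break
        objective_values.append(J)
    model = RegressionModel(
        Z=Z,
        p=p,
        class_index_map=enc.class_index_map,
        lam=lam,
        eta=eta if model_kind == "tdlsr" else 0.0,
        model_kind=model_kind,
    )
    trace = FitTrace(
        objective_values=objective_values,
        converged=converged,
        n_iterations=len(objective_values),
    )
    return model, trace


def fit_dlsr(
    X: np.ndarray,
    labels: Sequence[Any],
    lam: float,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[RegressionModel, FitTrace]:
    """Alternating closed-form fit of the epsilon-dragging classifier.

    Starts from W = 0 and alternates the (Z, p) ridge solve on the dragged
    targets with the slack clamp until the relative objective change drops
    below ``tol`` or ``max_iter`` iterations complete.  The traced objective
    is non-increasing: both steps are exact minimizers of a convex objective
    in their block.
    """
    return _fit_dragging(X, labels, lam, 0.0, None, max_iter, tol, "dlsr")


def tdlsr_update_Z(
    X: np.ndarray,
    L: np.ndarray,
    lam: float,
    eta: float,
    Z_s: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Transfer-regularized (Z, p) update.

    Minimizes ||XZ + e p^T - L||^2 + lam ||Z||^2 + eta ||Z - Z_s||^2 and
    reduces exactly to :func:`dlsr_update_Zp` at eta = 0.
    """
    X, L = _check_Xy(X, L)
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta}")
    Z_s = np.asarray(Z_s, dtype=float)
    if Z_s.shape != (X.shape[1], L.shape[1]):
        raise ValueError(
            f"Z_s shape {Z_s.shape} incompatible with (d={X.shape[1]}, C={L.shape[1]})"
        )
    if eta == 0.0:
        return _centered_solve(X, L, lam)
    return _centered_solve(X, L, lam, eta=eta, Z_s=Z_s)


def fit_tdlsr(
    X_target: np.ndarray,
    labels_target: Sequence[Any],
    source: SourceKnowledge | np.ndarray,
    lam: float,
    eta: float,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[RegressionModel, FitTrace]:
    """Fit the transfer classifier on scarce target data.

    ``source`` carries the coefficient matrix Z_s learned on the source
    domain; ``eta`` weighs the pull of the target coefficients toward Z_s.
    With eta = 0 the fit is identical, iterate by iterate, to
    :func:`fit_dlsr` on the same target data.

    Raises
    ------
    IncompatibleDomainsError
        If the source class set (when known) or the Z_s shape does not match
        the target problem.
    """
    if isinstance(source, SourceKnowledge):
        Z_s = source.Z_s
        src_map = source.class_index_map
    else:
        Z_s = np.asarray(source, dtype=float)
        src_map = None
    enc = encode_labels(labels_target)
    X_arr = np.asarray(X_target, dtype=float)
    if Z_s.shape != (X_arr.shape[1], enc.C):
        raise IncompatibleDomainsError(
            f"source Z_s shape {Z_s.shape} does not match target "
            f"(d={X_arr.shape[1]}, C={enc.C})"
        )
    if src_map is not None and set(src_map) != set(enc.class_index_map):
        raise IncompatibleDomainsError(
            f"source classes {sorted(src_map)} != target classes "
            f"{sorted(enc.class_index_map)}"
        )
    return _fit_dragging(
        X_target, labels_target, lam, eta, Z_s, max_iter, tol, "tdlsr"
    )


def extract_source_knowledge(
    X_source: np.ndarray,
    labels_source: Sequence[Any],
    lam: float,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    estimator: str = "dlsr",
) -> SourceKnowledge:
    """Learn the transferable coefficient matrix Z_s on the source domain.

    By default the source model is the same family as the target model
    (DLSR); ``estimator="lsr"`` uses the plain ridge closed form instead.
    """
    if estimator == "dlsr":
        model, trace = fit_dlsr(X_source, labels_source, lam, max_iter, tol)
        prov = {
            "estimator": "dlsr",
            "lam": lam,
            "n_samples": int(np.asarray(X_source).shape[0]),
            "n_iterations": trace.n_iterations,
            "converged": trace.converged,
        }
    elif estimator == "lsr":
        model = fit_lsr(X_source, labels_source, lam)
        prov = {
            "estimator": "lsr",
            "lam": lam,
            "n_samples": int(np.asarray(X_source).shape[0]),
        }
    else:
        raise ValueError(f"unknown source estimator {estimator!r}")
    return SourceKnowledge(
        Z_s=model.Z, provenance=prov, class_index_map=model.class_index_map
    )


def predict(model: RegressionModel, X_new: np.ndarray) -> np.ndarray:
    """Labels for new samples: argmax over columns of X Z + e p^T."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2:
        X_new = np.atleast_2d(X_new)
    if X_new.shape[0] == 0:
        return np.asarray([])
    scores = model.scores(X_new)
    if model.class_index_map is None:
        cmap = {j: j for j in range(model.Z.shape[1])}
    else:
        cmap = model.class_index_map
    return decode_scores(scores, cmap)


# --- serialization -----------------------------------------------------------
# Single JSON file: Z and p as nested lists, classes in column order,
# hyperparameters and free-form provenance.  Labels survive the round trip
# for JSON-representable types (int, float, str).

def save_model(model: RegressionModel, path: str | Path, provenance: dict | None = None) -> None:
    if model.class_index_map is not None:
        classes: list[Any] | None = [None] * len(model.class_index_map)
        for label, j in model.class_index_map.items():
            classes[j] = label.item() if isinstance(label, np.generic) else label
    else:
        classes = None
    payload = {
        "format": "tdlsr-model-v1",
        "model_kind": model.model_kind,
        "lam": model.lam,
        "eta": model.eta,
        "classes": classes,
        "Z": model.Z.tolist(),
        "p": model.p.tolist(),
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> RegressionModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "tdlsr-model-v1":
        raise ValueError(f"{path}: not a tdlsr model file")
    classes = payload["classes"]
    cmap = {c: j for j, c in enumerate(classes)} if classes is not None else None
    return RegressionModel(
        Z=np.asarray(payload["Z"], dtype=float),
        p=np.asarray(payload["p"], dtype=float),
        class_index_map=cmap,
        lam=payload["lam"],
        eta=payload["eta"],
        model_kind=payload["model_kind"],
    )
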