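"""Independent numeric oracles for the closed-form solvers.

Everything here minimizes the stated objective directly (L-BFGS from a
zero start, or per-entry scalar minimization), sharing no code with the
closed forms under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog, minimize, minimize_scalar


def numeric_ridge(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Minimize ||XZ - Y||_F^2 + lam ||Z||_F^2 numerically (no offset)."""
    d, C = X.shape[1], Y.shape[1]

    def fg(z):
        Z = z.reshape(d, C)
        R = X @ Z - Y
        f = np.sum(R * R) + lam * np.sum(Z * Z)
        g = 2.0 * X.T @ R + 2.0 * lam * Z
        return f, g.ravel()

    res = minimize(fg, np.zeros(d * C), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x.reshape(d, C)


def numeric_offset_ridge(
    X: np.ndarray,
    L: np.ndarray,
    lam: float,
    eta: float = 0.0,
    Z_s: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly minimize ||XZ + e p^T - L||^2 + lam||Z||^2 [+ eta||Z - Z_s||^2]."""
    N, d = X.shape
    C = L.shape[1]

    def fg(v):
        Z = v[: d * C].reshape(d, C)
        p = v[d * C:]
        R = X @ Z + p[None, :] - L
        f = np.sum(R * R) + lam * np.sum(Z * Z)
        gZ = 2.0 * X.T @ R + 2.0 * lam * Z
        gp = 2.0 * R.sum(axis=0)
        if eta:
            D = Z - Z_s
            f += eta * np.sum(D * D)
            gZ = gZ + 2.0 * eta * D
        return f, np.concatenate([gZ.ravel(), gp])

    res = minimize(fg, np.zeros(d * C + C), jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-13})
    return res.x[: d * C].reshape(d, C), res.x[d * C:]


def numeric_slack(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-entry minimization of (G_ij - B_ij w)^2 over w >= 0."""
    W = np.empty_like(G)
    hi = float(np.abs(G).max()) + 1.0
    for i in range(G.shape[0]):
        for j in range(G.shape[1]):
            res = minimize_scalar(
                lambda w: (G[i, j] - B[i, j] * w) ** 2,
                bounds=(0.0, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            W[i, j] = res.x
    return W


def is_linearly_separable(X: np.ndarray, y: np.ndarray) -> bool:
    """LP feasibility of y_i (w . x_i + b) >= 1 for binary labels."""
    classes = np.unique(y)
    assert classes.size == 2
    s = np.where(y == classes[0], -1.0, 1.0)
    # variables (w, b); constraints -s_i (x_i . w + b) <= -1
    A = -s[:, None] * np.hstack([X, np.ones((X.shape[0], 1))])
    b_ub = -np.ones(X.shape[0])
    res = linprog(
        c=np.zeros(X.shape[1] + 1), A_ub=A, b_ub=b_ub,
        bounds=[(None, None)] * (X.shape[1] + 1), method="highs",
    )
    return res.status == 0
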