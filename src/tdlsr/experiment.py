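"""Protocol driver: hyperparameter grids, cross-validated selection, accuracy tables.

Reproduces the evaluation protocol of the transfer study: each estimator is
tuned by k-fold cross-validation on the target training split only, fitted,
and scored on the held-out target test split.  Non-transfer estimators
(LSR, DLSR, SVM) train on the pooled source + target-train data — which is
why corrupting the source domain degrades them — while TDLSR learns Z_s on
the source and fits only the scarce target-train data, pulled toward Z_s.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import regressors
from .synthetic import DomainPair, LabeledDataset, add_source_noise, make_domain_pair

__all__ = [
    "LAMBDA_GRID",
    "ETA_GRID",
    "SVM_GRID",
    "DEFAULT_GRIDS",
    "ESTIMATORS",
    "grid_search",
    "fit_estimator",
    "accuracy",
    "run_experiment",
]

log = logging.getLogger(__name__)

# regularization grids of the evaluation protocol
LAMBDA_GRID = tuple(10.0 ** k for k in range(-4, 3))  # 1e-4 .. 1e2
ETA_GRID = tuple(10.0 ** k for k in range(-4, 3))
SVM_GRID = tuple(2.0 ** k for k in range(-5, 6))  # 2^-5 .. 2^5

DEFAULT_GRIDS: dict[str, dict[str, Sequence[float]]] = {
    "lsr": {"lam": LAMBDA_GRID},
    "dlsr": {"lam": LAMBDA_GRID},
    "tdlsr": {"lam": LAMBDA_GRID, "eta": ETA_GRID},
    "svm": {"c": SVM_GRID, "gamma": SVM_GRID},
}
ESTIMATORS = tuple(DEFAULT_GRIDS)

# parameter iteration order; ties in CV accuracy resolve toward the
# earlier (smaller) setting, lam before eta
_PARAM_ORDER = {"lam": 0, "eta": 1, "c": 0, "gamma": 1}


@dataclass
class _FittedEstimator:
    kind: str
    params: dict[str, float]
    _predict: Any

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._predict(X)


def fit_estimator(
    kind: str,
    source: LabeledDataset,
    target_train_X: np.ndarray,
    target_train_y: np.ndarray,
    params: Mapping[str, float],
    source_knowledge: regressors.SourceKnowledge | None = None,
    pool_source: bool = True,
) -> _FittedEstimator:
    """Fit one estimator under the pooled/transfer training protocol.

    ``pool_source`` controls whether the non-transfer estimators train on
    source + target-train (the pooled protocol) or on the target
    training split alone (the transfer-vs-target-only comparison); TDLSR
    always learns Z_s from the source and fits the target split only.
    ``source_knowledge`` lets callers reuse an already-extracted Z_s for
    TDLSR; otherwise it is learned here with the candidate lam.
    """
    params = dict(params)
    if kind in ("lsr", "dlsr", "svm"):
        if pool_source:
            X = np.vstack([source.X, target_train_X])
            y = np.concatenate([source.labels, target_train_y])
        else:
            X, y = target_train_X, target_train_y
        if kind == "lsr":
            model = regressors.fit_lsr(X, y, lam=params["lam"])
            return _FittedEstimator(kind, params, model.predict)
        if kind == "dlsr":
            model, _ = regressors.fit_dlsr(X, y, lam=params["lam"])
            return _FittedEstimator(kind, params, model.predict)
        clf = SVC(C=params["c"], gamma=params["gamma"], kernel="rbf")
        clf.fit(X, y)
        return _FittedEstimator(kind, params, clf.predict)
    if kind == "tdlsr":
        if source_knowledge is None:
            source_knowledge = regressors.extract_source_knowledge(
                source.X, source.labels, lam=params["lam"]
            )
        model, _ = regressors.fit_tdlsr(
            target_train_X,
            target_train_y,
            source_knowledge,
            lam=params["lam"],
            eta=params["eta"],
        )
        return _FittedEstimator(kind, params, model.predict)
    raise ValueError(f"unknown estimator {kind!r}")


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(np.asarray(pred) == np.asarray(truth)))


def _grid_points(grid: Mapping[str, Sequence[float]]) -> list[dict[str, float]]:
    names = sorted(grid, key=lambda n: _PARAM_ORDER.get(n, 99))
    if not names or any(len(grid[n]) == 0 for n in names):
        raise ValueError("hyperparameter grid must be non-empty")
    return [
        dict(zip(names, values))
        for values in itertools.product(*(sorted(grid[n]) for n in names))
    ]


def grid_search(
    kind: str,
    pair: DomainPair,
    grid: Mapping[str, Sequence[float]] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    pool_source: bool = True,
) -> dict[str, float]:
    """Pick hyperparameters by k-fold CV accuracy on the target training split.

    The test split never participates.  Ties break toward the smaller
    setting (lam first, then eta).  Deterministic for a given seed.
    """
    grid = DEFAULT_GRIDS[kind] if grid is None else grid
    points = _grid_points(grid)
    if len(points) == 1:
        return points[0]

    y = pair.target_train.labels
    _, counts = np.unique(y, return_counts=True)
    smallest = int(counts.min())
    if k_folds < 2 or k_folds > smallest:
        raise ValueError(
            f"k_folds={k_folds} invalid: the smallest target-train class has "
            f"{smallest} samples; use 2 <= k_folds <= {smallest}"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(pair.target_train.X, y))

    # Z_s depends only on lam: cache across eta values
    zs_cache: dict[float, regressors.SourceKnowledge] = {}

    def source_knowledge_for(lam: float) -> regressors.SourceKnowledge:
        if lam not in zs_cache:
            zs_cache[lam] = regressors.extract_source_knowledge(
                pair.source.X, pair.source.labels, lam=lam
            )
        return zs_cache[lam]

    best_params, best_acc = None, -np.inf
    for params in points:
        fold_acc = []
        for train_rows, val_rows in folds:
            sk = source_knowledge_for(params["lam"]) if kind == "tdlsr" else None
            est = fit_estimator(
                kind,
                pair.source,
                pair.target_train.X[train_rows],
                y[train_rows],
                params,
                source_knowledge=sk,
                pool_source=pool_source,
            )
            fold_acc.append(
                accuracy(est.predict(pair.target_train.X[val_rows]), y[val_rows])
            )
        mean_acc = float(np.mean(fold_acc))
        log.debug("grid %s %s: CV accuracy %.4f", kind, params, mean_acc)
        if mean_acc > best_acc:
            best_params, best_acc = params, mean_acc
    return best_params


def _make_pair(data: Mapping[str, Any], seed: int) -> DomainPair:
    data = dict(data)
    kind = data.pop("kind", "synthetic")
    if kind == "synthetic":
        return make_domain_pair(seed=seed, **data)
    if kind == "bonn":
        from .eeg import build_subdataset, read_bonn_segment

        root = Path(data.pop("dir"))
        recipe = data.pop("recipe")
        target_recipe = data.pop("target_recipe", None)
        letters = set(recipe + (target_recipe or ""))
        segments = {
            letter: [
                read_bonn_segment(f, set_label=letter)
                for f in sorted((root / letter).glob("*"))
            ]
            for letter in letters
        }
        return build_subdataset(
            segments, recipe, target_recipe=target_recipe, seed=seed, **data
        )
    raise ValueError(f"unknown data kind {kind!r}")


def run_experiment(config: Mapping[str, Any]) -> pd.DataFrame:
    """Run the full protocol described by a flat config mapping.

    Recognized keys: ``data`` (synthetic generator kwargs or a Bonn
    directory layout), ``estimators`` (names), ``grids`` (per-estimator
    hyperparameter grids; defaults otherwise), ``seeds`` (list of ints),
    ``noise_level`` (source-domain noise fraction, 0 disables),
    ``k_folds`` (CV folds, default 5) and ``output_dir`` (optional; writes
    results.tsv and summary.tsv).  Returns one row per estimator per seed;
    the result is a pure function of the config.
    """
    data = config.get("data", {"kind": "synthetic"})
    estimators = config.get("estimators", ["lsr", "dlsr", "tdlsr"])
    grids = config.get("grids", {})
    seeds = list(config.get("seeds", range(20)))
    noise_level = float(config.get("noise_level", 0.0))
    k_folds = int(config.get("k_folds", 5))
    pool_source = bool(config.get("pool_source", True))

    rows = []
    for seed in seeds:
        pair = _make_pair(data, seed)
        if noise_level > 0:
            pair = add_source_noise(pair, noise_level, seed=seed)
        for kind in estimators:
            if kind not in DEFAULT_GRIDS:
                raise ValueError(f"unknown estimator {kind!r}")
            grid = grids.get(kind, DEFAULT_GRIDS[kind])
            points = _grid_points(grid)
            if len(points) == 1:
                best = points[0]
            else:
                best = grid_search(
                    kind, pair, grid, k_folds=k_folds, seed=seed,
                    pool_source=pool_source,
                )
            est = fit_estimator(
                kind, pair.source, pair.target_train.X, pair.target_train.labels,
                best, pool_source=pool_source,
            )
            acc = accuracy(est.predict(pair.target_test.X), pair.target_test.labels)
            log.debug("seed %d %s %s: test accuracy %.4f", seed, kind, best, acc)
            rows.append(
                {
                    "seed": seed,
                    "estimator": kind,
                    "accuracy": acc,
                    "noise_level": noise_level,
                    **{f"param_{k}": v for k, v in best.items()},
                }
            )
    results = pd.DataFrame(rows)

    out_dir = config.get("output_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.tsv", sep="\t", index=False)
        summary = (
            results.groupby("estimator")["accuracy"].agg(["mean", "std", "count"])
        )
        summary.to_csv(out / "summary.tsv", sep="\t")
    return results
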