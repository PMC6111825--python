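"""Iterative random-forest elimination of subpathway features.

A bootstrap forest of sqrt-mtry decision trees is trained on the subpathway
activity matrix to classify good vs poor prognosis. Feature importance is
the mean per-tree drop in out-of-bag (OOB) accuracy when that feature's
column is permuted among the tree's OOB samples; at each iteration the least
important third of the features (floor(m/3), minimum 1) is discarded and the
OOB error re-estimated, down to two features. The selected set is then read
off the error trace; the default "min_plus_se" rule keeps the smallest set
whose OOB error is within one standard error of the trace minimum — a
deterministic surrogate for picking the elbow of the error curve by eye.

The forest is built with ``BaggingClassifier`` over
``DecisionTreeClassifier(max_features="sqrt")`` (the same estimator as a
classical random forest) because it exposes per-tree bootstrap samples,
which the OOB permutation importance needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .activity_search import ActivityMatrix
from .expression_io import ClinicalTable, POOR

logger = logging.getLogger(__name__)

__all__ = ["IterationRecord", "EliminationTrace", "rf_iterative_elimination"]


@dataclass
class IterationRecord:
    """State of one elimination step before any feature is dropped."""

    iteration: int
    retained_ids: tuple[str, ...]
    oob_error: float
    importances: pd.Series  # indexed by retained_ids

    @property
    def n_features(self) -> int:
        return len(self.retained_ids)


@dataclass
class EliminationTrace:
    """Full elimination history plus the stop-rule selection."""

    iterations: list[IterationRecord]
    selected_ids: tuple[str, ...]
    stop_rule: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [it.iteration for it in self.iterations],
                "n_features": [it.n_features for it in self.iterations],
                "oob_error": [it.oob_error for it in self.iterations],
            }
        )


def _fit_forest(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> BaggingClassifier:
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt",
                                         random_state=seed),
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with np.errstate(invalid="ignore"):
        model.fit(X, y)
    return model


def _oob_permutation_importance(
    model: BaggingClassifier, X: np.ndarray, y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean per-tree drop in OOB accuracy when each feature is permuted."""
    n, m = X.shape
    drop = np.zeros(m)
    used = np.zeros(m)
    for est, samp in zip(model.estimators_, model.estimators_samples_):
        inbag = np.zeros(n, dtype=bool)
        inbag[samp] = True
        oob = np.flatnonzero(~inbag)
        if oob.size == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        base_acc = (est.predict(Xo) == yo).mean()
        # One stacked predict per tree: m permuted copies of the OOB block.
        stack = np.broadcast_to(Xo, (m, oob.size, m)).copy()
        for f in range(m):
            stack[f, :, f] = Xo[rng.permutation(oob.size), f]
        pred = est.predict(stack.reshape(m * oob.size, m))
        acc = (pred.reshape(m, oob.size) == yo).mean(axis=1)
        drop += base_acc - acc
        used += 1
    with np.errstate(invalid="ignore"):
        imp = np.where(used > 0, drop / np.maximum(used, 1), 0.0)
    return imp


def rf_iterative_elimination(
    activity: ActivityMatrix,
    labels: pd.Series | ClinicalTable,
    n_trees: int = 10_000,
    drop_fraction: float = 1 / 3,
    seed: int | None = None,
    stop_rule: str = "min_plus_se",
) -> EliminationTrace:
    """Narrow the feature set by repeated forest fitting and importance drops.

    Parameters
    ----------
    activity
        Subpathways x samples activity matrix (features are rows).
    labels
        Prognosis classes per sample (good/poor).
    n_trees
        Trees per iteration (default 10 000); mtry is floor(sqrt(m)).
    drop_fraction
        Fraction of features discarded per iteration, floor(m * f), min 1.
    stop_rule
        ``min_plus_se`` (default) or ``min``: smallest retained set whose OOB
        error is within one standard error of (resp. equal to) the minimum.
    """
    if stop_rule not in ("min_plus_se", "min"):
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    if isinstance(labels, ClinicalTable):
        labels = labels.labels
    aligned = labels.reindex(activity.samples)
    if aligned.isna().any():
        raise ValueError("missing prognosis label for some activity samples")
    y = (aligned == POOR).to_numpy().astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("each class needs >= 2 samples")
    ids = list(activity.subpathway_ids)
    X_full = activity.data.to_numpy().T
    if len(ids) == 0:
        raise ValueError("activity matrix has no features")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    trace: list[IterationRecord] = []
    retained = ids
    it = 0
    while True:
        cols = [ids.index(i) for i in retained]
        X = X_full[:, cols]
        m = len(retained)
        if m == 1:
            # Forest of stumps still defined; record OOB error for the trace.
            model = _fit_forest(X, y, n_trees, int(ss.entropy or 0) % (2**31)
                                if seed is None else (seed + it) % (2**31))
            err = 1.0 - float(model.oob_score_)
            trace.append(IterationRecord(
                it, tuple(retained), err,
                pd.Series([np.nan], index=retained),
            ))
            break
        tree_seed = (0 if seed is None else seed)
        model = _fit_forest(X, y, n_trees, (tree_seed + 7919 * it) % (2**31))
        err = 1.0 - float(model.oob_score_)
        imp = _oob_permutation_importance(model, X, y, rng)
        trace.append(IterationRecord(
            it, tuple(retained), err, pd.Series(imp, index=retained),
        ))
        if m <= 2:
            break
        n_drop = max(1, math.floor(m * drop_fraction))
        # Stable order: drop lowest importance, ties resolved by id.
        order = sorted(range(m), key=lambda k: (imp[k], retained[k]))
        dropped = {retained[k] for k in order[:n_drop]}
        retained = [i for i in retained if i not in dropped]
        it += 1

    errors = np.array([r.oob_error for r in trace])
    n_samples = len(y)
    min_err = errors.min()
    if stop_rule == "min_plus_se":
        se = math.sqrt(max(min_err * (1 - min_err), 0.0) / n_samples)
        cutoff = min_err + se
    else:
        cutoff = min_err
    eligible = [r for r in trace if r.oob_error <= cutoff + 1e-12]
    selected = min(eligible, key=lambda r: r.n_features).retained_ids
    return EliminationTrace(trace, selected, stop_rule)
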