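"""Shapley-style feature attribution for the stacked classifier.

A model-agnostic permutation-sampling estimator: the contribution of
feature j to the predicted probability of class c for sample x is the
average, over feature orderings and background rows, of the change in
model output when x_j replaces the background value — the classic Shapley
construction.  Each sampled (ordering, background-row) pair contributes a
telescoping walk from the background row to x, so additivity

    base_value_c + sum_j phi_jc(x) = f_c(x)

holds *exactly* for the estimate (the Monte-Carlo error lives in how the
total is split among features, not in their sum).  With few features the
estimator enumerates all orderings and is exact with respect to the
empirical background distribution.

The estimator only needs a ``predict_proba`` callable, so it treats the
heterogeneous stack (boosted trees + SVC + extra trees + KNN meta) as one
black box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AttributionReport", "attribute", "summarize"]


@dataclass
class AttributionReport:
    """Per-sample, per-feature, per-class Shapley contribution estimates."""

    values: np.ndarray        # (n_samples, n_features, n_classes)
    base_values: np.ndarray   # (n_classes,)
    feature_names: list[str]
    classes: np.ndarray
    X: np.ndarray             # the explained rows
    n_evaluations: int
    mc_tolerance: float       # typical Monte-Carlo SE of a single phi
    exact: bool
    seed: int

    def additivity_gap(self, predict_proba) -> float:
        """Max |base + sum_j phi_j - f(x)| over samples and classes."""
        recon = self.base_values[None, :] + self.values.sum(axis=1)
        return float(np.abs(recon - predict_proba(self.X)).max())

    def global_importance(self) -> pd.Series:
        """Mean |contribution| over samples and classes, descending."""
        imp = np.abs(self.values).mean(axis=(0, 2))
        return pd.Series(imp, index=self.feature_names).sort_values(ascending=False)

    def class_importance(self, cls) -> pd.Series:
        j = int(np.nonzero(self.classes == cls)[0][0])
        imp = np.abs(self.values[:, :, j]).mean(axis=0)
        return pd.Series(imp, index=self.feature_names).sort_values(ascending=False)


def _as_predict_proba(model):
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    return model.predict_proba


def attribute(
    model,
    X,
    background,
    n_permutations: int = 20,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> AttributionReport:
    """Estimate Shapley contributions of every feature for every row of X.

    Parameters
    ----------
    model : fitted results object with ``predict_proba``, or the callable itself.
    background : array of reference rows defining the "feature withheld"
        distribution (typically a sample of the training set).
    n_permutations : sampled feature orderings per explained row.  When the
        full ordering space is at most ``n_permutations x n_background`` the
        estimator enumerates it and becomes exact.

    The same (ordering, background-row) pairs are used for every explained
    row, so the per-class base value is a constant: the mean model output
    over the background rows used.
    """
    f = _as_predict_proba(model)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        background = background[None, :]
    if background.size == 0:
        raise ValueError("background sample must be non-empty")
    n, d = X.shape
    if background.shape[1] != d:
        raise ValueError(
            f"background has {background.shape[1]} features, X has {d}"
        )
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(d)]

    rng = np.random.default_rng(seed)
    n_bg = len(background)
    exact = d <= 8 and math.factorial(d) <= n_permutations
    if exact:
        # enumerate every ordering against every background row
        import itertools

        pairs = [
            (np.array(p), b)
            for p in itertools.permutations(range(d))
            for b in range(n_bg)
        ]
    else:
        pairs = [
            (rng.permutation(d), int(i % n_bg))
            for i in range(n_permutations)
        ]

    n_classes = np.asarray(f(X[:1])).shape[1]
    classes = np.arange(n_classes)
    base = np.mean(
        np.asarray(f(background[[b for _, b in pairs]])), axis=0
    )

    values = np.zeros((n, d, n_classes))
    sq = np.zeros((n, d, n_classes))
    n_eval = 0
    for si in range(n):
        x = X[si]
        # batch every telescoping walk for this sample into one model call
        rows = np.empty((len(pairs) * (d + 1), d))
        for pi, (perm, b) in enumerate(pairs):
            z = background[b].copy()
            block = pi * (d + 1)
            rows[block] = z
            for step, j in enumerate(perm, start=1):
                z[j] = x[j]
                rows[block + step] = z
        out = np.asarray(f(rows))
        n_eval += len(rows)
        for pi, (perm, _) in enumerate(pairs):
            block = pi * (d + 1)
            diffs = out[block + 1: block + d + 1] - out[block: block + d]
            values[si, perm, :] += diffs
            sq[si, perm, :] += diffs**2
    m = len(pairs)
    values /= m
    if m > 1:
        var = np.maximum(sq / m - values**2, 0.0) / m
        mc_tol = float(np.sqrt(var).mean())
    else:
        mc_tol = 0.0
    return AttributionReport(
        values=values,
        base_values=base,
        feature_names=list(feature_names),
        classes=classes,
        X=X,
        n_evaluations=n_eval,
        mc_tolerance=0.0 if exact else mc_tol,
        exact=exact,
        seed=seed,
    )


def summarize(report: AttributionReport, top_n: int = 15) -> dict:
    """Global and per-class rankings plus high-value sign summaries.

    Returns a dict with ``global`` (DataFrame: feature, mean |phi|),
    ``per_class`` (class -> DataFrame) and ``sign`` (class -> DataFrame
    with the fraction of above-median-value samples whose contribution is
    positive, a beeswarm-style direction summary).
    """
    glob = report.global_importance().head(top_n).rename("mean_abs_contribution")
    per_class = {}
    sign = {}
    X = report.X
    medians = np.median(X, axis=0)
    for ci, cls in enumerate(report.classes):
        ranking = report.class_importance(cls).head(top_n).rename(
            "mean_abs_contribution"
        )
        rows = []
        for feat in ranking.index:
            j = report.feature_names.index(feat)
            high = X[:, j] > medians[j]
            contrib = report.values[:, j, ci]
            frac = float((contrib[high] > 0).mean()) if high.any() else np.nan
            rows.append((feat, frac))
        per_class[int(cls)] = ranking.rename_axis("feature").reset_index()
        sign[int(cls)] = pd.DataFrame(
            rows, columns=["feature", "frac_positive_at_high_value"]
        )
    return {
        "global": glob.rename_axis("feature").reset_index(),
        "per_class": per_class,
        "sign": sign,
    }
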