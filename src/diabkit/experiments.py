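"""Canonical validation experiments for the whole pipeline.

Each function sets up one study-condition experiment — the geometry
oracle sweep, metric-formula fidelity, the SMOTE contract, stratification,
weight-model recovery, attribution axioms, and the end-to-end planted
effect recovery / null-cohort power studies — and returns plain-number
summaries.  The test suite asserts thresholds on these numbers; the
reproduction script reports them.
"""

from __future__ import annotations

import numpy as np

from .attribution import attribute
from .cohort import CohortSpec, PlantedEffect, simulate_cohort
from .geometry import ParallelRayError, PhoneSpec, distance_from_image, max_valid_k
from .labels import assemble_predictors
from .metrics import classification_metrics
from .scene import make_cuisine_dataset, raycast_distance
from .stacking import StackConfig, StackedHbA1cModel, smote_oversample, stratified_folds
from .weight import WeightModel, analytic_noise_floor

__all__ = [
    "STRONG_PLANTS",
    "geometry_agreement",
    "metric_fidelity",
    "smote_contract",
    "stratification_check",
    "weight_recovery",
    "attribution_axioms",
    "planted_effect_recovery",
    "null_cohort_experiment",
]

#: the five strong numeric plants used for the power study: directions as the
#: attribution analysis reports them, magnitude at the 1.5-SD "strong" level
STRONG_PLANTS = (
    PlantedEffect("age", 0, +1.5),
    PlantedEffect("WHR_exam1", 0, -1.5),
    PlantedEffect("Se", 1, -1.5),
    PlantedEffect("HDL_exam1", 1, +1.5),
    PlantedEffect("TG_exam1", 2, +1.5),
)


def geometry_agreement(n_points: int = 100, p: float = 0.15, seed: int = 0) -> dict:
    """Closed-form vs ray-cast shooting distance over an (alpha, beta, k) grid,
    plus the literal printed-formula disagreement for the audit."""
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    literal_gap = []
    done = 0
    while done < n_points:
        alpha = rng.uniform(np.deg2rad(30), np.deg2rad(80))
        beta = rng.uniform(np.deg2rad(15), np.deg2rad(45))
        spec = PhoneSpec(p=p, beta=beta)
        k = rng.uniform(0.0, 0.95) * max_valid_k(spec, alpha)
        try:
            closed = distance_from_image(spec, alpha, k)
            cast = raycast_distance(spec, alpha, k)
        except ParallelRayError:
            continue
        max_rel = max(max_rel, abs(closed - cast) / abs(cast))
        literal = distance_from_image(spec, alpha, k, mode="literal")
        literal_gap.append(abs(literal - closed) / abs(closed))
        done += 1
    return {
        "n": n_points,
        "max_rel_error": float(max_rel),
        "literal_mode_mean_rel_gap": float(np.mean(literal_gap)),
    }


def _contingency_oracle(cm: np.ndarray) -> tuple[float, float, float, float]:
    n = cm.shape[0]
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    acc = tp.sum() / (tp + fn).sum()
    prec = np.mean([tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] else 0.0 for i in range(n)])
    rec = np.mean(tp / (tp + fn))
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return acc, float(prec), float(rec), f1


def metric_fidelity(n_matrices: int = 50, seed: int = 0) -> dict:
    """Max absolute deviation of the metric formulas from the per-class
    TP/FP/FN oracle over random 3-class confusion matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        cm = rng.integers(0, 20, size=(3, 3)) + np.eye(3, dtype=int)
        y_true, y_pred = [], []
        for i in range(3):
            for j in range(3):
                y_true += [i] * int(cm[i, j])
                y_pred += [j] * int(cm[i, j])
        rep = classification_metrics(y_true, y_pred)
        oracle = _contingency_oracle(cm)
        got = (rep.accuracy, rep.macro_precision, rep.macro_recall, rep.macro_f1)
        worst = max(worst, max(abs(a - b) for a, b in zip(got, oracle)))
        tp = np.diag(rep.confusion)
        fn = rep.confusion.sum(axis=1) - tp
        fp = rep.confusion.sum(axis=0) - tp
        assert (tp + fn).sum() == (tp + fp).sum() == cm.sum()
    return {"n": n_matrices, "max_abs_deviation": float(worst)}


def smote_contract(seed: int = 0) -> dict:
    """Oversample the study class split and audit the interpolation geometry."""
    rng = np.random.default_rng(seed)
    counts = (21, 15, 52)
    X = rng.normal(size=(sum(counts), 6))
    y = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    X2, y2 = smote_oversample(X, y, k_neighbors=5, seed=seed)
    balanced = dict(zip(*np.unique(y2, return_counts=True)))
    originals_kept = bool(
        np.array_equal(X2[: len(X)], X) and np.array_equal(y2[: len(y)], y)
    )
    from sklearn.neighbors import NearestNeighbors

    off_segment = 0
    for c in (0, 1):
        members = X[y == c]
        hood = (
            NearestNeighbors(n_neighbors=6).fit(members)
            .kneighbors(members, return_distance=False)[:, 1:]
        )
        synth = X2[len(X):][y2[len(X):] == c]
        for s in synth:
            ok = False
            for i in range(len(members)):
                for j in hood[i]:
                    a, b = members[i], members[j]
                    ab = b - a
                    lam = ((s - a) @ ab) / (ab @ ab)
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(a + lam * ab, s, atol=1e-8):
                        ok = True
                        break
                if ok:
                    break
            off_segment += not ok
    return {
        "balanced_counts": {int(k): int(v) for k, v in balanced.items()},
        "originals_preserved": originals_kept,
        "synthetic_off_segment": int(off_segment),
        "n_synthetic": int(len(X2) - len(X)),
    }


def stratification_check(K: int = 4, seed: int = 0) -> dict:
    """Fold class counts vs proportional allocation for the 21:15:52 split."""
    y = np.concatenate([np.zeros(21), np.ones(15), np.full(52, 2)])
    plan = stratified_folds(y, K=K, seed=seed)
    props = plan.class_proportions().to_numpy()
    ideal = np.array([21, 15, 52]) / K
    plan2 = stratified_folds(y, K=K, seed=seed)
    identical = all(np.array_equal(a, b) for a, b in zip(plan.folds, plan2.folds))
    return {
        "K": K,
        "max_deviation_from_proportional": float(np.abs(props - ideal).max()),
        "identical_under_same_seed": bool(identical),
    }


def weight_recovery(seed: int = 0) -> dict:
    """Planted-law coefficient recovery and the noisy held-out MAE ratio."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 200
    S = rng.uniform(10, 100, n)
    noiseless = pd.DataFrame(
        {
            "type_id": rng.integers(0, 4, n),
            "alpha": rng.uniform(0.5, 1.4, n),
            "l_OC": rng.uniform(0.2, 0.8, n),
            "S": S,
            "weight": 3.0 * S,
        }
    )
    res = WeightModel(noiseless, lam=0.0, interaction=False).fit(seed=seed)
    coef_err = abs(res.coef_raw["S"] - 3.0)

    train = make_cuisine_dataset(n=1000, n_types=19, seed=seed + 1)
    test = make_cuisine_dataset(n=500, n_types=19, seed=seed + 2)
    fitted = WeightModel(train, lam=None).fit(seed=seed)
    mae, _ = fitted.evaluate_mae(test)
    floor = analytic_noise_floor(float(test["true_weight"].mean()), 0.05)
    return {
        "coef_abs_error": float(coef_err),
        "heldout_mae_g": float(mae),
        "noise_floor_g": float(floor),
        "mae_over_floor": float(mae / floor),
    }


def attribution_axioms(seed: int = 0) -> dict:
    """Linear closed form, symmetry, null player, additivity."""
    rng = np.random.default_rng(seed)
    d = 12
    W = rng.normal(size=(3, d))
    b = rng.normal(size=3)

    def f(X):
        return np.atleast_2d(np.asarray(X, dtype=float)) @ W.T + b

    bg = rng.normal(size=(40, d))
    X = rng.normal(size=(4, d))
    rep = attribute(f, X, bg, n_permutations=400, seed=seed)
    expected = (X - bg.mean(axis=0))[:, :, None] * W.T[None, :, :]
    linear_err = float(
        np.abs(rep.values - expected).max() / np.abs(expected).max()
    )
    additivity = float(rep.additivity_gap(f))

    def g(X):
        X = np.atleast_2d(X)
        s = X[:, 0] + X[:, 1]
        return np.column_stack([s, -s, 0 * s])

    bg3 = rng.normal(size=(20, 3))
    bg3[:, 1] = bg3[:, 0]  # symmetry needs exchangeable background columns
    x = np.array([1.1, 1.1, 0.2])
    rep_sym = attribute(g, x, bg3, n_permutations=24, seed=seed)
    symmetry_gap = float(
        np.abs(rep_sym.values[0, 0, :] - rep_sym.values[0, 1, :]).max()
    )
    null_gap = float(np.abs(rep_sym.values[0, 2, :]).max())
    return {
        "linear_max_rel_error": linear_err,
        "symmetry_gap": symmetry_gap,
        "null_player_gap": null_gap,
        "additivity_gap": additivity,
    }


def _power_one_seed(seed: int, explain_rows: int = 32, n_perm: int = 8):
    cohort = simulate_cohort(CohortSpec(planted_effects=STRONG_PLANTS, seed=seed))
    X, y = assemble_predictors(cohort)
    model = StackedHbA1cModel(X, y, config=StackConfig(seed=seed))
    rep = model.cross_validate()
    results = model.fit()
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy()
    bg = Xv[rng.choice(len(Xv), 50, replace=False)]
    rows = Xv[rng.choice(len(Xv), explain_rows, replace=False)]
    att = attribute(results, rows, bg, n_permutations=n_perm, seed=seed,
                    feature_names=list(X.columns))
    top5 = set(att.global_importance().head(5).index)
    hits = len(top5 & {e.feature for e in STRONG_PLANTS})
    return rep.accuracy, hits


def planted_effect_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Power study: stacked CV accuracy and attribution top-5 hit rate on
    cohorts carrying the five strong plants."""
    accs, hits = [], []
    for i in range(n_seeds):
        acc, hit = _power_one_seed(seed + i)
        accs.append(acc)
        hits.append(hit)
    return {
        "n_seeds": n_seeds,
        "mean_cv_accuracy": float(np.mean(accs)),
        "sd_cv_accuracy": float(np.std(accs, ddof=1)),
        "mean_top5_hits": float(np.mean(hits)),
        "min_top5_hits": int(np.min(hits)),
    }


def null_cohort_experiment(n_seeds: int = 20, seed: int = 0) -> dict:
    """No-signal control: CV accuracy on cohorts without planted effects.

    With SMOTE-balanced training the stack has no majority-class prior, so
    a signal-free cohort should score at or below the majority rate (52/88),
    never above it; exceeding it would indicate leakage.
    """
    accs = []
    for i in range(n_seeds):
        cohort = simulate_cohort(CohortSpec(planted_effects=(), seed=seed + i))
        X, y = assemble_predictors(cohort)
        rep = StackedHbA1cModel(X, y, config=StackConfig(seed=seed + i)).cross_validate()
        accs.append(rep.accuracy)
    accs = np.asarray(accs)
    return {
        "n_seeds": n_seeds,
        "mean_cv_accuracy": float(accs.mean()),
        "se_cv_accuracy": float(accs.std(ddof=1) / np.sqrt(n_seeds)),
        "majority_rate": 52 / 88,
    }
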