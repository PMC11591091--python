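"""Stacked three-class HbA1c-change classifier with SMOTE and stratified CV.

The architecture follows the small-n / wide-p tabular recipe: three base
learners — gradient-boosted trees (XGBoost), an RBF support-vector
classifier with probability calibration, and extremely randomised trees,
each behind fold-internal univariate ANOVA-F screening — feed their class
probabilities to a k-nearest-neighbour meta learner.
Meta-learner training uses *out-of-fold* base probabilities from an
internal stratified K-fold so the meta inputs are honest; the bases are
then refit on the full training data.

Class imbalance is handled with SMOTE (synthetic minority points
interpolated toward one of the k nearest same-class neighbours) applied
strictly inside each training fold; validation rows never enter the
oversampler.  The oversample-then-split shortcut that leaks interpolated
copies of validation points into training is available only behind an
explicit flag (``protocol="oversample_then_split"``) for comparison
studies.

Usage follows the model/results convention::

    model = StackedHbA1cModel(X, y, config=StackConfig(seed=0))
    report = model.cross_validate()        # EvalReport, per-fold mean +/- sd
    results = model.fit()                  # StackedResults for new data
    proba = results.predict_proba(X_new)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import classification_metrics, confusion_matrix, macro_roc

# pairwise-coupling Platt calibration via SVC(probability=True) is the
# configuration this stack standardises on; quiet sklearn's migration notice
warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)

__all__ = [
    "FoldPlan",
    "StackConfig",
    "StackedHbA1cModel",
    "StackedResults",
    "EvalReport",
    "FoldError",
    "smote_oversample",
    "stratified_folds",
]


class FoldError(ValueError):
    """A fold whose training data cannot support the protocol."""


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(
    X, y, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class up to the majority count.

    Each synthetic row is ``x + lam * (x_nn - x)`` with ``lam ~ U[0, 1]``
    and ``x_nn`` one of the ``k_neighbors`` nearest same-class neighbours
    of ``x``.  Original rows are preserved verbatim and come first, in
    input order.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for c, count in zip(classes, counts):
        deficit = target - count
        if deficit == 0:
            continue
        if count < k_neighbors + 1:
            raise FoldError(
                f"class {c!r} has {count} members, fewer than k_neighbors+1="
                f"{k_neighbors + 1}; use a smaller k"
            )
        members = X[y == c]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(members)
        # drop the self-neighbour in column 0
        neighbours = nn.kneighbors(members, return_distance=False)[:, 1:]
        base_idx = rng.integers(0, count, size=deficit)
        nn_pick = neighbours[base_idx, rng.integers(0, k_neighbors, size=deficit)]
        lam = rng.uniform(0.0, 1.0, size=(deficit, 1))
        synth = members[base_idx] + lam * (members[nn_pick] - members[base_idx])
        new_X.append(synth)
        new_y.append(np.full(deficit, c, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """K test-index arrays partitioning the samples, class-stratified."""

    folds: tuple[np.ndarray, ...]
    y: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = len(self.y)
        flat = np.concatenate(self.folds)
        if len(flat) != n or len(np.unique(flat)) != n:
            raise FoldError("folds do not partition the sample indices")
        classes, counts = np.unique(self.y, return_counts=True)
        K = len(self.folds)
        for fi, fold in enumerate(self.folds):
            fold_counts = np.array([(self.y[fold] == c).sum() for c in classes])
            ideal = counts * len(fold) / n
            if np.any(np.abs(fold_counts - ideal) > 1.0 + 1e-9):
                raise FoldError(
                    f"fold {fi} class counts {fold_counts.tolist()} deviate more "
                    f"than 1 from proportional allocation {ideal.tolist()}"
                )

    @property
    def K(self) -> int:
        return len(self.folds)

    def split(self):
        n = len(self.y)
        for test_idx in self.folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            yield np.nonzero(train_mask)[0], test_idx

    def class_proportions(self) -> pd.DataFrame:
        classes = np.unique(self.y)
        rows = [
            [(self.y[f] == c).sum() for c in classes] for f in self.folds
        ]
        return pd.DataFrame(rows, columns=[f"class_{c}" for c in classes])


def stratified_folds(y, K: int, seed: int) -> FoldPlan:
    """Class-stratified K-fold assignment, deterministic per seed.

    Within each class, shuffled members are dealt round-robin to folds
    starting at a seed-dependent offset, which keeps every fold's class
    count within one of proportional allocation.
    """
    y = np.asarray(y)
    if K < 2 or K > len(y):
        raise ValueError(f"K={K} incompatible with n={len(y)}")
    rng = np.random.default_rng(seed)
    assignments = [[] for _ in range(K)]
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        rng.shuffle(idx)
        offset = int(rng.integers(K))
        for j, i in enumerate(idx):
            assignments[(j + offset) % K].append(int(i))
    folds = tuple(np.sort(np.array(f, dtype=int)) for f in assignments)
    return FoldPlan(folds=folds, y=y.copy(), seed=seed)


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackConfig:
    """Hyperparameters of the stack; defaults sized for n ~ 100, p ~ 100."""

    seed: int = 0
    outer_k: int = 5
    internal_k: int = 5
    smote_k: int = 5
    use_smote: bool = True
    knn_neighbors: int = 9
    knn_weights: str = "distance"
    #: repeated internal folds whose out-of-fold probabilities are averaged;
    #: damps fold noise in the meta features at n < 100
    oof_repeats: int = 2
    base_models: tuple[str, ...] = ("xgb", "svc", "et")
    xgb_params: dict = field(
        default_factory=lambda: dict(
            n_estimators=100, max_depth=3, learning_rate=0.15,
            subsample=0.9, colsample_bytree=0.9,
        )
    )
    svc_params: dict = field(default_factory=lambda: dict(C=1.0, gamma="scale"))
    et_params: dict = field(
        default_factory=lambda: dict(n_estimators=150, max_features=0.5)
    )
    #: univariate ANOVA-F screening (fitted inside each training fold) ahead
    #: of each base learner; 0 disables.  RBF distances and tree splits both
    #: degrade when most of a wide design is noise, so screening sized to the
    #: expected count of active risk factors is the default for n << p
    #: cohorts; the tree boosters tolerate (and use) a wider screen.
    svc_select_k: int = 6
    et_select_k: int = 10
    xgb_select_k: int = 40


class _SafeSelectKBest(SelectKBest):
    """SelectKBest that never asks for more features than exist."""

    def fit(self, X, y=None, **kw):
        self.k = min(self.k, np.asarray(X).shape[1])
        return super().fit(X, y, **kw)


def _make_base(name: str, config: StackConfig, seed: int):
    if name == "xgb":
        xgb = XGBClassifier(
            **config.xgb_params,
            objective="multi:softprob",
            eval_metric="mlogloss",
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
        if config.xgb_select_k:
            return make_pipeline(_SafeSelectKBest(f_classif, k=config.xgb_select_k), xgb)
        return xgb
    if name == "svc":
        steps = [StandardScaler()]
        if config.svc_select_k:
            steps.append(_SafeSelectKBest(f_classif, k=config.svc_select_k))
        steps.append(SVC(**config.svc_params, probability=True, random_state=seed))
        return make_pipeline(*steps)
    if name == "et":
        et = ExtraTreesClassifier(**config.et_params, random_state=seed, n_jobs=1)
        if config.et_select_k:
            return make_pipeline(_SafeSelectKBest(f_classif, k=config.et_select_k), et)
        return et
    raise ValueError(f"unknown base model {name!r}")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class StackedHbA1cModel:
    """Stacked classifier bound to a dataset (model/results convention)."""

    def __init__(self, X, y, config: StackConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        self.feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"x{i}" for i in range(self.X.shape[1])]
        )
        self.y = np.asarray(y)
        self.config = config or StackConfig()
        self.classes_ = np.unique(self.y)
        if len(self.classes_) < 2:
            raise FoldError("training data contains a single class")

    @classmethod
    def from_cohort(cls, cohort, epsilon: float = 0.0, config: StackConfig | None = None):
        from .labels import assemble_predictors

        X, y = assemble_predictors(cohort, epsilon=epsilon)
        return cls(X, y, config=config)

    # -- fitting ------------------------------------------------------------

    def fit(self, X=None, y=None, seed: int | None = None) -> "StackedResults":
        """Fit the full stack on (X, y), defaulting to the bound dataset."""
        X = self.X if X is None else np.asarray(X, dtype=float)
        y = self.y if y is None else np.asarray(y)
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        classes = np.unique(y)
        if len(classes) < 2:
            raise FoldError("cannot fit on single-class training data")
        min_count = np.unique(y, return_counts=True)[1].min()
        if not cfg.base_models:
            # meta learner alone: KNN on the standardised features themselves
            scaler = StandardScaler().fit(X)
            Xr, yr = self._resample(X, y, seed + 997)
            meta = KNeighborsClassifier(
                n_neighbors=min(cfg.knn_neighbors, len(yr)), weights=cfg.knn_weights
            )
            meta.fit(scaler.transform(Xr), yr)
            return StackedResults(
                model=self, bases=(), meta=meta, classes=classes,
                seed=seed, n_train=len(y), internal_k=0, scaler=scaler,
            )
        internal_k = min(cfg.internal_k, int(min_count))
        if internal_k < 2:
            raise FoldError(
                f"smallest training class has {min_count} members; "
                "cannot form internal stacking folds"
            )
        n = len(y)
        oof = np.zeros((n, len(cfg.base_models) * len(classes)))
        for rep in range(cfg.oof_repeats):
            plan = stratified_folds(y, internal_k, seed=seed + 101 + 37 * rep)
            fold_oof = np.full_like(oof, np.nan)
            for fi, (tr, te) in enumerate(plan.split()):
                Xtr, ytr = self._resample(X[tr], y[tr], seed + 7 * fi + 91 * rep)
                if len(np.unique(ytr)) < len(classes):
                    raise FoldError(f"internal fold {fi} lost a class during training")
                for bi, name in enumerate(cfg.base_models):
                    est = _make_base(name, cfg, seed + 13 * bi)
                    est.fit(Xtr, ytr)
                    proba = _aligned_proba(est, X[te], classes)
                    fold_oof[te, bi * len(classes):(bi + 1) * len(classes)] = proba
            assert not np.isnan(fold_oof).any()
            oof += fold_oof
        oof /= cfg.oof_repeats
        meta = KNeighborsClassifier(
            n_neighbors=min(cfg.knn_neighbors, n), weights=cfg.knn_weights
        )
        meta.fit(oof, y)
        # refit bases on the full training data for deployment
        Xfull, yfull = self._resample(X, y, seed + 997)
        bases = []
        for bi, name in enumerate(cfg.base_models):
            est = _make_base(name, cfg, seed + 13 * bi)
            est.fit(Xfull, yfull)
            bases.append((name, est))
        return StackedResults(
            model=self, bases=tuple(bases), meta=meta,
            classes=classes, seed=seed, n_train=n, internal_k=internal_k,
        )

    def _resample(self, X, y, seed):
        if not self.config.use_smote:
            return X, y
        counts = np.unique(y, return_counts=True)[1]
        k = min(self.config.smote_k, int(counts.min()) - 1)
        if k < 1:
            raise FoldError("a training class is too small even for k=1 SMOTE")
        return smote_oversample(X, y, k_neighbors=k, seed=seed)

    # -- evaluation ---------------------------------------------------------

    def cross_validate(
        self,
        plan: FoldPlan | None = None,
        protocol: str = "smote_within_folds",
    ) -> "EvalReport":
        """Stratified K-fold evaluation of the stack.

        ``protocol="smote_within_folds"`` (default) oversamples training
        folds only.  ``protocol="oversample_then_split"`` reproduces the
        leaky shortcut of balancing the whole dataset before splitting; its
        scores are optimistic and it exists for comparison only.
        """
        cfg = self.config
        if protocol == "oversample_then_split":
            Xall, yall = self._resample(self.X, self.y, cfg.seed + 31)
            inner = replace(cfg, use_smote=False)
            model = StackedHbA1cModel(Xall, yall, config=inner)
            plan = stratified_folds(yall, cfg.outer_k, seed=cfg.seed)
            return model.cross_validate(plan=plan, protocol="smote_within_folds")
        if protocol != "smote_within_folds":
            raise ValueError(f"unknown protocol {protocol!r}")
        if plan is None:
            plan = stratified_folds(self.y, cfg.outer_k, seed=cfg.seed)
        classes = self.classes_
        n = len(self.y)
        pooled_pred = np.empty(n, dtype=self.y.dtype)
        pooled_proba = np.full((n, len(classes)), np.nan)
        fold_rows = []
        smote_input_indices: list[np.ndarray] = []
        for fi, (tr, te) in enumerate(plan.split()):
            smote_input_indices.append(tr.copy())
            results = self.fit(self.X[tr], self.y[tr], seed=cfg.seed + 1000 * fi)
            proba = results.predict_proba(self.X[te])
            pred = classes[np.argmax(proba, axis=1)]
            pooled_pred[te] = pred
            pooled_proba[te] = proba
            rep = classification_metrics(self.y[te], pred, classes=classes)
            fold_rows.append(
                dict(
                    fold=fi,
                    accuracy=rep.accuracy,
                    macro_precision=rep.macro_precision,
                    macro_recall=rep.macro_recall,
                    macro_f1=rep.macro_f1,
                )
            )
        # leakage audit: no validation index ever entered the oversampler
        for fi, (tr_idx, fold) in enumerate(zip(smote_input_indices, plan.folds)):
            assert len(np.intersect1d(tr_idx, fold)) == 0, (
                f"fold {fi}: validation indices leaked into oversampling inputs"
            )
        pooled = classification_metrics(self.y, pooled_pred, classes=classes)
        fpr, tpr, auc = macro_roc(self.y, pooled_proba, classes)
        fold_metrics = pd.DataFrame(fold_rows).set_index("fold")
        return EvalReport(
            classes=classes,
            confusion=pooled.confusion,
            accuracy=pooled.accuracy,
            macro_precision=pooled.macro_precision,
            macro_recall=pooled.macro_recall,
            macro_f1=pooled.macro_f1,
            fold_metrics=fold_metrics,
            roc_fpr=fpr,
            roc_tpr=tpr,
            auc=auc,
            oversampling_inputs=tuple(smote_input_indices),
            plan=plan,
        )


def _aligned_proba(est, X, classes) -> np.ndarray:
    """predict_proba with columns aligned to ``classes``."""
    proba = est.predict_proba(X)
    est_classes = np.asarray(est.classes_ if hasattr(est, "classes_")
                             else est[-1].classes_)
    out = np.zeros((len(X), len(classes)))
    for j, c in enumerate(classes):
        where = np.nonzero(est_classes == c)[0]
        if len(where):
            out[:, j] = proba[:, where[0]]
    return out


@dataclass
class StackedResults:
    """A fitted stack: three base learners plus the KNN meta learner."""

    model: StackedHbA1cModel
    bases: tuple
    meta: KNeighborsClassifier
    classes: np.ndarray
    seed: int
    n_train: int
    internal_k: int
    scaler: StandardScaler | None = None

    def meta_features(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"feature count {X.shape[1]} does not match the "
                f"{self.model.X.shape[1]} the stack was fitted on"
            )
        if not self.bases:
            return self.scaler.transform(X)
        blocks = [_aligned_proba(est, X, self.classes) for _, est in self.bases]
        return np.hstack(blocks)

    def predict_proba(self, X) -> np.ndarray:
        return self.meta.predict_proba(self.meta_features(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes[np.argmax(proba, axis=1)]

    def summary(self) -> str:
        lines = [
            "Stacked HbA1c-change classifier",
            "=" * 46,
            f"base learners : {', '.join(name for name, _ in self.bases)}",
            f"meta learner  : KNN(k={self.meta.n_neighbors}) on "
            f"{len(self.bases)}x{len(self.classes)} out-of-fold probabilities",
            f"classes       : {self.classes.tolist()}"
            "  (0 no change / 1 increased / 2 decreased)",
            f"n_train       : {self.n_train}   internal folds: {self.internal_k}",
            f"SMOTE         : {'within training folds' if self.model.config.use_smote else 'off'}",
            f"seed          : {self.seed}",
        ]
        return "\n".join(lines)


@dataclass
class EvalReport:
    """Cross-validated evaluation with per-fold dispersion."""

    classes: np.ndarray
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    fold_metrics: pd.DataFrame
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    oversampling_inputs: tuple = ()
    plan: FoldPlan | None = None

    def __post_init__(self) -> None:
        assert int(self.confusion.sum()) == len(self.plan.y) if self.plan else True

    def fold_mean_sd(self) -> pd.DataFrame:
        mean = self.fold_metrics.mean()
        sd = self.fold_metrics.std(ddof=1)
        return pd.DataFrame({"mean": mean, "sd": sd})

    def summary(self) -> str:
        ms = self.fold_mean_sd()
        lines = [
            "Cross-validated HbA1c-change classification",
            "=" * 52,
            f"folds: {len(self.fold_metrics)}    samples: {int(self.confusion.sum())}"
            f"    macro AUC: {self.auc:.3f}",
            "",
            "metric            pooled    fold mean +/- sd (%)",
        ]
        for key, label in [
            ("accuracy", "accuracy"),
            ("macro_precision", "macro-precision"),
            ("macro_recall", "macro-recall"),
            ("macro_f1", "macro-F1"),
        ]:
            pooled = getattr(self, key) * 100
            lines.append(
                f"{label:<16}  {pooled:6.2f}    "
                f"{ms.loc[key, 'mean'] * 100:6.2f} +/- {ms.loc[key, 'sd'] * 100:5.2f}"
            )
        lines += ["", "confusion matrix (rows = true class):"]
        for c, row in zip(self.classes, self.confusion):
            lines.append(f"  class {c}: {row.tolist()}")
        return "\n".join(lines)
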