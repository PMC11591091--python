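"""Food-weight regression from photo features.

Predicts portion weight (grams) from the identified food type, the
shooting tilt angle alpha, the shooting distance l_OC and the projected
area S, as an L1-penalised (LASSO) linear model:

    minimise  ||w - Z beta - b||^2 / (2 n)  +  lambda ||beta||_1

with the numeric features standardised before penalisation, the food type
entering as an indicator block (optionally interacted with S, which lets
the model express a per-type area-to-mass density), and the intercept
unpenalised.  ``lambda`` defaults to internal 5-fold cross-validation.

Follows the model/results convention::

    model = WeightModel(dataset, lam=0.0)
    res = model.fit()
    res.predict(type_id=3, alpha=0.9, l_OC=0.4, S=0.02)
    res.evaluate_mae(heldout)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.linear_model import Lasso, LassoCV, LinearRegression

__all__ = [
    "WeightModel",
    "WeightResults",
    "UnknownTypeError",
    "analytic_noise_floor",
]

FEATURE_COLUMNS = ("type_id", "alpha", "l_OC", "S")
NUMERIC_FEATURES = ("alpha", "l_OC", "S")


class UnknownTypeError(KeyError):
    """Prediction requested for a food type not seen at fit time."""


def analytic_noise_floor(mean_true_weight: float, noise_sd: float) -> float:
    """Expected MAE of the best possible predictor under multiplicative
    log-normal weight noise: the irreducible error floor.

    For w_obs = w exp(eps), eps ~ N(0, s^2), predicting w gives
    E|w_obs - w| = w * e^{s^2/2} (2 Phi(s) - 1).
    """
    s = noise_sd
    return float(mean_true_weight * np.exp(s**2 / 2.0) * (2.0 * norm.cdf(s) - 1.0))


class WeightModel:
    """LASSO weight regression bound to a photo-feature dataset."""

    def __init__(
        self,
        data: pd.DataFrame,
        lam: float | None = None,
        interaction: bool = True,
    ):
        missing = [c for c in (*FEATURE_COLUMNS, "weight") if c not in data.columns]
        if missing:
            raise ValueError(f"dataset lacks columns {missing}")
        if lam is not None and lam < 0:
            raise ValueError("lambda must be non-negative")
        counts = data["type_id"].value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise ValueError(
                f"need >= 2 samples per food type; too few for {thin.index.tolist()}"
            )
        self.data = data.reset_index(drop=True)
        self.lam = lam
        self.interaction = interaction
        self.types_ = np.sort(data["type_id"].unique())

    # -- design matrix ------------------------------------------------------

    def _design(self, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols: list[np.ndarray] = []
        names: list[str] = []
        for f in NUMERIC_FEATURES:
            cols.append(frame[f].to_numpy(dtype=float))
            names.append(f)
        for t in self.types_:
            cols.append((frame["type_id"].to_numpy() == t).astype(float))
            names.append(f"type[{t}]")
        if self.interaction:
            S = frame["S"].to_numpy(dtype=float)
            for t in self.types_:
                cols.append(S * (frame["type_id"].to_numpy() == t))
                names.append(f"S:type[{t}]")
        return np.column_stack(cols), names

    def fit(self, seed: int = 0) -> "WeightResults":
        Z, names = self._design(self.data)
        w = self.data["weight"].to_numpy(dtype=float)
        mean = Z.mean(axis=0)
        scale = Z.std(axis=0)
        keep = scale > 1e-12
        dropped = [n for n, k in zip(names, keep) if not k]
        if dropped:
            warnings.warn(
                f"dropping constant design columns after standardisation: {dropped}",
                stacklevel=2,
            )
        Zs = (Z[:, keep] - mean[keep]) / scale[keep]
        lam = self.lam
        if lam is None:
            cv = LassoCV(cv=5, random_state=seed, max_iter=50_000)
            cv.fit(Zs, w)
            lam = float(cv.alpha_)
        if lam == 0.0:
            est = LinearRegression()
        else:
            est = Lasso(alpha=lam, max_iter=200_000, random_state=seed, tol=1e-8)
        est.fit(Zs, w)
        coef = np.zeros(len(names))
        coef[keep] = est.coef_
        return WeightResults(
            model=self,
            coef_std=coef,
            intercept_std=float(est.intercept_),
            mean=mean,
            scale=np.where(keep, scale, 1.0),
            kept=keep,
            names=names,
            lam=float(lam),
            seed=seed,
        )


@dataclass
class WeightResults:
    """Fitted LASSO weight model."""

    model: WeightModel
    coef_std: np.ndarray
    intercept_std: float
    mean: np.ndarray
    scale: np.ndarray
    kept: np.ndarray
    names: list[str]
    lam: float
    seed: int

    @property
    def coef_raw(self) -> pd.Series:
        """Coefficients on the original feature scale."""
        return pd.Series(self.coef_std / self.scale, index=self.names)

    @property
    def intercept_raw(self) -> float:
        return float(self.intercept_std - np.sum(self.coef_std * self.mean / self.scale))

    def nonzero(self, tol: float = 1e-10) -> pd.Series:
        raw = self.coef_raw
        return raw[np.abs(self.coef_std) > tol]

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        unseen = set(frame["type_id"].unique()) - set(self.model.types_)
        if unseen:
            raise UnknownTypeError(
                f"food types {sorted(unseen)} were not seen at fit time"
            )
        Z, _ = self.model._design(frame)
        Zs = (Z - self.mean) / self.scale
        pred = Zs @ self.coef_std + self.intercept_std
        return np.maximum(pred, 0.0)

    def predict(self, type_id, alpha, l_OC, S) -> float:
        frame = pd.DataFrame(
            {"type_id": [type_id], "alpha": [alpha], "l_OC": [l_OC], "S": [S]}
        )
        return float(self.predict_frame(frame)[0])

    def evaluate_mae(self, data: pd.DataFrame) -> tuple[float, pd.Series]:
        """Mean absolute error in grams, overall and per food type."""
        pred = self.predict_frame(data)
        err = np.abs(pred - data["weight"].to_numpy(dtype=float))
        per_type = (
            pd.Series(err, index=data["type_id"].to_numpy())
            .groupby(level=0).mean().rename("mae_g")
        )
        return float(err.mean()), per_type

    def summary(self) -> str:
        nz = self.nonzero()
        lines = [
            "LASSO food-weight regression",
            "=" * 40,
            f"lambda        : {self.lam:.6g}"
            + ("  (CV-selected)" if self.model.lam is None else ""),
            f"intercept     : {self.intercept_raw:.4f} g",
            f"food types    : {len(self.model.types_)}",
            f"nonzero terms : {len(nz)} / {len(self.names)}",
            "",
            "coefficient (raw scale):",
        ]
        for name, v in nz.items():
            lines.append(f"  {name:<14} {v:12.4f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "lam": self.lam,
            "seed": self.seed,
            "interaction": self.model.interaction,
            "types": [int(t) for t in self.model.types_],
            "names": self.names,
            "coef_std": self.coef_std.tolist(),
            "intercept_std": self.intercept_std,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "kept": self.kept.astype(int).tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "WeightResults":
        with open(path, "r", encoding="utf-8") as fh:
            p = json.load(fh)
        shell = WeightModel.__new__(WeightModel)
        shell.lam = p["lam"]
        shell.interaction = p["interaction"]
        shell.types_ = np.array(p["types"])
        shell.data = None
        return cls(
            model=shell,
            coef_std=np.array(p["coef_std"]),
            intercept_std=p["intercept_std"],
            mean=np.array(p["mean"]),
            scale=np.array(p["scale"]),
            kept=np.array(p["kept"], dtype=bool),
            names=list(p["names"]),
            lam=p["lam"],
            seed=p["seed"],
        )
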