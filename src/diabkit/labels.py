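"""HbA1c-change target derivation and predictor-matrix assembly.

The three-class target compares the second examination's HbA1c with the
first: class 0 = no change (|delta| <= epsilon), class 1 = increased
(delta > epsilon), class 2 = decreased (delta < -epsilon).  No clinical
no-change band is imposed by default (epsilon = 0, so class 0 requires an
exact tie); a band can be supplied where measurement noise warrants one.

The predictor matrix keeps the 6 personal, 10 lifestyle, 79 nutrient and
16 *first-exam* medical features (111 columns) and drops the entire
second-exam block — the quantity being predicted is derived from it, so
leaving any of it in would leak the answer.  Selection is driven by the
schema's category tags, never by column position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diabmini import CohortTable, SchemaError

__all__ = ["HbA1cLabel", "label_change", "assemble_predictors", "PREDICTOR_CATEGORIES"]

#: category tags admitted into the predictor matrix, in output order
PREDICTOR_CATEGORIES = ("personal", "lifestyle", "nutrient", "medical_exam1")

NO_CHANGE, INCREASED, DECREASED = 0, 1, 2


@dataclass(frozen=True)
class HbA1cLabel:
    cls: int
    delta: float


def label_change(hba1c_exam1: float, hba1c_exam2: float, epsilon: float = 0.0) -> HbA1cLabel:
    """Classify the between-exam HbA1c change (percentage points)."""
    if hba1c_exam1 <= 0 or hba1c_exam2 <= 0:
        raise ValueError(
            f"HbA1c measurements must be positive, got "
            f"({hba1c_exam1}, {hba1c_exam2})"
        )
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    delta = hba1c_exam2 - hba1c_exam1
    if abs(delta) <= epsilon:
        cls = NO_CHANGE
    elif delta > epsilon:
        cls = INCREASED
    else:
        cls = DECREASED
    return HbA1cLabel(cls=cls, delta=delta)


def _encode_categorical(series: pd.Series, codebook: tuple[str, ...], name: str) -> pd.Series:
    """Integer-encode codebook answers; already-numeric columns pass through
    after range validation."""
    if pd.api.types.is_numeric_dtype(series):
        values = series.astype(float)
        bad = values.dropna()[~values.dropna().isin(range(len(codebook)))]
        if len(bad):
            raise ValueError(
                f"feature {name!r}: numeric codes {sorted(set(bad))} outside "
                f"the codebook of size {len(codebook)}"
            )
        return values
    mapping = {level: float(i) for i, level in enumerate(codebook)}
    unknown = set(series.dropna()) - set(mapping)
    if unknown:
        raise ValueError(
            f"feature {name!r}: answers {sorted(unknown)} not in codebook {codebook}"
        )
    return series.map(mapping)


def assemble_predictors(
    cohort: CohortTable, epsilon: float = 0.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build (X, y) from a cohort table.

    X has the 111 predictor columns in category order personal, lifestyle,
    nutrient, medical-exam1 (schema order within each category), with
    categorical answers integer-encoded per their codebooks.  y is the
    three-class HbA1c-change label.
    """
    data = cohort.data
    for col in ("HbA1c_exam1", "HbA1c_exam2"):
        missing = data.index[data[col].isna()].tolist()
        if missing:
            raise SchemaError(
                f"column {col} missing for sample ids {missing}; cannot label"
            )
    y = np.array(
        [
            label_change(a, b, epsilon).cls
            for a, b in zip(data["HbA1c_exam1"], data["HbA1c_exam2"])
        ],
        dtype=int,
    )
    columns: dict[str, pd.Series] = {}
    for category in PREDICTOR_CATEGORIES:
        for name in cohort.features(category):
            f = cohort.by_name[name]
            series = data[name]
            if f.codebook is not None:
                series = _encode_categorical(series, f.codebook, name)
            else:
                series = pd.to_numeric(series, errors="raise")
            columns[name] = series.astype(float)
    X = pd.DataFrame(columns, index=data.index)
    leaked = [c for c in X.columns if cohort.by_name[c].category == "medical_exam2"]
    assert not leaked, f"second-exam features leaked into X: {leaked}"
    return X, y
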