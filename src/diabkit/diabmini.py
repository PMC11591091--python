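"""DiabMini-style cohort schema: 127 features over four categories.

The cohort table layout mirrors a small type-2-diabetes study in which 88
participants were examined twice (before and after a three-week dietary
tracking period) and characterised by

* 6 personal features,
* 16 medical indicators recorded at each of the two examinations
  (32 medical columns total, suffixed ``_exam1`` / ``_exam2``),
* 10 lifestyle-questionnaire answers, and
* 79 nutrient-intake features (14-day mean daily intake).

The module owns the canonical feature list, category tags, units and
categorical codebooks, plus the (CSV + YAML sidecar) on-disk format and
the :class:`CohortTable` container every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "FeatureDef",
    "CohortTable",
    "SchemaError",
    "PERSONAL_FEATURES",
    "MEDICAL_INDICATORS",
    "LIFESTYLE_FEATURES",
    "NUTRIENT_FEATURES",
    "CATEGORY_SIZES",
    "build_schema",
    "load_schema",
    "save_schema",
]


class SchemaError(ValueError):
    """Cohort table/schema that violates the 127-feature layout."""


# (name, unit, codebook-or-None)
PERSONAL_FEATURES = (
    ("gender", "code", ("Female", "Male")),
    ("age", "years", None),
    ("height", "cm", None),
    ("weight", "kg", None),
    ("BMI", "kg/m^2", None),
    ("BFP", "%", None),
)

MEDICAL_INDICATORS = (
    ("HbA1c", "%"),
    ("FPG", "mmol/L"),
    ("HDL", "mmol/L"),
    ("LDL", "mmol/L"),
    ("TG", "mmol/L"),
    ("TC", "mmol/L"),
    ("WHR", "ratio"),
    ("SBP", "mmHg"),
    ("DBP", "mmHg"),
    ("RBC", "10^12/L"),
    ("WBC", "10^9/L"),
    ("HGB", "g/L"),
    ("PLT", "10^9/L"),
    ("ALT", "U/L"),
    ("AST", "U/L"),
    ("CRE", "umol/L"),
)

_FREQ4 = ("Never or rarely", "1-2 times", "3-5 times", "Daily")
_OFTEN3 = ("Never or rarely", "Sometimes", "Often")

LIFESTYLE_FEATURES = (
    ("weekly_exercise", "code", _FREQ4),
    ("weekly_drinking", "code", _FREQ4),
    ("smoking", "code", ("Never", "Former", "Current")),
    ("sleep_duration", "h", None),
    ("sleep_quality", "code", ("Poor", "Fair", "Good")),
    ("diet_regularity", "code", ("Irregular", "Somewhat regular", "Regular")),
    ("food_selection", "code",
     ("Personal preference", "Nutritional value", "Health condition")),
    ("stress_level", "code", ("Low", "Moderate", "High")),
    ("snacking", "code", _OFTEN3),
    ("late_nights", "code", _OFTEN3),
)

_MACROS = (
    ("energy", "kcal"), ("protein", "g"), ("fat", "g"), ("carbohydrate", "g"),
    ("dietary_fiber", "g"), ("water", "g"), ("cholesterol", "mg"),
    ("sugar", "g"), ("starch", "g"), ("trans_fat", "g"),
)
_MINERALS = (
    ("Na", "mg"), ("K", "mg"), ("Ca", "mg"), ("Mg", "mg"), ("P", "mg"),
    ("Fe", "mg"), ("Zn", "mg"), ("Se", "ug"), ("Cu", "mg"), ("Mn", "mg"),
    ("I", "ug"), ("Cr", "ug"),
)
_VITAMINS = (
    ("vitamin_A", "ug"), ("carotene", "ug"), ("retinol", "ug"),
    ("vitamin_B1", "mg"), ("vitamin_B2", "mg"), ("vitamin_B6", "mg"),
    ("vitamin_B12", "ug"), ("vitamin_C", "mg"), ("vitamin_D", "ug"),
    ("vitamin_E", "mg"), ("vitamin_K", "ug"), ("niacin", "mg"),
    ("folate", "ug"), ("pantothenic_acid", "mg"), ("biotin", "ug"),
    ("choline", "mg"),
)
_AMINO_ACIDS = tuple(
    (name, "mg")
    for name in (
        "tryptophan", "lysine", "methionine", "phenylalanine", "threonine",
        "isoleucine", "leucine", "valine", "histidine", "arginine", "alanine",
        "aspartic_acid", "glutamic_acid", "glycine", "proline", "serine",
        "tyrosine", "cystine",
    )
)
_FATTY_ACIDS = tuple(
    (name, "g")
    for name in (
        "SFA", "MUFA", "PUFA", "C12:0", "C14:0", "C15:0", "C16:0", "C16:1",
        "C17:0", "C18:0", "C18:1", "C18:2 (n-6)", "C18:3 (n-3)", "C20:0",
        "C20:1 (n-11)", "C20:2 (n-6)", "C20:3 (n-6)", "C20:4 (n-6)",
        "C20:5 (n-3)", "C22:0", "C22:5 (n-3)", "C22:6 (n-3)", "C24:0",
    )
)
NUTRIENT_FEATURES = _MACROS + _MINERALS + _VITAMINS + _AMINO_ACIDS + _FATTY_ACIDS

CATEGORY_SIZES = {
    "personal": 6,
    "medical_exam1": 16,
    "medical_exam2": 16,
    "lifestyle": 10,
    "nutrient": 79,
}
assert len(PERSONAL_FEATURES) == CATEGORY_SIZES["personal"]
assert len(MEDICAL_INDICATORS) == CATEGORY_SIZES["medical_exam1"]
assert len(LIFESTYLE_FEATURES) == CATEGORY_SIZES["lifestyle"]
assert len(NUTRIENT_FEATURES) == CATEGORY_SIZES["nutrient"]


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str
    unit: str
    codebook: tuple[str, ...] | None = None


def build_schema() -> list[FeatureDef]:
    """The canonical ordered 127-feature schema."""
    schema: list[FeatureDef] = []
    for name, unit, codebook in PERSONAL_FEATURES:
        schema.append(FeatureDef(name, "personal", unit, codebook))
    for exam in ("exam1", "exam2"):
        for name, unit in MEDICAL_INDICATORS:
            schema.append(FeatureDef(f"{name}_{exam}", f"medical_{exam}", unit))
    for name, unit, codebook in LIFESTYLE_FEATURES:
        schema.append(FeatureDef(name, "lifestyle", unit, codebook))
    for name, unit in NUTRIENT_FEATURES:
        schema.append(FeatureDef(name, "nutrient", unit))
    assert len(schema) == 127
    return schema


def save_schema(schema: list[FeatureDef], path) -> None:
    payload = [
        {
            "name": f.name,
            "category": f.category,
            "unit": f.unit,
            **({"codebook": list(f.codebook)} if f.codebook else {}),
        }
        for f in schema
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def load_schema(path) -> list[FeatureDef]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, list):
        raise SchemaError(f"{path}: schema sidecar must be a list of features")
    schema = []
    for item in payload:
        try:
            schema.append(
                FeatureDef(
                    name=item["name"],
                    category=item["category"],
                    unit=item.get("unit", ""),
                    codebook=tuple(item["codebook"]) if item.get("codebook") else None,
                )
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed feature entry {item!r}") from exc
    return schema


class CohortTable:
    """Samples x features cohort with per-feature category tags.

    ``data`` holds one row per participant; categorical lifestyle/personal
    answers are stored as codebook strings (or already-encoded integers).
    Construction validates the category counts (6 + 32 + 10 + 79 = 127)
    and the presence of HbA1c in both exam blocks.
    """

    def __init__(self, data: pd.DataFrame, schema: list[FeatureDef] | None = None):
        self.schema = list(schema) if schema is not None else build_schema()
        self.by_name = {f.name: f for f in self.schema}
        missing = [f.name for f in self.schema if f.name not in data.columns]
        if missing:
            raise SchemaError(f"cohort missing schema features: {missing[:5]}...")
        counts: dict[str, int] = {}
        for f in self.schema:
            counts[f.category] = counts.get(f.category, 0) + 1
        if counts != CATEGORY_SIZES:
            raise SchemaError(
                f"category sizes {counts} do not match the schema {CATEGORY_SIZES}"
            )
        for col in ("HbA1c_exam1", "HbA1c_exam2"):
            if col not in data.columns:
                raise SchemaError(f"cohort lacks required column {col}")
        # canonical column order = schema order
        self.data = data[[f.name for f in self.schema]].copy()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return len(self.schema)

    def features(self, category: str) -> list[str]:
        return [f.name for f in self.schema if f.category == category]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.schema:
            counts[f.category] = counts.get(f.category, 0) + 1
        return counts

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / "cohort.csv"
        schema_path = directory / "schema.yaml"
        self.data.to_csv(csv_path, index=False)
        save_schema(self.schema, schema_path)
        return csv_path, schema_path

    @classmethod
    def load(cls, csv_path, schema_path) -> "CohortTable":
        schema = load_schema(schema_path)
        data = pd.read_csv(csv_path)
        return cls(data, schema)
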