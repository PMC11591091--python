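"""Composition-database loading, fuzzy lookup, and intake accounting."""

import datetime as dt

import numpy as np
import pytest

from diabkit import nutrition
from diabkit.nutrition import (
    ABSENT,
    ConflictError,
    DietRecord,
    FoodLookupError,
    ParseError,
    dish_nutrients,
    intake_series,
    load_database,
    match_food,
    mean_intake,
    normalize_name,
)


def brute_levenshtein(a: str, b: str) -> int:
    """Reference edit distance, simple DP."""
    m, n = len(a), len(b)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        D[i][0] = i
    for j in range(n + 1):
        D[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i][j] = min(
                D[i - 1][j] + 1,
                D[i][j - 1] + 1,
                D[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return D[m][n]


class TestLoading:
    def test_counts(self, db):
        assert db.counts == (6, 5, 5)

    def test_rice_energy_per_100g(self, db):
        rice = db.ingredient("Rice")
        assert rice.nutrients.get("energy") == 116

    def test_dash_is_absent_not_zero(self, db):
        pork = db.ingredient("Pork")
        assert pork.nutrients.get("dietary_fiber") is ABSENT
        assert "dietary_fiber" not in pork.nutrients.amounts

    def test_duplicate_name_conflict(self, db_files, tmp_path):
        bad = tmp_path / "dup.csv"
        bad.write_text(
            "name,energy,fat,carbohydrate,protein,water,dietary_fiber,"
            "vitamin_B1,Ca,Fe,Na\nRice,1,1,1,1,1,1,1,1,1,1\n"
            "rice ,2,2,2,2,2,2,2,2,2,2\n"
        )
        with pytest.raises(ConflictError, match="rice"):
            load_database(bad, db_files["packaged"], db_files["dishes"],
                          db_files["units"])

    def test_malformed_row_names_file_and_line(self, db_files, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("name,energy\nRice,notanumber\n")
        units = tmp_path / "u.yaml"
        units.write_text("energy: kcal\n")
        with pytest.raises(ParseError, match=r"bad\.csv:2"):
            load_database(bad, db_files["packaged"], db_files["dishes"], units)

    def test_packaged_restricted_to_core_five(self, db_files, tmp_path):
        bad = tmp_path / "pk.csv"
        bad.write_text("name,energy,fat\nThing,1,1\n")
        with pytest.raises(ParseError):
            load_database(db_files["ingredients"], bad, db_files["dishes"],
                          db_files["units"])

    def test_unknown_dish_ingredient_rejected_eagerly(self, db_files, tmp_path):
        bad = tmp_path / "d.csv"
        bad.write_text("name,ingredient_1,amount_1\nMystery,Unobtainium,100\n")
        with pytest.raises(FoodLookupError, match="Unobtainium"):
            load_database(db_files["ingredients"], db_files["packaged"], bad,
                          db_files["units"])

    def test_long_format_dishes_equivalent(self, db_files, tmp_path, db):
        long = tmp_path / "long.csv"
        long.write_text(
            "dish,ingredient,amount_g\n"
            "Rice Bowl,Rice,200\n"
            "Mushroom Pork,Pork,100\nMushroom Pork,Mushroom,50\n"
        )
        db2 = load_database(db_files["ingredients"], db_files["packaged"],
                            long, db_files["units"])
        d1 = db.lookup_exact("Mushroom Pork")
        d2 = db2.lookup_exact("Mushroom Pork")
        assert d1.composition == d2.composition


class TestMatchFood:
    def test_exact_match_scores_one(self, db):
        ranked = match_food("Potato", db)
        assert ranked[0][0].name == "Potato"
        assert ranked[0][1] == 1.0

    def test_case_and_whitespace_insensitive(self, db):
        ranked = match_food("  pOtAtO ", db)
        assert ranked[0][0].name == "Potato" and ranked[0][1] == 1.0

    def test_typo_ranks_target_first_below_one(self, db):
        ranked = match_food("Potatoo", db)
        assert ranked[0][0].name == "Potato"
        assert ranked[0][1] < 1.0

    def test_score_floor_filters_garbage(self, db):
        assert match_food("zzzz", db, min_score=0.5) == []

    def test_empty_query_rejected(self, db):
        with pytest.raises(ValueError):
            match_food("   ", db)

    def test_ranking_agrees_with_brute_force_scan(self, db):
        for query in ("Potatoo", "chiken", "ric", "mushrom soup"):
            q = normalize_name(query)
            expected = []
            for rec in db.all_records():
                name = normalize_name(rec.name)
                if name == q:
                    score = 1.0
                else:
                    score = 1.0 - brute_levenshtein(q, name) / max(len(q), len(name))
                expected.append((normalize_name(rec.name), score))
            expected.sort(key=lambda t: (-t[1], t[0]))
            got = [
                (normalize_name(r.name), s) for r, s in match_food(query, db)
            ]
            assert got == pytest.approx(expected)  # same order, same scores


class TestDishAggregation:
    def test_linear_arithmetic(self, db):
        # Rice Bowl = 200 g rice at 116 kcal/100 g
        whole, per100 = dish_nutrients(db.lookup_exact("Rice Bowl"), db)
        assert whole.amounts["energy"] == pytest.approx(232.0)
        assert per100.amounts["energy"] == pytest.approx(116.0)

    def test_two_ingredient_total(self, db):
        whole, _ = dish_nutrients(db.lookup_exact("Tomato Potato Stew"), db)
        assert whole.amounts["energy"] == pytest.approx(1.5 * 77 + 1.0 * 20)

    def test_absent_ingredient_nutrient_flags_partial(self, db):
        whole, per100 = dish_nutrients(db.lookup_exact("Mushroom Pork"), db)
        # Pork's fiber is absent; Mushroom contributes, so the value is partial
        assert "dietary_fiber" in whole.partially_known
        assert whole.amounts["dietary_fiber"] == pytest.approx(0.5 * 2.1)
        assert "energy" not in whole.partially_known

    def test_doubling_amounts_doubles_totals(self, db):
        dish = db.lookup_exact("Roast Chicken")
        doubled = nutrition.DishRecord(
            name="x2", composition=tuple((i, 2 * a) for i, a in dish.composition)
        )
        w1, _ = dish_nutrients(dish, db)
        w2, _ = dish_nutrients(doubled, db)
        for k, v in w1.amounts.items():
            assert w2.amounts[k] == pytest.approx(2 * v)


class TestIntake:
    def test_single_record_energy(self, db):
        day = dt.date(2024, 3, 1)
        series = intake_series([DietRecord(day, "Rice", 150.0)], db)
        assert series.loc[day, "energy"] == pytest.approx(174.0)

    def test_empty_records_empty_series(self, db):
        assert intake_series([], db).empty

    def test_same_day_additivity(self, db):
        day = dt.date(2024, 3, 1)
        split = intake_series(
            [DietRecord(day, "Rice", 50.0), DietRecord(day, "Rice", 50.0)], db
        )
        merged = intake_series([DietRecord(day, "Rice", 100.0)], db)
        assert np.allclose(split.to_numpy(), merged.to_numpy())

    def test_record_order_invariance(self, db):
        d1, d2 = dt.date(2024, 3, 1), dt.date(2024, 3, 2)
        recs = [
            DietRecord(d1, "Rice", 120.0),
            DietRecord(d2, "Oatmeal", 40.0),
            DietRecord(d1, "Cheese", 30.0),
        ]
        a = intake_series(recs, db)
        b = intake_series(recs[::-1], db)
        assert a.equals(b)

    def test_unresolved_food_lists_records(self, db):
        with pytest.raises(FoodLookupError, match="Dragonfruit"):
            intake_series([DietRecord(dt.date(2024, 3, 1), "Dragonfruit", 10.0)], db)

    def test_zero_days_in_requested_range(self, db):
        start = dt.date(2024, 3, 1)
        series = intake_series(
            [DietRecord(start, "Rice", 100.0)], db, start=start, days=3
        )
        assert len(series) == 3
        assert series.iloc[1].sum() == 0.0

    def test_mean_intake_constant_series(self, db):
        start = dt.date(2024, 3, 1)
        recs = [
            DietRecord(start + dt.timedelta(d), "Rice", 150.0) for d in range(14)
        ]
        series = intake_series(recs, db, start=start, days=14)
        assert mean_intake(series, 14)["energy"] == pytest.approx(174.0)

    def test_mean_intake_alternating(self, db):
        start = dt.date(2024, 3, 1)
        recs = []
        for d in range(14):
            grams = 100.0 if d % 2 == 0 else 200.0
            recs.append(DietRecord(start + dt.timedelta(d), "Tomato", grams))
        series = intake_series(recs, db, start=start, days=14)
        # tomato: 20 kcal/100 g -> alternating 20/40 kcal days
        assert mean_intake(series, 14)["energy"] == pytest.approx(30.0 * 20 / 20)

    def test_mean_intake_matches_brute_force(self, db):
        rng = np.random.default_rng(11)
        start = dt.date(2024, 3, 1)
        foods = ["Rice", "Potato", "Cheese", "Oatmeal"]
        recs = [
            DietRecord(
                start + dt.timedelta(int(rng.integers(14))),
                foods[rng.integers(len(foods))],
                float(rng.uniform(20, 300)),
            )
            for _ in range(40)
        ]
        series = intake_series(recs, db, start=start, days=14)
        brute = series.iloc[:14].to_numpy().sum(axis=0) / 14.0
        assert np.allclose(mean_intake(series, 14).to_numpy(), brute)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            DietRecord(dt.date(2024, 3, 1), "Rice", -5.0)
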