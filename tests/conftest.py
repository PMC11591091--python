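"""Shared fixtures: a small composition-table database written to disk."""

import textwrap

import pytest

from diabkit import nutrition

INGREDIENT_CSV = textwrap.dedent("""\
    name,energy,fat,carbohydrate,protein,water,dietary_fiber,vitamin_B1,Ca,Fe,Na
    Rice,116,0.3,25.9,2.6,70.9,0.3,0.02,7,1.3,2.5
    Potato,77,0.2,17.2,2,79.8,0.7,0.08,8,0.8,2.7
    Pork,395,37,2.4,13.2,46.8,-,0.22,6,1.6,59.4
    Chicken,167,9.4,1.3,19.3,69,-,0.05,9,1.4,63.3
    Mushroom,24,0.1,4.1,2.7,92.4,2.1,0.08,6,1.2,8.3
    Tomato,20,0.2,4,0.9,94.4,0.5,0.03,10,0.4,5
    """)

PACKAGED_CSV = textwrap.dedent("""\
    name,energy,fat,carbohydrate,protein,Na
    Oatmeal,377,6.7,66.9,15,3.7
    Biscuit,435,12.7,71.7,9,204.1
    Fried Chips,615,48.4,41.9,4,60.9
    Spicy Kelp,57.9,1.7,8.5,3.1,2590
    Cheese,328,23.5,3.5,25.7,584
    """)

DISH_CSV = textwrap.dedent("""\
    name,ingredient_1,amount_1,ingredient_2,amount_2,ingredient_3,amount_3
    Rice Bowl,Rice,200,,,,
    Roast Chicken,Rice,250,Chicken,200,Tomato,80
    Tomato Potato Stew,Potato,150,Tomato,100,,
    Mushroom Pork,Pork,100,Mushroom,50,,
    Chicken Mushroom Soup,Chicken,150,Mushroom,100,Tomato,50
    """)

UNITS_YAML = textwrap.dedent("""\
    energy: kcal
    fat: g
    carbohydrate: g
    protein: g
    water: g
    dietary_fiber: g
    vitamin_B1: mg
    Ca: mg
    Fe: mg
    Na: mg
    """)


@pytest.fixture()
def db_files(tmp_path):
    paths = {}
    for name, text in [
        ("ingredients.csv", INGREDIENT_CSV),
        ("packaged.csv", PACKAGED_CSV),
        ("dishes.csv", DISH_CSV),
        ("units.yaml", UNITS_YAML),
    ]:
        p = tmp_path / name
        p.write_text(text, encoding="utf-8")
        paths[name.split(".")[0]] = p
    return paths


@pytest.fixture()
def db(db_files):
    return nutrition.load_database(
        db_files["ingredients"], db_files["packaged"],
        db_files["dishes"], db_files["units"],
    )
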