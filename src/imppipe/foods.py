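"""Canonical 37-group FFQ food-group table (synthetic scenario defaults).

The 37 groups mirror an FFQ whose original 22 groups were subdivided for
amino-acid scoring. Histidine contents (mg per g of food) and energy
densities (kcal per g) are plausible food-composition values chosen as
scenario defaults for the synthetic cohort — they are configuration, not
measured facts, and every consumer of this table accepts an override.
"""

from __future__ import annotations

import pandas as pd

# name, histidine mg/g, kcal/g, typical intake g/day
_GROUPS = [
    ("potatoes", 0.6, 0.8, 120),
    ("vegetables", 0.3, 0.3, 180),
    ("legumes", 2.3, 1.2, 30),
    ("fruits", 0.2, 0.5, 150),
    ("nuts_seeds", 5.0, 6.0, 15),
    ("dairy_milk", 0.9, 0.6, 150),
    ("dairy_yogurt", 1.2, 0.8, 80),
    ("cheese", 7.0, 3.5, 40),
    ("cereals_refined", 1.4, 2.5, 120),
    ("cereals_wholegrain", 1.8, 2.4, 60),
    ("bread_white", 1.5, 2.6, 80),
    ("bread_wholemeal", 1.9, 2.3, 50),
    ("rice_pasta", 1.2, 1.4, 90),
    ("red_meat", 8.5, 2.2, 70),
    ("processed_meat", 6.8, 3.0, 40),
    ("poultry", 8.9, 1.7, 50),
    ("offal", 6.0, 1.4, 5),
    ("fish_white", 7.5, 1.0, 30),
    ("fish_fatty", 8.8, 2.0, 25),
    ("shellfish", 4.5, 0.9, 10),
    ("eggs", 3.0, 1.5, 30),
    ("butter_animal_fat", 0.1, 7.2, 15),
    ("vegetable_oils", 0.0, 8.8, 20),
    ("margarine", 0.1, 7.0, 10),
    ("sauces_dressings", 0.8, 2.5, 20),
    ("sugar_confectionery", 0.1, 4.0, 30),
    ("chocolate", 1.1, 5.3, 15),
    ("cakes_biscuits", 1.6, 4.3, 50),
    ("breakfast_cereals", 1.7, 3.8, 25),
    ("soft_drinks", 0.0, 0.4, 150),
    ("fruit_juice", 0.1, 0.45, 100),
    ("coffee_tea", 0.0, 0.0, 400),
    ("alcoholic_beverages", 0.1, 0.7, 100),
    ("soups", 0.5, 0.4, 80),
    ("savoury_snacks", 1.3, 5.0, 20),
    ("soy_products", 3.5, 1.2, 10),
    ("water", 0.0, 0.0, 1000),
]

FOOD_GROUPS = pd.DataFrame(
    _GROUPS, columns=["group", "histidine_mg_per_g", "kcal_per_g", "typical_intake_g"]
).set_index("group")

GROUP_NAMES: list[str] = list(FOOD_GROUPS.index)
HISTIDINE_MG_PER_G: pd.Series = FOOD_GROUPS["histidine_mg_per_g"]
KCAL_PER_G: pd.Series = FOOD_GROUPS["kcal_per_g"]
TYPICAL_INTAKE_G: pd.Series = FOOD_GROUPS["typical_intake_g"]

assert len(FOOD_GROUPS) == 37
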