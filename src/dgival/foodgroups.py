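"""Food groups and the short-FFQ item schema.

The instrument under study is a 30-item verbally administered food-frequency
questionnaire for very young children in remote Aboriginal communities.  Its
items cover six fruit/vegetable foods, three dairy foods, three breads and
cereals, six meat and meat alternatives, five healthy fats and five
discretionary foods (one of which is a sugar-sweetened beverage), plus two
non-quantifying questions (breastfeeding, traditional food).  Dairy is carried
through the data model but never scored; sugar-sweetened beverages are scored
as their own indicator in place of a water indicator.
"""

from __future__ import annotations

from enum import Enum


class FoodGroup(str, Enum):
    VEGETABLES = "vegetables"
    FRUIT = "fruit"
    BREADS_CEREALS = "breads_cereals"
    MEAT_ALTERNATIVES = "meat_alternatives"
    HEALTHY_FATS = "healthy_fats"
    DISCRETIONARY = "discretionary"
    SSB = "ssb"
    DAIRY = "dairy"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Groups that contribute quantity indicators to the diet-quality score.
#: Dairy is deliberately absent: milk-fed infants make dairy quantity
#: uninformative, so the index excludes it.
SCORED_QUANTITY_GROUPS = (
    FoodGroup.VEGETABLES,
    FoodGroup.FRUIT,
    FoodGroup.BREADS_CEREALS,
    FoodGroup.MEAT_ALTERNATIVES,
    FoodGroup.HEALTHY_FATS,
)

#: Groups entering the dietary-variety indicator.
VARIETY_GROUPS = SCORED_QUANTITY_GROUPS

AGE_BANDS = ("<12mo", "1-2y", ">2y")

#: Recall day types: the three recall days of each child are spread across a
#: fortnightly pay cycle to capture systematic food-availability variation.
DAY_TYPES = ("pay_week", "non_pay_week", "weekend")

# item_id -> (food group, sub-food tag).  28 quantifying items; together with
# the two non-quantifying questions (breastfed, traditional food) the
# instrument has 30 items.
DEFAULT_FFQ_ITEMS: dict[str, tuple[FoodGroup, str]] = {
    "veg_green": (FoodGroup.VEGETABLES, "green_veg"),
    "veg_root": (FoodGroup.VEGETABLES, "root_veg"),
    "veg_other": (FoodGroup.VEGETABLES, "other_veg"),
    "fruit_fresh": (FoodGroup.FRUIT, "fresh_fruit"),
    "fruit_canned": (FoodGroup.FRUIT, "canned_fruit"),
    "fruit_dried": (FoodGroup.FRUIT, "dried_fruit"),
    "dairy_milk": (FoodGroup.DAIRY, "milk"),
    "dairy_cheese": (FoodGroup.DAIRY, "cheese"),
    "dairy_yoghurt": (FoodGroup.DAIRY, "yoghurt"),
    "bread": (FoodGroup.BREADS_CEREALS, "bread"),
    "cereal": (FoodGroup.BREADS_CEREALS, "breakfast_cereal"),
    "rice_pasta": (FoodGroup.BREADS_CEREALS, "rice_pasta"),
    "meat_red": (FoodGroup.MEAT_ALTERNATIVES, "red_meat"),
    "meat_white": (FoodGroup.MEAT_ALTERNATIVES, "white_meat"),
    "meat_fish": (FoodGroup.MEAT_ALTERNATIVES, "fish"),
    "meat_eggs": (FoodGroup.MEAT_ALTERNATIVES, "eggs"),
    "meat_legumes": (FoodGroup.MEAT_ALTERNATIVES, "legumes"),
    "meat_traditional": (FoodGroup.MEAT_ALTERNATIVES, "traditional_meat"),
    "fat_avocado": (FoodGroup.HEALTHY_FATS, "avocado"),
    "fat_nut_paste": (FoodGroup.HEALTHY_FATS, "nut_paste"),
    "fat_oil": (FoodGroup.HEALTHY_FATS, "cooking_oil"),
    "fat_margarine": (FoodGroup.HEALTHY_FATS, "margarine"),
    "fat_oily_fish": (FoodGroup.HEALTHY_FATS, "oily_fish"),
    "disc_sweets": (FoodGroup.DISCRETIONARY, "sweets"),
    "disc_salty": (FoodGroup.DISCRETIONARY, "salty_snacks"),
    "disc_takeaway": (FoodGroup.DISCRETIONARY, "takeaway"),
    "disc_processed_meat": (FoodGroup.DISCRETIONARY, "processed_meat"),
    "ssb_soft_drink": (FoodGroup.SSB, "soft_drink"),
}

#: Sub-foods per group, in schema order (drives simulation and variety config).
SUB_FOODS: dict[FoodGroup, tuple[str, ...]] = {}
for _gid, (_grp, _sub) in DEFAULT_FFQ_ITEMS.items():
    SUB_FOODS.setdefault(_grp, ())
    SUB_FOODS[_grp] = SUB_FOODS[_grp] + (_sub,)
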