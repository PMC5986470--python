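"""Convert FFQ responses and 24-h recall records to daily food-group serves.

Serves/day per food group are the common currency of the two instruments:
the FFQ reports frequency × portion over a reference fortnight, while each
recall day lists foods already expressed in reference serves.  The available
recall days (1–3 per child, after dropout) are averaged with the number of
completed days as the divisor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import ReferenceServings
from .foodgroups import DAY_TYPES, DEFAULT_FFQ_ITEMS, FoodGroup


class SchemaError(ValueError):
    """Input table violates the expected schema."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested operation."""


@dataclass
class FFQItemResponse:
    item_id: str
    food_group: FoodGroup
    sub_food: str
    freq_per_period: float  # eating occasions in the reference period
    serves_per_occasion: float


@dataclass
class FFQResponse:
    """One child's short-FFQ answers over the reference fortnight."""

    child_id: str
    items: list[FFQItemResponse]
    period_days: float = 14.0
    breastfed: bool = False
    traditional_food: bool = False
    wholegrain_bread: bool = False

    def validate(self) -> None:
        if self.period_days <= 0:
            raise SchemaError("period_days must be > 0")
        for it in self.items:
            if it.item_id not in DEFAULT_FFQ_ITEMS:
                raise SchemaError(f"unknown FFQ item id: {it.item_id}")
            if it.freq_per_period < 0:
                raise SchemaError(
                    f"negative frequency for item {it.item_id}"
                )
            if it.serves_per_occasion < 0:
                raise SchemaError(
                    f"negative serves/occasion for item {it.item_id}"
                )


@dataclass
class RecallRecord:
    """One food on one recall day for one child, in reference serves."""

    child_id: str
    recall_index: int  # 1..3
    day_type: str  # pay_week | non_pay_week | weekend
    food_id: str
    food_group: FoodGroup
    sub_food: str
    serves: float

    def validate(self) -> None:
        if self.recall_index not in (1, 2, 3):
            raise SchemaError(f"recall_index must be 1..3: {self.recall_index}")
        if self.day_type not in DAY_TYPES:
            raise SchemaError(f"unknown day type: {self.day_type}")
        if self.serves < 0:
            raise SchemaError(f"negative serves for {self.food_id}")


@dataclass
class FoodGroupServings:
    """Per-child daily serves by food group, plus the presence flags the
    variety indicator needs.  ``n_recalls`` is 0 for FFQ-derived serves."""

    child_id: str
    serves: dict[FoodGroup, float] = field(
        default_factory=lambda: {g: 0.0 for g in FoodGroup}
    )
    sub_food_flags: frozenset[tuple[FoodGroup, str]] = frozenset()
    n_recalls: int = 0
    wholegrain: bool = False
    breastfed: bool = False

    def get(self, group: FoodGroup) -> float:
        return self.serves.get(group, 0.0)


def ffq_to_servings(resp: FFQResponse) -> FoodGroupServings:
    """Daily serves per group = Σ_items frequency × serves/occasion ÷ period.

    Sub-food presence flags are set for every item with positive daily
    serves; no minimum-serving threshold applies (recommended amounts for
    under-threes are small, so any consumption counts toward variety).
    """
    resp.validate()
    serves = {g: 0.0 for g in FoodGroup}
    flags: set[tuple[FoodGroup, str]] = set()
    for it in resp.items:
        daily = it.freq_per_period * it.serves_per_occasion / resp.period_days
        serves[it.food_group] += daily
        if daily > 0:
            flags.add((it.food_group, it.sub_food))
    return FoodGroupServings(
        child_id=resp.child_id,
        serves=serves,
        sub_food_flags=frozenset(flags),
        n_recalls=0,
        wholegrain=resp.wholegrain_bread,
        breastfed=resp.breastfed,
    )


def recall_day_to_servings(
    records: list[RecallRecord],
    ref: ReferenceServings,
    child_id: str | None = None,
) -> FoodGroupServings:
    """Sum one child-day's records into group serves.

    A day with no records is a valid all-zero day (recalls in this setting
    sometimes record only breastfeeds or nothing at all).  Every food id
    must have a reference serve size.
    """
    if records:
        ids = {r.child_id for r in records}
        idx = {r.recall_index for r in records}
        if len(ids) > 1 or len(idx) > 1:
            raise SchemaError(
                "recall_day_to_servings expects records of one child-day"
            )
        child_id = records[0].child_id
    elif child_id is None:
        child_id = ""
    serves = {g: 0.0 for g in FoodGroup}
    flags: set[tuple[FoodGroup, str]] = set()
    breastfed = False
    wholegrain = False
    for r in records:
        r.validate()
        if r.food_id not in ref.serve_sizes_g:
            raise SchemaError(
                f"food id {r.food_id!r} has no reference serve size"
            )
        if r.sub_food == "breastmilk":
            breastfed = True
            continue  # breastmilk is recorded but not quantified as dairy
        sub = r.sub_food
        if sub == "wholegrain_bread":
            # wholegrain is a separate binary indicator; for variety the
            # food still counts as bread
            wholegrain = wholegrain or r.serves > 0
            sub = "bread"
        serves[r.food_group] += r.serves
        if r.serves > 0:
            flags.add((r.food_group, sub))
    return FoodGroupServings(
        child_id=child_id,
        serves=serves,
        sub_food_flags=frozenset(flags),
        n_recalls=1,
        wholegrain=wholegrain,
        breastfed=breastfed,
    )


def average_recalls(days: list[FoodGroupServings]) -> FoodGroupServings:
    """Mean daily serves over the *available* recall days.

    The divisor is the number of completed recalls, not the intended three:
    the analysis keeps every child regardless of how many recalls they
    finished.  A sub-food (and wholegrain / breastfed) flag is true if set
    on any day.
    """
    if not days:
        raise InsufficientDataError("no recall days to average")
    if len(days) > 3:
        raise SchemaError("at most 3 recall days per child")
    ids = {d.child_id for d in days}
    if len(ids) > 1:
        raise SchemaError("recall days belong to different children")
    n = len(days)
    serves = {
        g: sum(d.get(g) for d in days) / n for g in FoodGroup
    }
    flags = frozenset().union(*(d.sub_food_flags for d in days))
    return FoodGroupServings(
        child_id=days[0].child_id,
        serves=serves,
        sub_food_flags=flags,
        n_recalls=n,
        wholegrain=any(d.wholegrain for d in days),
        breastfed=any(d.breastfed for d in days),
    )


def plausibility_check(
    s: FoodGroupServings, limits: dict[str, float]
) -> list[str]:
    """Flag group serves strictly exceeding the configured ceilings.

    Returns human-readable flags; never mutates the data — implausible
    values are surfaced for review, not silently truncated.
    """
    flags = []
    for g in FoodGroup:
        limit = limits.get(g.value)
        if limit is not None and s.get(g) > limit:
            flags.append(
                f"{s.child_id}: {g.value} = {s.get(g):.2f} serves/day "
                f"exceeds limit {limit:.2f}"
            )
    return flags


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

FFQ_COLUMNS = [
    "child_id", "item_id", "food_group", "sub_food", "freq_per_period",
    "serves_per_occasion", "period_days", "breastfed", "traditional_food",
    "wholegrain_bread",
]

RECALL_COLUMNS = [
    "child_id", "recall_index", "day_type", "food_id", "food_group",
    "sub_food", "serves",
]


def ffq_frame(responses: list[FFQResponse]) -> pd.DataFrame:
    rows = []
    for resp in responses:
        for it in resp.items:
            rows.append({
                "child_id": resp.child_id,
                "item_id": it.item_id,
                "food_group": it.food_group.value,
                "sub_food": it.sub_food,
                "freq_per_period": it.freq_per_period,
                "serves_per_occasion": it.serves_per_occasion,
                "period_days": resp.period_days,
                "breastfed": resp.breastfed,
                "traditional_food": resp.traditional_food,
                "wholegrain_bread": resp.wholegrain_bread,
            })
    return pd.DataFrame(rows, columns=FFQ_COLUMNS)


def recall_frame(records: list[RecallRecord]) -> pd.DataFrame:
    rows = [{
        "child_id": r.child_id,
        "recall_index": r.recall_index,
        "day_type": r.day_type,
        "food_id": r.food_id,
        "food_group": r.food_group.value,
        "sub_food": r.sub_food,
        "serves": r.serves,
    } for r in records]
    return pd.DataFrame(rows, columns=RECALL_COLUMNS)


def read_ffq_csv(path: str | Path) -> list[FFQResponse]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FFQ_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"ffq_responses.csv missing columns: {sorted(missing)}")
    responses = []
    for child_id, grp in df.groupby("child_id", sort=True):
        items = [
            FFQItemResponse(
                item_id=row.item_id,
                food_group=FoodGroup(row.food_group),
                sub_food=row.sub_food,
                freq_per_period=float(row.freq_per_period),
                serves_per_occasion=float(row.serves_per_occasion),
            )
            for row in grp.itertuples()
        ]
        first = grp.iloc[0]
        responses.append(FFQResponse(
            child_id=str(child_id),
            items=items,
            period_days=float(first.period_days),
            breastfed=bool(first.breastfed),
            traditional_food=bool(first.traditional_food),
            wholegrain_bread=bool(first.wholegrain_bread),
        ))
    return responses


def read_recall_csv(path: str | Path) -> list[RecallRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(RECALL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(
            f"recall_records.csv missing columns: {sorted(missing)}"
        )
    return [
        RecallRecord(
            child_id=str(row.child_id),
            recall_index=int(row.recall_index),
            day_type=row.day_type,
            food_id=row.food_id,
            food_group=FoodGroup(row.food_group),
            sub_food=row.sub_food,
            serves=float(row.serves),
        )
        for row in df.itertuples()
    ]


def child_recall_servings(
    records: list[RecallRecord], ref: ReferenceServings
) -> dict[str, FoodGroupServings]:
    """Group records by child, convert each completed day, and average.

    Children appear in the output keyed by id; a child's day with no food
    records at all can only be represented here if it carries at least a
    breastmilk record, matching how empty days arise in the field data.
    """
    by_child_day: dict[str, dict[int, list[RecallRecord]]] = {}
    for r in records:
        by_child_day.setdefault(r.child_id, {}).setdefault(
            r.recall_index, []
        ).append(r)
    out = {}
    for child_id in sorted(by_child_day):
        days = [
            recall_day_to_servings(by_child_day[child_id][idx], ref)
            for idx in sorted(by_child_day[child_id])
        ]
        out[child_id] = average_recalls(days)
    return out
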