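"""Modified children's diet-quality index (DGI-CA, ages 0–3): indicator
scores, 90-point total and its 100-point rescaling.

Scoring rules
-------------
* Quantity indicators (vegetables, fruit, meat & alternatives /10 each,
  breads & cereals /5, healthy fats /10) score proportionally to intake
  relative to the age-band recommendation, capped at the maximum:
  full points at or above the recommended serves, zero at zero intake,
  linear in between.
* Limiting indicators (sugar-sweetened beverages /10, discretionary foods
  /20) are negatively scored: full points at zero intake, zero points at or
  beyond the cutoff, linear in between.
* Wholegrain (/5) is binary on wholegrain-bread consumption.
* Dietary variety (/10) has two systems: System A distributes the 10 points
  over sub-foods within each group (e.g. 0.5 points each for red meat,
  white meat, fish and eggs) and awards each sub-food's points when it is
  consumed at all; System B awards a group's whole allocation (e.g. 2
  points for meat) for any consumption within the group.  No minimum
  serving applies in either system.
* The total is the sum of the nine indicators (max 90, dairy excluded) and
  is rescaled to /100 for comparability with other index variants.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ConfigurationError, INDICATORS, ReferenceServings, ScoringConfig
from .foodgroups import FoodGroup, VARIETY_GROUPS
from .servings import FoodGroupServings


@dataclass
class DGIScore:
    child_id: str
    indicators: dict[str, float]
    total_90: float
    total_100: float


def score_adequacy(intake: float, recommended: float, max_points: float) -> float:
    """Linear pro-rata points, capped at ``max_points`` once the
    recommendation is fully met."""
    if recommended <= 0:
        raise ConfigurationError("recommended serves must be > 0")
    if intake < 0:
        raise ValueError("intake must be >= 0")
    return min(intake / recommended, 1.0) * max_points


def score_limiting(intake: float, cutoff: float, max_points: float) -> float:
    """Negatively scored indicator: full points at zero intake, none at or
    beyond the cutoff, linear in between."""
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be > 0")
    if intake < 0:
        raise ValueError("intake must be >= 0")
    return max(0.0, 1.0 - intake / cutoff) * max_points


def score_variety_a(
    flags: frozenset[tuple[FoodGroup, str]],
    allocation: dict[str, dict[str, float]],
    max_points: float = 10.0,
) -> float:
    """Sum the per-sub-food point allocation over consumed sub-foods."""
    total_alloc = sum(p for subs in allocation.values() for p in subs.values())
    if abs(total_alloc - max_points) > 1e-9:
        raise ConfigurationError(
            f"variety allocation must sum to {max_points}, got {total_alloc}"
        )
    pts = 0.0
    for group, sub in flags:
        pts += allocation.get(group.value, {}).get(sub, 0.0)
    return pts


def score_variety_b(
    flags: frozenset[tuple[FoodGroup, str]],
    allocation: dict[str, float],
    max_points: float = 10.0,
) -> float:
    """Award a group's whole allocation for any consumption in the group."""
    total_alloc = sum(allocation.values())
    if abs(total_alloc - max_points) > 1e-9:
        raise ConfigurationError(
            f"variety allocation must sum to {max_points}, got {total_alloc}"
        )
    consumed = {group.value for group, _sub in flags}
    return sum(p for g, p in allocation.items() if g in consumed)


def score_wholegrain(consumes_wholegrain: bool, max_points: float = 5.0) -> float:
    """Binary indicator: full points for any wholegrain-bread consumption."""
    return max_points if consumes_wholegrain else 0.0


def total_score(indicators: dict[str, float], child_id: str = "") -> DGIScore:
    """Sum the nine indicator scores into the /90 total and scale to /100."""
    if "dairy" in indicators:
        raise ConfigurationError(
            "dairy indicator is excluded from this index variant"
        )
    missing = set(INDICATORS) - set(indicators)
    if missing:
        raise ConfigurationError(f"missing indicators: {sorted(missing)}")
    extra = set(indicators) - set(INDICATORS)
    if extra:
        raise ConfigurationError(f"unexpected indicators: {sorted(extra)}")
    total_90 = sum(indicators.values())
    return DGIScore(
        child_id=child_id,
        indicators=dict(indicators),
        total_90=total_90,
        total_100=total_90 * 100.0 / 90.0,
    )


def score_child(
    s: FoodGroupServings,
    age_band: str,
    cfg: ScoringConfig,
    ref: ReferenceServings,
) -> DGIScore:
    """Score one child's daily food-group serves against the index rules."""
    cfg.validate()
    mp = cfg.max_points
    ind = {
        "vegetables": score_adequacy(
            s.get(FoodGroup.VEGETABLES),
            ref.recommended_serves(FoodGroup.VEGETABLES, age_band),
            mp["vegetables"],
        ),
        "fruit": score_adequacy(
            s.get(FoodGroup.FRUIT),
            ref.recommended_serves(FoodGroup.FRUIT, age_band),
            mp["fruit"],
        ),
        "meat_alternatives": score_adequacy(
            s.get(FoodGroup.MEAT_ALTERNATIVES),
            ref.recommended_serves(FoodGroup.MEAT_ALTERNATIVES, age_band),
            mp["meat_alternatives"],
        ),
        "breads_cereals": score_adequacy(
            s.get(FoodGroup.BREADS_CEREALS),
            ref.recommended_serves(FoodGroup.BREADS_CEREALS, age_band),
            mp["breads_cereals"],
        ),
        "healthy_fats": score_adequacy(
            s.get(FoodGroup.HEALTHY_FATS),
            ref.recommended_serves(FoodGroup.HEALTHY_FATS, age_band),
            mp["healthy_fats"],
        ),
        "wholegrain": score_wholegrain(s.wholegrain, mp["wholegrain"]),
        "ssb": score_limiting(
            s.get(FoodGroup.SSB), cfg.ssb_cutoff, mp["ssb"]
        ),
        "discretionary": score_limiting(
            s.get(FoodGroup.DISCRETIONARY),
            cfg.discretionary_cutoff,
            mp["discretionary"],
        ),
    }
    if cfg.variety_system == "A":
        ind["variety"] = score_variety_a(
            s.sub_food_flags, cfg.variety_allocation_a, mp["variety"]
        )
    else:
        ind["variety"] = score_variety_b(
            s.sub_food_flags, cfg.variety_allocation_b, mp["variety"]
        )
    return total_score(ind, child_id=s.child_id)


def scores_frame(scores: list[DGIScore], method: str) -> "pd.DataFrame":
    """Tabulate per-child indicator scores (method ∈ {ffq, recall})."""
    import pandas as pd

    rows = []
    for sc in scores:
        row = {"child_id": sc.child_id, "method": method}
        row.update(sc.indicators)
        row["total_90"] = sc.total_90
        row["total_100"] = sc.total_100
        rows.append(row)
    cols = ["child_id", "method", *INDICATORS, "total_90", "total_100"]
    return pd.DataFrame(rows, columns=cols)
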