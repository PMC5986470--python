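"""Synthetic validation cohort: paired FFQ and multi-day recall data with
known ground truth.

The generator emulates the structure of a small remote-community infant
feeding study: ~40 children across three age bands with high breastfeeding
prevalence, one short-FFQ response per child, and up to three 24-h recall
days spread over a fortnightly pay cycle (pay week / non-pay week /
weekend) with monotone session dropout.

Both instruments are modelled as noisy reports of the same latent usual
diet.  Each child has gamma-distributed usual daily serves per food group
and a sub-food repertoire; a recall day multiplies the usual serves by a
day-type factor and mean-one log-normal within-person noise, with
occasional zero-intake days (food insecurity, power outages); the FFQ
applies a per-group multiplicative reporting bias and its own mean-one
log-normal noise.  Because the noise is mean-one, expected reported serves
equal ``bias × usual`` exactly, which the parameter-recovery tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortParams, DietModelParams
from .foodgroups import (
    AGE_BANDS,
    DAY_TYPES,
    DEFAULT_FFQ_ITEMS,
    FoodGroup,
    SUB_FOODS,
)
from .servings import (
    FFQItemResponse,
    FFQResponse,
    RecallRecord,
    ffq_frame,
    recall_frame,
)

#: item ids per food group, in schema order
_ITEMS_BY_GROUP: dict[FoodGroup, tuple[str, ...]] = {}
for _iid, (_g, _s) in DEFAULT_FFQ_ITEMS.items():
    _ITEMS_BY_GROUP.setdefault(_g, ())
    _ITEMS_BY_GROUP[_g] = _ITEMS_BY_GROUP[_g] + (_iid,)

_REPERTOIRE_PROB = 0.6  # P(a sub-food is in a child's repertoire)
_TRADITIONAL_FOOD_PROB = 0.3
_BREASTMILK_SERVES = 1.0


@dataclass
class LatentChild:
    """Ground-truth usual diet for one simulated child."""

    child_id: str
    age_band: str
    breastfed: bool
    usual_serves: dict[FoodGroup, float]
    wholegrain_consumer: bool
    # item ids the child ever consumes, per group (part of the latent truth:
    # both instruments report from the same repertoire)
    repertoire: dict[FoodGroup, tuple[str, ...]] = field(default_factory=dict)
    traditional_food: bool = False
    n_recalls: int = 3
    recall_breastfed: bool = False


def _lognormal_factor(rng: np.random.Generator, sd: float) -> float:
    """Mean-one multiplicative noise: exp(N(-sd^2/2, sd))."""
    if sd == 0:
        return 1.0
    return float(np.exp(rng.normal(-0.5 * sd * sd, sd)))


def _draw_usual(
    rng: np.random.Generator, mean: float, dispersion: float
) -> float:
    """Gamma draw with the given mean and squared coefficient of variation
    (non-negative and right-skewed, as sparse toddler intakes are)."""
    if mean == 0:
        return 0.0
    if dispersion == 0:
        return mean
    shape = 1.0 / dispersion
    return float(rng.gamma(shape, mean / shape))


def generate_cohort(
    params: CohortParams, diet: DietModelParams
) -> tuple[list[LatentChild], list[FFQResponse], list[RecallRecord]]:
    """Draw a full cohort: latent truths, one FFQ per child, and recall
    records for each completed session.

    Children complete session 1 always; sessions 2 and 3 follow the
    configured conditional completion probabilities (monotone dropout).
    Each child's recall days carry distinct day types in a random order.
    """
    params.validate()
    diet.validate()
    rng = np.random.default_rng(params.seed)

    children: list[LatentChild] = []
    ffqs: list[FFQResponse] = []
    records: list[RecallRecord] = []

    width = max(3, len(str(params.n_children)))
    band_probs = np.array([params.age_band_probs[b] for b in AGE_BANDS])

    for i in range(params.n_children):
        cid = f"c{i + 1:0{width}d}"
        band = AGE_BANDS[rng.choice(len(AGE_BANDS), p=band_probs)]
        breastfed = bool(
            rng.random() < params.breastfeeding_prob_by_band[band]
        )
        scale = diet.infant_intake_factor if band == "<12mo" else 1.0
        usual = {
            g: scale * _draw_usual(
                rng, diet.usual_serves_mean.get(g, 0.0),
                diet.usual_serves_dispersion,
            )
            for g in FoodGroup
        }
        wholegrain = bool(rng.random() < diet.wholegrain_consumer_prob)
        repertoire: dict[FoodGroup, tuple[str, ...]] = {}
        for g, item_ids in _ITEMS_BY_GROUP.items():
            keep = tuple(
                iid for iid in item_ids if rng.random() < _REPERTOIRE_PROB
            )
            if not keep:  # every child eats something in each group
                keep = (item_ids[rng.choice(len(item_ids))],)
            repertoire[g] = keep
        # wholegrain consumption is expressed through bread, so it requires
        # bread in the repertoire; both instruments then see it consistently
        wholegrain = wholegrain and (
            "bread" in repertoire[FoodGroup.BREADS_CEREALS]
        )
        traditional = bool(rng.random() < _TRADITIONAL_FOOD_PROB)

        # monotone session dropout
        n_recalls = 1
        if rng.random() < params.dropout_probs[0]:
            n_recalls = 2
            if rng.random() < params.dropout_probs[1]:
                n_recalls = 3
        # the instruments may disagree on breastfeeding for a few children
        recall_breastfed = breastfed
        if rng.random() < diet.breastfeeding_flip_prob:
            recall_breastfed = not breastfed

        child = LatentChild(
            child_id=cid,
            age_band=band,
            breastfed=breastfed,
            usual_serves=usual,
            wholegrain_consumer=wholegrain,
            repertoire=repertoire,
            traditional_food=traditional,
            n_recalls=n_recalls,
            recall_breastfed=recall_breastfed,
        )
        children.append(child)
        ffqs.append(_make_ffq(rng, child, diet))
        records.extend(_make_recalls(rng, child, diet))

    return children, ffqs, records


def _make_ffq(
    rng: np.random.Generator, child: LatentChild, diet: DietModelParams
) -> FFQResponse:
    period = 14.0
    items: list[FFQItemResponse] = []
    for g, item_ids in _ITEMS_BY_GROUP.items():
        reported = (
            child.usual_serves[g]
            * diet.ffq_bias.get(g, 1.0)
            * _lognormal_factor(rng, diet.ffq_noise_sd)
        )
        eaten = child.repertoire[g]
        per_item = reported / len(eaten) if eaten else 0.0
        for iid in item_ids:
            grp, sub = DEFAULT_FFQ_ITEMS[iid]
            freq = per_item * period if iid in eaten else 0.0
            items.append(FFQItemResponse(
                item_id=iid,
                food_group=grp,
                sub_food=sub,
                freq_per_period=freq,
                serves_per_occasion=1.0,
            ))
    return FFQResponse(
        child_id=child.child_id,
        items=items,
        period_days=period,
        breastfed=child.breastfed,
        traditional_food=child.traditional_food,
        wholegrain_bread=child.wholegrain_consumer,
    )


def _make_recalls(
    rng: np.random.Generator, child: LatentChild, diet: DietModelParams
) -> list[RecallRecord]:
    day_order = [DAY_TYPES[j] for j in rng.permutation(len(DAY_TYPES))]
    records: list[RecallRecord] = []
    for session in range(1, child.n_recalls + 1):
        day_type = day_order[session - 1]
        zero_day = rng.random() < diet.zero_intake_day_prob
        day_records: list[RecallRecord] = []
        if not zero_day:
            for g, eaten in child.repertoire.items():
                day_serves = (
                    child.usual_serves[g]
                    * diet.day_type_multipliers[day_type]
                    * _lognormal_factor(rng, diet.recall_noise_sd)
                )
                if day_serves <= 0:
                    continue
                # a day's group intake spreads over the child's whole
                # repertoire: at these ages children graze small amounts of
                # their usual foods rather than rotating through them
                for iid in eaten:
                    grp, sub = DEFAULT_FFQ_ITEMS[iid]
                    if sub == "bread" and child.wholegrain_consumer:
                        sub = "wholegrain_bread"
                    day_records.append(RecallRecord(
                        child_id=child.child_id,
                        recall_index=session,
                        day_type=day_type,
                        food_id=iid,
                        food_group=grp,
                        sub_food=sub,
                        serves=day_serves / len(eaten),
                    ))
        if child.recall_breastfed:
            # breastfeeds are recorded even on no-food days
            day_records.append(RecallRecord(
                child_id=child.child_id,
                recall_index=session,
                day_type=day_type,
                food_id="breastmilk",
                food_group=FoodGroup.DAIRY,
                sub_food="breastmilk",
                serves=_BREASTMILK_SERVES,
            ))
        elif not day_records:
            # keep the completed-but-empty day visible in the records table
            day_records.append(RecallRecord(
                child_id=child.child_id,
                recall_index=session,
                day_type=day_type,
                food_id="bread",
                food_group=FoodGroup.BREADS_CEREALS,
                sub_food="bread",
                serves=0.0,
            ))
        records.extend(day_records)
    return records


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

def children_frame(children: list[LatentChild]) -> pd.DataFrame:
    rows = [{
        "child_id": c.child_id,
        "age_band": c.age_band,
        "breastfed": c.breastfed,
        "n_recalls": c.n_recalls,
    } for c in children]
    return pd.DataFrame(
        rows, columns=["child_id", "age_band", "breastfed", "n_recalls"]
    )


def truth_frame(children: list[LatentChild]) -> pd.DataFrame:
    rows = []
    for c in children:
        row = {
            "child_id": c.child_id,
            "age_band": c.age_band,
            "breastfed": c.breastfed,
            "wholegrain_consumer": c.wholegrain_consumer,
        }
        for g in FoodGroup:
            row[f"usual_{g.value}"] = c.usual_serves[g]
        rows.append(row)
    cols = ["child_id", "age_band", "breastfed", "wholegrain_consumer"] + [
        f"usual_{g.value}" for g in FoodGroup
    ]
    return pd.DataFrame(rows, columns=cols)


def write_fixtures(
    children: list[LatentChild],
    ffqs: list[FFQResponse],
    records: list[RecallRecord],
    path: str | Path,
) -> dict[str, Path]:
    """Write the four cohort CSVs; deterministic bytes for a given cohort,
    and lossless through the CSV readers."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "ffq_responses": out / "ffq_responses.csv",
        "recall_records": out / "recall_records.csv",
        "children": out / "children.csv",
        "truth": out / "truth.csv",
    }
    # %.17g round-trips IEEE doubles exactly through the CSV readers
    ffq_frame(ffqs).to_csv(
        files["ffq_responses"], index=False, float_format="%.17g")
    recall_frame(records).to_csv(
        files["recall_records"], index=False, float_format="%.17g")
    children_frame(children).to_csv(files["children"], index=False)
    truth_frame(children).to_csv(
        files["truth"], index=False, float_format="%.17g")
    return files
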