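"""Configuration objects: cohort/diet simulation parameters, reference
servings and diet-quality scoring rules, with YAML round-trip.

Reference serve sizes and recommended daily serves are not universal
constants — they come from the Australian Dietary Guidelines age 0–3 bands
and are deliberately shipped as editable configuration; every computation
takes them as input rather than hard-coding them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .foodgroups import (
    AGE_BANDS,
    DEFAULT_FFQ_ITEMS,
    FoodGroup,
    SUB_FOODS,
    VARIETY_GROUPS,
)


class ConfigurationError(ValueError):
    """Invalid parameter or scoring configuration."""


_PROB_TOL = 1e-9


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {p}")


# ---------------------------------------------------------------------------
# Simulation parameters
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Structure of the simulated validation cohort.

    Defaults mirror the study design this package analyses: 40 children in
    three age bands (30% under 12 months, 55% aged 1–2 years, 15% older),
    high breastfeeding prevalence (92% / 86% / 67% by band, ≈85% overall),
    and monotone dropout across the three recall sessions (all complete
    session 1, 90% session 2, and 33/36 of those session 3, so ≈83%
    complete all three).
    """

    n_children: int = 40
    age_band_probs: dict[str, float] = field(
        default_factory=lambda: {"<12mo": 0.30, "1-2y": 0.55, ">2y": 0.15}
    )
    breastfeeding_prob_by_band: dict[str, float] = field(
        default_factory=lambda: {"<12mo": 11 / 12, "1-2y": 19 / 22, ">2y": 4 / 6}
    )
    # P(complete session 2 | session 1), P(complete session 3 | session 2)
    dropout_probs: tuple[float, float] = (36 / 40, 33 / 36)
    seed: int = 0

    def validate(self) -> None:
        if self.n_children < 1:
            raise ConfigurationError("n_children must be >= 1")
        if set(self.age_band_probs) != set(AGE_BANDS):
            raise ConfigurationError(f"age_band_probs must cover {AGE_BANDS}")
        total = sum(self.age_band_probs.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ConfigurationError(
                f"age_band_probs must sum to 1 (got {total})"
            )
        for band, p in self.age_band_probs.items():
            _check_prob(p, f"age_band_probs[{band}]")
        for band in AGE_BANDS:
            _check_prob(
                self.breastfeeding_prob_by_band[band],
                f"breastfeeding_prob_by_band[{band}]",
            )
        for i, p in enumerate(self.dropout_probs):
            _check_prob(p, f"dropout_probs[{i}]")


def _default_usual_means() -> dict[FoodGroup, float]:
    # Usual daily serves for a 1–2-year-old in a food-insecure remote
    # setting: sparse vegetables/fruit, bread-heavy, modest meat, low SSB.
    return {
        FoodGroup.VEGETABLES: 0.7,
        FoodGroup.FRUIT: 0.9,
        FoodGroup.BREADS_CEREALS: 2.0,
        FoodGroup.MEAT_ALTERNATIVES: 0.9,
        FoodGroup.HEALTHY_FATS: 0.5,
        FoodGroup.DISCRETIONARY: 0.4,
        FoodGroup.SSB: 0.1,
        FoodGroup.DAIRY: 1.0,
    }


@dataclass
class DietModelParams:
    """Latent usual-diet model and the two instruments' reporting error.

    Both the FFQ and the recalls are modelled as noisy reports of the same
    latent usual intake: recall days multiply the usual serves by a day-type
    factor (pay week > non-pay week; weekends in between) and log-normal
    within-person noise, with occasional zero-intake days (power outages,
    food insecurity); the FFQ applies a per-group multiplicative reporting
    bias and its own log-normal noise.
    """

    usual_serves_mean: dict[FoodGroup, float] = field(
        default_factory=_default_usual_means
    )
    # squared coefficient of variation of usual serves between children
    usual_serves_dispersion: float = 0.4
    day_type_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "pay_week": 1.25,
            "non_pay_week": 0.75,
            "weekend": 1.0,
        }
    )
    zero_intake_day_prob: float = 0.05
    # FFQ over-reporting relative to recalls, strongest for meat and fats,
    # with fruit the one group reported lower — the pattern seen when short
    # FFQs are validated against recalls in young children
    ffq_bias: dict[FoodGroup, float] = field(
        default_factory=lambda: {
            FoodGroup.VEGETABLES: 1.1,
            FoodGroup.FRUIT: 0.9,
            FoodGroup.BREADS_CEREALS: 1.3,
            FoodGroup.MEAT_ALTERNATIVES: 2.5,
            FoodGroup.HEALTHY_FATS: 2.0,
            FoodGroup.DISCRETIONARY: 1.3,
            FoodGroup.SSB: 1.2,
            FoodGroup.DAIRY: 1.0,
        }
    )
    ffq_noise_sd: float = 0.30
    recall_noise_sd: float = 0.35
    # intake scaling for infants under 12 months (milk-fed, small solids)
    infant_intake_factor: float = 0.5
    # P(FFQ and recall disagree on breastfeeding); default ≈ 1 child in 40
    breastfeeding_flip_prob: float = 0.025
    wholegrain_consumer_prob: float = 0.7

    def validate(self) -> None:
        for g, m in self.usual_serves_mean.items():
            if m < 0:
                raise ConfigurationError(f"usual_serves_mean[{g}] < 0")
        if self.usual_serves_dispersion < 0:
            raise ConfigurationError("usual_serves_dispersion < 0")
        for d, m in self.day_type_multipliers.items():
            if m < 0:
                raise ConfigurationError(f"day_type_multipliers[{d}] < 0")
        for g, b in self.ffq_bias.items():
            if b < 0:
                raise ConfigurationError(f"ffq_bias[{g}] < 0")
        _check_prob(self.zero_intake_day_prob, "zero_intake_day_prob")
        _check_prob(self.breastfeeding_flip_prob, "breastfeeding_flip_prob")
        _check_prob(self.wholegrain_consumer_prob, "wholegrain_consumer_prob")
        if self.ffq_noise_sd < 0 or self.recall_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not 0 <= self.infant_intake_factor:
            raise ConfigurationError("infant_intake_factor must be >= 0")


# ---------------------------------------------------------------------------
# Reference servings
# ---------------------------------------------------------------------------

def _default_recommended() -> dict[str, dict[str, float]]:
    # Serves/day drawn from the Australian Dietary Guidelines 0–3-year
    # bands; the under-12-month column reflects late-infancy solids amounts.
    by_group = {
        FoodGroup.VEGETABLES: {"<12mo": 1.5, "1-2y": 2.5, ">2y": 2.5},
        FoodGroup.FRUIT: {"<12mo": 0.5, "1-2y": 0.5, ">2y": 1.0},
        FoodGroup.BREADS_CEREALS: {"<12mo": 1.5, "1-2y": 4.0, ">2y": 4.0},
        FoodGroup.MEAT_ALTERNATIVES: {"<12mo": 1.0, "1-2y": 1.0, ">2y": 1.0},
        FoodGroup.HEALTHY_FATS: {"<12mo": 0.5, "1-2y": 1.0, ">2y": 1.0},
        FoodGroup.DAIRY: {"<12mo": 1.0, "1-2y": 1.0, ">2y": 1.5},
    }
    return {g.value: dict(v) for g, v in by_group.items()}


def _default_serve_sizes() -> dict[str, float]:
    # grams per reference serve for every food id the schema can emit
    sizes = {
        "veg_green": 75.0, "veg_root": 75.0, "veg_other": 75.0,
        "fruit_fresh": 150.0, "fruit_canned": 150.0, "fruit_dried": 30.0,
        "dairy_milk": 250.0, "dairy_cheese": 40.0, "dairy_yoghurt": 200.0,
        "bread": 40.0, "cereal": 30.0, "rice_pasta": 75.0,
        "meat_red": 65.0, "meat_white": 80.0, "meat_fish": 100.0,
        "meat_eggs": 120.0, "meat_legumes": 150.0, "meat_traditional": 65.0,
        "fat_avocado": 20.0, "fat_nut_paste": 10.0, "fat_oil": 7.0,
        "fat_margarine": 10.0, "fat_oily_fish": 100.0,
        "disc_sweets": 25.0, "disc_salty": 30.0, "disc_takeaway": 150.0,
        "disc_processed_meat": 50.0, "ssb_soft_drink": 250.0,
        "breastmilk": 100.0,
    }
    return sizes


@dataclass
class ReferenceServings:
    """Recommended daily serves per (food group, age band), per-food serve
    sizes, and plausibility ceilings."""

    recommended: dict[str, dict[str, float]] = field(
        default_factory=_default_recommended
    )
    serve_sizes_g: dict[str, float] = field(default_factory=_default_serve_sizes)
    plausibility_limits: dict[str, float] = field(
        default_factory=lambda: {g.value: 10.0 for g in FoodGroup}
    )

    def recommended_serves(self, group: FoodGroup, age_band: str) -> float:
        try:
            return self.recommended[group.value][age_band]
        except KeyError as exc:
            raise ConfigurationError(
                f"no recommended serves for {group} in band {age_band}"
            ) from exc

    def validate(self) -> None:
        for g, bands in self.recommended.items():
            for band, v in bands.items():
                if v < 0:
                    raise ConfigurationError(
                        f"recommended[{g}][{band}] < 0"
                    )
        for fid, sz in self.serve_sizes_g.items():
            if sz <= 0:
                raise ConfigurationError(f"serve size for {fid} must be > 0")


# ---------------------------------------------------------------------------
# Scoring configuration
# ---------------------------------------------------------------------------

INDICATORS = (
    "vegetables",
    "fruit",
    "meat_alternatives",
    "breads_cereals",
    "wholegrain",
    "ssb",
    "discretionary",
    "variety",
    "healthy_fats",
)


def _default_variety_a() -> dict[str, dict[str, float]]:
    """10 variety points spread over sub-foods: 2 points per scored group,
    split equally within the group, except meat which follows the published
    0.5-point allocation over red meat, white meat, fish and eggs."""
    alloc: dict[str, dict[str, float]] = {}
    for g in VARIETY_GROUPS:
        subs = SUB_FOODS[g]
        if g is FoodGroup.MEAT_ALTERNATIVES:
            alloc[g.value] = {s: 0.0 for s in subs}
            for s in ("red_meat", "white_meat", "fish", "eggs"):
                alloc[g.value][s] = 0.5
        else:
            alloc[g.value] = {s: 2.0 / len(subs) for s in subs}
    return alloc


@dataclass
class ScoringConfig:
    """Point rules for the modified children's diet-quality index.

    Nine indicators totalling 90 points: four /10 quantity indicators
    (vegetables, fruit, meat & alternatives, healthy fats), breads &
    cereals split as /5 quantity + /5 wholegrain, /10 sugar-sweetened
    beverages and /20 discretionary foods (both scored negatively), and
    /10 dietary variety.  Dairy is excluded by design.
    """

    max_points: dict[str, float] = field(
        default_factory=lambda: {
            "vegetables": 10.0,
            "fruit": 10.0,
            "meat_alternatives": 10.0,
            "breads_cereals": 5.0,
            "wholegrain": 5.0,
            "ssb": 10.0,
            "discretionary": 20.0,
            "variety": 10.0,
            "healthy_fats": 10.0,
        }
    )
    discretionary_cutoff: float = 1.0  # serves/day at which 20 pts reach 0
    ssb_cutoff: float = 1.0  # serves/day at which 10 pts reach 0
    variety_system: str = "A"
    variety_allocation_a: dict[str, dict[str, float]] = field(
        default_factory=_default_variety_a
    )
    variety_allocation_b: dict[str, float] = field(
        default_factory=lambda: {g.value: 2.0 for g in VARIETY_GROUPS}
    )

    def validate(self) -> None:
        if set(self.max_points) != set(INDICATORS):
            raise ConfigurationError(
                f"max_points must cover exactly {INDICATORS}"
            )
        if "dairy" in self.max_points:
            raise ConfigurationError("dairy is excluded from scoring")
        total = sum(self.max_points.values())
        if abs(total - 90.0) > 1e-9:
            raise ConfigurationError(
                f"indicator maxima must sum to 90, got {total}"
            )
        if self.discretionary_cutoff <= 0 or self.ssb_cutoff <= 0:
            raise ConfigurationError("cutoffs must be > 0")
        if self.variety_system not in ("A", "B"):
            raise ConfigurationError("variety_system must be 'A' or 'B'")
        tot_a = sum(
            p for subs in self.variety_allocation_a.values()
            for p in subs.values()
        )
        if abs(tot_a - self.max_points["variety"]) > 1e-9:
            raise ConfigurationError(
                f"system-A variety allocation must sum to "
                f"{self.max_points['variety']}, got {tot_a}"
            )
        tot_b = sum(self.variety_allocation_b.values())
        if abs(tot_b - self.max_points["variety"]) > 1e-9:
            raise ConfigurationError(
                f"system-B variety allocation must sum to "
                f"{self.max_points['variety']}, got {tot_b}"
            )


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {
            (k.value if isinstance(k, FoodGroup) else k): _to_plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, FoodGroup):
        return obj.value
    return obj


def save_yaml(obj, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(obj), sort_keys=True))


def _group_keyed(d: dict[str, float]) -> dict[FoodGroup, float]:
    return {FoodGroup(k): v for k, v in d.items()}


def load_cohort_config(path: str | Path) -> tuple[CohortParams, DietModelParams]:
    """Read a simulation config with optional ``cohort:`` and ``diet:``
    sections; omitted fields keep their documented defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    craw = dict(raw.get("cohort", {}))
    if "dropout_probs" in craw:
        craw["dropout_probs"] = tuple(craw["dropout_probs"])
    cohort = CohortParams(**craw)
    draw = dict(raw.get("diet", {}))
    for key in ("usual_serves_mean", "ffq_bias"):
        if key in draw:
            base = dict(getattr(DietModelParams(), key))
            base.update(_group_keyed(draw[key]))
            draw[key] = base
    diet = DietModelParams(**draw)
    cohort.validate()
    diet.validate()
    return cohort, diet


def load_reference_servings(path: str | Path) -> ReferenceServings:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    ref = ReferenceServings(**raw)
    ref.validate()
    return ref


def load_scoring_config(path: str | Path) -> ScoringConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = ScoringConfig(**raw)
    cfg.validate()
    return cfg
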