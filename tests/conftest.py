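import numpy as np
import pytest

from dgival.config import (
    CohortParams,
    DietModelParams,
    ReferenceServings,
    ScoringConfig,
)
from dgival.foodgroups import FoodGroup


@pytest.fixture
def scoring_cfg() -> ScoringConfig:
    return ScoringConfig()


@pytest.fixture
def ref() -> ReferenceServings:
    return ReferenceServings()


def noise_free_diet(**overrides) -> DietModelParams:
    """Diet model in the degenerate no-noise limit: both instruments report
    the latent usual serves exactly."""
    base = dict(
        ffq_noise_sd=0.0,
        recall_noise_sd=0.0,
        zero_intake_day_prob=0.0,
        day_type_multipliers={
            "pay_week": 1.0, "non_pay_week": 1.0, "weekend": 1.0
        },
        ffq_bias={g: 1.0 for g in FoodGroup},
    )
    base.update(overrides)
    return DietModelParams(**base)


@pytest.fixture
def small_cohort_params() -> CohortParams:
    return CohortParams(n_children=40, seed=11)


def ratio_of_means_se(x: np.ndarray, y: np.ndarray) -> float:
    """Delta-method standard error of mean(x)/mean(y) on paired samples."""
    n = len(x)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    cxy = np.cov(x, y, ddof=1)[0, 1]
    r = mx / my
    var = (r**2) * (vx / mx**2 + vy / my**2 - 2 * cxy / (mx * my)) / n
    return float(np.sqrt(max(var, 0.0)))
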