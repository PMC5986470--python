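"""End-to-end relative-validity pipeline: simulate (or load) → convert to
serves → score → compare methods → emit report tables.

Outputs mirror the shape of a dietary validation write-up: a food-group
intake comparison table (medians, IQRs, Wilcoxon Z), an indicator score
comparison table with proportional-bias columns, the full agreement
report, Bland–Altman data (and optionally a plot), and a log of the
configuration and seed that produced them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from .config import (
    CohortParams,
    ConfigurationError,
    DietModelParams,
    INDICATORS,
    ReferenceServings,
    ScoringConfig,
)
from .foodgroups import FoodGroup
from .scoring import DGIScore, score_child, scores_frame
from .servings import (
    FFQResponse,
    RecallRecord,
    child_recall_servings,
    ffq_to_servings,
    plausibility_check,
    read_ffq_csv,
    read_recall_csv,
)
from .simulate import LatentChild, generate_cohort, write_fixtures

#: food groups reported in the intake comparison table
_INTAKE_GROUPS = (
    FoodGroup.VEGETABLES,
    FoodGroup.FRUIT,
    FoodGroup.BREADS_CEREALS,
    FoodGroup.MEAT_ALTERNATIVES,
    FoodGroup.SSB,
    FoodGroup.DISCRETIONARY,
)


@dataclass
class RunConfig:
    """One pipeline run: either simulate a cohort or load CSV inputs."""

    cohort: CohortParams | None = None
    diet: DietModelParams | None = None
    input_dir: str | Path | None = None  # dir with ffq/recall/children CSVs
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    reference: ReferenceServings = field(default_factory=ReferenceServings)
    kappa_weights: str = "linear"
    loa_k: float = 1.96
    exclude_under_12m: bool = False
    out_dir: str | Path | None = None
    seed: int | None = None

    def validate(self) -> None:
        simulated = self.cohort is not None
        if simulated == (self.input_dir is not None):
            raise ConfigurationError(
                "provide exactly one of a simulation config or an input dir"
            )
        if simulated and self.diet is None:
            raise ConfigurationError("simulation requires diet parameters")


@dataclass
class ReportBundle:
    n_per_session: dict[int, int]
    scores: pd.DataFrame  # long: one row per child × method
    intake_table: pd.DataFrame  # food-group medians/IQR + Wilcoxon
    indicator_table: pd.DataFrame  # per-indicator comparison + bias slope
    report: agr.AgreementReport  # on the /100 totals
    report_completers: agr.AgreementReport | None
    subgroup: agr.SubgroupDirectionResult
    bland_altman_points: pd.DataFrame  # child_id, mean, difference
    plausibility_flags: list[str]
    run_log: dict

    def to_json_dict(self) -> dict:
        out = {
            "n_per_session": {str(k): v for k, v in self.n_per_session.items()},
            "agreement": self.report.to_dict(),
            "agreement_completers_only": (
                self.report_completers.to_dict()
                if self.report_completers is not None else None
            ),
            "subgroup_direction": {
                "counts": self.subgroup.counts,
                "table": self.subgroup.table.tolist(),
                "fisher_p": self.subgroup.fisher_p,
                "bland_altman_excluding_infants": (
                    vars(self.subgroup.bland_altman_excluding_infants)
                    if self.subgroup.bland_altman_excluding_infants else None
                ),
            },
            "plausibility_flags": self.plausibility_flags,
            "run_log": self.run_log,
        }
        return out


def _config_hash(cfg: RunConfig) -> str:
    from .config import _to_plain

    payload = json.dumps(
        {
            "cohort": _to_plain(cfg.cohort) if cfg.cohort else None,
            "diet": _to_plain(cfg.diet) if cfg.diet else None,
            "scoring": _to_plain(cfg.scoring),
            "reference": _to_plain(cfg.reference),
            "kappa_weights": cfg.kappa_weights,
            "loa_k": cfg.loa_k,
            "exclude_under_12m": cfg.exclude_under_12m,
            "seed": cfg.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(
    cfg: RunConfig,
) -> tuple[list[FFQResponse], list[RecallRecord], dict[str, str]]:
    """Return (ffqs, records, age band per child)."""
    if cfg.cohort is not None:
        params = cfg.cohort
        if cfg.seed is not None:
            params = CohortParams(**{**vars(params), "seed": cfg.seed})
        children, ffqs, records = generate_cohort(params, cfg.diet)
        bands = {c.child_id: c.age_band for c in children}
        if cfg.out_dir is not None:
            write_fixtures(children, ffqs, records, Path(cfg.out_dir) / "data")
        return ffqs, records, bands
    d = Path(cfg.input_dir)
    ffqs = read_ffq_csv(d / "ffq_responses.csv")
    records = read_recall_csv(d / "recall_records.csv")
    children = pd.read_csv(d / "children.csv")
    bands = dict(zip(children.child_id.astype(str), children.age_band))
    return ffqs, records, bands


def _intake_comparison(
    ffq_servings: dict, recall_servings: dict, ids: list[str]
) -> pd.DataFrame:
    rows = []
    for g in _INTAKE_GROUPS:
        x = np.array([ffq_servings[i].get(g) for i in ids])
        y = np.array([recall_servings[i].get(g) for i in ids])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = agr.paired_location_test(x, y, method="wilcoxon")
                z, p = res.statistic, res.p
            except agr.DegenerateInputError:
                z, p = np.nan, np.nan
        rows.append({
            "food_group": g.value,
            "ffq_median": np.median(x),
            "ffq_iqr_low": np.percentile(x, 25),
            "ffq_iqr_high": np.percentile(x, 75),
            "recall_median": np.median(y),
            "recall_iqr_low": np.percentile(y, 25),
            "recall_iqr_high": np.percentile(y, 75),
            "wilcoxon_z": z,
            "p": p,
        })
    return pd.DataFrame(rows)


def _indicator_comparison(
    ffq_scores: list[DGIScore], recall_scores: list[DGIScore]
) -> pd.DataFrame:
    rows = []
    items = [*INDICATORS, "total_90", "total_100"]
    for name in items:
        def pull(sc: DGIScore) -> float:
            if name == "total_90":
                return sc.total_90
            if name == "total_100":
                return sc.total_100
            return sc.indicators[name]

        x = np.array([pull(s) for s in ffq_scores])
        y = np.array([pull(s) for s in recall_scores])
        ba = agr.bland_altman(x, y)
        try:
            t = agr.paired_location_test(x, y, method="t")
            t_stat, t_p = t.statistic, t.p
        except agr.DegenerateInputError:
            t_stat, t_p = np.nan, np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                w = agr.paired_location_test(x, y, method="wilcoxon")
                w_z, w_p = w.statistic, w.p
            except agr.DegenerateInputError:
                w_z, w_p = np.nan, np.nan
        rows.append({
            "indicator": name,
            "ffq_mean": x.mean(), "ffq_sd": x.std(ddof=1),
            "ffq_median": np.median(x),
            "recall_mean": y.mean(), "recall_sd": y.std(ddof=1),
            "recall_median": np.median(y),
            "mean_difference": ba.mean_diff,
            "t_statistic": t_stat, "t_p": t_p,
            "wilcoxon_z": w_z, "wilcoxon_p": w_p,
            "bias_slope": ba.slope, "bias_slope_p": ba.slope_p,
        })
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the full validation analysis for one configuration."""
    cfg.validate()
    cfg.scoring.validate()
    cfg.reference.validate()
    ffqs, records, bands = _load_inputs(cfg)

    ffq_servings = {f.child_id: ffq_to_servings(f) for f in ffqs}
    recall_servings = child_recall_servings(records, cfg.reference)
    ids = sorted(set(ffq_servings) & set(recall_servings))
    if cfg.exclude_under_12m:
        ids = [i for i in ids if bands.get(i) != "<12mo"]
    if len(ids) < 4:
        raise agr.DegenerateInputError(
            "pipeline requires at least 4 children with both instruments"
        )

    flags = []
    for i in ids:
        flags += plausibility_check(
            ffq_servings[i], cfg.reference.plausibility_limits
        )
        flags += plausibility_check(
            recall_servings[i], cfg.reference.plausibility_limits
        )

    ffq_scores = [
        score_child(ffq_servings[i], bands[i], cfg.scoring, cfg.reference)
        for i in ids
    ]
    recall_scores = [
        score_child(recall_servings[i], bands[i], cfg.scoring, cfg.reference)
        for i in ids
    ]

    x = np.array([s.total_100 for s in ffq_scores])
    y = np.array([s.total_100 for s in recall_scores])
    pairs = agr.PairedScores(ids, x, y)
    report = agr.compare_methods(
        pairs, kappa_weights=cfg.kappa_weights, loa_k=cfg.loa_k
    )

    completers = [
        i for i in ids if recall_servings[i].n_recalls == 3
    ]
    report_completers = None
    if len(completers) >= 4:
        sel = [ids.index(i) for i in completers]
        report_completers = agr.compare_methods(
            agr.PairedScores(completers, x[sel], y[sel]),
            kappa_weights=cfg.kappa_weights, loa_k=cfg.loa_k,
        )

    subgroup = agr.subgroup_direction_analysis(
        pairs, [bands[i] for i in ids]
    )

    n_per_session = {1: len(ids)}
    for s in (2, 3):
        n_per_session[s] = sum(
            1 for i in ids if recall_servings[i].n_recalls >= s
        )

    ba_points = pd.DataFrame({
        "child_id": ids,
        "mean": (x + y) / 2.0,
        "difference": x - y,
    })

    scores = pd.concat(
        [scores_frame(ffq_scores, "ffq"), scores_frame(recall_scores, "recall")],
        ignore_index=True,
    )

    run_log = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed if cfg.seed is not None else (
            cfg.cohort.seed if cfg.cohort else None
        ),
        "n_children": len(ids),
        "variety_system": cfg.scoring.variety_system,
        "kappa_weights": cfg.kappa_weights,
        "exclude_under_12m": cfg.exclude_under_12m,
    }

    return ReportBundle(
        n_per_session=n_per_session,
        scores=scores,
        intake_table=_intake_comparison(ffq_servings, recall_servings, ids),
        indicator_table=_indicator_comparison(ffq_scores, recall_scores),
        report=report,
        report_completers=report_completers,
        subgroup=subgroup,
        bland_altman_points=ba_points,
        plausibility_flags=flags,
        run_log=run_log,
    )


def sensitivity_variety_systems(cfg: RunConfig) -> dict:
    """Run the comparison under variety Systems A and B and report deltas.

    System A splits each group's variety points across its sub-foods;
    System B awards the whole group allocation for any consumption, so
    per-child System B variety ≥ System A under the default allocations.
    """
    bundles = {}
    for system in ("A", "B"):
        scoring = ScoringConfig(**{
            **vars(cfg.scoring), "variety_system": system
        })
        run = RunConfig(**{**vars(cfg), "scoring": scoring})
        bundles[system] = run_pipeline(run)
    ra, rb = bundles["A"].report, bundles["B"].report
    return {
        "A": bundles["A"],
        "B": bundles["B"],
        "delta": {
            "ccc": rb.ccc - ra.ccc,
            "mean_difference": (
                rb.bland_altman.mean_diff - ra.bland_altman.mean_diff
            ),
        },
    }


# ---------------------------------------------------------------------------
# Writing the bundle
# ---------------------------------------------------------------------------

def write_bundle(
    bundle: ReportBundle, out_dir: str | Path, plot: bool = False
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    files["scores"] = out / "scores.csv"
    bundle.scores.to_csv(files["scores"], index=False)
    files["intake_table"] = out / "intake_comparison.csv"
    bundle.intake_table.to_csv(files["intake_table"], index=False)
    files["indicator_table"] = out / "indicator_comparison.csv"
    bundle.indicator_table.to_csv(files["indicator_table"], index=False)
    files["bland_altman"] = out / "bland_altman.csv"
    bundle.bland_altman_points.to_csv(files["bland_altman"], index=False)
    files["report"] = out / "agreement_report.json"
    files["report"].write_text(
        json.dumps(bundle.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    if plot:
        files["plot"] = out / "bland_altman.png"
        plot_bland_altman(bundle, files["plot"])
    return files


def plot_bland_altman(bundle: ReportBundle, path: str | Path) -> None:
    """Basic Bland–Altman plot: differences vs pair means with the bias
    line and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bundle.report.bland_altman
    pts = bundle.bland_altman_points
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(pts["mean"], pts["difference"], s=18, alpha=0.8)
    ax.axhline(ba.mean_diff, color="k", label=f"bias {ba.mean_diff:.2f}")
    ax.axhline(ba.upper_loa, color="k", ls="--",
               label=f"LOA ({ba.lower_loa:.2f}, {ba.upper_loa:.2f})")
    ax.axhline(ba.lower_loa, color="k", ls="--")
    ax.axhline(0.0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("Mean of methods (score /100)")
    ax.set_ylabel("FFQ − recalls (score /100)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
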