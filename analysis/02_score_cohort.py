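"""Convert both instruments to daily food-group serves and score the
modified diet-quality index.

Reads the fixtures written by 01_simulate_cohort.py, converts the FFQ
responses and averaged recall days to serves/day, screens them for
plausibility, scores every child under both instruments, and writes
results/scores.csv (one row per child × method, with all nine indicator
scores and the /90 and /100 totals).
"""

from pathlib import Path

import pandas as pd

from dgival.config import ReferenceServings, ScoringConfig
from dgival.scoring import score_child, scores_frame
from dgival.servings import (
    child_recall_servings,
    ffq_to_servings,
    plausibility_check,
    read_ffq_csv,
    read_recall_csv,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "scores.csv"


def main() -> None:
    ref = ReferenceServings()
    cfg = ScoringConfig()
    ffqs = read_ffq_csv(DATA / "ffq_responses.csv")
    records = read_recall_csv(DATA / "recall_records.csv")
    bands = dict(
        pd.read_csv(DATA / "children.csv")[["child_id", "age_band"]]
        .astype({"child_id": str}).itertuples(index=False)
    )

    ffq_s = {f.child_id: ffq_to_servings(f) for f in ffqs}
    rec_s = child_recall_servings(records, ref)
    ids = sorted(set(ffq_s) & set(rec_s))

    flags = []
    for i in ids:
        flags += plausibility_check(ffq_s[i], ref.plausibility_limits)
        flags += plausibility_check(rec_s[i], ref.plausibility_limits)
    print(f"plausibility flags: {len(flags)}")
    for f in flags:
        print("  " + f)

    frames = [
        scores_frame(
            [score_child(ffq_s[i], bands[i], cfg, ref) for i in ids], "ffq"),
        scores_frame(
            [score_child(rec_s[i], bands[i], cfg, ref) for i in ids], "recall"),
    ]
    scores = pd.concat(frames, ignore_index=True)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(OUT, index=False)

    summary = scores.groupby("method")[["total_90", "total_100"]].agg(
        ["mean", "std"]).round(2)
    print(f"scored {len(ids)} children under both instruments")
    print(summary)
    print(f"wrote {OUT.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
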