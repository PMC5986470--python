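"""Simulate the validation cohort.

Generates the default synthetic cohort — 40 children across three age
bands, high breastfeeding prevalence, one short-FFQ response each, and up
to three 24-h recall days (pay week / non-pay week / weekend) with monotone
dropout — and writes the four fixture CSVs plus the latent ground truth
under results/data/.
"""

from pathlib import Path

from dgival.config import CohortParams, DietModelParams
from dgival.simulate import generate_cohort, write_fixtures

SEED = 20180510
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    params = CohortParams(seed=SEED)
    diet = DietModelParams()
    children, ffqs, records = generate_cohort(params, diet)
    files = write_fixtures(children, ffqs, records, OUT)

    n = len(children)
    n2 = sum(c.n_recalls >= 2 for c in children)
    n3 = sum(c.n_recalls == 3 for c in children)
    bf = sum(c.breastfed for c in children)
    print(f"simulated {n} children (seed {SEED})")
    print(f"recall sessions completed: {n}/{n2}/{n3}")
    print(f"breastfeeding prevalence: {bf}/{n} ({100 * bf / n:.0f}%)")
    print(f"recall records: {len(records)}")
    for name, path in files.items():
        print(f"wrote {name}: {path.relative_to(OUT.parents[1])}")


if __name__ == "__main__":
    main()
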