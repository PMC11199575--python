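"""Pre/post inference between body-fat response categories.

For every outcome: the 2 (Rs/NRs by body fat) x 2 (pre/post) mixed
between-within ANOVA with generalized eta squared, Bonferroni post-hoc
contrasts with Cohen's d, the baseline-adjusted ANCOVA at post, percent
changes, and assumption diagnostics. Writes one JSON bundle per outcome.

Run:  python analysis/04_prepost_inference.py
"""

import json
from pathlib import Path

from ivret.classify import classify
from ivret.cohort import DEFAULT_OUTCOME_SPECS, read_cohort
from ivret.prepost import prepost_summary

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort(RESULTS / "cohort.csv")
    labels = classify(table, DEFAULT_OUTCOME_SPECS["BFP"], strata="sex")

    for name, spec in DEFAULT_OUTCOME_SPECS.items():
        res = prepost_summary(table, labels, spec)
        (RESULTS / f"prepost_{name}.json").write_text(
            json.dumps(res, indent=2, sort_keys=True, default=str)
        )
        inter = next(r for r in res["anova"] if r["effect"] == "interaction")
        time = next(r for r in res["anova"] if r["effect"] == "time")
        print(
            f"{name:>3}: interaction F(1,{inter['df2']}) = {inter['F']:6.2f}, "
            f"p = {inter['p']:.4f}, ges = {inter['ges']:.3f} | "
            f"time F = {time['F']:6.2f}, p = {time['p']:.4f}"
        )
        for d in res["deltas"]:
            print(
                f"     {d['group']:>3}: delta = {d['mean']:+6.2f} +/- {d['sd']:5.2f} "
                f"({d['pct_change']:.2f}%)"
            )
    print(f"wrote prepost_<outcome>.json under {RESULTS}")


if __name__ == "__main__":
    main()
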