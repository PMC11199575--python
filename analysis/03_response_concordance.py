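"""Cross-outcome concordance of response categories.

Do body-fat responders also respond in blood pressure and fitness? Builds
the flow table (Sankey data) from the BFP categories to each physiological
outcome's categories, with chi-squared independence tests, odds ratios
and Cramer's V per pairing. Writes results/flow.csv and
results/concordance.json.

Run:  python analysis/03_response_concordance.py
"""

import json
from pathlib import Path

from ivret.classify import classify
from ivret.cohort import DEFAULT_OUTCOME_SPECS, read_cohort
from ivret.concordance import flow_export, pairwise_stats

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort(RESULTS / "cohort.csv")
    labels = {
        name: classify(table, spec, strata="sex")
        for name, spec in DEFAULT_OUTCOME_SPECS.items()
    }
    flow = flow_export(labels, source_outcome="BFP")
    stats = pairwise_stats(labels, source_outcome="BFP")

    flow.to_csv(RESULTS / "flow.csv", index=False)
    (RESULTS / "concordance.json").write_text(
        json.dumps(stats.to_dict(orient="records"), indent=2)
    )

    for _, row in stats.iterrows():
        print(
            f"BFP vs {row.target:>3}: chi2(1) = {row.chi2:5.2f}, p = {row.p_value:.3f}, "
            f"OR = {row.odds_ratio:5.2f}, V = {row.cramers_v:.3f}"
        )
    print(f"wrote {RESULTS / 'flow.csv'} and {RESULTS / 'concordance.json'}")


if __name__ == "__main__":
    main()
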