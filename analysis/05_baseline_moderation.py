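"""Does baseline body fat moderate the physiological response?

Per response category, OLS of each outcome's change on baseline BFP, then
the two-line comparison: interaction (slope) test first, vertical-shift
(intercept) test from the parallel-slopes model. Writes
results/moderation.json.

Run:  python analysis/05_baseline_moderation.py
"""

import json
from pathlib import Path

from ivret.classify import classify
from ivret.cohort import DEFAULT_OUTCOME_SPECS, read_cohort
from ivret.moderation import compare_lines

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort(RESULTS / "cohort.csv")
    labels = classify(table, DEFAULT_OUTCOME_SPECS["BFP"], strata="sex")

    payload = {}
    for name in ("SBP", "DBP", "FI"):
        cmp = compare_lines(table, labels, DEFAULT_OUTCOME_SPECS[name])
        payload[name] = {
            "lines": {g: vars(l) for g, l in cmp.lines.items()},
            "slope_diff": cmp.slope_diff,
            "slope_p": cmp.slope_p,
            "intercept_diff": cmp.intercept_diff,
            "intercept_p": cmp.intercept_p,
        }
        print(
            f"{name:>3}: slopes b = {cmp.slope_diff:+.3f} (p = {cmp.slope_p:.3f}); "
            f"vertical shift b = {cmp.intercept_diff:+.3f} (p = {cmp.intercept_p:.3f})"
        )
        for g, line in cmp.lines.items():
            print(
                f"     {g:>3}: delta = {line.b0:+.2f} {line.b1:+.3f} * BFP  "
                f"(R^2 = {line.r_squared:.3f}, n = {line.n})"
            )

    (RESULTS / "moderation.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {RESULTS / 'moderation.json'}")


if __name__ == "__main__":
    main()
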