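"""Intra-individual association between body fat and each outcome.

Within each response category, the repeated-measures correlation between
body fat percentage and each physiological outcome over the two
measurement occasions: the common within-subject slope with
subject-specific intercepts. Writes results/rmcorr.json.

Run:  python analysis/06_rmcorr.py
"""

import json
from pathlib import Path

from ivret.classify import classify, NON_RESPONDER, RESPONDER
from ivret.cohort import DEFAULT_OUTCOME_SPECS, read_cohort
from ivret.rmcorr import rmcorr_prepost

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort(RESULTS / "cohort.csv")
    labels = classify(table, DEFAULT_OUTCOME_SPECS["BFP"], strata="sex")
    lab = labels.label_series
    bfp = DEFAULT_OUTCOME_SPECS["BFP"]

    payload = {}
    for name in ("SBP", "DBP", "FI"):
        payload[name] = {}
        for g in (RESPONDER, NON_RESPONDER):
            sub = table[table["subject_id"].isin(lab.index[lab == g])]
            res = rmcorr_prepost(sub, bfp, DEFAULT_OUTCOME_SPECS[name])
            payload[name][g] = {
                "r_rm": res.r_rm,
                "df": res.df,
                "p_value": res.p_value,
                "common_slope": res.common_slope,
                "n_subjects": res.n_subjects,
            }
            print(
                f"BFP vs {name:>3} in {g:>3}: r_rm = {res.r_rm:+.2f} "
                f"(df = {res.df}, p = {res.p_value:.3f})"
            )

    (RESULTS / "rmcorr.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {RESULTS / 'rmcorr.json'}")


if __name__ == "__main__":
    main()
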