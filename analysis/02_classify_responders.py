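"""Classify responders and non-responders by the typical-error criterion.

Reads results/cohort.csv, computes sex-specific typical errors and 2*TE
cutoffs for every outcome, labels each subject Rs/NRs, and writes
results/labels.csv plus results/cutoffs.json.

Run:  python analysis/02_classify_responders.py
"""

import json
from pathlib import Path

import pandas as pd

from ivret.classify import classify, RESPONDER
from ivret.cohort import DEFAULT_OUTCOME_SPECS, read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_cohort(RESULTS / "cohort.csv")
    all_labels = []
    cutoffs = {}
    for name, spec in DEFAULT_OUTCOME_SPECS.items():
        res = classify(table, spec, strata="sex")
        all_labels.append(res.labels)
        cutoffs[name] = {
            s: {"TE": te, "cutoff": cut} for s, (te, cut) in res.cutoffs.items()
        }
        c = res.counts()
        cuts = ", ".join(f"{s} {v['cutoff']:.3f}" for s, v in cutoffs[name].items())
        print(f"{name:>3}: Rs = {c['Rs']:2d}, NRs = {c['NRs']:2d}   (cutoffs: {cuts})")
        if name == "BFP":
            truth = table.set_index("subject_id")["true_responder_BFP"]
            got = res.labels.set_index("subject_id")["label"] == RESPONDER
            agree = (got == truth).mean()
            print(f"     agreement with simulated ground truth: {agree:.1%}")

    pd.concat(all_labels, ignore_index=True).to_csv(RESULTS / "labels.csv", index=False)
    (RESULTS / "cutoffs.json").write_text(json.dumps(cutoffs, indent=2, sort_keys=True))
    print(f"wrote {RESULTS / 'labels.csv'} and {RESULTS / 'cutoffs.json'}")


if __name__ == "__main__":
    main()
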