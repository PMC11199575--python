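"""End-to-end orchestration of the responder analysis.

Sequence: load or simulate the cohort -> classify Rs/NRs per outcome by
the typical-error criterion -> cross-outcome concordance and flow table
-> per-outcome mixed between-within inference -> baseline (BFP)
moderation regressions -> repeated-measures correlations within each
response category. Every artefact lands in the configured output
directory with full provenance (config hash, package version, seed), and
identical config + seed produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import read_cohort
from .classify import classify, RESPONDER, NON_RESPONDER
from .concordance import flow_export, pairwise_stats
from .config import AnalysisConfig
from .moderation import compare_lines
from .prepost import prepost_summary
from .rmcorr import rmcorr_prepost
from .simulate import simulate_cohort, write_cohort

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("ivret")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _config_hash(config: AnalysisConfig) -> str:
    payload = config.to_dict()
    payload.pop("output_dir", None)  # where results land is not an analysis setting
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_json(path: Path, payload: dict, provenance: dict) -> None:
    payload = {"_provenance": provenance, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _write_csv(path: Path, df: pd.DataFrame, provenance: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# ivret {provenance['version']} | config {provenance['config_hash']} "
            f"| seed {provenance['seed']}\n"
        )
        df.to_csv(fh, index=False)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the in-memory report bundle.

    Writes cohort.csv (simulated runs), labels.csv, flow.csv,
    concordance.json, prepost_<outcome>.json, moderation.json,
    rmcorr.json and summary.txt under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
    }
    bundle: dict = {"provenance": prov}

    # --- input -----------------------------------------------------------
    stage = "input"
    try:
        if config.simulation is not None:
            log.info("simulating cohort: n=%d, seed=%d",
                     config.simulation.n_total, config.simulation.seed)
            table = simulate_cohort(config.simulation)
            write_cohort(table, outdir / "cohort.csv")
        else:
            log.info("reading cohort from %s", config.csv_path)
            table = read_cohort(config.csv_path)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    bundle["n_subjects"] = int(len(table))
    bundle["n_by_sex"] = table["sex"].value_counts().to_dict()

    # --- classification --------------------------------------------------
    stage = "classification"
    try:
        labels_by_outcome = {}
        for name, spec in config.outcome_specs.items():
            # fixed cutoffs, when supplied, apply to the classifying outcome;
            # the others always estimate their own within-stratum TE
            is_primary = name == config.classify_outcome
            labels_by_outcome[name] = classify(
                table,
                spec,
                strata=config.stratify,
                te_source=config.te_source if is_primary else "within",
                fixed_cutoffs=config.fixed_cutoffs if is_primary else None,
            )
        primary = labels_by_outcome[config.classify_outcome]
        all_labels = pd.concat(
            [r.labels for r in labels_by_outcome.values()], ignore_index=True
        )
        _write_csv(outdir / "labels.csv", all_labels, prov)
        log.info(
            "classified %s: %s", config.classify_outcome, primary.counts()
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    bundle["cutoffs"] = {
        name: {s: {"TE": te, "cutoff": cut} for s, (te, cut) in r.cutoffs.items()}
        for name, r in labels_by_outcome.items()
    }
    bundle["counts"] = {name: r.counts() for name, r in labels_by_outcome.items()}

    # --- concordance / flow ----------------------------------------------
    stage = "concordance"
    try:
        flow = flow_export(labels_by_outcome, source_outcome=config.classify_outcome)
        stats_df = pairwise_stats(labels_by_outcome, source_outcome=config.classify_outcome)
        _write_csv(outdir / "flow.csv", flow, prov)
        _write_json(
            outdir / "concordance.json",
            {"pairwise": stats_df.to_dict(orient="records")},
            prov,
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    bundle["concordance"] = stats_df.to_dict(orient="records")

    # --- pre/post inference ----------------------------------------------
    stage = "prepost"
    bundle["prepost"] = {}
    for name, spec in config.outcome_specs.items():
        try:
            res = prepost_summary(table, primary, spec)
        except Exception as exc:
            raise PipelineError(f"{stage}:{name}", exc) from exc
        bundle["prepost"][name] = res
        _write_json(outdir / f"prepost_{name}.json", res, prov)

    # --- baseline moderation ---------------------------------------------
    stage = "moderation"
    moderation = {}
    for name, spec in config.outcome_specs.items():
        if name == config.classify_outcome:
            continue
        try:
            cmp = compare_lines(table, primary, spec)
        except Exception as exc:
            raise PipelineError(f"{stage}:{name}", exc) from exc
        moderation[name] = {
            "lines": {g: vars(l) for g, l in cmp.lines.items()},
            "slope_diff": cmp.slope_diff,
            "slope_t": cmp.slope_t,
            "slope_p": cmp.slope_p,
            "intercept_diff": cmp.intercept_diff,
            "intercept_t": cmp.intercept_t,
            "intercept_p": cmp.intercept_p,
        }
    _write_json(outdir / "moderation.json", {"by_outcome": moderation}, prov)
    bundle["moderation"] = moderation

    # --- repeated-measures correlation -----------------------------------
    stage = "rmcorr"
    rm = {}
    lab = primary.label_series
    x_spec = config.outcome_specs[config.classify_outcome]
    for name, spec in config.outcome_specs.items():
        if name == config.classify_outcome:
            continue
        rm[name] = {}
        for g in (RESPONDER, NON_RESPONDER):
            ids = lab.index[lab == g]
            sub = table[table["subject_id"].isin(ids)]
            if len(sub) < 3:
                rm[name][g] = {"skipped": f"only {len(sub)} subjects"}
                continue
            try:
                res = rmcorr_prepost(sub, x_spec, spec)
            except Exception as exc:
                raise PipelineError(f"{stage}:{name}:{g}", exc) from exc
            rm[name][g] = {
                "r_rm": res.r_rm,
                "df": res.df,
                "p_value": res.p_value,
                "common_slope": res.common_slope,
                "n_subjects": res.n_subjects,
            }
    _write_json(outdir / "rmcorr.json", {"by_outcome": rm}, prov)
    bundle["rmcorr"] = rm

    # --- summary ----------------------------------------------------------
    lines = [
        f"ivret {__version__} | config {prov['config_hash']} | seed {prov['seed']}",
        f"cohort: n = {bundle['n_subjects']} "
        f"({bundle['n_by_sex'].get('male', 0)} male, {bundle['n_by_sex'].get('female', 0)} female)",
        f"classifying outcome: {config.classify_outcome} "
        f"(stratified by {config.stratify or 'nothing'}, te_source={config.te_source})",
    ]
    for name, r in labels_by_outcome.items():
        c = r.counts()
        cuts = ", ".join(
            f"{s}: cutoff {cut:.3f}" for s, (_, cut) in r.cutoffs.items()
        )
        lines.append(f"  {name}: Rs = {c[RESPONDER]}, NRs = {c[NON_RESPONDER]} ({cuts})")
    for name, res in bundle["prepost"].items():
        inter = next(r for r in res["anova"] if r["effect"] == "interaction")
        lines.append(
            f"  {name}: interaction F(1,{inter['df2']}) = {inter['F']:.2f}, "
            f"p = {inter['p']:.4f}, ges = {inter['ges']:.3f}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    for line in lines:
        log.info("%s", line)
    return bundle
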