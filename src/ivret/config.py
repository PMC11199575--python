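"""Analysis configuration: schema, validation, YAML round-trip.

Validation is collect-all: every schema violation is gathered and reported
in one :class:`ConfigError` rather than failing on the first. Unknown keys
warn (forward compatibility) instead of erroring.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import OutcomeSpec, OUTCOMES, DEFAULT_OUTCOME_SPECS
from .simulate import SimulationParams, OutcomeParams, BodyParams, default_params

__all__ = ["AnalysisConfig", "ConfigError", "validate_config"]

_KNOWN_TOP = {
    "seed",
    "output_dir",
    "input",
    "simulation",
    "outcomes",
    "classification",
    "inference",
    "verbosity",
}


class ConfigError(ValueError):
    """All collected configuration problems, one per line."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass(frozen=True)
class AnalysisConfig:
    seed: int = 0
    output_dir: str = "results/run"
    csv_path: str | None = None  # exclusive with simulation
    simulation: SimulationParams | None = None
    outcome_specs: dict[str, OutcomeSpec] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_SPECS)
    )
    classify_outcome: str = "BFP"
    stratify: str | None = "sex"
    te_source: str = "within"
    fixed_cutoffs: dict[str, float] | float | None = None
    esb_weighting: str = "equal"
    family_size: int = 4
    welch: bool = False
    verbosity: str = "info"

    def to_dict(self) -> dict:
        sim = None
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            if sim.get("response_correlation") is not None:
                sim["response_correlation"] = np.asarray(
                    sim["response_correlation"]
                ).tolist()
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "input": {"csv": self.csv_path} if self.csv_path else None,
            "simulation": sim,
            "outcomes": {
                n: s.benefit_direction for n, s in self.outcome_specs.items()
            },
            "classification": {
                "outcome": self.classify_outcome,
                "stratify": self.stratify,
                "te_source": self.te_source,
                "fixed_cutoffs": self.fixed_cutoffs,
            },
            "inference": {
                "esb_weighting": self.esb_weighting,
                "family_size": self.family_size,
                "welch": self.welch,
            },
            "verbosity": self.verbosity,
        }


def _build_simulation(block: dict, seed: int, errors: list[str]) -> SimulationParams | None:
    """Simulation block mirroring SimulationParams; partial outcome
    overrides are merged into the study-calibrated defaults."""
    base = default_params(seed=seed)
    kwargs: dict = {"seed": int(block.get("seed", seed))}
    for key in ("n_male", "n_female", "age_mean", "age_sd", "responder_fraction_override"):
        if key in block and block[key] is not None:
            kwargs[key] = block[key]
    out_block = block.get("outcomes", {}) or {}
    outcomes = {}
    for o in OUTCOMES:
        ov = out_block.get(o, {}) or {}
        unknown = set(ov) - {f.name for f in dataclasses.fields(OutcomeParams)}
        if unknown:
            errors.append(f"simulation.outcomes.{o}: unknown field(s) {sorted(unknown)}")
            ov = {k: v for k, v in ov.items() if k not in unknown}
        outcomes[o] = dataclasses.replace(base.outcomes[o], **ov)
    kwargs["outcomes"] = outcomes
    kwargs["body"] = {
        sex: BodyParams(**bb) if isinstance(bb := block.get("body", {}).get(sex), dict)
        else base.body[sex]
        for sex in ("male", "female")
    }
    rc = block.get("response_correlation")
    kwargs["response_correlation"] = (
        np.asarray(rc, dtype=float) if rc is not None else base.response_correlation
    )
    try:
        return dataclasses.replace(base, **kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"simulation: {exc}")
        return None


def validate_config(source: str | Path | dict) -> AnalysisConfig:
    """Parse and validate a YAML/JSON config file or an equivalent dict.

    Raises :class:`ConfigError` listing *all* problems found; unknown keys
    produce warnings only.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])

    errors: list[str] = []
    for key in set(raw) - _KNOWN_TOP:
        warnings.warn(f"unknown configuration key {key!r} ignored", stacklevel=2)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: must be an integer, got {seed!r}")
        seed = 0

    out_dirs = raw.get("output_dir", "results/run")

    # outcomes: name -> benefit direction
    outcome_specs: dict[str, OutcomeSpec] = {}
    raw_outcomes = raw.get("outcomes")
    if raw_outcomes is None:
        outcome_specs = dict(DEFAULT_OUTCOME_SPECS)
    else:
        for name, direction in raw_outcomes.items():
            if direction not in ("decrease", "increase"):
                errors.append(
                    f"outcomes.{name}: benefit direction must be 'decrease' or "
                    f"'increase', got {direction!r}"
                )
            else:
                units = DEFAULT_OUTCOME_SPECS.get(name)
                outcome_specs[name] = OutcomeSpec(
                    name, units.units if units else "", direction
                )
        for name in OUTCOMES:
            if name not in outcome_specs:
                errors.append(
                    f"outcomes: missing benefit direction for {name!r}"
                )

    input_block = raw.get("input") or {}
    csv_path = input_block.get("csv") if isinstance(input_block, dict) else None
    sim_block = raw.get("simulation")
    simulation = None
    if csv_path and sim_block:
        errors.append("provide either input.csv or a simulation block, not both")
    elif sim_block is not None:
        if not isinstance(sim_block, dict):
            errors.append("simulation: must be a mapping")
        else:
            simulation = _build_simulation(sim_block, seed, errors)
    elif not csv_path:
        errors.append("no input: provide input.csv or a simulation block")

    cls = raw.get("classification", {}) or {}
    classify_outcome = cls.get("outcome", "BFP")
    if outcome_specs and classify_outcome not in outcome_specs:
        errors.append(
            f"classification.outcome {classify_outcome!r} has no declared "
            "benefit direction"
        )
    te_source = cls.get("te_source", "within")
    if te_source not in ("within", "fixed"):
        errors.append(f"classification.te_source: unknown value {te_source!r}")
    fixed_cutoffs = cls.get("fixed_cutoffs")
    if te_source == "fixed" and fixed_cutoffs is None:
        errors.append("classification.te_source='fixed' requires fixed_cutoffs")

    inf = raw.get("inference", {}) or {}
    family_size = inf.get("family_size", 4)
    if not isinstance(family_size, int) or family_size < 1:
        errors.append(f"inference.family_size: must be a positive integer, got {family_size!r}")
    esb_weighting = inf.get("esb_weighting", "equal")
    if esb_weighting not in ("equal", "sample-size"):
        errors.append(f"inference.esb_weighting: unknown value {esb_weighting!r}")

    if errors:
        raise ConfigError(errors)

    return AnalysisConfig(
        seed=seed,
        output_dir=str(out_dirs),
        csv_path=csv_path,
        simulation=simulation,
        outcome_specs=outcome_specs,
        classify_outcome=classify_outcome,
        stratify=cls.get("stratify", "sex"),
        te_source=te_source,
        fixed_cutoffs=fixed_cutoffs,
        esb_weighting=esb_weighting,
        family_size=family_size,
        welch=bool(inf.get("welch", False)),
        verbosity=str(raw.get("verbosity", "info")),
    )
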