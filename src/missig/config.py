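"""Run configuration: one validated object drives every pipeline stage.

The config dialect is a flat YAML key tree.  Every run can serialize its
fully resolved configuration back to JSON/YAML (and the pipeline writes it
next to its outputs), and a resolved config round-trips to an identical
object.  Unknown keys are rejected, and every validation error names the
offending field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imputation import ImputationSpec
from .lasso import CVScheme
from .prediction import ModelSpec
from .schema import LabSchema, default_lab_schema
from .simulate import (
    DEFAULT_DAY1_MISSINGNESS,
    DEFAULT_DAY_SHIFT,
    OUTCOME_NAMES,
    OutcomeModel,
    SimulationConfig,
)

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A config file failed validation; the message names the field."""


DEFAULT_MODEL_FAMILIES = ("logistic", "decision_tree", "random_forest")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    schema: LabSchema = field(default_factory=default_lab_schema)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outcomes: tuple[str, ...] = OUTCOME_NAMES
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    cv: CVScheme = field(default_factory=CVScheme)
    model_families: tuple[str, ...] = DEFAULT_MODEL_FAMILIES
    rf_trees: int = 500
    # soft prevalence targets used when re-deriving outcome intercepts
    prevalence: dict = field(
        default_factory=lambda: {"in_hospital": 0.11, "day30": 0.15}
    )
    outcome_beta: float = 1.5

    @property
    def n_patients(self) -> int:
        return self.sim.n_patients

    @property
    def days(self) -> tuple[int, ...]:
        return self.sim.days

    def model_specs(self) -> list[ModelSpec]:
        return [ModelSpec(family=f, rf_trees=self.rf_trees) for f in self.model_families]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_patients": self.sim.n_patients,
            "days": list(self.sim.days),
            "outcomes": list(self.outcomes),
            "imputation": {
                "method": self.imputation.method,
                "donors": self.imputation.pmm_donors,
            },
            "cv": {
                "n_folds": self.cv.n_folds,
                "n_repeats": self.cv.n_repeats,
                "stratified": self.cv.stratified,
            },
            "models": {
                "families": list(self.model_families),
                "rf_trees": self.rf_trees,
            },
            "simulation": {
                "delta": self.sim.delta,
                "dropout": self.sim.dropout,
                "day_shift": self.sim.day_shift,
                "value_loading": self.sim.value_loading,
                "value_noise": self.sim.value_noise,
                "value_mean": self.sim.value_mean,
                "severity_noise": self.sim.severity_noise,
                "mcar": self.sim.mcar,
                "prevalence": dict(self.prevalence),
                "outcome_beta": self.outcome_beta,
                "day1_missingness": dict(self.sim.day1_missingness),
            },
            "schema": {
                "tests": list(self.schema.test_names),
                "panels": {p: list(m) for p, m in self.schema.panels.items()},
            },
        }

    def write_resolved(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _reject_unknown(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {where!r}")


def _get(d: dict, key: str, default, where: str, typ=None):
    v = d.get(key, default)
    if typ is not None and v is not None and not isinstance(v, typ):
        raise ConfigError(f"{where}.{key}: expected {typ}, got {type(v).__name__}")
    return v


def from_dict(cfg: dict) -> RunConfig:
    """Build a validated RunConfig from a (possibly partial) key tree."""
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(
        cfg,
        {"seed", "n_patients", "days", "outcomes", "imputation", "cv", "models",
         "simulation", "schema"},
        "<root>",
    )

    seed = _get(cfg, "seed", 0, "<root>", int)

    sch = cfg.get("schema", {}) or {}
    _reject_unknown(sch, {"tests", "panels"}, "schema")
    if sch:
        base = default_lab_schema()
        tests = tuple(sch.get("tests", base.test_names))
        panels_in = sch.get("panels")
        if panels_in is not None:
            panels = {p: tuple(m) for p, m in panels_in.items()}
            grouped = {t for m in panels.values() for t in m}
            for t in tests:
                if t not in grouped:
                    panels[t] = (t,)
        else:
            panels = {p: m for p, m in base.panels.items() if set(m) <= set(tests)}
        try:
            schema = LabSchema(test_names=tests, panels=panels)
        except ValueError as e:
            raise ConfigError(f"schema: {e}") from e
    else:
        schema = default_lab_schema()

    sim_in = cfg.get("simulation", {}) or {}
    _reject_unknown(
        sim_in,
        {"delta", "dropout", "day_shift", "value_loading", "value_noise",
         "value_mean", "severity_noise", "mcar", "prevalence", "outcome_beta",
         "day1_missingness"},
        "simulation",
    )
    prevalence = _get(sim_in, "prevalence", {"in_hospital": 0.11, "day30": 0.15},
                      "simulation", dict)
    _reject_unknown(prevalence, set(OUTCOME_NAMES), "simulation.prevalence")
    outcome_beta = float(_get(sim_in, "outcome_beta", 1.5, "simulation", (int, float)))
    outcome_models = {
        name: OutcomeModel.from_prevalence(float(prevalence.get(name, dflt)), outcome_beta)
        for name, dflt in (("in_hospital", 0.11), ("day30", 0.15))
    }
    day1 = _get(sim_in, "day1_missingness", dict(DEFAULT_DAY1_MISSINGNESS),
                "simulation", dict)
    days = tuple(_get(cfg, "days", [1, 2, 3], "<root>", list))
    if any(d not in (1, 2, 3) for d in days) or not days:
        raise ConfigError("days: must be a non-empty subset of [1, 2, 3]")
    try:
        sim = SimulationConfig(
            n_patients=_get(cfg, "n_patients", 2000, "<root>", int),
            outcome_models=outcome_models,
            day1_missingness=dict(day1),
            day_shift=float(_get(sim_in, "day_shift", DEFAULT_DAY_SHIFT, "simulation", (int, float))),
            delta=_get(sim_in, "delta", 1.0, "simulation", (int, float, dict)),
            dropout=float(_get(sim_in, "dropout", 0.01, "simulation", (int, float))),
            value_mean=_get(sim_in, "value_mean", 0.0, "simulation", (int, float, dict)),
            value_loading=_get(sim_in, "value_loading", 0.15, "simulation", (int, float, dict)),
            value_noise=_get(sim_in, "value_noise", 1.0, "simulation", (int, float, dict)),
            severity_noise=float(_get(sim_in, "severity_noise", 0.75, "simulation", (int, float))),
            mcar=bool(_get(sim_in, "mcar", False, "simulation", bool)),
            days=days,
        )
    except ValueError as e:
        raise ConfigError(f"simulation: {e}") from e

    outcomes = tuple(_get(cfg, "outcomes", list(OUTCOME_NAMES), "<root>", list))
    for o in outcomes:
        if o not in OUTCOME_NAMES:
            raise ConfigError(f"outcomes: unknown outcome {o!r}; expected {OUTCOME_NAMES}")

    imp_in = cfg.get("imputation", {}) or {}
    _reject_unknown(imp_in, {"method", "donors"}, "imputation")
    try:
        imputation = ImputationSpec(
            method=_get(imp_in, "method", "pmm", "imputation", str),
            pmm_donors=_get(imp_in, "donors", 5, "imputation", int),
            rng_seed=seed,
        )
    except ValueError as e:
        raise ConfigError(f"imputation: {e}") from e

    cv_in = cfg.get("cv", {}) or {}
    _reject_unknown(cv_in, {"n_folds", "n_repeats", "stratified"}, "cv")
    try:
        cv = CVScheme(
            n_folds=_get(cv_in, "n_folds", 10, "cv", int),
            n_repeats=_get(cv_in, "n_repeats", 20, "cv", int),
            stratified=_get(cv_in, "stratified", True, "cv", bool),
        )
    except ValueError as e:
        raise ConfigError(f"cv: {e}") from e

    mdl_in = cfg.get("models", {}) or {}
    _reject_unknown(mdl_in, {"families", "rf_trees"}, "models")
    families = tuple(_get(mdl_in, "families", list(DEFAULT_MODEL_FAMILIES), "models", list))
    for f in families:
        if f not in DEFAULT_MODEL_FAMILIES:
            raise ConfigError(f"models.families: unknown family {f!r}")
    rf_trees = _get(mdl_in, "rf_trees", 500, "models", int)
    if rf_trees < 1:
        raise ConfigError("models.rf_trees: must be positive")

    return RunConfig(
        seed=seed,
        schema=schema,
        sim=sim,
        outcomes=outcomes,
        imputation=imputation,
        cv=cv,
        model_families=families,
        rf_trees=rf_trees,
        prevalence={k: float(prevalence.get(k, d)) for k, d in
                    (("in_hospital", 0.11), ("day30", 0.15))},
        outcome_beta=outcome_beta,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) config file.

    An empty file yields the all-defaults configuration.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    return from_dict(raw)
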