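"""Synthetic ICU cohort generator with severity-linked (MNAR) missingness.

The generator emulates the structure of a daily ICU laboratory extract:

* one latent severity scalar per patient, standard normal;
* binary mortality outcomes (in-hospital and 30-day) drawn through a
  logistic link on severity;
* per day and per ordering panel, a Bernoulli "panel ordered" draw whose
  log-odds rise with severity (sicker patients get more tests ordered, so
  their profiles have *fewer* missing entries) — setting the severity link
  delta to zero everywhere yields an MCAR null cohort;
* test values drawn Gaussian around a severity-loaded mean, present only if
  the panel was ordered and the test survived an independent within-panel
  dropout;
* a noisy observed severity score standing in for a clinical severity-of-
  illness index such as SAPS-II.

Ordering becomes more selective over the three ICU days (day-1 care is
protocolized, later days are need-driven), encoded as a per-day decrement of
the panel-ordering log-odds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .schema import LabSchema, default_lab_schema

__all__ = [
    "OutcomeModel",
    "SimulationConfig",
    "CohortDay",
    "Cohort",
    "generate_cohort",
    "mcar_variant",
    "logistic_normal_mean",
    "solve_intercept",
    "write_cohort",
]

logger = logging.getLogger(__name__)

OUTCOME_NAMES = ("in_hospital", "day30")

# Gauss-Hermite nodes/weights for E_{s~N(0,1)}[f(s)] (probabilists' weight).
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(64)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def logistic_normal_mean(alpha: float, beta: float) -> float:
    """E[expit(alpha + beta*s)] for s ~ N(0,1), by 64-point quadrature."""
    return float(_GH_WEIGHTS @ expit(alpha + beta * _GH_NODES))


def solve_intercept(target_p: float, beta: float) -> float:
    """Intercept alpha with E[expit(alpha + beta*s)] = target_p, s ~ N(0,1)."""
    if not 0.0 < target_p < 1.0:
        raise ValueError(f"target probability must be in (0,1), got {target_p}")
    lo = logit(target_p) - 3.0 * abs(beta) - 1.0
    hi = logit(target_p) + 3.0 * abs(beta) + 1.0
    return float(brentq(lambda a: logistic_normal_mean(a, beta) - target_p, lo, hi))


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome model: y ~ Bernoulli(expit(alpha + beta * severity))."""

    alpha: float
    beta: float

    @classmethod
    def from_prevalence(cls, prevalence: float, beta: float) -> "OutcomeModel":
        """Calibrate the intercept so the population prevalence equals `prevalence`."""
        return cls(alpha=solve_intercept(prevalence, beta), beta=beta)

    def marginal_prevalence(self) -> float:
        return logistic_normal_mean(self.alpha, self.beta)


# Target day-1 missingness fraction per panel.  Singleton electrolyte/CBC
# panels are near-universal (1.5%-3% missing); multi-test panels sit at 25%
# or higher so that co-ordering, not independent dropout, dominates their
# missingness; liver enzymes, the differential white count, and lactate are
# the need-driven tests missing for well over half the cohort.
DEFAULT_DAY1_MISSINGNESS = {
    "cbc_diff": 0.65,
    "rbc_indices": 0.25,
    "blood_gas": 0.45,
    "liver": 0.70,
    "renal": 0.25,
    "anion": 0.25,
    "coag": 0.35,
    "pH": 0.45,
    "Na": 0.015,
    "K": 0.015,
    "AG": 0.03,
    "BG": 0.03,
    "WBC": 0.03,
    "HGB": 0.025,
    "HCT": 0.025,
    "PLT": 0.03,
    "Lac": 0.75,
    "Ca": 0.10,
    "Mg": 0.12,
    "Phos": 0.25,
}

#: Per-day decrement of the panel-ordering log-odds (ordering grows more
#: selective on days 2 and 3).
DEFAULT_DAY_SHIFT = 0.5


def _default_outcome_models() -> dict[str, OutcomeModel]:
    return {
        "in_hospital": OutcomeModel.from_prevalence(0.11, beta=1.5),
        "day30": OutcomeModel.from_prevalence(0.15, beta=1.5),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-cohort mechanism.

    Attributes
    ----------
    n_patients
        Cohort size before the eligibility filter.
    outcome_models
        Per-outcome logistic models on latent severity.
    day1_missingness
        Target day-1 marginal missingness fraction per panel; the ordering
        baseline gamma(g, d) is solved so the realized marginal matches the
        target given `delta`.
    day_shift
        Per-day decrement of the ordering log-odds target.
    delta
        Severity link of panel ordering (log-odds per severity SD); a scalar
        shared by all panels, or a dict of per-panel overrides (panels not
        named fall back to 0).  All links must be >= 0; all zero means MCAR.
    dropout
        Probability a test is independently missing despite its panel being
        ordered.
    value_mean, value_loading, value_noise
        Gaussian value model per test: value = mean + loading*severity +
        noise*eps.  Scalars broadcast over tests; dicts override per test.
    severity_noise
        SD of the observation noise added to latent severity to form the
        emitted severity score.
    mcar
        True only for configs produced by `mcar_variant` (delta forced to 0).
    """

    n_patients: int = 2000
    outcome_models: dict[str, OutcomeModel] = field(default_factory=_default_outcome_models)
    day1_missingness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DAY1_MISSINGNESS)
    )
    day_shift: float = DEFAULT_DAY_SHIFT
    delta: float | dict[str, float] = 1.0
    dropout: float = 0.01
    value_mean: float | dict[str, float] = 0.0
    value_loading: float | dict[str, float] = 0.15
    value_noise: float | dict[str, float] = 1.0
    severity_noise: float = 0.75
    mcar: bool = False
    days: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        deltas = self.delta.values() if isinstance(self.delta, dict) else [self.delta]
        for dv in deltas:
            if dv < 0:
                raise ValueError(f"delta must be >= 0, got {dv}")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError(f"dropout must be in [0,1], got {self.dropout}")
        for panel, m in self.day1_missingness.items():
            if not 0.0 <= m < 1.0:
                raise ValueError(f"day1_missingness[{panel!r}] must be in [0,1), got {m}")
        for name in self.outcome_models:
            if name not in OUTCOME_NAMES:
                raise ValueError(f"unknown outcome {name!r}; expected {OUTCOME_NAMES}")

    # -- resolved mechanism parameters ------------------------------------

    def ordering_target(self, panel: str, day: int) -> float:
        """Target marginal probability that `panel` is ordered on `day`."""
        m1 = self.day1_missingness[panel]
        return float(expit(logit(1.0 - m1) - self.day_shift * (day - 1)))

    def delta_of(self, panel: str) -> float:
        """Severity link of one panel's ordering model."""
        if isinstance(self.delta, dict):
            return float(self.delta.get(panel, 0.0))
        return float(self.delta)

    def gamma(self, panel: str, day: int) -> float:
        """Ordering log-odds baseline solved against the marginal target."""
        target = self.ordering_target(panel, day)
        d = self.delta_of(panel)
        if d == 0.0:
            return float(logit(target))
        return solve_intercept(target, d)

    def resolve_values(self, schema: LabSchema) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-test (mean, loading, noise) arrays in schema column order."""

        def as_array(v: float | dict[str, float]) -> np.ndarray:
            if isinstance(v, dict):
                return np.array([v.get(t, 0.0) for t in schema.test_names], dtype=float)
            return np.full(schema.n_tests, float(v))

        return (
            as_array(self.value_mean),
            as_array(self.value_loading),
            as_array(self.value_noise),
        )


@dataclass
class CohortDay:
    """One ICU day of a cohort: values with NaN marking absent tests."""

    day: int
    values: pd.DataFrame
    outcomes: pd.DataFrame
    severity_score: pd.Series

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_patients(self) -> int:
        return len(self.values)


@dataclass
class Cohort:
    """A multi-day synthetic cohort plus the latent ground truth behind it."""

    days: list[CohortDay]
    ground_truth: dict

    def __iter__(self):
        return iter(self.days)

    def __getitem__(self, i: int) -> CohortDay:
        return self.days[i]

    def __len__(self) -> int:
        return len(self.days)

    def day(self, d: int) -> CohortDay:
        for cd in self.days:
            if cd.day == d:
                return cd
        raise KeyError(f"no day {d} in cohort (have {[c.day for c in self.days]})")


class DegenerateOrderingError(ValueError):
    """All panels are (almost) never ordered: eligibility cannot be met."""


def generate_cohort(
    schema: LabSchema | None = None,
    sim: SimulationConfig | None = None,
    seed: int = 0,
) -> Cohort:
    """Draw a fully reproducible multi-day synthetic ICU cohort.

    Patients whose day row is entirely absent violate the eligibility rule
    ("at least one data point per day").  For cohorts over 1000 patients the
    violators are dropped (and counted in the ground truth log); smaller
    cohorts redraw violators so small fixtures keep their exact size.
    """
    schema = schema or default_lab_schema()
    sim = sim or SimulationConfig()

    max_order = max(sim.ordering_target(p, max(sim.days)) for p in sim.day1_missingness)
    if max_order < 1e-6:
        raise DegenerateOrderingError(
            "every panel's ordering probability is ~0 (check day1_missingness / "
            "day_shift): no patient can satisfy the eligibility rule"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    n = sim.n_patients
    regenerate = n <= 1000

    severity = rng.standard_normal(n)
    outcome_draws = {name: rng.random(n) for name in OUTCOME_NAMES}

    panels = list(schema.panels)
    mean, loading, noise = sim.resolve_values(schema)
    test_idx = {t: i for i, t in enumerate(schema.test_names)}

    # Presence masks per day, then regenerate/drop eligibility violators.
    def draw_day_presence(day: int, sev: np.ndarray, day_rng: np.random.Generator) -> np.ndarray:
        present = np.zeros((len(sev), schema.n_tests), dtype=bool)
        for panel in panels:
            g = sim.gamma(panel, day)
            p_order = expit(g + sim.delta_of(panel) * sev)
            ordered = day_rng.random(len(sev)) < p_order
            for t in schema.panels[panel]:
                kept = ordered & (day_rng.random(len(sev)) >= sim.dropout)
                present[:, test_idx[t]] = kept
        return present

    day_rngs = {d: np.random.default_rng(np.random.SeedSequence([int(seed), 1, d])) for d in sim.days}
    presence = {d: draw_day_presence(d, severity, day_rngs[d]) for d in sim.days}

    eligible = np.ones(n, dtype=bool)
    for d in sim.days:
        eligible &= presence[d].any(axis=1)

    n_violations = int((~eligible).sum())
    if regenerate and n_violations:
        redraw_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
        for attempt in range(200):
            bad = np.flatnonzero(~eligible)
            if bad.size == 0:
                break
            severity[bad] = redraw_rng.standard_normal(bad.size)
            for name in OUTCOME_NAMES:
                outcome_draws[name][bad] = redraw_rng.random(bad.size)
            for d in sim.days:
                presence[d][bad] = draw_day_presence(d, severity[bad], redraw_rng)
            eligible = np.ones(n, dtype=bool)
            for d in sim.days:
                eligible &= presence[d].any(axis=1)
        else:
            raise DegenerateOrderingError(
                "could not satisfy eligibility after 200 redraw rounds; "
                "ordering probabilities are too close to 0"
            )
        kept = np.arange(n)
    else:
        kept = np.flatnonzero(eligible)
        if kept.size == 0:
            raise DegenerateOrderingError(
                "all patients violate the eligibility rule; ordering "
                "probabilities are too close to 0"
            )
        if n_violations:
            logger.info("dropped %d eligibility-violating patients", n_violations)

    severity = severity[kept]
    patient_ids = pd.Index(kept + 1, name="patient_id")

    outcomes = pd.DataFrame(index=patient_ids)
    for name in OUTCOME_NAMES:
        model = sim.outcome_models[name]
        p = expit(model.alpha + model.beta * severity)
        outcomes[name] = (outcome_draws[name][kept] < p).astype(np.int8)

    sev_obs_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    severity_score = pd.Series(
        severity + sim.severity_noise * sev_obs_rng.standard_normal(len(severity)),
        index=patient_ids,
        name="severity_score",
    )

    days: list[CohortDay] = []
    for d in sim.days:
        val_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4, d]))
        raw = mean + loading * severity[:, None] + noise * val_rng.standard_normal(
            (len(severity), schema.n_tests)
        )
        raw[~presence[d][kept]] = np.nan
        values = pd.DataFrame(raw, index=patient_ids, columns=list(schema.test_names))
        days.append(
            CohortDay(day=d, values=values, outcomes=outcomes, severity_score=severity_score)
        )

    truth = {
        "seed": int(seed),
        "latent_severity": severity.tolist(),
        "patient_ids": patient_ids.tolist(),
        "eligibility_violations": n_violations,
        "eligibility_policy": "regenerated" if regenerate else "dropped",
        "delta": {p: sim.delta_of(p) for p in sim.day1_missingness},
        "dropout": sim.dropout,
        "mcar": sim.mcar,
        "outcome_models": {
            k: {"alpha": m.alpha, "beta": m.beta} for k, m in sim.outcome_models.items()
        },
        "gamma": {
            panel: {int(d): sim.gamma(panel, d) for d in sim.days}
            for panel in sim.day1_missingness
        },
    }
    return Cohort(days=days, ground_truth=truth)


def mcar_variant(sim: SimulationConfig) -> SimulationConfig:
    """MCAR null twin of `sim`: severity link removed, marginal rates kept.

    The ordering baselines are re-solved so each panel's expected ordering
    probability matches the original population average; applying the
    transform twice is a fixed point.
    """
    if sim.mcar and not any(sim.delta_of(p) for p in sim.day1_missingness):
        return sim
    # ordering_target() already is the population-average ordering probability
    # (gamma is solved against it), so the targets carry over unchanged.
    return replace(sim, delta=0.0, mcar=True)


def write_cohort(cohort: Cohort, outdir: str | Path) -> list[Path]:
    """Write per-day value CSVs (absent = empty cell), outcomes, severity,
    and the ground-truth JSON.  Returns the list of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for cd in cohort:
        p = outdir / f"day{cd.day}_values.csv"
        cd.values.to_csv(p)
        written.append(p)
    p = outdir / "outcomes.csv"
    cohort[0].outcomes.to_csv(p)
    written.append(p)
    p = outdir / "severity.csv"
    cohort[0].severity_score.to_frame().to_csv(p)
    written.append(p)
    p = outdir / "ground_truth.json"
    p.write_text(json.dumps(cohort.ground_truth, indent=1))
    written.append(p)
    return written
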