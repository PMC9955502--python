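"""Seeded generator of study-shaped synthetic cohorts.

The real cohort behind the published analysis (adolescents screened for
hyperinsulinemia by oral glucose tolerance testing) is not publicly
available, so this module emulates its printed group structure: an
experimental group with elevated insulinemia and a larger control group,
each with published means +/- SD for BMI, cholesterol, behavioural scores,
binary family-history/substance indicators, and OGTT glucose/insulin
trajectories at 0/30/60/90/120 min.

Continuous variables are drawn from truncated normals, binary factors from
Bernoulli prevalences; a continuous risk target in [0, 1] is attached
either from a known generating network (for parameter-recovery testing) or
from a linear index.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .effects import homa_ir
from .network import FeatureScale, NetworkSpec, forward

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "attach_network_target",
    "ogtt_summary",
    "FACTORS_3",
    "FACTORS_4",
    "FACTORS_6",
    "DEFAULT_TRUE_WEIGHTS",
    "default_spec",
]

# The six modelled risk factors, in fixed report order.
FACTORS_6 = (
    "BMI",
    "cholesterol",
    "physical_activity",
    "nutrition",
    "family_history",
    "psychoactive_substances",
)
FACTORS_3 = FACTORS_6[:3]
FACTORS_4 = FACTORS_6[:4]

# (mean_exp, sd_exp, mean_ctrl, sd_ctrl, lower, upper) per continuous
# variable.  BMI from the published group summaries; cholesterol pooled
# over gender strata; the two behavioural scores are continuous 0-1
# "poor-behaviour" indices whose group means equal the published
# prevalences of poor physical activity / poor nutrition.
CONTINUOUS_DEFAULTS = {
    "BMI": (27.1, 4.3, 22.7, 1.2, 12.0, 45.0),
    "cholesterol": (7.7, 4.8, 6.0, 4.0, 2.0, 15.0),
    "physical_activity": (0.696, 0.15, 0.607, 0.15, 0.0, 1.0),
    "nutrition": (0.580, 0.15, 0.456, 0.15, 0.0, 1.0),
}

# (prevalence_exp, prevalence_ctrl) per binary factor.
BINARY_DEFAULTS = {
    "family_history": (0.491, 0.415),
    "psychoactive_substances": (0.384, 0.348),
}

# OGTT trajectories: (mean_exp, sd_exp, mean_ctrl, sd_ctrl); glucose in
# mmol/L, insulin in uIU/mL, truncated at zero.
OGTT_DEFAULTS = {
    "glucose_0": (7.2, 1.1, 6.3, 0.9),
    "glucose_30": (13.5, 1.3, 11.3, 1.4),
    "glucose_60": (10.7, 1.4, 9.3, 1.2),
    "glucose_90": (9.4, 1.3, 8.2, 1.3),
    "glucose_120": (8.1, 0.7, 7.3, 0.9),
    "insulin_0": (20.3, 3.6, 17.8, 2.4),
    "insulin_30": (162.5, 6.1, 151.2, 7.1),
    "insulin_60": (125.7, 4.5, 117.3, 5.2),
    "insulin_90": (98.3, 2.2, 83.5, 3.7),
    "insulin_120": (83.5, 3.4, 65.3, 2.4),
}

# Generating weights per input count (input-major hidden weights, then
# output weights, then the bias).  Each vector lies on the initial training
# grid ({-1, 1} or {-1, 0, 1}) and coincides with one row of the canonical
# training plan, so a noise-free target is exactly recoverable: the plan
# itself evaluates the generating point.
DEFAULT_TRUE_WEIGHTS = {
    6: np.array([1, -1, 1, 1, -1, 1, -1, -1, 1, -1, 1, 1, -1, 1, -1], dtype=float),
    4: np.array([1, -1, 1, 1, -1, 1, 1, 1, -1, -1, -1], dtype=float),
    3: np.array([-1, 0, 0, 0, 1, 0, 1, 1, -1, 1, -1, -1, 0], dtype=float),
}


def default_spec(n_factors: int) -> NetworkSpec:
    """The published architecture for each input count: 3x3, 4x2, 6x2."""
    hidden = {3: 3, 4: 2, 6: 2}
    if n_factors not in hidden:
        raise ValueError(f"no default architecture for {n_factors} factors")
    return NetworkSpec(n_factors, hidden[n_factors])


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults mirror the published group summaries."""

    n_experimental: int = 224
    n_control: int = 448
    continuous: dict = field(default_factory=lambda: dict(CONTINUOUS_DEFAULTS))
    binary: dict = field(default_factory=lambda: dict(BINARY_DEFAULTS))
    ogtt: dict = field(default_factory=lambda: dict(OGTT_DEFAULTS))
    factors: tuple = FACTORS_6
    target_mode: str = "known-network"  # or "linear-index" or "none"
    true_weights: np.ndarray | None = None
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_experimental < 0 or self.n_control < 0:
            raise ValueError("config error: group sizes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("config error: noise_sd must be >= 0")
        for name, (pe, pc) in self.binary.items():
            if not (0 <= pe <= 1 and 0 <= pc <= 1):
                raise ValueError(f"config error: prevalence of {name} outside [0,1]")
        for name, (me, se, mc, sc, lo, hi) in self.continuous.items():
            if se < 0 or sc < 0 or hi <= lo:
                raise ValueError(f"config error: bad distribution for {name}")


@dataclass
class Cohort:
    """Per-subject factor table with coded features and a risk target."""

    data: pd.DataFrame          # raw values incl. subject_id and group
    factors: tuple              # factor column names, model input order
    scales: list                # FeatureScale per factor
    coded: np.ndarray           # (n, m) coded factor matrix in [0,1]
    target: np.ndarray | None = None
    spec: NetworkSpec | None = None
    true_weights: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def subset_factors(self, factors) -> "Cohort":
        """View of the cohort restricted to a factor subset (model inputs)."""
        idx = [self.factors.index(f) for f in factors]
        return Cohort(
            data=self.data,
            factors=tuple(factors),
            scales=[self.scales[i] for i in idx],
            coded=self.coded[:, idx],
            target=self.target,
            spec=None,
            true_weights=None,
        )

    def to_csv(self, path_or_buf=None):
        df = self.data.copy()
        for i, f in enumerate(self.factors):
            df[f"coded_{f}"] = self.coded[:, i]
        if self.target is not None:
            df["risk_target"] = self.target
        return df.to_csv(path_or_buf, index=False)


def _truncnorm(rng, mean, sd, lo, hi, n):
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _scales_from_data(df, factors, config) -> list:
    scales = []
    for f in factors:
        lo, hi = float(df[f].min()), float(df[f].max())
        if hi <= lo:  # degenerate observed range: fall back to config bounds
            if f in config.continuous:
                lo, hi = config.continuous[f][4], config.continuous[f][5]
            else:
                lo, hi = 0.0, 1.0
        scales.append(FeatureScale(f, lo, hi))
    return scales


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw a two-group synthetic cohort; reproducible given the seed.

    Continuous variables are truncated normals with the configured group
    means/SDs; binary factors are Bernoulli.  Feature scales (min/max) are
    computed from the generated raw data.  If ``config.target_mode`` is not
    ``"none"`` a risk target is attached (see :func:`attach_network_target`).
    """
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    frames = []
    for group, n in (("experimental", config.n_experimental),
                     ("control", config.n_control)):
        cols = {"group": [group] * n}
        for name, (me, se, mc, sc, lo, hi) in config.continuous.items():
            mean, sd = (me, se) if group == "experimental" else (mc, sc)
            cols[name] = _truncnorm(rng, mean, sd, lo, hi, n)
        for name, (pe, pc) in config.binary.items():
            p = pe if group == "experimental" else pc
            cols[name] = (rng.random(n) < p).astype(float)
        for name, (me, se, mc, sc) in config.ogtt.items():
            mean, sd = (me, se) if group == "experimental" else (mc, sc)
            cols[name] = _truncnorm(rng, mean, sd, 0.0, np.inf, n)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id", np.arange(1, len(df) + 1))
    if {"glucose_0", "insulin_0"} <= set(df.columns) and len(df):
        df["HOMA_IR"] = homa_ir(df["glucose_0"].values, df["insulin_0"].values)

    factors = tuple(config.factors)
    if len(df) == 0:
        scales = [FeatureScale(f, 0.0, 1.0) for f in factors]
        coded = np.empty((0, len(factors)))
        return Cohort(df, factors, scales, coded)

    scales = _scales_from_data(df, factors, config)
    coded = np.column_stack(
        [
            (df[f].values - s.x_min) / (s.x_max - s.x_min)
            for f, s in zip(factors, scales)
        ]
    )
    cohort = Cohort(df, factors, scales, coded)

    if config.target_mode == "known-network":
        m = len(factors)
        w = (
            np.asarray(config.true_weights, dtype=float)
            if config.true_weights is not None
            else DEFAULT_TRUE_WEIGHTS[m]
        )
        cohort = attach_network_target(
            cohort, default_spec(m), w, config.noise_sd, rng=rng
        )
    elif config.target_mode == "linear-index":
        coefs = np.linspace(1.0, 0.3, len(factors))
        index = coded @ coefs / coefs.sum()
        noise = rng.normal(0.0, config.noise_sd, len(df))
        cohort.target = np.clip(index + noise, 0.0, 1.0)
    elif config.target_mode != "none":
        raise ValueError(f"config error: unknown target mode {config.target_mode!r}")
    return cohort


def attach_network_target(
    cohort: Cohort,
    spec: NetworkSpec,
    true_weights,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Attach a ground-truth network target: forward pass + Gaussian noise.

    The generating weights are stored on the cohort so recovery tests can
    compare trained effects against the truth.
    """
    w = np.asarray(true_weights, dtype=float)
    if spec.n_inputs != cohort.coded.shape[1]:
        raise ValueError("shape error: spec inputs != cohort factor count")
    if w.shape != (spec.n_weights,):
        raise ValueError("shape error: wrong weight count")
    clean = forward(spec, w, cohort.coded)
    clean = np.atleast_1d(clean)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd, clean.size)
    cohort.target = np.clip(clean, 0.0, 1.0)
    cohort.spec = spec
    cohort.true_weights = w
    return cohort


_OGTT_ROWS = [
    ("Glucose in 0 min (mmol/L)", "glucose_0"),
    ("Glucose in 30 min (mmol/L)", "glucose_30"),
    ("Glucose in 60 min (mmol/L)", "glucose_60"),
    ("Glucose in 90 min (mmol/L)", "glucose_90"),
    ("Glucose in 120 min (mmol/L)", "glucose_120"),
    ("Insulin in 0 min (uIU/mL)", "insulin_0"),
    ("Insulin in 30 min (uIU/mL)", "insulin_30"),
    ("Insulin in 60 min (uIU/mL)", "insulin_60"),
    ("Insulin in 90 min (uIU/mL)", "insulin_90"),
    ("Insulin in 120 min (uIU/mL)", "insulin_120"),
    ("HOMA-IR", "HOMA_IR"),
]


def ogtt_summary(cohort: Cohort) -> pd.DataFrame:
    """Group-stratified mean +/- SD of the OGTT variables and HOMA-IR.

    Returns an 11-row frame (5 glucose + 5 insulin timepoints + HOMA-IR)
    with experimental/control mean and SD columns.
    """
    df = cohort.data
    missing = [c for _, c in _OGTT_ROWS if c not in df.columns]
    if missing:
        raise ValueError(f"not generated: missing OGTT variables {missing}")
    rows = []
    for label, col in _OGTT_ROWS:
        row = {"variable": label}
        for group in ("experimental", "control"):
            vals = df.loc[df["group"] == group, col]
            row[f"{group}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{group}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
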