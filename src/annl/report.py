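"""Pipeline orchestration and the multi-model risk-share comparison.

``run_pipeline`` chains simulate -> train -> effects -> baselines and
writes all artifacts (model JSON, training log CSV, comparison CSV/JSON).
Baselines are standard scikit-learn learners scored by seeded permutation
importance; their per-factor shares are normalized exactly like the
network's ablation shares so the columns are comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import factor_effect, risk_shares
from .network import save_model
from .synthetic import Cohort, CohortConfig, default_spec, generate_cohort
from .training import TrainingConfig, train

logger = logging.getLogger("annl")

__all__ = ["RunConfig", "ComparisonTable", "baseline_shares", "run_pipeline"]

_BASELINES = ("naive_bayes", "decision_tree", "random_forest")

_ARCH = {"L27": 3, "L12": 4, "L16": 6}


@dataclass(frozen=True)
class RunConfig:
    """Settings of the full comparison pipeline."""

    outdir: str = "annl_out"
    cohort_csv: str | None = None   # None -> simulate
    architectures: tuple = ("L16",)
    baselines: tuple = _BASELINES
    other_share: float = 6.7
    tolerance: float = 0.01
    max_iter: int = 10
    n_experimental: int = 224
    n_control: int = 448
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        bad = [b for b in self.baselines if b not in _BASELINES]
        if bad:
            raise ValueError(f"unknown baselines: {bad}")
        bad = [a for a in self.architectures if a not in _ARCH]
        if bad:
            raise ValueError(f"unknown architectures: {bad}")


@dataclass
class ComparisonTable:
    """Per-model factor shares (%) plus an MMRE (%) row."""

    frame: pd.DataFrame  # index: factor rows + "Other factors" + "MMRE"

    def validate(self) -> None:
        shares = self.frame.drop(index="MMRE", errors="ignore")
        sums = shares.sum(axis=0)
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError(f"model columns must sum to 100, got {sums.to_dict()}")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="Risk Factors")

    @classmethod
    def from_csv(cls, path) -> "ComparisonTable":
        t = cls(pd.read_csv(path, index_col="Risk Factors"))
        t.validate()
        return t


@dataclass(frozen=True)
class BaselineShares:
    """Normalized permutation-importance shares of one baseline learner."""

    kind: str
    factors: tuple
    shares: tuple
    other_share: float
    mmre: float
    stable: bool  # False when there is essentially no importance signal


def _fit_baseline(kind: str, X, y, seed: int):
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.naive_bayes import GaussianNB
    from sklearn.tree import DecisionTreeRegressor

    if kind == "naive_bayes":
        # GaussianNB is a classifier; the continuous risk target is
        # binarized at its median for the fit.
        yb = (y > np.median(y)).astype(int)
        if yb.min() == yb.max():
            raise ValueError("baseline unfit: target is constant")
        model = GaussianNB().fit(X, yb)
        return model, yb
    if kind == "decision_tree":
        model = DecisionTreeRegressor(random_state=seed).fit(X, y)
        return model, y
    if kind == "random_forest":
        model = RandomForestRegressor(random_state=seed).fit(X, y)
        return model, y
    raise ValueError(f"unknown baseline {kind!r}")


def baseline_shares(
    cohort: Cohort, kind: str, seed: int = 0, other_share: float = 6.7
) -> BaselineShares:
    """Per-factor shares of one standard learner via permutation importance.

    The learner is fitted to (coded factors -> target); permutation
    importance (20 shuffles) is normalized to ``100 - other_share`` like
    the network's ablation shares.
    """
    from sklearn.inspection import permutation_importance

    if cohort.target is None:
        raise ValueError("baseline unfit: cohort has no target")
    y = np.asarray(cohort.target, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("baseline unfit: target is constant")
    X = cohort.coded
    model, y_fit = _fit_baseline(kind, X, y, seed)
    res = permutation_importance(model, X, y_fit, n_repeats=20, random_state=seed)
    mags = np.abs(res.importances_mean)
    # a factor is informative when its mean importance clears twice the
    # spread across shuffles; with none, the shares are flagged unstable
    stable = bool(np.any(res.importances_mean > 2.0 * res.importances_std))
    if mags.sum() == 0:
        mags = np.ones_like(mags)  # no signal at all: uniform, flagged
    shares = mags / mags.sum() * (100.0 - other_share)
    from .effects import mre

    # score each learner against the continuous risk target; the NB
    # classifier predicts through its class-1 probability
    if kind == "naive_bayes":
        pred = model.predict_proba(X)[:, 1]
    else:
        pred = model.predict(X)
    return BaselineShares(
        kind=kind,
        factors=cohort.factors,
        shares=tuple(float(s) for s in shares),
        other_share=float(other_share),
        mmre=mre(y, pred),
        stable=stable,
    )


def run_pipeline(config: RunConfig) -> ComparisonTable:
    """Execute the full pipeline and write artifacts under ``config.outdir``.

    Stages: simulate (unless a cohort CSV is given) -> train one network per
    requested architecture -> ablation effects and risk shares -> baseline
    learners -> comparison table.  Deterministic given the seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage=%s seed=%d outdir=%s", name, config.seed, outdir)

    if config.cohort_csv is None:
        stage("simulate")
        cohort = generate_cohort(
            CohortConfig(
                n_experimental=config.n_experimental,
                n_control=config.n_control,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
        )
        cohort.to_csv(outdir / "cohort.csv")
    else:
        stage("load-cohort")
        cohort = load_cohort_csv(config.cohort_csv)

    columns = {}
    for arch in config.architectures:
        stage(f"train-{arch}")
        m = _ARCH[arch]
        sub = cohort.subset_factors(cohort.factors[:m])
        spec = default_spec(m)
        state = train(
            sub,
            TrainingConfig(
                spec=spec,
                array=arch,
                tolerance=config.tolerance,
                max_iter=config.max_iter,
                seed=config.seed,
            ),
        )
        save_model(outdir / f"model_{arch}.json", spec, state.best_weights, sub.scales)
        log = pd.DataFrame(
            {
                "iteration": np.arange(1, len(state.mmre_history) + 1),
                "mmre": state.mmre_history,
                "ga": [np.nan]
                + [
                    state.mmre_history[i - 1] - state.mmre_history[i]
                    for i in range(1, len(state.mmre_history))
                ],
                "delta": [np.nan] + state.delta_history,
            }
        )
        log.to_csv(outdir / f"training_log_{arch}.csv", index=False)

        effects = [
            factor_effect(spec, state.best_weights, sub.coded, j, name=f)
            for j, f in enumerate(sub.factors)
        ]
        report = risk_shares(
            effects,
            other_share=config.other_share,
            mmre_value=state.mmre_history[-1],
            model=f"ANN-{arch}",
        )
        col = {f: s for f, s in zip(report.factors, report.shares)}
        col["Other factors"] = report.other_share
        col["MMRE"] = state.mmre_history[-1] * 100
        columns[f"ANN-{arch}"] = col

    for kind in config.baselines:
        stage(f"baseline-{kind}")
        bs = baseline_shares(
            cohort, kind, seed=config.seed, other_share=config.other_share
        )
        col = {f: s for f, s in zip(bs.factors, bs.shares)}
        col["Other factors"] = bs.other_share
        col["MMRE"] = bs.mmre * 100
        columns[kind] = col

    row_order = list(cohort.factors) + ["Other factors", "MMRE"]
    frame = pd.DataFrame(columns).reindex(row_order).fillna(0.0)
    table = ComparisonTable(frame)
    table.validate()
    stage("write-comparison")
    table.to_csv(outdir / "comparison.csv")
    with open(outdir / "comparison.json", "w") as fh:
        json.dump(frame.to_dict(), fh, indent=2)
    return table


def load_cohort_csv(path) -> Cohort:
    """Rebuild a Cohort from the CSV written by :meth:`Cohort.to_csv`."""
    from .network import FeatureScale

    df = pd.read_csv(path)
    factors = tuple(
        c[len("coded_"):] for c in df.columns if c.startswith("coded_")
    )
    coded = df[[f"coded_{f}" for f in factors]].to_numpy(dtype=float)
    scales = [
        FeatureScale(f, float(df[f].min()), float(df[f].max())) for f in factors
    ]
    target = df["risk_target"].to_numpy(dtype=float) if "risk_target" in df else None
    raw = df[[c for c in df.columns if not c.startswith("coded_") and c != "risk_target"]]
    return Cohort(raw, factors, scales, coded, target)
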