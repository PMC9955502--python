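"""Error metrics, factor-effect ablation, risk shares, correlations, HOMA-IR.

The magnitude-of-relative-error metrics (MRE per cohort, MMRE as the mean
of MREs) score the network; factor effects are ablation differences in the
mean output when one coded input is forced to zero; risk shares normalize
the absolute effects to percentage points of attributable risk, leaving a
configurable residual for unmodelled factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import NetworkSpec, forward

__all__ = [
    "EPS",
    "relative_error",
    "mre",
    "mmre",
    "factor_effect",
    "EffectEstimate",
    "RiskShareReport",
    "risk_shares",
    "homa_ir",
    "pearson",
    "spearman",
]

#: Guard for relative error when the actual value is ~0.
EPS = 1e-8


def relative_error(actual, estimate):
    """Per-subject magnitude of relative error |a - e| / max(|a|, EPS)."""
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimate, dtype=float)
    err = np.abs(a - e) / np.maximum(np.abs(a), EPS)
    return float(err) if err.ndim == 0 else err


def mre(actual, estimate) -> float:
    """Mean relative error over one cohort (a fraction, not a percent)."""
    return float(np.mean(relative_error(actual, estimate)))


def mmre(per_group_mres) -> float:
    """Mean of MREs over groups/runs."""
    vals = np.asarray(list(per_group_mres), dtype=float)
    if vals.size == 0:
        raise ValueError("no groups")
    return float(vals.mean())


@dataclass(frozen=True)
class EffectEstimate:
    """Signed mean-output change when one coded factor is ablated to zero."""

    factor: str
    delta: float


def factor_effect(
    spec: NetworkSpec, weights, coded: np.ndarray, j: int, name: str | None = None
) -> EffectEstimate:
    """Ablation effect of coded factor ``j`` (0-based column of ``coded``).

    delta_j = mean output with all factors active
              - mean output with coded factor j forced to 0.
    """
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    if not 0 <= j < coded.shape[1]:
        raise ValueError(f"unknown factor index {j}")
    base = np.mean(forward(spec, weights, coded))
    ablated = coded.copy()
    ablated[:, j] = 0.0
    abl = np.mean(forward(spec, weights, ablated))
    return EffectEstimate(factor=name or f"X{j + 1}", delta=float(base - abl))


@dataclass(frozen=True)
class RiskShareReport:
    """Per-factor percentage shares plus the residual 'other factors' row."""

    factors: tuple
    shares: tuple          # percentages, same order as factors
    other_share: float
    mmre: float | None = None
    model: str = "ANN-L"

    def to_frame(self) -> pd.DataFrame:
        rows = list(zip(self.factors, self.shares)) + [
            ("Other factors", self.other_share)
        ]
        df = pd.DataFrame(rows, columns=["factor", f"share_{self.model}"])
        if self.mmre is not None:
            df.loc[len(df)] = ["MMRE", self.mmre * 100]
        return df

    def rounded(self, ndigits: int = 1):
        """Presentation view: shares rounded to 1 decimal."""
        return {f: round(s, ndigits) for f, s in zip(self.factors, self.shares)}


def risk_shares(
    effects, other_share: float = 6.7, mmre_value: float | None = None,
    model: str = "ANN-L",
) -> RiskShareReport:
    """Normalize |delta| effects to percentages of (100 - other_share).

    ``other_share`` is the residual percentage attributed to factors not in
    the model; it is an input, not an estimate.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("no effects")
    if not 0 <= other_share < 100:
        raise ValueError("other_share must be in [0, 100)")
    mags = np.array([abs(e.delta) for e in effects])
    total = mags.sum()
    if total == 0:
        raise ValueError("no attributable risk: all effects are zero")
    shares = mags / total * (100.0 - other_share)
    return RiskShareReport(
        factors=tuple(e.factor for e in effects),
        shares=tuple(float(s) for s in shares),
        other_share=float(other_share),
        mmre=mmre_value,
        model=model,
    )


def homa_ir(glucose0, insulin0):
    """Homeostatic model assessment of insulin resistance.

    fasting glucose (mmol/L) x fasting insulin (uIU/mL) / 22.5.
    """
    g = np.asarray(glucose0, dtype=float)
    i = np.asarray(insulin0, dtype=float)
    if np.any(g < 0) or np.any(i < 0):
        raise ValueError("invalid measurement: negative glucose or insulin")
    out = g * i / 22.5
    return float(out) if out.ndim == 0 else out


def _check_corr_args(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation."""
    x, y = _check_corr_args(x, y)
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Rank correlation."""
    x, y = _check_corr_args(x, y)
    return float(stats.spearmanr(x, y).statistic)
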