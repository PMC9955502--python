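"""Derivative-free network training over an orthogonal experiment plan.

Each training iteration evaluates every run of the plan (one candidate
level per weight), accumulates a per-(weight, level) cost-effect table from
the run costs, keeps the per-weight level with the lowest accumulated cost,
and then halves every weight's candidate interval around its best level
while rejecting the worst one.  Iterations stop when the improvement in the
mean magnitude of relative error (MMRE) falls below the tolerance.

No gradients are used anywhere: the search is a sequence of fractional
factorial experiments on a shrinking grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import doe
from .effects import mre, relative_error
from .network import NetworkSpec, forward, risk_score

__all__ = [
    "LevelGrid",
    "CostTable",
    "TrainingConfig",
    "TrainingState",
    "initial_grid",
    "materialize_weights",
    "run_cost",
    "cost_effect_table",
    "select_best_levels",
    "halve_grid",
    "ga_criterion",
    "delta_step",
    "train",
]


@dataclass(frozen=True)
class LevelGrid:
    """Per-weight candidate interval and its level values.

    3-level grids test {lo, mid, hi}; 2-level grids test {lo, hi}.
    ``iteration`` counts halvings performed (0 = initial grid).
    """

    lo: np.ndarray
    hi: np.ndarray
    n_levels: int
    iteration: int = 0

    def __post_init__(self):
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lo/hi must be equal-length vectors")
        if np.any(hi <= lo):
            raise ValueError("each interval needs hi > lo")
        if self.n_levels not in (2, 3):
            raise ValueError("only 2- or 3-level grids are supported")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def n_weights(self) -> int:
        return self.lo.size

    @property
    def values(self) -> np.ndarray:
        """(P, L) matrix of level values per weight."""
        if self.n_levels == 2:
            return np.column_stack([self.lo, self.hi])
        mid = (self.lo + self.hi) / 2.0
        return np.column_stack([self.lo, mid, self.hi])

    @property
    def width(self) -> np.ndarray:
        return self.hi - self.lo


def initial_grid(n_weights: int, n_levels: int, interval=(-1.0, 1.0)) -> LevelGrid:
    """The iteration-0 grid: every weight on the same interval."""
    lo, hi = float(interval[0]), float(interval[1])
    return LevelGrid(
        lo=np.full(n_weights, lo), hi=np.full(n_weights, hi), n_levels=n_levels
    )


@dataclass(frozen=True)
class CostTable:
    """Accumulated run costs per (weight, level): ``cost[w, l-1]``."""

    cost: np.ndarray  # (P, L)

    @property
    def n_weights(self) -> int:
        return self.cost.shape[0]

    @property
    def n_levels(self) -> int:
        return self.cost.shape[1]


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the orthogonal-plan training loop.

    ``array`` names the plan; ``source`` selects the canonical construction
    (default) or the verbatim printed table.  ``tolerance`` is the absolute
    MMRE-improvement threshold of the stopping rule, on the fraction scale.
    """

    spec: NetworkSpec
    array: str = "L16"
    source: str = "canonical"
    tolerance: float = 0.01
    max_iter: int = 10
    initial_interval: tuple = (-1.0, 1.0)
    seed: int | None = None

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def load_array(self) -> doe.OrthogonalArray:
        if self.source == "printed":
            return doe.load_printed_array(self.array)
        return doe.canonical_like(doe.load_printed_array(self.array))


@dataclass
class TrainingState:
    """Full trace of one training run."""

    iteration: int
    grid: LevelGrid
    best_levels: np.ndarray
    best_weights: np.ndarray
    mmre_history: list = field(default_factory=list)
    delta_history: list = field(default_factory=list)
    risk_history: list = field(default_factory=list)
    ga: float = float("nan")
    converged: bool = False


def materialize_weights(row, grid: LevelGrid) -> np.ndarray:
    """Weight vector for one plan row: each weight at its prescribed level."""
    row = np.asarray(row, dtype=int)
    if row.size != grid.n_weights:
        raise ValueError("plan/grid mismatch: row length != weight count")
    if row.min() < 1 or row.max() > grid.n_levels:
        raise ValueError("plan/grid mismatch: level index out of range")
    return grid.values[np.arange(grid.n_weights), row - 1]


def run_cost(target, estimates) -> float:
    """Cost of one run: sum over subjects of the relative error."""
    return float(np.sum(relative_error(target, estimates)))


def cost_effect_table(oa: doe.OrthogonalArray, run_costs) -> CostTable:
    """Accumulate run costs into the per-(weight, level) marginal table.

    ``cost[w, l]`` sums the costs of exactly those runs whose plan row holds
    weight ``w`` at level ``l``; memberships come from the plan matrix.
    """
    run_costs = np.asarray(run_costs, dtype=float)
    if run_costs.shape != (oa.n_runs,):
        raise ValueError(f"expected {oa.n_runs} run costs")
    cost = np.zeros((oa.n_factors, oa.n_levels))
    for l in range(1, oa.n_levels + 1):
        mask = oa.plan == l  # (R, P)
        cost[:, l - 1] = mask.T @ run_costs
    return CostTable(cost=cost)


def select_best_levels(table: CostTable):
    """Per-weight argmin (best) and argmax (worst) level, 1-based.

    Ties break toward the lowest level index.
    """
    best = np.argmin(table.cost, axis=1) + 1
    worst = np.argmax(table.cost, axis=1) + 1
    return best, worst


def halve_grid(grid: LevelGrid, best_levels, worst_levels) -> LevelGrid:
    """Shrink every weight's interval to half width around its best level.

    The new interval is centered on the best level's value, has half the
    old width, and is translated (not clipped) back inside the old interval
    when it would overhang an endpoint.  When the worst level's value would
    still fall inside the new interval (only possible for a 3-level grid
    with the best level at an endpoint and the worst at mid), the offending
    endpoint is pulled to the midpoint between best and worst so the worst
    value is excluded.
    """
    best = np.asarray(best_levels, dtype=int)
    worst = np.asarray(worst_levels, dtype=int)
    vals = grid.values
    idx = np.arange(grid.n_weights)
    best_val = vals[idx, best - 1]
    worst_val = vals[idx, worst - 1]
    half = grid.width / 2.0

    lo_new = best_val - half / 2.0
    hi_new = best_val + half / 2.0
    # translate into the old interval, preserving the halved width
    shift = np.maximum(grid.lo - lo_new, 0.0) - np.maximum(hi_new - grid.hi, 0.0)
    lo_new += shift
    hi_new += shift
    # exclude the worst level's value where it survived at an endpoint
    clash = (best != worst) & (lo_new <= worst_val) & (worst_val <= hi_new)
    pull_hi = clash & (worst_val > best_val)
    pull_lo = clash & (worst_val < best_val)
    hi_new[pull_hi] = (best_val[pull_hi] + worst_val[pull_hi]) / 2.0
    lo_new[pull_lo] = (best_val[pull_lo] + worst_val[pull_lo]) / 2.0
    return LevelGrid(
        lo=lo_new, hi=hi_new, n_levels=grid.n_levels, iteration=grid.iteration + 1
    )


def ga_criterion(mmre_prev: float, mmre_curr: float, tol: float) -> bool:
    """Stop when the iteration improved MMRE by less than ``tol`` (absolute)."""
    return (mmre_prev - mmre_curr) < tol


def delta_step(risk_k: float, risk_prev: float, m: int) -> float:
    """Per-factor mean-risk step between iterations: (risk_k - risk_prev)/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return (risk_k - risk_prev) / m


def train(cohort, config: TrainingConfig) -> TrainingState:
    """Run the full orthogonal-plan training loop on a coded cohort.

    Parameters
    ----------
    cohort
        Anything with ``coded`` (n x m matrix in [0,1]) and ``target``
        (length-n vector in [0,1]) attributes, or a ``(coded, target)``
        tuple.
    config : TrainingConfig

    Returns
    -------
    TrainingState
        With the incumbent-best weight vector, the non-increasing MMRE
        history, the per-iteration risk deltas, and the convergence flag.
    """
    if isinstance(cohort, tuple):
        coded, target = cohort
    else:
        coded, target = cohort.coded, cohort.target
    coded = np.asarray(coded, dtype=float)
    target = np.asarray(target, dtype=float)
    if coded.ndim != 2 or coded.shape[0] != target.size or target.size == 0:
        raise ValueError("cohort must supply a coded matrix and matching targets")
    spec = config.spec
    if coded.shape[1] != spec.n_inputs:
        raise ValueError("plan incompatible with network: wrong input count")
    oa = config.load_array()
    if oa.n_factors != spec.n_weights:
        raise ValueError(
            "plan incompatible with network: "
            f"{oa.n_factors} plan columns vs {spec.n_weights} weights"
        )

    grid = initial_grid(spec.n_weights, oa.n_levels, config.initial_interval)
    best_weights = None
    best_mmre = np.inf
    mmre_history: list[float] = []
    delta_history: list[float] = []
    risk_history: list[float] = []
    ga = float("nan")
    converged = False
    best_levels = np.ones(spec.n_weights, dtype=int)

    for k in range(1, config.max_iter + 1):
        run_costs = np.empty(oa.n_runs)
        run_weights = np.empty((oa.n_runs, spec.n_weights))
        for r in range(oa.n_runs):
            run_weights[r] = materialize_weights(oa.plan[r], grid)
            run_costs[r] = run_cost(target, forward(spec, run_weights[r], coded))
        table = cost_effect_table(oa, run_costs)
        best_levels, worst_levels = select_best_levels(table)

        # Incumbent retention over every candidate evaluated this iteration:
        # each plan row is itself a full weight vector, so the best run
        # competes with the marginal best-levels network.
        best_run = int(np.argmin(run_costs))
        run_mmre = run_costs[best_run] / target.size
        if run_mmre < best_mmre:
            best_mmre = run_mmre
            best_weights = run_weights[best_run]
        cand_w = materialize_weights(best_levels, grid)
        cand_mmre = mre(target, forward(spec, cand_w, coded))
        if cand_mmre < best_mmre:
            best_mmre = cand_mmre
            best_weights = cand_w
        mmre_history.append(best_mmre)

        risk = risk_score(forward(spec, best_weights, coded))
        if risk_history:
            delta_history.append(delta_step(risk, risk_history[-1], spec.n_inputs))
        risk_history.append(risk)

        if k >= 2:
            ga = mmre_history[-2] - mmre_history[-1]
            if ga_criterion(mmre_history[-2], mmre_history[-1], config.tolerance):
                converged = True
                break
        grid = halve_grid(grid, best_levels, worst_levels)

    return TrainingState(
        iteration=len(mmre_history),
        grid=grid,
        best_levels=best_levels,
        best_weights=best_weights,
        mmre_history=mmre_history,
        delta_history=delta_history,
        risk_history=risk_history,
        ga=ga,
        converged=converged or len(mmre_history) >= config.max_iter,
    )
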