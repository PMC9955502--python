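"""Orthogonal experiment plans (Taguchi-style fractional factorials).

The training loop evaluates a small orthogonal array instead of the full
factorial grid of weight levels: an L27 plan screens 13 three-level factors
in 27 runs, an L12 (Plackett-Burman) screens 11 two-level factors in 12
runs, and an L16 screens 15 two-level factors in 16 runs.

Two sources are available for each plan.  ``printed`` plans are transcribed
cell-for-cell from the published tables (kept verbatim for fidelity, even
where rows deviate from strength-2 balance); ``canonical`` plans are
constructed algebraically and always pass the strength-2 balance check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "OrthogonalArray",
    "load_printed_array",
    "canonical_array",
    "balance_report",
    "full_factorial_count",
    "reduction_fraction",
]

_PRINTED = {"L27": (27, 13, 3), "L12": (12, 11, 2), "L16": (16, 15, 2)}


@dataclass(frozen=True)
class OrthogonalArray:
    """A runs x factors plan of 1-based level indices.

    Attributes
    ----------
    name : str
        Plan identifier, e.g. ``"L27"``.
    n_runs : int
        Number of runs R (rows).
    n_factors : int
        Number of factors P (columns).
    n_levels : int
        Number of levels L per factor.
    plan : numpy.ndarray
        Integer matrix of shape (R, P) with entries in ``1..L``.
    source : str
        ``"printed"`` (verbatim from the published tables) or
        ``"canonical"`` (algebraic construction).
    run_labels : tuple of str
        Row labels in run order (``ANN1`` ... ``ANNR``).
    """

    name: str
    n_runs: int
    n_factors: int
    n_levels: int
    plan: np.ndarray
    source: str
    run_labels: tuple = field(default=())

    def __post_init__(self):
        plan = np.asarray(self.plan, dtype=int)
        if plan.shape != (self.n_runs, self.n_factors):
            raise ValueError(
                f"plan shape {plan.shape} != ({self.n_runs}, {self.n_factors})"
            )
        if plan.min() < 1 or plan.max() > self.n_levels:
            raise ValueError(f"plan entries must lie in [1, {self.n_levels}]")
        if self.n_runs > self.n_levels**self.n_factors:
            raise ValueError("more runs than full-factorial combinations")
        object.__setattr__(self, "plan", plan)
        if not self.run_labels:
            object.__setattr__(
                self,
                "run_labels",
                tuple(f"ANN{i + 1}" for i in range(self.n_runs)),
            )

    def __eq__(self, other):
        if not isinstance(other, OrthogonalArray):
            return NotImplemented
        return (
            self.name == other.name
            and self.source == other.source
            and np.array_equal(self.plan, other.plan)
        )


def load_printed_array(name: str) -> OrthogonalArray:
    """Load a plan transcribed verbatim from the published tables.

    Parameters
    ----------
    name : {"L27", "L12", "L16"}

    Returns
    -------
    OrthogonalArray
        With ``source="printed"``.
    """
    if name not in _PRINTED:
        raise ValueError(f"no such printed plan: {name!r}")
    n_runs, n_factors, n_levels = _PRINTED[name]
    with resources.files("annl.data").joinpath(f"{name}.csv").open() as fh:
        df = pd.read_csv(fh)
    plan = df.iloc[:, 1:].to_numpy(dtype=int)
    return OrthogonalArray(
        name=name,
        n_runs=n_runs,
        n_factors=n_factors,
        n_levels=n_levels,
        plan=plan,
        source="printed",
        run_labels=tuple(df.iloc[:, 0]),
    )


def _pb12(n_factors: int) -> np.ndarray:
    # Plackett-Burman 12-run design: 11 cyclic shifts of the generator row
    # plus an all-low row; levels coded 1/2.
    gen = np.array([2, 2, 1, 2, 2, 2, 1, 1, 1, 2, 1])
    rows = [np.roll(gen, i) for i in range(11)]
    rows.append(np.ones(11, dtype=int))
    return np.array(rows)[:, :n_factors]


def _l16(n_factors: int) -> np.ndarray:
    # Regular 2^(15-11) fraction: 4 basic bits, one column per nonzero mask.
    runs = np.array(list(itertools.product((0, 1), repeat=4)))
    cols = []
    for mask in range(1, 16):
        bits = [(mask >> b) & 1 for b in range(4)]
        cols.append(runs @ np.array(bits) % 2)
    return np.column_stack(cols)[:, :n_factors] + 1


def _l27(n_factors: int) -> np.ndarray:
    # Regular 3^(13-10) fraction over GF(3): 3 basic trits, one column per
    # representative of each of the 13 lines through the origin.
    runs = np.array(list(itertools.product((0, 1, 2), repeat=3)))
    lines = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, 2, 0), (1, 0, 1), (1, 0, 2),
        (0, 1, 1), (0, 1, 2),
        (1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2),
    ]
    cols = [runs @ np.array(c) % 3 for c in lines]
    return np.column_stack(cols)[:, :n_factors] + 1


def canonical_array(
    levels: int, factors: int, full_factorial: bool = False
) -> OrthogonalArray:
    """Construct a balanced (strength-2) array for the supported shapes.

    Supported: ``(2, <=11)`` -> 12 runs, ``(2, <=15)`` -> 16 runs,
    ``(3, <=13)`` -> 27 runs, and full factorials for ``factors <= 4``.
    Two-level requests with at most 11 factors resolve to the 12-run
    Plackett-Burman plan; 12-15 factors resolve to the 16-run plan.

    Parameters
    ----------
    levels, factors : int
        Number of levels per factor and number of factors.
    full_factorial : bool
        Enumerate all ``levels**factors`` combinations instead (factors <= 4).
    """
    if full_factorial:
        if factors > 4:
            raise ValueError("no canonical construction: full factorial limited to <=4 factors")
        plan = (
            np.array(list(itertools.product(range(levels), repeat=factors)))
            .reshape(levels**factors, factors)
            + 1
        )
        return OrthogonalArray(
            name=f"FF{levels}^{factors}",
            n_runs=levels**factors,
            n_factors=factors,
            n_levels=levels,
            plan=plan,
            source="canonical",
        )
    if levels == 2 and 1 <= factors <= 11:
        if factors == 1:
            plan = np.array([[1], [2]])
            return OrthogonalArray("FF2^1", 2, 1, 2, plan, "canonical")
        plan = _pb12(factors)
        return OrthogonalArray("L12", 12, factors, 2, plan, "canonical")
    if levels == 2 and factors <= 15:
        return OrthogonalArray("L16", 16, factors, 2, _l16(factors), "canonical")
    if levels == 3 and 1 <= factors <= 13:
        return OrthogonalArray("L27", 27, factors, 3, _l27(factors), "canonical")
    raise ValueError(f"no canonical construction for ({levels}, {factors})")


def canonical_like(oa: OrthogonalArray) -> OrthogonalArray:
    """The canonical plan with the same run/factor/level counts as ``oa``."""
    if oa.name == "L12":
        return OrthogonalArray(
            "L12", 12, oa.n_factors, 2, _pb12(oa.n_factors), "canonical"
        )
    if oa.name == "L16":
        return OrthogonalArray(
            "L16", 16, oa.n_factors, 2, _l16(oa.n_factors), "canonical"
        )
    if oa.name == "L27":
        return OrthogonalArray(
            "L27", 27, oa.n_factors, 3, _l27(oa.n_factors), "canonical"
        )
    raise ValueError(f"no canonical counterpart for {oa.name!r}")


def balance_report(oa: OrthogonalArray) -> dict:
    """Per-column level counts, per-pair joint counts, and a strength-2 flag.

    A strength-2 array has every ordered level pair occurring equally often
    in every pair of columns.  The report lists each column pair whose joint
    counts are unequal so that imbalance in a printed plan is surfaced
    rather than silently accepted.
    """
    plan = oa.plan
    L = oa.n_levels
    col_counts = {}
    for j in range(oa.n_factors):
        col_counts[f"W{j + 1}"] = {
            f"L{l}": int(np.sum(plan[:, j] == l)) for l in range(1, L + 1)
        }
    pair_counts = {}
    unbalanced = []
    for j, k in itertools.combinations(range(oa.n_factors), 2):
        counts = {}
        for a in range(1, L + 1):
            for b in range(1, L + 1):
                counts[f"L{a}L{b}"] = int(
                    np.sum((plan[:, j] == a) & (plan[:, k] == b))
                )
        key = f"W{j + 1}xW{k + 1}"
        pair_counts[key] = counts
        if len(set(counts.values())) > 1:
            unbalanced.append(key)
    levels_balanced = all(
        len(set(c.values())) == 1 for c in col_counts.values()
    )
    return {
        "name": oa.name,
        "source": oa.source,
        "column_level_counts": col_counts,
        "pair_joint_counts": pair_counts,
        "unbalanced_pairs": unbalanced,
        "strength2": levels_balanced and not unbalanced,
    }


def full_factorial_count(levels: int, factors: int) -> int:
    """Number of runs a full factorial would need: ``levels ** factors``."""
    if levels < 1 or factors < 1:
        raise ValueError("levels and factors must be >= 1")
    return levels**factors


def reduction_fraction(oa: OrthogonalArray) -> float:
    """Fraction of the full factorial avoided: ``1 - R / L**P``."""
    from fractions import Fraction

    return float(1 - Fraction(oa.n_runs, oa.n_levels**oa.n_factors))
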