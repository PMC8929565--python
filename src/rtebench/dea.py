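"""Input-oriented, variable-returns-to-scale DEA (the BCC envelopment model).

For DMU *o* with inputs ``x_o`` and outputs ``y_o`` among ``d`` peers, the
envelopment LP is

    min  theta
    s.t. X' lam + S- = theta * x_o      (inputs, one row per input h)
         Y' lam - S+ = y_o              (outputs, one row per output r)
         sum(lam) = 1                   (convexity -> variable returns to scale)
         lam, S-, S+ >= 0

theta in (0, 1] is the relative technical efficiency: the largest
equiproportional contraction of the DMU's inputs that some convex
combination of peers can still dominate at the DMU's output level.

The classical single-LP formulation subtracts a non-Archimedean epsilon
times the slack sum from the objective; a finite epsilon corrupts theta
numerically, so by default the model is solved in two phases — phase 1
minimises theta, phase 2 maximises the slack sum with theta held fixed.
A literal epsilon objective is available via ``epsilon=``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = ["DEAInstance", "DEAResult", "solve_dmu", "assess_all", "reference_oracle"]

_TOL = 1e-6


@dataclass(frozen=True)
class DEAInstance:
    """Input/output matrices for a set of decision-making units.

    X : (d, i) strictly positive inputs; Y : (d, j) nonnegative outputs.
    """

    X: np.ndarray
    Y: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of DMUs")
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("DEA data must not contain NaN")
        if (X <= 0).any():
            raise ValueError("inputs must be strictly positive")
        if (Y < 0).any():
            raise ValueError("outputs must be nonnegative")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(str(k) for k in range(X.shape[0]))
            )
        elif len(self.labels) != X.shape[0]:
            raise ValueError("labels length must equal number of DMUs")

    @property
    def n_dmu(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class DEAResult:
    """Per-DMU efficiency scores, slacks and reference weights."""

    theta: np.ndarray          # (d,) in (0, 1]
    input_slacks: np.ndarray   # (d, i)
    output_slacks: np.ndarray  # (d, j)
    lambdas: np.ndarray        # (d, d) convex reference weights
    labels: tuple[str, ...]

    @property
    def efficient(self) -> np.ndarray:
        """Strongly efficient: theta = 1 and all slacks zero (within tol)."""
        return (
            (self.theta >= 1.0 - _TOL)
            & (self.input_slacks.max(axis=1, initial=0.0) <= _TOL)
            & (self.output_slacks.max(axis=1, initial=0.0) <= _TOL)
        )

    @property
    def weakly_efficient(self) -> np.ndarray:
        """theta = 1 but nonzero slacks remain."""
        return (self.theta >= 1.0 - _TOL) & ~self.efficient

    def peers(self, o: int, tol: float = 1e-8) -> list[str]:
        return [self.labels[m] for m in np.nonzero(self.lambdas[o] > tol)[0]]


def _phase1(X: np.ndarray, Y: np.ndarray, o: int, vrs: bool, epsilon: float) -> tuple:
    """Solve min theta (- epsilon * slack sum). Returns (theta, lam, sm, sp)."""
    d, i = X.shape
    j = Y.shape[1]
    n = 1 + d + i + j  # theta, lambda, S-, S+
    c = np.zeros(n)
    c[0] = 1.0
    if epsilon:
        c[1 + d:] = -epsilon
    rows = i + j + (1 if vrs else 0)
    A = np.zeros((rows, n))
    b = np.zeros(rows)
    A[:i, 0] = -X[o]
    A[:i, 1:1 + d] = X.T
    A[:i, 1 + d:1 + d + i] = np.eye(i)
    A[i:i + j, 1:1 + d] = Y.T
    A[i:i + j, 1 + d + i:] = -np.eye(j)
    b[i:i + j] = Y[o]
    if vrs:
        A[i + j, 1:1 + d] = 1.0
        b[i + j] = 1.0
    res = linprog(c, A_eq=A, b_eq=b, bounds=[(0, None)] * n, method="highs")
    if not res.success:
        raise RuntimeError(
            f"DEA phase-1 LP failed for DMU {o}: {res.message} (status {res.status})"
        )
    x = res.x
    return float(x[0]), x[1:1 + d], x[1 + d:1 + d + i], x[1 + d + i:], A, b


def _phase2(A: np.ndarray, b: np.ndarray, theta: float, d: int, i: int, j: int):
    """Max slack sum with theta fixed at its phase-1 optimum."""
    n = A.shape[1]
    c = np.zeros(n)
    c[1 + d:] = -1.0  # maximise slacks
    A2 = np.vstack([A, np.zeros(n)])
    A2[-1, 0] = 1.0
    b2 = np.append(b, theta)
    res = linprog(c, A_eq=A2, b_eq=b2, bounds=[(0, None)] * n, method="highs")
    if not res.success:
        raise RuntimeError(f"DEA phase-2 LP failed: {res.message}")
    x = res.x
    return x[1:1 + d], x[1 + d:1 + d + i], x[1 + d + i:]


def solve_dmu(
    instance: DEAInstance,
    o: int,
    *,
    vrs: bool = True,
    two_phase: bool = True,
    epsilon: float = 0.0,
) -> dict:
    """Solve the envelopment LP for DMU ``o`` (0-based index).

    Returns a dict with ``theta``, ``lambdas``, ``input_slacks``,
    ``output_slacks``. Self-reference (lam_o = 1, theta = 1) is always
    feasible, so theta <= 1 and the LP cannot be infeasible on valid data.
    """
    X, Y = instance.X, instance.Y
    d, i = X.shape
    j = Y.shape[1]
    if not 0 <= o < d:
        raise IndexError(f"DMU index {o} out of range for {d} DMUs")
    theta, lam, sm, sp, A, b = _phase1(X, Y, o, vrs, 0.0 if two_phase else epsilon)
    if two_phase:
        lam, sm, sp = _phase2(A, b, theta, d, i, j)
    if theta > 1.0 + 1e-7 or theta <= 0.0:
        raise RuntimeError(f"DEA theta out of range for DMU {o}: {theta}")
    if theta >= 1.0 - 1e-7:  # snap to the frontier within solver tolerance
        theta = 1.0
    return {
        "theta": theta,
        "lambdas": lam,
        "input_slacks": np.maximum(sm, 0.0),
        "output_slacks": np.maximum(sp, 0.0),
    }


def efficiency_scores(instance: DEAInstance, *, vrs: bool = True) -> np.ndarray:
    """Phase-1 theta for every DMU (no slack maximisation; the fast path
    used inside the Monte Carlo loop, where only theta is aggregated)."""
    d = instance.n_dmu
    out = np.empty(d)
    for o in range(d):
        theta, *_ = _phase1(instance.X, instance.Y, o, vrs, 0.0)
        out[o] = min(theta, 1.0)
    return out


def assess_all(
    instance: DEAInstance, *, vrs: bool = True, two_phase: bool = True,
    epsilon: float = 0.0,
) -> DEAResult:
    """Run :func:`solve_dmu` for every DMU and collect a :class:`DEAResult`."""
    d, i = instance.X.shape
    j = instance.Y.shape[1]
    theta = np.empty(d)
    lambdas = np.empty((d, d))
    sm = np.empty((d, i))
    sp = np.empty((d, j))
    for o in range(d):
        r = solve_dmu(instance, o, vrs=vrs, two_phase=two_phase, epsilon=epsilon)
        theta[o] = r["theta"]
        lambdas[o] = r["lambdas"]
        sm[o] = r["input_slacks"]
        sp[o] = r["output_slacks"]
    return DEAResult(theta, sm, sp, lambdas, instance.labels)


def reference_oracle(instance: DEAInstance, o: int, grid: float = 1e-2) -> float:
    """Brute-force approximation of input-oriented VRS theta for DMU ``o``.

    Enumerates convex weight vectors lambda on a simplex grid of resolution
    ``grid``; for each lambda whose combined output dominates ``y_o``, the
    smallest feasible radial contraction is ``max_h (X'lam)_h / x_oh``.
    The minimum over the grid upper-bounds the LP optimum and converges to
    it as the grid refines. Intended for small instances (d <= 6) as an
    independent check on the LP — it shares no code with the solver.
    """
    X, Y = instance.X, instance.Y
    d = instance.n_dmu
    steps = int(round(1.0 / grid))
    best = 1.0  # self-reference always feasible
    y_o = Y[o]
    x_o = X[o]
    # lambda vectors with entries k/steps summing to 1
    for combo in itertools.combinations_with_replacement(range(d), steps):
        lam = np.bincount(np.array(combo), minlength=d) / steps
        if (lam @ Y < y_o - 1e-12).any():
            continue
        theta = float(np.max((lam @ X) / x_o))
        if theta < best:
            best = theta
    return best
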