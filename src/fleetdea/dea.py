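"""Multiplier-form DEA: the CCR model and its cone-constrained extension.

Each decision-making unit (DMU) is one device-month with m positive inputs
and s non-negative outputs.  The input-oriented CCR multiplier program under
constant returns to scale is, for evaluated unit j0::

    max   mu' y_j0
    s.t.  w' x_j - mu' y_j >= 0   for every DMU j
          w' x_j0 = 1
          w, mu >= 0

The cone-constrained variant adds multiplier restrictions B w >= 0 and
C mu >= 0, where B (resp. C) is built from a preferred weight vector w*:
W_A[i][j] = w*_i / w*_j is the consistent ratio matrix, its principal
eigenvalue equals the order, and B = W_A - order * I.  The region
{B w >= 0, w >= 0} is the cone generated by w* (for the consistent ratio
matrix it pins the multiplier ratios to those of w*), so the score of j0
admits the closed form ratio_j0 / max_j ratio_j with
ratio_j = (w*'-weighted outputs) / (w*'-weighted inputs) — used as an
independent oracle in the test-suite, never as the implementation here.

Waiting times are "undesirable outputs" (smaller is better); they are
direction-reversed by a linear translation before entering Y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .weighting import WeightVector

__all__ = [
    "DEAInstance",
    "ConeConstraint",
    "DEAResult",
    "prepare_dea_data",
    "ccr_efficiency",
    "build_cone",
    "cone_dea_efficiency",
    "score_series",
]

INPUT_INDICATORS = ("X1", "X2", "X3", "X4")
OUTPUT_INDICATORS = ("X5", "X6", "X7", "X8")
#: waiting times: smaller is better, reversed before entering the output matrix
DEFAULT_UNDESIRABLE = ("X6", "X8")

_FEAS_TOL = 1e-7


@dataclass(frozen=True)
class DEAInstance:
    """Input matrix X (m x n), output matrix Y (s x n) and DMU labels."""

    X: np.ndarray
    Y: np.ndarray
    labels: tuple[str, ...]
    input_names: tuple[str, ...] = ()
    output_names: tuple[str, ...] = ()
    transform_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.shape[1] != Y.shape[1]:
            raise ValueError("X and Y must have one column per DMU")
        if len(self.labels) != X.shape[1]:
            raise ValueError("one label per DMU required")
        if np.any(X <= 0):
            raise ValueError("all inputs must be strictly positive")
        if np.any(Y < 0):
            raise ValueError("outputs must be non-negative")
        if np.any(Y.sum(axis=0) == 0):
            raise ValueError("a DMU with all-zero outputs is not scoreable")

    @property
    def n_dmus(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def s(self) -> int:
        return self.Y.shape[0]


@dataclass(frozen=True)
class ConeConstraint:
    """Polyhedral multiplier cone {B w >= 0, w >= 0} generated by w*."""

    generator: np.ndarray
    B: np.ndarray
    order: int

    def __post_init__(self) -> None:
        g = np.asarray(self.generator, dtype=float)
        object.__setattr__(self, "generator", g)
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))


@dataclass(frozen=True)
class DEAResult:
    label: str
    score: float
    input_multipliers: np.ndarray
    output_multipliers: np.ndarray
    status: str
    binding: tuple[int, ...] = ()


def prepare_dea_data(panel: pd.DataFrame,
                     inputs: tuple[str, ...] = INPUT_INDICATORS,
                     outputs: tuple[str, ...] = OUTPUT_INDICATORS,
                     undesirable: tuple[str, ...] = DEFAULT_UNDESIRABLE,
                     eps_frac: float = 0.01) -> DEAInstance:
    """Assemble a DEA instance from an indicator panel.

    Undesirable output columns v are reversed to v' = (max v + eps) - v with
    eps = ``eps_frac`` of the column range, so larger is better and all
    values stay positive.  The applied shift is recorded in
    ``transform_meta``.
    """
    if panel.empty:
        raise ValueError("empty panel")
    bad = set(undesirable) - set(outputs)
    if bad:
        raise ValueError(f"undesirable columns must be outputs: {sorted(bad)}")
    labels = tuple(f"{d}:{m}" for d, m in zip(panel["device_id"], panel["month"]))
    X = panel.loc[:, list(inputs)].to_numpy(dtype=float).T
    Y = panel.loc[:, list(outputs)].to_numpy(dtype=float).T
    meta: dict = {}
    for name in undesirable:
        k = outputs.index(name)
        col = Y[k]
        rng = col.max() - col.min()
        eps = eps_frac * rng if rng > 0 else eps_frac * max(col.max(), 1.0)
        shift = col.max() + eps
        Y[k] = shift - col
        meta[name] = {"transform": "linear_reversal", "shift": float(shift)}
    if np.any(X <= 0):
        i, j = np.argwhere(X <= 0)[0]
        raise ValueError(
            f"non-positive input {inputs[i]} for DMU {labels[j]}"
        )
    return DEAInstance(X=X, Y=Y, labels=labels, input_names=tuple(inputs),
                       output_names=tuple(outputs), transform_meta=meta)


def _solve_multiplier_lp(instance: DEAInstance, j0: int,
                         extra_A_ub: np.ndarray | None = None) -> DEAResult:
    """Solve the CCR multiplier LP for DMU ``j0``.

    Decision vector is (w, mu).  ``extra_A_ub`` stacks additional
    A_ub (w, mu) <= 0 rows (the negated cone constraints).
    """
    X, Y = instance.X, instance.Y
    m, s, n = instance.m, instance.s, instance.n_dmus
    c = np.concatenate([np.zeros(m), -Y[:, j0]])          # maximize mu'y0
    A_ub = np.hstack([-X.T, Y.T])                          # mu'y_j - w'x_j <= 0
    b_ub = np.zeros(n)
    if extra_A_ub is not None:
        A_ub = np.vstack([A_ub, extra_A_ub])
        b_ub = np.concatenate([b_ub, np.zeros(extra_A_ub.shape[0])])
    A_eq = np.concatenate([X[:, j0], np.zeros(s)])[None, :]  # w'x0 = 1
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(
            f"LP for DMU {instance.labels[j0]} failed: {res.message}\n"
            f"c={c!r}\nA_ub={A_ub!r}\nA_eq={A_eq!r}"
        )
    w = res.x[:m]
    mu = res.x[m:]
    score = float(mu @ Y[:, j0])
    if score > 1.0 and score <= 1.0 + _FEAS_TOL:
        score = 1.0
    slack = X.T @ w - Y.T @ mu
    binding = tuple(int(j) for j in np.flatnonzero(slack <= _FEAS_TOL))
    return DEAResult(label=instance.labels[j0], score=score,
                     input_multipliers=w, output_multipliers=mu,
                     status="optimal", binding=binding)


def ccr_efficiency(instance: DEAInstance, j0: int) -> DEAResult:
    """Input-oriented CCR (constant returns to scale) score of DMU ``j0``."""
    return _solve_multiplier_lp(instance, j0)


def build_cone(w_star: WeightVector | np.ndarray) -> ConeConstraint:
    """Multiplier cone generated by a strictly positive weight vector.

    W_A[i][j] = w*_i/w*_j is consistent, so its principal eigenvalue equals
    its order; B = W_A - order*I satisfies B w* = 0 exactly.
    """
    g = w_star.weights if isinstance(w_star, WeightVector) else np.asarray(w_star, float)
    if np.any(g <= 0):
        raise ValueError("cone generator weights must be strictly positive")
    order = g.size
    W_A = g[:, None] / g[None, :]
    B = W_A - order * np.eye(order)
    return ConeConstraint(generator=g, B=B, order=order)


def cone_dea_efficiency(instance: DEAInstance, input_cone: ConeConstraint,
                        output_cone: ConeConstraint, j0: int) -> DEAResult:
    """CCR score of DMU ``j0`` under multiplier cones B w >= 0, C mu >= 0."""
    if input_cone.order != instance.m or output_cone.order != instance.s:
        raise ValueError("cone orders must match instance dimensions")
    m, s = instance.m, instance.s
    rows = []
    if m > 1:
        rows.append(np.hstack([-input_cone.B, np.zeros((m, s))]))
    if s > 1:
        rows.append(np.hstack([np.zeros((s, m)), -output_cone.B]))
    extra = np.vstack(rows) if rows else None
    try:
        return _solve_multiplier_lp(instance, j0, extra_A_ub=extra)
    except RuntimeError:
        # retry with the cone rows relaxed by a tiny tolerance
        if extra is not None:
            res = _solve_multiplier_lp_relaxed(instance, j0, extra)
            return res
        raise


def _solve_multiplier_lp_relaxed(instance: DEAInstance, j0: int,
                                 extra: np.ndarray) -> DEAResult:
    X, Y = instance.X, instance.Y
    m, s, n = instance.m, instance.s, instance.n_dmus
    c = np.concatenate([np.zeros(m), -Y[:, j0]])
    A_ub = np.vstack([np.hstack([-X.T, Y.T]), extra])
    b_ub = np.concatenate([np.zeros(n), np.full(extra.shape[0], 1e-9)])
    A_eq = np.concatenate([X[:, j0], np.zeros(s)])[None, :]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"cone LP for DMU {instance.labels[j0]} infeasible "
                           f"even with relaxed tolerance: {res.message}")
    score = float(res.x[m:] @ Y[:, j0])
    if 1.0 < score <= 1.0 + _FEAS_TOL:
        score = 1.0
    return DEAResult(label=instance.labels[j0], score=score,
                     input_multipliers=res.x[:m], output_multipliers=res.x[m:],
                     status="optimal_relaxed")


def score_series(panel: pd.DataFrame,
                 input_weights: WeightVector | None = None,
                 output_weights: WeightVector | None = None,
                 mode: str = "pooled",
                 use_cone: bool = True,
                 inputs: tuple[str, ...] = INPUT_INDICATORS,
                 outputs: tuple[str, ...] = OUTPUT_INDICATORS,
                 undesirable: tuple[str, ...] = DEFAULT_UNDESIRABLE) -> pd.DataFrame:
    """Monthly efficiency scores for every device.

    ``mode="pooled"`` builds one frontier over all device-months;
    ``mode="per_month"`` scores each calendar month against its own
    cross-sectional frontier.  Returns a tidy frame with columns
    device_id, month, score_ccr and (if ``use_cone``) score_cone.
    """
    if mode not in ("pooled", "per_month"):
        raise ValueError(f"unknown mode {mode!r}")
    if use_cone and (input_weights is None or output_weights is None):
        raise ValueError("cone scoring requires both weight vectors")

    def _score_block(block: pd.DataFrame) -> pd.DataFrame:
        rows = []
        if mode == "per_month" and len(block) < 2:
            warnings.warn(
                f"month {block['month'].iloc[0]} has fewer than 2 DMUs; "
                "scores set to 1 by convention", stacklevel=3)
            for _, r in block.iterrows():
                rec = {"device_id": r["device_id"], "month": r["month"],
                       "score_ccr": 1.0, "solver_status": "degenerate_frontier"}
                if use_cone:
                    rec["score_cone"] = 1.0
                rows.append(rec)
            return pd.DataFrame(rows)
        inst = prepare_dea_data(block, inputs, outputs, undesirable)
        if use_cone:
            icone = build_cone(input_weights)
            ocone = build_cone(output_weights)
        for k in range(inst.n_dmus):
            ccr = ccr_efficiency(inst, k)
            rec = {"device_id": block["device_id"].iloc[k],
                   "month": block["month"].iloc[k],
                   "score_ccr": round(ccr.score, 6),
                   "solver_status": ccr.status}
            if use_cone:
                cone = cone_dea_efficiency(inst, icone, ocone, k)
                rec["score_cone"] = round(cone.score, 6)
                rec["solver_status"] = cone.status
            rows.append(rec)
        return pd.DataFrame(rows)

    if mode == "pooled":
        out = _score_block(panel.reset_index(drop=True))
    else:
        parts = [_score_block(g.reset_index(drop=True))
                 for _, g in panel.groupby("month", sort=True)]
        out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["device_id", "month"]).reset_index(drop=True)
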