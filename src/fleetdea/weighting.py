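"""Indicator weighting: AHP, improved CRITIC, and game-theoretic combination.

Three weighting schemes feed the cone-constrained DEA stage:

* **AHP** turns a positive reciprocal pairwise-comparison matrix (1-9 scale)
  into a subjective priority vector via row geometric means, with Saaty's
  consistency test (CR < 0.10 acceptable).
* **Improved CRITIC** derives objective weights from the data itself: a
  column's information volume is ``(entropy_value + std) * conflict`` where
  conflict is ``sum_i (1 - |r_ij|)`` over Pearson correlations of the
  min-max standardized columns.
* **Game combination** fuses one subjective and one objective vector by
  solving for linear-combination coefficients that minimize the total
  deviation from both (Nash-equilibrium reading of combination weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JudgementMatrix",
    "WeightVector",
    "ConsistencyResult",
    "CriticBreakdown",
    "ahp_weights",
    "consistency_ratio",
    "minmax_standardize",
    "critic_weights",
    "game_combine",
    "SAATY_RI",
]

# Saaty's random consistency index, indexed by matrix order.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
            7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

RECIPROCITY_RTOL = 1e-2  # published matrices carry rounded reciprocals (0.476 ~ 1/2.1)


@dataclass(frozen=True)
class JudgementMatrix:
    """Positive reciprocal pairwise-comparison matrix with indicator labels."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("judgement matrix must be square")
        if len(self.labels) != a.shape[0]:
            raise ValueError("label count must match matrix order")
        if np.any(a <= 0):
            raise ValueError("judgement matrix entries must be positive")
        if np.any(a < 1 / 9 - 1e-9) or np.any(a > 9 + 1e-9):
            raise ValueError("entries must lie in the 1/9..9 comparison scale")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise ValueError("diagonal entries must equal 1")
        recip = a * a.T
        if np.any(np.abs(recip - 1.0) > RECIPROCITY_RTOL * 3):
            i, j = np.unravel_index(np.argmax(np.abs(recip - 1.0)), a.shape)
            raise ValueError(
                f"reciprocity violated beyond tolerance at ({i},{j}): "
                f"A_ij*A_ji = {recip[i, j]:.4f}"
            )

    @property
    def order(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightVector:
    """Normalized non-negative weights for one indicator group."""

    group: str  # "input" | "output"
    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(self.labels) != w.size:
            raise ValueError("weights must be a vector matching labels")
        if np.any(w < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class ConsistencyResult:
    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool
    note: str = ""


@dataclass(frozen=True)
class CriticBreakdown:
    """Per-indicator decomposition of the improved CRITIC weighting."""

    labels: tuple[str, ...]
    entropy: np.ndarray      # information-entropy value of each column, in [0, 1]
    dispersion: np.ndarray   # sample standard deviation of the standardized column
    conflict: np.ndarray     # sum_i (1 - |r_ij|)
    volume: np.ndarray       # (entropy + dispersion) * conflict
    weights: np.ndarray      # volume normalized within the group


def ahp_weights(j: JudgementMatrix, group: str = "input",
                method: str = "geometric") -> WeightVector:
    """Priority weights of a judgement matrix.

    The default is the row geometric-mean method: V_i is the n-th root of the
    product of row i, normalized to sum 1.  ``method="eigen"`` uses the
    principal right eigenvector instead (both coincide on consistent
    matrices).
    """
    a = j.values
    n = j.order
    if method == "geometric":
        v = np.prod(a, axis=1) ** (1.0 / n)
        w = v / v.sum()
    elif method == "eigen":
        vals, vecs = np.linalg.eig(a)
        k = int(np.argmax(vals.real))
        w = np.abs(vecs[:, k].real)
        w = w / w.sum()
    else:
        raise ValueError(f"unknown AHP method {method!r}")
    return WeightVector(group=group, labels=j.labels, weights=w)


def consistency_ratio(j: JudgementMatrix,
                      weights: WeightVector | None = None) -> ConsistencyResult:
    """Saaty consistency test.

    lambda_max is estimated as the mean of (A w)_i / w_i, CI as
    (lambda_max - n)/(n - 1), and CR = CI / RI with Saaty's random index.
    Orders <= 2 are always consistent and report CR = 0.
    """
    if weights is None:
        weights = ahp_weights(j)
    n = j.order
    w = weights.weights
    bw = j.values @ w
    lambda_max = float(np.sum(bw / (n * w)))
    if n <= 2:
        return ConsistencyResult(lambda_max=lambda_max, ci=0.0,
                                 ri=SAATY_RI.get(n, 0.0), cr=0.0,
                                 acceptable=True,
                                 note="order <= 2 matrices are always consistent")
    try:
        ri = SAATY_RI[n]
    except KeyError:
        raise ValueError(f"no random index tabulated for order {n}") from None
    ci = (lambda_max - n) / (n - 1)
    cr = ci / ri
    return ConsistencyResult(lambda_max=lambda_max, ci=ci, ri=ri, cr=cr,
                             acceptable=cr < 0.10)


def minmax_standardize(x: np.ndarray, directions: list[str] | tuple[str, ...],
                       labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Deviation (min-max) standardization per column.

    ``directions[j]`` is ``"benefit"`` (larger better, z=(x-min)/range) or
    ``"cost"`` (smaller better, z=(max-x)/range).  A constant column has no
    range and is rejected by name.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix (rows = observations)")
    if x.shape[1] != len(directions):
        raise ValueError("one direction per column required")
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    rng = hi - lo
    if np.any(rng == 0):
        k = int(np.argmax(rng == 0))
        name = labels[k] if labels else f"column {k}"
        raise ValueError(f"degenerate (constant) column: {name}")
    z = np.empty_like(x)
    for k, d in enumerate(directions):
        if d == "benefit":
            z[:, k] = (x[:, k] - lo[k]) / rng[k]
        elif d == "cost":
            z[:, k] = (hi[k] - x[:, k]) / rng[k]
        else:
            raise ValueError(f"direction must be 'benefit' or 'cost', got {d!r}")
    return z


def _entropy_value(col: np.ndarray, eps: float = 1e-12) -> float:
    # Information-entropy value of one standardized column (entropy method):
    # p_i = z_i / sum(z), e = -sum(p ln p) / ln(m).  eps guards z == 0.
    z = col + eps
    p = z / z.sum()
    m = col.size
    return float(-np.sum(p * np.log(p)) / np.log(m))


def critic_weights(z: np.ndarray, labels: tuple[str, ...] | None = None,
                   group: str = "input") -> tuple[CriticBreakdown, WeightVector]:
    """Improved CRITIC weights from a standardized decision matrix.

    Information volume of column j is ``(sigma_j + h_j) * sum_i(1 - |r_ij|)``
    where sigma_j is the entropy-method value of the column, h_j its sample
    standard deviation, and r_ij the Pearson correlations between columns.
    Weights are the volumes normalized within the group.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] < 2:
        raise ValueError("need a matrix with at least two columns")
    n_cols = z.shape[1]
    if labels is None:
        labels = tuple(f"C{k + 1}" for k in range(n_cols))
    ent = np.array([_entropy_value(z[:, k]) for k in range(n_cols)])
    disp = z.std(axis=0, ddof=1)
    r = np.corrcoef(z, rowvar=False)
    conflict = np.sum(1.0 - np.abs(r), axis=0)
    volume = (ent + disp) * conflict
    total = volume.sum()
    if total <= 1e-12:
        raise ValueError(
            "degenerate weights: all columns are mutually |r| = 1, "
            "total information volume is zero"
        )
    w = volume / total
    breakdown = CriticBreakdown(labels=tuple(labels), entropy=ent, dispersion=disp,
                                conflict=conflict, volume=volume, weights=w)
    return breakdown, WeightVector(group=group, labels=tuple(labels), weights=w)


def game_combine(w1: WeightVector, w2: WeightVector,
                 rhs: str = "standard") -> tuple[np.ndarray, WeightVector]:
    """Game-theoretic combination of two weight vectors.

    Solves the 2x2 Gram system for the combination coefficients lambda that
    minimize the summed deviation of ``lambda1*W1 + lambda2*W2`` from each
    individual vector, then normalizes lambda to sum 1 and returns the
    renormalized convex combination.

    ``rhs="standard"`` uses the symmetric right-hand side (W1.W1, W2.W2);
    ``rhs="as_printed"`` uses (W1.W1, W1.W2), kept for comparison with a
    variant form seen in the combination-weighting literature.
    """
    if w1.group != w2.group or len(w1) != len(w2):
        raise ValueError("weight vectors must share group and length")
    a, b = w1.weights, w2.weights
    gram = np.array([[a @ a, a @ b], [b @ a, b @ b]])
    if rhs == "standard":
        target = np.array([a @ a, b @ b])
    elif rhs == "as_printed":
        target = np.array([a @ a, a @ b])
    else:
        raise ValueError(f"unknown rhs form {rhs!r}")
    if np.allclose(a, b):
        lam = np.array([0.5, 0.5])
    else:
        # parallel-but-unequal vectors give a singular Gram: fall back to
        # the least-squares pseudo-solution.
        lam, *_ = np.linalg.lstsq(gram, target, rcond=None)
        if np.any(lam < 0):
            # constrained minimum of the deviation quadratic lies on the
            # boundary: zero the offending coefficient and solve the
            # remaining 1-D problem, keeping the combination convex.
            cands = [np.array([target[0] / gram[0, 0], 0.0]),
                     np.array([0.0, target[1] / gram[1, 1]])]
            J = [0.5 * lc @ gram @ lc - target @ lc for lc in cands]
            lam = cands[int(np.argmin(J))]
        lam = lam / lam.sum()
    combined = lam[0] * a + lam[1] * b
    combined = combined / combined.sum()
    return lam, WeightVector(group=w1.group, labels=w1.labels, weights=combined)
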