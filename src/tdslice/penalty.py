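"""Cost-sensitive penalty-weight classification loss.

Replaces cross-entropy with an expected-misclassification-cost objective.
A penalty matrix W holds the cost W[i, j] of predicting class i when the
true class is j; by convention the diagonal is 1 and off-diagonal costs grow
with the deviation |i - j| (ordinal intent).  Two equivalent forms exist:

* the q-form:  loss = sum_i W[i, j] * q_i  with q_i = p_i for i != j and
  q_j = 1 - p_j, so a correct confident prediction costs nothing;
* the corrected form:  loss = sum_i W'[i, j] * p_i  with W'[i, i] = 0 and
  W'[i, j] = W[i, j] + 1 off-diagonal.

Both are identical whenever the base matrix has a unit diagonal, and the
corrected form is a drop-in replacement for cross-entropy on softmax output.
Internal class labels are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PenaltyMatrix",
    "build_penalty_matrix",
    "balanced_binary_overrides",
    "penalty_loss_q",
    "penalty_loss_corrected",
    "batch_loss",
    "penalty_loss_grad_logits",
    "cross_entropy_grad_logits",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class PenaltyMatrix:
    """Base (unit-diagonal) and corrected (zero-diagonal) cost matrices."""

    n: int
    base: np.ndarray
    corrected: np.ndarray

    def __post_init__(self) -> None:
        base = np.asarray(self.base, dtype=float)
        corr = np.asarray(self.corrected, dtype=float)
        if self.n < 2:
            raise ValueError("need at least two classes")
        if base.shape != (self.n, self.n) or corr.shape != (self.n, self.n):
            raise ValueError("penalty matrices must be n x n")
        if np.any(base < 0) or np.any(corr < 0):
            raise ValueError("penalty costs must be non-negative")
        if not np.all(np.isfinite(base)) or not np.all(np.isfinite(corr)):
            raise ValueError("penalty costs must be finite")
        if np.any(np.diag(corr) != 0):
            raise ValueError("corrected matrix must have a zero diagonal")
        object.__setattr__(self, "base", base)
        object.__setattr__(self, "corrected", corr)


def build_penalty_matrix(
    n: int,
    base_rule: str = "absolute-distance",
    overrides: Mapping[tuple[int, int], float] | None = None,
) -> PenaltyMatrix:
    """Construct the cost matrices for ``n`` classes.

    ``base_rule='absolute-distance'`` sets off-diagonal base costs to |i - j|
    (and 1 on the diagonal); ``'custom'`` starts from an all-ones matrix.
    ``overrides`` maps (predicted, true) 0-based index pairs to replacement
    off-diagonal base costs, e.g. a heavier cost for calling a torn ligament
    healthy: ``{(0, 1): 3.0}``.  The corrected matrix is derived as
    W'[i, i] = 0, W'[i, j] = W[i, j] + 1.
    """
    if n < 2:
        raise ValueError("need at least two classes")
    if base_rule == "absolute-distance":
        idx = np.arange(n)
        base = np.abs(idx[:, None] - idx[None, :]).astype(float)
        np.fill_diagonal(base, 1.0)
    elif base_rule == "custom":
        base = np.ones((n, n), dtype=float)
    else:
        raise ValueError(f"unknown base rule {base_rule!r}")
    for (i, j), cost in (overrides or {}).items():
        if i == j:
            raise ValueError("diagonal base costs are fixed at 1 by convention")
        if cost < 0:
            raise ValueError("penalty costs must be non-negative")
        base[i, j] = float(cost)
    corrected = base + 1.0
    np.fill_diagonal(corrected, 0.0)
    return PenaltyMatrix(n=n, base=base, corrected=corrected)


def balanced_binary_overrides(labels) -> dict[tuple[int, int], float]:
    """Cost override matching the miss-positive/false-alarm cost ratio to the
    inverse class ratio of ``labels`` (binary, 0 = negative, 1 = positive).

    The expected loss of a constant prediction p under corrected costs is
    (1-pi)*c_fp*p + pi*c_fn*(1-p) for prevalence pi; it is *linear* in p,
    so with symmetric costs and pi < 1/2 it is minimised at p = 0 and
    gradient descent is actively pulled toward "always negative" — the loss
    has no log barrier to resist.  Setting c_fn / c_fp = (1-pi)/pi makes a
    constant prediction cost-neutral, so only genuinely discriminative
    directions move the loss.  This is the classic cost-sensitive remedy
    for class imbalance, the very use case the penalty weighting exists for.
    """
    y = np.asarray(labels, dtype=int).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance costs")
    ratio = n_neg / n_pos
    # default base has W[1,0] = 1, so c_fp = 2; choose W[0,1] with
    # c_fn = W[0,1] + 1 = ratio * c_fp
    return {(0, 1): max(ratio * 2.0 - 1.0, 0.0)}


def _check_probs(probs: np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float).ravel()
    if p.size != n:
        raise ValueError(f"expected {n} class probabilities, got {p.size}")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("probabilities must be a simplex vector")
    return np.maximum(p, _PROB_FLOOR)


def penalty_loss_q(probs: np.ndarray, true_class: int, pm: PenaltyMatrix) -> float:
    """q-form loss: sum_i base[i, j] * q_i with q_j = 1 - p_j, q_i = p_i."""
    p = _check_probs(probs, pm.n)
    j = _check_label(true_class, pm.n)
    q = p.copy()
    q[j] = 1.0 - p[j]
    return float(pm.base[:, j] @ q)


def penalty_loss_corrected(probs: np.ndarray, true_class: int, pm: PenaltyMatrix) -> float:
    """Corrected-form loss: sum_i corrected[i, j] * p_i."""
    p = _check_probs(probs, pm.n)
    j = _check_label(true_class, pm.n)
    return float(pm.corrected[:, j] @ p)


def _check_label(true_class: int, n: int) -> int:
    j = int(true_class)
    if not 0 <= j < n:
        raise ValueError(f"true class {j} out of range 0..{n - 1}")
    return j


def batch_loss(
    probs_batch: Sequence[np.ndarray] | np.ndarray,
    labels: Sequence[int],
    pm: PenaltyMatrix,
    reduction: str = "mean",
) -> float:
    """Reduce per-example corrected-form losses over a batch."""
    probs_batch = np.atleast_2d(np.asarray(probs_batch, dtype=float))
    labels = np.asarray(labels, dtype=int).ravel()
    if probs_batch.shape[0] == 0:
        raise ValueError("empty batch")
    if probs_batch.shape[0] != labels.size:
        raise ValueError("batch size mismatch between probabilities and labels")
    losses = [
        penalty_loss_corrected(p, j, pm) for p, j in zip(probs_batch, labels)
    ]
    if reduction == "mean":
        return float(np.mean(losses))
    if reduction == "sum":
        return float(np.sum(losses))
    raise ValueError(f"unknown reduction {reduction!r}")


def penalty_loss_grad_logits(
    logits: np.ndarray, true_class: int, pm: PenaltyMatrix
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. pre-softmax scores.

    With p = softmax(z) and cost column c = corrected[:, j],
    d(c.p)/dz_k = p_k * (c_k - c.p).
    """
    z = np.asarray(logits, dtype=float).ravel()
    j = _check_label(true_class, pm.n)
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    c = pm.corrected[:, j]
    expected = float(c @ p)
    grad = p * (c - expected)
    return expected, grad


def cross_entropy_grad_logits(
    logits: np.ndarray, true_class: int
) -> tuple[float, np.ndarray]:
    """Cross-entropy loss and gradient w.r.t. pre-softmax scores (ablation comparator)."""
    z = np.asarray(logits, dtype=float).ravel()
    j = _check_label(true_class, z.size)
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    loss = -float(np.log(max(p[j], _PROB_FLOOR)))
    grad = p.copy()
    grad[j] -= 1.0
    return loss, grad
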