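"""Student-t slice attention.

Volumetric exams (e.g. knee MRI) arrive as ordered stacks of 2-D slices in
which diagnostically relevant content concentrates in the central slices
while the first and last few slices are mostly noise.  This module derives a
per-slice importance weighting from the slice features themselves:

1.  Each slice's feature map is summarised by global average and global max
    pooling (:func:`pool_slice_features`).
2.  Cross-similarities between the two descriptor sets give two row-stochastic
    S x S matrices (:func:`similarity_pair`).
3.  Averaging the matrices and summing over the row index for each column
    yields an initial weight per slice position (:func:`initial_weights`).
4.  A location-shifted Student-t density is fitted over the 1-based slice
    positions — its location is the weighted mean position, its degrees of
    freedom are moment-matched from the weighted position variance
    (:func:`fit_t_params`).
5.  Evaluating the density at the integer positions and normalising gives the
    final attention weights (:func:`slice_weights`), which multiply the
    feature maps slice-wise (:func:`apply_weights`).

The heavy tails of the Student-t make the weighting forgiving of exams whose
informative region is broad, while still suppressing the noisy end slices.
All steps are deterministic given the features; the fitted scalars (mu, nu)
and the resulting weights are treated as constants during backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, softmax

__all__ = [
    "FeatureMap",
    "PooledDescriptors",
    "SimilarityPair",
    "InitialWeights",
    "TParams",
    "AttentionWeights",
    "AttentionState",
    "TFitConfig",
    "pool_slice_features",
    "similarity_pair",
    "initial_weights",
    "fit_t_params",
    "t_pdf",
    "slice_weights",
    "apply_weights",
    "attend",
]


def _require_finite(a: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class FeatureMap:
    """Per-slice feature maps of one exam, shape (S, C, H, W)."""

    values: np.ndarray
    exam_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4:
            raise ValueError(f"feature map must be 4-D (S, C, H, W), got shape {v.shape}")
        if v.shape[0] < 1:
            raise ValueError("feature map needs at least one slice")
        _require_finite(v, "feature map")
        object.__setattr__(self, "values", v)

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PooledDescriptors:
    """Global average- and max-pooled slice descriptors, each (S, C)."""

    avg: np.ndarray
    max: np.ndarray

    def __post_init__(self) -> None:
        avg = np.atleast_2d(np.asarray(self.avg, dtype=float))
        mx = np.atleast_2d(np.asarray(self.max, dtype=float))
        if avg.shape != mx.shape:
            raise ValueError(f"avg {avg.shape} and max {mx.shape} descriptors must share shape")
        _require_finite(avg, "avg descriptors")
        _require_finite(mx, "max descriptors")
        object.__setattr__(self, "avg", avg)
        object.__setattr__(self, "max", mx)


@dataclass(frozen=True)
class SimilarityPair:
    """Row-stochastic cross-similarity matrices S1, S2 of shape (S, S)."""

    s1: np.ndarray
    s2: np.ndarray

    def __post_init__(self) -> None:
        s1 = np.atleast_2d(np.asarray(self.s1, dtype=float))
        s2 = np.atleast_2d(np.asarray(self.s2, dtype=float))
        for name, m in (("s1", s1), ("s2", s2)):
            if m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square, got {m.shape}")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        object.__setattr__(self, "s1", s1)
        object.__setattr__(self, "s2", s2)


@dataclass(frozen=True)
class InitialWeights:
    """Averaged similarity matrix D and normalised initial slice weights."""

    d: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float).ravel()
        if np.any(omega < 0) or not np.isclose(omega.sum(), 1.0, atol=1e-9):
            raise ValueError("omega must be non-negative and sum to 1")
        object.__setattr__(self, "d", np.atleast_2d(np.asarray(self.d, dtype=float)))
        object.__setattr__(self, "omega", omega)


@dataclass(frozen=True)
class TParams:
    """Fitted Student-t location (slice position, 1-based) and dof."""

    mu: float
    nu: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not np.isfinite(self.nu):
            raise ValueError("t parameters must be finite")
        if self.nu <= 0:
            raise ValueError(f"degrees of freedom must be positive, got {self.nu}")


@dataclass(frozen=True)
class AttentionWeights:
    """Normalised per-slice attention weights, length S."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float).ravel()
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("attention weights must be non-negative and sum to 1")
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class TFitConfig:
    """Controls the Student-t fit.

    nu
        If set, use this dof verbatim instead of moment matching (must be > 0).
    nu_min, nu_max
        Clamp range for the moment-matched dof.  The lower clamp keeps the
        fitted variance finite (dof > 2); the upper clamp bounds the density
        away from a degenerate spike when the weighted position variance
        collapses.
    """

    nu: float | None = None
    nu_min: float = 2.05
    nu_max: float = 200.0

    def __post_init__(self) -> None:
        if self.nu is not None and self.nu <= 0:
            raise ValueError("fixed nu must be positive")
        if not (0 < self.nu_min <= self.nu_max):
            raise ValueError("require 0 < nu_min <= nu_max")


@dataclass(frozen=True)
class AttentionState:
    """Every intermediate of the attention chain for one exam."""

    pooled: PooledDescriptors
    similarity: SimilarityPair
    initial: InitialWeights
    tparams: TParams
    weights: AttentionWeights


def pool_slice_features(m: FeatureMap) -> PooledDescriptors:
    """Summarise each slice by global average and global max pooling.

    The average descriptor captures global context per channel; the max
    descriptor captures the strongest local response.
    """
    v = m.values
    return PooledDescriptors(avg=v.mean(axis=(2, 3)), max=v.max(axis=(2, 3)))


def similarity_pair(p: PooledDescriptors, kind: str = "dot") -> SimilarityPair:
    """Cross-similarity matrices between average and max descriptors.

    s1 = row-softmax(avg @ max.T), s2 = row-softmax(max @ avg.T): each row is
    one slice's attention distribution over all slices (standard query/key
    convention).

    ``kind='dot'`` uses the raw dot products.  ``kind='cosine'`` L2-normalises
    each slice descriptor first, bounding the logits to [-1, 1]: raw dot
    products of unnormalised CNN features can span hundreds of units, which
    saturates the row softmax into near-one-hot form and makes the derived
    position statistics erratic; cosine similarity keeps the rows soft so the
    Student-t fit stays anchored near the centre of coherent feature clusters.
    """
    if kind == "cosine":
        avg = p.avg / np.maximum(np.linalg.norm(p.avg, axis=1, keepdims=True), 1e-12)
        mx = p.max / np.maximum(np.linalg.norm(p.max, axis=1, keepdims=True), 1e-12)
    elif kind == "dot":
        avg, mx = p.avg, p.max
    else:
        raise ValueError(f"unknown similarity kind {kind!r}")
    logits1 = avg @ mx.T
    logits2 = mx @ avg.T
    return SimilarityPair(s1=softmax(logits1, axis=1), s2=softmax(logits2, axis=1))


def initial_weights(sp: SimilarityPair) -> InitialWeights:
    """Initial per-slice weights from the averaged similarity matrix.

    D = (S1 + S2) / 2 is averaged over the row index for each column: column
    s collects how much attention every slice pays *to* slice s.  (Summing
    over the column index instead is degenerate — rows are stochastic, so it
    returns 1 for every slice.)  The column means are normalised to the
    simplex.
    """
    d = 0.5 * (sp.s1 + sp.s2)
    t = d.mean(axis=0)  # (1/S) * sum over row index k of D[k, s]
    return InitialWeights(d=d, omega=t / t.sum())


def fit_t_params(iw: InitialWeights, cfg: TFitConfig | None = None) -> TParams:
    """Fit the Student-t location and dof from the initial weights.

    Location is the weighted mean slice position mu = sum_s omega_s * s
    (1-based positions).  The dof are moment-matched from the weighted
    position variance v = sum_s omega_s * (s - mu)^2: a unit-scale Student-t
    has variance nu/(nu-2), so nu = 2v/(v-1) when v > 1.  Degenerate cases
    (single slice, v <= 1, i.e. weights at least as concentrated as the
    distribution can express) clamp to nu_max, giving a near-point weighting.
    """
    cfg = cfg or TFitConfig()
    omega = iw.omega
    s = np.arange(1, omega.size + 1, dtype=float)
    mu = float(omega @ s)
    if cfg.nu is not None:
        return TParams(mu=mu, nu=float(cfg.nu))
    v = float(omega @ (s - mu) ** 2)
    if v <= 1.0:
        nu = cfg.nu_max
    else:
        nu = 2.0 * v / (v - 1.0)
    return TParams(mu=mu, nu=float(np.clip(nu, cfg.nu_min, cfg.nu_max)))


def t_pdf(x, tp: TParams):
    """Unit-scale, location-shifted Student-t density.

    f(x) = Gamma((nu+1)/2) / (Gamma(nu/2) * sqrt(nu*pi))
           * (1 + (x-mu)^2/nu)^(-(nu+1)/2)

    Evaluated in log space via gammaln for numerical stability at large nu.
    Scalar in, scalar out; array in, array out.
    """
    x = np.asarray(x, dtype=float)
    nu, mu = tp.nu, tp.mu
    logc = gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0) - 0.5 * np.log(nu * np.pi)
    logk = -(nu + 1.0) / 2.0 * np.log1p((x - mu) ** 2 / nu)
    out = np.exp(logc + logk)
    return float(out) if out.ndim == 0 else out


def slice_weights(s: int, tp: TParams) -> AttentionWeights:
    """Normalised Student-t weights at the 1-based slice positions 1..S."""
    if s < 1:
        raise ValueError("need at least one slice")
    if s == 1:
        return AttentionWeights(w=np.ones(1))
    dens = t_pdf(np.arange(1, s + 1, dtype=float), tp)
    return AttentionWeights(w=dens / dens.sum())


def apply_weights(m: FeatureMap, aw: AttentionWeights) -> FeatureMap:
    """Multiply each slice's feature map by its attention weight."""
    if aw.w.size != m.n_slices:
        raise ValueError(
            f"weight length {aw.w.size} does not match slice count {m.n_slices}"
        )
    return FeatureMap(values=m.values * aw.w[:, None, None, None], exam_id=m.exam_id)


def attend(m: FeatureMap, cfg: TFitConfig | None = None,
           similarity: str = "dot") -> tuple[FeatureMap, AttentionState]:
    """Run the full attention chain on one exam's feature maps.

    Returns the re-weighted feature maps and every intermediate (useful for
    diagnostics and for exporting per-exam attention statistics).
    ``similarity`` selects the logit form of :func:`similarity_pair`.
    """
    pooled = pool_slice_features(m)
    sims = similarity_pair(pooled, kind=similarity)
    init = initial_weights(sims)
    tp = fit_t_params(init, cfg)
    w = slice_weights(m.n_slices, tp)
    state = AttentionState(pooled=pooled, similarity=sims, initial=init, tparams=tp, weights=w)
    return apply_weights(m, w), state
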