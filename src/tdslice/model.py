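"""Slice-stack classifier.

One exam = an ordered stack of grayscale slices.  The forward pass is:

    slices -> (replicate to 3 channels, resize) -> backbone CNN ->
    per-slice feature maps M (S, C', H', W') ->
    [optional] Student-t slice attention re-weighting ->
    per-slice global average pooling (S, C') ->
    coordinatewise max over slices (C')  ->
    dense head -> softmax class probabilities.

Max fusion keeps, for every feature coordinate, the strongest response across
slices, so the exam-level vector is dominated by the most salient slice; the
attention weighting suppresses noisy end slices before that competition.

The attention statistics (mu, nu, weights) are recomputed on every forward
pass from the current features but are treated as constants during
backpropagation: gradients flow through the product w * M with w detached.
The mechanism therefore adds no learned parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from . import attention as att
from .backbones import build_backbone
from .nn import Linear, VecNorm, softmax

__all__ = ["BackboneSpec", "ExamPrediction", "SliceClassifier", "aggregate_max"]


@dataclass(frozen=True)
class BackboneSpec:
    """Which trunk to use and at what input resolution."""

    name: str = "tiny"
    image_size: int = 64
    pretrained: bool = False  # reserved; no pretrained weights ship with the package

    def __post_init__(self) -> None:
        if self.pretrained:
            raise ValueError("no pretrained weights are available for these backbones")
        if self.image_size < 16 or self.image_size % 16:
            raise ValueError("image_size must be a positive multiple of 16")


@dataclass(frozen=True)
class ExamPrediction:
    exam_id: str
    score: float  # positive-class probability
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float).ravel()
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError("probabilities must lie on the simplex")
        if not np.isclose(self.score, p[1], atol=1e-9):
            raise ValueError("score must equal the positive-class probability")
        object.__setattr__(self, "probs", p)


def aggregate_max(vectors) -> np.ndarray:
    """Coordinatewise maximum over S equal-length per-slice vectors."""
    rows = [np.asarray(v, dtype=float).ravel() for v in vectors]
    if len(rows) == 0:
        raise ValueError("need at least one slice vector")
    n = rows[0].size
    if any(r.size != n for r in rows):
        raise ValueError("ragged input: slice vectors must have equal length")
    return np.max(np.stack(rows), axis=0)


class SliceClassifier:
    """Backbone + optional slice attention + max fusion + dense head."""

    def __init__(
        self,
        backbone: str | BackboneSpec = "tiny",
        n_classes: int = 2,
        attention: bool = True,
        tfit: att.TFitConfig | None = None,
        seed: int = 0,
        dtype=np.float32,
    ):
        spec = backbone if isinstance(backbone, BackboneSpec) else BackboneSpec(name=backbone)
        self.spec = spec
        self.n_classes = n_classes
        self.attention = bool(attention)
        self.tfit = tfit or att.TFitConfig()
        self.dtype = np.dtype(dtype)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.trunk, self.c_out, self.downsample = build_backbone(spec.name, rng, self.dtype)
        # per-slice descriptor = [global avg || global max] over the spatial axes;
        # the fused exam vector is layer-normalised so logits stay bounded
        self.norm = VecNorm()
        self.head = Linear(2 * self.c_out, n_classes, rng=rng, dtype=self.dtype)
        self._cache = None

    # ------------------------------------------------------------------ setup

    def parameters(self):
        return self.trunk.params() + self.head.params()

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # ------------------------------------------------------------- data prep

    def prepare_stack(self, slices: np.ndarray) -> np.ndarray:
        """Grayscale stack (S, H, W) -> model input (S, 3, size, size)."""
        x = np.asarray(slices, dtype=float)
        if x.ndim != 3 or x.shape[0] < 1:
            raise ValueError("expected a non-empty (S, H, W) grayscale stack")
        size = self.spec.image_size
        if x.shape[1:] != (size, size):
            x = _sk_resize(x, (x.shape[0], size, size), order=1, preserve_range=True,
                           anti_aliasing=False)
        x = np.repeat(x[:, None, :, :], 3, axis=1)  # grayscale -> 3 channels
        x = (x - 0.4) / 0.3  # fixed intensity centering for [0, 1] grayscale input
        return np.ascontiguousarray(x, dtype=self.dtype)

    # ---------------------------------------------------------------- forward

    def forward(self, slices: np.ndarray, exam_id: str = "", train: bool = False):
        """Predict one exam.  With ``train=True`` intermediates are cached for
        :meth:`backward`.  Returns (ExamPrediction, AttentionState | None)."""
        x = self.prepare_stack(slices)
        m = self.trunk.forward(x)  # (S, C', H', W')
        state = None
        if self.attention:
            # cosine similarity keeps the position fit stable on raw
            # (unnormalised) CNN features; see the attention module docs
            weighted, state = att.attend(att.FeatureMap(m.astype(np.float64)),
                                         self.tfit, similarity="cosine")
            w = state.weights.w.astype(self.dtype)
            m_att = m * w[:, None, None, None]
        else:
            w = None
            m_att = m
        s, cch, hh, ww_ = m_att.shape
        flat = m_att.reshape(s, cch, hh * ww_)
        # per-slice descriptor: global average and global max over space
        vecs = np.concatenate([flat.mean(axis=2), flat.max(axis=2)], axis=1)  # (S, 2C')
        sp_argmax = flat.argmax(axis=2)  # winning spatial cell per slice/channel
        argmax = vecs.argmax(axis=0)  # winning slice per feature coordinate
        fused = vecs.max(axis=0)
        logits = self.head.forward(self.norm.forward(fused))
        probs = softmax(logits.astype(np.float64))
        if train:
            self._cache = {"w": w, "argmax": argmax, "sp_argmax": sp_argmax,
                           "m_shape": m.shape}
        pred = ExamPrediction(exam_id=exam_id, score=float(probs[1]), probs=probs)
        return pred, state

    def predict_score(self, slices: np.ndarray) -> float:
        return self.forward(slices)[0].score

    # --------------------------------------------------------------- backward

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate from d loss / d logits through head, fusion,
        attention scaling (weights detached) and the backbone trunk."""
        if self._cache is None:
            raise RuntimeError("call forward(..., train=True) before backward()")
        c = self._cache
        dfused = self.norm.backward(self.head.backward(dlogits.astype(self.dtype)))
        s, cch, hh, ww = c["m_shape"]
        dvecs = np.zeros((s, 2 * cch), dtype=self.dtype)
        dvecs[c["argmax"], np.arange(2 * cch)] = dfused  # max fusion routes to winners
        davg, dmax = dvecs[:, :cch], dvecs[:, cch:]
        dm = np.broadcast_to(davg[:, :, None, None], c["m_shape"]) / (hh * ww)
        dflat = np.zeros((s, cch, hh * ww), dtype=self.dtype)
        np.put_along_axis(dflat, c["sp_argmax"][..., None], dmax[..., None], axis=2)
        dm = dm + dflat.reshape(c["m_shape"])
        if c["w"] is not None:
            dm = dm * c["w"][:, None, None, None]
        self.trunk.backward(np.ascontiguousarray(dm))
        self._cache = None

    # ------------------------------------------------------------ persistence

    def save(self, path) -> None:
        """Single-file checkpoint: weights + config (npz archive)."""
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        config = {
            "backbone": self.spec.name,
            "image_size": self.spec.image_size,
            "n_classes": self.n_classes,
            "attention": self.attention,
            "tfit": {"nu": self.tfit.nu, "nu_min": self.tfit.nu_min,
                     "nu_max": self.tfit.nu_max},
            "seed": self.seed,
            "dtype": self.dtype.name,
        }
        np.savez(path, __config__=np.frombuffer(json.dumps(config).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "SliceClassifier":
        with np.load(path) as z:
            config = json.loads(bytes(z["__config__"]).decode())
            model = cls(
                backbone=BackboneSpec(name=config["backbone"],
                                      image_size=config["image_size"]),
                n_classes=config["n_classes"],
                attention=config["attention"],
                tfit=att.TFitConfig(**config["tfit"]),
                seed=config["seed"],
                dtype=np.dtype(config["dtype"]),
            )
            for i, p in enumerate(model.parameters()):
                p.value[...] = z[f"param_{i}"]
        return model

    def state_copy(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v
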