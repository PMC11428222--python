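"""Synthetic knee-MRI-style exam generator.

Emulates the statistical structure the slice-attention model assumes, without
any real patient data:

* each exam is an ordered stack of S grayscale slices, S drawn uniformly from
  a configurable range (real knee series run 17-61 slices);
* a smooth "anatomy" background of soft blobs is shared across slices with a
  small slice-to-slice drift, plus Gaussian pixel noise;
* the first and last few slices are pure noise — no anatomy — mirroring the
  uninformative sequence ends of real series;
* positive exams carry a circular lesion stamped into a contiguous run of
  slices whose centre slice is drawn around the middle of the stack, so the
  diagnostic signal concentrates centrally;
* labels are Bernoulli draws at a configurable prevalence (default 0.2,
  approximating the ACL-tear fraction of public knee-MRI cohorts).

The generator is deterministic given its seed, which makes every downstream
experiment byte-reproducible.  It is a structural phantom, not a physical MRI
simulation: there is no k-space, bias field or sequence physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SyntheticSpec",
    "SliceStack",
    "DatasetSplit",
    "generate_exam",
    "generate_dataset",
    "stratified_split",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of the phantom cohort.

    Units: slice quantities in slices, spatial quantities in pixels,
    intensities on the [0, 1] grayscale scale.
    """

    n_exams: int = 250
    prevalence: float = 0.2
    slice_count_range: tuple[int, int] = (17, 61)
    image_size: int = 64
    lesion_center_sd: float = 1.5     # slices, around S/2
    lesion_radius: float = 6.0        # pixels
    lesion_contrast: float = 0.3      # added intensity at the lesion core
    lesion_span_frac: float = 0.25    # lesion run length as a fraction of S
    anatomy_blob_count: int = 5
    anatomy_blob_scale: float = 10.0  # pixels, blob radius scale
    noise_sd: float = 0.08
    end_noise_slices: int = 2         # irrelevant-noise slices at each end
    end_noise_sd: float = 0.0         # extra pixel noise on the end slices
    end_distractor_prob: float = 0.2  # chance an end slice carries a bright
                                      # lesion-like spot (label-independent)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.slice_count_range
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (1 <= lo <= hi <= 512):
            raise ValueError("slice_count_range must lie within [1, 512]")
        if min(self.lesion_center_sd, self.noise_sd, self.end_noise_sd,
               self.lesion_radius, self.lesion_contrast, self.anatomy_blob_scale) < 0:
            raise ValueError("spreads, radii and contrasts must be non-negative")
        if self.n_exams < 1 or self.image_size < 8:
            raise ValueError("need n_exams >= 1 and image_size >= 8")
        if not (0.0 <= self.end_distractor_prob <= 1.0):
            raise ValueError("end_distractor_prob must lie in [0, 1]")
        if 2 * self.end_noise_slices >= lo:
            raise ValueError("end_noise_slices would consume the whole shortest stack")


@dataclass(frozen=True)
class SliceStack:
    """One exam: ordered grayscale slices in [0, 1] plus its binary label."""

    exam_id: str
    slices: np.ndarray  # (S, H, W)
    label: int
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.slices, dtype=float)
        if s.ndim != 3 or s.shape[0] < 1:
            raise ValueError("slices must be a non-empty (S, H, W) array")
        if s.min() < 0 or s.max() > 1:
            raise ValueError("slice intensities must lie in [0, 1]")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        object.__setattr__(self, "slices", s)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass(frozen=True)
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split parts must be disjoint")

    def as_dict(self) -> dict:
        return asdict(self)


def _blob_background(spec: SyntheticSpec, s: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth anatomy: Gaussian blobs shared across slices with per-slice drift."""
    n, size = spec.anatomy_blob_count, spec.image_size
    centers = rng.uniform(0.15 * size, 0.85 * size, size=(n, 2))
    radii = spec.anatomy_blob_scale * rng.uniform(0.6, 1.6, size=n)
    amps = rng.uniform(0.25, 0.55, size=n)
    drift = rng.normal(0.0, 1.0, size=(s, n, 2)).cumsum(axis=0)  # random-walk drift
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    stack = np.zeros((s, size, size))
    for t in range(s):
        c = centers + drift[t]
        d2 = (yy[None] - c[:, 0, None, None]) ** 2 + (xx[None] - c[:, 1, None, None]) ** 2
        stack[t] = (amps[:, None, None] * np.exp(-d2 / (2 * radii[:, None, None] ** 2))).sum(axis=0)
    # soft-compress so overlapping blobs cannot saturate the grayscale range;
    # anatomy stays below ~0.75 and a bright lesion remains distinguishable
    return 0.6 * np.tanh(stack)


def _disk(spec: SyntheticSpec, cy: float, cx: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.image_size, 0 : spec.image_size].astype(float)
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return 1.0 / (1.0 + np.exp(dist - spec.lesion_radius))  # hard edge, thin rim


def _end_noise_slice(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """One irrelevant end slice.

    Marginally indistinguishable from an interior slice — same smooth-blob
    process, same intensity offset, same disk geometry — but its content is
    freshly drawn (decorrelated from the exam's anatomy) and, with
    probability ``end_distractor_prob``, it carries a bright lesion-like
    distractor that is independent of the label.  Only *position* separates
    this irrelevant content from a true lesion, which is exactly the premise
    a slice filter exploits.
    """
    size = spec.image_size
    n = spec.anatomy_blob_count
    centers = rng.uniform(0.15 * size, 0.85 * size, size=(n, 2))
    radii = spec.anatomy_blob_scale * rng.uniform(0.6, 1.6, size=n)
    amps = rng.uniform(0.25, 0.55, size=n)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    d2 = (yy[None] - centers[:, 0, None, None]) ** 2 + (xx[None] - centers[:, 1, None, None]) ** 2
    img = 0.15 + 0.6 * np.tanh(
        (amps[:, None, None] * np.exp(-d2 / (2 * radii[:, None, None] ** 2))).sum(axis=0)
    )
    if rng.random() < spec.end_distractor_prob:
        cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
        img = img + spec.lesion_contrast * _disk(spec, cy, cx)
    if spec.end_noise_sd > 0:
        img = img + rng.normal(0.0, spec.end_noise_sd, size=(size, size))
    return img


def _stamp_lesion(stack: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> dict:
    """Add a circular bright lesion to a contiguous central run of slices."""
    s, size = stack.shape[0], spec.image_size
    e = spec.end_noise_slices
    center_slice = int(round(rng.normal(s / 2.0, spec.lesion_center_sd)))
    # 1-based; clamped so the lesion run stays inside the informative interior
    # (the pure-noise end slices never carry signal)
    center_slice = int(np.clip(center_slice, e + 1, s - e))
    span = max(3, int(round(spec.lesion_span_frac * s)))
    lo = max(e + 1, center_slice - span // 2)
    hi = min(s - e, lo + span - 1)
    cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
    disk = _disk(spec, cy, cx)
    for t in range(lo - 1, hi):
        # taper the contrast toward the ends of the lesion run
        frac = 1.0 - abs((t + 1) - center_slice) / max(span, 1)
        stack[t] += spec.lesion_contrast * max(frac, 0.35) * disk
    return {
        "center_slice": center_slice,
        "first_slice": lo,
        "last_slice": hi,
        "center_px": (float(cy), float(cx)),
        "radius": spec.lesion_radius,
    }


def generate_exam(spec: SyntheticSpec, label: int, rng: np.random.Generator,
                  exam_id: str = "exam") -> SliceStack:
    """Draw one exam: anatomy + noise background, pure-noise ends, and (for
    positive labels) a central lesion.  ``truth`` records the placement."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    lo, hi = spec.slice_count_range
    s = int(rng.integers(lo, hi + 1))
    stack = 0.15 + _blob_background(spec, s, rng)
    e = spec.end_noise_slices
    if e > 0:
        # sequence ends carry irrelevant content unrelated to the exam's
        # anatomy or label: fresh smooth clutter, extra pixel noise, and
        # (with probability end_distractor_prob per slice) a bright
        # lesion-like spot — the "noise at the ends" a slice filter must
        # learn to ignore, because it fools max-fusion otherwise
        for t in list(range(e)) + list(range(s - e, s)):
            stack[t] = _end_noise_slice(spec, rng)
    truth: dict = {"lesion": None, "n_end_noise": e}
    if label == 1:
        truth["lesion"] = _stamp_lesion(stack, spec, rng)
    stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)
    return SliceStack(exam_id=exam_id, slices=np.clip(stack, 0.0, 1.0),
                      label=int(label), truth=truth)


def generate_dataset(spec: SyntheticSpec) -> list[SliceStack]:
    """Draw the full cohort; labels are Bernoulli(prevalence).

    Identical spec (including seed) reproduces the dataset bit-exactly: each
    exam gets an independent child generator spawned from the spec seed, so
    the draws for one exam never perturb another's.
    """
    root = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    labels = (label_rng.random(spec.n_exams) < spec.prevalence).astype(int)
    exams = []
    for i, child in enumerate(root.spawn(spec.n_exams + 1)[1:]):
        rng = np.random.default_rng(child)
        exams.append(generate_exam(spec, int(labels[i]), rng, exam_id=f"exam_{i:04d}"))
    return exams


def stratified_split(labels, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> DatasetSplit:
    """Class-stratified train/val/test allocation at the given ratios.

    ``labels`` may be a mapping exam_id -> label or a sequence (ids become
    their indices as strings).  Within each class, exams are shuffled
    (seeded) and cut at round(cumsum(ratios) * class size), so each part's
    prevalence matches the cohort's up to rounding.
    """
    if isinstance(labels, dict):
        ids = np.array(list(labels.keys()))
        y = np.array([labels[i] for i in ids], dtype=int)
    else:
        y = np.asarray(labels, dtype=int).ravel()
        ids = np.array([str(i) for i in range(y.size)])
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size != 3 or np.any(ratios < 0) or not np.isclose(ratios.sum(), 1.0):
        raise ValueError("ratios must be three non-negative numbers summing to 1")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present to stratify")
    n_parts = int(np.sum(ratios > 0))
    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[], [], []]
    for cls in classes:
        members = ids[y == cls]
        if members.size < n_parts:
            raise ValueError(
                f"class {cls} has {members.size} members but {n_parts} split parts"
            )
        members = members[rng.permutation(members.size)]
        cuts = np.round(np.cumsum(ratios) * members.size).astype(int)
        start = 0
        for k, stop in enumerate(cuts):
            parts[k].extend(members[start:stop].tolist())
            start = stop
    return DatasetSplit(train=sorted(parts[0]), val=sorted(parts[1]), test=sorted(parts[2]))
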