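"""On-disk layout mirroring the public knee-MRI dataset distribution:

    <dir>/
        labels.csv          # two columns: exam_id,label
        <exam_id>.npy       # one (S, H, W) float array per exam
        truth.json          # optional synthetic-lesion sidecar metadata

Round-trip identity is guaranteed: writing a cohort and reading it back
reproduces the arrays bit-exactly and the labels exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SliceStack

__all__ = ["write_exam_dir", "read_exam_dir"]


def write_exam_dir(path, stacks: list[SliceStack]) -> None:
    """Write one ``.npy`` stack per exam plus the label table (and a truth
    sidecar when any exam carries synthetic-lesion metadata)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = {}
    for st in stacks:
        np.save(path / f"{st.exam_id}.npy", st.slices)
        rows.append({"exam_id": st.exam_id, "label": st.label})
        if st.truth:
            truths[st.exam_id] = st.truth
    pd.DataFrame(rows).to_csv(path / "labels.csv", index=False)
    if truths:
        (path / "truth.json").write_text(json.dumps(truths, indent=2))


def read_exam_dir(path) -> list[SliceStack]:
    """Read a cohort back; validates referential integrity and array shape."""
    path = Path(path)
    label_file = path / "labels.csv"
    if not label_file.exists():
        raise FileNotFoundError(f"no label table at {label_file}")
    table = pd.read_csv(label_file)
    if not {"exam_id", "label"} <= set(table.columns):
        raise ValueError("label table must have columns exam_id,label")
    truths = {}
    truth_file = path / "truth.json"
    if truth_file.exists():
        truths = json.loads(truth_file.read_text())
    stacks = []
    for _, row in table.iterrows():
        exam_id, label = str(row["exam_id"]), int(row["label"])
        f = path / f"{exam_id}.npy"
        if not f.exists():
            raise FileNotFoundError(f"label table names exam {exam_id!r} but {f} is missing")
        arr = np.load(f)
        if arr.ndim != 3:
            raise ValueError(
                f"exam {exam_id!r} must be a 3-D grayscale stack, got shape {arr.shape}"
            )
        stacks.append(SliceStack(exam_id=exam_id, slices=arr, label=label,
                                 truth=truths.get(exam_id, {})))
    return stacks
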