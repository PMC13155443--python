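"""Core domain types and dataset/report I/O.

An :class:`ImageDataset` is an ordered collection of same-shape RGB images,
each carrying an *assigned* class label (possibly wrong) and, when ground
truth is known (synthetic data, audited subsets), a hidden *true* label.
Datasets travel on disk as a directory of 8-bit PNGs plus a CSV manifest
``file,label[,true_label]``; detection results travel as a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ClassVocabulary",
    "ImageDataset",
    "NoiseInjectionRecord",
    "MislabelReport",
    "load_dataset",
    "save_dataset",
    "one_hot",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class ClassVocabulary:
    """Ordered, unique class names; a name's index is its one-hot position."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("vocabulary needs at least 2 classes")
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "ClassVocabulary":
        # lexicographic order keeps one-hot positions stable across runs
        return cls(tuple(sorted(set(map(str, labels)))))

    @property
    def K(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return self.K

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)


@dataclass
class ImageDataset:
    """N same-shape RGB images with assigned (and optionally true) labels.

    ``images`` is float32 of shape (N, H, W, 3) with intensities in [0, 1],
    quantized to the 8-bit grid so that PNG round-trips are lossless.
    Labels are integer indices into ``vocabulary``.
    """

    images: np.ndarray
    assigned: np.ndarray
    vocabulary: ClassVocabulary
    true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError("images must have shape (N, H, W, 3)")
        self.assigned = np.asarray(self.assigned, dtype=np.int64)
        if self.assigned.shape != (len(self.images),):
            raise ValueError("one assigned label per image required")
        K = self.vocabulary.K
        if self.assigned.size and (self.assigned.min() < 0 or self.assigned.max() >= K):
            raise ValueError("assigned label index out of vocabulary range")
        if self.true is not None:
            self.true = np.asarray(self.true, dtype=np.int64)
            if self.true.shape != self.assigned.shape:
                raise ValueError("true labels must align with assigned labels")
            if self.true.size and (self.true.min() < 0 or self.true.max() >= K):
                raise ValueError("true label index out of vocabulary range")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return tuple(self.images.shape[1:])  # type: ignore[return-value]

    def label_names(self, indices: np.ndarray) -> list[str]:
        return [self.vocabulary.names[i] for i in np.asarray(indices)]

    def copy(self) -> "ImageDataset":
        return ImageDataset(
            self.images.copy(),
            self.assigned.copy(),
            self.vocabulary,
            None if self.true is None else self.true.copy(),
        )


@dataclass
class NoiseInjectionRecord:
    """Ground truth of injected label flips: (index, original, modified)."""

    flipped: list[tuple[int, int, int]]
    seed: int

    def __post_init__(self) -> None:
        self.flipped = [(int(i), int(a), int(b)) for i, a, b in self.flipped]
        idx = [i for i, _, _ in self.flipped]
        if len(set(idx)) != len(idx):
            raise ValueError("flip indices must be unique")
        if any(a == b for _, a, b in self.flipped):
            raise ValueError("a flip must change the label")

    @property
    def count(self) -> int:
        return len(self.flipped)

    @property
    def indices(self) -> set[int]:
        return {i for i, _, _ in self.flipped}

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": int(self.seed),
            "count": self.count,
            "flipped": [
                {"index": i, "original_label": a, "modified_label": b}
                for i, a, b in self.flipped
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "NoiseInjectionRecord":
        payload = json.loads(Path(path).read_text())
        flips = [
            (f["index"], f["original_label"], f["modified_label"])
            for f in payload["flipped"]
        ]
        rec = cls(flips, seed=int(payload["seed"]))
        if rec.count != payload.get("count", rec.count):
            raise ValueError("injection record count mismatch")
        return rec


@dataclass
class SampleEntry:
    """Per-sample detection outcome: ensemble predictions, votes, decisions."""

    index: int
    assigned_label: int
    predictions: list[dict]  # per classifier: {classifier, predicted, top_p}
    votes: int
    flagged: dict[str, bool]  # rule name -> decision
    recovered_label: int | None = None


@dataclass
class MislabelReport:
    """Full detection report: config echo plus one entry per sample."""

    config: dict
    samples: list[SampleEntry] = field(default_factory=list)

    REQUIRED_CONFIG = ("n_subsets", "m", "delta", "rules", "seed")

    def __post_init__(self) -> None:
        missing = [k for k in self.REQUIRED_CONFIG if k not in self.config]
        if missing:
            raise ValueError(f"report config echo missing keys: {missing}")
        m = int(self.config["m"])
        for s in self.samples:
            if not 0 <= s.votes <= m:
                raise ValueError(f"sample {s.index}: votes {s.votes} outside [0, {m}]")

    def flagged_set(self, rule: str) -> set[int]:
        return {s.index for s in self.samples if s.flagged.get(rule, False)}

    @property
    def rules(self) -> list[str]:
        return list(self.config["rules"])

    def entry(self, index: int) -> SampleEntry:
        for s in self.samples:
            if s.index == index:
                return s
        raise KeyError(index)


def one_hot(label: int, vocabulary: ClassVocabulary) -> np.ndarray:
    """Binary indicator vector of length K with a single 1 at ``label``."""
    label = int(label)
    if not 0 <= label < vocabulary.K:
        raise IndexError(f"label {label} out of range for K={vocabulary.K}")
    v = np.zeros(vocabulary.K, dtype=np.int64)
    v[label] = 1
    return v


def quantize01(images: np.ndarray) -> np.ndarray:
    """Snap float intensities in [0,1] onto the 8-bit grid (lossless PNG I/O)."""
    arr = np.clip(np.asarray(images, dtype=np.float64), 0.0, 1.0)
    return (np.round(arr * 255.0) / 255.0).astype(np.float32)


def save_dataset(dataset: ImageDataset, dir: str | os.PathLike) -> Path:
    """Write one PNG per item plus ``manifest.csv``; returns the manifest path.

    File names are deterministic functions of the item index, so saving the
    same dataset twice yields byte-identical manifests.
    """
    out = Path(dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(max(len(dataset) - 1, 0))))
    rows = []
    for i in range(len(dataset)):
        fname = f"img_{i:0{width}d}.png"
        arr8 = np.round(np.clip(dataset.images[i], 0, 1) * 255.0).astype(np.uint8)
        Image.fromarray(arr8, mode="RGB").save(out / fname)
        row = {"file": fname, "label": dataset.vocabulary.names[dataset.assigned[i]]}
        if dataset.true is not None:
            row["true_label"] = dataset.vocabulary.names[dataset.true[i]]
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, lineterminator="\n")
    return manifest


def load_dataset(manifest_path: str | os.PathLike) -> ImageDataset:
    """Read a manifest CSV (``file,label[,true_label]``) and its PNGs.

    Items keep manifest row order; the vocabulary is the lexicographically
    sorted set of labels seen (true labels included, so hidden classes keep
    stable indices).
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str)
    if "file" not in df.columns or "label" not in df.columns:
        raise ValueError("manifest must have columns 'file' and 'label'")
    if len(df) == 0:
        raise ValueError("no samples in manifest")
    has_true = "true_label" in df.columns
    labels = list(df["label"])
    if has_true:
        labels += list(df["true_label"])
    vocab = ClassVocabulary.from_labels(labels)
    base = manifest_path.parent
    images, shape = [], None
    for row_i, fname in enumerate(df["file"]):
        fpath = base / fname
        if not fpath.exists():
            raise FileNotFoundError(f"manifest row {row_i}: missing image file {fname}")
        arr = np.asarray(Image.open(fpath).convert("RGB"), dtype=np.float32) / 255.0
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"manifest row {row_i}: image shape {arr.shape} != {shape}"
            )
        images.append(arr)
    assigned = np.array([vocab.index(l) for l in df["label"]], dtype=np.int64)
    true = (
        np.array([vocab.index(l) for l in df["true_label"]], dtype=np.int64)
        if has_true
        else None
    )
    return ImageDataset(np.stack(images), assigned, vocab, true)


def write_report(report: MislabelReport, path: str | os.PathLike) -> None:
    payload = {
        "config": report.config,
        "samples": [dataclasses.asdict(s) for s in report.samples],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_report(path: str | os.PathLike) -> MislabelReport:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed report JSON at line {e.lineno} col {e.colno}") from e
    if "config" not in payload or "samples" not in payload:
        raise ValueError("report missing 'config' or 'samples' section")
    samples = [
        SampleEntry(
            index=int(s["index"]),
            assigned_label=int(s["assigned_label"]),
            predictions=list(s["predictions"]),
            votes=int(s["votes"]),
            flagged={str(k): bool(v) for k, v in s["flagged"].items()},
            recovered_label=(
                None if s.get("recovered_label") is None else int(s["recovered_label"])
            ),
        )
        for s in payload["samples"]
    ]
    return MislabelReport(config=payload["config"], samples=samples)
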