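"""Synthetic data: nanopore-like current traces, segment images, stand-in sets.

Solid-state nanopore recordings are a baseline ionic current with transient
deflections whenever a particle translocates the pore; the deflection depth
and dwell time depend on what the particle carries (an empty capsid blocks
less current than one packed with dsDNA). The simulator here reproduces that
morphology — baseline + Gaussian noise + Poisson-arriving rectangular
blockade pulses with per-class depth/dwell distributions — and renders fixed
duration segments as small RGB line plots, mirroring the preprocessing that
turns a long trace into a CNN-ready image dataset.

A second generator produces a generic well-separated multi-class image set
(distinct per-class template patterns plus jitter and pixel noise), a
desk-scale stand-in for handwritten-digit style benchmarks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import ClassVocabulary, ImageDataset, NoiseInjectionRecord, quantize01

__all__ = [
    "TraceParams",
    "RenderConfig",
    "SignalTrace",
    "simulate_trace",
    "segment_trace",
    "render_segment",
    "make_nanopore_dataset",
    "make_stand_in_dataset",
    "inject_mislabels",
    "load_trace_csv",
    "DEFAULT_SAMPLE_RATE",
]

logger = logging.getLogger(__name__)

#: Samples per second such that a 1-second segment holds 250,000 points.
DEFAULT_SAMPLE_RATE = 250_000.0


@dataclass(frozen=True)
class TraceParams:
    """Per-class statistical signature of a translocation trace.

    Currents are in arbitrary units (the detector never sees absolute
    scale, only the rendered image). ``amplitude_*`` is the blockade depth
    subtracted from the baseline during an event; ``dwell_*`` is the event
    duration in seconds.
    """

    baseline: float = 100.0
    noise_sd: float = 2.0
    event_rate: float = 10.0
    amplitude_mean: float = 45.0
    amplitude_sd: float = 2.0
    dwell_mean: float = 0.05
    dwell_sd: float = 0.0125

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be > 0")


@dataclass(frozen=True)
class RenderConfig:
    """How a segment is rasterized: canvas size, fixed y-range, colors.

    y_limits are shared across *all* segments; per-segment autoscaling would
    leak class identity through the axis scale.
    """

    width: int = 32
    height: int = 32
    y_limits: tuple[float, float] = (0.0, 120.0)
    line_rgb: tuple[float, float, float] = (0.1, 0.2, 0.7)
    background_rgb: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if not self.y_limits[0] < self.y_limits[1]:
            raise ValueError("y_limits must satisfy lo < hi")


@dataclass
class SignalTrace:
    """A simulated (or imported) current-vs-time series at a fixed rate."""

    samples: np.ndarray
    sample_rate: float
    class_kind: int
    seed: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


def simulate_trace(
    params: TraceParams,
    duration_s: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    class_kind: int = 0,
    seed: int = 0,
) -> SignalTrace:
    """Simulate a translocation trace of ``duration_s`` seconds.

    The trace is baseline + N(0, noise_sd) white noise; event count is
    Poisson(event_rate * duration), start times uniform, each event a
    rectangular blockade of depth ~ N(amplitude_mean, amplitude_sd) lasting
    dwell ~ N(dwell_mean, dwell_sd) truncated above zero. Fully reproducible
    from ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    samples = np.full(n, params.baseline, dtype=np.float64)
    if params.noise_sd > 0:
        samples += rng.normal(0.0, params.noise_sd, size=n)
    n_events = rng.poisson(params.event_rate * duration_s)
    if n_events:
        starts = rng.uniform(0.0, duration_s, size=n_events)
        depths = rng.normal(params.amplitude_mean, params.amplitude_sd, size=n_events)
        dwells = rng.normal(params.dwell_mean, params.dwell_sd, size=n_events)
        tiny = 1.0 / sample_rate  # truncate dwell strictly above zero
        dwells = np.maximum(dwells, tiny)
        for t0, depth, dw in zip(starts, depths, dwells):
            i0 = int(t0 * sample_rate)
            i1 = min(n, int((t0 + dw) * sample_rate) + 1)
            samples[i0:i1] -= depth
    return SignalTrace(samples, sample_rate, class_kind=class_kind, seed=seed)


def segment_trace(trace: SignalTrace, segment_s: float = 1.0) -> list[np.ndarray]:
    """Split into consecutive non-overlapping windows; trailing partial dropped."""
    if segment_s <= 0:
        raise ValueError("segment_s must be positive")
    win = int(round(segment_s * trace.sample_rate))
    n_win = len(trace.samples) // win
    return [trace.samples[i * win : (i + 1) * win] for i in range(n_win)]


def render_segment(window: np.ndarray, config: RenderConfig) -> np.ndarray:
    """Rasterize one window as a (height, width, 3) float image in [0, 1].

    Column-envelope rendering: each pixel column covers an equal span of
    samples and is stroked from that span's minimum to its maximum (joined
    to the previous column's last value so the trace is continuous). This is
    what a line plot of many points per pixel converges to, and it is a pure
    function of (window, config). Values outside ``y_limits`` are clipped
    with a logged warning.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    lo, hi = config.y_limits
    if window.min() < lo or window.max() > hi:
        warnings.warn("segment values outside y_limits were clipped", stacklevel=2)
        window = np.clip(window, lo, hi)
    W, H = config.width, config.height
    img = np.empty((H, W, 3), dtype=np.float32)
    img[:] = np.asarray(config.background_rgb, dtype=np.float32)
    # map a current value to a pixel row (row 0 = top = y_limits hi)
    def to_row(v: np.ndarray) -> np.ndarray:
        frac = (v - lo) / (hi - lo)
        return np.clip(((1.0 - frac) * (H - 1)).round().astype(int), 0, H - 1)

    edges = np.linspace(0, window.size, W + 1).round().astype(int)
    line = np.asarray(config.line_rgb, dtype=np.float32)
    prev = window[0]
    for j in range(W):
        a, b = edges[j], edges[j + 1]
        span = window[a:b] if b > a else window[max(a - 1, 0) : a + 1]
        vlo = min(span.min(), prev)
        vhi = max(span.max(), prev)
        r0, r1 = to_row(np.array([vhi, vlo]))
        img[r0 : r1 + 1, j, :] = line
        prev = span[-1]
    return quantize01(img)


def make_nanopore_dataset(
    class_specs: dict[str, tuple[TraceParams, float]],
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    render: RenderConfig | None = None,
    segment_s: float = 1.0,
    seed: int = 0,
) -> ImageDataset:
    """Simulate one trace per class, segment, render, and assemble a dataset.

    ``class_specs`` maps class name -> (TraceParams, duration_s). Per-class
    image count is floor(duration_s / segment_s). Items are grouped by class
    in vocabulary order; labels are the class names.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    names = list(class_specs)
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")
    render = render or RenderConfig()
    vocab = ClassVocabulary.from_labels(names)
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for name in vocab.names:
        params, duration = class_specs[name]
        trace_seed = int(rng.integers(0, 2**31 - 1))
        trace = simulate_trace(
            params, duration, sample_rate, class_kind=vocab.index(name), seed=trace_seed
        )
        for window in segment_trace(trace, segment_s):
            images.append(render_segment(window, render))
            labels.append(vocab.index(name))
    return ImageDataset(
        np.stack(images), np.asarray(labels), vocab, true=np.asarray(labels)
    )


def _class_template(class_i: int, size: tuple[int, int]) -> np.ndarray:
    """Deterministic per-class RGB template: a smoothed thresholded random field.

    Seeded by the class index only, so the template is a fixed identity mark;
    distinct classes get visually distinct blob patterns.
    """
    from scipy.ndimage import gaussian_filter

    h, w = size
    rng = np.random.default_rng(1_000_003 + class_i)
    field = gaussian_filter(rng.normal(size=(h, w)), sigma=min(h, w) / 8.0)
    mask = field > np.quantile(field, 0.7)
    color = rng.uniform(0.3, 1.0, size=3)
    img = np.zeros((h, w, 3), dtype=np.float64)
    img[mask] = color
    return img


def make_stand_in_dataset(
    n_classes: int = 10,
    per_class: int = 100,
    image_size: tuple[int, int] = (28, 28),
    jitter_sd: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ImageDataset:
    """Generic separable multi-class image set (digit-benchmark stand-in).

    Each class has a fixed template pattern; each sample is the template
    shifted by an integer jitter ~ round(N(0, jitter_sd)) per axis plus
    N(0, noise_sd) pixel noise, clipped to [0, 1]. Separability is dialed by
    ``jitter_sd`` and ``noise_sd`` (both zero gives identical same-class
    images).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = ClassVocabulary(tuple(f"class_{i:02d}" for i in range(n_classes)))
    templates = [_class_template(c, image_size) for c in range(n_classes)]
    images, labels = [], []
    for c in range(n_classes):
        for _ in range(per_class):
            img = templates[c]
            if jitter_sd > 0:
                dy, dx = np.round(rng.normal(0, jitter_sd, size=2)).astype(int)
                img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
            if noise_sd > 0:
                img = img + rng.normal(0, noise_sd, size=img.shape)
            images.append(quantize01(img))
            labels.append(c)
    return ImageDataset(
        np.stack(images), np.asarray(labels), vocab, true=np.asarray(labels)
    )


def inject_mislabels(
    dataset: ImageDataset, count: int, seed: int = 0
) -> tuple[ImageDataset, NoiseInjectionRecord]:
    """Flip ``count`` labels chosen uniformly without replacement.

    Each chosen sample's assigned label is replaced by a uniformly chosen
    *different* class; the original is preserved in ``true``. Returns the
    modified copy and the ground-truth record.
    """
    n = len(dataset)
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, {n}]")
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    if out.true is None:
        out.true = out.assigned.copy()
    K = dataset.vocabulary.K
    idx = rng.choice(n, size=count, replace=False) if count else np.array([], dtype=int)
    flips = []
    for i in np.sort(idx):
        orig = int(out.assigned[i])
        # uniform over the K-1 other classes
        new = int(rng.integers(0, K - 1))
        if new >= orig:
            new += 1
        out.assigned[i] = new
        flips.append((int(i), orig, new))
    return out, NoiseInjectionRecord(flips, seed=seed)


def load_trace_csv(
    path, sample_rate: float | None = None, class_kind: int = 0
) -> SignalTrace:
    """Import a two-column ``time_s,current`` CSV recorded at a fixed rate."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace CSV needs two columns: time_s,current")
    t = df.iloc[:, 0].to_numpy(dtype=np.float64)
    cur = df.iloc[:, 1].to_numpy(dtype=np.float64)
    if sample_rate is None:
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-3):
            raise ValueError("cannot infer a fixed sample rate from time column")
        sample_rate = 1.0 / dt[0]
    return SignalTrace(cur, sample_rate, class_kind=class_kind, seed=-1)
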