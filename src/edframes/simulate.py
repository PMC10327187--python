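"""Electron-counting detector simulator.

Generates ground-truthed test frames by the same mechanism the model in
:mod:`edframes.coincidence` describes: electrons arrive on each pixel as a
Poisson process, each electron is assigned uniformly at random to one of
the ``M`` internal frames of a batch, each internal frame is binarized per
pixel (at most one electron can be registered on a given pixel per
internal frame), and the batch output is the sum of the internal frames —
so the recorded value is the number of *occupied* internal frames, capped
at ``M``, and coincidence loss emerges naturally.

A synthetic diffraction-pattern generator layers Gaussian Bragg spots on a
square lattice over a flat background, with spot intensity decaying
exponentially with resolution (distance from the beam centre), emulating
the strong-low-resolution / weak-high-resolution structure of a real
macromolecular pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .kernels import KernelBank, clipped_kernel, default_kernel_bank

__all__ = [
    "EventField",
    "InternalFrameStack",
    "BatchFrame",
    "PatternSpec",
    "EventList",
    "count_coincidence",
    "simulate_counts",
    "simulate_pattern",
    "render_events_with_kernels",
]

RngLike = Union[int, np.random.Generator, None]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class EventField:
    """Expected electron fluence per pixel per batch (electrons/pixel)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 2:
            raise ValueError("rates must be a 2-D image")
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("rates must be finite and nonnegative")
        object.__setattr__(self, "rates", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rates.shape

    @property
    def height(self) -> int:
        return self.rates.shape[0]

    @property
    def width(self) -> int:
        return self.rates.shape[1]


@dataclass(frozen=True)
class InternalFrameStack:
    """``M`` binary per-pixel frames; the pre-summation detector state."""

    frames: np.ndarray  # (M, H, W), values in {0, 1}

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (M, H, W) stack")
        if not np.isin(f, (0, 1)).all():
            raise ValueError("internal frame pixel values must be 0 or 1")
        object.__setattr__(self, "frames", f.astype(np.uint8))

    @property
    def frames_per_batch(self) -> int:
        return self.frames.shape[0]

    def sum(self) -> "BatchFrame":
        """Sum the internal frames into the camera's batch output."""
        return BatchFrame(self.frames.sum(axis=0, dtype=np.int64),
                          self.frames_per_batch)


@dataclass(frozen=True)
class BatchFrame:
    """Integer image with per-pixel values capped at ``frames_per_batch``."""

    data: np.ndarray
    frames_per_batch: int

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2 or not np.issubdtype(d.dtype, np.integer):
            raise ValueError("BatchFrame data must be a 2-D integer image")
        if self.frames_per_batch < 1:
            raise ValueError("frames_per_batch must be >= 1")
        if d.size and (d.min() < 0 or d.max() > self.frames_per_batch):
            raise ValueError(
                "BatchFrame values must lie in [0, frames_per_batch]"
            )
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class EventList:
    """Discrete electron events: pixel, sub-pixel offset, internal frame."""

    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    frame: np.ndarray

    def __post_init__(self) -> None:
        arrs = {
            "x": np.asarray(self.x, dtype=np.int64),
            "y": np.asarray(self.y, dtype=np.int64),
            "dx": np.asarray(self.dx, dtype=float),
            "dy": np.asarray(self.dy, dtype=float),
            "frame": np.asarray(self.frame, dtype=np.int64),
        }
        n = len(arrs["x"])
        if any(len(a) != n for a in arrs.values()):
            raise ValueError("event arrays must have equal length")
        if n and (arrs["dx"].min() < 0 or arrs["dx"].max() >= 1
                  or arrs["dy"].min() < 0 or arrs["dy"].max() >= 1):
            raise ValueError("sub-pixel offsets must lie in [0, 1)")
        for k, a in arrs.items():
            object.__setattr__(self, k, a)

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def empty(cls) -> "EventList":
        z = np.empty(0)
        return cls(z, z, z, z, z)


@dataclass(frozen=True)
class PatternSpec:
    """Geometry and rates of a synthetic diffraction pattern.

    ``peak_intensity`` is the expected *integrated* electron count of the
    strongest (lowest-resolution) spot per batch; spot amplitudes decay as
    ``exp(-resolution_falloff * r)`` with ``r`` the distance of the spot
    centre from the beam centre in pixels.  ``background_rate`` is in
    electrons per pixel per batch.
    """

    width: int = 512
    height: int = 512
    beam_center: tuple[float, float] = (255.5, 255.5)  # (x, y), pixels
    lattice_spacing: float = 32.0
    spot_sigma: float = 1.2
    peak_intensity: float = 50.0
    resolution_falloff: float = 0.01
    background_rate: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if self.lattice_spacing <= 0:
            raise ValueError("lattice_spacing must be positive")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if (self.peak_intensity < 0 or self.background_rate < 0
                or self.resolution_falloff < 0):
            raise ValueError("rates must be nonnegative")


def count_coincidence(true_counts: np.ndarray, M: int,
                      seed: RngLike = None) -> np.ndarray:
    """Recorded counts after uniform frame assignment and binarization.

    For each element of ``true_counts`` (true electrons on one pixel in
    one batch), assigns every electron independently and uniformly to one
    of ``M`` internal frames and returns the number of occupied frames —
    the value the camera records.  Vectorized over arbitrarily shaped
    inputs; ``recorded <= min(true, M)`` elementwise.
    """
    if M < 1:
        raise ValueError("frames per batch M must be >= 1")
    true = np.asarray(true_counts)
    if true.size and true.min() < 0:
        raise ValueError("true counts must be nonnegative")
    rng = _as_rng(seed)
    flat = true.ravel().astype(np.int64)
    pixel = np.repeat(np.arange(flat.size, dtype=np.int64), flat)
    frames = rng.integers(0, M, size=pixel.size)
    occupied = np.unique(pixel * M + frames)
    rec = np.bincount(occupied // M, minlength=flat.size)
    return rec.reshape(true.shape)


def simulate_counts(
    field: EventField, M: int, seed: RngLike = None
) -> tuple[BatchFrame, np.ndarray, EventList]:
    """Simulate one counted batch over an expected-fluence field.

    Per pixel the true electron count is Poisson with the field's rate;
    each electron receives a uniform internal-frame index and a uniform
    sub-pixel offset in [0, 1)^2.  Returns the recorded
    :class:`BatchFrame` (occupied internal frames per pixel), the true
    count image, and the ground-truth :class:`EventList`.  Reproducible
    under a fixed seed.
    """
    if not isinstance(field, EventField):
        field = EventField(np.asarray(field))
    if M < 1:
        raise ValueError("frames per batch M must be >= 1")
    rng = _as_rng(seed)
    h, w = field.shape
    true = rng.poisson(field.rates).astype(np.int64)
    flat = true.ravel()
    pixel = np.repeat(np.arange(flat.size, dtype=np.int64), flat)
    n_events = pixel.size
    frames = rng.integers(0, M, size=n_events)
    dx = rng.random(n_events)
    dy = rng.random(n_events)
    occupied = np.unique(pixel * M + frames)
    rec = np.bincount(occupied // M, minlength=flat.size).reshape(h, w)
    events = EventList(x=pixel % w, y=pixel // w, dx=dx, dy=dy, frame=frames)
    return BatchFrame(rec, M), true, events


def pattern_field(spec: PatternSpec) -> EventField:
    """Expected-fluence field of a synthetic diffraction pattern.

    Flat background plus normalized Gaussian spots centred on a square
    lattice around the beam centre, each spot's integrated intensity being
    ``peak_intensity * exp(-resolution_falloff * r)``.
    """
    h, w = spec.height, spec.width
    rates = np.full((h, w), float(spec.background_rate))
    cx, cy = spec.beam_center
    a = spec.lattice_spacing
    sig = spec.spot_sigma
    margin = 4.0 * sig
    i_lo = int(np.floor((-margin - cx) / a))
    i_hi = int(np.ceil((w - 1 + margin - cx) / a))
    j_lo = int(np.floor((-margin - cy) / a))
    j_hi = int(np.ceil((h - 1 + margin - cy) / a))
    norm = 1.0 / (2.0 * np.pi * sig * sig)
    for j in range(j_lo, j_hi + 1):
        sy = cy + j * a
        for i in range(i_lo, i_hi + 1):
            sx = cx + i * a
            r = np.hypot(sx - cx, sy - cy)
            amp = spec.peak_intensity * np.exp(-spec.resolution_falloff * r)
            if amp <= 0:
                continue
            x0, x1 = max(0, int(sx - margin)), min(w, int(sx + margin) + 2)
            y0, y1 = max(0, int(sy - margin)), min(h, int(sy + margin) + 2)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (xx - sx) ** 2 + (yy - sy) ** 2
            rates[y0:y1, x0:x1] += amp * norm * np.exp(-d2 / (2 * sig * sig))
    return EventField(rates)


def simulate_pattern(
    spec: PatternSpec, M: int, seed: RngLike = None
) -> tuple[BatchFrame, EventField, EventList]:
    """Simulate one counted batch of a synthetic diffraction pattern.

    Builds the expected-fluence field with :func:`pattern_field` and
    delegates to :func:`simulate_counts`.  ``seed`` overrides
    ``spec.seed`` when given.
    """
    field = pattern_field(spec)
    if seed is None:
        seed = spec.seed
    frame, _true, events = simulate_counts(field, M, seed)
    return frame, field, events


def render_events_with_kernels(
    events: EventList,
    shape: tuple[int, int],
    bank: Optional[KernelBank] = None,
) -> np.ndarray:
    """Render discrete events into a float frame with sub-pixel kernels.

    Each event deposits its quadrant's kernel centred on its pixel; events
    near the edge deposit a clipped, renormalized kernel so the total
    frame sum equals the number of events to within 1e-6.
    """
    if bank is None:
        bank = default_kernel_bank()
    if not isinstance(bank, KernelBank):
        raise TypeError("bank must be a KernelBank")
    h, w = shape
    out = np.zeros((h, w))
    if len(events) == 0:
        return out
    if (events.x.min() < 0 or events.x.max() >= w
            or events.y.min() < 0 or events.y.max() >= h):
        raise ValueError("event coordinates out of image bounds")
    qy = (events.dy >= 0.5).astype(int)
    qx = (events.dx >= 0.5).astype(int)
    for i in range(len(events)):
        k = bank.kernel(qy[i], qx[i])
        patch, rs, cs = clipped_kernel(k, int(events.y[i]), int(events.x[i]),
                                       (h, w))
        out[rs, cs] += patch
    return out
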