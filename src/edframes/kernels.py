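"""Sub-pixel kernel banks.

Counting cameras that retain superresolution information in their summed
output blur each electron event over a small pixel neighbourhood with a
kernel chosen by the sub-pixel quadrant of the event's point of impact.
The same bank of kernels is used here both to render simulated events
(forward model) and to sharpen recorded frames back into discrete events
(inverse model), which makes round-trip tests self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelBank", "default_kernel_bank"]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class KernelBank:
    """Quadrant-indexed set of small normalized convolution kernels.

    ``kernels`` has shape ``(2, 2, k, k)`` and is indexed ``[qy, qx]``
    where ``qx = 1`` if the sub-pixel x-offset is >= 0.5 (event closer to
    the +x neighbour) and 0 otherwise, likewise ``qy``.  ``k`` is odd and
    every kernel is nonnegative and sums to 1 within 1e-12.
    """

    kernels: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.kernels, dtype=float)
        if k.ndim != 4 or k.shape[:2] != (2, 2) or k.shape[2] != k.shape[3]:
            raise ValueError("kernel bank must have shape (2, 2, k, k)")
        if k.shape[2] % 2 != 1:
            raise ValueError("kernel dimensions must be odd")
        if np.any(k < 0):
            raise ValueError("kernels must be nonnegative")
        sums = k.sum(axis=(2, 3))
        if np.any(np.abs(sums - 1.0) > _NORM_TOL):
            raise ValueError("every kernel must sum to 1 within 1e-12")
        object.__setattr__(self, "kernels", k)

    @property
    def size(self) -> int:
        """Kernel side length (odd)."""
        return self.kernels.shape[2]

    @property
    def radius(self) -> int:
        return self.size // 2

    def kernel(self, qy: int, qx: int) -> np.ndarray:
        return self.kernels[qy, qx]

    @staticmethod
    def quadrant(dx: float, dy: float) -> tuple[int, int]:
        """Map a sub-pixel offset ``(dx, dy)`` in [0, 1)^2 to ``(qy, qx)``."""
        return int(dy >= 0.5), int(dx >= 0.5)

    def kernel_for_offset(self, dx: float, dy: float) -> np.ndarray:
        qy, qx = self.quadrant(dx, dy)
        return self.kernels[qy, qx]


def default_kernel_bank() -> KernelBank:
    """Four quadrant kernels on a 3x3 footprint.

    Unit event mass is split bilinearly between the centre pixel and the
    neighbours toward the sub-pixel offset, evaluated at the quadrant
    centres (+-0.25, +-0.25): centre weight 0.5625, edge neighbours
    0.1875 each, corner 0.0625.
    """
    bank = np.zeros((2, 2, 3, 3))
    for qy in (0, 1):
        for qx in (0, 1):
            ox = 0.25 if qx else -0.25
            oy = 0.25 if qy else -0.25
            sx, sy = int(np.sign(ox)), int(np.sign(oy))
            ax, ay = abs(ox), abs(oy)
            k = np.zeros((3, 3))
            k[1, 1] = (1 - ax) * (1 - ay)
            k[1, 1 + sx] = ax * (1 - ay)
            k[1 + sy, 1] = (1 - ax) * ay
            k[1 + sy, 1 + sx] = ax * ay
            bank[qy, qx] = k
    return KernelBank(bank)


def clipped_kernel(kernel: np.ndarray, y: int, x: int,
                   shape: tuple[int, int]) -> tuple[np.ndarray, slice, slice]:
    """Clip ``kernel`` centred at ``(y, x)`` to an image of ``shape``,
    renormalizing the in-bounds mass to 1.

    Returns ``(kernel_patch, row_slice, col_slice)`` where the patch sums
    to 1 and the slices address the target image.
    """
    r = kernel.shape[0] // 2
    h, w = shape
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    patch = kernel[y0 - y + r:y1 - y + r, x0 - x + r:x1 - x + r]
    s = patch.sum()
    if s <= 0:
        raise ValueError(f"kernel at ({y}, {x}) has no in-bounds mass")
    if s != 1.0:
        patch = patch / s
    return patch, slice(y0, y1), slice(x0, x1)
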