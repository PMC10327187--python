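"""Analytic model of coincidence loss on an electron-counting detector.

In counting mode a detector pixel can register at most one electron per
internal frame; the camera then sums batches of ``M`` consecutive internal
frames into one output frame.  If two or more electrons land on the same
pixel within a single internal frame they are recorded as one event
("coincidence loss", also called pile-up), making the detector response
nonlinear at high flux.

Under the simplifying assumption that the arrival times of ``N`` electrons
on one pixel are uniformly distributed over the ``M`` internal frames of a
batch, the probability that *no* two electrons share an internal frame is

    p_M(N) = p_M(N-1) * (M - (N - 1)) / M  =  M! / ((M - N)! * M**N)

with ``p_M(1) = 1`` — the classic birthday-problem survival probability.
This module evaluates that model stably (via log-gamma) and derives the
exposure-planning and pile-up-correction utilities built on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BatchSpec",
    "CoincidenceCurve",
    "prob_zero_loss",
    "prob_zero_loss_recursive",
    "prob_curve",
    "expected_occupied_frames",
    "correct_pileup",
    "max_electrons_at_tolerance",
]


@dataclass(frozen=True)
class BatchSpec:
    """Detector batching parameters.

    Parameters
    ----------
    frames_per_batch
        Number of internal frames summed into one camera output frame
        (``M``).  Must be at least 1.
    internal_frame_rate
        Optional internal frame rate in Hz (e.g. 250 for a Falcon 4 or
        1500 for a K3).
    effective_frame_rate
        Optional output frame rate in Hz.  When ``internal_frame_rate`` is
        given this is derived as ``internal_frame_rate / frames_per_batch``
        and must not be supplied inconsistently.
    """

    frames_per_batch: int
    internal_frame_rate: Optional[float] = None
    effective_frame_rate: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.frames_per_batch < 1:
            raise ValueError("frames_per_batch must be >= 1")
        if self.internal_frame_rate is not None:
            if self.internal_frame_rate <= 0:
                raise ValueError("internal_frame_rate must be positive")
            derived = self.internal_frame_rate / self.frames_per_batch
            if self.effective_frame_rate is None:
                object.__setattr__(self, "effective_frame_rate", derived)
            elif not math.isclose(self.effective_frame_rate, derived,
                                  rel_tol=1e-9):
                raise ValueError(
                    "effective_frame_rate inconsistent with "
                    "internal_frame_rate / frames_per_batch"
                )


@dataclass(frozen=True)
class CoincidenceCurve:
    """Tabulated zero-coincidence-loss probabilities ``p_M(N)``.

    ``points`` is an ordered list of ``(N, probability)`` pairs for
    ``N = 1 .. N_max``.
    """

    frames_per_batch: int
    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if self.frames_per_batch < 1:
            raise ValueError("frames_per_batch must be >= 1")
        probs = [p for _, p in self.points]
        if self.points and self.points[0][0] == 1 and probs[0] != 1.0:
            raise ValueError("p_M(1) must equal 1")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(b > a + 1e-15 for a, b in zip(probs, probs[1:])):
            raise ValueError("probabilities must be nonincreasing in N")
        for n, p in self.points:
            if n > self.frames_per_batch and p != 0.0:
                raise ValueError("p_M(N) must be 0 for N > M")

    @property
    def n(self) -> np.ndarray:
        return np.array([n for n, _ in self.points], dtype=int)

    @property
    def probability(self) -> np.ndarray:
        return np.array([p for _, p in self.points], dtype=float)


def _check_domain(M: int, N: int) -> None:
    if M < 1:
        raise ValueError(f"frames per batch M must be >= 1, got {M}")
    if N < 0:
        raise ValueError(f"electron count N must be >= 0, got {N}")


def prob_zero_loss(M: int, N: int) -> float:
    """Probability that ``N`` electrons on one pixel suffer no coincidence
    loss over a batch of ``M`` internal frames.

    Evaluates the closed form ``M! / ((M - N)! * M**N)``: exactly (big
    integer falling factorial, correctly rounded on division) for moderate
    ``M``, and through log-gamma for large ``M`` so it remains finite and
    accurate for ``M`` up to at least ``10**4``.  ``N = 0`` is defined to
    have probability 1 (no electrons, no loss); ``N > M`` forces a
    collision and returns exactly 0.

    Examples
    --------
    >>> round(prob_zero_loss(10, 8), 3)
    0.018
    >>> prob_zero_loss(5, 2)
    0.8
    """
    _check_domain(M, N)
    if N <= 1:
        return 1.0
    if N > M:
        return 0.0
    if M <= 1024:
        # exact: big-int ratio rounds correctly to float
        try:
            return math.perm(M, N) / M**N
        except OverflowError:
            pass  # ratio underflows float; fall through to log space
    log_p = gammaln(M + 1) - gammaln(M - N + 1) - N * math.log(M)
    return float(math.exp(log_p))


def prob_zero_loss_recursive(M: int, N: int) -> float:
    """Evaluate ``p_M(N)`` by the recursion
    ``p_M(N) = p_M(N-1) * (M - (N - 1)) / M`` with ``p_M(1) = 1``.

    Independent evaluation path cross-checking :func:`prob_zero_loss`;
    the recursion is accumulated in exact rational arithmetic for
    moderate ``M`` (plain floats above that), so the two agree to well
    within 10 ulp for ``N <= M``.
    """
    _check_domain(M, N)
    if N <= 1:
        return 1.0
    if N > M:
        return 0.0
    if M <= 1024:
        p = Fraction(1)
        for n in range(2, N + 1):
            p *= Fraction(M - (n - 1), M)
        return float(p)
    pf = 1.0
    for n in range(2, N + 1):
        pf *= (M - (n - 1)) / M
    return pf


def prob_curve(M: int, N_max: int) -> CoincidenceCurve:
    """Tabulate ``p_M(N)`` for ``N = 1 .. N_max``."""
    _check_domain(M, 1)
    if N_max < 1:
        raise ValueError(f"N_max must be >= 1, got {N_max}")
    pts = tuple((n, prob_zero_loss(M, n)) for n in range(1, N_max + 1))
    return CoincidenceCurve(frames_per_batch=M, points=pts)


def expected_occupied_frames(M: int, N: int) -> float:
    """Expected number of internal frames receiving at least one electron
    when ``N`` electrons are assigned uniformly at random to ``M`` frames.

    Equals ``M * (1 - (1 - 1/M)**N)``; this is also the expected *recorded*
    count on the pixel after per-frame binarization, and is always at most
    ``min(N, M)``.
    """
    _check_domain(M, N)
    if N == 0:
        return 0.0
    if M == 1:
        return 1.0  # a single frame is occupied by any N >= 1
    # -expm1(N*log1p(-1/M)) = 1 - (1 - 1/M)**N, stable for large M
    return float(-M * math.expm1(N * math.log1p(-1.0 / M)))


def correct_pileup(observed: float, M: int) -> float:
    """Mean-field estimate of the true electron count from an observed
    (pile-up-suppressed) count on one pixel per batch.

    Inverts :func:`expected_occupied_frames`:
    ``N = ln(1 - observed/M) / ln(1 - 1/M)``.  Returns a real, not an
    integer: this is an occupancy inversion, not an event count.

    Raises
    ------
    ValueError
        If ``observed`` is negative.
    OverflowError
        If ``observed >= M``: the pixel is saturated at the cap and the
        true count is unrecoverable.
    """
    if M < 1:
        raise ValueError(f"frames per batch M must be >= 1, got {M}")
    if observed < 0:
        raise ValueError(f"observed count must be >= 0, got {observed}")
    if observed >= M:
        raise OverflowError(
            f"observed count {observed} at or above the cap M={M}: "
            "pixel saturated, true count unrecoverable"
        )
    if observed == 0:
        return 0.0
    return float(math.log1p(-observed / M) / math.log1p(-1.0 / M))


def max_electrons_at_tolerance(M: int, p_min: float) -> int:
    """Largest electron count ``N`` with ``p_M(N) >= p_min``.

    Exposure-planning helper: given an acceptable probability of zero
    coincidence loss, how many electrons may strike one pixel per batch?
    Since ``p_M(1) = 1`` always passes, the result is at least 1.
    """
    if M < 1:
        raise ValueError(f"frames per batch M must be >= 1, got {M}")
    if not 0.0 < p_min <= 1.0:
        raise ValueError(f"p_min must lie in (0, 1], got {p_min}")
    # p_M(N) is nonincreasing in N and 0 for N > M: scan until it drops.
    n = 1
    while n < M and prob_zero_loss(M, n + 1) >= p_min:
        n += 1
    return n
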