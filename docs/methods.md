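# Methods

## Coincidence-loss model

A counting detector in electron-counting mode binarizes every pixel of
every internal frame: a pixel registers 0 or 1 electrons per readout
cycle regardless of how many arrive. The camera sums batches of `M`
consecutive internal frames, so an output pixel holds the number of
*occupied* internal frames, capped at `M`.

The model assumes the `N` electrons striking one pixel during a batch
are assigned independently and uniformly to the `M` internal frames.
This is a simplification — real arrival times within a batch are not
exactly uniform — but it is the standard mean-field treatment and is the
assumption the simulator implements, so model and simulator are tested
against each other on equal footing. Under it:

- **Zero-loss probability** `p_M(N) = M!/((M−N)!·M^N)`, equivalently the
  recursion `p_M(N) = p_M(N−1)·(M−(N−1))/M` with `p_M(1)=1`. Defined as
  1 at `N=0` (no electrons, no loss) and exactly 0 for `N > M`
  (pigeonhole).
- **Expected occupancy** (the mean recorded count)
  `E[occupied] = M·(1 − (1 − 1/M)^N)`, always ≤ min(N, M).
- **Pile-up inversion** `N̂ = ln(1 − observed/M)/ln(1 − 1/M)`, the exact
  inverse of the occupancy formula. It is a mean-field correction and
  returns a real number, not an event count. At `observed ≥ M` the pixel
  is saturated and the inversion raises rather than extrapolating.
- **Exposure planning** `max_electrons_at_tolerance(M, p_min)` scans the
  (nonincreasing) curve for the largest admissible `N`; since
  `p_M(1) = 1` the answer is at least 1.

### Numerical evaluation

For `M ≤ 1024` the closed form is evaluated exactly as a big-integer
falling-factorial ratio (`math.perm(M, N) / M**N`), which rounds
correctly to double precision; for larger `M` it switches to log-gamma
accumulation, which stays finite and accurate to `M` of at least 10^4.
The recursive evaluator mirrors this (exact rationals for moderate `M`,
plain floats above), so the two independent paths agree to well within
10 ulp wherever both are exact-path. Occupancy and its inverse use
`expm1`/`log1p` so they remain stable for large `M`; `M = 1` is handled
specially (a single frame is occupied by any `N ≥ 1`, and the inversion
is defined only at `observed = 0`).

## Detector simulator

`count_coincidence` / `simulate_counts` implement the forward process
literally: Poisson draws per pixel for the true counts, a uniform
internal-frame index per electron, occupancy counting per
(pixel, frame), batch output = number of occupied frames. The recorded
value is therefore ≤ min(true, M) by construction and the zero-loss
frequency converges to `p_M(N)` — the module-pair agreement is tested at
3 binomial standard errors with 10^5–10^6 trials.

`simulate_pattern` builds an expected-fluence field as a flat background
plus normalized Gaussian spots on a square lattice around the beam
centre. Spot integrated intensity is `peak_intensity·exp(−falloff·r)`
with `r` the spot-centre radius in pixels, emulating the
strong-low-resolution / weak-high-resolution falloff of a macromolecular
pattern. Defaults (512×512, lattice spacing 32 px, spot σ 1.2 px, peak
50 e⁻/spot/batch, background 0.01 e⁻/pixel/batch, falloff 0.01/px) were
chosen once to give the sparsity regime typical of counted MicroED
frames (zero fraction ≳ 0.98 at M = 35) and realistic spot extents; the
square lattice is a fixture choice, not crystallographic rigor — no
reciprocal-cell geometry, rocking curves, or stage rotation is modelled,
and detector physics (charge sharing, Landau noise, backscattering) is
deliberately absent. Passing tests on these fixtures therefore
demonstrate the counting/summation/sharpening arithmetic, not robustness
to real-detector artefacts.

Randomness: one `numpy.random.Generator` per call, seeded explicitly; no
global state. Same seed ⇒ bit-identical outputs.

## Sub-pixel kernels and sharpening

The kernel bank is a set of four 3×3 kernels indexed by sub-pixel
quadrant, built by bilinear splitting of unit mass toward the offset,
evaluated at the quadrant centres (±0.25, ±0.25): centre 0.5625, edge
neighbours 0.1875, corner 0.0625. Vendor kernels are proprietary and
unpublished, so the bank is configurable; simulation and sharpening
share whatever bank is supplied. Events clipped at the image edge
deposit renormalized mass so rendering conserves the event count.

`sharpen` is a greedy matched subtraction. The score of placing a unit
event of quadrant `q` at pixel `(y, x)` is the least-squares amplitude
`⟨residual, k_q⟩ / ⟨k_q, k_q⟩` (clipped, renormalized kernels at the
border). Each iteration takes the global maximum, subtracts that kernel,
and refreshes scores only in the affected 5×5 neighbourhood — one full
correlation up front, O(1) work per event — stopping when the best
amplitude drops below 0.5 of a unit event or an iteration cap is hit.
For the bilinear bank all four kernels have equal norm, so by
Cauchy–Schwarz the score of a correctly placed isolated unit event (=1)
strictly dominates every shifted or wrong-quadrant score, and subtraction
cancels exactly in floating point; isolated events are therefore
recovered with exact counts and positions.

Where recovered events fall strictly closer than `min_separation` pixels
to one another the kernel tails overlap and single-event inversion is
ill-posed. Such events are *revoked*: their kernels are restored into
the residual (leaving those regions untouched) and a disk of radius
`min_separation` around each is flagged in the dense-region mask. The
boundary is exclusive — separations of exactly `min_separation` are
accepted — matching the isolated-input contract.

## Frame processing conventions

- **Gain** is multiplicative (`corrected = frame × gain`) and the map is
  normalized to mean 1 by default, so a uniform gain is a no-op and
  global statistics are preserved; normalization can be disabled
  explicitly. Order of operations in conversion is fixed as
  gain → (optional summation) → scaling.
- **Summation** drops an incomplete trailing group with a warning and
  reports the count, mirroring fixed-batch camera behaviour; integer
  input stays integer and totals are conserved exactly.
- **Binning** is sum-pooling and requires the factor to divide the
  dimensions (the error advises cropping) so counts are conserved with
  no padding ambiguity.
- **Integer scaling** multiplies by 32 by default (five fractional bits
  survive the integer conversion), rounds half-to-even (unbiased under
  symmetric fractional parts), clamps to [0, 65535], and reports the
  clamp count.
- **Histograms** default to integer-centred bins of width 0.5
  (edges −0.25, 0.25, 0.75, …) plus underflow/overflow entries, which
  makes the integer concentration of raw counted data — and its loss
  after kernel convolution — directly visible on a log count axis.
- **Compression diagnostic** uses deflate at fixed level 6 so the ratio
  is reproducible for a given input.

## I/O conventions

Frames are 0-based, row-major; the slowest MRC axis is the frame index.
MRC follows the MRC2014 convention via `mrcfile` (modes 0, 1, 2, 6;
machine-stamp endianness; MIN/MAX/MEAN filled; extended headers ignored
on read and never written). Integer-mode writes *error* on
unrepresentable values rather than clamping. SMV uses the de facto
ADSC key=value dialect: a 512-byte null-padded ASCII header opening with
`{` and carrying HEADER_BYTES, DIM, BYTE_ORDER, TYPE, SIZE1/2,
PIXEL_SIZE, DISTANCE, WAVELENGTH, OSC_START, OSC_RANGE, PHI and
BEAM_CENTER_X/Y (in mm — reduction packages disagree on this convention,
so it is fixed and documented here), followed by little-endian uint16
data. TIFF output is single-image grayscale, lossless, optionally
deflate-compressed. Gain maps are read from single-frame float MRC or
raw little-endian float32 (shape supplied), with normalization left as
an explicit step.

## Problem sizes in the test suite

Monte-Carlo checks use 10^5 trials (10^6 for the headline
simulator-vs-model agreement) at 3-standard-error tolerances; the
sharpening round trip runs 50 independent 200-event layouts on 512×512
frames plus smaller multi-seed variants; exhaustive model cross-checks
cover all 1 ≤ N ≤ M ≤ 64. These sizes keep the full suite under a
minute on one CPU while leaving every statistical tolerance at its
stated 3σ.

## Known limitations

- The uniform-arrival assumption ignores beam-current structure within a
  batch; clustered arrivals would lower `p_M(N)` below the model.
- The pile-up inversion is mean-field: it is exact for the expected
  occupancy but biased when applied per-pixel to single noisy batches,
  and undefined at saturation.
- Dense-region sharpening is declined, not solved: overlapping kernel
  tails are masked rather than deconvolved.
- Spot finding, indexing, integration and merging are out of scope, as
  are event-based sparse formats and vendor-proprietary (Digital
  Micrograph) inputs — convert to MRC upstream.
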