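# Methods

## Signal model

The sequence is a spoiled gradient echo in which a saturation block (with
its spoiler) precedes every second excitation, producing two alternating
effective repetition times TR₁ (short) and TR₂ (long).  Under perfect
spoiling the transverse magnetization is destroyed every TR, so the
longitudinal magnetization follows a two-step recursion: multiplication by
cos θ at each pulse, exponential recovery toward M₀ in between.  Its fixed
point gives the closed-form signal pair implemented in
`signal_model.steady_state_signals`; the two-flip-angle generalization
(`steady_state_signals_general`) lets the pulse after the long interval use
a different angle θ₁ than the pulse after the short interval (θ₂).
`bloch_steady_state` iterates the recursion directly and is used as an
independent oracle: the suite checks agreement below 1e−10 relative over
the full angle grid.  Signals are real non-negative magnitudes; the echo
time enters only through the global factor e^(−TE/T₂*), which cancels in
every ratio metric.

Labelling is by recovery interval, not by position: `s_strong` is the
signal after the longer interval.  This removes the index ambiguity between
the dual-TR imaging convention and the AFI convention when TRs are swapped.

Assumptions: ideal spoiling, no off-resonance, no slice-profile or
magnetization-transfer effects of the saturation pulse, steady state fully
reached (no transient at the start of the echo train), time-invariant
signals (no flow, no triggering).

## Parameters

| parameter | default | meaning |
|---|---|---|
| TR₁ / TR₂ | 4 / 7 ms | the two effective repetition times |
| TE | 3 ms | echo time; pure global attenuation via T₂* |
| T₁ | 1420 ms | longitudinal relaxation (oil-phantom value) |
| T₂* | 450 ms | effective transverse relaxation |
| M₀ | 1 | equilibrium magnetization; cancels in all ratio metrics |
| grid N | 256 | simulation matrix (multiple of 4) |
| radius_frac | 0.22 | disc radius as fraction of N; must stay < 0.25 |
| flip range | 1°–90° | linear gradient across the disc |
| nominal adaptation angle | 70° | where S₁ = S₂ is enforced |

The defaults are the static-phantom measurement conditions the simulation
mirrors.  The matrix size is not dictated by the physics; N = 256 keeps the
run in the sub-second range, and every inequality-type result is re-checked
at N = 320 (the measurement matrix) to confirm it is not a grid artifact.
`radius_frac < 0.25` guarantees that the half-FOV ghost replica of the disc
is disjoint from the disc itself, so ghost and source intensities can be
measured independently.

## The synthetic phantom

`make_gradient_flip_map` emulates a 2-D flip-angle field with compact
circular support and a linear 1°–90° gradient — a stylized version of the
strongly inhomogeneous 7-T transmit profile.  The gradient runs along the
readout axis so each readout column has a single flip angle and every curve
bins exactly by column, with no interpolation.  Flip angles vary
continuously (no quantization to whole degrees).  What the phantom does
*not* model: anatomy, flow and pulsatility, receive-coil weighting, noise,
partial-volume edges (the disc edge is binary).  Passing tests therefore
demonstrate the artifact *mechanism* and the relative merits of the
countermeasures, not in-vivo artifact levels, which also depend on coil
profiles, noise and flow.

## k-space conventions

Transforms are centered and unitary (`fftshift`/`ifftshift` around an
orthonormal FFT), so Parseval holds exactly and round trips are identity to
machine precision.  Rows are phase encode with ky = row − N/2.  Assemblies
only ever copy whole rows from one of the two source k-spaces (or zero, for
the truncation reference); no row is synthesized.  The interleave scheme
gives even ky (including DC) to the strong signal — the choice matches a
sequence in which the center line is kept from the higher-signal
acquisition, and flipping the parity only conjugate-shifts the ghost
without changing any magnitude metric.

The reordered acquisition order (`acquisition_order`) alternates weak-block
and strong-block indices, both traversed in ascending order, with the
alternation phase flipping at the halfway point so that ky = 0 is acquired
exactly in the middle of the train (0-based position n/2).  For n = 64 this
yields −32, −16, −31, −15, …, −1, −17, 0, 16, 1, …, 15, 31.  The order is
scanner-facing bookkeeping only: the simulated steady state is
time-invariant, so line acquisition time never affects the images.

## Correction factor

The center-line correction multiplies every weak-provenance line by the
inverse of a weak/strong ratio estimated from the two ky = 0 lines.  The
default estimator (`center_ratio`) is the magnitude ratio of the two
k-space center samples, i.e. the ratio of the total image signals.  It is
exact for homogeneous phantoms and equals the signal-weighted mean of the
local weak/strong ratio for inhomogeneous ones — which is why the corrected
ghost nulls near the signal-weighted mean flip angle (≈ 40° for the 1°–90°
gradient disc, whose intensity is dominated by the low-angle side where the
signal peaks near the Ernst angle of ≈ 5°).  Two alternatives are
selectable: `l1_ratio` (L1-norm ratio of the full DC rows) weights the
line's spectral tails and lands much closer to 1 (nulling near 19°), and
`masked_pointwise_mean` (mean of pointwise magnitude ratios above a
1e−6-of-max threshold) is noisy because the two rows' near-zeros do not
coincide.  The center-sample ratio is the default because it is the only
one of the three whose nulling angle, low-flip signal gain (≈ 3.8%) and
crossover (≈ 29°) reproduce the behavior the method is meant to show.

## Metrics

All metrics are intensity ratios, invariant under global scaling, sampled
per readout column (= per flip angle):

* **ghost ratio** — mean |image| over the column's ghost pixels (mask
  shifted by N/2 along phase encode) divided by the mean over the column's
  phantom pixels, in percent.
* **signal ratio** — column-mean of one reconstruction over another inside
  the mask, in percent.
* **ringing amplitude** — half the peak-to-peak of |image|/|reference| − 1
  per column, inside the mask eroded by 3 px.  The erosion excludes the
  edge-overshoot band so the number describes interior ringing; the margin
  equals the ~2-px main-lobe radius of the truncation point-spread function
  plus one pixel.
* **oscillation vs local mean** — maximum |image − reference| per column
  (mask eroded by 1 px) divided by the column's mean reference signal.
  Normalizing by the *local* (same-flip-bin) mean rather than the global
  phantom mean makes the measure comparable across the phantom's large
  dynamic range: on this scale zero-filled truncation rings at ~7% at every
  flip angle while reordering rings in proportion to the local strong/weak
  gap (≈ 0.06% at 15°, ≈ 1.2% at 90°).
* **crossover** — the largest flip angle at which one curve drops below
  another, linearly interpolated between column samples; used to delimit
  the range where adaptation or correction makes the artifact worse.

## Flip-angle adaptation

`solve_adapted_flip` brackets the sign change of S₁ − S₂ in θ₁ ∈ (0, θ₂]
and refines it with Brent's method (xtol 1e−12 degrees); the residual is
verified ≤ 1e−10·M₀ across the sweep and against a 0.01°-step exhaustive
grid.  The solution is applied as a single multiplicative scale
θ₁(θ₂₀)/θ₂₀ on the whole flip map — the way a transmit-voltage change acts
physically.  A per-pixel application would null the artifact everywhere and
would misrepresent what a scanner can do with one global voltage per pulse.
The alternative of *raising* θ₂ instead (SAR-costly) is not implemented.

## Numerical choices and degenerate inputs

Brent tolerance 1e−12°, Bloch-iteration relative tolerance 1e−13 with a
100 000-cycle cap, AFI arccos argument clamped to [−1, 1] for noise-free
boundary cases.  Equal TRs short-circuit the adaptation solver (θ₁ = θ₂
exactly).  Empty phantoms, zero center lines, non-square grids, sizes not
divisible by 4, and angles outside [0°, 180°] are rejected with descriptive
errors.  Zero-signal columns are excluded from ratio curves rather than
propagated as NaN.

## Problem sizes

The standard sweep runs the nine-variant comparison at N = 256 in well
under a second; the test suite repeats structural checks at N = 64–128 and
the bound set additionally at N = 320.  These sizes fully resolve the
artifact (the ghost displacement is N/2 pixels and the ringing period a few
pixels), so nothing is scaled down relative to the phenomena being
measured.

## Known limitations

* The AFI inversion uses the published short-TR approximation, not an exact
  numerical inversion of the signal equations; its bias (≈ 0.05° at 90°
  with the default TRs) is well inside the 0.5° recovery tolerance.
* Quantities that depend on the phantom geometry (the corrected-ghost
  nulling angle, the low-flip gain, the zero-fill oscillation maximum) are
  reproduced for *this* phantom; a different flip-angle distribution shifts
  the signal-weighted mean and with it those numbers.
* Measured-data effects — noise amplification by the correction factor,
  pulsatile-flow ghosting under reordering, parallel-imaging interactions —
  are outside the simulation's scope.
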