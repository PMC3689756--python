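# Methods

## Forward model

A pulse-type electric fish in shallow water is modeled as an ideal current
dipole in two dimensions. The reduction to 2-D rests on two facts: the
water column is thin (≈ 10 cm) compared with the tank (1.5 m), and the
recording electrodes are vertical rods spanning the column, so each
measurement is a depth average. The exact potential of two opposite line
sources separated by *d* is logarithmic, `V = c·ln(r₋/r₊)`; for
observation distances `R ≫ d` it reduces to `V = m·cosφ/R` with moment
`m = c·d`. The relative error of the far-field form decays as `(d/R)²` and
is below 1 % for `R/d ≥ 20` (checked against the exact form over a
log-spaced sweep).

The constant *c* and separation *d* are collapsed into the single `moment`
parameter (default 1): the inverse search normalizes every vector, so both
cancel. `potential_exact` exposes *d* (default 10 cm, about half a body
length) only for the approximation-error study.

**Side boundary.** The tank wall carries an induced surface charge,
representable by a circle-inversion image dipole outside the boundary. For
electrodes *on* the wall the image contributes exactly `k` times the direct
differential voltage, with `k = (ρ−1)/(ρ+1)` for permittivity ratio
`ρ = ε_water/ε_wall` — so the boundary multiplies every channel by the same
`(1+k)`. The tests verify this against an explicit image construction. The
numeric value of `ρ` (default 17, water against plastic/glass) is
configurable and provably irrelevant to localization: unit normalization
removes the common factor.

**Top/bottom boundaries.** The air/water and water/glass interfaces are
handled by the method of image charges: two alternating reflection chains
with coefficients `k = (ε_w − ε_other)/(ε_w + ε_other)`. With these
coefficients (< 1) the partial sums converge geometrically with strictly
decreasing increments, and the depth-averaged potential of a vertical
electrode is linear in 1/R in the far field (R² > 0.99 for R between 20 and
200 water depths) — the distance scaling the 2-D model assumes. This
machinery (`image_series_potential`, `vertical_electrode_potential`) is a
validation utility only; the localization path is always 2-D. A
conductivity-based reading of the boundary contrast (insulating boundaries,
coefficients → 1) would make the single-source series diverge harmonically;
the permittivity-based coefficients are therefore used, and are
configurable.

## Lookup table

Grid nodes enumerate positions on a rectangular lattice intersected with
the tank disc and orientations over [0°, 180°) (the dot-product sign
resolves polarity at query time, halving the table). Defaults follow the
tracking system's settings: coarse 2 cm / 4°, fine 0.5 cm / 1°, coarse
position density doubled within 10 cm of the wall. Nodes whose head or tail
endpoint (± fish_length/2 along the axis; default body length 22 cm,
animals were 20–24 cm) would leave the tank are excluded, as are nodes
coinciding exactly with an electrode (relevant only for grid layouts whose
electrodes sit inside the search region). Rows are unit-normalized, stored
in single precision (accumulations are double precision), and partitioned
by strongest-|channel| index; the table can be cached to HDF5.

## Inverse search

`match_bruteforce` scans every row for the maximum |dot product|; ties
break to the lowest row index. The production `localize_two_step`:

1. **Coarse scan.** Only the partitions of the query's strongest and
   second-strongest |channel| are scanned (the second covers noise-induced
   order reversals).
2. **Start selection.** The |cosine| landscape near the wall can carry
   several near-tied lobes, so up to 4 mutually distant coarse candidates
   (non-maximum suppression over ±2 position steps and ±3 angle steps)
   within 0.005 of the best |score| seed the refinement; weaker candidates
   cannot overtake after refinement and are pruned. In the interior one
   start is typical.
3. **Iterated fine refinement.** A fine-resolution scan spanning ±1 coarse
   step around the current center is re-centered on its winner while the
   score strictly improves (≤ 10 iterations). This deterministic hill climb
   recovers the globally best match even when the coarse argmax sits more
   than one coarse step from it. Fine candidate responses are computed on
   demand, rounded to single precision exactly as stored LUT rows (so a
   node scores identically on either path), and memoized in a 16-entry LRU
   cache keyed on the center node and channel mask.

Against an exhaustive scan of a full fine-resolution LUT, this search
returns the identical state for ≈ 99 % of random noiseless queries (100 %
in the interior); the residual disagreements are near-wall near-ties whose
|cosine| scores differ by < 10⁻⁴ — physically indistinguishable matches on
a locally flat response manifold.

**Near-field exclusion.** The ideal-dipole assumption fails close to an
electrode, so channels with an electrode within 13 cm (configurable; the
value was tuned empirically on the physical system) of the estimated center
are masked and the pulse re-localized, at most twice to avoid oscillation.
Masking removes columns from both query and LUT rows with re-normalization
per query; under masking the partition index is meaningless, so the coarse
scan falls back to the full table. If fewer than 4 channels survive, the
unmasked estimate is kept and flagged.

**Batch driver.** `localize_batch` vectorizes the same two-step search for
simulation experiments. Channel responses are linear in
(cos θ, sin θ), so two basis responses per candidate position cover the
whole orientation scan. Its start selection uses the two partition winners
rather than the NMS of the scalar path (the NMS is not profitably
vectorizable); results differ from the scalar path only on near-tie
multimodal queries.

**Moment estimation.** `estimate_moment` returns the least-squares scale
between observed RSIs and the unit-moment prediction at the localized
state — the EOD amplitude up to a constant — with its residual norm.

## Pulse measurement

The pulse timing reference is the peak of the global envelope: channels are
rectified (preventing cross-channel cancellation), summed, and smoothed by
a moving RMS filter (τ = 250 µs). If a pulse's envelope is multimodal,
triangular smoothing passes of widening window (τ, 2τ, 3τ; at most 3
passes) are applied until each pulse carries one peak — a fixed-width pass
cannot merge peaks separated by more than one window. Detection takes local
maxima above threshold (user-set, or median + 8·MAD of the envelope) with a
5 ms refractory (EOD rate ≈ 50 Hz) and parabolic sub-sample interpolation.

RSIs are least-squares straight-line slopes over five ADC samples
(40 kS/s), measured at fixed offsets from the reference on all channels at
identical sample indices (phase-locked). The central-body phase precedes
the reference by 225 µs (the EOD initiates rostrally), the tail phase
follows by 225 µs; both offsets are configurable. The slope estimator is a
least-squares fit rather than an endpoint difference for noise robustness.

## Tracking

Pulses are assigned to individuals by the nearest previously identified
state, minimizing position distance + λ·angular distance with
λ = 0.1 cm/deg, gated at 20 cm of positional displacement (generous for
≈ 50 Hz pulses); ties break to the smaller angular distance, then the lower
animal id. Temporally collided pulses match no single-dipole prediction, so
points with |score| < 0.9 are removed after labeling (so removals are
attributable to an animal). Residual 180° polarity flips are corrected by
temporal continuity before smoothing. Position traces are median-filtered
(window 8) then triangular-filtered (15); orientations are unwrapped,
filtered with windows 15/30, and re-wrapped. Even-window medians use the
lower median and triangular kernels are renormalized at the edges, so
constants pass through exactly and output never leaves the hull of its
window. Trajectories can be resampled at frame times (default 15 FPS) with
linear position and circular orientation interpolation; extrapolation is
refused.

The tail-bend angle is the signed difference between the tail-phase and
central-phase dipole orientations, in (−180°, 180°], positive when the tail
is bent toward the animal's left. The tail fit uses the same LUT — the tail
source is simply another ideal dipole.

## Simulator

`make_configuration` builds the four benchmark layouts: 4 channels paired
at 180° or 90° (8 wall electrodes), 8 channels paired at 67.5° (16 wall
electrodes, each used once; the production layout), and an 8-channel square
grid (2 m side, 0.5 m spacing, 8 adjacent-node pairs arranged with 4-fold
symmetry — the figure the layout comes from does not fully specify the
wiring, so this is a documented stand-in).

The static noise sweep draws dipole states uniformly inside the boundary
(shared across configurations), adds i.i.d. Gaussian noise to the noiseless
RSIs with SD = level × median |RSI| over the sampled points (the median of
the *absolute* values — the signed median is ≈ 0), and localizes with the
two-step search. Desk-scale default is 10⁴ points per level (the original
study used 10⁷); point count is a parameter.

A notable structural result: the diametric-pair layout (4P180) carries an
**exact point-reflection ambiguity** — for every channel whose electrodes
satisfy e₋ = −e₊, a dipole at (−x, −y) with the same heading produces
identical differential voltages. Its position error is therefore
catastrophic at any noise level while its orientation error (untouched by
the symmetry) remains small. Changing the pairing angle to 90° removes the
degeneracy, which is the structural reason behind the reported accuracy
improvement; the configuration ordering check in the acceptance tests
asserts the full ordering for position and the channel-doubling improvement
for orientation.

The swimming-fish generator is a mean-reverting turning-rate walk
(τ = 2 s, diffusion 40 °·s⁻¹·√s⁻¹) with wall avoidance, speeds
~N(8, 3²) cm/s truncated at 0, pulse intervals jittered 5 % around 50 Hz,
and a sinusoidal tail bend (15°, 2 Hz) applied to a tail dipole half a body
length behind the center; an optional soft anchor tethers a fish to a home
region (used to build non-crossing dyad paths). All randomness flows from a
seed.

Waveform synthesis renders each pulse as a shared biphasic template (a
dominant positive Gaussian lobe, σ = 150 µs, followed 400 µs later by a
−0.6 amplitude lobe, σ = 200 µs; ≈ 1.5 ms total), amplitude-modulated per
channel by the response of an effective state that blends from the central
to the tail dipole across ±100 µs around the template's envelope peak —
emulating the rostral-to-caudal source progression while keeping the ±225 µs
slope windows on pure phases. The tail response is rescaled to the central
response's per-pulse norm, which stabilizes the envelope shape and is
invisible to the scale-invariant search. Sensor noise is calibrated in the
RSI domain: the SD of slope-measurement noise equals `10^(−SNR/20)` times
the SD of the clean slope values, with the measured system SNR (46.5 dB) as
default.

What the generator does **not** emulate: distributed multi-source body
fields (the real EOD has several spatially separated components), skin
conductance and body-induced field distortion, amplifier saturation on
electrode contact, object-induced distortion, and pulse-rate modulation
during social interaction. Passing the synthetic end-to-end checks
therefore demonstrates the correctness of the measurement-to-trajectory
chain under the ideal-dipole model, not robustness to those real-world
effects — the near-field exclusion, collision filter, and smoothing stages
exist precisely because real data violate the model in these ways.

## Numerical choices and degenerate inputs

- LUT rows and fine candidates are single precision; all dot-product
  accumulations and statistics are double precision.
- Ties in |dot| break to the lowest row index; a sign-ambiguous polarity
  (dot = 0) falls back to temporal continuity when a previous state exists.
- A query scaled by any positive constant yields the identical state; the
  score agrees to float rounding (re-normalization is not bit-exact).
- All-zero RSI vectors, fewer than 4 usable channels, degenerate grids, and
  all-zero LUT rows raise errors; empty fine neighborhoods at extreme wall
  positions fall back to the coarse estimate with a warning flag.
- Chunked streaming overlaps blocks by four envelope windows so pulses at
  block edges are not lost; duplicate detections in the overlap are
  dropped by half-open time windows.

## Problem sizes

Default experiment sizes are chosen for workstation runs: 1,000 dipoles for
the noiseless recovery and oracle-equivalence checks, 10⁴ points per noise
level per configuration for the sweep, 60 s of simulated swimming (≈ 3,000
pulses) for the single-fish end-to-end check and 40 s per fish for dyads.
All are parameters of the corresponding functions.

## Known limitations

- Near the wall the inverse problem is intrinsically ill-conditioned: the
  response manifold flattens and distinct states match almost equally well.
  The search finds *a* globally near-optimal match, but which of two
  near-tied lobes wins can depend on sub-10⁻⁴ score differences.
- The 4P180 configuration cannot localize position reliably at all (exact
  antipodal ambiguity); it is retained for the configuration comparison.
- The 2-D model ignores vertical structure; fish rolling or strongly
  pitching will violate it.
- Identity assignment is greedy nearest-neighbor; crossing trajectories of
  two fish closer than the gate can swap identities. The collision filter
  rejects merged pulses but cannot recover both constituent states.
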