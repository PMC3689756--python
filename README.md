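# dipoletrack

Localize and track freely swimming pulse-type weakly electric fish — or any
slowly moving two-dimensional current dipole — from multichannel
differential voltage recordings.

Pulse-type weakly electric fish (e.g. *Gymnotus* sp.) emit brief (1–2 ms)
biphasic electric organ discharges (EODs) at roughly 50 Hz. In shallow
water, recorded through vertical electrodes that average the field over
depth, each fish is well approximated by an ideal 2-D current dipole.
`dipoletrack` solves the resulting inverse problem — *where is the fish and
which way is it pointing, given the per-channel received signal
intensities?* — without per-animal calibration, and assembles per-pulse
estimates into smoothed multi-animal trajectories with tail-bending angles.

## The model and the search

The potential of a 2-D dipole with moment *m* at distance *R* and axis
angle φ is

    V(R, φ) = m · cos φ / R,

the far-field limit of the exact two-line-source potential
*V* = *c* · ln(*r*₋ / *r*₊). A differential channel (electrode pair on the
tank wall) measures the difference of two such potentials; the circular
tank boundary only rescales every channel by a common factor (1 + *k*)
through its image dipole, and the scale cancels because the search uses
normalized vectors.

The inverse problem has no closed form, so it is solved by enumeration: a
lookup table (LUT) stores unit-normalized predicted RSI vectors at every
node of a position × orientation grid (coarse 2 cm / 4°, density doubled
within 10 cm of the wall, orientations over [0°, 180°)). A measured vector
**v** is matched by the maximum |cosine|,

    cos θ_uv = v̂ · û,   computed for all rows as  M v̂,

with the sign of the dot product resolving head-tail polarity. A
partition-filtered coarse scan (only rows whose strongest channel matches
the query's strongest or second-strongest) is followed by an iterated
fine-grid refinement (0.5 cm / 1°) around the coarse candidates. Channels
with an electrode within 13 cm of the estimate are excluded and the pulse
re-localized (near-field correction). Per-pulse estimates are assigned to
individuals by nearest previous state, collided pulses (match score < 0.9)
are rejected, and traces are median- and triangular-filtered with
orientation unwrapping.

## Worked example

Simulate one fish swimming for 8 s in a 1.5 m tank recorded by the
8-channel circular array at the measured system SNR, then track it:

```python
import numpy as np
from dipoletrack import TankGeometry, make_configuration
from dipoletrack.simulate import SwimParams, generate_swim, synthesize_waveforms
from dipoletrack.pipeline import RunConfig, run_track
from dipoletrack.simulate import error_metrics

tank = TankGeometry()                       # 75 cm radius, 10 cm deep
array = make_configuration("8P67.5", tank)  # 16 wall electrodes, 8 channels
rng = np.random.default_rng(8)
truth = generate_swim(SwimParams(seed=8), tank, duration=8.0, rng=rng)
waveform, _ = synthesize_waveforms(truth, array, tank, snr_db=46.5, rng=rng)

result = run_track(RunConfig(tank=tank, array=array), waveform)
print(result["counts"])
est = result["per_pulse"].rename(columns={"x_cm": "x", "y_cm": "y",
                                          "theta_deg": "theta"})
stats = error_metrics(est, truth.iloc[:len(est)])
print(f"median position error {stats['position_median']:.2f} cm, "
      f"median orientation error {stats['orientation_median']:.2f} deg")
```

This prints:

```
{'pulses_detected': 401, 'pulses_labeled': 401, 'pulses_kept': 401, 'collisions_removed': 0}
median position error 0.32 cm, median orientation error 0.31 deg
```

All 401 emitted pulses were detected and localized; none were rejected by
the collision filter (a single fish cannot collide with itself), and the
median per-pulse error is well inside the fine grid pitch.

The same machinery is scriptable from the shell: `dipoletrack simulate
swim`, `dipoletrack detect-pulses`, `dipoletrack build-lut`, `dipoletrack
localize` and `dipoletrack track` (see `--help` on each).

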