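# File formats

## Geometry config (YAML)

Tank and electrode-array description consumed by `--geometry` options and
`dipoletrack.io.load_geometry`. Coordinates are tank-centered, cm.

```yaml
label: 8P67.5
tank:
  radius_cm: 75.0
  water_depth_cm: 10.0        # used by the 3-D validation utilities only
  boundary_contrast: 17.0     # eps_water / eps_wall; cancels in localization
channels:                     # ordered; one differential pair per channel
  - pos: [75.0, 0.0]
    neg: [28.7, 69.3]
  - ...
```

Validation: ≥ 4 channels for localization, no coincident electrodes.
`examples/tank_8P67.5.yaml` is the production layout.

## Waveforms

* **WAV**: multichannel, float32 or int16, any rate (40 kS/s per channel is
  the reference). Integer data are scaled to [−1, 1) and multiplied by the
  sidecar gain.
* **CSV** (long format): columns `time` (s), `channel` (0-based), `value`
  (V). Sample times must be uniform unless the sidecar supplies `rate`.
* **Sidecar** (YAML, optional): `rate` (Hz), `gain` (V per unit),
  `start_time` (s), `n_channels`.

## Pulses CSV (`detect-pulses` output, `localize` input)

One row per detected EOD pulse: `t_ref` (s, envelope peak),
`envelope_peak` (V), then per channel `c`: `central_slope_c` /
`tail_slope_c` (V/s) and `central_mask_c` / `tail_mask_c` (1 = usable).
A `#`-prefixed provenance header precedes the column row.

## Localization CSV (`localize` output)

`time, x_cm, y_cm, theta_deg, score, n_channels_used` — one row per pulse;
`theta_deg` in [0, 360) counterclockwise from +x, `score` the |cosine|
match in [0, 1].

## Trajectory CSV (`track` output)

`time_s, animal_id, x_cm, y_cm, theta_deg, tail_bend_deg, score,
n_channels_used, smoothed` — written separately for per-pulse
(`*_pulses.csv`, smoothed = 0), smoothed (`*_smoothed.csv`, smoothed = 1)
and optionally frame-resampled points. The `#` provenance header carries
the config hash and seed.

## LUT cache (HDF5)

Datasets `/vectors` (float32, n × n_channels, unit rows),
`/states` (n × 3: x, y, theta), `/partition` (channel, start, stop row
ranges), `/pos_electrodes`, `/neg_electrodes`, and a `/meta` attribute
group (grid steps, fish length, tank parameters, label). Build parameters
are therefore self-describing; `dipoletrack.LUT.load` validates nothing
beyond shapes, so treat caches as disposable artifacts, not archives.

## Noise-sweep CSV (`simulate sweep` output)

One row per (configuration, noise level): mean/median/Q90 position error
(cm) and orientation error (deg), order-statistic 95% CI bounds of both
medians (`*_median_lo/hi`), median match score, `n`, and `seed`.
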