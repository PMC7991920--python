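# perisim

A hardware-free **static automated perimetry engine**: the computational
core of a (VR headset) visual-field perimeter, reimplemented as a pure
Python library with a simulated observer in place of the human subject.

Perimetry maps retinal light sensitivity by flashing small stimuli of
varying intensity at fixed field locations and recording button-press
responses. `perisim` implements everything between the photometer and
the printed report:

- **Calibration** — a measured gray-level → luminance table (CSV),
  linearly interpolated, anchors the attenuation scale
  `dB(L) = 10·log₁₀(L_max / L)` with 0 dB = 120 cd/m² (the display
  maximum) and thresholds reported on 0–49 dB against a 1 cd/m² black
  background.
- **Test patterns** — the T-24 grid (50 points, 6° spacing, central 24°,
  two temporal points yielded to the physiologic blind spot), the T-10
  (68 points, 2° spacing, central 10°), and the single-presentation
  suprathreshold S-24.
- **Threshold strategy** — a 4-2 *double-crossover* staircase per
  location: coarse 4 dB steps until the first response reversal, 2 dB
  steps until the second, estimate = last seen level. Four anchor points
  (one per quadrant) are thresholded first; every other location unlocks
  when a lattice neighbor finishes and inherits its estimate as the
  starting level.
- **Reliability** — Heijl-Krakau fixation monitoring (the blind spot is
  mapped with 0 dB probes at test start, then re-probed periodically; a
  response is a fixation loss), stimulus-free false-positive windows,
  and false-negative re-probes offset 0.5 cd/m² from the last seen
  stimulus.
- **Reports** — sector means (ST/SN/IN/IT quadrants; central ≤ 12°,
  pericentral 12–24°, global), grayscale map, total/pattern deviation
  maps with 5/2/1/0.5 % probability grades against a (simulated)
  normative database, and the global indices

  MD = Σ wᵢ·TDᵢ / Σ wᵢ,  PSD = √(Σ wᵢ·(TDᵢ − MD)² / Σ wᵢ),  wᵢ = 1/σᵢ²

- **Simulated observer** — a "hill of vision" sensitivity surface
  (optionally carved by scotomas, with an absolute blind spot), a
  cumulative-Gaussian frequency-of-seeing response model with guess and
  lapse rates, per-trial gaze jitter, and lognormal response times.
  Healthy cohorts land near the ~32 dB global-mean regime of real
  healthy fields, central above pericentral.

Intended for perimetry-strategy research and teaching: every session is
seed-deterministic, every presentation is logged, and a session result
can be recomputed byte-identically from its event log alone.

## Worked example

Build a normative model from 30 simulated healthy eyes, then test an
observer with a 14 dB superior scotoma at (9°, 9°):

```sh
cat > obs.yaml <<EOF
surface:
  kind: hill
  peak: 33.0
  slope: 0.2
  scotomas:
    - {x: 9, y: 9, radius: 4, depth: 14}
  blind_spot: {x: 15, y: -2, radius: 2.5}
psychometric: {sigma: 1.0, guess: 0.01, lapse: 0.01, fixation_sigma: 0.5}
rt: {log_mean: 6.1, log_sd: 0.25}
eye: OD
EOF
perisim build-norms --n 30 --seed 1 --out norms.json
perisim simulate --observer obs.yaml --norms norms.json --seed 42 --out-dir run
```

`run/report.json` from this exact invocation contains (right eye):

```
fixation_losses  0/21      false_positives 0.0 %   false_negatives 10.0 %
MD  -1.38 dB     PSD  2.38 dB
worst total deviations: -15.1, -9.9 dB at the locations inside the
scotoma, graded <0.5%
```

and a simulated duration of 540.5 s per eye for the binocular run. The
left eye (the mirrored fellow observer) prints MD −1.34, PSD 1.86. The
negative MD reflects mild overall depression relative to the simulated
norms; the high PSD and the <0.5 % grades flag the focal defect, which
survives in the pattern-deviation map after the general height is
removed.

The same pipeline is available as a library:

```python
import numpy as np, perisim as ps

obs = ps.Observer(surface=ps.SensitivitySurface(kind="flat", peak=32.0),
                  params=ps.PsychometricParams(sigma=1.0))
res = ps.run_session(ps.SessionConfig(protocol="T-24", seed=7),
                     {"OD": obs, "OS": ps.mirror_observer(obs)},
                     ps.default_curve())
assert ps.replay(res.log).to_json() == res.to_json()
```

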