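# Methods

This note documents the models, parameter choices, and numerical decisions
behind `spikesim`. Units throughout: μm for distances, ms for waveform time,
s for spike times, nA for currents, μV for potentials, S/m for conductivity.

## Forward model: line-source approximation

Each neurite segment is treated as a uniform line of current in an infinite
homogeneous medium of conductivity σ (default 0.3 S/m). For a segment of
length `ds`, transverse distance `r` from the electrode to the segment line,
and longitudinal distances `h` (to the near end) and `l = h + ds` (to the far
end), the potential of a current `I` is

    φ = 1e3 · I / (4π σ ds) · ln[ (√(l² + r²) + l) / (√(h² + r²) + h) ]   [μV]

The prefactor 1e3 converts nA/(S/m·μm) to μV. The transverse distance is
clamped to ≥ 1 μm so electrodes arbitrarily close to a segment line do not
produce unbounded potentials; 1 μm is below any realistic electrode–membrane
separation. In the far field (verified at 100× segment length) the expression
converges to the point source `I/(4πσr)` within 1 %.

An extracellular template (EAP) is the sum of all segment contributions at
every electrode. The waveform is cut out around the global trough
(`cut_out = (2, 5)` ms before/after), zero-padded if the trough sits near the
simulation edge; at 32 kHz this yields 224 samples.

## Synthetic cell bank

Thirteen stylized multicompartment models (10 excitatory, 3 inhibitory)
provide morphological and electrophysiological diversity without external
morphology files. Each model is a soma segment plus a 5-segment apical trunk
and two basal dendrites ("ball and stick plus"), with per-model randomized
geometry (seeded). The soma action-potential current is a difference of
exponentials time-scaled so the trough width matches the model's
`trough_width` (excitatory 0.55–0.7 ms, inhibitory 0.25–0.35 ms, reflecting
narrower interneuron spikes), with peak amplitude 4–7 nA, followed by a
rectangular after-hyperpolarization sized to zero the net charge. Return
currents are distributed over the dendritic segments in proportion to membrane
area with opposite sign, so every time-column of the currents matrix sums to
zero (charge conservation, exact to rounding).

What the bank does **not** emulate: dendritic spike propagation delays,
active conductances, axonal signals, or morphology-class-specific branching
statistics. It produces realistic amplitude decay, spatial asymmetry, and
waveform-width diversity — the features spike sorters are sensitive to — not
biophysically faithful single-cell reconstructions.

## Template generation

Coordinate convention: axis 0 is distance from the probe plane, axes 1–2 span
the electrode plane (axis 2 vertical). Cells are placed by rejection
sampling: soma position uniform in a box (axis 0 ∈ [10, 80] μm; plane bounds =
electrode bounding box padded by 30 μm), orientation per `rotation_mode`
("3d": uniform yaw plus tilt within ±15°; "z-only"; "none"), accepted if the
peak amplitude (max over channels of |trough|) lies in
`[min_amplitude, max_amplitude]` (default [30, ∞) μV). Generation fails with
a descriptive error after 1000 × `n_per_model` rejected draws per model.

Drifting libraries compute each template along a linear trajectory of
`n_drift_steps` (default 30) equally spaced positions. The trajectory
endpoint is re-sampled until its direction lies within ±30° of the probe
vertical axis and its length is uniform in [20, 60] μm.

## Spike trains

Homogeneous renewal processes: Poisson (exponential ISIs) or gamma (shape 2,
mean 1/rate; more regular, closer to cortical ISI statistics). Spikes closer
than the refractory period (2 ms) to their predecessor are deleted.
Excitatory default 5 Hz, inhibitory 15 Hz.

### Synchrony control

A collision is a spike pair from two spatially overlapping units within
±`collision_window` (default 1 ms). `sync_rate = 0` deletes the later spike
of every collision, re-scanned to fixpoint. `sync_rate = s > 0` *moves*
spikes of the higher-rate unit next to free spikes of the lower-rate unit
until a fraction `s` of the lower-rate unit's spikes collide. Moving (rather
than inserting) preserves per-unit spike counts and hence firing rates.

## Per-spike modulation

Without bursting, each spike's amplitude is scaled by an independent
Normal(1, `mod_sd`²) draw (default sd 0.05). With bursting, spikes are
grouped into burst events (consecutive ISIs < 50 ms; an event closes at 10
spikes or 100 ms) and the modulation decays with the number of prior spikes
`n` in the event, recovering with their mean ISI:

    value = q · max(0.1, exp(−0.2 · n · max(0, 1 − meanISI/50 ms)))

In "amplitude+shape" mode, depressed spikes (value m < 1) are also widened by
stretching the waveform about its trough by `k = 1 + shape_stretch·(1 − m)`
using band-limited resampling (16× polyphase upsampling, linear interpolation
of the stretched time base), preserving sample count and trough position.

## Drift playback

Slow drift moves the active trajectory step at `velocity` (default
5 μm/min), reflecting at both trajectory ends (triangle wave). Fast drift
jumps every `fast_period` (default 20 s) to a random step whose max-channel
amplitude differs from the current one by 5–20 μV (nearest step if no
candidate lies in the band). "slow+fast" superimposes the jump offsets on the
slow index. Jump schedules are precomputed so playback is identical for any
query order or chunking.

## Recording assembly and reproducibility

Each selected unit's spike train is convolved with its (jittered, modulated,
possibly drifting) template and summed into the recording; clean per-unit
traces (`spike_traces`) and signed per-channel peaks (`voltage_peaks`) are
kept as ground truth. Temporal jitter picks one of `n_jitters` sub-sample
shifts (10× upsampling) per spike; jitter version 0 is the exact unshifted
template.

Four independent seed streams control spike trains (`st_seed`), template
selection (`temp_seed`), noise (`noise_seed`), and convolution randomness —
jitter, modulation, drift schedules (`conv_seed`). Changing one stream leaves
the others' output untouched. All per-spike draws are made upfront in spike
order, which makes assembly bit-exact under any `chunk_duration`.

## Noise models

All models are calibrated to a target per-channel standard deviation `level`:

- `uncorrelated`: i.i.d. Gaussian.
- `distance-correlated`: multivariate Gaussian with covariance
  `level²·exp(−d/λ)` (λ = 30 μm) via Cholesky factorization.
- `colored-*`: the Gaussian profiles filtered with a second-order resonant
  low-pass biquad (peak 300 Hz, Q = 1) mixed with a 0.3 white floor and
  rescaled per channel; the common filter preserves spatial correlation.
- `far-neurons`: templates of sub-threshold neurons (accepted only below
  10 μV, placed in a far shell 50–300 μm from the probe plane) convolved with
  independent 5 Hz Poisson trains, plus a Gaussian floor (0.3·level), rescaled
  to `level`. The resulting amplitude distribution is negatively skewed, as
  in biological noise.

Optional output filtering: zero-phase Butterworth (`sosfiltfilt`, default
3rd order band-pass 300–6000 Hz).

## Persistence

Template libraries and recordings are HDF5 containers with a
`schema_version` attribute and an `info` dataset holding every generation
parameter and seed as YAML. HDF5 object time-tracking is disabled, so files
with identical content are byte-identical — the basis of the end-to-end
seeded reproducibility guarantee. Templates are stored at native float64;
recordings and spike traces at float32 (sub-0.01 μV quantization, far below
the noise floor).

## Numerical choices

- Transmembrane currents are simulated on a 10 ms window at the recording
  sampling rate; trough timing is stable under dt refinement to within one
  coarse sample.
- The forward kernel is evaluated as an (n_segments × n_electrodes) matrix
  once per placement; an EAP is then a single matrix product.
- Band-limited operations (jitter, stretch) use polyphase resampling
  (`scipy.signal.resample_poly`), not FFT resampling, to avoid periodic
  boundary artifacts.
- Fast-drift candidate selection and slow-drift reflection are pure integer
  arithmetic on precomputed schedules, so playback is exactly reproducible.

## Limitations

- The medium is infinite and homogeneous: no electrode-surface, saline-layer,
  or tissue-anisotropy corrections.
- Cell models are stylized; template diversity is narrower than libraries
  built from full morphological reconstructions.
- Spike trains are homogeneous renewal processes — no rate drift, no
  cross-unit rate correlations beyond explicit synchrony control.
- Drift moves units along precomputed linear trajectories only, and all units
  share the drift schedule timing parameters.
- Electrode impedance, saturation, and digitization artifacts are not
  modeled; output is an ideal voltage trace.
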