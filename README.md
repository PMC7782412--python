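# spikesim

Ground-truth simulation of extracellular neural recordings for benchmarking
spike-sorting pipelines.

## The problem

Spike sorting — recovering the activity of individual neurons from
multi-electrode extracellular voltage traces — can only be evaluated
rigorously when the true spike times of every neuron are known. Paired
intracellular/extracellular recordings provide such ground truth but are rare,
low-yield, and cover a handful of neurons at best. A simulator fills the gap:
it synthesizes recordings in which every spike, every waveform, and every
corruption (noise, bursting, electrode drift, overlapping units) is known
exactly, so sorter output can be scored against the truth.

`spikesim` implements a two-phase workflow:

1. **Template generation** (`spikesim.templategen`): a bank of synthetic
   multicompartment cell models is placed at random positions and orientations
   around a probe, transmembrane action-potential currents are mapped to
   electrode potentials with the line-source approximation, and templates
   passing an amplitude criterion are collected into a library. Libraries can
   optionally hold *drifting* templates computed along a movement trajectory.
2. **Recording assembly** (`spikesim.recgen`): templates are selected from
   the library, convolved with stochastic spike trains (Poisson or gamma,
   refractory-period aware), optionally modulated (amplitude variability,
   bursting with waveform widening, synchrony control for overlapping pairs,
   slow/fast electrode drift), summed with one of five noise models, and
   optionally band-pass filtered. The output bundle keeps the complete ground
   truth: spike times, per-unit templates, locations, and clean per-unit
   signal traces.

Both phases are deterministic given their seeds; recordings are controlled by
four independent seed streams (spike trains, template selection, noise,
convolution), and re-running with the same seeds reproduces output files
byte-for-byte.

## Worked example

```python
import numpy as np
import spikesim as ss

# Phase 1: template library on a tetrode
probe = ss.build_probe("tetrode")
bank = ss.default_cell_bank(seed=0)
library = ss.generate_templates(bank, probe, n_per_model=6, seed=0)
print("templates:", library.templates.shape)  # (n_templates, n_channels, n_points)
amps = np.abs(library.templates.min(axis=-1)).max(axis=-1)
print(f"peak amplitudes: {amps.min():.1f} to {amps.max():.1f} uV")

# Phase 2: 10 s recording with 2 excitatory + 1 inhibitory units
bundle = ss.assemble_recording(
    library,
    rules=ss.SelectionRules(n_exc=2, n_inh=1, min_dist=0.0),
    noise_spec=ss.NoiseSpec(model="distance-correlated", level=10.0),
    rec_params=ss.RecordingParams(duration=10.0),
)
print("recording:", bundle.recordings.shape)  # (n_channels, n_samples)
for u, times in enumerate(bundle.spiketrains.trains):
    kind = bundle.spiketrains.celltypes[u]
    amp = np.abs(bundle.voltage_peaks[u]).max()
    print(f"unit {u} ({kind}): {len(times)} spikes, peak {amp:.1f} uV")
print(f"noise sd: {np.median(bundle.recordings.std(axis=1)):.2f} uV")

ss.save_recording(bundle, "recording.h5")
```

Output:

```
templates: (78, 4, 224)
peak amplitudes: 30.1 to 92.9 uV
recording: (4, 320000)
unit 0 (excitatory): 54 spikes, peak 40.6 uV
unit 1 (excitatory): 59 spikes, peak 35.5 uV
unit 2 (inhibitory): 150 spikes, peak 60.8 uV
noise sd: 10.66 uV
```

The same workflow is available from the command line:

```
$ spikesim available-probes
Neuronexus-32
Neuropixels-128
SqMEA-10-15
tetrode

$ spikesim gen-templates -prb tetrode -n 6 --seed 0 --out templates.h5
wrote 78 templates to templates.h5

$ spikesim gen-recordings -t templates.h5 -ne 2 -ni 1 -d 10 --out recording.h5
wrote 3-unit, 10 s recording to recording.h5
```

Both commands accept a YAML parameter file (`--params`) that can override any
default; explicit flags win over the file. Custom probes are plain YAML files
with `name` and `positions` keys (`--probe-file`).

Output files are self-describing HDF5 containers: every generation parameter
and seed is embedded in an `info` dataset, so a saved file is sufficient to
regenerate its own content. See `docs/methods.md` for the model details and
parameter reference.

## Testing

```
python -m pytest -q tests/
```

The suite covers probe geometry, the forward model against analytic oracles,
charge conservation, spike-train statistics, synchrony control, modulation
and bursting, drift playback, noise calibration, HDF5 round-trips, the CLI,
byte-identical seeded reproducibility, and bit-exact chunked assembly.

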