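"""Recording synthesis.

A recording is assembled from a template library and stochastic spike
trains: templates are selected under user rules (cell types, amplitude
bounds, minimum inter-soma distance, number of spatially overlapping
pairs), optionally modulated in amplitude and shape to mimic bursting,
jittered by sub-sample shifts, moved along drifting trajectories, convolved
with the spike trains, and summed with additive noise before an optional
zero-phase filter.

Four independent seed streams keep the stochastic components separable:
``st_seed`` (spike trains and synchrony), ``temp_seed`` (template
selection), ``noise_seed`` (additive noise) and ``conv_seed`` (jitter,
modulation and drift-jump draws in the convolution).  Changing one stream
leaves the others' outputs untouched, which makes controlled experiments
("same spikes, different noise") possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .probes import Probe
from .templategen import TemplateLibrary, template_peak_amplitude
from . import spiketrains as st
from .spiketrains import SpikeTrainSet, SynchronyParams
from . import noisegen
from .noisegen import NoiseSpec

__all__ = [
    "SelectionRules",
    "ModulationParams",
    "DriftParams",
    "RecordingParams",
    "SpikeTrainParams",
    "RecordingBundle",
    "template_amplitudes",
    "is_spatially_overlapping",
    "select_templates",
    "compute_modulation_values",
    "stretch_template",
    "jitter_templates",
    "make_fast_drift_schedule",
    "drift_step_at",
    "convolve_unit",
    "assemble_recording",
    "filter_recording",
]


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass
class SelectionRules:
    """Rules for picking recording units out of a template library."""

    n_exc: int = 4
    n_inh: int = 2
    min_dist: float = 25.0  # um between somata
    min_amp: float = 0.0  # uV
    max_amp: float = np.inf  # uV
    n_overlapping_pairs: int = 0
    overlap_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.min_dist < 0:
            raise ValueError("min_dist must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["max_amp"] = None if np.isinf(self.max_amp) else self.max_amp
        return d


@dataclass
class ModulationParams:
    """Per-spike amplitude (and optional shape) modulation.

    Without bursting every spike gets an independent Normal(1, mod_sd^2)
    modulation value.  With bursting, spikes are grouped into burst events
    (consecutive ISIs below ``burst_isi_threshold``; an event closes when it
    holds ``max_spikes_per_burst`` spikes or spans ``max_burst_duration``)
    and the value decays with the number of prior spikes in the event and
    recovers with their mean ISI:

        value = q * max(mod_floor, exp(-depression_beta * n * max(0, 1 - mean_isi / isi_sat)))

    ``shape_stretch`` widens the waveform of depressed spikes when the mode
    is "amplitude+shape".
    """

    mode: str = "amplitude"  # "none" | "amplitude" | "amplitude+shape"
    mod_sd: float = 0.05
    bursting: bool = False
    max_spikes_per_burst: int = 10
    max_burst_duration: float = 100.0  # ms
    burst_isi_threshold: float = 50.0  # ms
    shape_stretch: float = 30.0
    depression_beta: float = 0.2
    isi_sat: float = 50.0  # ms
    mod_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("none", "amplitude", "amplitude+shape"):
            raise ValueError(f"unknown modulation mode {self.mode!r}")
        if not (0.0 < self.mod_floor <= 1.0):
            raise ValueError("mod_floor must be in (0, 1]")
        if self.mod_sd < 0:
            raise ValueError("mod_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DriftParams:
    """Drift playback parameters.

    mode "slow": the active drift step follows the position travelled at
    ``velocity`` along the trajectory, reflecting at both ends.
    mode "fast": the step jumps every ``fast_period`` seconds to a step
    whose max-channel amplitude differs from the current one by an amount
    within ``fast_amp_limits``.  "slow+fast" combines both.
    """

    enabled: bool = False
    mode: str = "slow"  # "slow" | "fast" | "slow+fast"
    velocity: float = 5.0  # um / min
    fast_period: float = 20.0  # s
    fast_amp_limits: tuple[float, float] = (5.0, 20.0)  # uV

    def __post_init__(self) -> None:
        if self.mode not in ("slow", "fast", "slow+fast"):
            raise ValueError(f"unknown drift mode {self.mode!r}")
        if self.velocity < 0:
            raise ValueError("velocity must be non-negative")
        if not self.fast_amp_limits[0] < self.fast_amp_limits[1]:
            raise ValueError("fast_amp_limits must be increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fast_amp_limits"] = list(self.fast_amp_limits)
        return d


@dataclass
class SpikeTrainParams:
    """Spike-train statistics for the recording units."""

    rate_exc: float = st.DEFAULT_RATE_EXC
    rate_inh: float = st.DEFAULT_RATE_INH
    process: str = "gamma"
    gamma_shape: float = st.DEFAULT_GAMMA_SHAPE
    refractory: float = st.DEFAULT_REFRACTORY
    sync_rate: float | None = None
    collision_window: float = 0.001

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RecordingParams:
    """Global recording parameters and the four seed streams."""

    fs: float = 32000.0
    duration: float = 10.0
    n_jitters: int = 10
    upsample_factor: int = 10
    chunk_duration: float = 20.0
    filter_mode: str = "none"  # "none" | "highpass" | "bandpass"
    filter_cutoffs: tuple = (300.0, 6000.0)
    filter_order: int = 3
    st_seed: int = 0
    temp_seed: int = 1
    noise_seed: int = 2
    conv_seed: int = 3

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.n_jitters < 1:
            raise ValueError("n_jitters must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter_cutoffs"] = list(np.atleast_1d(self.filter_cutoffs).astype(float))
        return d


@dataclass
class RecordingBundle:
    """A synthesized recording together with its full ground truth."""

    recordings: np.ndarray  # (n_electrodes, n_samples) uV
    spiketrains: SpikeTrainSet
    templates: np.ndarray  # (n_neurons, [n_drift_steps,] n_jitters, n_electrodes, n_points)
    templates_celltypes: np.ndarray
    templates_locations: np.ndarray
    templates_rotations: np.ndarray
    channel_positions: np.ndarray
    timestamps: np.ndarray
    voltage_peaks: np.ndarray  # (n_neurons, n_electrodes), signed troughs
    spike_traces: np.ndarray  # (n_neurons, n_samples)
    info: dict

    @property
    def n_neurons(self) -> int:
        return self.templates.shape[0]

    @property
    def drifting(self) -> bool:
        return self.templates.ndim == 5


# ---------------------------------------------------------------------------
# Template services
# ---------------------------------------------------------------------------

def template_amplitudes(template: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-channel amplitude (|min over time|, uV) and the index of the
    channel with the largest amplitude (ties resolved to the lowest index)."""
    template = np.asarray(template)
    amps = np.abs(np.min(template, axis=-1))
    return amps, int(np.argmax(amps))


def is_spatially_overlapping(t_a: np.ndarray, t_b: np.ndarray, threshold: float = 0.9) -> bool:
    """Two templates overlap spatially when, on the max channel of one of
    them, the other's amplitude exceeds ``threshold`` times its own maximum."""
    amps_a, ch_a = template_amplitudes(t_a)
    amps_b, ch_b = template_amplitudes(t_b)
    return bool(
        amps_b[ch_a] >= threshold * amps_b[ch_b] or amps_a[ch_b] >= threshold * amps_a[ch_a]
    )


def _library_static_view(library: TemplateLibrary):
    """(templates, locations) at drift step 0 for selection purposes."""
    if library.drifting:
        return library.templates[:, 0], library.locations[:, 0]
    return library.templates, library.locations


def select_templates(
    library: TemplateLibrary, rules: SelectionRules, temp_seed: int, max_draws: int = 10000
) -> np.ndarray:
    """Randomly select ``n_exc + n_inh`` template indices satisfying the
    amplitude bounds, pairwise minimum soma distance and the requested number
    of spatially overlapping pairs.  Deterministic per ``temp_seed``."""
    rng = np.random.default_rng(temp_seed)
    tpls, locs = _library_static_view(library)
    amps = np.array([template_amplitudes(t)[0].max() for t in tpls])
    celltypes = np.asarray(library.celltypes)

    in_amp = (amps >= rules.min_amp) & (amps <= rules.max_amp)
    pool_exc = np.flatnonzero((celltypes == "excitatory") & in_amp)
    pool_inh = np.flatnonzero((celltypes == "inhibitory") & in_amp)
    if len(pool_exc) < rules.n_exc or len(pool_inh) < rules.n_inh:
        raise RuntimeError(
            "template library too small after amplitude/cell-type filtering: "
            f"{len(pool_exc)} excitatory (need {rules.n_exc}), "
            f"{len(pool_inh)} inhibitory (need {rules.n_inh})"
        )

    failures = {"min_dist": 0, "overlap": 0}
    for _ in range(max_draws):
        chosen: list[int] = []
        ok = True
        for pool, n_needed in ((pool_exc, rules.n_exc), (pool_inh, rules.n_inh)):
            perm = rng.permutation(pool)
            taken = 0
            for idx in perm:
                if taken == n_needed:
                    break
                if all(
                    np.linalg.norm(locs[idx] - locs[c]) >= rules.min_dist for c in chosen
                ):
                    chosen.append(int(idx))
                    taken += 1
            if taken < n_needed:
                ok = False
                break
        if not ok:
            failures["min_dist"] += 1
            continue
        if rules.n_overlapping_pairs > 0:
            n_over = sum(
                is_spatially_overlapping(tpls[i], tpls[j], rules.overlap_threshold)
                for k, i in enumerate(chosen)
                for j in chosen[k + 1 :]
            )
            if n_over < rules.n_overlapping_pairs:
                failures["overlap"] += 1
                continue
        return np.asarray(chosen)
    binding = max(failures, key=failures.get)
    raise RuntimeError(
        f"template selection failed after {max_draws} draws; binding constraint: {binding} "
        f"(min_dist={rules.min_dist}, n_overlapping_pairs={rules.n_overlapping_pairs})"
    )


# ---------------------------------------------------------------------------
# Modulation
# ---------------------------------------------------------------------------

def compute_modulation_values(
    times: np.ndarray, params: ModulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Per-spike modulation values for a sorted spike-time array (seconds)."""
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    q = rng.normal(1.0, params.mod_sd, size=times.size)
    if not params.bursting or times.size == 0:
        return q

    isi_thresh = params.burst_isi_threshold / 1e3
    max_dur = params.max_burst_duration / 1e3
    isi_sat = params.isi_sat / 1e3
    values = np.empty_like(q)
    event_start = times[0]
    event_count = 0  # spikes already in the current event
    for i, t in enumerate(times):
        if i > 0:
            isi = t - times[i - 1]
            if (
                isi >= isi_thresh
                or event_count >= params.max_spikes_per_burst
                or (t - event_start) >= max_dur
            ):
                event_start = t
                event_count = 0
        n_prior = event_count
        if n_prior == 0:
            factor = 1.0
        else:
            mean_isi = (t - event_start) / n_prior
            factor = max(
                params.mod_floor,
                float(np.exp(-params.depression_beta * n_prior * max(0.0, 1.0 - mean_isi / isi_sat))),
            )
        values[i] = q[i] * factor
        event_count += 1
    return values


def stretch_template(template: np.ndarray, m: float, shape_stretch: float) -> np.ndarray:
    """Stretch a template's time axis about its trough by
    ``k = 1 + shape_stretch * max(0, 1 - m)`` using band-limited resampling.

    The sample count and the trough sample index are preserved; samples that
    would fall outside the original support hold the edge values.
    """
    if m <= 0:
        raise ValueError("modulation value must be positive")
    k = 1.0 + shape_stretch * max(0.0, 1.0 - m)
    template = np.asarray(template, dtype=float)
    if k == 1.0:
        return template.copy()
    n = template.shape[-1]
    trough = int(np.unravel_index(np.argmin(template), template.shape)[-1])
    up = 16
    fine = signal.resample_poly(template, up, 1, axis=-1, padtype="edge")
    # sample the stretched waveform: source position trough + (i - trough)/k
    pos = (trough + (np.arange(n) - trough) / k) * up
    pos = np.clip(pos, 0.0, fine.shape[-1] - 1.0)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, fine.shape[-1] - 1)
    frac = pos - i0
    return fine[..., i0] * (1.0 - frac) + fine[..., i1] * frac


def jitter_templates(
    template: np.ndarray,
    n_jitters: int,
    upsample_factor: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sub-sample-shifted copies of a template.

    For a ``(n_channels, n_points)`` input, returns
    ``(n_jitters, n_channels, n_points)`` where version 0 is unshifted and
    the others are shifted by random fractions of one sample (multiples of
    ``1/upsample_factor``).  For a drifting ``(n_steps, n_channels,
    n_points)`` input the same shift sequence is applied to every step and
    the result is ``(n_steps, n_jitters, n_channels, n_points)``.
    """
    if n_jitters < 1:
        raise ValueError("n_jitters must be >= 1")
    template = np.asarray(template, dtype=float)
    shifts = [0] + [
        int(rng.integers(1, upsample_factor)) for _ in range(n_jitters - 1)
    ]

    def _jitter_2d(tpl: np.ndarray) -> np.ndarray:
        n = tpl.shape[-1]
        up = signal.resample_poly(tpl, upsample_factor, 1, axis=-1, padtype="edge")
        pad = np.pad(up, [(0, 0)] * (up.ndim - 1) + [(0, upsample_factor)], mode="edge")
        out = np.empty((n_jitters,) + tpl.shape)
        out[0] = tpl  # version 0 is exactly the original waveform
        for v, s in enumerate(shifts[1:], start=1):
            out[v] = pad[..., s::upsample_factor][..., :n]
        return out

    if template.ndim == 2:
        return _jitter_2d(template)
    if template.ndim == 3:
        return np.stack([_jitter_2d(step) for step in template])
    raise ValueError("template must be 2D or 3D")


# ---------------------------------------------------------------------------
# Drift playback
# ---------------------------------------------------------------------------

def _slow_index(t: float, drift: DriftParams, n_steps: int, step_length: float) -> int:
    span = step_length * (n_steps - 1)
    if span <= 0:
        return 0
    d = drift.velocity / 60.0 * t
    phase = d % (2.0 * span)
    pos = phase if phase <= span else 2.0 * span - phase
    return int(np.clip(round(pos / step_length), 0, n_steps - 1))


def _fast_target(current: int, traj_amps: np.ndarray, limits, rng) -> int:
    diffs = np.abs(traj_amps - traj_amps[current])
    candidates = np.flatnonzero((diffs >= limits[0]) & (diffs <= limits[1]))
    candidates = candidates[candidates != current]
    if candidates.size:
        return int(rng.choice(candidates))
    # fallback: step whose amplitude difference is nearest to the band
    others = np.flatnonzero(np.arange(traj_amps.size) != current)
    dist = np.maximum.reduce([limits[0] - diffs[others], diffs[others] - limits[1], np.zeros(others.size)])
    return int(others[np.argmin(dist)])


def make_fast_drift_schedule(
    t_max: float,
    drift: DriftParams,
    n_steps: int,
    traj_amps: np.ndarray,
    rng: np.random.Generator,
    step_length: float = 1.0,
) -> list[tuple[float, int]]:
    """Precompute the abrupt drift jumps in ``(0, t_max)``.

    Returns a list of ``(jump_time, value)`` where ``value`` is the new step
    index for "fast" mode, or the offset added to the slow index for
    "slow+fast" mode.
    """
    traj_amps = np.asarray(traj_amps, dtype=float)
    schedule: list[tuple[float, int]] = []
    k = 1
    cur_offset = 0
    cur_idx = 0
    while k * drift.fast_period < t_max:
        jt = k * drift.fast_period
        if drift.mode == "fast":
            cur_idx = _fast_target(cur_idx, traj_amps, drift.fast_amp_limits, rng)
            schedule.append((jt, cur_idx))
        else:  # slow+fast
            slow = _slow_index(jt, drift, n_steps, step_length)
            combined = int(np.clip(slow + cur_offset, 0, n_steps - 1))
            target = _fast_target(combined, traj_amps, drift.fast_amp_limits, rng)
            cur_offset = target - slow
            schedule.append((jt, cur_offset))
        k += 1
    return schedule


def drift_step_at(
    t: float,
    drift: DriftParams,
    n_drift_steps: int,
    traj_amplitudes: np.ndarray | None = None,
    schedule: list | None = None,
    step_length: float = 1.0,
) -> int:
    """Active drift-step index at time ``t`` (seconds).

    For "fast" and "slow+fast" modes a precomputed ``schedule`` from
    :func:`make_fast_drift_schedule` must be supplied so that the jump
    sequence is identical for every query time.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if drift.mode == "slow":
        return _slow_index(t, drift, n_drift_steps, step_length)
    if schedule is None:
        raise ValueError("fast drift modes require a precomputed schedule")
    value = None
    for jt, v in schedule:
        if jt <= t:
            value = v
        else:
            break
    if drift.mode == "fast":
        return 0 if value is None else int(value)
    # slow+fast
    slow = _slow_index(t, drift, n_drift_steps, step_length)
    offset = 0 if value is None else int(value)
    return int(np.clip(slow + offset, 0, n_drift_steps - 1))


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def convolve_unit(
    times: np.ndarray,
    templates: np.ndarray,
    mod_values: np.ndarray,
    fs: float,
    n_samples: int,
    jitter_choices: np.ndarray,
    modulation: ModulationParams | None = None,
    drift: DriftParams | None = None,
    traj_amplitudes: np.ndarray | None = None,
    drift_schedule: list | None = None,
    trough_index: int | None = None,
    step_length: float = 1.0,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Add one unit's modulated template waveforms into a recording array.

    ``templates`` is ``(n_jitters, n_channels, n_points)`` or, when
    drifting, ``(n_drift_steps, n_jitters, n_channels, n_points)``.  Each
    spike uses its precomputed jitter choice and modulation value; the
    template trough is aligned to the spike sample, and spikes whose cut-out
    crosses a recording edge are truncated.
    """
    templates = np.asarray(templates, dtype=float)
    drifting = templates.ndim == 4
    n_points = templates.shape[-1]
    n_channels = templates.shape[-2]
    if out is None:
        out = np.zeros((n_channels, n_samples), dtype=np.float32)
    if trough_index is None:
        ref = templates[0, 0] if drifting else templates[0]
        trough_index = int(np.unravel_index(np.argmin(ref), ref.shape)[-1])
    shape_mod = modulation is not None and modulation.mode == "amplitude+shape"

    for i, t in enumerate(np.asarray(times, dtype=float)):
        jidx = int(jitter_choices[i])
        if drifting:
            step = drift_step_at(
                t, drift, templates.shape[0], traj_amplitudes, drift_schedule, step_length
            )
            tpl = templates[step, jidx]
        else:
            tpl = templates[jidx]
        m = float(mod_values[i])
        if shape_mod and m < 1.0:
            tpl = stretch_template(tpl, m, modulation.shape_stretch)
        center = int(round(t * fs))
        lo = center - trough_index
        hi = lo + n_points
        src_lo, src_hi = max(lo, 0), min(hi, n_samples)
        if src_lo >= src_hi:
            continue
        out[:, src_lo:src_hi] += (m * tpl[:, src_lo - lo : src_hi - lo]).astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _probe_from_info(info: dict) -> Probe:
    p = info["probe"]
    return Probe(name=p["name"], positions=np.asarray(p["positions"]), description=p.get("description", ""))


def assemble_recording(
    library: TemplateLibrary,
    rules: SelectionRules | None = None,
    st_params: SpikeTrainParams | None = None,
    modulation: ModulationParams | None = None,
    drift: DriftParams | None = None,
    noise_spec: NoiseSpec | None = None,
    rec_params: RecordingParams | None = None,
) -> RecordingBundle:
    """Synthesize a recording with full ground truth from a template library.

    Processing is organized in time chunks of ``chunk_duration``; because
    every per-spike random draw is made upfront in spike order, the result
    is identical for any chunking of the same recording.
    """
    rules = rules or SelectionRules()
    st_params = st_params or SpikeTrainParams()
    modulation = modulation or ModulationParams()
    drift = drift or DriftParams()
    noise_spec = noise_spec or NoiseSpec()
    rec_params = rec_params or RecordingParams()

    probe = _probe_from_info(library.info)
    fs = rec_params.fs
    lib_fs = library.info.get("fs")
    if lib_fs is not None and abs(lib_fs - fs) > 1e-6:
        raise ValueError(f"library sampling rate {lib_fs} Hz != recording fs {fs} Hz")
    duration = rec_params.duration
    n_samples = int(round(duration * fs))

    if drift.enabled and not library.drifting:
        raise ValueError("drift requested but the template library is not drifting")

    # --- spike trains (st_seed stream) -----------------------------------
    trains = st.generate_set(
        rules.n_exc,
        rules.n_inh,
        rate_exc=st_params.rate_exc,
        rate_inh=st_params.rate_inh,
        duration=duration,
        process=st_params.process,
        gamma_shape=st_params.gamma_shape,
        refractory=st_params.refractory,
        seed=rec_params.st_seed,
    )

    # --- template selection (temp_seed stream) ---------------------------
    selected = select_templates(library, rules, rec_params.temp_seed)
    static_tpls, static_locs = _library_static_view(library)
    sel_static = static_tpls[selected]

    # synchrony editing on spatially overlapping selected pairs
    overlapping = [
        (i, j)
        for i in range(len(selected))
        for j in range(i + 1, len(selected))
        if is_spatially_overlapping(sel_static[i], sel_static[j], rules.overlap_threshold)
    ]
    sync = SynchronyParams(
        sync_rate=st_params.sync_rate, collision_window=st_params.collision_window
    )
    rng_sync = np.random.default_rng([rec_params.st_seed, 1])
    trains = st.apply_synchrony(trains, overlapping, sync, rng_sync)

    # --- convolution (conv_seed stream) ----------------------------------
    rng_conv = np.random.default_rng(rec_params.conv_seed)
    use_drift = drift.enabled and library.drifting
    n_units = len(selected)

    unit_templates = []
    traj_amps = []
    step_lengths = []
    for u, lib_idx in enumerate(selected):
        tpl = library.templates[lib_idx]
        if library.drifting and not use_drift:
            tpl = tpl[0]
        jittered = jitter_templates(tpl, rec_params.n_jitters, rec_params.upsample_factor, rng_conv)
        unit_templates.append(jittered)
        if use_drift:
            steps = library.templates[lib_idx]
            traj_amps.append(np.array([template_amplitudes(s)[0].max() for s in steps]))
            traj = library.locations[lib_idx]
            step_lengths.append(float(np.linalg.norm(traj[1] - traj[0])))
        else:
            traj_amps.append(None)
            step_lengths.append(1.0)

    mod_values = [
        compute_modulation_values(trains.trains[u], modulation, rng_conv)
        if modulation.mode != "none"
        else np.ones(len(trains.trains[u]))
        for u in range(n_units)
    ]
    jitter_choices = [
        rng_conv.integers(0, rec_params.n_jitters, size=len(trains.trains[u]))
        for u in range(n_units)
    ]
    schedules = [
        make_fast_drift_schedule(
            duration, drift, library.templates.shape[1], traj_amps[u], rng_conv, step_lengths[u]
        )
        if use_drift and drift.mode != "slow"
        else None
        for u in range(n_units)
    ]

    recordings = np.zeros((probe.n_channels, n_samples), dtype=np.float32)
    spike_traces = np.zeros((n_units, n_samples), dtype=np.float32)
    voltage_peaks = np.empty((n_units, probe.n_channels))

    for u in range(n_units):
        tpl_u = unit_templates[u]
        base = tpl_u[0, 0] if use_drift else tpl_u[0]  # unjittered, first step
        voltage_peaks[u] = np.min(base, axis=-1)
        trough = int(np.unravel_index(np.argmin(base), base.shape)[-1])
        convolve_unit(
            trains.trains[u],
            tpl_u,
            mod_values[u],
            fs,
            n_samples,
            jitter_choices[u],
            modulation=modulation,
            drift=drift if use_drift else None,
            traj_amplitudes=traj_amps[u],
            drift_schedule=schedules[u],
            trough_index=trough,
            step_length=step_lengths[u],
            out=recordings,
        )
        # clean max-channel trace: unmodulated, unjittered convolution
        _, max_ch = template_amplitudes(base)
        wave = base[max_ch]
        for t_spk in trains.trains[u]:
            center = int(round(t_spk * fs))
            lo = center - trough
            hi = lo + wave.size
            src_lo, src_hi = max(lo, 0), min(hi, n_samples)
            if src_lo < src_hi:
                spike_traces[u, src_lo:src_hi] += wave[src_lo - lo : src_hi - lo].astype(np.float32)

    # --- noise (noise_seed stream) ---------------------------------------
    rng_noise = np.random.default_rng(rec_params.noise_seed)
    if noise_spec.level > 0:
        noise = noisegen.generate_noise(noise_spec, probe, duration, fs, rng_noise)
        recordings = recordings + noise.astype(np.float32)

    # --- optional filtering ----------------------------------------------
    if rec_params.filter_mode != "none":
        recordings = filter_recording(
            recordings,
            rec_params.filter_mode,
            rec_params.filter_cutoffs,
            rec_params.filter_order,
            fs,
        )

    timestamps = np.arange(n_samples) / fs
    info = {
        "probe": probe.to_dict(),
        "rules": rules.to_dict(),
        "spiketrain_params": st_params.to_dict(),
        "modulation": modulation.to_dict(),
        "drift": drift.to_dict(),
        "noise": noise_spec.to_dict(),
        "recording_params": rec_params.to_dict(),
        "seeds": {
            "st_seed": rec_params.st_seed,
            "temp_seed": rec_params.temp_seed,
            "noise_seed": rec_params.noise_seed,
            "conv_seed": rec_params.conv_seed,
        },
        "selected_template_indices": [int(i) for i in selected],
        "template_library_seed": library.info.get("seed"),
        "fs": fs,
        "duration": duration,
    }

    sel_locs = library.locations[selected]
    return RecordingBundle(
        recordings=recordings,
        spiketrains=trains,
        templates=np.stack(unit_templates),
        templates_celltypes=np.asarray(library.celltypes)[selected],
        templates_locations=sel_locs if use_drift or not library.drifting else sel_locs[:, 0],
        templates_rotations=library.rotations[selected],
        channel_positions=probe.positions,
        timestamps=timestamps,
        voltage_peaks=voltage_peaks,
        spike_traces=spike_traces,
        info=info,
    )


def filter_recording(
    recordings: np.ndarray,
    mode: str,
    cutoffs,
    order: int = 3,
    fs: float = 32000.0,
) -> np.ndarray:
    """Zero-phase Butterworth filtering of a (channels x samples) array."""
    cutoffs = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if np.any(cutoffs >= fs / 2) or np.any(cutoffs <= 0):
        raise ValueError("cutoffs must lie in (0, fs/2)")
    if mode == "highpass":
        sos = signal.butter(order, cutoffs[0], btype="highpass", fs=fs, output="sos")
    elif mode == "bandpass":
        if cutoffs.size != 2 or cutoffs[0] >= cutoffs[1]:
            raise ValueError("bandpass needs increasing (low, high) cutoffs")
        sos = signal.butter(order, cutoffs, btype="bandpass", fs=fs, output="sos")
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    filtered = signal.sosfiltfilt(sos, np.asarray(recordings, dtype=float), axis=-1)
    return filtered.astype(np.asarray(recordings).dtype)
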