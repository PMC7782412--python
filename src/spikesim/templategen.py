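"""Extracellular template (EAP) library generation.

The template library is built in two conceptual steps that mirror how
biophysical simulators produce extracellular action potentials:

1. an *intracellular* step computes, for each cell model, the transmembrane
   currents of an action potential on every morphological segment, and
2. an *extracellular* step places the cell at a random position/rotation next
   to a probe and evaluates the extracellular potential at every electrode
   with the line-source approximation for a homogeneous conductive medium.

Instead of compartmental neuron models, the package ships a bank of 13
parametric "ball-and-stick+" cells (a soma segment, a 5-segment apical trunk
and two basal dendrites).  The somatic segment carries a stereotyped action
potential current (difference of exponentials plus a shallow rectangular
after-hyperpolarization, zero net charge), and the dendritic segments carry
the negated return current distributed proportionally to membrane area, so
the summed transmembrane current is zero at every instant, as required by
charge conservation.  This preserves the spatial structure of the forward
problem (negative-dominant somatic trough, dipolar far field, distance
decay) while keeping the generator fully self-contained.

Units: positions in um, currents in nA, conductivity in S/m, potentials in
uV, times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .probes import Probe

__all__ = [
    "APParams",
    "SyntheticCellModel",
    "ForwardModelParams",
    "DriftRules",
    "TemplateLibrary",
    "default_cell_bank",
    "simulate_transmembrane_currents",
    "place_cell",
    "line_source_potential",
    "compute_eap",
    "make_drift_trajectory",
    "generate_templates",
    "template_peak_amplitude",
]

#: conversion factor so that I[nA] / (4 pi sigma[S/m] d[um]) comes out in uV
_UNIT_FACTOR = 1e3

#: default sampling rate (Hz) of the intracellular waveforms
DEFAULT_FS = 32000.0


# ---------------------------------------------------------------------------
# Cell bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APParams:
    """Somatic action-potential current parameters.

    peak_amplitude : nA, absolute amplitude of the somatic trough current
    tau_depol : ms, depolarization (rise) time constant
    tau_repol : ms, repolarization (decay) time constant
    trough_width : ms, full width at half minimum of the somatic current
    """

    peak_amplitude: float
    tau_depol: float
    tau_repol: float
    trough_width: float


@dataclass(frozen=True)
class SyntheticCellModel:
    """Segmented stick morphology plus AP current parameters.

    segments is a list of ``(start, end, radius)`` with start/end 3D points
    in um; ``soma_index`` marks the segment carrying the AP current.
    """

    model_id: str
    cell_type: str  # "excitatory" | "inhibitory"
    segments: tuple
    soma_index: int
    ap_params: APParams

    def __post_init__(self) -> None:
        if len(self.segments) < 2:
            raise ValueError("a cell model needs at least 2 segments")
        for start, end, radius in self.segments:
            if np.linalg.norm(np.asarray(end) - np.asarray(start)) <= 0:
                raise ValueError("zero-length segment in cell model")
            if radius <= 0:
                raise ValueError("non-positive segment radius")

    def segment_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        starts = np.array([s for s, _, _ in self.segments], dtype=float)
        ends = np.array([e for _, e, _ in self.segments], dtype=float)
        radii = np.array([r for _, _, r in self.segments], dtype=float)
        return starts, ends, radii


def _stick(start, direction, length, n, radius) -> list:
    """Split a straight neurite of given length into n segments."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pts = [np.asarray(start, dtype=float) + d * length * i / n for i in range(n + 1)]
    return [(tuple(pts[i]), tuple(pts[i + 1]), radius) for i in range(n)]


def default_cell_bank(seed: int) -> list[SyntheticCellModel]:
    """Build the default bank of 13 cortical-like cells (10 excitatory
    pyramidal-style, 3 inhibitory basket-style), deterministically per seed.

    Inhibitory cells have narrower somatic troughs (0.3 ms vs 0.6 ms) and a
    faster repolarization time constant, giving the narrow extracellular
    spikes typical of fast-spiking interneurons.
    """
    rng = np.random.default_rng(seed)
    bank: list[SyntheticCellModel] = []
    for i in range(13):
        cell_type = "excitatory" if i < 10 else "inhibitory"
        # small per-model geometric variability
        apical_len = rng.uniform(250.0, 350.0)
        basal_len = rng.uniform(80.0, 120.0)
        soma_len = rng.uniform(15.0, 25.0)
        soma_r = rng.uniform(7.0, 10.0)
        tilt = rng.uniform(-0.15, 0.15, size=2)  # slight apical tilt (radians)

        segments = []
        # soma: short thick vertical segment centered at the origin
        segments.append(((0.0, 0.0, -soma_len / 2), (0.0, 0.0, soma_len / 2), soma_r))
        soma_index = 0
        # apical trunk: 5 segments going up (axis 2), slightly tilted
        apical_dir = np.array([np.sin(tilt[0]), np.sin(tilt[1]), 1.0])
        segments += _stick((0.0, 0.0, soma_len / 2), apical_dir, apical_len, 5, 1.5)
        # two basal dendrites going down and sideways
        segments += _stick((0.0, 0.0, -soma_len / 2), (0.0, 0.6, -1.0), basal_len, 1, 1.0)
        segments += _stick((0.0, 0.0, -soma_len / 2), (0.0, -0.6, -1.0), basal_len, 1, 1.0)

        if cell_type == "excitatory":
            ap = APParams(
                peak_amplitude=rng.uniform(4.0, 7.0),
                tau_depol=0.1,
                tau_repol=0.5,
                trough_width=rng.uniform(0.55, 0.7),
            )
        else:
            ap = APParams(
                peak_amplitude=rng.uniform(4.0, 7.0),
                tau_depol=0.1,
                tau_repol=0.25,
                trough_width=rng.uniform(0.25, 0.35),
            )
        bank.append(
            SyntheticCellModel(
                model_id=f"{cell_type[:3]}_{i:02d}",
                cell_type=cell_type,
                segments=tuple(segments),
                soma_index=soma_index,
                ap_params=ap,
            )
        )
    return bank


# ---------------------------------------------------------------------------
# Intracellular step: transmembrane currents
# ---------------------------------------------------------------------------

#: duration (ms) of the simulated current window and AP onset time (ms)
_CURRENT_WINDOW_MS = 10.0
_AP_ONSET_MS = 2.5


def _soma_current(ap: APParams, dt: float) -> np.ndarray:
    """Somatic AP transmembrane current: negative difference-of-exponentials
    trough, time-scaled to the requested trough width, plus a shallow
    rectangular after-hyperpolarization lobe that zeroes the net charge."""
    n_t = int(round(_CURRENT_WINDOW_MS / dt))
    t = np.arange(n_t) * dt
    # reference biphasic core on a fine grid to measure its FWHM
    tau_d, tau_r = ap.tau_depol, ap.tau_repol
    fine = np.arange(0.0, 8.0 * tau_r, min(dt, 0.001))
    core_fine = np.exp(-fine / tau_r) - np.exp(-fine / tau_d)
    core_fine /= core_fine.max()
    above = fine[core_fine >= 0.5]
    base_width = above[-1] - above[0]
    scale = base_width / ap.trough_width  # time-compression factor

    tt = (t - _AP_ONSET_MS) * scale
    core = np.where(tt >= 0.0, np.exp(-np.maximum(tt, 0.0) / tau_r) - np.exp(-np.maximum(tt, 0.0) / tau_d), 0.0)
    peak = core.max()
    current = -ap.peak_amplitude * core / peak

    # rectangular AHP starting once the core has decayed to <1% of its peak
    decay_end = _AP_ONSET_MS + 5.0 * tau_r / scale
    ahp_start = min(decay_end, _CURRENT_WINDOW_MS - 2.5)
    ahp_mask = (t >= ahp_start) & (t < ahp_start + 2.0)
    n_ahp = ahp_mask.sum()
    if n_ahp:
        current[ahp_mask] -= current.sum() / n_ahp  # zero net charge
    return current


def simulate_transmembrane_currents(model: SyntheticCellModel, dt: float) -> np.ndarray:
    """Transmembrane current of every segment during one action potential.

    Returns an ``(n_segments, n_t)`` array in nA whose columns sum to zero:
    the soma carries the AP current and the other segments carry the negated
    return current weighted by their lateral membrane area.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    soma = _soma_current(model.ap_params, dt)
    starts, ends, radii = model.segment_arrays()
    lengths = np.linalg.norm(ends - starts, axis=1)
    areas = 2.0 * np.pi * radii * lengths
    weights = np.delete(areas, model.soma_index)
    weights = weights / weights.sum()

    currents = np.empty((len(model.segments), soma.size))
    currents[model.soma_index] = soma
    others = [i for i in range(len(model.segments)) if i != model.soma_index]
    for w, i in zip(weights, others):
        currents[i] = -w * soma
    return currents


# ---------------------------------------------------------------------------
# Extracellular step: placement and line-source forward model
# ---------------------------------------------------------------------------

@dataclass
class ForwardModelParams:
    """Forward-model and template-acceptance parameters.

    sigma : S/m, extracellular conductivity
    dt : ms, sampling step of the waveforms
    cut_out : (pre, post) ms around the global trough kept in the template
    min_amplitude : uV, smallest accepted peak template amplitude
    max_amplitude : uV or None, largest accepted amplitude (used e.g. to
        select sub-threshold far-field neurons)
    position_bounds : ((lo, hi) per axis) um soma placement box; ``None``
        means the default box relative to the probe (axis 0 in [10, 80] um,
        plane axes = probe bounding box padded by 30 um)
    rotation_mode : "none" | "z-only" | "3d"
    tilt_limit : radians, maximum off-vertical tilt in "3d" mode
    """

    sigma: float = 0.3
    dt: float = 1e3 / DEFAULT_FS
    cut_out: tuple[float, float] = (2.0, 5.0)
    min_amplitude: float = 30.0
    max_amplitude: float | None = None
    position_bounds: tuple | None = None
    rotation_mode: str = "3d"
    tilt_limit: float = np.deg2rad(15.0)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.cut_out[0] <= 0 or self.cut_out[1] <= 0:
            raise ValueError("cut_out components must be positive")

    def resolve_bounds(self, probe: Probe) -> np.ndarray:
        if self.position_bounds is not None:
            b = np.asarray(self.position_bounds, dtype=float)
            if b.shape != (3, 2) or np.any(b[:, 1] < b[:, 0]):
                raise ValueError("position_bounds must be three non-degenerate (lo, hi) pairs")
            return b
        pos = probe.positions
        bounds = np.empty((3, 2))
        bounds[0] = (10.0, 80.0)
        for ax in (1, 2):
            bounds[ax] = (pos[:, ax].min() - 30.0, pos[:, ax].max() + 30.0)
        return bounds

    def to_dict(self) -> dict:
        d = asdict(self)
        d["position_bounds"] = (
            None if self.position_bounds is None else np.asarray(self.position_bounds).tolist()
        )
        # lists rather than tuples so the record round-trips through YAML
        d["cut_out"] = list(self.cut_out)
        return d


def _rotation_from_mode(mode: str, tilt_limit: float, rng: np.random.Generator) -> np.ndarray:
    """Draw Euler angles (radians, xyz order) for the requested mode."""
    if mode == "none":
        return np.zeros(3)
    if mode == "z-only":
        return np.array([0.0, 0.0, rng.uniform(0.0, 2.0 * np.pi)])
    if mode == "3d":
        return np.array(
            [
                rng.uniform(-tilt_limit, tilt_limit),
                rng.uniform(-tilt_limit, tilt_limit),
                rng.uniform(0.0, 2.0 * np.pi),
            ]
        )
    raise ValueError(f"unknown rotation_mode {mode!r}")


def _transform_segments(model, rotation_angles, location):
    starts, ends, radii = model.segment_arrays()
    rot = Rotation.from_euler("xyz", rotation_angles)
    soma_start, soma_end, _ = model.segments[model.soma_index]
    center = (np.asarray(soma_start) + np.asarray(soma_end)) / 2.0
    starts = rot.apply(starts - center) + location
    ends = rot.apply(ends - center) + location
    return starts, ends, radii


def place_cell(
    model: SyntheticCellModel,
    probe: Probe,
    params: ForwardModelParams,
    rng: np.random.Generator,
):
    """Rigidly place a cell near the probe: uniform soma location within the
    placement box and a random rotation per ``rotation_mode``.

    Returns ``(starts, ends, radii, location, rotation_angles)``.
    """
    bounds = params.resolve_bounds(probe)
    location = rng.uniform(bounds[:, 0], bounds[:, 1])
    angles = _rotation_from_mode(params.rotation_mode, params.tilt_limit, rng)
    starts, ends, radii = _transform_segments(model, angles, location)
    return starts, ends, radii, location, angles


def line_source_potential(start, end, current, point, sigma: float) -> np.ndarray:
    """Extracellular potential (uV) of a uniform line current.

    The segment from ``start`` to ``end`` (um) carries the transmembrane
    current trace (nA); the potential at ``point`` follows the line-source
    kernel phi = I / (4 pi sigma ds) * ln[(sqrt(l^2+r^2)+l) / (sqrt(h^2+r^2)+h)]
    with ds the segment length, r the transverse distance (clamped to 1 um)
    and h, l the signed longitudinal distances to the two segment ends.
    """
    k = _line_source_kernel(
        np.asarray(start, float)[None, :],
        np.asarray(end, float)[None, :],
        np.asarray(point, float)[None, :],
        sigma,
    )[0, 0]
    return k * np.asarray(current, dtype=float)


def _line_source_kernel(starts, ends, points, sigma) -> np.ndarray:
    """(n_segments, n_points) matrix mapping segment currents (nA) to uV."""
    seg = ends - starts  # (n_seg, 3)
    ds = np.linalg.norm(seg, axis=1)  # (n_seg,)
    u = seg / ds[:, None]
    rel = points[None, :, :] - ends[:, None, :]  # from segment end to point
    h = np.einsum("spk,sk->sp", rel, u)  # signed longitudinal distance
    r2 = np.einsum("spk,spk->sp", rel, rel) - h * h
    r2 = np.maximum(r2, 1.0)  # clamp transverse distance to >= 1 um
    l = h + ds[:, None]
    num = np.sqrt(l * l + r2) + l
    den = np.sqrt(h * h + r2) + h
    # den > 0 always because r2 >= 1; guard against rounding anyway
    den = np.maximum(den, 1e-12)
    return _UNIT_FACTOR * np.log(num / den) / (4.0 * np.pi * sigma * ds[:, None])


def compute_eap(
    starts: np.ndarray,
    ends: np.ndarray,
    currents: np.ndarray,
    probe: Probe,
    params: ForwardModelParams,
) -> np.ndarray:
    """Extracellular action potential on every probe channel.

    Sums the line-source potentials of all segments and trims the result to
    ``cut_out`` around the global (all-channel) trough.  Returns an
    ``(n_channels, n_points)`` array in uV.
    """
    kernel = _line_source_kernel(starts, ends, probe.positions, params.sigma)
    eap = kernel.T @ currents  # (n_channels, n_t)
    return _trim_to_cutout(eap, params)


def _trim_to_cutout(eap: np.ndarray, params: ForwardModelParams) -> np.ndarray:
    n_pre = int(round(params.cut_out[0] / params.dt))
    n_post = int(round(params.cut_out[1] / params.dt))
    trough = int(np.unravel_index(np.argmin(eap), eap.shape)[1])
    lo, hi = trough - n_pre, trough + n_post
    out = np.zeros((eap.shape[0], n_pre + n_post))
    src_lo, src_hi = max(lo, 0), min(hi, eap.shape[1])
    out[:, src_lo - lo : src_hi - lo] = eap[:, src_lo:src_hi]
    return out


def template_peak_amplitude(template: np.ndarray) -> float:
    """Peak amplitude of a template: max over channels of |min over time|."""
    return float(np.max(np.abs(np.min(template, axis=-1))))


# ---------------------------------------------------------------------------
# Drifting trajectories
# ---------------------------------------------------------------------------

@dataclass
class DriftRules:
    """Rules for sampling the drift trajectory endpoint.

    preferred_direction : unit-vector the trajectory should roughly follow
        (default: the probe vertical axis)
    angular_tolerance : radians, half-angle of the acceptance cone
    drift_limits : (min, max) um trajectory length, sampled uniformly
    """

    preferred_direction: tuple = (0.0, 0.0, 1.0)
    angular_tolerance: float = np.deg2rad(30.0)
    drift_limits: tuple[float, float] = (20.0, 60.0)


def make_drift_trajectory(initial, final, n_steps: int) -> np.ndarray:
    """Equally spaced positions on the segment from initial to final."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    return initial[None, :] + np.linspace(0.0, 1.0, n_steps)[:, None] * (final - initial)


def _sample_drift_endpoint(initial, rules: DriftRules, rng) -> np.ndarray:
    pref = np.asarray(rules.preferred_direction, dtype=float)
    pref = pref / np.linalg.norm(pref)
    for _ in range(10000):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if np.arccos(np.clip(v @ pref, -1.0, 1.0)) <= rules.angular_tolerance:
            dist = rng.uniform(*rules.drift_limits)
            return np.asarray(initial) + dist * v
    raise RuntimeError("could not sample a drift direction within the tolerance cone")


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

@dataclass
class TemplateLibrary:
    """Bank of extracellular templates with their generation metadata.

    templates : (n_templates, n_channels, n_points) uV, or with an extra
        drift-step axis (n_templates, n_drift_steps, n_channels, n_points)
    locations : (n_templates, 3) um soma locations (drifting: extra step axis)
    rotations : (n_templates, 3) radians Euler angles (xyz)
    celltypes : (n_templates,) labels
    info : dict with every generation parameter, the probe and the seed
    """

    templates: np.ndarray
    locations: np.ndarray
    rotations: np.ndarray
    celltypes: np.ndarray
    info: dict

    @property
    def drifting(self) -> bool:
        return self.templates.ndim == 4

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    def __post_init__(self) -> None:
        n = self.templates.shape[0]
        if not (len(self.locations) == len(self.rotations) == len(self.celltypes) == n):
            raise ValueError("inconsistent template library array lengths")
        if self.drifting and self.locations.shape[1] != self.templates.shape[1]:
            raise ValueError("drifting locations must carry one row per drift step")


def generate_templates(
    bank: list[SyntheticCellModel],
    probe: Probe,
    n_per_model: int,
    params: ForwardModelParams | None = None,
    drifting: bool = False,
    n_drift_steps: int = 30,
    drift_rules: DriftRules | None = None,
    seed: int = 0,
) -> TemplateLibrary:
    """Generate ``n_per_model`` accepted templates for every cell in the bank.

    Placements are rejection-sampled until the template peak amplitude lies
    within ``[min_amplitude, max_amplitude]``; for drifting libraries one
    template per trajectory step is computed with a fixed rotation and the
    acceptance test applies to the initial step.  Fully deterministic per
    seed.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    params = params or ForwardModelParams()
    drift_rules = drift_rules or DriftRules()
    rng = np.random.default_rng(seed)

    templates, locations, rotations, celltypes = [], [], [], []
    max_attempts = 1000 * n_per_model
    for model in bank:
        currents = simulate_transmembrane_currents(model, params.dt)
        accepted = 0
        attempts = 0
        while accepted < n_per_model:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not find {n_per_model} templates for model "
                    f"{model.model_id} with min_amplitude={params.min_amplitude}"
                    + (
                        f", max_amplitude={params.max_amplitude}"
                        if params.max_amplitude is not None
                        else ""
                    )
                )
            starts, ends, radii, loc, angles = place_cell(model, probe, params, rng)
            eap = compute_eap(starts, ends, currents, probe, params)
            amp = template_peak_amplitude(eap)
            if amp < params.min_amplitude:
                continue
            if params.max_amplitude is not None and amp >= params.max_amplitude:
                continue
            if drifting:
                final = _sample_drift_endpoint(loc, drift_rules, rng)
                traj = make_drift_trajectory(loc, final, n_drift_steps)
                steps = [eap]
                for p in traj[1:]:
                    s2, e2, _ = _transform_segments(model, angles, p)
                    steps.append(compute_eap(s2, e2, currents, probe, params))
                templates.append(np.stack(steps))
                locations.append(traj)
            else:
                templates.append(eap)
                locations.append(loc)
            rotations.append(angles)
            celltypes.append(model.cell_type)
            accepted += 1

    info = {
        "probe": probe.to_dict(),
        "params": params.to_dict(),
        "n_per_model": n_per_model,
        "drifting": bool(drifting),
        "n_drift_steps": int(n_drift_steps) if drifting else None,
        "drift_rules": asdict(drift_rules) if drifting else None,
        "n_models": len(bank),
        "seed": int(seed),
        "fs": 1e3 / params.dt,
    }
    return TemplateLibrary(
        templates=np.asarray(templates),
        locations=np.asarray(locations),
        rotations=np.asarray(rotations),
        celltypes=np.asarray(celltypes),
        info=info,
    )
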