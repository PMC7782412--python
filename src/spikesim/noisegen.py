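"""Additive noise models for synthetic extracellular recordings.

Five profiles are supported, all scaled to a target per-channel standard
deviation (the *noise level*, in uV):

* ``uncorrelated``: i.i.d. Gaussian samples, flat spectrum, diagonal
  channel covariance.
* ``distance-correlated``: multivariate Gaussian with covariance
  ``level^2 * exp(-d_ij / lambda)`` where ``d_ij`` is the inter-electrode
  distance, realized through a Cholesky factor.
* ``colored-uncorrelated`` / ``colored-distance-correlated``: the Gaussian
  profiles passed through a second-order resonant IIR low-pass (peak near
  the spiking band) mixed with a white floor, reproducing the non-flat
  spectrum of biological noise while preserving any spatial correlation.
* ``far-neurons``: the summed activity of many sub-threshold neurons —
  templates accepted only below an amplitude threshold, convolved with
  independent Poisson trains — plus a Gaussian floor; the amplitude
  distribution is skewed towards negative values like real biological
  noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .probes import Probe
from . import templategen
from .templategen import ForwardModelParams

__all__ = [
    "NoiseSpec",
    "uncorrelated_gaussian",
    "distance_correlated_gaussian",
    "color_noise",
    "far_neurons_noise",
    "generate_noise",
]

NOISE_MODELS = (
    "uncorrelated",
    "distance-correlated",
    "colored-uncorrelated",
    "colored-distance-correlated",
    "far-neurons",
)

#: firing rate (Hz) of the sub-threshold neurons in the far-neurons model
FAR_NEURON_RATE = 5.0


@dataclass
class NoiseSpec:
    """Noise model selection and parameters.

    level : uV, target per-channel standard deviation
    half_distance_lambda : um, spatial decay constant of the covariance
    color_peak / color_q : Hz / quality factor of the coloring resonator
    color_floor : fraction of white noise mixed into colored profiles
    far_n : number of sub-threshold neurons in the far-neurons model
    far_amp_threshold : uV, acceptance ceiling for far-neuron templates
    far_floor_fraction : Gaussian floor sd as a fraction of level
    """

    model: str = "uncorrelated"
    level: float = 10.0
    half_distance_lambda: float = 30.0
    color_peak: float = 300.0
    color_q: float = 1.0
    color_floor: float = 0.3
    far_n: int = 300
    far_amp_threshold: float = 10.0
    far_floor_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.model!r}; choose from {NOISE_MODELS}")
        if self.level < 0:
            raise ValueError("noise level must be non-negative")
        if self.far_n < 1:
            raise ValueError("far_n must be >= 1")
        if self.far_amp_threshold <= 0 or self.half_distance_lambda <= 0:
            raise ValueError("thresholds must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def uncorrelated_gaussian(
    level: float, n_channels: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent Normal(0, level^2) samples, shape (n_channels, n_samples)."""
    if level < 0:
        raise ValueError("level must be non-negative")
    return level * rng.standard_normal((n_channels, n_samples))


def distance_correlated_gaussian(
    level: float,
    positions: np.ndarray,
    lam: float,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean multivariate Gaussian with covariance
    ``level^2 * exp(-d_ij / lam)`` across channels."""
    if level < 0:
        raise ValueError("level must be non-negative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n_channels = positions.shape[0]
    white = rng.standard_normal((n_channels, n_samples))
    if level == 0:
        return np.zeros_like(white)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    cov = level**2 * np.exp(-d / lam)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + 1e-9 * level**2 * np.eye(n_channels)
        chol = np.linalg.cholesky(cov)  # raises if still not PD
    return chol @ white


def color_noise(
    white: np.ndarray,
    fs: float,
    peak: float = 300.0,
    q: float = 1.0,
    floor_fraction: float = 0.3,
    level: float = 10.0,
) -> np.ndarray:
    """Color a (channels x samples) Gaussian array with a second-order
    resonant low-pass IIR (peak frequency ``peak``, quality ``q``), mix in a
    white floor, and rescale channel-wise to sd = ``level``.

    The same filter is applied to every channel, so any inter-channel
    correlation of the input is preserved.
    """
    if peak >= fs / 2:
        raise ValueError("coloring peak frequency must be below Nyquist")
    white = np.atleast_2d(np.asarray(white, dtype=float))
    # RBJ resonant low-pass biquad
    w0 = 2.0 * np.pi * peak / fs
    alpha = np.sin(w0) / (2.0 * q)
    cw = np.cos(w0)
    b = np.array([(1 - cw) / 2.0, 1 - cw, (1 - cw) / 2.0])
    a = np.array([1 + alpha, -2 * cw, 1 - alpha])
    colored = signal.lfilter(b, a, white, axis=-1)

    sd_c = colored.std(axis=-1, keepdims=True)
    sd_w = white.std(axis=-1, keepdims=True)
    sd_c[sd_c == 0] = 1.0
    sd_w[sd_w == 0] = 1.0
    mix = colored / sd_c + floor_fraction * white / sd_w
    sd_m = mix.std(axis=-1, keepdims=True)
    sd_m[sd_m == 0] = 1.0
    return level * mix / sd_m


def far_neurons_noise(
    probe: Probe,
    cell_bank: list,
    spec: NoiseSpec,
    duration: float,
    fs: float,
    rng: np.random.Generator,
    return_templates: bool = False,
):
    """Biological noise from many distant sub-threshold neurons.

    Templates are generated in a far-field placement shell and accepted only
    if their peak amplitude is below ``far_amp_threshold``; each is convolved
    with an independent Poisson train, the contributions are summed, a
    Gaussian floor of sd ``far_floor_fraction * level`` is added, and every
    channel is rescaled to sd = ``level``.
    """
    if spec.model != "far-neurons":
        raise ValueError("spec.model must be 'far-neurons'")
    pos = probe.positions
    pad = 100.0
    bounds = (
        (50.0, 300.0),
        (pos[:, 1].min() - pad, pos[:, 1].max() + pad),
        (pos[:, 2].min() - pad, pos[:, 2].max() + pad),
    )
    params = ForwardModelParams(
        dt=1e3 / fs,
        cut_out=(1.0, 2.0),
        min_amplitude=0.0,
        max_amplitude=spec.far_amp_threshold,
        position_bounds=bounds,
    )
    n_per_model = int(np.ceil(spec.far_n / len(cell_bank)))
    lib = templategen.generate_templates(
        cell_bank, probe, n_per_model, params,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    templates = lib.templates[: spec.far_n]

    n_samples = int(round(duration * fs))
    out = np.zeros((probe.n_channels, n_samples))
    n_pre = int(round(params.cut_out[0] * fs / 1e3))
    for tpl in templates:
        times = _poisson_times(FAR_NEURON_RATE, duration, rng)
        idx = np.round(times * fs).astype(int)
        for i in idx:
            lo = i - n_pre
            hi = lo + tpl.shape[1]
            src_lo, src_hi = max(lo, 0), min(hi, n_samples)
            out[:, src_lo:src_hi] += tpl[:, src_lo - lo : src_hi - lo]

    out += spec.far_floor_fraction * spec.level * rng.standard_normal(out.shape)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    out = spec.level * out / sd
    if return_templates:
        return out, templates
    return out


def _poisson_times(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def generate_noise(
    spec: NoiseSpec,
    probe: Probe,
    duration: float,
    fs: float,
    rng: np.random.Generator,
    cell_bank: list | None = None,
) -> np.ndarray:
    """Dispatch to the requested noise model; returns (channels x samples)."""
    n_samples = int(round(duration * fs))
    n_ch = probe.n_channels
    if spec.model == "uncorrelated":
        return uncorrelated_gaussian(spec.level, n_ch, n_samples, rng)
    if spec.model == "distance-correlated":
        return distance_correlated_gaussian(
            spec.level, probe.positions, spec.half_distance_lambda, n_samples, rng
        )
    if spec.model == "colored-uncorrelated":
        white = rng.standard_normal((n_ch, n_samples))
        return color_noise(white, fs, spec.color_peak, spec.color_q, spec.color_floor, spec.level)
    if spec.model == "colored-distance-correlated":
        base = distance_correlated_gaussian(
            1.0, probe.positions, spec.half_distance_lambda, n_samples, rng
        )
        return color_noise(base, fs, spec.color_peak, spec.color_q, spec.color_floor, spec.level)
    if spec.model == "far-neurons":
        if cell_bank is None:
            cell_bank = templategen.default_cell_bank(seed=int(rng.integers(0, 2**31 - 1)))
        return far_neurons_noise(probe, cell_bank, spec, duration, fs, rng)
    raise ValueError(f"unknown noise model {spec.model!r}")
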