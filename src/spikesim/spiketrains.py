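"""Stochastic spike trains and spatio-temporal synchrony editing.

Spike trains are homogeneous renewal processes (Poisson or gamma) with a
hard refractory period enforced by deletion.  Synchrony between pairs of
spatially overlapping units is controlled through an explicit synchrony
rate: collisions (pairs of spikes from the two units closer than a short
window) can be removed entirely (``sync_rate = 0``) or raised to a target
fraction of the lower-rate unit's spikes by *moving* existing spikes of the
higher-rate unit next to spikes of the other unit — moving, rather than
inserting, keeps per-unit firing rates untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "SynchronyParams",
    "generate_spiketrain",
    "generate_set",
    "find_collisions",
    "apply_synchrony",
]

DEFAULT_RATE_EXC = 5.0  # Hz
DEFAULT_RATE_INH = 15.0  # Hz
DEFAULT_REFRACTORY = 0.002  # s
DEFAULT_GAMMA_SHAPE = 2.0


@dataclass
class SpikeTrainSet:
    """Per-unit sorted spike times (seconds) plus bookkeeping.

    trains : list of strictly increasing 1D float arrays within
        [t_start, t_stop]
    celltypes : one label per unit
    rates : nominal rate (Hz) per unit
    """

    trains: list
    t_start: float
    t_stop: float
    celltypes: list
    rates: list
    seed: int | None = None
    refractory: float = DEFAULT_REFRACTORY

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for t in self.trains:
            if t.size and (np.any(np.diff(t) <= 0) or t[0] < self.t_start or t[-1] > self.t_stop):
                raise ValueError("spike trains must be strictly increasing within [t_start, t_stop]")

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def copy(self) -> "SpikeTrainSet":
        return replace(self, trains=[t.copy() for t in self.trains])


@dataclass
class SynchronyParams:
    """sync_rate: target collision fraction in [0, 1], or None to leave the
    trains untouched; collision_window: full coincidence window in seconds."""

    sync_rate: float | None = None
    collision_window: float = 0.001

    def __post_init__(self) -> None:
        if self.collision_window <= 0:
            raise ValueError("collision window must be positive")
        if self.sync_rate is not None and not (0.0 <= self.sync_rate <= 1.0):
            raise ValueError("sync_rate must be in [0, 1]")


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Delete spikes closer than the refractory period to the last kept one."""
    if times.size == 0 or refractory <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def generate_spiketrain(
    rate: float,
    t_start: float,
    t_stop: float,
    process: str = "gamma",
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    refractory: float = DEFAULT_REFRACTORY,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sorted spike times of a homogeneous renewal process.

    ``process`` is "poisson" (exponential ISIs) or "gamma" (gamma ISIs with
    the given shape, mean 1/rate).  Spikes violating the refractory period
    are deleted.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if t_stop <= t_start:
        raise ValueError("t_stop must exceed t_start")
    if rate == 0:
        return np.empty(0)
    rng = rng or np.random.default_rng()
    duration = t_stop - t_start
    # draw ISIs in batches until the interval is covered
    n_guess = max(16, int(rate * duration * 1.5) + 10)
    times: list[np.ndarray] = []
    t_last = t_start
    while t_last < t_stop:
        if process == "poisson":
            isis = rng.exponential(1.0 / rate, size=n_guess)
        elif process == "gamma":
            isis = rng.gamma(gamma_shape, 1.0 / (rate * gamma_shape), size=n_guess)
        else:
            raise ValueError(f"unknown process {process!r}")
        chunk = t_last + np.cumsum(isis)
        times.append(chunk)
        t_last = chunk[-1]
    all_times = np.concatenate(times)
    all_times = all_times[all_times < t_stop]
    return _enforce_refractory(all_times, refractory)


def generate_set(
    n_exc: int,
    n_inh: int,
    rate_exc: float = DEFAULT_RATE_EXC,
    rate_inh: float = DEFAULT_RATE_INH,
    duration: float = 10.0,
    t_start: float = 0.0,
    process: str = "gamma",
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    refractory: float = DEFAULT_REFRACTORY,
    seed: int = 0,
) -> SpikeTrainSet:
    """Generate ``n_exc`` excitatory + ``n_inh`` inhibitory trains.

    Inhibitory units fire at ``rate_inh`` (default 15 Hz, above the 5 Hz
    excitatory default, matching the faster firing of interneurons).
    """
    if n_exc + n_inh < 1:
        raise ValueError("need at least one unit")
    rng = np.random.default_rng(seed)
    t_stop = t_start + duration
    trains, celltypes, rates = [], [], []
    for _ in range(n_exc):
        trains.append(generate_spiketrain(rate_exc, t_start, t_stop, process, gamma_shape, refractory, rng))
        celltypes.append("excitatory")
        rates.append(rate_exc)
    for _ in range(n_inh):
        trains.append(generate_spiketrain(rate_inh, t_start, t_stop, process, gamma_shape, refractory, rng))
        celltypes.append("inhibitory")
        rates.append(rate_inh)
    return SpikeTrainSet(
        trains=trains, t_start=t_start, t_stop=t_stop,
        celltypes=celltypes, rates=rates, seed=seed, refractory=refractory,
    )


def find_collisions(a: np.ndarray, b: np.ndarray, window: float) -> list[tuple[int, int]]:
    """All index pairs (i, j) with ``|a[i] - b[j]| <= window`` for sorted
    inputs; a spike may participate in several pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pairs: list[tuple[int, int]] = []
    lo = np.searchsorted(b, a - window, side="left")
    hi = np.searchsorted(b, a + window, side="right")
    for i, (l, h) in enumerate(zip(lo, hi)):
        for j in range(l, h):
            pairs.append((i, int(j)))
    return pairs


def _remove_collisions(a: np.ndarray, b: np.ndarray, window: float):
    """Delete the later spike of every colliding pair, to fixpoint."""
    while True:
        pairs = find_collisions(a, b, window)
        if not pairs:
            return a, b
        drop_a, drop_b = set(), set()
        for i, j in pairs:
            if a[i] <= b[j]:
                drop_b.add(j)
            else:
                drop_a.add(i)
        a = np.delete(a, sorted(drop_a))
        b = np.delete(b, sorted(drop_b))


def apply_synchrony(
    spiketrains: SpikeTrainSet,
    overlapping_pairs: list[tuple[int, int]],
    params: SynchronyParams,
    rng: np.random.Generator | None = None,
) -> SpikeTrainSet:
    """Enforce the synchrony rate on every spatially overlapping unit pair.

    * ``sync_rate`` unset: the set is returned unchanged (copy).
    * ``sync_rate == 0``: every spatio-temporal collision is resolved by
      deleting the later spike of the colliding pair, re-scanned to fixpoint.
    * ``sync_rate == s > 0``: non-colliding spikes of the higher-rate unit
      are moved next to randomly chosen spikes of the other unit (within
      half a collision window) until the fraction of the lower-rate unit's
      spikes participating in collisions reaches ``s``; per-unit spike
      counts are preserved and refractoriness respected.
    """
    out = spiketrains.copy()
    s = params.sync_rate
    if s is None:
        return out
    rng = rng or np.random.default_rng()
    w = params.collision_window
    for ui, uj in overlapping_pairs:
        if not (0 <= ui < out.n_units and 0 <= uj < out.n_units) or ui == uj:
            raise ValueError(f"invalid overlapping pair ({ui}, {uj})")
        a, b = out.trains[ui], out.trains[uj]
        if s == 0:
            a, b = _remove_collisions(a, b, w)
            out.trains[ui], out.trains[uj] = a, b
            continue
        # identify lower-rate (anchor) and higher-rate (mover) unit
        low_is_ui = len(a) <= len(b)
        low, high = (a, b) if low_is_ui else (b, a)
        if len(low) == 0:
            continue
        target = int(round(s * len(low)))
        attempts = 0
        max_attempts = 200 * max(target, 1)
        while attempts < max_attempts:
            pairs = find_collisions(low, high, w)
            if len({p[0] for p in pairs}) >= target:
                break
            attempts += 1
            free_low = [i for i in range(len(low)) if i not in {p[0] for p in pairs}]
            free_high = [j for j in range(len(high)) if j not in {p[1] for p in pairs}]
            if not free_low or not free_high:
                break
            anchor = low[rng.choice(free_low)]
            mover = int(rng.choice(free_high))
            new_t = anchor + rng.uniform(-w / 2.0, w / 2.0)
            if not (out.t_start <= new_t <= out.t_stop):
                continue
            cand = np.delete(high, mover)
            pos = np.searchsorted(cand, new_t)
            if pos > 0 and new_t - cand[pos - 1] < out.refractory:
                continue
            if pos < len(cand) and cand[pos] - new_t < out.refractory:
                continue
            high = np.insert(cand, pos, new_t)
        if low_is_ui:
            out.trains[ui], out.trains[uj] = low, high
        else:
            out.trains[ui], out.trains[uj] = high, low
    return out
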