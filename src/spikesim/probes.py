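"""Electrode probe geometries.

A :class:`Probe` is a named set of recording sites with 3D positions in
micrometers.  The convention used throughout the package is that axis 0 is
the distance from the probe plane (the probe itself sits at axis-0 = 0) and
axes 1 and 2 span the electrode plane, with axis 2 the "vertical" direction
along the probe shank.

Built-in geometries cover the common device classes used in extracellular
electrophysiology: a tetrode, a 32-site polytrode, a dense 128-site silicon
probe and a square high-density MEA.  Custom probes are loaded from a small
YAML dialect with explicit per-electrode positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.distance import cdist

__all__ = [
    "Probe",
    "ProbeFileError",
    "list_available_probes",
    "build_probe",
    "load_probe_file",
    "write_probe_file",
    "pairwise_distances",
]


class ProbeFileError(ValueError):
    """Raised when a probe definition file violates the probe contract."""


@dataclass(frozen=True)
class Probe:
    """A named electrode geometry.

    Parameters
    ----------
    name:
        Identifier of the probe.
    positions:
        ``(n_channels, 3)`` array of electrode positions in micrometers.
    plane_axes:
        Pair of axis indices spanning the electrode plane.
    description:
        Free-text description.
    """

    name: str
    positions: np.ndarray
    plane_axes: tuple[int, int] = (1, 2)
    description: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n_channels, 3) array")
        if pos.shape[0] < 1:
            raise ValueError("a probe needs at least one electrode")
        # duplicate electrode positions make the geometry degenerate
        if pos.shape[0] > 1:
            d = cdist(pos, pos)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 0.0:
                raise ValueError("duplicate electrode positions in probe %r" % self.name)
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "positions": self.positions.tolist(),
            "description": self.description,
        }


# ---------------------------------------------------------------------------
# Built-in registry
# ---------------------------------------------------------------------------

def _tetrode() -> np.ndarray:
    # four sites at the corners of a 25 um square
    h = 25.0 / 2.0
    yz = [(-h, -h), (-h, h), (h, -h), (h, h)]
    return np.array([[0.0, y, z] for y, z in yz])


def _neuronexus_32() -> np.ndarray:
    # 32 sites in 3 staggered columns (10 / 12 / 10), 25 um vertical pitch
    pitch = 25.0
    cols = {-18.0: 10, 0.0: 12, 18.0: 10}
    rows = []
    for y, n in cols.items():
        # middle column is offset half a pitch downwards relative to outer ones
        z0 = -(n - 1) / 2.0 * pitch
        for i in range(n):
            rows.append([0.0, y, z0 + i * pitch])
    return np.array(rows)


def _neuropixels_128() -> np.ndarray:
    # 4-column checkerboard, 128 sites, 25 um pitch: 64 rows of 2 sites,
    # alternating between columns {0, 2} and {1, 3}
    pitch = 25.0
    rows = []
    for r in range(64):
        z = r * pitch
        ys = (0.0, 2 * pitch) if r % 2 == 0 else (pitch, 3 * pitch)
        for y in ys:
            rows.append([0.0, y - 1.5 * pitch, z])
    pos = np.array(rows)
    pos[:, 2] -= pos[:, 2].mean()
    return pos


def _sqmea_10_15() -> np.ndarray:
    # square 10x10 MEA, 15 um inter-electrode distance
    pitch = 15.0
    grid = (np.arange(10) - 4.5) * pitch
    rows = [[0.0, y, z] for y in grid for z in grid]
    return np.array(rows)


_BUILTIN = {
    "tetrode": (_tetrode, "4-site tetrode, 25 um square"),
    "Neuronexus-32": (_neuronexus_32, "32-site polytrode, 3 staggered columns, 25 um pitch"),
    "Neuropixels-128": (_neuropixels_128, "128-site dense probe, 4-column checkerboard, 25 um pitch"),
    "SqMEA-10-15": (_sqmea_10_15, "square 10x10 MEA, 15 um pitch"),
}


def list_available_probes() -> list[str]:
    """Return the sorted list of built-in probe identifiers."""
    return sorted(_BUILTIN)


def build_probe(name: str) -> Probe:
    """Construct a built-in probe by name.

    Raises
    ------
    KeyError
        If ``name`` is not a known probe identifier.
    """
    try:
        builder, desc = _BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown probe {name!r}; available: {', '.join(list_available_probes())}"
        ) from None
    return Probe(name=name, positions=builder(), description=desc)


# ---------------------------------------------------------------------------
# Probe files
# ---------------------------------------------------------------------------

def load_probe_file(path) -> Probe:
    """Load a probe from a YAML file with keys ``name``, ``positions``
    (list of ``[x, y, z]`` in micrometers) and optional ``description``."""
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise ProbeFileError(f"probe file {path} does not contain a mapping")
    for key in ("name", "positions"):
        if key not in data:
            raise ProbeFileError(f"probe file {path} is missing required key {key!r}")
    pos = data["positions"]
    try:
        arr = np.asarray(pos, dtype=float)
    except (TypeError, ValueError):
        raise ProbeFileError(f"probe file {path}: positions must be numeric") from None
    if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
        raise ProbeFileError(
            f"probe file {path}: positions must be a finite (n, 3) list of [x, y, z]"
        )
    try:
        return Probe(
            name=str(data["name"]),
            positions=arr,
            description=str(data.get("description", "")),
        )
    except ValueError as exc:
        raise ProbeFileError(f"probe file {path}: {exc}") from None


def write_probe_file(probe: Probe, path) -> None:
    """Write a probe to the YAML probe-file dialect (lossless roundtrip)."""
    with open(path, "w") as f:
        yaml.safe_dump(probe.to_dict(), f, sort_keys=False)


def pairwise_distances(probe: Probe) -> np.ndarray:
    """Symmetric matrix of Euclidean inter-electrode distances in micrometers."""
    return cdist(probe.positions, probe.positions)
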