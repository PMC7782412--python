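"""Self-describing HDF5 persistence for template libraries and recordings.

Both containers embed every generation parameter and seed as a YAML string
in an ``info`` dataset, so a saved file is sufficient to regenerate its own
content.  Dataset creation disables HDF5 time tracking, which makes files
written with identical content byte-identical — a requirement for seeded
end-to-end reproducibility checks.
"""

from __future__ import annotations

import numpy as np
import h5py
import yaml

from .templategen import TemplateLibrary
from .spiketrains import SpikeTrainSet
from .recgen import RecordingBundle

__all__ = [
    "FormatError",
    "save_template_library",
    "load_template_library",
    "save_recording",
    "load_recording",
]

SCHEMA_VERSION = 1

_TEMPLATE_DATASETS = ("templates", "locations", "rotations", "celltypes", "info")
_RECORDING_DATASETS = (
    "recordings",
    "templates",
    "templates_celltypes",
    "templates_locations",
    "templates_rotations",
    "channel_positions",
    "timestamps",
    "voltage_peaks",
    "spike_traces",
    "info",
)


class FormatError(ValueError):
    """Raised when a file does not conform to the container layout."""


def _str_dtype():
    return h5py.string_dtype(encoding="utf-8")


def _write_info(f: h5py.File, info: dict) -> None:
    f.create_dataset(
        "info", data=yaml.safe_dump(_sanitize(info), sort_keys=True), dtype=_str_dtype(),
        track_times=False,
    )
    f.attrs["schema_version"] = SCHEMA_VERSION


def _sanitize(obj):
    """Make a parameter record YAML-serializable."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isinf(obj):
        return None
    return obj


def _open_checked(path, expected: tuple[str, ...]) -> h5py.File:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path} is not a readable HDF5 file: {exc}") from None
    version = f.attrs.get("schema_version")
    if version != SCHEMA_VERSION:
        f.close()
        raise FormatError(
            f"{path}: schema version mismatch (found {version!r}, expected {SCHEMA_VERSION})"
        )
    for name in expected:
        if name not in f:
            f.close()
            raise FormatError(f"{path}: missing dataset {name!r}")
    return f


def _load_info(f: h5py.File) -> dict:
    return yaml.safe_load(f["info"][()].decode("utf-8"))


def _dset(f, name, data):
    f.create_dataset(name, data=data, track_times=False)


# ---------------------------------------------------------------------------
# Template libraries
# ---------------------------------------------------------------------------

def save_template_library(lib: TemplateLibrary, path) -> None:
    """Write a template library to ``path`` (HDF5)."""
    with h5py.File(path, "w") as f:
        _dset(f, "templates", lib.templates)
        _dset(f, "locations", np.asarray(lib.locations, dtype=float))
        _dset(f, "rotations", np.asarray(lib.rotations, dtype=float))
        f.create_dataset(
            "celltypes",
            data=[str(c) for c in lib.celltypes],
            dtype=_str_dtype(),
            track_times=False,
        )
        _write_info(f, lib.info)


def load_template_library(path) -> TemplateLibrary:
    """Read a template library saved by :func:`save_template_library`."""
    with _open_checked(path, _TEMPLATE_DATASETS) as f:
        return TemplateLibrary(
            templates=f["templates"][()],
            locations=f["locations"][()],
            rotations=f["rotations"][()],
            celltypes=np.asarray([c.decode("utf-8") for c in f["celltypes"][()]]),
            info=_load_info(f),
        )


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def save_recording(bundle: RecordingBundle, path) -> None:
    """Write a recording bundle (with full ground truth) to ``path``."""
    with h5py.File(path, "w") as f:
        _dset(f, "recordings", bundle.recordings.astype(np.float32))
        _dset(f, "templates", bundle.templates)
        f.create_dataset(
            "templates_celltypes",
            data=[str(c) for c in bundle.templates_celltypes],
            dtype=_str_dtype(),
            track_times=False,
        )
        _dset(f, "templates_locations", np.asarray(bundle.templates_locations, dtype=float))
        _dset(f, "templates_rotations", np.asarray(bundle.templates_rotations, dtype=float))
        _dset(f, "channel_positions", np.asarray(bundle.channel_positions, dtype=float))
        _dset(f, "timestamps", np.asarray(bundle.timestamps, dtype=float))
        _dset(f, "voltage_peaks", np.asarray(bundle.voltage_peaks, dtype=float))
        _dset(f, "spike_traces", bundle.spike_traces.astype(np.float32))
        grp = f.create_group("spiketrains")
        sts = bundle.spiketrains
        for u, times in enumerate(sts.trains):
            sub = grp.create_group(f"unit_{u:04d}")
            sub.create_dataset("times", data=np.asarray(times, dtype=float), track_times=False)
            sub.attrs["t_start"] = float(sts.t_start)
            sub.attrs["t_stop"] = float(sts.t_stop)
            sub.attrs["celltype"] = str(sts.celltypes[u])
            sub.attrs["rate"] = float(sts.rates[u])
        grp.attrs["refractory"] = float(sts.refractory)
        if sts.seed is not None:
            grp.attrs["seed"] = int(sts.seed)
        _write_info(f, bundle.info)


def load_recording(path) -> RecordingBundle:
    """Read a recording bundle saved by :func:`save_recording`."""
    with _open_checked(path, _RECORDING_DATASETS + ("spiketrains",)) as f:
        grp = f["spiketrains"]
        keys = sorted(grp.keys())
        trains = [grp[k]["times"][()] for k in keys]
        celltypes = [grp[k].attrs["celltype"] for k in keys]
        rates = [float(grp[k].attrs["rate"]) for k in keys]
        t_start = float(grp[keys[0]].attrs["t_start"]) if keys else 0.0
        t_stop = float(grp[keys[0]].attrs["t_stop"]) if keys else 0.0
        sts = SpikeTrainSet(
            trains=trains,
            t_start=t_start,
            t_stop=t_stop,
            celltypes=celltypes,
            rates=rates,
            seed=int(grp.attrs["seed"]) if "seed" in grp.attrs else None,
            refractory=float(grp.attrs.get("refractory", 0.002)),
        )
        return RecordingBundle(
            recordings=f["recordings"][()],
            spiketrains=sts,
            templates=f["templates"][()],
            templates_celltypes=np.asarray(
                [c.decode("utf-8") for c in f["templates_celltypes"][()]]
            ),
            templates_locations=f["templates_locations"][()],
            templates_rotations=f["templates_rotations"][()],
            channel_positions=f["channel_positions"][()],
            timestamps=f["timestamps"][()],
            voltage_peaks=f["voltage_peaks"][()],
            spike_traces=f["spike_traces"][()],
            info=_load_info(f),
        )
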