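"""Event sources: file-list splitting, CXI / generic HDF5 readers, extraction.

An *event* is one collection of time-related readouts — one detector frame
plus its beam metadata.  Sources present events to the engine as per-worker
iterators; the file-list backend splits a user-supplied list of files evenly
(round-robin in listed order) among workers, each worker then streaming the
events stored in its files.

Corrupted events (unreadable or non-finite frame payloads) are flagged, not
fatal: the extraction step raises :class:`SkipEvent` and the engine moves on
to the next event.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "Event",
    "ExtractedData",
    "SkipEvent",
    "ConfigurationError",
    "split_file_list",
    "read_cxi_events",
    "read_cbf_events",
    "extract_data",
    "validate_extraction_spec",
    "file_list_source",
    "list_source",
    "DEFAULT_DATA_PATH",
    "TIMESTAMP_PATH",
    "PHOTON_ENERGY_PATH",
    "DETECTOR_DISTANCE_PATH",
    "KNOWN_PROPERTIES",
]

DEFAULT_DATA_PATH = "/entry_1/data_1/data"
TIMESTAMP_PATH = "/LCLS/timestamp"
PHOTON_ENERGY_PATH = "/LCLS/photon_energy_eV"
DETECTOR_DISTANCE_PATH = "/LCLS/detector_distance_mm"

#: Properties an extraction spec may request from the file backends.
KNOWN_PROPERTIES = frozenset(
    {"raw_data", "event_timestamp", "photon_energy", "detector_distance"}
)


class SkipEvent(Exception):
    """Signal that an event is unusable and must be skipped, never aborted on."""


class ConfigurationError(ValueError):
    """Raised at startup for invalid monitor/source configuration."""


@dataclass
class Event:
    """One per-source record, with its arrival ordinal."""

    payload: dict
    source_id: str
    arrival_index: int


@dataclass
class ExtractedData:
    """Named properties pulled out of an event for the processing layer."""

    raw_data: np.ndarray | None = None
    event_timestamp: float | None = None
    photon_energy: float | None = None
    detector_distance: float | None = None
    event_id: str = ""


def split_file_list(files: Sequence, n_workers: int) -> list[list]:
    """Split a file list evenly among workers, round-robin in listed order.

    Every file is assigned exactly once; assignment sizes differ by at most
    one, with earlier workers receiving the extra file on uneven splits.
    An empty list yields empty assignments for every worker.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    files = list(files)
    return [files[i::n_workers] for i in range(n_workers)]


def _slice_payload(stack: h5py.Dataset, i: int) -> dict:
    payload: dict = {}
    try:
        frame = np.asarray(stack[i])
    except Exception:
        payload["raw_data"] = None
        payload["corrupt"] = True
        return payload
    payload["raw_data"] = frame
    payload["corrupt"] = not np.isfinite(frame).all()
    return payload


def read_cxi_events(
    path: str | os.PathLike,
    dataset_path: str = DEFAULT_DATA_PATH,
    nominal_rate_hz: float = 120.0,
) -> Iterator[Event]:
    """Yield one :class:`Event` per slice of the frame stack in a CXI/HDF5 file.

    The file must contain a 3-D (event, slow, fast) stack at ``dataset_path``.
    Per-event metadata (timestamps, photon energies, detector distance) are
    read when present.  Files without per-event timestamps fall back to file
    mtime plus the event index at ``nominal_rate_hz``, so downstream delay
    estimation always has something to work with.  Unreadable or non-finite
    slices are yielded with a ``corrupt`` flag; iteration continues.
    """
    path = os.fspath(path)
    with h5py.File(path, "r") as fh:
        if dataset_path not in fh:
            raise KeyError(
                f"dataset {dataset_path!r} not found in {path!r}"
            )
        stack = fh[dataset_path]
        if stack.ndim != 3:
            raise ValueError(
                f"dataset {dataset_path!r} in {path!r} must be a 3-D "
                f"(event, slow, fast) stack, got shape {stack.shape}"
            )
        n = stack.shape[0]
        timestamps = fh[TIMESTAMP_PATH][...] if TIMESTAMP_PATH in fh else None
        energies = (fh[PHOTON_ENERGY_PATH][...]
                    if PHOTON_ENERGY_PATH in fh else None)
        distances = (fh[DETECTOR_DISTANCE_PATH][...]
                     if DETECTOR_DISTANCE_PATH in fh else None)
        mtime = os.path.getmtime(path)
        for i in range(n):
            payload = _slice_payload(stack, i)
            if timestamps is not None and i < len(timestamps):
                payload["event_timestamp"] = float(timestamps[i])
            else:
                payload["event_timestamp"] = mtime + i / nominal_rate_hz
            if energies is not None and i < len(energies):
                payload["photon_energy"] = float(energies[i])
            if distances is not None and i < len(distances):
                payload["detector_distance"] = float(distances[i])
            payload["event_id"] = f"{os.path.basename(path)}//{i}"
            yield Event(payload=payload, source_id=path, arrival_index=i)


def read_cbf_events(path, *_args, **_kwargs):
    """CBF single-frame files: recognised by the reader interface, unimplemented."""
    raise NotImplementedError(
        "CBF reading is not implemented; convert frames to CXI/HDF5 stacks"
    )


def validate_extraction_spec(extraction_spec: Sequence[str]) -> tuple[str, ...]:
    """Fail fast (before streaming) on a spec naming unknown properties."""
    spec = tuple(extraction_spec)
    unknown = [p for p in spec if p not in KNOWN_PROPERTIES]
    if unknown:
        raise ConfigurationError(
            f"extraction spec requests unknown properties {unknown}; "
            f"known: {sorted(KNOWN_PROPERTIES)}"
        )
    return spec


def extract_data(
    event: Event,
    extraction_spec: Sequence[str] = ("raw_data", "event_timestamp"),
) -> ExtractedData:
    """Populate the named properties from an event, or raise :class:`SkipEvent`.

    A corrupted payload, or a missing/None required property, produces a
    skip signal — never an abort.
    """
    payload = event.payload
    if payload.get("corrupt"):
        raise SkipEvent(f"event {event.arrival_index} of {event.source_id}: "
                        "corrupted payload")
    out = ExtractedData(event_id=payload.get("event_id", ""))
    for prop in extraction_spec:
        value = payload.get(prop)
        if value is None:
            raise SkipEvent(
                f"event {event.arrival_index} of {event.source_id}: "
                f"missing required property {prop!r}"
            )
        setattr(out, prop, value)
    return out


# --- source factories (worker_id, n_workers) -> iterator[Event] ----------

SourceFactory = Callable[[int, int], Iterator[Event]]


def file_list_source(
    paths: Sequence[str | os.PathLike],
    dataset_path: str = DEFAULT_DATA_PATH,
    nominal_rate_hz: float = 120.0,
) -> SourceFactory:
    """The file-list backend: each worker streams its round-robin file share."""
    paths = [os.fspath(p) for p in paths]

    def factory(worker_id: int, n_workers: int) -> Iterator[Event]:
        for p in split_file_list(paths, n_workers)[worker_id]:
            yield from read_cxi_events(p, dataset_path, nominal_rate_hz)

    return factory


def list_source(events: Sequence[Event]) -> SourceFactory:
    """An in-memory source; events are dealt round-robin to workers."""
    events = list(events)

    def factory(worker_id: int, n_workers: int) -> Iterator[Event]:
        yield from events[worker_id::n_workers]

    return factory
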