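"""Recording containers, event tables and per-event segment extraction.

Two on-disk forms are supported:

* EDF+ files with an annotation channel (the format of the public
  motor/imagery database), read through :mod:`mne` when it is installed;
* a neutral text container — a tab-delimited signal matrix (rows =
  channels), a ``code latency duration`` event TSV and a YAML sidecar with
  the sampling rate — so synthetic cohorts need no binary writer.

All public latencies are 1-based inclusive sample indices: latency 1 is the
first sample, and an event of duration ``d`` starting at ``s`` occupies
samples ``s .. s + d - 1``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .channels import ChannelMap, RelaxedChannelMap

#: Default mapping from EDF+ annotation labels to the three event codes:
#: rest, left/both-fists onset, right/both-feet onset.
DEFAULT_CODE_MAP: dict[str, int] = {"T0": 1, "T1": 2, "T2": 3}

EVENT_CODES = (1, 2, 3)


class AnnotationError(ValueError):
    """An annotation label has no entry in the code map."""


@dataclass(frozen=True, order=True)
class EventRecord:
    """One annotated event: ``code`` in {1, 2, 3}, 1-based ``latency``, ``duration`` in samples."""

    latency: int
    code: int
    duration: int

    def __post_init__(self) -> None:
        if self.code not in EVENT_CODES:
            raise ValueError(f"event code must be 1, 2 or 3, got {self.code}")
        if self.latency < 1:
            raise ValueError(f"latency must be >= 1 (1-based), got {self.latency}")
        if self.duration < 1:
            raise ValueError(f"duration must be positive, got {self.duration}")


def event_end(record: EventRecord) -> int:
    """Last sample (1-based, inclusive) covered by ``record``.

    An event starting at latency 1 with duration 672 lasts until sample 672.
    """
    return record.latency + record.duration - 1


def intermission(previous: EventRecord, nxt: EventRecord) -> int:
    """Gap between two consecutive events, as ``next start − previous end``.

    Under this convention the reference event table's rest-to-task gaps come
    out as 641 samples (e.g. 1313 − 672).  Back-to-back events give 1; an
    overlap raises.
    """
    gap = nxt.latency - event_end(previous)
    if gap < 1:
        raise ValueError(
            f"events overlap: previous ends at {event_end(previous)}, "
            f"next starts at {nxt.latency}"
        )
    return gap


class EventTable:
    """Ordered sequence of :class:`EventRecord` with strictly increasing latencies."""

    def __init__(self, records: Iterable[EventRecord] = ()):
        self.records: tuple[EventRecord, ...] = tuple(records)
        lats = [r.latency for r in self.records]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("event latencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EventRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EventTable) and self.records == other.records

    def codes(self) -> set[int]:
        return {r.code for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [r.code for r in self.records],
                "latency": [r.latency for r in self.records],
                "duration": [r.duration for r in self.records],
            }
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        missing = {"code", "latency", "duration"}.difference(df.columns)
        if missing:
            raise ValueError(f"event TSV missing columns: {sorted(missing)}")
        return cls(
            EventRecord(code=int(c), latency=int(l), duration=int(d))
            for c, l, d in zip(df["code"], df["latency"], df["duration"])
        )


@dataclass
class Recording:
    """A single run: ``signal`` is channels × time in µV, plus its event table."""

    participant_id: int
    run_id: int
    sampling_rate: float
    signal: np.ndarray
    events: EventTable
    channel_map: ChannelMap = field(default_factory=ChannelMap)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels × time array")
        if self.signal.shape[0] != len(self.channel_map):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but the channel map "
                f"defines {len(self.channel_map)} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.signal.shape[1]
        for rec in self.events:
            if event_end(rec) > n:
                raise ValueError(
                    f"event {rec} extends to sample {event_end(rec)} beyond "
                    f"signal length {n}"
                )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class Segment:
    """Per-event slice of a run: ``data`` is channels × time.

    ``task`` runs 1..15 — the 14 experimental runs plus the pooled rest
    signal as task 15 — and ``event`` is the 1..3 code.
    """

    participant_id: int
    task: int
    event: int
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("segment data must be a non-empty 2-D array")
        if not 1 <= self.task <= 15:
            raise ValueError(f"task must lie in 1..15, got {self.task}")
        if self.event not in EVENT_CODES:
            raise ValueError(f"event must be 1, 2 or 3, got {self.event}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def extract_segments(
    recording: Recording, concatenate_same_event: bool = False
) -> list[Segment]:
    """Cut the recording into per-event segments.

    With ``concatenate_same_event`` set, all occurrences of the same code in
    the run are concatenated in time order, yielding one segment per
    (task, event); otherwise one segment per event occurrence.
    """
    by_code: dict[int, list[np.ndarray]] = {}
    out: list[Segment] = []
    for rec in recording.events:
        lo, hi = rec.latency - 1, event_end(rec)  # half-open 0-based slice
        if hi > recording.n_samples:
            raise ValueError(f"event {rec} exceeds signal length {recording.n_samples}")
        chunk = recording.signal[:, lo:hi]
        if concatenate_same_event:
            by_code.setdefault(rec.code, []).append(chunk)
        else:
            out.append(
                Segment(
                    participant_id=recording.participant_id,
                    task=recording.run_id,
                    event=rec.code,
                    data=chunk,
                )
            )
    if concatenate_same_event:
        for code in sorted(by_code):
            out.append(
                Segment(
                    participant_id=recording.participant_id,
                    task=recording.run_id,
                    event=code,
                    data=np.concatenate(by_code[code], axis=1),
                )
            )
    return out


def pooled_rest_segment(recordings: Sequence[Recording]) -> Segment:
    """Concatenate every rest (code-1) span of the given runs into task 15."""
    chunks = []
    pid = recordings[0].participant_id
    for rec in recordings:
        for ev in rec.events:
            if ev.code == 1:
                chunks.append(rec.signal[:, ev.latency - 1 : event_end(ev)])
    if not chunks:
        raise ValueError("no rest (code 1) events found in the given runs")
    return Segment(participant_id=pid, task=15, event=1, data=np.concatenate(chunks, axis=1))


# ---------------------------------------------------------------------------
# Neutral text container
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, directory: str | os.PathLike, stem: str) -> Path:
    """Write the neutral container: ``<stem>.signal.tsv``, ``<stem>.events.tsv``
    and ``<stem>.meta.yaml``.  Returns the sidecar path (the read entry point)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / f"{stem}.signal.tsv", recording.signal, delimiter="\t", fmt="%.10g")
    recording.events.to_tsv(directory / f"{stem}.events.tsv")
    meta = {
        "participant_id": int(recording.participant_id),
        "run_id": int(recording.run_id),
        "sampling_rate": float(recording.sampling_rate),
        "channels": list(recording.channel_map.names),
        "signal_file": f"{stem}.signal.tsv",
        "events_file": f"{stem}.events.tsv",
    }
    sidecar = directory / f"{stem}.meta.yaml"
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    return sidecar


def _read_neutral(sidecar: Path, relaxed: bool) -> Recording:
    meta = yaml.safe_load(sidecar.read_text())
    directory = sidecar.parent
    signal = np.loadtxt(directory / meta["signal_file"], delimiter="\t", ndmin=2)
    events = EventTable.from_tsv(directory / meta["events_file"])
    names = tuple(meta.get("channels", ()))
    if len(names) == 64:
        cmap = ChannelMap(names)
    elif relaxed:
        cmap = RelaxedChannelMap(names)  # type: ignore[assignment]
    else:
        raise ValueError(
            f"expected 64 channels, sidecar lists {len(names)} (pass relaxed=True to accept)"
        )
    return Recording(
        participant_id=int(meta["participant_id"]),
        run_id=int(meta["run_id"]),
        sampling_rate=float(meta["sampling_rate"]),
        signal=signal,
        events=events,
        channel_map=cmap,
    )


def read_recording(
    path: str | os.PathLike,
    code_map: Mapping[str, int] | None = None,
    participant_id: int | None = None,
    run_id: int | None = None,
    relaxed: bool = False,
) -> Recording:
    """Read a run from EDF+ or from the neutral text container.

    ``code_map`` translates annotation labels to event codes 1..3 (default
    T0→1, T1→2, T2→3).  A label absent from the map raises
    :class:`AnnotationError`; a channel count other than 64 raises unless
    ``relaxed`` is set.  For EDF+ input, ``participant_id`` and ``run_id``
    default to values parsed from names of the form ``S001R03.edf``.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, code_map or DEFAULT_CODE_MAP, participant_id, run_id, relaxed)
    if path.name.endswith(".meta.yaml"):
        return _read_neutral(path, relaxed)
    # allow passing the bare stem of a neutral container
    sidecar = path.with_name(path.name + ".meta.yaml")
    if sidecar.exists():
        return _read_neutral(sidecar, relaxed)
    raise ValueError(f"unrecognized recording path: {path}")


def _parse_edf_ids(name: str) -> tuple[int | None, int | None]:
    import re

    m = re.match(r"S(\d+)R(\d+)", name)
    if m:
        return int(m.group(1)), int(m.group(2))
    return None, None


def _read_edf(
    path: Path,
    code_map: Mapping[str, int],
    participant_id: int | None,
    run_id: int | None,
    relaxed: bool,
) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF+ requires the optional dependency mne "
            "(pip install brainfingerprint[edf])"
        ) from exc

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # volts → µV
    names = tuple(ch.rstrip(".") for ch in raw.ch_names)
    records = []
    for ann in raw.annotations:
        label = ann["description"]
        if label not in code_map:
            raise AnnotationError(f"annotation label {label!r} not in code map")
        latency = int(round(ann["onset"] * sfreq)) + 1
        duration = max(1, int(round(ann["duration"] * sfreq)))
        records.append(EventRecord(code=int(code_map[label]), latency=latency, duration=duration))
    pid, rid = _parse_edf_ids(path.stem)
    pid = participant_id if participant_id is not None else (pid or 0)
    rid = run_id if run_id is not None else (rid or 0)
    if len(names) == 64:
        try:
            cmap = ChannelMap(names)
        except ValueError:
            # vendor-specific casing ("Fc5" vs "FC5"); keep labels as recorded
            cmap = RelaxedChannelMap(names)  # type: ignore[assignment]
    elif relaxed:
        cmap = RelaxedChannelMap(names)  # type: ignore[assignment]
    else:
        raise ValueError(f"expected 64 channels, EDF has {len(names)}")
    return Recording(
        participant_id=pid,
        run_id=rid,
        sampling_rate=sfreq,
        signal=data_uv,
        events=EventTable(sorted(records)),
        channel_map=cmap,
    )
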