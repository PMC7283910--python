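"""Band-pass / notch filtering, artifact-removal hook, first differencing.

The preprocessing chain is fixed: zero-phase FIR filtering of the whole run,
an (optional) artifact-removal hook, then segment extraction and first-order
differencing.  Differencing whitens the slow EEG trends so the subsequent
amplitude-tercile symbolization reflects sample-to-sample dynamics rather
than drifts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import signal as sps

from .io import Recording, Segment


class StageError(RuntimeError):
    """A preprocessing stage failed or violated its contract."""


@dataclass(frozen=True)
class FilterSpec:
    """FIR band-pass + notch specification.

    ``fir_order="auto"`` follows the common EEG heuristic — 3.3 divided by
    the normalized transition width, with the transition width taken as
    ``min(max(0.25·band_low, 2), band_low)`` Hz — which yields order 528 for
    a 1 Hz low edge at 160 samples/s.
    """

    band_low: float = 1.0
    band_high: float = 70.0
    notch: float | None = 60.0
    notch_width: float = 2.0
    fir_order: int | str = "auto"

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not 0 < self.band_low < self.band_high < nyq:
            raise ValueError(
                f"band ({self.band_low}, {self.band_high}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyq} Hz)"
            )
        if self.notch is not None and not self.band_low < self.notch < self.band_high:
            raise ValueError(f"notch {self.notch} Hz must lie inside the pass band")

    def order(self, sampling_rate: float) -> int:
        if self.fir_order != "auto":
            return int(self.fir_order)
        transition = min(max(0.25 * self.band_low, 2.0), self.band_low)
        order = int(np.ceil(3.3 * sampling_rate / transition))
        return order + order % 2  # even order -> odd tap count (type-I FIR)


def design_bandpass(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Hamming windowed-sinc band-pass taps for ``spec``."""
    spec.validate(sampling_rate)
    numtaps = spec.order(sampling_rate) + 1
    return sps.firwin(
        numtaps,
        [spec.band_low, spec.band_high],
        pass_zero=False,
        window="hamming",
        fs=sampling_rate,
    )


def design_notch(spec: FilterSpec, sampling_rate: float) -> np.ndarray | None:
    """Narrow FIR band-stop taps around ``spec.notch`` (None if no notch)."""
    if spec.notch is None:
        return None
    numtaps = spec.order(sampling_rate) + 1
    half = spec.notch_width / 2.0
    return sps.firwin(
        numtaps,
        [spec.notch - half, spec.notch + half],
        pass_zero="bandstop",
        window="hamming",
        fs=sampling_rate,
    )


def _zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # forward-backward application with reflect padding of one filter length
    padlen = min(len(taps), data.shape[-1] - 1)
    return sps.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


def bandpass(segment: Segment, spec: FilterSpec, sampling_rate: float) -> Segment:
    """Zero-phase FIR band-pass (and notch) a segment; shape is preserved."""
    filtered = filter_array(segment.data, spec, sampling_rate)
    return replace(segment, data=filtered)


def filter_recording(recording: Recording, spec: FilterSpec) -> Recording:
    """Filter every channel of a whole run (the default pipeline granularity)."""
    filtered = filter_array(recording.signal, spec, recording.sampling_rate)
    return replace(recording, signal=filtered)


def filter_array(data: np.ndarray, spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    order = spec.order(sampling_rate)
    if data.shape[-1] <= 3 * order:
        raise StageError(
            f"segment of {data.shape[-1]} samples too short for filter order "
            f"{order} (needs > {3 * order})"
        )
    out = _zero_phase(data, design_bandpass(spec, sampling_rate))
    notch = design_notch(spec, sampling_rate)
    if notch is not None:
        out = _zero_phase(out, notch)
    return out


Hook = Callable[[np.ndarray], np.ndarray]


def artifact_removal(recording: Recording, hook: Hook | None = None) -> Recording:
    """Delegate artifact cleaning to ``hook`` (channels × time → same shape).

    The default is the identity: automatic ICA-based artifact classification
    is deliberately out of scope and users plug in an established cleaner.
    A hook that raises, or that changes the signal shape, aborts with a
    stage-labelled :class:`StageError`.
    """
    if hook is None:
        return recording
    try:
        cleaned = np.asarray(hook(recording.signal), dtype=float)
    except Exception as exc:
        raise StageError(f"artifact-removal hook failed: {exc}") from exc
    if cleaned.shape != recording.signal.shape:
        raise StageError(
            f"artifact-removal hook changed shape {recording.signal.shape} "
            f"-> {cleaned.shape}"
        )
    return replace(recording, signal=cleaned)


class DifferencedSegment(Segment):
    """Segment after first-order differencing; units µV per sample step."""


def first_difference(segment: Segment) -> DifferencedSegment:
    """Per-channel first difference: ``out[n] = in[n+1] − in[n]``."""
    if segment.data.shape[1] < 2:
        raise ValueError("first difference needs at least 2 samples")
    return DifferencedSegment(
        participant_id=segment.participant_id,
        task=segment.task,
        event=segment.event,
        data=np.diff(segment.data, axis=1),
    )
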