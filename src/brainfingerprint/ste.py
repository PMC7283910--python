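"""Symbolic transfer entropy between EEG channels.

The differenced signal of every channel is symbolized against the pooled
amplitude terciles of all 64 channels of the same (participant, task, event)
segment.  Directed coupling from channel *i* to channel *j* is the plug-in
transfer entropy, in bits,

    TE(y→x) = Σ P(x⁺, x, y) · log2 [ P(x⁺ | x, y) / P(x⁺ | x) ]

estimated with Markov orders k = l = 1 from empirical joint frequencies.
Terms with zero joint probability contribute zero.

By default the estimate is taken directly on the 3-symbol tercile sequence
(27-cell joint histogram).  Phase-space word embedding (``m`` symbols,
delay τ) is available and turns each channel into a ``3^m``-state process,
but at the event-segment lengths of the reference protocol (roughly
2,000–5,400 differenced samples) an ``m = 3`` word process has a 19,683-cell
joint histogram whose plug-in estimate is dominated by a segment-length-
dependent small-sample bias common to all channels; that floor drowns the
participant-specific coupling structure, so word-level estimation is opt-in
rather than the default.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .channels import CHANNELS_64
from .preprocess import DifferencedSegment

N_SYMBOLS = 3
DEFAULT_EMBED_DIM = 3      # phase-space word length when embedding is requested
DEFAULT_EMBED_DELAY = 1
DEFAULT_TE_WORD_DIM = 1    # TE is estimated on the raw tercile symbols


@dataclass(frozen=True)
class TercileThresholds:
    """Lower/upper tercile cut points of a pooled, ascending-sorted sequence.

    ``t_low`` is the value at rank ``⌊L/3⌋`` and ``t_high`` the value at rank
    ``⌊2L/3⌋`` (1-based) of the pooled sequence of length ``L``.
    """

    t_low: float
    t_high: float
    pooled_length: int

    def __post_init__(self) -> None:
        if self.t_low > self.t_high:
            raise ValueError("t_low must not exceed t_high")


def pooled_thresholds(segment: DifferencedSegment | np.ndarray) -> TercileThresholds:
    """Tercile thresholds of all channels of one segment pooled together."""
    data = segment.data if hasattr(segment, "data") else np.asarray(segment, dtype=float)
    pooled = np.sort(data, axis=None)
    L = pooled.size
    if L < 3:
        raise ValueError(f"pooled length {L} too short for terciles (need >= 3)")
    # 1-based ranks floor(L/3) and floor(2L/3)
    return TercileThresholds(
        t_low=float(pooled[L // 3 - 1]),
        t_high=float(pooled[2 * L // 3 - 1]),
        pooled_length=L,
    )


def symbolize(values: np.ndarray, thresholds: TercileThresholds) -> np.ndarray:
    """Map values to symbols {1, 2, 3} by tercile band.

    Bands are half-open upward: ``v < t_low → 1``, ``t_low ≤ v < t_high → 2``,
    ``v ≥ t_high → 3`` — a value exactly at a threshold joins the upper band.
    """
    values = np.asarray(values, dtype=float)
    return (
        1
        + (values >= thresholds.t_low).astype(np.int64)
        + (values >= thresholds.t_high).astype(np.int64)
    )


def embed(
    symbols: np.ndarray,
    m: int = DEFAULT_EMBED_DIM,
    tau: int = DEFAULT_EMBED_DELAY,
) -> np.ndarray:
    """Encode overlapping ``m``-tuples (delay ``tau``) of symbols as words 1..3^m.

    ``word_n`` encodes ``(s_n, s_{n+τ}, …, s_{n+(m−1)τ})`` big-endian, so the
    mapping is a bijection between tuples and integers; the word count is the
    symbol count minus ``(m−1)·τ``.
    """
    symbols = np.asarray(symbols, dtype=np.int64)
    n = symbols.size
    span = (m - 1) * tau
    if n < span + 1:
        raise ValueError(f"sequence of {n} symbols too short to embed (m={m}, tau={tau})")
    words = np.zeros(n - span, dtype=np.int64)
    for j in range(m):
        words = words * N_SYMBOLS + (symbols[j * tau : n - span + j * tau] - 1)
    return words + 1


def unembed(word: int, m: int = DEFAULT_EMBED_DIM) -> tuple[int, ...]:
    """Inverse of :func:`embed` for a single word."""
    w = int(word) - 1
    out = []
    for _ in range(m):
        out.append(w % N_SYMBOLS + 1)
        w //= N_SYMBOLS
    return tuple(reversed(out))


def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _tuple_encode(seq: np.ndarray, order: int, base: int) -> np.ndarray:
    """Encode sliding ``order``-tuples of a 0-based integer sequence."""
    n = seq.size - order + 1
    out = np.zeros(n, dtype=np.int64)
    for j in range(order):
        out = out * base + seq[j : j + n]
    return out


def ste_pair(source: np.ndarray, target: np.ndarray, k: int = 1, l: int = 1) -> float:
    """Plug-in transfer entropy (bits) from ``source`` to ``target`` words.

    ``target`` is treated as a Markov process of order ``k`` and ``source``
    of order ``l``; with the package defaults both are 1 and the estimate
    uses the empirical joint frequencies of ``(x_{n+1}, x_n, y_n)``.
    """
    x = np.asarray(target, dtype=np.int64)
    y = np.asarray(source, dtype=np.int64)
    if x.size != y.size:
        raise ValueError(f"length mismatch: source {y.size} vs target {x.size}")
    if x.size < max(k, l) + 1:
        raise ValueError("sequences too short for the requested Markov orders")
    base = int(max(x.max(), y.max()))
    x0, y0 = x - 1, y - 1
    start = max(k, l)
    n = x.size - start
    # composite past states, aligned so each ends just before x_{n+1}
    xk = _tuple_encode(x0, k, base)[start - k : start - k + n]
    yl = _tuple_encode(y0, l, base)[start - l : start - l + n]
    xnext = x0[start:]
    joint_xx = xnext * base**k + xk
    joint_xy = xk * base**l + yl
    joint_xxy = joint_xx * base**l + yl
    te = (
        _entropy_bits(np.bincount(joint_xx))
        + _entropy_bits(np.bincount(joint_xy))
        - _entropy_bits(np.bincount(xk))
        - _entropy_bits(np.bincount(joint_xxy))
    )
    if te < 0:
        if te < -1e-9:
            raise AssertionError(f"plug-in TE should be non-negative, got {te}")
        te = 0.0
    return te


@dataclass
class STEMatrix:
    """64×64 directed coupling matrix; entry (i, j) is TE from channel i to j in bits."""

    values: np.ndarray
    participant_id: int = 0
    task: int = 1
    event: int = 1
    channels: tuple[str, ...] = field(default=CHANNELS_64)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("STE matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("STE matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("STE matrix entries must be non-negative")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("STE matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | os.PathLike) -> None:
        header = (
            f"# participant={self.participant_id} task={self.task} event={self.event}\n"
            "# channels=" + ",".join(self.channels) + "\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, delimiter="\t", fmt="%.10g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "STEMatrix":
        meta: dict[str, str] = {}
        channels = CHANNELS_64
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                text = line[1:].strip()
                if text.startswith("channels="):
                    channels = tuple(text[len("channels="):].split(","))
                else:
                    for tok in text.split():
                        if "=" in tok:
                            key, _, val = tok.partition("=")
                            meta[key] = val
            else:
                body.append(line)
        values = np.loadtxt(body, delimiter="\t", ndmin=2)
        return cls(
            values=values,
            participant_id=int(meta.get("participant", 0)),
            task=int(meta.get("task", 1)),
            event=int(meta.get("event", 1)),
            channels=channels,
        )


def symbolic_words(
    segment: DifferencedSegment,
    m: int = DEFAULT_TE_WORD_DIM,
    tau: int = DEFAULT_EMBED_DELAY,
) -> np.ndarray:
    """Symbolize every channel against the pooled terciles and embed into words.

    With ``m = 1`` the words are the tercile symbols themselves."""
    thr = pooled_thresholds(segment)
    symbols = symbolize(segment.data, thr)
    return np.stack([embed(row, m=m, tau=tau) for row in symbols])


def ste_matrix(
    segment: DifferencedSegment,
    m: int = DEFAULT_TE_WORD_DIM,
    tau: int = DEFAULT_EMBED_DELAY,
) -> STEMatrix:
    """All-pairs symbolic transfer entropy of one segment.

    Entry (i, j) is the transfer entropy from channel i's word sequence to
    channel j's; the diagonal is zero by convention.  The computation is
    vectorized over sources for each target via flat bin counting.
    """
    words = symbolic_words(segment, m=m, tau=tau) - 1  # 0-based words
    n_ch, n_w = words.shape
    if n_w < 2:
        raise ValueError("need at least 2 words per channel for TE estimation")
    n_states = N_SYMBOLS**m
    x0 = words[:, :-1]
    x1 = words[:, 1:]
    npairs = n_w - 1

    h_x = np.empty(n_ch)
    h_xx = np.empty(n_ch)
    code_xx = np.empty((n_ch, npairs), dtype=np.int64)
    for j in range(n_ch):
        code_xx[j] = x1[j] * n_states + x0[j]
        h_x[j] = _entropy_bits(np.bincount(x0[j], minlength=n_states))
        h_xx[j] = _entropy_bits(np.bincount(code_xx[j]))

    def _row_entropies(codes: np.ndarray, n_cells: int) -> np.ndarray:
        # rows = sources; entropy of each row's empirical code distribution,
        # touching only occupied histogram cells
        flat = np.bincount(
            (codes + np.arange(n_ch)[:, None] * n_cells).ravel(),
            minlength=n_ch * n_cells,
        )
        nz = np.nonzero(flat)[0]
        c = flat[nz].astype(float)
        clogc = np.bincount(nz // n_cells, weights=c * np.log2(c), minlength=n_ch)
        return np.log2(npairs) - clogc / npairs

    values = np.zeros((n_ch, n_ch))
    for j in range(n_ch):
        # joint (x_n, y_n) and (x_{n+1}, x_n, y_n) for all sources i at once
        h_xy = _row_entropies(x0[j][None, :] * n_states + x0, n_states * n_states)
        h_xxy = _row_entropies(code_xx[j][None, :] * n_states + x0, n_states**3)
        values[:, j] = h_xx[j] + h_xy - h_x[j] - h_xxy
    neg = values < 0
    if np.any(values[neg] < -1e-9):
        raise AssertionError("plug-in TE should be non-negative up to round-off")
    values[neg] = 0.0
    np.fill_diagonal(values, 0.0)
    return STEMatrix(
        values=values,
        participant_id=segment.participant_id,
        task=segment.task,
        event=segment.event,
        channels=CHANNELS_64 if n_ch == 64 else tuple(f"ch{i+1}" for i in range(n_ch)),
    )
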