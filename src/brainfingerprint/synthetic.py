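"""Synthetic 64-channel cohorts with participant-specific directed coupling.

Each synthetic participant carries a sparse random coupling matrix A that is
constant across all of their runs — the ground-truth "fingerprint".  Entry
A[i, j] couples channel i onto channel j (the same i→j orientation as the
STE matrix), and signals follow first-order vector-autoregressive dynamics

    x_{t+1} = Aᵀ·x_t + η·ε_t,       ε_t ~ N(0, I)

which is the simplest generator whose directed coupling is detectable by
transfer entropy.  During task events a gain multiplies an event-specific
subset of the coupling edges, so the two task events are distinguishable
while the support of A (the fingerprint) never changes.  Event protocols
reproduce the reference recording timing: ~4.2 s task events (656 samples at
160 samples/s) alternating with rest, separated by 641-sample gaps.

The generator makes no claim to biophysical realism — no 1/f spectra, no
volume conduction; it exists so that every pipeline stage, and participant
identification end-to-end, can be exercised with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .channels import generic_channel_map
from .io import EventRecord, EventTable, Recording, write_recording

SAMPLING_RATE = 160.0

#: The printed (code, latency, duration) rows of the reference 2-minute task
#: run: 672-sample rest events alternating with 656-sample task events,
#: mostly 641 samples apart (with two longer 801-sample gaps mid-run).
TASK_RUN_EVENTS: tuple[tuple[int, int, int], ...] = (
    (1, 1, 672), (3, 1313, 656), (1, 2609, 672), (2, 3921, 656),
    (1, 5217, 672), (2, 6529, 656), (1, 7825, 672), (3, 9297, 656),
    (1, 10593, 672), (3, 11905, 656), (1, 13201, 672), (2, 14513, 656),
    (1, 15809, 672), (3, 17281, 656), (1, 18577, 672),
)
REST_DURATION = 672
TASK_DURATION = 656
INTERMISSION = 641


@dataclass(frozen=True)
class Protocol:
    """Timing template of one run: (code, latency, duration) triplets."""

    sampling_rate: float = SAMPLING_RATE
    records: tuple[tuple[int, int, int], ...] = TASK_RUN_EVENTS

    def event_table(self) -> EventTable:
        return EventTable(
            EventRecord(code=c, latency=l, duration=d) for c, l, d in self.records
        )

    @property
    def run_length(self) -> int:
        c, l, d = self.records[-1]
        return l + d - 1

    @classmethod
    def task_run(cls, n_events: int | None = None) -> "Protocol":
        """The reference task-run template, optionally truncated."""
        return cls(records=TASK_RUN_EVENTS[: n_events or len(TASK_RUN_EVENTS)])

    @classmethod
    def from_durations(
        cls, events: tuple[tuple[int, int], ...], intermission: int = INTERMISSION
    ) -> "Protocol":
        """Build a uniform-gap protocol from (code, duration) pairs."""
        records = []
        latency = 1
        for code, duration in events:
            records.append((code, latency, duration))
            latency = latency + duration - 1 + intermission
        return cls(records=tuple(records))

    @classmethod
    def baseline(cls, seconds: float = 60.0) -> "Protocol":
        """A baseline run: one long rest event."""
        return cls(records=((1, 1, int(seconds * SAMPLING_RATE)),))


@dataclass
class SyntheticParticipant:
    """Ground-truth coupling fingerprint of one synthetic participant."""

    id: int
    coupling: np.ndarray
    noise_scale: float
    seed: int
    event_subsets: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        rho = spectral_radius(self.coupling)
        if rho >= 1.0:
            raise ValueError(f"coupling is unstable (spectral radius {rho:.3f} >= 1)")


def spectral_radius(a: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(a)).max())


def _draw_coupling(
    rng: np.random.Generator, n_channels: int, density: float, radius: float
) -> np.ndarray:
    a = np.zeros((n_channels, n_channels))
    off = ~np.eye(n_channels, dtype=bool)
    mask = off & (rng.random((n_channels, n_channels)) < density)
    magnitudes = rng.uniform(0.5, 1.5, size=mask.sum())
    signs = rng.choice([-1.0, 1.0], size=mask.sum())
    a[mask] = magnitudes * signs
    rho = spectral_radius(a)
    if rho > 0:
        a *= radius / rho
    return a


def make_cohort(
    n_participants: int,
    separability: float = 1.0,
    density: float = 0.03,
    seed: int | None = None,
    n_channels: int = 64,
    spectral_radius_target: float = 0.95,
    noise_scale: float = 1.0,
    max_retries: int = 50,
) -> list[SyntheticParticipant]:
    """Draw a cohort of stable, mutually distinct coupling fingerprints.

    Every pairwise Frobenius distance between couplings is at least
    ``separability`` (0 disables the floor); infeasible settings raise after
    ``max_retries`` redraws per participant.  Reproducible from ``seed``.
    """
    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    if separability < 0:
        raise ValueError("separability must be non-negative")
    root = np.random.SeedSequence(seed)
    cohort: list[SyntheticParticipant] = []
    couplings: list[np.ndarray] = []
    for pid in range(1, n_participants + 1):
        sub = np.random.SeedSequence((seed if seed is not None else 0, pid))
        rng = np.random.default_rng(sub)
        for attempt in range(max_retries):
            a = _draw_coupling(rng, n_channels, density, spectral_radius_target)
            dists = [float(np.sqrt(((a - b) ** 2).sum())) for b in couplings]
            if not dists or min(dists) >= separability:
                break
        else:
            raise ValueError(
                f"could not draw a coupling {separability} apart from the "
                f"cohort after {max_retries} retries (density {density})"
            )
        # fixed event-specific edge subsets: half the support modulated by
        # task event 2, the other half by task event 3
        us, vs = np.nonzero(a)
        perm = rng.permutation(us.size)
        half = us.size // 2
        subsets = {
            2: np.stack([us[perm[:half]], vs[perm[:half]]], axis=1),
            3: np.stack([us[perm[half:]], vs[perm[half:]]], axis=1),
        }
        couplings.append(a)
        cohort.append(
            SyntheticParticipant(
                id=pid,
                coupling=a,
                noise_scale=noise_scale,
                seed=int(rng.integers(2**31)),
                event_subsets=subsets,
            )
        )
    return cohort


def _modulated(participant: SyntheticParticipant, code: int, task_gain: float) -> np.ndarray:
    """Coupling in effect during an event of the given code."""
    a = participant.coupling
    if code == 1 or task_gain == 1.0 or code not in participant.event_subsets:
        return a
    mod = a.copy()
    idx = participant.event_subsets[code]
    if idx.size:
        mod[idx[:, 0], idx[:, 1]] *= task_gain
    rho = spectral_radius(mod)
    if rho >= 0.98:  # keep the modulated regime comfortably stable
        mod *= 0.95 / rho
    return mod


def simulate_run(
    participant: SyntheticParticipant,
    protocol: Protocol | None = None,
    run_id: int = 1,
    task_gain: float = 1.5,
    seed: int | None = None,
    burn_in: int = 200,
) -> Recording:
    """Simulate one run of VAR(1) dynamics under the protocol's event schedule.

    The baseline coupling drives rest spans and intermissions; during task
    events the event-specific gain-modulated coupling takes over.  Raises if
    the trajectory diverges (instability guard).
    """
    protocol = protocol or Protocol.task_run()
    table = protocol.event_table()
    n = protocol.run_length
    n_ch = participant.coupling.shape[0]
    rng = np.random.default_rng(
        np.random.SeedSequence((participant.seed, run_id) if seed is None else (seed, run_id))
    )
    # per-sample coupling regime
    regime = np.full(n, 1, dtype=int)
    for rec in table:
        regime[rec.latency - 1 : rec.latency - 1 + rec.duration] = rec.code
    mats = {code: _modulated(participant, code, task_gain) for code in (1, 2, 3)}

    x = np.zeros(n_ch)
    trans = {code: m.T.copy() for code, m in mats.items()}  # x_{t+1} = Aᵀ x_t + noise
    for _ in range(burn_in):
        x = trans[1] @ x + participant.noise_scale * rng.standard_normal(n_ch)
    signal = np.empty((n_ch, n))
    for t in range(n):
        x = trans[regime[t]] @ x + participant.noise_scale * rng.standard_normal(n_ch)
        signal[:, t] = x
    if not np.all(np.isfinite(signal)) or np.abs(signal).max() > 1e6:
        raise RuntimeError("simulated trajectory diverged; coupling unstable")
    return Recording(
        participant_id=participant.id,
        run_id=run_id,
        sampling_rate=protocol.sampling_rate,
        signal=signal,
        events=table,
        channel_map=generic_channel_map(n_ch),
    )


def cohort_recordings(
    cohort: Sequence[SyntheticParticipant],
    n_runs: int = 4,
    protocol: Protocol | None = None,
    task_gain: float = 1.5,
) -> dict[int, list[Recording]]:
    """Simulate ``n_runs`` task runs per participant (run ids 1..n_runs)."""
    return {
        p.id: [
            simulate_run(p, protocol=protocol, run_id=r, task_gain=task_gain)
            for r in range(1, n_runs + 1)
        ]
        for p in cohort
    }


def write_cohort(
    cohort: Sequence[SyntheticParticipant],
    directory: str | Path,
    n_runs: int = 4,
    protocol: Protocol | None = None,
    task_gain: float = 1.5,
) -> list[Path]:
    """Simulate and write each run as a neutral text container."""
    paths = []
    for pid, runs in cohort_recordings(cohort, n_runs, protocol, task_gain).items():
        for rec in runs:
            paths.append(write_recording(rec, directory, f"P{pid:03d}R{rec.run_id:02d}"))
    return paths
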