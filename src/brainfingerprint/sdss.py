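"""Spectrum Distribution Set Scoring (SDSS): fingerprint identification.

Per participant, the coarse-grained eigenvalue grids of the three task-1
events are summed cell-wise into a reference fingerprint on a grid range
pooled over the whole cohort.  A test spectrum (any other task) is binned on
the same grid and scored against every reference by histogram intersection
— the summed cell-wise minimum of the two count grids, i.e. the size of the
overlapping part.  The participant with the highest score wins.  The cross
test repeats identification over many random partitions of the cohort into
three task groups and reports the mean accuracy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .spectrum import Spectrum, SpectrumGrid, coarse_grain

REFERENCE_EVENTS = (1, 2, 3)


@dataclass
class ReferenceSet:
    """Per-participant aggregated fingerprint grids on a shared cell-aligned range."""

    theta: float
    real_range: tuple[float, float]
    imag_range: tuple[float, float]
    grids: dict[int, SpectrumGrid]

    def __post_init__(self) -> None:
        for pid, grid in self.grids.items():
            if grid.theta != self.theta or grid.real_range != self.real_range or (
                grid.imag_range != self.imag_range
            ):
                raise ValueError(f"grid of participant {pid} is not cell-aligned")

    @property
    def participants(self) -> list[int]:
        return sorted(self.grids)

    def __len__(self) -> int:
        return len(self.grids)

    def save(self, directory: str | os.PathLike) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "theta": float(self.theta),
            "real_range": [float(x) for x in self.real_range],
            "imag_range": [float(x) for x in self.imag_range],
            "participants": self.participants,
        }
        (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
        for pid, grid in self.grids.items():
            grid.to_tsv(directory / f"reference_p{pid:03d}.tsv")

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "ReferenceSet":
        directory = Path(directory)
        manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
        grids = {
            int(pid): SpectrumGrid.from_tsv(directory / f"reference_p{pid:03d}.tsv")
            for pid in manifest["participants"]
        }
        return cls(
            theta=float(manifest["theta"]),
            real_range=tuple(manifest["real_range"]),
            imag_range=tuple(manifest["imag_range"]),
            grids=grids,
        )


def build_reference(spectra: Iterable[Spectrum], theta: float = 0.5) -> ReferenceSet:
    """Aggregate task-1 event spectra into per-participant reference grids.

    Every participant must contribute all three events; the shared grid
    range is the pooled min/max of all contributing eigenvalues, so grids
    are cell-aligned across the cohort.
    """
    by_participant: dict[int, dict[int, Spectrum]] = {}
    all_points: list[np.ndarray] = []
    for spec in spectra:
        by_participant.setdefault(spec.participant_id, {})[spec.event] = spec
        all_points.append(spec.eigenvalues)
    if not by_participant:
        raise ValueError("no spectra supplied")
    for pid, events in by_participant.items():
        missing = set(REFERENCE_EVENTS) - set(events)
        if missing:
            raise ValueError(f"participant {pid} missing event(s) {sorted(missing)}")
    pooled = np.concatenate(all_points)
    real_range = (float(pooled.real.min()), float(pooled.real.max()))
    imag_range = (float(pooled.imag.min()), float(pooled.imag.max()))
    grids: dict[int, SpectrumGrid] = {}
    for pid, events in by_participant.items():
        event_grids = [
            coarse_grain(events[e], theta, real_range, imag_range) for e in REFERENCE_EVENTS
        ]
        total = event_grids[0]
        for g in event_grids[1:]:
            total = total + g
        grids[pid] = total
    return ReferenceSet(theta=theta, real_range=real_range, imag_range=imag_range, grids=grids)


def overlap_score(test: SpectrumGrid, reference: SpectrumGrid) -> int:
    """Histogram intersection: Σ over cells of min(test, reference) counts."""
    if not test.aligned_with(reference):
        raise ValueError("grids are not cell-aligned (theta/ranges differ)")
    return int(np.minimum(test.counts, reference.counts).sum())


@dataclass
class ScoreVector:
    """Overlap scores of one test grid against every reference."""

    scores: dict[int, int]
    winner: int
    tie_flag: bool
    n_clipped: int = 0

    def as_array(self, order: Sequence[int] | None = None) -> np.ndarray:
        order = order if order is not None else sorted(self.scores)
        return np.array([self.scores[p] for p in order], dtype=float)


def project_to_reference(spectrum: Spectrum, refset: ReferenceSet) -> SpectrumGrid:
    """Bin a test spectrum on the reference ranges, clipping outliers into
    boundary cells (the clip count is carried on the grid)."""
    return coarse_grain(
        spectrum,
        refset.theta,
        refset.real_range,
        refset.imag_range,
        clip=True,
    )


def identify(test: Spectrum | SpectrumGrid, refset: ReferenceSet) -> ScoreVector:
    """Score a test spectrum against every participant's reference grid.

    The winner is the argmax of the overlap score; ties go to the lowest
    participant id with ``tie_flag`` set.
    """
    if len(refset) == 0:
        raise ValueError("reference set is empty")
    grid = test if isinstance(test, SpectrumGrid) else project_to_reference(test, refset)
    scores = {pid: overlap_score(grid, refset.grids[pid]) for pid in refset.participants}
    best = max(scores.values())
    winners = [pid for pid in refset.participants if scores[pid] == best]
    return ScoreVector(
        scores=scores,
        winner=winners[0],
        tie_flag=len(winners) > 1,
        n_clipped=grid.n_clipped,
    )


@dataclass
class CrossTestResult:
    """Accuracy of repeated identification over random cohort partitions."""

    n_draws: int
    group_size: int
    accuracies: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


def cross_test(
    refset: ReferenceSet,
    group_spectra: Sequence[Mapping[int, Spectrum]],
    n_draws: int = 1000,
    group_size: int | None = None,
    seed: int | None = None,
) -> CrossTestResult:
    """Repeated-draw identification across three held-out task groups.

    ``group_spectra`` holds, per test task group, one spectrum per
    participant.  Each draw partitions the cohort into three disjoint sets
    of ``group_size`` participants (cohort size / 3 by default), tests each
    set against its group's task, and scores accuracy as correct / cohort
    size.  The draw-wise accuracies and their mean are returned.
    """
    participants = refset.participants
    n = len(participants)
    if len(group_spectra) != 3:
        raise ValueError("cross test expects exactly 3 task groups")
    for g, spectra in enumerate(group_spectra):
        missing = set(participants) - set(spectra)
        if missing:
            raise ValueError(f"group {g + 1} missing participants {sorted(missing)}")
    if group_size is None:
        if n % 3:
            raise ValueError(f"cohort of {n} cannot be split into 3 equal groups")
        group_size = n // 3
    if 3 * group_size != n:
        raise ValueError(f"3 × group_size {group_size} incompatible with cohort of {n}")

    # pre-computed grids and score winners: identification is deterministic
    # per (participant, group), only the draw partition is random
    winners = np.empty((3, n), dtype=int)
    for g, spectra in enumerate(group_spectra):
        for idx, pid in enumerate(participants):
            winners[g, idx] = identify(spectra[pid], refset).winner

    rng = np.random.default_rng(seed)
    accuracies = np.empty(n_draws)
    pid_arr = np.array(participants)
    for d in range(n_draws):
        perm = rng.permutation(n)
        correct = 0
        for g in range(3):
            chosen = perm[g * group_size : (g + 1) * group_size]
            correct += int(np.sum(winners[g, chosen] == pid_arr[chosen]))
        accuracies[d] = correct / n
    return CrossTestResult(
        n_draws=n_draws, group_size=group_size, accuracies=accuracies, seed=seed
    )
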