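#!/usr/bin/env python
"""OPTIONAL: run the full 99-participant experiment on the public dataset.

Downloads the motor/movement-imagery EEG recordings (EDF+, ~3.4 GB) from
PhysioNet and pushes the whole cohort through the fingerprinting pipeline:
STE matrices for every (run, event), task-1 references, held-out
identification and the 1,000-draw cross test. Needs network access, the
`mne` extra, tens of GB of scratch space and several hours of CPU time; it
is deliberately not part of the test suite.

    python scripts/run_physionet.py --out physionet_results --participants 99
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

import numpy as np

from brainfingerprint.config import PipelineConfig
from brainfingerprint.io import read_recording
from brainfingerprint.pipeline import preprocess_recording
from brainfingerprint.sdss import build_reference, cross_test, identify
from brainfingerprint.spectrum import eigen_spectrum, zscore
from brainfingerprint.stats import distance_summaries, two_sample_ztest
from brainfingerprint.ste import ste_matrix

BASE_URL = "https://physionet.org/files/eegmmidb/1.0.0"
TASK_RUNS = range(3, 15)  # runs 3..14 are the motor/imagery task runs
REFERENCE_RUN = 3  # the first task-1 run provides the reference events


def download(participant: int, run: int, dest: Path) -> Path:
    name = f"S{participant:03d}R{run:02d}.edf"
    path = dest / name
    if not path.exists():
        url = f"{BASE_URL}/S{participant:03d}/{name}"
        print(f"fetching {url}")
        urllib.request.urlretrieve(url, path)
    return path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--participants", type=int, default=99)
    parser.add_argument("--draws", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    raw_dir = args.out / "edf"
    raw_dir.mkdir(parents=True, exist_ok=True)
    ste_dir = args.out / "ste"
    ste_dir.mkdir(exist_ok=True)

    cfg = PipelineConfig()
    matrices = []
    for pid in range(1, args.participants + 1):
        for run in TASK_RUNS:
            path = download(pid, run, raw_dir)
            rec = read_recording(path, participant_id=pid, run_id=run)
            for seg in preprocess_recording(rec, cfg):
                m = ste_matrix(seg)
                m.to_tsv(ste_dir / f"p{pid:03d}_t{run:02d}_e{seg.event}.tsv")
                matrices.append(m)
        print(f"participant {pid}: {len(matrices)} matrices so far")

    between, within = distance_summaries(matrices)
    z = two_sample_ztest(between.mean, between.sd, between.n_pairs,
                         within.mean, within.sd, within.n_pairs)
    print(f"between {between.mean:.3f}±{between.sd:.3f} ({between.n_pairs} pairs)")
    print(f"within  {within.mean:.3f}±{within.sd:.3f} ({within.n_pairs} pairs)")
    print(f"z = {z.z:.3f}")

    spectra = [zscore(eigen_spectrum(m)) for m in matrices]
    refset = build_reference([s for s in spectra if s.task == REFERENCE_RUN])
    held = [s for s in spectra if s.task != REFERENCE_RUN]
    correct = sum(identify(s, refset).winner == s.participant_id for s in held)
    print(f"held-out identification: {correct}/{len(held)} = {correct/len(held):.4f}")

    by_condition: dict[tuple[int, int], dict] = {}
    for s in held:
        by_condition.setdefault((s.task, s.event), {})[s.participant_id] = s
    pids = set(refset.participants)
    full = [c for c, d in sorted(by_condition.items()) if set(d) == pids]
    if len(full) >= 3 and len(pids) % 3 == 0:
        ct = cross_test(refset, [by_condition[c] for c in full[:3]],
                        n_draws=args.draws, seed=args.seed)
        np.savetxt(args.out / "cross_test_accuracies.tsv", ct.accuracies)
        print(f"cross-test mean accuracy over {args.draws} draws: "
              f"{ct.mean_accuracy:.4f}")


if __name__ == "__main__":
    main()
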