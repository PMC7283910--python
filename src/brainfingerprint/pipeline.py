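"""End-to-end orchestration: data → preprocessing → STE → networks,
spectra, identification and statistics, with every artifact written to disk.

The stage order is fixed: read (or simulate) → band-pass/notch filter →
artifact hook → per-event segmentation (same-event spans concatenated) →
first difference → symbolic transfer entropy → {arborescence, eigen
spectrum} → reference building, identification, cross test and the distance
/ ANOVA statistics.  Run 1 of every participant provides the reference
fingerprints; all other runs are held-out test material.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import generic_channel_map
from .config import PipelineConfig
from .dmst import from_ste, minimum_arborescence, out_degree_profile, select_root
from .io import Recording, extract_segments, read_recording
from .preprocess import FilterSpec, artifact_removal, filter_recording, first_difference
from .sdss import CrossTestResult, build_reference, cross_test, identify
from .spectrum import Spectrum, eigen_spectrum, zscore
from .stats import distance_summaries, two_sample_ztest, two_way_anova
from .ste import STEMatrix, ste_matrix
from .synthetic import Protocol, cohort_recordings, make_cohort, write_cohort

log = logging.getLogger("brainfingerprint")

REFERENCE_TASK = 1


@dataclass
class PipelineResult:
    """Key outcomes of one pipeline run (artifacts live under ``out_dir``)."""

    out_dir: Path
    matrices: list[STEMatrix]
    spectra: list[Spectrum]
    holdout_accuracy: float | None = None
    cross_test: CrossTestResult | None = None
    between_mean: float | None = None
    within_mean: float | None = None
    anova: pd.DataFrame | None = None


def _load_recordings(config: PipelineConfig, out_dir: Path) -> dict[int, list[Recording]]:
    if config.data_dir is not None:
        paths = sorted(Path(config.data_dir).glob("*.meta.yaml"))
        if not paths:
            raise FileNotFoundError(f"no recordings (*.meta.yaml) under {config.data_dir}")
        runs: dict[int, list[Recording]] = {}
        for p in paths:
            rec = read_recording(p)
            runs.setdefault(rec.participant_id, []).append(rec)
        return runs
    syn = config.synthetic
    protocol = Protocol.task_run(syn.protocol_events)
    cohort = make_cohort(
        syn.participants,
        separability=syn.separability,
        density=syn.density,
        seed=syn.seed,
        n_channels=syn.n_channels,
        spectral_radius_target=syn.spectral_radius,
    )
    log.info("simulated cohort of %d participants (seed %s)", syn.participants, syn.seed)
    write_cohort(cohort, out_dir / "data", n_runs=syn.runs, protocol=protocol,
                 task_gain=syn.task_gain)
    return cohort_recordings(cohort, n_runs=syn.runs, protocol=protocol,
                             task_gain=syn.task_gain)


def preprocess_recording(rec: Recording, config: PipelineConfig, hook=None):
    """Filter a whole run, apply the artifact hook, cut and difference segments."""
    spec = FilterSpec(
        band_low=config.filter.band_low,
        band_high=config.filter.band_high,
        notch=config.filter.notch,
        fir_order=config.filter.fir_order,
    )
    filtered = filter_recording(rec, spec)
    cleaned = artifact_removal(filtered, hook)
    segments = extract_segments(cleaned, concatenate_same_event=True)
    return [first_difference(s) for s in segments]


def run_pipeline(config: PipelineConfig, out_dir: str | Path, hook=None) -> PipelineResult:
    """Execute every stage and write artifacts; see the module docstring."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out_dir / "run.log")
    log.addHandler(fh)
    try:
        return _run(config, out_dir, hook)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, out_dir: Path, hook) -> PipelineResult:
    config.save(out_dir / "config.yaml")
    log.info("config hash %s", config.hash())

    runs = _load_recordings(config, out_dir)

    # --- STE matrices per (participant, run, event) ---------------------
    ste_dir = out_dir / "ste"
    ste_dir.mkdir(exist_ok=True)
    matrices: list[STEMatrix] = []
    for pid, recs in sorted(runs.items()):
        for rec in recs:
            for seg in preprocess_recording(rec, config, hook):
                m = ste_matrix(seg, m=config.symbols.m, tau=config.symbols.tau)
                m.to_tsv(ste_dir / f"p{pid:03d}_t{seg.task:02d}_e{seg.event}.tsv")
                matrices.append(m)
                log.info("STE p%d task %d event %d done", pid, seg.task, seg.event)

    # --- brain networks for the reference task --------------------------
    net_dir = out_dir / "dmst"
    net_dir.mkdir(exist_ok=True)
    n_ch = matrices[0].n
    cmap = generic_channel_map(n_ch)
    profiles = []
    for m in matrices:
        if m.task != REFERENCE_TASK:
            continue
        graph = from_ste(m, mode=config.dmst.mode)
        root = select_root(m, config.dmst.root, seed=config.dmst.seed)
        tree = minimum_arborescence(graph, root, mode=config.dmst.mode)
        stem = f"p{m.participant_id:03d}_t{m.task:02d}_e{m.event}"
        tree.to_edge_tsv(net_dir / f"{stem}.tsv")
        (net_dir / f"{stem}.dot").write_text(tree.to_dot(cmap.names))
        table, key = out_degree_profile(tree, cmap)
        profiles.append(
            {"participant": m.participant_id, "event": m.event,
             "root": cmap.label(root + 1), "key_nodes": ",".join(sorted(key))}
        )
    pd.DataFrame(profiles).to_csv(net_dir / "key_nodes.tsv", sep="\t", index=False)

    # --- spectra ---------------------------------------------------------
    spectra = []
    for m in matrices:
        s = eigen_spectrum(m)
        if config.spectrum.normalize:
            s = zscore(s)
        spectra.append(s)

    # --- reference set and identification of held-out runs --------------
    ref_spectra = [s for s in spectra if s.task == REFERENCE_TASK]
    refset = build_reference(ref_spectra, theta=config.spectrum.theta)
    refset.save(out_dir / "reference")

    score_rows = []
    test_spectra = [s for s in spectra if s.task != REFERENCE_TASK]
    for s in test_spectra:
        sv = identify(s, refset)
        score_rows.append(
            {"participant": s.participant_id, "task": s.task, "event": s.event,
             "winner": sv.winner, "correct": int(sv.winner == s.participant_id),
             "tie": int(sv.tie_flag), "clipped": sv.n_clipped}
        )
    scores = pd.DataFrame(score_rows)
    holdout_accuracy = float(scores["correct"].mean()) if len(scores) else None
    scores.to_csv(out_dir / "identification.tsv", sep="\t", index=False)

    # --- cross test over three held-out conditions ----------------------
    ct = None
    participants = sorted(runs)
    by_condition: dict[tuple[int, int], dict[int, Spectrum]] = {}
    for s in test_spectra:
        by_condition.setdefault((s.task, s.event), {})[s.participant_id] = s
    full = [c for c, d in sorted(by_condition.items()) if set(d) == set(participants)]
    if len(full) >= 3 and len(participants) % 3 == 0:
        groups = [by_condition[c] for c in full[:3]]
        ct = cross_test(
            refset, groups, n_draws=config.sdss.draws,
            group_size=config.sdss.group_size, seed=config.sdss.seed,
        )
        pd.DataFrame({"draw": np.arange(1, ct.n_draws + 1),
                      "accuracy": ct.accuracies}).to_csv(
            out_dir / "cross_test.tsv", sep="\t", index=False)

    # --- statistics ------------------------------------------------------
    between, within = distance_summaries(matrices)
    ztest = two_sample_ztest(
        between.mean, between.sd, between.n_pairs,
        within.mean, within.sd, within.n_pairs,
    )
    conditions = sorted({(m.task, m.event) for m in matrices})
    spec_by = {(s.participant_id, s.task, s.event): s for s in spectra}
    complete = [c for c in conditions
                if all((p, *c) in spec_by for p in participants)]
    anova = None
    if len(complete) >= 2 and len(participants) >= 2:
        reps = 2 * n_ch
        blocks = [
            np.column_stack([spec_by[(p, *c)].vector for p in participants])
            for c in complete
        ]
        anova = two_way_anova(
            np.vstack(blocks), len(participants), len(complete), reps
        )
        anova.to_csv(out_dir / "anova.tsv", sep="\t")

    summary = {
        "config_hash": config.hash(),
        "n_participants": len(participants),
        "n_matrices": len(matrices),
        "holdout_accuracy": holdout_accuracy,
        "cross_test_mean_accuracy": ct.mean_accuracy if ct else None,
        "between_participant_mean_distance": between.mean,
        "within_participant_mean_distance": within.mean,
        "z": ztest.z,
    }
    (out_dir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
    log.info("pipeline complete: %s", summary)

    return PipelineResult(
        out_dir=out_dir,
        matrices=matrices,
        spectra=spectra,
        holdout_accuracy=holdout_accuracy,
        cross_test=ct,
        between_mean=between.mean,
        within_mean=within.mean,
        anova=anova,
    )
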