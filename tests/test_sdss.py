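"""Reference building, overlap scoring, identification and the cross test."""

import numpy as np
import pytest

from brainfingerprint.sdss import (
    ReferenceSet,
    build_reference,
    cross_test,
    identify,
    overlap_score,
    project_to_reference,
)
from brainfingerprint.spectrum import Spectrum, SpectrumGrid, coarse_grain


def _spectrum(points, pid=1, task=1, event=1) -> Spectrum:
    return Spectrum(np.asarray(points, dtype=complex), participant_id=pid,
                    task=task, event=event)


def _cloud(rng, centre, n=64, spread=0.3):
    return (centre.real + spread * rng.standard_normal(n)) + 1j * (
        centre.imag + spread * rng.standard_normal(n)
    )


def _cohort_spectra(rng, n_participants=4, tasks=(1, 2), spread=0.3):
    """Synthetic spectra with participant-specific cluster centres: the
    same centre for every task/event of one participant."""
    centres = [complex(3 * p, 2 * ((p * 7) % 5)) for p in range(n_participants)]
    out = []
    for p in range(n_participants):
        for t in tasks:
            for e in (1, 2, 3):
                out.append(
                    _spectrum(_cloud(rng, centres[p], spread=spread),
                              pid=p + 1, task=t, event=e)
                )
    return out


class TestBuildReference:
    def test_three_identical_events_triple_the_grid(self, rng):
        pts = _cloud(rng, 1 + 1j)
        spectra = [_spectrum(pts, event=e) for e in (1, 2, 3)]
        spectra.append(_spectrum(pts + 10, pid=2, event=1))
        spectra.append(_spectrum(pts + 10, pid=2, event=2))
        spectra.append(_spectrum(pts + 10, pid=2, event=3))
        refset = build_reference(spectra, theta=1.0)
        single = coarse_grain(pts, 1.0, refset.real_range, refset.imag_range)
        np.testing.assert_array_equal(refset.grids[1].counts, 3 * single.counts)

    def test_total_mass_is_three_events_of_64(self, rng):
        spectra = _cohort_spectra(rng, n_participants=3, tasks=(1,))
        refset = build_reference(spectra)
        for pid in refset.participants:
            assert refset.grids[pid].total_mass == 3 * 64

    def test_missing_event_is_named(self, rng):
        spectra = [_spectrum(_cloud(rng, 0j), event=e) for e in (1, 2)]
        with pytest.raises(ValueError, match="missing event.*3"):
            build_reference(spectra)

    def test_disjoint_cohorts_have_disjoint_support(self, rng):
        spectra = []
        for pid, centre in ((1, 0 + 0j), (2, 50 + 50j)):
            for e in (1, 2, 3):
                spectra.append(_spectrum(_cloud(rng, centre), pid=pid, event=e))
        refset = build_reference(spectra)
        overlap = np.minimum(refset.grids[1].counts, refset.grids[2].counts)
        assert overlap.sum() == 0

    def test_grids_are_cell_aligned(self, rng):
        refset = build_reference(_cohort_spectra(rng, tasks=(1,)))
        grids = list(refset.grids.values())
        assert all(g.aligned_with(grids[0]) for g in grids)

    def test_save_load_round_trip(self, tmp_path, rng):
        refset = build_reference(_cohort_spectra(rng, tasks=(1,)))
        refset.save(tmp_path / "ref")
        back = ReferenceSet.load(tmp_path / "ref")
        assert back.participants == refset.participants
        for pid in back.participants:
            np.testing.assert_array_equal(
                back.grids[pid].counts, refset.grids[pid].counts
            )


class TestOverlapScore:
    def _grid(self, counts):
        return SpectrumGrid(theta=1.0, real_range=(0.0, 2.0),
                            imag_range=(0.0, 1.0), counts=np.asarray(counts))

    def test_identical_grids_score_total_mass(self):
        g = self._grid([[2, 3], [0, 1]])
        assert overlap_score(g, g) == 6

    def test_disjoint_grids_score_zero(self):
        assert overlap_score(self._grid([[2, 0]]), self._grid([[0, 5]])) == 0

    def test_cellwise_minimum(self):
        assert overlap_score(self._grid([[2, 0]]), self._grid([[1, 5]])) == 1

    def test_symmetry_and_bound(self, rng):
        a = self._grid(rng.integers(0, 5, (2, 2)))
        b = self._grid(rng.integers(0, 5, (2, 2)))
        s = overlap_score(a, b)
        assert s == overlap_score(b, a)
        assert s <= min(a.total_mass, b.total_mass)

    def test_misaligned_grids_rejected(self):
        a = self._grid([[1]])
        b = SpectrumGrid(theta=0.5, real_range=(0.0, 2.0),
                         imag_range=(0.0, 1.0), counts=np.array([[1]]))
        with pytest.raises(ValueError, match="aligned"):
            overlap_score(a, b)


class TestIdentify:
    def test_self_identification(self, rng):
        spectra = _cohort_spectra(rng, n_participants=4, tasks=(1, 2))
        refset = build_reference([s for s in spectra if s.task == 1])
        for s in spectra:
            if s.task == 2:
                sv = identify(s, refset)
                assert sv.winner == s.participant_id
                assert sv.scores[sv.winner] >= max(sv.scores.values())

    def test_out_of_range_test_points_are_clipped_and_counted(self, rng):
        spectra = _cohort_spectra(rng, n_participants=2, tasks=(1,))
        refset = build_reference(spectra)
        far = _spectrum(_cloud(rng, 200 + 200j), pid=1, task=2)
        grid = project_to_reference(far, refset)
        assert grid.n_clipped > 0
        assert grid.total_mass == 64

    def test_empty_reference_rejected(self, rng):
        refset = ReferenceSet(theta=1.0, real_range=(0, 1), imag_range=(0, 1), grids={})
        with pytest.raises(ValueError, match="empty"):
            identify(_spectrum(_cloud(rng, 0j)), refset)

    def test_all_zero_test_grid_ties_to_lowest_id(self, rng):
        spectra = _cohort_spectra(rng, n_participants=3, tasks=(1,))
        refset = build_reference(spectra)
        empty = SpectrumGrid(
            theta=refset.theta, real_range=refset.real_range,
            imag_range=refset.imag_range,
            counts=np.zeros_like(refset.grids[1].counts),
        )
        sv = identify(empty, refset)
        assert sv.tie_flag and sv.winner == refset.participants[0]


class TestCrossTest:
    def _refset_and_groups(self, rng, n=3, spread=0.3):
        spectra = _cohort_spectra(rng, n_participants=n, tasks=(1, 2), spread=spread)
        refset = build_reference([s for s in spectra if s.task == 1])
        groups = [
            {s.participant_id: s for s in spectra if s.task == 2 and s.event == e}
            for e in (1, 2, 3)
        ]
        return refset, groups

    def test_perfectly_separable_cohort_scores_one(self, rng):
        refset, groups = self._refset_and_groups(rng)
        result = cross_test(refset, groups, n_draws=50, seed=0)
        assert result.mean_accuracy == 1.0
        assert np.all(result.accuracies == 1.0)

    def test_indistinguishable_tests_hit_chance_level(self, rng):
        # every test spectrum identical -> a single fixed winner -> exactly
        # one correct identification per draw, i.e. accuracy 1/N
        spectra = _cohort_spectra(rng, n_participants=3, tasks=(1,))
        refset = build_reference(spectra)
        same = _cloud(rng, 1 + 1j)
        groups = [
            {pid: _spectrum(same, pid=pid, task=2, event=e) for pid in (1, 2, 3)}
            for e in (1, 2, 3)
        ]
        result = cross_test(refset, groups, n_draws=100, seed=1)
        assert result.mean_accuracy == pytest.approx(1 / 3)

    def test_deterministic_under_seed(self, rng):
        refset, groups = self._refset_and_groups(rng, spread=2.0)
        a = cross_test(refset, groups, n_draws=30, seed=5)
        b = cross_test(refset, groups, n_draws=30, seed=5)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_indivisible_cohort_rejected(self, rng):
        spectra = _cohort_spectra(rng, n_participants=4, tasks=(1, 2))
        refset = build_reference([s for s in spectra if s.task == 1])
        groups = [
            {s.participant_id: s for s in spectra if s.task == 2 and s.event == e}
            for e in (1, 2, 3)
        ]
        with pytest.raises(ValueError, match="split"):
            cross_test(refset, groups, n_draws=5)

    def test_missing_participant_in_group_rejected(self, rng):
        refset, groups = self._refset_and_groups(rng)
        del groups[1][2]
        with pytest.raises(ValueError, match="missing participants"):
            cross_test(refset, groups, n_draws=5)
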