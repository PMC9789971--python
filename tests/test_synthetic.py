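"""The synthetic cohort generator: determinism, round-trips, generative model."""

import numpy as np
import pytest

from disconnectomics import (
    ConfigurationError,
    DataContractError,
    EmptyLesionError,
    GroundTruth,
    build_connectome,
    coc,
    make_cohort,
    make_lesion,
    make_parcellation,
    make_tractogram,
    simulate_behaviour,
)


class TestMakeParcellation:
    def test_construction_contract(self):
        parc = make_parcellation(6, 4, voxel_size_mm=2.0, seed=1)
        labels = set(np.unique(parc.labels)) - {0}
        assert len(labels) == 10
        for lab in labels:
            assert parc.names[lab]
            assert parc.hemisphere[lab] in ("left", "right")
        # disjoint supports are implied by a single label volume; check sizes
        sizes = [(parc.labels == lab).sum() for lab in labels]
        assert len(set(sizes)) == 1  # identical blocks
        # the affine maps voxel (0,0,0) to a defined mm origin
        origin = parc.voxel_to_mm([0, 0, 0])[0]
        assert np.all(np.isfinite(origin))

    def test_hemisphere_sides_of_midline(self):
        parc = make_parcellation(6, 4, voxel_size_mm=2.0, seed=1)
        for lab in parc.roi_labels:
            xs = parc.voxel_to_mm(np.argwhere(parc.labels == lab))[:, 0]
            if parc.hemisphere[lab] == "right":
                assert np.all(xs > 0)
            else:
                assert np.all(xs < 0)

    def test_determinism(self):
        a = make_parcellation(6, 4, 2.0, seed=1)
        b = make_parcellation(6, 4, 2.0, seed=1)
        assert np.array_equal(a.labels, b.labels)
        assert a.names == b.names

    def test_impossible_packing_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            make_parcellation(500, 2, 2.0, seed=0, shape=(20, 20, 20))


class TestMakeTractogram:
    def test_round_trip_counts(self, toy_parcellation):
        spec = {(1, 2): 5}
        sls = make_tractogram(toy_parcellation, spec, wobble_sd_mm=0.0, seed=0)
        assert len(sls) == 5
        cm = build_connectome(toy_parcellation, sls)
        assert cm.get(1, 2) == 5
        assert cm.total() == 5

    def test_zero_wobble_shares_corridor(self, toy_parcellation):
        """Without wobble a bundle's streamlines share one corridor; only the
        entry/exit near the endpoints differs."""
        sls = make_tractogram(toy_parcellation, {(1, 3): 4}, wobble_sd_mm=0.0, seed=0)
        ref = sls[0]
        for sl in sls[1:]:
            # middle third of each streamline lies on the shared corridor
            mid = sl[len(sl) // 3 : 2 * len(sl) // 3]
            d = np.linalg.norm(mid[:, None, :] - ref[None, :, :], axis=2).min(axis=1)
            assert d.max() < 0.6  # within one densification step of the corridor

    def test_determinism_and_unknown_pair(self, toy_parcellation):
        spec = {(1, 2): 3, (1, 4): 2}
        a = make_tractogram(toy_parcellation, spec, wobble_sd_mm=0.4, seed=9)
        b = make_tractogram(toy_parcellation, spec, wobble_sd_mm=0.4, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        with pytest.raises(ConfigurationError):
            make_tractogram(toy_parcellation, {(1, 99): 1}, seed=0)

    def test_vertex_spacing_bound(self, toy_parcellation):
        sls = make_tractogram(toy_parcellation, {(1, 2): 2}, wobble_sd_mm=0.0, seed=0)
        bound = 0.5 * toy_parcellation.voxel_size.min()
        for sl in sls:
            steps = np.linalg.norm(np.diff(sl, axis=0), axis=1)
            assert np.all(steps <= bound + 1e-9)


class TestMakeLesion:
    def test_single_voxel_lesion(self, toy_parcellation):
        centre = toy_parcellation.voxel_to_mm([5, 5, 4])[0]
        lesion = make_lesion(toy_parcellation, centre, [0.1, 0.1, 0.1])
        assert lesion.n_voxels == 1

    def test_saturating_lesion_covers_volume(self, toy_parcellation):
        lesion = make_lesion(toy_parcellation, [0.0, 0.0, 0.0], [1e4, 1e4, 1e4])
        assert lesion.n_voxels == np.prod(toy_parcellation.shape)

    def test_empty_lesion_raises(self, toy_parcellation):
        centre = toy_parcellation.voxel_to_mm([5, 5, 4])[0] + 0.9
        with pytest.raises(EmptyLesionError):
            make_lesion(toy_parcellation, centre, [0.05, 0.05, 0.05])

    def test_determinism_with_roughening(self, toy_parcellation):
        a = make_lesion(toy_parcellation, [5.0, 0.0, 0.0], [6, 6, 6], seed=3, roughen_sd=0.2)
        b = make_lesion(toy_parcellation, [5.0, 0.0, 0.0], [6, 6, 6], seed=3, roughen_sd=0.2)
        assert np.array_equal(a.mask, b.mask)


class TestSimulateBehaviour:
    def gt(self, weights, noise_sd=0.0, seed=0):
        return GroundTruth(
            critical_links=set(weights),
            effect_weights=weights,
            noise_sd=noise_sd,
            seed=seed,
        )

    def test_null_cohort_scores_zero(self):
        gt = self.gt({(1, 2): 0.4, (3, 4): 0.4})
        records = simulate_behaviour(
            [{(1, 2): 0.0, (3, 4): 0.0}] * 5, gt
        )
        assert all(r.coc_compound == 0.0 for r in records)
        assert not any(r.neglect for r in records)

    def test_single_fully_disconnected_link(self):
        gt = self.gt({(1, 2): 0.4})
        (record,) = simulate_behaviour([{(1, 2): 1.0}], gt)
        assert record.coc_compound == pytest.approx(0.4)
        assert record.neglect

    def test_fraction_out_of_range_rejected(self):
        gt = self.gt({(1, 2): 0.4})
        with pytest.raises(DataContractError):
            simulate_behaviour([{(1, 2): 1.5}], gt)
        with pytest.raises(DataContractError):
            simulate_behaviour([{}], gt)  # missing critical fraction

    def test_monte_carlo_correlation_with_weighted_fractions(self, rng):
        """n=200, noise_sd=0.1, two critical links: corr(score, signal) > 0.8."""
        gt = self.gt({(1, 2): 0.4, (3, 4): 0.4}, noise_sd=0.1, seed=11)
        fractions = [
            {(1, 2): float(rng.uniform()), (3, 4): float(rng.uniform())}
            for _ in range(200)
        ]
        records = simulate_behaviour(fractions, gt)
        signal = np.array([0.4 * f[(1, 2)] + 0.4 * f[(3, 4)] for f in fractions])
        scores = np.array([r.coc_compound for r in records])
        assert np.corrcoef(signal, scores)[0, 1] > 0.8

    def test_sheet_expansion_is_scoreable_and_monotone(self):
        gt = self.gt({(1, 2): 0.9}, noise_sd=0.0, seed=4)
        fractions = [{(1, 2): f} for f in (0.0, 0.5, 1.0)]
        records = simulate_behaviour(fractions, gt, expand_sheets=True)
        compounds = [r.coc_compound for r in records]
        assert compounds[0] < compounds[-1]
        assert records[0].coc_compound == pytest.approx(0.0, abs=0.05)


class TestMakeCohort:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        return make_cohort(
            n_patients=12,
            n_right_rois=6,
            n_left_rois=3,
            n_links=10,
            streamlines_per_bundle=(10, 20),
            n_critical_links=2,
            seed=5,
        )

    def test_structure_and_invariants(self, small_cohort):
        c = small_cohort
        assert c.n_patients == 12
        assert len(c.behaviour) == len(c.lesions)
        shape = np.array(c.parcellation.shape)
        for lesion in c.lesions:
            assert lesion.mask.shape == c.parcellation.shape
            assert lesion.n_voxels > 0
            # right-hemisphere stroke sample: no lesion left of the midline
            xs = c.parcellation.voxel_to_mm(np.argwhere(lesion.mask))[:, 0]
            assert np.all(xs >= 0)
        for link in c.ground_truth.critical_links:
            assert c.normative.get(*link) > 0
        assert all(w > 0 for w in c.ground_truth.effect_weights.values())

    def test_determinism(self, small_cohort):
        again = make_cohort(
            n_patients=12,
            n_right_rois=6,
            n_left_rois=3,
            n_links=10,
            streamlines_per_bundle=(10, 20),
            n_critical_links=2,
            seed=5,
        )
        assert np.array_equal(again.parcellation.labels, small_cohort.parcellation.labels)
        assert all(
            np.array_equal(a.mask, b.mask)
            for a, b in zip(again.lesions, small_cohort.lesions)
        )
        assert [r.coc_compound for r in again.behaviour] == [
            r.coc_compound for r in small_cohort.behaviour
        ]
        assert again.ground_truth.critical_links == small_cohort.ground_truth.critical_links

    def test_null_cohort_breaks_anatomy_behaviour_link(self):
        c = make_cohort(
            n_patients=20,
            n_right_rois=6,
            n_left_rois=3,
            n_links=10,
            streamlines_per_bundle=(10, 20),
            n_critical_links=2,
            null_behaviour=True,
            seed=6,
        )
        scores = np.array([r.coc_compound for r in c.behaviour])
        fractions = np.array(
            [
                [d.get(*link) / c.normative.get(*link) for link in sorted(c.ground_truth.critical_links)]
                for d in c.disconnectomes
            ]
        )
        # scores vary (noise) but carry no anatomical signal by construction
        assert scores.std() > 0
        r = np.corrcoef(fractions.sum(axis=1), scores)[0, 1]
        assert abs(r) < 0.5  # loose: n=20 null correlation

    def test_zero_patients_rejected(self):
        with pytest.raises(ConfigurationError):
            make_cohort(n_patients=0, seed=1)
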