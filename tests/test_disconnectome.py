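"""Lesion intersection, spared connectomes, conservation and feature assembly."""

import numpy as np
import pytest

from disconnectomics import (
    CohortDisconnectomePipeline,
    DataContractError,
    GridMismatchError,
    LesionMask,
    assemble_features,
    build_connectome,
    make_lesion,
    patient_disconnectome,
    spared_connectome,
    streamline_hits_lesion,
)
from disconnectomics.connectome import ConnectomeMatrix


def lesion_from_mask(parc, mask, pid="p0"):
    return LesionMask(mask=mask, affine=parc.affine, patient_id=pid)


def brute_force_hits(streamline, lesion, parc, step=0.004):
    """Oracle: rasterize every segment at a very fine step and test voxels."""
    sl = np.asarray(streamline, float)
    pts = []
    for p, q in zip(sl[:-1], sl[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(q - p) / step)) + 1)
        pts.append(np.linspace(p, q, n))
    pts = np.vstack(pts)
    ijk = np.round(parc.mm_to_voxel(pts)).astype(int)
    shape = np.array(parc.shape)
    ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
    ijk = ijk[ok]
    return bool(lesion.mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]].any())


class TestStreamlineHitsLesion:
    def test_empty_lesion_never_hits(self, toy_parcellation, toy_bundles):
        _, streamlines = toy_bundles
        empty = lesion_from_mask(
            toy_parcellation, np.zeros(toy_parcellation.shape, bool)
        )
        assert not any(
            streamline_hits_lesion(sl, empty, toy_parcellation) for sl in streamlines
        )

    def test_vertex_in_lesioned_voxel_hits(self, toy_parcellation, toy_bundles):
        _, streamlines = toy_bundles
        sl = streamlines[0]
        mid = sl[len(sl) // 2]
        ijk = np.round(toy_parcellation.mm_to_voxel(mid)[0]).astype(int)
        mask = np.zeros(toy_parcellation.shape, bool)
        mask[tuple(ijk)] = True
        assert streamline_hits_lesion(sl, lesion_from_mask(toy_parcellation, mask), toy_parcellation)

    def test_thin_wall_between_vertices_is_caught(self, toy_parcellation):
        """A 1-voxel wall crossed between two distant vertices must register."""
        shape = toy_parcellation.shape
        mask = np.zeros(shape, bool)
        mask[shape[0] // 2, :, :] = True
        wall = lesion_from_mask(toy_parcellation, mask)
        p = toy_parcellation.voxel_to_mm([0, shape[1] // 2, shape[2] // 2])[0]
        q = toy_parcellation.voxel_to_mm([shape[0] - 1, shape[1] // 2, shape[2] // 2])[0]
        sl = np.array([p, q])  # two vertices only, wall in between
        assert streamline_hits_lesion(sl, wall, toy_parcellation)
        assert brute_force_hits(sl, wall, toy_parcellation)

    def test_grid_mismatch_rejected(self, toy_parcellation):
        bad = LesionMask(
            mask=np.zeros((3, 3, 3), bool), affine=np.eye(4), patient_id="bad"
        )
        sl = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        with pytest.raises(GridMismatchError):
            streamline_hits_lesion(sl, bad, toy_parcellation)

    def test_agrees_with_fine_rasterization_on_random_scenes(
        self, toy_parcellation, rng
    ):
        """>= 100 randomized lesion/streamline scenes, exact agreement."""
        shape = toy_parcellation.shape
        extent = toy_parcellation.voxel_to_mm(np.array(shape) - 1)[0]
        origin = toy_parcellation.voxel_to_mm([0, 0, 0])[0]
        n_agree = 0
        for _ in range(120):
            mask = rng.random(shape) < 0.03
            lesion = lesion_from_mask(toy_parcellation, mask)
            sl = rng.uniform(origin, extent, size=(rng.integers(2, 6), 3))
            got = streamline_hits_lesion(sl, lesion, toy_parcellation)
            want = brute_force_hits(sl, lesion, toy_parcellation)
            assert got == want
            n_agree += 1
        assert n_agree == 120


class TestSparedAndDisconnectome:
    def test_empty_lesion_spares_everything(self, toy_parcellation, toy_bundles):
        _, streamlines = toy_bundles
        normative = build_connectome(toy_parcellation, streamlines)
        empty = lesion_from_mask(toy_parcellation, np.zeros(toy_parcellation.shape, bool))
        spared = spared_connectome(toy_parcellation, streamlines, empty)
        assert np.array_equal(spared.counts, normative.counts)
        assert patient_disconnectome(normative, spared).counts.sum() == 0

    def test_partial_and_total_disconnection(self, toy_parcellation, toy_bundles):
        spec, streamlines = toy_bundles
        normative = build_connectome(toy_parcellation, streamlines)
        # lesion = the full corridor of bundle (1, 2): everything disconnected
        full = lesion_from_mask(toy_parcellation, np.ones(toy_parcellation.shape, bool))
        spared = spared_connectome(toy_parcellation, streamlines, full)
        assert spared.counts.sum() == 0
        disc = patient_disconnectome(normative, spared)
        assert np.array_equal(disc.counts, normative.counts)

    def test_lesion_removing_some_streamlines_counts_exactly(
        self, toy_parcellation, toy_bundles
    ):
        spec, streamlines = toy_bundles
        normative = build_connectome(toy_parcellation, streamlines)
        # lesion covering two specific streamlines of bundle (1, 2) mid-course
        targets = [sl for sl in streamlines[:5]][:2]
        mask = np.zeros(toy_parcellation.shape, bool)
        for sl in targets:
            ijk = np.round(toy_parcellation.mm_to_voxel(sl[len(sl) // 2])[0]).astype(int)
            mask[tuple(ijk)] = True
        lesion = lesion_from_mask(toy_parcellation, mask)
        spared = spared_connectome(toy_parcellation, streamlines, lesion)
        disc = patient_disconnectome(normative, spared)
        # brute-force oracle: count removed streamlines per link
        removed = sum(
            1 for sl in streamlines if brute_force_hits(sl, lesion, toy_parcellation)
        )
        assert disc.counts.sum() // 2 == removed

    def test_inconsistent_spared_raises(self, toy_parcellation, toy_bundles):
        _, streamlines = toy_bundles
        normative = build_connectome(toy_parcellation, streamlines)
        bigger = ConnectomeMatrix(normative.counts * 2, normative.roi_order)
        with pytest.raises(DataContractError):
            patient_disconnectome(normative, bigger)

    def test_conservation_and_monotonicity(self, toy_parcellation, toy_bundles, rng):
        _, streamlines = toy_bundles
        pipe = CohortDisconnectomePipeline(toy_parcellation, streamlines)
        centre = np.array([10.0, 0.0, 0.0])
        small = make_lesion(toy_parcellation, centre, [6.0, 6.0, 6.0], patient_id="s")
        big = make_lesion(toy_parcellation, centre, [12.0, 12.0, 12.0], patient_id="b")
        assert np.all(big.mask >= small.mask)
        for lesion in (small, big):
            spared = pipe.spared(lesion)
            disc = pipe.disconnectome(lesion)
            assert np.array_equal(
                pipe.normative.counts, spared.counts + disc.counts
            )
        assert np.all(
            pipe.disconnectome(big).counts >= pipe.disconnectome(small).counts
        )

    def test_fast_path_equals_reference_path(self, toy_parcellation, toy_bundles, rng):
        """The precomputed cohort pipeline must equal filter-then-count exactly."""
        _, streamlines = toy_bundles
        pipe = CohortDisconnectomePipeline(toy_parcellation, streamlines)
        for k in range(5):
            mask = rng.random(toy_parcellation.shape) < 0.05
            lesion = lesion_from_mask(toy_parcellation, mask, pid=f"p{k}")
            ref = spared_connectome(toy_parcellation, streamlines, lesion)
            assert np.array_equal(pipe.spared(lesion).counts, ref.counts)


class TestAssembleFeatures:
    def make_disc(self, roi_order, entries):
        n = len(roi_order)
        counts = np.zeros((n, n), int)
        index = {l: i for i, l in enumerate(roi_order)}
        for (a, b), v in entries.items():
            counts[index[a], index[b]] = v
            counts[index[b], index[a]] = v
        return ConnectomeMatrix(counts, list(roi_order))

    def test_single_altered_right_link(self):
        hemi = {1: "right", 2: "right", 3: "left"}
        d = self.make_disc([1, 2, 3], {(1, 2): 4})
        feats = assemble_features([d], hemi)
        assert feats.matrix.shape == (1, 1)
        assert feats.link_index == [(1, 2)]
        assert feats.matrix[0, 0] == 4

    def test_left_left_links_dropped(self):
        hemi = {1: "right", 2: "left", 3: "left"}
        d = self.make_disc([1, 2, 3], {(2, 3): 5, (1, 2): 2})
        feats = assemble_features([d], hemi)
        assert feats.link_index == [(1, 2)]

    def test_midline_links_kept(self):
        hemi = {1: "midline", 2: "left", 3: "right"}
        d = self.make_disc([1, 2, 3], {(1, 2): 5})
        feats = assemble_features([d], hemi)
        assert feats.link_index == [(1, 2)]

    def test_reciprocal_links_collapse_to_one_column(self):
        hemi = {1: "right", 2: "right"}
        d = self.make_disc([1, 2], {(1, 2): 3})  # symmetric entries (1,2) and (2,1)
        feats = assemble_features([d, d], hemi)
        assert feats.matrix.shape == (2, 1)

    def test_all_zero_links_dropped_and_empty_cohort_rejected(self):
        hemi = {1: "right", 2: "right", 3: "right"}
        d1 = self.make_disc([1, 2, 3], {(1, 2): 1})
        d2 = self.make_disc([1, 2, 3], {(1, 2): 2})
        feats = assemble_features([d1, d2], hemi)
        assert feats.link_index == [(1, 2)]
        with pytest.raises(DataContractError):
            assemble_features([], hemi)
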