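"""Head/tail estimation and contact segmentation on straight phantoms."""

import numpy as np
import pytest

from seegseg import (
    CubicRegion,
    ElectrodeNotFoundError,
    PhantomElectrode,
    PhantomSpec,
    PlannedTrajectory,
    SegmentationConfig,
    default_model,
    displace_target,
    estimate_head,
    estimate_tail,
    make_phantom,
    segment_implant,
)

S = 1600.0
CFG = SegmentationConfig(threshold=S)


@pytest.fixture(scope="module")
def head_phantom():
    """Noise-free single electrode whose screw sits on a voxel center."""
    model = default_model(8)
    entry = np.array([10.0, 10.0, 24.0])      # exact voxel center
    target = entry + (3 + 2 + 7 * 3.5) * np.array([1.0, 0.0, 0.0])
    spec = PhantomSpec(shape=(120, 60, 60),
                       electrodes=[PhantomElectrode("A", entry, target, model)],
                       seed=0, noise_level=0.0)
    vol, truth = make_phantom(spec)
    return vol, truth, entry


class TestEstimateHead:
    def test_matches_blob_centroid_oracle(self, head_phantom):
        """Planned entry 2 mm off the screw: H lands on the screw blob's
        above-threshold mass centroid."""
        vol, truth, screw = head_phantom
        planned = screw + np.array([0.0, 2.0, 0.0])
        head = estimate_head(vol, planned, S, config=CFG)
        values, coords = vol.region_voxels(CubicRegion(screw, 5.0), above=S)
        oracle = coords.T @ values / values.sum()
        assert np.linalg.norm(head - oracle) < 1e-3

    def test_entry_at_blob_centroid_is_fixed_point(self, head_phantom):
        vol, truth, screw = head_phantom
        head = estimate_head(vol, screw, S, config=CFG)
        np.testing.assert_allclose(head, screw, atol=1e-6)

    def test_nothing_within_ten_mm_raises(self, head_phantom):
        vol, _, _ = head_phantom
        with pytest.raises(ElectrodeNotFoundError):
            estimate_head(vol, np.array([40.0, 20.0, 40.0]), S, config=CFG)


class TestEstimateTail:
    def test_tip_reaches_deepest_contact(self, straight_case, seg_config):
        """On straight shafts the last axis point lies within half a voxel
        pitch of the deepest contact's rasterization centroid."""
        vol, truth = straight_case["vol"], straight_case["truth"]
        for traj in truth.trajectories:
            head = estimate_head(vol, traj.entry, S, config=seg_config)
            tip, axis = estimate_tail(vol, head, traj.target, S,
                                      model=truth.models[traj.label],
                                      config=seg_config)
            assert np.linalg.norm(tip - truth.contacts[traj.label][0]) < 0.4
            assert len(axis) >= truth.models[traj.label].n_contacts

    def test_empty_volume_raises(self):
        from seegseg import VoxelVolume

        vol = VoxelVolume(np.zeros((40, 40, 40)), np.diag([0.4, 0.4, 0.8, 1.0]))
        with pytest.raises(ElectrodeNotFoundError):
            estimate_tail(vol, np.array([2.0, 2.0, 2.0]),
                          np.array([12.0, 12.0, 12.0]), S, config=CFG)


class TestSegmentImplant:
    def test_all_contacts_recovered_with_submillimetre_error(self, straight_case,
                                                             seg_config):
        vol, truth = straight_case["vol"], straight_case["truth"]
        implant = segment_implant(vol, truth.trajectories,
                                  models=truth.models, config=seg_config)
        assert not implant.failures
        errors = []
        for label, expected in truth.contacts.items():
            elec = implant.get(label)
            assert elec.n_contacts == len(expected)
            errors.append(np.linalg.norm(elec.contacts - expected, axis=1))
        errors = np.concatenate(errors)
        assert errors.mean() < 0.4
        assert errors.max() < 0.5

    def test_contacts_ordered_tip_first(self, straight_case, seg_config):
        vol, truth = straight_case["vol"], straight_case["truth"]
        implant = segment_implant(vol, truth.trajectories,
                                  models=truth.models, config=seg_config)
        for elec in implant.electrodes:
            depth = np.linalg.norm(elec.contacts - elec.head, axis=1)
            assert np.all(np.diff(depth) < 0)  # contact 1 deepest

    def test_contact_spacing_conserved_on_undistorted_shafts(self, aligned_case,
                                                             seg_config):
        vol, truth = aligned_case["vol"], aligned_case["truth"]
        implant = segment_implant(vol, truth.trajectories,
                                  models=truth.models, config=seg_config)
        for elec in implant.electrodes:
            spacing = np.linalg.norm(np.diff(elec.contacts, axis=0), axis=1)
            d = truth.models[elec.label].spacing
            assert np.abs(spacing - d).max() < 0.2

    def test_perpendicular_target_displacement_leaves_result_unchanged(
            self, straight_case, seg_config):
        """A 12 mm perpendicular target error must not move any contact:
        the walk re-locks onto the same shaft from the first step."""
        vol, truth = straight_case["vol"], straight_case["truth"]
        baseline = segment_implant(vol, truth.trajectories,
                                   models=truth.models, config=seg_config)
        rng = np.random.default_rng(42)
        displaced = [
            PlannedTrajectory(t.label, t.entry,
                              displace_target(t.entry, t.target, 12.0, rng))
            for t in truth.trajectories
        ]
        moved = segment_implant(vol, displaced, models=truth.models,
                                config=seg_config)
        for elec in baseline.electrodes:
            other = moved.get(elec.label)
            assert other.n_contacts == elec.n_contacts
            dist = np.linalg.norm(other.contacts - elec.contacts, axis=1)
            assert dist.max() < 1e-3

    def test_rerun_is_bitwise_identical(self, straight_case, seg_config):
        vol, truth = straight_case["vol"], straight_case["truth"]
        a = segment_implant(vol, truth.trajectories, models=truth.models,
                            config=seg_config)
        b = segment_implant(vol, truth.trajectories, models=truth.models,
                            config=seg_config)
        for ea, eb in zip(a.electrodes, b.electrodes):
            np.testing.assert_array_equal(ea.contacts, eb.contacts)
            np.testing.assert_array_equal(ea.axis.points, eb.axis.points)

    def test_empty_trajectory_list_warns(self, straight_case, seg_config):
        with pytest.warns(UserWarning, match="empty"):
            implant = segment_implant(straight_case["vol"], [], config=seg_config)
        assert implant.electrodes == [] and not implant.failures

    def test_duplicate_labels_rejected(self, straight_case, seg_config):
        traj = straight_case["truth"].trajectories[0]
        with pytest.raises(ValueError, match="duplicate"):
            segment_implant(straight_case["vol"], [traj, traj], config=seg_config)

    def test_failed_electrode_does_not_abort_the_run(self, straight_case,
                                                     seg_config):
        vol, truth = straight_case["vol"], straight_case["truth"]
        good = truth.trajectories[0]
        bad = PlannedTrajectory("Z", entry=np.array([70.0, 54.0, 78.0]),
                                target=np.array([50.0, 54.0, 78.0]))
        implant = segment_implant(vol, [good, bad],
                                  models=truth.models, config=seg_config)
        assert "Z" in implant.failures
        assert implant.get(good.label).n_contacts == \
            truth.models[good.label].n_contacts

    def test_detections_beyond_model_count_are_flagged_not_kept(
            self, straight_case, seg_config):
        vol, truth = straight_case["vol"], straight_case["truth"]
        traj = truth.trajectories[0]
        true_n = truth.models[traj.label].n_contacts
        short_model = default_model(true_n - 2)
        implant = segment_implant(vol, [traj], models=short_model,
                                  config=seg_config)
        elec = implant.get(traj.label)
        assert elec.n_contacts == true_n - 2
        assert len(elec.extras) >= 1

    def test_without_model_walk_runs_to_signal_loss(self, straight_case,
                                                    seg_config):
        vol, truth = straight_case["vol"], straight_case["truth"]
        traj = truth.trajectories[0]
        implant = segment_implant(vol, [traj], models=None, config=seg_config)
        assert implant.get(traj.label).n_contacts == \
            truth.models[traj.label].n_contacts
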