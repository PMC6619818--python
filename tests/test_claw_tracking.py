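"""Body pose, tip detection, identity assignment, corrections."""

import itertools

import numpy as np
import pytest

from clawtrack.claw_tracking import (
    BodyPose,
    Correction,
    InitializationError,
    TipSet,
    apply_corrections,
    assign_tips,
    body_pose,
    find_claw_candidates,
    from_body_frame,
    initialize_tracks,
    to_body_frame,
    track_claws,
)
from clawtrack.imaging_io import SilhouetteMask
from clawtrack.leg_segmentation import LegSegmentation


def _ellipse_mask(angle_deg=0.0, centre=(100, 100), a=60, b=20, size=200):
    yy, xx = np.mgrid[0:size, 0:size]
    ang = np.radians(angle_deg)
    uy = np.array([np.sin(ang), -np.cos(ang)])  # axis tilted off image-y
    ux = np.array([-uy[1], uy[0]])
    dx, dy = xx - centre[0], yy - centre[1]
    along = dx * uy[0] + dy * uy[1]
    across = dx * ux[0] + dy * ux[1]
    return (along / a) ** 2 + (across / b) ** 2 <= 1


class TestBodyPose:
    def test_axis_aligned_ellipse_has_zero_theta(self):
        p = body_pose(SilhouetteMask(_ellipse_mask(0.0), 0))
        assert p.theta == pytest.approx(0.0, abs=0.2)

    @pytest.mark.parametrize("angle", [30.0, -30.0, 60.0])
    def test_rotated_ellipse_recovers_angle(self, angle):
        p = body_pose(SilhouetteMask(_ellipse_mask(angle), 0))
        assert p.theta == pytest.approx(angle, abs=0.5)

    def test_translation_equivariance(self):
        p0 = body_pose(SilhouetteMask(_ellipse_mask(20.0, centre=(90, 95)), 0))
        p1 = body_pose(SilhouetteMask(_ellipse_mask(20.0, centre=(95, 102)), 0))
        np.testing.assert_allclose(p1.centroid - p0.centroid, [5.0, 7.0], atol=0.05)
        assert p1.theta == pytest.approx(p0.theta, abs=0.05)

    def test_motion_direction_orients_anterior(self):
        mask = SilhouetteMask(_ellipse_mask(0.0), 0)
        up = body_pose(mask, motion_dir=np.array([0.0, -1.0]))
        down = body_pose(mask, motion_dir=np.array([0.0, 1.0]))
        assert up.axis @ np.array([0, -1]) > 0.99
        assert down.axis @ np.array([0, 1]) > 0.99

    def test_degenerate_mask_carries_previous_theta(self):
        yy, xx = np.mgrid[0:50, 0:50]
        disk = (xx - 25) ** 2 + (yy - 25) ** 2 <= 15**2
        prev = body_pose(SilhouetteMask(_ellipse_mask(40.0), 0))
        p = body_pose(SilhouetteMask(disk, 1), prev=prev)
        assert p.theta == pytest.approx(prev.theta, abs=1e-6)


class TestBodyFrame:
    def _pose(self, axis=(0.0, -1.0), centroid=(100.0, 100.0)):
        a = np.asarray(axis, float)
        return BodyPose(np.asarray(centroid, float), 0.0, a / np.linalg.norm(a), 0)

    def test_centroid_maps_to_origin(self):
        pose = self._pose()
        np.testing.assert_allclose(to_body_frame(pose.centroid, pose), [0, 0], atol=1e-12)

    def test_no_rotation_offsets_pass_through(self):
        # anterior pointing "up" the image: +x lateral = image +x,
        # +y anterior = image -y (row indices grow downward)
        pose = self._pose(axis=(0, -1))
        np.testing.assert_allclose(
            to_body_frame(pose.centroid + np.array([3.0, -4.0]), pose), [3.0, 4.0]
        )

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(size=2)
            pose = self._pose(axis=a, centroid=rng.uniform(0, 200, 2))
            pts = rng.uniform(-50, 50, (10, 2))
            back = to_body_frame(from_body_frame(pts, pose), pose)
            np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_anterior_maps_to_positive_y(self):
        pose = self._pose(axis=(0.6, -0.8))
        ahead = pose.centroid + 10 * pose.axis
        assert to_body_frame(ahead, pose)[1] == pytest.approx(10.0)


def _seg_from_mask(mask, frame_index=0):
    from scipy import ndimage

    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return LegSegmentation(lab, sizes.astype(int), frame_index)


class TestFindClawCandidates:
    def _pose(self):
        return BodyPose(np.array([10.0, 32.0]), 0.0, np.array([0.0, -1.0]), 0)

    def test_straight_segment_tip_is_far_end(self):
        m = np.zeros((64, 64), bool)
        m[32, 20:40] = True
        tips = find_claw_candidates(_seg_from_mask(m), self._pose())
        assert len(tips) == 1
        np.testing.assert_allclose(tips.tips_arena[0], [39, 32])

    def test_l_shape_yields_single_distal_tip(self):
        m = np.zeros((64, 64), bool)
        m[32, 20:40] = True
        m[20:33, 39] = True  # turn upward: endpoints at (20,32) and (39,20)
        tips = find_claw_candidates(_seg_from_mask(m), self._pose())
        assert len(tips) == 1
        # brute-force oracle: farthest endpoint from the body centroid
        endpoints = np.array([[20, 32], [39, 20]], dtype=float)
        d = np.hypot(*(endpoints - [10, 32]).T)
        np.testing.assert_allclose(tips.tips_arena[0], endpoints[np.argmax(d)])

    def test_ring_component_emits_no_tip(self):
        yy, xx = np.mgrid[0:64, 0:64]
        r2 = (xx - 40) ** 2 + (yy - 32) ** 2
        ring = (r2 <= 12**2) & (r2 >= 8**2)
        tips = find_claw_candidates(_seg_from_mask(ring), self._pose())
        assert len(tips) == 0


def _tipset(body_pts, frame_index=0, pose=None):
    body_pts = np.asarray(body_pts, dtype=float).reshape(-1, 2)
    pose = pose or BodyPose(np.array([256.0, 256.0]), 0.0, np.array([0.0, -1.0]), frame_index)
    return TipSet(
        tips_body=body_pts,
        tips_arena=from_body_frame(body_pts, pose) if len(body_pts) else np.empty((0, 2)),
        component_of=np.arange(len(body_pts)),
        frame_index=frame_index,
    )


CANONICAL_STANCE = {
    "L1": (-45.0, 55.0), "L2": (-55.0, 3.0), "L3": (-46.0, -50.0),
    "R1": (45.0, 55.0), "R2": (55.0, 3.0), "R3": (46.0, -50.0),
}


class TestInitializeTracks:
    def test_canonical_stance_labels_match_geometry(self):
        order = ["R2", "L1", "L3", "R1", "L2", "R3"]  # scrambled tip order
        tips = _tipset([CANONICAL_STANCE[l] for l in order])
        tracks = initialize_tracks([tips], n_legs=6)
        assert tracks.init_frame == 0
        for j, leg in enumerate(tracks.legs):
            np.testing.assert_allclose(tracks.body[0, j], CANONICAL_STANCE[leg])

    def test_wrong_tip_count_everywhere_raises(self):
        tips = _tipset(list(CANONICAL_STANCE.values())[:5])
        with pytest.raises(InitializationError):
            initialize_tracks([tips, tips], n_legs=6)

    def test_mirrored_configuration_swaps_sides(self):
        mirrored = {l: (-x, y) for l, (x, y) in CANONICAL_STANCE.items()}
        tips = _tipset(list(mirrored.values()))
        tracks = initialize_tracks([tips], n_legs=6)
        for j, leg in enumerate(tracks.legs):
            twin = ("R" if leg[0] == "L" else "L") + leg[1]
            np.testing.assert_allclose(tracks.body[0, j], mirrored[twin])

    def test_manual_first_frame_seeds_identities(self):
        pts = [CANONICAL_STANCE[l] for l in ("L1", "L2", "R1", "R2")]
        tips = _tipset(pts)
        tracks = initialize_tracks(
            [tips], n_legs=4, legs=["L1", "L2", "R1", "R2"],
            manual_first_frame={l: CANONICAL_STANCE[l] for l in ("L1", "L2", "R1", "R2")},
        )
        np.testing.assert_allclose(tracks.body[0, 0], CANONICAL_STANCE["L1"])


def _brute_force_cost(sources, targets, gate=20.0):
    """Minimum total squared distance over injective gate-feasible matchings,
    maximizing the number of matches first (greedy cardinality like the
    two-pass tracker is not needed here: configurations keep all pairs
    feasible)."""
    m = len(targets)
    best = (0, 0.0)
    for perm in itertools.permutations(range(m), len(sources)):
        cost, matched = 0.0, 0
        for i, j in enumerate(perm):
            d2 = np.sum((sources[i] - targets[j]) ** 2)
            if d2 <= gate * gate:
                cost += d2
                matched += 1
        if matched > best[0] or (matched == best[0] and cost < best[1]):
            best = (matched, cost)
    return best


class TestAssignTips:
    def test_unmoved_tips_identity_assignment(self):
        pts = np.array(list(CANONICAL_STANCE.values()))
        new, matched, idx = assign_tips(pts, np.ones(6, bool), pts, _tipset(pts))
        assert matched.all()
        np.testing.assert_allclose(new, pts)

    def test_displacement_beyond_gate_goes_missing(self):
        pts = np.array(list(CANONICAL_STANCE.values()))
        moved = pts.copy()
        moved[0] += [25.0, 0.0]  # one tip jumps past the 20-px gate
        new, matched, _ = assign_tips(pts, np.ones(6, bool), pts, _tipset(moved))
        assert matched.sum() == 5
        assert not matched[0]

    def test_matches_brute_force_permutation_minimum(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            src = rng.uniform(-40, 40, (6, 2))
            tgt = src + rng.uniform(-10, 10, (6, 2))
            new, matched, idx = assign_tips(
                src, np.ones(6, bool), src, _tipset(tgt)
            )
            cost = sum(
                np.sum((tgt[idx[j]] - src[j]) ** 2) for j in range(6) if matched[j]
            )
            bf_matched, bf_cost = _brute_force_cost(src, tgt)
            assert matched.sum() == bf_matched
            assert cost == pytest.approx(bf_cost, rel=1e-9)

    def test_lost_leg_recovered_from_last_seen_position(self):
        pts = np.array(list(CANONICAL_STANCE.values()))
        active = np.ones(6, bool)
        active[2] = False  # L3 currently missing
        positions = pts.copy()
        positions[2] = np.nan
        last_seen = pts.copy()  # but its last seen position is known
        tips = _tipset(pts)  # all six tips reappear
        new, matched, _ = assign_tips(positions, active, last_seen, tips)
        assert matched.all()
        np.testing.assert_allclose(new[2], pts[2])


class TestCorrections:
    def _scripted_scenario(self):
        """L1 is hijacked by a distractor object; R1 is a stable anchor."""
        n = 30
        pose = BodyPose(np.array([256.0, 256.0]), 0.0, np.array([0.0, -1.0]), 0)
        poses = [
            BodyPose(pose.centroid, 0.0, pose.axis, i) for i in range(n)
        ]
        L1, R1, D = (-10.0, 5.0), (10.0, 5.0), (-24.0, 5.0)
        tipsets = []
        for i in range(n):
            pts = [R1]
            if i < 10:
                pts.append(L1)  # true leg visible
            elif i < 20:
                pts.append(D)  # leg occluded, distractor present (14 px away)
            else:
                pts.extend([D, L1])  # leg back; distractor persists
            tipsets.append(_tipset(pts, frame_index=i, pose=pose))
        tracks = track_claws(tipsets, poses, n_legs=2)
        return tracks, tipsets, poses, (L1, R1, D)

    def test_empty_fix_list_is_identity(self):
        tracks, tipsets, poses, _ = self._scripted_scenario()
        same = apply_corrections(tracks, [], tipsets, poses)
        np.testing.assert_array_equal(same.body, tracks.body)

    def test_distractor_hijacks_track_without_correction(self):
        tracks, _, _, (L1, R1, D) = self._scripted_scenario()
        j = tracks.legs.index("L1")
        np.testing.assert_allclose(tracks.body[25, j], D)  # stuck on distractor

    def test_correction_relocks_onto_reappearing_leg(self):
        tracks, tipsets, poses, (L1, R1, D) = self._scripted_scenario()
        j = tracks.legs.index("L1")
        # correction > 20 px from the distractor, < 20 px from reappearance
        fix = Correction(frame_index=15, leg="L1",
                         x=256.0 - 2.0, y=256.0 - 5.0)  # body (-2, 5)
        fixed = apply_corrections(tracks, [fix], tipsets, poses)
        assert np.all(fixed.missing[16:20, j])  # distractor now out of gate
        np.testing.assert_allclose(fixed.body[25, j], L1)  # re-locked

    def test_absent_mark_until_reappearance(self):
        tracks, tipsets, poses, (L1, R1, D) = self._scripted_scenario()
        j = tracks.legs.index("L1")
        fix = Correction(frame_index=5, leg="L1")  # mark absent
        fixed = apply_corrections(tracks, [fix], tipsets, poses)
        assert fixed.missing[5, j]
        # true tip at frames 6-9 sits within the gate of the last seen
        # position, so the leg re-locks immediately after
        assert not fixed.missing[6, j]

    def test_out_of_image_correction_rejected(self):
        tracks, tipsets, poses, _ = self._scripted_scenario()
        with pytest.raises(ValueError, match="outside"):
            apply_corrections(
                tracks, [Correction(3, "L1", 9999.0, 10.0)], tipsets, poses
            )


class TestGateInvariant:
    def test_no_matched_step_exceeds_gate_on_scripted_tracks(self):
        tracks, *_ = TestCorrections()._scripted_scenario()
        for j in range(len(tracks.legs)):
            p = tracks.body[:, j]
            ok = np.isfinite(p[:-1, 0]) & np.isfinite(p[1:, 0])
            steps = np.hypot(*(p[1:] - p[:-1]).T)[ok]
            assert np.all(steps <= tracks.gate_px + 1e-9)
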