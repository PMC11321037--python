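"""Chromatin mobility: registration, detection, linking, CD(tau) and the
power-law fit."""

import numpy as np
import pytest

from mscstage.mobility import (
    CDCurve,
    compare_conditions,
    compute_cd,
    detect_puncta,
    ensemble_cd,
    fit_power_law,
    fit_power_law_nls,
    link_tracks,
    register_frames,
    remove_motion,
)
from mscstage.synthetic import (
    RigidMotion,
    Trajectory,
    TrajectoryParams,
    apply_rigid_motion,
    generate_trajectories,
    render_puncta_movie,
)


def make_traj(positions, dt=180.0, tid=0):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return Trajectory(tid, np.arange(n), np.arange(n) * dt, positions)


class TestComputeCD:
    def test_static_particle_zero(self):
        cd = compute_cd(make_traj(np.zeros((10, 2))))
        assert np.all(cd.cd_um2 == 0)

    def test_ballistic_closed_form(self):
        v = 0.02
        t = np.arange(11) * 180.0
        traj = make_traj(np.column_stack([v * t, np.zeros_like(t)]))
        cd = compute_cd(traj)
        np.testing.assert_allclose(cd.cd_um2, v**2 * cd.lags_tau_s**2, rtol=1e-12)
        fit = fit_power_law(cd)
        assert fit.beta == pytest.approx(2.0, abs=1e-9)
        assert fit.d_eff == pytest.approx(v**2, rel=1e-9)

    def test_brownian_ensemble_matches_4dtau(self):
        rng = np.random.default_rng(0)
        D, dt = 0.005, 180.0
        trajs = []
        for k in range(500):
            steps = rng.normal(0, np.sqrt(2 * D * dt), size=(20, 2))
            pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            trajs.append(make_traj(pos, tid=k))
        ens = ensemble_cd([compute_cd(t) for t in trajs])
        np.testing.assert_allclose(ens.cd_um2, 4 * D * ens.lags_tau_s, rtol=0.10)

    def test_lag_grid_and_pair_counts(self):
        cd = compute_cd(make_traj(np.zeros((21, 2))), max_lag_fraction=0.5)
        assert len(cd.lags_tau_s) == 10
        assert cd.lags_tau_s[0] == 180.0
        assert np.all(np.diff(cd.n_pairs) < 0)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_cd(make_traj(np.zeros((2, 2))))

    def test_pixel_size_scaling(self):
        """Doubling the pixel size quadruples CD and leaves beta unchanged."""
        trajs = generate_trajectories(TrajectoryParams(seed=3, n_trajectories=50))
        ens1 = ensemble_cd([compute_cd(t) for t in trajs])
        doubled = [make_traj(t.positions * 2.0, tid=t.trajectory_id) for t in trajs]
        ens2 = ensemble_cd([compute_cd(t) for t in doubled])
        np.testing.assert_allclose(ens2.cd_um2, 4 * ens1.cd_um2, rtol=1e-12)
        assert fit_power_law(ens2).beta == pytest.approx(fit_power_law(ens1).beta, abs=1e-12)


class TestEnsembleCD:
    def test_single_curve_identity(self):
        c = CDCurve(np.array([180.0, 360.0, 540.0]), np.array([1.0, 2.0, 3.0]), np.array([5, 4, 3]))
        e = ensemble_cd([c])
        np.testing.assert_allclose(e.cd_um2, c.cd_um2)

    def test_two_identical_curves(self):
        c = CDCurve(np.array([180.0, 360.0, 540.0]), np.array([1.0, 2.0, 3.0]), np.array([5, 4, 3]))
        e = ensemble_cd([c, c])
        np.testing.assert_allclose(e.cd_um2, c.cd_um2)

    def test_mismatched_grids_rejected(self):
        a = CDCurve(np.array([180.0, 360.0, 540.0]), np.ones(3), np.ones(3, dtype=int))
        b = CDCurve(np.array([180.0, 360.0]), np.ones(2), np.ones(2, dtype=int))
        with pytest.raises(ValueError, match="lag"):
            ensemble_cd([a, b])


class TestFitPowerLaw:
    def test_exact_points_machine_precision(self):
        tau = np.arange(1, 11) * 180.0
        curve = CDCurve(tau, 0.01 * tau**0.5, np.full(10, 100))
        fit = fit_power_law(curve)
        assert fit.beta == pytest.approx(0.5, abs=1e-12)
        assert fit.d_eff == pytest.approx(0.01, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_simulated_beta_recovery(self):
        p = TrajectoryParams(d_eff=0.01, beta=1.0, n_trajectories=500, seed=11)
        ens = ensemble_cd([compute_cd(t) for t in generate_trajectories(p)])
        assert fit_power_law(ens).beta == pytest.approx(1.0, abs=0.1)

    def test_agrees_with_nonlinear_least_squares(self):
        p = TrajectoryParams(d_eff=0.01, beta=0.8, n_trajectories=1000, seed=12)
        ens = ensemble_cd([compute_cd(t) for t in generate_trajectories(p)])
        a = fit_power_law(ens)
        b = fit_power_law_nls(ens)
        assert a.r_squared > 0.99
        assert a.beta == pytest.approx(b.beta, rel=0.05)
        assert a.d_eff == pytest.approx(b.d_eff, rel=0.05)

    def test_too_few_lags_rejected(self):
        curve = CDCurve(np.array([180.0, 360.0, 540.0]), np.array([0.0, 0.0, 1.0]), np.ones(3, dtype=int))
        with pytest.raises(ValueError, match="lags"):
            fit_power_law(curve)


class TestRegistration:
    def _moved_setup(self, seed=0, n_trajs=12):
        trajs = generate_trajectories(
            TrajectoryParams(d_eff=0.005, beta=0.8, n_trajectories=n_trajs, seed=seed)
        )
        n_frames = trajs[0].n_frames
        rng = np.random.default_rng(seed + 1)
        angles = np.cumsum(rng.uniform(-0.05, 0.05, n_frames))
        angles[0] = 0.0
        trans = np.cumsum(rng.uniform(-1.0, 1.0, (n_frames, 2)), axis=0)
        trans[0] = 0.0
        motion = RigidMotion(angles, trans, center=(3.0, -2.0))
        moved = apply_rigid_motion(trajs, motion)
        return trajs, moved, motion

    def test_registration_reduces_apparent_motion(self):
        """With diffusing puncta the estimate is noisy, but correcting with
        it must bring the ensemble CD far closer to the unmoved truth than
        the corrupted data are."""
        trajs, moved, motion = self._moved_setup(n_trajs=40)
        pts = np.stack([t.positions for t in moved], axis=1)
        est, _ = register_frames(pts)
        restored = remove_motion(moved, est)
        cd_true = ensemble_cd([compute_cd(t) for t in trajs]).cd_um2
        cd_moved = ensemble_cd([compute_cd(t) for t in moved]).cd_um2
        cd_rest = ensemble_cd([compute_cd(t) for t in restored]).cd_um2
        err_moved = np.median(np.abs(cd_moved - cd_true) / cd_true)
        err_rest = np.median(np.abs(cd_rest - cd_true) / cd_true)
        assert err_rest < 0.2 * err_moved

    def test_identity_motion_estimated_as_identity(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 5, (6, 2))
        pts = np.tile(base, (8, 1, 1))
        est, corrected = register_frames(pts)
        assert np.allclose(est.angles_rad, 0, atol=1e-10)
        assert np.allclose(est.translations, 0, atol=1e-10)
        assert np.allclose(corrected, pts)

    def test_exact_recovery_of_static_points_under_motion(self):
        """Static puncta under pure rigid motion: registration inverts it
        to machine precision (angle < 0.5 deg, translation < 0.1 px)."""
        rng = np.random.default_rng(5)
        base = rng.normal(0, 10, (8, 2))
        n_frames = 10
        angles = np.deg2rad(3.0) * np.arange(n_frames)
        trans = np.column_stack([0.5 * np.arange(n_frames), -0.3 * np.arange(n_frames)])
        motion = RigidMotion(angles, trans, center=(0.0, 0.0))
        pts = np.stack([motion.apply(f, base) for f in range(n_frames)])
        est, corrected = register_frames(pts)
        true_angles, true_d = motion.as_global()
        assert np.max(np.abs(est.angles_rad - true_angles)) < np.deg2rad(0.5)
        assert np.max(np.abs(est.translations - true_d)) < 0.1
        assert np.allclose(corrected, np.tile(base, (n_frames, 1, 1)), atol=1e-8)

    def test_cd_restored_after_registration(self):
        """CD after removing an applied rigid nuclear motion matches the
        unmoved ground truth within 5% median relative error."""
        trajs, moved, motion = self._moved_setup(seed=2, n_trajs=40)
        pts = np.stack([t.positions for t in moved], axis=1)
        est, _ = register_frames(pts)
        restored = remove_motion(moved, est)
        cd_true = ensemble_cd([compute_cd(t) for t in trajs])
        cd_rest = ensemble_cd([compute_cd(t) for t in restored])
        rel = np.abs(cd_rest.cd_um2 - cd_true.cd_um2) / cd_true.cd_um2
        assert np.median(rel) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            register_frames(np.zeros((5, 2, 2)))

    def test_mask_registration_recovers_translation_and_rotation(self):
        from scipy import ndimage as ndi

        from mscstage.mobility import register_masks

        base = np.zeros((200, 200), dtype=float)
        rr, cc = np.mgrid[0:200, 0:200]
        base[((rr - 100) / 20) ** 2 + ((cc - 100) / 45) ** 2 <= 1] = 1.0
        masks = []
        shifts = [(0, 0), (3, -4), (6, -8)]
        angles_deg = [0.0, 5.0, 10.0]
        for (dr, dc), ang in zip(shifts, angles_deg):
            m = ndi.rotate(base, ang, reshape=False, order=1)
            m = ndi.shift(m, (dr, dc), order=1)
            masks.append(m > 0.5)
        est = register_masks(np.stack(masks))
        # scipy rotates CCW in (row, col); our angle is measured in (x, y)
        assert np.rad2deg(abs(est.angles_rad[1])) == pytest.approx(5.0, abs=1.0)
        assert np.rad2deg(abs(est.angles_rad[2])) == pytest.approx(10.0, abs=1.0)
        np.testing.assert_allclose(est.translations[1], [-4, 3], atol=1.0)
        np.testing.assert_allclose(est.translations[2], [-8, 6], atol=1.0)


class TestDetectLink:
    def test_detects_ground_truth_no_false_positives(self):
        rng = np.random.default_rng(6)
        trajs = [
            Trajectory(k, np.arange(5), np.arange(5) * 180.0, np.tile(rng.uniform(20, 100, 2), (5, 1)))
            for k in range(5)
        ]
        stack, coords = render_puncta_movie(trajs, shape=(128, 128), noise_sd=0.0)
        for t in range(stack.shape[0]):
            det, scores = detect_puncta(stack[t], expected_sigma_px=1.5)
            assert len(det) == 5
            for gt in coords[t]:
                assert np.min(np.linalg.norm(det - gt, axis=1)) <= 1.0

    def test_blank_frame_empty(self):
        det, scores = detect_puncta(np.full((64, 64), 10.0), expected_sigma_px=1.5)
        assert len(det) == 0

    def test_two_well_separated_spots(self):
        trajs = [
            Trajectory(0, np.arange(3), np.arange(3) * 180.0, np.tile([30.0, 30.0], (3, 1))),
            Trajectory(1, np.arange(3), np.arange(3) * 180.0, np.tile([90.0, 90.0], (3, 1))),
        ]
        stack, _ = render_puncta_movie(trajs, shape=(128, 128))
        det, _ = detect_puncta(stack[0], expected_sigma_px=1.5)
        assert len(det) == 2

    def test_static_spots_two_full_tracks(self):
        dets = [np.array([[20.0, 20.0], [80.0, 80.0]]) for _ in range(21)]
        tracks = link_tracks(dets, max_disp_px=5.0)
        assert len(tracks) == 2
        assert all(t.n_frames == 21 for t in tracks)

    def test_gap_bridged(self):
        dets = [np.array([[50.0, 50.0]]) for _ in range(10)]
        dets[4] = np.empty((0, 2))
        tracks = link_tracks(dets, max_disp_px=5.0, max_gap_frames=1)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 9

    def test_retrack_recovers_links_at_high_snr(self):
        trajs = generate_trajectories(
            TrajectoryParams(d_eff=0.02, beta=1.0, n_trajectories=6, start_spread_um=40.0, seed=8)
        )
        # offset into the frame; positions in um with 1 um/px
        shifted = [
            Trajectory(t.trajectory_id, t.frames, t.t_seconds, t.positions + 64.0) for t in trajs
        ]
        stack, coords = render_puncta_movie(shifted, shape=(128, 128), noise_sd=100.0,
                                            amplitude=1000.0, seed=9)
        dets = [detect_puncta(stack[t], expected_sigma_px=1.5)[0] for t in range(stack.shape[0])]
        tracks = link_tracks(dets, max_disp_px=6.0, min_length=5)
        n_links = 0
        n_recovered = 0
        for t in range(coords.shape[0] - 1):
            for p in range(coords.shape[1]):
                n_links += 1
                for tr in tracks:
                    fidx = {int(f): i for i, f in enumerate(tr.frames)}
                    if t in fidx and t + 1 in fidx:
                        if (
                            np.linalg.norm(tr.positions[fidx[t]] - coords[t, p]) <= 1.5
                            and np.linalg.norm(tr.positions[fidx[t + 1]] - coords[t + 1, p]) <= 1.5
                        ):
                            n_recovered += 1
                            break
        assert n_recovered / n_links >= 0.9


class TestCompareConditions:
    def _fits(self, d_effs, betas):
        from mscstage.mobility import PowerLawFit

        return [PowerLawFit(d, b, 0.99, (180.0, 1800.0), 10) for d, b in zip(d_effs, betas)]

    def test_identical_samples_p_one(self):
        fits = self._fits(np.full(5, 0.01), np.full(5, 0.8))
        res = compare_conditions(fits, fits)
        assert res["d_eff"]["p_value"] == 1.0
        assert res["d_eff"]["degenerate"]

    def test_shifted_distributions_significant(self):
        """0.5x median shift in d_eff at n = 12 per arm is detected."""
        rng = np.random.default_rng(13)
        a = self._fits(rng.lognormal(np.log(0.01), 0.3, 12), rng.normal(0.8, 0.1, 12))
        b = self._fits(rng.lognormal(np.log(0.005), 0.3, 12), rng.normal(0.8, 0.1, 12))
        res = compare_conditions(a, b)
        assert res["d_eff"]["significant"]
        assert res["d_eff"]["direction"] == -1
        assert not res["beta"]["significant"]
        # power at this effect size and n, by simulation
        hits = 0
        for rep in range(100):
            r2 = np.random.default_rng(1000 + rep)
            fa = self._fits(r2.lognormal(np.log(0.01), 0.3, 12), np.full(12, 0.8))
            fb = self._fits(r2.lognormal(np.log(0.005), 0.3, 12), np.full(12, 0.8))
            hits += compare_conditions(fa, fb)["d_eff"]["significant"]
        assert hits / 100 >= 0.8

    def test_label_swap_flips_direction(self):
        rng = np.random.default_rng(14)
        a = self._fits(rng.lognormal(np.log(0.01), 0.2, 10), np.full(10, 0.8))
        b = self._fits(rng.lognormal(np.log(0.004), 0.2, 10), np.full(10, 0.8))
        assert compare_conditions(a, b)["d_eff"]["direction"] == -compare_conditions(b, a)["d_eff"]["direction"]

    def test_minimum_group_size(self):
        f = self._fits([0.01, 0.02], [0.8, 0.9])
        with pytest.raises(ValueError, match="3"):
            compare_conditions(f, f)


class TestParameterRecoveryGrid:
    def test_median_errors_within_bounds(self):
        """Over (d_eff, beta) in {0.005, 0.01, 0.02} x {0.5, 1.0, 1.5}:
        median |beta error| <= 0.1 and median |d_eff error| <= 15%."""
        beta_errs, deff_errs = [], []
        for i, d in enumerate((0.005, 0.01, 0.02)):
            for j, b in enumerate((0.5, 1.0, 1.5)):
                p = TrajectoryParams(d_eff=d, beta=b, n_trajectories=500, seed=100 + 10 * i + j)
                ens = ensemble_cd([compute_cd(t) for t in generate_trajectories(p)])
                fit = fit_power_law(ens)
                beta_errs.append(abs(fit.beta - b))
                deff_errs.append(abs(fit.d_eff - d) / d)
        assert np.median(beta_errs) <= 0.1
        assert np.median(deff_errs) <= 0.15
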