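"""Inversion chain: Stokes filtering, cumulative rotation, compensation,
layer peeling, guide-star correction."""

import numpy as np
import pytest

from catheter_psoct import polarimetry as pol
from catheter_psoct.acquisition import (
    AcquisitionConfig,
    CatheterModel,
    INPUT_STOKES,
    simulate_pullback,
)
from catheter_psoct.phantom import LayerSpec, PhantomConfig, Trajectory, build_dbs_phantom
from catheter_psoct.reconstruction import (
    CumulativeMap,
    ReconstructionConfig,
    compensate_transmission,
    compute_stokes,
    estimate_cumulative,
    guide_star_correct,
    peel_layers,
    reconstruct_pullback,
)

from conftest import (
    NOISE_FREE_ACQ,
    NOISE_FREE_RECON,
    ang_diff_deg,
    pair_truth,
    short_phantom_config,
    tissue_mask,
)


class TestComputeStokes:
    def test_identity_sample_recovers_input_states(self):
        cfg = PhantomConfig(length_mm=2.0, layers=(LayerSpec("cortex_gm", 0, 2.0),),
                            inclusions=())
        ph = build_dbs_phantom(cfg, seed=0)
        acq = AcquisitionConfig(alines_per_frame=16, depth_range_mm=0.5, speckle=False,
                                detector_noise_sigma=0.0)
        with pytest.warns(UserWarning):
            raw = simulate_pullback(ph, Trajectory(length_mm=2.0),
                                    CatheterModel(sheath_retardance_rad=0.0,
                                                  offset_amplitude_deg=0.0,
                                                  drift_amplitude_deg=0.0),
                                    acq, seed=0)
        sv = compute_stokes(raw, ReconstructionConfig(**NOISE_FREE_RECON))
        for s in range(2):
            assert np.allclose(sv.states[0, ..., s, :], INPUT_STOKES[s], atol=1e-6)

    def test_zero_filter_width_equals_plain_stokes(self, oracle_run):
        raw, _ = oracle_run
        sv = compute_stokes(raw, ReconstructionConfig(axial_sigma_px=0.0,
                                                      lateral_sigma_pairs=0.0))
        h = raw.fields[0, :, 0::2, :, 0]
        v = raw.fields[0, :, 0::2, :, 1]
        manual = pol.stokes_from_fields(h, v)
        assert np.allclose(sv.states[0, ..., 0, :], manual.normalized().vec, atol=1e-9)
        assert np.allclose(sv.intensity[0, ..., 0], manual.intensity, atol=1e-9)

    def test_filtering_improves_noisy_states_monotonically(self):
        # angular error vs the noise-free states shrinks as lateral sigma grows
        cfg = PhantomConfig(length_mm=2.0, layers=(LayerSpec("wm", 0, 2.0),),
                            inclusions=())
        ph = build_dbs_phantom(cfg, seed=0)
        traj = Trajectory(length_mm=2.0)
        cat = CatheterModel(offset_amplitude_deg=0.0, drift_amplitude_deg=0.0)
        acq_clean = AcquisitionConfig(alines_per_frame=32, depth_range_mm=0.4,
                                      speckle=False, detector_noise_sigma=0.0)
        clean = simulate_pullback(ph, traj, cat, acq_clean, seed=0)
        ref = compute_stokes(clean, ReconstructionConfig(axial_sigma_px=0.0,
                                                         lateral_sigma_pairs=0.0))
        errors = {0.0: [], 2.0: [], 4.0: []}
        for seed in range(20):
            acq = AcquisitionConfig(alines_per_frame=32, depth_range_mm=0.4)
            noisy = simulate_pullback(ph, traj, cat, acq, seed=100 + seed)
            for sig in errors:
                sv = compute_stokes(noisy, ReconstructionConfig(axial_sigma_px=1.0,
                                                                lateral_sigma_pairs=sig))
                dot = np.clip(np.sum(sv.states * ref.states, axis=-1), -1, 1)
                errors[sig].append(np.rad2deg(np.arccos(dot)).mean())
        means = {sig: np.mean(v) for sig, v in errors.items()}
        assert means[0.0] > means[2.0] > means[4.0]


class TestEstimateCumulative:
    def test_noise_free_matches_forward_model(self, oracle_run):
        # oracle: recompose C(z) from the stored ground-truth layer stack
        raw, _ = oracle_run
        cfg = ReconstructionConfig(**NOISE_FREE_RECON)
        sv = compute_stokes(raw, cfg)
        cm = estimate_cumulative(sv, cfg)
        acq, cat = raw.acq, raw.catheter
        n_sheath = raw.sheath_band[1]
        tr_ret, tr_ori = pair_truth(raw)
        pair, frame = 3, 10
        per_px_deg = tr_ret[:, pair, frame] * acq.axial_pixel_um / 100.0
        orient = np.where(np.isfinite(tr_ori[:, pair, frame]), tr_ori[:, pair, frame], 0.0)
        orient = orient + np.where(np.arange(acq.n_depth) >= n_sheath,
                                   90.0 if raw.phantom_sign < 0 else 0.0, 0.0)
        p = np.eye(3)
        for z in range(acq.n_depth):
            p = p @ pol.linear_retarder(orient[z], np.deg2rad(per_px_deg[z]))
            c_true = p @ pol.d_transpose(p)
            err = pol.rotation_angle(cm.rot[z, pair, frame] @ c_true.T)
            assert err < 1e-6
        assert cm.valid[:, pair, frame].all()

    def test_transmission_conjugates_cumulative(self, transmission_run):
        raw, _ = transmission_run
        cfg = ReconstructionConfig(**NOISE_FREE_RECON)
        sv = compute_stokes(raw, cfg)
        cm = estimate_cumulative(sv, cfg)
        # rebuild the identity-transmission cumulative via an identical
        # simulation without offsets, then conjugate by the known T
        cat0 = CatheterModel(offset_amplitude_deg=0.0, drift_amplitude_deg=0.0)
        ph = build_dbs_phantom(short_phantom_config(), seed=0)
        raw0 = simulate_pullback(ph, raw.trajectory, cat0, raw.acq, seed=99)
        sv0 = compute_stokes(raw0, cfg)
        cm0 = estimate_cumulative(sv0, cfg)
        phi = raw.true_offset_deg.T[0::2, :]  # (pair, frame) offsets in degrees
        for pair, frame in [(0, 0), (5, 7), (11, 20)]:
            t = pol.retvec_to_rotation(np.array([0.0, 0.0, 1.0]),
                                       np.asarray(2 * np.deg2rad(phi[pair, frame])))
            expected = pol.d_transpose(t) @ cm0.rot[60, pair, frame] @ t
            err = pol.rotation_angle(cm.rot[60, pair, frame] @ expected.T)
            assert err < 1e-6

    def test_low_dop_pixels_masked(self, oracle_run):
        raw, _ = oracle_run
        cfg = ReconstructionConfig(**NOISE_FREE_RECON)
        sv = compute_stokes(raw, cfg)
        sv.dop[0, 5, 2, 3] = 0.1
        cm = estimate_cumulative(sv, cfg)
        assert not cm.valid[5, 2, 3]


class TestCompensateTransmission:
    def test_identity_transmission_preserved(self, oracle_run):
        raw, _ = oracle_run
        cfg = ReconstructionConfig(**NOISE_FREE_RECON)
        sv = compute_stokes(raw, cfg)
        cm = estimate_cumulative(sv, cfg)
        out = compensate_transmission(cm, cfg)
        err = pol.rotation_angle(out.rot @ np.swapaxes(cm.rot, -1, -2))
        assert np.max(err[cm.valid]) < 1e-6

    def test_known_transmission_residual_asymmetry_small(self, transmission_run):
        raw, _ = transmission_run
        cfg = ReconstructionConfig(**NOISE_FREE_RECON)
        sv = compute_stokes(raw, cfg)
        cm = estimate_cumulative(sv, cfg)
        out = compensate_transmission(cm, cfg)
        assert np.nanmax(out.residual_asymmetry) < 1e-3

    def test_rotation_angle_preserved_per_depth(self, transmission_run):
        raw, _ = transmission_run
        cfg = ReconstructionConfig(**NOISE_FREE_RECON)
        sv = compute_stokes(raw, cfg)
        cm = estimate_cumulative(sv, cfg)
        out = compensate_transmission(cm, cfg)
        assert np.allclose(
            pol.rotation_angle(out.rot), pol.rotation_angle(cm.rot), atol=1e-8
        )


def synthetic_map(rot_stack):
    rot = np.asarray(rot_stack)[:, None, None]
    return CumulativeMap(rot=rot, valid=np.ones(rot.shape[:3], bool),
                         azimuth_pair_deg=np.zeros(1))


class TestPeelLayers:
    PX_UM = 4.8

    def test_homogeneous_slab_exact(self):
        delta = 0.02
        layer = pol.linear_retarder(30.0, delta)
        p = np.eye(3)
        rots = []
        for _ in range(40):
            p = p @ layer
            rots.append(p @ pol.d_transpose(p))
        lb = peel_layers(synthetic_map(rots), self.PX_UM,
                         ReconstructionConfig(retardance_floor_deg_per_100um=0.0))
        expected = np.rad2deg(delta) * 100 / self.PX_UM
        assert np.allclose(lb.retardance[:, 0, 0], expected, rtol=1e-6)
        assert np.allclose(ang_diff_deg(lb.orientation_apparent[:, 0, 0], 30.0), 0.0,
                           atol=0.1)

    def test_second_layer_unaffected_by_first(self):
        l1 = pol.linear_retarder(0.0, 0.03)
        l2 = pol.linear_retarder(90.0, 0.05)
        p = np.eye(3)
        rots = []
        for z in range(40):
            p = p @ (l1 if z < 20 else l2)
            rots.append(p @ pol.d_transpose(p))
        lb = peel_layers(synthetic_map(rots), self.PX_UM,
                         ReconstructionConfig(retardance_floor_deg_per_100um=0.0))
        assert np.allclose(ang_diff_deg(lb.orientation_apparent[:20, 0, 0], 0.0),
                           0.0, atol=0.1)
        assert np.allclose(ang_diff_deg(lb.orientation_apparent[20:, 0, 0], 90.0),
                           0.0, atol=0.1)
        assert np.allclose(lb.retardance[20:, 0, 0],
                           np.rad2deg(0.05) * 100 / self.PX_UM, rtol=1e-6)

    def test_zero_birefringence_masked(self):
        rots = [np.eye(3)] * 20
        lb = peel_layers(synthetic_map(rots), self.PX_UM, ReconstructionConfig())
        assert np.all(lb.retardance == 0.0)
        assert not lb.mask.any()

    def test_invalid_depth_masked_and_recursion_carries_on(self):
        delta = 0.02
        layer = pol.linear_retarder(30.0, delta)
        p = np.eye(3)
        rots = []
        for _ in range(30):
            p = p @ layer
            rots.append(p @ pol.d_transpose(p))
        cm = synthetic_map(rots)
        cm.valid[10:12] = False
        lb = peel_layers(cm, self.PX_UM,
                         ReconstructionConfig(retardance_floor_deg_per_100um=0.0))
        assert not lb.mask[10:12].any()
        assert np.allclose(ang_diff_deg(lb.orientation_apparent[15:, 0, 0], 30.0),
                           0.0, atol=0.1)


class TestGuideStar:
    def run_with_offsets(self, cat, seed=5):
        ph = build_dbs_phantom(short_phantom_config(), seed=0)
        acq = AcquisitionConfig(**NOISE_FREE_ACQ)
        raw = simulate_pullback(ph, Trajectory(length_mm=6.0), cat, acq, seed=seed)
        lb = reconstruct_pullback(raw, ReconstructionConfig(**NOISE_FREE_RECON,
                                                            compensation_enabled=False))
        return raw, lb

    def test_zero_offsets_absolute_equals_apparent(self, oracle_run):
        raw, lb = oracle_run
        assert np.allclose(lb.sheath_offset_deg, 0.0, atol=0.5)
        m = lb.mask & np.isfinite(lb.orientation_apparent)
        assert np.allclose(
            ang_diff_deg(lb.orientation_absolute[m], lb.orientation_apparent[m]),
            0.0, atol=0.5,
        )

    def test_constant_offset_recovered(self):
        cat = CatheterModel(offset_amplitude_deg=25.0, offset_cycles_per_rotation=0.0,
                            offset_phase_deg=90.0, drift_amplitude_deg=0.0)
        raw, lb = self.run_with_offsets(cat)
        # a circular transmission with orientation offset phi shifts every
        # reported orientation by -phi; the guide star measures that shift
        assert np.allclose(np.abs(lb.sheath_offset_deg), 25.0, atol=0.5)
        _, tr_ori = pair_truth(raw)
        m = tissue_mask(raw, lb)
        assert np.abs(ang_diff_deg(lb.orientation_absolute[m], tr_ori[m])).max() < 0.5

    def test_missing_sheath_alines_interpolated_and_flagged(self):
        # constant offset: interpolation from azimuthal neighbors is exact
        cat = CatheterModel(offset_amplitude_deg=25.0, offset_cycles_per_rotation=0.0,
                            offset_phase_deg=90.0, drift_amplitude_deg=0.0)
        ph = build_dbs_phantom(short_phantom_config(), seed=0)
        acq = AcquisitionConfig(**NOISE_FREE_ACQ)
        raw = simulate_pullback(ph, Trajectory(length_mm=6.0), cat, acq, seed=6)
        cfg = ReconstructionConfig(**NOISE_FREE_RECON)
        sv = compute_stokes(raw, cfg)
        cm = estimate_cumulative(sv, cfg)
        lb = peel_layers(cm, raw.acq.axial_pixel_um, cfg, raw.acq.pitch_mm,
                         raw.sheath_band)
        # kill the sheath retardance estimate on one A-line pair
        lb.retardance[: raw.sheath_band[1], 4, :] = 0.0
        out = guide_star_correct(lb, raw.sheath_band,
                                 raw.catheter.sheath_orientation_deg, cfg)
        assert out.sheath_flagged[:, 4].all()
        phi = raw.true_offset_deg[:, 8]  # A-line 8 = pair 4
        assert np.abs(ang_diff_deg(out.sheath_offset_deg[:, 4], -phi)).max() < 0.5

    def test_invalid_band_rejected(self, oracle_run):
        raw, lb = oracle_run
        with pytest.raises(ValueError):
            guide_star_correct(lb, (50, 10), 0.0, ReconstructionConfig())


class TestEndToEnd:
    def test_noise_free_oracle_equivalence(self, oracle_run):
        raw, lb = oracle_run
        tr_ret, tr_ori = pair_truth(raw)
        m = tissue_mask(raw, lb)
        assert m.sum() > 1000
        rel = np.abs(lb.retardance[m] - tr_ret[m]) / tr_ret[m]
        assert rel.max() < 1e-4
        assert np.abs(ang_diff_deg(lb.orientation_absolute[m], tr_ori[m])).max() < 0.5

    def test_negative_birefringence_flag_shifts_by_ninety(self, oracle_run):
        raw, lb_neg = oracle_run
        cfg = ReconstructionConfig(**NOISE_FREE_RECON, compensation_enabled=False,
                                   negative_birefringence=False)
        lb_pos = reconstruct_pullback(raw, cfg)
        m = lb_neg.mask & lb_pos.mask
        d = ang_diff_deg(lb_neg.orientation_apparent[m], lb_pos.orientation_apparent[m])
        assert np.allclose(np.abs(d), 90.0, atol=1e-6)

    def test_spectral_binning_merges_per_bin_reconstructions(self):
        cfg_ph = PhantomConfig(length_mm=3.0, layers=(LayerSpec("cortex_gm", 0, 1),
                                                      LayerSpec("wm", 1, 3)),
                               inclusions=())
        ph = build_dbs_phantom(cfg_ph, seed=0)
        traj = Trajectory(length_mm=3.0)
        rcfg = ReconstructionConfig(**NOISE_FREE_RECON)
        acq3 = AcquisitionConfig(alines_per_frame=32, depth_range_mm=0.6,
                                 speckle=False, detector_noise_sigma=0.0,
                                 spectral_bins=3, spectral_offset_magnitude_deg=5.0)
        raw3 = simulate_pullback(ph, traj, CatheterModel(), acq3, seed=2)
        assert raw3.fields.shape[0] == 3
        lb3 = reconstruct_pullback(raw3, rcfg)
        tr_ret, tr_ori = pair_truth(raw3)
        m = tissue_mask(raw3, lb3)
        rel = np.abs(lb3.retardance[m] - tr_ret[m]) / tr_ret[m]
        assert rel.max() < 1e-4  # conjugations never change rotation angles
        # the bin-dependent static system rotation (5 deg) tilts axes; the
        # guide star removes the common offset, leaving a sub-magnitude residual
        d = ang_diff_deg(lb3.orientation_absolute[m], tr_ori[m])
        assert np.abs(d).max() < 1.5

    def test_orientation_rmse_non_increasing_in_sheath_retardance(self):
        ph = build_dbs_phantom(short_phantom_config(length_mm=3.0), seed=0)
        traj = Trajectory(length_mm=3.0)
        rmse = {0.1: [], 0.3: [], 0.6: []}
        for seed in range(5):
            for s_ret in rmse:
                cat = CatheterModel(sheath_retardance_rad=s_ret,
                                    offset_amplitude_deg=0.0, drift_amplitude_deg=0.0)
                acq = AcquisitionConfig(alines_per_frame=32, depth_range_mm=0.55)
                raw = simulate_pullback(ph, traj, cat, acq, seed=40 + seed)
                cfg = ReconstructionConfig(offset_smoothing_window_pairs=5,
                                           compensation_enabled=False)
                lb = reconstruct_pullback(raw, cfg)
                _, tr_ori = pair_truth(raw)
                m = tissue_mask(raw, lb)
                d = ang_diff_deg(lb.orientation_absolute[m], tr_ori[m])
                rmse[s_ret].append(np.sqrt(np.mean(d**2)))
        means = {k: np.mean(v) for k, v in rmse.items()}
        assert means[0.1] >= means[0.3] - 0.2
        assert means[0.3] >= means[0.6] - 0.2
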