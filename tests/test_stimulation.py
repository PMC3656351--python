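import numpy as np
import pytest

from pulsecr import (
    EnsembleState,
    HarmonicPRC,
    ModelParams,
    StimulationProtocol,
    build_target_pattern,
    cluster_fixed_point,
    cluster_outcome,
    estimate_critical_duration,
    ml_like_prc,
    optimize_onsets,
    pin_time,
    resetting_map,
    stimulated_fixed_points,
    uniform_protocol,
    wrap,
    wrap_diff,
)

TWO_PI = 2 * np.pi


class TestStimulatedFixedPoints:
    def test_harmonic_analytic_roots(self, harmonic_params):
        fps = stimulated_fixed_points(harmonic_params, 10.0)
        assert fps.phi_s == pytest.approx(np.arcsin(0.1), abs=1e-10)
        assert fps.phi_u == pytest.approx(np.pi - np.arcsin(0.1), abs=1e-10)

    def test_subthreshold_intensity_rejected(self, harmonic_params):
        # |I| < omega / max|Z|: the flow never vanishes
        with pytest.raises(ValueError, match="resetting point"):
            stimulated_fixed_points(harmonic_params, 0.5)

    def test_zero_intensity_rejected(self, harmonic_params):
        with pytest.raises(ValueError):
            stimulated_fixed_points(harmonic_params, 0.0)

    def test_ml_like_negative_intensity(self, ml_params):
        fps = stimulated_fixed_points(ml_params, -10.0)
        # stable root on the rising flank of the hump: I*Z' < 0 there
        assert ml_params.prc.derivative(fps.phi_s) > 0
        assert ml_params.prc(fps.phi_s) == pytest.approx(0.1, abs=1e-10)


class TestUniformProtocol:
    def test_release_gaps_and_onset_pattern(self, harmonic_params):
        proto = uniform_protocol(harmonic_params, 4, 10.0, 10.0)
        delta = TWO_PI / 4
        assert np.allclose(proto.onsets,
                           [0.0, 3 * delta, 2 * delta, delta])
        gaps = np.diff(np.sort(proto.releases))
        assert np.allclose(gaps, delta)

    def test_cycle_length(self, harmonic_params):
        proto = uniform_protocol(harmonic_params, 4, 10.0, 10.0, t_on=5.0)
        assert proto.t_off - proto.t_on == pytest.approx(10.0 + 3 * TWO_PI / 4)

    def test_single_site_rejected(self, harmonic_params):
        with pytest.raises(ValueError):
            uniform_protocol(harmonic_params, 1, 10.0, 10.0)


class TestProtocolContainer:
    def test_onset_gauge_normalization(self):
        proto = StimulationProtocol(2, [1.0, 2.0], 3.0, 5.0, t_on=10.0)
        assert proto.onsets.min() == 0.0
        assert proto.t_on == 11.0

    def test_json_roundtrip(self, tmp_path, harmonic_params):
        proto = uniform_protocol(harmonic_params, 4, 10.0, 10.0, t_on=250.0)
        path = tmp_path / "protocol.json"
        proto.write_json(path)
        back = StimulationProtocol.read_json(path)
        assert np.allclose(back.onsets, proto.onsets)
        assert back.tau == proto.tau and back.t_on == proto.t_on
        assert all(np.array_equal(a, b)
                   for a, b in zip(back.assignment, proto.assignment))


class TestResettingMap:
    def test_uncoupled_pinning_formula(self):
        """With kappa = 0 every neuron of site j ends at
        wrap(phi_s + omega*(t_off - t_j - tau))."""
        p = ModelParams(8, 1.0, 0.0, HarmonicPRC())
        proto = uniform_protocol(p, 4, 10.0, 10.0)
        rng = np.random.default_rng(2)
        init = EnsembleState(rng.uniform(0, TWO_PI, 8), 0.0)
        out = resetting_map(p, proto, init)
        phi_s = np.arcsin(0.1)
        for j, idx in enumerate(proto.assignment):
            expect = wrap(phi_s + (proto.t_off_rel - proto.releases[j]))
            assert np.max(np.abs(wrap_diff(out.phases[idx] - expect))) < 1e-7

    def test_zero_duration_is_free_flow(self, harmonic_params):
        p = harmonic_params
        proto = StimulationProtocol(4, uniform_protocol(p, 4, 10.0, 10.0).onsets,
                                    0.0, 10.0).with_sites(p.N)
        rng = np.random.default_rng(3)
        init = EnsembleState(rng.uniform(0, TWO_PI, p.N), 0.0)
        from pulsecr import advance_free
        free = advance_free(init.copy(), p, proto.t_off)
        out = resetting_map(p, proto, init.copy())
        dev = np.max(np.abs(wrap_diff(out.phases - free.final_state.phases)))
        assert dev < 1e-9

    def test_initial_condition_independence(self, harmonic_params):
        """Above the critical duration the outcome forgets the initial state."""
        p = harmonic_params
        proto = uniform_protocol(p, 4, 10.0, 10.0)
        outs = []
        for seed in (4, 5):
            rng = np.random.default_rng(seed)
            init = EnsembleState(rng.uniform(0, TWO_PI, p.N), 0.0)
            outs.append(resetting_map(p, proto, init).phases)
        assert np.max(np.abs(wrap_diff(outs[0] - outs[1]))) < 1e-6


class TestClusterOutcome:
    def test_uncoupled_matches_per_site_formula(self):
        p = ModelParams(8, 1.0, 0.0, HarmonicPRC())
        proto = uniform_protocol(p, 4, 10.0, 10.0)
        psi = cluster_outcome(p, proto).psi
        phi_s = np.arcsin(0.1)
        expect = wrap(phi_s + (proto.t_off_rel - proto.releases))
        assert np.max(np.abs(wrap_diff(psi - expect))) < 1e-7

    def test_reduced_matches_full_from_synchronized_state(self, harmonic_params):
        p = harmonic_params
        proto = uniform_protocol(p, 4, 10.0, 10.0)
        psi_reduced = cluster_outcome(p, proto).psi
        sync = EnsembleState(np.full(p.N, TWO_PI - 1e-9), 0.0)
        psi_full = cluster_outcome(p, proto, initial=sync).psi
        assert np.max(np.abs(wrap_diff(psi_reduced - psi_full))) < 1e-8

    def test_gauge_invariance_in_t_on(self, harmonic_params):
        p = harmonic_params
        a = uniform_protocol(p, 4, 10.0, 10.0, t_on=0.0)
        b = uniform_protocol(p, 4, 10.0, 10.0, t_on=123.4)
        assert np.max(np.abs(wrap_diff(
            cluster_outcome(p, a).psi - cluster_outcome(p, b).psi))) < 1e-9

    def test_delaying_one_release_shifts_its_cluster(self):
        """Drift algebra at kappa = 0: delaying a non-final onset by c moves
        that site's outcome phase down by omega*c."""
        p = ModelParams(8, 1.0, 0.0, HarmonicPRC())
        base = uniform_protocol(p, 4, 10.0, 10.0)
        c = 0.3
        onsets = base.onsets.copy()
        onsets[2] += c  # not the max onset, t_off unchanged
        proto = StimulationProtocol(4, onsets, 10.0, 10.0).with_sites(8)
        psi0 = cluster_outcome(p, base).psi
        psi1 = cluster_outcome(p, proto).psi
        assert wrap_diff(psi1[2] - psi0[2]) == pytest.approx(-c, abs=1e-7)
        for j in (0, 1, 3):
            assert abs(wrap_diff(psi1[j] - psi0[j])) < 1e-7

    def test_incomplete_reset_raises(self, harmonic_params):
        p = harmonic_params
        proto = uniform_protocol(p, 4, 0.05, 10.0)
        rng = np.random.default_rng(8)
        init = EnsembleState(rng.uniform(0, TWO_PI, p.N), 0.0)
        with pytest.raises(ValueError, match="reset incomplete"):
            cluster_outcome(p, proto, initial=init)


class TestTargetPattern:
    def test_anchored_at_resetting_point(self, harmonic_params):
        tgt = build_target_pattern(harmonic_params, 4, 10.0, 10.0)
        assert np.min(np.abs(wrap_diff(tgt.psi_star - tgt.phi_s))) < 1e-9

    def test_phases_are_rotation_of_cluster_state(self, harmonic_params):
        tgt = build_target_pattern(harmonic_params, 4, 10.0, 10.0)
        cs = tgt.source
        # circular gaps between sorted target phases match the stationary
        # cluster state's gaps up to the rotation placing psi_m at phi_s
        def cyc_gaps(v):
            s = np.sort(v)
            return np.sort(np.diff(np.concatenate([s, [s[0] + TWO_PI]])))
        assert np.allclose(cyc_gaps(tgt.psi_star), cyc_gaps(cs.psi), atol=5e-3)


class TestOptimizeOnsets:
    def test_uncoupled_returns_uniform(self):
        p = ModelParams(8, 1.0, 0.0, HarmonicPRC())
        proto, resid = optimize_onsets(p, 4, 10.0, 10.0)
        uni = uniform_protocol(p, 4, 10.0, 10.0)
        assert resid < 1e-7
        assert np.max(np.abs(proto.onsets - uni.onsets)) < 1e-6

    def test_harmonic_residual_verified_by_full_resimulation(self, harmonic_params):
        """The optimizer contract: ||Psi(t_opt) - Psi*|| < 1e-6, re-checked by
        an independent full-N simulation of the optimized protocol."""
        p = harmonic_params
        tgt = build_target_pattern(p, 4, 10.0, 10.0)
        proto, resid = optimize_onsets(p, 4, 10.0, 10.0, target=tgt)
        assert resid < 1e-6
        sync = EnsembleState(np.full(p.N, TWO_PI - 1e-9), proto.t_on)
        psi_full = cluster_outcome(p, proto, initial=sync).psi
        assert np.linalg.norm(wrap_diff(psi_full - tgt.psi_star)) < 1e-6

    def test_weak_coupling_onsets_near_uniform(self):
        """Optimized onsets converge to the uniform ones as kappa -> 0
        (cluster phases deviate at first order in the coupling)."""
        devs = []
        for kappa in (0.2, 0.1):
            p = ModelParams(240, 1.0, kappa, HarmonicPRC())
            proto, _ = optimize_onsets(p, 4, 10.0, 10.0)
            uni = uniform_protocol(p, 4, 10.0, 10.0)
            devs.append(np.max(np.abs(proto.onsets - uni.onsets)))
        assert devs[1] < 0.7 * devs[0]


class TestCriticalDuration:
    def test_tau_c_decreases_with_intensity(self):
        # note: I = -5 is avoided; there phi_s = pi/2 for this PRC and the
        # first cluster's post-release spike coincides exactly with t_off,
        # a genuine discontinuity point of the outcome map
        prc = ml_like_prc()
        p = ModelParams(8, 1.0, 0.5, prc)
        grid = np.arange(0.5, 14.0, 0.5)
        tcs = []
        for I in (-6.0, -20.0):
            tpl = uniform_protocol(p, 4, 1.0, I)
            tcs.append(estimate_critical_duration(p, tpl, grid))
        assert tcs[0] is not None and tcs[1] is not None
        assert tcs[1] <= tcs[0]

    def test_uncoupled_matches_quadrature_oracle(self):
        """kappa = 0: tau_c equals the pinning time of the slowest neuron,
        computable by quadrature of dphi / (omega + I Z)."""
        p = ModelParams(8, 1.0, 0.0, HarmonicPRC())
        grid = np.arange(0.25, 10.0, 0.25)
        tpl = uniform_protocol(p, 4, 1.0, 10.0)
        tc = estimate_critical_duration(p, tpl, grid, seeds=(101, 202),
                                        tol=1e-4)
        phases = np.concatenate([
            np.random.default_rng(101).uniform(0, TWO_PI, 8),
            np.random.default_rng(202).uniform(0, TWO_PI, 8)])
        t_slowest = max(pin_time(p, 10.0, phi, tol=5e-5) for phi in phases)
        assert tc is not None
        assert tc - 0.25 <= t_slowest <= tc + 0.25

    def test_not_reached_reported_as_none(self, harmonic_params):
        tpl = uniform_protocol(harmonic_params, 4, 1.0, 10.0)
        assert estimate_critical_duration(harmonic_params, tpl, [0.01]) is None
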