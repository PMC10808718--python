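import numpy as np
import pytest
from scipy.linalg import expm

from faceloop.cohort import (
    ALL_GROUPS,
    GroupSpec,
    NeuralParams,
    SimulationConfig,
    UnstableParametersError,
    default_neural_params,
    hemodynamic_observe,
    integrate_neural,
    make_block_design,
    null_scenario,
    simulate_cohort,
    simulate_run_closed_loop,
)


class TestGroupSpec:
    def test_congruency_and_polarity_mapping(self):
        assert GroupSpec("happy", "up").polarity == +1
        assert GroupSpec("fear", "down").polarity == +1
        assert GroupSpec("happy", "down").polarity == -1
        assert GroupSpec("fear", "up").polarity == -1

    def test_unknown_levels_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("sad", "up")


class TestBlockDesign:
    def test_default_paradigm(self, default_config):
        d = make_block_design(default_config)
        kinds = [k for _, _, k in d.blocks]
        assert kinds == ["baseline", "regulation"] * 4
        durations = [dur for _, dur, _ in d.blocks]
        assert durations == [20.0, 40.0] * 4
        assert sum(durations) == 240.0
        assert d.n_volumes == 245 and d.dummy_volumes == 5

    def test_single_cycle(self):
        d = make_block_design(SimulationConfig(n_blocks_per_kind=1))
        assert len(d.blocks) == 2
        assert sum(dur for _, dur, _ in d.blocks) == 60.0

    def test_two_second_tr_volume_count(self):
        d = make_block_design(SimulationConfig(tr=2.0, integration_dt=0.1))
        assert d.n_retained == 120

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(baseline_len=-20.0)


class TestIntegrateNeural:
    def test_zero_input_zero_trajectory(self):
        p = default_neural_params()
        n = 100
        z = integrate_neural(p, np.zeros(n), np.zeros(n), dt=0.1)
        assert np.all(z == 0.0)

    def test_single_region_step_response_closed_form(self):
        # decoupled A = -I, face drive 1 into V1: z_V1(t) = 1 - exp(-t)
        A = -np.eye(4)
        C = np.zeros((4, 2))
        C[0, 0] = 1.0
        p = NeuralParams(A=A, B_face=np.zeros((4, 4)), B_int=np.zeros((4, 4)), C=C)
        dt = 0.001
        t_end = 8.0
        n = int(t_end / dt)
        z = integrate_neural(p, np.ones(n), np.zeros(n), dt=dt)
        t = (np.arange(n) + 1) * dt
        assert np.allclose(z[:, 0], 1 - np.exp(-t), atol=5e-3)
        assert np.allclose(z[:, 1:], 0.0)

    def test_two_region_chain_matches_matrix_exponential(self):
        A = -np.eye(4)
        A[1, 0] = 0.5  # V1 -> FFA
        C = np.zeros((4, 2))
        C[0, 0] = 1.0
        p = NeuralParams(A=A, B_face=np.zeros((4, 4)), B_int=np.zeros((4, 4)), C=C)
        dt = 0.01
        n = 1000
        z = integrate_neural(p, np.ones(n), np.zeros(n), dt=dt)
        # closed form for dz = Az + c with z(0)=0: z(t) = A^-1 (e^{At} - I) c
        c = C[:, 0]
        for k in (99, 499, 999):
            t = (k + 1) * dt
            exact = np.linalg.solve(A, (expm(A * t) - np.eye(4)) @ c)
            assert np.allclose(z[k], exact, atol=1e-3)

    def test_divergence_flagged(self):
        A = -np.eye(4)
        A[0, 0] = +0.5  # unstable self-excitation
        with pytest.raises(ValueError):
            NeuralParams(A=A, B_face=np.zeros((4, 4)), B_int=np.zeros((4, 4)), C=np.zeros((4, 2)))
        # bypassing validation still trips the runtime bound
        p = NeuralParams(A=A, B_face=np.zeros((4, 4)), B_int=np.zeros((4, 4)),
                         C=np.zeros((4, 2)), validate=False)
        z0 = np.array([1.0, 0, 0, 0])
        with pytest.raises(UnstableParametersError):
            integrate_neural(p, np.zeros(40000), np.zeros(40000), dt=0.1,
                             z0=z0, divergence_bound=10.0)

    def test_nonpositive_dt_rejected(self):
        p = default_neural_params()
        with pytest.raises(ValueError):
            integrate_neural(p, np.zeros(10), np.zeros(10), dt=0.0)


class TestHemodynamicObserve:
    def test_zero_neural_zero_bold(self, hrf):
        bold = hemodynamic_observe(np.zeros((600, 4)), hrf, tr=1.0)
        assert np.all(bold == 0.0)

    def test_impulse_reproduces_kernel(self, hrf):
        n = 600
        neural = np.zeros((n, 1))
        neural[0, 0] = 1.0 / hrf.dt  # unit-area impulse on the dt grid
        bold = hemodynamic_observe(neural, hrf, tr=1.0)
        sub = round(1.0 / hrf.dt)
        idx = np.arange(sub - 1, min(n, hrf.kernel_dt.size), sub)
        assert np.allclose(bold[: idx.size, 0], hrf.kernel_dt[idx], atol=1e-12)

    def test_boxcar_matches_direct_convolution(self, hrf, rng):
        n = 1200
        neural = np.zeros((n, 1))
        neural[200:600, 0] = 1.0
        bold = hemodynamic_observe(neural, hrf, tr=1.0)
        k = hrf.kernel_dt
        direct = np.convolve(neural[:, 0], k)[:n] * hrf.dt
        sub = round(1.0 / hrf.dt)
        assert np.allclose(bold[:, 0], direct[sub - 1 :: sub], atol=1e-10)

    def test_kernel_longer_than_series_rejected(self, hrf):
        with pytest.raises(ValueError):
            hemodynamic_observe(np.zeros((10, 4)), hrf, tr=1.0)


class TestClosedLoop:
    def test_regulation_raises_morph_for_positive_loop(self, noiseless_run):
        box = noiseless_run.design.boxcar().astype(bool)
        m = noiseless_run.morph_trace
        assert m[box].mean() > m[~box].mean()
        assert m.min() >= 0 and m.max() <= 30

    def test_bit_identical_repeat(self, default_config):
        p = default_neural_params()
        g = GroupSpec("fear", "down")
        a = simulate_run_closed_loop(p, g, default_config, seed=42, regulation_effort=0.2)
        b = simulate_run_closed_loop(p, g, default_config, seed=42, regulation_effort=0.2)
        assert np.array_equal(a.roi_bold, b.roi_bold)
        assert np.array_equal(a.morph_trace, b.morph_trace)
        assert np.array_equal(a.motion_nuisance, b.motion_nuisance)

    def test_opposite_polarity_anticorrelates(self):
        cfg = SimulationConfig(obs_noise_sd=0.0, neural_noise_sd=0.0)
        p = default_neural_params()
        up = simulate_run_closed_loop(p, GroupSpec("happy", "up"), cfg, seed=3,
                                      regulation_effort=0.3)
        down = simulate_run_closed_loop(p, GroupSpec("happy", "down"), cfg, seed=3,
                                        regulation_effort=0.3)
        box = up.design.boxcar().astype(bool)
        c = np.corrcoef(up.morph_trace[box], down.morph_trace[box])[0, 1]
        assert c < 0

    def test_loop_feedback_value_matches_recorded_bold(self, noiseless_run):
        amy = noiseless_run.roi_bold[:, 2]
        assert np.array_equal(amy, noiseless_run.amy_feedback_raw)


class TestCohort:
    def test_structure_groups_and_ids(self, small_cohort):
        assert len(small_cohort.participants) == 8
        names = [p.group.name for p in small_cohort.participants]
        for g in ALL_GROUPS:
            assert names.count(g.name) == 2
        ids = [p.id for p in small_cohort.participants]
        assert len(set(ids)) == len(ids)
        for p in small_cohort.participants:
            assert len(p.runs) == 4
            assert set(p.scores) == {"panas_pos", "panas_neg", "sds"}

    def test_deterministic_under_master_seed(self):
        cfg = SimulationConfig(n_per_group=1, seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for pa, pb in zip(a.participants, b.participants):
            assert np.array_equal(pa.runs[0].roi_bold, pb.runs[0].roi_bold)
            assert pa.scores == pb.scores

    def test_unknown_scenario_group_rejected(self):
        bad = null_scenario()
        bad.regulation_amp["lizard-up"] = (0, 0, 0, 0)
        with pytest.raises(ValueError, match="unknown groups"):
            simulate_cohort(SimulationConfig(n_per_group=1), bad)

    def test_null_scenario_removes_group_separation(self):
        """With all regulation amplitudes zero, late-run block betas carry
        only the (group-independent) stimulus response; the reference
        scenario separates fear-down from fear-up by design."""
        from faceloop.cohort import reference_scenario
        from faceloop.glm import block_beta_table

        def late_run_means(scenario):
            ds = simulate_cohort(SimulationConfig(n_per_group=2, seed=55), scenario)
            bb = block_beta_table(ds)
            return bb[bb.run >= 3].groupby("group")["beta"].mean()

        null_m = late_run_means(null_scenario())
        ref_m = late_run_means(reference_scenario())
        assert abs(null_m["fear-down"] - null_m["fear-up"]) < 0.05
        assert ref_m["fear-down"] - ref_m["fear-up"] < -0.3

    def test_no_trajectory_diverges_with_defaults(self, small_cohort):
        for p in small_cohort.participants:
            for rec in p.runs:
                assert np.all(np.isfinite(rec.neural_truth))
                assert np.abs(rec.neural_truth).max() < small_cohort.config.divergence_bound
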