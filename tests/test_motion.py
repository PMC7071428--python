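import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from playmotion import (
    DEFAULT_CALIBRATION,
    CalibrationModel,
    ProjectionWindow,
    RunConfig,
    accelerations,
    fit_calibration,
    fourier_velocity,
    to_mps,
    vm_epochs,
)

G = 9.80665


class TestCalibration:
    def test_exact_synthetic_observations_recover_printed_line(self):
        depths = np.arange(1000, 4001, 250)
        obs = [(d, 1.75 / DEFAULT_CALIBRATION.scaling(d)) for d in depths]
        cal = fit_calibration(obs, 1.75)
        assert cal.slope == pytest.approx(1.5e-06, rel=1e-10)
        assert cal.intercept == pytest.approx(6.4e-04, rel=1e-10)

    def test_two_exact_points_line_through_both(self):
        cal = fit_calibration([(1000, 875.0), (2000, 700.0)], 1.75)
        for d, h in [(1000, 875.0), (2000, 700.0)]:
            assert cal.scaling(d) == pytest.approx(1.75 / h, rel=1e-12)

    def test_noisy_fit_within_5pct(self):
        rng = np.random.default_rng(42)
        depths = rng.uniform(1000, 4000, 50)
        heights = 1.75 / DEFAULT_CALIBRATION.scaling(depths)
        heights *= 1 + 0.01 * rng.standard_normal(50)
        cal = fit_calibration(list(zip(depths, heights)), 1.75)
        assert cal.slope == pytest.approx(1.5e-06, rel=0.05)
        assert cal.intercept == pytest.approx(6.4e-04, rel=0.05)

    def test_single_depth_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(2000, 700.0), (2000, 701.0)], 1.75)


def _window(positions, plane="x", a1=7.5, intensities=None):
    positions = np.asarray(positions, float)
    if intensities is None:
        intensities = np.full(positions.shape, 30000.0)
    return ProjectionWindow(
        plane=plane, second_index=0, positions=positions,
        intensities=intensities, a1=a1, dt=1 / 30,
    )


class TestFourierVelocity:
    def test_stationary_constant_intensity_is_zero(self):
        assert fourier_velocity(_window(np.full(30, 123.0))) == 0.0

    @pytest.mark.parametrize("u", [2.0, 4 / 3, 2 / 3])
    def test_uniform_motion_matches_finite_difference_oracle(self, u):
        pos = 100 + u * np.arange(30)
        v = fourier_velocity(_window(pos))
        fd = (pos[-1] - pos[0]) / 29 * 30  # px per 30 frames
        assert v == pytest.approx(fd, abs=1.0)

    @pytest.mark.parametrize("u", [4 / 3, 2 / 3])
    def test_mirrored_motion_same_magnitude_opposite_sign(self, u):
        fwd = fourier_velocity(_window(100 + u * np.arange(30)))
        rev = fourier_velocity(_window(100 - u * np.arange(30)))
        assert rev == pytest.approx(-fwd)
        assert fwd > 0

    def test_y_plane_scaling_constant(self):
        a1_y = 30 / 2.8
        u = 2 * 2.8 / 30  # two bins
        v = fourier_velocity(_window(200 + u * np.arange(30), plane="y", a1=a1_y))
        assert v == pytest.approx(u * 30, abs=1.0)

    def test_majority_missing_window_is_missing(self):
        pos = 100 + 2.0 * np.arange(30)
        pos[:16] = np.nan
        assert fourier_velocity(_window(pos)) is None

    def test_half_missing_window_still_recovers(self):
        pos = 100 + 2.0 * np.arange(30.0)
        pos[::2] = np.nan  # 15 valid frames
        v = fourier_velocity(_window(pos))
        assert v == pytest.approx(60.0, abs=4.0)


class TestToMps:
    def test_zero_depth_uses_intercept_only(self):
        assert DEFAULT_CALIBRATION.scaling(0) == pytest.approx(6.4e-04)
        assert to_mps(100.0, 0, DEFAULT_CALIBRATION) == pytest.approx(0.064)

    def test_printed_line_arithmetic(self):
        v = to_mps(60.0, 2400, DEFAULT_CALIBRATION)
        assert v == pytest.approx(60 * (1.5e-6 * 2400 + 6.4e-4))
        assert v == pytest.approx(0.2544)

    def test_zero_velocity_any_depth(self):
        assert to_mps(0.0, 3333, DEFAULT_CALIBRATION) == 0.0

    def test_missing_depth_missing_sample(self):
        assert to_mps(60.0, None, DEFAULT_CALIBRATION) is None

    def test_clipped_at_vmax_with_sign(self):
        v = to_mps(-10000.0, 3000, DEFAULT_CALIBRATION, vmax=4.0)
        assert v == -4.0


class TestAccelerations:
    def test_constant_velocity_zero_acceleration(self):
        a = accelerations([1.5, 1.5, 1.5, 1.5])
        np.testing.assert_allclose(a, 0.0)

    def test_known_rise_is_point_one_g(self):
        a = accelerations([0.0, 0.980665])
        assert a[1] == pytest.approx(0.1)

    def test_antisymmetric_under_reversal(self):
        up = accelerations([0.0, 1.0, 2.5, 3.0])
        down = accelerations([0.0, -1.0, -2.5, -3.0])
        np.testing.assert_allclose(down[1:], -up[1:])

    def test_missing_velocity_propagates(self):
        a = accelerations([1.0, np.nan, 2.0, 2.0])
        assert np.isnan(a[1]) and np.isnan(a[2])
        assert a[3] == 0.0

    def test_timestamps_scale_dt(self):
        a = accelerations([0.0, 1.0], timestamps_s=[0.0, 2.0])
        assert a[1] == pytest.approx(0.5 / G)


class TestVmEpochs:
    def test_all_zero_accelerations_zero_epochs(self):
        z = np.zeros(15)
        epochs = vm_epochs(z, z, z)
        assert [e.vm_value for e in epochs] == [0.0, 0.0, 0.0]

    def test_three_four_five_triple(self):
        ax = np.zeros(5); ay = np.zeros(5); az = np.zeros(5)
        ax[2], ay[2] = 0.003, 0.004
        (epoch,) = vm_epochs(ax, ay, az)
        # second VM = 5.0 (x1000 of the 3-4-5 norm), epoch mean over 5 s = 1.0
        assert epoch.vm_value == pytest.approx(1.0)
        assert epoch.n_valid_seconds == 5

    def test_missing_plane_throughout_epoch_is_missing(self):
        ax = np.zeros(5); ay = np.zeros(5); az = np.full(5, np.nan)
        (epoch,) = vm_epochs(ax, ay, az)
        assert epoch.vm_value is None

    def test_up_to_two_missing_seconds_tolerated(self):
        ax = np.zeros(5); ax[:2] = np.nan
        (epoch,) = vm_epochs(ax, np.zeros(5), np.zeros(5))
        assert epoch.vm_value == 0.0
        assert epoch.n_valid_seconds == 3

    def test_sum_mode(self):
        ones = np.full(5, 0.001)
        (mean_e,) = vm_epochs(ones, np.zeros(5), np.zeros(5), stat="mean")
        (sum_e,) = vm_epochs(ones, np.zeros(5), np.zeros(5), stat="sum")
        assert sum_e.vm_value == pytest.approx(5 * mean_e.vm_value)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-0.5, 0.5), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5)
            ),
            min_size=5,
            max_size=20,
        ),
        st.permutations([0, 1, 2]),
        st.tuples(st.sampled_from([-1, 1]), st.sampled_from([-1, 1]), st.sampled_from([-1, 1])),
    )
    def test_vm_invariant_to_axis_permutation_and_sign(self, tri, perm, signs):
        arr = np.asarray(tri, float)
        base = vm_epochs(arr[:, 0], arr[:, 1], arr[:, 2])
        mixed = arr[:, perm] * np.asarray(signs)
        other = vm_epochs(mixed[:, 0], mixed[:, 1], mixed[:, 2])
        for a, b in zip(base, other):
            assert a.vm_value == pytest.approx(b.vm_value)


class TestEndToEndVelocityRecovery:
    def test_recovery_within_15pct_in_90pct_of_seconds(self, velocity_recovery):
        df = velocity_recovery
        assert (df["rel_err"] <= 0.15).mean() >= 0.90
        # and per plane
        for _, sub in df.groupby("plane"):
            assert (sub["rel_err"] <= 0.15).mean() >= 0.90

    def test_fourier_agrees_with_finite_difference_after_burn_in(self, velocity_recovery):
        df = velocity_recovery
        steady = df[df["second"] >= 1]
        dev = (steady["v_est_px"] - steady["fd_oracle_px"]).abs()
        assert dev.max() <= 1.0


def test_config_a1_values():
    cfg = RunConfig()
    assert cfg.a1("x") == pytest.approx(7.5)
    assert cfg.a1("y") == pytest.approx(30 / 2.8)
    assert RunConfig(integer_a1=True).a1("x") == 8.0
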