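"""Instant-rigidity formulas, step aggregation, protocol summaries."""

import numpy as np
import pytest

from spinetrack import (
    CalibrationFit,
    DataError,
    LoadStep,
    LoadingMode,
    ParameterError,
    RigidityResult,
    UndefinedRigidityError,
    aggregate_steps,
    normalize_to_intact,
    normalized_table,
    rigidity_bending,
    rigidity_compression,
    rigidity_of,
    rigidity_torsion,
    run_protocol,
)


def step(force, disp=None, angle=None, arm=None, idx=0):
    return LoadStep(step_index=idx, force_N=force, displacement_mm=disp, angle_rad=angle, arm_m=arm)


class TestFormulas:
    def test_compression_is_force_over_length_change(self):
        assert rigidity_compression(step(100.0, disp=2.0)) == pytest.approx(50.0)

    def test_zero_force_gives_zero_rigidity(self):
        assert rigidity_compression(step(0.0, disp=1.0)) == 0.0

    def test_zero_displacement_is_undefined(self):
        with pytest.raises(UndefinedRigidityError):
            rigidity_compression(step(10.0, disp=0.0))

    def test_torsion_angle_variant(self):
        assert rigidity_torsion(step(10.0, angle=0.1, arm=0.2), "angle") == pytest.approx(20.0)

    def test_torsion_shift_variant(self):
        assert rigidity_torsion(step(10.0, disp=4.0, arm=0.2), "shift") == pytest.approx(0.5)

    def test_torsion_zero_angle_undefined(self):
        with pytest.raises(UndefinedRigidityError):
            rigidity_torsion(step(10.0, angle=0.0, disp=1.0, arm=0.2), "angle")

    def test_bending_angle_variant(self):
        assert rigidity_bending(step(20.0, angle=0.05, arm=0.15), "angle") == pytest.approx(60.0)

    def test_bending_odd_symmetry(self):
        plus = rigidity_bending(step(20.0, angle=0.05, arm=0.15), "angle")
        minus = rigidity_bending(step(-20.0, angle=-0.05, arm=0.15), "angle")
        assert plus == pytest.approx(minus)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        f, d, a, arm = rng.uniform(1, 100), rng.uniform(0.1, 5), rng.uniform(0.01, 0.5), rng.uniform(0.05, 0.3)
        s = step(f, disp=d, angle=a, arm=arm)
        assert rigidity_bending(s, "shift") == pytest.approx(f * arm / d, abs=1e-12)
        assert rigidity_bending(s, "angle") == pytest.approx(f * arm / a, abs=1e-12)
        assert rigidity_torsion(s, "shift") == pytest.approx(f * arm / d, abs=1e-12)

    def test_linearity_in_force(self):
        s1 = step(10.0, disp=2.0, arm=0.2)
        s2 = step(20.0, disp=2.0, arm=0.2)
        assert rigidity_torsion(s2, "shift") == pytest.approx(2 * rigidity_torsion(s1, "shift"))

    def test_missing_arm_rejected(self):
        with pytest.raises(ParameterError):
            rigidity_torsion(step(10.0, disp=1.0), "shift")


class TestAggregateSteps:
    def test_mean_of_readings(self):
        steps = aggregate_steps([[10.0, 12.0, 14.0]], displacements_mm=[1.0], n_avg=3)
        assert steps[0].force_N == pytest.approx(12.0)
        assert steps[0].n_readings_averaged == 3

    def test_n_avg_one_is_first_reading_passthrough(self):
        steps = aggregate_steps([[10.0, 99.0]], displacements_mm=[1.0], n_avg=1)
        assert steps[0].force_N == pytest.approx(10.0)

    def test_calibration_applied_to_voltages(self):
        fit = CalibrationFit(a=0.0, b=100.0, n=3, residual_sd=0.0, r_squared=1.0)
        steps = aggregate_steps([[1.0, 1.2]], displacements_mm=[1.0], n_avg=2, fit=fit)
        assert steps[0].force_N == pytest.approx(110.0)

    def test_insufficient_readings_rejected(self):
        with pytest.raises(DataError):
            aggregate_steps([[1.0]], displacements_mm=[1.0], n_avg=3)

    def test_averaging_suppresses_noise_like_sqrt_n(self):
        """Monte Carlo: SD of aggregated force ~ sigma / sqrt(n_avg) within 20%."""
        rng = np.random.default_rng(42)
        sigma, n_avg, trials = 2.0, 8, 200
        agg = []
        for _ in range(trials):
            readings = 100.0 + rng.normal(0, sigma, n_avg)
            (s,) = aggregate_steps([list(readings)], displacements_mm=[1.0], n_avg=n_avg)
            agg.append(s.force_N)
        assert np.std(agg) == pytest.approx(sigma / np.sqrt(n_avg), rel=0.2)


def linear_specimen_steps(k: float, mode: LoadingMode, repeats: int, noise_frac: float, seed: int,
                          arm: float | None = 0.15):
    """Load steps of a specimen with programmed stiffness k (shift variant).

    For bending/torsion, k is the moment stiffness F*arm/d; displacements are
    set from the noiseless force, then gauge noise (fraction of the 100 N
    full scale) lands on the recorded force.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        steps = []
        for i, force in enumerate(np.linspace(20, 100, 5)):
            if mode == LoadingMode.COMPRESSION:
                disp = force / k
                a = None
            else:
                disp = force * arm / k
                a = arm
            noisy = force + rng.normal(0, noise_frac * 100.0)
            steps.append(step(noisy, disp=disp, arm=a, idx=i))
        out.append(steps)
    return out


class TestRunProtocol:
    def test_identical_repeats_have_zero_sd(self):
        reps = [[step(50.0, disp=1.0, idx=0)]] * 10
        (res,) = run_protocol({LoadingMode.COMPRESSION: reps})
        assert res.sd == 0.0
        assert res.mean == pytest.approx(50.0)
        assert res.units == "N/mm"

    def test_programmed_stiffness_recovered_within_two_percent(self):
        k = 30.0
        data = {
            LoadingMode.FLEXION: linear_specimen_steps(k, LoadingMode.FLEXION, 10, 0.02, 1),
            LoadingMode.COMPRESSION: linear_specimen_steps(k, LoadingMode.COMPRESSION, 10, 0.02, 2),
        }
        for res in run_protocol(data, variant="shift"):
            assert res.mean == pytest.approx(k, rel=0.02)

    def test_missing_mode_absent_from_output(self):
        reps = [[step(50.0, disp=1.0)]]
        results = run_protocol({LoadingMode.COMPRESSION: reps})
        assert [r.mode for r in results] == [LoadingMode.COMPRESSION]

    def test_units_follow_variant(self):
        reps = [[step(50.0, disp=1.0, angle=0.1, arm=0.2)]]
        (shift_res,) = run_protocol({LoadingMode.TORSION_LEFT: reps}, variant="shift")
        (angle_res,) = run_protocol({LoadingMode.TORSION_LEFT: reps}, variant="angle")
        assert shift_res.units == "Nm/mm"
        assert angle_res.units == "Nm/rad"


def result(mode, mean, units="Nm/mm"):
    return RigidityResult(mode=mode, values=(mean,), units=units, mean=mean, sd=0.0, n_repeats=1)


class TestNormalization:
    def test_intact_vs_itself_is_exactly_100(self):
        r = result(LoadingMode.FLEXION, 12.34)
        assert normalize_to_intact(r, r) == 100.0

    def test_ratio_in_percent(self):
        intact = result(LoadingMode.FLEXION, 10.0)
        treated = result(LoadingMode.FLEXION, 11.2)
        assert normalize_to_intact(intact, treated) == pytest.approx(112.0)

    def test_zero_intact_rejected(self):
        z = result(LoadingMode.FLEXION, 0.0)
        with pytest.raises(ParameterError):
            normalize_to_intact(z, z)

    def test_mode_and_unit_mismatch_rejected(self):
        a = result(LoadingMode.FLEXION, 10.0)
        b = result(LoadingMode.EXTENSION, 10.0)
        with pytest.raises(ParameterError):
            normalize_to_intact(a, b)
        c = result(LoadingMode.FLEXION, 10.0, units="Nm/rad")
        with pytest.raises(ParameterError):
            normalize_to_intact(a, c)

    def test_table_covers_common_modes_only(self):
        intact = [result(LoadingMode.FLEXION, 10.0), result(LoadingMode.EXTENSION, 8.0)]
        treated = [result(LoadingMode.FLEXION, 11.2)]
        table = normalized_table(intact, treated)
        assert table == {"flexion": pytest.approx(112.0)}
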