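"""Rigid 4D dose accumulation and DVH metrics, checked against
independent brute-force oracles."""

import numpy as np
import pytest

from breath4d import accumulate as acc
from breath4d import dose, motion, phantom


def brute_force_accumulate(field, gtv, displacements):
    """Independent oracle: plain python loop over samples and voxels,
    with explicit linear interpolation along the SI axis."""
    grid = gtv.grid
    idx = np.argwhere(gtv.mask)
    out = np.zeros(len(idx))
    for n, (i, j, k) in enumerate(idx):
        total = 0.0
        for z in displacements:
            pos = k + z / grid.voxel_mm
            pos = min(max(pos, 0.0), grid.shape[2] - 1.0)
            k0 = int(np.floor(pos))
            k1 = min(k0 + 1, grid.shape[2] - 1)
            w = pos - k0
            total += (1 - w) * field.dose_gy[i, j, k0] + w * field.dose_gy[i, j, k1]
        out[n] = total / len(displacements)
    return out


def sort_oracle_dx(doses, x, prescription):
    """Independent D_x oracle: explicit sort and rank walk."""
    ordered = sorted(doses, reverse=True)
    rank = int(np.ceil(x / 100 * len(ordered)))
    return 100 * ordered[rank - 1] / prescription


@pytest.fixture(scope="module")
def tiny_setup():
    grid = phantom.PhantomGrid(shape=(24, 24, 80))
    gtv = phantom.make_gtv_mask(grid, phantom.TargetGeometry(2.0, 0))
    spec = dose.PlanSpec()
    itv = phantom.build_itv(grid, 2.0, [-5, -2, 1, 5])
    field = dose.plan_dose(itv, spec)
    return grid, gtv, spec, field


class TestSampleDoseAtDisplacement:
    def test_zero_shift_is_identity(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        sampled = acc.sample_dose_at_displacement(field, gtv, 0.0)
        assert np.array_equal(sampled, field.dose_gy[gtv.mask])

    def test_uniform_dose_invariant_to_shift(self, tiny_setup):
        grid, gtv, spec, field = tiny_setup
        uniform = dose.DoseField(np.full(grid.shape, 42.0), grid, spec, field.itv)
        for z in (-15, -3.3, 0.5, 15):
            assert np.allclose(acc.sample_dose_at_displacement(uniform, gtv, z), 42.0)

    def test_linear_ramp_shifts_by_slope_times_z(self, tiny_setup):
        grid, gtv, spec, field = tiny_setup
        g = 0.7  # Gy per mm along SI
        ramp = np.broadcast_to(
            g * np.arange(grid.shape[2], dtype=float), grid.shape
        ).copy()
        ramp_field = dose.DoseField(ramp, grid, spec, field.itv)
        base = acc.sample_dose_at_displacement(ramp_field, gtv, 0.0)
        shifted = acc.sample_dose_at_displacement(ramp_field, gtv, 3.0)
        assert np.allclose(shifted - base, 3 * g, atol=1e-9)

    def test_beyond_range_clamped(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        a = acc.sample_dose_at_displacement(field, gtv, 40.0)
        b = acc.sample_dose_at_displacement(field, gtv, 15.0)
        assert np.array_equal(a, b)


class TestAccumulate:
    def test_all_zero_displacements_equal_static_dose(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        out = acc.accumulate(field, gtv, [0.0] * 5)
        assert np.array_equal(out.voxel_doses_gy, field.dose_gy[gtv.mask])

    def test_two_displacements_average(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        d1 = acc.sample_dose_at_displacement(field, gtv, -4.0)
        d2 = acc.sample_dose_at_displacement(field, gtv, 6.0)
        out = acc.accumulate(field, gtv, [-4.0, 6.0])
        assert np.allclose(out.voxel_doses_gy, (d1 + d2) / 2, atol=1e-12)

    def test_matches_brute_force_loop(self, tiny_setup, rng):
        _, gtv, _, field = tiny_setup
        displacements = rng.uniform(-12, 12, size=7)
        out = acc.accumulate(field, gtv, displacements)
        oracle = brute_force_accumulate(field, gtv, displacements)
        assert np.max(np.abs(out.voxel_doses_gy - oracle)) < 1e-12

    def test_concatenation_linearity(self, tiny_setup, rng):
        _, gtv, _, field = tiny_setup
        l1 = rng.uniform(-10, 10, size=4)
        l2 = rng.uniform(-10, 10, size=6)
        both = acc.accumulate(field, gtv, np.concatenate([l1, l2]))
        a1 = acc.accumulate(field, gtv, l1)
        a2 = acc.accumulate(field, gtv, l2)
        weighted = (4 * a1.voxel_doses_gy + 6 * a2.voxel_doses_gy) / 10
        assert np.max(np.abs(both.voxel_doses_gy - weighted)) < 1e-12

    def test_voxel_dose_within_per_sample_bounds(self, tiny_setup, rng):
        _, gtv, _, field = tiny_setup
        displacements = rng.uniform(-12, 12, size=5)
        singles = np.array(
            [acc.sample_dose_at_displacement(field, gtv, z) for z in displacements]
        )
        out = acc.accumulate(field, gtv, displacements)
        assert np.all(out.voxel_doses_gy <= singles.max(axis=0) + 1e-12)
        assert np.all(out.voxel_doses_gy >= singles.min(axis=0) - 1e-12)

    def test_empty_list_rejected(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        with pytest.raises(ValueError):
            acc.accumulate(field, gtv, [])


class TestAccumulate4dAndTrue:
    def test_4d_records_ten_samples(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        out = acc.accumulate_4d_traditional(field, gtv, np.linspace(-5, 5, 10))
        assert out.sample_count == 10

    def test_4d_requires_ten_phases(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        with pytest.raises(ValueError, match="10"):
            acc.accumulate_4d_traditional(field, gtv, [0.0] * 9)

    def test_true_sample_count_100s_at_0p4s(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        trace = motion.simulate_trace(motion.MotionParams(5, 0, 4, 0, duration_s=100))
        out = acc.accumulate_true(field, gtv, trace)
        assert out.sample_count == 250

    def test_zero_amplitude_trace_gives_static_dose(self, tiny_setup):
        _, gtv, _, field = tiny_setup
        t = np.arange(0, 100, 0.02)
        flat = motion.BreathingTrace(t, np.zeros_like(t), 0.02)
        out = acc.accumulate_true(field, gtv, flat)
        assert np.array_equal(out.voxel_doses_gy, field.dose_gy[gtv.mask])


class TestDoseAtVolume:
    def test_uniform_dose(self):
        assert acc.dose_at_volume(np.full(100, 60.0), 99, 60.0) == pytest.approx(100.0)

    def test_five_voxel_worked_example(self):
        voxels = np.array([70.0, 65.0, 60.0, 55.0, 50.0])
        assert acc.dose_at_volume(voxels, 60, 60.0) == pytest.approx(100.0)
        assert acc.dose_at_volume(voxels, 100, 60.0) == pytest.approx(83.3333, abs=1e-3)

    def test_matches_sort_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 101))
            doses = rng.uniform(20, 80, size=n)
            x = float(rng.uniform(0.5, 100))
            assert acc.dose_at_volume(doses, x, 60.0) == pytest.approx(
                sort_oracle_dx(doses, x, 60.0), abs=1e-12
            )

    def test_monotone_nonincreasing_in_x(self, rng):
        doses = rng.uniform(40, 80, size=500)
        values = [acc.dose_at_volume(doses, x, 60.0) for x in (5, 25, 50, 75, 95, 100)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_x_rejected(self):
        with pytest.raises(ValueError):
            acc.dose_at_volume(np.ones(5), 0, 60.0)


class TestDvhCurve:
    def test_monotone_and_starts_at_full_volume(self, tiny_setup):
        _, gtv, spec, field = tiny_setup
        out = acc.accumulate(field, gtv, [0.0, 3.0, -3.0])
        curve = acc.dvh_curve(out, spec.prescription_gy)
        assert curve.volume_fraction[0] == 1.0
        assert (np.diff(curve.volume_fraction) <= 0).all()

    def test_csv_roundtrip(self, tiny_setup, tmp_path):
        _, gtv, spec, field = tiny_setup
        curve = acc.dvh_curve(acc.accumulate(field, gtv, [0.0]), spec.prescription_gy)
        path = tmp_path / "dvh.csv"
        curve.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert np.allclose(data[:, 0], curve.dose_pct)
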