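"""Force-curve segmentation, event detection and mechanical metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mechanoca import (
    ForceCurve,
    ProbeMeta,
    analyze_curve,
    classify_load,
    compute_force,
    detect_contact_point,
    detect_rupture_events,
    measure_contact_time,
    measure_deformation_extent,
    measure_hysteresis_energy,
    measure_penetration_depth,
    segment_curve,
)
from mechanoca.errors import InvalidMetadataError, MalformedCurveError, PreconditionError
from mechanoca.force_curves import APPROACH, DWELL, RETRACT, HIGH_LOAD, LOW_LOAD
from mechanoca.synthetic import CurveConfig, gen_force_curve

from conftest import triangle_curve


# ---------------------------------------------------------------------------
# Hooke's law conversion


class TestComputeForce:
    @pytest.mark.parametrize(
        "k, d, expected",
        [(39.0, 10.0, 390.0), (39.0, 0.0, 0.0), (50.0, -2.0, -100.0)],
    )
    def test_single_values(self, k, d, expected):
        curve = triangle_curve(k=k)
        curve.deflection[:] = d
        assert compute_force(curve)[0] == pytest.approx(expected)

    def test_elementwise_oracle(self, rng):
        curve = triangle_curve()
        curve.deflection = rng.normal(0, 10, len(curve))
        force = compute_force(curve)
        oracle = np.array([39.0 * d for d in curve.deflection])
        np.testing.assert_array_equal(force, oracle)

    @given(alpha=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity(self, alpha):
        curve = triangle_curve()
        base = compute_force(curve)
        curve.deflection = alpha * curve.deflection
        np.testing.assert_allclose(compute_force(curve), alpha * base, rtol=1e-12)

    def test_bad_spring_constant(self):
        with pytest.raises(InvalidMetadataError):
            ProbeMeta(spring_constant=-1.0, indentation_speed=2.0)


# ---------------------------------------------------------------------------
# Segmentation


class TestSegmentCurve:
    def test_ramp_hold_ramp(self):
        curve = triangle_curve(dwell=1.0)
        labels = segment_curve(curve.time, curve.z)
        assert set(labels) == {APPROACH, DWELL, RETRACT}
        # order: approach before dwell before retract
        changes = np.flatnonzero(labels[:-1] != labels[1:])
        assert list(labels[changes]) == [APPROACH, DWELL]

    def test_strict_triangle_has_empty_dwell(self):
        # z ramps up and immediately down: the single apex sample belongs
        # to the approach and no sample is labeled dwell
        z = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)[1:]])
        t = np.arange(z.size) * 0.01
        labels = segment_curve(t, z)
        assert DWELL not in labels
        assert labels[49] == APPROACH and labels[50] == RETRACT

    def test_noisy_plateau_matches_exhaustive_scan(self, rng):
        curve = triangle_curve(dwell=1.0)
        z = curve.z + rng.normal(0, 1e-4, len(curve))
        tol = 1e-3
        labels = segment_curve(curve.time, z, plateau_tol=tol)
        # oracle: first attainment closes the approach; dwell is the
        # subsequent contiguous run within tol of max z
        at_max = z >= z.max() - tol
        first = int(np.argmax(at_max))
        expected = np.full(len(z), RETRACT, dtype="<U8")
        expected[: first + 1] = APPROACH
        i = first + 1
        while i < len(z) and at_max[i]:
            expected[i] = DWELL
            i += 1
        assert list(labels) == list(expected)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(MalformedCurveError):
            segment_curve(np.array([0.0, 1.0, 0.5, 2.0]), np.arange(4.0))


# ---------------------------------------------------------------------------
# Contact point


class TestContactPoint:
    def test_noiseless_changepoint_is_exact(self):
        curve = triangle_curve(contact_z=2.0, dz=0.01)
        index, contact_z = detect_contact_point(curve)
        assert contact_z == pytest.approx(2.0, abs=1e-12)
        assert curve.z[index] == contact_z

    def test_pure_noise_gives_no_contact(self, rng):
        curve = triangle_curve()
        curve.deflection = rng.normal(0, 2.0 / 39.0, len(curve))
        assert detect_contact_point(curve) is None

    def test_noisy_recovery_within_three_spacings(self):
        cfg = CurveConfig(force_noise_sd=2.0)
        failures = 0
        rng = np.random.default_rng(1234)
        for _ in range(20):
            curve, truth = gen_force_curve(cfg, LOW_LOAD, rng)
            _, contact_z = detect_contact_point(curve)
            if abs(contact_z - truth["contact_z_um"]) > 3 * truth["sample_spacing_um"]:
                failures += 1
        assert failures == 0


# ---------------------------------------------------------------------------
# Rupture events


def _rupture_curve(rupture_force=672.0, drop=300.0, k=39.0, dz=0.01):
    """Noiseless high-load curve with one injected drop."""
    slope = 400.0
    cz = 2.0
    z_r = cz + rupture_force / slope
    z_max = z_r + (2800.0 - (rupture_force - drop)) / slope
    n = int(round((z_max - 1.0) / dz))
    z_app = 1.0 + dz * np.arange(n + 1)
    f_app = np.clip(slope * (z_app - cz), 0, None)
    f_app = np.where(z_app > z_r + dz / 2, f_app - drop, f_app)
    z_ret = z_max - dz * np.arange(1, n + 1)
    f_ret = 0.5 * np.clip(f_app[-1] / (z_max - cz) * (z_ret - cz), 0, None)
    z = np.concatenate([z_app, z_ret])
    force = np.concatenate([f_app, f_ret])
    time = np.arange(z.size) * 1e-3
    meta = ProbeMeta(spring_constant=k, indentation_speed=20.0)
    return ForceCurve(time=time, z=z, deflection=force / k, meta=meta), z_r


class TestRuptureDetection:
    def test_monotone_force_has_no_events(self):
        curve = triangle_curve()
        index, _ = detect_contact_point(curve)
        assert detect_rupture_events(curve, index) == []

    def test_injected_drop_recovers_rupture_force(self):
        curve, z_r = _rupture_curve(rupture_force=672.0, drop=300.0)
        index, _ = detect_contact_point(curve)
        events = detect_rupture_events(curve, index)
        assert len(events) == 1
        ev = events[0]
        assert ev.force_before == pytest.approx(672.0, abs=5.0)
        assert ev.force_drop == pytest.approx(300.0, abs=5.0)
        assert ev.z_at_rupture == pytest.approx(z_r, abs=0.02)

    def test_subthreshold_drop_ignored(self):
        # 1% of the local force (6.7 nN at 672 nN) is the operative
        # threshold on a noiseless curve; the sampled drop magnitude is
        # the injected drop minus one sample's force rise (4 nN here)
        small, _ = _rupture_curve(rupture_force=672.0, drop=5.0)
        index, _ = detect_contact_point(small)
        assert detect_rupture_events(small, index) == []
        big, _ = _rupture_curve(rupture_force=672.0, drop=15.0)
        index, _ = detect_contact_point(big)
        assert len(detect_rupture_events(big, index)) == 1

    def test_requires_contact(self):
        curve = triangle_curve()
        with pytest.raises(PreconditionError):
            detect_rupture_events(curve, None)


class TestClassifyLoad:
    def test_load_class_is_a_function_of_rupture_presence_only(self):
        curve, _ = _rupture_curve()
        index, _ = detect_contact_point(curve)
        events = detect_rupture_events(curve, index)
        assert classify_load(events) == HIGH_LOAD
        assert classify_load([]) == LOW_LOAD

    def test_generator_presets_map_to_expected_classes(self, rng):
        cfg = CurveConfig()
        low, truth_low = gen_force_curve(cfg, LOW_LOAD, rng)
        high, truth_high = gen_force_curve(cfg, HIGH_LOAD, rng)
        f_low = analyze_curve(low)
        f_high = analyze_curve(high)
        assert f_low.load_class == LOW_LOAD
        assert f_low.max_force == pytest.approx(400.0, rel=0.05)
        assert f_high.load_class == HIGH_LOAD
        assert f_high.max_force == pytest.approx(2800.0, rel=0.05)


# ---------------------------------------------------------------------------
# Deformation, penetration, energy, contact time


class TestDeformationMetrics:
    def test_deformation_extent(self):
        curve = triangle_curve(contact_z=2.0, z_max=5.0, z_start=1.0)
        assert measure_deformation_extent(curve, 2.0) == pytest.approx(3.0)
        assert measure_deformation_extent(curve, curve.z.max()) == pytest.approx(0.0)
        assert measure_deformation_extent(curve, None) is None

    def test_penetration_depth_from_first_rupture(self):
        curve, z_r = _rupture_curve()
        index, _ = detect_contact_point(curve)
        events = detect_rupture_events(curve, index)
        depth = measure_penetration_depth(curve, events)
        assert depth == pytest.approx(curve.z.max() - z_r, abs=0.02)
        assert measure_penetration_depth(curve, []) is None

    def test_generator_ground_truth_recovery(self, rng):
        cfg = CurveConfig(force_noise_sd=0.0)
        curve, truth = gen_force_curve(cfg, HIGH_LOAD, rng)
        feats = analyze_curve(curve)
        spacing = truth["sample_spacing_um"]
        assert feats.deformation_extent == pytest.approx(
            truth["deformation_extent_um"], abs=spacing
        )
        assert feats.penetration_depth == pytest.approx(
            truth["penetration_depth_um"], abs=spacing
        )
        assert feats.rupture.force_before == pytest.approx(
            truth["rupture_force_nN"], abs=1.0
        )


class TestHysteresisEnergy:
    def test_identical_paths_dissipate_nothing(self):
        curve = triangle_curve(retract_scale=1.0)
        index, cz = detect_contact_point(curve)
        assert measure_hysteresis_energy(curve, index, cz) == pytest.approx(0.0, abs=1e-9)

    def test_triangle_fixture_is_exactly_50_fJ(self):
        # approach rises 0 -> 100 nN over 1 um of contact; retract == 0
        curve = triangle_curve(
            contact_z=0.0, z_max=1.0, z_start=0.0, slope_nn_per_um=100.0,
            retract_scale=0.0, dz=0.01,
        )
        energy = measure_hysteresis_energy(curve, 0, 0.0)
        assert energy == pytest.approx(50.0, abs=1e-9)

    def test_matches_fine_grid_quadrature_within_1_percent(self):
        # smooth, non-linear force paths sampled at moderate resolution
        cz, zmax = 1.0, 4.0
        z_app = np.linspace(0.0, zmax, 300)
        f_app = np.where(z_app > cz, 200 * np.sin(np.pi * (z_app - cz) / 6.0) ** 2, 0.0)
        z_ret = z_app[::-1][1:]
        f_ret = 0.5 * np.where(z_ret > cz, 200 * np.sin(np.pi * (z_ret - cz) / 6.0) ** 2, 0.0)
        time = np.arange(z_app.size + z_ret.size) * 1e-3
        meta = ProbeMeta(spring_constant=39.0, indentation_speed=2.0)
        curve = ForceCurve(
            time=time,
            z=np.concatenate([z_app, z_ret]),
            deflection=np.concatenate([f_app, f_ret]) / 39.0,
            meta=meta,
        )
        energy = measure_hysteresis_energy(curve, int(np.searchsorted(z_app, cz)), cz)
        zf = np.linspace(cz, zmax, 200001)
        f = 200 * np.sin(np.pi * (zf - cz) / 6.0) ** 2
        oracle = np.trapezoid(f - 0.5 * f, zf)
        assert energy == pytest.approx(oracle, rel=0.01)

    def test_invariant_under_time_reparameterization(self):
        curve = triangle_curve(retract_scale=0.5)
        index, cz = detect_contact_point(curve)
        e1 = measure_hysteresis_energy(curve, index, cz)
        warped = ForceCurve(
            time=np.cumsum(np.linspace(0.5, 2.0, len(curve))),
            z=curve.z.copy(),
            deflection=curve.deflection.copy(),
            meta=curve.meta,
        )
        e2 = measure_hysteresis_energy(warped, index, cz)
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestContactTime:
    def test_symmetric_kinematics_with_dwell(self):
        # speed 2 um/s, 1 um deformation each way, dwell 1 s -> 2.0 s
        curve = triangle_curve(
            contact_z=2.0, z_max=3.0, speed=2.0, dwell=1.0, dz=0.01
        )
        index, _ = detect_contact_point(curve)
        ct = measure_contact_time(curve, index)
        assert ct == pytest.approx(2.0, abs=2 * 0.01 / 2.0)

    def test_contact_time_grid_recovered_within_10_percent(self):
        rng = np.random.default_rng(7)
        for target in (0.1, 0.2, 1.0, 1.1, 1.2, 2.0):
            cfg = CurveConfig(dwell=max(0.0, target - 0.1))
            curve, truth = gen_force_curve(cfg, LOW_LOAD, rng)
            feats = analyze_curve(curve)
            assert truth["contact_time_s"] == pytest.approx(target, rel=0.02)
            assert feats.contact_time == pytest.approx(target, rel=0.10)

    def test_ground_truth_recovery_within_two_samples(self, rng):
        cfg = CurveConfig(force_noise_sd=0.0, dwell=0.5)
        curve, truth = gen_force_curve(cfg, LOW_LOAD, rng)
        feats = analyze_curve(curve)
        dt = 1.0 / cfg.sample_rate
        assert feats.contact_time == pytest.approx(truth["contact_time_s"], abs=2 * dt)
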