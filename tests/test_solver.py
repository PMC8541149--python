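import numpy as np
import pytest

import sloshsim as ss
from sloshsim.errors import InstabilityError, ValidationError
from sloshsim.materials import CoefficientField



def make_system(name, anatomy, materials, numerics):
    cfg = ss.apply_pattern(anatomy, ss.SyrinxPattern.from_name(name))
    coeffs = ss.derive_coefficients(materials, cfg, numerics)
    return ss.assemble(cfg, coeffs, materials, numerics)


@pytest.fixture(scope="module")
def smoke_numerics():
    """Coarse, short runs for cheap structural checks."""
    return ss.NumericsOptions(dx_mm=2.5, duration_s=0.25, gamma=1.0)


@pytest.fixture(scope="module")
def smoke_anatomy():
    return ss.synthesize_anatomy(ss.AnatomyParams(grid_spacing_mm=2.5))


class TestAssemble:
    def test_baseline_has_no_syrinx_fluid(self, smoke_anatomy, default_materials, smoke_numerics):
        system = make_system("baseline", smoke_anatomy, default_materials, smoke_numerics)
        assert not system.fluid_center.any()
        assert not system.fluid_face.any()
        assert np.all(system.A_f0 == 0.0)

    def test_excitation_acts_only_on_205_to_325(
        self, smoke_anatomy, default_materials, smoke_numerics
    ):
        system = make_system("baseline", smoke_anatomy, default_materials, smoke_numerics)
        x = system.x / 1e-3
        assert np.array_equal(system.exc_mask, (x >= 205 - 1e-6) & (x <= 325 + 1e-6))

    def test_syrinx_fluid_faces_interior_to_cavity(
        self, smoke_anatomy, default_materials, smoke_numerics
    ):
        system = make_system("S8", smoke_anatomy, default_materials, smoke_numerics)
        # fluid faces only where both neighbouring centers hold fluid
        inner = system.fluid_center[:-1] & system.fluid_center[1:]
        assert np.array_equal(system.fluid_face[1:-1], inner)


class TestStableTimestep:
    def test_halving_dx_halves_dt(self, default_materials):
        dts = {}
        for dx in (2.5, 1.25):
            anat = ss.synthesize_anatomy(ss.AnatomyParams(grid_spacing_mm=dx))
            num = ss.NumericsOptions(dx_mm=dx, gamma=1.0)
            dts[dx] = make_system("baseline", anat, default_materials, num).dt
        assert dts[1.25] == pytest.approx(dts[2.5] / 2.0, rel=1e-9)

    def test_quadrupling_bulk_modulus_halves_dt(self, smoke_anatomy, default_materials):
        dts = {}
        for ka in (1e7, 4e7):
            num = ss.NumericsOptions(dx_mm=2.5, bulk_modulus_pa=ka, gamma=1.0)
            dts[ka] = make_system("baseline", smoke_anatomy, default_materials, num).dt
        assert dts[4e7] == pytest.approx(dts[1e7] / 2.0, rel=1e-6)

    def test_zero_safety_rejected(self, smoke_anatomy, default_materials, smoke_numerics):
        system = make_system("baseline", smoke_anatomy, default_materials, smoke_numerics)
        with pytest.raises(ValidationError):
            ss.stable_timestep(system, safety=0.0)


class TestRun:
    def test_zero_amplitude_keeps_all_fields_identically_zero(
        self, smoke_anatomy, default_materials, smoke_numerics
    ):
        system = make_system("S8", smoke_anatomy, default_materials, smoke_numerics)
        result = ss.run(system, ss.ExcitationSpec(amplitude_half_pa=0.0))
        for name, field in result.fields.items():
            assert np.all(field == 0.0), name
        assert np.all(result.raw_peak_stress == 0.0)

    def test_instability_reports_step_and_station(
        self, smoke_anatomy, default_materials, smoke_numerics
    ):
        system = make_system("baseline", smoke_anatomy, default_materials, smoke_numerics)
        system.dt = ss.stable_timestep(system, safety=10.0)  # deliberately unstable
        with pytest.raises(InstabilityError) as exc:
            ss.run(system)
        assert exc.value.step > 0
        assert np.isfinite(exc.value.x_mm)

    def test_peak_map_independent_of_output_stride(
        self, smoke_anatomy, default_materials
    ):
        results = []
        for stride in (1e-3, 1e-2):
            num = ss.NumericsOptions(dx_mm=2.5, duration_s=0.25, gamma=1.0, output_stride_s=stride)
            system = make_system("S8", smoke_anatomy, default_materials, num)
            results.append(ss.run(system, store_fields=False))
        assert np.array_equal(results[0].raw_peak_stress, results[1].raw_peak_stress)

    def test_drag_exchange_equal_and_opposite(self, s8_run):
        result, _, _ = s8_run
        cord = result.audit["drag_impulse_cord"]
        fluid = result.audit["drag_impulse_fluid"]
        assert np.any(fluid != 0.0)  # drag actually exchanged
        assert np.allclose(cord, fluid, rtol=1e-12, atol=1e-300)

    def test_result_round_trips_through_hdf5(self, tmp_path, smoke_anatomy, default_materials, smoke_numerics):
        system = make_system("S3", smoke_anatomy, default_materials, smoke_numerics)
        result = ss.run(system)
        path = tmp_path / "s3.h5"
        result.save(str(path))
        again = ss.SimulationResult.load(str(path))
        assert np.array_equal(again.raw_peak_stress, result.raw_peak_stress)
        assert np.array_equal(again.fields["p_s"], result.fields["p_s"])
        assert again.meta["name"] == "S3"


class TestStressField:
    def test_gamma_missing_instructs_calibration(self, baseline_run):
        result, _, coeffs = baseline_run
        blank = CoefficientField(
            C_f=coeffs.C_f, C_w=coeffs.C_w, D_f=coeffs.D_f, D_s=coeffs.D_s,
            K_a=coeffs.K_a, gamma=None,
        )
        with pytest.raises(ValidationError, match="calibrat"):
            ss.stress_field(result, blank)
        with pytest.raises(ValidationError, match="calibrat"):
            ss.peak_stress(result, blank)

    def test_gamma_scales_reported_stress_exactly(self, baseline_run):
        result, _, coeffs = baseline_run
        double = CoefficientField(
            C_f=coeffs.C_f, C_w=coeffs.C_w, D_f=coeffs.D_f, D_s=coeffs.D_s,
            K_a=coeffs.K_a, gamma=2.0,
        )
        assert np.array_equal(
            ss.peak_stress(result, double), 2.0 * ss.peak_stress(result, coeffs)
        )

    def test_uniform_displacement_gives_zero_interior_stress(self, baseline_run):
        result, _, coeffs = baseline_run
        frozen = ss.SimulationResult(
            x_mm=result.x_mm,
            t=result.t[:1],
            fields={"w": np.full((1, len(result.x_mm)), 1e-4)},
            raw_peak_stress=np.zeros(len(result.x_mm)),
            audit=result.audit,
            meta=result.meta,
        )
        s = ss.stress_field(frozen, coeffs)
        assert np.allclose(s[0, 1:-1], 0.0, atol=1e-12)

    def test_baseline_stress_finite_and_nonzero(self, baseline_run):
        result, _, coeffs = baseline_run
        peaks = ss.peak_stress(result, coeffs)
        assert np.isfinite(peaks).all()
        assert peaks.max() > 0


class TestVolumeAudit:
    def test_zero_excitation_reports_zero_residual(
        self, smoke_anatomy, default_materials, smoke_numerics
    ):
        system = make_system("baseline", smoke_anatomy, default_materials, smoke_numerics)
        audit = ss.volume_audit(ss.run(system, ss.ExcitationSpec(amplitude_half_pa=0.0)))
        assert audit["peak_injected"] == 0.0
        assert audit["residual_fraction"] == 0.0

    def test_larger_bulk_modulus_shrinks_compressibility_storage(
        self, smoke_anatomy, default_materials
    ):
        stores = []
        for ka in (1e7, 4e7):
            num = ss.NumericsOptions(dx_mm=2.5, duration_s=0.25, bulk_modulus_pa=ka, gamma=1.0)
            system = make_system("baseline", smoke_anatomy, default_materials, num)
            result = ss.run(system, store_fields=False)
            stores.append(np.max(np.abs(result.audit["compressibility"])))
        assert stores[1] < stores[0]
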