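import pytest

import sloshsim as ss


@pytest.fixture(scope="session")
def default_anatomy():
    return ss.synthesize_anatomy()


@pytest.fixture(scope="session")
def default_materials():
    return ss.MaterialSet()


@pytest.fixture(scope="session")
def raw_numerics():
    """Default numerics with unit stress scale (pre-calibration)."""
    return ss.NumericsOptions(gamma=1.0)


def simulate(name, anatomy, materials, numerics, store_fields=True):
    cfg = ss.apply_pattern(anatomy, ss.SyrinxPattern.from_name(name))
    coeffs = ss.derive_coefficients(materials, cfg, numerics)
    system = ss.assemble(cfg, coeffs, materials, numerics)
    return ss.run(system, store_fields=store_fields), cfg, coeffs


@pytest.fixture(scope="session")
def baseline_run(default_anatomy, default_materials, raw_numerics):
    """Baseline (syrinx-free) run at default resolution, shared session-wide."""
    return simulate("baseline", default_anatomy, default_materials, raw_numerics)


@pytest.fixture(scope="session")
def s8_run(default_anatomy, default_materials, raw_numerics):
    """Isolated cervico-thoracic syrinx S8, shared session-wide."""
    return simulate("S8", default_anatomy, default_materials, raw_numerics)


@pytest.fixture(scope="session")
def baseline_profile(baseline_run):
    result, _, _ = baseline_run
    pmap = ss.peak_stress_map(result.raw_peak_stress, result.x_mm)
    return ss.slice_medians(pmap)


def profile_of(result):
    return ss.slice_medians(ss.peak_stress_map(result.raw_peak_stress, result.x_mm))


@pytest.fixture(scope="session")
def suite_profiles(default_anatomy, default_materials, raw_numerics, baseline_run):
    """Slice-median stress profiles for the configurations the pattern checks
    need: baseline, all 28 isolated syringes, and the expansion stages 1-10
    plus the fully developed syrinx."""
    profiles = {"baseline": profile_of(baseline_run[0])}
    extents = {}
    names = [f"S{i}" for i in range(1, 29)]
    names += [f"S1-{j}" for j in range(1, 11)] + ["S1-28"]
    for name in names:
        result, cfg, _ = simulate(
            name, default_anatomy, default_materials, raw_numerics, store_fields=False
        )
        profiles[name] = profile_of(result)
        extents[name] = cfg.pattern.extent_mm()
    return profiles, extents
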