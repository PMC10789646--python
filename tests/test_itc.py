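import math

import numpy as np
import pytest

from xlquant.itc import (
    DEFAULT_INJECTIONS,
    FlatIsothermError,
    ITCProtocol,
    Isotherm,
    OneSiteParams,
    R_KCAL,
    bound_fraction,
    concentrations_after_injection,
    fit_one_site,
    read_isotherm_csv,
    simulate_isotherm,
    thermodynamics,
    write_isotherm_csv,
)

from oracles import theta_by_bisection


@pytest.fixture
def protocol():
    return ITCProtocol()


class TestConcentrations:
    def test_no_injection_limit(self):
        tiny = ITCProtocol(injection_volumes_ul=(1e-9,))
        mt, xt = concentrations_after_injection(tiny, 1)
        assert mt == pytest.approx(tiny.cell_conc_uM, rel=1e-8)
        assert xt == pytest.approx(0.0, abs=1e-6)

    def test_full_protocol_dilution_by_hand(self, protocol):
        # cumulative 0.4 + 18*2 = 36.4 ul into 200 ul: d = 36.4/400 = 0.091
        mt, xt = concentrations_after_injection(protocol, 19)
        assert mt == pytest.approx(protocol.cell_conc_uM * (1 - 0.091) / (1 + 0.091))
        assert xt == pytest.approx(protocol.syringe_conc_uM * (36.4 / 200) / (1 + 0.091))

    def test_depends_only_on_cumulative_volume(self):
        one = ITCProtocol(injection_volumes_ul=(4.0,))
        two = ITCProtocol(injection_volumes_ul=(2.0, 2.0))
        assert concentrations_after_injection(one, 1) == pytest.approx(
            concentrations_after_injection(two, 2)
        )

    def test_monotonic(self, protocol):
        pairs = [concentrations_after_injection(protocol, i) for i in range(1, 20)]
        mts, xts = zip(*pairs)
        assert all(a > b for a, b in zip(mts, mts[1:]))
        assert all(a < b for a, b in zip(xts, xts[1:]))

    def test_validity_errors(self, protocol):
        with pytest.raises(ValueError):
            concentrations_after_injection(protocol, 0)
        with pytest.raises(ValueError):
            concentrations_after_injection(protocol, 20)
        huge = ITCProtocol(injection_volumes_ul=(500.0,))
        with pytest.raises(ValueError, match="validity"):
            concentrations_after_injection(huge, 1)


def test_bound_fraction_matches_bisection(rng):
    for _ in range(12):
        xt = float(rng.uniform(1, 400))
        mt = float(rng.uniform(10, 120))
        N = float(rng.uniform(0.5, 2.0))
        kd = float(10 ** rng.uniform(-1, 2.7))
        theta = bound_fraction(xt, mt, N, kd)
        assert 0.0 <= theta <= 1.0
        assert theta == pytest.approx(theta_by_bisection(xt, mt, N, kd), abs=1e-10)


class TestSimulate:
    def test_null_enthalpy_gives_zero_heats(self, protocol):
        iso = simulate_isotherm(OneSiteParams(N=1, Kd_uM=25, dH_kcal=0.0), protocol)
        assert np.allclose(iso.raw_heat_ucal, 0.0)
        assert np.allclose(iso.molar_heat, 0.0)

    def test_tight_binding_saturation(self, protocol):
        iso = simulate_isotherm(OneSiteParams(N=1, Kd_uM=1e-6, dH_kcal=-8.0), protocol)
        early = iso.molar_heat[(~iso.discarded) & (iso.molar_ratio < 0.5)]
        late = iso.molar_heat[iso.molar_ratio > 1.5]
        assert np.allclose(early, -8.0, atol=0.05)
        assert np.allclose(late, 0.0, atol=0.05)

    def test_first_injection_flagged_and_ratios_increase(self, protocol):
        iso = simulate_isotherm(OneSiteParams(N=1, Kd_uM=25, dH_kcal=-8.0), protocol)
        assert iso.discarded[0] and not iso.discarded[1:].any()
        assert (np.diff(iso.molar_ratio) > 0).all()

    def test_noise_is_seeded(self, protocol):
        p = OneSiteParams(N=1, Kd_uM=25, dH_kcal=-8.0)
        a = simulate_isotherm(p, protocol, noise_sd_ucal=0.5, seed=7)
        b = simulate_isotherm(p, protocol, noise_sd_ucal=0.5, seed=7)
        c = simulate_isotherm(p, protocol, noise_sd_ucal=0.5, seed=8)
        assert np.array_equal(a.raw_heat_ucal, b.raw_heat_ucal)
        assert not np.array_equal(a.raw_heat_ucal, c.raw_heat_ucal)

    def test_larger_kd_flattens_transition(self, protocol):
        def max_slope(kd):
            iso = simulate_isotherm(OneSiteParams(N=1, Kd_uM=kd, dH_kcal=-8.0), protocol)
            return np.max(np.abs(np.diff(iso.molar_heat) / np.diff(iso.molar_ratio)))

        slopes = [max_slope(kd) for kd in (1.0, 10.0, 50.0, 250.0)]
        assert all(a > b for a, b in zip(slopes, slopes[1:]))


class TestFit:
    def test_round_trip_noise_free(self, protocol):
        true = OneSiteParams(N=1.3, Kd_uM=40.0, dH_kcal=-6.5, offset_kcal=-0.08)
        iso = simulate_isotherm(true, protocol)
        init = OneSiteParams(N=1.3 * 0.7, Kd_uM=40.0 * 1.3, dH_kcal=-6.5 * 0.7, offset_kcal=0.0)
        fit = fit_one_site(iso, protocol, init)
        assert fit.converged
        assert fit.params.N == pytest.approx(true.N, rel=1e-3)
        assert fit.params.Kd_uM == pytest.approx(true.Kd_uM, rel=1e-3)
        assert fit.params.dH_kcal == pytest.approx(true.dH_kcal, rel=1e-3)

    def test_self_initialized_fit(self, protocol):
        true = OneSiteParams(N=0.95, Kd_uM=25.0, dH_kcal=-8.0, offset_kcal=-0.05)
        fit = fit_one_site(simulate_isotherm(true, protocol), protocol)
        assert fit.params.Kd_uM == pytest.approx(25.0, rel=1e-3)

    def test_flat_isotherm_refused(self, protocol):
        iso = simulate_isotherm(OneSiteParams(N=1, Kd_uM=25, dH_kcal=0.0), protocol)
        with pytest.raises(FlatIsothermError, match="flat isotherm"):
            fit_one_site(iso, protocol)

    def test_discarded_injection_value_is_ignored(self, protocol):
        true = OneSiteParams(N=1.0, Kd_uM=25.0, dH_kcal=-8.0)
        iso = simulate_isotherm(true, protocol)
        perturbed = Isotherm(
            molar_ratio=iso.molar_ratio.copy(),
            molar_heat=iso.molar_heat.copy(),
            raw_heat_ucal=iso.raw_heat_ucal.copy(),
            discarded=iso.discarded.copy(),
        )
        perturbed.raw_heat_ucal[0] += 100.0
        perturbed.molar_heat[0] += 50.0
        init = OneSiteParams(N=1.2, Kd_uM=20.0, dH_kcal=-7.0)
        a = fit_one_site(iso, protocol, init)
        b = fit_one_site(perturbed, protocol, init)
        assert a.params == b.params

    def test_stderr_intervals_cover_truth(self, protocol):
        """±2 SE intervals from the local quadratic approximation should cover
        the truth for most noisy realizations (loose calibration)."""
        true = OneSiteParams(N=1.0, Kd_uM=25.0, dH_kcal=-8.0, offset_kcal=-0.05)
        covered = {"N": 0, "Kd_uM": 0, "dH_kcal": 0}
        n_seeds = 25
        for seed in range(n_seeds):
            iso = simulate_isotherm(true, protocol, noise_sd_ucal=0.5, seed=seed)
            fit = fit_one_site(iso, protocol, init=true)
            for name in covered:
                est = getattr(fit.params, name)
                tv = getattr(true, name)
                if abs(est - tv) <= 2 * fit.stderr[name]:
                    covered[name] += 1
        for name, k in covered.items():
            assert k / n_seeds >= 0.8, (name, k)


class TestThermodynamics:
    def test_reference_state(self):
        dg, _ = thermodynamics(OneSiteParams(N=1, Kd_uM=1e6, dH_kcal=-8.0), 288.15)
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_identity(self):
        p = OneSiteParams(N=1, Kd_uM=24.6, dH_kcal=-8.0)
        dg, mtds = thermodynamics(p, 288.15)
        assert dg == pytest.approx(p.dH_kcal + mtds, abs=1e-12)

    def test_bromodomain_affinity_free_energy(self):
        # Kd = 24.6 uM at 15 C
        dg, _ = thermodynamics(OneSiteParams(N=1, Kd_uM=24.6, dH_kcal=-8.0), 288.15)
        assert dg == pytest.approx(R_KCAL * 288.15 * math.log(24.6e-6), abs=1e-12)
        assert dg < 0  # spontaneous binding


def test_isotherm_csv_round_trip(tmp_path, protocol):
    iso = simulate_isotherm(OneSiteParams(N=1, Kd_uM=25, dH_kcal=-8.0), protocol, 0.5, seed=3)
    path = tmp_path / "iso.csv"
    write_isotherm_csv(iso, protocol, path)
    back = read_isotherm_csv(path, protocol)
    assert np.allclose(back.raw_heat_ucal, iso.raw_heat_ucal)
    assert np.allclose(back.molar_heat, iso.molar_heat)
    assert np.array_equal(back.discarded, iso.discarded)


def test_default_protocol_geometry():
    assert DEFAULT_INJECTIONS[0] == 0.4
    assert len(DEFAULT_INJECTIONS) == 19
    assert set(DEFAULT_INJECTIONS[1:]) == {2.0}
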