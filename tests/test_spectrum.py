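import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glandfrac.materials import PathComposition, mu_at, reference_composition
from glandfrac.spectrum import (
    EnergySpectrum,
    NoSolutionError,
    UnsupportedConfigurationError,
    build_spectrum,
    effective_energy,
    effective_energy_from_mu,
    loss_percent_error,
    poly_transmission,
    read_spectrum,
    write_spectrum,
)


def _fwhm(spec):
    w = spec.normalized_weights
    half = w.max() / 2
    above = spec.energies[w >= half]
    return above.max() - above.min()


class TestBuildSpectrum:
    def test_study_beam_bins_and_mode(self):
        s = build_spectrum(28, "W", "Al", 0.7, bin_width=2.0, e_min=14.0)
        assert len(s.energies) == 8
        assert s.energies[0] == 14.0 and s.energies[-1] == 28.0
        mode = s.energies[np.argmax(s.weights)]
        assert 18.0 <= mode <= 22.0

    def test_filtration_removes_relative_low_energy_weight(self):
        bare = build_spectrum(28, "W", None, 0.0, bin_width=1.0)
        filtered = build_spectrum(28, "W", "Al", 0.7, bin_width=1.0)
        low = bare.energies <= 16.0
        assert (bare.normalized_weights[low].sum()
                > filtered.normalized_weights[low].sum())

    def test_silver_beam_core_is_narrower(self, wal, wag):
        """The W/Ag clinical beam concentrates under the Ag K edge; its
        full-width-at-half-maximum is smaller than the broad W/Al beam's."""
        al_1kev = build_spectrum(28, "W", "Al", 0.7, bin_width=1.0)
        assert _fwhm(wag) < _fwhm(al_1kev)
        assert wag.energies[np.argmax(wag.weights)] < 25.514  # under the edge

    def test_unsupported_configuration(self):
        with pytest.raises(UnsupportedConfigurationError):
            build_spectrum(28, "Mo")
        with pytest.raises(UnsupportedConfigurationError):
            build_spectrum(28, "W", "Cu", 0.1)
        with pytest.raises(ValueError):
            build_spectrum(55)

    def test_spectrum_invariants(self):
        with pytest.raises(ValueError):
            EnergySpectrum(np.array([20.0, 30.0]), np.array([1.0, 1.0]), kvp=28.0)
        with pytest.raises(ValueError):
            EnergySpectrum(np.array([15.0, 20.0]), np.array([0.0, 0.0]), kvp=28.0)

    def test_round_trip_file(self, tmp_path, wal):
        path = tmp_path / "spec.txt"
        write_spectrum(path, wal)
        back = read_spectrum(path, kvp=wal.kvp)
        np.testing.assert_allclose(back.energies, wal.energies)
        np.testing.assert_allclose(back.weights, wal.weights, rtol=1e-6)


class TestPolyTransmission:
    def test_zero_length_path(self, wal, tables):
        assert poly_transmission(wal, PathComposition(), tables) == pytest.approx(1.0)

    def test_monochromatic_reduces_to_beer_lambert(self, tables):
        mono = EnergySpectrum.monochromatic(20.0)
        comp = PathComposition(adipose=1.0)
        expected = np.exp(-mu_at(tables["adipose"], 20.0) * 1.0)
        assert poly_transmission(mono, comp, tables) == pytest.approx(expected, rel=1e-14)

    def test_against_independent_per_bin_summation(self, wal, tables):
        """Brute-force oracle: explicit python loop over bins and materials."""
        comp = PathComposition(lexan=0.5, skin=0.145, adipose=2.0, glandular=2.0)
        num = 0.0
        den = 0.0
        for e, w in zip(wal.energies, wal.weights):
            optical = 0.0
            for name, t in comp.items():
                optical += mu_at(tables[name], float(e)) * t
            num += w * np.exp(-optical)
            den += w
        assert poly_transmission(wal, comp, tables) == pytest.approx(num / den, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(extra=st.floats(0.01, 2.0),
           which=st.sampled_from(["lexan", "skin", "adipose", "glandular"]))
    def test_strictly_decreasing_in_each_component(self, wal, tables, extra, which):
        base = dict(lexan=0.3, skin=0.2, adipose=1.0, glandular=0.5)
        grown = dict(base)
        grown[which] += extra
        assert (poly_transmission(wal, PathComposition(**grown), tables)
                < poly_transmission(wal, PathComposition(**base), tables))


class TestEffectiveEnergy:
    def test_monochromatic_line_is_its_own_effective_energy(self, tables):
        mono = EnergySpectrum.monochromatic(20.0)
        res = effective_energy(mono, PathComposition(adipose=3.0), tables)
        assert res.e_eff == pytest.approx(20.0, abs=1e-9)

    def test_matches_brute_force_grid_search(self, wal, tables):
        comp = reference_composition(5.0, 0.3)
        res = effective_energy(wal, comp, tables)
        # 1 eV brute-force scan of |mu_mix(E) - mu_eq|
        grid = np.arange(wal.energies[0], wal.energies[-1], 1e-3)
        mu_mix = comp.mu_mix(grid, tables)
        e_brute = grid[np.argmin(np.abs(mu_mix - res.mu_equivalent))]
        assert abs(res.e_eff - e_brute) < 0.01

    def test_range_over_study_grid(self, wal, tables):
        """Effective energies across 2-9 cm and 20-50% glandular fractions
        stay within the 20.65-22.25 keV mammographic band (+-0.5 keV)."""
        vals = [
            effective_energy(wal, reference_composition(T, g), tables).e_eff
            for T in range(2, 10) for g in (0.2, 0.3, 0.5)
        ]
        assert min(vals) > 20.65 - 0.5
        assert max(vals) < 22.25 + 0.5

    def test_idempotent_on_its_own_monochromatic_image(self, wal, tables):
        comp = reference_composition(4.0, 0.5)
        e1 = effective_energy(wal, comp, tables).e_eff
        mono = EnergySpectrum.monochromatic(e1)
        assert effective_energy(mono, comp, tables).e_eff == pytest.approx(e1, abs=1e-9)

    def test_mu_mix_at_e_eff_between_support_extremes(self, wal, tables):
        comp = PathComposition(adipose=2.0, glandular=2.0)
        res = effective_energy(wal, comp, tables)
        lo = comp.mu_mix(float(wal.energies[-1]), tables)
        hi = comp.mu_mix(float(wal.energies[0]), tables)
        assert lo <= res.mu_equivalent <= hi

    def test_added_filtration_raises_effective_energy(self, tables):
        comp = reference_composition(4.0, 0.5)
        soft = build_spectrum(28, "W", "Al", 0.2, bin_width=1.0)
        hard = build_spectrum(28, "W", "Al", 1.5, bin_width=1.0)
        assert (effective_energy(hard, comp, tables).e_eff
                > effective_energy(soft, comp, tables).e_eff)

    def test_no_solution_error(self, tables):
        comp = PathComposition(adipose=1.0)
        with pytest.raises(NoSolutionError):
            effective_energy_from_mu(99.0, comp, 14.0, 28.0, tables)


class TestLossPercentError:
    def test_arithmetic(self):
        assert loss_percent_error(1.0, 0.5, 0.5) == 0.0
        assert loss_percent_error(1.0, 1 - 0.505, 1 - 0.500) == pytest.approx(1.0)

    def test_zero_mono_loss(self):
        with pytest.raises(ZeroDivisionError):
            loss_percent_error(1.0, 0.9, 1.0)
        with pytest.raises(ValueError):
            loss_percent_error(0.0, 0.5, 0.5)
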