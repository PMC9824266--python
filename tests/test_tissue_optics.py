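"""Tissue optical-property model: chromophore mixing, skin layers, materials."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemophoton import tissue_optics as to
from hemophoton.tissue_optics import (
    DEFAULT_CHROMOPHORES,
    SKIN_SUBLAYER_EDGES_MM,
    SKIN_SUBLAYERS,
    BloodState,
    OpticalProperties,
    SkinSublayerSpec,
    baseline_absorption,
    blood_absorption,
    epidermis_absorption,
    material_properties,
    skin_sublayer_absorption,
    stratum_corneum_absorption,
)


class TestBaseline:
    @pytest.mark.parametrize(
        "wavelength, expected", [(465.0, 0.163), (525.0, 0.110), (615.0, 0.066)]
    )
    def test_reproduces_tabulated_row(self, wavelength, expected):
        assert baseline_absorption(wavelength) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("wavelength", [200.0, 1500.0])
    def test_rejects_out_of_range_wavelength(self, wavelength):
        with pytest.raises(ValueError):
            baseline_absorption(wavelength)


class TestBloodAbsorption:
    @pytest.mark.parametrize("wavelength", [465.0, 525.0, 615.0])
    def test_pure_oxy_and_deoxy_limits(self, wavelength):
        hbo = BloodState(hba1c=0.0, spo2_arterial=1.0)
        hhb = BloodState(hba1c=0.0, spo2_arterial=0.0)
        assert blood_absorption(hbo, "arterial", wavelength) == pytest.approx(
            DEFAULT_CHROMOPHORES.hbo(wavelength)
        )
        assert blood_absorption(hhb, "arterial", wavelength) == pytest.approx(
            DEFAULT_CHROMOPHORES.hhb(wavelength)
        )

    def test_mixture_matches_direct_arithmetic(self):
        # oracle: mu_HHb + SpO2 (1-A) (mu_HbO - mu_HHb) + A (mu_A1c - mu_HHb)
        expected = 1.76 + 0.97 * 0.94 * (0.27 - 1.76) + 0.06 * (39.66 - 1.76)
        state = BloodState(hba1c=0.06, spo2_arterial=0.97)
        assert blood_absorption(state, "arterial", 615.0) == pytest.approx(expected)

    def test_venous_uses_offset_reduced_spo2(self):
        state = BloodState(hba1c=0.06, spo2_arterial=0.97)
        direct = blood_absorption(
            BloodState(hba1c=0.06, spo2_arterial=0.87), "arterial", 615.0
        )
        assert blood_absorption(state, "venous", 615.0) == pytest.approx(direct)

    @pytest.mark.parametrize("wavelength", [465.0, 525.0, 615.0])
    def test_affine_in_hba1c_and_spo2(self, wavelength):
        # three-point collinearity in each argument
        f = lambda a, s: blood_absorption(
            BloodState(hba1c=a, spo2_arterial=s), "arterial", wavelength
        )
        a0, a1, a2 = 0.03, 0.08, 0.13
        assert f(a1, 0.9) == pytest.approx(0.5 * (f(a0, 0.9) + f(a2, 0.9)))
        s0, s1, s2 = 0.7, 0.85, 1.0
        assert f(0.06, s1) == pytest.approx(0.5 * (f(0.06, s0) + f(0.06, s2)))

    def test_rejects_out_of_range_state(self):
        with pytest.raises(ValueError):
            BloodState(hba1c=0.5)
        with pytest.raises(ValueError):
            BloodState(spo2_arterial=1.5)

    def test_unlisted_wavelength_fails_loudly(self):
        with pytest.raises(KeyError):
            blood_absorption(BloodState(), "arterial", 800.0)


class TestSkinLayers:
    def test_stratum_corneum_value(self):
        # oracle in the cm^-1 convention with the baseline power law
        base_cm = 7.8375e8 * 465.0**-3.255
        water_cm = DEFAULT_CHROMOPHORES.water(465.0) * 10
        expected = (((0.1 - 0.3e-4 * 465) + 0.125 * base_cm) * 0.95 + 0.05 * water_cm) / 10
        assert stratum_corneum_absorption(465.0) == pytest.approx(expected)
        assert stratum_corneum_absorption(465.0) == pytest.approx(0.0275, abs=2e-4)

    def test_stratum_corneum_collapses_without_water(self):
        spec = SkinSublayerSpec("stratum_corneum", 0, 0, 0.0, 0, 0.02)
        got = stratum_corneum_absorption(615.0, spec=spec)
        base_cm = baseline_absorption(615.0) * 10
        assert got == pytest.approx(((0.1 - 0.3e-4 * 615) + 0.125 * base_cm) / 10)

    def test_epidermis_value_and_collapses(self):
        expected = (0.1 * 88.66 + 0.9 * baseline_absorption(465.0)) * 0.8 + (
            0.2 * DEFAULT_CHROMOPHORES.water(465.0)
        )
        assert epidermis_absorption(465.0) == pytest.approx(expected)
        assert epidermis_absorption(465.0) == pytest.approx(7.21, abs=0.01)
        # no melanin: water-diluted baseline
        spec = SkinSublayerSpec("epidermis", 0, 0, 0.2, 0.0, 0.25)
        assert epidermis_absorption(525.0, spec=spec) == pytest.approx(
            0.8 * baseline_absorption(525.0) + 0.2 * DEFAULT_CHROMOPHORES.water(525.0)
        )
        # pure melanin
        spec = SkinSublayerSpec("epidermis", 0, 0, 0.0, 1.0, 0.25)
        assert epidermis_absorption(525.0, spec=spec) == pytest.approx(58.12)

    def test_dermal_sublayer_value(self):
        # papillary dermis, diastolic: oracle from the volume-fraction mixture
        state = BloodState(hba1c=0.06, spo2_arterial=0.97, phase="diastolic")
        mu_art = blood_absorption(state, "arterial", 615.0)
        mu_vein = blood_absorption(state, "venous", 615.0)
        spec = SKIN_SUBLAYERS[2]
        expected = (
            0.02 * mu_art
            + 0.02 * mu_vein
            + 0.5 * DEFAULT_CHROMOPHORES.water(615.0)
            + 0.46 * baseline_absorption(615.0)
        )
        got = skin_sublayer_absorption(spec, state, 615.0)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.140, abs=2e-3)

    def test_zero_blood_reduces_to_water_baseline_mixture(self):
        spec = SkinSublayerSpec("papillary_dermis", 0.0, 0.0, 0.5, 0.0, 0.1)
        state = BloodState()
        got = skin_sublayer_absorption(spec, state, 525.0)
        expected = 0.5 * DEFAULT_CHROMOPHORES.water(525.0) + 0.5 * baseline_absorption(525.0)
        assert got == pytest.approx(expected)

    @pytest.mark.parametrize("sub_index", [2, 3, 4, 5])
    def test_systolic_doubles_only_the_blood_terms(self, sub_index):
        spec = SKIN_SUBLAYERS[sub_index]
        dia = BloodState(hba1c=0.06, spo2_arterial=0.97, phase="diastolic")
        sys_ = dia.with_phase("systolic")
        mu_art = blood_absorption(dia, "arterial", 525.0)
        mu_vein = blood_absorption(dia, "venous", 525.0)
        delta = skin_sublayer_absorption(spec, sys_, 525.0) - skin_sublayer_absorption(
            spec, dia, 525.0
        )
        # doubling adds one extra blood volume at the baseline's expense
        expected = spec.v_blood_art * (mu_art - baseline_absorption(525.0)) + (
            spec.v_blood_vein * (mu_vein - baseline_absorption(525.0))
        )
        assert delta == pytest.approx(expected)

    @pytest.mark.parametrize("wavelength", [465.0, 525.0, 615.0])
    def test_absorption_nonnegative_over_physiological_grid(self, wavelength):
        for hba1c in np.linspace(0.03, 0.14, 6):
            for spo2 in np.linspace(0.7, 1.0, 5):
                for phase in ("systolic", "diastolic"):
                    state = BloodState(hba1c=hba1c, spo2_arterial=spo2, phase=phase)
                    for i in range(6):
                        assert to.skin_absorption(i, state, wavelength) >= 0.0

    def test_default_stack_matches_reference_fractions(self):
        rows = [
            ("stratum_corneum", 0, 0, 0.05, 0, 0.02),
            ("epidermis", 0, 0, 0.2, 0.1, 0.25),
            ("papillary_dermis", 0.02, 0.02, 0.5, 0, 0.1),
            ("upper_blood_net_dermis", 0.15, 0.15, 0.6, 0, 0.08),
            ("reticular_dermis", 0.02, 0.02, 0.7, 0, 0.2),
            ("deep_blood_net_dermis", 0.05, 0.05, 0.05, 0, 0.3),
        ]
        for spec, row in zip(SKIN_SUBLAYERS, rows):
            assert (
                spec.name, spec.v_blood_art, spec.v_blood_vein,
                spec.v_water, spec.v_melanin, spec.thickness_mm,
            ) == row
        assert SKIN_SUBLAYER_EDGES_MM[-1] == pytest.approx(0.95)
        assert tuple(np.round(SKIN_SUBLAYER_EDGES_MM, 10)) == (
            0.02, 0.27, 0.37, 0.45, 0.65, 0.95,
        )


class TestMaterials:
    def test_bone_row(self):
        p = material_properties("bone", BloodState(), 525.0)
        assert (p.mu_a, p.mu_s, p.g, p.n) == (0.118, 44.68, 0.92, 1.37)

    @pytest.mark.parametrize("wavelength", [465.0, 525.0, 615.0])
    def test_nail_is_wavelength_constant(self, wavelength):
        p = material_properties("nail", BloodState(), wavelength)
        assert (p.mu_a, p.mu_s, p.g, p.n) == (0.012, 21.0, 0.90, 1.51)

    def test_ambient_is_vacuum_like(self):
        p = material_properties("ambient", BloodState(), 525.0)
        assert (p.mu_a, p.mu_s, p.n) == (0.0, 0.0, 1.0)

    def test_artery_uses_blood_mixture_with_blood_scattering(self):
        state = BloodState(hba1c=0.06, spo2_arterial=0.97)
        p = material_properties("artery", state, 615.0)
        assert p.mu_a == pytest.approx(blood_absorption(state, "arterial", 615.0))
        assert (p.mu_s, p.g, p.n) == (53.00, 0.995, 1.354)

    def test_unknown_material_and_wavelength_raise(self):
        with pytest.raises(KeyError):
            material_properties("cartilage", BloodState(), 525.0)
        with pytest.raises(KeyError):
            material_properties("bone", BloodState(), 700.0)

    def test_mu_t_is_sum(self):
        p = OpticalProperties(0.3, 2.7, 0.9, 1.4)
        assert p.mu_t == pytest.approx(3.0)

    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            OpticalProperties(-0.1, 1.0, 0.9, 1.4)
        with pytest.raises(ValueError):
            OpticalProperties(0.1, 1.0, 1.5, 1.4)
        with pytest.raises(ValueError):
            OpticalProperties(0.1, 1.0, 0.9, 0.5)

    def test_material_table_csv_roundtrip(self, tmp_path):
        path = tmp_path / "materials.csv"
        to.save_material_table(path, BloodState(), 525.0)
        df = to.load_material_table(path)
        direct = to.material_table(BloodState(), 525.0)
        assert np.allclose(df["mu_a_mm"], direct["mu_a_mm"])
        assert list(df["material"]) == list(direct["material"])

    def test_load_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("material,mu_a_mm\nbone,0.1\n")
        with pytest.raises(ValueError):
            to.load_material_table(path)


@settings(derandomize=True, max_examples=50)
@given(
    hba1c=st.floats(0.0, 0.2),
    spo2=st.floats(0.0, 1.0),
    lam=st.sampled_from([465.0, 525.0, 615.0]),
)
def test_blood_absorption_always_nonnegative(hba1c, spo2, lam):
    state = BloodState(hba1c=hba1c, spo2_arterial=spo2)
    assert blood_absorption(state, "arterial", lam) >= 0.0
    assert blood_absorption(state, "venous", lam) >= 0.0
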