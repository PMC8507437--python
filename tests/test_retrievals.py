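"""Unit and property tests for the retrieval formulas."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakealign import (
    GilersonCoefficients,
    GonsCoefficients,
    LinearCalibration,
    NechadCoefficients,
    OcxCoefficients,
    apply_linear_calibration,
    band_ratio,
    gilerson_chla,
    gons_backscatter,
    gons_chla,
    nechad_turbidity,
    ocx_chla,
    retrieve_products,
    scaled_ratio_chla,
)
from lakealign.coefficients import CoefficientRegistry
from lakealign.retrievals import REASON_NONPOS_DENOMINATOR

from conftest import random_spectra_frame


class TestBandRatio:
    @pytest.mark.parametrize(
        "spectrum, kind, expected",
        [
            ({"b490": 0.01, "b560": 0.01}, "oc2", 0.0),
            ({"b443": 0.02, "b490": 0.01, "b560": 0.01}, "oc3", math.log10(2)),
            ({"b443": 0.005, "b490": 0.01, "b560": 0.01}, "oc3", 0.0),
            ({"b665": 0.004, "b708": 0.005}, "nir_red", 1.25),
        ],
    )
    def test_examples(self, spectrum, kind, expected):
        assert band_ratio(spectrum, kind) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "spectrum, kind",
        [
            ({"b490": 0.01, "b560": 0.0}, "oc2"),       # zero denominator
            ({"b490": -0.01, "b560": 0.01}, "oc2"),     # negative ratio
            ({"b665": 0.0, "b708": 0.005}, "nir_red"),  # zero denominator
            ({"b560": 0.01}, "oc2"),                    # missing band
        ],
    )
    def test_invalid_domains_raise(self, spectrum, kind):
        with pytest.raises(ValueError):
            band_ratio(spectrum, kind)


class TestOcx:
    def test_degree_zero_term(self, registry):
        coeffs = registry.get("initial", "msi", "oc2")
        assert coeffs.a0 == 0.2389
        assert ocx_chla(0.0, coeffs) == pytest.approx(10 ** 0.2389, rel=1e-12)

    def test_all_zero_coefficients(self):
        coeffs = OcxCoefficients(0, 0, 0, 0, 0)
        assert ocx_chla(0.0, coeffs) == 1.0

    def test_tuned_polynomial_against_polyval_oracle(self, registry):
        coeffs = registry.get("tuned", "msi", "oc2")
        x = 0.1
        expected = 10 ** np.polyval(list(coeffs.values)[::-1], x)
        assert ocx_chla(x, coeffs) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.758, abs=5e-4)

    @given(st.floats(-3, 3))
    @settings(deadline=None, max_examples=200)
    def test_positive_for_any_finite_ratio(self, x):
        coeffs = OcxCoefficients(0.2389, -1.9369, 1.7627, -3.0777, -0.1054)
        assert ocx_chla(x, coeffs) > 0


class TestGilerson:
    COEFFS = GilersonCoefficients(35.75, -19.30, 1.124)

    def test_unit_base(self):
        # a*x + b = 1 for x = 20.30/35.75
        x = (1 + 19.30) / 35.75
        assert gilerson_chla(x, self.COEFFS) == pytest.approx(1.0, rel=1e-12)

    def test_hand_value(self):
        # base = 35.75*0.56 - 19.30 = 0.72
        expected = 0.72 ** 1.124
        assert gilerson_chla(0.56, self.COEFFS) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.6913, abs=2e-4)

    def test_nonpositive_base(self):
        with pytest.raises(ValueError):
            gilerson_chla(0.5, self.COEFFS)  # base = -1.425
        assert np.isnan(gilerson_chla(np.array([0.5]), self.COEFFS)[0])

    @given(st.floats(0.6, 5.0), st.floats(0.6, 5.0))
    @settings(deadline=None, max_examples=100)
    def test_monotone_increasing(self, x1, x2):
        lo, hi = sorted([x1, x2])
        assert gilerson_chla(lo, self.COEFFS) <= gilerson_chla(hi, self.COEFFS)


class TestGons:
    COEFFS = GonsCoefficients(p=1.06, a_chl_star=0.016)

    def test_zero_reflectance_gives_zero_backscatter(self):
        assert gons_backscatter(0.0, self.COEFFS) == 0.0

    def test_backscatter_hand_value(self):
        # 0.6*2.71*0.01 / (0.082 - 0.006)
        assert gons_backscatter(0.01, self.COEFFS) == pytest.approx(
            0.6 * 2.71 * 0.01 / (0.082 - 0.006), rel=1e-12
        )
        assert gons_backscatter(0.01, self.COEFFS) == pytest.approx(0.21395, abs=1e-5)

    def test_backscatter_domain(self):
        with pytest.raises(ValueError):
            gons_backscatter(0.14, self.COEFFS)  # 0.082 - 0.084 < 0

    def test_chla_vanishes_when_numerator_cancels(self):
        # bb = 0 and ratio = aw665/aw709 makes the numerator zero
        ratio = self.COEFFS.aw665 / self.COEFFS.aw709
        rw665 = 0.01
        assert gons_chla(rw665, ratio * rw665, 0.0, self.COEFFS) == pytest.approx(0.0, abs=1e-12)

    def test_chla_hand_value(self):
        # bb = 0, ratio = 1: (0.70 - 0.40)/0.016 = 18.75
        assert gons_chla(0.01, 0.01, 0.0, self.COEFFS) == pytest.approx(18.75, rel=1e-12)

    def test_inverse_scaling_in_specific_absorption(self):
        doubled = GonsCoefficients(p=1.06, a_chl_star=0.032)
        v1 = gons_chla(0.01, 0.012, 0.005, self.COEFFS)
        v2 = gons_chla(0.01, 0.012, 0.005, doubled)
        assert v2 == pytest.approx(v1 / 2, rel=1e-12)


class TestNechad:
    def test_zero(self):
        assert nechad_turbidity(0.0, NechadCoefficients(300, 0.2)) == 0.0

    def test_hand_value(self):
        assert nechad_turbidity(0.1, NechadCoefficients(300, 0.2)) == pytest.approx(60.0)

    @given(st.floats(10, 4000), st.floats(0.05, 0.95))
    @settings(deadline=None, max_examples=100)
    def test_half_asymptote_identity(self, A, C):
        coeffs = NechadCoefficients(A, C)
        assert nechad_turbidity(C / 2, coeffs) == pytest.approx(A * C, rel=1e-9)

    def test_domain(self):
        coeffs = NechadCoefficients(300, 0.2)
        with pytest.raises(ValueError):
            nechad_turbidity(0.25, coeffs)
        with pytest.raises(ValueError):
            nechad_turbidity(-0.01, coeffs)

    def test_monotone_on_domain(self):
        coeffs = NechadCoefficients(300, 0.2)
        rw = np.linspace(0, 0.199, 500)
        t = nechad_turbidity(rw, coeffs)
        assert np.all(np.diff(t) > 0)


class TestLinearCalibration:
    def test_turbidity_calibration_hand_value(self, registry):
        cal = registry.get("turbidity_calibration", "msi", "b665")
        assert apply_linear_calibration(2.0, cal) == pytest.approx(1.740, abs=1e-12)

    def test_identity(self):
        assert apply_linear_calibration(3.7, LinearCalibration(1, 0)) == 3.7

    def test_ratio_scaling_hand_value(self, registry):
        cal = registry.get("ratio_scaling", "msi", "oc2")
        assert apply_linear_calibration(1.0, cal) == pytest.approx(0.932, abs=1e-12)


def test_scaled_ratio_identity_path_equals_direct(registry):
    """Rescaling the ratio with an identity calibration then applying the
    reference coefficients is exactly the direct reference retrieval."""
    olci = registry.get("initial", "olci", "oc2")
    x = np.linspace(-0.2, 1.0, 101)
    direct = ocx_chla(x, olci)
    scaled = scaled_ratio_chla(x, LinearCalibration(1.0, 0.0), olci)
    np.testing.assert_array_equal(direct, scaled)


def test_independent_scalar_oracle_agreement():
    """Vectorized Gons backscatter and Nechad turbidity agree with plain
    python/math re-implementations to 1e-12 relative on random valid inputs."""
    rng = np.random.default_rng(7)
    gons = GonsCoefficients(p=1.06, a_chl_star=0.016)
    nech = NechadCoefficients(415.29, 0.1875)
    rw_bb = rng.uniform(0, 0.08 / 0.6 * 0.9, 1000)
    rw_t = rng.uniform(0, nech.C * 0.99, 1000)
    bb = gons_backscatter(rw_bb, gons)
    t = nechad_turbidity(rw_t, nech)
    for i in range(1000):
        bb_ref = 0.6 * 2.71 * rw_bb[i] / (0.082 - 0.6 * rw_bb[i])
        t_ref = 415.29 * rw_t[i] / (1.0 - rw_t[i] / 0.1875)
        assert math.isclose(bb[i], bb_ref, rel_tol=1e-12)
        assert math.isclose(t[i], t_ref, rel_tol=1e-12)


class TestRetrieveProducts:
    def test_empty_table(self, registry):
        rng = np.random.default_rng(0)
        df = random_spectra_frame(rng, 3).iloc[:0]
        out, tallies = retrieve_products(df, "oc2", registry)
        assert len(out) == 0
        assert all(t.total == 0 for t in tallies.values())

    def test_rowwise_equals_scalar(self, registry):
        rng = np.random.default_rng(1)
        df = random_spectra_frame(rng, 50)
        for algorithm in ("oc2", "oc3", "gilerson", "gons05"):
            out, _ = retrieve_products(df, algorithm, registry)
            for sensor in ("msi", "olci"):
                coeffs = registry.get("initial", sensor, algorithm)
                for i in range(len(df)):
                    row = df.iloc[i]
                    spec = {b: row[f"rw_{sensor}_{b}"] for b in
                            ("b443", "b490", "b560", "b665", "b708", "b778", "b865")}
                    try:
                        if algorithm in ("oc2", "oc3"):
                            expected = ocx_chla(band_ratio(spec, algorithm), coeffs)
                        elif algorithm == "gilerson":
                            expected = gilerson_chla(band_ratio(spec, "nir_red"), coeffs)
                        else:
                            expected = gons_chla(
                                spec["b665"], spec["b708"], spec["b778"], coeffs
                            )
                    except ValueError:
                        # scalar path raises where the bulk path yields missing
                        assert np.isnan(out[f"chla_{sensor}"].iloc[i])
                        continue
                    assert out[f"chla_{sensor}"].iloc[i] == expected

    def test_missing_band_counted_not_raised(self, registry):
        rng = np.random.default_rng(2)
        df = random_spectra_frame(rng, 5)
        df.loc[2, "rw_msi_b560"] = 0.0
        out, tallies = retrieve_products(df, "oc2", registry)
        assert np.isnan(out["chla_msi"].iloc[2])
        assert tallies["msi"].counts[REASON_NONPOS_DENOMINATOR] == 1
        assert len(out) == len(df)

    def test_unknown_algorithm_is_hard_error(self, registry):
        rng = np.random.default_rng(3)
        df = random_spectra_frame(rng, 2)
        with pytest.raises(ValueError):
            retrieve_products(df, "oc9", registry)

    def test_turbidity_products(self, registry):
        rng = np.random.default_rng(4)
        df = random_spectra_frame(rng, 10)
        out, tallies = retrieve_products(df, "turbidity_b665", registry)
        coeffs = registry.get("nechad", "shared", "b665")
        expected = nechad_turbidity(df["rw_msi_b665"].to_numpy(), coeffs)
        np.testing.assert_array_equal(out["turbidity_msi"].to_numpy(), expected)


def test_registry_roundtrip_bit_identical(registry, tmp_path):
    path = tmp_path / "reg.json"
    registry.save(path)
    reloaded = CoefficientRegistry.load(path)
    assert reloaded.to_json() == registry.to_json()
    assert reloaded.get("tuned", "msi", "gons05") == registry.get("tuned", "msi", "gons05")
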