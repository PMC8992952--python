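import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from rbedose.rbe import (
    RBEModelSpec,
    UnsupportedModelError,
    model_spec,
    rbe_field,
    rbe_lq,
    rbe_max_min,
)
from tests.conftest import make_case


def lq_equivalence_rbe(model, d, letd):
    """Independent oracle: solve RBEmax*d + RBEmin^2*d^2/ab = R*d + (R*d)^2/ab
    for R numerically instead of using the closed form."""
    rmax, rmin = (float(v) for v in rbe_max_min(model, letd))
    ab = model.alpha_beta_Gy
    lhs = rmax * d + rmin**2 * d**2 / ab

    def g(r):
        return r * d + (r * d) ** 2 / ab - lhs

    lo, hi = 0.0, max(rmax, rmin) + 1.0
    return brentq(g, lo, hi, xtol=1e-14, rtol=1e-15)


class TestAsymptotes:
    def test_mcnamara_zero_let_intercepts(self):
        rmax, rmin = rbe_max_min(model_spec("mcnamara"), 0.0)
        assert rmax == pytest.approx(0.99064, abs=1e-12)
        assert rmin == pytest.approx(1.1012, abs=1e-12)

    def test_wedenberg_rbe_min_is_unity(self):
        for letd in (0.0, 2.0, 8.0, 15.0):
            _, rmin = rbe_max_min(model_spec("wedenberg"), letd)
            assert rmin == 1.0

    def test_mcnamara_at_let_2(self):
        rmax, rmin = rbe_max_min(model_spec("mcnamara"), 2.0)
        assert rmax == pytest.approx(1.2280067, abs=1e-6)
        assert rmin == pytest.approx(1.0877929, abs=1e-6)

    def test_mcnamara_rbe_min_clamped_at_zero(self):
        # extreme LET pushes the linear RBEmin fit below zero; it is clamped
        _, rmin = rbe_max_min(model_spec("mcnamara"), 200.0)
        assert rmin == 0.0

    @pytest.mark.parametrize("name", ["constant_1p1", "mcmahon_linear"])
    def test_models_without_lq_structure_rejected(self, name):
        with pytest.raises(UnsupportedModelError):
            rbe_max_min(model_spec(name), 2.0)


class TestLQClosedForm:
    @pytest.mark.parametrize(
        "name, expected",
        [("mcnamara", 1.14415), ("wedenberg", 1.11989)],
    )
    def test_frozen_values_at_2gy_let2(self, name, expected):
        assert rbe_lq(model_spec(name), 2.0, 2.0) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("name", ["mcnamara", "wedenberg"])
    @pytest.mark.parametrize("letd", [0.0, 1.0, 4.0, 8.0])
    def test_low_and_high_dose_limits(self, name, letd):
        model = model_spec(name)
        rmax, rmin = (float(v) for v in rbe_max_min(model, letd))
        assert rbe_lq(model, 1e-8, letd) == pytest.approx(rmax, abs=1e-5)
        assert rbe_lq(model, 1e6, letd) == pytest.approx(rmin, abs=1e-4)

    def test_agrees_with_numeric_survival_equivalence_solver(self):
        """Closed form vs brentq on the LQ equivalence, 100-point (d, letd) lattice."""
        for name in ("mcnamara", "wedenberg"):
            model = model_spec(name)
            for d in np.linspace(0.25, 20.0, 10):
                for letd in np.linspace(0.0, 12.0, 10):
                    closed = float(rbe_lq(model, d, letd))
                    assert closed == pytest.approx(
                        lq_equivalence_rbe(model, d, letd), abs=1e-9
                    )

    def test_value_lies_between_min_and_max(self):
        model = model_spec("mcnamara")
        for d in (0.1, 2.0, 30.0):
            for letd in (0.0, 3.0, 9.0):
                r = float(rbe_lq(model, d, letd))
                rmax, rmin = (float(v) for v in rbe_max_min(model, letd))
                assert min(rmax, rmin) - 1e-12 <= r <= max(rmax, rmin) + 1e-12

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            rbe_lq(model_spec("wedenberg"), 0.0, 2.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    d=st.floats(0.1, 30.0),
    l1=st.floats(0.0, 15.0),
    dl=st.floats(0.01, 5.0),
    name=st.sampled_from(["wedenberg", "mcmahon_linear"]),
)
def test_rbe_nondecreasing_in_letd(d, l1, dl, name):
    """Positive slope coefficients make RBE monotone in LETd at fixed dose."""
    model = model_spec(name)
    if name == "mcmahon_linear":
        r1 = 1 + model.coefficients["slope_um_per_keV"] * l1
        r2 = 1 + model.coefficients["slope_um_per_keV"] * (l1 + dl)
    else:
        r1 = float(rbe_lq(model, d, l1))
        r2 = float(rbe_lq(model, d, l1 + dl))
    assert r2 >= r1 - 1e-12


class TestRBEField:
    def test_constant_model_scales_dose_exactly(self, default_case):
        result = rbe_field(default_case, model_spec("constant_1p1"))
        np.testing.assert_array_equal(
            result.weighted_dose.values, 1.1 * default_case.physical_dose.values
        )
        assert result.weighted_dose.units == "GyRBE"

    def test_linear_model_hand_value(self):
        case = make_case(dose=np.full((1, 1, 1), 2.0), letd=np.full((1, 1, 1), 8.0))
        result = rbe_field(case, model_spec("mcmahon_linear"))
        assert result.rbe.values[0, 0, 0] == pytest.approx(1.44, abs=1e-12)
        assert result.weighted_dose.values[0, 0, 0] == pytest.approx(2.88, abs=1e-12)

    def test_below_threshold_voxels_use_clinical_rbe(self):
        dose = np.array([[[0.05, 2.0]]])
        letd = np.array([[[15.0, 2.0]]])
        case = make_case(dose=dose, letd=letd)
        for name in ("mcmahon_linear", "mcnamara", "wedenberg"):
            result = rbe_field(case, model_spec(name))
            assert result.rbe.values[0, 0, 0] == 1.1  # 0.05 Gy < 10 cGy threshold
            assert result.rbe.values[0, 0, 1] != 1.1

    def test_weighted_dose_is_rbe_times_physical(self, default_case):
        result = rbe_field(default_case, model_spec("wedenberg"))
        np.testing.assert_allclose(
            result.weighted_dose.values,
            result.rbe.values * default_case.physical_dose.values,
            rtol=1e-12,
        )
        assert result.rbe.values.min() >= 0

    def test_per_fraction_differs_from_total_dose_mode(self, default_case):
        per = rbe_field(default_case, model_spec("mcnamara"), "per_fraction")
        tot = rbe_field(default_case, model_spec("mcnamara"), "total_dose")
        assert not np.allclose(per.rbe.values, tot.rbe.values)

    def test_nonfinite_letd_in_scored_region_rejected(self):
        case = make_case(dose=np.full((2, 1, 1), 2.0))
        case.letd.values[0, 0, 0] = np.nan  # corrupt after construction
        with pytest.raises(ValueError, match="1 supra-threshold"):
            rbe_field(case, model_spec("wedenberg"))

    def test_unknown_model_name_rejected(self):
        with pytest.raises(UnsupportedModelError):
            RBEModelSpec(name="carabe")
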