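"""Hill-equation pharmacology: evaluators, factor sets, fitting, library."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosim import pharmacology as ph
from cardiosim.pharmacology import (ConductanceFactors, DoseResponsePoints,
                                    HillActivation, HillBlock,
                                    activation_factor, block_fraction,
                                    compose_factors, drug_factors, fit_hill,
                                    remaining_fraction)
from cardiosim.synthetic import make_hill_dataset


class TestBlockFraction:
    @pytest.mark.parametrize("dose,ic50,nh,expected", [
        # ranolazine 10 µM on I_Na / I_NaCa / I_CaL (values computed from
        # theta = 1/(1+(IC50/dose)^nH))
        (10.0, 53.6, 2.4, 0.0174716),
        (10.0, 91.0, 1.48, 0.0366727),
        (10.0, 296.0, 1.0, 0.0326797),
    ])
    def test_low_dose_block_fractions(self, dose, ic50, nh, expected):
        theta = block_fraction(dose, HillBlock(ic50=ic50, nh=nh))
        assert theta == pytest.approx(expected, abs=5e-6)

    def test_half_block_at_ic50(self):
        assert block_fraction(53.6, HillBlock(53.6, 2.4)) == pytest.approx(0.5)

    def test_zero_dose_is_zero_block(self):
        assert block_fraction(0.0, HillBlock(10.0, 1.0)) == 0.0
        assert remaining_fraction(0.0, HillBlock(10.0, 1.0)) == 1.0

    @given(dose=st.floats(1e-6, 1e5), ic50=st.floats(1e-3, 1e3),
           nh=st.floats(0.2, 5.0))
    @settings(max_examples=80, deadline=None)
    def test_complementarity(self, dose, ic50, nh):
        h = HillBlock(ic50, nh)
        assert block_fraction(dose, h) + remaining_fraction(dose, h) == \
            pytest.approx(1.0)

    @given(ic50=st.floats(1e-2, 1e2), nh=st.floats(0.3, 4.0),
           d1=st.floats(1e-3, 1e3), d2=st.floats(1e-3, 1e3))
    @settings(max_examples=80, deadline=None)
    def test_strict_monotonicity_in_dose(self, ic50, nh, d1, d2):
        if abs(d1 - d2) < 1e-9:
            return
        lo, hi = sorted((d1, d2))
        h = HillBlock(ic50, nh)
        t_lo, t_hi = block_fraction(lo, h), block_fraction(hi, h)
        assert t_hi >= t_lo
        if 1e-12 < t_lo and t_hi < 1.0 - 1e-12:   # strict when unsaturated
            assert t_hi > t_lo

    def test_saturation_limit(self):
        h = HillBlock(1.0, 1.5)
        assert block_fraction(1e9, h) == pytest.approx(1.0, abs=1e-6)


class TestActivationFactor:
    def test_identity_at_zero_dose(self):
        h = HillActivation(0.41, 0.73, 2.8)
        assert activation_factor(0.0, h) == 1.0

    def test_half_span_at_ec50(self):
        h = HillActivation(0.41, 0.73, 2.8)
        assert activation_factor(0.41, h) == pytest.approx(1.9)

    def test_saturates_at_act_max(self):
        h = HillActivation(0.41, 0.73, 2.8)
        assert activation_factor(1e12, h) == pytest.approx(2.8, rel=1e-3)

    @given(dose=st.floats(1e-4, 1e4))
    @settings(max_examples=60, deadline=None)
    def test_bounded_between_one_and_act_max(self, dose):
        h = HillActivation(1.0, 1.3, 3.5)
        f = activation_factor(dose, h)
        assert 1.0 < f < 3.5


class TestFactorSets:
    def test_ranolazine_affects_exactly_five_channels(self, drug_library):
        fac = drug_factors(drug_library["ranolazine"], 10.0)
        touched = {ch for ch, f in fac.items() if f != 1.0}
        assert touched == {"I_Na", "I_NaL", "I_NaCa", "I_CaL", "I_Kr"}
        assert all(0.0 < fac[ch] < 1.0 for ch in touched)

    def test_activator_only_raises_ikr(self, drug_library):
        fac = drug_factors(drug_library["hw-0168"], 0.5)
        assert fac["I_Kr"] > 1.0
        assert all(fac[ch] == 1.0 for ch in fac if ch != "I_Kr")

    def test_zero_dose_gives_identity_for_every_drug(self, drug_library):
        for spec in drug_library.values():
            fac = drug_factors(spec, 0.0)
            assert all(f == 1.0 for f in fac.values()), spec.name

    def test_compose_identity_commutativity_product(self):
        a = ConductanceFactors({"I_Kr": 0.5, "I_NaL": 2.0})
        b = ConductanceFactors({"I_Kr": 0.5})
        ones = ConductanceFactors()
        assert dict(compose_factors(a, ones)) == dict(a)
        assert dict(compose_factors(a, b)) == dict(compose_factors(b, a))
        assert compose_factors(b, b)["I_Kr"] == pytest.approx(0.25)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            ConductanceFactors({"I_Kr": -0.1})
        with pytest.raises(ValueError):
            ConductanceFactors({"bogus": 0.5})


class TestFitHill:
    def test_noise_free_block_recovery(self):
        truth = HillBlock(12.0, 1.0)
        doses = np.logspace(-1, 2, 8)
        pts = make_hill_dataset(truth, doses, noise_sd=0.0)
        fit = fit_hill(pts, mode="block")
        assert fit.hill.ic50 == pytest.approx(12.0, rel=1e-2)
        assert fit.hill.nh == pytest.approx(1.0, rel=1e-2)
        assert fit.residual_norm < 1e-8

    def test_noisy_activation_recovery_within_ten_percent(self):
        truth = HillActivation(0.41, 0.73, 2.8)
        doses = np.logspace(-2, 1.5, 8)
        pts = make_hill_dataset(truth, doses, noise_sd=0.01, seed=42)
        fit = fit_hill(pts, mode="activate")
        assert fit.hill.ec50 == pytest.approx(0.41, rel=0.10)
        assert fit.hill.nh == pytest.approx(0.73, rel=0.10)
        assert fit.hill.act_max == pytest.approx(2.8, rel=0.10)

    def test_underdetermined_input_rejected(self):
        pts = DoseResponsePoints(doses=np.array([1.0, 10.0]),
                                 responses=np.array([0.1, 0.6]))
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_hill(pts, mode="block")

    def test_degenerate_flat_responses_rejected(self):
        pts = DoseResponsePoints(doses=np.array([1.0, 3.0, 9.0]),
                                 responses=np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ValueError, match="degenerate"):
            fit_hill(pts, mode="block")


class TestLibrary:
    def test_printed_parameters(self, drug_library):
        q = drug_library["quinidine"].entries["I_Kr"].hill
        assert (q.ic50, q.nh) == (0.41, 0.76)
        assert drug_library["vanoxerine"].doses["high"] == 0.05
        ica = drug_library["ica-105574"].entries["I_Kr"].hill
        assert (ica.ec50, ica.nh, ica.act_max) == (0.42, 2.5, 5.5)

    def test_all_twelve_compounds_present(self, drug_library):
        assert len(drug_library) == 12
        assert {"ranolazine", "hw-0168", "amiodarone", "verapamil",
                "nifedipine", "quinidine", "vanoxerine", "bepridil",
                "kb130015", "ica-105574", "ns1643", "ns3623"} \
            == set(drug_library)

    def test_library_round_trip(self, drug_library, tmp_path):
        path = tmp_path / "drugs.yaml"
        ph.save_drug_library(drug_library, path)
        again = ph.load_drug_library(path)
        assert again.keys() == drug_library.keys()
        for name in drug_library:
            assert again[name] == drug_library[name]


class TestRemodeling:
    def test_co_direction_of_effects(self):
        fac, meta = ph.load_remodeling("CO")
        assert fac["I_Kr"] < 1.0 and fac["I_NaL"] > 1.0
        assert fac["I_Na"] < 1.0 and fac["I_CaL"] < 1.0 and fac["I_K1"] < 1.0
        assert "PLACEHOLDER" in meta["provenance"]

    def test_hf_co_is_product_of_hf_and_co(self):
        hf, _ = ph.load_remodeling("HF")
        co, _ = ph.load_remodeling("CO")
        both, _ = ph.load_remodeling("HF+CO")
        np.testing.assert_allclose(compose_factors(hf, co).as_array(),
                                   both.as_array())

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError):
            ph.load_remodeling("ischemia")
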