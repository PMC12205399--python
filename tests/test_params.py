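import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import housefirst as hf
from housefirst.io import save_config
from housefirst.params import (SAMPLED_FIELDS, ParamValue, TransitionRates,
                               load_config_dict)


class TestLoad:
    def test_default_methadone_base_values(self, ps):
        assert ps.housing_cost.base == 20900.0
        assert ps.entry_h.base == 0.426
        assert ps.surv_u.base == 0.883
        assert ps.disc_h.base == 1.051
        assert ps.c_treatment.base == 8584.0
        assert ps.induction_mult.base == 14.0
        assert ps.discount_rate == 0.03

    def test_buprenorphine_branch(self):
        bup = hf.load_parameter_set(medication="buprenorphine")
        assert bup.disc_h.base == 1.608
        assert bup.c_treatment.base == 7836.0
        assert bup.induction_mult.base == 1.0

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="low <= base <= high"):
            ParamValue(base=0.426, low=0.5, high=0.4, family="lognormal")

    def test_missing_key_named(self, tmp_path):
        cfg = load_config_dict()
        del cfg["transitions"]["entry_housed"]
        path = save_config(cfg, tmp_path / "broken.yaml")
        with pytest.raises(KeyError, match="entry_housed"):
            hf.load_parameter_set(path)

    def test_config_round_trip(self, ps, tmp_path):
        path = save_config(load_config_dict(), tmp_path / "copy.yaml")
        assert hf.load_parameter_set(path) == ps

    def test_beta_family_requires_unit_interval(self):
        with pytest.raises(ValueError, match="bounded"):
            ParamValue(base=2.0, low=1.5, high=2.5, family="beta")


class TestHazardRatioDerivation:
    def test_entry_rate_matches_published_unhoused_value(self, ps):
        derived = hf.derive_unhoused_rates(ps.housed_transitions(),
                                           ps.hazard_ratios)
        assert derived.entry.base == pytest.approx(0.213, abs=1e-12)

    def test_discontinuation_consistent_with_published(self, ps):
        # 1.051 * 1.36 = 1.429, within 0.2% of the published 1.431
        derived = hf.derive_unhoused_rates(ps.housed_transitions(),
                                           ps.hazard_ratios)
        assert derived.discontinuation.base == pytest.approx(1.431, rel=2e-3)

    def test_unit_ratios_are_identity(self, ps):
        hr = hf.HazardRatios(entry=1.0, discontinuation=1.0, success=1.0,
                             relapse=1.0)
        housed = ps.housed_transitions()
        assert hf.derive_unhoused_rates(housed, hr) == housed

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(0.1, 10.0))
    def test_homogeneous_in_housed_rates(self, ps, c):
        hr = ps.hazard_ratios
        housed = ps.housed_transitions()
        scaled = TransitionRates(*(
            ParamValue(base=pv.base * c, low=pv.low * c, high=pv.high * c,
                       family=pv.family)
            for pv in (housed.entry, housed.discontinuation, housed.success,
                       housed.abstinence_untreated, housed.relapse_early,
                       housed.relapse_late)))
        a = hf.derive_unhoused_rates(scaled, hr)
        b = hf.derive_unhoused_rates(housed, hr)
        assert a.entry.base == pytest.approx(c * b.entry.base, rel=1e-12)
        assert a.relapse_late.high == pytest.approx(c * b.relapse_late.high,
                                                    rel=1e-12)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hf.HazardRatios(entry=-0.5, discontinuation=1.0, success=1.0,
                            relapse=1.0)


class TestSampling:
    def test_degenerate_range_returns_base(self, ps):
        d = hf.sample_draw(ps, 11, 0)
        assert d.housing_cost == 20900.0  # fixed family
        assert d.bg_cost_male_30 == 2764.0

    def test_same_seed_bit_identical(self, ps):
        assert hf.sample_draw(ps, 7, 3) == hf.sample_draw(ps, 7, 3)
        assert hf.sample_draw(ps, 7, 3) != hf.sample_draw(ps, 7, 4)

    def test_samples_within_ranges_and_means_inside(self, ps):
        draws = hf.sample_draws(ps, 5, 5000)
        for name in SAMPLED_FIELDS:
            pv = getattr(ps, name)
            x = np.array([getattr(d, name) for d in draws])
            assert x.min() >= pv.low - 1e-12
            assert x.max() <= pv.high + 1e-12
            if not pv.is_degenerate:
                assert pv.low < x.mean() < pv.high

    def test_beta_quantiles_recover_published_interval(self, ps):
        # overdose survival (housed): 0.880 (0.794-0.943), beta family
        draws = hf.sample_draws(ps, 42, 20000)
        x = np.array([d.surv_h for d in draws])
        assert np.percentile(x, 2.5) == pytest.approx(0.794, abs=0.01)
        assert np.percentile(x, 97.5) == pytest.approx(0.943, abs=0.01)

    @settings(derandomize=True, max_examples=40)
    @given(low=st.floats(0.01, 1.0), width=st.floats(1.1, 20.0),
           pos=st.floats(0.1, 0.9), seed=st.integers(0, 2**20))
    def test_lognormal_samples_respect_bounds(self, low, width, pos, seed):
        high = low * width
        base = low + pos * (high - low)
        pv = ParamValue(base=base, low=low, high=high, family="lognormal")
        rng = np.random.default_rng(seed)
        from housefirst.params import _sample_value
        x = [_sample_value(pv, rng) for _ in range(50)]
        assert min(x) >= low and max(x) <= high
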