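import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csspanel import (
    EffectSize,
    PreconditionError,
    UndefinedNormalizerError,
    average_effect,
    compute_effects,
    detect_qtls,
    effect_sem,
    hi_low,
    norm_unit,
)
from helpers import panel_from_means, ts


def eff(nu, sem=1.0, sig=True, strain="C", trait="t1"):
    return EffectSize(strain, trait, "M", nu, nu / 2, sem, sig)


class TestNormUnit:
    def test_css_at_host_is_zero(self):
        assert norm_unit(ts("C", 10), ts("H", 10), ts("D", 20)) == 0.0

    def test_css_at_donor_is_hundred(self):
        assert norm_unit(ts("C", 20), ts("H", 10), ts("D", 20)) == 100.0

    def test_beyond_donor(self):
        assert norm_unit(ts("C", 35), ts("H", 10), ts("D", 20)) == 250.0

    def test_equal_parents_undefined(self):
        with pytest.raises(UndefinedNormalizerError):
            norm_unit(ts("C", 5), ts("H", 10), ts("D", 10))

    @given(
        st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100),
        st.floats(-50, 50), st.floats(0.01, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariant(self, c, h, d, shift, scale):
        if abs(d - h) < 1e-6:
            return
        base = norm_unit(ts("C", c), ts("H", h), ts("D", d))
        moved = norm_unit(
            ts("C", c * scale + shift), ts("H", h * scale + shift),
            ts("D", d * scale + shift),
        )
        assert moved == pytest.approx(base, rel=1e-6, abs=1e-6)


class TestHiLow:
    def test_midpoint_of_parental_range(self):
        assert hi_low(ts("C", 5), ts("H", 0), [0, 10, 5]) == 50.0

    def test_full_span(self):
        assert hi_low(ts("C", 10), ts("H", 0), [0, 10]) == 100.0

    def test_css_below_host(self):
        assert hi_low(ts("C", -5), ts("H", 0), [0, 10, -5, 5]) == pytest.approx(-100 / 3)

    def test_zero_range_undefined(self):
        with pytest.raises(UndefinedNormalizerError):
            hi_low(ts("C", 5), ts("H", 5), [5, 5, 5])

    def test_same_sign_as_norm_unit_when_donor_above_host(self):
        # both measures share the numerator T_CSS - T_host; with the donor
        # above the host both denominators are positive, so signs agree
        rng = np.random.default_rng(7)
        for _ in range(50):
            h = rng.normal(0, 10)
            d = h + abs(rng.normal(1, 5)) + 0.1
            c = rng.normal(0, 10)
            means = [h, d, c, *rng.normal(0, 10, 4)]
            nu = norm_unit(ts("C", c), ts("H", h), ts("D", d))
            hl = hi_low(ts("C", c), ts("H", h), means)
            assert np.sign(nu) == np.sign(hl)


class TestEffectSem:
    def test_only_css_noise(self):
        host, donor = ts("H", 0, 0, 10), ts("D", 10, 0, 10)
        css = ts("C", 3, 2, 16)  # sem = 0.5
        assert effect_sem(css, host, donor) == pytest.approx(100 * 0.5 / 10)

    def test_css_at_host_donor_term_vanishes(self):
        host = ts("H", 0, 2, 16)
        donor = ts("D", 10, 7, 4)  # arbitrary donor sem
        css = ts("C", 0, 2, 16)    # N = 0, sem = 0.5
        expected = 100 * 0.5 * math.sqrt(2) / 10
        assert effect_sem(css, host, donor) == pytest.approx(expected)

    def test_matches_monte_carlo_sd(self):
        # delta-method validity: all SEMs well below |D|/10
        host, donor, css = ts("H", 0, 1, 100), ts("D", 10, 1, 100), ts("C", 5, 1, 100)
        prop = effect_sem(css, host, donor)
        rng = np.random.default_rng(11)
        h = rng.normal(host.mean, host.sem, 10_000)
        d = rng.normal(donor.mean, donor.sem, 10_000)
        c = rng.normal(css.mean, css.sem, 10_000)
        empirical = np.std(100 * (c - h) / (d - h), ddof=1)
        assert prop == pytest.approx(empirical, rel=0.05)

    def test_equal_parents_undefined(self):
        with pytest.raises(UndefinedNormalizerError):
            effect_sem(ts("C", 5), ts("H", 1), ts("D", 1))


class TestAverageEffect:
    def test_opposite_signs_do_not_cancel(self):
        assert average_effect([eff(50), eff(-50)]) == 50.0

    def test_single_effect(self):
        assert average_effect([eff(76)]) == 76.0

    def test_three_effect_mean(self):
        effects = [eff(29.0), eff(408.6), eff(21.4)]
        assert average_effect(effects) == pytest.approx(153.0)

    def test_significant_only_filter(self):
        effects = [eff(100, sig=True), eff(10, sig=False)]
        assert average_effect(effects, significant_only=True) == 100.0
        assert average_effect(effects, significant_only=False) == 55.0

    def test_empty_selection_rejected(self):
        with pytest.raises(PreconditionError):
            average_effect([eff(10, sig=False)], significant_only=True)


class TestComputeEffects:
    def test_pipeline_effect_values(self):
        panel = panel_from_means({"C1": 0.5, "C2": -0.25}, host_mean=0.0,
                                 donor_mean=1.0, sd=0.1, n=10)
        calls = detect_qtls(panel, "t1", "M")
        effects = {e.strain_id: e for e in compute_effects(panel, "t1", "M", calls)}
        assert effects["C1"].norm_unit == pytest.approx(50.0)
        assert effects["C2"].norm_unit == pytest.approx(-25.0)
        # panel range is [-0.25, 1.0] -> 1.25
        assert effects["C1"].hi_low == pytest.approx(100 * 0.5 / 1.25)
        for e in effects.values():
            assert e.sem_norm_unit > 0
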