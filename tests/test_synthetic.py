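import numpy as np
import pytest

from csspanel import (
    SynthConfig,
    ValidationError,
    compute_effects,
    cumulative_effect,
    detect_qtls,
    generate_measurements,
    generate_panel,
    recovery_metrics,
    simulate_null_fwer,
)

SEX = "pooled"


class TestSynthConfig:
    def test_invalid_field_named(self):
        with pytest.raises(Exception, match="delta"):
            SynthConfig(delta=0.0)

    def test_fraction_length_checked(self):
        with pytest.raises(Exception, match="effect_fractions"):
            SynthConfig(n_css=5, effect_fractions=[0.5, 0.5])


class TestGeneratePanel:
    def test_same_seed_identical(self):
        cfg = SynthConfig(n_css=6, n_traits=2, seed=99)
        m1, t1 = generate_measurements(cfg)
        m2, t2 = generate_measurements(cfg)
        assert m1 == m2 and t1.effect_fractions == t2.effect_fractions

    def test_adding_strain_preserves_existing_draws(self):
        fr8 = [0.2] * 5 + [0.0] * 3
        m1, _ = generate_measurements(
            SynthConfig(n_css=8, effect_fractions=fr8, seed=4)
        )
        m2, _ = generate_measurements(
            SynthConfig(n_css=9, effect_fractions=fr8 + [0.0], seed=4)
        )
        shared = {m.strain_id for m in m1}
        kept2 = [m for m in m2 if m.strain_id in shared]
        assert m1 == kept2

    def test_fractions_sum_to_cumulative_target(self):
        for seed in range(5):
            cfg = SynthConfig(n_css=20, n_traits=3, cumulative_target=800.0,
                              seed=seed)
            _, truth = generate_panel(cfg)
            for trait, cum in truth.cumulative_percent.items():
                assert cum == pytest.approx(800.0)
                assert 100 * sum(truth.effect_fractions[trait].values()) == (
                    pytest.approx(cum)
                )

    def test_full_fraction_lands_on_donor(self):
        cfg = SynthConfig(n_css=3, effect_fractions=[1.0, 0.0, 0.0],
                          sigma=0.01, n_per_strain=50, seed=1)
        panel, _ = generate_panel(cfg)
        calls = detect_qtls(panel, "trait001", SEX)
        effects = {
            e.strain_id: e
            for e in compute_effects(panel, "trait001", SEX, calls)
        }
        assert effects["CSS01"].norm_unit == pytest.approx(100.0, abs=2.0)
        assert abs(effects["CSS02"].norm_unit) < 2.0

    def test_host_and_donor_at_configured_means(self):
        cfg = SynthConfig(n_css=4, n_nonzero=2, mu_host=7.0, delta=3.0,
                          sigma=0.05, n_per_strain=100, seed=2)
        panel, _ = generate_panel(cfg)
        assert panel.summary("HOST", "trait001", SEX).mean == pytest.approx(7.0, abs=0.05)
        assert panel.summary("DONOR", "trait001", SEX).mean == pytest.approx(10.0, abs=0.05)


class TestRecoveryMetrics:
    def test_perfect_detection_strong_effects(self):
        cfg = SynthConfig(n_css=8, effect_fractions=[1.5, -1.5, 2.0, 0, 0, 0, 0, 0],
                          sigma=0.05, n_per_strain=20, seed=5)
        panel, truth = generate_panel(cfg)
        calls = detect_qtls(panel, "trait001", SEX)
        effects = compute_effects(panel, "trait001", SEX, calls)
        rep = recovery_metrics(truth, calls, effects)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.n_direction_wrong == 0

    def test_effect_estimate_tight_at_large_n(self):
        fr = [0.5] + [0.0] * 19
        cfg = SynthConfig(n_css=20, effect_fractions=fr, sigma=0.1,
                          n_per_strain=200, seed=6)
        panel, truth = generate_panel(cfg)
        calls = detect_qtls(panel, "trait001", SEX)
        effects = compute_effects(panel, "trait001", SEX, calls)
        e = next(e for e in effects if e.strain_id == "CSS01")
        assert abs(e.norm_unit - 50.0) <= 3 * e.sem_norm_unit

    def test_cumulative_recovery(self):
        cfg = SynthConfig(n_css=20, cumulative_target=800.0, sigma=0.2,
                          n_per_strain=100, seed=7)
        panel, truth = generate_panel(cfg)
        calls = detect_qtls(panel, "trait001", SEX)
        effects = compute_effects(panel, "trait001", SEX, calls)
        host = panel.summary("HOST", "trait001", SEX)
        donor = panel.summary("DONOR", "trait001", SEX)
        ce = cumulative_effect(effects, "combined", host=host, donor=donor,
                               covariance_aware=True)
        assert abs(ce.sum_percent - 800.0) <= 2 * ce.sem_percent

    def test_mismatched_panel_rejected(self):
        _, truth = generate_panel(SynthConfig(n_css=3, n_nonzero=2, seed=8, n_traits=1))
        panel2, _ = generate_panel(SynthConfig(n_css=3, n_nonzero=2, seed=8, n_traits=2))
        calls = detect_qtls(panel2, "trait002", SEX)
        with pytest.raises(ValidationError):
            recovery_metrics(truth, calls, [])


class TestStatisticalProperties:
    def test_null_fwer_controlled(self):
        fwer = simulate_null_fwer(n_panels=400, n_css=20, n_per_strain=10, seed=21)
        # Bonferroni guarantees FWER <= alpha; allow binomial sampling slack
        assert fwer <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 400)

    def test_directionality_bias_recovered(self):
        towards = total = 0
        for seed in range(60):
            cfg = SynthConfig(n_css=20, n_nonzero=8, towards_bias=0.9,
                              cumulative_target=300.0, sigma=0.1,
                              n_per_strain=20, seed=seed)
            panel, truth = generate_panel(cfg)
            calls = detect_qtls(panel, "trait001", SEX)
            effects = compute_effects(panel, "trait001", SEX, calls)
            for e in effects:
                if e.significant:
                    total += 1
                    towards += e.norm_unit > 0
        frac = towards / total
        se = np.sqrt(0.9 * 0.1 / total)
        assert frac == pytest.approx(0.9, abs=max(4 * se, 0.06))
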