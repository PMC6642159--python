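"""Circadian PBPK forward model: rate laws, conservation, limits."""

import numpy as np
import pytest

from chronopk import (
    CircadianComponent,
    CircadianRate,
    DoseEvent,
    PBPKParameters,
    circadian_rate_value,
    mass_balance_residual,
    model_auc,
    simulate,
)
from chronopk.pbpk import get_param, set_param


def _random_params(rng):
    def comps():
        n = rng.integers(0, 3)
        periods = rng.permutation([24.0, 12.0, 8.0])[:n]
        amps = rng.uniform(0, 1, n)
        if amps.sum() > 1:
            amps = amps / amps.sum() * 0.95
        return tuple(
            CircadianComponent(float(T), float(a), float(rng.uniform(0, T)))
            for T, a in zip(periods, amps)
        )

    return PBPKParameters(
        ka=rng.uniform(0.1, 5),
        k_ib=rng.uniform(0.1, 5),
        k_pl_il=rng.uniform(0, 3),
        k_pl_li=rng.uniform(0.1, 5),
        k_li_pl=rng.uniform(0.1, 2),
        pgp_ileum=CircadianRate(rng.uniform(0, 3), comps()),
        pgp_liver=CircadianRate(rng.uniform(0, 3), comps()),
        renal=CircadianRate(rng.uniform(0.1, 3), comps()),
        intestinal=CircadianRate(rng.uniform(0, 0.1), comps()),
    )


class TestCircadianRate:
    def test_maximum_at_acrophase(self):
        r = CircadianRate(1.0, (CircadianComponent(24.0, 0.5, 15.0),))
        assert circadian_rate_value(r, 15.0) == pytest.approx(1.5)

    def test_trough_opposite_acrophase(self):
        r = CircadianRate(1.0, (CircadianComponent(24.0, 0.5, 15.0),))
        assert circadian_rate_value(r, 3.0) == pytest.approx(0.5)

    def test_arrhythmic_constant(self):
        r = CircadianRate(2.0)
        assert circadian_rate_value(r, 7.3) == pytest.approx(2.0)

    def test_amplitude_budget_enforced(self):
        with pytest.raises(ValueError, match="negative rate"):
            CircadianRate(1.0, (
                CircadianComponent(24.0, 0.7, 0.0),
                CircadianComponent(12.0, 0.5, 0.0),
            ))

    def test_rate_never_negative_under_budget(self):
        r = CircadianRate(1.0, (
            CircadianComponent(24.0, 0.6, 3.0),
            CircadianComponent(12.0, 0.4, 7.0),
        ))
        zt = np.linspace(0, 24, 1000)
        assert np.all(r.value(zt) >= -1e-12)


class TestSimulate:
    def test_no_transfer_everything_stays_in_lumen(self):
        p = PBPKParameters(
            ka=0.0, k_ib=0.0, k_pl_il=0.0, k_pl_li=0.0, k_li_pl=0.0,
            pgp_ileum=CircadianRate(0.0), pgp_liver=CircadianRate(0.0),
            renal=CircadianRate(0.0), intestinal=CircadianRate(0.0),
        )
        s = simulate(p, DoseEvent(dose_mg_per_kg=100, zt_dose=3), t_end=8)
        assert s.dose_ug == pytest.approx(2500.0)  # 100 mg/kg x 25 g
        assert np.allclose(s.amounts["lumen"], 2500.0, atol=1e-6)
        for c in ("ileum", "plasma", "liver", "urine_cum", "feces_cum"):
            assert np.allclose(s.amounts[c], 0.0, atol=1e-8)

    def test_zero_amplitude_dosing_time_invariant(self):
        p = PBPKParameters()  # defaults carry no circadian components
        s3 = simulate(p, DoseEvent(zt_dose=3), t_end=8)
        s15 = simulate(p, DoseEvent(zt_dose=15), t_end=8)
        for m in ("plasma", "ileum", "liver"):
            assert np.allclose(s3.concentration(m), s15.concentration(m), rtol=1e-9, atol=1e-12)

    def test_mass_conserved_random_parameters(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = _random_params(rng)
            s = simulate(p, DoseEvent(zt_dose=float(rng.uniform(0, 24))), t_end=8)
            assert mass_balance_residual(s) < 1e-6

    def test_corrupted_amounts_detected(self):
        s = simulate(PBPKParameters(), DoseEvent(zt_dose=3), t_end=8)
        s.amounts["plasma"] = s.amounts["plasma"] + 0.05 * s.dose_ug
        assert mass_balance_residual(s) > 0.01

    def test_circadian_forcing_is_24h_periodic(self):
        """The forcing seen at t and t+24 h is identical, so a dose repeated
        24 h later reproduces the solution shifted by exactly one day."""
        from chronopk.presets import reference_params

        p = reference_params()
        zt = np.linspace(0, 24, 97)
        for r in (p.pgp_ileum, p.pgp_liver, p.renal, p.intestinal):
            assert np.allclose(r.value(zt), r.value(zt + 24.0), rtol=1e-12)
        a = simulate(p, DoseEvent(zt_dose=5.0), t_end=32.0, dt_out=0.5)
        # solution over [24, 32] after a ZT5 dose equals the first 8 h of a
        # fresh ZT5 dose scaled by the amount still in transit being ~0; the
        # directly checkable statement is equality of the forcing, asserted
        # above, plus determinism of the solver:
        b = simulate(p, DoseEvent(zt_dose=5.0), t_end=32.0, dt_out=0.5)
        for m in ("plasma", "ileum", "liver"):
            assert np.array_equal(a.concentration(m), b.concentration(m))

    def test_renal_dominance_routes_to_urine(self):
        """Renal rate 5 orders above intestinal: >99% of absorbed drug in urine."""
        p = PBPKParameters(
            ka=2.0, k_ib=2.0, k_pl_il=0.0, k_pl_li=1.0, k_li_pl=0.5,
            pgp_ileum=CircadianRate(0.5), pgp_liver=CircadianRate(0.5),
            renal=CircadianRate(1.0), intestinal=CircadianRate(1e-5),
        )
        s = simulate(p, DoseEvent(zt_dose=3), t_end=400.0, dt_out=1.0)
        absorbed = s.dose_ug - s.amounts["lumen"][-1] - s.amounts["feces_cum"][-1]
        assert s.amounts["urine_cum"][-1] / absorbed > 0.99

    def test_bateman_limit(self):
        """Fast ileum transit reduces the chain to the one-compartment
        first-order absorption model (Bateman equation)."""
        ka, ke = 0.8, 0.3
        p = PBPKParameters(
            ka=ka, k_ib=4000.0, k_pl_il=0.0, k_pl_li=0.0, k_li_pl=0.0,
            pgp_ileum=CircadianRate(0.0), pgp_liver=CircadianRate(0.0),
            renal=CircadianRate(ke), intestinal=CircadianRate(0.0),
        )
        s = simulate(p, DoseEvent(zt_dose=3), t_end=24.0)
        bate = s.dose_ug * ka / (ke - ka) * (np.exp(-ka * s.t) - np.exp(-ke * s.t))
        assert np.max(np.abs(s.amounts["plasma"] - bate)) / bate.max() < 1e-3

    def test_invalid_t_end(self):
        with pytest.raises(ValueError):
            simulate(PBPKParameters(), DoseEvent(zt_dose=3), t_end=0.0)


class TestModelAuc:
    def test_constant_concentration(self):
        s = simulate(
            PBPKParameters(ka=0.0, k_ib=0.0, k_pl_il=0.0, k_pl_li=0.0, k_li_pl=0.0,
                           pgp_ileum=CircadianRate(0.0), pgp_liver=CircadianRate(0.0),
                           renal=CircadianRate(0.0), intestinal=CircadianRate(0.0)),
            DoseEvent(zt_dose=3), t_end=8,
        )
        # lumen holds the full dose; fabricate a constant matrix curve
        s.concentrations["plasma"] = np.ones_like(s.t)
        assert model_auc(s, "plasma", (0, 8)) == pytest.approx(8.0)
        s.concentrations["plasma"] = np.zeros_like(s.t)
        assert model_auc(s, "plasma", (0, 8)) == pytest.approx(0.0)

    def test_grid_refinement_agreement(self):
        from chronopk.presets import recovery_params

        p = recovery_params()
        coarse = simulate(p, DoseEvent(zt_dose=3), t_end=8, dt_out=0.05)
        fine = simulate(p, DoseEvent(zt_dose=3), t_end=8, dt_out=0.005)
        for m in ("plasma", "ileum", "liver"):
            a, b = model_auc(coarse, m), model_auc(fine, m)
            assert abs(a - b) / b < 1e-3

    def test_window_outside_grid_rejected(self):
        s = simulate(PBPKParameters(), DoseEvent(zt_dose=3), t_end=4)
        with pytest.raises(ValueError, match="window"):
            model_auc(s, "plasma", (0, 8))


class TestParamPaths:
    def test_get_set_roundtrip(self):
        from chronopk.presets import reference_params

        p = reference_params()
        for path in ("ka", "renal.mean_rate", "pgp_ileum.amp0", "renal.phase0"):
            v = get_param(p, path)
            p2 = set_param(p, path, v * 0.5 if "phase" not in path else (v + 1) % 24)
            assert get_param(p2, path) != pytest.approx(v)
            assert get_param(set_param(p2, path, v), path) == pytest.approx(v)

    def test_unknown_path_rejected(self):
        with pytest.raises((KeyError, AttributeError)):
            get_param(PBPKParameters(), "renal.bogus0")
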