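import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fenpbpk as f
from fenpbpk import evaluation as ev


def _obs(times, conc, **kw):
    return ev.ObservedDataset(study_id="s", analyte="fentanyl",
                              sampling_site="venous_plasma",
                              times=np.asarray(times, float),
                              conc=np.asarray(conc, float), **kw)


class TestMrd:
    def test_perfect_prediction(self):
        t = np.linspace(0.1, 10, 20)
        c = 50.0 * np.exp(-0.3 * t)
        assert ev.mrd(t, c, _obs(t, c)) == pytest.approx(1.0, abs=1e-12)

    def test_tenfold_overprediction(self):
        t = np.linspace(0.1, 10, 20)
        c = 50.0 * np.exp(-0.3 * t)
        assert ev.mrd(t, 10 * c, _obs(t, c)) == pytest.approx(10.0, abs=1e-10)

    def test_hand_computed_two_points(self):
        # predictions 1 and 4 against observations 2 and 2:
        # 10^sqrt(mean((log10 .5)^2, (log10 2)^2)) = 2
        assert ev.mrd([1.0, 2.0], [1.0, 4.0], _obs([1.0, 2.0], [2.0, 2.0])) \
            == pytest.approx(2.0, abs=1e-12)

    def test_unit_invariance(self):
        t = np.linspace(0.1, 10, 15)
        c = 20.0 * np.exp(-0.2 * t)
        obs_c = c * np.exp(0.1 * np.sin(t))
        mw = 336.5
        a = ev.mrd(t, c, _obs(t, obs_c))
        b = ev.mrd(t, c / mw, _obs(t, obs_c / mw))
        assert a == pytest.approx(b, abs=1e-12)

    def test_lloq_handling(self):
        t = np.array([1.0, 2.0, 3.0])
        pred = np.array([10.0, 5.0, 1.0])
        obs = _obs(t, [10.0, 5.0, 0.05], lloq=0.1)
        assert ev.mrd(t, pred, obs) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            ev.mrd(t, pred, _obs(t, [0.01, 0.01, 0.01], lloq=0.1))


class TestGmfe:
    def test_closed_forms(self):
        assert ev.gmfe([1.0, 1.0]) == pytest.approx(1.0, abs=1e-12)
        assert ev.gmfe([2.0, 0.5]) == pytest.approx(2.0, abs=1e-12)
        assert ev.gmfe([1.25]) == pytest.approx(1.25, abs=1e-12)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            ev.gmfe([])
        with pytest.raises(ValueError):
            ev.gmfe([1.0, -2.0])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0.05, 20.0), min_size=1, max_size=10))
    def test_at_least_one_and_inversion_invariant(self, ratios):
        g = ev.gmfe(ratios)
        assert g >= 1.0 - 1e-12
        assert ev.gmfe([1.0 / r for r in ratios]) == pytest.approx(g, rel=1e-9)


class TestFoldCoverage:
    def test_enumerated_cases(self):
        assert ev.fold_coverage([(3.0, 3.0), (1.0, 1.0)]) == 100.0
        assert ev.fold_coverage([(1.0, 3.0)]) == 0.0
        assert ev.fold_coverage([(1.0, 1.9), (1.0, 2.1)]) == 50.0

    def test_symmetric_under_pred_obs_exchange(self):
        pairs = [(1.0, 1.8), (5.0, 2.0), (0.3, 0.35), (4.0, 9.0)]
        swapped = [(o, p) for p, o in pairs]
        assert ev.fold_coverage(pairs) == ev.fold_coverage(swapped)


class TestSensitivity:
    def test_one_compartment_closed_form(self):
        """For AUC = D/(k V), the normalized sensitivity to k is exactly -1."""
        def modifier(model, name, value):
            assert name == "k"
            return f.PBPKModel.one_compartment(10.0, value, mw=336.5, name="drug")

        m = f.PBPKModel.one_compartment(10.0, 0.05, mw=336.5, name="drug")
        s = ev.sensitivity(m, [f.DoseEvent("drug", 0.0, 0.0, 1000.0)],
                           {"k": 0.05}, delta=0.01, t_end=10.0,
                           modifier=modifier)
        assert s["k"] == pytest.approx(-1.0, abs=1e-3)

    def test_structural_zero_and_sign(self, adult_model, ziesenitz_regimen):
        s = ev.sensitivity(adult_model, ziesenitz_regimen,
                           {"unspecific_k": 1.46,
                            "GFR_fraction_norfentanyl": 4.3},
                           delta=0.1, t_end=24.0)
        assert abs(s["GFR_fraction_norfentanyl"]) < 1e-6
        assert s["unspecific_k"] < 0.0

    def test_richardson_convergence(self, adult_model, ziesenitz_regimen):
        """Central-difference coefficients converge as delta shrinks."""
        s1 = ev.sensitivity(adult_model, ziesenitz_regimen,
                            {"unspecific_k": 1.46}, delta=0.1, t_end=24.0)
        s2 = ev.sensitivity(adult_model, ziesenitz_regimen,
                            {"unspecific_k": 1.46}, delta=0.05, t_end=24.0)
        assert abs(s2["unspecific_k"] - s1["unspecific_k"]) < \
            0.01 * abs(s1["unspecific_k"]) + 1e-4


class TestGofSummary:
    def test_perfect_predictions(self):
        t = np.linspace(0.5, 12, 10)
        profiles = [(t, 30.0 * np.exp(-0.25 * t)), (t, 8.0 * np.exp(-0.4 * t))]
        observations = [_obs(t, c) for _, c in profiles]
        g = ev.gof_summary(profiles, observations)
        assert g.gmfe_auc == pytest.approx(1.0, abs=1e-9)
        assert g.pct_within_2fold_conc == 100.0
        assert g.pct_within_2fold_auc == 100.0
        assert g.n_profiles == 2
        assert np.allclose(g.per_profile["mrd"], 1.0)
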