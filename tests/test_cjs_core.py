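"""CJS likelihood, chi recursion, fitting, and the AIC trait scan."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import cmrselect.synthetic_data as sd
from cmrselect.capture_io import EncounterHistory, build_histories
from cmrselect.cjs_core import (
    CJSError,
    CJSParams,
    ModelComparison,
    SelectorResult,
    chi_vector,
    consistency,
    dataset_loglik,
    fit_cjs,
    history_loglik,
    scan_frame,
    scan_traits,
)
from cmrselect.trait_prep import build_covariate_table


def brute_force_prob(h: EncounterHistory, phi: float, p: float) -> float:
    """Independent oracle: sum over the (unobserved) last occasion alive.

    Conditioned on release at the first detection f, the individual is alive
    through occasions f..a (surviving a-f intervals, then dying unless a = T);
    detection applies at each occasion in (f, a].
    """
    T = len(h.detections)
    f, last = h.first, h.last
    total = 0.0
    for a in range(last, T + 1):
        pr = phi ** (a - f) * ((1.0 - phi) if a < T else 1.0)
        for t in range(f + 1, a + 1):
            pr *= p if h.detections[t - 1] else (1.0 - p)
        total += pr
    return total


class TestChiVector:
    def test_one_step_recursion(self):
        chi = chi_vector(0.5, 0.5, first=1, T=2)
        assert chi[0] == pytest.approx(0.75)
        assert chi[-1] == 1.0

    def test_certain_detection(self):
        chi = chi_vector(0.3, 1.0, first=1, T=5)
        assert np.allclose(chi[:-1], 0.7)

    def test_no_survival(self):
        chi = chi_vector(0.0, 0.5, first=1, T=5)
        assert np.allclose(chi, 1.0)

    def test_entries_in_unit_interval(self):
        for phi in (0.1, 0.5, 0.9):
            for p in (0.1, 0.5, 0.9):
                chi = chi_vector(phi, p, first=1, T=8)
                assert np.all((chi > 0) & (chi <= 1))


class TestHistoryLoglik:
    def test_release_then_recapture(self):
        h = EncounterHistory.from_string("x", "11")
        assert history_loglik(h, 0.5, 0.5) == pytest.approx(math.log(0.25))

    def test_survive_miss_survive_detect(self):
        h = EncounterHistory.from_string("x", "101")
        assert history_loglik(h, 0.5, 0.5) == pytest.approx(math.log(0.0625))

    def test_never_seen_again_equals_chi(self):
        h = EncounterHistory.from_string("x", "10")
        assert history_loglik(h, 0.5, 0.5) == pytest.approx(math.log(0.75))

    def test_rejects_boundary_parameters(self):
        h = EncounterHistory.from_string("x", "11")
        with pytest.raises(CJSError):
            history_loglik(h, 1.0, 0.5)

    def test_matches_exhaustive_oracle_T4(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            phi, p = rng.uniform(0.05, 0.95, 2)
            f = int(rng.integers(1, 4))
            suffix = tuple(int(b) for b in rng.integers(0, 2, 4 - f))
            det = (0,) * (f - 1) + (1,) + suffix
            h = EncounterHistory("x", det)
            expected = brute_force_prob(h, phi, p)
            assert history_loglik(h, phi, p) == pytest.approx(
                math.log(expected), abs=1e-10
            )

    def test_normalization_over_all_suffixes(self):
        # acceptance runs the full grid; spot-check here
        T, f = 6, 2
        for phi, p in [(0.3, 0.7), (0.8, 0.2)]:
            total = 0.0
            for suffix in itertools.product([0, 1], repeat=T - f):
                det = (0,) * (f - 1) + (1,) + suffix
                total += math.exp(history_loglik(EncounterHistory("x", det), phi, p))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_detections_monotone_in_phi_and_p(self):
        h = EncounterHistory.from_string("x", "1111")
        grid = np.linspace(0.1, 0.9, 9)
        ll_phi = [history_loglik(h, g, 0.5) for g in grid]
        ll_p = [history_loglik(h, 0.5, g) for g in grid]
        assert np.all(np.diff(ll_phi) > 0)
        assert np.all(np.diff(ll_p) > 0)


class TestDatasetLoglik:
    def test_two_identical_histories_double_the_loglik(self):
        h = EncounterHistory.from_string("a", "101")
        h2 = EncounterHistory.from_string("b", "101")
        params = CJSParams(np.array([0.3]), -0.2)
        single = history_loglik(h, params.phi(), params.p)
        assert dataset_loglik([h, h2], None, params) == pytest.approx(2 * single)

    def test_terminal_captures_contribute_nothing(self):
        hs = [EncounterHistory.from_string(f"i{k}", "00001") for k in range(5)]
        params = CJSParams(np.array([0.1]), 0.4)
        assert dataset_loglik(hs, None, params) == pytest.approx(0.0, abs=1e-14)

    def test_vectorized_path_matches_scalar_reference(self):
        rng = np.random.default_rng(6)
        out = sd.simulate(sd.preset("cowlesi", n_initial=40, recruits_per_occasion=5), seed=9)
        hs = build_histories(out.dataset)
        x = {h.individual_id: float(v) for h, v in zip(hs, rng.normal(size=len(hs)))}
        params = CJSParams(np.array([0.2, 0.4]), -0.1)
        expected = sum(
            history_loglik(h, params.phi(x[h.individual_id]), params.p) for h in hs
        )
        assert dataset_loglik(hs, x, params) == pytest.approx(expected, abs=1e-9)


class TestFitCJS:
    def test_null_fit_k_and_aic_arithmetic(self):
        hs = [EncounterHistory.from_string(f"i{k}", "110") for k in range(10)]
        fit = fit_cjs(hs)
        assert fit.k == 2
        assert fit.AIC == pytest.approx(-2 * fit.logL + 4, abs=1e-12)

    def test_t2_only_the_product_is_identifiable(self):
        hs = [EncounterHistory.from_string(f"r{k}", "11") for k in range(20)] + [
            EncounterHistory.from_string(f"m{k}", "10") for k in range(30)
        ]
        fit = fit_cjs(hs)
        assert fit.params.phi() * fit.params.p == pytest.approx(0.4, abs=1e-6)
        assert fit.se is None  # flat ridge: information is singular

    def test_no_recaptures_flagged_non_identifiable(self):
        hs = [EncounterHistory.from_string(f"i{k}", "100") for k in range(8)]
        fit = fit_cjs(hs)
        assert not fit.identifiable

    def test_recovers_simulation_truth(self):
        cfg = sd.preset("maculata", n_initial=500, recruits_per_occasion=0)
        fit = fit_cjs(build_histories(sd.simulate(cfg, seed=21).dataset))
        assert fit.converged
        assert abs(fit.phi_hat - 0.68) <= 3 * fit.phi_se
        assert abs(fit.p_hat - 0.57) <= 3 * fit.p_se

    def test_covariate_recovery_within_3_se(self):
        # selection on the latent trait, measured without within-individual noise
        cfg = sd.SimConfig(
            n_initial=2000, recruits_per_occasion=0,
            occasion_times=(0.0, 1.0, 2.0, 3.0, 4.0),
            p_true=0.55, beta0=-0.2,
            traits=(sd.TraitSpec("t", sigma_among=1.0, sigma_within=0.0, beta1=0.6),),
        )
        out = sd.simulate(cfg, seed=17)
        hs = build_histories(out.dataset)
        tab = build_covariate_table(out.dataset, "t", "first")
        fit = fit_cjs(hs, tab.values)
        assert fit.converged and fit.se is not None
        assert abs(fit.params.beta[0] - (-0.2)) <= 3 * fit.se[0]
        assert abs(fit.params.beta[1] - 0.6) <= 3 * fit.se[1]
        assert abs(fit.params.p_logit - math.log(0.55 / 0.45)) <= 3 * fit.se[2]


class TestScanTraits:
    def test_strong_effect_beats_null_for_all_selectors(self):
        cfg = sd.preset(
            "cowlesi", n_initial=400, recruits_per_occasion=0,
            selection={"dorsal_a": 1.0},
        )
        out = sd.simulate(cfg, seed=12)
        (mc,) = scan_traits(out.dataset, ["dorsal_a"])
        assert mc.complete
        assert all(d < 0 for d in mc.dAIC())
        assert consistency(mc)

    def test_constant_trait_flagged_not_fatal(self, design5):
        import pandas as pd

        from cmrselect.capture_io import Dataset

        frame = pd.DataFrame(
            {"individual_id": ["a", "a", "b", "b"],
             "species": ["fence_lizard"] * 4, "occasion": [1, 2, 1, 3],
             "flat": [5.0] * 4}
        )
        ds = Dataset.from_events(design5, frame)
        (mc,) = scan_traits(ds, ["flat"])
        assert not mc.complete
        assert all(r.error is not None for r in mc.results.values())

    def test_scan_frame_layout(self):
        out = sd.simulate(sd.preset("maculata", n_initial=150), seed=4)
        comparisons = scan_traits(out.dataset, ["dorsal_L"])
        frame = scan_frame(comparisons)
        assert set(frame["selector"]) == {"first", "median", "last"}
        assert {"species", "trait", "dAIC", "beta1", "converged"} <= set(frame.columns)


class TestConsistency:
    def _mc(self, daics, margin_errors=()):
        mc = ModelComparison("sp", "t")
        for sel, d in zip(("first", "median", "last"), daics):
            mc.results[sel] = SelectorResult(selector=sel, dAIC=d)
        return mc

    def test_all_negative_is_consistent(self):
        assert consistency(self._mc((-1.2, -0.3, -4.0)))

    def test_any_positive_breaks_consistency(self):
        assert not consistency(self._mc((-1.2, +0.3, -4.0)))

    def test_strict_margin(self):
        assert not consistency(self._mc((-1.0, -1.0, -1.0)), strict_margin=2.0)
        assert consistency(self._mc((-3.0, -2.5, -2.1)), strict_margin=2.0)
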