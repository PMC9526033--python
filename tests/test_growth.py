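"""Seasonal VBGF evaluation, Rn scoring and the four ELEFAN workflows."""

import numpy as np
import pytest

import stockhab as sh
from stockhab.errors import ComputationError, ValidationError
from stockhab.growth import (
    GAConfig,
    SAConfig,
    VBGFParams,
    _best_over_anchors,
    elefan_ga,
    elefan_kscan,
    elefan_rsa,
    elefan_sa,
    inverse_vbgf_age,
    score_rn,
    seasonal_vbgf_length,
)

from .conftest import TRUE_K, TRUE_LINF


class TestVBGF:
    def test_asymptote(self):
        p = VBGFParams(434.0, 0.43, t0_yr=-0.06)
        assert seasonal_vbgf_length(p, 200.0) == pytest.approx(434.0)

    def test_zero_length_at_t0(self):
        p = VBGFParams(434.0, 0.43, t0_yr=-0.06)
        assert seasonal_vbgf_length(p, -0.06) == pytest.approx(0.0, abs=1e-12)

    def test_length_at_age_one(self):
        # direct evaluation: 434 * (1 - exp(-0.43 * 1.06))
        p = VBGFParams(434.0, 0.43, t0_yr=-0.06)
        assert seasonal_vbgf_length(p, 1.0) == pytest.approx(
            434.0 * (1.0 - np.exp(-0.43 * 1.06)), rel=1e-12
        )
        assert seasonal_vbgf_length(p, 1.0) == pytest.approx(158.9, abs=0.1)

    def test_non_decreasing_and_seasonal_reduces_to_plain(self):
        ages = np.linspace(0.0, 10.0, 400)
        seasonal = VBGFParams(434.0, 0.43, c_amp=1.0, ts_yr=0.3, t0_yr=0.0)
        assert np.all(np.diff(seasonal_vbgf_length(seasonal, ages)) >= -1e-9)
        plain = VBGFParams(434.0, 0.43, c_amp=0.0, t0_yr=0.0)
        classic = 434.0 * (1.0 - np.exp(-0.43 * ages))
        np.testing.assert_allclose(seasonal_vbgf_length(plain, ages), classic, rtol=1e-12)

    def test_inverse_round_trip(self):
        p = VBGFParams(434.0, 0.43, t0_yr=-0.06)
        lengths = np.array([50.0, 150.0, 300.0, 420.0])
        np.testing.assert_allclose(
            seasonal_vbgf_length(p, inverse_vbgf_age(p, lengths)), lengths, rtol=1e-10
        )
        with pytest.raises(ValidationError):
            inverse_vbgf_age(p, 434.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            VBGFParams(434.0, 0.43, c_amp=1.2)
        with pytest.raises(ValidationError):
            VBGFParams(-1.0, 0.43)


class TestScoreRn:
    def _restr(self, values, dates=(2020.0,)):
        values = np.asarray(values, dtype=float)
        return sh.RestructuredLFQ(
            values=values,
            ma_window=5,
            bin_lower_mm=50.0 * np.arange(values.shape[0]),
            sample_dates=np.asarray(dates, dtype=float),
            bin_width_mm=50.0,
        )

    def _hit_bin(self, params, date):
        # bin the 1-year-old cohort's length falls into, for anchor 0
        length = seasonal_vbgf_length(VBGFParams(params.linf_mm, params.k_per_yr), date % 1.0 + 1.0)
        return int(length // 50.0)

    def test_rn_formula_endpoints(self):
        params = VBGFParams(434.0, 0.43, t_anchor_yr=0.0)
        values = np.zeros((9, 1))
        # find every bin any cohort trajectory hits at the single date
        probe = self._restr(np.ones((9, 1)))
        hit = set()
        for age in range(1, 10):
            length = seasonal_vbgf_length(VBGFParams(434.0, 0.43), float(age))
            hit.add(int(length // 50.0))
        hit = {b for b in hit if 0 <= b < 9}
        miss = [b for b in range(9) if b not in hit][0]
        # all positive score inside hit bins: ESP = ASP -> Rn = 1
        for b in hit:
            values[b, 0] = 1.0
        assert score_rn(self._restr(values), params) == pytest.approx(1.0)
        # positive score only in an unreachable bin: ESP = 0 -> Rn = 0.1
        values = np.zeros((9, 1))
        values[miss, 0] = 1.0
        assert score_rn(self._restr(values), params) == pytest.approx(0.1)
        # half explained: Rn = 10**0.5 / 10
        values = np.zeros((9, 1))
        values[next(iter(hit)), 0] = 1.0
        values[miss, 0] = 1.0
        assert score_rn(self._restr(values), params) == pytest.approx(10**0.5 / 10.0)

    def test_rn_bounded_for_random_params(self, clean_restructured):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = VBGFParams(
                linf_mm=float(rng.uniform(300, 600)),
                k_per_yr=float(rng.uniform(0.1, 1.2)),
                t_anchor_yr=float(rng.uniform(0, 1)),
                c_amp=float(rng.uniform(0, 1)),
                ts_yr=float(rng.uniform(0, 1)),
            )
            rn = score_rn(clean_restructured, p)
            assert 0.0 < rn <= 1.0

    def test_zero_asp_raises(self):
        restr = self._restr(np.zeros((9, 1)))
        with pytest.raises(ComputationError):
            score_rn(restr, VBGFParams(434.0, 0.43))


class TestKScan:
    def test_recovers_k_at_true_linf(self, clean_lfq):
        fit = elefan_kscan(clean_lfq, TRUE_LINF, np.arange(0.1, 1.001, 0.01))
        assert fit.params.k_per_yr == pytest.approx(TRUE_K, abs=0.011)

    def test_single_element_grid(self, clean_lfq):
        fit = elefan_kscan(clean_lfq, TRUE_LINF, [0.7])
        assert fit.params.k_per_yr == 0.7

    def test_tie_breaks_to_smaller_k(self):
        # a flat landscape: single positive bin unreachable by either K
        lfq = sh.LengthFrequencyData(
            np.arange(6) * 10.0, [2019.0], [[3], [3], [3], [3], [9], [3]]
        )
        fit = elefan_kscan(lfq, 5000.0, [0.9, 0.2, 0.5])
        rns = [
            _best_over_anchors(sh.restructure(lfq, 5), 5000.0, k,
                               np.round(np.arange(0, 1, 0.05), 10), 0.0, 0.0)[0]
            for k in (0.2, 0.5, 0.9)
        ]
        assert rns.count(fit.rn) >= 1
        ties = [k for k, r in zip((0.2, 0.5, 0.9), rns) if r == fit.rn]
        assert fit.params.k_per_yr == min(ties)

    def test_empty_grid_rejected(self, clean_lfq):
        with pytest.raises(ValidationError):
            elefan_kscan(clean_lfq, TRUE_LINF, [])


class TestRSA:
    def test_surface_matches_double_loop_oracle(self, clean_lfq):
        linf_grid = np.linspace(400, 470, 6)
        k_grid = np.linspace(0.3, 0.6, 5)
        anchors = np.round(np.arange(0, 1, 0.05), 10)
        fit = elefan_rsa(clean_lfq, linf_grid, k_grid, anchors=anchors)
        restr = sh.restructure(clean_lfq, 5)
        oracle = np.empty((6, 5))
        for i, linf in enumerate(linf_grid):
            for j, k in enumerate(k_grid):
                oracle[i, j] = max(
                    score_rn(restr, VBGFParams(float(linf), float(k), float(a)))
                    for a in anchors
                )
        np.testing.assert_allclose(fit.surface, oracle, atol=1e-12)
        best = np.unravel_index(np.argmax(oracle), oracle.shape)
        assert fit.rn == pytest.approx(oracle[best])

    def test_one_by_one_grid(self, clean_lfq):
        fit = elefan_rsa(clean_lfq, [434.0], [0.43])
        assert (fit.params.linf_mm, fit.params.k_per_yr) == (434.0, 0.43)

    def test_recovery_within_one_step(self, clean_lfq):
        fit = elefan_rsa(clean_lfq, np.arange(394, 475, 10.0), np.arange(0.33, 0.54, 0.025))
        assert abs(fit.params.linf_mm - TRUE_LINF) <= 10.0 + 1e-9
        assert abs(fit.params.k_per_yr - TRUE_K) <= 0.025 + 1e-9


TINY_GRIDS = {
    "linf_mm": [420.0, 434.0, 450.0],
    "k_per_yr": [0.38, 0.43, 0.50],
    "t_anchor_yr": [0.94],
    "c_amp": [0.0],
    "ts_yr": [0.0],
}
TINY_BOUNDS = {k: (min(v), max(v)) for k, v in TINY_GRIDS.items()}


def _enumerate_optimum(restr):
    best = -np.inf
    for linf in TINY_GRIDS["linf_mm"]:
        for k in TINY_GRIDS["k_per_yr"]:
            best = max(best, score_rn(restr, VBGFParams(linf, k, 0.94)))
    return best


class TestStochasticWorkflows:
    def test_sa_equals_enumeration_on_tiny_space(self, clean_lfq, clean_restructured):
        cfg = SAConfig(n_temps=40, n_per_temp=10, grids=TINY_GRIDS)
        fit = elefan_sa(clean_lfq, TINY_BOUNDS, cfg, seed=5)
        assert fit.rn == pytest.approx(_enumerate_optimum(clean_restructured), abs=1e-12)

    def test_ga_at_least_enumeration_on_tiny_space(self, clean_lfq, clean_restructured):
        cfg = GAConfig(pop_size=20, n_generations=10, grids=TINY_GRIDS)
        fit = elefan_ga(clean_lfq, TINY_BOUNDS, cfg, seed=5)
        assert fit.rn >= _enumerate_optimum(clean_restructured) - 1e-12

    def test_same_seed_reproduces(self, clean_lfq, search_bounds):
        cfg = SAConfig(n_temps=20, n_per_temp=10)
        a = elefan_sa(clean_lfq, search_bounds, cfg, seed=9)
        b = elefan_sa(clean_lfq, search_bounds, cfg, seed=9)
        assert a.params == b.params and a.rn == b.rn
        gcfg = GAConfig(pop_size=15, n_generations=8)
        c = elefan_ga(clean_lfq, search_bounds, gcfg, seed=9)
        d = elefan_ga(clean_lfq, search_bounds, gcfg, seed=9)
        assert c.params == d.params and c.rn == d.rn

    def test_seed_mandatory(self, clean_lfq, search_bounds):
        with pytest.raises(ValidationError):
            elefan_sa(clean_lfq, search_bounds)
        with pytest.raises(ValidationError):
            elefan_ga(clean_lfq, search_bounds)

    def test_inverted_bounds_rejected(self, clean_lfq):
        bad = dict(TINY_BOUNDS)
        bad["linf_mm"] = (450.0, 420.0)
        with pytest.raises(ValidationError):
            elefan_sa(clean_lfq, bad, seed=1)


class TestSweep:
    def test_enumerates_and_ranks(self, noisy_samples):
        cfg_sa = SAConfig(n_temps=10, n_per_temp=5, n_anchor_profile=20)
        cfg_ga = GAConfig(pop_size=10, n_generations=4, n_anchor_profile=20)
        fits = sh.scenario_sweep(
            noisy_samples.samples, bins=(10.0, 20.0), mas=(5, 7),
            workflows=("KS", "SA"), seed=4, sa_config=cfg_sa, ga_config=cfg_ga,
        )
        assert len(fits) == 2 * 2 * 2
        rns = [f.rn for f in fits]
        assert rns == sorted(rns, reverse=True)
        assert {(f.workflow, f.bin_mm, f.ma_window) for f in fits} == {
            (w, b, m) for w in ("KS", "SA") for b in (10.0, 20.0) for m in (5, 7)
        }

    def test_model_interface(self, noisy_samples):
        model = sh.ElefanModel(noisy_samples.samples, bin_mm=10.0, ma_window=5)
        fit = model.fit("KS", fixed_linf=450.0, k_grid=[0.3, 0.43, 0.6])
        assert "ELEFAN KS" in fit.summary()
        assert 0 < fit.rn <= 1
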