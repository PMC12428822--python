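"""Wald-ratio SMR estimator and the HEIDI heterogeneity test."""

import numpy as np
import pytest
from scipy import stats

from omicsmr.qc import HarmonizedPair
from omicsmr.smr import (
    HeidiConfig,
    heidi_test,
    heidi_test_arrays,
    select_heidi_snps,
    smr_analysis,
    smr_test,
)

from conftest import make_assoc, make_panel, make_qtl


def make_pair(vid, b_exp, se_exp, b_out, se_out, pos=2_000_000, p_exp=None):
    exp = make_qtl(vid, beta=b_exp, se=se_exp, p=p_exp, pos=pos)
    out = make_assoc(vid, beta=b_out, se=se_out, pos=pos)
    return HarmonizedPair(exp, out)


class TestSmrTest:
    def test_ratio(self):
        b, _, _ = smr_test(0.5, 0.05, 0.1, 0.05)
        assert b == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        b, se, p = smr_test(0.5, 0.05, 0.0, 0.05)
        assert (b, p) == (0.0, 1.0)

    def test_statistic_against_hand_formula(self):
        # z_exp = 10, z_out = 2: T = 400/104, p from the 1-df chi-square tail
        b, se, p = smr_test(1.0, 0.1, 0.2, 0.1)
        t_expected = 400.0 / 104.0
        assert b == pytest.approx(0.2)
        assert p == pytest.approx(stats.chi2.sf(t_expected, 1), rel=1e-12)
        assert se == pytest.approx(abs(b) / np.sqrt(t_expected), rel=1e-12)

    def test_zero_exposure_guarded(self):
        with pytest.raises(ZeroDivisionError):
            smr_test(0.0, 0.1, 0.2, 0.1)

    def test_scale_equivariance_in_outcome(self):
        b1, se1, p1 = smr_test(0.5, 0.05, 0.1, 0.02)
        b2, se2, p2 = smr_test(0.5, 0.05, 0.2, 0.04)
        assert b2 == pytest.approx(2 * b1)
        assert se2 == pytest.approx(2 * se1)
        assert p2 == pytest.approx(p1, rel=1e-12)

    @pytest.mark.parametrize("z_exp,z_out", [(10, 2), (5, 5), (30, 1.5), (3.3, 8)])
    def test_t_bounded_by_component_chi_squares(self, z_exp, z_out):
        _, _, p = smr_test(z_exp * 0.1, 0.1, z_out * 0.1, 0.1)
        t = (z_exp**2 * z_out**2) / (z_exp**2 + z_out**2)
        assert t <= min(z_exp**2, z_out**2) + 1e-12
        p_exp = 2 * stats.norm.sf(abs(z_exp))
        p_out = 2 * stats.norm.sf(abs(z_out))
        assert p >= max(p_exp, p_out) - 1e-12


class TestSelectHeidiSnps:
    def _setup(self, r_values, p_exp=1e-6):
        """Panel where each candidate has a chosen approximate r to the top."""
        rng = np.random.default_rng(0)
        n = 60_000
        top = rng.binomial(2, 0.5, n).astype(float)
        cols = {"top": top}
        pairs = []
        top_pair = make_pair("top", 0.5, 0.02, 0.1, 0.02)
        for i, r in enumerate(r_values):
            vid = f"c{i}"
            # mixture construction: copy the top column with probability ~r
            keep = rng.random(n) < abs(r)
            col = np.where(keep, top, rng.binomial(2, 0.5, n)).astype(float)
            cols[vid] = col
            pairs.append(make_pair(vid, 0.4, 0.02, 0.08, 0.02, p_exp=p_exp))
        return make_panel(cols), top_pair, pairs

    def test_band_membership(self):
        # approximate r^2 of the mixture construction: (r)^2 of copy prob
        panel, top, pairs = self._setup([0.98, 0.7, 0.1])
        got = select_heidi_snps(pairs, top, panel,
                                HeidiConfig(min_snps=1))
        ids = [p.exposure.variant.id for p in got]
        assert ids == ["c1"]  # 0.98^2 ~ 0.96 too high, 0.1^2 too low

    def test_truncation_keeps_top_r2(self):
        rng = np.random.default_rng(1)
        rs = list(rng.uniform(0.35, 0.9, 30))
        panel, top, pairs = self._setup(rs)
        got = select_heidi_snps(pairs, top, panel, HeidiConfig(max_snps=20))
        assert len(got) == 20
        r2 = [panel.r2("top", p.exposure.variant.id) for p in got]
        assert all(x >= 0.05 for x in r2)
        excluded = set(p.exposure.variant.id for p in pairs) - set(
            p.exposure.variant.id for p in got
        )
        best_excluded = max(
            panel.r2("top", v) for v in excluded if panel.r2("top", v) <= 0.9
        )
        assert min(r2) >= best_excluded - 1e-12

    def test_min_snps_not_evaluable(self):
        panel, top, pairs = self._setup([0.7, 0.6])
        assert select_heidi_snps(pairs, top, panel, HeidiConfig()) is None

    def test_exposure_p_cap(self):
        panel, top, pairs = self._setup([0.7, 0.65, 0.6], p_exp=0.01)
        assert select_heidi_snps(pairs, top, panel,
                                 HeidiConfig(min_snps=1)) is None

    def test_top_absent_from_panel_raises(self):
        panel, top, pairs = self._setup([0.7])
        orphan = make_pair("nowhere", 0.5, 0.02, 0.1, 0.02)
        with pytest.raises(KeyError):
            select_heidi_snps(pairs, orphan, panel, HeidiConfig())


class TestHeidiTest:
    def test_homogeneous_ratios_give_p_near_one(self):
        # all b_xy identical and tiny SEs: no heterogeneity
        m = 5
        R = 0.5 * np.ones((m, m)) + 0.5 * np.eye(m)
        b_exp = np.full(m, 0.5)
        b_out = np.full(m, 0.1)
        p = heidi_test_arrays(b_exp, np.full(m, 1e-5), b_out, np.full(m, 1e-5), R)
        assert p > 0.99

    def test_heterogeneous_ratios_rejected(self):
        m = 5
        R = 0.5 * np.ones((m, m)) + 0.5 * np.eye(m)
        b_exp = np.full(m, 0.5)
        b_out = np.array([0.1, 0.1, -0.1, 0.1, -0.1])
        p = heidi_test_arrays(b_exp, np.full(m, 1e-4), b_out, np.full(m, 1e-4), R)
        assert p < 1e-6

    def test_object_wrapper_matches_arrays(self):
        rng = np.random.default_rng(4)
        n = 50_000
        base = rng.binomial(2, 0.4, n).astype(float)
        cols, pairs = {"top": base}, []
        top_pair = make_pair("top", 0.5, 0.02, 0.1, 0.02)
        for i in range(4):
            keep = rng.random(n) < 0.6
            cols[f"c{i}"] = np.where(keep, base,
                                     rng.binomial(2, 0.4, n)).astype(float)
            pairs.append(make_pair(f"c{i}", 0.35 + 0.02 * i, 0.02,
                                   0.07 + 0.01 * i, 0.02))
        panel = make_panel(cols)
        p_obj = heidi_test(top_pair, pairs, panel)
        ids = ["top"] + [f"c{i}" for i in range(4)]
        R = panel.corr_matrix(ids)
        ordered = [top_pair] + pairs
        p_arr = heidi_test_arrays(
            np.array([p.exposure.assoc.beta for p in ordered]),
            np.array([p.exposure.assoc.se for p in ordered]),
            np.array([p.outcome.beta for p in ordered]),
            np.array([p.outcome.se for p in ordered]),
            R,
        )
        assert p_obj == pytest.approx(p_arr, rel=1e-12)


class TestDeltaMethodCovariance:
    def test_analytic_covariance_matches_simulation(self):
        """Empirical covariance of d across replicates vs the delta-method
        form, entrywise within 15% at n = 10^4 and strong instruments."""
        from omicsmr.experiments import _locus_summary_stats, _rep_config
        from omicsmr.simulate import ScenarioConfig, simulate_panel

        scenario = ScenarioConfig(
            m_variants=8, ld_rho=0.8, n_ref=50_000, n_exposure=10_000,
            n_outcome=10_000, hypothesis="H4", causal_idx_exposure=3,
            causal_idx_outcome=3, var_explained_exposure=0.1,
            outcome_prevalence=0.3, outcome_log_or=0.3,
        )
        panel = simulate_panel(
            _rep_config(scenario, seed=77, rep=-1)  # law seed 77
        )
        R = panel.corr_matrix([v.id for v in panel.variants])
        idx = [3, 2, 1, 0]  # top (causal) + three one-sided LD partners
        n_reps = 1500
        d_samples = np.empty((n_reps, 3))
        covs = np.zeros((3, 3))
        from omicsmr.smr import HeidiConfig

        for rep in range(n_reps):
            cfg = _rep_config(scenario, seed=77, rep=rep)
            (be, se_e, _), (bo, se_o, _), _, _ = _locus_summary_stats(cfg)
            b_xy = bo[idx] / be[idx]
            d_samples[rep] = b_xy[1:] - b_xy[0]
            # analytic covariance at this replicate's estimates
            bexp, seexp = be[idx], se_e[idx]
            bout, seout = bo[idx], se_o[idx]
            Rsub = R[np.ix_(idx, idx)]
            bo_ = bout / bexp
            beo = np.outer(bexp, bexp)
            C = Rsub * np.outer(seout, seout) / beo + (
                np.outer(bo_, bo_) * Rsub * np.outer(seexp, seexp) / beo
            )
            covs += C[1:, 1:] - C[1:, [0]] - C[[0], 1:] + C[0, 0]
        analytic = covs / n_reps
        empirical = np.cov(d_samples, rowvar=False)
        rel = np.abs(empirical - analytic) / np.abs(analytic)
        assert np.max(rel) < 0.15


class TestSmrAnalysis:
    def test_top_snp_is_smallest_exposure_p(self):
        rng = np.random.default_rng(8)
        cols = {f"v{i}": None for i in range(5)}
        panel = make_panel(cols, n_individuals=500, seed=8)
        pairs = [
            make_pair(f"v{i}", 0.3 + 0.05 * i, 0.02, 0.06, 0.02)
            for i in range(5)
        ]
        res = smr_analysis(pairs, panel)
        assert res.top_snp == "v4"  # largest |z| -> smallest p
        assert res.b_smr == pytest.approx(0.06 / 0.5)
        assert res.or_smr == pytest.approx(np.exp(res.b_smr))

    def test_sign_consistency(self):
        panel = make_panel({"v0": None}, n_individuals=500)
        res = smr_analysis([make_pair("v0", 0.5, 0.02, -0.1, 0.02)], panel)
        assert res.b_smr < 0
        assert np.sign(res.b_smr) == np.sign(-0.1 * 0.5)
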