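"""Domain types, file round-trips, and LD panel correlations."""

import gzip

import numpy as np
import pytest

from omicsmr.simulate import ScenarioConfig, simulate_exposure_sumstats
from omicsmr.sumstats import (
    AssocRecord,
    LdPanel,
    SumstatsFormatError,
    SumstatsRowError,
    UndefinedLdError,
    Variant,
    read_panel,
    read_sumstats,
    write_panel,
    write_sumstats,
)

from conftest import make_assoc, make_panel, make_variant


class TestDomainTypes:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(a1="A", a2="A"),  # identical alleles
            dict(a1="AT", a2="G"),  # indel
            dict(a1="N", a2="G"),  # non-ACGT
            dict(pos=0),
            dict(eaf=1.5),
        ],
    )
    def test_variant_invariants_rejected(self, kw):
        with pytest.raises(ValueError):
            make_variant(**kw)

    def test_palindromic_detection(self):
        assert make_variant(a1="A", a2="T").is_palindromic
        assert make_variant(a1="C", a2="G").is_palindromic
        assert not make_variant(a1="A", a2="G").is_palindromic

    @pytest.mark.parametrize("kw", [dict(se=0.0), dict(se=-1.0), dict(p=0.0),
                                    dict(p=1.5)])
    def test_assoc_invariants_rejected(self, kw):
        with pytest.raises(ValueError):
            AssocRecord(make_variant(), beta=0.1,
                        **{"se": 0.02, "p": 0.5, "n": 100, **kw})

    def test_inconsistent_p_warns_but_keeps_value(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            rec = AssocRecord(make_variant(), beta=0.5, se=0.05, p=0.5, n=100)
        assert rec.p == 0.5  # stored as given, never recomputed


class TestReadWrite:
    def test_round_trip_lossless(self, tmp_path):
        cfg = ScenarioConfig(
            m_variants=50, n_exposure=500, n_ref=100, n_outcome=100,
            hypothesis="H1", causal_idx_exposure=25, n_probes_per_gene=2,
            seed=11,
        )
        records = simulate_exposure_sumstats(cfg)
        assert len(records) == 100
        path = tmp_path / "qtl.tsv"
        write_sumstats(records, path)
        back = read_sumstats(path, "qtl")
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.variant == b.variant
            assert a.assoc.beta == pytest.approx(b.assoc.beta, abs=1e-12)
            assert a.assoc.se == pytest.approx(b.assoc.se, abs=1e-12)
            assert a.assoc.p == pytest.approx(b.assoc.p, rel=1e-12)
            assert (a.probe_id, a.gene, a.layer, a.probe_pos) == (
                b.probe_id, b.gene, b.layer, b.probe_pos
            )

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "gwas.tsv.gz"
        write_sumstats([make_assoc("rs9", beta=0.2, se=0.05)], path)
        with gzip.open(path, "rt") as fh:
            assert fh.readline().startswith("SNP\t")
        (rec,) = read_sumstats(path, "gwas")
        assert rec.variant.id == "rs9"

    def test_direct_field_mapping_and_case(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tFREQ\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\ta\tg\t0.30\t0.10\t0.02\t5e-7\t1980\n"
        )
        (rec,) = read_sumstats(path, "gwas")
        assert (rec.beta, rec.se, rec.n) == (0.10, 0.02, 1980)
        assert (rec.variant.a1, rec.variant.a2) == ("A", "G")

    def test_zero_se_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tFREQ\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.30\t0.10\t0.02\t5e-7\t1980\n"
            "rs2\t1\t200\tA\tG\t0.30\t0.10\t0\t5e-7\t1980\n"
        )
        with pytest.raises(SumstatsRowError, match="line 3"):
            read_sumstats(path, "gwas")
        records, problems = read_sumstats(path, "gwas", strict=False)
        assert len(records) == 1 and len(problems) == 1
        assert problems[0].line == 3

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tFREQ\tBETA\tSE\tP\n")
        with pytest.raises(SumstatsFormatError, match="N"):
            read_sumstats(path, "gwas")

    def test_unparsable_numeric_cites_line(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tFREQ\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.30\tzzz\t0.02\t5e-7\t1980\n"
        )
        with pytest.raises(SumstatsRowError, match="line 2.*BETA"):
            read_sumstats(path, "gwas")

    def test_panel_round_trip(self, tmp_path):
        panel = make_panel({f"rs{i}": None for i in range(5)}, seed=3)
        write_panel(panel, tmp_path / "d.tsv", tmp_path / "v.tsv")
        back = read_panel(tmp_path / "d.tsv", tmp_path / "v.tsv")
        np.testing.assert_array_equal(panel.genotypes, back.genotypes)
        assert [v.id for v in back.variants] == [v.id for v in panel.variants]


class TestLdPanel:
    def test_self_correlation_is_one(self):
        panel = make_panel({"a": None, "b": None})
        assert panel.r("a", "a") == pytest.approx(1.0)

    def test_reflection_gives_minus_one(self):
        col = np.random.default_rng(0).binomial(2, 0.4, 100).astype(float)
        panel = make_panel({"a": col, "b": 2.0 - col})
        assert panel.r("a", "b") == pytest.approx(-1.0)

    def test_symmetry_and_individual_order_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, (150, 2)).astype(float)
        panel = make_panel({"a": g[:, 0], "b": g[:, 1]})
        perm = rng.permutation(150)
        shuffled = make_panel({"a": g[perm, 0], "b": g[perm, 1]})
        assert panel.r("a", "b") == pytest.approx(panel.r("b", "a"))
        assert panel.r("a", "b") == pytest.approx(shuffled.r("a", "b"))

    def test_allele_flip_negates_r(self):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], 500)
        g = (z < 0).astype(float) + (rng.multivariate_normal(
            [0, 0], [[1, 0.7], [0.7, 1]], 500) < 0)
        panel = make_panel({"a": g[:, 0], "b": g[:, 1]})
        flipped = make_panel({"a": 2.0 - g[:, 0], "b": g[:, 1]})
        assert flipped.r("a", "b") == pytest.approx(-panel.r("a", "b"))

    def test_zero_variance_is_undefined(self):
        panel = make_panel({"a": np.ones(50), "b": None})
        with pytest.raises(UndefinedLdError):
            panel.r("a", "b")

    def test_pairwise_complete_with_missing(self):
        col = np.array([0, 1, 2, 1, 0, np.nan, 2, 1, 0, 1], dtype=float)
        other = np.array([0, 1, 2, 1, 0, 2, np.nan, 1, 0, 1], dtype=float)
        panel = make_panel({"a": col, "b": other})
        # shared non-missing entries are identical -> r = 1
        assert panel.r("a", "b") == pytest.approx(1.0)

    def test_low_call_rate_flagged(self):
        col = np.full(100, 1.0)
        col[:10] = np.nan  # call rate 0.90 < 0.95
        panel = make_panel({"a": col, "b": None})
        assert "a" in panel.low_call_rate and "b" not in panel.low_call_rate

    def test_ar1_panel_r_tracks_latent_correlation(self):
        from omicsmr.simulate import ScenarioConfig, simulate_panel

        cfg = ScenarioConfig(
            m_variants=10, ld_rho=0.8, n_ref=5000, maf_range=(0.3, 0.3001),
            n_exposure=100, n_outcome=100, hypothesis="H0", seed=42,
        )
        panel = simulate_panel(cfg)
        # independent oracle: dosage correlation of thresholded bivariate
        # normal haplotypes, r = (Phi2(t, t, rho) - f^2) / (f (1 - f))
        from scipy.stats import multivariate_normal, norm

        f = 0.3
        t = norm.ppf(f)
        joint = multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]]).cdf([t, t])
        expected = (joint - f**2) / (f * (1 - f))
        rs = [panel.r(f"rs{i}", f"rs{i+1}") for i in range(1, 10)]
        assert np.mean(rs) == pytest.approx(expected, abs=0.05)
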