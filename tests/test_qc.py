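"""Instrument QC: windows, thresholds, clumping, harmonization, and the
hand-enumerated 20-record funnel."""

import numpy as np
import pytest

from omicsmr.qc import (
    DropReason,
    QcConfig,
    clump,
    filter_af_concordance,
    filter_significance,
    filter_weak,
    harmonize,
    run_qc,
    select_cis,
)

from conftest import make_assoc, make_panel, make_qtl


class TestSelectCis:
    def test_boundary_inclusive(self):
        rec = make_qtl("rs1", pos=1_000_000)
        assert select_cis([rec], gene_pos=2_000_000, window_kb=1000) == [rec]

    def test_just_outside_dropped(self):
        rec = make_qtl("rs1", pos=999_999)
        assert select_cis([rec], gene_pos=2_000_000, window_kb=1000) == []

    def test_hand_enumerated_window(self):
        positions = [100, 500_000, 999_999, 1_000_000, 1_500_000, 2_000_000,
                     2_500_000, 3_000_000, 3_000_001, 4_000_000]
        recs = [make_qtl(f"rs{i}", pos=p) for i, p in enumerate(positions)]
        kept = select_cis(recs, gene_pos=2_000_000, window_kb=1000)
        assert [r.variant.pos for r in kept] == [
            1_000_000, 1_500_000, 2_000_000, 2_500_000, 3_000_000
        ]

    def test_cross_chromosome_excluded(self):
        rec = make_qtl("rs1", pos=2_000_000, chrom="2")
        assert select_cis([rec], 2_000_000, 1000, gene_chrom="1") == []


class TestSignificance:
    def test_exact_threshold_dropped_strict(self):
        rec = make_qtl("rs1", beta=0.3, se=0.05, p=5e-8)
        assert filter_significance([rec], "mQTL") == []

    def test_pqtl_threshold(self):
        rec = make_qtl("rs1", beta=0.3, se=0.05, p=1e-9, layer="pQTL")
        assert filter_significance([rec], "pQTL") == [rec]
        border = make_qtl("rs2", beta=0.3, se=0.05, p=1.8e-9, layer="pQTL")
        assert filter_significance([border], "pQTL") == []

    def test_mixed_fixture_hand_enumerated(self):
        ps = [1e-9, 5e-8, 4e-8, 0.03, 1e-12, 2e-8, 1.0, 6e-8, 1e-10, 0.5,
              4.9e-8, 5.1e-8]
        recs = [make_qtl(f"rs{i}", beta=0.5, se=0.05, p=p)
                for i, p in enumerate(ps)]
        kept = filter_significance(recs, "eQTL")
        # strictly below 5e-8: indices 0, 2, 4, 5, 8, 10
        assert [r.variant.id for r in kept] == [
            "rs0", "rs2", "rs4", "rs5", "rs8", "rs10"
        ]


class TestClump:
    def _fixture(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.3, 2000).astype(float)
        noisy = base.copy()
        flip = rng.random(2000) < 0.25  # r^2 ~ 0.5 to base
        noisy[flip] = rng.binomial(2, 0.3, int(flip.sum()))
        indep = rng.binomial(2, 0.3, 2000).astype(float)
        panel = make_panel({"rs1": base, "rs2": noisy, "rs3": indep})
        recs = [
            make_qtl("rs1", pos=1_000_000, beta=0.6, se=0.05, p=1e-10),
            make_qtl("rs2", pos=1_100_000, beta=0.55, se=0.05, p=1e-9),
            make_qtl("rs3", pos=1_200_000, beta=0.5, se=0.05, p=1e-8),
        ]
        assert panel.r2("rs1", "rs2") > 0.3
        assert panel.r2("rs1", "rs3") < 0.01
        return recs, panel

    def test_greedy_rule_keeps_index_and_independent(self):
        recs, panel = self._fixture()
        kept = clump(recs, panel, clump_kb=10_000, clump_r2=0.001)
        assert [r.variant.id for r in kept] == ["rs1", "rs3"]

    def test_single_record_kept(self):
        recs, panel = self._fixture()
        assert clump(recs[:1], panel) == recs[:1]

    def test_input_order_invariance(self):
        recs, panel = self._fixture()
        expected = {r.variant.id for r in clump(recs, panel)}
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            out = clump([recs[i] for i in perm], panel)
            assert {r.variant.id for r in out} == expected

    def test_smallest_p_always_survives(self):
        recs, panel = self._fixture()
        kept = clump(recs, panel, clump_kb=10_000, clump_r2=0.0001)
        assert "rs1" in {r.variant.id for r in kept}

    def test_outside_kb_window_not_clumped(self):
        recs, panel = self._fixture()
        # distance condition: rs2 sits 100 kb away; a 0.05 kb window spares it
        kept = clump(recs, panel, clump_kb=0.05, clump_r2=0.001)
        assert {r.variant.id for r in kept} == {"rs1", "rs2", "rs3"}

    def test_undefined_ld_conservatively_removed(self):
        panel = make_panel({"rs1": None, "rs2": np.ones(200)})
        recs = [
            make_qtl("rs1", pos=1_000_000, beta=0.6, se=0.05, p=1e-10),
            make_qtl("rs2", pos=1_001_000, beta=0.5, se=0.05, p=1e-9),
        ]
        with pytest.warns(UserWarning, match="undefined reference LD"):
            kept = clump(recs, panel)
        assert [r.variant.id for r in kept] == ["rs1"]


class TestWeakAndAf:
    @pytest.mark.parametrize(
        "beta,se,kept",
        [(0.1, 0.05, False), (0.5, 0.05, True),
         (0.1 * np.sqrt(10), 0.1, True)],  # F exactly 10 -> kept
    )
    def test_f_statistic_rule(self, beta, se, kept):
        rec = make_qtl("rs1", beta=beta, se=se, p=0.5)
        assert (filter_weak([rec]) == [rec]) is kept

    @pytest.mark.parametrize(
        "ref,qtl,gwas,expect",
        [
            (0.30, 0.35, 0.55, DropReason.af_discordant),  # 0.25 > 0.2
            (0.30, 0.35, 0.45, None),  # max diff 0.15
            (0.30, 0.30, 0.50, None),  # exactly 0.2 kept
        ],
    )
    def test_pairwise_af_rule(self, ref, qtl, gwas, expect):
        n = 5000
        col = np.random.default_rng(1).binomial(2, ref, n).astype(float)
        # force the panel frequency to the exact target
        col[: int(2 * ref * n) - int(col.sum())] = 0
        panel = make_panel({"rs1": col})
        exp = make_qtl("rs1", beta=0.5, se=0.05, eaf=qtl)
        out = make_assoc("rs1", beta=0.2, se=0.05, eaf=gwas)
        pair = harmonize(exp, out)
        checked = filter_af_concordance(pair, panel)
        ref_realized = panel.eaf("rs1")
        assert abs(ref_realized - ref) < 0.01
        if expect is None and abs(max(ref_realized, qtl, gwas)
                                  - min(ref_realized, qtl, gwas)) <= 0.2:
            assert not checked.dropped
        elif expect is not None:
            assert checked.dropped_reason == expect

    def test_missing_eaf_distinct_reason(self):
        panel = make_panel({"rsX": None})
        exp = make_qtl("rs1", beta=0.5, se=0.05, eaf=0.3)
        out = make_assoc("rs1", beta=0.2, se=0.05, eaf=0.3)
        pair = harmonize(exp, out)
        checked = filter_af_concordance(pair, panel)  # rs1 absent from panel
        assert checked.dropped_reason == DropReason.af_missing


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_qtl("rs1", beta=0.3, se=0.05, a1="A", a2="G", eaf=0.3)
        out = make_assoc("rs1", beta=0.2, se=0.05, a1="G", a2="A", eaf=0.6)
        pair = harmonize(exp, out)
        assert pair.flipped
        assert pair.outcome.beta == pytest.approx(-0.2)
        assert pair.outcome.variant.eaf == pytest.approx(0.4)
        assert pair.outcome.se == 0.05  # SE and p never altered
        assert pair.outcome.p == out.p

    def test_strand_complement_resolved(self):
        exp = make_qtl("rs1", beta=0.3, se=0.05, a1="A", a2="G", eaf=0.3)
        out = make_assoc("rs1", beta=0.2, se=0.05, a1="T", a2="C", eaf=0.31)
        pair = harmonize(exp, out)
        assert not pair.dropped and not pair.flipped
        assert pair.outcome.beta == pytest.approx(0.2)

    def test_idempotent(self):
        exp = make_qtl("rs1", beta=0.3, se=0.05, a1="A", a2="G", eaf=0.3)
        out = make_assoc("rs1", beta=0.2, se=0.05, a1="G", a2="A", eaf=0.6)
        once = harmonize(exp, out)
        twice = harmonize(exp, once.outcome)
        assert not twice.flipped
        assert twice.outcome == once.outcome

    def test_palindromic_ambiguous_band(self):
        exp = make_qtl("rs1", beta=0.3, se=0.05, a1="A", a2="T", eaf=0.50)
        out = make_assoc("rs1", beta=0.2, se=0.05, a1="A", a2="T", eaf=0.30)
        pair = harmonize(exp, out)
        assert pair.dropped_reason == DropReason.palindromic_ambiguous

    def test_palindromic_outside_band_resolved_by_frequency(self):
        exp = make_qtl("rs1", beta=0.3, se=0.05, a1="A", a2="T", eaf=0.20)
        same = make_assoc("rs1", beta=0.2, se=0.05, a1="A", a2="T", eaf=0.22)
        other = make_assoc("rs1", beta=0.2, se=0.05, a1="A", a2="T", eaf=0.80)
        assert not harmonize(exp, same).flipped
        assert harmonize(exp, other).flipped

    def test_irreconcilable_alleles_dropped(self):
        exp = make_qtl("rs1", beta=0.3, se=0.05, a1="A", a2="G", eaf=0.3)
        out = make_assoc("rs1", beta=0.2, se=0.05, a1="A", a2="C", eaf=0.3)
        assert harmonize(exp, out).dropped_reason == DropReason.allele_mismatch


def _z(p):
    from scipy import stats
    return stats.norm.isf(p / 2)


def build_funnel_fixture():
    """20 QTL records engineered so every funnel stage drops a known subset.

    Hand-enumerated outcome (gene at 2 Mb, +/-1000 kb window, eQTL layer):
      not_cis:               r01, r02
      not_significant:       r03, r04, r05
      pruned (r^2 > 0.9):    r06 (duplicate of the stronger r07)
      weak_instrument:       r08 (F = 4)
      no_outcome_match:      r12
      palindromic_ambiguous: r10
      allele_mismatch:       r11
      af_discordant:         r09
      survivors:             r07, r13 (flipped), r14..r20  -> 9 pairs
    """
    rng = np.random.default_rng(99)
    n = 300
    cols = {}
    base = rng.binomial(2, 0.3, n).astype(float)
    for i in range(1, 21):
        cols[f"r{i:02d}"] = rng.binomial(2, 0.3, n).astype(float)
    cols["r07"] = base
    cols["r06"] = base.copy()  # r^2 = 1 with r07
    meta = {f"r{i:02d}": dict(pos=2_000_000 + 1000 * i) for i in range(1, 21)}
    meta["r10"].update(a1="A", a2="T")
    panel = make_panel(cols, meta)

    strong = dict(beta=0.5, se=0.05)  # z = 10, F = 100
    def qtl(vid, pos, **kw):
        base_kw = dict(eaf=0.3, **strong)
        base_kw.update(kw)
        return make_qtl(vid, pos=pos, layer="eQTL", **base_kw)

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # r08's p is deliberately inconsistent
        records = [
            qtl("r01", 500_000),
            qtl("r02", 999_999),
            qtl("r03", 1_100_000, p=1e-3, beta=0.16),
            qtl("r04", 1_200_000, p=5e-8, beta=0.27),
            qtl("r05", 1_300_000, p=0.2, beta=0.06),
            qtl("r06", 2_006_000),  # z = 10: p ~ 1.5e-23
            qtl("r07", 2_007_000, beta=0.6),  # z = 12: wins the clump
            qtl("r08", 2_008_000, p=1e-9, beta=0.1),  # F = 4, p kept as given
            qtl("r09", 2_009_000),
            qtl("r10", 2_010_000, a1="A", a2="T", eaf=0.5),
            qtl("r11", 2_011_000),
            qtl("r12", 2_012_000),
        ] + [qtl(f"r{i}", 2_000_000 + 1000 * i) for i in range(13, 21)]

    out = dict(beta=0.1, se=0.03, eaf=0.31)
    gwas = []
    for rec in records:
        vid = rec.variant.id
        if vid == "r12":
            continue  # absent from the outcome GWAS
        kw = dict(out)
        if vid == "r09":
            kw["eaf"] = 0.55  # discordant vs reference/QTL ~0.3
        if vid == "r13":
            kw.update(a1="G", a2="A", eaf=0.69)  # swapped orientation
        elif vid == "r10":
            kw.update(a1="A", a2="T", eaf=0.5)
        elif vid == "r11":
            kw.update(a1="A", a2="C")  # irreconcilable with exposure A/G
        else:
            kw.update(a1="A", a2="G")
        gwas.append(make_assoc(vid, **kw))
    return records, gwas, panel


EXPECTED_SURVIVORS = {"r07", "r13", "r14", "r15", "r16", "r17", "r18", "r19",
                      "r20"}
EXPECTED_REASONS = {
    DropReason.not_cis: 2,
    DropReason.not_significant: 3,
    DropReason.pruned: 1,
    DropReason.weak_instrument: 1,
    DropReason.no_outcome_match: 1,
    DropReason.palindromic_ambiguous: 1,
    DropReason.allele_mismatch: 1,
    DropReason.af_discordant: 1,
}


class TestQcFunnel:
    def test_twenty_record_funnel_hand_enumerated(self):
        records, gwas, panel = build_funnel_fixture()
        pairs, funnel = run_qc(records, gwas, panel, 2_000_000, "eQTL")
        assert {p.exposure.variant.id for p in pairs} == EXPECTED_SURVIVORS
        assert funnel.reasons == EXPECTED_REASONS
        assert funnel.total_dropped() == 20 - len(pairs)
        flipped = {p.exposure.variant.id for p in pairs if p.flipped}
        assert flipped == {"r13"}

    def test_funnel_counts_chain(self):
        records, gwas, panel = build_funnel_fixture()
        _, funnel = run_qc(records, gwas, panel, 2_000_000, "eQTL")
        for (_, _, n_out), (_, n_in, _) in zip(funnel.stages, funnel.stages[1:]):
            assert n_out == n_in

    def test_order_invariance(self):
        records, gwas, panel = build_funnel_fixture()
        rng = np.random.default_rng(3)
        shuffled = list(records)
        rng.shuffle(shuffled)
        pairs, _ = run_qc(shuffled, gwas, panel, 2_000_000, "eQTL")
        assert {p.exposure.variant.id for p in pairs} == EXPECTED_SURVIVORS

    def test_each_dropped_record_has_exactly_one_reason(self):
        records, gwas, panel = build_funnel_fixture()
        pairs, funnel = run_qc(records, gwas, panel, 2_000_000, "eQTL")
        assert sum(funnel.reasons.values()) == len(records) - len(pairs)


class TestQcConfig:
    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            QcConfig(f_min=-1)

    def test_clump_below_prune(self):
        with pytest.raises(ValueError):
            QcConfig(clump_r2=0.95, prune_r2=0.9)
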