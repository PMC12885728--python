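"""Instrument filters: BH FDR, F statistics, clumping, outcome exclusion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from mirmr import (bh_fdr, f_statistic, filter_instruments,
                   filter_outcome_significant, harmonize, ld_clump, load_ld)
from mirmr.errors import AlignmentError, ConfigurationError, DomainError

from conftest import make_exposure, make_outcome, make_variant


def brute_force_bh(p):
    """Independent BH oracle: sort, scale, cumulative min from the tail."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestBHFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_domain_error_outside_unit_interval(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], []):
            with pytest.raises(DomainError):
                bh_fdr(bad)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_and_statsmodels(self, pvals):
        q = bh_fdr(pvals)
        np.testing.assert_allclose(q, brute_force_bh(pvals), atol=1e-12)
        sm = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, sm, atol=1e-12)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_adjusted_values_dominate_raw(self, pvals):
        q = bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestFStatistic:
    @pytest.mark.parametrize("beta, se, expected",
                             [(0.5, 0.1, 25.0), (0.0, 0.1, 0.0)])
    def test_arithmetic(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_weak_instrument_boundary(self):
        assert f_statistic(-0.3162278, 0.1) == pytest.approx(10.0, rel=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(DomainError):
            f_statistic(0.5, 0.0)


class TestFilterInstruments:
    def strong(self, i, **kw):
        kw.setdefault("cis", True)
        kw.setdefault("consequence", "intergenic")
        return make_exposure(i, 0.5, se=0.02, **kw)

    def test_clean_records_pass_through(self):
        records = [self.strong(i) for i in range(5)]
        out = filter_instruments(records)
        assert len(out.records) == 5
        assert all(v == 0 for v in out.filter_log.values())
        assert np.all(out.f_stats > 10) and np.all(out.qvalues < 0.1)

    def test_coding_consequences_removed(self):
        records = [self.strong(0), self.strong(1, consequence="missense"),
                   self.strong(2, consequence="synonymous")]
        out = filter_instruments(records)
        assert len(out.records) == 1 and out.filter_log["consequence"] == 2

    def test_trans_acting_removed(self):
        records = [self.strong(0), self.strong(1, cis=False)]
        out = filter_instruments(records)
        assert len(out.records) == 1 and out.filter_log["cis"] == 1

    def test_fdr_stage_keeps_constructed_survivors(self):
        # 4 tiny p-values pass BH at q<0.1; 6 large ones fail by construction
        records = ([self.strong(i, p=1e-6) for i in range(4)]
                   + [self.strong(i + 4, p=0.9) for i in range(6)])
        out = filter_instruments(records, f_threshold=0.0)
        kept = {r.variant.rsid for r in out.records}
        assert kept == {f"rs{i}" for i in range(4)}
        assert out.filter_log["fdr"] == 6

    def test_weak_instruments_removed_at_f_stage(self):
        records = [self.strong(0), self.strong(1, variant=None)]
        weak = make_exposure(2, 0.01, se=0.02, p=1e-12, cis=True,
                             consequence="intergenic")  # F = 0.25
        out = filter_instruments(records + [weak])
        assert weak.variant not in [r.variant for r in out.records]
        assert out.filter_log["f_stat"] == 1

    def test_missing_annotations_skip_those_stages(self):
        records = [make_exposure(i, 0.5, se=0.02) for i in range(4)]
        out = filter_instruments(records)
        assert len(out.records) == 4
        assert out.filter_log["cis"] == 0 and out.filter_log["consequence"] == 0

    def test_order_insensitive(self, rng):
        records = [self.strong(i, p=float(p))
                   for i, p in enumerate(rng.uniform(1e-8, 1, 12))]
        a = filter_instruments(records)
        b = filter_instruments(records[::-1])
        assert [r.variant for r in a.records] == [r.variant for r in b.records]
        np.testing.assert_allclose(a.qvalues, b.qvalues)


def brute_force_clump(records, r2, r2_threshold, window_bp):
    """Independent greedy-clump oracle over an explicit conflict matrix."""
    recs = sorted(records, key=lambda r: (r.pvalue,) + r.variant.sort_key)
    n = len(recs)
    conflict = [[recs[i].variant.chrom == recs[j].variant.chrom
                 and abs(recs[i].variant.pos - recs[j].variant.pos) <= window_bp
                 and r2(recs[i].variant, recs[j].variant) >= r2_threshold
                 for j in range(n)] for i in range(n)]
    kept_idx = []
    for i in range(n):
        if not any(conflict[i][j] for j in kept_idx):
            kept_idx.append(i)
    return sorted((recs[i] for i in kept_idx), key=lambda r: r.variant.sort_key)


class TestLdClump:
    def test_correlated_neighbors_keep_best_pvalue(self):
        a = make_exposure(0, 0.5, p=1e-10, pos=1000)
        b = make_exposure(1, 0.5, p=1e-5, pos=6000)
        kept = ld_clump([a, b], lambda x, y: 0.9)
        assert kept == [a]

    def test_distant_correlated_snps_both_kept(self):
        a = make_exposure(0, 0.5, p=1e-10, pos=1000)
        b = make_exposure(1, 0.5, p=1e-5, pos=51000)
        assert len(ld_clump([a, b], lambda x, y: 0.9)) == 2

    def test_uncorrelated_neighbors_both_kept(self):
        a = make_exposure(0, 0.5, p=1e-10, pos=1000)
        b = make_exposure(1, 0.5, p=1e-5, pos=2000)
        assert len(ld_clump([a, b], lambda x, y: 0.1)) == 2

    def test_degenerate_thresholds_keep_everything(self):
        records = [make_exposure(i, 0.5, p=1e-5, pos=1000 + i) for i in range(5)]
        assert len(ld_clump(records, lambda x, y: 0.99, r2_threshold=1.0)) == 5
        assert len(ld_clump(records, lambda x, y: 1.0, window_bp=0)) == 5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ld_clump([], lambda x, y: 0, window_bp=-1)
        with pytest.raises(ConfigurationError):
            ld_clump([], lambda x, y: 0, r2_threshold=1.5)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for trial in range(30):
            j = int(rng.integers(2, 13))
            records = [make_exposure(i, 0.5, p=float(rng.uniform(1e-8, 1)),
                                     chrom=str(rng.integers(1, 3)),
                                     pos=int(rng.integers(1, 30000)))
                       for i in range(j)]
            table = {}
            for i in range(j):
                for k in range(i + 1, j):
                    table[frozenset((f"rs{i}", f"rs{k}"))] = float(rng.uniform(0, 1))
            r2 = lambda a, b: table.get(frozenset((a.rsid, b.rsid)), 1.0)
            kept = ld_clump(records, r2)
            oracle = brute_force_clump(records, r2, 0.5, 10000)
            assert [r.variant for r in kept] == [r.variant for r in oracle]
            # antichain validity: no kept pair conflicts jointly
            for a in kept:
                for b in kept:
                    if a is not b and a.variant.chrom == b.variant.chrom:
                        assert not (abs(a.variant.pos - b.variant.pos) <= 10000
                                    and r2(a.variant, b.variant) >= 0.5)


class TestFilterOutcomeSignificant:
    def h(self, pvals):
        es = [make_exposure(i, 0.5) for i in range(len(pvals))]
        os_ = [make_outcome(e.variant, 0.01, p=p) for e, p in zip(es, pvals)]
        return harmonize(es, os_)

    def test_nonsignificant_snps_pass_through(self):
        h = filter_outcome_significant(self.h([0.5, 0.5, 0.5]))
        assert h.nsnp == 3 and h.dropped == []

    def test_genome_wide_significant_snp_dropped(self):
        h = filter_outcome_significant(self.h([0.5, 1e-9, 0.5]))
        assert h.nsnp == 2
        assert [r for _, r in h.dropped] == ["outcome genome-wide significant"]

    def test_threshold_one_empties_the_set(self):
        h = filter_outcome_significant(self.h([0.5, 0.5]), threshold=1.0)
        assert h.nsnp == 0

    def test_length_mismatch_is_alignment_error(self):
        with pytest.raises(AlignmentError):
            filter_outcome_significant(self.h([0.5, 0.5]), [0.5])


def test_load_ld_triplet_and_square(tmp_path):
    trip = tmp_path / "ld.tsv"
    trip.write_text("rsid_a\trsid_b\tr2\nrs0\trs1\t0.8\n")
    f = load_ld(trip)
    a, b, c = make_variant(0), make_variant(1), make_variant(2)
    assert f(a, b) == 0.8 and f(b, a) == 0.8
    assert f(a, c) == 0.0 and f(a, a) == 1.0

    sq = tmp_path / "ld_sq.tsv"
    sq.write_text("rsid\trs0\trs1\nrs0\t1.0\t0.7\nrs1\t0.7\t1.0\n")
    g = load_ld(sq)
    assert g(a, b) == 0.7
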