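import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epidriver import methylome as em
from epidriver._stats import bh_adjust
from epidriver.errors import UndefinedValueError, ValidationError
from epidriver.io import GenomicInterval, GeneModel
from conftest import make_methylome


class TestCoverageFilter:
    def test_boundary_at_min_cov(self):
        m = make_methylome(
            [100, 200, 300, 400, 500],
            [[1], [2], [3], [1], [2]],
            [[4], [3], [10], [2], [4]],
            sample_names=["S1"],
            conditions=["tumor"],
        )
        out = em.filter_by_coverage(m, 4)
        assert out.n_sites == 3
        assert list(out.sites["pos"]) == [100, 300, 500]

    def test_min_cov_zero_is_identity(self):
        m = make_methylome([100], [[1, 1]], [[2, 3]])
        assert em.filter_by_coverage(m, 0) is m

    def test_all_below_threshold_gives_empty(self):
        m = make_methylome([100, 200], [[1], [1]], [[2], [3]],
                           sample_names=["S1"], conditions=["tumor"])
        assert em.filter_by_coverage(m, 4).n_sites == 0


class TestRegionMean:
    def test_unweighted_mean_of_site_betas(self):
        m = make_methylome(
            [101, 151, 201], [[0], [2], [4]], [[10], [10], [10]],
            sample_names=["S1"], conditions=["tumor"],
        )
        v = em.region_mean_methylation(m, GenomicInterval("chr1", 0, 1000), ["S1"])
        assert v == pytest.approx(0.2)

    def test_single_site(self):
        m = make_methylome([101], [[3]], [[10]], sample_names=["S1"], conditions=["tumor"])
        assert em.region_mean_methylation(m, GenomicInterval("chr1", 0, 200)) == pytest.approx(0.3)

    def test_region_without_cpgs_errors(self):
        m = make_methylome([101], [[3]], [[10]], sample_names=["S1"], conditions=["tumor"])
        with pytest.raises(UndefinedValueError):
            em.region_mean_methylation(m, GenomicInterval("chr2", 0, 200))


class TestCallUMRs:
    def _embedded_low_run(self, beta_low=0.05, n_low=20):
        pos = np.arange(1, 61) * 50
        beta = np.full(60, 0.8)
        beta[20:20 + n_low] = beta_low
        total = np.full((60, 1), 20)
        meth = np.round(beta * 20).astype(int)[:, None]
        return make_methylome(pos, meth, total, sample_names=["S1"], conditions=["normal"]), pos

    def test_recovers_planted_run(self):
        m, pos = self._embedded_low_run()
        umrs = em.call_umrs(m, ["S1"])
        assert len(umrs) == 1
        u = umrs[0]
        assert u.n_cpgs == 20
        assert u.interval.start == pos[20] - 1
        assert u.interval.end == pos[39]
        assert u.mean_meth <= 0.10

    def test_uniform_high_methylation_gives_nothing(self):
        pos = np.arange(1, 31) * 50
        m = make_methylome(pos, np.full((30, 1), 16), np.full((30, 1), 20),
                           sample_names=["S1"], conditions=["normal"])
        assert em.call_umrs(m, ["S1"]) == []

    def test_min_cpgs_threshold(self):
        m, _ = self._embedded_low_run()
        assert em.call_umrs(m, ["S1"], umr_min_cpgs=30) == []

    def test_gap_constraint_splits_runs(self):
        pos = np.concatenate([np.arange(1, 16) * 50, 5000 + np.arange(15) * 50])
        m = make_methylome(pos, np.zeros((30, 1), int), np.full((30, 1), 20),
                           sample_names=["S1"], conditions=["normal"])
        umrs = em.call_umrs(m, ["S1"], max_gap_bp=1000)
        assert len(umrs) == 2


class TestCallDMRs:
    def _paired(self, beta_t, beta_n, n_pairs=10, cov=20, pos=None):
        n_sites = len(beta_t)
        if pos is None:
            pos = (np.arange(n_sites) + 1) * 50
        bt = np.tile(np.asarray(beta_t)[:, None], (1, n_pairs))
        bn = np.tile(np.asarray(beta_n)[:, None], (1, n_pairs))
        beta = np.hstack([bt, bn])
        total = np.full(beta.shape, cov)
        meth = np.round(beta * cov).astype(int)
        names = [f"T{i}" for i in range(n_pairs)] + [f"N{i}" for i in range(n_pairs)]
        conds = ["tumor"] * n_pairs + ["normal"] * n_pairs
        return make_methylome(pos, meth, total, names, conds)

    def test_maximal_separation_yields_one_hyper_dmr(self):
        m = self._paired([0.9] * 15, [0.1] * 15)
        dmrs = em.call_dmrs(m)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert d.n_cpgs == 15
        assert d.mean_diff == pytest.approx(0.8, abs=0.02)
        assert d.q_value < 0.05

    def test_small_difference_below_threshold_never_called(self):
        m = self._paired([0.55] * 15, [0.50] * 15)
        assert em.call_dmrs(m) == []

    def test_identical_distributions_yield_no_dmrs(self):
        rng = np.random.default_rng(7)
        n_sites, n_pairs, cov = 200, 10, 20
        total = np.full((n_sites, 2 * n_pairs), cov)
        meth = rng.binomial(cov, 0.5, size=total.shape)
        names = [f"T{i}" for i in range(n_pairs)] + [f"N{i}" for i in range(n_pairs)]
        conds = ["tumor"] * n_pairs + ["normal"] * n_pairs
        m = make_methylome((np.arange(n_sites) + 1) * 50, meth, total, names, conds)
        assert em.call_dmrs(m) == []

    def test_missing_pairing_errors(self):
        m = self._paired([0.9] * 15, [0.1] * 15)
        with pytest.raises(ValidationError):
            em.call_dmrs(m, pairing=[])

    def test_monotone_in_planted_difference(self):
        """A larger planted tumor-normal difference never yields fewer DMRs."""
        detected = []
        for delta in (0.0, 0.15, 0.3, 0.6):
            rng = np.random.default_rng(11)
            n_pairs, cov = 8, 20
            beta = np.full((60, 2 * n_pairs), 0.2)
            beta[20:40, :n_pairs] += delta
            total = np.full(beta.shape, cov)
            meth = rng.binomial(cov, beta)
            names = [f"T{i}" for i in range(n_pairs)] + [f"N{i}" for i in range(n_pairs)]
            conds = ["tumor"] * n_pairs + ["normal"] * n_pairs
            m = make_methylome((np.arange(60) + 1) * 50, meth, total, names, conds)
            detected.append(len(em.call_dmrs(m)))
        assert detected == sorted(detected)


class TestSummarize:
    def test_reported_fraction_at_study_counts(self):
        s = em.DMRSummary(n_hyper=8670, n_hypo=250696)
        assert s.hypo_fraction_pct == pytest.approx(96.6, abs=0.1)
        assert s.fold_ratio == pytest.approx(250696 / 8670)

    def test_even_split(self):
        assert em.DMRSummary(5, 5).hypo_fraction_pct == pytest.approx(50.0)

    def test_empty_input_flagged_undefined(self):
        s = em.summarize_dmrs([])
        assert not s.defined
        assert np.isnan(s.hypo_fraction_pct)

    def test_counts_conserved(self):
        iv = GenomicInterval("chr1", 0, 100)
        dmrs = [em.DMRRecord(iv, 10, d, 1e-4, 1e-3) for d in (0.3, -0.2, 0.5, -0.4)]
        s = em.summarize_dmrs(dmrs)
        assert s.n_hyper + s.n_hypo == len(dmrs)
        assert s.n_hyper == 2


class TestAnnotateContext:
    GENES = [
        GeneModel("A", GenomicInterval("chr1", 10000, 20000, "+")),
        GeneModel("B", GenomicInterval("chr1", 50000, 60000, "-")),
    ]

    def test_promoter_wins(self):
        region = GenomicInterval("chr1", 9000, 9500)  # inside A's −1500/+500 window
        (_, label, gid), = em.annotate_context([region], self.GENES)
        assert (label, gid) == (em.PROMOTER, "A")

    def test_gene_body_when_outside_promoter(self):
        region = GenomicInterval("chr1", 15000, 15500)
        (_, label, gid), = em.annotate_context([region], self.GENES)
        assert (label, gid) == (em.GENE_BODY, "A")

    def test_minus_strand_promoter_is_upstream_of_end(self):
        region = GenomicInterval("chr1", 60500, 60600)  # upstream of B's TSS at 59999
        (_, label, gid), = em.annotate_context([region], self.GENES)
        assert (label, gid) == (em.PROMOTER, "B")

    def test_far_region_is_intergenic(self):
        region = GenomicInterval("chr1", 150000, 150100)
        (_, label, gid), = em.annotate_context([region], self.GENES)
        assert (label, gid) == (em.INTERGENIC, None)

    def test_every_region_gets_exactly_one_label(self):
        rng = np.random.default_rng(3)
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 100000, size=50)
        ]
        out = em.annotate_context(regions, self.GENES)
        assert len(out) == 50
        assert all(lbl in (em.PROMOTER, em.GENE_BODY, em.INTERGENIC) for _, lbl, _ in out)


class TestGeneBodyProfile:
    def test_constant_field_gives_flat_profile(self):
        pos = np.arange(1, 101) * 50
        m = make_methylome(pos, np.full((100, 1), 10), np.full((100, 1), 20),
                           sample_names=["S1"], conditions=["normal"])
        genes = [GeneModel("A", GenomicInterval("chr1", 0, 5000, "+"))]
        prof = em.gene_body_profile(m, genes, n_bins=10)
        assert np.allclose(prof, 0.5)

    def test_minus_strand_profile_is_reversed(self):
        pos = np.arange(1, 101) * 50
        beta = np.linspace(0, 1, 100)
        cov = 100
        m = make_methylome(pos, np.round(beta * cov).astype(int)[:, None],
                           np.full((100, 1), cov), ["S1"], ["normal"])
        fwd = em.gene_body_profile(
            m, [GeneModel("A", GenomicInterval("chr1", 0, 5000, "+"))], n_bins=10
        )
        rev = em.gene_body_profile(
            m, [GeneModel("A", GenomicInterval("chr1", 0, 5000, "-"))], n_bins=10
        )
        assert np.allclose(fwd, rev[::-1])

    def test_single_cpg_populates_one_bin(self):
        m = make_methylome([501], [[6]], [[10]], ["S1"], ["normal"])
        prof = em.gene_body_profile(
            m, [GeneModel("A", GenomicInterval("chr1", 0, 5000, "+"))], n_bins=10
        )
        assert prof[1] == pytest.approx(0.6)  # CpG at 10% of the body
        assert np.isnan(np.delete(prof, 1)).all()

    def test_invalid_bins(self):
        m = make_methylome([501], [[6]], [[10]], ["S1"], ["normal"])
        with pytest.raises(ValidationError):
            em.gene_body_profile(m, [], n_bins=0)


@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=100))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_bh_matches_brute_force_step_up(pvals):
    """The BH adjustment agrees with a literal step-up implementation."""
    p = np.array(pvals)
    n = len(p)
    order = np.argsort(p)
    brute = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = n - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * n / i)
        brute[idx] = running
    assert np.allclose(bh_adjust(p), brute, atol=1e-12)
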