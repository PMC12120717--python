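import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from epidriver import survival as esurv
from epidriver.errors import ValidationError
from epidriver.io import SurvivalTable


def surv_table(times, events, samples=None):
    samples = samples or [f"S{i + 1}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame({"time": times, "event": events},
                     index=pd.Index(samples, name="sample"))
    )


class TestPlage:
    def test_singleton_set_is_zscored_gene(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, size=(3, 8)),
                              index=["A", "B", "C"],
                              columns=[f"S{i}" for i in range(8)])
        act = esurv.plage_score(counts, ["A"])
        x = np.log2(counts.loc["A"].to_numpy(float) + 1)
        z = (x - x.mean()) / x.std(ddof=1)
        # activity is the unit-normalised z-score with non-negative correlation
        assert np.allclose(act, z / np.linalg.norm(z), atol=1e-10)

    def test_duplicated_gene_row_matches_singleton(self):
        rng = np.random.default_rng(1)
        row = rng.poisson(80, size=10)
        counts = pd.DataFrame([row, row, rng.poisson(80, size=10)],
                              index=["A", "A2", "B"],
                              columns=[f"S{i}" for i in range(10)])
        single = esurv.plage_score(counts, ["A"])
        double = esurv.plage_score(counts, ["A", "A2"])
        assert np.allclose(single, double, atol=1e-10)

    def test_matches_independent_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(200, size=(5, 12)).astype(float),
                              index=[f"G{i}" for i in range(5)],
                              columns=[f"S{i}" for i in range(12)])
        act = esurv.plage_score(counts, list(counts.index))
        X = np.log2(counts.to_numpy() + 1)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        # oracle: leading eigenvector of Z^T Z (independent of the SVD route)
        vals, vecs = np.linalg.eigh(Z.T @ Z)
        lead = vecs[:, -1]
        assert min(np.abs(act.to_numpy() - lead).max(),
                   np.abs(act.to_numpy() + lead).max()) < 1e-10

    def test_sign_convention_tracks_mean_expression(self):
        rng = np.random.default_rng(3)
        high = rng.poisson(400, size=(4, 6))
        low = rng.poisson(50, size=(4, 6))
        counts = pd.DataFrame(np.hstack([high, low]),
                              index=[f"G{i}" for i in range(4)],
                              columns=[f"S{i}" for i in range(12)])
        act = esurv.plage_score(counts, list(counts.index))
        assert act.iloc[:6].mean() > act.iloc[6:].mean()

    def test_invariant_to_per_gene_rescaling(self):
        rng = np.random.default_rng(4)
        X = rng.normal(10, 2, size=(4, 9))
        counts = pd.DataFrame(X, index=list("ABCD"),
                              columns=[f"S{i}" for i in range(9)])
        scaled = counts * np.array([2.0, 5.0, 0.5, 10.0])[:, None] + \
            np.array([1.0, -3.0, 0.0, 7.0])[:, None]
        a1 = esurv.plage_score(counts, list("ABCD"), log_transform=False)
        a2 = esurv.plage_score(scaled, list("ABCD"), log_transform=False)
        assert np.allclose(a1, a2, atol=1e-10)

    def test_zero_variance_gene_named_in_error(self):
        counts = pd.DataFrame([[5, 5, 5], [1, 2, 3]], index=["FLAT", "OK"],
                              columns=["S1", "S2", "S3"])
        with pytest.raises(ValidationError, match="FLAT"):
            esurv.plage_score(counts, ["FLAT", "OK"])

    def test_empty_set_errors(self):
        counts = pd.DataFrame([[1, 2]], index=["A"], columns=["S1", "S2"])
        with pytest.raises(ValidationError):
            esurv.plage_score(counts, [])


class TestOptimalCutoff:
    def test_perfect_separation_cut_between_clusters(self):
        scores = pd.Series([1, 1, 1, 1, 1, 10, 10, 10, 10, 10.0],
                           index=[f"S{i + 1}" for i in range(10)])
        t = surv_table([2, 3, 4, 2.5, 3.5, 50, 60, 55, 52, 58],
                       [1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        c = esurv.optimal_cutoff(scores, t, min_prop=0.1)
        assert 1 < c < 10

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(5)
        n = 20
        scores = pd.Series(rng.normal(size=n), index=[f"S{i + 1}" for i in range(n)])
        t = surv_table(rng.exponential(20, size=n) + 0.1,
                       rng.integers(0, 2, size=n))
        got = esurv.optimal_cutoff(scores, t, min_prop=0.1)
        # oracle: brute-force |standardized log-rank| over every midpoint
        s = scores.to_numpy()
        uniq = np.unique(s)
        best = None
        for c in (uniq[:-1] + uniq[1:]) / 2:
            high = s > c
            if min(high.sum(), n - high.sum()) < 0.1 * n:
                continue
            oe, var = esurv._logrank_oev(t.time, t.event, high)
            z = abs(oe) / np.sqrt(var) if var > 0 else 0.0
            if best is None or z > best[0] + 1e-12:
                best = (z, c)
        assert got == pytest.approx(best[1])

    def test_constant_scores_error(self):
        scores = pd.Series(np.ones(12), index=[f"S{i + 1}" for i in range(12)])
        t = surv_table(np.arange(1, 13.0), [1] * 12)
        with pytest.raises(ValidationError):
            esurv.optimal_cutoff(scores, t)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5.0]
        events = [1, 1, 0, 1, 0] * 2
        t = surv_table(times, events)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=t.data.index)
        chi2, p = esurv.logrank_test(t, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_table(self):
        # group A: events at t=1,2; group B: events at t=3,4 — no censoring
        t = surv_table([1, 2, 3, 4.0], [1, 1, 1, 1])
        groups = pd.Series(["A", "A", "B", "B"], index=t.data.index)
        # hand table (A as the index group):
        # t=1: n=4, nA=2, d=1, dA=1 → E=0.5,   V=0.25
        # t=2: n=3, nA=1, d=1, dA=1 → E=1/3,   V=2/9
        # t=3: n=2, nA=0, d=1, dA=0 → E=0,     V=0
        # t=4: n=1, nA=0, d=1, dA=0 → E=0,     V=0
        oe = (1 - 0.5) + (1 - 1 / 3)
        var = 0.25 + 2 / 9
        chi2, _ = esurv.logrank_test(t, groups)
        assert chi2 == pytest.approx(oe**2 / var, abs=1e-12)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(6)
        t = surv_table(rng.exponential(10, size=30) + 0.1, rng.integers(0, 2, 30))
        g = pd.Series(rng.choice(["x", "y"], size=30), index=t.data.index)
        if g.nunique() < 2:
            g.iloc[0] = "x" if g.iloc[1] == "y" else "y"
        chi2a, _ = esurv.logrank_test(t, g)
        swap = g.map({"x": "y", "y": "x"})
        chi2b, _ = esurv.logrank_test(t, swap)
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(7)
        n = 60
        t = surv_table(rng.exponential(12, size=n) + 0.1, rng.integers(0, 2, n))
        g = pd.Series(["a"] * 30 + ["b"] * 30, index=t.data.index)
        chi2, p = esurv.logrank_test(t, g)
        ref = ll_logrank(
            t.time[:30], t.time[30:], t.event[:30], t.event[30:]
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_errors(self):
        t = surv_table([1, 2, 3.0], [1, 1, 1])
        g = pd.Series(["a", "a", "a"], index=t.data.index)
        with pytest.raises(ValidationError):
            esurv.logrank_test(t, g)


class TestKaplanMeier:
    def test_three_events_no_censoring_closed_form(self):
        km = esurv.km_estimate(surv_table([1, 2, 3.0], [1, 1, 1]))
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_stays_at_one(self):
        km = esurv.km_estimate(surv_table([5, 8, 12.0], [0, 0, 0]))
        assert km.times.size == 0  # no event times; S stays 1 throughout

    def test_tied_events(self):
        km = esurv.km_estimate(surv_table([1, 1, 5, 9.0], [1, 1, 0, 0]))
        assert km.survival[0] == pytest.approx(0.5)
        assert km.at_risk[0] == 4 and km.events[0] == 2

    def test_censored_at_event_time_counted_at_risk(self):
        km = esurv.km_estimate(surv_table([1, 1, 2.0], [1, 0, 1]))
        assert km.survival[0] == pytest.approx(2 / 3)  # 3 at risk at t=1

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(5, size=40) + 0.01
        km = esurv.km_estimate(surv_table(times, np.ones(40, int)))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, size=50) + 0.1
        events = rng.integers(0, 2, size=50)
        km = esurv.km_estimate(surv_table(times, events))
        kmf = KaplanMeierFitter().fit(times, events)
        ref = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.allclose(km.survival, ref, atol=1e-10)


def test_high_activity_group_has_worse_survival(small_bundle):
    """On the synthetic cohort the PLAGE-high group carries the planted
    higher hazard."""
    b = small_bundle
    counts = b.expression.counts[list(b.survival.data.index)]
    res = esurv.stratify_by_activity(counts, b.truth.axis_genes, b.survival)
    # planted truth: activity raises hazard; recovered high group should
    # have higher mean true activity
    truth = b.truth.activity
    assert truth[res.groups == "high"].mean() > truth[res.groups == "low"].mean()
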