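"""Uniting, filtering, the per-CpG logistic LRT, FDR, and Ward clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import rrbspipe as rp
from conftest import make_genome
from rrbspipe.bscall import CytosineCall, CytosineCallSet
from rrbspipe.diffmeth import LOGIT_BOUND, MethylMatrix, _ward


def callset(sample: str, entries: dict) -> CytosineCallSet:
    cs = CytosineCallSet(sample=sample)
    for (contig, pos, strand), (ctx, m, u) in entries.items():
        cs.calls[(contig, pos, strand)] = CytosineCall(contig, pos, strand, ctx, m, u)
    return cs


class TestUnite:
    def test_low_coverage_site_dropped(self):
        a = callset("a", {("c", 1, "+"): ("CpG", 5, 4)})  # 9x
        b = callset("b", {("c", 1, "+"): ("CpG", 10, 5)})
        with pytest.warns(UserWarning):
            m = rp.unite({"a": a, "b": b}, {"a": "G1", "b": "G2"})
        assert m.n_sites == 0

    def test_boundary_coverage_kept(self):
        a = callset("a", {("c", 1, "+"): ("CpG", 5, 5)})
        b = callset("b", {("c", 1, "+"): ("CpG", 4, 6)})
        m = rp.unite({"a": a, "b": b}, {"a": "G1", "b": "G2"})
        assert m.n_sites == 1 and (m.cov == 10).all()

    def test_non_cpg_context_excluded(self):
        a = callset("a", {("c", 1, "+"): ("CHH", 50, 50)})
        b = callset("b", {("c", 1, "+"): ("CHH", 50, 50)})
        with pytest.warns(UserWarning):
            m = rp.unite({"a": a, "b": b}, {"a": "G1", "b": "G2"})
        assert m.n_sites == 0

    def test_disjoint_sites_empty_with_warning(self):
        a = callset("a", {("c", 1, "+"): ("CpG", 10, 10)})
        b = callset("b", {("c", 9, "+"): ("CpG", 10, 10)})
        c = callset("c", {("c", 20, "+"): ("CpG", 10, 10)})
        with pytest.warns(UserWarning):
            m = rp.unite({"a": a, "b": b, "c": c}, {"a": "G1", "b": "G2", "c": "G2"})
        assert m.n_sites == 0

    def test_fewer_than_two_samples_rejected(self):
        a = callset("a", {("c", 1, "+"): ("CpG", 10, 10)})
        with pytest.raises(ValueError):
            rp.unite({"a": a}, {"a": "G1"})


class TestDropInvariant:
    def _matrix(self, meth, cov):
        meth = np.asarray(meth)
        sites = [("c", i, "+") for i in range(meth.shape[0])]
        return MethylMatrix(sites=sites, meth=meth, cov=np.asarray(cov),
                            samples=["s1", "s2"], groups={"s1": "A", "s2": "B"})

    def test_all_zero_and_all_full_dropped(self):
        m = self._matrix([[0, 0], [10, 20]], [[10, 20], [10, 20]])
        assert rp.drop_invariant(m).n_sites == 0

    def test_constant_fifty_percent_dropped(self):
        m = self._matrix([[5, 10]], [[10, 20]])
        assert rp.drop_invariant(m).n_sites == 0

    def test_varying_site_kept(self):
        m = self._matrix([[4, 12]], [[10, 20]])
        assert rp.drop_invariant(m).n_sites == 1


class TestPileupScreen:
    def _run(self, n_alt, n_ref, contig_seq="ACGTACGTACGTACGTACGTACGTACGTAAAC"):
        g = make_genome(contig_seq)
        reads, placements = [], []
        pos = 5
        ref, alt = contig_seq[pos], "A" if contig_seq[pos] != "A" else "G"
        for i in range(n_alt + n_ref):
            s = list(contig_seq)
            if i < n_alt:
                s[pos] = alt
            r = rp.Read(read_id=f"r{i}", sequence="".join(s), quality="I" * len(s))
            reads.append(r)
            placements.append(rp.Placement(f"r{i}", "contig_1", 0, "OT", 0, read_index=i))
        screen = rp.call_variants_pileup(placements, rp.ReadSet(reads), g)
        return ("contig_1", pos) in screen

    def test_six_of_ten_flagged(self):
        assert self._run(6, 4)

    def test_no_alt_not_flagged(self):
        assert not self._run(0, 10)

    def test_one_of_hundred_not_flagged(self):
        assert not self._run(1, 99)


class TestExcludeSnpSites:
    def _matrix(self, n_sites):
        sites = [("c", 2 * i, "+") for i in range(n_sites)]
        meth = np.full((n_sites, 2), 5)
        cov = np.full((n_sites, 2), 10)
        return MethylMatrix(sites=sites, meth=meth, cov=cov,
                            samples=["s1", "s2"], groups={"s1": "A", "s2": "B"})

    def test_flagged_sites_removed_with_count(self):
        m = self._matrix(100)
        screen = rp.VariantScreen(positions={("c", 2 * i) for i in range(7)})
        out, n = rp.exclude_snp_sites(m, screen)
        assert (out.n_sites, n) == (93, 7)

    def test_cpg_partner_position_also_excluded(self):
        m = self._matrix(3)  # sites at 0, 2, 4 on '+', partners at 1, 3, 5
        screen = rp.VariantScreen(positions={("c", 3)})
        out, n = rp.exclude_snp_sites(m, screen)
        assert n == 1 and ("c", 2, "+") not in out.sites

    def test_empty_screen_no_change(self):
        m = self._matrix(5)
        out, n = rp.exclude_snp_sites(m, rp.VariantScreen())
        assert n == 0 and out.n_sites == 5

    def test_all_flagged_empty(self):
        m = self._matrix(4)
        screen = rp.VariantScreen(positions={("c", 2 * i) for i in range(4)})
        out, n = rp.exclude_snp_sites(m, screen)
        assert out.n_sites == 0 and n == 4


# ---------------------------------------------------------------------------
# Logistic LRT
# ---------------------------------------------------------------------------


def profile_likelihood_p(counts1, counts2) -> float:
    """Independent numeric oracle: maximize the binomial-logistic likelihood
    by nested 1-D bounded optimization over (b0, b1), LRT against b1=0."""

    def nll(b0, b1):
        total = 0.0
        for grp, counts in ((0, counts1), (1, counts2)):
            eta = np.clip(b0 + b1 * grp, -LOGIT_BOUND, LOGIT_BOUND)
            p = 1 / (1 + np.exp(-eta))
            for m, u in counts:
                total -= m * np.log(p) + u * np.log1p(-p)
        return total

    def profile(b1):
        res = optimize.minimize_scalar(
            lambda b0: nll(b0, b1), bounds=(-LOGIT_BOUND, LOGIT_BOUND),
            method="bounded", options={"xatol": 1e-10},
        )
        return res.fun

    res_alt = optimize.minimize_scalar(
        profile, bounds=(-2 * LOGIT_BOUND, 2 * LOGIT_BOUND),
        method="bounded", options={"xatol": 1e-10},
    )
    lrt = 2.0 * (profile(0.0) - res_alt.fun)
    return float(stats.chi2.sf(max(lrt, 0.0), df=1))


class TestTestSite:
    def test_identical_groups_null(self):
        p, d = rp.test_site([(5, 5), (5, 5)], [(5, 5), (5, 5)])
        assert p == pytest.approx(1.0) and d == 0.0

    def test_complete_separation(self):
        p, d = rp.test_site([(10, 0), (10, 0)], [(0, 10), (0, 10)])
        assert d == pytest.approx(-100.0)
        assert p < 1e-6

    def test_pooled_proportions_diff(self):
        p, d = rp.test_site([(10, 5), (5, 0)], [(3, 10), (2, 5)])
        assert d == pytest.approx(100 * (5 / 20 - 15 / 20))
        oracle = profile_likelihood_p([(10, 5), (5, 0)], [(3, 10), (2, 5)])
        assert p == pytest.approx(oracle, abs=1e-4)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            rp.test_site([(0, 0)], [(5, 5)])

    def test_agrees_with_profile_likelihood_oracle(self, rng):
        # 50 random small tables, no complete separation
        for _ in range(50):
            n1, n2 = rng.integers(1, 4, size=2)
            c1 = [(int(rng.integers(1, 20)), int(rng.integers(1, 20))) for _ in range(n1)]
            c2 = [(int(rng.integers(1, 20)), int(rng.integers(1, 20))) for _ in range(n2)]
            p, _ = rp.test_site(c1, c2)
            assert p == pytest.approx(profile_likelihood_p(c1, c2), abs=1e-4)

    def test_agrees_with_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            c1 = [(int(rng.integers(1, 30)), int(rng.integers(1, 30))) for _ in range(3)]
            c2 = [(int(rng.integers(1, 30)), int(rng.integers(1, 30))) for _ in range(3)]
            endog = np.array(c1 + c2, dtype=float)
            exog = sm.add_constant(np.array([0] * 3 + [1] * 3, dtype=float))
            full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, exog[:, :1], family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - null.llf)
            p_sm = stats.chi2.sf(max(lrt, 0), 1)
            p, _ = rp.test_site(c1, c2)
            assert p == pytest.approx(p_sm, abs=1e-6)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition computed without vectorized shortcuts."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return np.array(q)


class TestAdjustFdr:
    def test_hand_computed_example(self):
        q = rp.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert rp.adjust_fdr([0.3]) == pytest.approx([0.3])
        assert rp.adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rp.adjust_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, ps):
        p = np.array(ps)
        assert rp.adjust_fdr(p) == pytest.approx(brute_force_bh(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert rp.adjust_fdr(p) == pytest.approx(q_sm)


class TestSignificantSites:
    def _rec(self, q, d, hyper="B"):
        return rp.DiffMethRecord(site=("c", 1, "+"), p_value=q / 2, q_value=q,
                                 meth_diff=d, hyper_group=hyper, significant=False)

    def test_thresholds_are_strict(self):
        kept, _ = rp.significant_sites([self._rec(0.05, 40), self._rec(0.01, 25.0)])
        assert kept == []

    def test_passing_record_kept_with_tally(self):
        kept, tally = rp.significant_sites(
            [self._rec(0.01, 40, "B"), self._rec(0.001, -30, "A"), self._rec(0.2, 50, "B")]
        )
        assert len(kept) == 2 and tally == {"B": 1, "A": 1}


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


class TestClusterSamples:
    def _matrix(self, pct_by_sample: dict, groups=None):
        samples = list(pct_by_sample)
        pct = np.array([pct_by_sample[s] for s in samples], dtype=float).T
        cov = np.full(pct.shape, 100, dtype=int)
        meth = np.round(pct / 100 * cov).astype(int)
        return MethylMatrix(
            sites=[("c", i, "+") for i in range(pct.shape[0])],
            meth=meth, cov=cov, samples=samples,
            groups=groups or {s: s for s in samples},
        )

    def test_identical_samples_merge_first_at_zero(self):
        m = self._matrix({"a": [10, 50, 90], "b": [10, 50, 90], "c": [90, 50, 10]})
        dend = rp.cluster_samples(m)
        first = dend.merges[0]
        assert {first[0], first[1]} == {0, 1} and first[2] == pytest.approx(0.0, abs=1e-7)

    def test_constant_sample_raises_with_name(self):
        m = self._matrix({"a": [10, 50, 90], "b": [20, 20, 20], "c": [90, 50, 10]})
        with pytest.raises(ValueError, match="b"):
            rp.cluster_samples(m)

    def test_merge_order_matches_scipy_ward(self, rng):
        # independent cross-check on random distinct distance matrices
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        for n in (3, 4, 5):
            profiles = {f"s{i}": rng.uniform(0, 100, size=12) for i in range(n)}
            m = self._matrix(profiles)
            pct = m.percent()
            d = 1 - np.corrcoef(pct.T)
            np.fill_diagonal(d, 0)
            Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
            dend = rp.cluster_samples(m)
            ours = [(sorted((a if a < n else a, b if b < n else b))[0:2], h)
                    for a, b, h in dend.merges]
            for (a, b, h), row in zip(dend.merges, Z):
                assert {a, b} == {int(row[0]), int(row[1])}
                assert h == pytest.approx(row[2], rel=1e-8)

    def test_hand_computed_three_sample_toy(self):
        # 3 sites, 3 samples; Ward on 1-corr reduces to: first merge the
        # closest pair, then the root ties the remaining sample in
        m = self._matrix({"a": [0, 50, 100], "b": [0, 60, 100], "c": [100, 50, 0]})
        dend = rp.cluster_samples(m)
        assert {dend.merges[0][0], dend.merges[0][1]} == {0, 1}
        cut = dend.cut(2)
        assert cut["a"] == cut["b"] != cut["c"]

    def test_two_group_simulation_recovers_labels(self, small_genome):
        m = rp.simulate_methylome(small_genome, ["A", "B"], diff_fraction=0.2,
                                  delta=40, seed=21)
        samples = {f"A_{i}": "A" for i in range(5)} | {f"B_{i}": "B" for i in range(5)}
        mat = rp.simulate_count_matrix(m, small_genome, samples, coverage=30, seed=22)
        mat = rp.drop_invariant(mat)
        dend = rp.cluster_samples(mat)
        cut = dend.cut(2)
        a_clusters = {cut[s] for s in samples if s.startswith("A")}
        b_clusters = {cut[s] for s in samples if s.startswith("B")}
        assert len(a_clusters) == 1 and len(b_clusters) == 1 and a_clusters != b_clusters

    def test_newick_contains_all_samples(self):
        m = self._matrix({"a": [0, 50, 100], "b": [0, 60, 100], "c": [100, 50, 0]})
        nwk = rp.cluster_samples(m).to_newick()
        assert nwk.endswith(";") and all(s in nwk for s in ("a", "b", "c"))

    def test_too_few_samples_rejected(self):
        m = self._matrix({"a": [0, 50], "b": [10, 60]})
        with pytest.raises(ValueError):
            rp.cluster_samples(m)
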