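import math

import numpy as np
import pytest

from hybridzone import (
    GenotypeTable,
    allele_freqs,
    hwe_test,
    ld_test,
    permutation_p,
    phi_st,
    private_alleles,
    reynolds_fst,
    sample_parental,
    slatkin_rst,
)
from hybridzone.data import MISSING


def _table(rows, pops, loci=None):
    rows = np.asarray(rows, dtype=np.int32)
    n, L = rows.shape[0], rows.shape[1] // 2
    return GenotypeTable(
        ids=[f"i{k}" for k in range(n)],
        loci=loci or [f"L{j}" for j in range(L)],
        alleles=rows.reshape(n, L, 2),
        population=np.asarray(pops, dtype=object),
    )


# ----------------------------------------------------------------------
# brute-force AMOVA oracle: explicit pairwise distances between gene copies
# ----------------------------------------------------------------------

def _amova_brute(copy_lists, d2):
    """Two-level AMOVA Φ from explicit pairwise squared distances."""
    sizes = np.array([len(c) for c in copy_lists], dtype=float)
    pooled = [x for c in copy_lists for x in c]
    n, s = int(sizes.sum()), len(copy_lists)

    def ssd(copies):
        total = 0.0
        for x in copies:
            for y in copies:
                total += d2(x, y)
        return total / (2 * len(copies))

    ssd_t = ssd(pooled)
    ssd_w = sum(ssd(c) for c in copy_lists)
    sigma_w = ssd_w / (n - s)
    ms_a = (ssd_t - ssd_w) / (s - 1)
    n_prime = (n - (sizes**2).sum() / n) / (s - 1)
    sigma_a = (ms_a - sigma_w) / n_prime
    return sigma_a, sigma_w


def _multilocus_brute(gt, pop_a, pop_b, d2):
    num = den = 0.0
    for l in range(gt.n_loci):
        lists = []
        for p in (pop_a, pop_b):
            idx = np.flatnonzero(gt.population == p)
            copies = gt.alleles[idx, l, :].ravel()
            lists.append(list(copies[copies != MISSING]))
        sa, sw = _amova_brute(lists, d2)
        num += sa
        den += sa + sw
    return num / den


class TestAlleleFreqs:
    def test_simple_counts(self):
        gt = _table([[100, 100], [100, 102]], ["A", "A"])
        assert allele_freqs(gt, "A")[0] == {100: 0.75, 102: 0.25}

    def test_all_missing_locus_flagged(self):
        gt = _table([[MISSING, MISSING]], ["A"])
        with pytest.warns(UserWarning, match="missing"):
            assert allele_freqs(gt, "A")[0] == {}

    def test_matches_generator_truth(self, diverged_models):
        gt = sample_parental(diverged_models, "B", 1000, seed=5)
        freqs = allele_freqs(gt, "B")
        for f, m in zip(freqs, diverged_models):
            for allele, truth in zip(m.alleles, m.freqs_b):
                assert abs(f.get(allele, 0.0) - truth) < 0.03


class TestPrivateAlleles:
    def test_symmetric_toy(self):
        fa, fb = [{1: 0.5, 2: 0.5}], [{2: 0.5, 3: 0.5}]
        assert private_alleles(fa, fb, 0.0) == (1, 1)

    def test_low_frequency_cutoff(self):
        fa, fb = [{1: 0.04, 2: 0.96}], [{2: 1.0}]
        assert private_alleles(fa, fb, 0.05) == (0, 0)

    def test_matches_exhaustive_scan(self, rng):
        fa, fb = [], []
        for _ in range(10):
            alleles = rng.choice(20, size=6, replace=False)
            va = rng.dirichlet(np.ones(6))
            vb = rng.dirichlet(np.ones(6))
            va[rng.random(6) < 0.4] = 0.0
            vb[rng.random(6) < 0.4] = 0.0
            fa.append({int(a): v / va.sum() for a, v in zip(alleles, va) if va.sum()})
            fb.append({int(a): v / vb.sum() for a, v in zip(alleles, vb) if vb.sum()})
        cutoff = 0.05
        exp_a = exp_b = 0
        for da, db in zip(fa, fb):
            for a, v in da.items():
                if v >= cutoff and v > 0 and db.get(a, 0) == 0:
                    exp_a += 1
            for a, v in db.items():
                if v >= cutoff and v > 0 and da.get(a, 0) == 0:
                    exp_b += 1
        assert private_alleles(fa, fb, cutoff) == (exp_a, exp_b)


class TestHWE:
    def test_monomorphic(self):
        res = hwe_test(np.full((10, 2), 100))
        assert res.p == 1.0 and res.method == "exact"

    def test_extreme_homozygote_excess_matches_enumeration(self):
        # 5 AA + 5 aa individuals: 10 A genes, 10 a genes
        genos = np.array([[1, 1]] * 5 + [[2, 2]] * 5)
        res = hwe_test(genos)
        # independent oracle: enumerate over the number of heterozygotes
        def prob(h):
            naa, nbb = (10 - h) // 2, (10 - h) // 2
            return (
                math.factorial(10) * math.factorial(10) * math.factorial(10)
                * 2**h
                / (math.factorial(20) * math.factorial(naa)
                   * math.factorial(nbb) * math.factorial(h))
            )
        probs = {h: prob(h) for h in range(0, 11, 2)}
        expected = sum(p for p in probs.values() if p <= probs[0] * (1 + 1e-9))
        assert res.method == "exact"
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            g = rng.choice([1, 2], size=(50, 2), p=[0.6, 0.4])
            if np.unique(g).size == 1:
                continue
            if hwe_test(g).p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        bound = 2.58 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rate < 0.05 + bound  # exact test is valid (possibly conservative)

    def test_monte_carlo_fallback_close_to_exact(self):
        rng = np.random.default_rng(7)
        g = rng.choice([1, 2, 3], size=(40, 2))
        exact = hwe_test(g, max_tables=10**6)
        mc = hwe_test(g, max_tables=1, reps=20000, seed=9)
        assert exact.method == "exact" and mc.method == "monte-carlo"
        assert mc.p == pytest.approx(exact.p, abs=0.02)


class TestLD:
    def test_constant_locus_gives_p_one(self):
        gt = _table([[100, 102, 50, 50]] * 6, ["A"] * 6)
        res = ld_test(gt, 0, 1, reps=100)
        assert res.p == 1.0

    def test_duplicated_locus_strong_association(self, rng):
        col = rng.choice([100, 102, 104], size=(30, 2))
        rows = np.concatenate([col, col], axis=1)
        gt = _table(rows, ["A"] * 30)
        res = ld_test(gt, 0, 1, reps=10000, seed=1)
        assert res.p < 0.01

    def test_independent_loci_uniform_p(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        ps = []
        for s in range(60):
            rows = rng.choice([100, 102], size=(40, 4))
            gt = _table(rows, ["A"] * 40)
            ps.append(ld_test(gt, 0, 1, reps=200, seed=s).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDifferentiation:
    def test_identical_pops_near_zero(self, diverged_models):
        a = sample_parental(diverged_models, "A", 50, seed=1)
        b = sample_parental(diverged_models, "A", 50, seed=1)
        b = GenotypeTable(
            ids=[f"b{i}" for i in range(50)], loci=b.loci, alleles=b.alleles,
            population=np.full(50, "B", dtype=object),
        )
        gt = GenotypeTable.concat([a, b])
        assert abs(reynolds_fst(gt, "A", "B")) < 0.02
        assert abs(slatkin_rst(gt, "A", "B")) < 0.02

    def test_fixed_difference_limits(self, fixed_models):
        a = sample_parental(fixed_models, "A", 50, seed=1)
        b = sample_parental(fixed_models, "B", 50, seed=2)
        gt = GenotypeTable.concat([a, b])
        assert reynolds_fst(gt, "A", "B") >= 0.95
        assert slatkin_rst(gt, "A", "B") >= 0.95

    def test_fst_matches_brute_force_amova(self, rng):
        rows = rng.choice([100, 102, 104], size=(10, 6))
        gt = _table(rows, ["A"] * 5 + ["B"] * 5)
        ours = reynolds_fst(gt, "A", "B")
        brute = _multilocus_brute(gt, "A", "B", lambda x, y: float(x != y))
        assert ours == pytest.approx(brute, abs=1e-10)

    def test_rst_matches_brute_force_amova(self, rng):
        rows = rng.choice([100, 104, 110], size=(10, 6))
        gt = _table(rows, ["A"] * 5 + ["B"] * 5)
        ours = slatkin_rst(gt, "A", "B")
        brute = _multilocus_brute(
            gt, "A", "B", lambda x, y: float(x - y) ** 2
        )
        assert ours == pytest.approx(brute, abs=1e-10)

    def test_label_swap_invariance(self, rng):
        rows = rng.choice([100, 102, 104, 106], size=(12, 8))
        gt = _table(rows, ["A"] * 6 + ["B"] * 6)
        assert reynolds_fst(gt, "A", "B") == pytest.approx(
            reynolds_fst(gt, "B", "A"), abs=1e-12
        )

    def test_all_missing_individual_changes_nothing(self, rng):
        rows = rng.choice([100, 102], size=(10, 6))
        gt = _table(rows, ["A"] * 5 + ["B"] * 5)
        base = reynolds_fst(gt, "A", "B")
        extra = np.full((1, 3, 2), MISSING, dtype=np.int32)
        gt2 = GenotypeTable(
            ids=gt.ids + ["ghost"], loci=gt.loci,
            alleles=np.concatenate([gt.alleles, extra]),
            population=np.append(gt.population, "A"),
        )
        assert reynolds_fst(gt2, "A", "B") == pytest.approx(base, abs=1e-12)

    def test_fst_equals_rst_for_equidistant_alleles(self, rng):
        rows = rng.choice([100, 102], size=(16, 10))
        gt = _table(rows, ["A"] * 8 + ["B"] * 8)
        assert reynolds_fst(gt, "A", "B") == pytest.approx(
            slatkin_rst(gt, "A", "B"), abs=1e-9
        )


class TestPhiST:
    def test_identical_haplotypes_zero(self):
        d2 = np.zeros((8, 8))
        assert phi_st(d2, ["A"] * 4 + ["B"] * 4) == 0.0

    def test_fixed_distinct_haplotypes_one(self):
        groups = np.array(["A"] * 5 + ["B"] * 5)
        d2 = (groups[:, None] != groups[None, :]).astype(float)
        assert phi_st(d2, groups) == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_amova_on_toy(self):
        # 6 haplotypes, p-distance-style squared distances
        h = np.array([0.0, 0.1, 0.2, 0.8, 0.9, 1.0])
        d2 = (h[:, None] - h[None, :]) ** 2
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        sa, sw = _amova_brute(
            [list(h[:3]), list(h[3:])],
            lambda x, y: float(x - y) ** 2,
        )
        assert phi_st(d2, groups) == pytest.approx(sa / (sa + sw), abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            phi_st(np.zeros((3, 3)), ["A", "B", "B"])


class TestPermutationP:
    def test_observed_above_all_permutations(self):
        labels = np.array(["A"] * 5 + ["B"] * 5)
        calls = {"first": True}

        def stat(g):
            if calls["first"]:
                calls["first"] = False
                return 1e9
            return 0.0

        assert permutation_p(stat, labels, n_perm=99, seed=0) == pytest.approx(
            1 / 100
        )

    def test_label_invariant_statistic_mean_p_half(self):
        rng = np.random.default_rng(1)
        ps = []
        for s in range(200):
            vals = rng.normal(size=10)
            labels = np.arange(10)

            def stat(g, vals=vals):
                return float(vals[g[:5]].sum())

            ps.append(permutation_p(stat, labels, n_perm=49, seed=s))
        assert abs(np.mean(ps) - 0.5) < 0.05

    def test_seed_determinism(self, rng):
        vals = rng.normal(size=12)
        labels = np.array(["A"] * 6 + ["B"] * 6)

        def stat(g):
            return float(vals[g == "A"].mean())

        p1 = permutation_p(stat, labels, n_perm=200, seed=11)
        p2 = permutation_p(stat, labels, n_perm=200, seed=11)
        assert p1 == p2
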