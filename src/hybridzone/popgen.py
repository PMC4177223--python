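"""Classical population-genetic summaries with permutation significance.

Differentiation statistics share one two-level AMOVA variance-component
engine operating on gene copies:

* FST — 0/1 allele identity as the distance; this is the coancestry-style
  FST analog of Reynolds, Weir & Cockerham (1983) as computed by AMOVA on
  allele frequencies (ratio of summed among-population to total variance
  components across loci).
* RST — squared repeat-size difference as the distance (Slatkin 1995).
* ΦST — arbitrary supplied squared distances between haplotypes (p-distances
  for sequence markers).

Hardy–Weinberg testing follows the exact probability-ordering test of
Guo & Thompson: complete enumeration of genotype tables with the observed
allele counts where feasible, otherwise a seeded Monte-Carlo version of the
same test.  Linkage equilibrium uses a G-test on the two-locus genotype
contingency table with a permutation null.

Negative estimator values are reported as computed (not truncated to zero).
Per-locus p-values are reported raw, without multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeTable

__all__ = [
    "allele_freqs",
    "private_alleles",
    "hwe_test",
    "ld_test",
    "reynolds_fst",
    "slatkin_rst",
    "phi_st",
    "permutation_p",
    "diff_stats",
    "LocusTestResult",
]


@dataclass
class LocusTestResult:
    locus_id: str
    statistic: float
    p: float
    method: str  # "exact" | "monte-carlo" | "g-test"


# ----------------------------------------------------------------------
# allele frequencies and private alleles
# ----------------------------------------------------------------------

def allele_freqs(gt: GenotypeTable, pop: str) -> list[dict[int, float]]:
    """Per-locus allele frequency vectors for one population.

    Missing calls are excluded.  A locus with no calls in the population
    yields an empty dict (flagged with a warning).
    """
    idx = np.flatnonzero(gt.population == pop)
    if idx.size == 0:
        raise ValueError(f"population {pop!r} is empty or unknown")
    out: list[dict[int, float]] = []
    for l in range(gt.n_loci):
        copies = gt.alleles[idx, l, :].ravel()
        copies = copies[copies != MISSING]
        if copies.size == 0:
            warnings.warn(f"locus {gt.loci[l]}: all calls missing in {pop}")
            out.append({})
            continue
        vals, counts = np.unique(copies, return_counts=True)
        out.append({int(v): c / copies.size for v, c in zip(vals, counts)})
    return out


def private_alleles(
    freqs_a: list[dict[int, float]],
    freqs_b: list[dict[int, float]],
    min_freq: float = 0.0,
) -> tuple[int, int]:
    """Count alleles private to each population across loci.

    An allele is private to A when it segregates in A (frequency >= the
    ``min_freq`` cutoff) and is absent from B; symmetrically for B.
    """
    if len(freqs_a) != len(freqs_b):
        raise ValueError("frequency lists cover different locus sets")
    n_a = n_b = 0
    for fa, fb in zip(freqs_a, freqs_b):
        for allele, f in fa.items():
            if f > 0 and f >= min_freq and fb.get(allele, 0.0) == 0.0:
                n_a += 1
        for allele, f in fb.items():
            if f > 0 and f >= min_freq and fa.get(allele, 0.0) == 0.0:
                n_b += 1
    return n_a, n_b


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test (Guo & Thompson probability ordering)
# ----------------------------------------------------------------------

def _table_log_prob(table: dict[tuple[int, int], int], allele_counts: dict[int, int]) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    n = sum(table.values())
    two_n = sum(allele_counts.values())
    h = sum(c for (u, v), c in table.items() if u != v)
    lp = lgamma(n + 1) - lgamma(two_n + 1) + h * log(2.0)
    for c in allele_counts.values():
        lp += lgamma(c + 1)
    for c in table.values():
        lp -= lgamma(c + 1)
    return lp


def _enumerate_tables(allele_counts: list[int], max_tables: int):
    """Yield all genotype-count tables with the given allele-count margins.

    Tables are dicts {(u, v): count} over ordered allele indices u <= v.
    Raises OverflowError when more than ``max_tables`` tables are reached.
    """
    k = len(allele_counts)
    cells = [(u, v) for u in range(k) for v in range(u, k)]
    remaining = list(allele_counts)
    table: dict[tuple[int, int], int] = {}
    produced = [0]

    def rec(ci: int):
        if ci == len(cells):
            if all(r == 0 for r in remaining):
                produced[0] += 1
                if produced[0] > max_tables:
                    raise OverflowError("enumeration bound exceeded")
                yield dict(table)
            return
        u, v = cells[ci]
        last_for_u = (v == k - 1) or (u == v == k - 1)
        if u == v:
            if last_for_u:  # must consume all remaining copies of u
                if remaining[u] % 2 == 0:
                    c = remaining[u] // 2
                    table[(u, v)] = c
                    remaining[u] -= 2 * c
                    yield from rec(ci + 1)
                    remaining[u] += 2 * c
                    del table[(u, v)]
                return
            for c in range(remaining[u] // 2 + 1):
                table[(u, v)] = c
                remaining[u] -= 2 * c
                yield from rec(ci + 1)
                remaining[u] += 2 * c
            del table[(u, v)]
        else:
            if last_for_u:
                c = remaining[u]
                if c <= remaining[v]:
                    table[(u, v)] = c
                    remaining[u] -= c
                    remaining[v] -= c
                    yield from rec(ci + 1)
                    remaining[u] += c
                    remaining[v] += c
                    del table[(u, v)]
                return
            for c in range(min(remaining[u], remaining[v]) + 1):
                table[(u, v)] = c
                remaining[u] -= c
                remaining[v] -= c
                yield from rec(ci + 1)
                remaining[u] += c
                remaining[v] += c
            del table[(u, v)]

    yield from rec(0)


def hwe_test(
    genotypes: np.ndarray,
    locus_id: str = "locus",
    max_tables: int = 200_000,
    reps: int = 10_000,
    seed: int = 0,
) -> LocusTestResult:
    """Exact (or Monte-Carlo) Hardy-Weinberg test at one locus.

    Parameters
    ----------
    genotypes : array of shape (n, 2)
        Non-missing diploid calls (allele sizes or arbitrary codes).
    max_tables : int
        Enumeration bound; beyond it the Monte-Carlo flavour of the same
        probability-ordering test is used.

    The p-value sums conditional probabilities of all genotype tables (with
    the observed allele counts) no more probable than the observed table.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[1] != 2:
        raise ValueError("genotypes must have shape (n, 2)")
    if genotypes.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    alleles = np.unique(genotypes)
    if alleles.size == 1:
        return LocusTestResult(locus_id, 1.0, 1.0, "exact")
    code = {int(a): i for i, a in enumerate(alleles)}
    counts: dict[tuple[int, int], int] = {}
    allele_counts = [0] * alleles.size
    for a, b in genotypes:
        u, v = sorted((code[int(a)], code[int(b)]))
        counts[(u, v)] = counts.get((u, v), 0) + 1
        allele_counts[u] += 1
        allele_counts[v] += 1
    obs_lp = _table_log_prob(counts, dict(enumerate(allele_counts)))
    tol = 1e-9
    try:
        p = 0.0
        for table in _enumerate_tables(allele_counts, max_tables):
            lp = _table_log_prob(table, dict(enumerate(allele_counts)))
            if lp <= obs_lp + tol:
                p += np.exp(lp)
        return LocusTestResult(locus_id, float(np.exp(obs_lp)), min(p, 1.0), "exact")
    except OverflowError:
        pass
    # Monte-Carlo: shuffle gene copies into pairs, same ordering criterion
    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(alleles.size), allele_counts)
    hits = 0
    ac = dict(enumerate(allele_counts))
    for _ in range(reps):
        rng.shuffle(copies)
        pairs = copies.reshape(-1, 2)
        t: dict[tuple[int, int], int] = {}
        for a, b in pairs:
            u, v = (a, b) if a <= b else (b, a)
            t[(u, v)] = t.get((u, v), 0) + 1
        if _table_log_prob(t, ac) <= obs_lp + tol:
            hits += 1
    return LocusTestResult(
        locus_id, float(np.exp(obs_lp)), (1 + hits) / (reps + 1), "monte-carlo"
    )


def hwe_tests(gt: GenotypeTable, pop: str | None = None, **kwargs) -> list[LocusTestResult]:
    """Run :func:`hwe_test` at every locus (optionally within one population)."""
    idx = (
        np.arange(gt.n_individuals)
        if pop is None
        else np.flatnonzero(gt.population == pop)
    )
    out = []
    for l in range(gt.n_loci):
        g = gt.alleles[idx, l, :]
        g = g[g[:, 0] != MISSING]
        if g.shape[0] < 2:
            warnings.warn(f"locus {gt.loci[l]}: fewer than 2 calls, skipped")
            continue
        out.append(hwe_test(g, locus_id=gt.loci[l], **kwargs))
    return out


# ----------------------------------------------------------------------
# linkage (genotypic) equilibrium: permutation G-test
# ----------------------------------------------------------------------

def _g_statistic(ri: np.ndarray, cj: np.ndarray, nr: int, nc: int) -> float:
    obs = np.bincount(ri * nc + cj, minlength=nr * nc).reshape(nr, nc).astype(float)
    rows = obs.sum(1, keepdims=True)
    cols = obs.sum(0, keepdims=True)
    exp = rows * cols / obs.sum()
    nz = obs > 0
    return float(2.0 * (obs[nz] * np.log(obs[nz] / exp[nz])).sum())


def ld_test(
    gt: GenotypeTable,
    locus_i: int,
    locus_j: int,
    reps: int = 10_000,
    seed: int = 0,
) -> LocusTestResult:
    """Permutation G-test of genotypic association between two loci.

    The null distribution shuffles one locus's genotypes across individuals
    typed at both loci, breaking any association while preserving both
    genotype margins.
    """
    name = f"{gt.loci[locus_i]}x{gt.loci[locus_j]}"
    ok = ~gt.missing_mask[:, locus_i] & ~gt.missing_mask[:, locus_j]
    if ok.sum() < 2:
        raise ValueError("loci co-typed in fewer than 2 individuals")
    gi = [tuple(sorted(g)) for g in gt.alleles[ok, locus_i, :]]
    gj = [tuple(sorted(g)) for g in gt.alleles[ok, locus_j, :]]
    ui, ri = np.unique(gi, axis=0, return_inverse=True)
    uj, cj = np.unique(gj, axis=0, return_inverse=True)
    if len(ui) < 2 or len(uj) < 2:
        return LocusTestResult(name, 0.0, 1.0, "g-test")
    g_obs = _g_statistic(ri, cj, len(ui), len(uj))
    rng = np.random.default_rng(seed)
    hits = 0
    cj_perm = cj.copy()
    for _ in range(reps):
        rng.shuffle(cj_perm)
        if _g_statistic(ri, cj_perm, len(ui), len(uj)) >= g_obs - 1e-12:
            hits += 1
    return LocusTestResult(name, g_obs, (1 + hits) / (reps + 1), "g-test")


# ----------------------------------------------------------------------
# AMOVA variance-component engine
# ----------------------------------------------------------------------

def _amova_components(ssd_total: float, ssd_within: float, group_sizes: np.ndarray):
    """Return (sigma2_among, sigma2_within) for a two-level AMOVA locus."""
    n = group_sizes.sum()
    s = len(group_sizes)
    df_w = n - s
    if df_w <= 0 or s < 2:
        return 0.0, 0.0
    sigma_w = ssd_within / df_w
    ms_a = (ssd_total - ssd_within) / (s - 1)
    n_prime = (n - (group_sizes**2).sum() / n) / (s - 1)
    sigma_a = (ms_a - sigma_w) / n_prime
    return float(sigma_a), float(sigma_w)


def _locus_copy_lists(gt: GenotypeTable, pops: tuple[str, str], locus: int):
    out = []
    for p in pops:
        idx = np.flatnonzero(gt.population == p)
        copies = gt.alleles[idx, locus, :].ravel()
        out.append(copies[copies != MISSING])
    return out


def _freq_ssd_identity(copies: np.ndarray) -> float:
    """SSD of 0/1-distance gene copies around their group centroid."""
    n = copies.size
    if n == 0:
        return 0.0
    _, counts = np.unique(copies, return_counts=True)
    p = counts / n
    return n * (1.0 - (p**2).sum()) / 2.0


def _freq_ssd_size(copies: np.ndarray) -> float:
    """SSD of repeat sizes: N x biased variance."""
    n = copies.size
    if n == 0:
        return 0.0
    return float(n * np.var(copies.astype(float)))


def _multilocus_phi(gt, pop_a, pop_b, ssd_fn) -> float:
    num = den = 0.0
    used = 0
    for l in range(gt.n_loci):
        ca, cb = _locus_copy_lists(gt, (pop_a, pop_b), l)
        if ca.size == 0 or cb.size == 0:
            continue
        pooled = np.concatenate([ca, cb])
        ssd_t = ssd_fn(pooled)
        ssd_w = ssd_fn(ca) + ssd_fn(cb)
        sa, sw = _amova_components(
            ssd_t, ssd_w, np.array([ca.size, cb.size], dtype=float)
        )
        num += sa
        den += sa + sw
        used += 1
    if used == 0:
        raise ValueError("no locus typed in both populations")
    if den == 0.0:
        return 0.0
    return num / den


def reynolds_fst(gt: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Multi-locus FST analog (ratio of summed variance components).

    AMOVA on gene copies with an identity (0/1) allele distance; equivalent
    to the Reynolds et al. (1983) coancestry-style estimator used for
    co-dominant markers, combined across loci as a ratio of sums.
    """
    _check_two_pops(gt, pop_a, pop_b)
    return _multilocus_phi(gt, pop_a, pop_b, _freq_ssd_identity)


def slatkin_rst(gt: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Slatkin's RST: AMOVA on squared allele-size (repeat) differences."""
    _check_two_pops(gt, pop_a, pop_b)
    return _multilocus_phi(gt, pop_a, pop_b, _freq_ssd_size)


def _check_two_pops(gt, pop_a, pop_b):
    for p in (pop_a, pop_b):
        if (gt.population == p).sum() < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")


def phi_st(d2: np.ndarray, groups: np.ndarray) -> float:
    """AMOVA Φ-statistic among two groups of haplotypes.

    Parameters
    ----------
    d2 : (n, n) array
        Squared pairwise distances between haplotypes (e.g. p-distances for
        sequence data).
    groups : (n,) array of labels (exactly two distinct values).
    """
    d2 = np.asarray(d2, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("phi_st requires exactly two groups")
    sizes = np.array([(groups == g).sum() for g in labels], dtype=float)
    if (sizes < 2).any():
        raise ValueError("each group needs at least 2 haplotypes")
    n = int(sizes.sum())
    ssd_t = d2.sum() / (2.0 * n)
    ssd_w = 0.0
    for g, sz in zip(labels, sizes):
        idx = np.flatnonzero(groups == g)
        ssd_w += d2[np.ix_(idx, idx)].sum() / (2.0 * sz)
    sa, sw = _amova_components(ssd_t, ssd_w, sizes)
    if sa + sw == 0.0:
        return 0.0
    return sa / (sa + sw)


# ----------------------------------------------------------------------
# permutation significance
# ----------------------------------------------------------------------

def permutation_p(
    stat_fn,
    grouping: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Upper-tail permutation p-value for a grouping-based statistic.

    ``stat_fn(grouping)`` must return the statistic for any permutation of
    the group labels.  p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    grouping = np.asarray(grouping)
    observed = stat_fn(grouping)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = grouping.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if stat_fn(perm) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def diff_stats(
    gt: GenotypeTable,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """FST and RST between two populations with permutation p-values.

    Permutations shuffle individuals between the two populations.
    """
    idx = np.flatnonzero((gt.population == pop_a) | (gt.population == pop_b))
    sub = gt.subset(idx)
    rows = []
    for name, fn in (("fst", reynolds_fst), ("rst", slatkin_rst)):
        def stat(labels, fn=fn):
            tmp = GenotypeTable(
                ids=sub.ids, loci=sub.loci, alleles=sub.alleles,
                population=labels, phenotype=sub.phenotype,
            )
            return fn(tmp, pop_a, pop_b)
        value = stat(sub.population)
        p = permutation_p(stat, sub.population, n_perm=n_perm, seed=seed)
        rows.append({"statistic": name, "value": value, "p": p})
    return pd.DataFrame(rows)
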