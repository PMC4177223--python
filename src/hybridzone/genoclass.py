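"""Posterior probabilities over six hybrid genotype-frequency classes.

Each pedigree class (pure A, pure B, F1, F2, backcross to A, backcross to
B) is characterised by the expected proportions (φ0, φ1, φ2) of loci at
which an individual carries both gene copies from species A, one from
each, or both from B:

    pure A (1, 0, 0)    pure B (0, 0, 1)    F1 (0, 1, 0)
    F2 (1/4, 1/2, 1/4)  BX_A (1/2, 1/2, 0)  BX_B (0, 1/2, 1/2)

The genotype likelihood under a class mixes the three source-state
genotype probabilities with these weights; loci are independent.  Two
estimation modes are exposed: a plug-in mode that fixes the parental
allele frequencies at their reference-panel estimates and computes the
class posterior in closed form, and a joint mode that Gibbs-samples class
memberships, per-locus source states and parental frequencies together
(reference individuals pinned to their pure class).  Class priors are
equal by default.  Only first/second-generation classes are modelled;
deeper backcross generations are not identifiable with ~10 loci.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import MISSING, GenotypeTable

__all__ = [
    "CLASS_NAMES",
    "HYBRID_CLASSES",
    "PHI",
    "genotype_class_likelihood",
    "GenotypeClassModel",
    "fit_classes",
]

CLASS_NAMES = ("pure_a", "pure_b", "f1", "f2", "bx_a", "bx_b")
HYBRID_CLASSES = ("f1", "f2", "bx_a", "bx_b")

# rows: classes, columns: P(both copies from A | one each | both from B)
PHI = np.array([
    [1.00, 0.00, 0.00],
    [0.00, 0.00, 1.00],
    [0.00, 1.00, 0.00],
    [0.25, 0.50, 0.25],
    [0.50, 0.50, 0.00],
    [0.00, 0.50, 0.50],
])

_CAT_TO_CLASS = {
    "PURE_A": "pure_a", "PURE_B": "pure_b", "F1": "f1", "F2": "f2",
    "BX_A": "bx_a", "BX_B": "bx_b",
}


def _source_state_probs(a: int, b: int, pa, pb) -> tuple[float, float, float]:
    """P(genotype | both-from-A), P(| one-each), P(| both-from-B)."""
    paa, pab_ = pa.get(a, 0.0), pa.get(b, 0.0)
    pba, pbb_ = pb.get(a, 0.0), pb.get(b, 0.0)
    if a == b:
        return paa * pab_, paa * pbb_, pba * pbb_
    return (
        2.0 * paa * pab_,
        paa * pbb_ + pab_ * pba,
        2.0 * pba * pbb_,
    )


def genotype_class_likelihood(
    genotype: tuple[int, int],
    freqs_a: dict[int, float],
    freqs_b: dict[int, float],
    category: str,
) -> float:
    """Likelihood of one unordered genotype under one pedigree class.

    Mixes the three source-state genotype probabilities with the class's
    (φ0, φ1, φ2) weights.  An allele absent from both frequency supports
    yields zero likelihood with a warning.
    """
    if category not in CLASS_NAMES and category not in _CAT_TO_CLASS:
        raise ValueError(f"unknown class {category!r}")
    cls = _CAT_TO_CLASS.get(category, category)
    a, b = genotype
    for allele in (a, b):
        if freqs_a.get(allele, 0.0) == 0.0 and freqs_b.get(allele, 0.0) == 0.0:
            warnings.warn(f"allele {allele} absent from both reference supports")
            return 0.0
    vec = _source_state_probs(a, b, freqs_a, freqs_b)
    return float(PHI[CLASS_NAMES.index(cls)] @ np.asarray(vec))


class GenotypeClassModel(BaseEstimator):
    """Six-class hybrid genotype-frequency classifier.

    Parameters
    ----------
    mode : 'plugin' or 'joint'
        Plug-in fixes parental frequencies at reference-panel estimates;
        joint Gibbs-samples frequencies together with class memberships.
    prior : array-like of 6 or None
        Class prior; equal by default.
    pseudocount : float
        Added per allele (union support) when estimating reference
        frequencies in plug-in mode, so private reference alleles do not
        zero out whole classes.
    sweeps, burn_in, random_state : joint-mode MCMC controls.

    After :meth:`fit` (on the two parental reference panels),
    :meth:`predict_proba` returns a DataFrame of class posteriors Q plus
    the pooled hybrid posterior (sum over the four hybrid classes).
    """

    def __init__(self, mode: str = "plugin", prior=None, pseudocount: float = 0.5,
                 sweeps: int = 2000, burn_in: int = 500,
                 random_state: int | None = None):
        self.mode = mode
        self.prior = prior
        self.pseudocount = pseudocount
        self.sweeps = sweeps
        self.burn_in = burn_in
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, ref_a: GenotypeTable, ref_b: GenotypeTable) -> "GenotypeClassModel":
        if self.mode not in ("plugin", "joint"):
            raise ValueError("mode must be 'plugin' or 'joint'")
        if list(ref_a.loci) != list(ref_b.loci):
            raise ValueError("reference panels differ in loci")
        if self.sweeps <= self.burn_in:
            raise ValueError("sweeps must exceed burn_in")
        self.loci_ = list(ref_a.loci)
        self.ref_a_ = ref_a
        self.ref_b_ = ref_b
        self.freqs_a_, self.freqs_b_ = self._reference_freqs(ref_a, ref_b)
        self.prior_ = (np.full(6, 1.0 / 6.0) if self.prior is None
                       else np.asarray(self.prior, dtype=float))
        if abs(self.prior_.sum() - 1.0) > 1e-9 or (self.prior_ < 0).any():
            raise ValueError("prior must be a probability vector of length 6")
        return self

    def _reference_freqs(self, ref_a, ref_b):
        fa_list, fb_list = [], []
        for l in range(len(self.loci_)):
            support = sorted(
                set(ref_a.locus_alleles(l)) | set(ref_b.locus_alleles(l))
            )
            out = []
            for ref in (ref_a, ref_b):
                copies = ref.alleles[:, l, :].ravel()
                copies = copies[copies != MISSING]
                vals, counts = np.unique(copies, return_counts=True)
                cmap = dict(zip(vals.astype(int), counts.astype(float)))
                tot = copies.size + self.pseudocount * len(support)
                out.append({
                    int(s): (cmap.get(int(s), 0.0) + self.pseudocount) / tot
                    for s in support
                })
            fa_list.append(out[0])
            fb_list.append(out[1])
        return fa_list, fb_list

    # ------------------------------------------------------------------
    def predict_proba(self, gt: GenotypeTable) -> pd.DataFrame:
        """Class posteriors for each individual in ``gt``.

        Returns a DataFrame indexed by individual id with the six class
        columns plus ``pooled_hybrid``.  Individuals with no typed locus
        receive the prior and are listed in ``df.attrs['no_data_ids']``.
        """
        if list(gt.loci) != self.loci_:
            raise ValueError("loci differ from the fitted reference panels")
        if self.mode == "plugin":
            q = self._plugin(gt)
        else:
            q = self._joint(gt)
        df = pd.DataFrame(q, index=gt.ids, columns=list(CLASS_NAMES))
        df["pooled_hybrid"] = df[list(HYBRID_CLASSES)].sum(axis=1)
        no_data = [gt.ids[i] for i in range(gt.n_individuals)
                   if gt.missing_mask[i].all()]
        df.attrs["no_data_ids"] = no_data
        return df

    # ------------------------------------------------------------------
    def _plugin(self, gt: GenotypeTable) -> np.ndarray:
        n = gt.n_individuals
        logq = np.tile(np.log(np.maximum(self.prior_, 1e-300)), (n, 1))
        for l in range(gt.n_loci):
            pa, pb = self.freqs_a_[l], self.freqs_b_[l]
            for i in range(n):
                a, b = gt.alleles[i, l]
                if a == MISSING:
                    continue
                vec = np.asarray(_source_state_probs(int(a), int(b), pa, pb))
                lik = PHI @ vec
                if (lik == 0.0).all():
                    warnings.warn(
                        f"{gt.ids[i]}, locus {gt.loci[l]}: allele outside both "
                        "reference supports; locus skipped"
                    )
                    continue
                logq[i] += np.log(np.maximum(lik, 1e-300))
        logq -= logq.max(axis=1, keepdims=True)
        q = np.exp(logq)
        return q / q.sum(axis=1, keepdims=True)

    # ------------------------------------------------------------------
    def _joint(self, gt: GenotypeTable) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        combined = GenotypeTable.concat([self.ref_a_, self.ref_b_, gt])
        n_a, n_b, n_u = (self.ref_a_.n_individuals,
                         self.ref_b_.n_individuals, gt.n_individuals)
        n = combined.n_individuals
        L = combined.n_loci
        unknown = np.arange(n_a + n_b, n)
        # per-locus supports and coded genotypes
        supports, ia, ib, miss = [], [], [], []
        for l in range(L):
            sup = combined.locus_alleles(l)
            lut = {int(a): k for k, a in enumerate(sup)}
            supports.append(sup)
            g = combined.alleles[:, l, :]
            m = g[:, 0] == MISSING
            miss.append(m)
            ia.append(np.array([lut[int(a)] if not mm else 0
                                for a, mm in zip(g[:, 0], m)]))
            ib.append(np.array([lut[int(b)] if not mm else 0
                                for b, mm in zip(g[:, 1], m)]))
        classes = np.zeros(n, dtype=np.int64)
        classes[n_a:n_a + n_b] = 1
        classes[unknown] = rng.integers(0, 6, size=n_u)
        pa = [np.full(len(s), 1.0 / len(s)) for s in supports]
        pb = [np.full(len(s), 1.0 / len(s)) for s in supports]
        q_counts = np.zeros((n_u, 6))
        for sweep in range(self.sweeps):
            # class memberships for unknowns | frequencies
            loglik = np.tile(np.log(np.maximum(self.prior_, 1e-300)), (n_u, 1))
            state_p = []
            for l in range(L):
                va, vb = pa[l], pb[l]
                A, B = ia[l], ib[l]
                hom = A == B
                s0 = np.where(hom, va[A] * va[B], 2 * va[A] * va[B])
                s1 = np.where(hom, va[A] * vb[B], va[A] * vb[B] + va[B] * vb[A])
                s2 = np.where(hom, vb[A] * vb[B], 2 * vb[A] * vb[B])
                sp = np.stack([s0, s1, s2], axis=1)  # (n, 3)
                state_p.append(sp)
                lik = sp[unknown] @ PHI.T  # (n_u, 6)
                ok = ~miss[l][unknown]
                loglik[ok] += np.log(np.maximum(lik[ok], 1e-300))
            loglik -= loglik.max(axis=1, keepdims=True)
            w = np.exp(loglik)
            w /= w.sum(axis=1, keepdims=True)
            u = rng.random(n_u)[:, None]
            classes[unknown] = (u > np.cumsum(w, axis=1)).sum(axis=1)
            if sweep >= self.burn_in:
                q_counts[np.arange(n_u), classes[unknown]] += 1
            # source states and allele-count updates | classes
            for l in range(L):
                sp = state_p[l]
                ws = PHI[classes] * sp  # (n, 3)
                ok = ~miss[l]
                tot = ws.sum(axis=1)
                ok &= tot > 0
                probs = ws[ok] / tot[ok, None]
                u = rng.random(probs.shape[0])[:, None]
                s = (u > np.cumsum(probs, axis=1)).sum(axis=1)
                A, B = ia[l][ok], ib[l][ok]
                ca = np.zeros(len(supports[l]))
                cb = np.zeros(len(supports[l]))
                both_a, both_b, one_each = s == 0, s == 2, s == 1
                np.add.at(ca, A[both_a], 1.0)
                np.add.at(ca, B[both_a], 1.0)
                np.add.at(cb, A[both_b], 1.0)
                np.add.at(cb, B[both_b], 1.0)
                # heterogeneous-source loci: attribute one copy to each pool
                Ae, Be = A[one_each], B[one_each]
                va, vb = pa[l], pb[l]
                pa_first = va[Ae] * vb[Be]
                denom = pa_first + va[Be] * vb[Ae]
                take_a_first = rng.random(len(Ae)) < np.where(
                    denom > 0, pa_first / np.maximum(denom, 1e-300), 0.5
                )
                np.add.at(ca, np.where(take_a_first, Ae, Be), 1.0)
                np.add.at(cb, np.where(take_a_first, Be, Ae), 1.0)
                pa[l] = rng.dirichlet(1.0 + ca)
                pb[l] = rng.dirichlet(1.0 + cb)
        return q_counts / q_counts.sum(axis=1, keepdims=True)


def fit_classes(
    gt: GenotypeTable,
    ref_a: GenotypeTable,
    ref_b: GenotypeTable,
    mode: str = "plugin",
    sweeps: int = 2000,
    burn_in: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Functional wrapper: class posteriors for ``gt`` given reference panels."""
    model = GenotypeClassModel(
        mode=mode, sweeps=sweeps, burn_in=burn_in, random_state=seed
    ).fit(ref_a, ref_b)
    return model.predict_proba(gt)
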