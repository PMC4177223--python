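"""Simulation-based power analysis of classification thresholds.

Reproduces the hybrid-detection power experiment: simulate parental
populations (default 200 individuals each) from a set of locus models,
generate hybrid categories (default 100 each of F1, F2 and the two
backcrosses), run the chosen assignment engine on the combined sample,
and score per-category correct-assignment rates under the studied
thresholds.

Correctness rules (made explicit and configurable):

* admixture engine (membership coefficient q) — a parental individual is
  correct when its membership in its own cluster reaches the threshold; a
  hybrid is correctly flagged when *both* cluster memberships fall below
  the threshold (assignment to neither cluster).
* genotype-class engine (posterior Q) — a parental individual is correct
  when its own pure-class posterior exceeds the Q threshold (default
  0.6); a hybrid when its pooled hybrid-class posterior exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admixture import AdmixtureModel
from .data import GenotypeTable
from .genoclass import GenotypeClassModel
from .synthdata import HYBRID_CATEGORIES, LocusModel, cross, sample_parental

__all__ = ["CalibrationReport", "run_calibration", "threshold_sweep"]


@dataclass
class CalibrationReport:
    """Raw per-individual assignments plus threshold summaries.

    ``per_individual`` carries one row per simulated individual with its
    true category and, depending on the engine, the two cluster
    memberships (``q_a``, ``q_b``) or the pure/pooled class posteriors
    (``q_own_pure``-style columns).
    """

    engine: str
    per_individual: pd.DataFrame
    q_threshold_hybrid: float = 0.6

    def summary(self, thresholds=(0.8, 0.9)) -> pd.DataFrame:
        """Per-category assignment summary table.

        Columns mirror the power-analysis layout: mean membership in each
        cluster, the min/max of the own-side membership, and the percent
        of individuals correctly assigned under each threshold.
        """
        df = self.per_individual
        rows = []
        for cat, grp in df.groupby("category", sort=False):
            row = {"category": cat, "n": len(grp)}
            if self.engine == "admixture":
                row["mean_q_a"] = grp["q_a"].mean()
                row["mean_q_b"] = grp["q_b"].mean()
                own = _own_membership(cat, grp)
                row["min_q"] = own.min()
                row["max_q"] = own.max()
                for t in thresholds:
                    row[f"pct_correct_{t}"] = 100.0 * _q_correct(cat, grp, t).mean()
            else:
                row["mean_pooled_hybrid"] = grp["pooled_hybrid"].mean()
                t = self.q_threshold_hybrid
                row[f"pct_correct_{t}"] = 100.0 * _class_correct(cat, grp, t).mean()
            rows.append(row)
        return pd.DataFrame(rows)


def _own_membership(cat: str, grp: pd.DataFrame) -> pd.Series:
    if cat == "PURE_A":
        return grp["q_a"]
    if cat == "PURE_B":
        return grp["q_b"]
    return grp[["q_a", "q_b"]].max(axis=1)


def _q_correct(cat: str, grp: pd.DataFrame, t: float) -> pd.Series:
    if cat == "PURE_A":
        return grp["q_a"] >= t
    if cat == "PURE_B":
        return grp["q_b"] >= t
    return (grp["q_a"] < t) & (grp["q_b"] < t)


def _class_correct(cat: str, grp: pd.DataFrame, t: float) -> pd.Series:
    if cat == "PURE_A":
        return grp["pure_a"] > t
    if cat == "PURE_B":
        return grp["pure_b"] > t
    return grp["pooled_hybrid"] > t


def run_calibration(
    models: list[LocusModel],
    n_parental: int = 200,
    n_hybrid: int = 100,
    thresholds=(0.8, 0.9),
    engine: str = "admixture",
    q_threshold_hybrid: float = 0.6,
    sweeps: int = 2000,
    burn_in: int = 500,
    seed: int = 0,
    include_reference: bool = True,
    f1_dam_species: str = "B",
) -> CalibrationReport:
    """Run the full simulate-then-assign calibration experiment.

    ``include_reference`` analyses the simulated parental reference sets
    together with the hybrids in one run (the admixture engine is
    unsupervised, so the parentals anchor the clusters).
    """
    if engine not in ("admixture", "genoclass"):
        raise ValueError("engine must be 'admixture' or 'genoclass'")
    if not all(0.0 < t < 1.0 or t == 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(8)]
    par_a = sample_parental(models, "A", n_parental, seed=seeds[0], id_prefix="simA")
    par_b = sample_parental(models, "B", n_parental, seed=seeds[1], id_prefix="simB")
    parts = [par_a, par_b] if include_reference else []
    categories = (["PURE_A"] * (n_parental if include_reference else 0)
                  + ["PURE_B"] * (n_parental if include_reference else 0))
    for j, cat in enumerate(HYBRID_CATEGORIES):
        gt_c, _ = cross(cat, models, n=n_hybrid, seed=seeds[2 + j],
                        f1_dam_species=f1_dam_species, id_prefix=f"sim{cat}")
        parts.append(gt_c)
        categories.extend([cat] * n_hybrid)
    combined = GenotypeTable.concat(parts)

    if engine == "admixture":
        model = AdmixtureModel(n_clusters=2, sweeps=sweeps, burn_in=burn_in,
                               random_state=seeds[6]).fit(combined)
        q = model.q_
        cats = np.asarray(categories)
        # anchor cluster labels on the parental means
        if include_reference:
            a_idx = np.flatnonzero(cats == "PURE_A")
        else:  # fall back: anchor on F1-free heuristic, first individual
            a_idx = np.array([0])
        col_a = int(np.argmax(q[a_idx].mean(axis=0)))
        per = pd.DataFrame({
            "individual_id": combined.ids,
            "category": categories,
            "q_a": q[:, col_a],
            "q_b": q[:, 1 - col_a],
        })
    else:
        clf = GenotypeClassModel(mode="plugin").fit(par_a, par_b)
        proba = clf.predict_proba(combined)
        per = proba.reset_index(names="individual_id")
        per.insert(1, "category", categories)
    return CalibrationReport(engine=engine, per_individual=per,
                             q_threshold_hybrid=q_threshold_hybrid)


def threshold_sweep(report: CalibrationReport, grid) -> pd.DataFrame:
    """Correct-assignment rates over a grid of thresholds.

    Long-format table (threshold, category, pct_correct).  Parental rates
    are non-increasing and hybrid rates non-decreasing in the threshold by
    construction (nested events).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if report.engine != "admixture":
        raise ValueError("threshold sweep applies to the membership engine")
    rows = []
    for t in grid:
        for cat, grp in report.per_individual.groupby("category", sort=False):
            rows.append({
                "threshold": t,
                "category": cat,
                "pct_correct": 100.0 * _q_correct(cat, grp, t).mean(),
            })
    return pd.DataFrame(rows)
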