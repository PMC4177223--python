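"""Integrated pure/hybrid decision procedure.

Three evidence sources per individual are combined:

* STR — microsatellite membership coefficient q of the individual in the
  cluster of its own phenotype (admixture engine); flagged when below the
  chosen threshold (0.8 by default, 0.9 as the stricter alternative).
* NH — genotype-class posterior Q; flagged when the pooled hybrid-class
  posterior exceeds 0.6 (equivalently, when the own-pure-class posterior
  falls below 0.6 when only that marginal is available).
* SEQ — species-diagnostic uniparental/sex-linked haplotypes; flagged on
  any incongruence between an individual's phenotype and the species of
  origin of its mtDNA, X or Y haplotype (a heterozygous X carrying one
  other-species allele counts).

Decision rule: an individual is called a hybrid when the two
microsatellite analyses agree (STR flag AND NH flag) or when the
sequence-based markers show incongruence; otherwise it is called pure of
its own phenotype.  Individuals that are pure by both microsatellite
analyses but sequence-incongruent are therefore hybrids (later-generation
backcrosses leave little microsatellite signal while a foreign haplotype
is unambiguous).  No hard F1/F2/backcross call is emitted — raw class
posteriors are reported instead.

A bundled fixture transcribes the printed per-individual hybrid-evidence
table of the source study (38 individuals; phenotype labels 'Lge' and
'Lgut'), used as a worked example throughout the tests.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_table4_fixture",
    "sequence_incongruence",
    "sequence_flags",
    "select_parental",
    "integrate_calls",
    "summarize_population",
]

_MISSING_TOKENS = {"", "NA", "N/A", "nan", None}


def load_table4_fixture() -> pd.DataFrame:
    """The bundled per-individual hybrid-evidence table.

    Columns: individual_id, phenotype (Lge/Lgut), sex (M/F/U), nh (own
    pure-class posterior Q), str (own-cluster membership q), mtdna, x1,
    x2, y (species-of-origin labels; empty = not analysed / absent).
    """
    path = resources.files("hybridzone").joinpath("fixtures/table4_fixture.csv")
    with path.open() as fh:
        return pd.read_csv(fh, dtype={"nh": float, "str": float}, keep_default_na=False)


def _labels(*values) -> list[str]:
    out = []
    for v in values:
        if v in _MISSING_TOKENS or (isinstance(v, float) and np.isnan(v)):
            continue
        out.append(str(v))
    return out


def evidence_from_fixture(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """Evidence table (see :func:`integrate_calls`) from the bundled fixture."""
    fix = load_table4_fixture() if fixture is None else fixture
    flags = sequence_flags(
        fix[["individual_id", "mtdna", "x1", "x2", "y"]],
        fix.set_index("individual_id")["phenotype"],
    )
    ev = fix.rename(columns={"str": "q_own", "nh": "nh_own"})[
        ["individual_id", "phenotype", "q_own", "nh_own"]
    ]
    ev["seq_flag"] = flags.loc[ev["individual_id"], "seq_flag"].to_numpy()
    ev["markers"] = flags.loc[ev["individual_id"], "markers"].to_numpy()
    return ev


def sequence_incongruence(record, phenotype: str) -> tuple[bool, list[str]]:
    """Flag any phenotype/haplotype-origin mismatch for one individual.

    ``record`` is a mapping (dict, Series, namedtuple-as-dict) with keys
    mtdna, x1, x2, y; missing markers are ignored.  Returns the flag and
    the list of contributing markers; with every marker missing the flag
    is False and the marker list is ``['no-data']``.
    """
    rec = dict(record)
    markers: list[str] = []
    seen_any = False
    for key in ("mtdna", "x1", "x2", "y"):
        vals = _labels(rec.get(key))
        if not vals:
            continue
        seen_any = True
        if any(v != phenotype for v in vals):
            markers.append("x" if key.startswith("x") else key)
    markers = sorted(set(markers), key=["mtdna", "x", "y"].index)
    if not seen_any:
        return False, ["no-data"]
    return bool(markers), markers


def sequence_flags(haplotypes: pd.DataFrame, phenotypes: pd.Series) -> pd.DataFrame:
    """Vector version of :func:`sequence_incongruence` over a haplotype table."""
    rows = []
    for _, rec in haplotypes.iterrows():
        iid = rec["individual_id"]
        flag, markers = sequence_incongruence(rec, str(phenotypes.loc[iid]))
        rows.append({"individual_id": iid, "seq_flag": flag,
                     "markers": "+".join(markers)})
    return pd.DataFrame(rows).set_index("individual_id")


def select_parental(
    q_own: pd.Series,
    seq_flag: pd.Series,
    threshold: float = 0.95,
) -> list[str]:
    """Select the parental reference panel.

    Keeps individuals whose own-cluster membership is at least the
    threshold (boundary included) and that carry no sequence
    incongruence.  An empty panel triggers a warning.
    """
    keep = [str(i) for i in q_own.index
            if q_own.loc[i] >= threshold and not bool(seq_flag.get(i, False))]
    if not keep:
        warnings.warn("parental panel is empty after filtering")
    return keep


def integrate_calls(
    evidence: pd.DataFrame,
    t_str: float = 0.8,
    t_nh: float = 0.6,
    nh_rule: str = "auto",
) -> pd.DataFrame:
    """Apply the integrated pure/hybrid decision rule.

    Parameters
    ----------
    evidence : DataFrame
        One row per individual with columns ``individual_id``,
        ``phenotype``, ``q_own`` (STR membership in own cluster),
        ``seq_flag`` (bool) and either ``pooled_hybrid`` or ``nh_own``
        (own pure-class posterior).  Rows with a missing evidence source
        are skipped with a warning.
    nh_rule : 'pooled', 'own' or 'auto'
        Which NH column drives the flag; 'auto' prefers ``pooled_hybrid``
        when present.

    Returns
    -------
    DataFrame with per-individual flags, status ('pure-<phenotype>' or
    'hybrid') and a human-readable evidence summary.
    """
    if nh_rule == "auto":
        nh_rule = "pooled" if "pooled_hybrid" in evidence.columns else "own"
    nh_col = {"pooled": "pooled_hybrid", "own": "nh_own"}[nh_rule]
    required = ["individual_id", "phenotype", "q_own", "seq_flag", nh_col]
    missing_cols = set(required) - set(evidence.columns)
    if missing_cols:
        raise ValueError(f"evidence table lacks columns: {sorted(missing_cols)}")
    rows = []
    for rec in evidence.to_dict("records"):
        if any(pd.isna(rec[c]) for c in required):
            warnings.warn(f"{rec.get('individual_id')}: incomplete evidence, skipped")
            continue
        str_flag = rec["q_own"] < t_str
        nh_flag = (rec[nh_col] > t_nh) if nh_rule == "pooled" else (rec[nh_col] < t_nh)
        seq_flag = bool(rec["seq_flag"])
        hybrid = (str_flag and nh_flag) or seq_flag
        bits = []
        if str_flag:
            bits.append(f"STR q_own={rec['q_own']:.3f}<{t_str}")
        if nh_flag:
            bits.append("NH " + (f"pooled>{t_nh}" if nh_rule == "pooled"
                                 else f"Q_own<{t_nh}"))
        if seq_flag:
            bits.append("SEQ " + str(rec.get("markers", "incongruent")))
        rows.append({
            "individual_id": rec["individual_id"],
            "phenotype": rec["phenotype"],
            "str_flag": str_flag,
            "nh_flag": nh_flag,
            "seq_flag": seq_flag,
            "status": "hybrid" if hybrid else f"pure-{rec['phenotype']}",
            "evidence": "; ".join(bits) if bits else "none",
        })
    columns = ["individual_id", "phenotype", "str_flag", "nh_flag",
               "seq_flag", "status", "evidence"]
    return pd.DataFrame(rows, columns=columns)


def summarize_population(
    evidence: pd.DataFrame,
    pop_sizes: dict[str, int],
    t_strs=(0.8, 0.9),
    t_nh: float = 0.6,
    nh_rule: str = "auto",
) -> pd.DataFrame:
    """Per-phenotype hybrid/pure counts under each single method and integrated.

    ``evidence`` may cover only the flagged individuals (as the printed
    evidence table does); ``pop_sizes`` gives the full sample size per
    phenotype, and unlisted individuals count as pure under every method.
    Percentages are reported to two decimals.
    """
    if nh_rule == "auto":
        nh_rule = "pooled" if "pooled_hybrid" in evidence.columns else "own"
    nh_col = {"pooled": "pooled_hybrid", "own": "nh_own"}[nh_rule]
    rows = []
    for phen, n_total in pop_sizes.items():
        grp = evidence[evidence["phenotype"] == phen]
        methods: dict[str, int] = {}
        for t in t_strs:
            methods[f"STR<{t}"] = int((grp["q_own"] < t).sum())
        if nh_rule == "pooled":
            methods[f"NH>{t_nh}"] = int((grp[nh_col] > t_nh).sum())
        else:
            methods[f"NH<{t_nh}"] = int((grp[nh_col] < t_nh).sum())
        methods["SEQ"] = int(grp["seq_flag"].astype(bool).sum())
        calls = integrate_calls(grp, t_str=min(t_strs), t_nh=t_nh, nh_rule=nh_rule)
        methods["integrated"] = int((calls["status"] == "hybrid").sum())
        for method, n_hyb in methods.items():
            rows.append({
                "phenotype": phen,
                "method": method,
                "n_hybrid": n_hyb,
                "pct_hybrid": round(100.0 * n_hyb / n_total, 2),
                "n_pure": n_total - n_hyb,
                "pct_pure": round(100.0 * (n_total - n_hyb) / n_total, 2),
            })
    return pd.DataFrame(rows)
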