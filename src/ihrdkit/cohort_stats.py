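"""Cohort-level statistics and biomarker evaluation.

Conventions, chosen to match standard R behaviour:

* Rank-sum comparisons use the Mann-Whitney U test — exact when the smaller
  group has at most 10 members and the data are tie-free, otherwise the
  normal approximation with continuity and tie correction.
* Fisher's exact test reports the hypergeometric two-sided p-value (sum of
  table probabilities no larger than the observed one) and the sample
  cross-product odds ratio, with a 0.5 Haldane shift applied only when a
  zero cell makes the ratio degenerate (display convention; p-values are
  always exact).
* Batched tests are corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClinicalOutcome",
    "BiomarkerPerformance",
    "compare_groups",
    "bh_adjust",
    "fisher_exact_2x2",
    "fisher_exact_batch",
    "cooccurrence_matrix",
    "low_expression_flag",
    "biomarker_performance",
    "time_on_treatment_compare",
]

_EXACT_RANKSUM_MAX_N = 10


@dataclass(frozen=True)
class ClinicalOutcome:
    """Treatment-response record for one tumor."""

    sample_id: str
    treatment: str  # "parpi", "carboplatin", or "other"
    psa50_response: bool | None = None
    days_on_treatment: int | None = None

    def __post_init__(self):
        if self.treatment not in ("parpi", "carboplatin", "other"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.days_on_treatment is not None and self.days_on_treatment < 0:
            raise ValueError("days_on_treatment must be non-negative")


@dataclass(frozen=True)
class BiomarkerPerformance:
    """2x2 confusion counts and the derived sensitivity/specificity."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def compare_groups(
    values: Mapping[str, float],
    group_a: Sequence[str],
    group_b: Sequence[str],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney rank-sum comparison of two disjoint sample groups.

    Returns ``(U statistic, p value)``; the U statistic is for group A.
    Exact for small tie-free samples, normal approximation (continuity and
    tie corrected) otherwise.
    """
    a_ids, b_ids = list(group_a), list(group_b)
    if set(a_ids) & set(b_ids):
        raise ValueError("groups must be disjoint")
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs at least 2 members")
    a = np.array([values[s] for s in a_ids], dtype=float)
    b = np.array([values[s] for s in b_ids], dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = (
        "exact"
        if (min(len(a), len(b)) <= _EXACT_RANKSUM_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on the table ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p)``: the sample cross-product odds ratio
    (Haldane-shifted by 0.5 in every cell when any cell is zero) and the
    exact hypergeometric p-value.
    """
    cells = (a, b, c, d)
    if min(cells) < 0 or any(int(x) != x for x in cells):
        raise ValueError("table cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(cells) == 0:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = cells
    return (a_ * d_) / (b_ * c_), float(p)


def fisher_exact_batch(
    tables: Sequence[tuple[int, int, int, int]], alternative: str = "two-sided"
) -> pd.DataFrame:
    """Fisher tests over a batch of tables with BH-adjusted q-values."""
    rows = [fisher_exact_2x2(*t, alternative=alternative) for t in tables]
    out = pd.DataFrame(rows, columns=["odds_ratio", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def cooccurrence_matrix(
    mal: pd.DataFrame,
    status: pd.Series,
    bal: pd.DataFrame | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise gene-loss co-occurrence versus a binary tumor status.

    ``mal`` is a boolean samples x genes frame of monoallelic-loss flags and
    ``status`` a boolean series on the same samples (e.g. CSig3 or iHRD
    positivity).  For every unordered gene pair the exposed set is tumors
    with *both* genes lost, tested against status by Fisher's exact test;
    the diagonal, when ``bal`` flags are given, tests biallelic loss of the
    single gene.  Pairs with zero exposed tumors are returned as untestable
    (NaN p/q).  BH correction runs over all testable pairs.
    """
    if mal.shape[1] < 2 or mal.shape[0] < 4:
        raise ValueError("need >= 2 genes and >= 4 tumors")
    status = status.reindex(mal.index)
    if status.isna().any():
        raise ValueError("status missing for some samples")
    status = status.astype(bool)

    genes = list(mal.columns)
    records = []
    for i, g1 in enumerate(genes):
        for g2 in genes[i:]:
            if g1 == g2:
                if bal is None:
                    continue
                exposed = bal[g1].reindex(mal.index).fillna(False).astype(bool)
            else:
                exposed = mal[g1].astype(bool) & mal[g2].astype(bool)
            if exposed.sum() == 0:
                records.append((g1, g2, 0, np.nan, np.nan))
                continue
            a = int((exposed & status).sum())
            b = int((exposed & ~status).sum())
            c = int((~exposed & status).sum())
            d = int((~exposed & ~status).sum())
            orat, p = fisher_exact_2x2(a, b, c, d, alternative=alternative)
            records.append((g1, g2, int(exposed.sum()), orat, p))
    out = pd.DataFrame(
        records, columns=["gene_a", "gene_b", "n_exposed", "odds_ratio", "p"]
    )
    out["q"] = np.nan
    testable = out["p"].notna()
    if testable.any():
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["testable"] = testable
    return out


def low_expression_flag(expression: pd.Series) -> pd.Series:
    """Flag samples whose expression is more than 2-fold below the gene median.

    Expression is on a log2 scale, so the rule is ``x < median - 1.0``
    (strict inequality).
    """
    expr = expression.dropna()
    if len(expr) < 3:
        raise ValueError("need expression for at least 3 samples")
    threshold = float(expr.median()) - 1.0
    return expression < threshold


def biomarker_performance(
    calls: Mapping[str, bool], responses: Mapping[str, bool]
) -> BiomarkerPerformance:
    """Exact 2x2 performance of a biomarker call against observed responses.

    Samples must be present in both mappings; the cohort needs at least one
    responder and one non-responder.
    """
    shared = sorted(set(calls) & set(responses))
    if not shared:
        raise ValueError("no samples shared between calls and responses")
    resp = np.array([bool(responses[s]) for s in shared])
    call = np.array([bool(calls[s]) for s in shared])
    if resp.all() or not resp.any():
        raise ValueError(
            "degenerate cohort: need at least one responder and one "
            "non-responder to compute sensitivity and specificity"
        )
    return BiomarkerPerformance(
        tp=int((call & resp).sum()),
        fp=int((call & ~resp).sum()),
        fn=int((~call & resp).sum()),
        tn=int((~call & ~resp).sum()),
    )


def time_on_treatment_compare(
    days: Mapping[str, float], calls: Mapping[str, bool]
) -> dict:
    """Compare treatment duration between biomarker-positive and -negative
    patients (Mann-Whitney).  Reports both medians and means — published
    group summaries do not always state which — plus a tidy per-patient
    table for swimmer plots."""
    shared = sorted(set(days) & set(calls))
    pos = [s for s in shared if calls[s]]
    neg = [s for s in shared if not calls[s]]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 patients per biomarker group")
    _, p = compare_groups({s: float(days[s]) for s in shared}, pos, neg)
    pos_days = np.array([days[s] for s in pos], dtype=float)
    neg_days = np.array([days[s] for s in neg], dtype=float)
    table = pd.DataFrame({
        "sample_id": shared,
        "biomarker_positive": [calls[s] for s in shared],
        "days_on_treatment": [days[s] for s in shared],
    }).sort_values("days_on_treatment", ascending=False, ignore_index=True)
    return {
        "median_positive": float(np.median(pos_days)),
        "median_negative": float(np.median(neg_days)),
        "mean_positive": float(pos_days.mean()),
        "mean_negative": float(neg_days.mean()),
        "n_positive": len(pos),
        "n_negative": len(neg),
        "p": p,
        "table": table,
    }
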