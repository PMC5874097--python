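"""Cohort statistics: subregion contrasts and parameter-MVD correlations.

Given the per-(tumor, region) summary table, this module runs the study's
statistical plan: Wilcoxon signed-rank tests comparing each pharmacokinetic
parameter (and MVD) between region pairs across tumors, and Pearson
correlations of each parameter with MVD within each region, plus the
combined PNA+VTA analysis in which each tumor contributes the unweighted
mean of its two perfused regions (n stays at the number of tumors).  All
p-values are two-sided; zero-difference pairs are dropped from the signed
rank test and no multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "PairedTestResult",
    "pearson",
    "wilcoxon_signed_rank",
    "combined_pna_vta",
    "run_full_analysis",
]

log = logging.getLogger(__name__)

REGIONS = ("CNA", "PNA", "VTA")
PARAMS = ("ktrans", "ve", "vp")
ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    region_set: tuple[str, ...]
    parameter: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 or not 0.0 <= self.p <= 1.0:
            raise ValueError("r must be in [-1, 1] and p in [0, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 observations")

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA


@dataclass(frozen=True)
class PairedTestResult:
    region_pair: tuple[str, str]
    quantity: str
    statistic: float   # signed-rank W (sum of ranks of the rarer sign)
    p: float
    n_pairs: int       # pairs remaining after dropping zero differences
    degenerate: bool = False


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-distribution p-value.

    Requires >= 3 finite paired observations; zero variance in either
    variable leaves r undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for a zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign patterns, mid-ranked ties included.

    Doubled ranks are integers even under mid-ranking, so the permutation
    distribution of 2*W+ is built by dynamic programming (one convolution
    per rank) instead of explicit enumeration.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for rk in r2:
        shifted = np.zeros_like(counts)
        shifted[rk:] = counts[: total + 1 - rk]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(a, b) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; rank ties are mid-ranked.  The exact
    permutation distribution (ties included) is used up to 25 effective
    pairs; beyond that the tie-corrected normal approximation takes over
    (scipy).  All differences zero is a degenerate comparison, flagged
    rather than raised.  The statistic is min(W+, W-), scipy's two-sided
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = (a - b)[a != b]
    n_pairs = d.size
    if n_pairs == 0:
        return PairedTestResult(("", ""), "", float("nan"), float("nan"), 0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    if n_pairs <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(
            sps.wilcoxon(d, zero_method="wilcox", correction=False, method="approx").pvalue
        )
    return PairedTestResult(("", ""), "", min(w_plus, w_minus), p, n_pairs)


def combined_pna_vta(records: pd.DataFrame, mode: str = "mean") -> pd.DataFrame:
    """Combine each tumor's PNA and VTA rows for the two-region analysis.

    ``mode="mean"`` (the primary analysis): per tumor, the unweighted mean
    of its PNA and VTA values for each parameter and for MVD — one row per
    tumor.  ``mode="pooled"`` concatenates the PNA and VTA rows (2n rows)
    for sensitivity analysis.  Tumors missing either region are excluded
    with a warning.
    """
    pv = records[records.region.isin(["PNA", "VTA"])]
    counts = pv.groupby("tumor_id").region.nunique()
    complete = counts[counts == 2].index
    dropped = sorted(set(pv.tumor_id) - set(complete))
    if dropped:
        log.warning("tumors missing a PNA or VTA row excluded from combined analysis: %s", dropped)
    pv = pv[pv.tumor_id.isin(complete)]
    if mode == "pooled":
        return pv.reset_index(drop=True)
    if mode != "mean":
        raise ValueError("mode must be 'mean' or 'pooled'")
    cols = [c for c in ("ktrans", "ve", "vp", "mvd") if c in pv.columns]
    out = pv.groupby("tumor_id", as_index=False)[cols].mean()
    out.insert(1, "region", "PNA+VTA")
    return out


def run_full_analysis(records: pd.DataFrame, mode: str = "mean"):
    """All paired contrasts and MVD correlations for a summary table.

    Returns ``(correlations, paired_tests, report)``: two tidy DataFrames
    and a human-readable text report.  Correlations cover each parameter
    against MVD within CNA, PNA, VTA and the combined PNA+VTA set; paired
    tests cover each parameter and MVD for the three region pairs.
    """
    wide = records.pivot_table(index="tumor_id", columns="region",
                               values=["ktrans", "ve", "vp", "mvd"])
    paired_rows = []
    for q in (*PARAMS, "mvd"):
        for a, b in itertools.combinations(REGIONS, 2):
            res = wilcoxon_signed_rank(wide[(q, a)].to_numpy(), wide[(q, b)].to_numpy())
            paired_rows.append({
                "quantity": q, "region_a": a, "region_b": b,
                "W": res.statistic, "p": res.p, "n_pairs": res.n_pairs,
                "degenerate": res.degenerate,
            })
    paired = pd.DataFrame(paired_rows)

    combined = combined_pna_vta(records, mode=mode)
    corr_rows = []
    for region in (*REGIONS, "PNA+VTA"):
        sub = combined if region == "PNA+VTA" else records[records.region == region]
        for p in PARAMS:
            r, pv = pearson(sub[p].to_numpy(), sub["mvd"].to_numpy())
            corr_rows.append({
                "region_set": region, "parameter": p, "r": r, "p": pv, "n": len(sub),
                "significant": pv <= ALPHA,
            })
    corr = pd.DataFrame(corr_rows)

    lines = ["Parameter-MVD correlations (Pearson, two-sided):"]
    for row in corr.itertuples():
        star = " *" if row.significant else ""
        lines.append(
            f"  {row.region_set:8s} {row.parameter:6s} r={row.r:+.4f} p={row.p:.4f} n={row.n}{star}"
        )
    lines.append("Subregion contrasts (Wilcoxon signed-rank, two-sided):")
    for row in paired.itertuples():
        lines.append(
            f"  {row.quantity:6s} {row.region_a} vs {row.region_b}: W={row.W:.1f} "
            f"p={row.p:.5f} (n={row.n_pairs})"
        )
    return corr, paired, "\n".join(lines)
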