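"""Clinical characterization and healthy-control contextualization.

Symptom change scores (follow-up minus baseline; negative = improvement),
CGI-I category summaries, paired and two-sample nonparametric tests with
Benjamini-Hochberg FDR, extreme-responder stratification, overlap-voxel
masks, and the six-cell Mann-Whitney comparison of FND vs healthy-control
mean connectivity values.

scipy.stats and statsmodels supply the test engines; this module fixes the
conventions (two-sided tests, zero-difference pairs dropped with midrank
ties for Wilcoxon so a signed z is reported, tie-corrected normal
approximation for Mann-Whitney, exact binomial McNemar for < 25 discordant
pairs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "change_score",
    "summarize_cgi",
    "paired_test",
    "mann_whitney_u",
    "bh_fdr",
    "stratify_extremes",
    "overlap_mask",
    "hc_contextualize",
    "spearman_assoc",
]

T_CAP = 1e6


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    n: int
    df: int | None = None
    flag: str = ""


def change_score(follow_total, base_total) -> float:
    """Follow-up minus baseline total; negative = improvement.

    Missing values propagate as NaN so the row can be excluded from change
    analyses.
    """
    if follow_total is None or base_total is None:
        return float("nan")
    f, b = float(follow_total), float(base_total)
    if math.isnan(f) or math.isnan(b):
        return float("nan")
    return f - b


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


def summarize_cgi(category_counts) -> dict[str, float]:
    """Percent improved / unchanged / worsened from CGI-I category counts.

    ``category_counts`` is (much improved, improved, unchanged, worse,
    much worse).  "Improved" aggregates much improved + improved and
    "worsened" aggregates worse + much worse.  Improved and unchanged
    percents are rounded half-up to 1 decimal; the worsened percent is the
    complement to 100.0, so the three categories always partition the
    cohort exactly (19/10/3 of 32 prints as 59.4 / 31.3 / 9.3).
    """
    counts = [int(c) for c in category_counts]
    if len(counts) != 5 or any(c < 0 for c in counts):
        raise ValueError("need 5 nonnegative category counts")
    total = sum(counts)
    if total == 0:
        raise ValueError("total count is zero")
    improved = _round_half_up(100.0 * (counts[0] + counts[1]) / total)
    unchanged = _round_half_up(100.0 * counts[2] / total)
    worsened = round(100.0 - improved - unchanged, 1)
    return {"improved": improved, "unchanged": unchanged, "worsened": worsened}


def paired_test(x_base, x_follow, method: str) -> TestResult:
    """Two-sided paired test of follow-up vs baseline.

    method:
      ``wilcoxon_signed_rank`` — zero differences dropped, midrank ties,
        normal approximation (signed z reported);
      ``paired_t`` — t with df = n - 1;
      ``mcnemar`` — paired binary; exact binomial on discordant pairs when
        < 25 discordants, chi-square otherwise.
    """
    a = np.asarray(x_base, dtype=float)
    b = np.asarray(x_follow, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    n = len(a)

    if method == "wilcoxon_signed_rank":
        if n < 5:
            raise ValueError("need n >= 5 pairs")
        d = b - a
        if np.all(d == 0):
            return TestResult("wilcoxon_signed_rank", 0.0, 1.0, n,
                              flag="all differences zero")
        res = stats.wilcoxon(b, a, zero_method="wilcox", correction=False,
                             method="approx")
        return TestResult("wilcoxon_signed_rank", float(res.zstatistic),
                          float(res.pvalue), n)

    if method == "paired_t":
        if n < 5:
            raise ValueError("need n >= 5 pairs")
        d = b - a
        if d.std(ddof=1) == 0:
            t = 0.0 if d.mean() == 0 else math.copysign(T_CAP, d.mean())
            p = 1.0 if t == 0 else 0.0
            return TestResult("paired_t", t, p, n, df=n - 1,
                              flag="zero-variance differences")
        res = stats.ttest_rel(b, a)
        return TestResult("paired_t", float(res.statistic), float(res.pvalue),
                          n, df=n - 1)

    if method == "mcnemar":
        a_bin, b_bin = a.astype(int), b.astype(int)
        if not set(np.unique(np.concatenate([a_bin, b_bin]))) <= {0, 1}:
            raise ValueError("mcnemar requires paired binary data")
        table = np.zeros((2, 2), dtype=int)
        for i in range(n):
            table[a_bin[i], b_bin[i]] += 1
        discordant = table[0, 1] + table[1, 0]
        exact = discordant < 25
        res = _sm_mcnemar(table, exact=exact, correction=not exact)
        return TestResult("mcnemar", float(res.statistic), float(res.pvalue), n,
                          flag="" if discordant else "no discordant pairs")

    raise ValueError(f"unknown paired test method {method!r}")


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U with midrank ties and tie-corrected normal
    approximation; U is reported for the first sample."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      len(a) + len(b))


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def stratify_extremes(
    change_scores, subject_ids=None, fraction: float = 0.2
) -> tuple[list, list]:
    """Top/bottom extreme responders: (most improved, most worsened) ids.

    k = floor(n * fraction), at least 1.  Most improved = k most negative
    change scores (lower questionnaire totals are better); most worsened =
    k most positive.  Ties break by subject-id order with a warning.
    """
    scores = np.asarray(change_scores, dtype=float)
    n = len(scores)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    ids = list(range(n)) if subject_ids is None else list(subject_ids)
    k = max(1, int(np.floor(n * fraction)))
    order = np.argsort(scores, kind="stable")  # stable = id-order tiebreak
    worsened_order = np.argsort(-scores, kind="stable")
    improved = [ids[i] for i in order[:k]]
    worsened = [ids[i] for i in worsened_order[:k]]
    # warn when the selection boundary is tied
    if (scores[order[k - 1]] == scores[order[k]]
            or scores[worsened_order[k - 1]] == scores[worsened_order[k]]):
        warnings.warn("tied change scores at the stratification boundary; "
                      "selection uses subject-id order", RuntimeWarning,
                      stacklevel=2)
    return improved, worsened


def overlap_mask(baseline_sig: np.ndarray, longitudinal_sig: np.ndarray) -> np.ndarray:
    """Voxels significant in both the baseline-predictor and longitudinal
    change analyses."""
    if baseline_sig.shape != longitudinal_sig.shape:
        raise ValueError("masks are on different grids")
    return baseline_sig & longitudinal_sig


def hc_contextualize(
    fnd_values_base,
    fnd_values_follow,
    hc_values,
    improved_idx,
    worsened_idx,
) -> pd.DataFrame:
    """Mann-Whitney tests of FND vs HC overlap-voxel means.

    Six cells: {full cohort, most-improved stratum, most-worsened stratum}
    x {baseline, follow-up} against the same HC sample.  Empty strata are
    flagged not-computed.
    """
    hc = np.asarray(hc_values, dtype=float)
    if len(hc) == 0:
        raise ValueError("HC sample is empty")
    base = np.asarray(fnd_values_base, dtype=float)
    follow = np.asarray(fnd_values_follow, dtype=float)
    strata = {
        "full": np.arange(len(base)),
        "most_improved": np.asarray(improved_idx, dtype=int),
        "most_worsened": np.asarray(worsened_idx, dtype=int),
    }
    rows = []
    for name, idx in strata.items():
        for tp, vals in (("baseline", base), ("followup", follow)):
            sel = vals[idx]
            sel = sel[~np.isnan(sel)]
            if len(sel) == 0:
                rows.append({"stratum": name, "timepoint": tp, "U": np.nan,
                             "p": np.nan, "n_fnd": 0, "n_hc": len(hc),
                             "flag": "empty stratum"})
                continue
            res = mann_whitney_u(sel, hc)
            rows.append({"stratum": name, "timepoint": tp,
                         "U": res.statistic, "p": res.p,
                         "n_fnd": len(sel), "n_hc": len(hc), "flag": ""})
    return pd.DataFrame(rows)


def spearman_assoc(x, y) -> TestResult:
    """Spearman rank correlation (midranks), two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult("spearman", float("nan"), float("nan"), len(x),
                          flag="zero-variance input")
    rho, p = stats.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), len(x))
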