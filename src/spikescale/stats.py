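"""Descriptive statistics for area comparisons.

Bootstrap confidence intervals on medians, Mann-Whitney U / Wilcoxon
signed-rank group comparisons with Bonferroni correction, and the
correlation of per-area medians with the anatomical hierarchy score.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def median_ci_bootstrap(
    values,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile-bootstrap confidence interval on the median."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    med = float(np.median(v))
    if v.size == 1:
        return med, med, med
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    boot = np.median(v[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return med, float(lo), float(hi)


#: below this per-group size the Mann-Whitney p-value is computed exactly
EXACT_N = 20


def group_compare(
    a,
    b,
    paired: bool = False,
    family_size: int = 1,
) -> dict:
    """Two-sided nonparametric comparison of two samples.

    Unpaired: Mann-Whitney U (exact p for groups of <= 20 without ties,
    normal approximation with tie correction above).  Paired: Wilcoxon
    signed-rank on matched values.  The Bonferroni-adjusted p-value is
    min(1, p * family_size) and the effect summary is the relative median
    difference (median(b) - median(a)) / median(a).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison needs equal lengths")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    delta = (med_b - med_a) / med_a if med_a != 0 else np.nan
    out = {
        "test": "wilcoxon" if paired else "mannwhitneyu",
        "median_a": med_a,
        "median_b": med_b,
        "delta_rel": delta,
        "family_size": int(family_size),
    }
    if paired:
        diffs = b - a
        if np.all(diffs == 0):
            out.update(stat=np.nan, p=np.nan, p_adj=np.nan,
                       note="all paired differences tied; p undefined")
            return out
        stat, p = sps.wilcoxon(a, b, alternative="two-sided")
    else:
        method = "exact" if max(len(a), len(b)) <= EXACT_N else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    out.update(stat=float(stat), p=float(p), p_adj=float(min(1.0, p * family_size)))
    return out


def hierarchy_correlation(area_medians, scores) -> dict:
    """Pearson/Spearman correlation of area medians with hierarchy scores.

    Also returns the ordinary least-squares line through the
    (score, median) pairs.  Zero-variance medians are reported as undefined
    rather than raising.
    """
    med = np.asarray(area_medians, dtype=float)
    hs = np.asarray(scores, dtype=float)
    if len(med) != len(hs) or len(med) < 3:
        raise ValueError("need >= 3 (median, score) pairs")
    if np.ptp(med) == 0 or np.ptp(hs) == 0:
        return {
            "r_pearson": np.nan, "p_pearson": np.nan,
            "r_spearman": np.nan, "p_spearman": np.nan,
            "slope": np.nan, "intercept": np.nan,
            "note": "zero variance; correlation undefined",
        }
    rp = sps.pearsonr(hs, med)
    rs = sps.spearmanr(hs, med)
    lin = sps.linregress(hs, med)
    return {
        "r_pearson": float(rp.statistic), "p_pearson": float(rp.pvalue),
        "r_spearman": float(rs.statistic), "p_spearman": float(rs.pvalue),
        "slope": float(lin.slope), "intercept": float(lin.intercept),
    }
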