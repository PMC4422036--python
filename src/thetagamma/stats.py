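"""Statistical battery: normality-gated rank tests with corrections.

The testing scheme mirrors common practice for within/between-group
comparisons of normalized electrophysiological measures: an
Anderson-Darling normality gate routes each comparison to a parametric
t-test or to rank statistics (Wilcoxon rank-sum between groups,
Kruskal-Wallis across time windows with a Tukey-type rank post hoc and
Bonferroni-corrected thresholds, Friedman for repeated-measures
relationships).  Effect sizes for rank tests are r = Z / sqrt(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "normality_gate",
    "rank_between",
    "t_between",
    "gated_between",
    "kw_within",
    "friedman_relationship",
    "bonferroni",
]


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    p: float
    df: float | None = None
    alpha_corrected: float = 0.05
    significant: bool = False
    effect_r: float | None = None
    z: float | None = None
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


def bonferroni(alpha: float, m_comparisons: int) -> float:
    """Corrected per-comparison threshold alpha / m."""
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    return alpha / m_comparisons


def normality_gate(sample: np.ndarray, alpha: float = 0.05) -> str:
    """Route a sample to ``"parametric"`` or ``"nonparametric"`` via the
    Anderson-Darling normality test at the 5% level.  Samples with n < 8 or
    zero variance default to nonparametric with a warning."""
    x = np.asarray(sample, float)
    if len(x) < 8:
        warnings.warn("sample too small for the normality gate; defaulting "
                      "to nonparametric", stacklevel=2)
        return "nonparametric"
    if np.ptp(x) == 0:
        warnings.warn("degenerate (constant) sample; defaulting to "
                      "nonparametric", stacklevel=2)
        return "nonparametric"
    with warnings.catch_warnings():
        # scipy >= 1.17 deprecation chatter about p-value methods; the
        # critical-value gate below is version-stable
        warnings.simplefilter("ignore", FutureWarning)
        res = sps.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, float)
    idx = int(np.argmin(np.abs(levels - 100.0 * alpha)))
    crit = res.critical_values[idx]
    return "nonparametric" if res.statistic > crit else "parametric"


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U of the first sample and its tie-corrected normal
    deviate with continuity correction."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1.0)) if n > 1 else 0
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return u1, 0.0
    diff = u1 - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    return u1, (diff - cc) / np.sqrt(var)


def rank_between(group_a: np.ndarray, group_b: np.ndarray,
                 alpha: float = 0.05, m_comparisons: int = 1
                 ) -> GroupComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney) between independent groups.

    Reports the rank statistic W (the first group's U), the tie-corrected
    normal deviate Z with continuity correction, the two-sided asymptotic
    p, and the effect size r = Z / sqrt(N)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    w, z = _rank_sum_z(a, b)
    p = 2.0 * sps.norm.sf(abs(z))
    n = len(a) + len(b)
    thr = bonferroni(alpha, m_comparisons)
    return GroupComparisonResult(test="wilcoxon_rank_sum", statistic=float(w),
                                 p=float(p), alpha_corrected=thr,
                                 significant=bool(p < thr),
                                 effect_r=float(z / np.sqrt(n)), z=float(z))


def t_between(group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05,
              m_comparisons: int = 1) -> GroupComparisonResult:
    """Two-sample t-test (the parametric route of the gate)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    t, p = sps.ttest_ind(a, b)
    thr = bonferroni(alpha, m_comparisons)
    return GroupComparisonResult(test="t_test", statistic=float(t),
                                 p=float(p), df=float(len(a) + len(b) - 2),
                                 alpha_corrected=thr,
                                 significant=bool(p < thr))


def gated_between(group_a: np.ndarray, group_b: np.ndarray,
                  alpha: float = 0.05, m_comparisons: int = 1
                  ) -> GroupComparisonResult:
    """Normality-gated between-group comparison: t-test when both samples
    pass the Anderson-Darling gate, rank-sum otherwise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        routes = {normality_gate(group_a, alpha),
                  normality_gate(group_b, alpha)}
    if routes == {"parametric"}:
        return t_between(group_a, group_b, alpha, m_comparisons)
    return rank_between(group_a, group_b, alpha, m_comparisons)


def kw_within(samples: list[np.ndarray], alpha: float = 0.05,
              posthoc: str = "nemenyi", baseline_index: int = 0,
              labels: list[str] | None = None) -> GroupComparisonResult:
    """Kruskal-Wallis across >= 3 groups (e.g. time windows) with a
    Tukey-type rank post hoc.

    The post hoc compares mean ranks pairwise: ``"nemenyi"`` uses the
    studentized range distribution, ``"conover"`` t-statistics on ranks;
    post hoc flags are Bonferroni-corrected.  Groups with n < 2 are
    excluded with a warning.  The table carries a ``vs_baseline`` flag so
    per-cell significance against the baseline window can be drawn."""
    if posthoc not in ("nemenyi", "conover"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    groups = [np.asarray(g, float) for g in samples]
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    keep = [i for i, g in enumerate(groups) if len(g) >= 2]
    if len(keep) < len(groups):
        warnings.warn("groups with n < 2 excluded from Kruskal-Wallis",
                      stacklevel=2)
        baseline_label = labels[baseline_index]
        groups = [groups[i] for i in keep]
        labels = [labels[i] for i in keep]
        baseline_index = labels.index(baseline_label) \
            if baseline_label in labels else 0
    k = len(groups)
    if k < 3:
        raise ValueError("need >= 3 groups for Kruskal-Wallis")
    h, p = sps.kruskal(*groups)

    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    splits = np.cumsum(ns)[:-1]
    mean_ranks = np.array([r.mean() for r in np.split(ranks, splits)])

    m_pairs = k * (k - 1) // 2
    thr = bonferroni(alpha, m_pairs)
    rows = []
    if posthoc == "nemenyi":
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(n * (n + 1) / 12.0 * (1 / ns[i] + 1 / ns[j]))
                q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
                pij = float(sps.studentized_range.sf(q, k, np.inf))
                rows.append((labels[i], labels[j], q, pij))
    else:                                # Conover: t on ranks
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
        s2 = (n * (n + 1) / 12.0) * tie
        denom_df = n - k
        s2_adj = s2 * (n - 1 - h) / max(denom_df, 1)
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(s2_adj * (1 / ns[i] + 1 / ns[j]))
                t = abs(mean_ranks[i] - mean_ranks[j]) / se
                pij = float(2.0 * sps.t.sf(t, denom_df))
                rows.append((labels[i], labels[j], t, pij))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic",
                                        "p"])
    table["significant"] = table["p"] < thr
    base = labels[baseline_index]
    table["vs_baseline"] = ((table["group_a"] == base)
                            | (table["group_b"] == base))
    return GroupComparisonResult(test=f"kruskal_wallis+{posthoc}",
                                 statistic=float(h), p=float(p),
                                 df=float(k - 1), alpha_corrected=thr,
                                 significant=bool(p < alpha),
                                 posthoc=table)


def friedman_relationship(series: list[np.ndarray],
                          orientation: str = "epochs_as_treatments",
                          alpha: float = 0.05) -> GroupComparisonResult:
    """Friedman test for a relationship among repeated-measure series.

    ``series`` is a list of aligned sequences (e.g. relative theta power,
    relative gamma power and relative coupling over the 10 HFS epochs).
    With the default orientation the aligned positions (epochs) are the
    treatments and the series the blocks, giving df = n_epochs - 1 -- the
    convention matching a chi-square with df 9 over 10 HFS epochs.  The
    ``"series_as_treatments"`` orientation is the textbook one
    (df = n_series - 1)."""
    arrays = [np.asarray(s, float) for s in series]
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ValueError("series must be aligned (equal lengths)")
    mat = np.vstack(arrays)              # series x positions
    if orientation == "epochs_as_treatments":
        treatments = [mat[:, j] for j in range(mat.shape[1])]
    elif orientation == "series_as_treatments":
        treatments = [mat[i, :] for i in range(mat.shape[0])]
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    k = len(treatments)
    blocks = np.column_stack(treatments)     # blocks x treatments
    if np.all(np.ptp(blocks, axis=1) == 0):
        chi2, p = 0.0, 1.0                   # every block fully tied
    else:
        chi2, p = sps.friedmanchisquare(*treatments)
    return GroupComparisonResult(test="friedman", statistic=float(chi2),
                                 p=float(p), df=float(k - 1),
                                 alpha_corrected=alpha,
                                 significant=bool(p < alpha))
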