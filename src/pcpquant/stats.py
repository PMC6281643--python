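"""Shared statistical decision tree and small closed-form computations.

Two-group comparisons follow a normality gate: D'Agostino-Pearson on each
group, Student's unpaired two-tailed t-test when both groups look normal,
Mann-Whitney otherwise (and always for groups too small for the normality
test).  Multi-group comparisons use Kruskal-Wallis with Dunn's multiple
comparisons; 2x2 docking tables use Fisher's exact test.  Relative mRNA
expression is the 2^dCt transform with dCt = Ct(reference) - Ct(gene), and
reporter activity the Renilla-normalised firefly signal relative to a
control ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "KruskalDunnResult",
    "FisherResult",
    "ExpressionRecord",
    "compare_two_groups",
    "kruskal_dunn",
    "fisher_exact",
    "rel_expression",
    "luciferase_fold",
]

MIN_N_NORMALITY = 8  # below this, D'Agostino-Pearson is unreliable; use ranks


@dataclass(frozen=True)
class GroupComparisonResult:
    test_name: str  # "t_unpaired_two_tailed" | "mann_whitney"
    statistic: float
    p_value: float
    normality_p: tuple  # per-group D'Agostino-Pearson p (None when skipped)
    alpha: float
    significant: bool
    note: str = ""


@dataclass(frozen=True)
class KruskalDunnResult:
    statistic: float
    p_value: float
    pairs: pd.DataFrame  # group_a, group_b, z, p_unadjusted, p_adjusted
    adjust: str
    alpha: float


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    degenerate: bool = False  # a zero margin: p = 1 by convention


@dataclass(frozen=True)
class ExpressionRecord:
    """Relative expression 2^dCt with dCt = Ct(reference) - Ct(gene)."""

    gene: str
    ct_gene: float
    ct_reference: float
    delta_ct: float
    rel_expression: float


def compare_two_groups(a, b, alpha: float = 0.05) -> GroupComparisonResult:
    """Normality-gated two-group comparison (two-sided).

    With n >= 8 in both groups, D'Agostino-Pearson is run per group; if
    either group rejects normality at ``alpha`` the groups are compared with
    Mann-Whitney, otherwise with the unpaired two-tailed t-test.  Smaller
    groups skip the gate and fall back to Mann-Whitney (noted in the
    result).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    note = ""
    if a.size >= MIN_N_NORMALITY and b.size >= MIN_N_NORMALITY:
        p_norm = (float(sps.normaltest(a).pvalue), float(sps.normaltest(b).pvalue))
        use_ranks = min(p_norm) < alpha
    else:
        p_norm = (None, None)
        use_ranks = True
        note = f"group below n={MIN_N_NORMALITY}: normality gate skipped, rank test used"
    if use_ranks:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        name = "mann_whitney"
    else:
        res = sps.ttest_ind(a, b, alternative="two-sided")
        name = "t_unpaired_two_tailed"
    p = float(res.pvalue)
    return GroupComparisonResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=p,
        normality_p=p_norm,
        alpha=alpha,
        significant=bool(p < alpha),
        note=note,
    )


def kruskal_dunn(groups, alpha: float = 0.05, adjust: str = "bonferroni") -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn's pairwise z comparisons.

    ``groups`` is a mapping of label -> sample or a sequence of samples.
    Dunn's z uses the pooled mid-ranks with tie correction; pairwise p's are
    adjusted over all tested pairs (Bonferroni by default, 'none' to skip).
    """
    if isinstance(groups, dict):
        labels = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        labels = list(range(len(samples)))
    if len(samples) < 3:
        raise ValueError("kruskal_dunn needs at least 3 groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")
    stat, p_omni = sps.kruskal(*samples)

    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction term for the Dunn z variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + s.size].mean())
        sizes.append(s.size)
        start += s.size
    n_pairs = len(samples) * (len(samples) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        p_unadj = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_unadj * n_pairs)
        elif adjust == "none":
            p_adj = p_unadj
        else:
            raise ValueError("adjust must be 'bonferroni' or 'none'")
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_unadjusted": float(p_unadj),
                "p_adjusted": float(p_adj),
            }
        )
    return KruskalDunnResult(
        statistic=float(stat),
        p_value=float(p_omni),
        pairs=pd.DataFrame(rows),
        adjust=adjust,
        alpha=alpha,
    )


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table of non-negative counts.

    The two-sided p sums hypergeometric probabilities of tables (at fixed
    margins) no more probable than the observed one.  A zero margin makes
    the table degenerate: p = 1 by convention, flagged in the result.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_float = np.asarray(table, dtype=float)
        if np.any(t_float < 0) or np.any(t_float != np.round(t_float)):
            raise ValueError("counts must be non-negative integers")
        t = t_float.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        a, b, c, d = t.ravel()
        odds = np.nan if (b * c == 0) else (a * d) / (b * c)
        return FisherResult(p_value=1.0, odds_ratio=float(odds), degenerate=True)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return FisherResult(p_value=float(p), odds_ratio=float(odds))


def rel_expression(ct_gene: float, ct_reference: float, gene: str = "") -> ExpressionRecord:
    """Relative mRNA expression as 2^dCt, dCt = Ct(reference) - Ct(gene)."""
    if not (np.isfinite(ct_gene) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    delta = float(ct_reference - ct_gene)
    return ExpressionRecord(
        gene=gene,
        ct_gene=float(ct_gene),
        ct_reference=float(ct_reference),
        delta_ct=delta,
        rel_expression=float(2.0**delta),
    )


def luciferase_fold(firefly: float, renilla: float, control_ratio: float) -> float:
    """Renilla-normalised firefly activity relative to a control ratio."""
    if renilla <= 0:
        raise ValueError("renilla reading must be > 0")
    if control_ratio <= 0:
        raise ValueError("control_ratio must be > 0")
    return float((firefly / renilla) / control_ratio)
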