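"""Expression-level statistics: normalisation, differential expression,
over-representation analysis, module-score aggregation and distribution-gated
group comparisons.

Differential expression between niche classes uses the two-sided Wilcoxon
rank-sum test with Benjamini-Hochberg adjustment; significance is declared
at |log fold change| >= 0.25 (inclusive) and adjusted p < 0.05 (strict),
the conventional spot/cell-level cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

log = logging.getLogger(__name__)

#: combined sample size below which the exact rank-sum null is enumerated
EXACT_N_MAX = 20


def log_normalize(counts, scale: float = 1e4):
    """log1p(count * scale / spot_total), the standard log-normalisation.

    Accepts a dense/sparse matrix (spots x genes) and returns a dense float
    array. Zero-total spots yield an all-zero row (flagged via logging).
    """
    X = np.asarray(sp.csr_matrix(counts).todense(), dtype=float) \
        if sp.issparse(counts) else np.asarray(counts, dtype=float)
    if (X < 0).any():
        raise ValidationError("counts must be nonnegative")
    totals = X.sum(axis=1, keepdims=True)
    n_zero = int((totals == 0).sum())
    if n_zero:
        log.warning("%d zero-total spots normalised to all-zero rows", n_zero)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(X * (scale / safe))


@dataclass
class DERecord:
    gene: str
    log_fc: float
    p: float
    p_adj: float = np.nan
    pct_a: float = np.nan
    pct_b: float = np.nan


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_de(log_expr: np.ndarray, genes, group_mask) -> list[DERecord]:
    """Per-gene two-sided Wilcoxon rank-sum between two spot groups.

    ``group_mask`` is boolean (True = group A). log_fc is the difference of
    group means of log-normalised expression (group A minus group B). The
    exact null is enumerated when the combined sample size is below 20,
    otherwise the tie-corrected normal approximation with continuity
    correction is used. Genes expressed in neither group are skipped.
    """
    log_expr = np.asarray(log_expr, dtype=float)
    mask = np.asarray(group_mask, dtype=bool)
    n_a, n_b = int(mask.sum()), int((~mask).sum())
    if n_a < 3 or n_b < 3:
        raise ValidationError("each group needs >= 3 spots")
    A, B = log_expr[mask], log_expr[~mask]
    expressed = (A > 0).any(axis=0) | (B > 0).any(axis=0)
    n_skipped = int((~expressed).sum())
    if n_skipped:
        log.info("wilcoxon_de: skipping %d genes expressed in neither group",
                 n_skipped)
    idx = np.flatnonzero(expressed)
    if idx.size == 0:
        return []
    method = "exact" if n_a + n_b < EXACT_N_MAX else "asymptotic"
    res = scipy.stats.mannwhitneyu(A[:, idx], B[:, idx], axis=0,
                                   alternative="two-sided", method=method)
    pvals = np.minimum(np.atleast_1d(res.pvalue), 1.0)
    p_adj = bh_adjust(pvals)
    lfc = A[:, idx].mean(axis=0) - B[:, idx].mean(axis=0)
    pct_a = (A[:, idx] > 0).mean(axis=0)
    pct_b = (B[:, idx] > 0).mean(axis=0)
    genes = np.asarray(genes)
    return [
        DERecord(gene=str(genes[j]), log_fc=float(lfc[k]), p=float(pvals[k]),
                 p_adj=float(p_adj[k]), pct_a=float(pct_a[k]),
                 pct_b=float(pct_b[k]))
        for k, j in enumerate(idx)
    ]


def filter_de(records, lfc_min: float = 0.25, alpha: float = 0.05):
    """Keep records with |log_fc| >= lfc_min and p_adj < alpha.

    The fold-change cut is inclusive ("at least") and the significance cut
    strict ("below"). Returns (up, down) split by log_fc sign.
    """
    kept = [r for r in records
            if abs(r.log_fc) >= lfc_min and r.p_adj < alpha]
    up = [r for r in kept if r.log_fc > 0]
    down = [r for r in kept if r.log_fc < 0]
    return up, down


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    gene_ratio: float
    p: float
    p_adj: float = np.nan


def hypergeom_enrich(query_genes, signature_sets, universe) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric over-representation against flat gene sets.

    Sets are intersected with the universe; p = P(overlap >= observed);
    BH across sets. Records are sorted by gene_ratio (descending) then
    p_adj (ascending).
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValidationError("empty universe")
    uni = set(universe)
    query = [g for g in dict.fromkeys(query_genes)]
    outside = [g for g in query if g not in uni]
    if outside:
        raise ValidationError(
            f"query genes outside universe: {outside[:5]}"
        )
    n = len(query)
    N_u = len(universe)
    qset = set(query)
    records = []
    for name, genes in signature_sets.items():
        members = [g for g in genes if g in uni]
        K = len(members)
        k = len(qset.intersection(members))
        # P(X >= k) with X ~ Hypergeom(N_u, K, n)
        p = float(scipy.stats.hypergeom.sf(k - 1, N_u, K, n)) if K else 1.0
        records.append(EnrichmentRecord(
            set_name=name, overlap=k, set_size=K, query_size=n,
            universe_size=N_u, gene_ratio=(k / n if n else 0.0), p=min(p, 1.0),
        ))
    p_adj = bh_adjust([r.p for r in records])
    for r, q in zip(records, p_adj):
        r.p_adj = float(q)
    records.sort(key=lambda r: (-r.gene_ratio, r.p_adj, r.set_name))
    return records


def module_score_summary(scores: pd.DataFrame, calls: pd.DataFrame,
                         obs: pd.DataFrame, min_spots: int = 5) -> pd.DataFrame:
    """Mean module score per (sample, layer, niche) cell.

    ``scores``: spot x module DataFrame; ``calls`` must carry a ``label``
    column; ``obs`` supplies sample and layer. Cells with fewer than
    ``min_spots`` spots are flagged low_n.
    """
    df = pd.concat(
        [obs[["sample", "layer"]], calls[["label"]], scores], axis=1,
        join="inner",
    )
    modules = list(scores.columns)
    grouped = df.groupby(["sample", "layer", "label"], observed=True)
    out = grouped[modules].mean()
    out["n_spots"] = grouped.size()
    out["low_n"] = out["n_spots"] < min_spots
    return out.reset_index()


@dataclass
class GroupTestResult:
    test: str  # t | wilcoxon | anova_tukey | kruskal_wilcoxon
    statistic: float
    p: float
    normality_p: dict[str, float] = field(default_factory=dict)
    forced_nonparametric: bool = False
    pairwise: pd.DataFrame | None = None


def _shapiro_p(x) -> float:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:  # constant sample: trivially non-normal
        return 0.0
    return float(scipy.stats.shapiro(x).pvalue)


def compare_groups(values, group_labels, alpha_normal: float = 0.05
                   ) -> GroupTestResult:
    """Normality-gated group comparison.

    Each group is screened with Shapiro-Wilk; if every group looks normal
    (p >= alpha_normal) the parametric branch runs (t-test for two groups,
    one-way ANOVA with Tukey HSD for more), otherwise the nonparametric one
    (Wilcoxon rank-sum; Kruskal-Wallis with pairwise rank-sum tests,
    BH-adjusted within the post-hoc family). Groups smaller than 3 force
    the nonparametric branch.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    groups = [values[labels == g] for g in names]
    forced = any(len(g) < 3 for g in groups)
    normality = {} if forced else {
        str(name): _shapiro_p(g) for name, g in zip(names, groups)
    }
    normal = (not forced) and all(p >= alpha_normal
                                  for p in normality.values())

    if len(names) == 2:
        a, b = groups
        if normal:
            stat, p = scipy.stats.ttest_ind(a, b)
            return GroupTestResult("t", float(stat), float(p), normality)
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupTestResult("wilcoxon", float(res.statistic),
                               float(res.pvalue), normality, forced)
    if normal:
        stat, p = scipy.stats.f_oneway(*groups)
        tukey = scipy.stats.tukey_hsd(*groups)
        pairs = [
            (str(names[i]), str(names[j]), float(tukey.pvalue[i, j]))
            for i in range(len(names)) for j in range(i + 1, len(names))
        ]
        table = pd.DataFrame(pairs, columns=["group_a", "group_b", "p_adj"])
        return GroupTestResult("anova_tukey", float(stat), float(p),
                               normality, pairwise=table)
    stat, p = scipy.stats.kruskal(*groups)
    raw = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = scipy.stats.mannwhitneyu(groups[i], groups[j],
                                         alternative="two-sided")
            raw.append((str(names[i]), str(names[j]), float(r.pvalue)))
    table = pd.DataFrame(raw, columns=["group_a", "group_b", "p"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return GroupTestResult("kruskal_wilcoxon", float(stat), float(p),
                           normality, forced, table)
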