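"""Joining binding sites to expression data.

Differential-expression status filters, control-day-5 normalization,
two-cluster structure of putative target genes, per-day lncRNA-target
Pearson correlation, and the neural-candidate screen. Expression
matrices are pandas DataFrames (genes x samples) with a sidecar sample
metadata table (condition CON/KD, day, replicate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "de_status",
    "de_status_table",
    "normalize_to_control_day5",
    "cluster_targets",
    "lnc_target_correlation",
    "correlation_report",
    "screen_candidates",
    "validate_metadata",
]

DEFAULT_FDR_CUT = 0.05
DEFAULT_STAT_CUT = 2.0


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    for col in ("condition", "day", "replicate"):
        if col not in metadata.columns:
            raise ValueError(f"sample metadata lacks column {col!r}")
    dup = metadata.duplicated(subset=["condition", "day", "replicate"])
    if dup.any():
        raise ValueError("duplicate (condition, day, replicate) combinations")
    return metadata


def de_status(
    stat: float,
    fdr: float,
    fdr_cut: float = DEFAULT_FDR_CUT,
    stat_cut: float = DEFAULT_STAT_CUT,
) -> str:
    """'up' iff fdr < cut and stat > stat_cut; 'down' mirrors; else 'unchanged'.

    All inequalities are strict, so boundary values (fdr == 0.05 or
    |stat| == 2) are 'unchanged'.
    """
    if fdr < fdr_cut:
        if stat > stat_cut:
            return "up"
        if stat < -stat_cut:
            return "down"
    return "unchanged"


def de_status_table(
    de: pd.DataFrame,
    fdr_cut: float = DEFAULT_FDR_CUT,
    stat_cut: float = DEFAULT_STAT_CUT,
) -> pd.Series:
    """Vectorized de_status over a table with 'stat' and 'fdr' columns."""
    sig = de["fdr"] < fdr_cut
    out = pd.Series("unchanged", index=de.index)
    out[sig & (de["stat"] > stat_cut)] = "up"
    out[sig & (de["stat"] < -stat_cut)] = "down"
    return out


def normalize_to_control_day5(
    matrix: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Index]:
    """Divide each gene by its mean over CON day-5 replicates.

    Genes whose CON/day-5 mean is not strictly positive cannot be
    normalized; they are excluded and their ids returned separately.
    """
    validate_metadata(metadata)
    ref_samples = metadata.index[
        (metadata["condition"] == "CON") & (metadata["day"] == 5)
    ]
    if len(ref_samples) == 0:
        raise ValueError("no CON day-5 samples in metadata")
    ref_mean = matrix[ref_samples].mean(axis=1)
    bad = matrix.index[~(ref_mean > 0)]
    good = matrix.index.difference(bad, sort=False)
    normalized = matrix.loc[good].div(ref_mean.loc[good], axis=0)
    return normalized, bad


def cluster_targets(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    linkage: str = "average",
    pseudocount: float = 1.0,
) -> tuple[pd.Series, list[str]]:
    """Two-cluster agglomerative structure of putative target genes.

    Genes are log2(x + pseudocount)-transformed and clustered on
    Euclidean distance over the concatenated day-5 + day-7 sample
    vectors; the tree is cut at k = 2. Cluster 'I' is the one with the
    lower mean KD/CON expression ratio (the down-regulated cluster),
    'II' the other. Returns (labels, dendrogram leaf order).
    """
    validate_metadata(metadata)
    if len(expr) < 2:
        raise ValueError("need at least two genes to cluster")
    logx = np.log2(expr + pseudocount)
    if float(logx.to_numpy().std()) == 0.0:
        raise ValueError("constant expression matrix has no cluster structure")
    dist = pdist(logx.to_numpy(), metric="euclidean")
    tree = hierarchy.linkage(dist, method=linkage)
    raw = hierarchy.fcluster(tree, t=2, criterion="maxclust")
    leaves = hierarchy.leaves_list(tree)
    kd = metadata.index[metadata["condition"] == "KD"]
    con = metadata.index[metadata["condition"] == "CON"]
    ratio = logx[kd].mean(axis=1) - logx[con].mean(axis=1)  # log scale
    means = {c: ratio[raw == c].mean() for c in np.unique(raw)}
    if len(means) == 1:
        mapping = {list(means)[0]: "I"}
    else:
        lo = min(means, key=means.get)
        mapping = {c: ("I" if c == lo else "II") for c in means}
    labels = pd.Series([mapping[c] for c in raw], index=expr.index, name="cluster")
    return labels, [expr.index[i] for i in leaves]


def lnc_target_correlation(
    lnc: pd.Series,
    target: pd.Series,
    metadata: pd.DataFrame | None = None,
    day: int | None = None,
) -> float:
    """Pearson r between lncRNA and one target over one day's samples.

    CON and KD samples are pooled (8 samples at the full design). With
    fewer than 3 paired samples, or zero variance in either vector, the
    correlation is undefined and NaN is returned.
    """
    if metadata is not None and day is not None:
        samples = metadata.index[metadata["day"] == day]
        lnc, target = lnc[samples], target[samples]
    x = np.asarray(lnc, dtype=float)
    y = np.asarray(target, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 paired samples")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def correlation_report(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    lnc_gene: str,
    target_genes: list[str],
    days: tuple[int, ...] = (5, 7),
) -> pd.DataFrame:
    """Per-target Pearson r with the lncRNA, one column per day."""
    out = {}
    for day in days:
        rs = []
        for g in target_genes:
            rs.append(
                lnc_target_correlation(expr.loc[lnc_gene], expr.loc[g], metadata, day)
            )
        out[f"r_day{day}"] = rs
    return pd.DataFrame(out, index=pd.Index(target_genes, name="gene_id"))


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def screen_candidates(
    tissue_expression: pd.DataFrame,
    neural_tissues: list[str],
    before: pd.DataFrame,
    after: pd.DataFrame,
    conservation: pd.Series,
    alpha: float = 0.05,
    expression_threshold: float = 1.0,
) -> pd.DataFrame:
    """Filter transcripts by tissue restriction, dynamics and conservation.

    A transcript passes iff (1) expression >= threshold in at least one
    neural tissue and < threshold in every non-neural tissue, (2) a
    two-sided paired t-test of before vs after differentiation across
    cell types rejects after Benjamini-Hochberg correction at ``alpha``,
    and (3) its conservation flag is set. Direction is the sign of the
    mean after-before change.
    """
    missing = [t for t in neural_tissues if t not in tissue_expression.columns]
    if missing:
        raise ValueError(f"neural tissues not in expression matrix: {missing}")
    non_neural = [c for c in tissue_expression.columns if c not in neural_tissues]
    if not list(before.columns) == list(after.columns):
        raise ValueError("before/after matrices must share cell-type columns")
    idx = tissue_expression.index
    neural_ok = (tissue_expression[neural_tissues] >= expression_threshold).any(axis=1)
    if non_neural:
        neural_ok &= (tissue_expression[non_neural] < expression_threshold).all(axis=1)
    delta = after.loc[idx] - before.loc[idx]
    t_res = stats.ttest_rel(after.loc[idx], before.loc[idx], axis=1)
    pvals = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
    padj = _bh_adjust(pvals)
    dynamic = padj < alpha
    conserved = conservation.reindex(idx).fillna(False).astype(bool)
    passed = neural_ok & dynamic & conserved
    mean_change = delta.mean(axis=1)
    direction = np.where(mean_change > 0, "increase", "decrease")
    return pd.DataFrame(
        {
            "neural_specific": neural_ok,
            "p_adj": padj,
            "dynamic": dynamic,
            "conserved": conserved,
            "candidate": passed,
            "direction": np.where(passed, direction, ""),
        },
        index=idx,
    )
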