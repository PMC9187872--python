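"""Differential enrichment statistics for label-free RNA pull-down proteomics.

The Perseus-style chain: flag filtering and log2 transform, the
five-of-five completeness rule, down-shifted Gaussian imputation of
missing intensities, the s0-moderated two-sample statistic with a fully
enumerated balanced-permutation FDR, and the fold-change / p-value
enrichment classification with nuclear-compartment summaries.

A packaged interactor fixture (UniProt id, gene name, -log10 p,
log2(mut/fl) ratio, exclusivity, nuclear compartment) ships with the
module for worked-example tests; see :func:`load_interactor_table`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LFQMatrix",
    "TestParams",
    "preprocess",
    "impute",
    "s0_t_test",
    "permutation_fdr",
    "classify_enrichment",
    "compartment_counts",
    "one_tailed_t_bonferroni",
    "load_interactor_table",
]

FLAG_COLUMNS = ("reverse", "contaminant", "identified_by_site")
N_PER_CONDITION = 5


@dataclass
class TestParams:
    s0: float = 0.1
    alpha: float = 0.05
    downshift: float = 2.0
    width: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LFQMatrix:
    """Protein x sample intensity matrix with flags and condition labels.

    ``intensities`` holds raw (not yet logged) intensities with NaN for
    missing values; ``conditions`` maps each sample column to one of two
    condition labels; ``flags`` is a boolean frame with the columns
    reverse / contaminant / identified_by_site.
    """

    intensities: pd.DataFrame
    conditions: pd.Series
    flags: pd.DataFrame
    gene_names: pd.Series | None = None

    def __post_init__(self) -> None:
        if set(self.conditions.index) != set(self.intensities.columns):
            raise ValueError("conditions must label exactly the intensity columns")
        present = self.intensities.to_numpy()
        if np.any(present[~np.isnan(present)] <= 0):
            raise ValueError("intensities must be positive where present")
        for col in FLAG_COLUMNS:
            if col not in self.flags.columns:
                raise ValueError(f"flags lack column {col!r}")


def preprocess(matrix: LFQMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Flag filtering, log2 transform and the five-of-five rule.

    Returns the filtered log2 matrix and a boolean 'exclusive' series
    marking proteins fully quantified in one condition and fully missing
    in the other.
    """
    levels = sorted(matrix.conditions.unique())
    if len(levels) != 2:
        raise ValueError("expected exactly two conditions")
    groups = {
        lvl: list(matrix.conditions.index[matrix.conditions == lvl]) for lvl in levels
    }
    for lvl, cols in groups.items():
        if len(cols) != N_PER_CONDITION:
            raise ValueError(
                f"condition {lvl!r} has {len(cols)} samples; design is 5 vs 5"
            )
    flagged = matrix.flags[list(FLAG_COLUMNS)].any(axis=1)
    kept = matrix.intensities.loc[~flagged]
    counts = {lvl: kept[cols].notna().sum(axis=1) for lvl, cols in groups.items()}
    full = {lvl: counts[lvl] == N_PER_CONDITION for lvl in levels}
    none = {lvl: counts[lvl] == 0 for lvl in levels}
    keep = full[levels[0]] | full[levels[1]]
    kept = kept.loc[keep]
    exclusive = (
        (full[levels[0]] & none[levels[1]]) | (full[levels[1]] & none[levels[0]])
    ).loc[keep]
    exclusive.name = "exclusive"
    return np.log2(kept), exclusive


def impute(
    log2_matrix: pd.DataFrame,
    downshift: float = 2.0,
    width: float = 0.2,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill missing cells from a down-shifted per-column Gaussian.

    Each missing value in column c is drawn from
    Normal(mu_c - downshift * sd_c, (width * sd_c)^2) where mu_c and
    sd_c are computed from that column's observed values. Observed
    cells are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = log2_matrix.copy()
    for col in out.columns:
        observed = out[col].dropna()
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has < 2 observed values")
        mu, sd = float(observed.mean()), float(observed.std(ddof=1))
        missing = out[col].isna()
        n_missing = int(missing.sum())
        if n_missing:
            out.loc[missing, col] = rng.normal(
                mu - downshift * sd, width * sd, size=n_missing
            )
    return out


def _d_stat(a: np.ndarray, b: np.ndarray, s0: float, axis: int = -1):
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    denom = sp * np.sqrt(1.0 / na + 1.0 / nb) + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ma - mb) / denom, denom


def s0_t_test(group_a, group_b, s0: float = 0.1) -> tuple[float, float]:
    """Fold-change-moderated two-sample statistic and two-sided p.

    ``d = (mean_a - mean_b) / (s_pooled * sqrt(1/n_a + 1/n_b) + s0)``.
    For s0 = 0 the p-value is the classical pooled-variance Student t
    (n_a + n_b - 2 df). For s0 > 0 the null is the enumeration of all
    distinct balanced relabelings of the pooled values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    d, denom = _d_stat(a, b, s0)
    if s0 == 0:
        if denom == 0:
            raise ValueError("zero pooled variance with s0 = 0: statistic undefined")
        p = 2.0 * stats.t.sf(abs(d), df=len(a) + len(b) - 2)
        return float(d), float(p)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    count = 0
    total = 0
    for idx in combinations(range(n), len(a)):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        dp, _ = _d_stat(pooled[sel], pooled[~sel], s0)
        total += 1
        if abs(dp) >= abs(d) - 1e-12:
            count += 1
    return float(d), count / total


def _balanced_permutations(n_a: int, n_b: int) -> np.ndarray:
    """All distinct splits of n_a + n_b samples into the two groups.

    Mirror-image splits give the same |d|, so only splits containing
    sample 0 in group A are kept: C(10,5)/2 = 126 for the 5 vs 5 design.
    """
    n = n_a + n_b
    splits = []
    for idx in combinations(range(1, n), n_a - 1):
        sel = np.zeros(n, dtype=bool)
        sel[0] = True
        sel[list(idx)] = True
        splits.append(sel)
    return np.asarray(splits)


def permutation_fdr(
    log2_matrix: pd.DataFrame,
    labels: pd.Series,
    params: TestParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric |d| cut with exact balanced-permutation FDR control.

    The null distribution pools the s0-statistic over every distinct
    balanced relabeling (126 for 5 vs 5) of every protein. The cut c is
    the smallest |d| threshold at which
    median_permutations(#null calls) / #observed calls <= alpha;
    proteins at or above the cut are flagged significant. Per-protein
    p-values come from the pooled null. The second return value samples
    the volcano boundary curve (log2 ratio, -log10 p) implied by the
    cut.

    ``log2_ratio`` is mean(second condition) - mean(first condition)
    with conditions in sorted label order, i.e. log2(mut/fl) when the
    labels sort as ("fl", "mut").
    """
    params = params or TestParams()
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("expected exactly two condition labels")
    cols_a = [c for c in log2_matrix.columns if labels[c] == levels[1]]  # mut
    cols_b = [c for c in log2_matrix.columns if labels[c] == levels[0]]  # fl
    if len(cols_a) != len(cols_b):
        raise ValueError("unbalanced design; permutation FDR requires n vs n")
    data = log2_matrix[cols_a + cols_b].to_numpy()
    n_a = len(cols_a)
    d_obs, _ = _d_stat(data[:, :n_a], data[:, n_a:], params.s0, axis=1)
    splits = _balanced_permutations(n_a, len(cols_b))
    null = np.empty((len(splits), len(d_obs)))
    for i, sel in enumerate(splits):
        dp, _ = _d_stat(data[:, sel], data[:, ~sel], params.s0, axis=1)
        null[i] = dp
    abs_null = np.abs(null)
    abs_obs = np.abs(d_obs)
    # pooled-null per-protein p-values (add-one to avoid exact zeros)
    flat = np.sort(abs_null.ravel())
    n_null = len(flat)
    ge = n_null - np.searchsorted(flat, abs_obs - 1e-12, side="left")
    pvals = (ge + 1) / (n_null + 1)
    # choose the most inclusive cut with estimated FDR <= alpha
    cut = np.inf
    for c in np.sort(abs_obs)[::-1]:
        r = int(np.sum(abs_obs >= c))
        v = float(np.median(np.sum(abs_null >= c, axis=1)))
        if r > 0 and v / r <= params.alpha:
            cut = c
        else:
            # FDR is not monotone in c, but we keep the first failure as
            # the stopping point for a deterministic, conservative cut
            break
    significant = abs_obs >= cut
    result = pd.DataFrame(
        {
            "d_s0": d_obs,
            "log2_ratio": data[:, :n_a].mean(axis=1) - data[:, n_a:].mean(axis=1),
            "p_value": pvals,
            "neg_log10_p": -np.log10(pvals),
            "significant": significant,
        },
        index=log2_matrix.index,
    )
    curve = _volcano_curve(cut, params.s0, n_a, len(cols_b), abs_obs)
    return result, curve


def _volcano_curve(
    cut: float, s0: float, n_a: int, n_b: int, abs_obs: np.ndarray
) -> pd.DataFrame:
    """Boundary of the significance region in volcano coordinates.

    On the cut, |ratio| / (se + s0) = cut, so se = |ratio|/cut - s0 and
    the displayed p is the Student tail of t = |ratio|/se.
    """
    if not np.isfinite(cut):
        return pd.DataFrame(columns=["log2_ratio", "neg_log10_p"])
    df = n_a + n_b - 2
    hi = max(1.0, float(abs_obs.max()) * 1.5) * (cut * s0 + 1.0)
    ratios = np.linspace(cut * s0 * 1.001 + 1e-6, hi, 200)
    se = ratios / cut - s0
    tvals = ratios / se
    p = 2.0 * stats.t.sf(tvals, df=df)
    neg = -np.log10(np.clip(p, 1e-300, None))
    pos = pd.DataFrame({"log2_ratio": ratios, "neg_log10_p": neg})
    negside = pd.DataFrame({"log2_ratio": -ratios[::-1], "neg_log10_p": neg[::-1]})
    return pd.concat([negside, pos], ignore_index=True)


def classify_enrichment(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.002,
) -> pd.DataFrame:
    """Flag robust binders by fold change and p-value.

    Enriched toward the full-length bait iff log2_ratio < -log2(fc) and
    p < p_threshold; toward the mutant iff log2_ratio > +log2(fc) with
    the same p gate. Accepts either a 'p_value' or a 'neg_log10_p'
    column.
    """
    log_fc = np.log2(fc_threshold)
    if "p_value" in records.columns:
        p_ok = records["p_value"] < p_threshold
    elif "neg_log10_p" in records.columns:
        p_ok = records["neg_log10_p"] > -np.log10(p_threshold)
    else:
        raise ValueError("records need a 'p_value' or 'neg_log10_p' column")
    out = records.copy()
    out["enriched_fl"] = p_ok & (records["log2_ratio"] < -log_fc)
    out["enriched_mut"] = p_ok & (records["log2_ratio"] > log_fc)
    out["enriched"] = out["enriched_fl"] | out["enriched_mut"]
    return out


def compartment_counts(
    records: pd.DataFrame,
    compartment: pd.Series | None = None,
    which: str = "enriched_fl",
) -> dict[str, int]:
    """Counts per nuclear compartment over enriched records."""
    if compartment is None:
        if "compartment" not in records.columns:
            raise ValueError("no compartment annotation supplied")
        compartment = records["compartment"]
    comp = compartment.reindex(records.index).fillna("none")
    enriched = records[records[which]]
    counts: dict[str, int] = {}
    for c in comp.loc[enriched.index]:
        counts[c] = counts.get(c, 0) + 1
    return counts


def one_tailed_t_bonferroni(
    values,
    mu0: float,
    m: int = 1,
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sample, one-tailed t-test with Bonferroni adjustment.

    Returns (t, adjusted p) with adjusted p = min(1, m * p). Degenerate
    zero-variance input is only tolerated when the mean equals mu0
    (t = 0, one-tailed p = 0.5); otherwise the statistic is undefined.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 values")
    if m < 1:
        raise ValueError("m must be >= 1")
    sd = x.std(ddof=1)
    if sd == 0:
        if x.mean() == mu0:
            return 0.0, min(1.0, m * 0.5)
        raise ValueError("zero variance: t statistic undefined")
    t = (x.mean() - mu0) / (sd / np.sqrt(len(x)))
    if alternative == "greater":
        p = stats.t.sf(t, df=len(x) - 1)
    elif alternative == "less":
        p = stats.t.cdf(t, df=len(x) - 1)
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return float(t), float(min(1.0, m * p))


def load_interactor_table() -> pd.DataFrame:
    """Packaged worked-example interactor table.

    Columns: uniprot_id (index), gene_name, neg_log10_p, log2_ratio
    (log2 mut/fl), exclusive (bool), compartment.
    """
    ref = importlib.resources.files("chirpkit") / "data" / "interactors.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="uniprot_id")
    df["exclusive"] = df["exclusive"].map({"Yes": True, "No": False})
    return df
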