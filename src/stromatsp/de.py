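"""Per-gene two-group testing: MWU + Welch t, BH FDR, ROC AUC, log2 ratio.

A gene is called differentially expressed under the dual-test rule iff both
the Mann-Whitney U p-value and the Welch t p-value fall below alpha — the
medians and the means must both separate.  q-values come from
Benjamini-Hochberg adjustment of the MWU p-values (a Welch-based q is also
reported but does not drive calls).  The ROC AUC is computed as the rank
statistic U/(n1*n2), ties counted one half, folded to [0.5, 1] so the
reported discriminative power is orientation-free; direction is carried by
the sign of log2(mean GP4 / mean GP3).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mwu_p",
    "welch_p",
    "bh_adjust",
    "gene_auc",
    "log2_ratio",
    "run_univariate",
    "EXACT_MWU_MAX_N",
]

#: Combined sample size at or below which the exact MWU null is enumerated
#: (tie-free data only); above it, normal approximation with tie and
#: continuity corrections.
EXACT_MWU_MAX_N = 12


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty group")
    if not np.isfinite(a).all():
        raise ValueError("non-finite values")
    return a


def mwu_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumeration when n_x + n_y <= 12 and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x, y = _as_1d(x), _as_1d(y)
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MWU_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def welch_p(x, y) -> float:
    """Two-sided Welch t-test p-value (Welch-Satterthwaite df).

    Degenerate variance is handled by the limit convention: zero variance
    in both groups gives p = 1 for equal means and p = 0 otherwise.
    """
    x, y = _as_1d(x), _as_1d(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch t test needs >= 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


def welch_statistic(x, y) -> tuple[float, float]:
    """(t, Welch-Satterthwaite df) for the two-sample unequal-variance t."""
    x, y = _as_1d(x), _as_1d(y)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
    return float(t), float(df)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_auc(values, labels, positive_class=None) -> float:
    """ROC AUC as the rank statistic U/(n1*n2), folded to [0.5, 1].

    Ties count one half (midrank convention), making the statistic
    identical to the Mann-Whitney U divided by the number of cross-pairs.
    """
    v = _as_1d(values)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("gene_auc requires exactly two classes present")
    pos = positive_class if positive_class is not None else classes[1]
    mask = labels == pos
    n1, n0 = int(mask.sum()), int((~mask).sum())
    ranks = stats.rankdata(v)
    u = ranks[mask].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return float(max(auc, 1.0 - auc))


def log2_ratio(values_gp4, values_gp3) -> float:
    """log2(mean GP4 / mean GP3) of normalized linear-scale values.

    A gene upregulated in GP3 yields a negative value.  Nonpositive group
    means leave the ratio undefined (NaN; callers flag the gene).
    """
    g4, g3 = _as_1d(values_gp4), _as_1d(values_gp3)
    m4, m3 = g4.mean(), g3.mean()
    if m4 <= 0 or m3 <= 0:
        return float("nan")
    return float(np.log2(m4 / m3))


def run_univariate(norm, labels: pd.Series | None = None,
                   alpha: float = 0.05,
                   group_a: str = "GP3", group_b: str = "GP4") -> pd.DataFrame:
    """Per-gene statistics table over a normalized matrix.

    Parameters
    ----------
    norm
        A :class:`~stromatsp.normalize.NormalizedMatrix` (values + missing
        mask); masked values are dropped per gene (pairwise complete).
    labels
        Per-lane group labels; defaults to ``norm.groups``.
    alpha
        Dual-test call threshold applied to both p-values.

    Returns a DataFrame indexed by gene, sorted by MWU p, with columns
    ``n_gp3, n_gp4, p_welch, p_mwu, q, q_welch, auc, log2fc, de_dual``.
    Genes with fewer than two usable values in either group are skipped and
    listed in ``result.attrs["skipped_genes"]``; genes with an undefined
    fold change are listed in ``result.attrs["undefined_log2fc"]``.
    """
    values, missing = norm.values, norm.missing
    if labels is None:
        labels = norm.groups
    if labels is None:
        raise ValueError("no group labels available")
    labels = labels.loc[values.columns]
    is_a = (labels == group_a).to_numpy()
    is_b = (labels == group_b).to_numpy()
    if is_a.sum() < 2 or is_b.sum() < 2:
        raise ValueError("need >= 2 samples per group")

    rows, index, skipped, bad_fc = [], [], [], []
    for gene in values.index:
        usable = ~missing.loc[gene].to_numpy()
        xa = values.loc[gene].to_numpy()[usable & is_a]
        xb = values.loc[gene].to_numpy()[usable & is_b]
        if xa.size < 2 or xb.size < 2:
            skipped.append(str(gene))
            continue
        v = np.concatenate([xa, xb])
        lab = np.array([group_a] * xa.size + [group_b] * xb.size)
        lfc = log2_ratio(xb, xa)
        if np.isnan(lfc):
            bad_fc.append(str(gene))
        rows.append({
            "n_gp3": xa.size,
            "n_gp4": xb.size,
            "p_welch": welch_p(xa, xb),
            "p_mwu": mwu_p(xa, xb),
            "auc": gene_auc(v, lab, positive_class=group_b),
            "log2fc": lfc,
        })
        index.append(gene)

    table = pd.DataFrame(rows, index=pd.Index(index, name="gene"))
    if len(table):
        table["q"] = bh_adjust(table["p_mwu"].to_numpy())
        table["q_welch"] = bh_adjust(table["p_welch"].to_numpy())
        table["de_dual"] = (table["p_mwu"] < alpha) & (table["p_welch"] < alpha)
        table = table.sort_values("p_mwu", kind="mergesort")
        table = table[["n_gp3", "n_gp4", "p_welch", "p_mwu", "q", "q_welch",
                       "auc", "log2fc", "de_dual"]]
    table.attrs["skipped_genes"] = skipped
    table.attrs["undefined_log2fc"] = bad_fc
    table.attrs["alpha"] = alpha
    return table
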