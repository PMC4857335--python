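"""Top-scoring-pair search, ordering classification, and permutation test.

A top-scoring pair (TSP) classifier uses only the within-sample ordering of
two genes: the indicator I_s = [Exp(i) > Exp(j) in sample s] (strict; ties
count as false).  The pair score is

    Delta_ij = | P(I | class A) - P(I | class B) |,

estimated by the class-conditional indicator means.  The search maximizes
Delta over all unordered pairs; score ties are broken by the classic
secondary rank score (the between-class difference of the mean within-sample
rank gap of the two genes), then lexicographically by gene names, so the
search is deterministic.  Because every quantity depends only on
within-sample orderings, any strictly increasing per-sample transform —
including content normalization — leaves the classifier unchanged; that is
the reason the method is run on raw, background-corrected counts.

Significance comes from a permutation null: class labels are reassigned at
random preserving group sizes and the statistic recomputed; by default the
full pair search is re-run each time (selection-adjusted null), with a
cheaper fixed-pair mode behind a flag.  For a single fixed pair the
two-sided permutation tail is also available in closed form by
hypergeometric enumeration.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TspResult",
    "pair_score",
    "tsp_search",
    "tsp_classify",
    "classify_matrix",
    "tsp_permutation_p",
    "exact_pair_permutation_p",
    "run_tsp",
]

MIN_PERMUTATIONS = 100
_SCORE_TOL = 1e-12


@dataclass
class TspResult:
    """Best pair, its score and classification/permutation summaries."""

    gene_i: str
    gene_j: str
    score: float
    orientation: str                  # class voted when Exp(i) > Exp(j)
    other_class: str
    p_ordered: dict                   # class -> fraction of samples with Exp(i) > Exp(j)
    majority_class: str               # assigned on within-sample ties
    secondary_score: float | None = None
    accuracy: float | None = None
    n_correct: int | None = None
    n_samples: int | None = None
    n_classify_ties: int = 0
    permutation_p: float | None = None
    permutation_p_corrected: float | None = None
    null_scores: np.ndarray | None = field(default=None, repr=False)
    n_permutations: int | None = None
    permutation_mode: str | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_i, self.gene_j)

    def to_dict(self) -> dict:
        d = {
            "pair": [self.gene_i, self.gene_j],
            "score": self.score,
            "orientation": self.orientation,
            "p_ordered": {k: float(v) for k, v in self.p_ordered.items()},
            "majority_class": self.majority_class,
            "secondary_score": self.secondary_score,
            "accuracy": self.accuracy,
            "n_correct": self.n_correct,
            "n_samples": self.n_samples,
            "n_classify_ties": self.n_classify_ties,
            "permutation_p": self.permutation_p,
            "permutation_p_corrected": self.permutation_p_corrected,
            "n_permutations": self.n_permutations,
            "permutation_mode": self.permutation_mode,
        }
        return d


def _two_classes(labels) -> tuple[np.ndarray, str, str]:
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return labels, str(classes[0]), str(classes[1])


def pair_score(x_i, x_j, labels) -> tuple[float, str]:
    """Score of one gene pair and the class its ordering votes for.

    Returns (Delta, orientation) where Delta = |P̂(x_i > x_j | A) −
    P̂(x_i > x_j | B)| and orientation is the class with the larger
    conditional ordering probability (the lexicographically first class
    when equal).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    labels, class_a, class_b = _two_classes(labels)
    ind = x_i > x_j
    in_a = labels == class_a
    p_a = float(ind[in_a].mean())
    p_b = float(ind[~in_a].mean())
    score = abs(p_a - p_b)
    orientation = class_a if p_a >= p_b else class_b
    return score, orientation


def _indicator_tensor(x: np.ndarray) -> np.ndarray:
    """Boolean (G, G, S) tensor of within-sample orderings x_i > x_j."""
    return x[:, None, :] > x[None, :, :]


def tsp_search(values: pd.DataFrame, labels: pd.Series | Sequence[str]) -> TspResult:
    """Exhaustive top-scoring-pair search over all unordered gene pairs.

    ``values`` is genes x samples, already background-corrected and
    filtered; no NaNs allowed (zeros are fine — ties count against the
    ordering).  Ties on the primary score are broken by the larger
    secondary rank score, then by lexicographic gene-name order, making the
    result deterministic.
    """
    if values.isna().any().any():
        raise ValueError("values must not contain NaN; filter first")
    if values.shape[0] < 2:
        raise ValueError("need at least two genes after filtering")
    if isinstance(labels, pd.Series):
        labels = labels.loc[values.columns]
    labels, class_a, class_b = _two_classes(labels)

    x = values.to_numpy(dtype=float)
    genes = values.index.to_numpy()
    in_a = labels == class_a
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("a class has zero usable samples")

    ind = _indicator_tensor(x)
    p_a = ind[:, :, in_a].mean(axis=2)
    p_b = ind[:, :, ~in_a].mean(axis=2)
    delta = np.abs(p_a - p_b)

    iu, ju = np.triu_indices(len(genes), k=1)
    scores = delta[iu, ju]
    best = scores.max()
    tied = np.flatnonzero(scores >= best - _SCORE_TOL)

    if tied.size > 1:
        # secondary: between-class difference of mean within-sample rank gaps
        ranks = stats.rankdata(x, axis=0)
        dr = ranks[:, None, :] - ranks[None, :, :]
        gamma_full = np.abs(dr[:, :, in_a].mean(axis=2) - dr[:, :, ~in_a].mean(axis=2))
        gammas = gamma_full[iu[tied], ju[tied]]
        gbest = gammas.max()
        tied = tied[np.flatnonzero(gammas >= gbest - _SCORE_TOL)]
        secondary = float(gbest)
        if tied.size > 1:
            names = sorted((str(genes[iu[t]]), str(genes[ju[t]]), t) for t in tied)
            tied = np.array([names[0][2]])
    else:
        ranks = stats.rankdata(x, axis=0)
        t = tied[0]
        gi, gj = iu[t], ju[t]
        dr = ranks[gi] - ranks[gj]
        secondary = float(abs(dr[in_a].mean() - dr[~in_a].mean()))

    t = int(tied[0])
    gi, gj = iu[t], ju[t]
    pa, pb = float(p_a[gi, gj]), float(p_b[gi, gj])
    orientation = class_a if pa >= pb else class_b
    other = class_b if orientation == class_a else class_a
    if n_a > n_b:
        majority = class_a
    elif n_b > n_a:
        majority = class_b
    else:
        majority = class_a  # tie-break: lexicographically first class

    result = TspResult(
        gene_i=str(genes[gi]), gene_j=str(genes[gj]),
        score=float(delta[gi, gj]), orientation=str(orientation),
        other_class=str(other),
        p_ordered={class_a: pa, class_b: pb},
        majority_class=str(majority),
        secondary_score=secondary,
    )
    preds, n_ties = classify_matrix(values.loc[[result.gene_i, result.gene_j]], result)
    correct = int((preds.to_numpy() == labels).sum())
    result.accuracy = correct / len(labels)
    result.n_correct = correct
    result.n_samples = len(labels)
    result.n_classify_ties = n_ties
    return result


def tsp_classify(sample: Mapping[str, float] | pd.Series, result: TspResult) -> str:
    """Classify one sample by the pair's ordering rule.

    Exp(i) > Exp(j) votes ``result.orientation``; the reverse votes the
    other class; a within-sample tie is assigned the training majority
    class.  Missing pair genes make the sample unclassifiable.
    """
    try:
        xi, xj = sample[result.gene_i], sample[result.gene_j]
    except (KeyError, IndexError) as err:
        raise ValueError(
            f"unclassifiable sample: pair gene missing ({err})") from err
    if pd.isna(xi) or pd.isna(xj):
        raise ValueError("unclassifiable sample: pair gene value missing")
    if xi > xj:
        return result.orientation
    if xi < xj:
        return result.other_class
    return result.majority_class


def classify_matrix(values: pd.DataFrame, result: TspResult) -> tuple[pd.Series, int]:
    """Classify every column of ``values``; returns (labels, tie count)."""
    preds, ties = [], 0
    for lane in values.columns:
        sample = values[lane]
        if sample[result.gene_i] == sample[result.gene_j]:
            ties += 1
        preds.append(tsp_classify(sample, result))
    return pd.Series(preds, index=values.columns, name="predicted"), ties


def tsp_permutation_p(values: pd.DataFrame, labels: pd.Series | Sequence[str],
                      n_permutations: int = 100_000,
                      seed: int | np.random.Generator | None = None,
                      mode: str = "search",
                      pair: tuple[str, str] | None = None,
                      observed: float | None = None,
                      batch: int = 2048) -> tuple[float, float, np.ndarray]:
    """Permutation p-value of the top score under label reshuffling.

    Labels are reassigned uniformly at random preserving group sizes.  In
    ``mode="search"`` the full pair search is re-maximized per permutation
    (the honest selection-adjusted null); ``mode="fixed_pair"`` rescores
    only ``pair``.  Returns (p, corrected p, null score sample) where p =
    #{null >= observed}/n and corrected p = (#{null >= observed}+1)/(n+1).
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise ValueError(
            f"n_permutations must be >= {MIN_PERMUTATIONS} to be meaningful")
    if mode not in ("search", "fixed_pair"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(labels, pd.Series):
        labels = labels.loc[values.columns]
    labels, class_a, class_b = _two_classes(labels)
    n_a = int((labels == class_a).sum())
    n_b = len(labels) - n_a

    x = values.to_numpy(dtype=float)
    if mode == "fixed_pair":
        if pair is None:
            raise ValueError("fixed_pair mode requires a pair")
        gi = values.index.get_loc(pair[0])
        gj = values.index.get_loc(pair[1])
        m = (x[gi] > x[gj]).astype(np.float32)[None, :]
    else:
        ind = _indicator_tensor(x)
        iu, ju = np.triu_indices(x.shape[0], k=1)
        m = ind[iu, ju].astype(np.float32)          # pairs x samples

    in_a = (labels == class_a)
    obs_sum_a = m[:, in_a].sum(axis=1)
    tot = m.sum(axis=1)
    obs_scores = np.abs(obs_sum_a / n_a - (tot - obs_sum_a) / n_b)
    if observed is None:
        observed = float(obs_scores.max())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = m.shape[1]
    null = np.empty(n_permutations, dtype=np.float64)
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        keys = rng.random((b, s))
        idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
        z = np.zeros((b, s), dtype=np.float32)
        np.put_along_axis(z, idx, 1.0, axis=1)
        sums_a = m @ z.T                             # pairs x b
        scores = np.abs(sums_a / n_a - (tot[:, None] - sums_a) / n_b)
        null[done:done + b] = scores.max(axis=0)
        done += b

    exceed = int((null >= observed - _SCORE_TOL).sum())
    p_raw = exceed / n_permutations
    p_corr = (exceed + 1) / (n_permutations + 1)
    return p_raw, p_corr, null


def exact_pair_permutation_p(n_a: int, n_b: int, k_a: int, k_b: int) -> float:
    """Exact two-sided permutation tail for one fixed pair.

    Under label permutation the number of ordered samples landing in group
    A is hypergeometric: a ~ Hypergeom(N = n_a + n_b, K = k_a + k_b, n_a).
    The tail sums P(a) over all a whose score |a/n_a − (K−a)/n_b| is at
    least the observed score.
    """
    n = n_a + n_b
    k = k_a + k_b
    observed = abs(k_a / n_a - k_b / n_b)
    rv = stats.hypergeom(n, k, n_a)
    support = np.arange(max(0, k - n_b), min(k, n_a) + 1)
    scores = np.abs(support / n_a - (k - support) / n_b)
    return float(rv.pmf(support[scores >= observed - _SCORE_TOL]).sum())


def run_tsp(values: pd.DataFrame, labels: pd.Series | Sequence[str],
            n_permutations: int = 100_000,
            seed: int | None = None,
            mode: str = "search") -> TspResult:
    """Search + classification + permutation test in one call."""
    result = tsp_search(values, labels)
    p_raw, p_corr, null = tsp_permutation_p(
        values, labels, n_permutations=n_permutations, seed=seed, mode=mode,
        pair=result.pair, observed=result.score)
    result.permutation_p = p_raw
    result.permutation_p_corrected = p_corr
    result.null_scores = null
    result.n_permutations = n_permutations
    result.permutation_mode = mode
    return result
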