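"""Three-step NanoString normalization with factor gating and missing filters.

The chain, applied in order:

1. **Positive-control factors** — each lane is scaled by
   ``G / g_l`` where ``g_l`` is the geometric mean of the lane's six
   spike-ins and ``G`` the geometric mean across all lanes; factors outside
   [0.3, 3] are flagged.
2. **Background subtraction** — the arithmetic mean of a lane's eight
   negative controls is subtracted from every content probe, floored at 0;
   zeros enter the missing mask ("failed to register counts").
3. **Content factors** — per lane, the geometric mean of its own top-75
   highest content values; factor = grand geometric mean / lane value;
   factors outside [0.1, 10] are flagged and those lanes removed.
4. **Missing filters** — entities with strictly more than 50% missing
   values are excluded, samples-then-genes for the univariate path.

The ordering-classifier path deliberately skips steps 1 and 3
(:func:`tsp_preprocess`): a rank-based pair classifier is invariant to any
within-sample monotone scaling, so only background correction and the
genes-then-samples missing filter are applied.

An exclusion ledger records every removed lane and gene with its reason, in
removal order, so `input = surviving + ledger` holds per axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .containers import CodeSet, CountMatrix

__all__ = [
    "NormalizationFactors",
    "NormalizedMatrix",
    "positive_factors",
    "subtract_background",
    "content_factors",
    "filter_missing",
    "normalize",
    "tsp_preprocess",
    "POS_FACTOR_RANGE",
    "CONTENT_FACTOR_RANGE",
]

POS_FACTOR_RANGE = (0.3, 3.0)
CONTENT_FACTOR_RANGE = (0.1, 10.0)
DEFAULT_TOP_N = 75
DEFAULT_MISSING_THRESHOLD = 0.5


@dataclass
class NormalizationFactors:
    """Per-lane factors and range flags; fields are None until computed."""

    positive: pd.Series | None = None
    positive_in_range: pd.Series | None = None
    background: pd.Series | None = None
    content: pd.Series | None = None
    content_in_range: pd.Series | None = None
    pos_range: tuple[float, float] = POS_FACTOR_RANGE
    content_range: tuple[float, float] = CONTENT_FACTOR_RANGE

    def to_frame(self) -> pd.DataFrame:
        """All factors as one lane-indexed table (for TSV export)."""
        parts = {}
        if self.positive is not None:
            parts["positive_factor"] = self.positive
            parts["positive_in_range"] = self.positive_in_range
        if self.background is not None:
            parts["background"] = self.background
        if self.content is not None:
            parts["content_factor"] = self.content
            parts["content_in_range"] = self.content_in_range
        return pd.DataFrame(parts)


@dataclass
class NormalizedMatrix:
    """Normalized values with explicit missingness and an exclusion ledger."""

    values: pd.DataFrame          # probes x lanes, >= 0
    missing: pd.DataFrame         # bool, aligned with values
    ledger: list[dict] = field(default_factory=list)
    factors: NormalizationFactors | None = None
    groups: pd.Series | None = None

    def excluded(self, axis: str) -> list[str]:
        """Names removed along ``axis`` ("sample" or "gene"), in order."""
        return [e["name"] for e in self.ledger if e["axis"] == axis]


def positive_factors(cm: CountMatrix,
                     accept_range: tuple[float, float] = POS_FACTOR_RANGE
                     ) -> tuple[pd.Series, pd.Series]:
    """Per-lane positive-control scale factors and in-range flags.

    factor_l = G / g_l with g_l the geometric mean of lane l's six positive
    spike-ins and G the geometric mean of all positive counts across lanes.
    The geometric mean of the returned factors is 1 by construction.
    """
    pos = cm.counts.loc[cm.codeset.positive]
    if pos.shape[0] == 0:
        raise ValueError("codeset has no positive probes")
    zero = pos.eq(0)
    if zero.any().any():
        lane = pos.columns[zero.any(axis=0)][0]
        raise ValueError(
            f"zero positive-control count in lane {lane!r}: geometric mean undefined")
    per_lane = pd.Series(gmean(pos.to_numpy(), axis=0), index=pos.columns)
    grand = gmean(pos.to_numpy(), axis=None)
    factors = grand / per_lane
    lo, hi = accept_range
    in_range = (factors >= lo) & (factors <= hi)
    return factors, in_range


def subtract_background(counts: pd.DataFrame, codeset: CodeSet
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Mean-of-negatives background correction, floored at zero.

    Returns (corrected content-probe matrix, missing mask, per-lane
    background).  A corrected value of exactly 0 is marked missing.
    """
    negs = counts.loc[counts.index.intersection(codeset.negative, sort=False)]
    if negs.shape[0] == 0:
        raise ValueError("codeset has no negative probes; background undefined")
    background = negs.mean(axis=0)
    content = counts.loc[counts.index.intersection(codeset.content_probes, sort=False)]
    corrected = (content - background).clip(lower=0.0)
    missing = corrected.eq(0.0)
    return corrected, missing, background


def content_factors(corrected: pd.DataFrame, top_n: int = DEFAULT_TOP_N,
                    accept_range: tuple[float, float] = CONTENT_FACTOR_RANGE
                    ) -> tuple[pd.Series, pd.Series]:
    """Sample-content factors from each lane's own top-``top_n`` values.

    r_l = geometric mean of lane l's top_n highest content values; factor =
    (geometric mean of r over evaluable lanes) / r_l.  Lanes with fewer than
    ``top_n`` nonzero values are unevaluable (NaN factor, flagged).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    r = {}
    for lane in corrected.columns:
        vals = corrected[lane].to_numpy()
        if int((vals > 0).sum()) < top_n:
            r[lane] = np.nan
            continue
        top = np.sort(vals)[-top_n:]
        r[lane] = gmean(top)
    r = pd.Series(r, index=corrected.columns)
    evaluable = r.notna()
    if not evaluable.any():
        raise ValueError(f"no lane has {top_n} nonzero content values")
    grand = gmean(r[evaluable].to_numpy())
    factors = grand / r
    lo, hi = accept_range
    in_range = (factors >= lo) & (factors <= hi) & evaluable
    return factors, in_range


def housekeeping_factors(corrected: pd.DataFrame, codeset: CodeSet,
                         accept_range: tuple[float, float] = CONTENT_FACTOR_RANGE
                         ) -> tuple[pd.Series, pd.Series]:
    """Content factors from housekeeping-probe geometric means (off by
    default: a panel whose references do not reproduce across samples —
    here only ACTB did in the emulated study — should not be anchored on
    them)."""
    hk = corrected.loc[corrected.index.intersection(codeset.housekeeping, sort=False)]
    if hk.shape[0] == 0:
        raise ValueError("codeset has no housekeeping probes")
    if hk.le(0).any().any():
        bad = hk.columns[hk.le(0).any(axis=0)].tolist()
        raise ValueError(f"nonpositive housekeeping values in lanes {bad}")
    r = pd.Series(gmean(hk.to_numpy(), axis=0), index=hk.columns)
    factors = gmean(r.to_numpy()) / r
    lo, hi = accept_range
    in_range = (factors >= lo) & (factors <= hi)
    return factors, in_range


def filter_missing(values: pd.DataFrame, missing: pd.DataFrame,
                   threshold: float = DEFAULT_MISSING_THRESHOLD,
                   order: str = "samples_then_genes",
                   prior_ledger: Sequence[dict] = (),
                   factors: NormalizationFactors | None = None,
                   groups: pd.Series | None = None) -> NormalizedMatrix:
    """Drop entities whose missing fraction strictly exceeds ``threshold``.

    The second pass is computed on the matrix remaining after the first;
    ``order`` selects samples-then-genes (univariate preset) or
    genes-then-samples (ordering-classifier preset).
    """
    if order not in ("samples_then_genes", "genes_then_samples"):
        raise ValueError(f"unknown filter order {order!r}")
    ledger = list(prior_ledger)

    def drop_axis(vals: pd.DataFrame, miss: pd.DataFrame, axis: str, step: int):
        frac = miss.mean(axis=0) if axis == "sample" else miss.mean(axis=1)
        dead = frac.index[frac > threshold]
        for name in dead:
            ledger.append({
                "axis": axis,
                "name": str(name),
                "step": step,
                "missing_fraction": float(frac[name]),
                "reason": f"missing fraction {frac[name]:.3f} > {threshold:g}",
            })
        if axis == "sample":
            return vals.drop(columns=dead), miss.drop(columns=dead)
        return vals.drop(index=dead), miss.drop(index=dead)

    first, second = (("sample", "gene") if order == "samples_then_genes"
                     else ("gene", "sample"))
    values, missing = drop_axis(values, missing, first, step=1)
    if values.size:
        values, missing = drop_axis(values, missing, second, step=2)
    if values.size == 0:
        raise RuntimeError("empty after filtering: all entities removed")
    if groups is not None:
        groups = groups.loc[values.columns]
    return NormalizedMatrix(values, missing, ledger, factors, groups)


def normalize(cm: CountMatrix,
              top_n: int = DEFAULT_TOP_N,
              pos_factor_range: tuple[float, float] = POS_FACTOR_RANGE,
              content_factor_range: tuple[float, float] = CONTENT_FACTOR_RANGE,
              missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
              filter_order: str = "samples_then_genes",
              content_basis: str = "top_n") -> NormalizedMatrix:
    """Full univariate-path normalization of a raw count matrix.

    Positive factors -> background subtraction -> content factors -> lane
    gating -> missing filters.  Lanes whose positive or content factor is
    out of range (or unevaluable) are removed before the missing filters
    and recorded in the ledger.
    """
    pos_f, pos_ok = positive_factors(cm, pos_factor_range)
    scaled = cm.counts.mul(pos_f, axis=1)
    corrected, missing, background = subtract_background(scaled, cm.codeset)
    if content_basis == "top_n":
        cont_f, cont_ok = content_factors(corrected, top_n, content_factor_range)
    elif content_basis == "housekeeping":
        cont_f, cont_ok = housekeeping_factors(corrected, cm.codeset, content_factor_range)
    else:
        raise ValueError(f"unknown content_basis {content_basis!r}")

    factors = NormalizationFactors(
        positive=pos_f, positive_in_range=pos_ok,
        background=background,
        content=cont_f, content_in_range=cont_ok,
        pos_range=tuple(pos_factor_range), content_range=tuple(content_factor_range),
    )

    ledger: list[dict] = []
    keep = []
    for lane in corrected.columns:
        if not pos_ok[lane]:
            ledger.append({
                "axis": "sample", "name": str(lane), "step": 0,
                "missing_fraction": float("nan"),
                "reason": f"positive factor {pos_f[lane]:.4g} outside "
                          f"[{pos_factor_range[0]:g}, {pos_factor_range[1]:g}]",
            })
        elif not cont_ok[lane]:
            detail = ("unevaluable (fewer than required nonzero values)"
                      if pd.isna(cont_f[lane]) else
                      f"{cont_f[lane]:.4g} outside "
                      f"[{content_factor_range[0]:g}, {content_factor_range[1]:g}]")
            ledger.append({
                "axis": "sample", "name": str(lane), "step": 0,
                "missing_fraction": float("nan"),
                "reason": f"content factor {detail}",
            })
        else:
            keep.append(lane)
    if not keep:
        raise RuntimeError("empty after filtering: no lane has in-range factors")

    values = corrected[keep].mul(cont_f[keep], axis=1)
    missing = missing[keep]
    return filter_missing(values, missing, missing_threshold, filter_order,
                          prior_ledger=ledger, factors=factors,
                          groups=cm.groups)


def tsp_preprocess(cm: CountMatrix,
                   missing_threshold: float = DEFAULT_MISSING_THRESHOLD
                   ) -> NormalizedMatrix:
    """Ordering-classifier preprocessing: background correction only.

    Raw counts are mean-background corrected, then genes and then samples
    with more than 50% zero values are excluded.  No positive-control or
    content scaling is applied — the pair classifier depends only on
    within-sample orderings, which such scalings cannot change.
    """
    corrected, missing, background = subtract_background(cm.counts.astype(float),
                                                         cm.codeset)
    factors = NormalizationFactors(background=background)
    return filter_missing(corrected, missing, missing_threshold,
                          order="genes_then_samples", factors=factors,
                          groups=cm.groups)
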