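"""Core data containers: probe catalogue and raw count matrix.

A NanoString nCounter run produces, per lane (hybridized sample), an integer
count for every probe in a codeset.  Probes fall into four classes:
*endogenous* targets, *housekeeping* references, *positive* spike-in controls
at known fM concentrations, and *negative* controls that measure background.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "housekeeping", "positive", "negative")

#: Spike-in concentration ladder (fM), highest first.  The endpoints are the
#: platform's standard 128 and 0.128 fM; interior steps are 4-fold (the final
#: step is therefore ~3.9-fold).
POSITIVE_LADDER_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.128)
N_NEGATIVE_PROBES = 8

#: Housekeeping references commonly used for prostate expression panels.
DEFAULT_HOUSEKEEPING = ("ACTB", "CLTC", "GUSB", "HPRT1", "TUBB")

LANE_META_COLUMNS = ("binding_density", "fov_counted", "fov_attempted", "group")

_POS_NAME_RE = re.compile(r"\(([0-9]*\.?[0-9]+)\)$")


@dataclass
class CodeSet:
    """Probe catalogue: names, probe classes and spike-in concentrations.

    Parameters
    ----------
    annotation
        DataFrame indexed by probe name with columns ``probe_class`` (one of
        :data:`PROBE_CLASSES`) and ``concentration`` (fM; positive probes
        only, NaN elsewhere).
    """

    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        ann = self.annotation
        if "probe_class" not in ann.columns:
            raise ValueError("codeset annotation requires a 'probe_class' column")
        if "concentration" not in ann.columns:
            ann = ann.copy()
            ann["concentration"] = np.nan
            self.annotation = ann
        if not ann.index.is_unique:
            dupes = ann.index[ann.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe names in codeset: {dupes}")
        unknown = set(ann["probe_class"]) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        conc = ann.loc[ann["probe_class"] == "positive", "concentration"]
        if conc.isna().any():
            raise ValueError("positive probes must carry a concentration (fM)")
        if len(conc) > 1 and not (np.diff(conc.to_numpy()) < 0).all():
            raise ValueError("positive-control concentrations must be strictly decreasing")
        other = ann.loc[ann["probe_class"] != "positive", "concentration"]
        if other.notna().any():
            raise ValueError("concentration is defined for positive probes only")

    def probes(self, probe_class: str) -> pd.Index:
        """Probe names of one class, in catalogue order."""
        if probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {probe_class!r}")
        return self.annotation.index[self.annotation["probe_class"] == probe_class]

    @property
    def endogenous(self) -> pd.Index:
        return self.probes("endogenous")

    @property
    def housekeeping(self) -> pd.Index:
        return self.probes("housekeeping")

    @property
    def positive(self) -> pd.Index:
        return self.probes("positive")

    @property
    def negative(self) -> pd.Index:
        return self.probes("negative")

    @property
    def content_probes(self) -> pd.Index:
        """Endogenous + housekeeping probes (the non-control pool)."""
        mask = self.annotation["probe_class"].isin(("endogenous", "housekeeping"))
        return self.annotation.index[mask]

    def class_counts(self) -> dict[str, int]:
        """Number of probes per class; classes with zero probes are omitted."""
        counts = self.annotation["probe_class"].value_counts()
        return {c: int(counts[c]) for c in PROBE_CLASSES if c in counts and counts[c] > 0}

    def positive_concentrations(self) -> pd.Series:
        """Spike-in concentrations (fM) indexed by positive-probe name."""
        return self.annotation.loc[self.positive, "concentration"]


def generate_codeset(n_endogenous: int = 102, n_housekeeping: int = 5) -> CodeSet:
    """Build a codeset with the standard control complement.

    Always includes exactly 6 positive spike-ins at 128, 32, 8, 2, 0.5 and
    0.128 fM and 8 negative probes, plus the requested numbers of endogenous
    and housekeeping probes.
    """
    if n_endogenous < 0 or n_housekeeping < 0:
        raise ValueError("probe counts must be nonnegative")
    names: list[str] = []
    classes: list[str] = []
    conc: list[float] = []

    for i in range(n_endogenous):
        names.append(f"GENE_{i + 1:03d}")
        classes.append("endogenous")
        conc.append(np.nan)
    for i in range(n_housekeeping):
        name = DEFAULT_HOUSEKEEPING[i] if i < len(DEFAULT_HOUSEKEEPING) else f"HK_{i + 1:02d}"
        names.append(name)
        classes.append("housekeeping")
        conc.append(np.nan)
    for letter, c in zip("ABCDEF", POSITIVE_LADDER_FM):
        names.append(f"POS_{letter}({c:g})")
        classes.append("positive")
        conc.append(c)
    for i in range(N_NEGATIVE_PROBES):
        names.append(f"NEG_{chr(ord('A') + i)}")
        classes.append("negative")
        conc.append(np.nan)

    ann = pd.DataFrame(
        {"probe_class": classes, "concentration": conc},
        index=pd.Index(names, name="probe"),
    )
    return CodeSet(ann)


def parse_positive_concentration(name: str) -> float | None:
    """Extract the fM concentration encoded in a positive-probe name.

    The platform convention embeds the concentration in parentheses, e.g.
    ``POS_A(128)``.  Returns None when the name carries no concentration.
    """
    m = _POS_NAME_RE.search(name)
    return float(m.group(1)) if m else None


@dataclass
class CountMatrix:
    """Raw counts (probes x lanes) with per-lane QC metadata.

    ``counts`` is a nonnegative integer DataFrame whose rows are probes of
    ``codeset`` and whose columns are lane IDs.  ``lane_meta`` is indexed by
    lane ID with columns ``binding_density`` (spots/um^2), ``fov_counted``,
    ``fov_attempted`` and ``group`` (e.g. GP3/GP4, or "unknown").
    """

    counts: pd.DataFrame
    codeset: CodeSet
    lane_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.counts.columns.is_unique:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate lane IDs: {dupes}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        neg = np.argwhere(vals < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count at probe {self.counts.index[i]!r}, "
                f"lane {self.counts.columns[j]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

        unknown = self.counts.index.difference(self.codeset.annotation.index)
        if len(unknown):
            raise ValueError(f"probes absent from codeset: {unknown.tolist()}")
        self.counts.index.name = "probe"
        self.counts.columns.name = "lane"

        if self.lane_meta is None:
            self.lane_meta = pd.DataFrame(index=self.counts.columns.copy())
        meta = self.lane_meta.reindex(self.counts.columns)
        for col in LANE_META_COLUMNS:
            if col not in meta.columns:
                meta[col] = "unknown" if col == "group" else np.nan
        meta["group"] = meta["group"].fillna("unknown")
        both = meta["fov_counted"].notna() & meta["fov_attempted"].notna()
        if (meta.loc[both, "fov_counted"] > meta.loc[both, "fov_attempted"]).any():
            bad = meta.index[both & (meta["fov_counted"] > meta["fov_attempted"])][0]
            raise ValueError(f"fov_counted exceeds fov_attempted in lane {bad!r}")
        self.lane_meta = meta[list(LANE_META_COLUMNS)]

    @property
    def lanes(self) -> pd.Index:
        return self.counts.columns

    @property
    def groups(self) -> pd.Series:
        """Per-lane group label, aligned with ``counts`` columns."""
        return self.lane_meta["group"]

    def subset(self, probes: Iterable[str] | None = None,
               lanes: Iterable[str] | None = None) -> "CountMatrix":
        """Restrict to the given probes and/or lanes (order preserved)."""
        counts = self.counts
        if probes is not None:
            counts = counts.loc[list(probes)]
        if lanes is not None:
            counts = counts[list(lanes)]
        return CountMatrix(counts.copy(), self.codeset, self.lane_meta.loc[counts.columns].copy())
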