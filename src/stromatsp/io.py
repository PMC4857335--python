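"""Reading and writing count data, and pre-normalization lane QC.

Two dialects are supported:

* ``rcc_directory`` — a directory of per-lane RCC files (the platform's
  INI-like sectioned text output: Header, Sample_Attributes,
  Lane_Attributes, Code_Summary).
* ``count_table`` — a probes-as-rows CSV/TSV with a mandatory
  ``probe_class`` column and an optional ``concentration`` column, plus a
  JSON lane-metadata sidecar.

Lane QC follows the platform's standard criteria: binding density inside
[0.05, 2.25] spots/um^2 and a counted/attempted field-of-view ratio of at
least 0.75.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CodeSet,
    CountMatrix,
    LANE_META_COLUMNS,
    parse_positive_concentration,
)

__all__ = [
    "load_counts",
    "write_count_table",
    "write_rcc_directory",
    "write_truth",
    "lane_qc",
    "QcReport",
    "DEFAULT_BD_RANGE",
    "DEFAULT_MIN_FOV_RATIO",
]

DEFAULT_BD_RANGE = (0.05, 2.25)
DEFAULT_MIN_FOV_RATIO = 0.75

_RCC_CLASS_TO_INTERNAL = {
    "Endogenous": "endogenous",
    "Housekeeping": "housekeeping",
    "Positive": "positive",
    "Negative": "negative",
}
_INTERNAL_TO_RCC_CLASS = {v: k for k, v in _RCC_CLASS_TO_INTERNAL.items()}

_GROUP_LABELS = ("GP3", "GP4")


# ---------------------------------------------------------------------------
# writers

def write_count_table(cm: CountMatrix, path: str | Path,
                      metadata_path: str | Path | None = None) -> Path:
    """Write counts as CSV (probes x lanes) plus a JSON lane-metadata sidecar.

    Layout: probe names as the index, a ``probe_class`` column, a
    ``concentration`` column and one column per lane.  The sidecar defaults
    to ``<path stem>.lanes.json``.
    """
    path = Path(path)
    out = cm.counts.copy()
    out.insert(0, "probe_class", cm.codeset.annotation.loc[out.index, "probe_class"])
    out.insert(1, "concentration", cm.codeset.annotation.loc[out.index, "concentration"])
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    out.to_csv(path, sep=sep)

    meta_path = Path(metadata_path) if metadata_path else _default_sidecar(path)
    meta = {}
    for lane, row in cm.lane_meta.iterrows():
        meta[str(lane)] = {
            "binding_density": None if pd.isna(row["binding_density"]) else float(row["binding_density"]),
            "fov_counted": None if pd.isna(row["fov_counted"]) else int(row["fov_counted"]),
            "fov_attempted": None if pd.isna(row["fov_attempted"]) else int(row["fov_attempted"]),
            "group": str(row["group"]),
        }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path


def _default_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".lanes.json")


def write_rcc_directory(cm: CountMatrix, directory: str | Path) -> Path:
    """Write one RCC file per lane into ``directory``.

    The RCC format has no group-label field; the group is stored in the
    Sample_Attributes ``Comments`` row and recovered by the reader.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ann = cm.codeset.annotation
    for lane_no, lane in enumerate(cm.lanes, start=1):
        meta = cm.lane_meta.loc[lane]
        lines = [
            "<Header>",
            "FileVersion,1.7",
            "SoftwareVersion,4.0.0.3",
            "</Header>",
            "",
            "<Sample_Attributes>",
            f"ID,{lane}",
            "Owner,",
            f"Comments,{meta['group']}",
            "Date,20150101",
            "GeneRLF,synthetic",
            "SystemAPF,n/a",
            "</Sample_Attributes>",
            "",
            "<Lane_Attributes>",
            f"ID,{lane_no}",
            f"FovCount,{_fmt_int(meta['fov_attempted'])}",
            f"FovCounted,{_fmt_int(meta['fov_counted'])}",
            "ScannerID,synthetic",
            f"StagePosition,{lane_no}",
            f"BindingDensity,{_fmt_float(meta['binding_density'])}",
            "CartridgeID,synthetic",
            "</Lane_Attributes>",
            "",
            "<Code_Summary>",
            "CodeClass,Name,Accession,Count",
        ]
        for probe in cm.counts.index:
            cls = _INTERNAL_TO_RCC_CLASS[ann.loc[probe, "probe_class"]]
            lines.append(f"{cls},{probe},{probe},{cm.counts.at[probe, lane]}")
        lines += ["</Code_Summary>", ""]
        (directory / f"{lane}.RCC").write_text("\n".join(lines))
    return directory


def _fmt_int(v) -> str:
    return "" if pd.isna(v) else str(int(v))


def _fmt_float(v) -> str:
    return "" if pd.isna(v) else f"{float(v):g}"


def write_truth(truth, path: str | Path) -> Path:
    """Serialize a :class:`~stromatsp.simulate.SyntheticTruth` as JSON."""
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# readers

def load_counts(path: str | Path, dialect: str,
                metadata: str | Path | None = None,
                codeset: CodeSet | None = None) -> CountMatrix:
    """Load a count matrix from disk.

    Parameters
    ----------
    path
        RCC directory or count-table file, per ``dialect``.
    dialect
        ``"rcc_directory"`` or ``"count_table"``.
    metadata
        Lane-metadata JSON sidecar (count_table dialect; defaults to
        ``<stem>.lanes.json`` next to the table).
    codeset
        Optional catalogue to validate probes against; by default the
        catalogue is reconstructed from the file's probe-class annotations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect == "count_table":
        return _load_count_table(path, metadata, codeset)
    if dialect == "rcc_directory":
        return _load_rcc_directory(path, codeset)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_count_table(path: Path, metadata: str | Path | None,
                      codeset: CodeSet | None) -> CountMatrix:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep, index_col=0)
    if "probe_class" not in table.columns:
        raise ValueError(f"{path}: count table requires a 'probe_class' column")
    classes = table.pop("probe_class")
    conc = table.pop("concentration") if "concentration" in table.columns else pd.Series(
        np.nan, index=table.index)
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate lane IDs: {dupes}")
    counts = table.apply(pd.to_numeric)
    bad = np.argwhere(counts.to_numpy() < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: negative count at probe {counts.index[i]!r}, lane {counts.columns[j]!r}")

    if codeset is None:
        codeset = CodeSet(pd.DataFrame(
            {"probe_class": classes, "concentration": conc}, index=table.index))

    meta_path = Path(metadata) if metadata else _default_sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(
            f"count_table dialect requires a lane-metadata sidecar; {meta_path} not found")
    raw = json.loads(meta_path.read_text())
    meta = pd.DataFrame.from_dict(raw, orient="index")
    for col in LANE_META_COLUMNS:
        if col not in meta.columns:
            meta[col] = "unknown" if col == "group" else np.nan
    return CountMatrix(counts, codeset, meta)


def _parse_rcc(text: str, source: str) -> dict:
    """Split an RCC file into its sections; returns attrs + code summary."""
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("</"):
            current = None
        elif line.startswith("<"):
            current = line.strip("<>")
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    for required in ("Sample_Attributes", "Lane_Attributes", "Code_Summary"):
        if required not in sections:
            raise ValueError(f"{source}: missing RCC section <{required}>")

    def kv(section: str) -> dict[str, str]:
        out = {}
        for line in sections[section]:
            key, _, value = line.partition(",")
            out[key] = value
        return out

    sample = kv("Sample_Attributes")
    lane = kv("Lane_Attributes")
    body = sections["Code_Summary"]
    header = body[0].split(",")
    if header[:2] != ["CodeClass", "Name"] or "Count" not in header:
        raise ValueError(f"{source}: unexpected Code_Summary header {body[0]!r}")
    count_col = header.index("Count")
    rows = []
    for line in body[1:]:
        parts = line.split(",")
        if len(parts) <= count_col:
            raise ValueError(f"{source}: malformed Code_Summary row {line!r}")
        rcc_class, name = parts[0], parts[1]
        if rcc_class not in _RCC_CLASS_TO_INTERNAL:
            raise ValueError(f"{source}: unknown CodeClass {rcc_class!r}")
        rows.append((name, _RCC_CLASS_TO_INTERNAL[rcc_class], float(parts[count_col])))
    return {"sample": sample, "lane": lane, "rows": rows}


def _load_rcc_directory(path: Path, codeset: CodeSet | None) -> CountMatrix:
    files = sorted(path.glob("*.RCC")) + sorted(path.glob("*.rcc"))
    if not files:
        raise ValueError(f"{path}: no RCC files found")

    lane_counts: dict[str, pd.Series] = {}
    meta_rows: dict[str, dict] = {}
    probe_classes: dict[str, str] = {}
    for f in files:
        parsed = _parse_rcc(f.read_text(), str(f))
        lane_id = parsed["sample"].get("ID") or f.stem
        if lane_id in lane_counts:
            raise ValueError(f"duplicate lane ID {lane_id!r} (file {f.name})")
        names = [r[0] for r in parsed["rows"]]
        series = pd.Series([r[2] for r in parsed["rows"]],
                           index=pd.Index(names, name="probe"))
        if series.index.duplicated().any():
            dupes = series.index[series.index.duplicated()].unique().tolist()
            raise ValueError(f"{f}: duplicate probes {dupes}")
        if (series < 0).any():
            probe = series.index[series.lt(0).argmax()]
            raise ValueError(f"{f}: negative count at probe {probe!r}, lane {lane_id!r}")
        for name, cls, _ in parsed["rows"]:
            if probe_classes.setdefault(name, cls) != cls:
                raise ValueError(f"probe {name!r} has inconsistent classes across lanes")
        lane_counts[lane_id] = series

        lane_attrs = parsed["lane"]
        comments = parsed["sample"].get("Comments", "")
        meta_rows[lane_id] = {
            "binding_density": _opt_float(lane_attrs.get("BindingDensity")),
            "fov_counted": _opt_float(lane_attrs.get("FovCounted")),
            "fov_attempted": _opt_float(lane_attrs.get("FovCount")),
            "group": comments if comments in _GROUP_LABELS else "unknown",
        }

    counts = pd.DataFrame(lane_counts)
    counts.columns.name = "lane"
    if counts.isna().any().any():
        missing = counts.columns[counts.isna().any()].tolist()
        raise ValueError(f"lanes with incomplete probe sets: {missing}")

    if codeset is None:
        conc = [parse_positive_concentration(n) if probe_classes[n] == "positive" else np.nan
                for n in counts.index]
        pos_order = [n for n in counts.index if probe_classes[n] == "positive"]
        pos_conc = [parse_positive_concentration(n) for n in pos_order]
        if any(c is None for c in pos_conc):
            bad = [n for n, c in zip(pos_order, pos_conc) if c is None]
            raise ValueError(f"positive probes without parseable concentrations: {bad}")
        ann = pd.DataFrame(
            {"probe_class": [probe_classes[n] for n in counts.index],
             "concentration": conc},
            index=counts.index,
        )
        # catalogue order: content probes as read, positives by falling
        # concentration, negatives last
        codeset = CodeSet(ann)

    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return CountMatrix(counts, codeset, meta)


def _opt_float(v) -> float:
    if v is None or v == "":
        return np.nan
    return float(v)


# ---------------------------------------------------------------------------
# lane QC

@dataclass
class QcReport:
    """Per-lane pass/fail flags for the pre-normalization checks.

    ``table`` is indexed by lane with columns ``binding_density``,
    ``fov_ratio``, ``bd_pass``, ``fov_pass``, ``evaluable``, ``passed`` and
    ``reasons`` (semicolon-joined).  Lanes with missing metadata are flagged
    unevaluable and do not pass.
    """

    table: pd.DataFrame
    bd_range: tuple[float, float]
    min_fov_ratio: float

    @property
    def passing_lanes(self) -> pd.Index:
        return self.table.index[self.table["passed"]]

    @property
    def failing_lanes(self) -> pd.Index:
        return self.table.index[~self.table["passed"]]


def lane_qc(cm: CountMatrix,
            bd_range: tuple[float, float] = DEFAULT_BD_RANGE,
            min_fov_ratio: float = DEFAULT_MIN_FOV_RATIO) -> QcReport:
    """Flag lanes failing binding-density or field-of-view criteria.

    A lane passes iff its binding density lies inside ``bd_range``
    (inclusive) and ``fov_counted / fov_attempted >= min_fov_ratio``.
    """
    lo, hi = bd_range
    rows = []
    for lane, meta in cm.lane_meta.iterrows():
        bd = meta["binding_density"]
        fc, fa = meta["fov_counted"], meta["fov_attempted"]
        reasons = []
        evaluable = True
        if pd.isna(bd) or pd.isna(fc) or pd.isna(fa) or fa == 0:
            evaluable = False
            bd_pass = fov_pass = False
            reasons.append("unevaluable: missing lane metadata")
            ratio = np.nan
        else:
            ratio = fc / fa
            bd_pass = lo <= bd <= hi
            fov_pass = ratio >= min_fov_ratio
            if not bd_pass:
                reasons.append(f"binding density {bd:g} outside [{lo:g}, {hi:g}]")
            if not fov_pass:
                reasons.append(f"FOV ratio {ratio:.3f} below {min_fov_ratio:g}")
        rows.append({
            "binding_density": bd,
            "fov_ratio": ratio,
            "bd_pass": bd_pass,
            "fov_pass": fov_pass,
            "evaluable": evaluable,
            "passed": evaluable and bd_pass and fov_pass,
            "reasons": "; ".join(reasons),
        })
    table = pd.DataFrame(rows, index=cm.lane_meta.index)
    return QcReport(table, bd_range=tuple(bd_range), min_fov_ratio=min_fov_ratio)
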