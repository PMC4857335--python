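"""End-to-end orchestration: simulate/load -> QC -> two analysis paths.

Both analysis paths start from the same QC-passing raw counts but never
share post-processing state: the univariate path applies the full
three-step normalization before per-gene testing, while the pair-classifier
path applies only background correction and the genes-then-samples missing
filter.  All thresholds, the seed and library versions are serialized into
a run manifest; identical config + seed reproduces byte-identical
artifacts.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix, generate_codeset
from .de import run_univariate
from .io import (
    DEFAULT_BD_RANGE,
    DEFAULT_MIN_FOV_RATIO,
    lane_qc,
    load_counts,
    write_count_table,
    write_truth,
)
from .normalize import (
    CONTENT_FACTOR_RANGE,
    DEFAULT_MISSING_THRESHOLD,
    DEFAULT_TOP_N,
    POS_FACTOR_RANGE,
    normalize,
    tsp_preprocess,
)
from .simulate import SimulationParams, simulate_cohort
from .tsp import run_tsp

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


@dataclass
class PipelineConfig:
    """All knobs of one reproducible run; defaults are the standard ones."""

    # input: either a simulation or a path + dialect
    simulate: bool = True
    n_endogenous: int = 102
    n_housekeeping: int = 5
    simulation: Mapping | None = None      # extra SimulationParams fields
    input_path: str | None = None
    dialect: str = "count_table"
    metadata: str | None = None

    # thresholds
    bd_range: tuple[float, float] = DEFAULT_BD_RANGE
    min_fov_ratio: float = DEFAULT_MIN_FOV_RATIO
    pos_factor_range: tuple[float, float] = POS_FACTOR_RANGE
    content_factor_range: tuple[float, float] = CONTENT_FACTOR_RANGE
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD
    top_n: int = DEFAULT_TOP_N
    alpha: float = 0.05
    n_permutations: int = 100_000
    permutation_mode: str = "search"

    seed: int = 0
    outdir: str = "stromatsp_run"

    def to_dict(self) -> dict:
        """Analysis-relevant fields (output location excluded, so the
        manifest and its hash identify the analysis, not where it lands)."""
        d = asdict(self)
        d.pop("outdir")
        d["simulation"] = dict(self.simulation) if self.simulation else None
        for key in ("bd_range", "pos_factor_range", "content_factor_range"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("bd_range", "pos_factor_range", "content_factor_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(f"stage {name!r} failed: {err}") from err
    return wrap


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, float) and np.isnan(o):
        return None
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute one full run; returns a dict of artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- ingest ---------------------------------------------------------
    if config.simulate:
        codeset = _stage("simulate")(generate_codeset, config.n_endogenous,
                                     config.n_housekeeping)
        sim_kwargs = dict(config.simulation or {})
        sim_kwargs.setdefault("seed", config.seed)
        params = SimulationParams(**sim_kwargs)
        cm, truth = _stage("simulate")(simulate_cohort, codeset, params)
        artifacts["counts"] = write_count_table(cm, outdir / "counts.csv")
        artifacts["truth"] = write_truth(truth, outdir / "truth.json")
    else:
        if not config.input_path:
            raise PipelineError("stage 'ingest' failed: no input_path and simulate=False")
        cm = _stage("ingest")(load_counts, config.input_path, config.dialect,
                              config.metadata)

    # --- lane QC --------------------------------------------------------
    qc = _stage("lane_qc")(lane_qc, cm, config.bd_range, config.min_fov_ratio)
    qc.table.to_csv(outdir / "qc_report.tsv", sep="\t")
    artifacts["qc_report"] = outdir / "qc_report.tsv"
    cm_qc = cm.subset(lanes=qc.passing_lanes) if len(qc.passing_lanes) else None
    if cm_qc is None:
        raise PipelineError("stage 'lane_qc' failed: no lane passed QC")

    # --- univariate path ------------------------------------------------
    norm = _stage("normalize")(
        normalize, cm_qc,
        top_n=config.top_n,
        pos_factor_range=config.pos_factor_range,
        content_factor_range=config.content_factor_range,
        missing_threshold=config.missing_threshold,
        filter_order="samples_then_genes",
    )
    norm.factors.to_frame().to_csv(outdir / "factors.tsv", sep="\t")
    norm.values.to_csv(outdir / "normalized.tsv", sep="\t")
    _write_json(outdir / "exclusions_univariate.json", norm.ledger)
    artifacts["factors"] = outdir / "factors.tsv"
    artifacts["normalized"] = outdir / "normalized.tsv"
    artifacts["exclusions_univariate"] = outdir / "exclusions_univariate.json"

    de_table = _stage("univariate")(run_univariate, norm, alpha=config.alpha)
    de_table.to_csv(outdir / "de_table.tsv", sep="\t")
    artifacts["de_table"] = outdir / "de_table.tsv"

    # --- TSP path (raw counts, background-corrected only) ---------------
    prep = _stage("tsp_preprocess")(tsp_preprocess, cm_qc,
                                    missing_threshold=config.missing_threshold)
    _write_json(outdir / "exclusions_tsp.json", prep.ledger)
    artifacts["exclusions_tsp"] = outdir / "exclusions_tsp.json"
    tsp_result = _stage("tsp")(run_tsp, prep.values, prep.groups,
                               n_permutations=config.n_permutations,
                               seed=config.seed, mode=config.permutation_mode)
    _write_json(outdir / "tsp_result.json", tsp_result.to_dict())
    artifacts["tsp_result"] = outdir / "tsp_result.json"
    pd.Series(tsp_result.null_scores, name="null_score").to_csv(
        outdir / "tsp_null_scores.tsv", sep="\t", index=False)
    artifacts["tsp_null_scores"] = outdir / "tsp_null_scores.tsv"

    scatter = pd.DataFrame({
        tsp_result.gene_i: prep.values.loc[tsp_result.gene_i],
        tsp_result.gene_j: prep.values.loc[tsp_result.gene_j],
        "group": prep.groups,
    })
    from .tsp import classify_matrix
    preds, _ = classify_matrix(prep.values.loc[[tsp_result.gene_i,
                                                tsp_result.gene_j]], tsp_result)
    scatter["predicted"] = preds
    scatter.to_csv(outdir / "tsp_scatter.tsv", sep="\t")
    artifacts["tsp_scatter"] = outdir / "tsp_scatter.tsv"

    # --- manifest + report ----------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": sorted(str(p.name) for p in artifacts.values()),
    }
    _write_json(outdir / "manifest.json", manifest)
    artifacts["manifest"] = outdir / "manifest.json"

    artifacts["report"] = write_report(outdir, de_table, tsp_result, norm, qc,
                                       alpha=config.alpha)
    return {k: Path(v) for k, v in artifacts.items()}


def write_report(outdir: Path, de_table: pd.DataFrame, tsp_result, norm, qc,
                 alpha: float = 0.05) -> Path:
    """Human-readable run summary (ranked gene table + TSP section)."""
    outdir = Path(outdir)
    lines = ["# Run report", ""]

    lines += ["## Lane QC", "",
              f"{int(qc.table['passed'].sum())}/{len(qc.table)} lanes passed "
              f"(binding density in [{qc.bd_range[0]:g}, {qc.bd_range[1]:g}], "
              f"FOV ratio >= {qc.min_fov_ratio:g})", ""]
    failed = qc.table[~qc.table["passed"]]
    for lane, row in failed.iterrows():
        lines.append(f"- {lane}: {row['reasons']}")
    if len(failed):
        lines.append("")

    lines += ["## Exclusions (univariate path)", ""]
    if norm.ledger:
        for entry in norm.ledger:
            lines.append(f"- {entry['axis']} {entry['name']}: {entry['reason']}")
    else:
        lines.append("- none")
    lines.append("")

    n_dual = int(de_table["de_dual"].sum()) if len(de_table) else 0
    lines += ["## Univariate differential expression", "",
              f"{len(de_table)} genes tested; "
              f"{n_dual} dual-test calls at alpha = {alpha:g}"
              + (" (zero dual-test calls)" if n_dual == 0 else ""), ""]
    cols = ["p_welch", "p_mwu", "q", "auc", "log2fc"]
    header = "| gene | " + " | ".join(cols) + " |"
    lines += [header, "|" + "---|" * (len(cols) + 1)]
    for gene, row in de_table.head(10).iterrows():
        cells = " | ".join(f"{row[c]:.4g}" for c in cols)
        lines.append(f"| {gene} | {cells} |")
    lines.append("")

    lines += ["## Top-scoring pair", "",
              f"- pair: {tsp_result.gene_i} / {tsp_result.gene_j}",
              f"- score: {tsp_result.score:.3f}",
              f"- ordering Exp({tsp_result.gene_i}) > Exp({tsp_result.gene_j}) "
              f"votes {tsp_result.orientation}",
              f"- training accuracy: {tsp_result.n_correct}/{tsp_result.n_samples} "
              f"({100 * tsp_result.accuracy:.1f}%)"]
    if tsp_result.permutation_p is not None:
        lines += [f"- permutation p: {tsp_result.permutation_p:.4g} "
                  f"(corrected {tsp_result.permutation_p_corrected:.4g}, "
                  f"{tsp_result.n_permutations} permutations, "
                  f"mode {tsp_result.permutation_mode})"]
    lines.append("")

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
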