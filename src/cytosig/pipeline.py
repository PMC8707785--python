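"""End-to-end orchestration: censoring → normalization → QC → significance
grid → signature / top-k / panel covers → modulation → clustering, with a
reproducible report bundle.

Every artifact is a plain CSV/JSON file; the manifest records the package
version, the configuration and a SHA-256 per output, so identical inputs
and configuration yield a bit-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import DRUG
from .clustering import build_response_matrix, cluster, correlation_cluster
from .errors import ConfigurationError, QcFailure
from .normalize import normalize_by_global_sd, qc_controls
from .panels import matrix_from_topk, minimal_covers
from .ranktests import significance_grid
from .signatures import modulation_table, select_top_k, signature_table
from .study import StudyTable, apply_censoring, average_replicates, read_study

log = logging.getLogger("cytosig")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    measurements: str
    design: str
    limits: str
    out_dir: str
    alpha: float = 0.05
    k: int = 3
    signature_mode: str = "paired"       # per-donor pairing against own NC
    signature_strict: bool = True        # p < alpha
    topk_mode: str = "unpaired"          # pooled NC as one sample
    topk_strict: bool = False            # p <= alpha
    linkage: str = "complete"
    co_exposure_label: str = DRUG
    cohort: str | None = None            # optional cohort filter
    modulation_per_dose: bool = False
    bh: bool = False
    exact_cutoff: int = 12
    strict_qc: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    buf = io.StringIO()
    df.to_csv(buf, index=index, float_format="%.17g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _write_json(doc: dict, path: Path) -> None:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True,
                               ensure_ascii=False) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig,
                 table: StudyTable | None = None) -> dict:
    """Execute the full analysis and write the report bundle.

    ``table`` may be passed directly (e.g. a freshly simulated study);
    otherwise the three input CSVs named in the config are read.
    Returns the manifest dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if table is None:
        table = read_study(config.measurements, config.design, config.limits)
    if config.cohort is not None:
        subset = table.data[table.data["cohort"] == config.cohort]
        table = dataclasses.replace(table, data=subset.reset_index(drop=True))
    design, panel = table.design, table.panel

    log.info("censoring substitution on %d records", table.n_records)
    censored = apply_censoring(table)
    norm = normalize_by_global_sd(censored.data)
    if norm.zero_variance:
        log.warning("zero-variance cytokines passed through unscaled: %s",
                    list(norm.zero_variance))

    qc = qc_controls(norm, alpha=config.alpha,
                     exact_cutoff=config.exact_cutoff)
    log.info("QC overall pass: %s", qc.overall_pass)

    averaged = average_replicates(norm.data)

    grid_sig = significance_grid(
        averaged, design, panel, alpha=config.alpha,
        mode=config.signature_mode, strict=config.signature_strict,
        exact_cutoff=config.exact_cutoff, bh=config.bh)
    if (config.topk_mode, config.topk_strict) == (
            config.signature_mode, config.signature_strict):
        grid_topk = grid_sig
    else:
        grid_topk = significance_grid(
            averaged, design, panel, alpha=config.alpha,
            mode=config.topk_mode, strict=config.topk_strict,
            exact_cutoff=config.exact_cutoff, bh=config.bh)

    stimuli = [s for s in design if s in set(grid_sig["stimulus"])]
    signatures = signature_table(grid_sig, stimuli, alpha=config.alpha,
                                 strict=config.signature_strict, panel=panel)
    topk_calls = [
        select_top_k(grid_topk, s, k=config.k, alpha=config.alpha,
                     strict=config.topk_strict, panel=panel)
        for s in stimuli
    ]
    induction = matrix_from_topk(topk_calls, panel)
    try:
        covers = minimal_covers(induction).to_dict(induction)
    except Exception as exc:                       # no cover possible
        covers = {"error": str(exc)}

    has_co = (table.data["co_exposure"] == config.co_exposure_label).any()
    modulation = None
    if has_co:
        modulation = modulation_table(
            averaged, config.co_exposure_label, alpha=config.alpha,
            per_dose=config.modulation_per_dose,
            exact_cutoff=config.exact_cutoff, panel=panel)

    response = build_response_matrix(averaged)
    dend_rows = cluster(response, axis="rows", method=config.linkage)
    dend_cols = cluster(response, axis="columns", method=config.linkage)
    corr, dend_corr, corr_excluded = correlation_cluster(
        response, axis="columns", method=config.linkage)

    # ---- write the bundle ----------------------------------------------
    paths: dict[str, Path] = {}

    def emit_csv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        paths[name] = out / f"{name}.csv"
        _write_csv(df, paths[name], index=index)

    def emit_json(name: str, doc: dict) -> None:
        paths[name] = out / f"{name}.json"
        _write_json(doc, paths[name])

    emit_json("qc_report", qc.to_dict())
    emit_csv("qc_replicate_cv", qc.replicate_cv)
    emit_csv("significance_grid", grid_sig)
    if grid_topk is not grid_sig:
        emit_csv("significance_grid_topk", grid_topk)
    emit_csv("signatures", signatures)
    paths["induction_matrix"] = out / "induction_matrix.csv"
    induction.to_csv(paths["induction_matrix"])
    emit_json("covers", covers)
    if modulation is not None:
        emit_csv("modulation", modulation)
    emit_csv("response_matrix", response, index=True)
    emit_csv("correlation_matrix", corr, index=True)
    for name, dend in (("dendrogram_rows", dend_rows),
                       ("dendrogram_columns", dend_cols),
                       ("dendrogram_correlation", dend_corr)):
        paths[name] = out / f"{name}.nwk"
        dend.write_newick(paths[name])
    emit_json("leaf_orders", {
        "rows": dend_rows.leaf_order,
        "columns": dend_cols.leaf_order,
        "correlation": dend_corr.leaf_order,
        "correlation_excluded": corr_excluded,
    })

    manifest = {
        "package": "cytosig",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "qc_overall_pass": qc.overall_pass,
        "zero_variance_cytokines": list(norm.zero_variance),
        "n_records": int(table.n_records),
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)}
                    for name, p in sorted(paths.items())},
    }
    _write_json(manifest, out / "manifest.json")

    if config.strict_qc and not qc.overall_pass:
        raise QcFailure("QC failed: not every cytokine reads higher in PC "
                        "than NC; see qc_report.json")
    return manifest
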