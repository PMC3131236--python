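"""End-to-end orchestration: simulate or load inputs, score, analyse, report.

A run is driven by a single config (YAML/JSON or dict) holding either input
file paths or a simulation block — never both.  Every output embeds the
seed and the normalised config, and a run is byte-identical for identical
config + seed (reports carry no timestamps).  Row counts at every join and
filter are logged and reported, so attrition between data sources is always
explicit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from bivalency import io as bio
from bivalency import signal as bsignal
from bivalency import stats as bstats
from bivalency.simulate import GroundTruth, SimulationConfig, config_manifest, simulate_genes, simulate_reads

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Normalised configuration for one pipeline run.

    Exactly one of ``inputs`` (file paths) or ``simulate`` (generator
    parameters) must be set.  Defaults mirror the headline analysis
    settings: a -3 kb/+3 kb promoter window, moving-average window 100 with
    step 1, top-20% H3K27me3 subset, allosome exclusion on.
    """

    simulate: dict | None = None
    inputs: dict | None = None
    upstream: int = 3000
    downstream: int = 3000
    pseudocount: float | str = "auto"
    overlap_rule: str = "any"
    raw_counts: bool = False
    lower_cut: float = 1.0
    top_fraction: float = 0.2
    top_key: str = "k27_norm"
    ma_window: int = 100
    ma_step: int = 1
    exclude_allosomes: bool = True
    welch: bool = False
    seed: int = 0
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' must be configured")
        if not 0 < self.top_fraction <= 1:
            raise ConfigError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if self.overlap_rule not in bsignal.OVERLAP_RULES:
            raise ConfigError(f"unknown overlap_rule {self.overlap_rule!r}")
        if self.ma_window < 1 or self.ma_step < 1:
            raise ConfigError("ma_window and ma_step must be >= 1")
        if self.inputs is not None:
            required = {"k4_bed", "k27_bed", "annotation", "expression"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs block missing keys: {sorted(missing)}")
            unknown = set(self.inputs) - required - {"annotation_one_based"}
            if unknown:
                raise ConfigError(f"unknown keys in inputs block: {sorted(unknown)}")
        if self.simulate is not None:
            known = {f.name for f in dc_fields(SimulationConfig)}
            unknown = set(self.simulate) - known
            if unknown:
                raise ConfigError(f"unknown keys in simulate block: {sorted(unknown)}")


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load and normalise a config from a YAML/JSON file or a dict.

    Unknown keys are an error (never silently ignored); missing keys take
    their documented defaults.  An empty config is valid only by adding a
    ``simulate: {}`` or ``inputs:`` block, since one input mode must be
    chosen; a bare ``simulate: {}`` block runs the default simulation.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{source}: config must be a mapping")
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    k4 = bio.read_bed(paths["k4_bed"], mark="H3K4me3")
    k27 = bio.read_bed(paths["k27_bed"], mark="H3K27me3")
    genes = bio.read_annotation(paths["annotation"], one_based=paths.get("annotation_one_based"))
    expr = bio.read_expression(paths["expression"])
    return genes, expr, k4, k27, None


def _simulate_inputs(cfg: PipelineConfig):
    sim_kwargs = dict(cfg.simulate or {})
    sim_kwargs.setdefault("seed", cfg.seed)
    sim_cfg = SimulationConfig(**sim_kwargs)
    genes, expr, truth = simulate_genes(sim_cfg)
    k4 = simulate_reads(genes, truth, sim_cfg, "H3K4me3")
    k27 = simulate_reads(genes, truth, sim_cfg, "H3K27me3")
    return genes, expr, k4, k27, truth


def run(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the full pipeline and return the machine-readable run report.

    Stages: acquire inputs (load or simulate) -> score genes (window counts,
    RPM, ratio) -> join to expression with filtering -> expression bins and
    box statistics -> ranked moving-average curve with Spearman -> top-K27
    subset -> detection-class summary (when class labels exist).  When
    ``output_dir`` is set, the report (JSON) and score table (TSV) are
    written there.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    cfg = config
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    stage = "inputs"
    counts: dict[str, int] = {}
    try:
        if cfg.simulate is not None:
            genes, expr, k4, k27, truth = _simulate_inputs(cfg)
        else:
            genes, expr, k4, k27, truth = _load_inputs(cfg)
        counts["genes"] = len(genes)
        counts["expression_rows"] = len(expr)
        counts["k4_reads"] = k4.library_size
        counts["k27_reads"] = k27.library_size

        stage = "score"
        spec = bsignal.WindowSpec(cfg.upstream, cfg.downstream)
        scores = bsignal.score_genes(
            genes, k4, k27, spec,
            pseudocount=cfg.pseudocount,
            overlap_rule=cfg.overlap_rule,
            raw_counts=cfg.raw_counts,
        )
        counts["scored_genes"] = len(scores)

        stage = "filter"
        joined = bstats.filter_genes(
            scores, expr, exclude_allosomes=cfg.exclude_allosomes
        )
        counts["joined_genes"] = len(joined)

        stage = "bins"
        expressed = (
            joined["expressed"].astype(bool).to_numpy()
            if "expressed" in joined and joined["expressed"].notna().all()
            else (joined["expression"].to_numpy() > 0)
        )
        labels, ref_mean = bstats.assign_expression_bins(
            joined["expression"].to_numpy(), expressed, lower_cut=cfg.lower_cut
        )
        summary = bstats.bin_summary(joined["ratio"].to_numpy(), labels, welch=cfg.welch)
        summary.reference_mean = ref_mean

        stage = "curve"
        curve = bstats.moving_average_curve(
            joined["expression"].to_numpy(),
            joined["ratio"].to_numpy(),
            window=cfg.ma_window,
            step=cfg.ma_step,
            gene_ids=joined["gene_id"].to_numpy(),
        )

        stage = "top_subset"
        subset = bstats.top_quantile_subset(joined, key=cfg.top_key, fraction=cfg.top_fraction)
        sub_curve_window = min(cfg.ma_window, max(2, len(subset)))
        sub_r, sub_p = bstats.spearman(
            subset["expression"].to_numpy(), subset["ratio"].to_numpy()
        )

        stage = "detection_classes"
        detection = None
        if truth is not None:
            merged = joined.merge(
                truth.table[["gene_id", "detection_class"]], on="gene_id", how="inner"
            )
            detection = bstats.detection_class_summary(
                merged["ratio"].to_numpy(), merged["detection_class"].to_numpy()
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "software_version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "row_counts": counts,
        "scores": {
            "n_genes": len(scores),
            "pseudocount": float(scores["pseudocount"].iloc[0]),
        },
        "bin_summary": {
            "reference_mean": summary.reference_mean,
            "bins": summary.bins,
            "tests": summary.tests,
        },
        "moving_average": {
            "window": curve.window,
            "step": curve.step,
            "y": curve.y.tolist(),
            "spearman_r": curve.spearman_r,
            "p_value": curve.p_value,
        },
        "top_subset": {
            "key": cfg.top_key,
            "fraction": cfg.top_fraction,
            "size": len(subset),
            "gene_ids": subset["gene_id"].tolist(),
            "spearman_r": sub_r,
            "p_value": sub_p,
            "curve_window": sub_curve_window,
        },
        "detection_classes": detection,
        "warnings": [],
    }
    if truth is not None:
        report["ground_truth"] = {
            "spearman_rho": truth.spearman_rho,
            "manifest": config_manifest(truth.config),
        }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        bio.write_json(report, out / "report.json")
        bio.write_tsv(scores, out / "scores.tsv")
        if truth is not None:
            bio.write_tsv(truth.table, out / "ground_truth.tsv")
    return report


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
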