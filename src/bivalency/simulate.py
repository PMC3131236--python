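"""Seeded generators for every input the pipeline consumes, with ground truth.

The generator emulates the statistical structure the downstream analyses
assume rather than any particular dataset:

* a gene population with a silent mass (zero expression) plus a log-normal
  expressed tail;
* uniformly high H3K27me3 promoter occupancy (the bivalent background) with
  H3K4me3 occupancy coupled monotonically — plus Gaussian noise — to
  log1p(expression);
* ChIP-seq reads as a Gaussian pileup around each TSS (focal reads, Poisson
  in number, proportional to occupancy) over a uniform Poisson background;
* qPCR Ct values as noisy negative log2 signals;
* single-cell RT-PCR wells with Bernoulli control positivity and
  zero-inflated, zero-truncated Poisson transcript counts thinned by a
  per-copy detection efficiency.

Every operation draws from its own RNG stream derived from (seed,
operation name), so adding operations never perturbs earlier draws, and all
outputs are byte-identical across runs with the same seed and config.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from bivalency.io import GeneAnnotation, ReadSet

TSS_MIN_SPACING = 20_000  # bp between simulated TSSs

# pseudocount on occupancies when forming the ground-truth log-ratio
OCCUPANCY_EPS = 0.01


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One RNG stream per (seed, operation); stable across code growth."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic bivalent-gene population.

    Defaults describe a 2,000-gene population on a 100-Mb chromosome with a
    40% silent mass, log-normal expression for the rest, high Polycomb
    (H3K27me3) occupancy everywhere and H3K4me3 occupancy rising with
    log1p(expression), read out at ~100 focal reads per fully occupied
    promoter over a 1 read/100 kb background.
    """

    n_genes: int = 2000
    chrom_length: int = 100_000_000
    chrom_name: str = "chr1"
    seed: int = 0
    p_silent: float = 0.4
    expr_log_mean: float = 1.0
    expr_log_sd: float = 1.0
    k27_occupancy_high: float = 0.8
    k4_basal: float = 0.1
    k4_slope: float = 0.3
    occupancy_noise_sd: float = 0.05
    reads_per_gene_scale: float = 100.0
    background_rate: float = 1e-5
    kernel_sd: float = 500.0
    read_length: int = 36

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.p_silent <= 1.0:
            raise ValueError("p_silent must be a probability")
        if self.kernel_sd <= 0:
            raise ValueError("kernel_sd must be > 0")
        if self.reads_per_gene_scale < 0:
            raise ValueError("reads_per_gene_scale must be >= 0")
        for name in ("k27_occupancy_high", "k4_basal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class GroundTruth:
    """Per-gene truth table plus the population-level rank correlation.

    ``spearman_rho`` is the Spearman correlation between the log2 ratio of
    (pseudocounted) true occupancies and expression, computed — never
    assumed — on the emitted table.
    """

    table: pd.DataFrame  # gene_id, expression, k4_occupancy, k27_occupancy, detection_class
    spearman_rho: float
    config: SimulationConfig

    def occupancy(self, mark: str) -> pd.Series:
        col = {"H3K4me3": "k4_occupancy", "H3K27me3": "k27_occupancy"}.get(mark)
        if col is None:
            raise ValueError(f"unknown mark {mark!r}")
        return self.table.set_index("gene_id")[col]


def _truth_log_ratio(k4: np.ndarray, k27: np.ndarray) -> np.ndarray:
    return np.log2((k4 + OCCUPANCY_EPS) / (k27 + OCCUPANCY_EPS))


def simulate_genes(
    config: SimulationConfig,
) -> tuple[list[GeneAnnotation], pd.DataFrame, GroundTruth]:
    """Draw a gene population: annotation, expression table and ground truth.

    TSSs are placed uniformly at random with >= 20 kb spacing; strands are
    Bernoulli(0.5); expression is 0 with probability ``p_silent`` and
    log-normal otherwise.  Detection classes (for single-cell-style
    summaries) are ``absent`` for silent genes, ``sporadic`` for expressed
    genes below the mean of expressed genes, and ``all_cells`` above it.
    """
    cfg = config
    if cfg.n_genes * TSS_MIN_SPACING > cfg.chrom_length:
        raise ValueError(
            f"cannot place {cfg.n_genes} TSSs with {TSS_MIN_SPACING} bp spacing "
            f"on a {cfg.chrom_length} bp chromosome"
        )
    rng = _rng(cfg.seed, "simulate_genes")

    # sorted uniforms on the shrunk interval + deterministic offsets => min gap
    slack = cfg.chrom_length - (cfg.n_genes - 1) * TSS_MIN_SPACING
    u = np.sort(rng.uniform(0, slack, size=cfg.n_genes))
    tss = (u + np.arange(cfg.n_genes) * TSS_MIN_SPACING).astype(np.int64)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")

    silent = rng.random(cfg.n_genes) < cfg.p_silent
    expression = np.where(
        silent, 0.0, rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, size=cfg.n_genes)
    )

    noise_k4 = rng.normal(0.0, cfg.occupancy_noise_sd, size=cfg.n_genes)
    noise_k27 = rng.normal(0.0, cfg.occupancy_noise_sd, size=cfg.n_genes)
    k4 = np.clip(cfg.k4_basal + cfg.k4_slope * np.log1p(expression) + noise_k4, 0.0, 1.0)
    k27 = np.clip(cfg.k27_occupancy_high + noise_k27, 0.0, 1.0)

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    genes = [
        GeneAnnotation(gid, cfg.chrom_name, int(t), str(s))
        for gid, t, s in zip(gene_ids, tss, strands)
    ]

    expressed = expression > 0
    mean_expr = expression[expressed].mean() if expressed.any() else 0.0
    detection_class = np.where(
        ~expressed, "absent", np.where(expression < mean_expr, "sporadic", "all_cells")
    )

    expr_table = pd.DataFrame(
        {"gene_id": gene_ids, "expression": expression, "expressed": expressed}
    )
    truth_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "expression": expression,
            "k4_occupancy": k4,
            "k27_occupancy": k27,
            "detection_class": detection_class,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = float(stats.spearmanr(_truth_log_ratio(k4, k27), expression).statistic)
    if not np.isfinite(rho):
        rho = 0.0  # degenerate population (constant expression or ratio)
    return genes, expr_table, GroundTruth(truth_table, rho, cfg)


def simulate_reads(
    annotation: list[GeneAnnotation],
    truth: GroundTruth,
    config: SimulationConfig,
    mark: str,
) -> ReadSet:
    """Simulate one ChIP library for ``mark`` over the gene population.

    Per gene: focal read count ~ Poisson(reads_per_gene_scale x occupancy),
    start positions ~ Normal(TSS, kernel_sd), rounded and clipped to the
    chromosome.  Background count ~ Poisson(background_rate x chrom_length),
    placed uniformly.  All reads have fixed length ``read_length``.
    """
    if mark not in ("H3K4me3", "H3K27me3"):
        raise ValueError(f"unknown mark {mark!r}; expected H3K4me3 or H3K27me3")
    cfg = config
    rng = _rng(cfg.seed, f"simulate_reads/{mark}")
    occ = truth.occupancy(mark)

    starts: list[np.ndarray] = []
    max_start = cfg.chrom_length - cfg.read_length
    for gene in annotation:
        lam = cfg.reads_per_gene_scale * float(occ[gene.gene_id])
        n_focal = rng.poisson(lam)
        if n_focal:
            pos = np.rint(rng.normal(gene.tss, cfg.kernel_sd, size=n_focal))
            starts.append(np.clip(pos, 0, max_start).astype(np.int64))
    n_bg = rng.poisson(cfg.background_rate * cfg.chrom_length)
    if n_bg:
        starts.append(rng.integers(0, max_start + 1, size=n_bg))

    if starts:
        all_starts = np.concatenate(starts)
    else:
        all_starts = np.empty(0, dtype=np.int64)
    reads = [
        (cfg.chrom_name, int(s), int(s) + cfg.read_length) for s in all_starts
    ]
    return ReadSet(mark=mark, reads=reads)


@dataclass
class SingleCellPlate:
    """Binary calls from a multiplex single-cell RT-PCR plate."""

    wells: list[tuple[str, str, str]]  # (well_id, control_call, target_call); calls pos/neg
    control_gene: str = "OCT4"
    target_gene: str = "HBA"

    def __post_init__(self) -> None:
        ids = [w[0] for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well_id values must be unique")
        for wid, c, t in self.wells:
            if c not in ("pos", "neg") or t not in ("pos", "neg"):
                raise ValueError(f"well {wid}: calls must be 'pos' or 'neg'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.wells, columns=["well_id", "control_call", "target_call"])


def simulate_single_cell_plate(
    n_wells: int,
    p_control_positive: float,
    p_on: float,
    mean_copies: float,
    detect_eff: float,
    seed: int,
    control_gene: str = "OCT4",
    target_gene: str = "HBA",
) -> SingleCellPlate:
    """Simulate a single-cell RT-PCR plate.

    Per well: control positive ~ Bernoulli(p_control_positive); target
    transcript copies are 0 with probability 1 - p_on, else drawn from a
    Poisson(mean_copies) conditioned on >= 1; the target scores positive iff
    at least one copy is detected under per-copy detection probability
    ``detect_eff``.
    """
    for name, p in (
        ("p_control_positive", p_control_positive),
        ("p_on", p_on),
        ("detect_eff", detect_eff),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {p}")
    if mean_copies < 0:
        raise ValueError("mean_copies must be >= 0")
    rng = _rng(seed, "simulate_single_cell_plate")

    control = rng.random(n_wells) < p_control_positive
    on = rng.random(n_wells) < p_on
    # zero-truncated Poisson via inverse CDF on U(P(X=0), 1)
    copies = np.zeros(n_wells, dtype=np.int64)
    if on.any() and mean_copies > 0:
        n_on = int(on.sum())
        u = rng.uniform(stats.poisson.cdf(0, mean_copies), 1.0, size=n_on)
        copies[on] = stats.poisson.ppf(u, mean_copies).astype(np.int64)
    elif on.any():
        copies[on] = 1  # degenerate mean: conditioning on >=1 forces one copy
    detected = rng.binomial(copies, detect_eff) >= 1

    wells = [
        (
            f"W{i:05d}",
            "pos" if control[i] else "neg",
            "pos" if detected[i] else "neg",
        )
        for i in range(n_wells)
    ]
    return SingleCellPlate(wells, control_gene=control_gene, target_gene=target_gene)


def simulate_qpcr_plate(
    true_signals: Mapping[tuple[str, str, str], float],
    ct_intercept: float = 30.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR plate from true template signals.

    ``true_signals`` maps (sample, amplicon, channel) -> signal > 0, with
    channel in {chip, input}.  Each replicate's Ct is
    ``ct_intercept - log2(signal) + Normal(0, noise_sd)`` — one cycle per
    twofold template, perfect amplification efficiency.
    """
    rng = _rng(seed, "simulate_qpcr_plate")
    rows = []
    for (sample, amplicon, channel), signal in true_signals.items():
        if signal <= 0:
            raise ValueError(
                f"signal must be > 0 for ({sample}, {amplicon}, {channel}), got {signal}"
            )
        for rep in range(1, n_replicates + 1):
            ct = ct_intercept - np.log2(signal) + rng.normal(0.0, noise_sd)
            rows.append((sample, amplicon, channel, rep, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "amplicon", "channel", "replicate", "ct"])


def config_manifest(config: SimulationConfig) -> dict:
    """Full generator configuration as a JSON-ready manifest."""
    return {"generator": "bivalency.simulate", "config": asdict(config)}
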