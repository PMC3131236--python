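"""Population-level analyses of the K4/K27 ratio versus expression.

Covers the global comparisons typically drawn for a bivalent gene set:
joining ratio scores to expression with X/Y exclusion, three-way expression
binning (above the mean of expressed genes; between the mean and 1; below
1), box statistics with pairwise Student's t tests, ranked moving-average
curves with a Spearman rank correlation, top-quantile subsets (e.g. the 20%
most H3K27me3-modified genes), and per-detection-class summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

BIN_LABELS = ("below_one", "mean_to_one", "above_mean")
DETECTION_CLASSES = ("all_cells", "sporadic", "absent")


def filter_genes(
    scores: pd.DataFrame,
    expression: pd.DataFrame,
    exclude_allosomes: bool = True,
    require_both: bool = True,
) -> pd.DataFrame:
    """Join ratio scores to expression by gene_id, with X/Y exclusion.

    Expression and ChIP data typically come from different sources (here
    even different cell lines of different sex), so allosomal genes are
    excluded by default and unmatched identifiers are counted and logged.
    ``require_both=False`` keeps score rows without expression (NaN).
    """
    how = "inner" if require_both else "left"
    joined = scores.merge(expression, on="gene_id", how=how)
    n_scores, n_expr = len(scores), len(expression)
    matched = joined["gene_id"].isin(expression["gene_id"]).sum() if not require_both else len(joined)
    logger.info(
        "join: %d score rows, %d expression rows, %d matched (%d score-only, %d expression-only)",
        n_scores, n_expr, matched, n_scores - matched, n_expr - matched,
    )
    if exclude_allosomes and "is_allosome" in joined.columns:
        before = len(joined)
        joined = joined[~joined["is_allosome"].astype(bool)].reset_index(drop=True)
        logger.info("allosome exclusion removed %d gene(s)", before - len(joined))
    if joined.empty:
        raise ValueError("gene join is empty: no shared gene_id between scores and expression")
    return joined.reset_index(drop=True)


def assign_expression_bins(
    expression_values: np.ndarray,
    expressed_mask: np.ndarray,
    lower_cut: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Assign each gene to one of three expression bins.

    The reference mean ``m`` is computed over expressed genes only.  A gene
    is ``above_mean`` if value > m, ``mean_to_one`` if lower_cut <= value
    <= m, and ``below_one`` if value < lower_cut.  Boundary rule: closed at
    ``lower_cut``, closed at the mean (strictly above the mean is required
    for ``above_mean``).  Returns (labels, m).
    """
    values = np.asarray(expression_values, dtype=float)
    mask = np.asarray(expressed_mask, dtype=bool)
    if (values < 0).any():
        raise ValueError("expression values must be >= 0")
    if not mask.any():
        raise ValueError("expressed_mask selects no genes; cannot compute the reference mean")
    m = float(values[mask].mean())
    if m < lower_cut:
        raise ValueError(
            f"mean of expressed genes ({m:.4g}) is below the lower cut ({lower_cut}); "
            "bins would be ill-ordered — check units or the expressed mask"
        )
    labels = np.where(
        values > m, "above_mean", np.where(values >= lower_cut, "mean_to_one", "below_one")
    )
    return labels, m


@dataclass
class BinSummary:
    """Box statistics per expression bin plus pairwise t tests."""

    bins: dict[str, dict] = field(default_factory=dict)  # label -> stats dict
    tests: list[dict] = field(default_factory=list)  # pairwise t tests
    reference_mean: float | None = None


def _box_stats(values: np.ndarray) -> dict:
    q25, q50, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return {
        "n": int(len(values)),
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "whisker_low": float(inside.min()) if len(inside) else float(q25),
        "whisker_high": float(inside.max()) if len(inside) else float(q75),
        "outliers": sorted(float(v) for v in outliers),
        "mean": float(values.mean()),
    }


def bin_summary(
    ratios: np.ndarray,
    bins: np.ndarray,
    welch: bool = False,
) -> BinSummary:
    """Quartiles, 1.5xIQR whiskers, outliers and mean per bin; pairwise t tests.

    The default test is the classic pooled-variance unpaired Student's t
    (two-sided); ``welch=True`` switches to the unequal-variance form.
    Bins with fewer than two members are summarised but excluded from tests
    (with a warning).
    """
    ratios = np.asarray(ratios, dtype=float)
    bins = np.asarray(bins)
    summary = BinSummary()
    groups: dict[str, np.ndarray] = {}
    for label in BIN_LABELS:
        vals = ratios[bins == label]
        if len(vals):
            groups[label] = vals
            summary.bins[label] = _box_stats(vals)
    for a, b in itertools.combinations([l for l in BIN_LABELS if l in groups], 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            warnings.warn(f"bin pair ({a}, {b}) skipped: fewer than 2 values in a bin")
            continue
        res = sps.ttest_ind(groups[a], groups[b], equal_var=not welch)
        summary.tests.append(
            {"bin_a": a, "bin_b": b, "t": float(res.statistic), "p": float(res.pvalue)}
        )
    return summary


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 10).

    Enumerates all n! permutations of the y ranks; p is the fraction with
    |rho| >= |rho_obs| (within numerical tolerance).
    """
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        return 1.0
    n = len(x)
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    perm_iter = itertools.permutations(ry_c)
    chunk_size = 100_000
    while True:
        chunk = list(itertools.islice(perm_iter, chunk_size))
        if not chunk:
            break
        mat = np.asarray(chunk)
        rhos = mat @ rx_c / denom
        count += int((np.abs(rhos) >= target).sum())
        total += len(chunk)
    return count / total


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    p-value by exact permutation for n <= ``exact_max_n``, otherwise by the
    usual t approximation.  Degenerate (constant) inputs give r = 0 with a
    warning rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        warnings.warn("Spearman undefined for constant input; reporting r = 0")
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p


@dataclass
class MovingAverageCurve:
    """Ranked moving-average of ratios against expression order."""

    window: int
    step: int
    x: np.ndarray  # rank index of the window start (0-based)
    y: np.ndarray  # windowed mean ratio
    spearman_r: float  # computed on the unwindowed gene-level pairs
    p_value: float
    order: pd.DataFrame  # the ranked gene table the curve was built from


def moving_average_curve(
    expression: np.ndarray,
    ratios: np.ndarray,
    window: int = 100,
    step: int = 1,
    gene_ids: np.ndarray | None = None,
) -> MovingAverageCurve:
    """Rank genes by expression (ascending) and average ratios in a sliding window.

    ``y[i]`` is the mean ratio over ranks [i, i+window); the Spearman
    correlation and p are computed on the unwindowed per-gene
    (expression, ratio) pairs.  Expression ties are broken by gene_id so the
    ranking — hence the curve — is deterministic.
    """
    expression = np.asarray(expression, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    n = len(expression)
    if n < window:
        raise ValueError(f"n = {n} < window = {window}; use a smaller window")
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(n)])
    df = pd.DataFrame({"gene_id": gene_ids, "expression": expression, "ratio": ratios})
    df = df.sort_values(["expression", "gene_id"], kind="mergesort").reset_index(drop=True)

    csum = np.concatenate([[0.0], np.cumsum(df["ratio"].to_numpy())])
    starts = np.arange(0, n - window + 1, step)
    y = (csum[starts + window] - csum[starts]) / window

    r, p = spearman(expression, ratios)
    return MovingAverageCurve(window, step, starts, y, r, p, df)


def top_quantile_subset(
    scores: pd.DataFrame,
    key: str = "k27_norm",
    fraction: float = 0.2,
) -> pd.DataFrame:
    """The genes with the largest ``key`` values; size = round-half-up(fraction x n).

    Ties at the boundary are broken by gene_id (ascending) for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(scores)
    size = math.floor(fraction * n + 0.5)
    ordered = scores.sort_values([key, "gene_id"], ascending=[False, True], kind="mergesort")
    return ordered.head(size).reset_index(drop=True)


def detection_class_summary(
    ratios: np.ndarray,
    classes: np.ndarray,
) -> dict[str, dict]:
    """Per-detection-class ratio lists and means.

    Classes are the single-cell expression patterns: present in all cells
    analysed, present sporadically, or absent.  Empty classes report a
    ``None`` mean, never 0.
    """
    ratios = np.asarray(ratios, dtype=float)
    classes = np.asarray(classes)
    unknown = set(classes) - set(DETECTION_CLASSES)
    if unknown:
        raise ValueError(f"unknown detection class label(s): {sorted(unknown)}")
    out: dict[str, dict] = {}
    for label in DETECTION_CLASSES:
        vals = ratios[classes == label]
        out[label] = {
            "n": int(len(vals)),
            "values": [float(v) for v in vals],
            "mean": float(vals.mean()) if len(vals) else None,
        }
    return out
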