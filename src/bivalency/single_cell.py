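"""Single-cell RT-PCR scoring and copies-per-expressing-cell estimation.

A multiplex single-cell RT-PCR plate is scored by first gating on the
control transcript (OCT4 in ES cells, HPRT in lymphoblastoid cells): only
control-positive wells are informative.  The expressing fraction is the
share of informative wells positive for the target, with a Wilson score
interval.  Combining that fraction with a reference cell's absolute
transcript content and the population-level expression deficit yields the
mean mRNA copies per expressing cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from bivalency.simulate import SingleCellPlate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressingFraction:
    """Fraction of informative (control-positive) wells positive for the target."""

    n_wells_total: int
    n_informative: int
    n_positive: int
    fraction: float
    ci_low: float
    ci_high: float


def score_plate(plate: SingleCellPlate, ci_level: float = 0.95) -> ExpressingFraction:
    """Score a plate: informative-well gating, positive fraction, Wilson CI.

    Informative wells are those positive for the control transcript; the
    fraction is target-positives among informative wells.  Target-positive
    but control-negative wells are excluded (and logged) — without the
    control there is no evidence a cell was present and lysed.
    """
    n_total = len(plate.wells)
    informative = [w for w in plate.wells if w[1] == "pos"]
    if not informative:
        raise ValueError("no informative (control-positive) wells on the plate")
    n_informative = len(informative)
    n_positive = sum(1 for w in informative if w[2] == "pos")
    excluded_positive = sum(1 for w in plate.wells if w[1] == "neg" and w[2] == "pos")
    if excluded_positive:
        logger.info(
            "%d target-positive but control-negative well(s) excluded from scoring",
            excluded_positive,
        )
    fraction = n_positive / n_informative
    lo, hi = fraction_ci(n_positive, n_informative, level=ci_level)
    return ExpressingFraction(n_total, n_informative, n_positive, fraction, lo, hi)


def fraction_ci(n_positive: int, n_informative: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for the expressing fraction.

    Preferred over the Wald interval because single-cell counts are small
    and often extreme (e.g. 0 positives out of 110 wells), where Wald
    degenerates to a zero-width interval.
    """
    if not 0 <= n_positive <= n_informative:
        raise ValueError("need 0 <= n_positive <= n_informative")
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    lo, hi = proportion_confint(n_positive, n_informative, alpha=1 - level, method="wilson")
    # Wilson bounds are algebraically 0 (resp. 1) at the extremes; clamp the
    # floating-point residue so boundary cases report exact limits.
    if n_positive == 0:
        lo = 0.0
    if n_positive == n_informative:
        hi = 1.0
    return float(lo), float(hi)


@dataclass(frozen=True)
class CopiesEstimate:
    """Mean mRNA copies per expressing cell, from population-level inputs."""

    molecules_per_reference_cell: float
    gene_fraction_of_reference: float
    relative_deficit: float
    expressing_fraction: float
    population_mean_copies: float
    copies_per_expressing_cell: float
    rounded_range: tuple[int, int]
    interval: tuple[float, float] | None = None  # from a deficit range, when given


def copies_per_expressing_cell(
    molecules_per_reference_cell: float,
    gene_fraction: float,
    relative_deficit: float | tuple[float, float],
    expressing_fraction: float,
) -> CopiesEstimate:
    """Estimate mean transcript copies per expressing cell.

    The population mean is ``molecules x gene_fraction / deficit``: a
    reference cell's absolute transcript count, scaled to the gene of
    interest (``gene_fraction``, e.g. 0.5 when the reference count covers
    two paralogous genes jointly), divided by how many-fold lower the
    study population's bulk expression is.  Dividing by the expressing
    fraction concentrates that mean onto the cells that actually express.

    ``relative_deficit`` may be a (low, high) range; the point estimate
    then uses the midpoint and ``interval`` carries the range-propagated
    bounds.
    """
    if isinstance(relative_deficit, (tuple, list)):
        lo, hi = float(relative_deficit[0]), float(relative_deficit[1])
        if lo <= 0 or hi <= 0:
            raise ValueError("relative_deficit bounds must be > 0")
        deficit = (lo + hi) / 2.0
        deficit_range: tuple[float, float] | None = (min(lo, hi), max(lo, hi))
    else:
        deficit = float(relative_deficit)
        deficit_range = None
    if molecules_per_reference_cell <= 0:
        raise ValueError("molecules_per_reference_cell must be > 0")
    if not 0 < gene_fraction <= 1:
        raise ValueError("gene_fraction must be in (0, 1]")
    if deficit <= 0:
        raise ValueError("relative_deficit must be > 0")
    if expressing_fraction <= 0:
        raise ValueError("expressing_fraction must be > 0 (no expressing cells: undefined)")
    if expressing_fraction > 1:
        raise ValueError("expressing_fraction must be <= 1")

    population_mean = molecules_per_reference_cell * gene_fraction / deficit
    per_cell = population_mean / expressing_fraction
    interval = None
    if deficit_range is not None:
        per_lo = molecules_per_reference_cell * gene_fraction / deficit_range[1] / expressing_fraction
        per_hi = molecules_per_reference_cell * gene_fraction / deficit_range[0] / expressing_fraction
        interval = (per_lo, per_hi)
    return CopiesEstimate(
        molecules_per_reference_cell=float(molecules_per_reference_cell),
        gene_fraction_of_reference=float(gene_fraction),
        relative_deficit=deficit,
        expressing_fraction=float(expressing_fraction),
        population_mean_copies=population_mean,
        copies_per_expressing_cell=per_cell,
        rounded_range=(math.floor(per_cell), math.ceil(per_cell)),
        interval=interval,
    )
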