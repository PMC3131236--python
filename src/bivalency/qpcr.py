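"""ChIP-qPCR fold enrichment, relative expression and the cell-mixture model.

Fold enrichment of a target amplicon is its ChIP/input recovery divided by
the recovery at a control amplicon (an ACTB-promoter-style reference), per
replicate, then summarised over replicates.  Sequential ChIP (re-ChIP)
plates go through the identical path with the first-antibody eluate playing
the role of the input channel.  The mixture model is linear in cell
fractions: pooled chromatin mass is additive, so a mixed population's
expected enrichment is the fraction-weighted mean of its components'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: amplification factor per cycle (perfect doubling)
DEFAULT_EFFICIENCY = 2.0


class PlateError(ValueError):
    """A plate is missing a channel, replicate or amplicon needed for pairing."""


def recovery(ct_chip: float, ct_input: float, efficiency: float = DEFAULT_EFFICIENCY) -> float:
    """Relative recovery of an amplicon: efficiency^(Ct_input - Ct_chip).

    One cycle difference is one factor of ``efficiency`` in template
    (default 2.0: perfect doubling).
    """
    if efficiency <= 1.0:
        raise ValueError(f"efficiency must be > 1, got {efficiency}")
    return float(efficiency ** (ct_input - ct_chip))


@dataclass(frozen=True)
class FoldEnrichment:
    """Summarised fold enrichment of one amplicon in one sample."""

    sample: str
    amplicon: str
    mean_fold: float
    sd: float
    n_replicates: int
    control_amplicon: str
    replicate_folds: tuple[float, ...] = ()


def _paired_recoveries(
    plate: pd.DataFrame, sample: str, amplicon: str, efficiency: float
) -> dict[int, float]:
    """Per-replicate recoveries, pairing chip and input Ct by replicate index."""
    sub = plate[(plate["sample"] == sample) & (plate["amplicon"] == amplicon)]
    chip = sub[sub["channel"] == "chip"].set_index("replicate")["ct"]
    inp = sub[sub["channel"] == "input"].set_index("replicate")["ct"]
    reps = sorted(set(chip.index) & set(inp.index))
    if not reps:
        missing = "chip" if chip.empty else "input"
        raise PlateError(f"sample {sample!r}, amplicon {amplicon!r}: no paired {missing} Ct")
    return {int(r): recovery(float(chip[r]), float(inp[r]), efficiency) for r in reps}


def fold_enrichment(
    plate: pd.DataFrame,
    control_amplicon: str,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> list[FoldEnrichment]:
    """Fold enrichment per (sample, amplicon) relative to the control amplicon.

    Per replicate: fold = recovery(amplicon) / recovery(control); the
    reported mean and sd are over replicates, so the control amplicon's own
    fold is exactly 1 with sd 0.  The plate is a long-format table with
    columns sample, amplicon, channel (chip|input), replicate, ct.
    """
    results = []
    for sample in plate["sample"].unique():
        amps = plate.loc[plate["sample"] == sample, "amplicon"].unique()
        if control_amplicon not in amps:
            raise PlateError(f"control amplicon {control_amplicon!r} missing for sample {sample!r}")
        ctrl = _paired_recoveries(plate, sample, control_amplicon, efficiency)
        for amplicon in amps:
            rec = _paired_recoveries(plate, sample, amplicon, efficiency)
            reps = sorted(set(rec) & set(ctrl))
            if not reps:
                raise PlateError(
                    f"sample {sample!r}, amplicon {amplicon!r}: no replicate shared with control"
                )
            folds = np.array([rec[r] / ctrl[r] for r in reps])
            results.append(
                FoldEnrichment(
                    sample=str(sample),
                    amplicon=str(amplicon),
                    mean_fold=float(folds.mean()),
                    sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
                    n_replicates=len(folds),
                    control_amplicon=control_amplicon,
                    replicate_folds=tuple(float(f) for f in folds),
                )
            )
    return results


def replicate_test(
    folds_a: np.ndarray,
    folds_b: np.ndarray,
    log2_transform: bool = True,
    welch: bool = False,
) -> tuple[float, float]:
    """Unpaired two-sided Student's t on replicate-level folds.

    Folds are multiplicative, so they are log2-transformed by default
    before the test.  The degenerate zero-variance case (both groups
    constant, different values) reports t = +/-inf and p = 0.0 with a
    warning rather than NaN; identical constant groups give t = 0, p = 1.
    """
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if log2_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("folds must be > 0 for the log2-scale test")
        a, b = np.log2(a), np.log2(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn(
            "zero variance in both groups with different means: reporting t = inf, p = 0"
        )
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MixtureSpec:
    """A mixed cell population: (label, fraction, per-component enrichment)."""

    components: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        total = sum(f for _, f, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {total}")
        for label, f, e in self.components:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"component {label!r}: fraction {f} outside [0,1]")
            if e <= 0:
                raise ValueError(f"component {label!r}: enrichment must be > 0")


def mixture_expected_enrichment(spec: MixtureSpec) -> float:
    """Expected fold enrichment of a mixed population: sum_i f_i * E_i.

    Linear pooling — the chromatin contributed by each cell type is
    proportional to its fraction, so a 10% high-enrichment population in a
    90% background at enrichment 1 yields 0.1 E + 0.9.
    """
    return float(sum(f * e for _, f, e in spec.components))


def relative_expression(
    plate: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Expression of target relative to a reference gene, per sample.

    Per replicate: efficiency^-(Ct_target - Ct_reference) — the standard
    ddCt-style normalisation to an 18S-like internal control.  Returns a
    table with per-sample mean, sd and replicate count; between-sample
    ratios should be formed from the means.
    """
    rows = []
    for sample in plate["sample"].unique():
        sub = plate[plate["sample"] == sample]
        tgt = sub[sub["amplicon"] == target_gene].set_index("replicate")["ct"]
        ref = sub[sub["amplicon"] == reference_gene].set_index("replicate")["ct"]
        if ref.empty:
            raise PlateError(f"reference gene {reference_gene!r} missing for sample {sample!r}")
        if tgt.empty:
            raise PlateError(f"target gene {target_gene!r} missing for sample {sample!r}")
        reps = sorted(set(tgt.index) & set(ref.index))
        vals = np.array(
            [efficiency ** -(float(tgt[r]) - float(ref[r])) for r in reps]
        )
        rows.append(
            {
                "sample": str(sample),
                "relative_expression": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_replicates": len(vals),
            }
        )
    return pd.DataFrame(rows)
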