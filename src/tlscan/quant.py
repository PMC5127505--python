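"""Phenotypic/fitness scoring from allele counts.

The phenotypic score of a variant under a condition is the log2 change of
its allele frequency under selection, normalised to wild type:

    f = log2(f_mut,sele / f_mut,unsele) - log2(f_wt,sele / f_wt,unsele)

Variants with fewer than ``min_pool_reads`` reads in the transformed pool
(SC-Leu) are excluded, and a score assessed from fewer than
``min_condition_reads`` reads in both the selected and the unselected
sample is masked.  Replicate scores are aggregated by the median.  The
same statistic on control media (SC-Leu heterozygous, 5FOA shuffled) is
the fitness score, on which a viable/lethal threshold is calibrated from
known viable and lethal variants by balanced-error minimisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readproc import AlleleCountTable
from .synthetic_data import WT_ID

__all__ = [
    "FilterConfig",
    "FrequencyTable",
    "ScoreMatrix",
    "LethalityModel",
    "frequencies",
    "phenotype_score",
    "score_counts",
    "replicate_scores",
    "apply_filters",
    "aggregate_replicates",
    "score_screen",
    "calibrate_lethality",
    "classify_fitness",
]


@dataclass(frozen=True)
class FilterConfig:
    """Read-count filters of the screen.

    ``require_both_below`` keeps the literal reading of the rule — a score
    is masked only when *both* the selected and unselected sample fall
    below ``min_condition_reads``; set it False for the stricter
    either-side rule.
    """

    min_pool_reads: int = 200
    min_condition_reads: int = 50
    pool_condition: str = "SC-Leu"
    require_both_below: bool = True

    def __post_init__(self) -> None:
        if self.min_pool_reads < 0 or self.min_condition_reads < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FrequencyTable:
    """Allele frequencies (fraction of mapped reads) per sample."""

    freq: pd.DataFrame  # variants x samples
    totals: pd.Series  # mapped reads per sample


def frequencies(table: AlleleCountTable) -> FrequencyTable:
    """Per-sample allele frequencies: count / total mapped reads."""
    totals = table.totals
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero mapped reads: {list(zero.index)}")
    return FrequencyTable(freq=table.counts / totals, totals=totals)


def phenotype_score(fm_sel, fm_unsel, fw_sel, fw_unsel, log_base: float = 2.0):
    """The enrichment log-ratio normalised to wild type (frequencies > 0)."""
    vals = [np.asarray(v, dtype=float) for v in (fm_sel, fm_unsel, fw_sel, fw_unsel)]
    if any((v <= 0).any() for v in vals):
        raise ValueError("frequencies must be positive; use score_counts for zeros")
    fm_sel, fm_unsel, fw_sel, fw_unsel = vals
    log = np.log(log_base)
    out = (np.log(fm_sel / fm_unsel) - np.log(fw_sel / fw_unsel)) / log
    return float(out) if out.ndim == 0 else out


def score_counts(
    cm_sel, cm_unsel, cw_sel, cw_unsel, pseudocount: float = 0.5,
    log_base: float = 2.0,
):
    """Score from raw counts (totals cancel against the WT normalisation).

    The pseudocount is a zero-handling device: it is added symmetrically to
    all four counts of a cell, but only for cells where at least one count
    is zero, which keeps scores finite for fully depleted variants while
    leaving scores of positive counts exactly invariant to sequencing
    depth.
    """
    arrs = [np.asarray(v, dtype=float) for v in (cm_sel, cm_unsel, cw_sel, cw_unsel)]
    if any((v < 0).any() for v in arrs):
        raise ValueError("counts must be non-negative")
    any_zero = np.zeros(np.broadcast(*arrs).shape, dtype=bool)
    for v in arrs:
        any_zero |= np.broadcast_to(v == 0, any_zero.shape)
    cm_s, cm_u, cw_s, cw_u = (
        np.where(any_zero, v + pseudocount, v) for v in arrs
    )
    out = (np.log(cm_s / cm_u) - np.log(cw_s / cw_u)) / np.log(log_base)
    return float(out) if out.ndim == 0 else out


def replicate_scores(
    table: AlleleCountTable,
    cfg: FilterConfig = FilterConfig(),
    pseudocount: float = 0.5,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-replicate scores, variants x (condition, replicate).

    For each condition other than the transformed pool, the selected sample
    is that condition's sample and the unselected sample is the pool sample
    of the same replicate.
    """
    if cfg.pool_condition not in set(table.samples["condition"]):
        raise ValueError(f"pool condition {cfg.pool_condition!r} not in counts")
    conditions = [c for c in table.conditions if c != cfg.pool_condition]
    cols = {}
    for rep in table.replicates:
        pool_sample = table.sample_for(cfg.pool_condition, rep)
        unsel = table.counts[pool_sample]
        for cond in conditions:
            sel = table.counts[table.sample_for(cond, rep)]
            cols[(cond, rep)] = score_counts(
                sel.to_numpy(), unsel.to_numpy(),
                sel[WT_ID], unsel[WT_ID],
                pseudocount=pseudocount, log_base=log_base,
            )
    out = pd.DataFrame(cols, index=table.counts.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "replicate"])
    return out


def apply_filters(
    table: AlleleCountTable, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Boolean keep-mask, variants x (condition, replicate).

    A variant with fewer than ``min_pool_reads`` transformed-pool reads
    (summed over the pool replicates) is dropped entirely; a cell whose
    selected and unselected counts are both below ``min_condition_reads``
    is masked (or either, with ``require_both_below=False``).
    """
    if cfg.pool_condition not in set(table.samples["condition"]):
        raise ValueError(f"pool condition {cfg.pool_condition!r} not in counts")
    conditions = [c for c in table.conditions if c != cfg.pool_condition]
    pool_samples = [
        table.sample_for(cfg.pool_condition, rep) for rep in table.replicates
    ]
    pool_ok = table.counts[pool_samples].sum(axis=1) >= cfg.min_pool_reads
    cols = {}
    for rep in table.replicates:
        pool_sample = table.sample_for(cfg.pool_condition, rep)
        unsel = table.counts[pool_sample]
        for cond in conditions:
            sel = table.counts[table.sample_for(cond, rep)]
            sel_low = sel < cfg.min_condition_reads
            unsel_low = unsel < cfg.min_condition_reads
            low = (sel_low & unsel_low) if cfg.require_both_below else (sel_low | unsel_low)
            cols[(cond, rep)] = pool_ok & ~low
    out = pd.DataFrame(cols, index=table.counts.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "replicate"])
    return out


@dataclass
class ScoreMatrix:
    """Replicate-median scores with a missing-data mask.

    ``mask`` values: ``measured`` (at least one unmasked replicate),
    ``filtered`` (all replicates masked).  Variants absent from the counts
    are simply absent from the matrix.  Per-replicate scores are retained
    for dispersion work.
    """

    scores: pd.DataFrame  # variants x conditions, NaN where not measured
    mask: pd.DataFrame  # variants x conditions, {"measured", "filtered"}
    replicate_scores: pd.DataFrame

    def measured(self, condition: str) -> pd.Series:
        col = self.scores[condition]
        return col[self.mask[condition] == "measured"]


def aggregate_replicates(
    rep_scores: pd.DataFrame, keep_mask: pd.DataFrame
) -> ScoreMatrix:
    """Median across unmasked replicate scores per (variant, condition)."""
    masked = rep_scores.where(keep_mask.reindex(columns=rep_scores.columns))
    med = masked.T.groupby(level="condition").median().T
    n_kept = keep_mask.T.groupby(level="condition").sum().T
    mask = pd.DataFrame(
        np.where(n_kept > 0, "measured", "filtered"),
        index=med.index, columns=med.columns,
    )
    med = med.where(mask == "measured")
    return ScoreMatrix(scores=med, mask=mask, replicate_scores=masked)


def score_screen(
    table: AlleleCountTable,
    cfg: FilterConfig = FilterConfig(),
    pseudocount: float = 0.5,
    log_base: float = 2.0,
) -> ScoreMatrix:
    """Counts -> filtered, replicate-aggregated score matrix."""
    reps = replicate_scores(table, cfg, pseudocount, log_base)
    keep = apply_filters(table, cfg)
    return aggregate_replicates(reps, keep)


# --------------------------------------------------------------------------
# Lethality
# --------------------------------------------------------------------------


@dataclass
class LethalityModel:
    """Fitness-score cutoff separating viable from lethal variants."""

    threshold: float
    viable_scores: pd.Series
    lethal_scores: pd.Series
    balanced_error: float

    def __post_init__(self) -> None:
        lo = min(self.viable_scores.min(), self.lethal_scores.min())
        hi = max(self.viable_scores.max(), self.lethal_scores.max())
        if not lo <= self.threshold <= hi:
            raise ValueError("threshold outside the calibration score range")


def _balanced_error(t: float, viable: np.ndarray, lethal: np.ndarray) -> float:
    return 0.5 * float((viable < t).mean()) + 0.5 * float((lethal >= t).mean())


def calibrate_lethality(
    fitness: pd.Series,
    viable_ids,
    lethal_ids,
) -> LethalityModel:
    """Threshold minimising balanced misclassification on calibration sets.

    Candidate cutpoints are the midpoints between consecutive distinct
    calibration scores; a variant scores lethal when strictly below the
    threshold.  Ties in balanced error resolve to the midpoint of the
    optimal cutpoint interval.  Balanced error weights the two classes
    equally, which keeps the heavily imbalanced calibration (163 viable vs
    16 lethal in the original screen) from swamping the lethal side.
    """
    viable = fitness.reindex(list(viable_ids)).dropna()
    lethal = fitness.reindex(list(lethal_ids)).dropna()
    if viable.empty or lethal.empty:
        raise ValueError("both calibration lists must be non-empty and scored")
    v, l = viable.to_numpy(), lethal.to_numpy()
    uniq = np.unique(np.concatenate([v, l]))
    if len(uniq) == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    errs = np.array([_balanced_error(t, v, l) for t in candidates])
    best = errs.min()
    opt = candidates[errs <= best + 1e-12]
    threshold = float((opt[0] + opt[-1]) / 2.0)
    return LethalityModel(
        threshold=threshold,
        viable_scores=viable,
        lethal_scores=lethal,
        balanced_error=float(best),
    )


def classify_fitness(
    fitness, model: LethalityModel, condition: str = "5FOA"
) -> pd.Series:
    """Label variants viable / predicted_lethal by the calibrated cutoff.

    ``fitness`` may be a :class:`ScoreMatrix` (the ``condition`` column is
    used) or a Series of fitness scores.  A score exactly at the threshold
    is viable (strict inequality); unmeasured variants are omitted.
    """
    if isinstance(fitness, ScoreMatrix):
        scores = fitness.measured(condition)
    else:
        scores = pd.Series(fitness).dropna()
    return pd.Series(
        np.where(scores < model.threshold, "predicted_lethal", "viable"),
        index=scores.index, name="label",
    )
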