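"""Quality control: spike-in template-switch estimation and reproducibility.

Five excluded single variants are spiked into the pool as controls.  Double
mutants combining two spike-ins cannot come from the programmed library, so
their frequency reports on PCR template switching.  The estimator is the
ratio

    R = Freq(double) / (Freq(single1) * Freq(single2))

computed for every spike-in pair at distinct residue positions and averaged.
Comparing the mean ratio between standard and emulsion PCR yields the fold
suppression achieved by emulsion amplification.  Replicate reproducibility
is summarised by pairwise Pearson correlation of per-variant frequencies.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import FrequencyTable
from .synthetic_data import parse_variant_id

__all__ = [
    "TemplateSwitchReport",
    "ModeComparison",
    "spike_pairs",
    "double_id",
    "template_switch_ratio",
    "compare_pcr_modes",
    "replicate_correlation",
]


def _residue_of(variant_id: str) -> int:
    parts = parse_variant_id(variant_id)
    if len(parts) != 1:
        raise ValueError(f"{variant_id!r} is not a single-substitution id")
    return parts[0][1]


def spike_pairs(spike_ids) -> list[tuple[str, str]]:
    """All unordered spike-in pairs at distinct residue positions.

    For the five canonical spike-ins (two of which share residue 1085) this
    yields exactly 9 pairs.
    """
    ids = sorted(spike_ids, key=lambda v: (_residue_of(v), v))
    return [
        (a, b)
        for a, b in itertools.combinations(ids, 2)
        if _residue_of(a) != _residue_of(b)
    ]


def double_id(id_a: str, id_b: str) -> str:
    """Composite id of the double mutant, ordered by residue number."""
    a, b = sorted((id_a, id_b), key=lambda v: (_residue_of(v), v))
    return f"{a},{b}"


@dataclass
class TemplateSwitchReport:
    """Per-pair switch ratios for one sample, with their mean."""

    per_pair: pd.DataFrame  # single1, single2, f1, f2, f_double, ratio
    mean_ratio: float
    sample: str
    skipped: tuple[tuple[str, str], ...] = ()


def template_switch_ratio(
    freq: FrequencyTable,
    spike_ids,
    sample: str,
) -> TemplateSwitchReport:
    """Estimate template switching from spike-in doubles in one sample.

    Pairs sharing a residue are excluded up front; a pair with a zero
    single frequency is skipped with a warning.  Absent doubles count as
    frequency 0 (ratio 0).
    """
    f = freq.freq[sample]
    rows, skipped = [], []
    for a, b in spike_pairs(spike_ids):
        fa = float(f.get(a, 0.0))
        fb = float(f.get(b, 0.0))
        if fa == 0.0 or fb == 0.0:
            warnings.warn(
                f"spike-in pair ({a}, {b}) skipped in {sample}: zero single frequency",
                stacklevel=2,
            )
            skipped.append((a, b))
            continue
        fd = float(f.get(double_id(a, b), 0.0))
        rows.append(
            {"single1": a, "single2": b, "f1": fa, "f2": fb,
             "f_double": fd, "ratio": fd / (fa * fb)}
        )
    per_pair = pd.DataFrame(
        rows, columns=["single1", "single2", "f1", "f2", "f_double", "ratio"]
    )
    mean_ratio = float(per_pair["ratio"].mean()) if len(rows) else float("nan")
    return TemplateSwitchReport(
        per_pair=per_pair, mean_ratio=mean_ratio, sample=sample,
        skipped=tuple(skipped),
    )


@dataclass
class ModeComparison:
    """Fold suppression of template switching by emulsion PCR."""

    fold_suppression: float
    infinite: bool = False


def compare_pcr_modes(
    report_regular: TemplateSwitchReport,
    report_emulsion: TemplateSwitchReport,
) -> ModeComparison:
    """Linear ratio of mean switch ratios, regular / emulsion."""
    reg, em = report_regular.mean_ratio, report_emulsion.mean_ratio
    if em == 0.0:
        if reg == 0.0:
            return ModeComparison(fold_suppression=0.0)
        return ModeComparison(fold_suppression=math.inf, infinite=True)
    return ModeComparison(fold_suppression=reg / em)


def replicate_correlation(
    freq: FrequencyTable, samples=None
) -> pd.DataFrame:
    """Pairwise Pearson r of per-variant frequencies across samples.

    Symmetric with unit diagonal; a constant frequency vector yields NaN
    against every other sample.
    """
    table = freq.freq if samples is None else freq.freq[list(samples)]
    corr = table.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr
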