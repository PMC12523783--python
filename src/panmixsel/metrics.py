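"""Per-generation summaries of a selection run: genetic gain, genotypic
variance, prediction accuracy, the three inbreeding coefficients, selected
full-sib family counts and favorable-allele frequency changes."""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GenerationRecord",
    "genetic_gain",
    "prediction_accuracy",
    "count_selected_progenies",
    "allele_frequency_summary",
    "records_to_frame",
    "aggregate_replicates",
]


@dataclass
class GenerationRecord:
    """Metrics of one generation within one scheme x replicate run.

    ``accuracy`` and ``n_selected_families`` refer to the selection event that
    happened in this generation (NaN where no model-based selection ran);
    means of true genotypic values are on the trait (FCR) scale.
    """

    scheme: str
    replicate: int
    generation: int
    mean_fcr: float
    genotypic_variance: float
    accuracy: float = np.nan
    pedigree_f: float = np.nan
    genomic_f: float = np.nan
    realized_f: float = np.nan
    n_selected_families: float = np.nan
    fav_freq_min: float = np.nan
    fav_freq_mean: float = np.nan
    fav_freq_max: float = np.nan
    n_fixed: int = 0
    n_lost: int = 0


def genetic_gain(means_by_generation) -> tuple[np.ndarray, float]:
    """Per-cycle gains (first differences of generation means) and the total
    gain (last minus first)."""
    m = np.asarray(means_by_generation, float)
    if m.size < 2:
        raise ValueError("need at least two generations")
    gains = np.diff(m)
    return gains, float(m[-1] - m[0])


def prediction_accuracy(predicted_additive, true_genotypic) -> float:
    """Pearson correlation between predicted additive values and true
    genotypic values; NaN when either vector is degenerate."""
    x = np.asarray(predicted_additive, float)
    g = np.asarray(true_genotypic, float)
    if x.size < 3 or x.std() == 0 or g.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, g)[0, 1])


def count_selected_progenies(selected_sires, selected_dams) -> int:
    """Number of distinct full-sib families (sire, dam pairs) represented
    among the selected individuals."""
    pairs = np.stack([np.asarray(selected_sires), np.asarray(selected_dams)], axis=1)
    return int(np.unique(pairs, axis=0).shape[0])


def allele_frequency_summary(fav_dosage: np.ndarray) -> dict:
    """Favorable-allele frequency summary over QTL: min/mean/max and counts of
    fixed (freq 1) and lost (freq 0) favorable alleles."""
    freq = np.asarray(fav_dosage, float).mean(axis=0) / 2.0
    return {
        "fav_freq_min": float(freq.min()),
        "fav_freq_mean": float(freq.mean()),
        "fav_freq_max": float(freq.max()),
        "n_fixed": int(np.count_nonzero(freq >= 1.0)),
        "n_lost": int(np.count_nonzero(freq <= 0.0)),
    }


def records_to_frame(records) -> pd.DataFrame:
    """Flatten GenerationRecords into a tidy frame (one row per scheme x
    replicate x generation)."""
    return pd.DataFrame([asdict(r) for r in records])


def aggregate_replicates(records) -> pd.DataFrame:
    """Mean and across-replicate SD per scheme x generation x metric.

    With a single replicate the SD is reported as NaN.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    value_cols = [c for c in df.columns if c not in ("scheme", "replicate", "generation")]
    long = df.melt(id_vars=["scheme", "replicate", "generation"],
                   value_vars=value_cols, var_name="metric")
    out = (long.groupby(["scheme", "generation", "metric"])["value"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                n_replicates="count")
           .reset_index())
    return out
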