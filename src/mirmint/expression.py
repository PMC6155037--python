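"""Normalization, fold changes and differential calls for two-condition counts.

Counts are library-size corrected to counts-per-million (CPM); fold changes
are log2 ratios of per-condition mean CPM with a pseudocount; significance
comes from an exact conditional binomial test on pooled per-condition counts
(Audic-Claverie style): conditioned on a feature's total count, the count in
one condition is Binomial(total, library-size share of that condition) under
the null of equal relative expression.  The test is exact under Poisson
sampling and is anti-conservative when counts are overdispersed between
biological replicates -- a deliberately simple, dependency-light stand-in
for negative-binomial empirical-Bayes machinery, adequate for recovering
planted effects in simulated designs.

Differential features are called at raw P <= 0.05 by default; Benjamini-
Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "normalize_cpm",
    "log2_fold_change",
    "call_differential",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
]

CONDITION_REF = "telogen"
CONDITION_ALT = "anagen"


@dataclass
class ExpressionMatrix:
    """Integer counts (features x samples) plus a sample -> condition design.

    ``counts`` columns are sample ids; ``design`` maps each sample id to its
    condition label.  Fold changes are reported for ``condition_alt``
    relative to ``condition_ref``.
    """

    counts: pd.DataFrame
    design: Mapping[str, str]
    condition_ref: str = CONDITION_REF
    condition_alt: str = CONDITION_ALT

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in matrix")
        missing = [s for s in self.counts.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")

    def samples(self, condition: str) -> list:
        cols = [s for s in self.counts.columns if self.design[s] == condition]
        if not cols:
            raise ValueError(f"no samples for condition {condition!r}")
        return cols


def normalize_cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million: every column rescaled to sum to 1e6."""
    sums = matrix.counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum library for sample(s): {list(zero.index)}")
    return 1e6 * matrix.counts / sums


def log2_fold_change(matrix: ExpressionMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-feature log2 fold change of mean CPM, alt condition over ref.

    log2fc = log2((mean_CPM_alt + pc) / (mean_CPM_ref + pc)); swapping the
    two condition labels negates every value exactly.
    """
    cpm = normalize_cpm(matrix)
    mean_ref = cpm[matrix.samples(matrix.condition_ref)].mean(axis=1)
    mean_alt = cpm[matrix.samples(matrix.condition_alt)].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_cpm_ref": mean_ref,
            "mean_cpm_alt": mean_alt,
            "log2fc": np.log2(mean_alt + pseudocount) - np.log2(mean_ref + pseudocount),
        }
    )


def call_differential(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    adjust: str = "none",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Fold changes, exact-test p-values and up/down/ns calls per feature.

    The p-value is a two-sided exact binomial test of the pooled alt-condition
    count against the conditions' library-size share, conditioned on the
    feature's pooled total.  Features with zero total get p = 1 and call
    ``ns``.  ``adjust`` is ``none`` (raw P, the default) or ``BH``.
    """
    if adjust not in ("none", "BH"):
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    fc = log2_fold_change(matrix, pseudocount=pseudocount)
    ref_cols = matrix.samples(matrix.condition_ref)
    alt_cols = matrix.samples(matrix.condition_alt)
    pooled_ref = matrix.counts[ref_cols].sum(axis=1).astype(int)
    pooled_alt = matrix.counts[alt_cols].sum(axis=1).astype(int)
    lib_ref = int(matrix.counts[ref_cols].values.sum())
    lib_alt = int(matrix.counts[alt_cols].values.sum())
    share_alt = lib_alt / (lib_alt + lib_ref)

    pvals = np.ones(len(fc))
    for i, (xr, xa) in enumerate(zip(pooled_ref.values, pooled_alt.values)):
        total = int(xr + xa)
        if total > 0:
            pvals[i] = stats.binomtest(int(xa), total, share_alt).pvalue
    fc = fc.assign(p_value=pvals)
    fc["adjusted_p"] = (
        multipletests(pvals, method="fdr_bh")[1] if adjust == "BH" else np.nan
    )
    crit = fc["adjusted_p"] if adjust == "BH" else fc["p_value"]
    call = np.where(
        (crit <= alpha) & (fc["log2fc"] > 0),
        "up",
        np.where((crit <= alpha) & (fc["log2fc"] < 0), "down", "ns"),
    )
    # zero-total features are never differential
    call = np.where((pooled_ref + pooled_alt) == 0, "ns", call)
    fc["call"] = call
    return fc


# ---------------------------------------------------------------------------
# I/O: tab-delimited count tables and design files

def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_design_tsv(path) -> Dict[str, str]:
    """Two-column sample-id / condition file (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"])
    return dict(zip(df["sample"].astype(str), df["condition"].astype(str)))
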