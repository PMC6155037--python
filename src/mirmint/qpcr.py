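"""Relative qPCR quantitation by the 2^-ddCt method and stage comparisons.

Per biological sample and gene, technical-replicate Ct values are averaged;
dCt is the gene's mean Ct minus the reference gene's mean Ct in the same
sample (reference-gene normalization), and ddCt subtracts the mean dCt of
the calibrator-stage samples, so the calibrator stage averages to a relative
quantity (RQ) of 1.  RQ = 2^-ddCt assumes a doubling per cycle (amplification
efficiency 2, no standard-curve correction).  Stage-level RQ aggregates
per-sample RQs by geometric mean (the quantity is multiplicative); an
arithmetic mean is available behind a flag.

Stage differences are assessed by one-way ANOVA on log2 RQ followed by
Fisher's LSD: pairwise t statistics on the pooled within-stage mean square.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RelativeExpression",
    "validate_ct_table",
    "delta_delta_ct",
    "compare_stages",
    "read_ct_tsv",
]

CT_COLUMNS = ["sample", "stage", "gene", "replicate", "ct"]


@dataclass(frozen=True)
class RelativeExpression:
    """Stage-level relative expression of one gene."""

    gene: str
    stage: str
    rq: float
    dispersion: float  # sd of per-sample RQ over biological samples
    n: int


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad = ct[(ct["ct"] <= 0) | (ct["ct"] >= 45)]
    if len(bad):
        raise ValueError(f"Ct values outside (0, 45) for rows: {list(bad.index)}")
    return ct


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_stage: str,
    aggregate: str = "geometric",
) -> Tuple[pd.DataFrame, List[RelativeExpression]]:
    """2^-ddCt relative quantitation against a reference gene and calibrator.

    Returns the per-sample table (sample, stage, gene, delta_ct,
    delta_delta_ct, rq) and the stage-level summaries.  Every sample must
    carry the reference gene; ``aggregate`` is ``geometric`` (default) or
    ``arithmetic``.
    """
    validate_ct_table(ct)
    if aggregate not in ("geometric", "arithmetic"):
        raise ValueError(f"aggregate must be geometric|arithmetic, got {aggregate!r}")
    if calibrator_stage not in set(ct["stage"]):
        raise ValueError(f"calibrator stage {calibrator_stage!r} absent from table")

    # mean Ct over technical replicates
    mean_ct = ct.groupby(["sample", "stage", "gene"], as_index=False)["ct"].mean()
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample")["ct"]
    samples_missing_ref = sorted(set(mean_ct["sample"]) - set(ref.index))
    if samples_missing_ref:
        raise ValueError(
            f"reference gene {reference_gene!r} missing for sample(s): "
            f"{samples_missing_ref}"
        )

    per = mean_ct[mean_ct["gene"] != reference_gene].copy()
    per["delta_ct"] = per["ct"] - per["sample"].map(ref)
    cal_mean = (
        per[per["stage"] == calibrator_stage]
        .groupby("gene")["delta_ct"]
        .mean()
    )
    per["delta_delta_ct"] = per["delta_ct"] - per["gene"].map(cal_mean)
    per["rq"] = np.power(2.0, -per["delta_delta_ct"])
    per = per.drop(columns="ct").reset_index(drop=True)

    summaries: List[RelativeExpression] = []
    for (gene, stage), grp in per.groupby(["gene", "stage"]):
        rqs = grp["rq"].to_numpy()
        if aggregate == "geometric":
            level = float(np.exp(np.mean(np.log(rqs))))
        else:
            level = float(np.mean(rqs))
        summaries.append(
            RelativeExpression(
                gene=str(gene),
                stage=str(stage),
                rq=level,
                dispersion=float(np.std(rqs, ddof=1)) if len(rqs) > 1 else 0.0,
                n=len(rqs),
            )
        )
    return per, summaries


def compare_stages(per_sample: pd.DataFrame, method: str = "LSD") -> pd.DataFrame:
    """Pairwise stage comparisons of log2 RQ per gene by Fisher's LSD.

    One-way ANOVA supplies the pooled within-stage mean square; each stage
    pair gets a two-sided t test on that MS_error with N - k degrees of
    freedom.  Stages with a single biological sample are excluded with a
    warning.  When the within-stage variance is exactly zero the comparison
    is degenerate: p is 0 for unequal means (flagged ``zero_variance``) and
    1 for equal means.
    """
    if method.upper() != "LSD":
        raise ValueError(f"unsupported method {method!r}; only LSD is implemented")
    rows = []
    for gene, grp in per_sample.groupby("gene"):
        by_stage = {
            str(stage): np.log2(sub["rq"].to_numpy())
            for stage, sub in grp.groupby("stage")
        }
        dropped = [s for s, v in by_stage.items() if len(v) < 2]
        if dropped:
            warnings.warn(
                f"gene {gene!r}: excluding single-sample stage(s) {dropped}"
            )
            by_stage = {s: v for s, v in by_stage.items() if len(v) >= 2}
        if len(by_stage) < 2:
            continue
        groups = list(by_stage.values())
        n_total = sum(len(g) for g in groups)
        k = len(groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_err = n_total - k
        mse = ss_within / df_err
        for (s1, g1), (s2, g2) in itertools.combinations(sorted(by_stage.items()), 2):
            diff = g1.mean() - g2.mean()
            zero_var = mse == 0.0
            if zero_var:
                p = 1.0 if diff == 0.0 else 0.0
                tstat = 0.0 if diff == 0.0 else math.inf * np.sign(diff)
            else:
                se = math.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
                tstat = diff / se
                p = 2.0 * stats.t.sf(abs(tstat), df_err)
            rows.append(
                {
                    "gene": str(gene),
                    "stage_a": s1,
                    "stage_b": s2,
                    "diff_log2rq": float(diff),
                    "t": float(tstat),
                    "df": int(df_err),
                    "p_value": float(p),
                    "zero_variance": bool(zero_var),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "stage_a", "stage_b", "diff_log2rq", "t", "df",
            "p_value", "zero_variance",
        ],
    )


def read_ct_tsv(path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path, sep="\t"))
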