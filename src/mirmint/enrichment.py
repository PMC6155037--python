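"""Hypergeometric GO/KEGG enrichment of target gene sets.

For a term annotating B of the TB annotated background genes, with a target
set contributing TS annotated genes of which S fall in the term, the
enrichment p-value is the exact upper tail

    P = 1 - sum_{i=0}^{S-1} C(B, i) C(TB-B, TS-i) / C(TB, TS)
      = P(X >= S),   X ~ Hypergeometric(TB, B, TS)

computed in log space so large annotation universes do not overflow.  The
empty-sum convention applies at S = 0 (P = 1).  The rich factor is S/B, the
fraction of the term's genes present in the target set.  Reported p-values
are raw by default; Benjamini-Hochberg adjustment is a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_p",
    "hypergeom_cdf",
    "enrich",
    "top_k",
    "read_annotation_tsv",
]


def _validate(TB: int, TS: int, B: int, S: int) -> None:
    if not 0 <= S:
        raise ValueError(f"invariant violated: 0 <= S (S={S})")
    if S > min(B, TS):
        raise ValueError(f"invariant violated: S <= min(B, TS) (S={S}, B={B}, TS={TS})")
    if B > TB:
        raise ValueError(f"invariant violated: B <= TB (B={B}, TB={TB})")
    if TS > TB:
        raise ValueError(f"invariant violated: TS <= TB (TS={TS}, TB={TB})")
    if B < 0 or TS < 0 or TB <= 0:
        raise ValueError(f"invariant violated: TB > 0, B >= 0, TS >= 0 "
                         f"(TB={TB}, TS={TS}, B={B})")


def _log_pmf_support(TB: int, TS: int, B: int):
    lo = max(0, TS - (TB - B))
    hi = min(B, TS)
    i = np.arange(lo, hi + 1)
    logp = (
        gammaln(B + 1) - gammaln(i + 1) - gammaln(B - i + 1)
        + gammaln(TB - B + 1) - gammaln(TS - i + 1) - gammaln(TB - B - (TS - i) + 1)
        - (gammaln(TB + 1) - gammaln(TS + 1) - gammaln(TB - TS + 1))
    )
    return i, logp


def _tail_weights(TB: int, TS: int, B: int):
    i, logp = _log_pmf_support(TB, TS, B)
    w = np.exp(logp - logp.max())
    return i, w, w.sum()


def hypergeom_p(TB: int, TS: int, B: int, S: int) -> float:
    """Exact upper-tail P(X >= S) of the hypergeometric draw.

    Weights over the whole support are renormalized before the tail sum, so
    the complement identity P(X >= S) + P(X <= S-1) = 1 holds to machine
    precision.  C(n, k) = 0 outside 0 <= k <= n is implicit in the support.
    """
    _validate(TB, TS, B, S)
    i, w, total = _tail_weights(TB, TS, B)
    return float(w[i >= S].sum() / total)


def hypergeom_cdf(TB: int, TS: int, B: int, S: int) -> float:
    """Exact lower tail P(X <= S), the complement companion of
    :func:`hypergeom_p`."""
    _validate(TB, TS, B, max(S, 0))
    i, w, total = _tail_weights(TB, TS, B)
    return float(w[i <= S].sum() / total)


@dataclass
class EnrichmentResult:
    """One term's enrichment: the four contingency counts and the exact P."""

    term: str
    namespace: str
    TB: int
    TS: int
    B: int
    S: int
    p_value: float
    rich_factor: float
    rank: int = 0
    adjusted_p: float = float("nan")


def enrich(
    target_genes: Iterable[str],
    annotation: pd.DataFrame,
    background: Optional[Iterable[str]] = None,
    adjust: bool = False,
) -> List[EnrichmentResult]:
    """Hypergeometric enrichment of ``target_genes`` over a term->gene map.

    ``annotation`` has columns ``term`` and ``gene`` and optionally
    ``namespace`` (default ``GO``).  The background defaults, per namespace,
    to every gene with at least one annotation; an explicit background
    restricts the universe and the annotation is intersected with it.
    Terms with S = 0 are suppressed.  Results are ordered by (p, term id)
    within each namespace and ranked from 1.
    """
    ann = annotation.copy()
    if "namespace" not in ann.columns:
        ann["namespace"] = "GO"
    targets = {str(g) for g in target_genes}
    if background is not None:
        universe: Optional[Set[str]] = {str(g) for g in background}
        if not universe:
            raise ValueError("empty background gene universe")
        if not targets <= universe:
            raise ValueError("target_genes must be a subset of the background")
        ann = ann[ann["gene"].astype(str).isin(universe)]

    results: List[EnrichmentResult] = []
    for ns, sub in ann.groupby("namespace"):
        annotated = set(sub["gene"].astype(str))
        if not annotated:
            raise ValueError(f"no annotated genes in namespace {ns!r}")
        TB = len(annotated)
        ts_genes = targets & annotated
        TS = len(ts_genes)
        ns_results = []
        for term, genes in sub.groupby("term")["gene"]:
            term_genes = set(genes.astype(str))
            B = len(term_genes)
            S = len(term_genes & ts_genes)
            if S == 0:
                continue
            ns_results.append(
                EnrichmentResult(
                    term=str(term),
                    namespace=str(ns),
                    TB=TB,
                    TS=TS,
                    B=B,
                    S=S,
                    p_value=hypergeom_p(TB, TS, B, S),
                    rich_factor=S / B,
                )
            )
        ns_results.sort(key=lambda r: (r.p_value, r.term))
        if adjust and ns_results:
            adj = multipletests([r.p_value for r in ns_results], method="fdr_bh")[1]
            for r, a in zip(ns_results, adj):
                r.adjusted_p = float(a)
        for rank, r in enumerate(ns_results, start=1):
            r.rank = rank
        results.extend(ns_results)
    results.sort(key=lambda r: (r.namespace, r.p_value, r.term))
    return results


def top_k(results: Sequence[EnrichmentResult], k: int = 8) -> List[EnrichmentResult]:
    """The k smallest-P terms per namespace (ties by term id); fewer than k
    returns all."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    out: List[EnrichmentResult] = []
    namespaces = sorted({r.namespace for r in results})
    for ns in namespaces:
        ns_results = sorted(
            (r for r in results if r.namespace == ns),
            key=lambda r: (r.p_value, r.term),
        )
        out.extend(ns_results[:k])
    return out


def read_annotation_tsv(path) -> pd.DataFrame:
    """Two-column term/gene TSV with an optional third namespace column."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 2:
        df.columns = ["term", "gene"]
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
        df.columns = ["term", "gene", "namespace"]
    else:
        raise ValueError("annotation file needs >= 2 columns (term, gene)")
    return df
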