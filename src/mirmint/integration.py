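"""Fold-change quadrant analysis of miRNA-mRNA target pairs.

Each predicted target pair whose members are both differential is placed in
the (x, y) = (mRNA log2FC, miRNA log2FC) plane and classified against
demarcation lines at 1.5-fold, i.e. t = log2(1.5) on both axes:

    I   x >= t,  y >= t         (both up)
    II  x <= -t, y >= t         (mRNA down, miRNA up)
    III x <= -t, y <= -t        (both down)
    IV  x >= t,  y <= -t        (mRNA up, miRNA down)

Pairs in quadrants II and IV move in opposite directions and are flagged as
negative regulation -- the candidate repressive miRNA-target relations.
Boundary values are inclusive; anything inside the demarcation band is
labeled ``none`` and excluded from the quadrants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import pandas as pd

from .targets import TargetPair

__all__ = [
    "QUADRANT_THRESHOLD",
    "QuadrantPair",
    "PairSummary",
    "assign_quadrant",
    "correlate",
    "summarize_pairs",
]

#: Default demarcation: 1.5-fold on the linear scale.
QUADRANT_THRESHOLD = math.log2(1.5)

NEGATIVE_QUADRANTS = ("II", "IV")


@dataclass(frozen=True)
class QuadrantPair:
    mirna_id: str
    mrna_id: str
    x: float  # mRNA log2 fold change
    y: float  # miRNA log2 fold change
    quadrant: str
    negative_regulation: bool


@dataclass(frozen=True)
class PairSummary:
    """Degree statistics over a pair set, in both directions."""

    n_pairs: int
    n_negative: int
    targets_per_mirna: Tuple[int, int, float]  # (min, max, mean to 2 dp)
    mirnas_per_transcript: Tuple[int, int, float]
    quadrant_counts: Dict[str, int]


def assign_quadrant(x: float, y: float, t: float = QUADRANT_THRESHOLD) -> str:
    """Quadrant label for a fold-change point; ``none`` inside the band."""
    if t <= 0:
        raise ValueError(f"demarcation t must be > 0, got {t}")
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite fold change: x={x}, y={y}")
    if x >= t and y >= t:
        return "I"
    if x <= -t and y >= t:
        return "II"
    if x <= -t and y <= -t:
        return "III"
    if x >= t and y <= -t:
        return "IV"
    return "none"


PairLike = Union[TargetPair, Tuple[str, str]]


def _pair_ids(pairs: Iterable[PairLike]) -> List[Tuple[str, str]]:
    out = []
    for p in pairs:
        if isinstance(p, TargetPair):
            if p.passes:
                out.append((p.mirna_id, p.transcript_id))
        else:
            m, g = p
            out.append((str(m), str(g)))
    return out


def correlate(
    target_pairs: Iterable[PairLike],
    mirna_fc: pd.DataFrame,
    mrna_fc: pd.DataFrame,
    t: float = QUADRANT_THRESHOLD,
) -> List[QuadrantPair]:
    """Quadrant-classify target pairs whose members are both differential.

    ``mirna_fc`` / ``mrna_fc`` are differential-call tables indexed by
    feature id with ``log2fc`` and ``call`` columns (see
    :func:`mirmint.expression.call_differential`).  :class:`TargetPair`
    inputs contribute only their passing pairs; plain (miRNA, mRNA) tuples
    are taken as given.  Pairs with a non-differential member are dropped;
    a pair referencing an id without a fold-change record is an error.
    """
    out: List[QuadrantPair] = []
    for mid, gid in sorted(set(_pair_ids(target_pairs))):
        if mid not in mirna_fc.index:
            raise KeyError(f"no miRNA fold-change record for {mid!r}")
        if gid not in mrna_fc.index:
            raise KeyError(f"no mRNA fold-change record for {gid!r}")
        if mirna_fc.loc[mid, "call"] == "ns" or mrna_fc.loc[gid, "call"] == "ns":
            continue
        x = float(mrna_fc.loc[gid, "log2fc"])
        y = float(mirna_fc.loc[mid, "log2fc"])
        quad = assign_quadrant(x, y, t)
        out.append(
            QuadrantPair(
                mirna_id=mid,
                mrna_id=gid,
                x=x,
                y=y,
                quadrant=quad,
                negative_regulation=quad in NEGATIVE_QUADRANTS,
            )
        )
    return out


def summarize_pairs(pairs: Sequence[QuadrantPair]) -> PairSummary:
    """Min/max/mean degree per miRNA and per transcript, plus quadrant tallies."""
    if not pairs:
        return PairSummary(0, 0, (0, 0, 0.0), (0, 0, 0.0), {})
    per_mirna: Dict[str, int] = {}
    per_gene: Dict[str, int] = {}
    quad_counts: Dict[str, int] = {}
    for p in pairs:
        per_mirna[p.mirna_id] = per_mirna.get(p.mirna_id, 0) + 1
        per_gene[p.mrna_id] = per_gene.get(p.mrna_id, 0) + 1
        quad_counts[p.quadrant] = quad_counts.get(p.quadrant, 0) + 1

    def stats(d: Dict[str, int]) -> Tuple[int, int, float]:
        vals = list(d.values())
        return min(vals), max(vals), round(sum(vals) / len(vals), 2)

    return PairSummary(
        n_pairs=len(pairs),
        n_negative=sum(p.negative_regulation for p in pairs),
        targets_per_mirna=stats(per_mirna),
        mirnas_per_transcript=stats(per_gene),
        quadrant_counts=quad_counts,
    )
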