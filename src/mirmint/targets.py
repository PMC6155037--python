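"""miRNA target prediction on 3'UTR sequences.

Canonical seed matching (6mer / 7mer-A1 / 7mer-m8 / 8mer site types),
nearest-neighbor duplex free energy over a gap-free antiparallel register,
and an empirical context-score percentile.  A (miRNA, transcript) pair passes
when its best site energy is at or below ``energy_max`` (default -20 kcal/mol)
and its best context-score percentile is at or above ``percentile_min``
(default 90) -- the two filter settings commonly used with miRanda and
TargetScan respectively.

The seed is miRNA nucleotides 2-8 (5' end).  Site types follow the standard
hierarchy:

========  =============================================================
6mer      UTR match to the reverse complement of miRNA 2-7
7mer-m8   match extended to position 8
7mer-A1   6mer match plus an adenosine opposite miRNA position 1
8mer      position-8 match plus the A1 adenosine
========  =============================================================

Energies are a sum of published RNA nearest-neighbor stacking free energies
(dG37, kcal/mol) over consecutive paired positions, plus a +4.09 kcal/mol
duplex-initiation penalty.  There is no loop or bulge model: unpaired
positions contribute nothing, they only interrupt stacking.  G:U wobbles
count as pairs.  This keeps every energy hand-checkable as a short sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MatureMiRNA",
    "TargetSite",
    "TargetPair",
    "ContextWeights",
    "DUPLEX_INITIATION_DG",
    "TYPE_POINTS",
    "to_rna",
    "to_dna",
    "revcomp_rna",
    "revcomp_dna",
    "find_seed_sites",
    "duplex_dg",
    "duplex_energy",
    "pairing_vector",
    "three_prime_pairing_fraction",
    "context_score",
    "score_percentiles",
    "predict_targets",
]

# ---------------------------------------------------------------------------
# Sequence alphabet helpers

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
_DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def to_rna(seq: str) -> str:
    """Uppercase and map T->U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(to_rna(seq)))


def revcomp_dna(seq: str) -> str:
    return "".join(_DNA_COMPLEMENT[b] for b in reversed(to_dna(seq)))


def _validate_nucleotides(seq: str, what: str) -> str:
    rna = to_rna(seq)
    bad = sorted(set(rna) - set("ACGUN"))
    if bad:
        raise ValueError(f"{what} contains non-nucleotide characters: {bad}")
    return rna


# ---------------------------------------------------------------------------
# Nearest-neighbor thermodynamics

DUPLEX_INITIATION_DG = 4.09  # kcal/mol

#: Base pairs allowed in a duplex (strand-1 base, strand-2 base), incl. wobble.
VALID_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

# Stack key: two adjacent base pairs read 5'->3' along strand 1; each pair is
# (strand-1 base, strand-2 base).  Watson-Crick entries are the published
# Turner-2004 / Xia-1998 dG37 set; G:U wobble entries are embedded parameter
# data approximating the Turner-2004 wobble set.  Positive (destabilizing)
# tandem-wobble stacks are stored as 0 so that adding a paired position can
# never raise the total energy.
_NN_SEED: Dict[Tuple[Tuple[str, str], Tuple[str, str]], float] = {
    # Watson-Crick x Watson-Crick
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
    # stacks with one G:U wobble
    (("A", "U"), ("G", "U")): -0.55,
    (("A", "U"), ("U", "G")): -1.36,
    (("C", "G"), ("G", "U")): -1.41,
    (("C", "G"), ("U", "G")): -2.11,
    (("G", "C"), ("G", "U")): -1.53,
    (("G", "C"), ("U", "G")): -2.51,
    (("G", "U"), ("A", "U")): -1.27,
    (("G", "U"), ("C", "G")): -2.11,
    (("G", "U"), ("G", "C")): -1.80,
    (("G", "U"), ("U", "A")): -1.00,
    (("U", "G"), ("A", "U")): -1.00,
    (("U", "G"), ("C", "G")): -1.50,
    (("U", "G"), ("G", "C")): -1.20,
    (("U", "G"), ("U", "A")): -0.80,
    # tandem wobbles (destabilizing entries clamped to zero; see module notes)
    (("G", "U"), ("G", "U")): -0.50,
    (("G", "U"), ("U", "G")): 0.0,
    (("U", "G"), ("G", "U")): 0.0,
    (("U", "G"), ("U", "G")): -0.30,
}


def _build_stack_table() -> Dict[Tuple[Tuple[str, str], Tuple[str, str]], float]:
    # A duplex read from the other strand maps stack ((X,W),(Y,Z)) to
    # ((Z,Y),(W,X)); both orientations share one free energy.
    table = dict(_NN_SEED)
    for (p1, p2), v in _NN_SEED.items():
        sym = ((p2[1], p2[0]), (p1[1], p1[0]))
        table.setdefault(sym, v)
    return {k: min(v, 0.0) for k, v in table.items()}


NN_STACK_DG = _build_stack_table()


def duplex_dg(pairs: Sequence[Optional[Tuple[str, str]]]) -> float:
    """Free energy of a gap-free duplex described position by position.

    ``pairs`` lists, 5'->3' along strand 1, either a (strand-1 base,
    strand-2 base) tuple for a paired position or ``None`` for an unpaired
    one.  The result is the initiation penalty plus the stacking energies of
    every run of consecutive paired positions; a duplex with no
    complementarity at all is just the +4.09 initiation term.
    """
    dg = DUPLEX_INITIATION_DG
    for left, right in zip(pairs, pairs[1:]):
        if left is not None and right is not None:
            dg += NN_STACK_DG.get((left, right), 0.0)
    return dg


# ---------------------------------------------------------------------------
# Domain types

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

#: Site-type contribution to the context score; longer matches score higher.
TYPE_POINTS = {"8mer": 3.0, "7mer-m8": 2.0, "7mer-A1": 1.5, "6mer": 1.0}


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, stored 5'->3' in the RNA alphabet.

    T is accepted on input and mapped to U.  The seed is positions 2-8
    (1-based, inclusive), i.e. seven nucleotides.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        rna = _validate_nucleotides(self.sequence, f"miRNA {self.id!r}")
        object.__setattr__(self, "sequence", rna)
        if len(rna) < 19:
            raise ValueError(f"miRNA {self.id!r}: length {len(rna)} < 19 nt")

    @property
    def seed(self) -> str:
        """Positions 2-8, the 7-nt seed."""
        return self.sequence[1:8]


@dataclass
class TargetSite:
    """One predicted binding site on a UTR (sense strand, 0-based half-open)."""

    transcript_id: str
    mirna_id: str
    start: int
    end: int
    site_type: str
    alignment_score: float = math.nan  # paired positions in the final duplex
    delta_g: float = math.nan  # kcal/mol
    context_score: float = math.nan
    context_percentile: float = math.nan


@dataclass
class TargetPair:
    """A miRNA -> transcript relation aggregating its sites."""

    mirna_id: str
    transcript_id: str
    sites: List[TargetSite]
    best_delta_g: float
    best_context_percentile: float
    passes: bool


@dataclass(frozen=True)
class ContextWeights:
    """Weights of the context-score terms.

    ``w_3p`` rewards pairing of the miRNA 3' region with the UTR upstream of
    the seed site (the 3'-supplementary-pairing feature); it is what lets
    sites with extended complementarity outrank chance seed matches in the
    percentile ranking.
    """

    w_type: float = 1.0
    w_au: float = 1.0
    w_pos: float = 0.5
    w_3p: float = 2.0
    au_window: int = 30
    max_end_distance: int = 1500


DEFAULT_WEIGHTS = ContextWeights()


# ---------------------------------------------------------------------------
# Seed matching

def find_seed_sites(mirna: MatureMiRNA, utr: str) -> List[TargetSite]:
    """All maximal seed-match sites of ``mirna`` in ``utr``.

    Overlapping matches of different extents collapse to the longest type
    (an 8mer is reported once, not additionally as its contained 7mers).
    Coordinates are 0-based half-open on the UTR as given (DNA or RNA).
    """
    utr_rna = _validate_nucleotides(utr, "UTR")
    if len(utr_rna) < 6:
        return []
    core6 = revcomp_rna(mirna.sequence[1:7])  # complement of positions 2-7
    m8_partner = _RNA_COMPLEMENT[mirna.sequence[7]]  # base opposite position 8
    sites: List[TargetSite] = []
    i = utr_rna.find(core6)
    while i != -1:
        has_m8 = i > 0 and utr_rna[i - 1] == m8_partner
        has_a1 = i + 6 < len(utr_rna) and utr_rna[i + 6] == "A"
        if has_m8 and has_a1:
            start, end, stype = i - 1, i + 7, "8mer"
        elif has_m8:
            start, end, stype = i - 1, i + 6, "7mer-m8"
        elif has_a1:
            start, end, stype = i, i + 7, "7mer-A1"
        else:
            start, end, stype = i, i + 6, "6mer"
        sites.append(
            TargetSite(
                transcript_id="",
                mirna_id=mirna.id,
                start=start,
                end=end,
                site_type=stype,
            )
        )
        i = utr_rna.find(core6, i + 1)
    return sites


# ---------------------------------------------------------------------------
# Duplex energy and context score

def pairing_vector(
    mirna: MatureMiRNA, utr: str, site: TargetSite, flank: int = 15
) -> List[Optional[Tuple[str, str]]]:
    """Pairing state of miRNA positions 2..min(L, 8+flank) at ``site``.

    The register is gap-free and antiparallel, anchored on the seed match:
    miRNA position p sits opposite the UTR base ``flank`` steps 5' of the
    seed core as p grows.  Entry p is a (miRNA base, UTR base) tuple when the
    two bases form a Watson-Crick or G:U pair, else ``None``.  The A1
    adenosine (opposite miRNA position 1) is site recognition, not a base
    pair, and is excluded.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    utr_rna = to_rna(utr)
    # UTR index of the 6mer core start (opposite miRNA position 7):
    core_start = site.start + (1 if site.site_type in ("7mer-m8", "8mer") else 0)
    p_max = min(len(mirna.sequence), 8 + flank)
    pairs: List[Optional[Tuple[str, str]]] = []
    for p in range(2, p_max + 1):
        u = core_start + 7 - p  # UTR base opposite miRNA position p
        if 0 <= u < len(utr_rna):
            duo = (mirna.sequence[p - 1], utr_rna[u])
            pairs.append(duo if duo in VALID_PAIRS else None)
        else:
            pairs.append(None)
    return pairs


def duplex_energy(
    mirna: MatureMiRNA, utr: str, site: TargetSite, flank: int = 15
) -> float:
    """Nearest-neighbor duplex dG (kcal/mol) for a site, seed plus 3' extension.

    Extends the seed duplex over up to ``flank`` UTR bases 5' of the site
    against the miRNA 3' region on the gap-free diagonal, then sums stacking
    energies over consecutive pairs plus the initiation penalty.  More paired
    stacks can only lower (never raise) the result.
    """
    return duplex_dg(pairing_vector(mirna, utr, site, flank=flank))


def three_prime_pairing_fraction(
    mirna: MatureMiRNA, utr: str, site: TargetSite, flank: int = 15
) -> float:
    """Fraction of miRNA 3'-region positions (9..) paired at this site."""
    pairs = pairing_vector(mirna, utr, site, flank=flank)
    tail = pairs[7:]  # vector starts at position 2, so index 7 is position 9
    if not tail:
        return 0.0
    return sum(p is not None for p in tail) / len(tail)


def _local_au_fraction(utr: str, site: TargetSite, window: int) -> float:
    utr_rna = to_rna(utr)
    flank5 = utr_rna[max(0, site.start - window): site.start]
    flank3 = utr_rna[site.end: site.end + window]
    context = flank5 + flank3
    if not context:
        return 0.0
    return sum(b in "AU" for b in context) / len(context)


def context_score(
    site: TargetSite,
    utr: str,
    mirna: Optional[MatureMiRNA] = None,
    weights: ContextWeights = DEFAULT_WEIGHTS,
    flank: int = 15,
    universe_scores: Optional[Sequence[float]] = None,
) -> Tuple[float, float]:
    """(score, percentile) of a site.

    score = w_type * type_points + w_au * local AU fraction
          + w_pos * min(distance to the nearer UTR end, 1500)/1500
          + w_3p * 3'-pairing fraction          (0 when ``mirna`` is None)

    The percentile is the site's empirical rank against ``universe_scores``
    (100 * #{scores <= this score} / n).  Without a universe the site is its
    own singleton universe and the percentile is 100 by convention.
    """
    score = weights.w_type * TYPE_POINTS[site.site_type]
    score += weights.w_au * _local_au_fraction(utr, site, weights.au_window)
    end_dist = min(site.start, len(utr) - site.end)
    score += weights.w_pos * min(end_dist, weights.max_end_distance) / weights.max_end_distance
    if mirna is not None:
        score += weights.w_3p * three_prime_pairing_fraction(mirna, utr, site, flank=flank)
    if universe_scores is None or len(universe_scores) == 0:
        return score, 100.0
    arr = np.asarray(universe_scores, dtype=float)
    return score, 100.0 * float(np.count_nonzero(arr <= score)) / arr.size


def score_percentiles(scores: Sequence[float]) -> List[float]:
    """Empirical percentile of each score within the full list (ties share
    the highest rank; a singleton gets 100)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        return []
    order = np.argsort(arr, kind="stable")
    # count of scores <= s, via searchsorted on the sorted array
    sorted_arr = arr[order]
    counts = np.searchsorted(sorted_arr, arr, side="right")
    return list(100.0 * counts / arr.size)


# ---------------------------------------------------------------------------
# Whole-run prediction

def predict_targets(
    mirnas: Iterable[MatureMiRNA],
    utrs: Mapping[str, str],
    energy_max: float = -20.0,
    percentile_min: float = 90.0,
    flank: int = 15,
    weights: ContextWeights = DEFAULT_WEIGHTS,
) -> List[TargetPair]:
    """Predict miRNA->transcript target pairs over a miRNA panel and a UTR set.

    One :class:`TargetPair` is produced per (miRNA, transcript) with at least
    one seed site; ``passes`` requires best dG <= ``energy_max`` and best
    context percentile >= ``percentile_min``.  Percentiles are empirical over
    every site found in the run.  Output is sorted by (miRNA id, transcript
    id) and is independent of input ordering.
    """
    mirna_list = sorted(mirnas, key=lambda m: m.id)
    ids = [m.id for m in mirna_list]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate miRNA ids in input")
    utr_ids = list(utrs)
    if len(set(utr_ids)) != len(utr_ids):
        raise ValueError("duplicate transcript ids in input")

    all_sites: List[TargetSite] = []
    for mirna in mirna_list:
        for tid in sorted(utrs):
            seq = utrs[tid]
            for site in find_seed_sites(mirna, seq):
                site.transcript_id = tid
                pairs = pairing_vector(mirna, seq, site, flank=flank)
                site.alignment_score = float(sum(p is not None for p in pairs))
                site.delta_g = duplex_dg(pairs)
                site.context_score, _ = context_score(
                    site, seq, mirna, weights=weights, flank=flank
                )
                all_sites.append(site)

    for site, pct in zip(all_sites, score_percentiles([s.context_score for s in all_sites])):
        site.context_percentile = pct

    grouped: Dict[Tuple[str, str], List[TargetSite]] = {}
    for site in all_sites:
        grouped.setdefault((site.mirna_id, site.transcript_id), []).append(site)

    result = []
    for (mid, tid) in sorted(grouped):
        sites = grouped[(mid, tid)]
        best_dg = min(s.delta_g for s in sites)
        best_pct = max(s.context_percentile for s in sites)
        result.append(
            TargetPair(
                mirna_id=mid,
                transcript_id=tid,
                sites=sites,
                best_delta_g=best_dg,
                best_context_percentile=best_pct,
                passes=(best_dg <= energy_max and best_pct >= percentile_min),
            )
        )
    return result
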