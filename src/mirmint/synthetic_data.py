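"""Simulated two-stage small-RNA/mRNA studies with known ground truth.

Every pipeline input is generated with its answer key: a telogen/anagen
design (two conditions x three biological replicates by default) with
negative-binomial counts and planted up/down features; mature miRNA panels
and 3'UTRs carrying planted seed sites for a designated set of negatively
regulated miRNA-target pairs; term->gene annotations with planted enriched
terms; raw FASTQ libraries with planted filter artifacts; and qPCR Ct
tables with planted fold changes.  The :class:`TruthSet` records every
planted structure before any file is written, so each downstream stage has
a recovery-testable fixture.

Reproducibility: every operation draws from its own RNG stream derived from
the master seed by a fixed offset, so identical (config, seed) gives
bit-identical output and individual fixtures regenerate independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import srna_qc
from .srna_qc import FILTER_CATEGORIES, QCConfig, ReadRecord
from .targets import MatureMiRNA, find_seed_sites, revcomp_dna, to_dna, to_rna

__all__ = [
    "GeneratorConfig",
    "TruthSet",
    "generate_mirnas",
    "generate_counts",
    "generate_utrs",
    "generate_reads",
    "generate_annotations",
    "generate_qpcr",
    "generate_all",
    "design_for",
]

_BASES = np.array(list("ACGT"))

# fixed per-operation RNG stream offsets (spawned off the master seed)
_STREAM = {
    "counts": 1,
    "mirnas": 2,
    "utrs": 3,
    "reads": 4,
    "annotations": 5,
    "qpcr": 6,
}

#: Insert-length distribution of clean reads: modal length 22 nt at 31%,
#: matching the canonical miRNA length profile of mammalian skin libraries.
DEFAULT_CLEAN_LENGTH_PROBS: Dict[int, float] = {
    18: 0.02, 19: 0.05, 20: 0.14, 21: 0.14, 22: 0.31, 23: 0.12, 24: 0.08,
    25: 0.05, 26: 0.03, 27: 0.02, 28: 0.02, 29: 0.01, 30: 0.01,
}

#: Default artifact fractions: a few percent of a library fails filtering,
#: dominated by adaptor/insert problems and short inserts.
DEFAULT_ARTIFACT_FRACTIONS: Dict[str, float] = {
    "low_quality": 0.003,
    "adaptor3_null": 0.010,
    "insert_null": 0.012,
    "adaptor5_contaminant": 0.0008,
    "size_lt_18": 0.013,
    "polyA": 0.0002,
}

DEFAULT_QPCR_LOG2FC: Dict[str, float] = {
    "CHP1": 2.0, "FZD6": 1.0, "SIAH1": 1.5, "SMAD2": 0.5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the simulated study; defaults are the study conditions.

    Baseline expression is drawn log-uniform between ``10**lo`` and
    ``10**hi`` counts (``nb_mean_log_range`` in log10), with negative-
    binomial noise of the given dispersion (variance mu + d*mu^2; 0 means
    Poisson).  Planted up/down features split the effect symmetrically:
    anagen mean = base * 2^(+m/2), telogen mean = base * 2^(-m/2).
    """

    seed: int = 0
    n_mirna: int = 60
    n_mrna: int = 300
    n_reps_per_condition: int = 3
    nb_mean_log_range: Tuple[float, float] = (1.0, 3.0)
    nb_dispersion: float = 0.1
    n_de_mirna_up: int = 15
    n_de_mirna_down: int = 15
    n_de_mrna_up: int = 60
    n_de_mrna_down: int = 60
    de_log2fc_magnitude: float = 2.0
    n_true_pairs: int = 50
    mirna_length: int = 22
    plant_3p_complement: bool = True
    utr_length_range: Tuple[int, int] = (300, 600)
    n_terms: int = 50
    genes_per_term: int = 20
    n_enriched_terms: int = 5
    enriched_term_overlap: int = 15
    annotation_namespaces: Tuple[str, ...] = ("GO", "KEGG")
    n_reads: int = 2000
    read_length: int = 50
    adaptor3: str = QCConfig.adaptor3
    adaptor5: str = QCConfig.adaptor5
    read_artifact_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_FRACTIONS)
    )
    clean_length_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLEAN_LENGTH_PROBS)
    )
    qpcr_log2fc: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QPCR_LOG2FC)
    )
    qpcr_reference: str = "ACTB"
    qpcr_calibrator: str = "telogen"
    qpcr_noise_sd: float = 0.2
    qpcr_n_bio: int = 3
    qpcr_n_tech: int = 3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def positive(name: str, minimum=1) -> None:
            if getattr(self, name) < minimum:
                raise ValueError(f"config field {name!r} must be >= {minimum}")

        for name in ("n_mirna", "n_mrna", "n_reps_per_condition", "n_reads",
                     "mirna_length", "read_length", "n_terms", "genes_per_term"):
            positive(name)
        for name in ("nb_dispersion", "de_log2fc_magnitude", "qpcr_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name!r} must be >= 0")
        if self.mirna_length < 19:
            raise ValueError("config field 'mirna_length' must be >= 19")
        if self.n_de_mirna_up + self.n_de_mirna_down > self.n_mirna:
            raise ValueError(
                "config fields 'n_de_mirna_up'+'n_de_mirna_down' exceed 'n_mirna'"
            )
        if self.n_de_mrna_up + self.n_de_mrna_down > self.n_mrna:
            raise ValueError(
                "config fields 'n_de_mrna_up'+'n_de_mrna_down' exceed 'n_mrna'"
            )
        cross = (self.n_de_mirna_down * self.n_de_mrna_up
                 + self.n_de_mirna_up * self.n_de_mrna_down)
        if self.n_true_pairs > cross:
            raise ValueError(
                "config field 'n_true_pairs' exceeds the up/down cross product"
            )
        if self.n_true_pairs > self.n_de_mrna_up + self.n_de_mrna_down:
            raise ValueError(
                "config field 'n_true_pairs' exceeds the number of planted "
                "differential mRNAs (one planted site per transcript)"
            )
        fracs = dict(self.read_artifact_fractions)
        unknown = set(fracs) - set(FILTER_CATEGORIES)
        if unknown:
            raise ValueError(f"config field 'read_artifact_fractions' has "
                             f"unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in fracs.values()) or sum(fracs.values()) >= 1:
            raise ValueError(
                "config field 'read_artifact_fractions' entries must be >= 0 "
                "and sum to < 1"
            )
        if not self.adaptor3 or not self.adaptor5:
            raise ValueError("config fields 'adaptor3'/'adaptor5' must be non-empty")
        if self.n_enriched_terms > self.n_terms:
            raise ValueError("config field 'n_enriched_terms' exceeds 'n_terms'")
        if self.genes_per_term > self.n_mrna:
            raise ValueError("config field 'genes_per_term' exceeds 'n_mrna'")
        if self.enriched_term_overlap > self.genes_per_term:
            raise ValueError(
                "config field 'enriched_term_overlap' exceeds 'genes_per_term'"
            )
        if not self.annotation_namespaces:
            raise ValueError("config field 'annotation_namespaces' must be non-empty")
        if self.utr_length_range[0] > self.utr_length_range[1]:
            raise ValueError("config field 'utr_length_range' must be (lo, hi)")
        probs = dict(self.clean_length_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("config field 'clean_length_probs' must sum to 1")

    def rng(self, op: str) -> np.random.Generator:
        return np.random.default_rng([_STREAM[op], self.seed])


@dataclass
class TruthSet:
    """Answer key of one simulated study."""

    de_direction: Dict[str, Dict[str, str]] = field(
        default_factory=lambda: {"mirna": {}, "mrna": {}}
    )
    true_pairs: Set[Tuple[str, str]] = field(default_factory=set)
    enriched_terms: Set[str] = field(default_factory=set)
    read_category: Dict[str, str] = field(default_factory=dict)
    planted_sites: Dict[Tuple[str, str], List[int]] = field(default_factory=dict)
    planted_rq: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "de_direction": self.de_direction,
            "true_pairs": sorted(f"{m}|{g}" for m, g in self.true_pairs),
            "enriched_terms": sorted(self.enriched_terms),
            "read_category": self.read_category,
            "planted_sites": {f"{m}|{g}": v for (m, g), v in self.planted_sites.items()},
            "planted_rq": self.planted_rq,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        t = cls()
        t.de_direction = payload["de_direction"]
        t.true_pairs = {tuple(s.split("|")) for s in payload["true_pairs"]}
        t.enriched_terms = set(payload["enriched_terms"])
        t.read_category = payload["read_category"]
        t.planted_sites = {
            tuple(k.split("|")): v for k, v in payload["planted_sites"].items()
        }
        t.planted_rq = payload["planted_rq"]
        return t


def design_for(config: GeneratorConfig) -> Dict[str, str]:
    """Sample -> condition map for the simulated design (T1..Tn, A1..An)."""
    d = {f"T{i+1}": "telogen" for i in range(config.n_reps_per_condition)}
    d.update({f"A{i+1}": "anagen" for i in range(config.n_reps_per_condition)})
    return d


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# ---------------------------------------------------------------------------
# Counts

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    return rng.negative_binomial(r, p, size=size)


def generate_counts(
    config: GeneratorConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Simulate the miRNA and mRNA count matrices and seed the truth set.

    Planted up features have an expected log2 fold change (anagen over
    telogen) of +``de_log2fc_magnitude``; down features the negative.  The
    truth set also receives the planted negative-regulation pairs: each
    pairs a differential miRNA with a distinct, oppositely differential
    transcript.
    """
    rng = config.rng("counts")
    truth = TruthSet()
    matrices: Dict[str, pd.DataFrame] = {}
    planted = {
        "mirna": (config.n_mirna, config.n_de_mirna_up, config.n_de_mirna_down, "mir-{:03d}"),
        "mrna": (config.n_mrna, config.n_de_mrna_up, config.n_de_mrna_down, "gene-{:04d}"),
    }
    design = design_for(config)
    samples = list(design)
    for kind, (n, n_up, n_down, fmt) in planted.items():
        ids = [fmt.format(i + 1) for i in range(n)]
        perm = rng.permutation(n)
        ups = {ids[i] for i in perm[:n_up]}
        downs = {ids[i] for i in perm[n_up: n_up + n_down]}
        lo, hi = config.nb_mean_log_range
        base = 10 ** rng.uniform(lo, hi, size=n)
        half = 2 ** (config.de_log2fc_magnitude / 2.0)
        mat = np.zeros((n, len(samples)), dtype=np.int64)
        for i, fid in enumerate(ids):
            direction = "up" if fid in ups else ("down" if fid in downs else "null")
            truth.de_direction[kind][fid] = direction
            shift = {"up": half, "down": 1 / half, "null": 1.0}[direction]
            for j, s in enumerate(samples):
                mean = base[i] * (shift if design[s] == "anagen" else 1 / shift)
                mat[i, j] = _nb_draw(rng, mean, config.nb_dispersion, 1)[0]
        matrices[kind] = pd.DataFrame(mat, index=ids, columns=samples)

    mi_up = sorted(f for f, d in truth.de_direction["mirna"].items() if d == "up")
    mi_down = sorted(f for f, d in truth.de_direction["mirna"].items() if d == "down")
    g_up = sorted(f for f, d in truth.de_direction["mrna"].items() if d == "up")
    g_down = sorted(f for f, d in truth.de_direction["mrna"].items() if d == "down")
    # distinct transcripts; each paired with an oppositely-regulated miRNA
    gene_pool = [(g, "up") for g in g_up] + [(g, "down") for g in g_down]
    if config.n_true_pairs:
        chosen = rng.choice(len(gene_pool), size=config.n_true_pairs, replace=False)
        for idx in sorted(chosen):
            gene, gdir = gene_pool[idx]
            partners = mi_down if gdir == "up" else mi_up
            if not partners:
                raise ValueError(
                    "config field 'n_true_pairs' requires oppositely "
                    "regulated miRNAs for every chosen transcript"
                )
            mirna = partners[rng.integers(len(partners))]
            truth.true_pairs.add((mirna, gene))
    return matrices["mirna"], matrices["mrna"], truth


# ---------------------------------------------------------------------------
# Sequences

def generate_mirnas(config: GeneratorConfig) -> Dict[str, str]:
    """Random mature miRNA panel (RNA alphabet) with pairwise-distinct seeds."""
    rng = config.rng("mirnas")
    ids = [f"mir-{i+1:03d}" for i in range(config.n_mirna)]
    seqs: Dict[str, str] = {}
    seeds_seen: Set[str] = set()
    for mid in ids:
        for _ in range(100):
            seq = to_rna(_random_seq(rng, config.mirna_length))
            if seq[1:8] not in seeds_seen:
                seeds_seen.add(seq[1:8])
                seqs[mid] = seq
                break
        else:
            raise RuntimeError("could not draw a miRNA with a distinct seed")
    return seqs


def _repair_seed_matches(
    rng: np.random.Generator,
    utr: List[str],
    cores: Mapping[str, str],
    protected: Sequence[Tuple[int, int]] = (),
    max_rounds: int = 100,
) -> List[str]:
    """Remove every occurrence of the given seed cores by redrawing the
    matched 6-nt windows (skipping protected spans), up to ``max_rounds``."""

    def overlaps_protected(i: int) -> bool:
        return any(i < e and i + 6 > s for s, e in protected)

    for _ in range(max_rounds):
        s = "".join(utr)
        hits = []
        for core in cores.values():
            j = s.find(core)
            while j != -1:
                if not overlaps_protected(j):
                    hits.append(j)
                j = s.find(core, j + 1)
        if not hits:
            return utr
        for j in hits:
            for k in range(j, j + 6):
                utr[k] = str(rng.choice(_BASES))
    raise RuntimeError("UTR seed-collision repair did not converge in 100 rounds")


def generate_utrs(
    config: GeneratorConfig,
    truth: TruthSet,
    mirna_sequences: Mapping[str, str],
) -> Tuple[Dict[str, str], TruthSet]:
    """Random 3'UTRs (DNA) with planted sites for every true pair.

    Each true pair's transcript carries one exact 7mer-m8 seed site; by
    default the planted cassette is the reverse complement of miRNA
    positions 2..L, so the miRNA 3' region finds full complementary pairing
    upstream of the seed and the planted duplex is strongly bound.  All UTRs
    are screened against the seed cores of every truth miRNA (outside the
    planted cassette), so no accidental seed match for a truth miRNA
    survives.  Planted seed-site start positions are recorded in
    ``truth.planted_sites``.
    """
    for mid, _gid in truth.true_pairs:
        if mid not in mirna_sequences:
            raise ValueError(f"true pair miRNA {mid!r} has no sequence")
        if len(mirna_sequences[mid]) < 19:
            raise ValueError(f"true pair miRNA {mid!r} is shorter than 19 nt")

    rng = config.rng("utrs")
    lo, hi = config.utr_length_range
    truth_mirnas = sorted({m for m, _ in truth.true_pairs})
    cores = {m: revcomp_dna(to_dna(mirna_sequences[m][1:7])) for m in truth_mirnas}
    pair_by_gene: Dict[str, List[str]] = {}
    for m, g in truth.true_pairs:
        pair_by_gene.setdefault(g, []).append(m)

    cassette_len = max(
        (len(mirna_sequences[m]) - 1 if config.plant_3p_complement else 7)
        for m in truth_mirnas
    ) if truth_mirnas else 0
    if truth_mirnas and lo < cassette_len + 10:
        raise ValueError(
            "config field 'utr_length_range' is too short to host a planted site"
        )

    utrs: Dict[str, str] = {}
    gene_ids = [f"gene-{i+1:04d}" for i in range(config.n_mrna)]
    for gid in gene_ids:
        length = int(rng.integers(lo, hi + 1))
        utr = list(_random_seq(rng, length))
        utr = _repair_seed_matches(rng, utr, cores)
        for mid in sorted(pair_by_gene.get(gid, [])):
            mseq = mirna_sequences[mid]
            cas = revcomp_dna(to_dna(mseq[1:] if config.plant_3p_complement else mseq[1:8]))
            start = int(rng.integers(1, length - len(cas) - 1))
            utr[start: start + len(cas)] = list(cas)
            # keep the site 7mer-m8: the base opposite position 1 must not be A
            if utr[start + len(cas)] == "A":
                utr[start + len(cas)] = str(rng.choice(np.array(list("CGT"))))
            utr = _repair_seed_matches(
                rng, utr, cores, protected=[(start, start + len(cas) + 1)]
            )
            seed_start = start + len(cas) - 7
            truth.planted_sites.setdefault((mid, gid), []).append(seed_start)
        utrs[gid] = "".join(utr)

    # verify the answer key against the written sequences: every recorded
    # start must come back as a 7mer-m8 site for its miRNA
    for (mid, gid), positions in truth.planted_sites.items():
        found = {
            s.start
            for s in find_seed_sites(MatureMiRNA(mid, mirna_sequences[mid]), utrs[gid])
            if s.site_type == "7mer-m8"
        }
        if not set(positions) <= found:
            raise RuntimeError(f"planted site for pair ({mid}, {gid}) not recoverable")
    return utrs, truth


# ---------------------------------------------------------------------------
# Reads

def _phred(rng: np.random.Generator, n: int, mean: float, sd: float,
           lo: int, hi: int) -> List[int]:
    return list(np.clip(np.rint(rng.normal(mean, sd, size=n)), lo, hi).astype(int))


def generate_reads(config: GeneratorConfig) -> Tuple[List[ReadRecord], TruthSet]:
    """Raw FASTQ-style reads with planted filter artifacts.

    Every read is assigned one category by a multinomial draw over the
    configured artifact fractions (remainder clean); the realized category
    is recorded in the truth set and verified against the QC classifier at
    generation time, so filtering reproduces the drawn tallies exactly.
    """
    rng = config.rng("reads")
    truth = TruthSet()
    cats = list(FILTER_CATEGORIES)
    fracs = dict(config.read_artifact_fractions)
    probs = [fracs.get(c, 0.0) for c in cats]
    probs.append(1.0 - sum(probs))  # clean
    qc_cfg = QCConfig(
        adaptor3=config.adaptor3,
        adaptor5=config.adaptor5,
        raw_read_length=config.read_length,
    )
    lengths = sorted(config.clean_length_probs)
    length_p = [config.clean_length_probs[k] for k in lengths]
    labels = cats + ["clean"]
    L = config.read_length

    def build(category: str) -> ReadRecord:
        if category == "low_quality":
            seq = (_random_seq(rng, int(rng.choice(lengths, p=length_p)))
                   + config.adaptor3)
            seq = (seq + _random_seq(rng, max(0, L - len(seq))))[:L]
            qual = _phred(rng, len(seq), 10, 2, 2, 17)
            return ReadRecord("", seq, qual)
        if category == "adaptor3_null":
            seq = _random_seq(rng, L)
        elif category == "insert_null":
            seq = (config.adaptor3 + _random_seq(rng, L))[:L]
        elif category == "adaptor5_contaminant":
            insert = config.adaptor5[:10] + _random_seq(rng, 12)
            seq = (insert + config.adaptor3 + _random_seq(rng, L))[:L]
        elif category == "size_lt_18":
            insert = _random_seq(rng, int(rng.integers(10, 18)))
            seq = (insert + config.adaptor3 + _random_seq(rng, L))[:L]
        elif category == "polyA":
            seq = ("A" * 22 + config.adaptor3 + _random_seq(rng, L))[:L]
        else:  # clean
            insert = _random_seq(rng, int(rng.choice(lengths, p=length_p)))
            seq = (insert + config.adaptor3 + _random_seq(rng, L))[:L]
        return ReadRecord("", seq, _phred(rng, len(seq), 36, 2, 25, 40))

    reads: List[ReadRecord] = []
    for i in range(config.n_reads):
        category = str(rng.choice(labels, p=probs))
        want = "high_quality" if category == "clean" else category
        for _ in range(100):
            read = build(category)
            read.id = f"read_{i+1:06d}"
            got, _trimmed = srna_qc.classify_read(read, qc_cfg)
            if got == want:
                break
        else:
            raise RuntimeError(f"could not construct a {category!r} read")
        reads.append(read)
        truth.read_category[read.id] = category
    return reads, truth


# ---------------------------------------------------------------------------
# Annotations

def generate_annotations(
    config: GeneratorConfig,
    truth: TruthSet,
    target_genes: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, TruthSet]:
    """Term->gene annotation with planted enriched terms.

    Planted terms receive ``enriched_term_overlap`` genes from the target
    set (default: the true-pair transcripts) plus background filler;
    background terms sample the gene universe uniformly, and every
    otherwise-unannotated gene is attached to one background term so the
    annotated background spans the full transcript universe.  Namespaces
    alternate GO / KEGG.
    """
    rng = config.rng("annotations")
    genes = [f"gene-{i+1:04d}" for i in range(config.n_mrna)]
    if target_genes is None:
        target_genes = sorted({g for _, g in truth.true_pairs})
    targets_list = [g for g in target_genes if g in set(genes)]
    overlap = min(config.enriched_term_overlap, len(targets_list))
    if config.n_enriched_terms and overlap == 0:
        raise ValueError("cannot plant enriched terms without target genes")
    non_targets = sorted(set(genes) - set(targets_list))

    rows: List[Tuple[str, str, str]] = []
    annotated: Set[str] = set()
    term_names: List[Tuple[str, str]] = []
    spaces = list(config.annotation_namespaces)
    for i in range(config.n_terms):
        ns = spaces[i % len(spaces)]
        term = f"GO:{i+1:07d}" if ns == "GO" else f"ko{i+1:05d}"
        term_names.append((term, ns))

    for i, (term, ns) in enumerate(term_names):
        if i < config.n_enriched_terms:
            members = list(rng.choice(targets_list, size=overlap, replace=False))
            filler = config.genes_per_term - overlap
            if filler:
                members += list(rng.choice(non_targets, size=filler, replace=False))
            truth.enriched_terms.add(term)
        else:
            members = list(rng.choice(genes, size=config.genes_per_term, replace=False))
        for g in members:
            rows.append((term, str(g), ns))
            annotated.add(str(g))

    background_terms = term_names[config.n_enriched_terms:] or term_names
    for g in genes:
        if g not in annotated:
            term, ns = background_terms[int(rng.integers(len(background_terms)))]
            rows.append((term, g, ns))
    ann = pd.DataFrame(rows, columns=["term", "gene", "namespace"])
    ann = ann.drop_duplicates().reset_index(drop=True)
    return ann, truth


# ---------------------------------------------------------------------------
# qPCR

def generate_qpcr(config: GeneratorConfig) -> Tuple[pd.DataFrame, TruthSet]:
    """Ct table with planted anagen/telogen fold changes.

    Three technical replicates per (sample, gene) by default; the reference
    gene sits at a constant Ct up to a shared per-sample offset (which
    cancels in dCt), and planted log2 fold changes appear as anagen Ct
    shifts.  With ``qpcr_noise_sd = 0`` the planted RQ round-trips exactly.
    """
    rng = config.rng("qpcr")
    truth = TruthSet()
    rows = []
    genes = dict(config.qpcr_log2fc)
    truth.planted_rq = {g: float(2.0 ** fc) for g, fc in genes.items()}
    stages = [("telogen", "T"), ("anagen", "A")]
    for stage, prefix in stages:
        for b in range(config.qpcr_n_bio):
            sample = f"{prefix}{b+1}"
            offset = float(rng.normal(0.0, 0.3))
            gene_base = {config.qpcr_reference: 20.0}
            for gi, (g, fc) in enumerate(sorted(genes.items())):
                ct0 = 24.0 + 0.7 * gi
                gene_base[g] = ct0 - (fc if stage == "anagen" else 0.0)
            for g, base in gene_base.items():
                noise = rng.normal(0.0, config.qpcr_noise_sd, size=config.qpcr_n_tech) \
                    if config.qpcr_noise_sd > 0 else np.zeros(config.qpcr_n_tech)
                for r in range(config.qpcr_n_tech):
                    rows.append(
                        {
                            "sample": sample,
                            "stage": stage,
                            "gene": g,
                            "replicate": r + 1,
                            "ct": base + offset + float(noise[r]),
                        }
                    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Whole-study convenience

def generate_all(config: GeneratorConfig) -> Dict[str, object]:
    """Generate every fixture of one study and one merged truth set."""
    mirna_counts, mrna_counts, truth = generate_counts(config)
    mirnas = generate_mirnas(config)
    utrs, truth = generate_utrs(config, truth, mirnas)
    reads, read_truth = generate_reads(config)
    truth.read_category = read_truth.read_category
    ann, truth = generate_annotations(config, truth)
    ct, qpcr_truth = generate_qpcr(config)
    truth.planted_rq = qpcr_truth.planted_rq
    return {
        "mirna_counts": mirna_counts,
        "mrna_counts": mrna_counts,
        "mirnas": mirnas,
        "utrs": utrs,
        "reads": reads,
        "annotation": ann,
        "ct": ct,
        "truth": truth,
        "design": design_for(config),
    }
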