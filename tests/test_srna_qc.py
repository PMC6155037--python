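"""Filter cascade, accounting identity, and clean-read summaries."""

import dataclasses

import numpy as np
import pytest

from mirmint.srna_qc import (
    FILTER_CATEGORIES,
    FilterReport,
    QCConfig,
    ReadRecord,
    annotate_known_mirnas,
    base_composition,
    classify_read,
    filter_reads,
    length_distribution,
)
from mirmint.synthetic_data import GeneratorConfig, generate_reads

CFG = QCConfig()
HIGH_Q = [35] * 60


def _read(seq, qual=None, rid="r1"):
    return ReadRecord(rid, seq, qual if qual is not None else [35] * len(seq))


@pytest.mark.parametrize(
    "read, expected",
    [
        # mean Phred below 20
        (_read("ACGT" * 10, [10] * 40), "low_quality"),
        # N content above 10%
        (_read("N" * 10 + "ACGT" * 10, [35] * 50), "low_quality"),
        # full-length read without the 3' adaptor
        (_read("ACGTACGTGA" * 5, [35] * 50), "adaptor3_null"),
        # adaptor at position 0 = empty insert
        (_read((CFG.adaptor3 + "ACGTACGTGACCTGACGTACGTGACCTGA")[:50], [35] * 50),
         "insert_null"),
        # 5' adaptor leading the insert
        (_read((CFG.adaptor5[:10] + "ACGTACGTGACC" + CFG.adaptor3 + "G" * 20)[:50],
               [35] * 50), "adaptor5_contaminant"),
        # 12-nt insert
        (_read(("ACGTACGTGACC" + CFG.adaptor3 + "G" * 20)[:50], [35] * 50),
         "size_lt_18"),
        # insert >= 80% A
        (_read(("A" * 20 + "CG" + CFG.adaptor3 + "G" * 20)[:50], [35] * 50), "polyA"),
        # ordinary insert + adaptor
        (_read(("ACGTTGCATGCATGCATGCCA" + CFG.adaptor3 + "G" * 20)[:50], [35] * 50),
         "high_quality"),
    ],
)
def test_classify_read_cascade(read, expected):
    category, trimmed = classify_read(read, CFG)
    assert category == expected
    if expected == "high_quality":
        assert len(trimmed.sequence) >= CFG.min_insert_length
        assert CFG.adaptor3[:8] not in trimmed.sequence


def test_empty_input_yields_zero_report():
    clean, report = filter_reads([], CFG)
    assert clean == [] and report.total_reads == 0 and report.high_quality == 0
    assert all(v == 0 for v in report.category_counts.values())


def test_report_invariants_and_percentages(small_config):
    reads, _ = generate_reads(small_config)
    qc = QCConfig(adaptor3=small_config.adaptor3, adaptor5=small_config.adaptor5,
                  raw_read_length=small_config.read_length)
    clean, report = filter_reads(reads, qc)
    assert report.total_reads == report.high_quality + sum(
        report.category_counts.values()
    )
    for cat in FILTER_CATEGORIES:
        assert report.percentages[cat] == round(
            100.0 * report.category_counts[cat] / report.total_reads, 2
        )
    # idempotence: the cascade is a partition, clean output stays clean
    clean2, report2 = filter_reads(clean, qc)
    assert report2.high_quality == len(clean)
    assert sum(report2.category_counts.values()) == 0


def test_from_counts_rejects_overflowing_categories():
    with pytest.raises(ValueError, match="exceed"):
        FilterReport.from_counts("s", 10, {"low_quality": 11})


def test_malformed_read_counted_low_quality_unless_strict():
    bad = ReadRecord("r", "ACGT", [30, 30])
    _, report = filter_reads([bad], CFG)
    assert report.category_counts["low_quality"] == 1
    with pytest.raises(ValueError, match="mismatch"):
        filter_reads([bad], dataclasses.replace(CFG, strict=True))


def test_length_distribution_arithmetic():
    reads = [_read("A" * 22, rid=f"r{i}") for i in range(3)] + [_read("C" * 20)]
    dist = length_distribution(reads)
    assert dist.total[22] == (3, 0.75)
    assert dist.distinct[22] == (1, 0.5)  # 3 copies of one distinct 22-mer
    assert length_distribution([]).total == {}


def test_modal_length_matches_generating_distribution():
    """10k clean inserts drawn with 22-nt probability 0.31."""
    cfg = GeneratorConfig(seed=13, n_reads=10_000, read_artifact_fractions={})
    reads, _ = generate_reads(cfg)
    qc = QCConfig(adaptor3=cfg.adaptor3, adaptor5=cfg.adaptor5,
                  raw_read_length=cfg.read_length)
    clean, _ = filter_reads(reads, qc)
    dist = length_distribution(clean)
    modal = max(dist.total, key=lambda k: dist.total[k][0])
    assert modal == 22
    assert dist.total[22][1] == pytest.approx(0.31, abs=0.02)


def test_base_composition_fractions():
    comp = base_composition([_read("AAAA"), _read("AAAA")])
    assert comp.loc[0, "A"] == 1.0
    comp = base_composition([_read("AC"), _read("GT")])
    assert comp.loc[0, "A"] == 0.5 and comp.loc[0, "G"] == 0.5
    # uniform random reads: every fraction near 0.25 at every position
    rng = np.random.default_rng(5)
    reads = [_read("".join(rng.choice(list("ACGT"), 30)), rid=f"r{i}")
             for i in range(10_000)]
    comp = base_composition(reads)
    assert comp.sum(axis=1).round(9).eq(1.0).all()
    assert (comp[["A", "C", "G", "T"]].sub(0.25).abs() < 0.02).all().all()


def test_known_mirna_annotation_with_3p_tolerance():
    ref = {"m1": "TGGTAGCAGCACAGAAATGTTGG"}
    labels, _ = annotate_known_mirnas(
        ["TGGTAGCAGCACAGAAATGTTGG",        # exact
         "TGGTAGCAGCACAGAAATGTTGGCA",      # +2 nt at 3' end
         "TGGTAGCAGCACAGAAATGTT",          # -2 nt at 3' end
         "AGGTAGCAGCACAGAAATGTTGG"],       # 5' mismatch -> unknown
        ref,
    )
    assert list(labels.values()) == ["known", "known", "known", "unknown"]


def test_known_fraction_by_construction():
    rng = np.random.default_rng(8)
    ref = {"".join(rng.choice(list("ACGT"), 22)) for _ in range(450)}
    known = sorted(ref)[:400]
    # distinct 27-mers cannot hit 22-mer references within +/-2 nt
    unknown = sorted({"".join(rng.choice(list("ACGT"), 27)) for _ in range(650)})[:600]
    labels, summary = annotate_known_mirnas(known + unknown, ref)
    assert summary["known_fraction"] == pytest.approx(0.400)
    assert all(labels[s] == "known" for s in known)
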