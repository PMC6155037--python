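"""Seed matching, duplex energies, context scores and whole-run prediction."""

import numpy as np
import pytest

from mirmint.synthetic_data import generate_counts, generate_mirnas, generate_utrs
from mirmint.targets import (
    ContextWeights,
    MatureMiRNA,
    TargetSite,
    DUPLEX_INITIATION_DG,
    context_score,
    duplex_dg,
    duplex_energy,
    find_seed_sites,
    predict_targets,
    revcomp_rna,
    score_percentiles,
    to_rna,
)

MIR195 = MatureMiRNA("miR-195", "TGGTAGCAGCACAGAAATGTTGG")


def test_seed_site_from_mir195_sequence():
    """revcomp of miR-195 positions 2-8 (GGTAGCA) = TGCTACC -> 7mer-m8."""
    sites = find_seed_sites(MIR195, "NNNNNNNNNNTGCTACCNNN")
    assert [(s.start, s.end, s.site_type) for s in sites] == [(10, 17, "7mer-m8")]


def test_short_utr_and_no_match():
    assert find_seed_sites(MIR195, "ACGT") == []


def test_site_types_by_construction():
    core7 = revcomp_rna(MIR195.sequence[1:8]).replace("U", "T")  # TGCTACC
    # 8mer: position-8 match plus A opposite position 1
    sites = find_seed_sites(MIR195, "GGGG" + core7 + "A" + "GGGG")
    assert [(s.site_type, s.start, s.end) for s in sites] == [("8mer", 4, 12)]
    # 7mer-A1: 6mer core plus the A, no m8 match
    sites = find_seed_sites(MIR195, "GGGG" + core7[1:] + "A" + "GGGG")
    assert [s.site_type for s in sites] == ["7mer-A1"]
    # bare 6mer
    sites = find_seed_sites(MIR195, "GGGG" + core7[1:] + "GGGG")
    assert [s.site_type for s in sites] == ["6mer"]


def test_full_complement_utr_gives_8mer():
    utr = revcomp_rna(MIR195.sequence[1:]) + "A"
    sites = find_seed_sites(MIR195, utr)
    assert any(s.site_type == "8mer" for s in sites)


def test_non_nucleotide_characters_error():
    with pytest.raises(ValueError, match="X"):
        find_seed_sites(MIR195, "ACGTXACGT")
    with pytest.raises(ValueError):
        MatureMiRNA("bad", "ACGTACGTACGTACGTACG9")


def test_reported_sites_are_reverse_complements():
    """Every site's UTR substring obeys its site type's complementarity."""
    rng = np.random.default_rng(0)
    utr = "".join(rng.choice(list("ACGT"), 2000))
    for s in find_seed_sites(MIR195, utr):
        sub = to_rna(utr[s.start: s.end])
        if s.site_type == "6mer":
            assert sub == revcomp_rna(MIR195.sequence[1:7])
        elif s.site_type == "7mer-m8":
            assert sub == revcomp_rna(MIR195.sequence[1:8])
        elif s.site_type == "7mer-A1":
            assert sub == revcomp_rna(MIR195.sequence[1:7]) + "A"
        else:
            assert sub == revcomp_rna(MIR195.sequence[1:8]) + "A"


def test_duplex_dg_model_definition():
    # no complementarity at all: initiation penalty only
    assert duplex_dg([]) == DUPLEX_INITIATION_DG
    assert duplex_dg([None, None, None]) == DUPLEX_INITIATION_DG
    # eight G:C pairs stack seven GG/CC entries at -3.26 each
    assert duplex_dg([("G", "C")] * 8) == pytest.approx(4.09 + 7 * -3.26)
    # removing an internal pair can only raise the energy
    perfect = [("G", "C")] * 8
    broken = perfect.copy()
    broken[4] = None
    assert duplex_dg(perfect) <= duplex_dg(broken)


def test_duplex_energy_translation_invariance():
    cassette = revcomp_rna(MIR195.sequence[1:]).replace("U", "T")
    for pad in (0, 37):
        utr = "G" * (3 + pad) + cassette + "C" * 40
        sites = [s for s in find_seed_sites(MIR195, utr) if s.site_type == "7mer-m8"]
        assert len(sites) == 1
        dg = duplex_energy(MIR195, utr, sites[0])
        if pad == 0:
            first = dg
    assert dg == pytest.approx(first)
    assert dg < -20  # full 3' complementarity binds strongly


def test_negative_flank_errors():
    utr = "NNNNNNNNNNTGCTACCNNN"
    site = find_seed_sites(MIR195, utr)[0]
    with pytest.raises(ValueError, match="flank"):
        duplex_energy(MIR195, utr, site, flank=-1)


def test_context_score_type_ordering_and_percentiles():
    utr = "G" * 30 + "NNNNNN" + "G" * 30
    s8 = TargetSite("t", "m", 30, 38, "8mer")
    s6 = TargetSite("t", "m", 30, 36, "6mer")
    score8, pct = context_score(s8, utr)
    score6, _ = context_score(s6, utr)
    assert score8 > score6
    assert pct == 100.0  # singleton universe convention
    pcts = score_percentiles(list(range(10)))
    assert max(pcts) == 100.0 and min(pcts) == pytest.approx(10.0)


def test_predict_targets_recovers_all_planted_pairs(default_study):
    """All 50 planted pairs present and passing at default thresholds."""
    panel = [MatureMiRNA(k, v) for k, v in default_study["mirnas"].items()]
    pairs = predict_targets(panel, default_study["utrs"])
    passing = {(p.mirna_id, p.transcript_id) for p in pairs if p.passes}
    assert default_study["truth"].true_pairs <= passing


def test_impossible_percentile_threshold_passes_nothing(default_study):
    panel = [MatureMiRNA(k, v) for k, v in default_study["mirnas"].items()]
    pairs = predict_targets(panel, default_study["utrs"],
                            energy_max=0.0, percentile_min=101.0)
    assert not any(p.passes for p in pairs)


def test_prediction_is_order_independent(small_config):
    _, _, truth = generate_counts(small_config)
    mirnas = generate_mirnas(small_config)
    utrs, truth = generate_utrs(small_config, truth, mirnas)
    panel = [MatureMiRNA(k, v) for k, v in mirnas.items()]
    fwd = predict_targets(panel, utrs)
    rev = predict_targets(list(reversed(panel)), dict(reversed(list(utrs.items()))))
    assert [(p.mirna_id, p.transcript_id, p.passes, p.best_delta_g) for p in fwd] == \
           [(p.mirna_id, p.transcript_id, p.passes, p.best_delta_g) for p in rev]


def test_shuffled_utrs_destroy_planted_sites(default_study):
    """Composition-preserving shuffle: planted-pair recovery collapses."""
    rng = np.random.default_rng(99)
    shuffled = {
        tid: "".join(rng.permutation(list(seq)))
        for tid, seq in default_study["utrs"].items()
    }
    panel = [MatureMiRNA(k, v) for k, v in default_study["mirnas"].items()]
    pairs = predict_targets(panel, shuffled)
    passing = {(p.mirna_id, p.transcript_id) for p in pairs if p.passes}
    truth = default_study["truth"].true_pairs
    assert len(passing & truth) <= 0.05 * len(truth)


def test_duplicate_mirna_ids_error():
    with pytest.raises(ValueError, match="duplicate miRNA"):
        predict_targets([MIR195, MIR195], {"t": "ACGTACGT"})
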