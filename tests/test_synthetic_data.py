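"""Generator contracts: determinism, truth consistency, planted effects."""

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mirmint.expression import ExpressionMatrix, log2_fold_change
from mirmint.qpcr import delta_delta_ct
from mirmint.srna_qc import QCConfig, filter_reads
from mirmint.synthetic_data import (
    GeneratorConfig,
    design_for,
    generate_annotations,
    generate_counts,
    generate_mirnas,
    generate_qpcr,
    generate_reads,
    generate_utrs,
)
from mirmint.targets import MatureMiRNA, find_seed_sites, revcomp_dna, to_dna


def test_counts_are_deterministic_and_nonnegative():
    cfg = GeneratorConfig(seed=5, n_mirna=10, n_mrna=40, n_de_mirna_up=2,
                          n_de_mirna_down=2, n_de_mrna_up=8, n_de_mrna_down=8,
                          n_true_pairs=5)
    a = generate_counts(cfg)
    b = generate_counts(cfg)
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])
    assert a[2].true_pairs == b[2].true_pairs
    assert (a[0].values >= 0).all() and (a[1].values >= 0).all()
    assert list(a[0].columns) == ["T1", "T2", "T3", "A1", "A2", "A3"]


def test_no_planted_mrna_effects_means_all_null_directions():
    cfg = GeneratorConfig(seed=2, n_mrna=50, n_de_mrna_up=0, n_de_mrna_down=0,
                          n_true_pairs=0)
    _, _, truth = generate_counts(cfg)
    assert set(truth.de_direction["mrna"].values()) == {"null"}


def test_planted_fold_change_recovered_on_average():
    """Monte-Carlo check of the generator against its own parameters."""
    cfg = GeneratorConfig(seed=1, n_mrna=200, de_log2fc_magnitude=2.0,
                          nb_dispersion=0.1)
    _, mrna, truth = generate_counts(cfg)
    fc = log2_fold_change(ExpressionMatrix(mrna, design_for(cfg)))
    ups = [f for f, d in truth.de_direction["mrna"].items() if d == "up"]
    assert abs(fc.loc[ups, "log2fc"].mean() - 2.0) < 0.5


@pytest.mark.parametrize(
    "overrides, field_name",
    [
        ({"n_mirna": 0}, "n_mirna"),
        ({"nb_dispersion": -1.0}, "nb_dispersion"),
        ({"n_de_mrna_up": 300, "n_de_mrna_down": 10}, "n_de_mrna"),
        ({"n_true_pairs": 10_000}, "n_true_pairs"),
        ({"read_artifact_fractions": {"polyA": 1.5}}, "read_artifact_fractions"),
        ({"read_artifact_fractions": {"bogus": 0.1}}, "read_artifact_fractions"),
        ({"n_enriched_terms": 100}, "n_enriched_terms"),
        ({"genes_per_term": 10_000}, "genes_per_term"),
        ({"adaptor3": ""}, "adaptor3"),
    ],
)
def test_invalid_config_errors_name_the_field(overrides, field_name):
    with pytest.raises(ValueError, match=field_name):
        GeneratorConfig(**overrides)


def test_utrs_host_planted_sites_and_screen_nonpair_utrs(small_config):
    _, _, truth = generate_counts(small_config)
    mirnas = generate_mirnas(small_config)
    utrs, truth = generate_utrs(small_config, truth, mirnas)
    # every planted pair has >= 1 recorded site, recoverable as a 7mer-m8
    assert set(truth.planted_sites) == truth.true_pairs
    for (mid, gid), positions in truth.planted_sites.items():
        found = find_seed_sites(MatureMiRNA(mid, mirnas[mid]), utrs[gid])
        starts = {s.start for s in found if s.site_type == "7mer-m8"}
        assert set(positions) <= starts
    # non-pair UTRs carry no seed core of any truth miRNA
    truth_mirnas = {m for m, _ in truth.true_pairs}
    pair_genes = {g for _, g in truth.true_pairs}
    for gid, seq in utrs.items():
        if gid in pair_genes:
            continue
        for m in truth_mirnas:
            core = revcomp_dna(to_dna(mirnas[m][1:7]))
            assert core not in seq


def test_utr_range_too_short_to_host_site_errors(small_config):
    cfg = dataclasses.replace(small_config, utr_length_range=(20, 25))
    _, _, truth = generate_counts(cfg)
    mirnas = generate_mirnas(cfg)
    with pytest.raises(ValueError, match="utr_length_range"):
        generate_utrs(cfg, truth, mirnas)


def test_reads_deterministic_and_category_truth_round_trip():
    cfg = GeneratorConfig(
        seed=4,
        n_reads=100,
        read_artifact_fractions={"polyA": 0.03, "size_lt_18": 0.10,
                                 "adaptor3_null": 0.05},
    )
    reads_a, truth_a = generate_reads(cfg)
    reads_b, truth_b = generate_reads(cfg)
    assert [(r.id, r.sequence, r.quality) for r in reads_a] == \
           [(r.id, r.sequence, r.quality) for r in reads_b]
    planted = Counter(truth_a.read_category.values())
    qc_cfg = QCConfig(adaptor3=cfg.adaptor3, adaptor5=cfg.adaptor5,
                      raw_read_length=cfg.read_length)
    clean, report = filter_reads(reads_a, qc_cfg)
    assert report.high_quality == planted["clean"]
    for cat, count in report.category_counts.items():
        assert count == planted.get(cat, 0)


def test_zero_artifact_fractions_give_all_clean_reads():
    cfg = GeneratorConfig(seed=9, n_reads=50, read_artifact_fractions={})
    reads, truth = generate_reads(cfg)
    assert set(truth.read_category.values()) == {"clean"}
    assert len(truth.read_category) == 50  # each read id appears exactly once


def test_annotations_plant_enriched_terms_and_cover_universe(small_config):
    _, _, truth = generate_counts(small_config)
    ann, truth = generate_annotations(small_config, truth)
    assert len(truth.enriched_terms) == small_config.n_enriched_terms
    # full-coverage fill: every gene annotated at least once
    genes = {f"gene-{i+1:04d}" for i in range(small_config.n_mrna)}
    assert set(ann["gene"]) == genes


def test_qpcr_noiseless_round_trip_and_noise_propagation():
    cfg = GeneratorConfig(seed=3, qpcr_noise_sd=0.0, qpcr_log2fc={"G1": 2.0})
    ct, truth = generate_qpcr(cfg)
    _, summaries = delta_delta_ct(ct, cfg.qpcr_reference, cfg.qpcr_calibrator)
    by = {(s.gene, s.stage): s.rq for s in summaries}
    assert by[("G1", "anagen")] == pytest.approx(4.0, rel=1e-12)
    assert by[("G1", "telogen")] == pytest.approx(1.0, rel=1e-12)
    # with Ct noise sd 0.2 and 3 replicates, RQ=4 recovers within [2.5, 6.5]
    cfg_noise = GeneratorConfig(seed=3, qpcr_noise_sd=0.2, qpcr_log2fc={"G1": 2.0})
    ct_n, _ = generate_qpcr(cfg_noise)
    _, summaries_n = delta_delta_ct(ct_n, cfg_noise.qpcr_reference,
                                    cfg_noise.qpcr_calibrator)
    rq = {(s.gene, s.stage): s.rq for s in summaries_n}[("G1", "anagen")]
    assert 2.5 <= rq <= 6.5
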