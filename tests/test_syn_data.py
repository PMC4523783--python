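"""Generator contracts: determinism, planted-locus validity, read model."""

import numpy as np
import pytest

from coldmir.novel_id import CriteriaThresholds, evaluate_cluster
from coldmir.syn_data import (
    GenomePackingError,
    LengthNoise,
    ReadSimulationParams,
    SyntheticGenomeSpec,
    build_genome,
    expected_tag_counts,
    simulate_library,
)
from coldmir.tagproc import clean_reads, collapse

from conftest import FIXTURE_SPEC, noiseless_params


def test_no_novel_loci_requested_means_none_planted(backend):
    spec = SyntheticGenomeSpec(
        genome_length=30_000, n_chromosomes=2, n_known_loci=2,
        n_novel_loci=0, n_ncrna_loci=2, seed=5,
    )
    _, truth = build_genome(spec, backend=backend)
    assert [t for t in truth if t.category == "novel_miRNA"] == []


def test_same_seed_is_byte_identical(backend):
    spec = SyntheticGenomeSpec(
        genome_length=30_000, n_chromosomes=2, n_known_loci=2,
        n_novel_loci=1, n_ncrna_loci=2, seed=9,
    )
    g1, t1 = build_genome(spec, backend=backend)
    g2, t2 = build_genome(spec, backend=backend)
    assert g1 == g2
    assert [(x.locus_id, x.location, x.mature_seq) for x in t1] == [
        (x.locus_id, x.location, x.mature_seq) for x in t2
    ]
    params = noiseless_params(seed=3, total=5_000)
    r1 = simulate_library(g1, t1, params, "NCT")
    r2 = simulate_library(g2, t2, params, "NCT")
    assert r1 == r2


def test_planted_loci_sit_at_recorded_coordinates(genome, truth):
    for locus in truth:
        seq = locus.sequence(genome)
        assert len(seq) == locus.end - locus.start + 1
        if locus.mature_seq:
            assert (
                seq[locus.mature_offset : locus.mature_offset + len(locus.mature_seq)]
                == locus.mature_seq
            )


def test_planted_novel_precursors_pass_all_criteria(backend):
    """Oracle: the ten-rule checker accepts every planted novel hairpin."""
    spec = SyntheticGenomeSpec(
        genome_length=40_000, n_chromosomes=2, n_known_loci=5,
        n_novel_loci=3, n_ncrna_loci=0, seed=7,
    )
    genome, truth = build_genome(spec, backend=backend)
    novel = [t for t in truth if t.category == "novel_miRNA"]
    assert len(novel) == 3
    for locus in novel:
        accepted = evaluate_cluster(
            locus.mature_genomic(), genome, backend,
            thresholds=CriteriaThresholds(), skip_support=True,
        )
        assert accepted, f"{locus.locus_id} rejected by the criteria checker"
        assert any(c.mature_seq == locus.mature_seq for c, _ in accepted)


def test_zero_abundance_locus_absent_from_library(genome, truth):
    params = noiseless_params(seed=2, total=None)
    # force one locus to zero in CT
    target = next(t for t in truth if t.category == "novel_miRNA")
    original = target.abundance_CT
    target.abundance_CT = 0.0
    try:
        reads = simulate_library(genome, truth, params, "CT")
        assert all(not seq.startswith(target.mature_seq) for _, seq, _ in reads)
    finally:
        target.abundance_CT = original


def test_noiseless_reads_are_mature_plus_adapter(genome, truth):
    params = noiseless_params(seed=4, total=None)
    mirna_only = [t for t in truth if t.mature_seq]
    reads = simulate_library(genome, mirna_only, params, "NCT")
    matures = {t.mature_seq for t in mirna_only}
    for _, seq, _ in reads:
        assert any(
            seq.startswith(m) and seq[len(m):] == (params.adapter_3p[: 36 - len(m)])
            for m in matures
        )


def test_poisson_mean_recovery():
    """Replicated simulation recovers a planted abundance of 200 (Poisson)."""
    spec = SyntheticGenomeSpec(
        genome_length=30_000, n_chromosomes=2, n_known_loci=2,
        n_novel_loci=1, n_ncrna_loci=0, seed=13,
    )
    genome, truth = build_genome(spec)
    locus = truth[0]
    locus.abundance_NCT = 200.0
    counts = []
    for seed in range(10):
        params = noiseless_params(seed=seed, total=None)
        reads = simulate_library(genome, truth, params, "NCT")
        counts.append(sum(1 for _, s, _ in reads if s.startswith(locus.mature_seq)))
    se = np.sqrt(200.0 / len(counts))
    assert abs(np.mean(counts) - 200.0) < 3 * se


def test_ground_truth_round_trip(genome, truth):
    """Noiseless reads, cleaned and collapsed, recover every planted mature."""
    params = noiseless_params(seed=6, total=40_000)
    tags_by_lib = {}
    for lib in ("NCT", "CT"):
        reads = simulate_library(genome, truth, params, lib)
        clean, _ = clean_reads(reads, params.adapter_3p)
        tags_by_lib[lib] = clean
    tags = {t.sequence for t in collapse(tags_by_lib)}
    scale_ok = [
        t for t in truth
        if t.mature_seq and (t.abundance_NCT >= 1 or t.abundance_CT >= 1)
    ]
    missing = [t.locus_id for t in scale_ok if t.mature_seq not in tags]
    assert missing == []


def test_expected_counts_match_noiseless_simulation(genome, truth):
    params = noiseless_params(seed=8, total=40_000)
    reads = simulate_library(genome, truth, params, "NCT")
    clean, _ = clean_reads(reads, params.adapter_3p)
    observed = {}
    for seq in clean:
        observed[seq] = observed.get(seq, 0) + 1
    expected = expected_tag_counts(truth, params, "NCT")
    for mature, exp in expected.items():
        if exp < 50:
            continue
        obs = observed.get(mature, 0)
        assert abs(obs - exp) < 5 * np.sqrt(exp), mature


def test_infeasible_packing_names_chromosome(backend):
    spec = SyntheticGenomeSpec(
        genome_length=600, n_chromosomes=2, n_known_loci=6,
        n_novel_loci=2, n_ncrna_loci=2, seed=1,
    )
    with pytest.raises(GenomePackingError, match="chr"):
        build_genome(spec, backend=backend)


def test_unknown_library_rejected(genome, truth):
    with pytest.raises(KeyError, match="abundance"):
        simulate_library(genome, truth, noiseless_params(), "XX")


def test_length_histogram_is_bimodal(genome, truth):
    """21-nt (miRNA) and 24-nt (ncRNA fragment) modes in the tag lengths."""
    params = ReadSimulationParams(seed=5, total_reads_per_library=60_000)
    reads = simulate_library(genome, truth, params, "NCT")
    clean, _ = clean_reads(reads, params.adapter_3p)
    hist = {}
    for seq in clean:
        hist[len(seq)] = hist.get(len(seq), 0) + 1
    # 21 nt is the global mode; 24 nt is a second local mode
    assert hist[21] == max(hist.values())
    assert hist[24] > hist[23] and hist[24] > hist[25]
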