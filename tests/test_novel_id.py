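"""Hairpin excision, duplex location (vs pair-table oracle), ten criteria."""

import numpy as np
import pytest

from coldmir._seq import random_seq, revcomp
from coldmir.fold import get_backend, nussinov_fold, pair_table, vienna_fold
from coldmir.novel_id import (
    CriteriaThresholds,
    DuplexStats,
    HairpinCandidate,
    check_criteria,
    discover_novel,
    excise_candidates,
    find_duplex,
)


def _stub_candidate(**overrides):
    """A fully populated candidate with all-passing defaults."""
    fields = dict(
        locus="chr1:100:200:+",
        precursor_seq="A" * 101,
        structure="." * 101,
        mfe=-30.0,
        mature_seq="A" * 21,
        mature_offset=0,
        duplex=DuplexStats(paired_bases=19, bulge_max=2, asymmetry=1,
                           spacing=10, star_start=40, star_end=62),
        n_genomic_copies=1,
        flank=20,
        read_support={"NCT": 120, "CT": 80},
    )
    fields.update(overrides)
    return HairpinCandidate(**fields)


# --- excision ---------------------------------------------------------------

def test_windows_extend_cluster_by_flank():
    genome = {"chr1": random_seq(400, np.random.default_rng(0))}
    windows = excise_candidates(("chr1", 100, 120, "+"), genome, flank=20)
    assert len(windows) == 2
    for w in windows:
        assert w.start <= 80 and w.end >= 140
        assert w.seq == genome["chr1"][w.start - 1 : w.end]


def test_window_clipped_at_chromosome_edge():
    genome = {"chr1": random_seq(150, np.random.default_rng(1))}
    windows = excise_candidates(("chr1", 10, 30, "+"), genome, flank=20)
    assert any(w.clipped for w in windows)
    for w in windows:
        assert w.start >= 1 and w.end <= 150


def test_copy_cap_suppresses_candidates():
    genome = {"chr1": random_seq(3000, np.random.default_rng(2))}
    tag = genome["chr1"][50:71]
    hits = [("chr1", 50 + 100 * i, 70 + 100 * i, "+") for i in range(25)]
    out = discover_novel({tag: hits}, {tag: {"NCT": 100}}, genome,
                         backend=lambda s: ("." * len(s), 0.0))
    assert out == []


# --- folding backends -------------------------------------------------------

def test_inverted_repeat_folds_into_stable_hairpin():
    stem = "GCTAGGCTCAGTTCAGGCAT"  # 20 bp stem
    seq = stem + "GCTTAAGC" + revcomp(stem)
    structure, mfe = vienna_fold(seq)
    assert structure.count("(") >= 15
    assert mfe < -18.0


def test_homopolymer_does_not_fold():
    structure, mfe = vienna_fold("A" * 60)
    assert "(" not in structure
    assert mfe >= -18.0


def test_nussinov_fallback_produces_balanced_hairpin():
    stem = "GCTAGGCTCAGTTCAGGCAT"
    seq = stem + "GCTTAAGC" + revcomp(stem)
    structure, energy = nussinov_fold(seq)
    pt = pair_table(structure)  # raises if unbalanced
    assert sum(1 for p in pt if p >= 0) >= 30
    assert energy < 0


def test_stub_backend_passthrough():
    """Criteria logic consumes injected (structure, mfe) unchanged."""
    cand = _stub_candidate(mfe=-25.5)
    report = check_criteria(cand)
    assert report.results[4].measured == -25.5
    assert report.overall


# --- duplex location --------------------------------------------------------

def test_fully_paired_mature_duplex_stats():
    # 21-nt mature fully paired to a 21-nt star across an 8-nt loop
    structure = "(" * 21 + "." * 8 + ")" * 21
    stats, reason = find_duplex(structure, 0, 21)
    assert reason is None
    assert stats.paired_bases == 21
    assert stats.bulge_max == 0 and stats.asymmetry == 0
    assert stats.spacing == 8


def test_loop_spanning_mature_fails():
    structure = "(" * 10 + "." * 8 + ")" * 10
    stats, reason = find_duplex(structure, 5, 14)  # spans the loop
    assert stats is None and reason == "loop_spanning"


def test_unpaired_mature_fails():
    stats, reason = find_duplex("." * 60, 10, 21)
    assert stats is None and reason == "mature_unpaired"


def test_duplex_stats_match_pair_table_oracle(backend):
    """Brute-force recomputation from the pair table on random hairpins."""
    from coldmir.syn_data import _draw_hairpin

    rng = np.random.default_rng(17)
    checked = 0
    for _ in range(200):
        mature = random_seq(21, rng)
        hairpin, m_off, _ = _draw_hairpin(mature, rng, 0.4)
        structure, _ = backend(hairpin)
        stats, reason = find_duplex(structure, m_off, 21)
        if stats is None:
            continue
        checked += 1
        pt = pair_table(structure)
        m_range = range(m_off, m_off + 21)
        partners = [pt[i] for i in m_range if pt[i] >= 0]
        assert stats.paired_bases == len(partners)
        lo, hi = min(partners), max(partners)
        assert stats.star_start == lo
        if lo > m_off:  # star on the 3' arm: free to extend its overhang
            assert stats.star_end == min(hi + 2, len(hairpin) - 1)
        else:  # star on the 5' arm: overhang stops at the mature
            assert stats.star_end == min(hi + 2, len(hairpin) - 1, m_off - 1)
        # bulge: longest unpaired run inside either duplex strand
        def runs(idxs, other):
            best = cur = 0
            for i in idxs:
                if pt[i] < 0 or pt[i] not in other:
                    cur += 1
                    best = max(best, cur)
                else:
                    cur = 0
            return best

        expect_bulge = max(runs(m_range, set(range(lo, hi + 1))),
                           runs(range(lo, hi + 1), set(m_range)))
        assert stats.bulge_max == expect_bulge
        assert stats.asymmetry == abs((21 - len(partners)) - (hi - lo + 1 - len(partners)))
    assert checked >= 150


# --- criteria ---------------------------------------------------------------

def test_all_passing_candidate_passes_overall():
    report = check_criteria(_stub_candidate())
    assert report.overall and report.failed() == []


@pytest.mark.parametrize(
    "override,criterion",
    [
        ({"mature_seq": "A" * 17}, 1),
        ({"mature_seq": "A" * 24}, 2),  # 24 nt: inside 18-25, outside 20-23
        ({"n_genomic_copies": 25}, 3),
        ({"mfe": -17.5}, 4),
        ({"duplex": DuplexStats(19, 2, 1, 31, 40, 62)}, 5),
        ({"duplex": DuplexStats(15, 2, 1, 10, 40, 62)}, 6),
        ({"duplex": DuplexStats(19, 5, 1, 10, 40, 62)}, 7),
        ({"duplex": DuplexStats(19, 2, 5, 10, 40, 62)}, 8),
        ({"flank": 19}, 9),
        ({"read_support": {"NCT": 49, "CT": 49}}, 10),
    ],
)
def test_single_perturbation_flips_exactly_one_criterion(override, criterion):
    report = check_criteria(_stub_candidate(**override))
    expected = {criterion}
    if criterion == 1:  # a 17-nt mature also leaves the 20-23 window
        expected = {1, 2}
    assert set(report.failed()) == expected
    assert not report.overall


def test_support_threshold_is_at_least_50_in_one_library():
    assert check_criteria(_stub_candidate(read_support={"NCT": 50, "CT": 0})).overall
    assert not check_criteria(_stub_candidate(read_support={"NCT": 49, "CT": 49})).overall


def test_support_monotonicity():
    """Dropping support below 50 in both libraries can only revoke a pass."""
    passing = check_criteria(_stub_candidate(read_support={"NCT": 200, "CT": 10}))
    lowered = check_criteria(_stub_candidate(read_support={"NCT": 49, "CT": 10}))
    assert passing.overall and not lowered.overall
    failing = check_criteria(_stub_candidate(mfe=-10.0,
                                             read_support={"NCT": 200, "CT": 10}))
    still_failing = check_criteria(_stub_candidate(mfe=-10.0,
                                                   read_support={"NCT": 9, "CT": 9}))
    assert not failing.overall and not still_failing.overall


def test_backend_independence_of_report():
    cand_a = _stub_candidate()
    cand_b = _stub_candidate()
    ra, rb = check_criteria(cand_a), check_criteria(cand_b)
    assert [(k, v.passed, v.measured) for k, v in ra.results.items()] == [
        (k, v.passed, v.measured) for k, v in rb.results.items()
    ]


def test_planted_locus_window_contains_precursor(genome, truth, backend):
    from coldmir.novel_id import evaluate_cluster

    locus = next(t for t in truth if t.category == "novel_miRNA")
    accepted = evaluate_cluster(
        locus.mature_genomic(), genome, backend,
        read_support={"NCT": int(max(locus.abundance_NCT, locus.abundance_CT))},
    )
    assert accepted
    cand, report = accepted[0]
    assert report.overall
    assert locus.mature_seq in cand.precursor_seq
    assert cand.star_seq is not None
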