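"""Target-site scoring (vs brute-force oracle), cleavage and correlation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldmir._seq import random_seq, revcomp
from coldmir.targets import (
    brute_force_scan,
    expression_correlation,
    scan_transcripts,
    score_site,
    summarize_cleavage,
)

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def _site_for(mirna, mismatch_at=None, wobble_at=None):
    """Transcript site (5'->3') complementary to the miRNA, with edits at
    given miRNA positions (1-based)."""
    site = list(revcomp(mirna))
    L = len(mirna)
    if mismatch_at:
        i = L - mismatch_at  # site index opposite miRNA position
        base = mirna[mismatch_at - 1]
        site[i] = base  # X:X never pairs and never wobbles
    if wobble_at:
        i = L - wobble_at
        base = mirna[wobble_at - 1]
        assert base in "GT", "wobble requires G or U on the miRNA"
        site[i] = "T" if base == "G" else "G"
    return "".join(site)


def test_perfect_complement_scores_zero():
    states, score = score_site(MIRNA, _site_for(MIRNA))
    assert score == 0.0
    assert set(states) == {"match"}


def test_single_wobble_outside_core_scores_half():
    # miRNA position 15 is G -> pair it with T on the site (G:U)
    assert MIRNA[14] == "G"
    _, score = score_site(MIRNA, _site_for(MIRNA, wobble_at=15))
    assert score == 0.5


def test_single_mismatch_in_core_scores_two():
    _, score = score_site(MIRNA, _site_for(MIRNA, mismatch_at=5))
    assert score == 2.0


def test_gap_penalty_doubled_in_core():
    site = _site_for(MIRNA)
    _, score = score_site(MIRNA[:4] + "-" + MIRNA[5:], site)
    assert score == 4.0  # gap (2) doubled at position 5


def test_alphabet_violation_rejected():
    with pytest.raises(ValueError):
        score_site("ACGTZ", "ACGTA")


def test_score_additivity_exhaustive_4mers():
    """Sum-of-penalties equals direct enumeration on all 4-mer pairs."""
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    for m in itertools.product("ACGT", repeat=4):
        for s in itertools.product("ACGT", repeat=4):
            mirna, site = "".join(m), "".join(s)
            expected = 0.0
            for i, (mb, sb) in enumerate(zip(mirna, site[::-1])):
                pen = 0.0 if (mb, sb) in wc else 0.5 if (mb, sb) in gu else 1.0
                expected += pen * (2.0 if 2 <= i + 1 <= 13 else 1.0)
            _, score = score_site(mirna, site)
            assert score == expected, (mirna, site)


def test_scan_finds_planted_perfect_site():
    rng = np.random.default_rng(5)
    site = _site_for(MIRNA)
    transcript = random_seq(60, rng) + site + random_seq(40, rng)
    hits = scan_transcripts("m", MIRNA, {"tx1": transcript}, max_score=3.0)
    perfect = [h for h in hits if h.score == 0.0]
    assert len(perfect) == 1
    h = perfect[0]
    assert h.site_start == 61 and h.site_end == 61 + len(MIRNA) - 1
    assert h.expected_cleavage == h.site_end - 9


def test_scan_finds_planted_one_mismatch_site():
    rng = np.random.default_rng(6)
    site = _site_for(MIRNA, mismatch_at=18)  # outside the doubled core
    transcript = random_seq(30, rng) + site + random_seq(30, rng)
    hits = scan_transcripts("m", MIRNA, {"tx": transcript}, max_score=3.0)
    assert any(h.score == 1.0 and h.site_start == 31 for h in hits)


def test_scan_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    mirna = random_seq(21, rng)
    transcripts = {}
    bases = list(_site_for(mirna))
    for i in range(8):
        # transcripts seeded with corrupted sites so some hits exist
        site = bases.copy()
        for pos in rng.choice(21, size=int(rng.integers(0, 4)), replace=False):
            site[pos] = "ACGT"[rng.integers(4)]
        transcripts[f"tx{i}"] = (
            random_seq(50, rng) + "".join(site) + random_seq(50, rng)
        )
    got = [
        (h.transcript_id, h.site_start, h.score)
        for h in scan_transcripts("m", mirna, transcripts, max_score=3.5)
    ]
    assert sorted(got) == brute_force_scan(mirna, transcripts, 3.5)


# --- cleavage summaries -------------------------------------------------------

def _alignment():
    hits = scan_transcripts("m", MIRNA, {"tx": "AAAA" + _site_for(MIRNA) + "AAAA"})
    return hits[0]


def test_all_clones_at_position_ten():
    a = _alignment()
    pos10 = a.site_end - 9
    s = summarize_cleavage(a, [pos10] * 8)
    assert s.fraction_by_offset == {10: 1.0}
    assert s.modal_offset == 10


def test_clone_fractions():
    a = _alignment()
    pos10, pos11 = a.site_end - 9, a.site_end - 10
    s = summarize_cleavage(a, [pos10, pos10, pos10, pos11])
    assert s.fraction_by_offset == {10: 0.75, 11: 0.25}
    assert s.modal_offset == 10


def test_random_clones_match_tally_oracle():
    rng = np.random.default_rng(9)
    a = _alignment()
    positions = [int(a.site_end - rng.integers(5, 15)) for _ in range(40)]
    s = summarize_cleavage(a, positions)
    tally = {}
    for p in positions:
        off = a.site_end - p + 1
        tally[off] = tally.get(off, 0) + 1
    assert s.fraction_by_offset == {k: v / 40 for k, v in sorted(tally.items())}
    assert abs(sum(s.fraction_by_offset.values()) - 1.0) < 1e-12


def test_empty_clone_list_rejected():
    with pytest.raises(ValueError):
        summarize_cleavage(_alignment(), [])


# --- correlation ----------------------------------------------------------------

def test_exact_negative_and_positive_correlation():
    a = [1.0, 0.8, 0.5, 0.6, 1.2, 2.0]
    b = [3.0 - x for x in a]
    r, _ = expression_correlation(a, b)
    assert math.isclose(r, -1.0, abs_tol=1e-12)
    r, _ = expression_correlation(a, a)
    assert math.isclose(r, 1.0, abs_tol=1e-12)


def test_correlation_matches_covariance_formula():
    rng = np.random.default_rng(12)
    a = rng.random(6)
    b = rng.random(6)
    r, _ = expression_correlation(a, b)
    expected = ((a - a.mean()) * (b - b.mean())).sum() / math.sqrt(
        ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
    )
    assert math.isclose(r, expected, abs_tol=1e-12)


def test_zero_variance_is_an_error():
    with pytest.raises(ValueError):
        expression_correlation([1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6])


@settings(deadline=None, derandomize=True)
@given(st.floats(0.1, 10), st.floats(-5, 5))
def test_correlation_affine_invariance(scale, shift):
    a = [1.0, 0.8, 0.5, 0.6, 1.2, 2.0]
    b = [0.9, 1.1, 1.8, 1.6, 0.7, 0.4]
    r0, _ = expression_correlation(a, b)
    r1, _ = expression_correlation([scale * x + shift for x in a], b)
    assert math.isclose(r0, r1, abs_tol=1e-9)
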