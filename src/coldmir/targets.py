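"""Plant miRNA target prediction and cleavage-site summarisation.

Target sites are scored with the classic plant complementarity penalty
scheme: per aligned position a Watson-Crick pair costs 0, a G:U wobble 0.5,
a mismatch 1 and a gap 2, with penalties doubled at miRNA positions 2-13
(the cleavage-critical core).  Sites scoring at or below a cutoff (default
3.0) over the CDS+UTR transcript set are reported, each with the expected
cleavage position opposite miRNA positions 10-11.

Cleavage-site evidence (5'-RACE clone ends) is summarised as the fraction
of clones terminating at each miRNA-relative position; miRNA-guided
cleavage canonically peaks opposite position 10.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from scipy import stats as _scipy_stats

from ._seq import as_dna, is_watson_crick, is_wobble, revcomp

DEFAULT_MAX_SCORE = 3.0
CORE_START = 2  # 1-based miRNA positions with doubled penalties
CORE_END = 13

PENALTY = {"match": 0.0, "GU": 0.5, "mismatch": 1.0, "gap": 2.0}


@dataclass
class TargetAlignment:
    mirna_name: str
    transcript_id: str
    site_start: int  # 1-based transcript coordinates
    site_end: int
    pair_states: List[str]  # per miRNA 5'->3' position
    score: float
    expected_cleavage: int  # transcript position opposite miRNA position 10
    annotation: str = ""


@dataclass
class CleavageSummary:
    target_id: str
    clone_positions: List[int]
    fraction_by_offset: Dict[int, float]
    modal_offset: int


def _pair_state(mirna_base: str, site_base: str) -> str:
    """Pairing state of a miRNA base against the opposite transcript base."""
    if mirna_base == "-" or site_base == "-":
        return "gap"
    # the miRNA pairs the transcript in antiparallel orientation, so a
    # "match" means the site base is the Watson-Crick complement
    if is_watson_crick(mirna_base, site_base):
        return "match"
    if is_wobble(mirna_base, site_base):
        return "GU"
    return "mismatch"


def score_site(mirna_seq: str, site_seq: str) -> Tuple[List[str], float]:
    """Score a miRNA against an aligned target site.

    ``mirna_seq`` is 5'->3'; ``site_seq`` is the transcript site 5'->3'
    (it is reversed internally so position i of the miRNA faces its
    opposite site base).  Both may contain ``-`` gap characters, already
    aligned.  Returns per-miRNA-position pairing states and the penalty
    score (unrounded).
    """
    m = as_dna(mirna_seq.replace("-", "x")).replace("X", "-")
    s = as_dna(site_seq.replace("-", "x")).replace("X", "-")
    if len(m) != len(s):
        raise ValueError("miRNA and site must be aligned to equal length")
    for seq in (m, s):
        if any(b not in "ACGT-" for b in seq):
            raise ValueError(f"non-nucleotide character in {seq!r}")
    s = s[::-1]  # antiparallel
    states: List[str] = []
    score = 0.0
    mir_pos = 0  # 1-based position within the miRNA (gaps don't advance it)
    for mb, sb in zip(m, s):
        state = _pair_state(mb, sb)
        if mb != "-":
            mir_pos += 1
        pos_for_weight = mir_pos if mb != "-" else mir_pos + 1
        weight = 2.0 if CORE_START <= pos_for_weight <= CORE_END else 1.0
        score += PENALTY[state] * weight
        states.append(state)
    return states, score


def scan_transcripts(
    mirna_name: str,
    mirna_seq: str,
    transcripts: Mapping[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
    annotations: Optional[Mapping[str, str]] = None,
) -> List[TargetAlignment]:
    """All ungapped sites with penalty <= ``max_score`` across transcripts.

    Sites are windows the length of the miRNA; the expected cleavage
    position is the transcript base opposite miRNA position 10.
    """
    m = as_dna(mirna_seq)
    L = len(m)
    out: List[TargetAlignment] = []
    for tid, seq in transcripts.items():
        seq = as_dna(seq)
        for start0 in range(0, len(seq) - L + 1):
            window = seq[start0 : start0 + L]
            states, score = score_site(m, window)
            if score <= max_score:
                site_start = start0 + 1
                site_end = start0 + L
                out.append(
                    TargetAlignment(
                        mirna_name=mirna_name,
                        transcript_id=tid,
                        site_start=site_start,
                        site_end=site_end,
                        pair_states=states,
                        score=score,
                        expected_cleavage=site_end - 9,
                        annotation=(annotations or {}).get(tid, ""),
                    )
                )
    out.sort(key=lambda a: (a.score, a.transcript_id, a.site_start))
    return out


def brute_force_scan(
    mirna_seq: str, transcripts: Mapping[str, str], max_score: float
) -> List[Tuple[str, int, float]]:
    """Independent sliding-window rescoring oracle for scan_transcripts.

    Evaluates every window with an explicit per-position penalty loop
    (no shared scoring helper).
    """
    m = as_dna(mirna_seq)
    L = len(m)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    hits = []
    for tid, seq in transcripts.items():
        seq = as_dna(seq)
        for start0 in range(0, len(seq) - L + 1):
            window = seq[start0 : start0 + L][::-1]
            score = 0.0
            for i in range(L):
                pair = (m[i], window[i])
                if pair in wc:
                    pen = 0.0
                elif pair in gu:
                    pen = 0.5
                else:
                    pen = 1.0
                if 2 <= i + 1 <= 13:
                    pen *= 2.0
                score += pen
            if score <= max_score:
                hits.append((tid, start0 + 1, score))
    return sorted(hits)


def summarize_cleavage(
    alignment: TargetAlignment, clone_positions: Sequence[int]
) -> CleavageSummary:
    """Fractions of 5'-RACE clone ends by miRNA-relative position.

    Offsets count from the miRNA 5' end: a clone terminating at the
    transcript base opposite miRNA position 10 has offset 10.
    """
    if not clone_positions:
        raise ValueError("clone position list is empty")
    offsets = [alignment.site_end - pos + 1 for pos in clone_positions]
    counts = Counter(offsets)
    total = sum(counts.values())
    fractions = {off: n / total for off, n in sorted(counts.items())}
    modal = max(fractions, key=lambda off: (fractions[off], -off))
    return CleavageSummary(
        target_id=alignment.transcript_id,
        clone_positions=list(clone_positions),
        fraction_by_offset=fractions,
        modal_offset=modal,
    )


def expression_correlation(
    series_a: Sequence[float], series_b: Sequence[float]
) -> Tuple[float, float]:
    """Pearson r and two-sided t-based p between two expression series."""
    if len(series_a) != len(series_b):
        raise ValueError("series must share the timepoint grid")
    import numpy as np

    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    r, p = _scipy_stats.pearsonr(a, b)
    return float(r), float(p)


def targets_table(alignments: Iterable[TargetAlignment]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "miRNA_name": a.mirna_name,
                "transcript_id": a.transcript_id,
                "site_start": a.site_start,
                "site_end": a.site_end,
                "score": a.score,
                "expected_cleavage": a.expected_cleavage,
                "annotation": a.annotation,
            }
            for a in alignments
        ]
    )
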