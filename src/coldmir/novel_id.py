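"""Novel miRNA prediction from unannotated genome-mapped tags.

Candidate precursor windows are excised around clusters of mapped tags,
folded, the miRNA/miRNA* duplex is located in the fold, and ten
hairpin-precursor criteria (Meyers-style rules) are applied:

 1. mature length 18-25 nt
 2. mature length in the canonical 20-23 nt reference window
 3. at most 20 genomic copies of the mature tag
 4. precursor minimum free energy <= -18 kcal/mol
 5. at most 30 nt between the mature and the star
 6. at least 16 base pairs in the mature/star duplex
 7. largest bulge in the duplex at most 4 nt
 8. duplex asymmetry at most 4 nt
 9. precursor flank length of 20 nt
10. >= 50 reads mapping to the precursor in at least one library

Criteria 1 and 2 both measure the mature sequence length; the narrower
20-23 nt window reflects the canonical size range of plant mature miRNAs
and the wider 18-25 nt window the permissive bound applied during
prediction.  Both are checked and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from ._seq import as_dna, as_rna, revcomp
from .fold import FoldBackend, get_backend, pair_table

DEFAULT_FLANK = 20
DEFAULT_MAX_PRECURSOR = 240


@dataclass
class CriteriaThresholds:
    """Tunable limits of the ten-rule novel-miRNA filter (defaults = study values)."""

    mature_len_min: int = 18
    mature_len_max: int = 25
    ref_len_min: int = 20
    ref_len_max: int = 23
    max_copies: int = 20
    max_mfe: float = -18.0  # kcal/mol
    max_spacing: int = 30
    min_paired: int = 16
    max_bulge: int = 4
    max_asymmetry: int = 4
    flank: int = DEFAULT_FLANK
    min_read_support: int = 50


@dataclass
class DuplexStats:
    paired_bases: int
    bulge_max: int
    asymmetry: int
    spacing: int
    star_start: int  # 0-based, within precursor
    star_end: int  # 0-based inclusive, includes the 2-nt 3' overhang


@dataclass
class HairpinCandidate:
    """An excised genomic window with its fold and located mature/star duplex."""

    locus: str  # chrom:start:end:strand, 1-based inclusive
    precursor_seq: str  # DNA alphabet internally
    structure: str
    mfe: float
    mature_seq: str
    mature_offset: int  # 0-based offset of the mature within the precursor
    star_seq: Optional[str] = None
    duplex: Optional[DuplexStats] = None
    n_genomic_copies: int = 1
    flank: int = DEFAULT_FLANK
    clipped: bool = False
    fail_reason: Optional[str] = None
    read_support: Dict[str, int] = field(default_factory=dict)

    @property
    def mature_rna(self) -> str:
        return as_rna(self.mature_seq)


@dataclass
class CriterionResult:
    passed: bool
    measured: object


@dataclass
class CriteriaReport:
    results: Dict[int, CriterionResult]

    @property
    def overall(self) -> bool:
        return all(r.passed for r in self.results.values())

    def failed(self) -> List[int]:
        return [k for k, r in self.results.items() if not r.passed]


@dataclass
class CandidateWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    seq: str  # window sequence, 5'->3' on `strand`
    mature_offset: int  # 0-based offset of the cluster/mature within seq
    mature_len: int
    arm: str  # '5p' or '3p' hypothesis used to place the window
    clipped: bool = False

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"


def excise_candidates(
    cluster: Tuple[str, int, int, str],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    max_precursor: int = DEFAULT_MAX_PRECURSOR,
) -> List[CandidateWindow]:
    """Two precursor windows around a tag cluster: tag as 5' arm and as 3' arm.

    ``cluster`` is (chrom, start, end, strand) with 1-based inclusive
    coordinates of the mapped tag cluster.  Windows extend the cluster by
    ``flank`` on both sides and by up to ``max_precursor`` total length on
    the side that would hold the opposite arm.  Windows running over the
    chromosome ends are clipped and flagged.
    """
    chrom, start, end, strand = cluster
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    chrom_len = len(genome[chrom])
    tag_len = end - start + 1
    windows: List[CandidateWindow] = []
    # genomic downstream/upstream depends on strand: for '-' the 5' arm lies
    # at higher genomic coordinates.
    for arm in ("5p", "3p"):
        extend_right = (arm == "5p") == (strand == "+")
        if extend_right:
            w_start = start - flank
            w_end = start - flank + max_precursor - 1
            w_end = max(w_end, end + flank)
        else:
            w_end = end + flank
            w_start = end + flank - max_precursor + 1
            w_start = min(w_start, start - flank)
        clipped = w_start < 1 or w_end > chrom_len
        w_start_c = max(1, w_start)
        w_end_c = min(chrom_len, w_end)
        sub = genome[chrom][w_start_c - 1 : w_end_c]
        if strand == "-":
            sub = revcomp(sub)
            mature_offset = w_end_c - end
        else:
            mature_offset = start - w_start_c
        windows.append(
            CandidateWindow(
                chrom=chrom,
                start=w_start_c,
                end=w_end_c,
                strand=strand,
                seq=as_dna(sub),
                mature_offset=mature_offset,
                mature_len=tag_len,
                arm=arm,
                clipped=clipped,
            )
        )
    return windows


def find_duplex(
    structure: str, mature_offset: int, mature_len: int
) -> Tuple[Optional[DuplexStats], Optional[str]]:
    """Locate the miRNA* of a mature placed at ``mature_offset`` in a fold.

    The star is the segment pairing with the mature, extended by the 2-nt
    3' overhang convention.  Returns (stats, None) on success or
    (None, reason) when the duplex is undefined (e.g. the mature spans the
    terminal loop or is unpaired).
    """
    pt = pair_table(structure)
    m_lo, m_hi = mature_offset, mature_offset + mature_len - 1
    if m_lo < 0 or m_hi >= len(structure):
        return None, "mature_outside_precursor"
    partners = [pt[i] for i in range(m_lo, m_hi + 1) if pt[i] >= 0]
    if not partners:
        return None, "mature_unpaired"
    if any(m_lo <= p <= m_hi for p in partners):
        return None, "loop_spanning"
    below = [p for p in partners if p < m_lo]
    above = [p for p in partners if p > m_hi]
    if below and above:
        return None, "loop_spanning"
    p_lo, p_hi = min(partners), max(partners)
    # 2-nt 3' overhang: a segment's 3' end is always its right end in
    # sequence coordinates.
    star_start = p_lo
    star_end = min(p_hi + 2, len(structure) - 1)
    if above:
        spacing = p_lo - m_hi - 1
    else:
        star_end = min(star_end, m_lo - 1)
        spacing = m_lo - star_end - 1
    paired = len(partners)
    star_core_len = p_hi - p_lo + 1
    unpaired_mature = mature_len - paired
    unpaired_star = star_core_len - paired
    asymmetry = abs(unpaired_mature - unpaired_star)

    def longest_unpaired_run(lo: int, hi: int, other_lo: int, other_hi: int) -> int:
        best = run = 0
        for i in range(lo, hi + 1):
            p = pt[i]
            if p < 0 or not (other_lo <= p <= other_hi):
                run += 1
                best = max(best, run)
            else:
                run = 0
        return best

    bulge = max(
        longest_unpaired_run(m_lo, m_hi, p_lo, p_hi),
        longest_unpaired_run(p_lo, p_hi, m_lo, m_hi),
    )
    return (
        DuplexStats(
            paired_bases=paired,
            bulge_max=bulge,
            asymmetry=asymmetry,
            spacing=spacing,
            star_start=star_start,
            star_end=star_end,
        ),
        None,
    )


def evaluate_window(
    window: CandidateWindow,
    backend: FoldBackend,
    n_genomic_copies: int = 1,
    read_support: Optional[Dict[str, int]] = None,
    flank: int = DEFAULT_FLANK,
) -> HairpinCandidate:
    """Fold a candidate window and populate duplex statistics."""
    structure, mfe = backend(window.seq)
    cand = HairpinCandidate(
        locus=window.locus,
        precursor_seq=window.seq,
        structure=structure,
        mfe=mfe,
        mature_seq=window.seq[
            window.mature_offset : window.mature_offset + window.mature_len
        ],
        mature_offset=window.mature_offset,
        n_genomic_copies=n_genomic_copies,
        flank=flank,
        clipped=window.clipped,
        read_support=dict(read_support or {}),
    )
    stats, reason = find_duplex(structure, window.mature_offset, window.mature_len)
    cand.duplex = stats
    cand.fail_reason = reason
    if stats is not None:
        cand.star_seq = window.seq[stats.star_start : stats.star_end + 1]
    return cand


def check_criteria(
    candidate: HairpinCandidate,
    read_support: Optional[Mapping[str, int]] = None,
    thresholds: Optional[CriteriaThresholds] = None,
    skip_support: bool = False,
) -> CriteriaReport:
    """Apply the ten hairpin criteria to a fully populated candidate.

    ``read_support`` overrides the candidate's own per-library precursor
    read counts; ``skip_support`` evaluates only the structural rules
    (criterion 10 recorded as passed with measured value None), which is
    how planted loci are validated before reads exist.
    """
    t = thresholds or CriteriaThresholds()
    support = dict(read_support) if read_support is not None else candidate.read_support
    m_len = len(candidate.mature_seq)
    d = candidate.duplex
    results: Dict[int, CriterionResult] = {
        1: CriterionResult(t.mature_len_min <= m_len <= t.mature_len_max, m_len),
        2: CriterionResult(t.ref_len_min <= m_len <= t.ref_len_max, m_len),
        3: CriterionResult(
            candidate.n_genomic_copies <= t.max_copies, candidate.n_genomic_copies
        ),
        4: CriterionResult(candidate.mfe <= t.max_mfe, candidate.mfe),
        5: CriterionResult(d is not None and d.spacing <= t.max_spacing,
                           d.spacing if d else None),
        6: CriterionResult(d is not None and d.paired_bases >= t.min_paired,
                           d.paired_bases if d else None),
        7: CriterionResult(d is not None and d.bulge_max <= t.max_bulge,
                           d.bulge_max if d else None),
        8: CriterionResult(d is not None and d.asymmetry <= t.max_asymmetry,
                           d.asymmetry if d else None),
        9: CriterionResult(candidate.flank == t.flank, candidate.flank),
    }
    if skip_support:
        results[10] = CriterionResult(True, None)
    else:
        best = max(support.values()) if support else 0
        results[10] = CriterionResult(best >= t.min_read_support, best)
    return CriteriaReport(results)


def trim_window(window: CandidateWindow, cand: HairpinCandidate,
                flank: int = DEFAULT_FLANK) -> CandidateWindow:
    """Shrink a candidate window to its located hairpin extent plus flanks.

    The initial excision windows are generous (up to the maximum precursor
    length); once the duplex is located, the reported precursor is the
    mature-to-star span extended by the flank, which keeps neighbouring
    loci from sharing coordinates.
    """
    d = cand.duplex
    if d is None:
        return window
    m_lo = cand.mature_offset
    m_hi = m_lo + len(cand.mature_seq) - 1
    lo = max(0, min(m_lo, d.star_start) - flank)
    hi = min(len(window.seq) - 1, max(m_hi, d.star_end) + flank)
    if window.strand == "+":
        new_start = window.start + lo
        new_end = window.start + hi
    else:
        new_start = window.end - hi
        new_end = window.end - lo
    return CandidateWindow(
        chrom=window.chrom,
        start=new_start,
        end=new_end,
        strand=window.strand,
        seq=window.seq[lo : hi + 1],
        mature_offset=m_lo - lo,
        mature_len=window.mature_len,
        arm=window.arm,
        clipped=window.clipped,
    )


def evaluate_cluster(
    cluster: Tuple[str, int, int, str],
    genome: Mapping[str, str],
    backend: FoldBackend,
    thresholds: Optional[CriteriaThresholds] = None,
    max_precursor: int = DEFAULT_MAX_PRECURSOR,
    n_genomic_copies: int = 1,
    read_support: Optional[Dict[str, int]] = None,
    skip_support: bool = False,
) -> List[Tuple[HairpinCandidate, CriteriaReport]]:
    """Excise, fold, trim and criteria-check both arm hypotheses of a cluster.

    Returns the accepted (candidate, report) pairs; this is the single code
    path shared by discovery and by the synthetic-data generator's planted
    hairpin validation.
    """
    t = thresholds or CriteriaThresholds()
    accepted = []
    for window in excise_candidates(cluster, genome, flank=t.flank,
                                    max_precursor=max_precursor):
        cand = evaluate_window(window, backend, n_genomic_copies=n_genomic_copies,
                               read_support=read_support, flank=t.flank)
        if cand.duplex is None:
            continue
        trimmed = trim_window(window, cand, flank=t.flank)
        if len(trimmed.seq) < len(window.seq):
            cand = evaluate_window(trimmed, backend,
                                   n_genomic_copies=n_genomic_copies,
                                   read_support=read_support, flank=t.flank)
            if cand.duplex is None:
                continue
        report = check_criteria(cand, thresholds=t, skip_support=skip_support)
        if report.overall:
            accepted.append((cand, report))
    return accepted


def _cluster_hits(
    hits: Iterable[Tuple[str, int, int, str]], gap: int = 3
) -> List[Tuple[str, int, int, str]]:
    """Merge mapped-tag intervals on the same chrom/strand within ``gap`` nt."""
    by_key: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for chrom, start, end, strand in hits:
        by_key.setdefault((chrom, strand), []).append((start, end))
    clusters = []
    for (chrom, strand), ivs in by_key.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                clusters.append((chrom, cur_s, cur_e, strand))
                cur_s, cur_e = s, e
        clusters.append((chrom, cur_s, cur_e, strand))
    return sorted(clusters)


def _overlap(a: HairpinCandidate, b: HairpinCandidate) -> bool:
    ca, sa, ea, ta = a.locus.rsplit(":", 3)
    cb, sb, eb, tb = b.locus.rsplit(":", 3)
    return ca == cb and ta == tb and int(sa) <= int(eb) and int(sb) <= int(ea)


def dedupe_candidates(cands: Sequence[HairpinCandidate]) -> List[HairpinCandidate]:
    """Merge overlapping same-strand candidates and candidates sharing a
    mature sequence; the kept candidate is the one whose mature tag has the
    highest read support (ties broken by lower MFE), so isomiR variants
    never shadow the dominant mature."""
    kept: List[HairpinCandidate] = []
    for cand in sorted(
        cands,
        key=lambda c: (-max(c.read_support.values() or [0]), c.mfe, c.locus),
    ):
        if not any(
            _overlap(cand, k) or k.mature_seq == cand.mature_seq for k in kept
        ):
            kept.append(cand)
    return sorted(kept, key=lambda c: c.locus)


def discover_novel(
    tag_hits: Mapping[str, List[Tuple[str, int, int, str]]],
    tag_counts: Mapping[str, Mapping[str, int]],
    genome: Mapping[str, str],
    backend: Optional[FoldBackend] = None,
    thresholds: Optional[CriteriaThresholds] = None,
    max_precursor: int = DEFAULT_MAX_PRECURSOR,
) -> List[Tuple[HairpinCandidate, CriteriaReport]]:
    """End-to-end novel-miRNA discovery over unannotated mapped tags.

    ``tag_hits`` maps tag sequence -> genome hits (chrom, start, end, strand);
    ``tag_counts`` maps tag sequence -> per-library read counts.  Tags
    exceeding the genomic copy cap are dropped up front (criterion 3).
    Returns accepted (candidate, report) pairs after deduplication.
    """
    backend = backend or get_backend("auto")
    t = thresholds or CriteriaThresholds()
    accepted: List[Tuple[HairpinCandidate, CriteriaReport]] = []
    for tag, hits in sorted(tag_hits.items()):
        if not hits or len(hits) > t.max_copies:
            continue
        support = {
            lib: int(n) for lib, n in (tag_counts.get(tag) or {}).items()
        }
        for cluster in _cluster_hits(hits):
            accepted.extend(
                evaluate_cluster(
                    cluster,
                    genome,
                    backend,
                    thresholds=t,
                    max_precursor=max_precursor,
                    n_genomic_copies=len(hits),
                    read_support=support,
                )
            )
    # dedupe on candidate loci, lowest MFE wins
    winners = dedupe_candidates([c for c, _ in accepted])
    winner_ids = {id(c) for c in winners}
    return [(c, r) for c, r in accepted if id(c) in winner_ids]
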