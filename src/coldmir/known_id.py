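"""Known-miRNA identification against a mature reference.

A tag is accepted as a known miRNA when it matches a reference mature
sequence with at most two mismatches under an ungapped alignment; the tag
may overhang or truncate the mature by up to two bases at either end (end
offsets are capped but not counted as mismatches).  Exact matches are
flagged as the annotated mature; everything else is an isomiR-style variant
listed separately and excluded from differential-expression input.

Family totals aggregate read counts over member matures; a tag tied between
several matures at the same mismatch count contributes to each tied mature
(rows marked shared) but is counted once per family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._seq import as_dna, as_rna
from .tagproc import SmallRNATag

MAX_MISMATCHES = 2
MAX_END_OFFSET = 2

_FAMILY_RE = re.compile(r"(miR[A-Za-z]?\d+)", re.IGNORECASE)


def parse_family(mature_name: str) -> str:
    """Family label from a mature name (vvi-miR156b -> miR156)."""
    m = _FAMILY_RE.search(mature_name)
    return m.group(1) if m else mature_name


@dataclass
class KnownMiRNAHit:
    tag_sequence: str
    mature_name: str
    family: str
    n_mismatches: int
    is_annotated_mature: bool


@dataclass
class FamilyCountRow:
    family: str
    n_members: int
    reads_NCT: int
    reads_CT: int


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def match_known(
    tag: str,
    matures: Mapping[str, str],
    max_mm: int = MAX_MISMATCHES,
    max_end_offset: int = MAX_END_OFFSET,
) -> List[KnownMiRNAHit]:
    """All reference matures within ``max_mm`` of the tag (ungapped).

    The tag start may be offset from the mature start by up to
    ``max_end_offset`` either way, and likewise at the 3' end; mismatches
    are counted over the overlapping core only.  Per mature, the alignment
    minimising mismatches is kept.
    """
    tag = as_dna(tag)
    hits: List[KnownMiRNAHit] = []
    for name, mature in matures.items():
        mature = as_dna(mature)
        best: Optional[int] = None
        for shift in range(-max_end_offset, max_end_offset + 1):
            # shift = position of tag start relative to mature start
            end_offset = abs(shift + len(tag) - len(mature))
            if end_offset > max_end_offset:
                continue
            lo = max(0, shift)
            hi = min(len(mature), shift + len(tag))
            if hi - lo < len(mature) - max_end_offset - max_end_offset:
                continue
            mm = _hamming(tag[lo - shift : hi - shift], mature[lo:hi])
            if mm <= max_mm and (best is None or mm < best):
                best = mm
        if best is not None:
            hits.append(
                KnownMiRNAHit(
                    tag_sequence=tag,
                    mature_name=name,
                    family=parse_family(name),
                    n_mismatches=best,
                    is_annotated_mature=(tag == mature),
                )
            )
    hits.sort(key=lambda h: (h.n_mismatches, h.mature_name))
    return hits


def brute_force_match(
    tag: str,
    matures: Mapping[str, str],
    max_mm: int = MAX_MISMATCHES,
    max_end_offset: int = MAX_END_OFFSET,
) -> List[Tuple[str, int]]:
    """Exhaustive re-computation of match_known (independent oracle).

    Enumerates every ungapped placement explicitly and re-counts mismatches
    position by position.
    """
    tag = as_dna(tag)
    out = []
    for name, mature in matures.items():
        mature = as_dna(mature)
        candidates = []
        for shift in range(-max_end_offset, max_end_offset + 1):
            if abs((shift + len(tag)) - len(mature)) > max_end_offset:
                continue
            mm = 0
            for i, base in enumerate(tag):
                j = shift + i
                if 0 <= j < len(mature) and mature[j] != base:
                    mm += 1
            candidates.append(mm)
        if candidates and min(candidates) <= max_mm:
            out.append((name, min(candidates)))
    return sorted(out)


def resolve_hits(hits: Sequence[KnownMiRNAHit]) -> List[KnownMiRNAHit]:
    """Tie-break one tag's hits: keep only minimum-mismatch hits (shared if >1)."""
    if not hits:
        return []
    best = min(h.n_mismatches for h in hits)
    return [h for h in hits if h.n_mismatches == best]


def match_tags(
    tags: Iterable[SmallRNATag],
    matures: Mapping[str, str],
    max_mm: int = MAX_MISMATCHES,
) -> Dict[str, List[KnownMiRNAHit]]:
    """Resolved known-miRNA hits per tag sequence."""
    out: Dict[str, List[KnownMiRNAHit]] = {}
    for tag in tags:
        resolved = resolve_hits(match_known(tag.sequence, matures, max_mm=max_mm))
        if resolved:
            out[tag.sequence] = resolved
    return out


def mature_counts(
    hits_by_tag: Mapping[str, List[KnownMiRNAHit]],
    tags: Iterable[SmallRNATag],
    libraries: Sequence[str],
    annotated_only: bool = True,
) -> pd.DataFrame:
    """Per-mature read counts (annotated mature sequence only by default).

    Only the exact annotated mature contributes to downstream
    differential-expression input; isomiR variants are bookkept via
    ``variant_table``.  Shared rows (one tag tied between matures) add the
    tag's counts to each tied mature.
    """
    tag_map = {t.sequence: t for t in tags}
    rows: Dict[str, Dict[str, object]] = {}
    for seq, hits in hits_by_tag.items():
        tag = tag_map.get(seq)
        if tag is None:
            continue
        for h in hits:
            if annotated_only and not h.is_annotated_mature:
                continue
            row = rows.setdefault(
                h.mature_name,
                {
                    "mature_name": h.mature_name,
                    "family": h.family,
                    "shared": len(hits) > 1,
                    **{lib: 0 for lib in libraries},
                },
            )
            for lib in libraries:
                row[lib] = int(row[lib]) + tag.count(lib)
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: str(r["mature_name"])),
        columns=["mature_name", "family", "shared", *libraries],
    )
    return df


def variant_table(
    hits_by_tag: Mapping[str, List[KnownMiRNAHit]],
    tags: Iterable[SmallRNATag],
    libraries: Sequence[str],
) -> pd.DataFrame:
    """IsomiR-style variants (non-annotated matches), listed but not analysed."""
    tag_map = {t.sequence: t for t in tags}
    rows = []
    for seq, hits in hits_by_tag.items():
        tag = tag_map.get(seq)
        for h in hits:
            if h.is_annotated_mature or tag is None:
                continue
            rows.append(
                {
                    "tag_sequence": as_rna(seq),
                    "mature_name": h.mature_name,
                    "n_mismatches": h.n_mismatches,
                    **{lib: tag.count(lib) for lib in libraries},
                }
            )
    return pd.DataFrame(
        rows, columns=["tag_sequence", "mature_name", "n_mismatches", *libraries]
    )


def aggregate_families(
    hits_by_tag: Mapping[str, List[KnownMiRNAHit]],
    tags: Iterable[SmallRNATag],
    libraries: Sequence[str] = ("NCT", "CT"),
) -> List[FamilyCountRow]:
    """Family-level read totals; each tag is counted once per family.

    A tag tied between matures of different families is assigned to the
    family with the most tied matures (alphabetical tie-break) so family
    totals never exceed total tag counts.
    """
    tag_map = {t.sequence: t for t in tags}
    totals: Dict[str, Dict[str, int]] = {}
    members: Dict[str, set] = {}
    for seq, hits in hits_by_tag.items():
        tag = tag_map.get(seq)
        if tag is None or not hits:
            continue
        fams = sorted({h.family for h in hits})
        for h in hits:
            members.setdefault(h.family, set()).add(h.mature_name)
        # a cross-family tie goes to the family with most tied matures
        fam = sorted(fams, key=lambda f: (-sum(h.family == f for h in hits), f))[0]
        bucket = totals.setdefault(fam, {lib: 0 for lib in libraries})
        for lib in libraries:
            bucket[lib] += tag.count(lib)
    rows = [
        FamilyCountRow(
            family=fam,
            n_members=len(members.get(fam, set())),
            reads_NCT=counts.get("NCT", 0),
            reads_CT=counts.get("CT", 0),
        )
        for fam, counts in totals.items()
    ]
    rows.sort(key=lambda r: r.family)
    return rows


def load_mature_reference(path: str) -> Dict[str, str]:
    """Mature sequences from a reference FASTA (precursor entries skipped)."""
    from Bio import SeqIO

    matures = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id.endswith("-precursor") or "MIR" in rec.id:
            continue
        matures[rec.id] = as_dna(str(rec.seq))
    return matures
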