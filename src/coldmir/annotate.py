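"""Exact genome mapping and category triage of unique tags.

Tags are mapped to the genome with zero mismatches on both strands and
triaged into ncRNA / genic / miRNA-candidate / unannotated categories.
ncRNA matching is exact substring containment against the reference sets
(the deterministic reading of "exact matches"), and categories are assigned
by a fixed priority, ncRNA first, so a tag gets exactly one category:

    rRNA > tRNA > snRNA > snoRNA > scRNA > miRNA_candidate > repeat >
    exon_sense > exon_antisense > intron_sense > intron_antisense > unannotated

Tags mapping to more genomic loci than the copy cap (default 20) are flagged
repeat-like and barred from miRNA candidacy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._seq import as_dna, revcomp

SEED_LEN = 18
DEFAULT_MAX_COPIES = 20

NCRNA_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA")
CATEGORIES = (
    *NCRNA_PRIORITY,
    "miRNA_candidate",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unannotated",
)


@dataclass
class GenomeHit:
    tag_sequence: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    n_genomic_copies: int = 1

    def as_tuple(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class CategoryAssignment:
    tag_sequence: str
    category: str


class GenomeIndex:
    """Exact-match lookup of 18-30 nt tags over both genome strands.

    Seeds the first ``SEED_LEN`` bases of every plus-strand position in a
    hash map and verifies full-length matches; minus-strand hits are found
    by querying the reverse complement.  Coordinates are 1-based inclusive
    on the plus strand.
    """

    def __init__(self, genome: Mapping[str, str]):
        names = list(genome)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome")
        self.genome: Dict[str, str] = {c: as_dna(s) for c, s in genome.items()}
        self._seeds: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - SEED_LEN + 1):
                self._seeds.setdefault(seq[i : i + SEED_LEN], []).append((chrom, i))

    def _scan(self, query: str) -> List[Tuple[str, int]]:
        hits = []
        for chrom, pos0 in self._seeds.get(query[:SEED_LEN], []):
            if self.genome[chrom].startswith(query, pos0):
                hits.append((chrom, pos0))
        return hits

    def lookup(self, tag: str) -> List[GenomeHit]:
        """All exact occurrences of ``tag`` on either strand."""
        tag = as_dna(tag)
        if len(tag) < SEED_LEN or "N" in tag:
            return []
        found: List[GenomeHit] = []
        for chrom, pos0 in self._scan(tag):
            found.append(GenomeHit(tag, chrom, pos0 + 1, pos0 + len(tag), "+"))
        rc = revcomp(tag)
        for chrom, pos0 in self._scan(rc):
            found.append(GenomeHit(tag, chrom, pos0 + 1, pos0 + len(tag), "-"))
        for h in found:
            h.n_genomic_copies = len(found)
        return sorted(found, key=lambda h: (h.chrom, h.start, h.strand))


def naive_scan(genome: Mapping[str, str], tag: str) -> List[Tuple[str, int, int, str]]:
    """Brute-force full-scan exact search (independent oracle for the index)."""
    tag = as_dna(tag)
    out = []
    if "N" in tag:
        return out
    for chrom, seq in genome.items():
        seq = as_dna(seq)
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            pos = seq.find(query)
            while pos >= 0:
                out.append((chrom, pos + 1, pos + len(tag), strand))
                pos = seq.find(query, pos + 1)
    return sorted(out)


@dataclass
class Feature:
    chrom: str
    start: int
    end: int
    strand: str
    ftype: str  # exon | intron | repeat


_REPEAT_TYPES = {"repeat", "repeat_region", "transposable_element"}


def load_features(gff3_path: str) -> List[Feature]:
    """Exon/intron/repeat features from a GFF3 file (other types ignored)."""
    import pyranges as pr

    df = pr.read_gff3(gff3_path).df
    feats = []
    for row in df.itertuples():
        ftype = str(row.Feature).lower()
        if ftype in _REPEAT_TYPES:
            ftype = "repeat"
        elif ftype not in {"exon", "intron"}:
            continue
        feats.append(
            Feature(
                chrom=str(row.Chromosome),
                start=int(row.Start) + 1,  # pyranges is 0-based half-open
                end=int(row.End),
                strand=str(row.Strand),
                ftype=ftype,
            )
        )
    return feats


def _matches_ncrna(tag: str, refs: Iterable[str]) -> bool:
    for ref in refs:
        ref = as_dna(ref)
        if tag in ref or tag in revcomp(ref):
            return True
    return False


def classify(
    tag: str,
    hits: Sequence[GenomeHit],
    ncrna_sets: Mapping[str, Iterable[str]],
    features: Optional[Sequence[Feature]] = None,
    is_known_mirna: Optional[Callable[[str], bool]] = None,
    max_copies: int = DEFAULT_MAX_COPIES,
) -> CategoryAssignment:
    """Assign exactly one category to a tag by the fixed priority order."""
    tag = as_dna(tag)
    for cat in NCRNA_PRIORITY:
        if cat in ncrna_sets and _matches_ncrna(tag, ncrna_sets[cat]):
            return CategoryAssignment(tag, cat)
    if is_known_mirna is not None and is_known_mirna(tag):
        return CategoryAssignment(tag, "miRNA_candidate")
    if not hits:
        return CategoryAssignment(tag, "unannotated")
    if len(hits) > max_copies:
        return CategoryAssignment(tag, "repeat")
    if features:
        found = set()
        for h in hits:
            for f in features:
                if f.chrom == h.chrom and f.start <= h.end and h.start <= f.end:
                    if f.ftype == "repeat":
                        found.add("repeat")
                    else:
                        sense = "sense" if f.strand == h.strand else "antisense"
                        found.add(f"{f.ftype}_{sense}")
        for cat in ("repeat", "exon_sense", "exon_antisense",
                    "intron_sense", "intron_antisense"):
            if cat in found:
                return CategoryAssignment(tag, cat)
    return CategoryAssignment(tag, "unannotated")


def classify_tags(
    tags: Sequence[str],
    index: GenomeIndex,
    ncrna_sets: Mapping[str, Iterable[str]],
    features: Optional[Sequence[Feature]] = None,
    is_known_mirna: Optional[Callable[[str], bool]] = None,
    max_copies: int = DEFAULT_MAX_COPIES,
) -> Tuple[Dict[str, CategoryAssignment], Dict[str, List[GenomeHit]]]:
    """Map and classify a batch of tags; returns (assignments, hits per tag)."""
    assignments: Dict[str, CategoryAssignment] = {}
    all_hits: Dict[str, List[GenomeHit]] = {}
    for tag in tags:
        tag = as_dna(tag)
        hits = index.lookup(tag)
        all_hits[tag] = hits
        assignments[tag] = classify(
            tag, hits, ncrna_sets, features, is_known_mirna, max_copies
        )
    return assignments, all_hits


def category_summary(assignments: Mapping[str, CategoryAssignment]) -> pd.DataFrame:
    """Unique-tag counts per category (partition of the input tags)."""
    counts = {cat: 0 for cat in CATEGORIES}
    for a in assignments.values():
        counts[a.category] += 1
    df = pd.DataFrame(
        [{"category": c, "unique_tags": n} for c, n in counts.items()]
    )
    return df


def load_ncrna_fasta(path: str) -> Dict[str, List[str]]:
    """Category FASTA (``>id category`` headers) -> per-category sequence sets."""
    from Bio import SeqIO

    sets: Dict[str, List[str]] = {}
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.description.split()
        cat = parts[1] if len(parts) > 1 else "rRNA"
        sets.setdefault(cat, []).append(as_dna(str(rec.seq)))
    return sets
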