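"""Raw-read cleaning and collapsing to unique small-RNA tags.

Cleaning trims the 3' adapter, drops reads containing N or with mean Phred
quality below a cutoff, and keeps only inserts of 18-30 nt.  "Low quality"
is pinned to mean Phred < 20 or any N call (configurable); the adapter is
found by exact leftmost match of its first 6 nt, and untrimmed reads within
the length window are kept since they may be full-length inserts.

Collapsing maps each library's cleaned reads to unique tags with per-library
counts; counts are conserved (sum of tag counts = clean reads) and the
result is independent of input order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple, Union

import pandas as pd

from ._seq import as_dna

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30
DEFAULT_QUAL_THRESHOLD = 20
ADAPTER_SEED_LEN = 6


@dataclass
class SmallRNATag:
    """A unique 18-30 nt sequence with per-library read counts."""

    sequence: str
    count_by_library: Dict[str, int] = field(default_factory=dict)
    annotations: List[str] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.count_by_library.values())

    def count(self, library: str) -> int:
        return self.count_by_library.get(library, 0)


@dataclass
class DiscardTally:
    """Partition of removed reads by (first failing) reason."""

    contains_n: int = 0
    low_quality: int = 0
    too_short: int = 0
    too_long: int = 0
    adapter_trimmed: int = 0  # bookkeeping stat, not a removal reason

    @property
    def total_discarded(self) -> int:
        return self.contains_n + self.low_quality + self.too_short + self.too_long


@dataclass
class LibrarySummary:
    library_name: str
    raw_reads: int
    clean_reads: int
    unique_tags: int
    length_histogram: Dict[int, Tuple[int, int]]  # length -> (unique, total)

    def validate(self) -> None:
        if self.clean_reads > self.raw_reads:
            raise ValueError("clean_reads exceeds raw_reads")
        if sum(u for u, _ in self.length_histogram.values()) != self.unique_tags:
            raise ValueError("histogram unique counts do not sum to unique_tags")
        if sum(t for _, t in self.length_histogram.values()) != self.clean_reads:
            raise ValueError("histogram totals do not sum to clean_reads")


ReadSource = Union[str, Iterable[Tuple[str, str, str]]]


def _iter_reads(source: ReadSource) -> Iterator[Tuple[str, str, str]]:
    """Yield (name, seq, qual) from a FASTQ path or an in-memory iterable."""
    if isinstance(source, str):
        import pysam

        with pysam.FastxFile(source) as fh:
            for i, rec in enumerate(fh):
                if rec.sequence is None or rec.quality is None:
                    raise ValueError(f"malformed FASTQ record at index {i}")
                yield rec.name, rec.sequence, rec.quality
    else:
        for i, rec in enumerate(source):
            if len(rec) != 3 or rec[1] is None or rec[2] is None:
                raise ValueError(f"malformed read record at index {i}")
            yield rec


def clean_reads(
    source: ReadSource,
    adapter_3p: str,
    qual_threshold: int = DEFAULT_QUAL_THRESHOLD,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> Tuple[List[str], DiscardTally]:
    """Adapter-trim, quality-filter and length-filter a read stream.

    Returns (clean insert sequences, discard tally).  Mean quality is
    evaluated over the retained insert.  Reasons are assessed in a fixed
    order: N content, quality, then post-trim length.
    """
    if not adapter_3p:
        raise ValueError("adapter_3p must be non-empty")
    seed = as_dna(adapter_3p)[:ADAPTER_SEED_LEN]
    tally = DiscardTally()
    clean: List[str] = []
    qmean_cache: Dict[str, float] = {}  # constant-quality runs dominate
    for _, seq, qual in _iter_reads(source):
        seq = as_dna(seq)
        pos = seq.find(seed)
        if pos >= 0:
            insert, q = seq[:pos], qual[:pos]
            tally.adapter_trimmed += 1
        else:
            insert, q = seq, qual
        if "N" in insert:
            tally.contains_n += 1
            continue
        if len(insert) == 0:
            tally.low_quality += 1
            continue
        qmean = qmean_cache.get(q)
        if qmean is None:
            qmean = sum(map(ord, q)) / len(q) - 33
            if len(qmean_cache) < 4096:
                qmean_cache[q] = qmean
        if qmean < qual_threshold:
            tally.low_quality += 1
            continue
        if len(insert) < min_len:
            tally.too_short += 1
            continue
        if len(insert) > max_len:
            tally.too_long += 1
            continue
        clean.append(insert)
    return clean, tally


def collapse(reads_by_library: Mapping[str, Iterable[str]]) -> List[SmallRNATag]:
    """Collapse cleaned reads to unique tags with per-library counts.

    Tags are returned sorted by descending total count, then sequence, so
    the output is independent of input order.
    """
    counters = {lib: Counter(map(as_dna, reads)) for lib, reads in reads_by_library.items()}
    sequences = set()
    for c in counters.values():
        sequences.update(c)
    tags = [
        SmallRNATag(
            sequence=seq,
            count_by_library={
                lib: c[seq] for lib, c in counters.items() if c[seq] > 0
            },
        )
        for seq in sequences
    ]
    tags.sort(key=lambda t: (-t.total_count, t.sequence))
    return tags


def tags_to_frame(tags: Iterable[SmallRNATag], libraries: Iterable[str]) -> pd.DataFrame:
    libs = list(libraries)
    rows = [
        {"sequence": t.sequence, **{lib: t.count(lib) for lib in libs}} for t in tags
    ]
    return pd.DataFrame(rows, columns=["sequence", *libs])


def summarize_library(
    library_name: str,
    raw_reads: int,
    clean: List[str],
    tags: Optional[List[SmallRNATag]] = None,
) -> LibrarySummary:
    """Per-library summary with the unique/total length histogram."""
    if tags is None:
        tags = collapse({library_name: clean})
    hist: Dict[int, Tuple[int, int]] = {}
    for t in tags:
        n = t.count(library_name)
        if n == 0:
            continue
        u, tot = hist.get(len(t.sequence), (0, 0))
        hist[len(t.sequence)] = (u + 1, tot + n)
    summary = LibrarySummary(
        library_name=library_name,
        raw_reads=raw_reads,
        clean_reads=len(clean),
        unique_tags=sum(u for u, _ in hist.values()),
        length_histogram=dict(sorted(hist.items())),
    )
    summary.validate()
    return summary


def write_collapsed_fasta(tags: Iterable[SmallRNATag], path: str) -> None:
    """Collapsed-tag FASTA with ``>tag<serial>_x<count>`` headers."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{t.total_count}\n{t.sequence}\n")


def write_tag_table(
    tags: Iterable[SmallRNATag], libraries: Iterable[str], path: str
) -> None:
    tags_to_frame(tags, libraries).to_csv(path, sep="\t", index=False)
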