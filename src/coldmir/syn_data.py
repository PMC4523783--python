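"""Synthetic genome, planted miRNA loci, and two-library read simulation.

Emulates the inputs of a two-library (control vs cold-treated) small-RNA
sequencing experiment: a toy genome carrying planted known-family miRNA
hairpins, novel miRNA hairpins, and ncRNA contaminant loci, plus simulated
18-30 nt reads whose per-locus counts are Poisson around planted abundances.
Every planted novel hairpin is validated against the full ten-criterion
hairpin filter (via the same code path the discovery module uses) before the
genome is accepted, so planted loci are positive controls by construction.

Read lengths are bimodal: miRNA-derived reads sit at ~21 nt and ncRNA
fragment reads are drawn with a mode at 24 nt, mirroring the two size
classes typical of plant small-RNA libraries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._seq import as_dna, as_rna, random_seq, revcomp
from .fold import FoldBackend, get_backend
from .novel_id import DEFAULT_MAX_PRECURSOR, CriteriaThresholds, evaluate_cluster

LIBRARIES = ("NCT", "CT")

# TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"

NCRNA_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")
_NCRNA_LENGTHS = {"rRNA": 220, "tRNA": 76, "snRNA": 110, "snoRNA": 90, "repeat": 160}

_SLOT = 70  # reserved genome bases per hairpin locus (max hairpin is 61 nt)
_MIN_GAP = 80  # minimum background between planted loci (> flank + tag length)


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the toy genome; the seed fully determines the output."""

    genome_length: int = 120_000
    n_chromosomes: int = 3
    n_known_loci: int = 12
    n_novel_loci: int = 6
    n_ncrna_loci: int = 10
    gc_fraction: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.n_chromosomes < 1 or self.genome_length < self.n_chromosomes:
            raise ValueError("need at least one chromosome of positive length")


@dataclass
class LengthNoise:
    """Truncated-geometric distribution over 5'/3' isomiR end offsets."""

    p: float = 0.1  # probability mass escaping offset 0
    max_offset: int = 2

    def probs(self) -> np.ndarray:
        w = np.array([1.0 - self.p] + [self.p * 0.5 ** k for k in range(self.max_offset)])
        return w / w.sum()


@dataclass
class ReadSimulationParams:
    total_reads_per_library: Optional[int] = 200_000
    adapter_3p: str = DEFAULT_ADAPTER_3P
    length_noise: LengthNoise = field(default_factory=LengthNoise)
    sequencing_error_rate: float = 0.001
    contaminant_fraction: float = 0.3
    seed: int = 0
    read_length: int = 36

    def validate(self) -> None:
        for p in (self.sequencing_error_rate, self.contaminant_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.adapter_3p:
            raise ValueError("adapter_3p must be non-empty")


@dataclass
class PlantedLocus:
    locus_id: str
    category: str  # known_miRNA | novel_miRNA | rRNA | tRNA | snRNA | snoRNA | repeat
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    mature_seq: str  # DNA alphabet; '' for ncRNA loci
    star_seq: str
    abundance_NCT: float
    abundance_CT: float
    mature_offset: int = 0  # 0-based offset of the mature within the locus (5'->3')
    family: str = ""

    @property
    def location(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"

    def sequence(self, genome: Mapping[str, str]) -> str:
        """Locus sequence 5'->3' on its own strand."""
        sub = genome[self.chrom][self.start - 1 : self.end]
        return revcomp(sub) if self.strand == "-" else sub

    def mature_genomic(self) -> Tuple[str, int, int, str]:
        """Genomic coordinates (1-based inclusive) of the mature sequence."""
        m, L = self.mature_offset, len(self.mature_seq)
        if self.strand == "+":
            return (self.chrom, self.start + m, self.start + m + L - 1, self.strand)
        return (self.chrom, self.end - m - L + 1, self.end - m, self.strand)

    def abundance(self, library: str) -> float:
        try:
            return {"NCT": self.abundance_NCT, "CT": self.abundance_CT}[library]
        except KeyError:
            raise KeyError(f"no abundance column for library {library!r}") from None


class GenomePackingError(ValueError):
    """Planted loci exceed a chromosome's capacity."""


def _draw_hairpin(
    mature: str, rng: np.random.Generator, gc: float
) -> Tuple[str, int, str]:
    """Random hairpin around ``mature``: (hairpin_seq, mature_offset, star_seq)."""
    loop = random_seq(int(rng.integers(8, 16)), rng, gc)
    star = list(revcomp(mature))
    # at least one mismatch: a perfect duplex would let the mature tag
    # exact-map onto its own star arm (two genomic copies)
    n_mut = int(rng.integers(1, 5))
    for pos in rng.choice(len(star), size=n_mut, replace=False):
        star[pos] = rng.choice([b for b in "ACGT" if b != star[pos]])
    star_s = "".join(star)
    if rng.random() < 0.5:  # mature on the 5' arm
        return mature + loop + star_s, 0, star_s
    return star_s + loop + mature, len(star_s) + len(loop), star_s


def _plant(
    chrom_arr: np.ndarray, pos0: int, seq: str
) -> None:  # pos0 is 0-based
    chrom_arr[pos0 : pos0 + len(seq)] = list(seq)


def build_genome(
    spec: SyntheticGenomeSpec,
    backend: Optional[FoldBackend] = None,
    dem_fraction: float = 0.25,
    dem_fold: float = 4.0,
    n_exclusive_novel: int = 2,
    mean_abundance: float = 800.0,
    max_retries: int = 60,
) -> Tuple[Dict[str, str], List[PlantedLocus]]:
    """Build the toy genome and its ground-truth locus table.

    Known and novel miRNA hairpins are planted and re-drawn (bounded retries)
    until the excised, folded candidate passes all structural hairpin
    criteria with the given backend.  Abundances: ~``dem_fraction`` of miRNA
    loci change ``dem_fold``-fold between libraries (split up/down), the
    last ``n_exclusive_novel`` novel loci are library-exclusive, the rest
    are null (equal expected counts).
    """
    spec.validate()
    backend = backend or get_backend("auto")
    rng = np.random.default_rng(spec.seed)
    thresholds = CriteriaThresholds()

    chrom_len = spec.genome_length // spec.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    arrays = {
        c: np.array(list(random_seq(chrom_len, rng, spec.gc_fraction)))
        for c in chroms
    }

    # --- plan locus slots -------------------------------------------------
    n_mirna = spec.n_known_loci + spec.n_novel_loci
    slots: List[Tuple[str, int, int]] = []  # (chrom, pos0, slot_len)
    cursors = {c: _MIN_GAP for c in chroms}
    sizes = [_SLOT] * n_mirna + [
        _NCRNA_LENGTHS[NCRNA_CATEGORIES[i % len(NCRNA_CATEGORIES)]]
        for i in range(spec.n_ncrna_loci)
    ]
    for i, size in enumerate(sizes):
        chrom = chroms[i % len(chroms)]
        pos0 = cursors[chrom] + int(rng.integers(0, 40))
        if pos0 + size + _MIN_GAP > chrom_len:
            raise GenomePackingError(
                f"planted loci exceed capacity of {chrom} "
                f"({pos0 + size + _MIN_GAP} > {chrom_len} bases)"
            )
        slots.append((chrom, pos0, size))
        cursors[chrom] = pos0 + size + _MIN_GAP

    # --- abundances -------------------------------------------------------
    base = np.maximum(
        60.0, rng.lognormal(np.log(mean_abundance), 0.8, size=n_mirna)
    ).round()
    n_dem = max(0, int(round(dem_fraction * n_mirna)) - n_exclusive_novel)
    classes = ["null"] * n_mirna
    dem_idx = rng.choice(n_mirna - n_exclusive_novel, size=n_dem, replace=False)
    for j, idx in enumerate(sorted(dem_idx)):
        classes[idx] = "up" if j % 2 == 0 else "down"
    for k in range(n_exclusive_novel):
        classes[n_mirna - 1 - k] = "exclusive_CT" if k % 2 == 0 else "exclusive_NCT"

    def abundances(i: int) -> Tuple[float, float]:
        a = float(base[i])
        cls = classes[i]
        if cls == "up":
            return a, a * dem_fold
        if cls == "down":
            return a * dem_fold, a
        if cls == "exclusive_CT":
            return 0.0, a
        if cls == "exclusive_NCT":
            return a, 0.0
        return a, a

    # --- plant miRNA hairpins --------------------------------------------
    truth: List[PlantedLocus] = []
    n_families = max(1, spec.n_known_loci // 3)
    members_per_family = max(1, spec.n_known_loci // n_families)
    for i in range(n_mirna):
        known = i < spec.n_known_loci
        chrom, pos0, slot = slots[i]
        strand = "+" if rng.random() < 0.5 else "-"
        a_nct, a_ct = abundances(i)
        adapter_seed = DEFAULT_ADAPTER_3P[:6]
        for attempt in range(max_retries):
            mature = random_seq(int(rng.choice([21, 21, 21, 22])), rng, 0.5)
            hairpin, m_off, star = _draw_hairpin(mature, rng, spec.gc_fraction)
            if adapter_seed in hairpin:
                # reads from such a locus would be mis-trimmed downstream;
                # planted loci must stay valid positive controls
                continue
            planted = revcomp(hairpin) if strand == "-" else hairpin
            pad = random_seq(slot - len(planted), rng, spec.gc_fraction)
            _plant(arrays[chrom], pos0, planted + pad)
            start, end = pos0 + 1, pos0 + len(planted)
            locus = PlantedLocus(
                locus_id="",
                category="known_miRNA" if known else "novel_miRNA",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                mature_seq=mature,
                star_seq=star,
                abundance_NCT=a_nct,
                abundance_CT=a_ct,
                mature_offset=m_off,
            )
            if _locus_passes(locus, {c: "".join(a) for c, a in arrays.items()},
                             backend, thresholds):
                break
        else:
            raise RuntimeError(
                f"could not plant a criteria-passing hairpin at {chrom}:{pos0 + 1} "
                f"after {max_retries} retries"
            )
        if known:
            fam = f"miR{901 + i // members_per_family}"
            member = chr(ord("a") + sum(1 for t in truth if t.family == fam))
            locus.locus_id = f"vvi-{fam}{member}"
            locus.family = fam
        else:
            locus.locus_id = f"novel_mir_{i - spec.n_known_loci + 1}"
        truth.append(locus)

    # --- ncRNA contaminant loci -------------------------------------------
    weights = rng.lognormal(np.log(500.0), 0.6, size=spec.n_ncrna_loci).round()
    for j in range(spec.n_ncrna_loci):
        chrom, pos0, size = slots[n_mirna + j]
        cat = NCRNA_CATEGORIES[j % len(NCRNA_CATEGORIES)]
        seq = random_seq(size, rng, spec.gc_fraction)
        _plant(arrays[chrom], pos0, seq)
        truth.append(
            PlantedLocus(
                locus_id=f"{cat.lower()}_{j + 1}",
                category=cat,
                chrom=chrom,
                start=pos0 + 1,
                end=pos0 + size,
                strand="+",
                mature_seq="",
                star_seq="",
                abundance_NCT=float(weights[j]),
                abundance_CT=float(weights[j]),
            )
        )

    genome = {c: "".join(a) for c, a in arrays.items()}
    return genome, truth


def _locus_passes(
    locus: PlantedLocus,
    genome: Mapping[str, str],
    backend: FoldBackend,
    thresholds: CriteriaThresholds,
) -> bool:
    """Validate a planted hairpin through the discovery module's own path."""
    cluster = locus.mature_genomic()
    accepted = evaluate_cluster(
        cluster,
        genome,
        backend,
        thresholds=thresholds,
        max_precursor=DEFAULT_MAX_PRECURSOR,
        skip_support=True,
    )
    return len(accepted) > 0


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _scales(
    truth: Sequence[PlantedLocus], params: ReadSimulationParams, library: str
) -> Tuple[float, float]:
    """(miRNA scale, ncRNA scale) so expected totals hit the requested depth."""
    if params.total_reads_per_library is None:
        return 1.0, 1.0
    mir = sum(t.abundance(library) for t in truth if t.mature_seq)
    nc = sum(t.abundance(library) for t in truth if not t.mature_seq)
    total = params.total_reads_per_library
    s_mir = total * (1.0 - params.contaminant_fraction) / mir if mir else 0.0
    s_nc = total * params.contaminant_fraction / nc if nc else 0.0
    return s_mir, s_nc


def expected_tag_counts(
    truth: Sequence[PlantedLocus], params: ReadSimulationParams, library: str
) -> Dict[str, float]:
    """Expected exact-mature read counts per planted mature (oracle helper).

    Accounts for depth scaling, the zero-offset fraction of the isomiR end
    distribution, and the fraction of reads left error-free.
    """
    s_mir, _ = _scales(truth, params, library)
    p0 = float(LengthNoise(params.length_noise.p, params.length_noise.max_offset).probs()[0])
    out = {}
    for t in truth:
        if not t.mature_seq:
            continue
        L = len(t.mature_seq) + len(params.adapter_3p)
        keep = (1.0 - params.sequencing_error_rate) ** min(L, params.read_length)
        out[t.mature_seq] = t.abundance(library) * s_mir * p0 * p0 * keep
    return out


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    arr = list(seq)
    n = rng.binomial(len(arr), rate)
    if n == 0:
        return seq
    for pos in rng.choice(len(arr), size=n, replace=False):
        arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
    return "".join(arr)


def simulate_library(
    genome: Mapping[str, str],
    truth: Sequence[PlantedLocus],
    params: ReadSimulationParams,
    library_name: str,
    out_path: Optional[str] = None,
) -> object:
    """Simulate one library's reads; write FASTQ if ``out_path`` else return them.

    Per-locus read counts are Poisson around the (depth-scaled) abundance of
    the selected library.  miRNA reads are the mature sequence with
    truncated-geometric 5'/3' end offsets; ncRNA reads are random fragments
    with a 24-nt length mode.  Inserts shorter than the read cycle carry the
    3' adapter.  Returns the list of (name, seq, qual) tuples, or
    ``out_path`` after writing.
    """
    params.validate()
    if not truth:
        raise ValueError("truth table is empty")
    if library_name not in LIBRARIES:
        raise KeyError(f"no abundance column for library {library_name!r}")
    lib_idx = LIBRARIES.index(library_name)
    rng = np.random.default_rng([params.seed, lib_idx])
    s_mir, s_nc = _scales(truth, params, library_name)
    off_probs = params.length_noise.probs()
    offsets = np.arange(len(off_probs))
    frag_lens = np.arange(21, 31)
    # ncRNA/siRNA-sized fragments: tight 24-nt mode, the second size class
    frag_probs = np.exp(-0.5 * ((frag_lens - 24) / 0.9) ** 2)
    frag_probs /= frag_probs.sum()

    reads: List[str] = []
    qual_cache: Dict[int, str] = {}

    def emit(insert: str, n: int) -> None:
        read = (insert + params.adapter_3p)[: params.read_length]
        n_err = rng.binomial(n, 1.0 - (1.0 - params.sequencing_error_rate) ** len(read))
        reads.extend([read] * (n - n_err))
        for _ in range(n_err):
            reads.append(_mutate(read, rng, params.sequencing_error_rate))

    for locus in truth:
        scale = s_mir if locus.mature_seq else s_nc
        lam = locus.abundance(library_name) * scale
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n == 0:
            continue
        if locus.mature_seq:
            precursor = locus.sequence(genome)
            m0, mL = locus.mature_offset, len(locus.mature_seq)
            combo_counts = rng.multinomial(
                n, np.outer(off_probs, off_probs).ravel()
            ).reshape(len(offsets), len(offsets))
            for i5 in offsets:
                for i3 in offsets:
                    c = int(combo_counts[i5, i3])
                    if c == 0:
                        continue
                    lo = m0 + int(i5)  # 5' trim
                    hi = min(m0 + mL + int(i3), len(precursor))  # 3' extension
                    emit(precursor[lo:hi], c)
        else:
            seq = locus.sequence(genome)
            lens = rng.choice(frag_lens, size=n, p=frag_probs)
            starts = rng.integers(0, np.maximum(1, len(seq) - lens + 1))
            for s, L in zip(starts, lens):
                emit(seq[int(s) : int(s) + int(L)], 1)

    order = rng.permutation(len(reads))
    records = []
    for serial, idx in enumerate(order):
        seq = reads[int(idx)]
        q = qual_cache.setdefault(len(seq), "I" * len(seq))
        records.append((f"{library_name}_{serial + 1}", seq, q))

    if out_path is None:
        return records
    opener = gzip.open if str(out_path).endswith(".gz") else open
    with opener(out_path, "wt") as fh:
        for name, seq, q in records:
            fh.write(f"@{name}\n{seq}\n+\n{q}\n")
    return out_path


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: Mapping[str, str], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=c, description="") for c, seq in genome.items()]
    seqio_write(records, path, "fasta")


def write_truth_tsv(truth: Sequence[PlantedLocus], path: str) -> None:
    import pandas as pd

    rows = [
        {
            "locus_id": t.locus_id,
            "category": t.category,
            "location": t.location,
            "mature_seq": as_rna(t.mature_seq),
            "star_seq": as_rna(t.star_seq),
            "mature_offset": t.mature_offset,
            "abundance_NCT": t.abundance_NCT,
            "abundance_CT": t.abundance_CT,
        }
        for t in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> List[PlantedLocus]:
    import pandas as pd

    truth = []
    for row in pd.read_csv(path, sep="\t", keep_default_na=False).to_dict("records"):
        chrom, start, end, strand = str(row["location"]).rsplit(":", 3)
        truth.append(
            PlantedLocus(
                locus_id=row["locus_id"],
                category=row["category"],
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                mature_seq=as_dna(str(row["mature_seq"])),
                star_seq=as_dna(str(row["star_seq"])),
                abundance_NCT=float(row["abundance_NCT"]),
                abundance_CT=float(row["abundance_CT"]),
                mature_offset=int(row["mature_offset"]),
            )
        )
    return truth


def write_known_reference(
    truth: Sequence[PlantedLocus], genome: Mapping[str, str], path: str
) -> None:
    """Mature + precursor reference FASTA for the planted known families."""
    with open(path, "w") as fh:
        for t in truth:
            if t.category != "known_miRNA":
                continue
            fh.write(f">{t.locus_id}\n{as_rna(t.mature_seq)}\n")
            fh.write(f">{t.locus_id}-precursor\n{as_rna(t.sequence(genome))}\n")


def write_ncrna_fasta(
    truth: Sequence[PlantedLocus], genome: Mapping[str, str], path: str
) -> None:
    with open(path, "w") as fh:
        for t in truth:
            if t.category in NCRNA_CATEGORIES:
                fh.write(f">{t.locus_id} {t.category}\n{t.sequence(genome)}\n")


_GFF_TYPES = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "repeat": "repeat_region",
    "known_miRNA": "miRNA",
    "novel_miRNA": "miRNA",
}


def write_annotation_gff3(truth: Sequence[PlantedLocus], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truth:
            if t.category not in NCRNA_CATEGORIES:
                continue
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        "coldmir_sim",
                        _GFF_TYPES[t.category],
                        str(t.start),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        f"ID={t.locus_id};category={t.category}",
                    ]
                )
                + "\n"
            )
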