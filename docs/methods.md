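# Methods

## Pipeline model

The pipeline assumes the classic replicate-free, two-library plant small-RNA
design: one control (NCT) and one treated (CT) library, sequenced deeply
enough that count noise is Poisson-like, with 18–30 nt inserts carrying a
known 3′ adapter. All sequences are normalised to the DNA alphabet
internally; miRNA-facing outputs print RNA (U). Genomic coordinates are
1-based, inclusive, strand-explicit, formatted `chrom:start:end:strand`.

Stages run in a fixed order — clean/collapse → genome mapping and category
triage → known-miRNA matching → novel hairpin prediction → differential
expression → target prediction — and every threshold applied is echoed into
the run log. Reruns with the same config and inputs are bit-identical apart
from the log timestamp.

## Tag processing

"Low quality" is pinned to mean Phred < 20 or any N call; the source data's
exact definition is not recoverable, so both knobs are configurable. The 3′
adapter is located by exact leftmost match of its first 6 nt; untrimmed reads
of ≤ 30 nt are kept because they may be full-length inserts. Inserts outside
18–30 nt are discarded, with the tally partitioned by first failing reason
(N → quality → length). Collapsing is order-invariant and count-conserving.

## Mapping and triage

Mapping is exact (zero mismatches) over both strands, via an 18-mer
seed-and-verify index checked in the tests against a brute-force string scan.
ncRNA matching is exact substring containment against the reference sets
(deterministic, rather than the BLAST heuristic a server pipeline would use).
Categories are assigned by fixed priority — rRNA > tRNA > snRNA > snoRNA >
scRNA > known miRNA > repeat > exon_sense > exon_antisense > intron_sense >
intron_antisense > unannotated — with ncRNA first, since ncRNA matches are
excluded from all miRNA analysis. Tags with more than 20 genomic copies are
flagged repeat-like and barred from novel candidacy.

## Known-miRNA matching

A tag matches a reference mature if an ungapped alignment has ≤ 2 mismatches,
allowing the tag to overhang or truncate the mature by ≤ 2 nt at either end
(end offsets are capped but not counted as mismatches). At these lengths this
is what short-word BLASTN matching effectively does; indel-tolerant matching
is out of scope. Ties are resolved to the minimum-mismatch hits; a tag tied
between several matures contributes to each (rows marked shared, the fused
row labels of family tables), but only once per family so family totals never
exceed tag totals; when a tie spans families the tag goes to the family with
the most tied members (alphabetical tie-break). Only exact annotated matures
feed differential expression; other matches are isomiR-style variants, listed
separately.

## Novel miRNA prediction

Candidate windows extend a mapped tag cluster by 20-nt flanks, up to a
maximum precursor length of 240 nt, under both arm hypotheses (tag as 5′ or
3′ arm). Windows are folded (ViennaRNA MFE structure by default), the star is
located as the segment pairing with the mature plus the 2-nt 3′ overhang, and
the window is then trimmed to the mature–star extent plus flanks and refolded
— without trimming, the generous initial windows of neighbouring loci overlap
and distinct miRNAs would be merged. A mature that pairs with itself or whose
partners straddle it is rejected as loop-spanning; a star is required.

Duplex statistics: paired bases = mature positions paired into the star
region; bulge = longest run of consecutive unpaired positions on either
duplex strand; asymmetry = |unpaired-in-mature − unpaired-in-star| over the
duplex core. The ten acceptance criteria and their defaults are listed in the
README; all are configurable. Criteria 1 (18–25 nt) and 2 (20–23 nt) are both
evaluated on the mature length — the distinction between the permissive
prediction bound and the canonical reference window is ambiguous in the
underlying rule set, so both are checked and reported separately. Read
support (criterion 10) is ≥ 50 reads in at least one library, reconciling the
"more than 50" rule with the "fewer than 50 in both libraries neglected"
screening step.

Overlapping same-strand candidates, and candidates sharing a mature sequence,
are merged keeping the candidate whose mature tag has the highest read
support (ties to lower MFE). Support-first, rather than lowest-MFE-first, is
deliberate: with isomiR end noise the lowest-MFE window can belong to a
shifted low-abundance variant, which would report the wrong mature.

The folding backend is pluggable (`seq -> (dot-bracket, energy)`).
The bundled fallback is a Nussinov-style maximum-pairing fold with a
stacking-weighted score surrogate; it is non-thermodynamic, and MFE-based
conclusions are only made with the ViennaRNA backend.

## Differential expression

TPM uses the library's total clean reads as denominator (mapped-read
normalisation is a config away; clean-read totals are consistent with the
worked examples). A zero count becomes TPM = 0.01 exactly; classification
uses unrounded values while tables print TPM and fold-change to 2 decimals.
Rows below 10 TPM in both libraries are filtered as low-expression. Up/down
calls need |log₂ FC| > 1 and p ≤ 0.001. No multiple-testing correction is
applied to the calls (a Benjamini–Hochberg column is emitted for reference).

The default p-value is the exact conditional form of the Audic–Claverie
model: conditioning P(y|x) on the observed total x+y gives
Binomial(x+y, N₁/(N₁+N₂)), tested two-sided by minimum likelihood. This is
exactly symmetric under swapping the libraries, which the raw two-tail
negative-binomial form is not when N₁ ≠ N₂; that literal tail form is kept as
`ac_tail` and verified against direct summation of the mass.

qPCR validation time courses (0, 2, 4, 8, 24, 48 h, normalised to 1 at 0 h)
are classified into four patterns: I — immediate repression with the minimum
at 4 or 8 h and stress-phase mean < 1; II — transient rise at 2 h, fallen by
8 h, stress mean < 1; III — interior peak above control with the early phase
elevated; IV — repressed through 8 h but ≥ 2-fold at 48 h. These boundaries
are this package's formalisation of a verbal description; they are
configurable in code and flat series return `unclassified`.

## Target prediction

Scoring follows the plant complementarity rules (match 0, G:U 0.5, mismatch
1, gap 2; doubled at positions 2–13) with default cutoff 3.0. Site discovery
scans ungapped windows of the miRNA length; gapped duplexes can be scored
when an alignment is supplied, but gapped discovery is not implemented — a
compatible approximation of server pipelines whose internal gap model is
unpublished. The expected cleavage position is the transcript base opposite
miRNA position 10. Cleavage summaries report the fraction of 5′-RACE clone
ends per miRNA-relative offset. Expression correlation is plain Pearson r
with a two-sided t-based p; zero-variance series are an explicit error.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- a uniform-random background genome (default 120 kb over 3 chromosomes,
  GC 0.35) — no repeats, isochores or gene structure;
- planted known-family and novel hairpins: a 21–22 nt mature, an 8–15 nt
  loop, and a star arm that is the reverse complement of the mature with 1–4
  point changes. Each planted hairpin is validated through the discovery
  module's own excise→fold→trim→criteria path and redrawn (bounded retries)
  until it passes, so planted loci are positive controls by construction.
  Hairpins containing the adapter seed are rejected at draw time, since their
  reads would be mis-trimmed and the locus would stop being a valid control;
- per-locus expected abundances (lognormal around 800 reads, floor 60 so
  criterion 10 is satisfiable), with a quarter of loci changing 4-fold
  between libraries and two novel loci library-exclusive — the planted
  ground truth for recovery tests;
- reads: per-locus Poisson counts, truncated-geometric 5′/3′ isomiR end
  offsets (90 % exact ends), a constant Phred-40 quality, uniform
  substitution errors (default 10⁻³), and the 3′ adapter filling the 36-nt
  read cycle;
- contaminants: ncRNA loci (rRNA/tRNA/snRNA/snoRNA/repeat) emitting random
  fragments with a tight 24-nt length mode, 30 % of reads by default, giving
  the bimodal 21/24-nt tag length histogram typical of plant libraries.

What passing tests on this generator do **not** show: behaviour on real
genomes (repeats, multi-mapping families, degraded RNA), realistic Illumina
error and quality profiles, siRNA biogenesis, or miRNA loci that violate the
planted-hairpin geometry. The generator is a correctness harness, not a
benchmark of sensitivity on real data.

## Problem sizes

The default synthetic study is 2 × 200,000 reads over 28 planted loci; the
test suite uses a 60 kb genome with 16 loci and 2 × 30,000–40,000 reads for
end-to-end checks, and the parameter-recovery evaluation runs 20 replicate
library pairs of 200,000 reads over 40 loci (30 null, 10 four-fold). These
sizes give per-locus depths of several thousand reads, at which a 4-fold
change is detected with essentially unit power while |log₂FC| > 1 keeps null
loci quiet; scaling them up changes runtimes, not conclusions.

## Known limitations

- Exact-match mapping only; a single sequencing error orphans a read rather
  than soft-matching it (as with zero-mismatch short-read mapping generally).
- Depth normalisation is compositional: planting strong up-regulation
  shrinks every other locus's share, so a planted 4-fold change is observed
  as a smaller library-normalised fold-change (still well above the 2-fold
  threshold at the default design).
- The published-table re-analysis carries one internally inconsistent row
  (its printed TPM pair cannot reproduce its printed fold-change to better
  than ~1.0); it is reported but excluded from exact numeric checks.
- GO enrichment, conservation screening against external databases, and
  figure rendering are out of scope.
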