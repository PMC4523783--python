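#!/usr/bin/env python
"""Generate the synthetic two-library study inputs.

Builds a toy genome with planted known-family miRNA hairpins, novel hairpins
and ncRNA contaminant loci, then simulates the control (NCT) and
cold-treated (CT) read libraries.  Writes genome, truth table, references
and FASTQ files under results/sim/.
"""

import argparse
import json
from pathlib import Path

from coldmir.syn_data import (
    ReadSimulationParams,
    SyntheticGenomeSpec,
    build_genome,
    simulate_library,
    write_annotation_gff3,
    write_genome_fasta,
    write_known_reference,
    write_ncrna_fasta,
    write_truth_tsv,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/sim"))
    parser.add_argument("--total-reads", type=int, default=200_000)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = SyntheticGenomeSpec(seed=args.seed)
    genome, truth = build_genome(spec)
    write_genome_fasta(genome, str(args.out / "genome.fa"))
    write_truth_tsv(truth, str(args.out / "truth.tsv"))
    write_known_reference(truth, genome, str(args.out / "known_mirnas.fa"))
    write_ncrna_fasta(truth, genome, str(args.out / "ncrna.fa"))
    write_annotation_gff3(truth, str(args.out / "annotation.gff3"))
    params = ReadSimulationParams(
        seed=args.seed, total_reads_per_library=args.total_reads
    )
    for lib in ("NCT", "CT"):
        simulate_library(genome, truth, params, lib,
                         out_path=str(args.out / f"{lib}.fastq.gz"))

    n_by_cat = {}
    for t in truth:
        n_by_cat[t.category] = n_by_cat.get(t.category, 0) + 1
    print(f"genome: {sum(map(len, genome.values()))} bases over "
          f"{len(genome)} chromosomes")
    print(f"planted loci: {json.dumps(n_by_cat)}")
    print(f"libraries: 2 x ~{args.total_reads} reads -> {args.out}")


if __name__ == "__main__":
    main()
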