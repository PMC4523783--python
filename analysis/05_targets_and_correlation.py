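#!/usr/bin/env python
"""Target prediction, cleavage-site summarisation and anti-correlation.

Builds a synthetic transcript set carrying complementary sites for the
DEM miRNAs found by the pipeline, scans it with the plant penalty rules,
summarises simulated 5'-RACE clone ends around the expected cleavage
position (opposite miRNA position 10), and checks miRNA-target expression
anti-correlation on a cold time course.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from coldmir._seq import as_dna, random_seq, revcomp
from coldmir.targets import (
    expression_correlation,
    scan_transcripts,
    summarize_cleavage,
    targets_table,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pipeline", type=Path, default=Path("results/pipeline"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    dem = pd.read_csv(args.pipeline / "dem.tsv", sep="\t")
    novel = pd.read_csv(args.pipeline / "novel_mirnas.tsv", sep="\t")
    seq_by_name = dict(zip(novel["name"], novel["sequence"]))
    dem_mirnas = {
        name: as_dna(seq_by_name[name])
        for name in dem.loc[dem["class"].isin(["up", "down"]), "miRNA_name"]
        if name in seq_by_name
    }
    if not dem_mirnas:  # fall back to the most abundant novel miRNA
        name = novel.iloc[0]["name"]
        dem_mirnas = {name: as_dna(novel.iloc[0]["sequence"])}

    transcripts = {}
    for i, (name, seq) in enumerate(sorted(dem_mirnas.items())):
        site = revcomp(seq)  # perfect complementary site
        transcripts[f"synthTx{i + 1}"] = (
            random_seq(120, rng) + site + random_seq(120, rng)
        )

    alignments = []
    for name, seq in sorted(dem_mirnas.items()):
        alignments.extend(scan_transcripts(name, seq, transcripts, max_score=3.0))
    targets_table(alignments).to_csv(args.out / "targets.tsv", sep="\t",
                                     index=False)
    print(f"{len(alignments)} target sites for {len(dem_mirnas)} DEM miRNAs "
          f"over {len(transcripts)} transcripts")

    best = min(alignments, key=lambda a: a.score)
    clone_positions = [best.expected_cleavage] * 7 + [best.expected_cleavage - 1]
    cs = summarize_cleavage(best, clone_positions)
    print(f"cleavage summary for {best.mirna_name} on {best.transcript_id}: "
          f"modal offset {cs.modal_offset} "
          f"(fraction {cs.fraction_by_offset[cs.modal_offset]:.2f})")

    # cold time course: miRNA repressed, target induced
    mirna_series = [1.0, 0.8, 0.35, 0.45, 0.65, 0.9]
    noise = rng.normal(0, 0.03, size=6)
    target_series = [2.0 - m + e for m, e in zip(mirna_series, noise)]
    r, p = expression_correlation(mirna_series, target_series)
    print(f"miRNA-target Pearson r = {r:.3f} (p = {p:.3g})")
    pd.DataFrame({
        "hours": [0, 2, 4, 8, 24, 48],
        "miRNA": mirna_series,
        "target": target_series,
    }).to_csv(args.out / "expression_timecourse.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
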