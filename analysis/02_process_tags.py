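#!/usr/bin/env python
"""Clean both read libraries and collapse them to unique tags.

Reports the discard tally and the tag length distribution (expected: a major
21-nt miRNA class and a second 24-nt class from ncRNA-sized fragments), and
writes the collapsed tag table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from coldmir.syn_data import DEFAULT_ADAPTER_3P
from coldmir.tagproc import clean_reads, collapse, summarize_library, write_tag_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--adapter", default=DEFAULT_ADAPTER_3P)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    clean_by_lib = {}
    for lib in ("NCT", "CT"):
        clean, tally = clean_reads(str(args.sim / f"{lib}.fastq.gz"), args.adapter)
        clean_by_lib[lib] = clean
        print(f"{lib}: {len(clean) + tally.total_discarded} raw -> "
              f"{len(clean)} clean "
              f"(N={tally.contains_n}, low-quality={tally.low_quality}, "
              f"<18nt={tally.too_short}, >30nt={tally.too_long})")

    tags = collapse(clean_by_lib)
    write_tag_table(tags, ["NCT", "CT"], str(args.out / "tags.tsv"))
    print(f"unique tags: {len(tags)}")

    rows = []
    for lib in ("NCT", "CT"):
        s = summarize_library(lib, len(clean_by_lib[lib]), clean_by_lib[lib], tags)
        for length, (uniq, total) in s.length_histogram.items():
            rows.append({"library": lib, "length": length,
                         "unique_tags": uniq, "reads": total})
    hist = pd.DataFrame(rows)
    hist.to_csv(args.out / "length_distribution.tsv", sep="\t", index=False)
    for lib in ("NCT", "CT"):
        sub = hist[hist.library == lib].set_index("length")["reads"]
        mode = sub.idxmax()
        print(f"{lib}: modal read length {mode} nt "
              f"({100 * sub[mode] / sub.sum():.1f}%), "
              f"24 nt share {100 * sub.get(24, 0) / sub.sum():.1f}%")


if __name__ == "__main__":
    main()
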