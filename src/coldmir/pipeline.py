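"""End-to-end pipeline orchestration: process -> annotate -> known -> novel
-> dem -> targets, from a single config, with every applied threshold echoed
into the run log and a machine-readable JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from ._seq import as_dna, as_rna
from .annotate import (
    DEFAULT_MAX_COPIES,
    GenomeIndex,
    category_summary,
    classify_tags,
    load_features,
    load_ncrna_fasta,
)
from .dem_stats import DEMThresholds, ExpressionRecord, bh_adjust, classify_dem, dem_table
from .fold import get_backend
from .known_id import (
    MAX_MISMATCHES,
    aggregate_families,
    load_mature_reference,
    match_tags,
    mature_counts,
    variant_table,
)
from .novel_id import CriteriaThresholds, discover_novel
from .tagproc import (
    DEFAULT_QUAL_THRESHOLD,
    clean_reads,
    collapse,
    summarize_library,
    tags_to_frame,
    write_collapsed_fasta,
)
from .targets import DEFAULT_MAX_SCORE, scan_transcripts, targets_table
from .syn_data import DEFAULT_ADAPTER_3P, LIBRARIES


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run; defaults are the study values."""

    genome_fasta: str = ""
    reads: Dict[str, str] = field(default_factory=dict)  # library -> FASTQ path
    known_reference: str = ""
    ncrna_fasta: str = ""
    annotation_gff3: str = ""
    transcripts_fasta: str = ""

    adapter_3p: str = DEFAULT_ADAPTER_3P
    qual_threshold: int = DEFAULT_QUAL_THRESHOLD
    min_tag_len: int = 18
    max_tag_len: int = 30
    max_mismatches: int = MAX_MISMATCHES
    max_copies: int = DEFAULT_MAX_COPIES
    criteria: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    dem: DEMThresholds = field(default_factory=DEMThresholds)
    p_method: str = "ac"
    target_max_score: float = DEFAULT_MAX_SCORE
    backend: str = "auto"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "criteria":
                cfg.criteria = CriteriaThresholds(**value)
            elif key == "dem":
                cfg.dem = DEMThresholds(**value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise KeyError(f"unknown config key: {key!r}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_genome(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    genome = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        genome[rec.id] = as_dna(str(rec.seq))
    return genome


def _load_transcripts(path: str):
    from Bio import SeqIO

    seqs, notes = {}, {}
    for rec in SeqIO.parse(path, "fasta"):
        seqs[rec.id] = as_dna(str(rec.seq))
        notes[rec.id] = rec.description.partition(" ")[2]
    return seqs, notes


class RunLog:
    def __init__(self) -> None:
        self.lines: List[str] = []
        self.counts: Dict[str, int] = {}

    def log(self, msg: str) -> None:
        self.lines.append(msg)

    def stage(self, name: str, records_in: int, records_out: int) -> None:
        if records_out > records_in:
            raise AssertionError(
                f"stage {name}: records_out {records_out} > records_in {records_in}"
            )
        self.counts[name] = records_out
        self.log(f"stage {name}: {records_in} -> {records_out} records")

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig, out_dir: str) -> Dict[str, object]:
    """Run all stages; writes TSVs, a run log and summary.json under out_dir.

    Returns the summary dict.  Reruns with identical config and inputs are
    bit-identical except the timestamp line of the run log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.log(f"coldmir {__version__}")
    log.log(f"started {time.strftime('%Y-%m-%dT%H:%M:%S')}")
    log.log(f"seed {config.seed}")
    for key, value in sorted(config.to_dict().items()):
        if key not in {"reads"}:
            log.log(f"config {key} = {value}")
    for lib, path in sorted(config.reads.items()):
        log.log(f"config reads[{lib}] = {path}")

    libraries = [lib for lib in LIBRARIES if lib in config.reads] or sorted(config.reads)
    if not libraries:
        raise ValueError("no read libraries configured")

    # --- stage 1: process ---------------------------------------------------
    clean_by_lib: Dict[str, List[str]] = {}
    totals: Dict[str, int] = {}
    for lib in libraries:
        clean, tally = clean_reads(
            config.reads[lib],
            config.adapter_3p,
            qual_threshold=config.qual_threshold,
            min_len=config.min_tag_len,
            max_len=config.max_tag_len,
        )
        clean_by_lib[lib] = clean
        totals[lib] = len(clean)
        raw = len(clean) + tally.total_discarded
        log.stage(f"process[{lib}]", raw, len(clean))
        log.log(
            f"  discards[{lib}]: N={tally.contains_n} lowq={tally.low_quality} "
            f"short={tally.too_short} long={tally.too_long} "
            f"(adapter trimmed in {tally.adapter_trimmed})"
        )
    tags = collapse(clean_by_lib)
    log.stage("collapse", sum(totals.values()), len(tags))
    tags_to_frame(tags, libraries).to_csv(out / "tags.tsv", sep="\t", index=False)
    write_collapsed_fasta(tags, str(out / "tags.fa"))
    summaries = [
        summarize_library(lib, totals[lib], clean_by_lib[lib], tags)
        for lib in libraries
    ]
    pd.DataFrame(
        [
            {
                "library": s.library_name,
                "raw_reads": s.raw_reads,
                "clean_reads": s.clean_reads,
                "unique_tags": s.unique_tags,
            }
            for s in summaries
        ]
    ).to_csv(out / "library_summary.tsv", sep="\t", index=False)

    # --- stage 2: annotate ---------------------------------------------------
    genome = _load_genome(config.genome_fasta)
    index = GenomeIndex(genome)
    ncrna_sets = load_ncrna_fasta(config.ncrna_fasta) if config.ncrna_fasta else {}
    features = load_features(config.annotation_gff3) if config.annotation_gff3 else []
    matures = (
        load_mature_reference(config.known_reference) if config.known_reference else {}
    )
    mature_set = set(matures.values())
    assignments, hits_by_tag = classify_tags(
        [t.sequence for t in tags],
        index,
        ncrna_sets,
        features,
        is_known_mirna=lambda s: s in mature_set,
        max_copies=config.max_copies,
    )
    cat_df = category_summary(assignments)
    cat_df.to_csv(out / "category_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sequence": s, "category": a.category, "n_hits": len(hits_by_tag[s])}
            for s, a in assignments.items()
        ]
    ).sort_values("sequence").to_csv(out / "categories.tsv", sep="\t", index=False)
    log.stage("annotate", len(tags), len(assignments))

    candidate_tags = [
        t
        for t in tags
        if assignments[t.sequence].category in ("miRNA_candidate", "unannotated")
    ]
    log.stage("ncRNA_exclusion", len(tags), len(candidate_tags))

    # --- stage 3: known ------------------------------------------------------
    hits = match_tags(candidate_tags, matures, max_mm=config.max_mismatches)
    known_counts = mature_counts(hits, candidate_tags, libraries)
    known_counts.to_csv(out / "known_counts.tsv", sep="\t", index=False)
    families = aggregate_families(hits, candidate_tags, libraries)
    pd.DataFrame(
        [
            {
                "family": f.family,
                "n_members": f.n_members,
                "NCT_reads": f.reads_NCT,
                "CT_reads": f.reads_CT,
            }
            for f in families
        ]
    ).to_csv(out / "family_counts.tsv", sep="\t", index=False)
    variant_table(hits, candidate_tags, libraries).to_csv(
        out / "known_variants.tsv", sep="\t", index=False
    )
    log.stage("known", max(len(candidate_tags), len(known_counts)), len(known_counts))

    # --- stage 4: novel ------------------------------------------------------
    known_tag_seqs = set(hits)
    novel_input = {
        t.sequence: [h.as_tuple() for h in hits_by_tag[t.sequence]]
        for t in candidate_tags
        if t.sequence not in known_tag_seqs and hits_by_tag[t.sequence]
    }
    novel_counts_map = {
        t.sequence: t.count_by_library
        for t in candidate_tags
        if t.sequence in novel_input
    }
    backend = get_backend(config.backend)
    novel = discover_novel(
        novel_input,
        novel_counts_map,
        genome,
        backend=backend,
        thresholds=config.criteria,
    )
    novel_rows = []
    with open(out / "novel_structures.txt", "w") as sfh:
        for i, (cand, report) in enumerate(
            sorted(novel, key=lambda cr: -max(cr[0].read_support.values() or [0])),
            start=1,
        ):
            name = f"novel_mir_{i}"
            novel_rows.append(
                {
                    "name": name,
                    "sequence": cand.mature_rna,
                    "length": len(cand.mature_seq),
                    **{
                        f"{lib}_reads": cand.read_support.get(lib, 0)
                        for lib in libraries
                    },
                    "location": cand.locus,
                    "MFE_kcal_mol": round(cand.mfe, 2),
                }
            )
            sfh.write(f">{name} {cand.locus}\n{as_rna(cand.precursor_seq)}\n"
                      f"{cand.structure}\n")
    novel_df = pd.DataFrame(
        novel_rows,
        columns=["name", "sequence", "length",
                 *[f"{lib}_reads" for lib in libraries], "location", "MFE_kcal_mol"],
    )
    novel_df.to_csv(out / "novel_mirnas.tsv", sep="\t", index=False)
    log.stage("novel", len(novel_input), len(novel_df))

    # --- stage 5: dem --------------------------------------------------------
    records = []
    for row in known_counts.itertuples():
        records.append(
            ExpressionRecord(
                mirna_name=row.mature_name,
                count_NCT=int(getattr(row, "NCT", 0)),
                count_CT=int(getattr(row, "CT", 0)),
                total_NCT=totals.get("NCT", 1),
                total_CT=totals.get("CT", 1),
            )
        )
    novel_seq_by_name = {r["name"]: str(r["sequence"]) for r in novel_rows}
    tag_by_seq = {t.sequence: t for t in tags}
    for name, rna_seq in novel_seq_by_name.items():
        t = tag_by_seq.get(as_dna(rna_seq))
        if t is None:
            continue
        records.append(
            ExpressionRecord(
                mirna_name=name,
                count_NCT=t.count("NCT"),
                count_CT=t.count("CT"),
                total_NCT=totals.get("NCT", 1),
                total_CT=totals.get("CT", 1),
            )
        )
    results = [classify_dem(r, config.dem, method=config.p_method) for r in records]
    df = dem_table(results)
    if len(df):
        df["p_adj_BH"] = bh_adjust(list(df["p_value"]))
    df.to_csv(out / "dem.tsv", sep="\t", index=False)
    n_dem = int((df["class"].isin(["up", "down"])).sum()) if len(df) else 0
    log.stage("dem", len(records), len(df))
    log.log(
        f"  DEM: up={int((df['class'] == 'up').sum()) if len(df) else 0} "
        f"down={int((df['class'] == 'down').sum()) if len(df) else 0}"
    )

    # --- stage 6: targets ----------------------------------------------------
    n_targets = 0
    if config.transcripts_fasta:
        transcripts, notes = _load_transcripts(config.transcripts_fasta)
        dem_names = set(df.loc[df["class"].isin(["up", "down"]), "miRNA_name"])
        mirna_seqs = {}
        for row in known_counts.itertuples():
            if row.mature_name in dem_names:
                for name, seq in matures.items():
                    if name == row.mature_name:
                        mirna_seqs[name] = seq
        for name, rna_seq in novel_seq_by_name.items():
            if name in dem_names:
                mirna_seqs[name] = as_dna(rna_seq)
        alignments = []
        for name, seq in sorted(mirna_seqs.items()):
            alignments.extend(
                scan_transcripts(
                    name, seq, transcripts, config.target_max_score, notes
                )
            )
        targets_table(alignments).to_csv(out / "targets.tsv", sep="\t", index=False)
        n_targets = len(alignments)
        log.stage(
            "targets",
            max(n_targets, len(mirna_seqs) * max(1, len(transcripts))),
            n_targets,
        )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "libraries": libraries,
        "clean_reads": totals,
        "unique_tags": len(tags),
        "candidate_tags": len(candidate_tags),
        "known_matures": len(known_counts),
        "novel_mirnas": len(novel_df),
        "dem_up": int((df["class"] == "up").sum()) if len(df) else 0,
        "dem_down": int((df["class"] == "down").sum()) if len(df) else 0,
        "dem_total": n_dem,
        "target_sites": n_targets,
        "stage_counts": log.counts,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.write(out / "run_log.txt")
    return summary
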