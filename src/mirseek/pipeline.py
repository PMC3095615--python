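"""End-to-end discovery orchestration.

``run_discovery`` executes the full flow — clean/collapse, library profile,
known-family matching, genome mapping, repeat filtering, precursor
excision/folding/duplex validation, Class A/B/C annotation and (optionally)
target prediction — and emits a report bundle with per-stage gate counts so
a run reads like a results narrative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io
from .config import PipelineConfig
from .genome_scan import excise_windows, filter_repeats, map_tags
from .hairpin_fold import best_precursor
from .known_profiler import (
    MatureRef, match_known, read_reference, summaries_to_frame,
    summarize_families,
)
from .novel_annotator import (
    NovelAnnotation, assign_class, exclude_known, find_star_reads,
    name_candidates, report_table,
)
from .preprocess import (
    UniqueTag, collapse, filter_structural_rna, length_filter, size_profile,
    trim_adapters,
)
from .target_predict import scan_transcriptome, sites_to_frame

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryReport:
    config: PipelineConfig
    profile: pd.DataFrame
    known: pd.DataFrame
    novel: pd.DataFrame
    targets: pd.DataFrame | None
    annotations: list[NovelAnnotation]
    gate_counts: dict[str, int] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash={self.config.config_hash}\n"
        for name, df in [
            ("size_profile.tsv", self.profile.reset_index()),
            ("known_families.tsv", self.known),
            ("novel_mirnas.tsv", self.novel),
        ] + ([("targets.tsv", self.targets)] if self.targets is not None else []):
            path = outdir / name
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write(header)
            for key, val in self.gate_counts.items():
                fh.write(f"{key}\t{val}\n")


def discover(
    reads: Sequence[tuple[str, int]],
    genome: Mapping[str, str],
    refs: Sequence[MatureRef] = (),
    transcripts: Mapping[str, str] | None = None,
    config: PipelineConfig | None = None,
    exclusion_db: Mapping[str, str] | None = None,
) -> DiscoveryReport:
    """Run the discovery pipeline on in-memory inputs."""
    cfg = config or PipelineConfig()
    counts: dict[str, int] = {}
    counts["raw_reads"] = sum(c for _, c in reads)

    if cfg.adapter_3p:
        expanded = [seq for seq, c in reads for _ in range(c)]
        reads = [(r, 1) for r in trim_adapters(
            expanded, cfg.adapter_3p, cfg.adapter_min_overlap)]
    tags = collapse(reads)
    counts["unique_tags"] = len(tags)
    tags = filter_structural_rna(tags, exclusion_db)
    counts["after_structural_filter"] = len(tags)
    tags = length_filter(tags, cfg.min_len, cfg.max_len)
    counts["after_length_filter"] = len(tags)

    profile = size_profile(tags, cfg.min_len, cfg.max_len)

    matches = match_known(tags, refs, cfg.max_mismatch, cfg.end_shift) if refs else []
    summaries = summarize_families(matches, refs) if matches else []
    counts["known_families"] = len(summaries)
    known_seqs = {m.tag.seq for m in matches}

    locus_sets = map_tags(tags, genome)
    mapped = [ls for ls in locus_sets if ls.n_loci > 0]
    counts["mapped_tags"] = len(mapped)
    kept, excluded = filter_repeats(mapped, cfg.max_loci)
    counts["repeat_excluded_tags"] = len(excluded)
    counts["candidate_tags"] = len(kept)

    validate_kwargs = dict(
        min_matched_pairs=cfg.min_matched_pairs,
        max_size_diff=cfg.max_size_diff,
        overhang=cfg.overhang,
    )
    annotations: list[NovelAnnotation] = []
    for ls in kept:
        tag = ls.tag
        if tag.seq in known_seqs:
            continue  # known miRNAs are profiled, not rediscovered
        for hit in ls.hits:
            windows = excise_windows(hit, genome, cfg.flank_lengths, cfg.near_flank)
            best = best_precursor(windows, tag.seq, validate_kwargs=validate_kwargs)
            if best is None:
                continue
            star_seq = best.star_seq
            star_count = find_star_reads(star_seq, tags, cfg.end_shift)
            label = assign_class(tag.count, star_count, cfg.class_b_min_reads)
            annotations.append(
                NovelAnnotation(
                    candidate_id="",
                    scaffold=hit.scaffold,
                    start=hit.start,
                    end=hit.end,
                    orientation=hit.strand,
                    abundance=tag.count,
                    mature_seq=tag.seq,
                    hairpin_len=best.hairpin_len,
                    energy=best.energy,
                    class_label=label,
                    star_seq=star_seq if star_count else None,
                    star_count=star_count,
                )
            )
    annotations = exclude_known(annotations, matches)
    annotations = name_candidates(annotations)
    counts["novel_candidates"] = len(annotations)
    counts["novel_class_a"] = sum(1 for a in annotations if a.class_label == "A")
    counts["novel_class_b"] = sum(1 for a in annotations if a.class_label == "B")
    counts["novel_class_c"] = sum(1 for a in annotations if a.class_label == "C")

    targets_df = None
    if transcripts:
        sites = []
        for ann in annotations:
            if ann.class_label == "C":
                continue
            sites.extend(
                scan_transcriptome(ann.candidate_id, ann.mature_seq,
                                   transcripts, cfg.target_max_score)
            )
        targets_df = sites_to_frame(sites)
        counts["target_sites"] = len(sites)

    for key, val in counts.items():
        logger.info("%s: %d", key, val)
    return DiscoveryReport(
        config=cfg,
        profile=profile,
        known=summaries_to_frame(summaries) if summaries else summaries_to_frame([]),
        novel=report_table(annotations),
        targets=targets_df,
        annotations=annotations,
        gate_counts=counts,
    )


def run_discovery(
    config: PipelineConfig,
    reads_path: str | Path,
    genome_path: str | Path,
    known_path: str | Path | None = None,
    transcripts_path: str | Path | None = None,
    exclusion_path: str | Path | None = None,
    outdir: str | Path | None = None,
) -> DiscoveryReport:
    """File-based entry point: read inputs, run :func:`discover`, write reports."""
    reads = io.read_reads(reads_path)
    genome = dict(io.read_fasta(genome_path))
    refs = read_reference(known_path) if known_path else ()
    transcripts = dict(io.read_fasta(transcripts_path)) if transcripts_path else None
    exclusion = dict(io.read_fasta(exclusion_path)) if exclusion_path else None
    report = discover(reads, genome, refs, transcripts, config, exclusion)
    if outdir is not None:
        report.write(outdir)
    return report
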