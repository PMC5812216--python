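"""Pull reads near a fusion breakpoint out of coordinate-sorted indexed BAMs.

A read is kept when its alignment start (leftmost mapped position, soft clips
excluded) lies within the search radius of either partner coordinate, or when
its alignment span overlaps an exon fragment reachable within that radius by
the exonic walk.  Mates of kept reads can be pulled in regardless of where (or
whether) they aligned.  Output is name-sorted FASTQ in original read
orientation, so it can feed straight back into the fanned aligner.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pysam

from .references import BreakpointSpec, ExonTable, Interval, exonic_walk

logger = logging.getLogger("fusionlens")

PLACEHOLDER_QUAL = "I"


@dataclass
class ExtractionConfig:
    sources: List[str]
    radius: int = 200
    include_mates: bool = True
    dedupe_by_name: bool = False

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not self.sources:
            raise ValueError("need at least one BAM source")


@dataclass(order=True)
class FastqRecord:
    name: str
    mate_index: Optional[int] = field(compare=False)
    sequence: str = field(compare=False)
    quality: str = field(compare=False)

    def format(self) -> str:
        suffix = f"/{self.mate_index}" if self.mate_index else ""
        return f"@{self.name}{suffix}\n{self.sequence}\n+\n{self.quality}\n"


def _merge_intervals(ivs: List[Interval]) -> List[Interval]:
    out: List[List[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def target_regions(exons: ExonTable, bp: BreakpointSpec,
                   radius: int) -> Dict[str, List[Interval]]:
    """Per-chromosome merged 1-based intervals to search for reads.

    Union of the +-radius genomic window around each partner coordinate and the
    exon fragments within exonic distance radius in both directions.
    """
    regions: Dict[str, List[Interval]] = {}
    for partner in (bp.partner5, bp.partner3):
        ivs = regions.setdefault(partner.chrom, [])
        ivs.append((max(1, partner.pos - radius), partner.pos + radius))
        for direction, include in (("5prime", True), ("3prime", False)):
            ivs.extend(exonic_walk(exons, partner.chrom, partner.pos,
                                   direction, include, radius))
        for direction, include in (("3prime", True), ("5prime", False)):
            ivs.extend(exonic_walk(exons, partner.chrom, partner.pos,
                                   direction, include, radius))
    return {chrom: _merge_intervals(ivs) for chrom, ivs in regions.items()}


def _mate_index(rec: pysam.AlignedSegment) -> Optional[int]:
    if not rec.is_paired:
        return None
    return 1 if rec.is_read1 else 2


def _to_fastq(rec: pysam.AlignedSegment) -> FastqRecord:
    """Original-orientation sequence/quality (BAM stores the mapped strand)."""
    if rec.is_unmapped:
        seq = rec.query_sequence or ""
        quals = rec.query_qualities
        qual = (pysam.qualities_to_qualitystring(quals) if quals is not None
                else PLACEHOLDER_QUAL * len(seq))
    else:
        seq = rec.get_forward_sequence() or ""
        quals = rec.get_forward_qualities()
        qual = (pysam.qualities_to_qualitystring(quals) if quals is not None
                else PLACEHOLDER_QUAL * len(seq))
    return FastqRecord(rec.query_name, _mate_index(rec), seq, qual)


def _matches(rec: pysam.AlignedSegment, bp: BreakpointSpec, radius: int,
             exonic: Dict[str, List[Interval]]) -> bool:
    if rec.is_unmapped:
        return False
    chrom = rec.reference_name
    start = rec.reference_start + 1  # 1-based leftmost mapped base
    for partner in (bp.partner5, bp.partner3):
        if chrom == partner.chrom and abs(start - partner.pos) <= radius:
            return True
    end = rec.reference_end  # 1-based inclusive end == 0-based half-open end
    for s, e in exonic.get(chrom, []):
        if start <= e and end >= s:
            return True
    return False


def extract_reads(cfg: ExtractionConfig, bp: BreakpointSpec,
                  exons: ExonTable) -> List[FastqRecord]:
    """Collect reads (and optionally their mates) near the breakpoint.

    Secondary/supplementary alignments are eligible for the distance test but
    each (name, mate) emits at most one record, primary preferred.  With
    dedupe_by_name off, the same read appearing in several sources is emitted
    once per source (mirroring chimeric+normal double counting); with it on,
    names are unique per mate index across sources.
    """
    exonic_raw: Dict[str, List[Interval]] = {}
    for partner in (bp.partner5, bp.partner3):
        ivs = exonic_raw.setdefault(partner.chrom, [])
        for direction, include in (("5prime", True), ("3prime", False),
                                   ("3prime", True), ("5prime", False)):
            ivs.extend(exonic_walk(exons, partner.chrom, partner.pos,
                                   direction, include, cfg.radius))
    exonic = {chrom: _merge_intervals(ivs) for chrom, ivs in exonic_raw.items()}

    all_records: List[FastqRecord] = []
    seen_global: set = set()
    for src in cfg.sources:
        if not os.path.exists(src):
            raise FileNotFoundError(f"BAM source not found: {src}")
        if not (os.path.exists(src + ".bai") or os.path.exists(src[:-4] + ".bai")):
            raise FileNotFoundError(f"index not found for {src}")
        picked: Dict[Tuple[str, Optional[int]], pysam.AlignedSegment] = {}
        wanted_names: set = set()
        with pysam.AlignmentFile(src, "rb") as bam:
            header_chroms = set(bam.references)
            for partner in (bp.partner5, bp.partner3):
                if partner.chrom not in header_chroms:
                    logger.warning("chromosome %s absent from %s header; "
                                   "partner skipped", partner.chrom, src)
                    continue
                fetch_ivs = _merge_intervals(
                    [(max(1, partner.pos - cfg.radius), partner.pos + cfg.radius)]
                    + exonic.get(partner.chrom, []))
                for s, e in fetch_ivs:
                    for rec in bam.fetch(partner.chrom, s - 1, e):
                        if not _matches(rec, bp, cfg.radius, exonic):
                            continue
                        key = (rec.query_name, _mate_index(rec))
                        prev = picked.get(key)
                        if prev is None or (prev.is_secondary or prev.is_supplementary):
                            if not (rec.is_secondary or rec.is_supplementary) or prev is None:
                                picked[key] = rec
                        wanted_names.add(rec.query_name)
            if cfg.include_mates and wanted_names:
                # second pass catches mates wherever (or whether) they aligned
                for rec in bam.fetch(until_eof=True):
                    if rec.query_name not in wanted_names:
                        continue
                    if rec.is_secondary or rec.is_supplementary:
                        continue
                    key = (rec.query_name, _mate_index(rec))
                    prev = picked.get(key)
                    if prev is None or prev.is_secondary or prev.is_supplementary:
                        picked[key] = rec
        for key in sorted(picked, key=lambda k: (k[0], k[1] or 0)):
            if cfg.dedupe_by_name:
                if key in seen_global:
                    continue
                seen_global.add(key)
            all_records.append(_to_fastq(picked[key]))
    all_records.sort(key=lambda r: (r.name, r.mate_index or 0))
    return all_records


def write_fastq(records: List[FastqRecord], out_prefix: str,
                paired: bool = False) -> List[str]:
    """One FASTQ for single-end; _1/_2 suffixed files for paired-end."""
    if not paired:
        path = f"{out_prefix}.fastq"
        with open(path, "w") as fh:
            for rec in records:
                fh.write(rec.format())
        return [path]
    paths = [f"{out_prefix}_1.fastq", f"{out_prefix}_2.fastq"]
    with open(paths[0], "w") as fh1, open(paths[1], "w") as fh2:
        for rec in records:
            (fh2 if rec.mate_index == 2 else fh1).write(rec.format())
    return paths


def write_region_bed(regions: Dict[str, List[Interval]], path: str) -> None:
    """Audit dump of the target regions (BED, 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(regions):
            for s, e in regions[chrom]:
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")
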