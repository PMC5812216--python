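"""Build left/right reference panels around a candidate fusion breakpoint.

A breakpoint is two genomic (coordinate, strand) pairs: the 5' partner
contributes the upstream portion of the putative chimeric transcript and the
3' partner the downstream portion.  For each partner and a search radius r,
four flanking sequences are assembled: a contiguous genomic flank and an
exon-walked ("exonic") flank on each side of the junction, giving the usual
8-reference panel (4 per side).  Conventions:

* Each partner's breakpoint base is included on the side matching its role:
  the 5' partner's base ends the left flank, the 3' partner's base starts the
  right flank.
* For a "-"-strand partner the genomic search directions swap and every
  retrieved sequence is reverse-complemented, so panel sequences always read
  in transcript orientation, left to right across the junction.
* Exonic flanks are built by walking exon fragments outward from the
  coordinate (starting at the nearest exon boundary when the start position is
  intronic) until the aggregate length reaches r, concatenating fragments in
  genomic order before any reverse complement.

Coordinates in this module and in all labels are 1-based inclusive; BED input
is converted on load.
"""
from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from ._seq import normalize, reverse_complement
from .alignment import Reference, ReferencePanel

logger = logging.getLogger("fusionlens")

Interval = Tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class Partner:
    chrom: str
    pos: int  # 1-based
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("breakpoint position must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class BreakpointSpec:
    partner5: Partner
    partner3: Partner
    radius: int = 200

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    def __str__(self) -> str:
        p5, p3 = self.partner5, self.partner3
        return f"{p5.chrom}:{p5.pos}:{p5.strand}>{p3.chrom}:{p3.pos}:{p3.strand}"


_BP_RE = re.compile(
    r"^([^:\s]+):(\d+):([+-])\s*(?:>|->|➔|➔)\s*([^:\s]+):(\d+):([+-])$"
)


def parse_breakpoint(text: str, radius: int = 200) -> BreakpointSpec:
    """Parse "chrom:pos:strand>chrom:pos:strand" (also accepts -> and arrows)."""
    m = _BP_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed breakpoint string {text!r}; "
                         "expected chrom:pos:strand>chrom:pos:strand")
    c5, p5, s5, c3, p3, s3 = m.groups()
    return BreakpointSpec(Partner(c5, int(p5), s5), Partner(c3, int(p3), s3), radius)


class ExonTable:
    """Per-chromosome merged exon intervals (1-based inclusive)."""

    def __init__(self, intervals: Dict[str, Sequence[Interval]]):
        self._starts: Dict[str, List[int]] = {}
        self._ends: Dict[str, List[int]] = {}
        for chrom, ivs in intervals.items():
            merged = self._merge(ivs)
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @staticmethod
    def _merge(ivs: Sequence[Interval]) -> List[Interval]:
        out: List[List[int]] = []
        for s, e in sorted(ivs):
            if s > e:
                raise ValueError(f"exon interval start {s} > end {e}")
            if out and s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]

    @classmethod
    def from_bed(cls, path: str) -> "ExonTable":
        """Load a BED file (0-based half-open; columns beyond 3 ignored)."""
        ivs: Dict[str, List[Interval]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                ivs.setdefault(chrom, []).append((start + 1, end))
        return cls(ivs)

    @classmethod
    def from_refflat(cls, path: str) -> "ExonTable":
        """Load a refFlat-style TSV (exonStarts/exonEnds comma lists, 0-based)."""
        ivs: Dict[str, List[Interval]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                chrom = parts[2]
                starts = [int(x) for x in parts[9].rstrip(",").split(",")]
                ends = [int(x) for x in parts[10].rstrip(",").split(",")]
                for s, e in zip(starts, ends):
                    ivs.setdefault(chrom, []).append((s + 1, e))
        return cls(ivs)

    def chroms(self) -> List[str]:
        return sorted(self._starts)

    def intervals(self, chrom: str) -> List[Interval]:
        return list(zip(self._starts.get(chrom, []), self._ends.get(chrom, [])))

    def is_empty(self) -> bool:
        return not any(self._starts.values())

    def exon_at(self, chrom: str, pos: int) -> Optional[Interval]:
        """The merged exon containing pos, if any."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        k = bisect.bisect_right(starts, pos) - 1
        if k >= 0 and self._ends[chrom][k] >= pos:
            return starts[k], self._ends[chrom][k]
        return None

    def next_exon(self, chrom: str, pos: int) -> Optional[Interval]:
        """First exon starting at or after pos."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        k = bisect.bisect_left(starts, pos)
        if k < len(starts):
            return starts[k], self._ends[chrom][k]
        return None

    def prev_exon(self, chrom: str, pos: int) -> Optional[Interval]:
        """Last exon ending at or before pos."""
        ends = self._ends.get(chrom)
        if not ends:
            return None
        k = bisect.bisect_right(ends, pos) - 1
        if k >= 0:
            return self._starts[chrom][k], ends[k]
        return None


class GenomeSource:
    """Substring retrieval from an indexed FASTA (1-based inclusive ranges)."""

    def __init__(self, fasta_path: str):
        self._fa = pysam.FastaFile(fasta_path)
        self.path = fasta_path

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._fa.references:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return self._fa.get_reference_length(chrom)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of chrom:start-end (1-based inclusive), truncated at contig
        ends with a warning."""
        length = self.chrom_length(chrom)
        lo, hi = max(start, 1), min(end, length)
        if lo != start or hi != end:
            logger.warning("range %s:%d-%d truncated to %d-%d at contig ends",
                           chrom, start, end, lo, hi)
        if hi < lo:
            return ""
        return normalize(self._fa.fetch(chrom, lo - 1, hi))

    def close(self) -> None:
        self._fa.close()

    def __enter__(self) -> "GenomeSource":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def genomic_flanks(genome: GenomeSource, chrom: str, pos: int, strand: str,
                   role: str, radius: int
                   ) -> Tuple[Tuple[str, Interval], Tuple[str, Interval]]:
    """Contiguous genomic flanks (left_seq, right_seq) with their genomic spans.

    role is "5prime_partner" or "3prime_partner"; the partner's breakpoint base
    lands on the side matching the role.  For "-" strand the search directions
    swap and both sequences are reverse-complemented.
    """
    if role not in ("5prime_partner", "3prime_partner"):
        raise ValueError(f"bad role {role!r}")
    r = radius
    if strand == "+":
        if role == "5prime_partner":
            left, right = (pos - r + 1, pos), (pos + 1, pos + r)
        else:
            left, right = (pos - r, pos - 1), (pos, pos + r - 1)
    else:
        if role == "5prime_partner":
            left, right = (pos, pos + r - 1), (pos - r, pos - 1)
        else:
            left, right = (pos + 1, pos + r), (pos - r + 1, pos)
    lseq = genome.fetch(chrom, *left)
    rseq = genome.fetch(chrom, *right)
    if strand == "-":
        lseq, rseq = reverse_complement(lseq), reverse_complement(rseq)
    return (lseq, left), (rseq, right)


def exonic_walk(exons: ExonTable, chrom: str, coord: int, direction: str,
                include_start: bool, radius: int) -> List[Interval]:
    """Accumulate exon sub-intervals outward from coord until radius bases.

    direction is genomic: "3prime" walks toward higher coordinates, "5prime"
    toward lower.  include_start keeps the coordinate base itself when it is
    exonic; an intronic start jumps to the nearest exon boundary in the search
    direction.  Fragments are returned in genomic order.  Returns fewer than
    radius bases (possibly none, with a warning) when exons are exhausted.
    """
    if direction not in ("3prime", "5prime"):
        raise ValueError(f"bad direction {direction!r}")
    step = 1 if direction == "3prime" else -1
    cur = coord if include_start else coord + step
    frags: List[Interval] = []
    remaining = radius
    while remaining > 0:
        exon = exons.exon_at(chrom, cur)
        if exon is None:
            exon = (exons.next_exon(chrom, cur) if step == 1
                    else exons.prev_exon(chrom, cur))
            if exon is None:
                break
            cur = exon[0] if step == 1 else exon[1]
        if step == 1:
            end = min(exon[1], cur + remaining - 1)
            frags.append((cur, end))
            remaining -= end - cur + 1
            cur = exon[1] + 1
        else:
            start = max(exon[0], cur - remaining + 1)
            frags.append((start, cur))
            remaining -= cur - start + 1
            cur = exon[0] - 1
    if not frags:
        logger.warning("no exonic sequence %s of %s:%d", direction, chrom, coord)
    elif remaining > 0:
        logger.warning("exonic walk %s of %s:%d exhausted after %d of %d bp",
                       direction, chrom, coord, radius - remaining, radius)
    return sorted(frags)


@dataclass
class Flank:
    sequence: str
    fragments: List[Interval] = field(default_factory=list)


def exonic_flanks(genome: GenomeSource, exons: ExonTable, chrom: str, pos: int,
                  strand: str, role: str, radius: int) -> Tuple[Flank, Flank]:
    """Exon-walked flanks (left, right) in transcript orientation.

    Fragments are fetched in genomic order, concatenated, then the whole flank
    is reverse-complemented for a "-"-strand partner.
    """
    if role not in ("5prime_partner", "3prime_partner"):
        raise ValueError(f"bad role {role!r}")
    include_left = role == "5prime_partner"
    if strand == "+":
        sides = (("5prime", include_left), ("3prime", not include_left))
    else:
        sides = (("3prime", include_left), ("5prime", not include_left))
    out: List[Flank] = []
    for direction, include in sides:
        frags = exonic_walk(exons, chrom, pos, direction, include, radius)
        seq = "".join(genome.fetch(chrom, s, e) for s, e in frags)
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(Flank(seq, frags))
    return out[0], out[1]


def _span_label(chrom: str, frags: Sequence[Interval], strand: str) -> str:
    spans = "+".join(f"{s}-{e}" for s, e in frags)
    return f"{chrom}:{spans}({strand})"


def build_reference_panel(genome: GenomeSource, exons: ExonTable,
                          bp: BreakpointSpec) -> ReferencePanel:
    """Assemble the panel: per partner, one genomic and one exonic reference on
    each side (8 references when every retrieval succeeds).

    Empty exonic retrievals are dropped with a warning, reducing the count.
    Identical genomic/exonic sequences are both kept.
    """
    # panel order: genomic references first (5p then 3p), then exonic (5p, 3p)
    left_genomic: List[Reference] = []
    left_exonic: List[Reference] = []
    right_genomic: List[Reference] = []
    right_exonic: List[Reference] = []
    for tag, partner, role in (("5p", bp.partner5, "5prime_partner"),
                               ("3p", bp.partner3, "3prime_partner")):
        (lseq, lspan), (rseq, rspan) = genomic_flanks(
            genome, partner.chrom, partner.pos, partner.strand, role, bp.radius)
        left_genomic.append(Reference(
            f"{tag}|genomic|{_span_label(partner.chrom, [lspan], partner.strand)}",
            "genomic", lseq))
        right_genomic.append(Reference(
            f"{tag}|genomic|{_span_label(partner.chrom, [rspan], partner.strand)}",
            "genomic", rseq))
        lfl, rfl = exonic_flanks(genome, exons, partner.chrom, partner.pos,
                                 partner.strand, role, bp.radius)
        for side_list, flank, side_name in ((left_exonic, lfl, "left"),
                                            (right_exonic, rfl, "right")):
            if flank.sequence:
                side_list.append(Reference(
                    f"{tag}|exonic|{_span_label(partner.chrom, flank.fragments, partner.strand)}",
                    "exonic", flank.sequence))
            else:
                logger.warning("dropping empty exonic %s reference for partner %s",
                               side_name, tag)
    panel = ReferencePanel(left_genomic + left_exonic, right_genomic + right_exonic)
    panel.validate()
    return panel


def _read_fasta(path: str) -> List[Tuple[str, str]]:
    records = []
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            records.append((rec.name, rec.sequence))
    return records


def load_custom_panel(left_fasta: str, right_fasta: str) -> ReferencePanel:
    """User-supplied panel: one FASTA per side; record IDs become labels.

    An optional "|genomic" / "|exonic" ID suffix sets the origin (default
    custom).  Duplicate IDs and empty files are errors.
    """
    def build(path: str, side: str) -> List[Reference]:
        records = _read_fasta(path)
        if not records:
            raise ValueError(f"no records in {side} reference FASTA {path}")
        refs = []
        for name, seq in records:
            origin = "custom"
            for suffix in ("genomic", "exonic"):
                if name.endswith(f"|{suffix}"):
                    origin = suffix
            refs.append(Reference(name, origin, seq))
        return refs

    panel = ReferencePanel(build(left_fasta, "left"), build(right_fasta, "right"))
    panel.validate()
    return panel


def write_panel_fasta(panel: ReferencePanel, left_path: str, right_path: str) -> None:
    for path, refs in ((left_path, panel.left_refs), (right_path, panel.right_refs)):
        with open(path, "w") as fh:
            for ref in refs:
                fh.write(f">{ref.label}\n{ref.sequence}\n")
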