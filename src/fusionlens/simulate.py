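"""Synthetic fusion locus generator: the package's self-contained test bed.

Emulates, at toy scale, the situations the realigner is built to expose:

* a true fusion joining two loci, with junction-crossing reads whose anchors
  are uniformly distributed over the read;
* normal (non-fused) transcript reads from both partners, drawn strictly on
  one side of each partner's coordinate, so they realign to a single panel
  reference;
* unspliced genomic reads near the junction;
* a homology decoy: the junction-proximal terminus of the 3' partner's left
  flank is made identical to that of the 5' partner's left flank, so reads
  from the *normal* 3'-partner locus that cross its coordinate with a short
  anchor realign across the junction into the wrong partner -- the
  "nonsense alignment" signature of homology-driven false positives.

Everything is seeded: a fixed seed fixes the full output byte stream.  BAM
output mimics a chimeric-capable aligner: non-fusion reads go to a "normal"
file (spliced alignments use N gaps), fusion reads to a "chimeric" file as a
soft-clipped primary plus a supplementary record on the partner chromosome.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from ._seq import reverse_complement
from .extraction import FastqRecord, write_fastq
from .references import (BreakpointSpec, ExonTable, GenomeSource, Partner,
                         exonic_walk)

logger = logging.getLogger("fusionlens")

READ_CLASSES = ("fusion", "normal5", "normal3", "genomic_unspliced",
                "homology_decoy")


@dataclass
class SimulationConfig:
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chrA": 8000, "chrB": 8000})
    chrom5: str = "chrA"
    pos5: int = 4000
    strand5: str = "+"
    chrom3: str = "chrB"
    pos3: int = 4000
    strand3: str = "+"
    radius: int = 200
    read_length: int = 75
    counts: Dict[str, int] = field(default_factory=lambda: {
        "fusion": 30, "normal5": 24, "normal3": 24,
        "genomic_unspliced": 12, "homology_decoy": 8})
    error_rate: float = 0.0
    paired: bool = False
    insert_mean: float = 160.0
    insert_sd: float = 15.0
    homology_k: int = 10
    exons: Optional[Dict[str, List[Tuple[int, int]]]] = None  # override layout
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("read counts must be >= 0")
        unknown = set(self.counts) - set(READ_CLASSES)
        if unknown:
            raise ValueError(f"unknown read classes {sorted(unknown)}")
        if self.read_length < 2:
            raise ValueError("read length must be >= 2")
        if self.read_length > self.radius:
            raise ValueError("read length must not exceed the search radius")
        if self.paired and self.insert_mean + 2 * self.insert_sd > self.radius:
            raise ValueError("infeasible insert size: mean + 2*sd exceeds the "
                             "search radius (one-sided transcripts are that long)")

    @property
    def breakpoint(self) -> BreakpointSpec:
        return BreakpointSpec(Partner(self.chrom5, self.pos5, self.strand5),
                              Partner(self.chrom3, self.pos3, self.strand3),
                              self.radius)

    def default_exons(self) -> Dict[str, List[Tuple[int, int]]]:
        """Exon layout relative to the breakpoint coordinates.

        The 5' partner has one long exon ending at its coordinate (so exonic
        and genomic left flanks coincide) and a fragmented downstream side;
        the 3' partner mirrors this: fragmented upstream, and a fragmented
        spliced run starting at its coordinate.
        """
        if self.exons is not None:
            return self.exons
        p5, p3 = self.pos5, self.pos3
        layout: Dict[str, List[Tuple[int, int]]] = {}
        layout.setdefault(self.chrom5, []).extend(
            [(p5 - 599, p5), (p5 + 31, p5 + 100),
             (p5 + 201, p5 + 270), (p5 + 401, p5 + 470)])
        layout.setdefault(self.chrom3, []).extend(
            [(p3 - 500, p3 - 301), (p3 - 270, p3 - 201), (p3 - 150, p3 - 81),
             (p3, p3 + 69), (p3 + 100, p3 + 169), (p3 + 200, p3 + 299)])
        return layout


class _Transcript:
    """Concatenation of genomic fragments with a transcript->genome map."""

    def __init__(self, name: str, frags: Sequence[Tuple[str, int, int]],
                 genome: GenomeSource, junction: Optional[int] = None):
        self.name = name
        self.frags = list(frags)  # (chrom, gstart, gend) 1-based inclusive
        self.seq = "".join(genome.fetch(c, s, e) for c, s, e in self.frags)
        # transcript offset at which the breakpoint falls, if any: a read
        # covering [t, t+L) crosses iff t < junction < t+L
        self.junction = junction

    def __len__(self) -> int:
        return len(self.seq)

    def blocks(self, tstart: int, length: int) -> List[Tuple[str, int, int]]:
        """Genomic blocks (chrom, gstart, gend) covered by transcript
        interval [tstart, tstart+length) (0-based transcript coords)."""
        out = []
        offset = 0
        lo, hi = tstart, tstart + length
        for chrom, s, e in self.frags:
            flen = e - s + 1
            a, b = max(lo, offset), min(hi, offset + flen)
            if a < b:
                out.append((chrom, s + (a - offset), s + (b - offset) - 1))
            offset += flen
        return out


@dataclass
class SimRead:
    name: str
    label: str
    sequence: str          # as sequenced (errors applied, orientation applied)
    mate_index: Optional[int]
    transcript: _Transcript
    tstart: int
    is_reverse: bool       # sequenced from the transcript's reverse strand
    crosses_junction: bool


@dataclass
class SimulatedLocus:
    config: SimulationConfig
    breakpoint: BreakpointSpec
    exons: ExonTable
    truth: pd.DataFrame
    paths: Dict[str, str]


def _random_genome(cfg: SimulationConfig, rng: np.random.Generator) -> Dict[str, str]:
    bases = np.array(list("ACGT"))
    genome = {}
    for chrom in sorted(cfg.chrom_lengths):
        n = cfg.chrom_lengths[chrom]
        genome[chrom] = "".join(bases[rng.integers(0, 4, size=n)])
    # plant the homology decoy: the k bases just 5' of the 3'-partner coordinate
    # repeat the 5' partner's junction-proximal terminus
    k = cfg.homology_k
    seqA = genome[cfg.chrom5]
    kmer = seqA[cfg.pos5 - k:cfg.pos5]
    seqB = genome[cfg.chrom3]
    genome[cfg.chrom3] = seqB[:cfg.pos3 - k - 1] + kmer + seqB[cfg.pos3 - 1:]
    return genome


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return seq
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGTN"}
    others["N"] = list("ACGT")
    for idx in np.nonzero(hit)[0]:
        arr[idx] = others.get(arr[idx], list("ACGT"))[rng.integers(0, 3)]
    return "".join(arr)


def _sample_reads(cfg: SimulationConfig, transcripts: Dict[str, _Transcript],
                  rng: np.random.Generator) -> List[SimRead]:
    L = cfg.read_length
    reads: List[SimRead] = []

    def crosses(tr: _Transcript, start: int) -> bool:
        return tr.junction is not None and start < tr.junction < start + L

    def emit(label: str, idx: int, tr: _Transcript, tstart: int) -> None:
        name = f"{label}_{idx:04d}"
        if cfg.paired:
            flen = int(np.clip(round(rng.normal(cfg.insert_mean, cfg.insert_sd)),
                               L, len(tr) - tstart))
            frag = tr.seq[tstart:tstart + flen]
            m1, m2 = frag[:L], reverse_complement(frag[-L:])
            for mate, seq, start, rev in ((1, m1, tstart, False),
                                          (2, m2, tstart + flen - L, True)):
                seq = _apply_errors(seq, cfg.error_rate, rng)
                reads.append(SimRead(name, label, seq, mate, tr, start, rev,
                                     crosses(tr, start)))
        else:
            seq = _apply_errors(tr.seq[tstart:tstart + L], cfg.error_rate, rng)
            reads.append(SimRead(name, label, seq, None, tr, tstart, False,
                                 crosses(tr, tstart)))

    fusion_tx = transcripts["fusion_tx"]
    for idx in range(cfg.counts.get("fusion", 0)):
        # anchor length on the left of the junction, uniform over the read
        u = int(rng.integers(1, L))
        emit("fusion", idx, fusion_tx, fusion_tx.junction - u)

    for label, keys in (("normal5", ("normal5_left", "normal5_right")),
                        ("normal3", ("normal3_left", "normal3_right")),
                        ("genomic_unspliced", ("genomicA", "genomicB"))):
        n = cfg.counts.get(label, 0)
        for idx in range(n):
            tr = transcripts[keys[idx % 2]]
            tstart = int(rng.integers(0, len(tr) - L + 1))
            emit(label, idx, tr, tstart)

    k = cfg.homology_k
    for idx in range(cfg.counts.get("homology_decoy", 0)):
        # short left anchor inside the planted k-mer
        a = int(rng.integers(3, k + 1))
        # decoyB is unspliced chrB sequence centered on the 3' coordinate;
        # its junction sits at transcript offset radius
        emit("homology_decoy", idx, transcripts["decoyB"], cfg.radius - a)

    return reads


def _spliced_cigar(blocks: Sequence[Tuple[str, int, int]],
                   lead_clip: int, tail_clip: int) -> List[Tuple[int, int]]:
    """CIGAR tuples for same-chromosome ascending blocks with N gaps."""
    cig: List[Tuple[int, int]] = []
    if lead_clip:
        cig.append((4, lead_clip))
    prev_end = None
    for _, s, e in blocks:
        if prev_end is not None and s > prev_end + 1:
            cig.append((3, s - prev_end - 1))
        cig.append((0, e - s + 1))
        prev_end = e
    if tail_clip:
        cig.append((4, tail_clip))
    return cig


def _emit_bam_records(read: SimRead, header: pysam.AlignmentHeader,
                      chimeric: bool) -> List[Tuple[str, pysam.AlignedSegment]]:
    """STAR-like records: ("normal"|"chimeric", segment) for one read."""
    L = len(read.sequence)
    blocks = read.transcript.blocks(read.tstart, L)
    first_chrom = blocks[0][0]
    same = [b for b in blocks if b[0] == first_chrom]
    split_at = len(same)
    consumed = sum(e - s + 1 for _, s, e in same)
    seq_fwd = (reverse_complement(read.sequence) if read.is_reverse
               else read.sequence)

    def make(seg_blocks, lead, tail, supplementary=False) -> pysam.AlignedSegment:
        rec = pysam.AlignedSegment(header)
        rec.query_name = read.name
        rec.query_sequence = seq_fwd
        rec.query_qualities = pysam.qualitystring_to_array("I" * L)
        rec.reference_id = header.get_tid(seg_blocks[0][0])
        rec.reference_start = seg_blocks[0][1] - 1
        rec.cigartuples = _spliced_cigar(seg_blocks, lead, tail)
        rec.mapping_quality = 60
        rec.is_reverse = read.is_reverse
        rec.is_supplementary = supplementary
        if read.mate_index is not None:
            rec.is_paired = True
            rec.is_read1 = read.mate_index == 1
            rec.is_read2 = read.mate_index == 2
        return rec

    out = []
    if split_at == len(blocks):
        out.append(("chimeric" if chimeric else "normal",
                    make(blocks, 0, 0)))
    else:
        # junction-crossing read: SEQ is stored genome-forward, so the first
        # chromosome's bases open the stored sequence in both orientations
        rest = blocks[split_at:]
        tail = L - consumed
        out.append(("chimeric", make(same, 0, tail)))
        out.append(("chimeric", make(rest, consumed, 0, supplementary=True)))
    return out


def _fix_mate_info(records: Dict[str, List[pysam.AlignedSegment]]) -> None:
    for recs in records.values():
        primaries: Dict[Tuple[str, int], pysam.AlignedSegment] = {}
        for rec in recs:
            if rec.is_paired and not rec.is_supplementary:
                primaries[(rec.query_name, 1 if rec.is_read1 else 2)] = rec
        for rec in recs:
            if not rec.is_paired:
                continue
            other = primaries.get((rec.query_name, 2 if rec.is_read1 else 1))
            if other is not None:
                rec.next_reference_id = other.reference_id
                rec.next_reference_start = other.reference_start
                rec.mate_is_reverse = other.is_reverse
                rec.is_proper_pair = rec.reference_id == other.reference_id


def simulate_locus(cfg: SimulationConfig, out_dir: str) -> SimulatedLocus:
    """Generate genome FASTA (+.fai), exon BED, truth table, FASTQ and BAMs."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome_seqs = _random_genome(cfg, rng)

    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "exons": os.path.join(out_dir, "exons.bed"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "normal_bam": os.path.join(out_dir, "normal.bam"),
        "chimeric_bam": os.path.join(out_dir, "chimeric.bam"),
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(genome_seqs):
            fh.write(f">{chrom}\n")
            seq = genome_seqs[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    pysam.faidx(paths["genome"])

    exon_layout = cfg.default_exons()
    with open(paths["exons"], "w") as fh:
        for chrom in sorted(exon_layout):
            for s, e in sorted(exon_layout[chrom]):
                fh.write(f"{chrom}\t{s - 1}\t{e}\texon\t0\t+\n")
    exons = ExonTable(exon_layout)

    bp = cfg.breakpoint
    genome = GenomeSource(paths["genome"])
    r = cfg.radius

    def walk_frags(chrom: str, pos: int, direction: str, include: bool):
        return [(chrom, s, e)
                for s, e in exonic_walk(exons, chrom, pos, direction, include, r)]

    left5 = walk_frags(cfg.chrom5, cfg.pos5, "5prime", True)
    right5 = walk_frags(cfg.chrom5, cfg.pos5, "3prime", False)
    left3 = walk_frags(cfg.chrom3, cfg.pos3, "5prime", False)
    right3 = walk_frags(cfg.chrom3, cfg.pos3, "3prime", True)

    junction_t = sum(e - s + 1 for _, s, e in left5)
    transcripts = {
        "fusion_tx": _Transcript("fusion_tx", left5 + right3, genome,
                                 junction=junction_t),
        "normal5_left": _Transcript("normal5_left", left5, genome),
        "normal5_right": _Transcript("normal5_right", right5, genome),
        "normal3_left": _Transcript("normal3_left", left3, genome),
        "normal3_right": _Transcript("normal3_right", right3, genome),
        "genomicA": _Transcript(
            "genomicA", [(cfg.chrom5, cfg.pos5 + 1, cfg.pos5 + r)], genome),
        "genomicB": _Transcript(
            "genomicB", [(cfg.chrom3, cfg.pos3 - r, cfg.pos3 - 1)], genome),
        "decoyB": _Transcript(
            "decoyB", [(cfg.chrom3, cfg.pos3 - r, cfg.pos3 + r - 1)], genome,
            junction=r),
    }

    reads = _sample_reads(cfg, transcripts, rng)

    fastq = [FastqRecord(rd.name, rd.mate_index, rd.sequence,
                         "I" * len(rd.sequence)) for rd in reads]
    fastq.sort(key=lambda rec: (rec.name, rec.mate_index or 0))
    fq_paths = write_fastq(fastq, os.path.join(out_dir, "reads"), cfg.paired)
    paths["fastq"] = fq_paths[0]
    if cfg.paired:
        paths["fastq_2"] = fq_paths[1]

    header = pysam.AlignmentHeader.from_references(
        list(sorted(genome_seqs)), [len(genome_seqs[c]) for c in sorted(genome_seqs)])
    by_file: Dict[str, List[pysam.AlignedSegment]] = {"normal": [], "chimeric": []}
    for rd in sorted(reads, key=lambda x: (x.name, x.mate_index or 0)):
        for dest, rec in _emit_bam_records(rd, header,
                                           chimeric=rd.label == "fusion"):
            by_file[dest].append(rec)
    _fix_mate_info(by_file)
    for dest, bam_key in (("normal", "normal_bam"), ("chimeric", "chimeric_bam")):
        tmp = paths[bam_key] + ".unsorted"
        with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
            for rec in by_file[dest]:
                bam.write(rec)
        pysam.sort("--no-PG", "-o", paths[bam_key], tmp)
        os.remove(tmp)
        pysam.index(paths[bam_key])

    truth = pd.DataFrame(
        [{"read": rd.name, "mate": rd.mate_index or 0, "label": rd.label,
          "transcript": rd.transcript.name, "tstart": rd.tstart,
          "crosses_junction": rd.crosses_junction,
          "strand": "-" if rd.is_reverse else "+"} for rd in reads]
    ).sort_values(["read", "mate"]).reset_index(drop=True)
    truth.to_csv(paths["truth"], sep="\t", index=False)

    genome.close()
    return SimulatedLocus(config=cfg, breakpoint=bp, exons=exons,
                          truth=truth, paths=paths)
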