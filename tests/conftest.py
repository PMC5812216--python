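import os
import random

import numpy as np
import pysam
import pytest

from fusionlens import (BreakpointSpec, ExonTable, Partner, Reference,
                        ReferencePanel, ScoringScheme)
from fusionlens.references import GenomeSource
from fusionlens.simulate import SimulationConfig, simulate_locus


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


class DictGenome:
    """In-memory stand-in for GenomeSource (same fetch contract)."""

    def __init__(self, seqs):
        self.seqs = {c: s.upper() for c, s in seqs.items()}

    def chrom_length(self, chrom):
        return len(self.seqs[chrom])

    def fetch(self, chrom, start, end):
        seq = self.seqs[chrom]
        lo, hi = max(start, 1), min(end, len(seq))
        if hi < lo:
            return ""
        return seq[lo - 1:hi]


@pytest.fixture
def dict_genome_cls():
    return DictGenome


def write_genome(path, seqs):
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            for i in range(0, len(seqs[chrom]), 80):
                fh.write(seqs[chrom][i:i + 80] + "\n")
    pysam.faidx(str(path))
    return str(path)


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    """Synthetic two-chromosome genome carrying the printed exon layout:
    breakpoint chr1:10,000:+ > chr2:20,000:-, radius 100, exons at
    chr1:9,801-10,000 / 10,031-10,100 / 10,201-10,270."""
    rng = random.Random(20180213)
    tmp = tmp_path_factory.mktemp("worked")
    seqs = {"chr1": random_seq(rng, 12000), "chr2": random_seq(rng, 22000)}
    fa = write_genome(tmp / "genome.fa", seqs)
    exons = ExonTable({"chr1": [(9801, 10000), (10031, 10100), (10201, 10270)],
                       "chr2": [(19801, 20100)]})
    bp = BreakpointSpec(Partner("chr1", 10000, "+"),
                        Partner("chr2", 20000, "-"), radius=100)
    return {"genome_path": fa, "seqs": seqs, "exons": exons, "bp": bp}


@pytest.fixture(scope="session")
def worked_genome(worked_example):
    gen = GenomeSource(worked_example["genome_path"])
    yield gen
    gen.close()


@pytest.fixture(scope="session")
def sim_locus(tmp_path_factory):
    """Default-condition simulated locus shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    return simulate_locus(SimulationConfig(seed=11), str(out))


def random_panel(rng, max_refs=3, max_len=10):
    """Random small panel for oracle comparisons (labels unique)."""
    L = rng.randint(1, max_refs)
    R = rng.randint(1, max_refs)
    left = [Reference(f"L{k}", "custom", random_seq(rng, rng.randint(1, max_len)))
            for k in range(L)]
    right = [Reference(f"R{k}", "custom", random_seq(rng, rng.randint(1, max_len)))
             for k in range(R)]
    return ReferencePanel(left, right)


def make_bam(path, references, records):
    """Build a sorted+indexed BAM from record dicts (1-based 'pos')."""
    header = pysam.AlignmentHeader.from_references(
        [r[0] for r in references], [r[1] for r in references])
    segs = []
    for rec in records:
        seg = pysam.AlignedSegment(header)
        seg.query_name = rec["name"]
        seg.query_sequence = rec["seq"]
        seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec["seq"]))
        if rec.get("unmapped"):
            seg.is_unmapped = True
        else:
            seg.reference_id = header.get_tid(rec["chrom"])
            seg.reference_start = rec["pos"] - 1
            seg.cigartuples = rec.get("cigar", [(0, len(rec["seq"]))])
            seg.mapping_quality = rec.get("mapq", 60)
        for flag in ("is_paired", "is_read1", "is_read2", "is_secondary",
                     "is_supplementary", "is_reverse"):
            if rec.get(flag):
                setattr(seg, flag, True)
        if rec.get("mate_unmapped"):
            seg.mate_is_unmapped = True
        segs.append(seg)
    tmp = str(path) + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for seg in segs:
            bam.write(seg)
    pysam.sort("--no-PG", "-o", str(path), tmp)
    os.remove(tmp)
    pysam.index(str(path))
    return str(path)
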