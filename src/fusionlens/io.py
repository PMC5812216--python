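"""FASTQ input and alignment-result (de)serialization."""
from __future__ import annotations

import json
import re
from typing import List, Optional, Sequence

import pysam

from .alignment import AlignmentResult, ReadSequence

_MATE_SUFFIX = re.compile(r"[/_]([12])$")


def _split_mate(name: str) -> tuple:
    m = _MATE_SUFFIX.search(name)
    if m:
        return name[:m.start()], int(m.group(1))
    return name, None


def read_fastq(paths: Sequence[str]) -> List[ReadSequence]:
    """Load reads from one (single-end) or two (paired _1/_2) FASTQ files.

    Gzip is handled transparently; qualities are ignored by the aligner.
    Mate indices come from the file position for two files, else from a
    trailing /1 /2 (or _1 _2) suffix on the read name.
    """
    if not 1 <= len(paths) <= 2:
        raise ValueError("expected one or two FASTQ files")
    reads: List[ReadSequence] = []
    for file_idx, path in enumerate(paths, 1):
        with pysam.FastxFile(path) as fh:
            for rec in fh:
                name, mate = _split_mate(rec.name)
                if len(paths) == 2:
                    mate = file_idx
                reads.append(ReadSequence(name, rec.sequence, mate_index=mate))
    return reads


def load_results_json(path: str) -> List[AlignmentResult]:
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for d in data:
        d = dict(d)
        d["path"] = [tuple(step) for step in d.get("path", [])]
        out.append(AlignmentResult(**d))
    return out
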