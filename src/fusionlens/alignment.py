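"""Fanned multi-reference Smith-Waterman alignment across a fusion breakpoint.

A candidate fusion junction is evaluated by realigning each read against an
arbitrary panel of 5' ("left") and 3' ("right") reference sequences that all
meet at a single shared breakpoint column.  One score matrix is filled per
reference; the left-side matrices converge into the breakpoint column (their
final reference column is withheld and replaced by it), and every right-side
matrix is seeded from that column, so a single backtrack can start in any
right reference, cross the junction, and finish in any left reference.  This
yields, per read, the most parsimonious explanation among "purely partner 1",
"purely partner 2", or "chimeric", in one pass.

Two modes are supported:

* ``local`` -- classic Smith-Waterman semantics: matrix entries floored at 0,
  backtrack from the global maximum until a zero entry.
* ``semiglobal`` -- every read base is traced: read ends are penalized
  (column 0 of the left matrices is ``i * W``), entries may go negative, the
  backtrack starts on the bottom row and terminates only on the top row.

The per-read alignment score is ``alpha = 100 * H_start / m`` where ``m`` is
the read length, so a read matching perfectly anywhere along the panel (with
unit match score) scores exactly 100.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._seq import encode, normalize, reverse_complement

GAP = "-"

#: recognised alignment modes
MODES = ("local", "semiglobal")

# origin tags a reference may carry
ORIGINS = ("genomic", "exonic", "custom")


@dataclass(frozen=True)
class ScoringScheme:
    """Unit similarity/gap scheme: sigma(a,b) = match if a == b else mismatch.

    N (or any non-ACGT symbol) mismatches everything, including another N.
    """

    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -1

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_score >= 0:
            raise ValueError("mismatch_score must be negative")
        if self.gap_score >= 0:
            raise ValueError("gap_score must be negative")

    def sigma(self, a: str, b: str) -> int:
        if a == b and a in "ACGT":
            return self.match_score
        return self.mismatch_score


@dataclass
class ReadSequence:
    """A sequencing read; bases are normalized to uppercase A/C/G/T/N."""

    name: str
    bases: str
    mate_index: Optional[int] = None  # 1, 2 or None for single-end
    orientation_used: str = "forward"

    def __post_init__(self) -> None:
        self.bases = normalize(self.bases)
        if self.mate_index not in (None, 1, 2):
            raise ValueError("mate_index must be 1, 2 or None")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Reference:
    label: str
    origin: str
    sequence: str

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown reference origin {self.origin!r}")
        object.__setattr__(self, "sequence", normalize(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferencePanel:
    """Ordered left-side (5') and right-side (3') references for one junction."""

    left_refs: List[Reference]
    right_refs: List[Reference]

    @property
    def L(self) -> int:
        return len(self.left_refs)

    @property
    def R(self) -> int:
        return len(self.right_refs)

    def validate(self) -> None:
        if self.L < 1 or self.R < 1:
            raise ValueError("panel needs at least one reference per side")
        labels = [r.label for r in self.left_refs + self.right_refs]
        seen = set()
        for lab in labels:
            if lab in seen:
                raise ValueError(f"duplicate reference label {lab!r}")
            seen.add(lab)
        for ref in self.left_refs + self.right_refs:
            if len(ref) < 1:
                raise ValueError(f"reference {ref.label!r} is empty")


@dataclass
class FannedMatrices:
    """Score matrices for one read orientation against one panel.

    ``left[f]`` has columns 0..n_f-1 (the reference's final column is withheld;
    the breakpoint column stands in for it).  ``right[f]`` has columns 0..n_f
    with column 0 a copy of the breakpoint column.
    """

    mode: str
    read: str  # oriented read bases
    left: List[np.ndarray]
    bkpt: np.ndarray
    right: List[np.ndarray]


@dataclass
class AlignmentResult:
    name: str = ""
    aligned_read: str = ""
    aligned_ref: str = ""
    score_raw: int = 0
    alpha: float = 0.0
    left_ref_index: Optional[int] = None   # 0-based into panel.left_refs
    right_ref_index: Optional[int] = None  # 0-based into panel.right_refs
    left_ref_label: Optional[str] = None
    right_ref_label: Optional[str] = None
    spanning: bool = False
    strand: str = "+"
    mode: str = "local"
    mate_index: Optional[int] = None
    read_length: int = 0
    # 1-based positions of the consumed read bases in the *oriented* read
    read_start: int = 0
    read_end: int = 0
    # 1-based positions within the chosen reference on each side
    left_ref_start: int = 0
    left_ref_end: int = 0
    right_ref_start: int = 0
    right_ref_end: int = 0
    # per alignment column: 'L' left side, 'J' breakpoint gap column, 'R' right
    column_sides: str = ""
    # backtrack cursor trace: (i, j, f, side)
    path: List[Tuple[int, int, Optional[int], str]] = field(default_factory=list)

    def cigar(self) -> str:
        """Compressed op string: = match, X mismatch, I gap-in-ref, D gap-in-read."""
        ops = []
        for a, b in zip(self.aligned_read, self.aligned_ref):
            if a == GAP:
                op = "D"
            elif b == GAP:
                op = "I"
            elif a == b and a in "ACGT":
                op = "="
            else:
                op = "X"
            if ops and ops[-1][1] == op:
                ops[-1][0] += 1
            else:
                ops.append([1, op])
        return "".join(f"{n}{op}" for n, op in ops)

    @property
    def anchor_length(self) -> int:
        """Read bases on the shorter side of the junction (0 if not spanning)."""
        if not self.spanning:
            return 0
        left = sum(1 for a, s in zip(self.aligned_read, self.column_sides)
                   if a != GAP and s == "L")
        right = sum(1 for a, s in zip(self.aligned_read, self.column_sides)
                    if a != GAP and s == "R")
        return min(left, right)


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _fill_matrix(read_codes: np.ndarray, ref_codes: np.ndarray,
                 scheme: ScoringScheme, mode: str,
                 init_col: Optional[np.ndarray] = None) -> np.ndarray:
    """Fill one (m+1) x (n+1) score matrix row by row.

    Column 0 is the supplied ``init_col`` (breakpoint column for right-side
    matrices), else zeros in local mode or ``i * W`` in semiglobal mode.
    Row 0 is zero beyond column 0 in both modes.
    """
    m, n = len(read_codes), len(ref_codes)
    W = scheme.gap_score
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    if init_col is not None:
        H[:, 0] = init_col
    elif mode == "semiglobal":
        H[:, 0] = np.arange(m + 1, dtype=np.int64) * W
    if n == 0 or m == 0:
        return H
    # deletion chain within a row is a running max with linear decay W, which
    # np.maximum.accumulate evaluates after removing the decay ramp
    ramp = np.arange(n + 1, dtype=np.int64) * W
    local = mode == "local"
    match = scheme.match_score
    mismatch = scheme.mismatch_score
    for i in range(1, m + 1):
        c = read_codes[i - 1]
        sig = np.where((ref_codes == c) & (c < 4), match, mismatch)
        base = np.maximum(H[i - 1, :-1] + sig, H[i - 1, 1:] + W)
        if local:
            np.maximum(base, 0, out=base)
        d = np.concatenate(([H[i, 0]], base))
        H[i, 1:] = (np.maximum.accumulate(d - ramp) + ramp)[1:]
    return H


def fill_left_stack(read: ReadSequence, panel: ReferencePanel,
                    scheme: ScoringScheme, mode: str = "local") -> List[np.ndarray]:
    """Score each left-side matrix over reference columns 1..n_f-1 only.

    The final reference column is withheld: its base instead feeds the
    breakpoint column.  A length-1 reference yields just the initialized
    column 0.
    """
    _check_mode(mode)
    codes = encode(read.bases)
    return [_fill_matrix(codes, encode(ref.sequence[:-1]), scheme, mode)
            for ref in panel.left_refs]


def fill_breakpoint_column(read: ReadSequence, left_stack: Sequence[np.ndarray],
                           panel: ReferencePanel, scheme: ScoringScheme,
                           mode: str = "local") -> np.ndarray:
    """Converge all left matrices into the shared breakpoint column.

    H_bkpt(i) is the best over: a diagonal move out of any left matrix's
    penultimate column consuming that reference's last base, a deletion move
    out of the same column, or a gap-in-reference step down the column itself
    (plus the zero floor in local mode).
    """
    _check_mode(mode)
    codes = encode(read.bases)
    m = len(codes)
    W = scheme.gap_score
    last_cols = np.stack([H[:, -1] for H in left_stack])  # (L, m+1)
    last_codes = np.array([encode(ref.sequence[-1:])[0] for ref in panel.left_refs])
    bk = np.zeros(m + 1, dtype=np.int64)
    if m == 0:
        return bk
    # sig[f, i-1] = sigma(read[i], last base of left ref f)
    sig = np.where((last_codes[:, None] == codes[None, :]) & (codes[None, :] < 4),
                   scheme.match_score, scheme.mismatch_score)
    diag = (last_cols[:, :-1] + sig).max(axis=0)      # candidates for i = 1..m
    dele = (last_cols[:, 1:] + W).max(axis=0)
    base = np.maximum(diag, dele)
    if mode == "local":
        np.maximum(base, 0, out=base)
    d = np.concatenate(([0], base))
    ramp = np.arange(m + 1, dtype=np.int64) * W
    return np.maximum.accumulate(d - ramp) + ramp


def fill_right_stack(read: ReadSequence, panel: ReferencePanel,
                     bkpt: np.ndarray, scheme: ScoringScheme,
                     mode: str = "local") -> List[np.ndarray]:
    """Score each right-side matrix, fanning out from the breakpoint column."""
    _check_mode(mode)
    codes = encode(read.bases)
    return [_fill_matrix(codes, encode(ref.sequence), scheme, mode, init_col=bkpt)
            for ref in panel.right_refs]


def fill_fanned(read: ReadSequence, panel: ReferencePanel, scheme: ScoringScheme,
                mode: str = "local") -> FannedMatrices:
    left = fill_left_stack(read, panel, scheme, mode)
    bkpt = fill_breakpoint_column(read, left, panel, scheme, mode)
    right = fill_right_stack(read, panel, bkpt, scheme, mode)
    return FannedMatrices(mode=mode, read=read.bases, left=left, bkpt=bkpt, right=right)


def _start_max(mat: FannedMatrices) -> int:
    """Best attainable starting score for the mode (strand comparison key)."""
    if mat.mode == "local":
        vals = [int(mat.bkpt.max())]
        vals += [int(H.max()) for H in mat.left]
        vals += [int(H.max()) for H in mat.right]
        return max(vals)
    m = len(mat.read)
    vals = [int(mat.bkpt[m])]
    vals += [int(H[m, 1:].max()) for H in mat.left if H.shape[1] > 1]
    vals += [int(H[m, 1:].max()) for H in mat.right]
    return max(vals)


def choose_strand(read: ReadSequence, panel: ReferencePanel, scheme: ScoringScheme,
                  mode: str = "local") -> Tuple[ReadSequence, FannedMatrices, str]:
    """Score both read orientations fully; keep the one with the larger maximum.

    The forward orientation wins ties.  Reverse-complement selection is
    reported as strand "-".
    """
    fwd = fill_fanned(read, panel, scheme, mode)
    rc_read = ReadSequence(read.name, reverse_complement(read.bases),
                           mate_index=read.mate_index,
                           orientation_used="reverse_complement")
    rev = fill_fanned(rc_read, panel, scheme, mode)
    if _start_max(rev) > _start_max(fwd):
        return rc_read, rev, "-"
    return read, fwd, "+"


_SIDE_RANK = {"right": 0, "bkpt": 1, "left": 2}


def _argmax_largest_ij(H: np.ndarray, rows: slice, cols: slice) -> Tuple[int, int, int]:
    """(value, i, j) of the maximum in H[rows, cols]; largest i then j wins ties."""
    sub = H[rows, cols]
    v = int(sub.max())
    where = np.argwhere(sub == v)
    i, j = where[-1]  # argwhere is row-major sorted: last entry = largest (i, j)
    return v, int(i) + (rows.start or 0), int(j) + (cols.start or 0)


def _select_start(mat: FannedMatrices) -> Tuple[int, str, Optional[int], int, int]:
    """Pick (value, side, f, i, j) where the backtrack begins.

    Ties resolve by side preference right > breakpoint > left, then lowest f,
    then largest i, then largest j.
    """
    m = len(mat.read)
    cands = []  # (-value, side_rank, f, -i, -j)
    if mat.mode == "local":
        for f, H in enumerate(mat.right):
            v, i, j = _argmax_largest_ij(H, slice(1, None), slice(1, None))
            cands.append((-v, _SIDE_RANK["right"], f, -i, -j, "right"))
        i = int(np.argwhere(mat.bkpt[1:] == mat.bkpt[1:].max())[-1][0]) + 1 if m else 0
        if m:
            cands.append((-int(mat.bkpt[i]), _SIDE_RANK["bkpt"], 0, -i, 0, "bkpt"))
        for f, H in enumerate(mat.left):
            if H.shape[1] > 1 and m:
                v, i, j = _argmax_largest_ij(H, slice(1, None), slice(1, None))
                cands.append((-v, _SIDE_RANK["left"], f, -i, -j, "left"))
    else:
        for f, H in enumerate(mat.right):
            row = H[m, 1:]
            j = int(np.argwhere(row == row.max())[-1][0]) + 1
            cands.append((-int(row.max()), _SIDE_RANK["right"], f, -m, -j, "right"))
        cands.append((-int(mat.bkpt[m]), _SIDE_RANK["bkpt"], 0, -m, 0, "bkpt"))
        for f, H in enumerate(mat.left):
            if H.shape[1] > 1:
                row = H[m, 1:]
                j = int(np.argwhere(row == row.max())[-1][0]) + 1
                cands.append((-int(row.max()), _SIDE_RANK["left"], f, -m, -j, "left"))
    nv, _rank, f, ni, nj, side = min(cands)
    return -nv, side, (f if side != "bkpt" else None), -ni, -nj


def backtrack(matrices: FannedMatrices, panel: ReferencePanel, read: ReadSequence,
              scheme: ScoringScheme, mode: str = "local") -> AlignmentResult:
    """Trace the best alignment back through the fanned matrices.

    Local mode: start at the global maximum and trace each score to the
    neighbor it was derived from, stopping at a cell whose (zero) value comes
    from the floor rather than any neighbor -- a zero cell with a valid
    derivation is traced through, which is what extends an alignment across a
    zero-scoring prefix.  Semiglobal mode: start on the bottom row, stop only
    on the top row, so all read bases are traced.  Move preference on ties:
    diagonal, then gap-in-read (left), then gap-in-reference (above); at the
    breakpoint column the left matrix and its last base are chosen jointly
    (lowest f on ties).
    """
    _check_mode(mode)
    if mode != matrices.mode:
        raise RuntimeError("inconsistent matrices: mode mismatch")
    bases = matrices.read
    m = len(bases)
    W = scheme.gap_score
    left_H, right_H, bk = matrices.left, matrices.right, matrices.bkpt

    res = AlignmentResult(name=read.name, mode=mode, mate_index=read.mate_index,
                          read_length=m)
    if m == 0:
        return res

    score, side, f, i, j = _select_start(matrices)
    if mode == "local" and score <= 0:
        return res  # nothing aligns: empty result, score 0

    res.score_raw = score
    res.alpha = alignment_score(score, m)

    a_out: List[str] = []
    b_out: List[str] = []
    sides: List[str] = []
    path: List[Tuple[int, int, Optional[int], str]] = [(i, j, f, side)]
    read_lo, read_hi = m + 1, 0
    lref_lo, lref_hi, rref_lo, rref_hi = 0, 0, 0, 0
    left_used: Optional[int] = None
    right_used: Optional[int] = None

    def consume_read(idx: int) -> None:
        nonlocal read_lo, read_hi
        read_lo = min(read_lo, idx)
        read_hi = max(read_hi, idx)

    while True:
        if side == "right":
            H = right_H[f]
            ref = panel.right_refs[f].sequence
            v = int(H[i, j])
            if mode == "semiglobal" and i == 0:
                break
            if j == 0:
                side, f = "bkpt", None
                path.append((i, 0, None, side))
                continue
            if i >= 1 and v == H[i - 1, j - 1] + scheme.sigma(bases[i - 1], ref[j - 1]):
                a_out.append(bases[i - 1]); b_out.append(ref[j - 1]); sides.append("R")
                consume_read(i)
                rref_lo, rref_hi = j, (rref_hi or j)
                right_used = f
                i, j = i - 1, j - 1
            elif v == H[i, j - 1] + W:
                a_out.append(GAP); b_out.append(ref[j - 1]); sides.append("R")
                rref_lo, rref_hi = j, (rref_hi or j)
                right_used = f
                j -= 1
            elif i >= 1 and v == H[i - 1, j] + W:
                a_out.append(bases[i - 1]); b_out.append(GAP); sides.append("R")
                consume_read(i)
                right_used = f
                i -= 1
            elif mode == "local" and v == 0:
                break  # floor-derived zero: trace ends here
            else:
                raise RuntimeError("inconsistent matrices: no valid move (right)")
            path.append((i, j, f, side))
        elif side == "bkpt":
            v = int(bk[i])
            if mode == "semiglobal" and i == 0:
                break
            move = None
            if i >= 1:
                for ff, H in enumerate(left_H):
                    last = panel.left_refs[ff].sequence[-1]
                    if v == H[i - 1, H.shape[1] - 1] + scheme.sigma(bases[i - 1], last):
                        move = ("diag", ff)
                        break
            if move is None:
                for ff, H in enumerate(left_H):
                    if v == H[i, H.shape[1] - 1] + W:
                        move = ("left", ff)
                        break
            if move is None and i >= 1 and v == int(bk[i - 1]) + W:
                move = ("above", None)
            if move is None:
                if mode == "local" and v == 0:
                    break  # floor-derived zero
                raise RuntimeError("inconsistent matrices: no valid move (bkpt)")
            kind, ff = move
            if kind == "diag":
                n_f = len(panel.left_refs[ff])
                a_out.append(bases[i - 1])
                b_out.append(panel.left_refs[ff].sequence[-1])
                sides.append("L")
                consume_read(i)
                left_used = ff
                lref_lo, lref_hi = n_f, n_f
                side, f, i, j = "left", ff, i - 1, left_H[ff].shape[1] - 1
            elif kind == "left":
                n_f = len(panel.left_refs[ff])
                a_out.append(GAP)
                b_out.append(panel.left_refs[ff].sequence[-1])
                sides.append("L")
                left_used = ff
                lref_lo, lref_hi = n_f, n_f
                side, f, j = "left", ff, left_H[ff].shape[1] - 1
            else:
                a_out.append(bases[i - 1]); b_out.append(GAP); sides.append("J")
                consume_read(i)
                i -= 1
            path.append((i, j if side == "left" else 0, f, side))
        else:  # left
            H = left_H[f]
            ref = panel.left_refs[f].sequence
            v = int(H[i, j])
            if mode == "semiglobal" and i == 0:
                break
            if (j >= 1 and i >= 1
                    and v == H[i - 1, j - 1] + scheme.sigma(bases[i - 1], ref[j - 1])):
                a_out.append(bases[i - 1]); b_out.append(ref[j - 1]); sides.append("L")
                consume_read(i)
                lref_lo, lref_hi = j, (lref_hi or j)
                left_used = f
                i, j = i - 1, j - 1
            elif j >= 1 and v == H[i, j - 1] + W:
                a_out.append(GAP); b_out.append(ref[j - 1]); sides.append("L")
                lref_lo, lref_hi = j, (lref_hi or j)
                left_used = f
                j -= 1
            elif i >= 1 and v == H[i - 1, j] + W:
                a_out.append(bases[i - 1]); b_out.append(GAP); sides.append("L")
                consume_read(i)
                left_used = f
                i -= 1
            elif mode == "local" and v == 0:
                break  # floor-derived zero
            else:
                raise RuntimeError("inconsistent matrices: no valid move (left)")
            path.append((i, j, f, side))

    res.aligned_read = "".join(reversed(a_out))
    res.aligned_ref = "".join(reversed(b_out))
    res.column_sides = "".join(reversed(sides))
    res.path = path
    if read_hi:
        res.read_start, res.read_end = read_lo, read_hi
    # a side counts only when it consumed at least one read base there; under
    # this scheme a pure-deletion excursion into a side cannot terminate the
    # trace, so "used" implies a consumed base (see methods note)
    left_bases = sum(1 for a, s in zip(res.aligned_read, res.column_sides)
                     if a != GAP and s == "L")
    right_bases = sum(1 for a, s in zip(res.aligned_read, res.column_sides)
                      if a != GAP and s == "R")
    if left_used is not None and left_bases > 0:
        res.left_ref_index = left_used
        res.left_ref_label = panel.left_refs[left_used].label
        res.left_ref_start, res.left_ref_end = lref_lo, lref_hi
    if right_used is not None and right_bases > 0:
        res.right_ref_index = right_used
        res.right_ref_label = panel.right_refs[right_used].label
        res.right_ref_start, res.right_ref_end = rref_lo, rref_hi
    res.spanning = res.left_ref_index is not None and res.right_ref_index is not None
    return res


def alignment_score(score_raw: int, read_length: int) -> float:
    """alpha = 100 * H_start / m.  In local mode this lies in [0, 100]."""
    if read_length == 0:
        raise ValueError("cannot score empty read")
    return score_raw / read_length * 100.0


def align_read(read: ReadSequence, panel: ReferencePanel, scheme: ScoringScheme,
               mode: str = "local") -> AlignmentResult:
    """Full per-read pipeline: strand choice, fanned fill, backtrack, score."""
    _check_mode(mode)
    panel.validate()
    if len(read) == 0:
        return AlignmentResult(name=read.name, mode=mode, mate_index=read.mate_index)
    oriented, matrices, strand = choose_strand(read, panel, scheme, mode)
    res = backtrack(matrices, panel, oriented, scheme, mode)
    res.strand = strand
    res.name = read.name
    return res


def classic_sw_align(read: ReadSequence, reference: str,
                     scheme: ScoringScheme) -> AlignmentResult:
    """Traditional single-reference Smith-Waterman local alignment.

    Backtrack starts at the maximum matrix element (largest i, then j on ties)
    and traces each score to its deriving neighbor, ending at a cell whose
    zero comes from the floor; move preference diagonal, gap-in-read,
    gap-in-reference.
    """
    if not reference:
        raise ValueError("empty reference")
    ref = normalize(reference)
    bases = read.bases
    m = len(bases)
    res = AlignmentResult(name=read.name, mode="local", mate_index=read.mate_index,
                          read_length=m)
    if m == 0:
        return res
    H = _fill_matrix(encode(bases), encode(ref), scheme, "local")
    v, i, j = _argmax_largest_ij(H, slice(1, None), slice(1, None))
    if v <= 0:
        return res
    res.score_raw = v
    res.alpha = alignment_score(v, m)
    W = scheme.gap_score
    a_out: List[str] = []
    b_out: List[str] = []
    path = [(i, j, 0, "right")]
    read_lo, read_hi = m + 1, 0
    ref_lo = ref_hi = j
    while True:
        cur = int(H[i, j])
        if i >= 1 and j >= 1 and cur == H[i - 1, j - 1] + scheme.sigma(bases[i - 1], ref[j - 1]):
            a_out.append(bases[i - 1]); b_out.append(ref[j - 1])
            read_lo, read_hi = min(read_lo, i), max(read_hi, i)
            ref_lo = j
            i, j = i - 1, j - 1
        elif j >= 1 and cur == H[i, j - 1] + W:
            a_out.append(GAP); b_out.append(ref[j - 1])
            ref_lo = j
            j -= 1
        elif i >= 1 and cur == H[i - 1, j] + W:
            a_out.append(bases[i - 1]); b_out.append(GAP)
            read_lo, read_hi = min(read_lo, i), max(read_hi, i)
            i -= 1
        elif cur == 0:
            break  # floor-derived zero: trace ends here
        else:
            raise RuntimeError("inconsistent matrix")
        path.append((i, j, 0, "right"))
    res.aligned_read = "".join(reversed(a_out))
    res.aligned_ref = "".join(reversed(b_out))
    res.column_sides = "R" * len(res.aligned_read)
    res.path = path
    res.read_start, res.read_end = read_lo, read_hi
    res.right_ref_start, res.right_ref_end = ref_lo, ref_hi
    return res
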