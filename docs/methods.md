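# Methods

## Problem setting

A candidate fusion breakpoint is two genomic (coordinate, strand) pairs: the
5′ partner contributes the upstream part of a putative chimeric transcript,
the 3′ partner the downstream part. Reads sampled near such a junction can
originate from the chimeric transcript, from either partner's normal
transcript (spliced), or from unspliced pre-mRNA. The package realigns each
read against all of these hypotheses simultaneously and reports, per read,
the winning explanation, an alignment score, and whether the alignment
crosses the junction.

## Reference retrieval

For each partner and search radius `r` (default 200 bp, a sensible span for
short-read RNA-seq), four flanks are assembled — genomic (contiguous) and
exonic (spliced) on each side of the junction — giving an 8-reference panel
when annotation covers both partners. Conventions:

* Coordinates are 1-based inclusive everywhere a user sees them; BED input
  (0-based half-open) is converted on load. Internal arithmetic converts at
  the boundary.
* The partner's breakpoint base is included on the side matching its role:
  the 5′ partner's base ends the left flank, the 3′ partner's base starts the
  right flank. For a `+`-strand partner at `pos` with the 5′ role this gives
  left `[pos−r+1, pos]` and right `[pos+1, pos+r]`.
* For a `−`-strand partner the genomic search directions swap and each
  retrieved sequence is reverse-complemented, so panel sequences always read
  in transcript orientation, left to right across the junction.
* The exonic walk accumulates exon fragments outward from the coordinate
  until `r` bases are collected. A start position inside an exon begins
  there (honoring the inclusion convention above); an intronic start jumps to
  the nearest exon boundary in the search direction, in which case the
  "include the breakpoint base" convention is moot because the base is not
  exonic. Fragments are concatenated in genomic order before any reverse
  complement. Exhausting the annotation yields a shorter flank (with a
  warning); no exonic sequence at all drops that reference from the panel.
* Overlapping (and bookended) exon intervals are merged into a flat set
  before walking; isoform identity is not tracked. Exons of unrelated
  overlapping genes are therefore walked through as if they were one locus —
  a deliberate simplification.
* Identical genomic and exonic flanks (coordinate deep inside one long exon)
  are both kept, with distinct labels.
* Retrieval is fully local: an indexed FASTA plus a BED or refFlat exon
  table. Ranges running off a contig are truncated with a warning. Users may
  instead supply their own left/right FASTA panels (any counts, any
  organism); an optional `|genomic` / `|exonic` ID suffix sets the origin
  tag used for coloring.

## Scoring

The similarity function is unit match/mismatch, `σ(a,b) = +1` if `a == b`
else `−1`, with linear gap penalty `W = −1`. `N` — and any symbol outside
`ACGT`, which ingestion normalizes to `N` — mismatches everything, including
another `N`; this is the conservative reading of a two-case similarity
function. Scores are kept as integers; the per-read score
`α = 100·H_start/m` is an exact rational, rounded to two decimals only for
presentation.

Each reference keeps its own length `n_f`; the breakpoint column draws on
each left matrix's own penultimate column and own last base, which is what
lets panels mix references of unequal length. A length-1 left reference has
only its initialized column and contributes solely through the breakpoint
column. The breakpoint column's gap-in-reference move references only the
column itself (`H_bkpt(i−1) + W`), never re-enters a left matrix vertically.

Two modes:

* **local** — entries floored at zero; `α ∈ [0, 100]`, and `α = 100` exactly
  when the read matches gaplessly somewhere along a left⊕right concatenation.
* **semiglobal** — the floor is removed, left matrices are initialized with
  `H(i,0) = i·W`, the backtrack starts on the bottom row (best of
  `H_left(m,·,·)`, `H_bkpt(m)`, `H_right(m,·,·)`) and terminates only on the
  top row, so all `m` read bases are traced. `α` can be negative and is
  reported as computed; a display layer may clamp it for plotting.

Both orientations of the read are scored in full; the larger mode-specific
maximum wins, ties go to the forward strand, and reverse-complement selection
is reported as strand `−`.

## Backtrack and tie-breaking

The backtrack starts at the global maximum (local mode), preferring — on
exact ties — the right stack over the breakpoint column over the left stack,
then the lowest reference index, then the largest row, then the largest
column. Within a cell, move preference is diagonal, then gap-in-read, then
gap-in-reference; at the breakpoint column the left matrix and its last base
are chosen jointly, lowest index first. Any fixed total order would do; this
one is documented so the test oracles can assume it. The trace follows each
score to the neighbor that produced it and stops at a cell whose zero value
comes from the floor rather than any neighbor; a zero cell *with* a valid
derivation is traced through, which extends alignments across zero-scoring
prefixes and is required to reproduce the canonical worked alignment
(`A-CGTGAT` / `ACCGTCAT`, whose first two columns score +1 −1).

A read is **spanning** when its trace consumes at least one read base on each
side of the breakpoint column. A base consumed by the column's diagonal move
is aligned to a left reference's last base and counts as the left side; a
base consumed by the column's gap-in-reference move sits at the junction and
counts for neither. The reported left/right reference indices are set only
when the corresponding side consumed a read base, so "spanning" and "both
indices set" coincide by construction. (Under this scoring scheme a
pure-deletion excursion into a side can never terminate the trace: backtrack
predecessors via gap moves always carry *higher* scores, so reaching a
floor-zero cell requires diagonal matches, which consume read bases.)

## Read extraction

From coordinate-sorted indexed BAMs, a read is kept when its alignment start
(leftmost mapped position, soft clips excluded — the BAM convention) is
within `r` of either partner coordinate, or when its alignment span
(including any splice gaps) overlaps an exon fragment reachable within
exonic distance `r`; span overlap was chosen over per-block overlap as the
simpler and more inclusive reading. Mates of kept reads are optionally
pulled in regardless of where or whether they aligned (a full second pass,
which also catches unmapped mates). Secondary and supplementary alignments
may satisfy the distance test, but each (name, mate) emits one FASTQ record,
primary preferred, in original read orientation. Reads present in several
sources (e.g. a chimeric aligner's normal + chimeric outputs) are emitted
once per source by default, mirroring the double-counting caveat of that
workflow; `dedupe_by_name` collapses them. Output is name-sorted, making
extraction deterministic and idempotent.

## Filtering and display

The score filter is inclusive (`α ≥ min_alpha`), so a threshold of 95 keeps
reads scoring exactly 95. In paired mode both mates must pass the score
threshold, and under the spanning filter a pair survives when at least one
mate spans. Filtering is monotone in the threshold.

Colors are assigned to sorted reference labels from a fixed colorblind-safe
palette (darkened shades on overflow), so the mapping follows labels, not
panel positions, and is stable across runs. Tracks are ordered spanning →
left-only → right-only, descending score within each group; mates share one
row joined by a connector. The x-axis is per-side base offsets from the
junction (left flanks end at 0, right flanks start at 0); read insertions
render as alignment columns without stretching the scale. The anchor length
reported for a spanning read is the smaller of its per-side consumed base
counts. Output is a standalone SVG, a single-file HTML report (embedded SVG
plus a table carrying the per-read metadata a click would reveal in an
interactive viewer), and TSV/JSON tables; all outputs are byte-stable for
identical inputs.

## Synthetic locus generator

The simulator emulates the read populations the tool is designed to
disentangle, at toy scale: two 8 kb chromosomes, breakpoint
`chrA:4000:+ > chrB:4000:+`, radius 200 bp, 75 bp reads. The 5′ partner has
one long exon ending at its coordinate and a fragmented downstream side; the
3′ partner mirrors this, so exonic flanks genuinely exercise the splice walk.
Read classes (defaults in parentheses):

* **fusion** (30) — junction-crossing reads from the chimeric transcript,
  anchor offsets uniform over the read;
* **normal5 / normal3** (24 each) — reads from each partner's normal spliced
  transcript, drawn strictly on one side of that partner's coordinate so
  each realigns within a single panel reference (reads crossing a partner's
  coordinate on its normal transcript would legitimately cross the breakpoint
  column and are the decoy class's job);
* **genomic_unspliced** (12) — contiguous genomic reads inside the flanks;
* **homology_decoy** (8) — the generator copies the 10 bases immediately 5′
  of the 3′ partner's coordinate from the 5′ partner's junction-proximal
  terminus, then draws reads from the *normal* 3′-partner locus crossing its
  coordinate with a 3-10 bp anchor. Those anchors match both partners' left
  flanks equally, and the deterministic tie-break sends them into the 5′
  partner — reproducing the cross-terminus "nonsense alignment" signature by
  which homology-driven false positives betray themselves.

The default error rate is 0 (per-base substitutions are available up to
50%), single-end by default with a paired mode (insert 160 ± 15 bp,
validated against the flank length). A fixed seed fixes every output byte.
BAMs mimic a chimeric-capable aligner: non-fusion reads in a "normal" file
with spliced `N` CIGARs, fusion reads in a "chimeric" file as a soft-clipped
primary plus a supplementary record on the partner chromosome. What passing
tests on this generator do *not* show: real base-quality structure, indel
sequencing errors, coverage biases, alternative isoforms, or reads from
repeats outside the planted homology.

## Numerical and interface choices

* Matrix fill is exact integer dynamic programming (numpy rows; the
  within-row deletion chain is a running maximum evaluated by removing the
  linear gap ramp, an identity for linear penalties).
* Empty read → empty alignment with raw score 0; scoring an empty read
  through `alignment_score` is an error. Empty references are rejected.
* The CLI maps outcomes to exit codes 0 (ok), 1 (usage), 2 (missing input,
  including a missing `.fai` index), 3 (internal). A YAML `--config` file
  sets options by long name and takes precedence over flags.
* Simulation and acceptance sizes (8 kb chromosomes, ~100 reads, 500-instance
  oracle sweeps) were chosen so the whole suite exercises every code path in
  seconds while keeping every check exact.

## Known limitations

Linear gap penalties only (no affine gaps); nucleotide alphabets only; no
banded or SIMD acceleration; reference retrieval is annotation-flat (no
isoform awareness); CRAM input and live annotation services are out of scope.
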