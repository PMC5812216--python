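# fusionlens

Visual evaluation of candidate gene fusions from RNA-seq data. Fusion
detectors frequently disagree with each other and report false positives
driven by sequence homology or read-throughs; when a detector reports a
breakpoint, the question "do the reads really support a chimeric transcript
here?" is best answered by realigning every read near the junction and
looking at the evidence. `fusionlens` does exactly that: given a candidate
breakpoint (two genomic coordinate+strand pairs), it gathers flanking
reference sequences, pulls nearby reads out of BAM files, realigns each read
with a fanned multi-reference Smith-Waterman variant, and renders a
color-coded evidence plot in which junction-crossing reads show two colors
meeting at the breakpoint guide.

It is aimed at researchers triaging fusion candidates from any detector
before committing to wet-lab validation.

## The fanned alignment

A read near a fusion point may come from the chimeric transcript, from either
partner's normal transcript, or from unspliced pre-mRNA — so it must be
allowed to start in any of `L` 5′ references and end in any of `R` 3′
references. Classic Smith-Waterman scores one matrix `H(i,j)` with similarity
`σ(a_i, b_j)` (+1 match, −1 mismatch) and linear gap penalty `W = −1`:

```
H(i,j) = max{ 0, H(i−1,j−1) + σ(a_i,b_j), H(i,j−1) + W, H(i−1,j) + W }
```

The fanned variant adds a third dimension: one matrix per reference
`H_s(i,j;f)`, with every left-side matrix converging into a shared
*breakpoint column* and every right-side matrix fanning out from it. Each
left matrix is scored over all but its final reference column; the breakpoint
column takes, per row, the best move out of any left matrix's penultimate
column using that reference's last base:

```
H_bkpt(i) = max{ 0,
                 max_f [ H_left(i−1, n_f−1; f) + σ(a_i, last_f) ],
                 max_f [ H_left(i,   n_f−1; f) + W ],
                 H_bkpt(i−1) + W }
```

and column 0 of every right matrix is a copy of `H_bkpt`. Both the read and
its reverse complement are scored; the orientation with the larger maximum
wins and sets the reported strand. The backtrack starts at the global maximum
(bottom row in semi-global mode, which forces every read base to be traced)
and may cross from a right matrix through the breakpoint column into
whichever left matrix explains the read best — that crossing is what marks a
read as *spanning*. Each read gets the score

```
α = 100 · H_start / m        (m = read length)
```

so a read matching perfectly anywhere along the panel scores exactly 100,
and every mismatch or gap costs points. Equivalently, the fanned maximum
equals the best classic Smith-Waterman score over all `L×R` concatenated
left+right references — computed in one pass instead of `L×R`.

## Worked example

```python
from fusionlens import (ReadSequence, Reference, ReferencePanel, ScoringScheme,
                        align_read)

panel = ReferencePanel(
    left_refs=[Reference("BCR-like|left", "custom", "GCTGAAGGTCATCGATGTAACCTTGAAT"),
               Reference("ABL1-like|left", "custom", "TTACCGGATTTCAGCCACAACTCGGTAC")],
    right_refs=[Reference("BCR-like|right", "custom", "CGGTTAGAACCTTGGATTCGCATTCAAG"),
                Reference("ABL1-like|right", "custom", "GGTCCATTGCAGACAATGCCTACGATCC")])

read = ReadSequence("candidate", "CATCGATGTAACCTTGAATGGTCCATTGCAGACA")
res = align_read(read, panel, ScoringScheme(), mode="local")
print(f"read={res.name} strand={res.strand} alpha={res.alpha:.1f} "
      f"spanning={res.spanning}")
print(f"left={res.left_ref_label} right={res.right_ref_label} "
      f"anchor={res.anchor_length}")
print(res.aligned_read)
print(res.aligned_ref)
```

prints

```
read=candidate strand=+ alpha=100.0 spanning=True
left=BCR-like|left right=ABL1-like|right anchor=15
CATCGATGTAACCTTGAATGGTCCATTGCAGACA
CATCGATGTAACCTTGAATGGTCCATTGCAGACA
```

The read realigned perfectly (α = 100) with its first 19 bases in one
partner's left flank and the remaining 15 in the other partner's right flank:
a spanning read with a 15 bp anchor — direct evidence for the junction.

## Command line

```
fusionlens simulate   --out-dir sim --seed 1          # toy locus + reads + BAMs
fusionlens build-refs --genome g.fa --exons exons.bed \
                      --breakpoint "chr1:10000:+>chr2:20000:-" --radius 200
fusionlens extract    --bam normal.bam --bam chimeric.bam \
                      --breakpoint "chr1:10000:+>chr2:20000:-"
fusionlens align      --fastq extracted.fastq --left-fasta refs_left.fa \
                      --right-fasta refs_right.fa --mode local
fusionlens plot       --results-json alignments.json --left-fasta refs_left.fa \
                      --right-fasta refs_right.fa --min-score 95
fusionlens run        --genome g.fa --exons exons.bed --bam normal.bam \
                      --breakpoint "chr1:10000:+>chr2:20000:-" --out-dir out
```

`run` chains everything and writes a standalone SVG/HTML evidence report plus
TSV/JSON tables. Reference retrieval is fully local (indexed FASTA + exon
BED/refFlat); see `docs/methods.md` for the retrieval conventions, scoring
details and design choices.

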