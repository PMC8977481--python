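# telomotif

De novo discovery of telomeric repeat motifs (TRMs) from short-read
whole-genome sequencing.

## The problem

Most eukaryotic chromosomes end in tandem arrays of a short G-rich repeat
(human `(TTAGGG)n`, most insects `(TTAGG)n`), but the motif itself varies —
some lineages carry elongated 8–9 bp units such as `(TTATTGGG)n` or
`(TTACTTGGG)n`, and others (e.g. *Drosophila*) have lost tandem-repeat
telomeres entirely. Hybridization assays can only confirm a motif you
already suspect. Because a telomeric repeat is normally the most abundant
perfect short tandem repeat in a genome, it can instead be discovered
directly from ordinary Illumina reads (75–250 bp, ≥10× depth): profile
every perfect tandem repeat, normalize abundances by coverage, and ask
whether one motif dominates.

`telomotif` implements that pipeline for sequence analysts and genome
projects that have short-read data but no chromosome-level assembly:

1. **Detection** — every maximal perfect tandem run with a primitive unit of
   2–25 bp (zero mismatches; `N` breaks runs) in every read.
2. **Canonicalization** — each unit is mapped to a strand/rotation-invariant
   canonical key (lexicographic minimum over all rotations of both strands,
   A<C<G<T), and to a G-convention display form (the rotation ending in the
   longest run of Gs: canonical `AACCT` ↔ display `TTAGG`).
3. **Statistics** — 19 per-motif summary statistics, including
   repeat-containing reads, total repeat length, percent of read bases in
   repeat, and total repeat length per 1× haploid genome
   (`total_bp / coverage`, with coverage given as `--avg_genome_cov` or
   derived from `--genome-size`).
4. **Calling** — motifs passing candidate thresholds (enough
   repeat-containing reads, enough per-1× repeat length, enough "pure" reads
   drawn from inside long arrays) are ranked by abundance *A*; the TRM is
   called when the best candidate satisfies *A₁/A₂ ≥ 3* (inclusive; a sole
   candidate is called outright). Otherwise the verdict is `ambiguous`
   (ranked list preserved for external evidence) or `absent` (no candidate —
   itself a meaningful result, indicating a non-tandem-repeat telomere).

Companion tools validate and extend a call: `scan-assembly` looks for the
motif's arrays at scaffold termini of a genome assembly, `subtelo` extracts
read pairs with exactly one telomeric mate and greedily assembles the
non-telomeric mates into sub-telomeric anchor contigs, and `simulate`
generates genomes with planted telomeres plus fully ground-truthed read
libraries so the entire pipeline is testable without any downloads.

## Worked example

Simulate two 50-kb chromosomes with 3-kb `(TTATTGGG)n` arrays at every end,
sequence to 20×, and run the pipeline:

```sh
telomotif simulate -o sim --n-chromosomes 2 --chromosome-length 50000 \
    --telomere-motif TTATTGGG --telomere-length 3000 \
    --terminal-buffer 5000 --coverage 20 --seed 1
telomotif profile sim/reads.fastq --genome-size 100000 -o out
```

which prints `called	TTATTGGG` and writes `out/profile.tsv`,
`out/candidates.tsv` and `out/trm_call.tsv`. The top of the profile table:

```
canonical	display	unit_length	n_reads_with_repeat	n_runs	total_copies	total_repeat_length_bp	total_repeat_length_per_1x
AACCCAAT	TTATTGGG	8	2390	2390	28375	236536	11826.8
```

2,390 of the 20,000 reads contain the repeat, 236,536 read bases lie inside
its runs, and dividing by the 20× coverage gives 11,827 bp of telomeric
repeat per 1× haploid genome — matching the 12 kb planted (4 ends × 3 kb).
The verdict record shows the call and its evidence:

```
status	canonical	display	fold_ratio	n_candidates
called	AACCCAAT	TTATTGGG	inf	1
```

(`fold_ratio` is `inf` when there is a single candidate.) Validating
against the simulated assembly finds the arrays at all four termini:

```sh
telomotif scan-assembly sim/genome.fasta --motif TTATTGGG -o scan
# termini_with_array	4/4	total_array_bp	12001
```

Note the 5′ termini match via the canonical key even though the forward
strand carries the C-rich `CCCAATAA` phase there.

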