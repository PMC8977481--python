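# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `telomotif`.

## Tandem-run detection

A *run* is a maximal stretch `s[a:b)` that is perfectly periodic with
period `p` (`s[i] == s[i+p]` for all `a <= i < b-p`), reported once at the
minimal period of the stretch. Implementation: for each candidate period
`p` the boolean array `s[i] == s[i+p]` is computed in one vectorized pass
(reads are concatenated with a non-nucleotide sentinel, so a whole read
chunk costs a constant number of numpy operations per period); maximal
true-stretches of length `t` become runs of length `t + p`. A run is kept
when

* `full_copies = len // p >= min_copies` (default 3),
* `len >= min_run_bp` (default 12 bp),
* `p` is the *minimal* period of the run substring (checked directly
  against every `q < p`), which simultaneously guarantees a primitive unit,
  removes duplicate reports at multiples of the true period, and excludes
  homopolymers (their minimal period is 1, below the 2-bp unit floor).

Any non-ACGT character breaks runs and can never occur inside a unit; input
is case-insensitive. The trailing partial copy of a run counts toward its
matched length but not its copy number — array length, not the copy
integer, is what drives abundance. Runs of *different* motifs may overlap;
the detector reports all of them. Unit bounds default to 2–25 bp.

The defaults `min_copies = 3` / `min_run_bp = 12` are the weakest
defensible evidence of tandemness inside a single read (three full copies)
while suppressing incidental dinucleotide noise; both are exposed on the
CLI. The test suite pins the detector to an independent brute-force oracle
that enumerates every `(start, end, period)` triple and re-derives
maximality, primitivity and N-handling per candidate.

## Canonicalization

A unit observed in a read is an arbitrary rotation of an arbitrary strand
of the underlying monomer, so counting uses the **canonical key**: the
lexicographic minimum (A<C<G<T on uppercase) over the `2·|u|` strings
formed by all rotations of the unit and of its reverse complement. The
**display form** follows the telomere-field convention of writing the
monomer ending in its Gs: among the same `2·|u|` strings, the one with the
longest trailing run of G, ties broken by lexicographic order, falling back
to the canonical key for G-free units (e.g. `AT`).

## Abundance statistics

One streaming pass accumulates per-motif tallies; chunks may be profiled
independently and merged, and the merge is exact — every accumulator is a
sum or a maximum, and the per-read covered-fraction sum is kept as an exact
rational so merge order cannot perturb the low-order bits. Nineteen
statistics are reported per motif (the column order is frozen in the TSV
header): unit length; repeat-containing reads; runs; full copies; total
repeat length; total repeat length per 1×; percent of read bases in
repeat; mean/max copies per run; mean runs per repeat-containing read;
mean/max run length; mean covered fraction of repeat-containing reads;
pure-read count; unit GC fraction; trailing-G length of the display form;
share of all repeat bp; abundance rank; and the fold ratio to the
next-ranked motif ("average number of repeats per read" is interpreted as
mean full copies per run together with mean runs per read; their product
recovers copies per repeat-containing read).

*Total repeat length* for a motif is the per-read **union** of its run
intervals, summed over reads. In ordinary data this equals the sum of run
lengths, but two maximal runs of the same canonical motif can overlap by up
to `p-1` bases in pathological sequences, and the union definition makes
the conservation law — per-motif totals equal per-read covered bases — hold
exactly, always.

A read is **pure** for a motif when ≥ 90% of its bases (configurable) lie
inside that motif's runs; reads sampled from inside multi-kb telomeric
arrays are pure, reads containing only interstitial microsatellite
snippets are not. Coverage for the per-1× normalization comes from
`--avg_genome_cov`, or is derived as `total_read_bases / genome_size`; an
explicit coverage wins when both are given. With neither, per-1× values
are NA and only raw counts are comparable.

## Candidate criteria and the dominance call

Defaults: ≥ 50 repeat-containing reads, ≥ 500 bp repeat per 1× genome,
≥ 10 pure reads, unit length within the detector bounds. They are sized so
that kb-scale telomeric arrays sequenced at ≥ 10× pass comfortably while
dispersed sub-read-length microsatellites fail (they produce no pure
reads); all are CLI-exposed, and negative-control simulations in the test
suite confirm the separation across 20 seeds. Candidates are ranked by
total repeat length per 1× genome (configurable to any of the 19 fields),
ties broken by canonical key.

The verdict: no candidates → `absent`; one candidate → `called`; otherwise
`called` iff best/second ≥ 3.0, with the boundary inclusive; anything else
is `ambiguous`, retaining the ranked list. Ambiguity is never resolved
automatically — corroboration (e.g. the assembly-terminus scan) is a
separate, explicit step. The dominance comparison is best-versus-second
rather than best-versus-all-others-pooled; with telomeric arrays the best
candidate typically exceeds the entire remainder anyway.

## Assembly-terminus scan

The first and last `window_bp` (default 10 kb) of each scaffold are scanned
with the same detector (`min_array_bp`, default 100 bp, acting as the run
length floor) and arrays whose edge lies within `max_terminal_gap`
(default 1 kb) of the end are reported. Matching is canonical, so the
C-rich phase on the forward strand of a 5′ terminus matches the same motif
as the G-rich 3′ array, and the report is invariant under
reverse-complementing a scaffold (the 5′/3′ labels swap). Window, array
floor and gap are judgment defaults sized to the hundreds-of-bp-to-kb
arrays real assemblies retain at scaffold ends; all are configurable.
Interrupted arrays are reported as separate arrays — no merging heuristic.

## Sub-telomeric anchors

Instead of aligning reads to the repeat, a mate is classified by motif
content: the fraction of its bases covered by runs of the target motif.
For perfect arrays this is equivalent to mapping and needs no external
aligner. A pair is kept when exactly one mate has fraction ≥ 0.8
(configurable); the other mate is the sub-telomeric anchor, which
originates within about one insert size of the array boundary. Anchors can
be merged by a deterministic greedy assembler: repeatedly merge the pair of
contigs with the longest exact suffix–prefix overlap ≥ 31 bp (both
orientations; ties broken by lexicographically smallest pair). This is a
desk-scale device for error-free data — for real libraries export the
anchors FASTA to a proper assembler instead (`--no-assemble`).

## Synthetic data

The simulator *is* the test substrate, so its construction mirrors
telomere biology where it matters and is deliberately simple elsewhere.
Each chromosome is `[revcomp(motif) array] + random core + [motif array]`,
placing the C-rich strand at the 5′ end of the forward sequence, as for a
telomerase-extended G-rich 3′ overhang; telomere length is fixed or
uniform per end. Interstitial arrays (unit, copies, sites) are planted
uniformly in the core, at least `terminal_buffer_bp` (default 10 kb) from
either end, rejecting overlaps. Reads are sampled uniformly over both
strands; paired mode draws insert sizes from a clipped normal with mates
on opposite strands; errors are substitution-only at a uniform rate; base
qualities are constant. Everything is reproducible bit-for-bit from the
spec seeds, and full truth (telomere/interstitial intervals, per-read
origins) round-trips through a TSV.

What the simulator does **not** model — and therefore what passing tests do
not demonstrate about real data: indels and quality-dependent errors, GC
and positional coverage bias, real telomere length heterogeneity and
degraded/variant repeat at array boundaries, interstitial telomere-like
sequence that has drifted from the perfect motif, and retrotransposon-type
chromosome ends (represented only as "no planted arrays"). The exact
detector discards any read window containing a mismatch, which on real
data trims abundance roughly in proportion to the per-read error footprint
but leaves the dominance ranking intact at realistic error rates.

## Problem sizes and numerical choices

Full-scale recovery checks use 5 × 100-kb chromosomes with 5-kb arrays per
end at 30× (150,000 reads), which the pipeline processes in a few seconds;
multi-seed sweeps (20 seeds × 4 motifs, and 20-seed negative controls) use
single 24–40-kb chromosomes at 12×, comfortably above the calling
thresholds while keeping the whole suite fast. Statistics are written with
6 significant digits; `inf` marks the fold-ratio sentinel of the last rank
(and of a sole candidate), `NA` an unavailable normalization. Ranking ties
are broken by canonical key, so all outputs are byte-reproducible.

## Known limitations

* Zero-mismatch detection is by design (it is what suppresses drifted
  interstitial repeats), so heavily degraded arrays or very high error
  rates depress abundance; the minimum-depth recommendation (10×) assumes
  typical Illumina error profiles.
* Units are bounded at 25 bp; longer monomers (known from some plants and
  yeasts) are out of range.
* The greedy assembler is quadratic and intended for hundreds of anchors,
  not whole libraries.
* Abundance says nothing about chromosomal position: a dominant motif is a
  *predicted* TRM until arrays are confirmed at termini (assembly scan) or
  cytogenetically.
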