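# Methods

## The molecules being designed

A polypurine reverse-Hoogsteen hairpin (PPRH) is a single-stranded,
unmodified DNA oligo built from two *mirror-repeat* polypurine arms in
antiparallel orientation joined by a pentathymidine loop. The arms pair
with each other intramolecularly through reverse-Hoogsteen bonds; one
arm then binds the polypyrimidine strand of a genomic target by
Watson–Crick bonds, displacing the purine strand. The mirror-repeat
relation is central and easy to get wrong: the 3' arm is the 5' arm
read **backwards with no complementation** (`arm2 == reverse(arm1)`),
not a reverse complement. Pyrimidine interruptions in the target track
are kept verbatim in the arm and mirrored into the second arm.

An *editing* PPRH extends the hairpin core at its 5' end with a
homology tail spanning an edit junction — here, the PstI site
(`CTGCAG`) at which an exon-containing cassette was inserted into
intron 1 of a DHFR minigene — with a second pentathymidine stretch as a
long-distance linker between tail and core:

```
5'-[tail: w nt upstream + w nt downstream of junction]-[TTTTT]-[arm]-[TTTTT]-[reverse(arm)]-3'
```

The tail provides the recombination template: its two halves are
adjacent only in the *restored* (post-edit) sequence, so recombination
guided by it deletes the intervening cassette.

## Coordinate and junction conventions

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) is converted at the I/O boundary, BED is native. The edit
junction is a point *between* bases. With the default
`site_starts_at_junction` policy the recognition motif lies immediately
3' of the junction, so the upstream homology window excludes `CTGCAG`
and the downstream window begins with it — the only convention under
which the published tails decompose cleanly into w-nt blocks.

Tail modes U/D are strand-relative: "U" is the window 5' of the
junction *on the chosen tail strand*. On the minus strand the two
genomic windows are reverse-complemented and swapped. Published design
names do not always agree with this (or any) convention, so names are
emitted in the traditional style but never parsed for meaning.

## Polypurine scanning

A track must (i) be at least `min_track_len` (default 15) nt, (ii)
start and end on a purine, (iii) have purine fraction ≥ `min_purity`
(default 0.80), and (iv) contain no pyrimidine run longer than
`max_pyr_run` (default 2). The defaults are the loosest gates that
admit the three experimentally used cores (17/20/22-mers, purities
0.82–0.87, worst interruption a CC dinucleotide); they are exposed in
`ScanConfig`. The scanner reports every *containment-maximal* valid
interval on both strands: the sequence is first segmented at Ns and at
pyrimidine runs longer than the gate (no valid track can span either),
valid purine-bounded windows are enumerated within segments with a
purity prefix sum, and non-maximal intervals are removed by a sweep.
Overlapping maximal tracks are all reported; ranking is a design-time,
not scan-time, concern. `brute_force_tracks` re-derives the same set by
exhaustive substring enumeration and serves as the test oracle.

Containment maximality (no valid strict superinterval) was chosen over
one-step non-extendability because purity can recover after a dip: a
pure run may be inextensible by one purine yet sit inside a longer
valid track.

## Decomposition grammar

`decompose_pprh` inverts assembly: it enumerates placements of one or
two exact 5-T windows inside maximal T-runs of length ≥ 5 (two windows
= linker + loop, one = loop only) and accepts a partition iff the arms
are mirror repeats with `len(arm) ≥ min_arm` (default 10 — below that,
spurious mirror partitions become common in random sequence). A tail
ending in T fused to the linker produces a 6-T run; the mirror
constraint picks the correct split. Ties are broken by longest arm,
then longest tail, then leftmost linker — deterministic and biased
toward the larger binding domain. The tail-only control (no core) is
correctly rejected and, when a reference and junction are supplied,
recognized as a junction-spanning homology segment.

## In-silico assays

*Restriction scan*: IUPAC-aware regex with lookahead (overlapping sites
reported); palindromic motifs return one position list, non-palindromic
motifs return (position, strand) pairs.

*Virtual PCR*: exact priming by default; with `max_mismatch` in {1, 2}
the three 3'-terminal bases must still match (extension requires an
annealed 3' end). Product length runs from the forward primer's 5' end
through the reverse primer's 5' end on the bottom strand — both
footprints included, the standard convention. All forward/reverse site
pairings up to `max_len` are reported, sorted by length.

*Isoforms*: the canonical isoform plus exactly the requested skip /
intron-retention events (and explicitly requested combinations) — no
combinatorial expansion. The band table applies virtual PCR to each
isoform cDNA and sorts largest-first (gel order); isoforms lacking a
primer site get a null entry.

## Physicochemistry

MW uses the anhydrous linear ssDNA free-acid convention (A 313.21,
T 304.2, C 289.18, G 329.21 Da, minus one 61.96 Da terminal
correction) — a common vendor convention; under it the five catalog
editing PPRHs average 25,652 Da, and 3 or 5 µg in the 1.0 mL
transfection volume (0.2 mL mix + 0.8 mL medium) give 117 and 195 nM.
Which convention the original average used is not stated anywhere, so
the agreement is checked at 0.5%. Tm is a deliberately simple QC aid
(Wallace rule below 14 nt, otherwise 64.9 + 41·(GC − 16.4)/L); no
nearest-neighbor or salt corrections.

## The synthetic minigene

`minigene_fixtures` generates, deterministically per seed, a reduced-
scale structural analogue of the exon-duplication cell model: a
~940 nt wildtype ("restored") minigene — 150 nt promoter-like region,
six exons (60/50/60/60/60/60 nt) with GT..AG introns (120 nt intron 1,
80 nt others) — and its duplication derivative (~1056 nt). Real
published elements are planted in uniform random background: the three
polypurine arms (promoter, exon 3, exon 6; each padded with 3-nt
pyrimidine runs so scanned tracks trim exactly to the arm), the 20-nt
homology blocks with their PstI site centered in intron 1, and the
exon-1/exon-3 primer footprints. The cassette (30 nt flank + a verbatim
copy of exon 2 + 30 nt flank, with flank edges patched to AG/GT so both
mutant introns splice) is inserted at the junction with one regenerated
PstI site on its upstream edge (`regenerate_sites="upstream"`; the true
junction structure of the original construct is unknown, so this is
configurable). Backgrounds that collide with any uniqueness constraint
(a chance PstI site, a duplicated homology block or primer footprint)
are rejected and resampled deterministically.

Exon and primer geometry are chosen so the exon-1→exon-3 RT-PCR
products are 166 bp (duplicate exon included) vs 116 bp (skipped), with
the 50 bp difference equal to the duplicated exon length. The edit
emulator locates the unique upstream/downstream homology blocks in the
mutant and splices out everything between them; on generator output
this reverts the duplication byte-identically and is idempotent on
already-restored input.

What the generator does *not* emulate: chromatin, promoter activity,
recombination frequency or mechanism, splice-site strength, or the real
hamster DHFR sequence outside the planted elements. Passing tests
demonstrate that the design grammar, scanning and assay logic are
internally consistent and agree with the published sequences and sizes
— not that any particular design will edit cells efficiently.

## Problem sizes and determinism

Test and acceptance runs use the default ~1 kb minigene, 100–500-case
property sweeps for the scanner/grammar oracles, and ≤ 10 generator
seeds per property; the whole suite completes in well under a minute.
All randomness flows from explicit seeds (`random.Random`,
seed-plus-attempt for rejection resampling), so every artifact —
FASTA, GFF3, TSV, BED — is byte-reproducible.

## Known limitations

- No triplex thermodynamics, pH/Mg dependence, or H-DNA detection; the
  scanner is purely compositional.
- The core-strand → tail-strand pairing rule is under-determined by
  sequence alone; both tail orientations are emitted per candidate
  rather than guessing.
- Virtual PCR ignores primer thermodynamics, dimers and quantitative
  band intensity.
- Repair-type PPRHs (single-nucleotide correction tails) parse under
  the same grammar but have no specialized designer.
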