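# pprh — editing polypurine reverse-Hoogsteen hairpin design

Polypurine reverse-Hoogsteen hairpins (PPRHs) are unmodified
single-stranded DNA oligos: two mirror-repeat polypurine arms joined by
a pentathymidine loop, pairing intramolecularly by reverse-Hoogsteen
bonds while one arm binds a genomic polypyrimidine target by
Watson–Crick bonds. *Editing* PPRHs add, at the 5' end, a homology tail
spanning an edit junction plus a second pentathymidine linker; the tail
templates recombination that removes an unwanted insertion — exon
skipping at the genomic (DNA) level rather than on pre-mRNA.

This package is a desk toolkit for anyone designing such molecules
against a characterized locus, built around the DHFR-minigene
exon-duplication model system:

- **`polypurine_scanner`** — find maximal polypurine tracks (purine
  fraction, pyrimidine-run and length gates) on both strands.
- **`pprh_design`** — assemble hairpin cores, junction homology tails
  and complete editing PPRHs; parse and validate arbitrary oligos
  against the design grammar (`arm2 == reverse(arm1)`, 5-T loop/linker).
- **`insilico_validation`** — restriction-site scan, virtual PCR,
  splice-isoform enumeration and RT-PCR band-size prediction.
- **`oligo_physchem`** — ssDNA molecular weight, GC, Tm, and µg → nM
  dose conversion.
- **`minigene_fixtures`** — a seeded generator for a synthetic minigene
  pair (wildtype + exon-duplication mutant) carrying the published
  polypurine arms, PstI junction blocks and primer sites, so the whole
  pipeline runs with no external data.
- **`pprh` CLI** — `scan`, `design`, `validate`, `pcr`, `isoforms`,
  `physchem`, `dose`, `fixtures`.

## Worked example

Generate the synthetic minigene pair and design editing PPRHs for the
cassette insertion at the PstI junction (coordinate 270, 0-based, in
intron 1 of the restored record):

```bash
$ pprh fixtures --out fx --seed 42
$ pprh design --fasta fx/mutant.fa --restored fx/restored.fa \
      --gff fx/genes.gff3 --junction minigene:270 | head -2
name	full_seq	arm	tail	strand	purity	offtarget_count
LDSHpPrI1UDPstI	ACCGCGGGCATGGGCAAGGGCTGCAGCCGGCGGGCCTACCTTTTTGGGGAAGGAAAAGTGGGTGACATTTTTACAGTGGGTGAAAAGGAAGGGG	GGGGAAGGAAAAGTGGGTGACA	ACCGCGGGCATGGGCAAGGGCTGCAGCCGGCGGGCCTACC	+	0.8636	0
```

The top-ranked candidate targets the 22-nt promoter track (purine
fraction 0.864) and carries the 40-nt UD tail — 20 nt upstream of the
junction plus 20 nt downstream beginning with `CTGCAG`. Its 94-nt
sequence reads tail, TTTTT linker, arm, TTTTT loop, reversed arm, and
is exactly the editing PPRH used against this target experimentally.

Predict the RT-PCR readout of editing (exon-1 → exon-3 primers on the
mutant's splice isoforms):

```bash
$ pprh isoforms --fasta fx/mutant.fa --gff fx/genes.gff3 --record minigene_dup \
      --skip E2a --retain 1 \
      --fwd AAGAACGGAGACCTTCCCTGGCCA --rev GAACCAGGTTTTCCGGCCCA
isoform	exons	product_bp
intron1_retained	E1-i1-E2a-E2b-E3-E4-E5-E6	262
canonical	E1-E2a-E2b-E3-E4-E5-E6	166
skip	E1-E2b-E3-E4-E5-E6	116
```

The 166 bp band is the duplicate-exon *inclusion* product, 116 bp is
the *skip* product (difference = the 50 nt duplicated exon), and the
intron-1-retained species runs above both — the gel pattern that
distinguishes edited from unedited cells. Dose arithmetic:

```bash
$ pprh dose --mass-ug 3 --mw 25652 --volume-ml 1.0
117 nM
```

In Python, the same end-to-end check in a few lines:

```python
from pprh import MinigeneSpec, make_fixture_set, apply_edit, design_candidates

fx = make_fixture_set(MinigeneSpec(seed=42))
designs = design_candidates(fx.mutant, fx.restored, fx.junction, fx.mutant_gene)
assert designs[0].verdict.tail_maps_to_reference
assert apply_edit(fx.mutant, fx.restored, fx.junction).seq == fx.restored.seq
```

See `docs/methods.md` for conventions (coordinates, junction policy,
tail strand semantics), the scanner and grammar definitions, and what
the synthetic minigene does and does not emulate.

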