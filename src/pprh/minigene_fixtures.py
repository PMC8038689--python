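"""Seeded synthetic minigene emulating the DHFR exon-duplication cell model.

The generator builds, at reduced scale, a structural analogue of the
experimental system: a wildtype multi-exon minigene ("restored") with a
unique PstI site in intron 1, a derivative carrying an exon-2 cassette
inserted at that site ("mutant", emulating the duplication construct),
and the sequence-level edit that reverts the mutant to the wildtype.

Everything is deterministic per seed. Real published sequence elements
(the three polypurine arms, the 20-nt homology blocks flanking the PstI
junction, and the exon-1/exon-3 PCR primers) are embedded into random
background so that every downstream module — scanner, designer,
restriction scan, virtual PCR, isoform enumeration — can be exercised
end-to-end without any external data. The geometry is chosen so the
exon-1 -> exon-3 RT-PCR products are 166 bp (duplicate exon included)
vs 116 bp (skipped). This is a constructed analogue of the hamster
minigene system, not a reproduction of the real locus.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import catalog
from .sequence_model import (
    EditJunction,
    GeneModel,
    SeqRecord,
    SequenceError,
    reverse_complement,
    write_fasta,
    write_gene_model,
)

__all__ = [
    "MinigeneSpec",
    "FixtureSet",
    "make_minigene",
    "make_fixture_set",
    "make_cassette",
    "apply_duplication",
    "apply_edit",
    "emit_fixtures",
]

#: Pyrimidine padding around embedded arms: a 3-pyrimidine run exceeds the
#: default max_pyr_run gate, so scanned tracks trim exactly to the arm.
_PYR_PAD = "CTC"


@dataclass(frozen=True)
class MinigeneSpec:
    """Parameters of the synthetic minigene pair.

    ``embed_arms`` maps region labels (``promoter`` or an exon label) to
    polypurine arm sequences planted there; defaults are the three
    experimentally used arms (promoter / exon 3 / exon 6 targets).
    ``cassette`` is ``(flank5_len, exon_copy_label, flank3_len)``: the
    insert carries a verbatim copy of the named exon between random
    flanks whose edges are patched to keep both mutant introns
    GT..AG-spliceable. ``regenerate_sites`` controls how many copies of
    the junction motif the insertion recreates.
    """

    seed: int = 42
    n_exons: int = 6
    exon_lengths: tuple[int, ...] = (60, 50, 60, 60, 60, 60)
    intron_lengths: tuple[int, ...] = (120, 80, 80, 80, 80)
    promoter_length: int = 150
    junction_intron: int = 1
    embed_arms: tuple[tuple[str, str], ...] = (
        ("promoter", catalog.ARMS["promoter"]),
        ("E3", catalog.ARMS["E3"]),
        ("E6", catalog.ARMS["E6"]),
    )
    cassette: tuple[int, str, int] = (30, "E2", 30)
    regenerate_sites: str = "upstream"
    motif: str = catalog.PSTI_MOTIF

    def __post_init__(self) -> None:
        if self.n_exons != len(self.exon_lengths):
            raise ValueError("n_exons must match exon_lengths")
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError("need n_exons - 1 intron lengths")
        if not (1 <= self.junction_intron <= self.n_exons - 1):
            raise ValueError("junction_intron out of range")
        if self.regenerate_sites not in ("none", "upstream", "both"):
            raise ValueError("regenerate_sites must be none, upstream or both")
        total = self.promoter_length + sum(self.exon_lengths) + sum(self.intron_lengths)
        if total >= 50_000:
            raise ValueError("minigene larger than the 50 kb guard")


@dataclass(frozen=True)
class FixtureSet:
    """Everything the generator knows about one seeded minigene pair."""

    spec: MinigeneSpec
    restored: SeqRecord
    restored_gene: GeneModel
    junction: EditJunction
    mutant: SeqRecord
    mutant_gene: GeneModel
    cassette: str


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _patch(seq: list[str], offset: int, insert: str) -> None:
    seq[offset : offset + len(insert)] = list(insert)


def _count(hay: str, needle: str) -> int:
    count = start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _build_restored(spec: MinigeneSpec, rng: random.Random) -> tuple[str, GeneModel, int]:
    """One candidate restored sequence (constraint checks happen later)."""
    exon_starts = []
    pos = spec.promoter_length
    coords = []
    for i in range(spec.n_exons):
        coords.append((pos, pos + spec.exon_lengths[i]))
        pos += spec.exon_lengths[i]
        if i < spec.n_exons - 1:
            pos += spec.intron_lengths[i]
    total = pos
    seq = list(_rand_seq(rng, total))

    gene = GeneModel(
        record_id="minigene",
        exons=[(f"E{i + 1}", iv) for i, iv in enumerate(coords)],
        promoter_region=(0, spec.promoter_length),
    )
    # canonical splice ends on every intron
    for (s, e) in gene.introns():
        _patch(seq, s, "GT")
        _patch(seq, e - 2, "AG")

    # U20 | CTGCAG+D20rest homology blocks centered in the junction intron
    js, je = gene.introns()[spec.junction_intron - 1]
    block = catalog.U20 + catalog.D20
    off = js + (je - js - len(block)) // 2
    if not (js + 2 <= off and off + len(block) <= je - 2):
        raise SequenceError("junction intron too short for the homology blocks")
    _patch(seq, off, block)
    junction_coord = off + len(catalog.U20)

    # polypurine arms with pyrimidine padding, at fixed in-region offsets
    for region, arm in spec.embed_arms:
        insert = _PYR_PAD + arm + _PYR_PAD
        if region == "promoter":
            start = (spec.promoter_length - len(insert)) // 2
            limit = spec.promoter_length
        else:
            s, e = gene.exon(region)
            start = e - len(insert) - 4  # clear of primer footprints at the exon 5' end
            limit = e
        if start + len(insert) > limit:
            raise SequenceError(f"region {region!r} too short for arm of {len(arm)} nt")
        _patch(seq, start, insert)

    # published exon-1 forward primer and exon-3 reverse primer footprints,
    # placed so the E1->E3 cDNA product is 116 bp when one E2 copy is spliced
    fwd = catalog.EXON1_FWD_PRIMER
    e1s, e1e = gene.exon("E1")
    _patch(seq, e1s + 20, fwd)
    rev_site = reverse_complement(catalog.EXON3_REV_PRIMER)
    e3s, _ = gene.exon("E3")
    _patch(seq, e3s + 6, rev_site)
    return "".join(seq), gene, junction_coord


def make_cassette(spec: MinigeneSpec, restored: SeqRecord, gene: GeneModel,
                  rng: random.Random) -> str:
    """Insertion cassette: random flank + exon copy + random flank.

    The 5' flank ends in AG and the 3' flank starts with GT so that,
    after insertion into the GT..AG junction intron, both resulting
    mutant introns remain canonically spliceable.
    """
    flank5_len, exon_label, flank3_len = spec.cassette
    if flank5_len < 4 or flank3_len < 4:
        raise ValueError("cassette flanks must be at least 4 nt")
    s, e = gene.exon(exon_label)
    exon_seq = restored.seq[s:e]
    flank5 = _rand_seq(rng, flank5_len - 2) + "AG"
    flank3 = "GT" + _rand_seq(rng, flank3_len - 2)
    return flank5 + exon_seq + flank3


def apply_duplication(
    restored: SeqRecord,
    junction: EditJunction,
    cassette: str,
    regenerate_sites: str = "upstream",
) -> SeqRecord:
    """Insert ``cassette`` at the junction point of the restored sequence.

    ``regenerate_sites`` prepends (``upstream``) and/or appends
    (``both``) a copy of the junction motif to the cassette, modelling
    how a restriction-cloned insert recreates the site at one or both
    of its ends; ``none`` inserts the bare cassette.
    """
    if not cassette:
        raise SequenceError("cassette must be nonempty")
    junction.validate(restored)
    c = junction.coord
    if regenerate_sites == "none":
        insert = cassette
    elif regenerate_sites == "upstream":
        insert = junction.motif + cassette
    elif regenerate_sites == "both":
        insert = junction.motif + cassette + junction.motif
    else:
        raise ValueError("regenerate_sites must be none, upstream or both")
    return SeqRecord(
        id=restored.id + "_dup",
        seq=restored.seq[:c] + insert + restored.seq[c:],
        description="duplication derivative",
    )


def apply_edit(
    mutant: SeqRecord,
    restored: SeqRecord,
    junction: EditJunction,
    w: int = 20,
) -> SeqRecord:
    """Sequence-level emulation of the recombination outcome.

    Locates the unique ``w``-nt upstream and downstream homology blocks
    of the restored reference within the mutant and splices out
    everything between them, making them adjacent — the edit templated
    by a UD homology tail. Idempotent on already-restored input.
    """
    junction.validate(restored)
    c = junction.coord
    if c - w < 0 or c + w > len(restored):
        raise SequenceError("junction closer than w to an end of the restored record")
    u_block = restored.seq[c - w : c]
    d_block = restored.seq[c : c + w]
    nu = _count(mutant.seq, u_block)
    nd = _count(mutant.seq, d_block)
    if nu != 1 or nd != 1:
        raise SequenceError(
            f"homology blocks not unique in mutant: U x{nu}, D x{nd}"
        )
    u_end = mutant.seq.find(u_block) + w
    d_start = mutant.seq.find(d_block)
    if d_start < u_end:
        raise SequenceError("downstream block precedes upstream block in mutant")
    return SeqRecord(
        id=mutant.id,
        seq=mutant.seq[:u_end] + mutant.seq[d_start:],
        description="edited",
    )


def _mutant_gene_model(
    spec: MinigeneSpec, gene: GeneModel, junction_coord: int, insert_len: int,
    cassette_exon_offset: int, exon_copy_len: int,
) -> GeneModel:
    """Gene model of the duplication mutant (duplicate labels E2a/E2b)."""
    _, copy_label, _ = spec.cassette
    exons = []
    copy_start = junction_coord + cassette_exon_offset
    inserted = False
    for label, (s, e) in gene.exons:
        if s >= junction_coord and not inserted:
            exons.append((f"{copy_label}a", (copy_start, copy_start + exon_copy_len)))
            inserted = True
        new_label = f"{copy_label}b" if label == copy_label else label
        if s >= junction_coord:
            exons.append((new_label, (s + insert_len, e + insert_len)))
        else:
            exons.append((new_label, (s, e)))
    return GeneModel(
        record_id=gene.record_id + "_dup",
        exons=exons,
        promoter_region=gene.promoter_region,
    )


def make_fixture_set(spec: MinigeneSpec = MinigeneSpec(), max_attempts: int = 1000) -> FixtureSet:
    """Generate a restored/mutant minigene pair satisfying all invariants.

    Random backgrounds occasionally collide with a constraint (a chance
    CTGCAG, a duplicated homology block...); such draws are rejected and
    resampled deterministically. Raises after ``max_attempts`` failures.
    """
    from .polypurine_scanner import ScanConfig, scan_polypurine_tracks

    flank5_len, copy_label, _ = spec.cassette
    for attempt in range(max_attempts):
        rng = random.Random(spec.seed * 1009 + attempt)
        seq, gene, junction_coord = _build_restored(spec, rng)
        restored = SeqRecord(id="minigene", seq=seq, description="restored minigene")
        junction = EditJunction(
            record_id="minigene", coord=junction_coord, motif=spec.motif
        )
        cassette = make_cassette(spec, restored, gene, rng)
        mutant = apply_duplication(restored, junction, cassette, spec.regenerate_sites)

        # --- invariant checks; any failure -> resample ---
        if _count(seq, spec.motif) != 1:
            continue
        expected_motifs = {"none": 1, "upstream": 2, "both": 3}[spec.regenerate_sites]
        if _count(mutant.seq, spec.motif) != expected_motifs:
            continue
        if _count(seq, catalog.U20) != 1 or _count(seq, catalog.D20) != 1:
            continue
        if _count(mutant.seq, catalog.U20) != 1 or _count(mutant.seq, catalog.D20) != 1:
            continue
        fwd = catalog.EXON1_FWD_PRIMER
        rev_site = reverse_complement(catalog.EXON3_REV_PRIMER)
        if any(
            _count(s, p) != 1
            for s in (seq, mutant.seq)
            for p in (fwd, rev_site)
        ):
            continue
        if any(_count(seq, arm) != 1 for _, arm in spec.embed_arms):
            continue
        tracks = scan_polypurine_tracks(restored, ScanConfig())
        found = {t.seq for t in tracks if t.strand == "+"}
        if not all(arm in found for _, arm in spec.embed_arms):
            continue

        motif_offset = len(spec.motif) if spec.regenerate_sites in ("upstream", "both") else 0
        exon_copy_len = gene.exon(copy_label)[1] - gene.exon(copy_label)[0]
        mutant_gene = _mutant_gene_model(
            spec, gene, junction_coord, len(mutant.seq) - len(seq),
            motif_offset + flank5_len, exon_copy_len,
        )
        return FixtureSet(spec, restored, gene, junction, mutant, mutant_gene, cassette)
    raise SequenceError(
        f"could not satisfy minigene invariants after {max_attempts} resamples"
    )


def make_minigene(spec: MinigeneSpec = MinigeneSpec()) -> tuple[SeqRecord, GeneModel, EditJunction]:
    """The restored minigene, its gene model, and the edit junction."""
    fx = make_fixture_set(spec)
    return fx.restored, fx.restored_gene, fx.junction


def emit_fixtures(out_dir: str | os.PathLike, spec: MinigeneSpec = MinigeneSpec()) -> list[Path]:
    """Write the complete fixture file set (deterministic per seed).

    Files: ``restored.fa``, ``mutant.fa``, ``genes.gff3`` (both
    models), ``junction.yaml``, ``table1_oligos.tsv`` (the six
    published oligos), ``primers.tsv`` (the four published primer
    pairs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_fixture_set(spec)
    paths = []

    p = out / "restored.fa"
    write_fasta([fx.restored], p)
    paths.append(p)
    p = out / "mutant.fa"
    write_fasta([fx.mutant], p)
    paths.append(p)
    p = out / "genes.gff3"
    write_gene_model([fx.restored_gene, fx.mutant_gene], p)
    paths.append(p)

    p = out / "junction.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(
            {
                "record": fx.junction.record_id,
                "coord": fx.junction.coord,
                "motif": fx.junction.motif,
            },
            fh,
            sort_keys=True,
        )
    paths.append(p)

    p = out / "table1_oligos.tsv"
    with open(p, "w") as fh:
        fh.write("name\tsequence\ttarget_region\n")
        for name, (seq, region) in catalog.TABLE1_OLIGOS.items():
            fh.write(f"{name}\t{seq}\t{region}\n")
    paths.append(p)

    p = out / "primers.tsv"
    with open(p, "w") as fh:
        fh.write("pair\tforward\treverse\n")
        for pair, (f, r) in catalog.PRIMER_PAIRS.items():
            fh.write(f"{pair}\t{f}\t{r}\n")
    paths.append(p)
    return paths
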