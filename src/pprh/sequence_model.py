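"""Core sequence and annotation types shared by the whole toolkit.

All internal coordinates are 0-based half-open intervals on the plus
strand. Human-facing reports (CLI tables, BED/GFF3 emission per format
convention) convert at the boundary. Sequences are concrete DNA over
``{A, C, G, T, N}``; degenerate IUPAC codes are only allowed in
restriction/recognition *motifs*, never in designed oligos.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "GeneModel",
    "EditJunction",
    "SequenceError",
    "FastaFormatError",
    "GeneModelError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "read_gene_model",
    "write_gene_model",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC degenerate codes, used for motif matching only.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class SequenceError(ValueError):
    """Invalid sequence content or coordinates."""


class FastaFormatError(SequenceError):
    """Malformed FASTA input."""


class GeneModelError(SequenceError):
    """Inconsistent exon/intron annotation."""


@dataclass
class SeqRecord:
    """A named DNA sequence, normalized to uppercase {A,C,G,T,N}.

    Lowercase input is accepted and uppercased; ``U`` is mapped to ``T``
    with a warning recorded in :attr:`warnings` (RNA-style input is
    tolerated, not silently equated with DNA).
    """

    id: str
    seq: str
    description: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if "U" in seq:
            seq = seq.replace("U", "T")
            self.warnings.append("U->T: RNA-style residues mapped to T")
        for pos, ch in enumerate(seq):
            if ch not in _VALID_BASES:
                raise SequenceError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        if len(seq) == 0:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        if not (0 <= start <= end <= len(self.seq)):
            raise SequenceError(
                f"interval [{start},{end}) outside record {self.id!r} of length {len(self)}"
            )
        return self.seq[start:end]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise SequenceError(f"non-ACGTN character(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_reverse_complement(motif: str) -> str:
    """Reverse complement of a degenerate IUPAC motif."""
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise SequenceError(f"non-IUPAC character(s) {sorted(bad)} in motif")
    return motif.translate(_IUPAC_COMPLEMENT)[::-1]


def matches_iupac(seq: str, motif: str) -> bool:
    """True if a concrete sequence matches a degenerate motif of equal length."""
    if len(seq) != len(motif):
        return False
    return all(s in IUPAC.get(m, "") for s, m in zip(seq.upper(), motif.upper()))


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a (multi-record) FASTA file into normalized records.

    Raises :class:`FileNotFoundError` for a missing file and
    :class:`FastaFormatError`/:class:`SequenceError` for malformed
    entries, naming the offending record and position.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SeqRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA, 60-column wrapped (round-trip stable)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


@dataclass
class GeneModel:
    """Exon/intron structure of one reference record.

    ``exons`` is an ordered list of ``(label, (start, end))`` with 0-based
    half-open intervals on the plus strand; the gaps between consecutive
    exons are the introns (1-based intron index ``i`` lies after the
    ``i``-th exon). ``promoter_region`` is an optional interval upstream
    of the first exon.
    """

    record_id: str
    strand: str = "+"
    exons: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    promoter_region: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"strand must be + or -, got {self.strand!r}")
        prev_end = None
        prev_label = None
        for label, (start, end) in self.exons:
            if not (0 <= start < end):
                raise GeneModelError(f"exon {label!r}: bad interval [{start},{end})")
            if prev_end is not None:
                if start < prev_end:
                    raise GeneModelError(
                        f"exons {prev_label!r} and {label!r} overlap or are unsorted"
                    )
                if start - prev_end < 4:
                    raise GeneModelError(
                        f"intron between {prev_label!r} and {label!r} shorter than 4 nt"
                    )
            prev_end, prev_label = end, label

    @property
    def exon_labels(self) -> list[str]:
        return [label for label, _ in self.exons]

    def exon(self, label: str) -> tuple[int, int]:
        for lab, iv in self.exons:
            if lab == label:
                return iv
        raise GeneModelError(f"no exon labeled {label!r} in {self.record_id!r}")

    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons; intron i (1-based) follows exon i."""
        out = []
        for (_, (_, e1)), (_, (s2, _)) in zip(self.exons, self.exons[1:]):
            out.append((e1, s2))
        return out

    def check_bounds(self, record: SeqRecord) -> None:
        if self.exons and self.exons[-1][1][1] > len(record):
            raise GeneModelError(
                f"exon {self.exons[-1][0]!r} extends past record "
                f"{record.id!r} (length {len(record)})"
            )
        if self.promoter_region and self.promoter_region[1] > len(record):
            raise GeneModelError("promoter region extends past record end")

    def region_of(self, pos: int) -> str:
        """Human-facing label of the region containing ``pos``.

        Returns an exon label, ``"Pr"`` for the promoter region, or
        ``"I<k>"`` for the k-th intron (1-based); positions outside the
        model map to ``"intergenic"``.
        """
        if self.promoter_region:
            s, e = self.promoter_region
            if s <= pos < e:
                return "Pr"
        for label, (s, e) in self.exons:
            if s <= pos < e:
                return label
        for k, (s, e) in enumerate(self.introns(), start=1):
            if s <= pos < e:
                return f"I{k}"
        return "intergenic"


@dataclass
class EditJunction:
    """The point between bases where an insertion was made / is removed.

    With the default ``site_starts_at_junction`` policy the recognition
    motif (PstI, ``CTGCAG``) lies immediately 3' of the junction on the
    restored reference, so the upstream homology window excludes the
    site and the downstream window begins with it.
    """

    record_id: str
    coord: int
    motif: str = "CTGCAG"
    motif_policy: str = "site_starts_at_junction"
    motif_name: str = "PstI"

    _POLICIES = ("site_starts_at_junction", "site_ends_at_junction", "none")

    def __post_init__(self) -> None:
        if self.coord < 0:
            raise SequenceError(f"junction coord must be >= 0, got {self.coord}")
        if self.motif_policy not in self._POLICIES:
            raise SequenceError(f"unknown motif_policy {self.motif_policy!r}")
        bad = set(self.motif.upper()) - set(IUPAC)
        if bad:
            raise SequenceError(f"non-IUPAC character(s) in motif: {sorted(bad)}")
        self.motif = self.motif.upper()

    def validate(self, record: SeqRecord) -> None:
        if self.record_id != record.id:
            raise SequenceError(
                f"junction refers to {self.record_id!r}, not record {record.id!r}"
            )
        if not (0 <= self.coord <= len(record)):
            raise SequenceError(
                f"junction coord {self.coord} outside record of length {len(record)}"
            )
        m = len(self.motif)
        if self.motif_policy == "site_starts_at_junction":
            window = record.seq[self.coord : self.coord + m]
            if not matches_iupac(window, self.motif):
                raise SequenceError(
                    f"motif {self.motif} does not start at junction "
                    f"(found {window!r} at {self.coord})"
                )
        elif self.motif_policy == "site_ends_at_junction":
            window = record.seq[max(0, self.coord - m) : self.coord]
            if not matches_iupac(window, self.motif):
                raise SequenceError(
                    f"motif {self.motif} does not end at junction "
                    f"(found {window!r} before {self.coord})"
                )


def _read_bed(path: str | os.PathLike) -> GeneModel:
    exons: list[tuple[str, tuple[int, int]]] = []
    record_id = None
    promoter = None
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GeneModelError(f"{path}:{n}: BED4 needs 4 columns")
            chrom, start, end, name = fields[:4]
            if record_id is None:
                record_id = chrom
            elif chrom != record_id:
                raise GeneModelError(f"{path}:{n}: multiple record ids in BED")
            iv = (int(start), int(end))
            if name.lower() == "promoter":
                promoter = iv
            else:
                exons.append((name, iv))
    if record_id is None:
        raise GeneModelError(f"no intervals in {path}")
    exons.sort(key=lambda x: x[1][0])
    return GeneModel(record_id=record_id, exons=exons, promoter_region=promoter)


def _read_gff3(path: str | os.PathLike, record_id: Optional[str]) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: list[tuple[str, tuple[int, int]]] = []
    promoter = None
    rid = record_id
    strand = "+"
    for feat in db.all_features(order_by=("seqid", "start")):
        if rid is None and feat.featuretype in ("exon", "promoter"):
            rid = feat.seqid
        if feat.seqid != rid:
            continue
        # GFF3 is 1-based inclusive; convert to 0-based half-open.
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            label = feat.attributes.get("Name", feat.attributes.get("ID", [None]))[0]
            if label is None:
                label = f"exon{len(exons) + 1}"
            exons.append((label, iv))
            if feat.strand in "+-":
                strand = feat.strand
        elif feat.featuretype == "promoter":
            promoter = iv
    if rid is None:
        raise GeneModelError(f"no exon features in {path}")
    exons.sort(key=lambda x: x[1][0])
    return GeneModel(record_id=rid, strand=strand, exons=exons, promoter_region=promoter)


def read_gene_model(
    path: str | os.PathLike, fmt: str = "gff3", record_id: Optional[str] = None
) -> GeneModel:
    """Read exon structure from GFF3 (exon features) or BED4.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is already native. When the file
    annotates several records, ``record_id`` selects one (GFF3 only).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"annotation file not found: {path}")
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "gff3":
        return _read_gff3(path, record_id)
    raise ValueError(f"unknown annotation format {fmt!r}")


def write_gene_model(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write one or more gene models as exon (+ promoter) GFF3 features."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for gm in models:
        if gm.promoter_region:
            s, e = gm.promoter_region
            buf.write(
                f"{gm.record_id}\tpprh\tpromoter\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                f"ID=promoter\n"
            )
        for label, (s, e) in gm.exons:
            buf.write(
                f"{gm.record_id}\tpprh\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                f"ID={label};Name={label}\n"
            )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
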