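"""Sequence-level assays: restriction scan, virtual PCR, splice isoforms.

These predict the experimental readouts used to verify genomic exon
skipping: the restriction map of the junction region, the PCR product
spanning the edit, and the RT-PCR band pattern distinguishing inclusion
vs skipping of a duplicated exon (plus intron-retention species).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .sequence_model import (
    IUPAC,
    GeneModel,
    GeneModelError,
    SeqRecord,
    SequenceError,
    iupac_reverse_complement,
    reverse_complement,
)

__all__ = [
    "Amplicon",
    "Isoform",
    "find_restriction_sites",
    "virtual_pcr",
    "enumerate_isoforms",
    "rtpcr_band_table",
    "skip",
    "retain",
]


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise SequenceError(f"non-IUPAC character {ch!r} in motif")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping sites are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def is_palindromic(motif: str) -> bool:
    return motif.upper() == iupac_reverse_complement(motif)


def find_restriction_sites(
    seq: str, motif: str
) -> Union[list[int], list[tuple[int, str]]]:
    """All match positions of an IUPAC recognition motif.

    For a palindromic motif (e.g. PstI ``CTGCAG``) the plus- and
    minus-strand site sets coincide, so a plain ascending list of
    0-based plus-strand start positions is returned. For non-palindromic
    motifs, ``(position, strand)`` pairs are returned, minus-strand
    matches reported at their plus-strand start coordinate.
    """
    if not motif:
        raise SequenceError("empty restriction motif")
    if len(motif) < 4:
        raise SequenceError("restriction motif must be at least 4 nt")
    seq = seq.upper()
    pattern = _iupac_regex(motif)
    plus = [m.start() for m in pattern.finditer(seq)]
    if is_palindromic(motif):
        return plus
    rc_pattern = _iupac_regex(iupac_reverse_complement(motif))
    minus = [m.start() for m in rc_pattern.finditer(seq)]
    return sorted([(p, "+") for p in plus] + [(p, "-") for p in minus])


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product on a given template.

    ``start``/``end`` are 0-based half-open template coordinates running
    from the forward primer's 5' end through the 5' end of the reverse
    primer on the bottom strand (both primer footprints included — the
    standard product-length convention).
    """

    template_id: str
    fwd: str
    rev: str
    start: int
    end: int
    product_seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _primer_sites(template: str, site: str, max_mismatch: int, anchor_left: bool) -> list[int]:
    """Start positions where ``site`` matches with <= max_mismatch errors.

    The three 3'-terminal primer bases must match exactly; for a forward
    primer the 3' end is the right edge of the footprint, for the
    reverse primer's bottom-strand footprint it is the left edge
    (``anchor_left``).
    """
    m = len(site)
    if max_mismatch == 0:
        return [i for i in range(len(template) - m + 1) if template[i : i + m] == site]
    out = []
    for i in range(len(template) - m + 1):
        window = template[i : i + m]
        anchor = window[:3] == site[:3] if anchor_left else window[-3:] == site[-3:]
        if not anchor:
            continue
        mismatches = sum(a != b for a, b in zip(window, site))
        if mismatches <= max_mismatch:
            out.append(i)
    return out


def virtual_pcr(
    template: SeqRecord | str,
    fwd: str,
    rev: str,
    max_len: int = 5000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Enumerate PCR products of an exact (or near-exact) primer pair.

    Every pairing of a forward site with a downstream reverse site whose
    product is at most ``max_len`` long is reported, sorted by length.
    Primers must be concrete sequences of at least 15 nt; with
    ``max_mismatch`` in {1, 2} the 3'-terminal 3 nt must still match
    exactly (polymerase extension requires an annealed 3' end).
    """
    if isinstance(template, SeqRecord):
        tid, seq = template.id, template.seq
    else:
        tid, seq = "template", template.upper()
    for name, primer in (("fwd", fwd), ("rev", rev)):
        if len(primer) < 15:
            raise SequenceError(f"{name} primer shorter than 15 nt")
        if set(primer.upper()) - set("ACGT"):
            raise SequenceError(f"{name} primer contains degenerate bases")
    if max_mismatch not in (0, 1, 2):
        raise SequenceError("max_mismatch must be 0, 1 or 2")
    fwd = fwd.upper()
    rev = rev.upper()
    rev_site = reverse_complement(rev)
    fwd_starts = _primer_sites(seq, fwd, max_mismatch, anchor_left=False)
    rev_starts = _primer_sites(seq, rev_site, max_mismatch, anchor_left=True)
    products = []
    for f in fwd_starts:
        for r in rev_starts:
            # forward 5' end strictly left of the reverse primer's 3' end
            if f < r:
                end = r + len(rev)
                if end - f <= max_len:
                    products.append(
                        Amplicon(tid, fwd, rev, f, end, seq[f:end])
                    )
    products.sort(key=lambda a: (a.length, a.start))
    return products


@dataclass(frozen=True)
class Isoform:
    """A simulated spliced mRNA species (as cDNA sequence)."""

    label: str
    exon_labels: tuple[str, ...]
    seq: str
    events: tuple = ()


def skip(exon_label: str) -> tuple[str, str]:
    """Event: omit the named exon from the mature transcript."""
    return ("skip", exon_label)


def retain(intron_index: int) -> tuple[str, int]:
    """Event: keep intron ``intron_index`` (1-based, after that exon)."""
    return ("retain", intron_index)


def _splice(
    record: SeqRecord, gene: GeneModel, events: Sequence[tuple]
) -> tuple[tuple[str, ...], str]:
    skipped = {ev[1] for ev in events if ev[0] == "skip"}
    retained = {ev[1] for ev in events if ev[0] == "retain"}
    labels = gene.exon_labels
    for lab in skipped:
        if lab not in labels:
            raise GeneModelError(f"unknown exon label {lab!r}")
    n_introns = len(gene.exons) - 1
    for idx in retained:
        if not (1 <= idx <= n_introns):
            raise GeneModelError(f"intron index {idx} out of range 1..{n_introns}")
    introns = gene.introns()
    parts = []
    kept_labels = []
    for i, (lab, (s, e)) in enumerate(gene.exons, start=1):
        if lab in skipped:
            continue
        parts.append(record.seq[s:e])
        kept_labels.append(lab)
        if i <= n_introns and i in retained:
            is_, ie = introns[i - 1]
            parts.append(record.seq[is_:ie])
            kept_labels.append(f"i{i}")
    return tuple(kept_labels), "".join(parts)


def _event_label(events: Sequence[tuple]) -> str:
    names = []
    for ev in events:
        if ev[0] == "skip":
            names.append("skip")
        elif ev[1] == 1:
            names.append("intron1_retained")
        else:
            names.append("intron_retained_other")
    return "+".join(names)


def enumerate_isoforms(
    record: SeqRecord,
    gene: GeneModel,
    events: Iterable[tuple] = (),
    combos: Iterable[Sequence[tuple]] = (),
) -> list[Isoform]:
    """Canonical isoform plus one isoform per event (and per combo).

    Only requested events and explicitly requested combinations are
    generated — no combinatorial expansion. Duplicate-exon gene models
    (e.g. labels ``E2a``/``E2b``) support skipping either copy.
    """
    gene.check_bounds(record)
    out = []
    labels, seq = _splice(record, gene, ())
    out.append(Isoform("canonical", labels, seq))
    for ev in events:
        labels, seq = _splice(record, gene, (ev,))
        out.append(Isoform(_event_label((ev,)), labels, seq, events=(ev,)))
    for combo in combos:
        combo = tuple(combo)
        labels, seq = _splice(record, gene, combo)
        out.append(Isoform(_event_label(combo), labels, seq, events=combo))
    return out


def rtpcr_band_table(
    isoforms: Sequence[Isoform], fwd: str, rev: str, max_len: int = 5000
) -> pd.DataFrame:
    """Predicted RT-PCR band sizes per isoform, in gel order.

    Columns ``isoform``, ``exons``, ``product_bp``; rows sorted by
    product length descending (largest band on top, as run on a gel),
    isoforms without a product last with ``product_bp`` <NA>. Where an
    isoform yields several products, the shortest (dominant) one is
    reported.
    """
    rows = []
    for iso in isoforms:
        amps = virtual_pcr(SeqRecord(id=iso.label, seq=iso.seq), fwd, rev, max_len=max_len)
        rows.append(
            {
                "isoform": iso.label,
                "exons": "-".join(iso.exon_labels),
                "product_bp": amps[0].length if amps else pd.NA,
            }
        )
    df = pd.DataFrame(rows, columns=["isoform", "exons", "product_bp"])
    df["product_bp"] = df["product_bp"].astype("Int64")
    df = df.sort_values(
        by="product_bp", ascending=False, na_position="last", kind="stable"
    ).reset_index(drop=True)
    return df
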