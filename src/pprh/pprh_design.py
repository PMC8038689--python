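"""Assembly and decomposition of editing PPRHs.

An editing PPRH is, 5' to 3':

    [homology tail] [TTTTT linker] [arm] [TTTTT loop] [reverse(arm)]

The hairpin core is two *mirror-repeat* arms — the 3' arm is the 5' arm
read backwards with NO complementation (the signature of intramolecular
reverse-Hoogsteen pairing) — joined by a pentathymidine loop. The tail
is homologous to the sequence flanking the edit junction on the restored
(post-edit) reference; a second pentathymidine stretch links it to the
core ("long-distance" design). Pyrimidine interruptions in the arm are
kept verbatim and mirrored into the second arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .polypurine_scanner import PurineTrack, ScanConfig, scan_polypurine_tracks
from .sequence_model import (
    PURINES,
    EditJunction,
    GeneModel,
    SeqRecord,
    SequenceError,
    reverse_complement,
)

__all__ = [
    "HairpinCore",
    "HomologyTail",
    "EditingPPRH",
    "Decomposition",
    "DecompositionError",
    "PPRHVerdict",
    "DesignCandidate",
    "build_core",
    "build_tail",
    "assemble_editing_pprh",
    "decompose_pprh",
    "try_decompose",
    "validate_pprh",
    "design_candidates",
]


class DesignError(SequenceError):
    """Invalid design component or parameters."""


@dataclass(frozen=True)
class HairpinCore:
    """Two mirror-repeat polypurine arms around a T-homopolymer loop."""

    arm: str
    loop: str = "TTTTT"

    def __post_init__(self) -> None:
        if set(self.loop) != {"T"}:
            raise DesignError("loop must be a T homopolymer")
        if len(self.loop) < 3:
            raise DesignError("loop shorter than 3 nt cannot close a hairpin")
        if "N" in self.arm or not self.arm:
            raise DesignError("arm must be a nonempty concrete sequence (no N)")

    @property
    def full_core(self) -> str:
        """arm + loop + reversed (not complemented) arm."""
        return self.arm + self.loop + self.arm[::-1]

    @property
    def arm_purine_fraction(self) -> float:
        return sum(c in PURINES for c in self.arm) / len(self.arm)


@dataclass(frozen=True)
class HomologyTail:
    """Homology segment(s) flanking the edit junction, in tail orientation.

    ``up_seq``/``down_seq`` are the ``w``-nt windows immediately 5' and
    3' of the junction *on the chosen tail strand*: on '-' the two
    genomic windows are reverse-complemented and swapped so the tail
    reads 5'->3' on the minus strand. ``mode`` selects which windows the
    tail carries (U, D, or UD).
    """

    up_seq: str
    down_seq: str
    tail_strand: str = "+"
    mode: str = "UD"
    w: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("U", "D", "UD"):
            raise DesignError(f"tail mode must be U, D or UD, got {self.mode!r}")
        if self.tail_strand not in "+-":
            raise DesignError("tail_strand must be + or -")

    @property
    def tail_sequence(self) -> str:
        if self.mode == "U":
            return self.up_seq
        if self.mode == "D":
            return self.down_seq
        return self.up_seq + self.down_seq

    def __len__(self) -> int:
        return len(self.tail_sequence)


@dataclass(frozen=True)
class EditingPPRH:
    """A fully assembled design with provenance of every segment."""

    name: str
    core: HairpinCore
    tail: Optional[HomologyTail] = None
    linker: str = ""

    def __post_init__(self) -> None:
        if self.tail is not None:
            if set(self.linker) != {"T"}:
                raise DesignError("linker must be a T homopolymer when a tail is present")
        elif self.linker:
            raise DesignError("linker without a tail")

    @property
    def full_seq(self) -> str:
        if self.tail is None:
            return self.core.full_core
        return self.tail.tail_sequence + self.linker + self.core.full_core

    def __len__(self) -> int:
        return len(self.full_seq)


def build_core(track: PurineTrack | str, loop_len: int = 5) -> HairpinCore:
    """Hairpin core from a polypurine track (or a raw arm sequence).

    The track sequence becomes the 5' arm verbatim; interruptions are
    mirrored, never complemented.
    """
    if loop_len < 3:
        raise DesignError("loop_len must be >= 3")
    arm = track.seq if isinstance(track, PurineTrack) else str(track)
    return HairpinCore(arm=arm.upper(), loop="T" * loop_len)


def build_tail(
    record: SeqRecord,
    junction: EditJunction,
    mode: str = "UD",
    w: int = 20,
    tail_strand: str = "+",
) -> HomologyTail:
    """Homology tail around ``junction`` on the RESTORED reference.

    On the plus strand ``up_seq = record[coord-w:coord]`` and
    ``down_seq = record[coord:coord+w]`` (with the default junction
    policy the downstream window begins with the recognition motif). On
    the minus strand the two windows are reverse-complemented and
    swapped so the tail still reads 5'->3' and, for mode UD, equals the
    reverse complement of the plus-strand 40-mer.
    """
    if w <= 0:
        raise DesignError("degenerate window: w must be positive")
    junction.validate(record)
    c = junction.coord
    if c - w < 0 or c + w > len(record):
        raise DesignError(
            f"junction at {c} closer than w={w} to an end of record of length {len(record)}"
        )
    up_plus = record.seq[c - w : c]
    down_plus = record.seq[c : c + w]
    if tail_strand == "+":
        return HomologyTail(up_plus, down_plus, "+", mode, w)
    if tail_strand == "-":
        return HomologyTail(
            reverse_complement(down_plus), reverse_complement(up_plus), "-", mode, w
        )
    raise DesignError("tail_strand must be + or -")


def assemble_editing_pprh(
    core: HairpinCore,
    tail: Optional[HomologyTail] = None,
    linker_len: int = 5,
    name: str = "",
) -> EditingPPRH:
    """Join tail, pentathymidine linker and hairpin core into one oligo."""
    linker = "T" * linker_len if tail is not None else ""
    return EditingPPRH(name=name, core=core, tail=tail, linker=linker)


@dataclass(frozen=True)
class Decomposition:
    """Result of parsing an oligo against the editing-PPRH grammar."""

    tail: Optional[str]
    linker: Optional[str]
    arm1: str
    loop: str
    arm2: str

    @property
    def full_seq(self) -> str:
        return (self.tail or "") + (self.linker or "") + self.arm1 + self.loop + self.arm2


class DecompositionError(ValueError):
    """No valid partition; carries the best-scoring rejected attempt."""

    def __init__(self, message: str, best_attempt: Optional[dict] = None):
        super().__init__(message)
        self.best_attempt = best_attempt


def _t_windows(seq: str, width: int = 5) -> list[tuple[int, int]]:
    """All ``width``-T windows inside maximal T-runs of length >= width."""
    windows = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "T":
            j = i
            while j < n and seq[j] == "T":
                j += 1
            if j - i >= width:
                for s in range(i, j - width + 1):
                    windows.append((s, s + width))
            i = j
        else:
            i += 1
    return windows


def try_decompose(seq: str, min_arm: int = 10) -> Optional[Decomposition]:
    """Like :func:`decompose_pprh` but returns None instead of raising."""
    try:
        return decompose_pprh(seq, min_arm)
    except DecompositionError:
        return None


def decompose_pprh(seq: str, min_arm: int = 10) -> Decomposition:
    """Parse an oligo into (tail, linker, arm1, loop, arm2).

    Enumerates placements of one (loop only) or two (linker + loop)
    exact 5-T windows inside maximal T-runs of length >= 5; a partition
    is accepted iff the arms are nonempty mirror repeats
    (``arm2 == reverse(arm1)``) with ``len(arm1) >= min_arm``. A tail
    ending in T fused to the linker yields a 6-T run; the mirror
    constraint disambiguates the split. Preference among valid
    partitions: longest arm, then longest tail, then leftmost linker.
    """
    seq = seq.upper()
    windows = _t_windows(seq, 5)
    candidates: list[Decomposition] = []
    best_reject: Optional[dict] = None
    best_reject_score = -1

    def consider(tail, linker, arm1, loop, arm2, first_start):
        nonlocal best_reject, best_reject_score
        rev = arm1[::-1]
        if arm1 and arm2 == rev and len(arm1) >= min_arm:
            candidates.append(Decomposition(tail, linker, arm1, loop, arm2))
            return
        score = sum(a == b for a, b in zip(arm2, rev))
        if score > best_reject_score:
            best_reject_score = score
            if not arm1 or arm2 != rev:
                why = "arm2 is not the reverse of arm1"
            else:
                why = f"arm shorter than min_arm={min_arm}"
            best_reject = {
                "tail": tail,
                "linker": linker,
                "arm1": arm1,
                "loop": loop,
                "arm2": arm2,
                "violation": why,
            }

    # one window: loop only, no tail/linker
    for ws, we in windows:
        consider(None, None, seq[:ws], seq[ws:we], seq[we:], ws)
    # two windows: linker + loop
    for i, (s1, e1) in enumerate(windows):
        for s2, e2 in windows[i + 1 :]:
            if s2 < e1:
                continue
            tail = seq[:s1]
            if not tail:
                continue
            consider(tail, seq[s1:e1], seq[e1:s2], seq[s2:e2], seq[e2:], s1)
    if not candidates:
        raise DecompositionError(
            "no valid editing-PPRH partition"
            + (f"; best attempt violated: {best_reject['violation']}" if best_reject else ""),
            best_attempt=best_reject,
        )

    def sort_key(d: Decomposition):
        linker_pos = len(d.tail) if d.tail is not None else len(d.arm1)
        return (-len(d.arm1), -(len(d.tail) if d.tail else 0), linker_pos)

    return sorted(candidates, key=sort_key)[0]


@dataclass
class PPRHVerdict:
    """QC summary for an arbitrary oligo against the design grammar."""

    seq: str
    decomposable: bool
    mirror_ok: bool
    arm: Optional[str] = None
    loop_len: Optional[int] = None
    linker_len: Optional[int] = None
    tail: Optional[str] = None
    arm_purity: Optional[float] = None
    tail_maps_to_reference: Optional[bool] = None
    motif_in_tail: Optional[bool] = None
    offtarget_count: Optional[int] = None
    tail_only: Optional[bool] = None
    failure: Optional[str] = None


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def validate_pprh(
    seq: str,
    config: ScanConfig = ScanConfig(),
    reference: Optional[SeqRecord] = None,
    junction: Optional[EditJunction] = None,
    min_arm: int = 10,
) -> PPRHVerdict:
    """Aggregate QC verdict (never raises for a well-formed DNA string).

    When ``reference`` (the restored, post-edit sequence) and
    ``junction`` are given, additionally checks that the tail maps
    exactly onto the reference across the junction, whether the
    recognition motif is present in the tail, and counts exact matches
    of the arm on both reference strands. ``offtarget_count`` is that
    total minus the intended target hit (floored at zero).
    """
    seq = seq.upper()
    v = PPRHVerdict(seq=seq, decomposable=False, mirror_ok=False)
    try:
        d = decompose_pprh(seq, min_arm=min_arm)
        v.decomposable = True
        v.mirror_ok = True
        v.arm = d.arm1
        v.loop_len = len(d.loop)
        v.linker_len = len(d.linker) if d.linker else None
        v.tail = d.tail
        v.arm_purity = sum(c in PURINES for c in d.arm1) / len(d.arm1)
    except DecompositionError as err:
        v.failure = str(err)

    if reference is not None and junction is not None:
        ref = reference.seq
        ref_rc = reverse_complement(ref)
        if v.decomposable and v.tail:
            v.tail_maps_to_reference = _tail_spans_junction(v.tail, reference, junction)
            v.motif_in_tail = (
                junction.motif in v.tail or reverse_complement(junction.motif) in v.tail
            )
        if v.arm:
            total = _count_occurrences(ref, v.arm) + _count_occurrences(ref_rc, v.arm)
            v.offtarget_count = max(0, total - 1)
        if not v.decomposable:
            v.tail_only = _tail_spans_junction(seq, reference, junction)
    return v


def _tail_spans_junction(tail: str, reference: SeqRecord, junction: EditJunction) -> bool:
    """True if ``tail`` maps exactly onto the reference across the junction."""
    c = junction.coord
    for hay, coord_map in (
        (reference.seq, lambda i: (i, i + len(tail))),
        (reverse_complement(reference.seq), lambda i: (len(reference) - i - len(tail), len(reference) - i)),
    ):
        start = 0
        while True:
            idx = hay.find(tail, start)
            if idx < 0:
                break
            s, e = coord_map(idx)
            if s <= c <= e:
                return True
            start = idx + 1
    return False


@dataclass
class DesignCandidate:
    """A ranked design produced by :func:`design_candidates`."""

    pprh: EditingPPRH
    track: PurineTrack
    region: str
    verdict: PPRHVerdict


def design_candidates(
    record: SeqRecord,
    restored_record: SeqRecord,
    junction: EditJunction,
    gene: GeneModel,
    config: ScanConfig = ScanConfig(),
    mode: str = "UD",
    w: int = 20,
    loop_len: int = 5,
    linker_len: int = 5,
    tail_strands: Sequence[str] = ("+", "-"),
    log: list[str] | None = None,
) -> list[DesignCandidate]:
    """Scan -> core -> tail -> assemble -> validate -> rank.

    Tracks are found on the *mutant* record; tails are built on the
    *restored* record around the junction. Because the strand-selection
    rule relating the targeted track to the tail orientation is not
    fully determined by sequence alone, both tail orientations are
    emitted per track by default ('+' first; '-' names get an ``-rc``
    suffix). Ranking: purity desc, arm length desc, track midpoint
    distance to the junction asc, then leftmost, '+' tail first.
    """
    if log is None:
        log = []
    tracks = scan_polypurine_tracks(record, config, log)
    if not tracks:
        log.append("no polypurine tracks found under the given ScanConfig")
        return []
    out: list[DesignCandidate] = []
    for track in tracks:
        region = gene.region_of((track.interval[0] + track.interval[1]) // 2)
        core = build_core(track, loop_len=loop_len)
        for strand in tail_strands:
            tail = build_tail(restored_record, junction, mode=mode, w=w, tail_strand=strand)
            name = f"LDSHp{region}I1{mode}{junction.motif_name}"
            if strand == "-":
                name += "-rc"
            pprh = assemble_editing_pprh(core, tail, linker_len=linker_len, name=name)
            verdict = validate_pprh(
                pprh.full_seq, config, reference=restored_record, junction=junction
            )
            out.append(DesignCandidate(pprh, track, region, verdict))

    def rank_key(c: DesignCandidate):
        mid = (c.track.interval[0] + c.track.interval[1]) // 2
        return (
            -c.track.purine_fraction,
            -len(c.track.seq),
            abs(mid - junction.coord),
            c.track.interval[0],
            c.pprh.tail.tail_strand != "+",
        )

    out.sort(key=rank_key)
    return out
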