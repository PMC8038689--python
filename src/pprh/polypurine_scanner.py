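"""Polypurine track scanner.

A PPRH binds, via Watson-Crick bonds, the polypyrimidine strand of a
purine/pyrimidine-asymmetric duplex region; the candidate target is
therefore a *polypurine track* on either strand. The scanner reports
every maximal interval (on both strands) whose sequence

* is at least ``min_track_len`` long,
* starts and ends on a purine (tracks are trimmed to purine boundaries),
* has purine fraction >= ``min_purity``, and
* contains no pyrimidine run longer than ``max_pyr_run``.

"Maximal" means not strictly contained in another interval that also
satisfies all of the above on the same strand. Windows containing N are
skipped and noted in the scan log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequence_model import PURINES, SeqRecord, reverse_complement

__all__ = ["ScanConfig", "PurineTrack", "scan_polypurine_tracks", "brute_force_tracks"]


@dataclass(frozen=True)
class ScanConfig:
    """Gates for track discovery.

    Defaults admit arms in the 17-22 nt range with purine fractions down
    to ~0.82 and at most a dinucleotide pyrimidine interruption — the
    loosest gates consistent with experimentally used PPRH cores.
    """

    min_track_len: int = 15
    min_purity: float = 0.80
    max_pyr_run: int = 2

    def __post_init__(self) -> None:
        if self.min_track_len < 8:
            raise ValueError("min_track_len must be >= 8")
        if not (0.5 <= self.min_purity <= 1.0):
            raise ValueError("min_purity must be in [0.5, 1.0]")
        if self.max_pyr_run < 0:
            raise ValueError("max_pyr_run must be >= 0")


@dataclass(frozen=True)
class PurineTrack:
    """A candidate PPRH target.

    ``interval`` is 0-based half-open on the plus strand; ``seq`` is the
    track read 5'->3' on its *own* strand (for '-' tracks this is the
    reverse complement of the plus-strand slice). Purity statistics are
    computed on the track's own strand.
    """

    record_id: str
    strand: str
    interval: tuple[int, int]
    seq: str

    @property
    def purine_fraction(self) -> float:
        return sum(c in PURINES for c in self.seq) / len(self.seq)

    @property
    def max_pyr_run(self) -> int:
        run = best = 0
        for c in self.seq:
            run = run + 1 if c in "CT" else 0
            best = max(best, run)
        return best

    @property
    def n_interruptions(self) -> int:
        """Number of pyrimidine runs (interruptions) inside the track."""
        n = 0
        prev_pyr = False
        for c in self.seq:
            pyr = c in "CT"
            if pyr and not prev_pyr:
                n += 1
            prev_pyr = pyr
        return n

    def satisfies(self, config: ScanConfig) -> bool:
        return (
            len(self.seq) >= config.min_track_len
            and self.seq[0] in PURINES
            and self.seq[-1] in PURINES
            and self.purine_fraction >= config.min_purity
            and self.max_pyr_run <= config.max_pyr_run
            and "N" not in self.seq
        )


def _valid_intervals_in_segment(
    seq: str, seg_start: int, seg_end: int, config: ScanConfig
) -> list[tuple[int, int]]:
    """All intervals within [seg_start, seg_end) passing every gate.

    The segment is guaranteed free of N and of pyrimidine runs longer
    than ``max_pyr_run``, so only length, purity and purine boundaries
    need checking. Purity uses a prefix sum for O(1) queries.
    """
    purine_pos = [i for i in range(seg_start, seg_end) if seq[i] in PURINES]
    if not purine_pos:
        return []
    pur_prefix = [0]
    for i in range(seg_start, seg_end):
        pur_prefix.append(pur_prefix[-1] + (seq[i] in PURINES))
    out = []
    for a in purine_pos:
        for b in purine_pos:
            if b - a + 1 < config.min_track_len:
                continue
            n_pur = pur_prefix[b + 1 - seg_start] - pur_prefix[a - seg_start]
            if n_pur / (b - a + 1) >= config.min_purity:
                out.append((a, b + 1))
    return out


def _keep_maximal(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop intervals strictly contained in another (containment maximality)."""
    kept = []
    max_end = -1
    for s, e in sorted(set(intervals), key=lambda iv: (iv[0], -iv[1])):
        if e > max_end:
            kept.append((s, e))
            max_end = e
    return kept


def _scan_one_strand(seq: str, config: ScanConfig, log: list[str]) -> list[tuple[int, int]]:
    """Maximal valid intervals in strand-local coordinates."""
    # Break at N and at pyrimidine runs longer than max_pyr_run: no valid
    # interval can span either, so segments are independent.
    n = len(seq)
    intervals: list[tuple[int, int]] = []
    seg_start = 0
    i = 0
    breaks: list[tuple[int, int]] = []  # half-open break regions
    while i < n:
        if seq[i] == "N":
            breaks.append((i, i + 1))
            log.append(f"skipped N at strand-local position {i}")
            i += 1
        elif seq[i] in "CT":
            j = i
            while j < n and seq[j] in "CT":
                j += 1
            if j - i > config.max_pyr_run:
                breaks.append((i, j))
            i = j
        else:
            i += 1
    prev = 0
    segments = []
    for bs, be in breaks:
        if bs > prev:
            segments.append((prev, bs))
        prev = be
    if prev < n:
        segments.append((prev, n))
    for seg_start, seg_end in segments:
        intervals.extend(_valid_intervals_in_segment(seq, seg_start, seg_end, config))
    return _keep_maximal(intervals)


def scan_polypurine_tracks(
    record: SeqRecord,
    config: ScanConfig = ScanConfig(),
    log: list[str] | None = None,
) -> list[PurineTrack]:
    """All maximal polypurine tracks on both strands of ``record``.

    Tracks are sorted plus strand first, then by start coordinate. A
    plus-strand polypurine track implies a poly*pyrimidine* region on
    the minus strand, so the same interval can never be reported twice;
    both strands are scanned independently.
    """
    if log is None:
        log = []
    L = len(record)
    if L < config.min_track_len:
        return []
    tracks: list[PurineTrack] = []
    plus = record.seq
    for s, e in _scan_one_strand(plus, config, log):
        tracks.append(PurineTrack(record.id, "+", (s, e), plus[s:e]))
    minus = reverse_complement(plus)
    for s, e in _scan_one_strand(minus, config, log):
        # map strand-local [s,e) on the reverse complement back to + coords
        tracks.append(PurineTrack(record.id, "-", (L - e, L - s), minus[s:e]))
    tracks.sort(key=lambda t: (t.strand != "+", t.interval[0], t.interval[1]))
    return tracks


def brute_force_tracks(
    record: SeqRecord, config: ScanConfig = ScanConfig()
) -> list[PurineTrack]:
    """Exhaustive-enumeration oracle for :func:`scan_polypurine_tracks`.

    Enumerates every substring on both strands, filters by the gates,
    and keeps containment-maximal intervals. Guarded to short records.
    """
    L = len(record)
    if L > 2000:
        raise ValueError("brute_force_tracks is a test oracle; record must be <= 2000 nt")
    tracks: list[PurineTrack] = []
    for strand in "+-":
        seq = record.seq if strand == "+" else reverse_complement(record.seq)
        valid = []
        for i in range(L):
            for j in range(i + config.min_track_len, L + 1):
                cand = PurineTrack(record.id, strand, (i, j), seq[i:j])
                if cand.satisfies(config):
                    valid.append((i, j))
        for s, e in _keep_maximal(valid):
            if strand == "+":
                tracks.append(PurineTrack(record.id, "+", (s, e), seq[s:e]))
            else:
                tracks.append(PurineTrack(record.id, "-", (L - e, L - s), seq[s:e]))
    tracks.sort(key=lambda t: (t.strand != "+", t.interval[0], t.interval[1]))
    return tracks
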