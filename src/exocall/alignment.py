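"""Alignment input and pileup construction.

Streams coordinate-sorted SAM/BAM into a light internal read model, applies
the per-read quality filters used to define effective depth, and compiles
per-locus site stacks carrying the read context (base quality, distance to
the 3' end, strand, per-read variation rate) that the feature modules
consume.

Coordinates are 0-based half-open internally; SAM/VCF conversion happens at
the I/O boundary.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

GAP = "-"

#: CIGAR operations that consume the query sequence.
_QUERY_OPS = set("MIS=X")
#: CIGAR operations that consume the reference.
_REF_OPS = set("MDN=X")

_OP_CHARS = "MIDNSHP=X"


class UnsortedInputError(ValueError):
    """Raised when reads are not in coordinate order."""


@dataclass
class AlignedRead:
    """One mapped read.

    ``pos`` is the 0-based leftmost reference coordinate of the alignment.
    ``cigar`` is an ordered list of ``(op, length)`` with op in
    ``M I D N S H P = X``.
    """

    read_id: str
    chrom: str
    pos: int
    strand: str  # "+" or "-"
    sequence: str
    base_qualities: Sequence[int]
    cigar: Sequence[tuple[str, int]]
    mapping_quality: int

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError("sequence and base_qualities lengths differ")
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.sequence):
            raise ValueError(
                f"CIGAR query length {qlen} != sequence length {len(self.sequence)}"
            )
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    # -- derived geometry ---------------------------------------------------

    @property
    def query_start(self) -> int:
        """Index of the first non-soft-clipped query base."""
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def query_end(self) -> int:
        """One past the last non-soft-clipped query base."""
        if self.cigar and self.cigar[-1][0] == "S":
            return len(self.sequence) - self.cigar[-1][1]
        return len(self.sequence)

    @property
    def aligned_length(self) -> int:
        """Query bases excluding soft clips; the read length used by features."""
        return self.query_end - self.query_start

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in _REF_OPS)

    def walk(self) -> Iterator[tuple[str, int, int, int]]:
        """Yield ``(op, length, ref_pos, query_pos)`` per CIGAR op."""
        rpos, qpos = self.pos, 0
        for op, n in self.cigar:
            yield op, n, rpos, qpos
            if op in _REF_OPS:
                rpos += n
            if op in _QUERY_OPS:
                qpos += n

    def aligned_index(self) -> dict[int, int]:
        """Map reference position -> query index for M/=/X columns."""
        out: dict[int, int] = {}
        for op, n, rpos, qpos in self.walk():
            if op in "M=X":
                for i in range(n):
                    out[rpos + i] = qpos + i
        return out

    def deletion_spans(self) -> list[tuple[int, int, int]]:
        """``(ref_start, ref_end, anchor_qpos)`` for each D op.

        ``anchor_qpos`` is the query index of the base preceding the gap.
        """
        return [
            (rpos, rpos + n, qpos - 1)
            for op, n, rpos, qpos in self.walk()
            if op == "D"
        ]

    def insertion_events(self) -> list[tuple[int, int, int]]:
        """``(ref_pos_after, qpos, length)`` for each I op."""
        return [(rpos, qpos, n) for op, n, rpos, qpos in self.walk() if op == "I"]


@dataclass
class ReadObservation:
    """One read's evidence at one locus."""

    base: str  # A/C/G/T/N or GAP
    base_quality: int | None
    dist3: int
    strand: str
    variation_rate: float
    near_read_end: bool
    source_read_id: str
    # Pooled NBQ window (variant base + <=5 flanks each side, truncated at
    # read boundaries); carried so features need no read back-reference.
    window_qual_sum: float = 0.0
    window_qual_n: int = 0


@dataclass
class SiteStack:
    """The pileup at one locus."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    observations: list[ReadObservation] = field(default_factory=list)
    color_corrected_count: int = 0

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class ReadFilterConfig:
    """Per-read quality filters defining the effective reads.

    ``mapq_mode`` is either ``"exact255"`` (uniquely-mapped flag used by
    aligners that reserve 255, the mode the SOLiD pipeline assumes) or
    ``"min:N"`` for a conventional minimum mapping-quality threshold.
    """

    max_variant_events: int = 3
    mapq_mode: str = "exact255"

    def mapq_ok(self, mapq: int) -> bool:
        if self.mapq_mode == "exact255":
            return mapq == 255
        if self.mapq_mode.startswith("min:"):
            return mapq >= int(self.mapq_mode.split(":", 1)[1])
        raise ValueError(f"unknown mapq_mode {self.mapq_mode!r}")


# ---------------------------------------------------------------------------
# reference access


def ref_slice(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence [start, end), from a dict or pyfaidx.Fasta."""
    if start < 0:
        raise ValueError("reference window start < 0")
    seq = reference[chrom]
    out = str(seq[start:end]).upper()
    if len(out) < end - start:
        raise ValueError(
            f"reference window {chrom}:{start}-{end} extends past contig end"
        )
    return out


# ---------------------------------------------------------------------------
# SAM/BAM streaming


def _from_pysam(aln: pysam.AlignedSegment) -> AlignedRead:
    cigar = [(_OP_CHARS[op], n) for op, n in aln.cigartuples]
    return AlignedRead(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        pos=aln.reference_start,
        strand="-" if aln.is_reverse else "+",
        sequence=aln.query_sequence,
        base_qualities=list(aln.query_qualities),
        cigar=cigar,
        mapping_quality=aln.mapping_quality,
    )


def read_alignments(path) -> Iterator[AlignedRead]:
    """Stream a coordinate-sorted SAM/BAM as :class:`AlignedRead`.

    Unmapped and duplicate-flagged reads are skipped.  Order is verified on
    the fly; an out-of-order record raises :class:`UnsortedInputError`.
    Memory is independent of file size (one record at a time).
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        last: tuple[int, int] | None = None
        for aln in af:
            if aln.is_unmapped or aln.is_duplicate:
                continue
            key = (aln.reference_id, aln.reference_start)
            if last is not None and key < last:
                raise UnsortedInputError(
                    f"input not coordinate-sorted at {aln.reference_name}:"
                    f"{aln.reference_start + 1}"
                )
            last = key
            yield _from_pysam(aln)


# ---------------------------------------------------------------------------
# per-read metrics


def _mismatch_positions(read: AlignedRead, reference) -> list[int]:
    out = []
    for op, n, rpos, qpos in read.walk():
        if op in "M=X":
            ref = ref_slice(reference, read.chrom, rpos, rpos + n)
            for i in range(n):
                b = read.sequence[qpos + i]
                if b != ref[i] and b != "N":
                    out.append(rpos + i)
    return out


def variant_event_count(read: AlignedRead, reference) -> int:
    """Mismatched bases plus indel events (each gap counts once)."""
    n_indel = sum(1 for op, _n in read.cigar if op in "ID")
    return len(_mismatch_positions(read, reference)) + n_indel


def variation_rate(read: AlignedRead, reference) -> float:
    """(mismatches + gap events) / aligned read length.

    A cheap surrogate for mapping quality: reads from mismapped or
    misaligned locations accumulate excess mismatches and gaps.
    """
    return variant_event_count(read, reference) / read.aligned_length


def passes_read_filters(
    read: AlignedRead, cfg: ReadFilterConfig, reference
) -> bool:
    """Effective-read test: mapping-quality rule and <= max variant events."""
    if not cfg.mapq_ok(read.mapping_quality):
        return False
    return variant_event_count(read, reference) <= cfg.max_variant_events


def distance_to_3prime(read: AlignedRead, query_index: int) -> int:
    """Distance (bases) from a query position to the read's 3' end.

    Measured in sequencing orientation and excluding soft clips: for a
    forward read the 3' end is the rightmost aligned base, for a reverse
    read the leftmost one in stored (reference) orientation.
    """
    if not (0 <= query_index < len(read.sequence)):
        raise IndexError(f"query index {query_index} out of range")
    if read.strand == "+":
        return read.query_end - 1 - query_index
    return query_index - read.query_start


def near_read_end(read: AlignedRead, query_index: int, threshold: int = 5) -> bool:
    """Whether a query position lies within ``threshold`` bp of either read end."""
    d_left = query_index - read.query_start
    d_right = read.query_end - 1 - query_index
    return min(d_left, d_right) <= threshold


def nbq_window(
    read: AlignedRead, query_index: int, flank: int = 5
) -> tuple[float, int]:
    """Sum and count of qualities in the NBQ window around ``query_index``.

    The window is the base itself plus up to ``flank`` bases on each side,
    truncated at the (clip-adjusted) read boundaries.
    """
    lo = max(read.query_start, query_index - flank)
    hi = min(read.query_end, query_index + flank + 1)
    quals = read.base_qualities[lo:hi]
    return float(sum(quals)), len(quals)


# ---------------------------------------------------------------------------
# pileup


def make_observation(
    read: AlignedRead, qpos: int, vrate: float
) -> ReadObservation:
    wsum, wn = nbq_window(read, qpos)
    return ReadObservation(
        base=read.sequence[qpos],
        base_quality=int(read.base_qualities[qpos]),
        dist3=distance_to_3prime(read, qpos),
        strand=read.strand,
        variation_rate=vrate,
        near_read_end=near_read_end(read, qpos),
        source_read_id=read.read_id,
        window_qual_sum=wsum,
        window_qual_n=wn,
    )


def _gap_observation(
    read: AlignedRead, anchor_qpos: int, vrate: float
) -> ReadObservation:
    return ReadObservation(
        base=GAP,
        base_quality=None,
        dist3=distance_to_3prime(read, max(anchor_qpos, read.query_start)),
        strand=read.strand,
        variation_rate=vrate,
        near_read_end=near_read_end(read, max(anchor_qpos, read.query_start)),
        source_read_id=read.read_id,
    )


def build_site_stack(
    reads: Iterable[AlignedRead],
    chrom: str,
    pos: int,
    reference,
    color_corrected_count: int = 0,
) -> SiteStack:
    """Compile the pileup at one 0-based locus from covering reads.

    Aligned bases yield base observations; deletions spanning the locus
    yield GAP observations.  Reads are assumed to have already passed the
    read filters.
    """
    ref_base = ref_slice(reference, chrom, pos, pos + 1)
    stack = SiteStack(chrom, pos, ref_base, color_corrected_count=color_corrected_count)
    for read in reads:
        if read.chrom != chrom or not (read.pos <= pos < read.reference_end):
            continue
        vrate = variation_rate(read, reference)
        qpos = read.aligned_index().get(pos)
        if qpos is not None:
            stack.observations.append(make_observation(read, qpos, vrate))
        else:
            for dstart, dend, anchor in read.deletion_spans():
                if dstart <= pos < dend:
                    stack.observations.append(_gap_observation(read, anchor, vrate))
                    break
    return stack


class PileupStream:
    """Streaming pileup over coordinate-sorted reads.

    Yields ``SiteStack`` for every covered reference position in order,
    retaining only reads overlapping the active window.  ``max_retained``
    instruments the streaming contract: it tracks the largest number of
    reads held simultaneously, which is bounded by depth x read length and
    independent of the total number of reads.
    """

    def __init__(self, reads: Iterable[AlignedRead], reference,
                 read_filter: ReadFilterConfig | None = None):
        self._reads = iter(reads)
        self._reference = reference
        self._filter = read_filter
        self.max_retained = 0
        self.n_reads = 0

    def __iter__(self) -> Iterator[SiteStack]:
        ref = self._reference
        active: deque = deque()  # (read, aligned_index, del_spans, vrate)
        emit_from: int | None = None
        chrom: str | None = None

        def columns(upto: int | None) -> Iterator[SiteStack]:
            nonlocal emit_from, active
            if chrom is None or emit_from is None:
                return
            end = max((r.reference_end for r, *_ in active), default=emit_from)
            stop = end if upto is None else min(upto, end)
            for pos in range(emit_from, stop):
                while active and active[0][0].reference_end <= pos:
                    active.popleft()
                if not active:
                    continue
                stack = SiteStack(chrom, pos, ref_slice(ref, chrom, pos, pos + 1))
                for read, aidx, dspans, vrate in active:
                    if read.pos > pos:
                        break
                    qpos = aidx.get(pos)
                    if qpos is not None:
                        stack.observations.append(make_observation(read, qpos, vrate))
                    else:
                        for dstart, dend, anchor in dspans:
                            if dstart <= pos < dend:
                                stack.observations.append(
                                    _gap_observation(read, anchor, vrate)
                                )
                                break
                if stack.observations:
                    yield stack
            emit_from = stop

        for read in self._reads:
            self.n_reads += 1
            if self._filter is not None and not passes_read_filters(
                read, self._filter, ref
            ):
                continue
            if chrom is not None and read.chrom == chrom and read.pos < (emit_from or 0):
                raise UnsortedInputError(f"read {read.read_id} out of order")
            if read.chrom != chrom:
                yield from columns(None)
                active.clear()
                chrom = read.chrom
                emit_from = read.pos
            else:
                yield from columns(read.pos)
                while active and active[0][0].reference_end <= read.pos:
                    active.popleft()
            active.append(
                (read, read.aligned_index(), read.deletion_spans(),
                 variation_rate(read, ref))
            )
            self.max_retained = max(self.max_retained, len(active))
        yield from columns(None)
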