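"""INDEL candidate discovery and model covariates.

Candidates come straight from I/D CIGAR operations, left-normalized against
the reference so that every aligner placement of the same haplotype event
maps to one canonical (chrom, pos, ref, alt) key.

The INDEL classifier uses four terms: the normalized variant square
(NVS = variant reads squared / total depth, coupling variant depth and
variant ratio in one covariate), the mean NBQ over the gap flanks, the mean
variation rate of the variant reads (a mapping-quality surrogate), and the
read-end ratio (fraction of variant reads where the event sits within 5 bp
of a read end, where both sequencing and gapped mapping degrade).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from exocall.alignment import (
    AlignedRead,
    near_read_end,
    ref_slice,
    variation_rate,
)

INDEL_VARIABLES = ("nvs", "mean_nbq", "mean_variation_rate", "read_end_ratio")


@dataclass(frozen=True)
class IndelCandidate:
    """A left-normalized insertion or deletion in VCF anchor convention.

    ``pos`` is the 0-based coordinate of the anchor base (the reference base
    preceding the event); ``ref_allele``/``alt_allele`` both start with it.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    @property
    def kind(self) -> str:
        return "INS" if len(self.alt_allele) > len(self.ref_allele) else "DEL"

    @property
    def length(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("not an indel: alleles have equal length")


@dataclass
class IndelSupport:
    """Per-read evidence for one candidate, captured at extraction time."""

    read_id: str
    strand: str
    variation_rate: float
    near_read_end: bool
    nbq_sum: float
    nbq_n: int


@dataclass
class IndelFeatures:
    nvs: float
    mean_nbq: float
    mean_variation_rate: float
    read_end_ratio: float
    var_depth: int
    total_depth: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEL_VARIABLES}


# ---------------------------------------------------------------------------
# candidate normalization


def left_normalize(
    chrom: str, pos: int, ref_allele: str, alt_allele: str, reference
) -> IndelCandidate:
    """Shift an anchored indel left while the representation is ambiguous.

    A gap can be shifted one base left whenever the last base of the longer
    allele equals the reference base before the anchor; repeating until that
    fails yields the canonical VCF form.  Idempotent by construction.
    """
    longer = ref_allele if len(ref_allele) > len(alt_allele) else alt_allele
    shorter = alt_allele if len(ref_allele) > len(alt_allele) else ref_allele
    if len(shorter) != 1 or longer[0] != shorter[0]:
        raise ValueError("expected anchor-base representation (anchor + event)")
    event = longer[1:]
    # The event can move one base left whenever its last base equals the
    # current anchor base; the new event is anchor + event[:-1].
    while pos > 0:
        anchor = ref_slice(reference, chrom, pos, pos + 1)
        if event[-1] != anchor:
            break
        event = anchor + event[:-1]
        pos -= 1
    anchor = ref_slice(reference, chrom, pos, pos + 1)
    if len(ref_allele) > len(alt_allele):
        return IndelCandidate(chrom, pos, anchor + event, anchor)
    return IndelCandidate(chrom, pos, anchor, anchor + event)


def extract_indel_candidates(
    read: AlignedRead, reference
) -> list[tuple[IndelCandidate, IndelSupport]]:
    """One left-normalized candidate per I/D CIGAR op, with read support."""
    out: list[tuple[IndelCandidate, IndelSupport]] = []
    vrate = variation_rate(read, reference)
    for op, n, rpos, qpos in read.walk():
        if op == "D":
            if rpos + n > len(reference[read.chrom]):
                raise ValueError("deletion extends past reference end")
            anchor_pos = rpos - 1
            deleted = ref_slice(reference, read.chrom, rpos, rpos + n)
            anchor = ref_slice(reference, read.chrom, anchor_pos, anchor_pos + 1)
            cand = left_normalize(
                read.chrom, anchor_pos, anchor + deleted, anchor, reference
            )
            # NBQ over <=5 read bases flanking the gap (no sequenced base
            # exists for the deleted positions themselves)
            lo = max(read.query_start, qpos - 5)
            hi = min(read.query_end, qpos + 5)
            quals = read.base_qualities[lo:hi]
            edge_q = max(qpos - 1, read.query_start)
            support = IndelSupport(
                read_id=read.read_id,
                strand=read.strand,
                variation_rate=vrate,
                near_read_end=(
                    near_read_end(read, edge_q)
                    or near_read_end(read, min(qpos, read.query_end - 1))
                ),
                nbq_sum=float(sum(quals)),
                nbq_n=len(quals),
            )
            out.append((cand, support))
        elif op == "I":
            anchor_pos = rpos - 1
            inserted = read.sequence[qpos : qpos + n]
            anchor = ref_slice(reference, read.chrom, anchor_pos, anchor_pos + 1)
            cand = left_normalize(
                read.chrom, anchor_pos, anchor, anchor + inserted, reference
            )
            # NBQ: inserted bases plus <=5 flanks on each side
            lo = max(read.query_start, qpos - 5)
            hi = min(read.query_end, qpos + n + 5)
            quals = read.base_qualities[lo:hi]
            support = IndelSupport(
                read_id=read.read_id,
                strand=read.strand,
                variation_rate=vrate,
                near_read_end=(
                    near_read_end(read, qpos)
                    or near_read_end(read, min(qpos + n - 1, read.query_end - 1))
                ),
                nbq_sum=float(sum(quals)),
                nbq_n=len(quals),
            )
            out.append((cand, support))
    return out


# ---------------------------------------------------------------------------
# covariates


def nvs(var_depth: int, total_depth: int) -> float:
    """Normalized variant square: variant reads squared over total depth."""
    if total_depth < 1:
        raise ValueError("total_depth must be >= 1")
    if not (0 <= var_depth <= total_depth):
        raise ValueError("need 0 <= var_depth <= total_depth")
    return var_depth * var_depth / total_depth


def read_end_ratio(supports: Iterable[IndelSupport]) -> float:
    """Fraction of variant reads with the event within 5 bp of a read end."""
    supports = list(supports)
    if not supports:
        raise ValueError("no variant reads")
    return sum(1 for s in supports if s.near_read_end) / len(supports)


def indel_feature_vector(
    supports: Iterable[IndelSupport], total_depth: int
) -> IndelFeatures:
    """All four INDEL covariates from per-read support records.

    ``total_depth`` is the number of passing reads spanning the anchor
    position (base and gap observations alike).
    """
    supports = list(supports)
    if not supports:
        raise ValueError("no variant reads for candidate")
    var_depth = len(supports)
    nbq_total = sum(s.nbq_sum for s in supports)
    nbq_n = sum(s.nbq_n for s in supports)
    return IndelFeatures(
        nvs=nvs(var_depth, total_depth),
        mean_nbq=nbq_total / nbq_n,
        mean_variation_rate=sum(s.variation_rate for s in supports) / var_depth,
        read_end_ratio=read_end_ratio(supports),
        var_depth=var_depth,
        total_depth=total_depth,
    )
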