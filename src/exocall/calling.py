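"""SNP and INDEL calling: candidate discovery, scoring, filtering, genotyping.

A candidate site's pileup features are scored by the logistic model to a
probability p; calls must then clear heuristic filters (all defaults are
the trained pipeline's published operating points):

* SNPs: p >= 0.5 and variant read depth >= 2, inside the callable region
  (effective depth >= 6).
* INDELs: p >= 0.5 (>= 0.88 for single base-pair deletions), variant
  reads >= 2, total depth >= 2, variant read ratio >= 0.05.

Passing calls are genotyped from the adjusted variant ratio
t = var_depth / (total_depth - color_corrected): t >= 0.8 homozygous,
t >= 0.1 heterozygous, below that the call is demoted (filter "low_t").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from exocall.alignment import (
    GAP,
    AlignedRead,
    PileupStream,
    ReadFilterConfig,
    SiteStack,
    read_alignments,
    ref_slice,
)
from exocall.features.indel import (
    INDEL_VARIABLES,
    IndelCandidate,
    IndelSupport,
    extract_indel_candidates,
    indel_feature_vector,
)
from exocall.features.snp import snp_feature_vector
from exocall.model import LogisticModel

BASES = "ACGT"


@dataclass
class SnpFilterConfig:
    min_p: float = 0.5
    min_var_depth: int = 2


@dataclass
class IndelFilterConfig:
    min_p: float = 0.5
    min_p_1bp_del: float = 0.88
    min_var_depth: int = 2
    min_total_depth: int = 2
    min_var_ratio: float = 0.05


@dataclass
class CallableConfig:
    min_effective_depth: int = 6


@dataclass
class GenotypeConfig:
    het_t: float = 0.1
    hom_t: float = 0.8

    def __post_init__(self) -> None:
        if not self.het_t < self.hom_t:
            raise ValueError("het_t must be < hom_t")


@dataclass
class FilterConfig:
    snp: SnpFilterConfig = field(default_factory=SnpFilterConfig)
    indel: IndelFilterConfig = field(default_factory=IndelFilterConfig)
    read: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    callable: CallableConfig = field(default_factory=CallableConfig)
    genotype: GenotypeConfig = field(default_factory=GenotypeConfig)

    def __post_init__(self) -> None:
        for p in (self.snp.min_p, self.indel.min_p, self.indel.min_p_1bp_del):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p cutoffs must be in [0, 1]")


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 0-based; SNP site or indel anchor
    ref_allele: str
    alt_allele: str
    kind: str  # SNP / INS / DEL
    p: float
    t: float | None
    genotype: str | None  # het / hom / None
    var_depth: int
    total_depth: int
    effective_depth: int
    filters_failed: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.filters_failed


@dataclass
class CallableRegion:
    chrom: str
    intervals: list[tuple[int, int]]  # 0-based half-open, sorted, merged

    @property
    def total_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        from bisect import bisect_right

        i = bisect_right(self.intervals, (pos, float("inf"))) - 1
        return i >= 0 and self.intervals[i][0] <= pos < self.intervals[i][1]


# ---------------------------------------------------------------------------
# elementary operations


def effective_depth(stack: SiteStack) -> int:
    """Reads carrying a reference or variant *base* at the site.

    Gap and N observations are excluded; reads failing the read filters
    never reach the stack.
    """
    return sum(1 for o in stack.observations if o.base in BASES)


def adjusted_variant_ratio(
    var_depth: int, total_depth: int, color_corrected: int = 0
) -> float:
    """t = variant depth / (total depth - color-corrected bases)."""
    denom = total_depth - color_corrected
    if denom < 1:
        raise ValueError("total_depth - color_corrected must be >= 1")
    if not 0 <= var_depth <= denom:
        raise ValueError("need 0 <= var_depth <= total_depth - color_corrected")
    return var_depth / denom


def genotype_from_t(t: float, cfg: GenotypeConfig | None = None) -> str | None:
    """hom for t >= 0.8, het for 0.1 <= t < 0.8, None below (both inclusive)."""
    cfg = cfg or GenotypeConfig()
    if t >= cfg.hom_t:
        return "hom"
    if t >= cfg.het_t:
        return "het"
    return None


def callable_regions(
    depths: Iterable[tuple[str, int, int]],
    cfg: CallableConfig | None = None,
) -> dict[str, CallableRegion]:
    """Merge runs of positions with effective depth >= threshold.

    ``depths`` yields (chrom, pos, effective_depth) in coordinate order;
    positions not yielded count as depth 0.
    """
    cfg = cfg or CallableConfig()
    out: dict[str, CallableRegion] = {}
    cur_chrom, run_start, last_pos = None, None, None
    for chrom, pos, depth in depths:
        ok = depth >= cfg.min_effective_depth
        if chrom != cur_chrom or (run_start is not None and pos != last_pos + 1):
            if run_start is not None:
                out.setdefault(cur_chrom, CallableRegion(cur_chrom, [])).intervals.append(
                    (run_start, last_pos + 1)
                )
            run_start = None
            cur_chrom = chrom
        if ok and run_start is None:
            run_start = pos
        elif not ok and run_start is not None:
            out.setdefault(chrom, CallableRegion(chrom, [])).intervals.append(
                (run_start, pos)
            )
            run_start = None
        last_pos = pos
    if run_start is not None:
        out.setdefault(cur_chrom, CallableRegion(cur_chrom, [])).intervals.append(
            (run_start, last_pos + 1)
        )
    return out


# ---------------------------------------------------------------------------
# pure filter logic (exercised directly by the boundary tests)


def snp_filter_failures(
    p: float,
    var_depth: int,
    in_callable: bool,
    cfg: FilterConfig,
) -> list[str]:
    failed = []
    if p < cfg.snp.min_p:
        failed.append("low_p")
    if var_depth < cfg.snp.min_var_depth:
        failed.append("min_var_depth")
    if not in_callable:
        failed.append("callable")
    return failed


def indel_filter_failures(
    p: float,
    kind: str,
    length: int,
    var_depth: int,
    total_depth: int,
    cfg: FilterConfig,
) -> list[str]:
    failed = []
    min_p = (
        cfg.indel.min_p_1bp_del
        if kind == "DEL" and length == 1
        else cfg.indel.min_p
    )
    if p < min_p:
        failed.append("low_p")
    if var_depth < cfg.indel.min_var_depth:
        failed.append("min_var_depth")
    if total_depth < cfg.indel.min_total_depth:
        failed.append("min_total_depth")
    if total_depth == 0 or var_depth / total_depth < cfg.indel.min_var_ratio:
        failed.append("low_var_ratio")
    return failed


def _genotype_or_demote(
    call: VariantCall, cfg: FilterConfig
) -> None:
    if call.filters_failed:
        return
    gt = genotype_from_t(call.t, cfg.genotype)
    if gt is None:
        call.filters_failed.append("low_t")
    else:
        call.genotype = gt


# ---------------------------------------------------------------------------
# region helpers


def _in_regions(regions, chrom: str, pos: int) -> bool:
    if regions is None:
        return True
    ivs = regions.get(chrom)
    if not ivs:
        return False
    from bisect import bisect_right

    i = bisect_right(ivs, (pos, float("inf"))) - 1
    return i >= 0 and ivs[i][0] <= pos < ivs[i][1]


def load_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read a 0-based half-open BED into per-chrom sorted interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            out.setdefault(parts[0], []).append((start, end))
    for ivs in out.values():
        ivs.sort()
    return out


def load_color_sidecar(path) -> dict[tuple[str, int], int]:
    """Per-site color-corrected base counts: chrom <tab> pos(1-based) <tab> count."""
    out: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, count = line.split("\t")[:3]
            out[(chrom, int(pos) - 1)] = int(count)
    return out


# ---------------------------------------------------------------------------
# callers


def _as_reads(alignments) -> Iterator[AlignedRead]:
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        return read_alignments(alignments)
    return iter(alignments)


def call_snps(
    alignments,
    reference,
    model: LogisticModel,
    cfg: FilterConfig | None = None,
    regions: Mapping[str, list[tuple[int, int]]] | None = None,
    color_corrected: Mapping[tuple[str, int], int] | None = None,
    keep_filtered: bool = False,
    collect_callable: dict | None = None,
) -> list[VariantCall]:
    """Call SNPs over a sorted alignment stream.

    Every locus (within ``regions`` if given) with at least one non-reference
    base observation is scored; each alternate base present becomes its own
    candidate.  Pass ``collect_callable={}`` to also receive the callable
    regions (filled in place, chrom -> CallableRegion).

    Site total depth (DP) is the effective depth: reads carrying a
    reference or variant base after read filtering.
    """
    cfg = cfg or FilterConfig()
    color_corrected = color_corrected or {}
    calls: list[VariantCall] = []
    depth_track: list[tuple[str, int, int]] = []
    stream = PileupStream(_as_reads(alignments), reference, cfg.read)
    for stack in stream:
        eff = effective_depth(stack)
        depth_track.append((stack.chrom, stack.pos, eff))
        if not _in_regions(regions, stack.chrom, stack.pos):
            continue
        alt_bases = sorted(
            {o.base for o in stack.observations}
            - {stack.ref_base, GAP, "N"}
        )
        if not alt_bases:
            continue
        in_callable = eff >= cfg.callable.min_effective_depth
        cc = color_corrected.get((stack.chrom, stack.pos), 0)
        for alt in alt_bases:
            feats = snp_feature_vector(stack, alt)
            p = model.score(feats.as_dict())
            failed = snp_filter_failures(p, feats.var_depth, in_callable, cfg)
            denom = eff - cc
            t = feats.var_depth / denom if denom >= 1 else None
            call = VariantCall(
                chrom=stack.chrom,
                pos=stack.pos,
                ref_allele=stack.ref_base,
                alt_allele=alt,
                kind="SNP",
                p=p,
                t=t,
                genotype=None,
                var_depth=feats.var_depth,
                total_depth=eff,
                effective_depth=eff,
                filters_failed=failed,
            )
            if t is None and not failed:
                call.filters_failed.append("low_t")
            else:
                _genotype_or_demote(call, cfg)
            if call.passed or keep_filtered:
                calls.append(call)
    if collect_callable is not None:
        collect_callable.update(callable_regions(depth_track, cfg.callable))
    return calls


def call_indels(
    alignments,
    reference,
    model: LogisticModel,
    cfg: FilterConfig | None = None,
    regions: Mapping[str, list[tuple[int, int]]] | None = None,
    color_corrected: Mapping[tuple[str, int], int] | None = None,
    keep_filtered: bool = False,
) -> list[VariantCall]:
    """Call INDELs: candidates come from I/D CIGAR ops, left-normalized and
    keyed by (chrom, pos, ref, alt); total depth is the number of passing
    reads spanning the anchor position."""
    from exocall.alignment import passes_read_filters

    cfg = cfg or FilterConfig()
    color_corrected = color_corrected or {}
    support: dict[IndelCandidate, list[IndelSupport]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for read in _as_reads(alignments):
        if not passes_read_filters(read, cfg.read, reference):
            continue
        spans.setdefault(read.chrom, []).append((read.pos, read.reference_end))
        for cand, sup in extract_indel_candidates(read, reference):
            support.setdefault(cand, []).append(sup)

    # spanning depth per anchor via sorted starts/ends
    import bisect

    span_index = {}
    for chrom, ivs in spans.items():
        starts = sorted(s for s, _ in ivs)
        ends = sorted(e for _, e in ivs)
        span_index[chrom] = (starts, ends)

    def spanning_depth(chrom: str, pos: int) -> int:
        if chrom not in span_index:
            return 0
        starts, ends = span_index[chrom]
        return bisect.bisect_right(starts, pos) - bisect.bisect_right(ends, pos)

    calls: list[VariantCall] = []
    for cand in sorted(
        support, key=lambda c: (c.chrom, c.pos, c.ref_allele, c.alt_allele)
    ):
        if not _in_regions(regions, cand.chrom, cand.pos):
            continue
        sups = support[cand]
        total = spanning_depth(cand.chrom, cand.pos)
        feats = indel_feature_vector(sups, total)
        p = model.score(feats.as_dict())
        failed = indel_filter_failures(
            p, cand.kind, cand.length, feats.var_depth, total, cfg
        )
        cc = color_corrected.get((cand.chrom, cand.pos), 0)
        denom = total - cc
        t = feats.var_depth / denom if denom >= 1 else None
        call = VariantCall(
            chrom=cand.chrom,
            pos=cand.pos,
            ref_allele=cand.ref_allele,
            alt_allele=cand.alt_allele,
            kind=cand.kind,
            p=p,
            t=t,
            genotype=None,
            var_depth=feats.var_depth,
            total_depth=total,
            effective_depth=total,
            filters_failed=failed,
        )
        if t is None and not failed:
            call.filters_failed.append("low_t")
        else:
            _genotype_or_demote(call, cfg)
        if call.passed or keep_filtered:
            calls.append(call)
    return calls
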