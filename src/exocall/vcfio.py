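"""VCF output, reading, population merging and target splitting.

Single-sample call sets are written as VCF 4.1 with the per-sample fields
GT (genotype), DP (total depth), VR (variant read depth) and TR (adjusted
variant ratio t), and the site probability p in INFO.  Multiple
single-sample VCFs merge into a population VCF over the union of sites;
a sample without a call at a union site is filled from its depth track
(0/0 with the observed depth when covered, ./. otherwise), so every cell
of the population matrix has a value.

Reading goes through pysam's VCF parser; the writer is a deterministic
text emitter so that write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

from exocall.calling import VariantCall

MISSING_GT = "./."


def _fmt_float(x: float) -> str:
    """%.6g, stable through float32 round-trips."""
    return f"{x:.6g}"


def qual_from_p(p: float, cap: float = 99.99) -> float:
    """Phred-scaled call quality -10 log10(1-p), capped."""
    if p >= 1.0:
        return cap
    return min(cap, -10.0 * math.log10(1.0 - p))


@dataclass
class VcfRecord:
    chrom: str
    pos: int  # 1-based, as in the file
    id: str
    ref: str
    alt: str
    qual: float
    filter: str
    p: float | None
    gt: str
    dp: int
    vr: int
    tr: float | None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


_GT_BY_GENOTYPE = {"het": "0/1", "hom": "1/1"}


def record_from_call(call: VariantCall) -> VcfRecord:
    return VcfRecord(
        chrom=call.chrom,
        pos=call.pos + 1,
        id=".",
        ref=call.ref_allele,
        alt=call.alt_allele,
        qual=round(qual_from_p(call.p), 2),
        filter="PASS" if call.passed else ";".join(call.filters_failed),
        p=call.p,
        gt=_GT_BY_GENOTYPE.get(call.genotype, MISSING_GT),
        dp=call.total_depth,
        vr=call.var_depth,
        tr=call.t,
    )


_FILTER_IDS = (
    "low_p",
    "min_var_depth",
    "min_total_depth",
    "low_var_ratio",
    "callable",
    "low_t",
)


def _header_lines(
    contigs: Mapping[str, int], sample_names: Sequence[str]
) -> list[str]:
    lines = ["##fileformat=VCFv4.1", "##source=exocall"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        '##INFO=<ID=P,Number=1,Type=Float,Description='
        '"Logistic model probability that the variant is true">'
    )
    for fid in _FILTER_IDS:
        lines.append(f'##FILTER=<ID={fid},Description="Heuristic filter {fid}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    lines.append(
        '##FORMAT=<ID=VR,Number=1,Type=Integer,Description="Variant read depth">'
    )
    lines.append(
        '##FORMAT=<ID=TR,Number=1,Type=Float,Description="Adjusted variant ratio t">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    return lines


def _record_line(rec: VcfRecord) -> str:
    info = f"P={_fmt_float(rec.p)}" if rec.p is not None else "."
    sample = _sample_field(rec.gt, rec.dp, rec.vr, rec.tr)
    return "\t".join(
        [
            rec.chrom,
            str(rec.pos),
            rec.id,
            rec.ref,
            rec.alt,
            f"{rec.qual:.2f}",
            rec.filter,
            info,
            "GT:DP:VR:TR",
            sample,
        ]
    )


def _sample_field(gt: str, dp: int, vr: int, tr: float | None) -> str:
    tr_s = _fmt_float(tr) if tr is not None else "."
    return f"{gt}:{dp}:{vr}:{tr_s}"


def write_vcf(
    calls: Sequence[VariantCall | VcfRecord],
    sample_name: str,
    contigs: Mapping[str, int],
    path,
) -> None:
    """Write a single-sample VCF 4.1. Calls must be sorted by (chrom, pos)."""
    records = [
        c if isinstance(c, VcfRecord) else record_from_call(c) for c in calls
    ]
    keys = [(r.chrom, r.pos) for r in records]
    if any(b < a for a, b in zip(keys, keys[1:])):
        raise ValueError("calls must be sorted by (chrom, pos)")
    with open(path, "w") as fh:
        for line in _header_lines(contigs, [sample_name]):
            fh.write(line + "\n")
        for rec in records:
            fh.write(_record_line(rec) + "\n")


def _gt_to_str(gt: tuple) -> str:
    if gt is None or all(a is None for a in gt):
        return MISSING_GT
    return "/".join("." if a is None else str(a) for a in gt)


def read_vcf(path) -> list[VcfRecord]:
    """Read a VCF (any 4.x) losslessly for the fields the suite consumes."""
    out: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or (".",)
            p = rec.info.get("P")
            if isinstance(p, tuple):
                p = p[0]
            fmt = rec.samples[samples[0]] if samples else None
            tr = fmt.get("TR") if fmt else None
            if isinstance(tr, tuple):
                tr = tr[0]
            out.append(
                VcfRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    id=rec.id or ".",
                    ref=rec.ref,
                    alt=alts[0],
                    qual=float(rec.qual) if rec.qual is not None else float("nan"),
                    filter=";".join(rec.filter.keys()) or "PASS",
                    p=float(p) if p is not None else None,
                    gt=_gt_to_str(fmt.get("GT")) if fmt else MISSING_GT,
                    dp=int(fmt.get("DP")) if fmt and fmt.get("DP") is not None else 0,
                    vr=int(fmt.get("VR")) if fmt and fmt.get("VR") is not None else 0,
                    tr=float(tr) if tr is not None else None,
                )
            )
    return out


def read_contigs(path) -> dict[str, int]:
    with pysam.VariantFile(str(path)) as vf:
        return {name: c.length for name, c in vf.header.contigs.items()}


# ---------------------------------------------------------------------------
# population merge


@dataclass
class PopulationSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    per_sample: dict[str, str]  # sample -> GT:DP:VR:TR string


@dataclass
class PopulationVcf:
    sample_names: list[str]
    contigs: dict[str, int]
    sites: list[PopulationSite]

    def genotype(self, sample: str, key: tuple) -> str:
        for site in self.sites:
            if (site.chrom, site.pos, site.ref, site.alt) == key:
                return site.per_sample[sample].split(":", 1)[0]
        raise KeyError(key)


def load_depth_track(path) -> dict[str, IntervalTree]:
    """chrom <tab> start <tab> end <tab> depth, 0-based half-open."""
    out: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, depth = line.split("\t")[:4]
            out.setdefault(chrom, IntervalTree()).addi(
                int(start), int(end), int(depth)
            )
    return out


def _depth_at(track, chrom: str, pos1: int) -> int:
    if track is None:
        return 0
    tree = track.get(chrom)
    if tree is None:
        return 0
    hits = tree[pos1 - 1]
    return max((iv.data for iv in hits), default=0)


def merge_population(
    vcf_paths: Sequence,
    depth_sources: Mapping[str, object] | None = None,
    sample_names: Sequence[str] | None = None,
) -> PopulationVcf:
    """Merge single-sample VCFs over the union of sites.

    ``depth_sources`` maps sample name -> depth track (path to a BED-like
    chrom/start/end/depth file, or a preloaded tree dict).  For a sample
    lacking a call at a union site: covered with depth >= 1 -> GT 0/0 with
    the observed DP; no coverage information -> ./. with DP 0.  Per-sample
    fields of called sites are preserved verbatim.
    """
    depth_sources = dict(depth_sources or {})
    per_sample_records: dict[str, dict[tuple, VcfRecord]] = {}
    names: list[str] = []
    contigs: dict[str, int] = {}
    for i, path in enumerate(vcf_paths):
        recs = read_vcf(path)
        with pysam.VariantFile(str(path)) as vf:
            file_samples = list(vf.header.samples)
            file_contigs = {n: c.length for n, c in vf.header.contigs.items()}
        name = (
            sample_names[i]
            if sample_names is not None
            else (file_samples[0] if file_samples else f"sample{i + 1}")
        )
        if name in per_sample_records:
            raise ValueError(f"duplicate sample name {name!r}")
        for cname, clen in file_contigs.items():
            if cname in contigs and contigs[cname] != clen:
                raise ValueError(f"contig mismatch for {cname!r} across inputs")
            contigs.setdefault(cname, clen)
        names.append(name)
        per_sample_records[name] = {r.key: r for r in recs}

    tracks = {
        s: (load_depth_track(src) if not isinstance(src, dict) else src)
        for s, src in depth_sources.items()
    }

    union = sorted(
        {k for recs in per_sample_records.values() for k in recs},
        key=lambda k: (k[0], k[1], k[2], k[3]),
    )
    sites = []
    for key in union:
        chrom, pos, ref, alt = key
        per_sample = {}
        for name in names:
            rec = per_sample_records[name].get(key)
            if rec is not None:
                per_sample[name] = _sample_field(rec.gt, rec.dp, rec.vr, rec.tr)
            else:
                depth = _depth_at(tracks.get(name), chrom, pos)
                if depth >= 1:
                    per_sample[name] = f"0/0:{depth}:0:."
                else:
                    per_sample[name] = f"{MISSING_GT}:0:0:."
        sites.append(PopulationSite(chrom, pos, ref, alt, per_sample))
    return PopulationVcf(sample_names=names, contigs=contigs, sites=sites)


def write_population(pop: PopulationVcf, path) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(pop.contigs, pop.sample_names):
            fh.write(line + "\n")
        for site in pop.sites:
            fields = [
                site.chrom,
                str(site.pos),
                ".",
                site.ref,
                site.alt,
                ".",
                ".",
                ".",
                "GT:DP:VR:TR",
            ] + [site.per_sample[s] for s in pop.sample_names]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# target splitting


def split_by_target(
    vcf_path, bed_path
) -> tuple[list[VcfRecord], list[VcfRecord]]:
    """Partition records into (on_target, off_target) by BED membership.

    A record is on-target iff its 1-based POS falls in a 0-based half-open
    BED interval.  Every record lands in exactly one output.
    """
    from exocall.calling import load_bed

    bed = load_bed(bed_path)
    trees = {
        chrom: IntervalTree.from_tuples(
            (s, e) for s, e in ivs if e > s
        )
        for chrom, ivs in bed.items()
    }
    on: list[VcfRecord] = []
    off: list[VcfRecord] = []
    for rec in read_vcf(vcf_path):
        tree = trees.get(rec.chrom)
        if tree is not None and tree[rec.pos - 1]:
            on.append(rec)
        else:
            off.append(rec)
    return on, off
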