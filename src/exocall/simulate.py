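"""Synthetic exome-like fixtures: reads, reference, truth sets, training tables.

The read simulator emulates the discriminative structure the classifiers
rely on, as a two-component mixture of candidate sites:

* true variant sites — planted het/hom SNPs and short (1-3 bp) indels whose
  supporting reads fall on both strands, carry normal base qualities and
  sit at uniform read positions;
* systematic error sites — clusters of wrong bases (or 1 bp deletions)
  that are strand-biased, carry depressed base and neighboring-base
  qualities, and preferentially sit near the 3' read end where sequencing
  quality decays.

On top of the mixture, baseline per-base substitution noise (3'-weighted)
and rare per-read indel errors provide singleton false candidates.  Phred
qualities are integers in [2, 40] with a linear decay toward the 3' end.
The reference is i.i.d. uniform A/C/G/T drawn from the seed; no external
genome is ever required.  All outputs are deterministic functions of the
config, including its seed.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from exocall.alignment import AlignedRead, distance_to_3prime
from exocall.features.indel import left_normalize
from exocall.model import LogisticModel

BASES = "ACGT"


@dataclass
class ErrorProfile:
    """Rates controlling the error component of the mixture."""

    substitution_rate: float = 0.0005  # baseline per-bp miscall rate
    end_multiplier: float = 4.0        # 3'-end enrichment of errors
    strand_bias: float = 0.85          # prob. an error site is single-strand
    indel_rate: float = 0.0001         # per-read random indel error rate

    def validate(self) -> None:
        for name in ("substitution_rate", "strand_bias", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.end_multiplier < 1.0:
            raise ValueError("end_multiplier must be >= 1")


@dataclass
class QualityProfile:
    """Phred quality model: linear decay toward the 3' end plus jitter."""

    mean_phred: float = 33.0
    decay: float = 12.0   # total phred drop from 5' to 3' end
    jitter: float = 2.0

    def validate(self) -> None:
        if not 2 <= self.mean_phred <= 40:
            raise ValueError("mean_phred must be in [2, 40]")
        if self.decay < 0 or self.jitter < 0:
            raise ValueError("decay and jitter must be >= 0")


@dataclass
class SimConfig:
    """Conditions for one simulated dataset.

    ``n_sites`` candidate loci are planted; a fraction ``tp_fraction`` are
    true variants, the rest systematic error sites.  ``indel_fraction`` of
    each kind are indels rather than substitutions.  ``reference_length``
    defaults to the smallest length that spaces sites three read lengths
    apart (None = auto).
    """

    seed: int = 0
    n_sites: int = 100
    reference_length: int | None = None
    read_length: int = 50
    depth_mean: float = 30.0
    tp_fraction: float = 0.5
    indel_fraction: float = 0.0
    weak_site_fraction: float = 0.15
    depth_cv: float = 0.35
    error_profile: ErrorProfile = field(default_factory=ErrorProfile)
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    chrom: str = "ref1"

    def __post_init__(self) -> None:
        if self.read_length < 11:
            raise ValueError("read_length must be >= 11 (NBQ window must fit)")
        if not 0.0 <= self.tp_fraction <= 1.0:
            raise ValueError("tp_fraction must be in [0, 1]")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")
        if not 0.0 <= self.weak_site_fraction <= 1.0:
            raise ValueError("weak_site_fraction must be in [0, 1]")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        self.error_profile.validate()
        self.quality_profile.validate()
        min_len = self.min_reference_length()
        if self.reference_length is None:
            self.reference_length = min_len
        if self.reference_length < self.read_length:
            raise ValueError("reference_length must be >= read_length")
        if self.reference_length < min_len:
            raise ValueError(
                f"reference_length {self.reference_length} too short for "
                f"{self.n_sites} sites (need >= {min_len})"
            )

    def min_reference_length(self) -> int:
        margin = 2 * self.read_length
        return max(
            self.n_sites * 3 * self.read_length + 2 * margin,
            4 * self.read_length,
        )


def make_reference(config: SimConfig) -> dict[str, str]:
    """I.i.d. uniform A/C/G/T reference, a deterministic function of the seed."""
    rng = np.random.default_rng((config.seed, 0xEF))
    seq = rng.integers(0, 4, size=config.reference_length)
    return {config.chrom: "".join(BASES[i] for i in seq)}


# ---------------------------------------------------------------------------
# read simulation


def _qualities(rng, rl: int, qp: QualityProfile, strand: str) -> np.ndarray:
    # decay runs in sequencing orientation; stored order is reference
    # orientation, so reverse for minus-strand reads
    j = np.arange(rl)
    base = qp.mean_phred - qp.decay * j / max(rl - 1, 1)
    q = base + qp.jitter * rng.standard_normal(rl)
    q = np.clip(np.rint(q), 2, 40).astype(int)
    return q[::-1] if strand == "-" else q


def _site_positions(rng, config: SimConfig) -> np.ndarray:
    rl = config.read_length
    margin = 2 * rl
    slots = np.arange(margin, config.reference_length - margin - rl, 3 * rl)
    if len(slots) < config.n_sites:
        raise ValueError("reference too short to place sites")
    chosen = np.sort(rng.choice(len(slots), size=config.n_sites, replace=False))
    jitter = rng.integers(0, rl, size=config.n_sites)
    return slots[chosen] + jitter


def simulate_reads(config: SimConfig):
    """Generate aligned reads plus the planted-variant truth set.

    Returns ``(reads, reference, truth)`` where ``reads`` is a
    coordinate-sorted list of :class:`AlignedRead`, ``reference`` maps
    contig name to sequence, and ``truth`` is a DataFrame with columns
    chrom, pos (0-based anchor/site), ref, alt, kind (SNP/INS/DEL) and
    zygosity — indel records already left-normalized.
    """
    rng = np.random.default_rng((config.seed, 1))
    reference = make_reference(config)
    ref = reference[config.chrom]
    L, rl = config.reference_length, config.read_length
    ep, qp = config.error_profile, config.quality_profile

    positions = _site_positions(rng, config)
    n_true = int(round(config.n_sites * config.tp_fraction))
    order = rng.permutation(config.n_sites)
    true_idx = set(order[:n_true].tolist())

    # site plans
    snp_sites: dict[int, tuple[str, str]] = {}     # pos -> (alt, zygosity)
    indel_sites: dict[int, dict] = {}              # anchor pos -> plan
    error_sub_sites: list[int] = []
    error_indel_sites: list[int] = []
    truth_rows = []
    n_true_indel = int(round(n_true * config.indel_fraction))
    true_seen = 0
    for i, pos in enumerate(positions.tolist()):
        if i in true_idx:
            is_indel = true_seen < n_true_indel
            true_seen += 1
            zyg = "het" if rng.random() < 0.6 else "hom"
            # a minority of het sites are weakly supported (allele dropout,
            # capture/reference bias), keeping the classes realistically
            # overlapped; homozygous sites carry the allele on every read
            weak = rng.random() < config.weak_site_fraction
            carry = ((0.25 if weak else 0.5) if zyg == "het" else 1.0)
            if not is_indel:
                alt = BASES[(BASES.index(ref[pos]) + rng.integers(1, 4)) % 4]
                snp_sites[pos] = (alt, carry)
                truth_rows.append((config.chrom, pos, ref[pos], alt, "SNP", zyg))
            else:
                kind = "DEL" if rng.random() < 0.5 else "INS"
                length = int(rng.integers(1, 4))
                ins = (
                    "".join(BASES[b] for b in rng.integers(0, 4, size=length))
                    if kind == "INS"
                    else ""
                )
                plan = {"kind": kind, "length": length, "zyg": zyg,
                        "ins": ins, "carry": carry}
                indel_sites[pos] = plan
                if kind == "DEL":
                    cand = left_normalize(
                        config.chrom, pos, ref[pos : pos + 1 + length],
                        ref[pos], reference,
                    )
                else:
                    cand = left_normalize(
                        config.chrom, pos, ref[pos],
                        ref[pos] + plan["ins"], reference,
                    )
                truth_rows.append(
                    (config.chrom, cand.pos, cand.ref_allele, cand.alt_allele,
                     kind, zyg)
                )
        else:
            # the systematic error component is gated by the error profile:
            # zero rates mean a noise-free dataset
            if rng.random() < config.indel_fraction:
                if ep.indel_rate > 0:
                    error_indel_sites.append(pos)
            elif ep.substitution_rate > 0:
                error_sub_sites.append(pos)

    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "ref", "alt", "kind", "zygosity"]
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # reads: window-heterogeneous capture depth (Gamma multipliers with the
    # configured coefficient of variation), Bernoulli strands
    n_reads = int(round(L * config.depth_mean / rl))
    n_start = L - rl + 1
    if config.depth_cv > 0:
        win = 2 * rl
        n_win = (n_start + win - 1) // win
        k = 1.0 / config.depth_cv**2
        mult = rng.gamma(k, 1.0 / k, size=n_win)
        weights = np.repeat(mult, win)[:n_start]
        weights /= weights.sum()
        starts = np.sort(rng.choice(n_start, size=n_reads, p=weights))
    else:
        starts = np.sort(rng.integers(0, n_start, size=n_reads))
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    site_list = sorted(
        list(snp_sites) + list(indel_sites)
        + error_sub_sites + error_indel_sites
    )

    reads: list[AlignedRead] = []
    for ridx in range(n_reads):
        s = int(starts[ridx])
        strand = str(strands[ridx])
        quals = _qualities(rng, rl, qp, strand)
        seq = list(ref[s : s + rl])
        cigar: list[tuple[str, int]] = [("M", rl)]

        lo = bisect_left(site_list, s)
        hi = bisect_right(site_list, s + rl + 4)
        overlapping = site_list[lo:hi]
        for pos in overlapping:
            if pos in snp_sites:
                alt, carry = snp_sites[pos]
                if s <= pos < s + rl and rng.random() < carry:
                    seq[pos - s] = alt
            elif pos in indel_sites:
                plan = indel_sites[pos]
                if rng.random() >= plan["carry"]:
                    continue
                length = plan["length"]
                if plan["kind"] == "DEL":
                    dstart = pos + 1
                    # only reads fully spanning the event carry the gap
                    if s + 3 <= dstart and dstart + length <= s + rl:
                        m1 = dstart - s
                        m2 = rl - m1
                        seq = list(ref[s : dstart] + ref[dstart + length : dstart + length + m2])
                        cigar = [("M", m1), ("D", length), ("M", m2)]
                else:
                    a = pos  # insert between a and a+1
                    m1 = a + 1 - s
                    m2 = rl - m1 - length
                    if m1 >= 3 and m2 >= 3:
                        seq = list(ref[s : a + 1] + plan["ins"] + ref[a + 1 : a + 1 + m2])
                        cigar = [("M", m1), ("I", length), ("M", m2)]

        # baseline substitution noise, weighted toward the 3' end
        if ep.substitution_rate > 0:
            j = np.arange(rl, dtype=float) / max(rl - 1, 1)
            if strand == "-":
                j = j[::-1]
            p_err = ep.substitution_rate * ep.end_multiplier ** j
            hits = np.nonzero(rng.random(rl) < p_err)[0]
            for h in hits:
                seq[h] = BASES[(BASES.index(seq[h]) + int(rng.integers(1, 4))) % 4]
                quals[h] = max(2, int(quals[h]) - int(rng.integers(4, 12)))

        # rare random per-read 1 bp indel errors
        if ep.indel_rate > 0 and len(cigar) == 1 and rng.random() < ep.indel_rate:
            cut = int(rng.integers(6, rl - 6))
            seq = list(ref[s : s + cut] + ref[s + cut + 1 : s + rl + 1])
            cigar = [("M", cut), ("D", 1), ("M", rl - cut)]

        reads.append(
            AlignedRead(
                read_id=f"r{ridx:06d}",
                chrom=config.chrom,
                pos=s,
                strand=strand,
                sequence="".join(seq),
                base_qualities=[int(q) for q in quals],
                cigar=cigar,
                mapping_quality=255,
            )
        )

    _apply_error_sites(rng, reads, ref, error_sub_sites, error_indel_sites, config)
    reads.sort(key=lambda r: (r.chrom, r.pos, r.read_id))
    return reads, reference, truth


def _apply_error_sites(rng, reads, ref, sub_sites, indel_sites, config: SimConfig):
    """Plant clustered, strand-biased, 3'-enriched systematic errors."""
    ep, rl = config.error_profile, config.read_length
    starts = [r.pos for r in reads]
    for pos in sorted(sub_sites) + sorted(indel_sites):
        is_indel = pos in set(indel_sites)
        lo = bisect_left(starts, pos - rl + 1)
        hi = bisect_right(starts, pos)
        covering = [
            i for i in range(lo, hi)
            if reads[i].cigar == [("M", rl)] and reads[i].pos <= pos < reads[i].pos + rl
        ]
        if len(covering) < 2:
            continue
        # strand bias: most error sites show evidence on one strand only
        if rng.random() < ep.strand_bias:
            keep = "+" if rng.random() < 0.5 else "-"
            eligible = [i for i in covering if reads[i].strand == keep]
        else:
            eligible = covering
        if len(eligible) < 2:
            eligible = covering
        degrade = rng.random() < 0.8  # some false sites carry normal quality
        # systematic errors recruit a small fraction of reads, so false sites
        # keep high reference/variant ratios (true sites sit well below)
        frac = rng.uniform(0.05, 0.2) if is_indel else rng.uniform(0.03, 0.15)
        k = min(len(eligible), max(2, int(rng.binomial(len(covering), frac))))
        # enrich toward reads where the site falls near their 3' end
        w = np.empty(len(eligible))
        for j, i in enumerate(eligible):
            qpos = pos - reads[i].pos
            d3 = distance_to_3prime(reads[i], qpos)
            w[j] = ep.end_multiplier ** (1.0 - d3 / max(rl - 1, 1))
        w /= w.sum()
        chosen = list(rng.choice(len(eligible), size=k, replace=False, p=w))
        # a minority of strand-biased false sites still pick up a stray
        # opposite-strand read, as observed for real false SNPs
        if len(eligible) < len(covering) and rng.random() < 0.15:
            other = [i for i in covering if i not in eligible]
            if other:
                extra = other[int(rng.integers(0, len(other)))]
                eligible = eligible + [extra]
                chosen.append(len(eligible) - 1)
        err_base = BASES[(BASES.index(ref[pos]) + int(rng.integers(1, 4))) % 4]
        for j in chosen:
            read = reads[eligible[j]]
            qpos = pos - read.pos
            quals = list(read.base_qualities)
            if is_indel:
                if not (1 <= qpos <= rl - 2):
                    continue
                s = read.pos
                seq = list(ref[s : s + qpos + 1] + ref[s + qpos + 2 : s + rl + 1])
                # mismapping signature: false gaps often co-occur with extra
                # mismatches, raising the read's variation rate
                if rng.random() < 0.6:
                    mm = int(rng.integers(0, rl))
                    if abs(mm - qpos) > 6:
                        seq[mm] = BASES[
                            (BASES.index(seq[mm]) + int(rng.integers(1, 4))) % 4
                        ]
                read.sequence = "".join(seq)
                read.cigar = [("M", qpos + 1), ("D", 1), ("M", rl - qpos - 1)]
            else:
                seq = list(read.sequence)
                seq[qpos] = err_base
                read.sequence = "".join(seq)
                if degrade:
                    quals[qpos] = max(2, quals[qpos] - int(rng.integers(8, 16)))
            if degrade:
                for f in range(max(0, qpos - 5), min(rl, qpos + 6)):
                    quals[f] = max(2, quals[f] - int(rng.integers(3, 9)))
            read.base_qualities = quals


# ---------------------------------------------------------------------------
# SAM/FASTA fixtures


def write_fasta(reference: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_sam_fixture(
    reads: Sequence[AlignedRead],
    reference: Mapping[str, str],
    sam_path,
    fasta_path=None,
) -> None:
    """Write reads as a headered, sorted SAM (and optionally the FASTA).

    Rejects unsorted input; round-trips losslessly through
    :func:`exocall.alignment.read_alignments` for every field the suite
    consumes.
    """
    contigs = list(reference)
    order = {c: i for i, c in enumerate(contigs)}
    keys = [(order[r.chrom], r.pos) for r in reads]
    if any(b < a for a, b in zip(keys, keys[1:])):
        raise ValueError("reads must be coordinate-sorted")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in contigs],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = order[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = r.mapping_quality
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            a.query_sequence = r.sequence
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_qualities)
            )
            out.write(a)
    if fasta_path is not None:
        write_fasta(reference, fasta_path)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Tab-delimited truth set; positions are written 1-based."""
    out = truth.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    truth["pos"] = truth["pos"] - 1
    return truth


# ---------------------------------------------------------------------------
# labeled training tables


SamplerSpec = Mapping[str, tuple | Callable]


def _draw(rng, spec, n: int) -> np.ndarray:
    if callable(spec):
        return np.asarray(spec(rng, n), dtype=float)
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    if kind == "bernoulli":
        return (rng.random(n) < spec[1]).astype(float)
    raise ValueError(f"unknown sampler spec {spec!r}")


def simulate_training_table(
    model: LogisticModel,
    n: int,
    tp_fraction: float | None,
    feature_sampler: SamplerSpec,
    seed: int = 0,
    resample: bool = True,
) -> pd.DataFrame:
    """Labeled feature table with labels drawn Bernoulli(logistic(beta.x)).

    Features come from ``feature_sampler`` (one distribution spec or
    callable per model variable); labels are then optionally resampled with
    replacement within class to hit ``tp_fraction`` exactly — mirroring
    training sets assembled to a fixed TP/FP mix (e.g. 10%/90%).
    """
    if n < 10:
        raise ValueError("n must be >= 10 to stratify labels")
    missing = [v for v in model.variable_names if v not in feature_sampler]
    if missing:
        raise ValueError(f"feature_sampler missing variables {missing}")
    rng = np.random.default_rng((seed, 2))
    X = np.column_stack(
        [_draw(rng, feature_sampler[v], n) for v in model.variable_names]
    )
    p = model.score_matrix(X)
    y = rng.random(n) < p
    df = pd.DataFrame(X, columns=list(model.variable_names))
    df["label"] = np.where(y, "TP", "FP")
    if resample:
        if tp_fraction is None:
            raise ValueError("tp_fraction required when resample=True")
        n_tp = int(round(n * tp_fraction))
        tp_rows = np.nonzero(y)[0]
        fp_rows = np.nonzero(~y)[0]
        if (n_tp > 0 and len(tp_rows) == 0) or (n_tp < n and len(fp_rows) == 0):
            raise ValueError("cannot resample: a required class is empty")
        take = np.concatenate(
            [
                rng.choice(tp_rows, size=n_tp, replace=True),
                rng.choice(fp_rows, size=n - n_tp, replace=True),
            ]
        )
        rng.shuffle(take)
        df = df.iloc[take].reset_index(drop=True)
    return df


def write_training_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_training_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
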