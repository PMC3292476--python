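"""Call-set quality metrics and comparisons.

Ts/Tv (transitions A<->G, C<->T over transversions; coding regions expect
3-4), known-site rediscovery, SNP density per kbp of callable sequence,
the INDEL in-frame rate (fraction of lengths divisible by 3 — frameshifts
are heavily depleted in functional coding sequence), pairwise call-set
concordance restricted to a shared region, and precision/sensitivity/ROC
curves for scored, labeled examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _site_key(rec, match_alleles: bool = True):
    # accepts VcfRecord, VariantCall, or (chrom, pos, ref, alt) tuples
    if isinstance(rec, tuple):
        chrom, pos, ref, alt = rec
    else:
        chrom, pos = rec.chrom, rec.pos
        ref = getattr(rec, "ref", None) or getattr(rec, "ref_allele")
        alt = getattr(rec, "alt", None) or getattr(rec, "alt_allele")
    return (chrom, pos, alt) if match_alleles else (chrom, pos)


def ts_tv_ratio(snp_calls: Iterable) -> float:
    """Transitions / transversions; ``inf`` flags a set with no transversions."""
    ts = tv = 0
    for rec in snp_calls:
        key = _site_key(rec)
        ref = rec[2] if isinstance(rec, tuple) else (
            getattr(rec, "ref", None) or getattr(rec, "ref_allele")
        )
        alt = key[2]
        if (ref, alt) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return math.inf
    return ts / tv


def known_site_rediscovery(
    calls: Iterable, known_sites: Iterable, match_alleles: bool = True
) -> float:
    """|calls intersect known| / |calls| (the dbSNP%-style rate)."""
    call_keys = {_site_key(c, match_alleles) for c in calls}
    known_keys = {_site_key(k, match_alleles) for k in known_sites}
    if not call_keys:
        return 0.0
    return len(call_keys & known_keys) / len(call_keys)


def snp_density(n_calls: int, callable_bp: int) -> float:
    """SNPs per 1000 bp of callable sequence."""
    if callable_bp < 1:
        raise ValueError("callable_bp must be >= 1")
    return 1000.0 * n_calls / callable_bp


def in_frame_rate(indel_lengths: Iterable[int]) -> float:
    """Fraction of INDELs whose length (|len(ref)-len(alt)|) is 3(n)."""
    lengths = list(indel_lengths)
    if not lengths:
        raise ValueError("in-frame rate undefined for an empty INDEL set")
    return sum(1 for l in lengths if l % 3 == 0) / len(lengths)


def indel_lengths(records: Iterable) -> list[int]:
    out = []
    for rec in records:
        ref = getattr(rec, "ref", None) or getattr(rec, "ref_allele")
        alt = getattr(rec, "alt", None) or getattr(rec, "alt_allele")
        out.append(abs(len(ref) - len(alt)))
    return out


@dataclass
class ConcordanceResult:
    n_shared_region_a: int
    n_shared_region_b: int
    rediscovery_rate: float   # fraction of B's calls also in A
    confirmation_rate: float  # fraction of A's calls also in B


def _restrict(keys, region: Mapping[str, Sequence[tuple[int, int]]] | None):
    if region is None:
        return set(keys)
    out = set()
    for key in keys:
        chrom, pos = key[0], key[1]
        for start, end in region.get(chrom, ()):  # pos is 1-based
            if start <= pos - 1 < end:
                out.add(key)
                break
    return out


def concordance(
    set_a: Iterable,
    set_b: Iterable,
    shared_region: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    match_alleles: bool = True,
) -> ConcordanceResult:
    """Pairwise call-set comparison restricted to a shared region.

    ``rediscovery`` asks how much of B the call set A recovers;
    ``confirmation`` how much of A is corroborated by B.  The two are
    mirror images: concordance(A, B).rediscovery == concordance(B, A).confirmation.
    """
    a = _restrict({_site_key(r, match_alleles) for r in set_a}, shared_region)
    b = _restrict({_site_key(r, match_alleles) for r in set_b}, shared_region)
    inter = len(a & b)
    return ConcordanceResult(
        n_shared_region_a=len(a),
        n_shared_region_b=len(b),
        rediscovery_rate=inter / len(b) if b else 0.0,
        confirmation_rate=inter / len(a) if a else 0.0,
    )


def pr_and_roc(
    labels: Sequence, scores: Sequence[float], cutoff_grid: Sequence[float] | None = None
) -> pd.DataFrame:
    """Confusion-matrix curves over a cutoff grid (call iff score >= cutoff).

    Returns a table with tp/fp/fn/tn, precision, sensitivity and FPR per
    cutoff.  Requires both classes to be present.
    """
    from exocall.model import DEFAULT_CUTOFF_GRID, labels_to_binary

    y = labels_to_binary(list(labels)).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("need both TP and FP examples to draw curves")
    if cutoff_grid is None:
        cutoff_grid = DEFAULT_CUTOFF_GRID
    rows = []
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    for c in cutoff_grid:
        called = s >= c
        tp = int((called & y).sum())
        fp = int((called & ~y).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        rows.append(
            (
                float(c), tp, fp, fn, tn,
                tp / (tp + fp) if tp + fp else float("nan"),
                tp / n_pos,
                fp / n_neg,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["cutoff", "tp", "fp", "fn", "tn", "precision", "sensitivity", "fpr"],
    )


def auroc(labels: Sequence, scores: Sequence[float]) -> float:
    """Area under the ROC curve (rank statistic, ties handled)."""
    from exocall.model import labels_to_binary

    y = labels_to_binary(list(labels)).astype(bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    return (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
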