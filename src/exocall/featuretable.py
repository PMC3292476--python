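"""Export per-candidate feature matrices for model training.

Tables are tab-delimited: chrom, pos (1-based), ref, alt (+ kind/length for
INDELs), then the model variables in declared order; labeling against a
truth set appends a TP/FP ``label`` column ready for the training CLI.
"""

from __future__ import annotations

import pandas as pd

from exocall.alignment import GAP, PileupStream
from exocall.calling import FilterConfig, _as_reads, effective_depth
from exocall.features.indel import (
    INDEL_VARIABLES,
    extract_indel_candidates,
    indel_feature_vector,
)
from exocall.features.snp import SNP_VARIABLES, snp_feature_vector


def snp_feature_table(
    alignments, reference, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """One row per (site, alt base) with the seven SNP covariates."""
    cfg = cfg or FilterConfig()
    rows = []
    for stack in PileupStream(_as_reads(alignments), reference, cfg.read):
        alts = sorted(
            {o.base for o in stack.observations} - {stack.ref_base, GAP, "N"}
        )
        for alt in alts:
            feats = snp_feature_vector(stack, alt)
            rows.append(
                {
                    "chrom": stack.chrom,
                    "pos": stack.pos + 1,
                    "ref": stack.ref_base,
                    "alt": alt,
                    **feats.as_dict(),
                    "var_depth": feats.var_depth,
                    "effective_depth": effective_depth(stack),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", *SNP_VARIABLES,
                 "var_depth", "effective_depth"],
    )


def indel_feature_table(
    alignments, reference, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """One row per normalized INDEL candidate with the four covariates."""
    import bisect

    from exocall.alignment import passes_read_filters

    cfg = cfg or FilterConfig()
    support: dict = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for read in _as_reads(alignments):
        if not passes_read_filters(read, cfg.read, reference):
            continue
        spans.setdefault(read.chrom, []).append((read.pos, read.reference_end))
        for cand, sup in extract_indel_candidates(read, reference):
            support.setdefault(cand, []).append(sup)
    span_index = {
        chrom: (sorted(s for s, _ in ivs), sorted(e for _, e in ivs))
        for chrom, ivs in spans.items()
    }
    rows = []
    for cand in sorted(
        support, key=lambda c: (c.chrom, c.pos, c.ref_allele, c.alt_allele)
    ):
        starts, ends = span_index[cand.chrom]
        total = bisect.bisect_right(starts, cand.pos) - bisect.bisect_right(
            ends, cand.pos
        )
        feats = indel_feature_vector(support[cand], total)
        rows.append(
            {
                "chrom": cand.chrom,
                "pos": cand.pos + 1,
                "ref": cand.ref_allele,
                "alt": cand.alt_allele,
                "kind": cand.kind,
                "length": cand.length,
                **feats.as_dict(),
                "var_depth": feats.var_depth,
                "total_depth": feats.total_depth,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "kind", "length",
                 *INDEL_VARIABLES, "var_depth", "total_depth"],
    )


def label_by_truth(table: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Append a TP/FP label column by matching (chrom, 1-based pos, alt)."""
    keys = {
        (row.chrom, row.pos + 1, row.alt) for row in truth.itertuples()
    }
    out = table.copy()
    out["label"] = [
        "TP" if (r.chrom, r.pos, r.alt) in keys else "FP"
        for r in table.itertuples()
    ]
    return out
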