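"""SNP model covariates.

The SNP classifier separates true substitutions from sequencing and mapping
errors using seven terms: the reference/variant reads ratio, the strand
direction standard (variant evidence on both strands), the mean distance of
the variant base to the 3' read end, the mean neighboring base quality
(NBQ: the variant base plus up to five flanking bases on each side of the
read), the mean variant base quality, and the two interactions
NBQ x dist3 and strand x dist3.
"""

from __future__ import annotations

from dataclasses import dataclass

from exocall.alignment import GAP, ReadObservation, SiteStack

#: Declared variable order for model files and feature tables.
SNP_VARIABLES = (
    "ref_var_ratio",
    "strand_both",
    "mean_dist3",
    "mean_nbq",
    "mean_var_qual",
    "nbq_x_dist3",
    "strand_x_dist3",
)


@dataclass
class SnpFeatures:
    ref_var_ratio: float
    strand_both: int
    mean_dist3: float
    mean_nbq: float
    mean_var_qual: float
    nbq_x_dist3: float
    strand_x_dist3: float
    var_depth: int
    ref_depth: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SNP_VARIABLES}


def _variant_obs(stack: SiteStack, alt: str) -> list[ReadObservation]:
    return [o for o in stack.observations if o.base == alt]


def mean_nbq(stack: SiteStack, alt: str) -> float:
    """Mean quality of the variant base and its <=5 bp flanks, pooled over
    all variant reads; windows truncate at read boundaries."""
    obs = _variant_obs(stack, alt)
    if not obs:
        raise ValueError("no variant observations at site")
    total = sum(o.window_qual_sum for o in obs)
    n = sum(o.window_qual_n for o in obs)
    return total / n


def strand_direction_standard(stack: SiteStack, alt: str) -> int:
    """1 iff at least one variant read exists in each strand direction."""
    strands = {o.strand for o in _variant_obs(stack, alt)}
    return int("+" in strands and "-" in strands)


def snp_feature_vector(stack: SiteStack, alt: str) -> SnpFeatures:
    """Compute all seven SNP covariates for ``alt`` at this site.

    Requires at least one variant observation.  With zero reference reads
    the ref/var ratio is 0 (the homozygous-alternate limit).
    """
    if alt == stack.ref_base or alt == GAP:
        raise ValueError(f"alt {alt!r} is not a substitution allele here")
    obs = _variant_obs(stack, alt)
    if not obs:
        raise ValueError(f"no {alt} observations at {stack.chrom}:{stack.pos + 1}")
    ref_depth = sum(1 for o in stack.observations if o.base == stack.ref_base)
    var_depth = len(obs)

    m_dist3 = sum(o.dist3 for o in obs) / var_depth
    m_nbq = mean_nbq(stack, alt)
    m_vq = sum(o.base_quality for o in obs) / var_depth
    strand_both = strand_direction_standard(stack, alt)
    return SnpFeatures(
        ref_var_ratio=ref_depth / var_depth,
        strand_both=strand_both,
        mean_dist3=m_dist3,
        mean_nbq=m_nbq,
        mean_var_qual=m_vq,
        nbq_x_dist3=m_nbq * m_dist3,
        strand_x_dist3=strand_both * m_dist3,
        var_depth=var_depth,
        ref_depth=ref_depth,
    )
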