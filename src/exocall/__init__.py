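"""exocall: logistic-regression variant calling for exome capture sequencing.

The suite streams a coordinate-sorted single-sample SAM/BAM, compiles the
read evidence at each candidate locus, scores it with a trained logistic
regression model (separate SNP and INDEL models), applies heuristic
filters, genotypes passing calls via the adjusted variant ratio, and
writes VCF; single-sample VCFs can be merged into a population VCF with
missing coverage filled in.  Training, stepwise selection, bootstrap CIs
and split-half cross-validation for building models on labeled data are
included, together with a synthetic-data generator so the whole pipeline
is exercisable without external data.
"""

from importlib import resources

from exocall.model import (
    CoefCI,
    CvResult,
    LogisticModel,
    VariantLogit,
    VariantLogitResults,
    bootstrap_ci,
    cross_validate,
    drop_nonsignificant,
    load_model,
    save_model,
    stepwise_select,
)
from exocall.calling import (
    FilterConfig,
    VariantCall,
    call_indels,
    call_snps,
)
from exocall.simulate import SimConfig, simulate_reads, simulate_training_table

__version__ = "0.1.0"


def default_model(kind: str) -> LogisticModel:
    """Load the packaged default SNP or INDEL model.

    Both are trained on the packaged synthetic fixture training set (no
    published coefficients exist for real capture data); retrain on your
    own labeled data for production use.
    """
    if kind not in ("snp", "indel"):
        raise ValueError("kind must be 'snp' or 'indel'")
    ref = resources.files("exocall") / "models" / f"default_{kind}.json"
    with resources.as_file(ref) as path:
        return load_model(path)


__all__ = [
    "LogisticModel",
    "VariantLogit",
    "VariantLogitResults",
    "CvResult",
    "CoefCI",
    "FilterConfig",
    "VariantCall",
    "SimConfig",
    "simulate_reads",
    "simulate_training_table",
    "call_snps",
    "call_indels",
    "cross_validate",
    "bootstrap_ci",
    "stepwise_select",
    "drop_nonsignificant",
    "save_model",
    "load_model",
    "default_model",
]
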