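"""Regenerate the packaged default models from the synthetic fixture sets.

The shipped coefficients in src/exocall/models/*.json are produced by this
script: simulate a labeled mixture of true variants and systematic errors,
extract the candidate feature tables, and fit the SNP and INDEL logistic
models on them.  Run from the repository root:

    python scripts/train_default_models.py
"""

from pathlib import Path

from exocall.featuretable import (
    indel_feature_table,
    label_by_truth,
    snp_feature_table,
)
from exocall.features.indel import INDEL_VARIABLES
from exocall.features.snp import SNP_VARIABLES
from exocall.model import VariantLogit, save_model
from exocall.simulate import SimConfig, simulate_reads

OUT = Path(__file__).resolve().parents[1] / "src" / "exocall" / "models"

PROVENANCE = (
    "synthetic fixture training set (exocall.simulate, seed {seed}); "
    "retrain on real labeled data for production use"
)


def train_snp() -> None:
    cfg = SimConfig(seed=1201, n_sites=2000, tp_fraction=0.12, depth_mean=30.0)
    reads, reference, truth = simulate_reads(cfg)
    table = label_by_truth(
        snp_feature_table(reads, reference), truth[truth.kind == "SNP"]
    )
    res = VariantLogit.from_dataframe(table, list(SNP_VARIABLES)).fit()
    print(res.summary())
    save_model(
        res.to_model("synthetic", PROVENANCE.format(seed=cfg.seed)),
        OUT / "default_snp.json",
    )


def train_indel() -> None:
    cfg = SimConfig(
        seed=1301, n_sites=2000, tp_fraction=0.10, indel_fraction=1.0,
        depth_mean=20.0,
    )
    reads, reference, truth = simulate_reads(cfg)
    table = label_by_truth(
        indel_feature_table(reads, reference), truth[truth.kind != "SNP"]
    )
    res = VariantLogit.from_dataframe(table, list(INDEL_VARIABLES)).fit()
    print(res.summary())
    save_model(
        res.to_model("synthetic", PROVENANCE.format(seed=cfg.seed)),
        OUT / "default_indel.json",
    )


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    train_snp()
    train_indel()
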