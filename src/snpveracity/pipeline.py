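"""End-to-end pipeline: label -> featurize -> train -> cutoff -> evaluate.

The protocol mirrors the benchmark workflow: the classifier and the
probability cutoff are both derived from training data only; validation
rows are encoded with the training-time encoder and evaluated at the
training-estimated cutoff (plus the default 0.5 for reference).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn

from . import __version__, concordance, evaluation, featurize, synthetic
from .classifier import NetworkConfig, TrainedClassifier, train
from .errors import ConfigError
from .featurize import FeatureEncoder, FeatureSpec


@dataclass
class PipelineConfig:
    """Merged settings for one end-to-end run.

    Either file inputs (vcf/array/reference) or a synthetic configuration
    must be given.  ``seed`` drives every stochastic stage through
    deterministic per-stage offsets (recorded in the provenance record).
    """

    vcf: str | None = None
    array: str | None = None
    reference: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None

    validation_fraction: float = 0.25
    strategy: str = "naive"
    ratio: float | None = None
    metric: str = "sumss"
    n_bootstrap: int = 100
    seed: int = 0
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    network: NetworkConfig | None = None

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31 derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _split_train_validation(
    table: pd.DataFrame, fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random stratified row split of a labeled site table."""
    rng = np.random.default_rng(seed)
    labeled = table[table["label"] != "excluded"]
    val_idx = []
    for label, sub in labeled.groupby("label"):
        k = int(round(fraction * len(sub)))
        val_idx.extend(rng.choice(sub.index.to_numpy(), size=k, replace=False))
    val_mask = table.index.isin(val_idx)
    return table[~val_mask].copy(), table[val_mask].copy()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Run the full workflow and return the evaluation report.

    With ``out_dir`` set, writes predictions.tsv, report.json, a model
    bundle and a provenance record there.
    """
    import pyfaidx

    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic)
        table = synthetic.generate_feature_table(syn)
        input_digests = {"synthetic": dataclasses.asdict(syn)}
    elif config.vcf and config.array:
        table, _ = concordance.label_dataset(config.vcf, config.array)
        if config.reference:
            table = featurize.add_context_trios(table, pyfaidx.Fasta(config.reference))
        input_digests = {
            os.path.basename(p): _sha256(p)
            for p in (config.vcf, config.array, config.reference)
            if p
        }
    else:
        raise ConfigError("either synthetic config or vcf+array paths required")

    train_table, val_table = _split_train_validation(
        table, config.validation_fraction, config.stage_seed("split")
    )

    encoder = FeatureEncoder(config.feature_spec).fit(
        train_table[train_table["label"] != "excluded"]
    )
    train_matrix = encoder.transform(train_table)
    val_matrix = encoder.transform(val_table)

    net_config = config.network or NetworkConfig(seed=config.stage_seed("train"))
    clf = train(
        train_matrix, strategy=config.strategy, ratio=config.ratio, config=net_config
    )

    p_train = clf.predict_incorrect_probability(train_matrix)
    p_val = clf.predict_incorrect_probability(val_matrix)

    cutoff_est = evaluation.bootstrap_cutoff(
        train_matrix.y,
        p_train,
        metric=config.metric,
        n_bootstrap=config.n_bootstrap,
        seed=config.stage_seed("cutoff"),
    )
    cutoff = cutoff_est.bootstrap_mean

    report = {
        "strategy": config.strategy,
        "ratio": config.ratio,
        "metric": config.metric,
        "n_train": int(train_matrix.n_rows),
        "n_validation": int(val_matrix.n_rows),
        "n_features": int(train_matrix.n_features),
        "cutoff": {
            "metric": cutoff_est.metric,
            "point": cutoff_est.point_cutoff,
            "bootstrap_mean": cutoff_est.bootstrap_mean,
            "bootstrap_sd": cutoff_est.bootstrap_sd,
            "n_bootstrap": cutoff_est.n_bootstrap,
        },
        "training": evaluation.evaluate(train_matrix.y, p_train, cutoff),
        "validation": evaluation.evaluate(val_matrix.y, p_val, cutoff),
        "training_default_cutoff": evaluation.evaluate(train_matrix.y, p_train, 0.5),
        "validation_default_cutoff": evaluation.evaluate(val_matrix.y, p_val, 0.5),
        "stopped_epoch": clf.history.stopped_epoch,
        "best_epoch": clf.history.best_epoch,
    }

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        preds = val_matrix.index.copy()
        preds["label"] = np.where(val_matrix.y == 1, "incorrect", "correct")
        preds["probability"] = p_val
        preds.to_csv(os.path.join(out_dir, "predictions.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        clf.save(os.path.join(out_dir, "model"))
        provenance = {
            "package_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "stage_seeds": {
                s: config.stage_seed(s) for s in ("split", "train", "cutoff")
            },
            "inputs": input_digests,
            "config": {
                "strategy": config.strategy,
                "ratio": config.ratio,
                "metric": config.metric,
                "n_bootstrap": config.n_bootstrap,
                "validation_fraction": config.validation_fraction,
                "network": dataclasses.asdict(net_config),
            },
        }
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2)
    return report
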