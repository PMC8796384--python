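"""End-to-end featurization and experiment orchestration.

``FeaturePipeline`` turns a peptide table (id, smiles[, ppb]) into feature
maps: decompose each peptide, compute substructure descriptors, standardize
them with whole-peptide training statistics, weight rows by substructure
appearance frequency, and center the vectors in D x 15 maps.  ``fit`` learns
the statistics from the training split only; ``transform`` applies them
unchanged, so there is no leakage from test peptides.

``run_experiment`` chains the full study: generate or load data, split with
Kennard-Stone on standardized whole-peptide descriptors, fit the pipeline
and a model variant on the training split, and score the held-out peptides
over both %PPB ranges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import clamp_ppb, kennard_stone_split
from .decompose import decompose, parse_peptide
from .descriptors import (
    DEFAULT_DESCRIPTORS,
    DescriptorMatrix,
    compute_matrix,
    standardize,
    weight_by_frequency,
)
from .featmap import FeatureMap, build_feature_map
from .metrics import MetricsReport, evaluate
from .model import ModelConfig, Network, build_model, predict, train

__all__ = ["FeaturePipeline", "ExperimentResult", "run_experiment"]


class FeaturePipeline:
    """Peptide table -> feature maps, with training-set statistics frozen."""

    def __init__(self, descriptor_set=DEFAULT_DESCRIPTORS, weighting: str = "linear"):
        self.descriptor_set = tuple(descriptor_set)
        self.weighting = weighting
        self.mu = None
        self.sigma = None
        self.counts: Counter[str] = Counter()
        self._cache: dict[str, list] = {}

    def _substructures(self, pid: str, smiles: str):
        if pid not in self._cache:
            self._cache[pid] = decompose(parse_peptide(pid, smiles))
        return self._cache[pid]

    def fit(self, records: pd.DataFrame) -> "FeaturePipeline":
        """Learn standardization statistics (whole-peptide, training split)
        and substructure appearance counts."""
        whole = compute_matrix(
            dict(zip(records["id"], records["smiles"])), self.descriptor_set
        )
        ref = standardize(whole, whole)
        self.mu, self.sigma = ref.mu, ref.sigma
        self.counts = Counter()
        for pid, smiles in zip(records["id"], records["smiles"]):
            for sub in self._substructures(pid, smiles):
                self.counts[sub.capped_smiles] += 1
        return self

    def whole_peptide_matrix(
        self, records: pd.DataFrame, standardized: bool = True
    ) -> DescriptorMatrix:
        whole = compute_matrix(
            dict(zip(records["id"], records["smiles"])), self.descriptor_set
        )
        if not standardized:
            return whole
        ref = DescriptorMatrix(data=whole.data, mu=self.mu, sigma=self.sigma)
        if self.mu is None:
            ref = whole
        return standardize(whole, ref)

    def transform(self, records: pd.DataFrame) -> list[FeatureMap]:
        """Feature maps for each row, using the fitted statistics."""
        if self.mu is None:
            raise RuntimeError("pipeline not fitted; call fit() on the training split")
        maps = []
        for pid, smiles in zip(records["id"], records["smiles"]):
            subs = self._substructures(pid, smiles)
            sub_ids = {f"{pid}:{s.position}": s.capped_smiles for s in subs}
            mat = compute_matrix(sub_ids, self.descriptor_set)
            ref = DescriptorMatrix(data=mat.data, mu=self.mu, sigma=self.sigma)
            z = standardize(mat, ref)
            w = weight_by_frequency(
                z,
                self.counts or {sm: 1 for sm in sub_ids.values()},
                strategy=self.weighting,
                key=lambda rid: sub_ids[rid],
            )
            maps.append(
                build_feature_map(w.data.to_numpy(dtype=float), peptide_id=pid)
            )
        return maps


    def to_json(self) -> dict:
        """Serializable fitted state (statistics, counts, configuration)."""
        if self.mu is None:
            raise RuntimeError("pipeline not fitted")
        return {
            "descriptor_set": list(self.descriptor_set),
            "weighting": self.weighting,
            "mu": self.mu.to_dict(),
            "sigma": self.sigma.to_dict(),
            "counts": dict(self.counts),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "FeaturePipeline":
        pipe = cls(tuple(payload["descriptor_set"]), payload["weighting"])
        pipe.mu = pd.Series(payload["mu"])
        pipe.sigma = pd.Series(payload["sigma"])
        pipe.counts = Counter(payload["counts"])
        return pipe


@dataclass
class ExperimentResult:
    train_ids: list
    test_ids: list
    history: dict
    predictions: pd.DataFrame  # id, y_exp, y_hat
    metrics: dict[str, MetricsReport]
    model: Network = field(repr=False, default=None)
    pipeline: FeaturePipeline = field(repr=False, default=None)


def run_experiment(
    records: pd.DataFrame,
    config: ModelConfig,
    test_fraction: float = 0.1,
    descriptor_set=DEFAULT_DESCRIPTORS,
    weighting: str = "linear",
) -> ExperimentResult:
    """Split, featurize, train and evaluate on one peptide table."""
    records = records.reset_index(drop=True)
    y = clamp_ppb(records["ppb"].to_numpy(dtype=float))

    pipeline = FeaturePipeline(descriptor_set, weighting)
    whole = pipeline.whole_peptide_matrix(records, standardized=False)
    ref = standardize(whole, whole)
    train_ids, test_ids = kennard_stone_split(
        ref.data.set_axis(records["id"]), test_fraction
    )

    is_train = records["id"].isin(train_ids)
    train_rec = records[is_train]
    test_rec = records[~is_train]
    pipeline.fit(train_rec)

    train_maps = pipeline.transform(train_rec)
    test_maps = pipeline.transform(test_rec)

    model = build_model(config)
    history = train(model, train_maps, y[is_train.to_numpy()], config)

    rows = []
    for fmap, y_exp in zip(test_maps, y[~is_train.to_numpy()]):
        res = predict(model, fmap, augment_input=config.augmented)
        rows.append({"id": fmap.peptide_id, "y_exp": y_exp, "y_hat": res.y_hat})
    preds = pd.DataFrame(rows)

    metrics = {"50-95": evaluate(preds["y_exp"], preds["y_hat"], "50-95")}
    if (preds["y_exp"] >= 80).sum() >= 1:
        metrics["80-95"] = evaluate(preds["y_exp"], preds["y_hat"], "80-95")
    return ExperimentResult(
        train_ids=train_ids,
        test_ids=test_ids,
        history=history,
        predictions=preds,
        metrics=metrics,
        model=model,
        pipeline=pipeline,
    )
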