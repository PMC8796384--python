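"""Attribute a prediction to individual residues with gradient saliency.

Trains a small model on synthetic peptides whose label is driven by the
most lipophilic residue, then checks that the replica-averaged saliency
ranks that residue first.
"""

import numpy as np

from cyclicppb.model import ModelConfig
from cyclicppb.pipeline import run_experiment
from cyclicppb.saliency import aggregate_saliency
from cyclicppb.synthetic import SyntheticSpec, generate_dataset

records, truth = generate_dataset(SyntheticSpec(n_peptides=150, seed=33))
config = ModelConfig(variant="augmented", epochs=40, patience=10, seed=0)
result = run_experiment(records, config, test_fraction=0.1)

test_rec = records[records["id"].isin(result.test_ids)].head(5)
print("peptide      n  top-saliency pos  planted pos  per-residue scores")
for fmap in result.pipeline.transform(test_rec):
    smap = aggregate_saliency(result.model, fmap)
    scores = smap.per_substructure
    top = int(np.argmax(scores))
    planted = truth["peptides"][fmap.peptide_id]["max_logp_position"]
    pretty = " ".join(f"{s:.2f}" for s in scores)
    print(f"{fmap.peptide_id}  {fmap.n:2d}  {top:16d}  {planted:11d}  [{pretty}]")

# A higher score means the prediction is more sensitive to that residue's
# descriptors.  When the top-saliency position matches the planted position,
# the model has localized the lipophilic residue that drives binding.
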