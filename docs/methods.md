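# Methods

## The problem and the modelling idea

Plasma protein binding of a cyclic peptide is dominated by local structure:
a single lipophilic residue that can occupy serum albumin's hydrophobic
pocket contributes more to %PPB than any whole-molecule average.  The
pipeline therefore represents a peptide not as one descriptor vector but as
the *sequence* of its residue-level fragments, laid out in ring order, and
lets a 1-D convolutional network read that sequence with its circular
topology intact.

## Decomposition and capping

The macrocycle is the largest smallest-set-of-smallest-rings ring with at
least 12 heavy atoms carrying at least two backbone amide bonds (ties go to
the ring with more amides).  Every amide C(=O)–N bond and every S–S bond
whose two atoms lie on that ring is cut simultaneously; amide bonds
anywhere else — side chains of Asn/Gln, exocyclic termini — are never cut.
Peptides with fewer than five cleavable bonds are rejected as too small.

Hydrolytic capping would create hydrogen-bond donors the intact chain does
not have, so the cut ends are completed non-hydrolytically: the amide
nitrogen receives a methyl group (emulating the tertiary-amide
environment), the carbonyl carbon becomes an aldehyde, and each disulfide
sulfur becomes a free thiol.  Capping by 2D valence completion is exact for
these three cases; no 3D conformer generation is involved.

Fragments inherit their side chains by post-cleavage connectivity and are
reported in ring order, traversed N→C.  The traversal origin is arbitrary
chemistry-wise; we anchor deterministically at the fragment whose capped
canonical SMILES sorts first (ties by smallest atom index) so that runs are
reproducible.  Augmentation (below) makes the model itself indifferent to
this choice, and a dedicated test asserts that rotating the ring merely
relabels the saliency output.

## Descriptors

Descriptors are 2D only.  The default trio is the lipophilicity /
charge-surface / solubility triple long associated with albumin binding:
Crippen atomic-contribution logP, the most-negative Gasteiger-charge bin of
van der Waals surface area, and a Delaney-style ESOL solubility estimate.
A 64-name RDKit search space (surface-area families, shape indices,
counts) is exposed for selection experiments.  The engine name is stored in
output metadata so values from different engines are never mixed.

Standardization is the Z-score z = (x − μ)/σ with μ, σ the mean and
population standard deviation of the *whole-peptide* descriptor over the
training split only; substructure values are scaled with the same
whole-peptide statistics so residue-level and whole-molecule values share a
scale.  Using training statistics for everything downstream is a
deliberate anti-leakage choice, and the null-control experiment (below)
verifies it.

Substructure rows are then weighted by appearance frequency in the
training data.  The shipped strategies are `linear` (count / max count,
the default), `sqrt`, and `none`; all are monotone in frequency, and
unseen substructures fall back to count 1.

## Splitting and the objective variable

Labels are clamped to [50, 95] (%PPB50−95): below 50% a peptide is not a
viable candidate, above 95% assay resolution saturates.  The test split is
chosen by the classic Kennard–Stone algorithm on the standardized
whole-peptide descriptor matrix: seed with the two most distant points,
then repeatedly add the point whose minimum distance to the selected set
is maximal; the selected points are the *test* set, so held-out peptides
cover descriptor space uniformly.  Test size is ceil(fraction × N) —
0.10 × 363 = 37 test / 326 train on a 363-row matrix.  Distance ties break
to the smallest row index, making the split fully deterministic.

## Descriptor selection

Two deterministic prefilters: drop exactly constant columns, then for
every pair with |Pearson r| ≥ 0.95 drop the member less correlated with
the clamped label (columns visited in descending target-correlation
order, so a clique of near-duplicates leaves exactly its most predictive
member).  Bootstrap-Lasso follows: for each penalty α on a grid
(default 0.5–4.9 in steps of 0.2) and each of 100 bootstrap row-resamples,
an L1-penalized fit records which coefficients are nonzero; a descriptor
is selected only if its nonzero frequency reaches the threshold (default
1.0, strict intersection) at every α in the stable window — by default the
upper region of the grid (4.3–4.9), where only the most robust signals
survive.  The α grid is scaled to %PPB-magnitude targets; targets on other
scales need a correspondingly scaled grid.  Exactly collinear informative
columns split the bootstrap votes; the result object reports this
instability rather than silently dropping both.

## Feature maps, augmentation, CyclicConv

A peptide's n ≤ 15 substructure vectors occupy a contiguous span centered
in a D × 15 zero-padded array (start = ⌊(15 − n)/2⌋; for odd gaps the
extra zero column sits on the right).  Since the ring has no intrinsic
start, augmentation enumerates all n cyclic rotations at all 15 − n + 1
translations: n·(15 − n + 1) replicas, identity included, never sampled —
at training time each replica is a training sample, at test time the raw
predictions of all replicas are averaged and then clamped to [50, 95]
(averaging first preserves the mean; clamping first would bias boundary
peptides).  Replica predictions are sorted before averaging so the mean is
bit-identical regardless of enumeration order, which makes the rotation
invariance of augmented prediction exact rather than approximate.

CyclicConv is a same-length 1-D convolution whose receptive field wraps
circularly *within the occupied span only*: output position j inside the
span reads input positions start + ((j − start + d) mod n); positions
outside the span stay zero.  For residues A, B, C and kernel 3 the fields
are (C,A,B), (A,B,C), (B,C,A).  It equals an ordinary valid convolution
applied to the span explicitly pre-padded with its own wrap-around
columns, and the test suite asserts this equivalence to 1e−6 on random
maps for k ∈ {3, 5}.  Kernels larger than the ring are rejected.

## Network, training, variants

All four variants share one body: two convolution layers (kernel 3,
32 then 64 channels), global pooling over the span, dense layers
64 → 16 → 1, batch normalization after every convolution and dense layer,
ReLU activations.  Variants differ only in convolution kind and whether
augmentation is applied: `baseline` (ordinary, none), `cyclicconv`
(circular, none), `augmented` (ordinary, full), `cyclicconv_augmented`
(circular, full).

The network is implemented directly in NumPy with hand-derived backward
passes (verified against central finite differences in the test suite);
the same machinery that trains the model returns input gradients for
saliency.  Training minimizes mean squared error on the clamped labels
with adaptive-moment gradient descent (lr 1e−3, batch 128), an internal
10% peptide-level validation split, early stopping (patience 30 of a
300-epoch budget by default), and restoration of the best-validation
parameter state.  The output layer's bias is initialized to the mean
training label so the optimizer spends its steps on structure rather than
on walking the ~70 %PPB offset.  Pooling is max over the span (masked, so
batch-norm shifts of the padding columns cannot leak into the pooled
value); average pooling is available by configuration.  Batch norm at
inference uses running statistics, and replica batches are forwarded in
eval mode, so augmented prediction is deterministic.  All initialization,
shuffling and splitting derive from the config seed; identical
data + config give bit-identical training histories.

## Saliency

The saliency score is s = |∂ŷ/∂x| (VanillaGrad), taken at the *raw*
network output before clamping — the clamp has zero gradient in its
saturated regions and would erase attribution exactly for strongly bound
peptides.  Each replica's span columns are mapped back to ring positions
through the replica's (rotation, translation) provenance and averaged;
padding columns are discarded.  The per-residue score is the sum over
descriptor rows.  For an exactly linear model the saliency equals the
absolute weights; for trained networks it matches central finite
differences (h = 1e−3) to 1e−3 relative error.

## Evaluation

MAE = Σ|y_i − ŷ_i|/n and Pearson R, over two ranges: 50–95 (all test
peptides, predictions clamped to [50, 95]) and 80–95 (only peptides whose
*experimental* value is ≥ 80 — predictions never drive the filter — with
the same clamp applied).  With fewer than two records, or zero variance,
R is reported as undefined rather than fabricated.

## Synthetic data: what it emulates and what it does not

The generator emulates the shape of real cyclic-peptide panels: 5–15
residues with the mode near 7–10, head-to-tail amide cyclization with a
10% admixture of terminal-cysteine disulfide bridges, optional backbone
N-methylation, and labels concentrated in 50–95 with mass on both clamp
boundaries.  Labels follow
%PPB = clamp(a + b·mean_s logP(s) + c·max_s logP(s) + ε),  ε ~ N(0, σ²),
with defaults a = 60, b = 24, c = 16, σ = 3 chosen so that roughly 90% of
labels are interior, both boundaries are populated, and the noiseless
signal spans ~10 percentage points of standard deviation — a realistic
signal-to-noise for equilibrium-dialysis %PPB assays.  The max term plants
a single "important residue" per peptide so attribution has a known
ground truth, mirroring the way one fatty side chain can dominate real
albumin binding.

What the generator does *not* emulate: real substructure chemistry beyond
the proteinogenic alphabet (no proline, no depsipeptides, no exotic
N-alkylations), correlations between residue identity and position,
3D conformation, or assay-specific error structure.  Passing tests
therefore demonstrate that the pipeline recovers a residue-localized
lipophilicity signal of realistic magnitude under realistic noise — not
that any particular accuracy carries over to proprietary panels.

## Study-scale experiments

The two end-to-end experiments run at desk scale on one CPU:

* **Parameter recovery** — 334 generated peptides, Kennard–Stone 10%
  split (300 train / 34 test), `augmented` variant, 60-epoch budget with
  patience 15.  Expected outcome: held-out R ≥ 0.8 (typically ≈ 0.95), and
  the planted residue tops the aggregated saliency ranking for a majority
  of test peptides in at least 2 of 3 seeds.
* **Null control** — 400 generated peptides with the signal removed
  (b = c = 0), trained on 200 and evaluated on 200 held-out peptides
  (25-epoch budget; the null outcome does not depend on fit quality), five
  seeds.  Expected outcome: held-out |R| < 0.25 throughout.  This guards
  against leakage through standardization statistics, frequency counts or
  augmentation.

## Known limitations

* One macrocycle per molecule; ester-bond (depsipeptide) cleavage and
  multi-ring topologies are out of scope.
* Maximum ring size is 15 substructures; longer peptides are rejected
  rather than truncated.
* Descriptor values are open-source surrogates; they are internally
  consistent but not numerically interchangeable with commercial engines.
* Batch-norm statistics are computed over all 15 map columns for
  convolution layers, including padding; pooling masks the padding, but
  channel statistics still see it.  Masked batch norm was not needed to
  meet any quality target and is left out for simplicity.
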