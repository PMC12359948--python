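# Methods

## Standardisation pipeline

Input SMILES pass through parse → element screen → normalise → parent
fragment → tautomer canonicalisation, in that order; the first failing stage
is recorded with a message and later stages are skipped. The element screen
keeps molecules built solely from H, C, N, O, F, P, S, Cl, Br and I — the
elements of stable drug-like organic chemistry — so organometallics and
boron/arsenic-containing specialist drugs are rejected whole. Normalisation
(RDKit `MolStandardize`) removes explicit hydrogens, disconnects covalent
metal bonds and neutralises ionic charges; net-neutral charge-separated
groups such as nitro survive unchanged. The parent molecule is the fragment
with the most heavy atoms; ties are broken by the lexicographically smallest
canonical SMILES, which is deterministic and invariant to input atom order.
After fragment selection the neutraliser runs again, because a parent split
off a salt can carry the charge its counterion balanced. Tautomer choice is
the toolkit's deterministic canonical form; what the pipeline guarantees is
only determinism and tautomer-class invariance (all tautomeric inputs of one
compound map to one SMILES). Tautomer canonicalisation may discard
stereocentres adjacent to tautomerisable groups; this is inherited toolkit
behaviour.

Under the default stage order a salt whose counterion contains a metal (e.g.
a sodium carboxylate) is rejected at the element screen before the counterion
could be stripped. The `screen_after_parent` flag moves the screen after
parent selection for users who prefer counterion stripping; it is off by
default so the screen judges the record as submitted. With the strict default
order the metal-disconnection step of normalisation is unreachable (any metal
already failed the screen); it is retained because the relaxed ordering makes
it live.

## Conformers and geometry features

Each standardised molecule gets explicit hydrogens and one distance-geometry
embedding from random coordinates. Attempts are issued one at a time with
per-attempt derived seeds (cap 5,000) so the consumed attempt count is
observable and the whole embedding is reproducible from a single seed.
Embedding exhaustion is a logged failure, not an exception. The embedded
conformer is relaxed with MMFF94 (RDKit implementation; iteration cap 2,000,
toolkit convergence criteria), which may only lower the energy. One conformer
per molecule is used; conformational ensembles are out of scope, and the
relaxed geometry approximates a gas-phase minimum rather than any
protein-bound pose.

Bond lengths are Euclidean distances between bonded-atom coordinates.
Bond-length change between the embedded and relaxed geometry is summarised
as absolute percent change 100·|after−before|/before (signed values can be
recovered by callers); the summary uses the sample standard deviation
(ddof=1, zero for a single bond). The paired t-test on matched change
samples delegates to `scipy.stats.ttest_rel` and raises on zero-variance
differences, where the statistic is undefined.

## Graph schemas

Graphs are over heavy atoms; hydrogens added for the 3D step contribute only
through the per-atom hydrogen count. Every chemical bond is stored as two
directed arcs carrying identical features. The basic schema encodes the
atomic number (one-hot over the nine heavy allowed elements) per node and
the bond type (single/double/triple/aromatic one-hot) per edge. The custom
schema adds, per node: heavy-atom degree, formal charge, hybridisation
(one-hot, SP/SP2/SP3/SP3D/SP3D2/other), aromaticity, hydrogen count, ring
membership, chirality (none/CW/CCW/other), radical electron count, Gasteiger
partial charge, total valence and explicit valence; and per edge: a ring
flag and the bond length measured on the relaxed conformer. Counts and
valences are small integers cast to floats; charge and length are raw
scalars. No feature standardisation is applied by default. Non-finite
Gasteiger charges (possible on exotic valence states) become 0 with a
per-graph warning flag. Vocabulary and dimension choices are recorded in the
dataset header so the encoding is auditable, and saved datasets round-trip
bit-exact.

## Model architecture and engine

The four convolution families implement their defining update rules exactly
as written (see the README for the equations): GCN with self-loop-augmented
symmetric degree normalisation and optional non-negative arc weights
entering the degrees; single-head GAT with LeakyReLU slope 0.2 on the
attention logits; GraphSAGE with mean aggregation (the neighbour term is
zero for isolated nodes); GIN with a fixed ε (default 0, configurable, never
trained) and a two-linear-layer rectified MLP. Edge features do not enter
the convolutions by default: the GCN/SAGE/GIN update rules contain no edge
terms, and the GCN's arc weight defaults to 1. This choice is deliberate —
the custom schema's information reaches the models through the node features
and through the data pipeline, and any edge-weight reduction a user supplies
is recorded with the run.

The model stacks three convolutions with output widths 2h, h and h/2 for
`hidden_channels = h` (h must be even), ReLU after each, dropout after the
third, global mean pooling, and a linear head producing one logit (binary)
or two (two-class cross-entropy, for two-task data such as FDA-approval
plus toxicity labels). The sigmoid/softmax lives inside the numerically
stable loss (log-sum-exp form), never in the forward pass. All weight
matrices are Glorot-uniform initialised (variance 2/(fan_in+fan_out));
biases start at zero; the attention vector is treated as a 2h→1 map for
fan purposes. Optimisation uses Adam at the grid's learning rate.

The engine is a small reverse-mode autodiff over NumPy arrays (gather /
segment-sum / segment-softmax primitives for arc-wise message passing).
Evaluation mode is deterministic; training mode draws dropout masks and
batch orders from an explicit generator, so an entire protocol run is
reproducible from its seeds. Analytic gradients match central finite
differences to 1e-4 relative error at random parameter points; exact-zero
ReLU pre-activations (e.g. from zero-initialised biases) are genuine
subgradient kinks where finite differences disagree by construction, which
is why gradient checks are performed at fully randomised points.

## Training protocol

`make_fold_plan` builds stratified outer and inner partitions with
scikit-learn's stratified K-fold (shuffled, seeded); with the default 4
outer × 5 inner folds each molecule sees 60/15/25 train/validation/test
roles. Both classes must have at least outer_k × inner_k members.

Grid search trains every combination (default grid: batch size {16, 32, 64},
hidden channels {32, 64, 128}, dropout {0.1, 0.3, 0.5}, learning rate
{1e-4, 3e-4, 1e-3, 3e-3, 1e-2}; 135 combinations, fully overridable) on each
inner split with early stopping, and selects the combination minimising the
sum of its descending rank by median and by minimum validation AUC
(mid-ranks for ties in each ranking; exact rank-sum ties go to the earliest
enumeration index). Seed reinitialisation then retrains the winning
combination from 20 fresh Xavier initialisations and picks the seed by the
same combined rank; seed search retrains rather than reusing grid-search
fits, since the two stages are distinct. Training failures inside a trial
score as AUC 0 for that fold rather than aborting the search.

Sequential warm starts then repeatedly train the selected model through
inner folds 1…k in fold-plan order, parameters persisting across folds and
runs, each fold fit guarded by early stopping (validation-AUC patience 50 by
default, best-epoch restore, 500-epoch cap). After every run the pooled
validation AUCs of all outer folds (inner_k × outer_k values per run) are
compared with each of the two previous runs by a one-sided Wilcoxon rank-sum
test for improvement; from the third run onward, warm starts halt when both
p-values exceed the Sidak-corrected level 1−(1−α)^(1/2) (α = 0.05). The test
is the unpaired rank-sum (not signed-rank), one-sided "current run greater";
two-sided is available by flag. A hard cap of 10 runs prevents
non-termination on pathological data. The model evaluated on each outer test
fold is the final warm-started state after the last completed run.

Outer evaluation reports AUC (Mann–Whitney formulation, ties counted half),
accuracy, F1 and MCC (zero-denominator F1/MCC are 0 by convention) per outer
fold with mean and standard deviation across folds; the classification
threshold is sigmoid probability 0.5. An index tracker records every dataset
index touched during selection or training per outer fold and evaluation
raises if any test index was seen — leakage freedom is asserted, not
assumed.

The rank-sum test uses mid-ranks and is exact by full enumeration of the
C(n+m, n) rank assignments for pooled sizes up to 12, conditional on the
observed tie pattern; beyond that, the tie-corrected normal approximation
(no continuity correction) is used.

## Synthetic data

The generators define the study conditions for everything that needs
labelled molecules.

*Substructure signal* — molecules are assembled from aromatic/aliphatic
scaffold templates with random substituents drawn over the ten allowed
elements; positives carry a nitro group. Template composition guarantees
chemical validity without a filter loop. The default acceptance-scale
dataset is 300 molecules, balanced classes, 5% label-flip noise — enough
noise to be realistic, little enough that the planted rule alone attains
AUC ≈ 0.95.

*Charge threshold* — molecules come from template pairs sharing one
heavy-atom skeleton and differing only in a single carbon–oxygen bond order:
ketone (max Gasteiger charge ≈ 0.126–0.136 at the carbonyl carbon) versus
secondary alcohol (≈ 0.048–0.057). The label thresholds the molecule's
maximum Gasteiger charge at τ = 0.09, inside the gap for every bundled
skeleton. Within a pair the atomic numbers and adjacency are identical, so
the basic-schema convolutions — which consume node features and connectivity
but no edge features — are at chance structurally, while the custom schema
sees the charge (and hydrogen-count/valence) features directly. Strictly
isomeric pairs cannot produce this contrast: Gasteiger charges are a
function of the element/bond-order graph, so identical basic graphs imply
identical charges, and different connectivity is learnable by message
passing; the isoskeletal construction is the clean way to make the
feature-set contrast a property of the data.

What the generators do not emulate: real pharmacology (no property-matched
decoys, no activity cliffs, no scaffold-split generalisation pressure),
assay label noise structure, or the size/diversity of curated datasets.
Passing the recovery tests therefore demonstrates that the pipeline and
protocol work end to end and that the custom features carry usable signal —
not that any particular real-world AUC is attainable.

## Reduced study conditions

The canned experiments in `molgnn.experiments` use 2 outer × 3 inner folds,
an 8-combination grid (batch 32; hidden {16, 32}; dropout {0.1, 0.3};
learning rate {3e-3, 1e-2}), 3 reinitialisation seeds, at most 3 warm-start
runs, and a 60-epoch budget with patience 15 — sized for a single CPU while
exercising every stage of the full protocol. The substructure recovery run
uses 300 molecules; the feature-contrast run uses 150 molecules featurised
twice (custom and basic) from identical inputs.

## Numerical choices and degenerate inputs

- Empty batches, empty samples, single-class AUC, zero-variance paired
  differences and out-of-range bond indices raise errors; standardisation
  and embedding failures never raise per record.
- Single-atom molecules yield valid graphs with zero arcs; isolated nodes
  get a zero neighbour term (SAGE), a self-only update (GCN, degree 1), or
  a pure MLP update (GIN, ε = 0).
- Dropout is inverted (scaling by 1/(1−p) at train time) and entirely
  absent in evaluation mode.
- Hidden width h/2 must be integral, hence h even, enforced at config
  construction.
- Non-finite training loss aborts the fit with a diagnostic; inside a grid
  or seed trial the fold scores 0.

## Known limitations

- Gasteiger charges and MMFF geometries are approximations; neither reflects
  conformational ensembles or a biological environment.
- GAT is single-head; multi-head attention, edge-feature message networks
  and pretraining are out of scope.
- The CSV adapters do not retrieve structures from external databases; users
  supply SMILES.
- The engine targets small-molecule graphs on CPU; it makes no attempt at
  GPU-scale performance.
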