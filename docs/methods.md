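# Methods

## Problem and scope

`contactnet` predicts residue–residue contacts of a protein from its
sequence, a multiple sequence alignment (MSA), and auxiliary per-residue
predictions, and turns confident predictions into distance restraints for
structural modelling.  A contact is defined on the native structure: the
Cβ atoms of the two residues (Cα for glycine, and for residues whose Cβ is
missing from the coordinate file) lie strictly closer than 8 Å.  Sequence
separation |i − j| partitions pairs into local [1, 5], short [6, 11],
medium [12, 23], and long [24, ∞) regimes; medium and long range pairs
carry the fold information and are the default evaluation focus.

The comparison at exactly 8.000 Å is taken as *not* a contact (strict
`<`); the choice only matters for coordinates constructed to land exactly
on the threshold.

## Input features

Each pair (i, j) of a length-L target is described by 51 channels:
40 sequence-profile values (20 per residue), 6 secondary-structure
probabilities (3-state × 2 residues), 2 relative solvent accessibilities,
and three genuinely pairwise channels — a coevolution coupling score, the
mutual information between alignment columns, and a statistical contact
pair potential U(a, b).

Design choices where the pipeline was open:

* **Profiles** are per-column amino-acid frequencies from the MSA, with a
  uniform pseudocount (default 1 observation spread over the 20 letters)
  and gaps excluded from normalisation.  A PSSM reader is provided for
  users who have PSI-BLAST output, but no external binary is required.
* **Mutual information** uses the natural logarithm, no sequence
  weighting, and no average-product correction.  Marginals are derived
  from the (optionally smoothed) joint distribution of each column pair,
  which keeps MI ≥ 0 by construction; the diagonal is set to 0.
* **Coevolution scores** are read from the flat whitespace L×L matrix
  dialect; the matrix is symmetrised as (M + Mᵀ)/2 and the diagonal
  zeroed.  The package does not run any coevolution tool itself.
* **Pair potential**: U(a, b) = −ln[P_obs(a, b | contact) / P_exp(a, b)],
  with additive smoothing (default 1 count) and P_exp from the corpus
  amino-acid composition.  It is a plain log-odds contact propensity
  derived from whatever structure corpus the user supplies — the table is
  swappable if a published potential is preferred.  Letters outside the
  20-letter alphabet map to the uniform profile row and the table mean.
* **Secondary structure** enters as the 3-state probability vector (not
  one-hot), matching the output of the 1D network; **accessibility** is a
  single scalar in [0, 1] per residue from any source.

## Network architecture

The contact network is a 2D fully convolutional residual network: one
entry convolution + ReLU, 19 identical residual blocks (conv → ReLU →
conv → add input → ReLU), a transpose-averaging step, and a final
convolution to 3 output channels (non-contact / contact / ignored)
followed by a per-pair softmax.  All convolutions use 64 filters of size
3 × 3, stride 1, zero "same" padding — 40 convolutional layers and
1,434,435 trainable parameters (closed form:
(3·3·51·64 + 64) + 19·2·(3·3·64·64 + 64) + (3·3·64·3 + 3)).
There is no batch normalisation (inputs have arbitrary L, batch size is
1) and no dropout (pixel-level output).

Symmetry: the residual trunk's output is averaged with its spatial
transpose before the final convolution, and the final logits are averaged
with their transpose again.  Because IEEE addition is commutative, the
two averaging steps make P[i, j] and P[j, i] bitwise identical for any
weights.  The second averaging is the package's own addition: a 3 × 3
final convolution applied to a symmetric feature map is *not* exactly
symmetric on its own, and the output contract here is exact symmetry.

The reported P is the raw contact-class probability; it is not
renormalised over the ignore class.  The `ignored` output class exists so
the softmax matches the three label states, but pairs labelled ignored
carry zero loss weight, so the class is never pushed as a target.

The secondary-structure predictor is the 1D analogue: 10 convolutional
layers (entry + 4 blocks + final) with 1 × 3 kernels over a (L, 40) input
(20 profile + 20 one-hot sequence channels), 3-state softmax output, no
transpose averaging.

The networks are implemented directly in NumPy: im2col/matmul
convolutions with analytically derived backward passes, verified against
central finite differences in the test suite.  Float32 is the default
parameter dtype; float64 is available (and used for the gradient-check
tests).

## Training protocol

Loss is softmax cross-entropy with class weights (1, w, 0) for
(non-contact, contact, ignored): ignored pairs contribute zero loss and
zero gradient, and w is the contact-class weight.  Because non-local
contacts are only a few percent of pairs, up-weighting contacts (w = 4)
raises recall; the benchmark protocol trains both w = 1 and w = 4.

The optimiser is momentum SGD (lr 0.01, momentum 0.9, L2 weight decay
1e−4), batch size 1 with per-epoch reshuffling; all randomness
(initialisation, shuffling, splits) derives from one mandatory seed, so
runs are bit-reproducible.  These hyper-parameters are defaults, not the
product of a search; all are configurable.

The ensemble protocol splits the training ids five times with
pairwise-disjoint validation subsets (production scale: 800 validation
cases per split) and trains one model per (split, weight ∈ {1, 4})
combination — ten models whose probability maps are combined by
arithmetic mean.

## Evaluation

Top-L/k precision (k = 1, 2, 5, 10): eligible pairs are the upper
triangle, restricted to the requested regimes, excluding pairs the native
map marks ignored; they are ranked by P descending with ties broken by
ascending (i, j); the top ⌈L/k⌉ are taken (all of them, if fewer exist,
with the denominator shrinking accordingly — the CASP convention); the
score is the fraction that are native contacts.  Ceiling was chosen for
the selection size; the source conventions do not state a rounding rule.
Targets with zero native contacts in the requested regimes score 0 even
if the predictor abstains, again following CASP practice.

Secondary views: precision of positive predictions (P > 0.5) within
probability bins (empty bins are *undefined*, not zero), and the contact
prediction depth D = |{medium/long pairs with P > 0.8}| / L.

## Contact-pattern analysis

Native medium/long contacts are clustered in (i, j) index space with
HDBSCAN (minimum cluster size 3, `min_samples` = minimum size, Euclidean
metric on the raw indices).  Two conventions adapt the generic hierarchy
to contact maps:

* a point set whose density hierarchy never splits (one dense pattern) is
  accepted as a single cluster rather than all noise;
* each cluster must be Chebyshev-connected within a two-residue shift —
  a geometric contact pattern is a set of near-adjacent map points, so
  stragglers attached only through a weak density bridge are reassigned
  to noise, and disconnected fragments below the minimum size dissolve.

A native cluster is **hit** if at least one correctly predicted contact
(true positive) lies in it; the hit criterion is the package's own, the
source material does not define one.  Cluster coverage = hit clusters /
all clusters; contact coverage = true positives inside clusters / native
in-cluster contacts; ΔCoverage is the signed difference of two methods'
coverages on the same native cluster set (enforced by a basis check).
False-positive proximity is the fraction of false positives within
Chebyshev distance ≤ 2 of any native cluster member ("two-residue
shift"); with zero false positives it is undefined.  When two predictors
are compared, the second is truncated to the same number of top-ranked
medium/long pairs as the first's positive count, so both are judged on
equal footing.

## Restraints

Every positive prediction (P strictly above the cutoff, default 0.5)
becomes one restraint: an 8.0 Å upper bound between the side-chain
centers of mass (mass-weighted over non-backbone heavy atoms; Cα for
glycine), carrying P as its confidence, sorted by descending P.  Template
contacts can be merged as a tagged union before conversion: predicted
probabilities are retained, template pairs are injected at a configurable
floor probability (default 0.5) and tagged `template` so downstream
modelling can keep template-derived restraints unchanged.  Only the
side-chain COM bound is emitted; no additional Cβ bound.

## Synthetic data

The generator emulates the input ecosystem at desk scale.  Toy folds are
antiparallel bundles of ideal helices (rise 1.5 Å/residue, 100°/turn,
radius 2.3 Å) and strands (rise 3.3 Å/residue), segment axes 9 Å apart,
connected by 4-residue loops bowed out of the packing interface; every
residue gets a pseudo-Cβ displaced 1.5 Å from its Cα away from the
segment's own axis, and glycines (rate 0.08) exercise the Cα fallback.
Packed neighbours produce the stripe-shaped medium/long contact clusters
real secondary-structure packings produce, at a realistic sparsity
(~2 % of non-local pairs).  MSAs are generated by mutating the target
(rate 0.35 per column, depth 300 by default, gap rate 0.02); contacting
column pairs instead draw jointly through a per-pair random letter
bijection with probability equal to the covariation strength (default
0.8), which creates mutual information above background exactly where
the fold has contacts.  The toy coevolution matrix is max-normalised MI
plus Gaussian noise (σ 0.05) — a stand-in with the right statistical
structure for a coupling-analysis score.

What the generator does *not* emulate: real backbone geometry and side
chains, indirect (chained) coevolution, phylogenetic sequence redundancy,
alignment errors, and domain boundaries.  Passing the learning tests
therefore shows that the stack can extract a planted covariation signal
end to end — not that it reaches published accuracy on real proteins,
which requires PDB-scale training.

## Desk-scale study sizes

The test suite and the acceptance script train a reduced network
(16 filters, 3 residual blocks ≈ 44k parameters) on 30 synthetic targets
(L 40–60, MSA depth 200, covariation 0.8) with 6 held-out targets,
40 epochs; the single-target overfit run uses 1000 epochs because one
target means one gradient step per epoch.  The full 64-filter/19-block
architecture is still instantiated and verified layer-by-layer and
parameter-by-parameter.  Property checks compare every metric against
brute-force enumeration oracles on randomized fixtures of L ≤ 60.

## Known limitations

* CPU-only NumPy training; PDB-scale training is out of reach by design.
* mmCIF structures are not parsed (PDB format only); Cα-only contact
  definitions and distance maps beyond the binary threshold are not
  provided.
* The statistical pair potential is derived from the user's corpus, not a
  published reference table.
* HDBSCAN label-boundary conventions differ slightly between
  implementations; the two refinements above define this package's
  behaviour precisely.
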