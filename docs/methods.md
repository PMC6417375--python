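# Methods

This note records the models, defaults and numerical choices behind
`psnkit`, and what the synthetic-data generators do and do not emulate.

## Interaction model

Interactions are side-chain–side-chain only; backbone atoms (N, CA, C, O,
their hydrogens, OXT) never enter a criterion, except that glycine's
"side chain" falls back to its Cα for centroid purposes. Defaults, all
overridable through the flat key/value configuration:

| parameter | default | meaning |
|---|---|---|
| `hydrophobic_cutoff` | 5.0 Å | side-chain mass-centroid distance |
| `salt_bridge_cutoff` | 4.5 Å | closest atoms of opposite charged groups |
| `hbond_distance_cutoff` | 3.5 Å | donor···acceptor heavy-atom distance |
| `hbond_angle_cutoff` | 120° | D–H···A angle (≥, inclusive) |
| `ion_cutoff` | 3.0 Å | ion to side-chain O/N |
| `persistence_step` | 0.1 % | cluster-curve grid |
| `hub_min_degree` | 4 | hub definition |
| `es_dimension` | 20 | essential-subspace size |
| `exclude_adjacent` | 1 | skip same-chain pairs with \|i−j\| ≤ 1 |

The hydrophobic set {Ala, Val, Leu, Ile, Phe, Pro, Trp, Met} plus acyl
pseudo-residues, the charged-group atoms (Asp/Glu carboxylates;
Lys/Arg/His⁺ amines/guanidinium) and the donor/acceptor tables follow the
defaults of widely used residue-interaction-network tooling; they are
assumptions, not measurements, and are kept in one module
(`chemistry.py`) precisely so they can be audited and overridden. Atom
masses are standard atomic weights.

Distance and angle comparisons are inclusive (≤ / ≥), so boundary
geometries count as contacts; boundary behaviour is tested explicitly.

Hydrogen handling is decided per model: if the structure carries any
side-chain hydrogens, a donor lacking its hydrogen is skipped (warned
once per residue); if the structure has none at all — the common case for
crystal-derived ensembles — the hydrogen-bond criterion degrades to
distance-only with a logged warning.

Sequence-adjacent pairs are excluded by default because backbone-linked
neighbours are trivially persistent and would dominate every network;
setting `exclude_adjacent = 0` restores them.

## Threshold estimation

The largest-hydrophobic-cluster size is computed at every grid threshold
by a single high-to-low sweep that adds edges as they qualify (the curve
is non-increasing by construction and asserted so). The decay is fitted
with a four-parameter logistic
y(p) = y_min + (y_max − y_min)/(1 + exp(k (p − p₀)))
by least squares (`scipy.optimize.curve_fit`, tolerances 1e-8, up to 10⁴
evaluations), initialised from the curve's quartile crossings. The
threshold *p*<sub>T</sub> is p₀ rounded **down** to one decimal — the
reading of "rounded at the lowest decimal value" consistent with
one-decimal reported thresholds — with a 1e-6 guard so a fit that
represents 36.8 as 36.79999… still reports 36.8; conventional rounding is
available via `pt_rounding = nearest`. Flat curves raise a
degenerate-curve error; fits whose residual norm exceeds half the curve
span (per point) are rejected with the residual reported. Fitted
inflections outside [0, 100] are clamped: a persistence threshold is a
percentage.

## Communication metrics

CR(a, b) = n/ℓ with n the number of distinct shortest paths and ℓ their
common length; it is undefined (not zero) for disconnected pairs. SB and
n are computed by BFS shortest-path DAG counting (σ-products, as in
betweenness algorithms), so they never materialise paths; explicit path
enumeration for pathway reports is capped (default 10⁵) with a hard error
beyond. Endpoints are excluded from SB, following the standard
betweenness convention. The defining supplementary text for CR/SB was not
available when this package was written; the n/ℓ form matches every
qualitative property claimed for the index (parallel routes strengthen,
length weakens), and both functions are deliberately isolated so that an
alternative formula is a one-line change. All co-maximal pathways are
reported, ordered lexicographically.

## Convergence diagnostics

Superposition is a least-squares rigid fit (SVD/Kabsch with proper-
rotation enforcement) computed on Cα and applied to all atoms; the
default reference is the first frame of the first ensemble. PCA
diagonalises the (3N×3N) Cα covariance about the ensemble mean with
`numpy.linalg.eigh`; eigenvalues are reported descending and the
essential fraction is clamped to [0, 1] against solver round-off. Cosine
content uses the discrete half-period-cosine overlap with uniform unit
time step (the statistic is invariant to uniform rescaling of t). Note
that sin(2πt/T) is *not* orthogonal to cos(πt/T) over [0, T] (their
overlap is 4T/3π, giving c₁ ≈ 0.72); the orthogonal references used in
tests are sin(πt/T) and the constant series. RMSIP follows the standard
root-mean-square inner product over the first D eigenvectors.

The replica-concatenability test builds, per replica pair, a Fisher LD1
from the two-class between/within scatter in the PC1/PC2 plane
(ε = 1e-9 × trace regularisation when the scatter is singular) and
classifies every frame to the nearest class mean on LD1 with equal
priors — the decision rule is a package choice, cross-checked against
scikit-learn's eigen-solver LDA in the tests. A pair is consistent iff at
least one frame is misclassified: perfect separability means the replicas
sampled disjoint regions and should not be concatenated.

## Conservation analysis

Conservation of seed residue s at an alignment column is the fraction of
non-seed cluster sequences carrying the same residue (mode `identity`,
the default strict reading) or a residue in the same Clustal strong group
(mode `similarity-groups`; groups STA, NEQK, NHQK, NDEQ, QHRK, MILV,
MILF, HY, FYW). Gaps never match, and the seed is excluded from both
numerator and denominator — "total number of sequences in the cluster" is
ambiguous by ±1 and the seed trivially conserves itself.

A residue that is a hub in several states contributes once, at its
maximum degree; per-degree means are regressed on degree with
`statsmodels` OLS, pooled across proteins (a per-protein option exists).
Residual normality uses Shapiro–Wilk and constant variance uses
Breusch–Pagan (switchable to Levene on a fitted-median split; the choice
of test is a package decision). On exactly collinear input the residuals
are numerically zero, both pre-tests are vacuous, and the report returns
p = 1 with R² = 1.

Pairwise identity comes from Biopython's global `PairwiseAligner` with
BLOSUM62 and affine gaps costing open + extend × (L − 1) (defaults 10 and
0.5); the score is verified against an independent three-state Gotoh DP
in the tests. With co-optimal alignments the aligner's first one defines
the printed identity; the optimal score is unique.

## Synthetic data: what it emulates, what it does not

The generators plant exactly the statistical structure each stage
assumes, and nothing more:

- **Contacts** switch as independent per-frame Bernoulli draws, so
  measured persistence is binomial with known variance. Geometry is
  realised on a 100 Å lattice with an anchor→mobile convention: the
  second node of each pair is displaced along a per-edge axis to
  cutoff − 0.5 Å (ON) or cutoff + 5 Å (OFF). Within a connected planted
  component, edges take mutually orthogonal axes, which bounds every
  unplanted separation below any cutoff; components needing more than
  three edges, nodes mobile in two pairs, cyclic anchor chains or
  contradictory residue-type demands raise a generation error rather
  than silently mis-planting.
- **Modes** are polynomial *shape* deformations with the six rigid-body
  modes projected out, because superposition removes global
  translation/rotation — a uniform-displacement "mode" would vanish from
  the analysis and silently defeat variance-recovery checks. Replica
  offsets shift the mean along the first mode and therefore survive
  fitting.
- **Alignments** substitute uniformly random different residues where the
  planted conservation draw fails; no gaps, no phylogenetic correlation.
- **Cluster curves** are logistics from y_max down to 1 with additive
  Gaussian noise.

Consequently, passing tests demonstrate correctness of the measurement
chain — detection, reduction, thresholding, path metrics, diagnostics,
regression — under known ground truth. They do not demonstrate that real
MD ensembles satisfy the generators' independence assumptions (real
contacts switch with temporal correlation; real conservation is
phylogenetically structured), nor do they reproduce any particular
protein's published network, which requires the original trajectories.

## Problem sizes

Default verification sizes were chosen so each property is statistically
decisive at desk scale: 10⁴ frames for binomial persistence separation
(20 % vs 80 % differ by ~75 standard errors at that depth) and for PCA
variance recovery (sampling error ≈ √(2/n) ≈ 1.4 %); 500 cluster
sequences for conservation ratios (s.e. ≤ 2.3 points); 500 random graphs
of ≤ 8 nodes for exhaustive path-metric comparison; 100 seeded repeats
for the noisy threshold fit; 20 seeds for the discriminant calls.

## Known limitations

- The CR/SB formulas implement the documented design reading (n/ℓ;
  endpoint-free SB) and have not been checked against the original
  supplementary definition.
- π-stacking, cation-π and water-mediated bridges are not detected;
  backbone–backbone hydrogen bonds are excluded by design.
- Multi-model PDB is the only mandatory trajectory reader; binary
  trajectory formats need an external conversion step.
- The cross-protein hub classification requires hub labels whose trailing
  digits are the seed-sequence position (custom parsers can be supplied).
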