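# Methods

This note records the models, the defaults and their reasons, the numerical
choices, and what the synthetic fixtures do and do not demonstrate.

## Trajectory preparation

Trajectories are read through MDAnalysis (PDB/PSF topologies, DCD/XTC
coordinates), resampled with an integer stride (default 10 in the pipeline
config, i.e. keeping every tenth stored frame), stripped of water and
counter-ions by residue-name tables (user-extensible, because topology
formats disagree on naming), and superposed by a proper-rotation Kabsch fit
(determinant +1; reflections rejected by flipping the smallest singular
direction).  The default fit selection is protein alpha carbons.  Units are
fixed: Å for coordinates, ps for time.

Each trajectory is aligned to its own first frame for per-system analyses.
Cross-system analyses (concatenated PCA, shared landscapes) need one global
reference; the pipeline uses the first frame of the first trajectory.  A
per-system alignment followed by concatenation would leave an arbitrary
rigid-body offset between systems in the shared coordinate space, which the
covariance would then report as spurious variance — hence the single
reference.

Concatenation matches atoms across systems by (segment, residue number,
residue name, atom name) identity, either strictly (first mismatch is an
error) or by intersection (common atoms, in the first trajectory's order).

## Hydrogen-bond features

A hydrogen bond is a (donor, hydrogen, acceptor) triple with N/O heavy
atoms, donor–acceptor distance ≤ 3.2 Å and D–H–A angle ≥ 120°.  The angle
threshold is a *floor*: near-linear arrangements (180°) are the strong
bonds, and 120° admits intermediate-strength bonds.  Donors must carry a
covalently bonded hydrogen, taken from topology connectivity when present
and otherwise inferred from a < 1.2 Å H–heavy distance in the first frame.

Atom-level events are collapsed to unordered residue-pair indicators
("is there any hydrogen bond between these two residues in this frame?"),
because the biological reading — which residue pairs interact — does not
depend on which partner donates.  Pair subsets mirror the three analysis
views: protein↔nucleic-or-cofactor (the bound DNA and ADP), protein↔protein
across the two monomer segments, and any-pair-with-protein.

The detector is validated against a brute-force double loop over all
(donor, acceptor) pairs on random dense geometries with exact event-set
equality, and is invariant under global rigid motion.

## Classification trees

CART with the Gini diversity index on binary features; a split is a
presence test, ties between equally good features break to the lowest
column index so fits are reproducible.  Growth stops at pure nodes or when
no split strictly reduces weighted impurity (identical rows with mixed
labels).  Trees are fitted on all frames deliberately: the goal is motif
*identification* on the data in hand, not generalisation, so no
train/validation split exists and resubstitution loss is the reported
error.

Leaf class probabilities are exactly `count(class, leaf) / count(leaf)`.

**Depth and pruning convention.** Depth counts *split levels*: a lone leaf
has depth 0, and the two-bond flow-chart tree has depth 2.  `prune(t, k)`
collapses every node deeper than `depth − k` split levels into a leaf with
the merged counts of its subtree; the merged leaf predicts the
subtree-majority class, which is the least-loss collapse.  `k = depth`
leaves the majority-baseline root leaf, so the prune curve has `depth + 1`
rows, starts at the full-tree loss, is non-decreasing, and ends at
`1 − max class frequency`.

## Conformational clustering (iMWK-means + explicit rescaling)

Frame features are flattened heavy-atom coordinates of a selection (for
binding-site analyses: all heavy atoms of residues with any atom within
10 Å of the DNA in the reference frame; the selection is evaluated on one
frame so the feature schema is fixed).

Stage 1, iMWK-means: anomalous-pattern initialisation repeatedly takes the
point farthest from the grand centre, grows a tentative cluster by a
two-pole assignment (tentative centroid vs grand centre) with Minkowski
weights recomputed from the tentative cluster's own dispersions, removes
it, and keeps clusters larger than θ (default 1: singletons discarded).
Survivors fix K and seed the main loop, which iterates assignment
(minimising `Σ_v w_kv^p |x_v − c_kv|^p`), Minkowski-centre update (the mean
for p = 2), and the closed-form weight update
`w_kv = 1/Σ_u (D_kv/D_ku)^{1/(p−1)}`.  Each step minimises the shared
objective, which is asserted non-increasing at every iteration.  Zero
dispersions are floored at `1e−12 ×` the cluster's mean dispersion before
the weight update.  p defaults to 2 (Euclidean); other p > 1 are supported
(the Minkowski centre is then found by bounded scalar minimisation).

Stage 2, explicit rescaling: the per-cluster weights are averaged into one
per-feature rescaling vector, the features are multiplied by it, and —
the point of the rescaling — the anomalous-pattern initialisation is
re-run *in the rescaled space*, where uninformative features have been
shrunk, to fix the final K; a standard K-means (fixed K, seeded from those
centroids) produces the final labels.  The second initialisation keeps
uniform weights: re-adapting weights in an already rescaled space would
re-inflate exactly the features the rescaling suppressed.  Setting
`reselect_k=False` instead keeps stage 1's K and centroids, for use when K
is known.

Why re-select K rather than trust stage 1: the two-pole anomalous pattern
has a geometric merge trap.  For any triangle of cluster centres, each
centre is closer to at least one pair-midpoint than to the grand centre
(in any triangle the median exceeds 3/4 of the shorter adjacent side), so
a tentative cluster that drifts to a pair midpoint is a stable fixed point
covering two true clusters.  With noise features present the initial
weights are diluted and such drifts happen regularly; after rescaling the
cluster structure dominates every retained axis and the same
initialisation is reliable.

**What the recovery fixture shows.** The planted-mixture fixture separates
the three Gaussian clusters by ≥ 8σ along *every* informative feature
(cyclic offset pattern), with uniform-noise features spanning the full
data range.  This is the per-coordinate well-separation regime of MD
conformational substates, which is what the trajectory generator also
plants, and there the procedure recovers K and the partition in ≥ 90% of
seeds with noise weights always below informative weights.  It does *not*
show recovery for weakly separated clusters: at 8σ *total* Euclidean
separation in 5-D (clusters of radius ≈ 2.2σ only ~4.6σ from the grand
centre), the merge trap above defeats the anomalous-pattern selection
regardless of rescaling; we measured 2–16/25 across variants and regard
that regime as outside the method's design envelope rather than a defect
of this implementation.

Occupancy tables report, per system, the percentage of that system's
frames in each cluster (rows sum to 100).  A cluster's representative
frame is the member with the smallest RMSD from the coordinate-wise mean
structure, ties to the lowest frame index.

## RMSF, DCCM, PCA, landscapes

All four assume a superposed trajectory.  RMSF is
`sqrt((1/N) Σ_j |r_i(t_j) − r̄_i|²)` per atom.  The DCCM is the Pearson
normalisation of displacement-vector covariances; zero-variance atoms
either raise or are flagged NaN, per configuration.

PCA diagonalises the 3N×3N coordinate covariance (divisor N−1) via SVD of
the centred coordinate matrix.  A wording ambiguity exists about whether
the N×N atom-correlation matrix or the 3N×3N covariance should be
decomposed; only the covariance form yields eigenvectors that frames can
be projected onto, so that is what is implemented (the atom-level DCCM is
computed separately).  Eigenvalues are reported with the full trace, so
explained-variance fractions are correct even when only leading components
are kept.

The free-energy landscape is a 2-D histogram over (PC1, PC2) converted by
`ΔG = −kT ln(P/P₀)` with P₀ the most-populated bin, k = 0.0019872
kcal·mol⁻¹·K⁻¹ and T = 300 K by default.  The reference bin is exactly 0;
empty bins are masked (unbounded), never assigned a large finite value;
duplicating every frame leaves the landscape unchanged because P/P₀ is
scale-free.  The default grid is 100 × 100 over the data range,
configurable, and an explicit extent lets several systems share one grid.

## Stacking states

The underlying study inferred stacking states from heavy-atom clustering
of the Phe/Glu pair; this package adds a transparent geometric classifier
so the states are directly testable: ring centroids and least-squares
plane normals (smallest singular direction), with defaults centroid
separation ≤ 5.0 Å, normal–normal angle ≤ 30° (axial vectors, folded to
[0°, 90°]), lateral offset ≤ 2.0 Å.  When both candidate bases pass, the
closer centroid wins.  The clustering route remains available by running
the conformational clustering on the two residues' heavy atoms and
labelling clusters by their representative frame's geometry.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *statistical structure* the analyses consume:
Bernoulli bond occupancies with planted class-discriminative bonds;
Gaussian conformational wells with class-dependent occupancy (wells are
per-atom displacements on per-atom random circle planes, so adjacent wells
are exactly `separation` Å apart at every atom and are not removable by a
rigid-body fit); inflated-variance flexible atoms; exactly ±ρ-coupled
atom pairs via shared latent Gaussian factors; donor–H–acceptor triads
toggling across the geometric criteria; and ring poses on either side of
the stacking thresholds.  Defaults mirror the study's design: 3 classes,
5000 frames per class for bond matrices (15 000 concatenated), 50
background bonds at occupancy 0.3 with 2 planted bonds at 0.9 vs 0.05, and
100 ps between frames.

They do **not** emulate force-field physics: no bonded geometry beyond the
planted triads, no solvent, no temporal autocorrelation (frames are
i.i.d.), and no gradual conformational transitions.  Passing tests
therefore demonstrate that each algorithm recovers the structure it claims
to detect when that structure is present, with known sampling noise — not
that real trajectories contain such structure.

Trajectory-based demo stages run at 3 × 500 frames and ~60 atoms, and the
recovery fixtures at 25–50 replicates; these sizes put every planted
effect many standard errors from its background while keeping the whole
suite and the acceptance script quick to run.

## Determinism

Every generator draws from one local `numpy.random.Generator` seeded per
call; nothing touches NumPy's global state.  The pipeline stamps outputs
with the config hash and seed, and two runs with the same config and seed
are byte-identical (checksummed in the manifest; the log is excluded).
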