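# mdworkbench

Machine-learning analysis of molecular-dynamics trajectories of a
protein–DNA complex — the MutSα (MSH2–MSH6) mismatch-repair heterodimer
bound to damaged DNA is the motivating system — asking one question at
every stage: *which features of the dynamics distinguish the damage
classes?*

The pipeline:

1. **Hydrogen-bond featurization** — geometric detection (donor–acceptor
   heavy-atom distance ≤ 3.2 Å, D–H–A angle ≥ 120°) collapsed to a binary
   frames × residue-pair matrix.
2. **Damage-classification trees** — CART with the Gini diversity index on
   the binary bond features; leaf class probabilities are exact count
   ratios `n(class, leaf) / n(leaf)`; *level pruning* trades resubstitution
   loss for interpretability until two or three hydrogen bonds carry the
   classification.
3. **Conformational clustering** — intelligent Minkowski-weighted K-means
   (anomalous-pattern initialisation selects K; per-cluster per-feature
   weights `w_kv = 1/Σ_u (D_kv/D_ku)^{1/(p−1)}`) followed by explicit
   rescaling and a standard K-means, on flattened heavy-atom coordinates.
4. **Ensemble kinetics** — per-atom RMSF
   `sqrt((1/N) Σ_j |r_i(t_j) − r̄_i|²)`, Pearson correlated-motion matrices
   `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`, PCA over a common basis,
   and free-energy landscapes `ΔG = −kT ln(P/P₀)` over (PC1, PC2) at
   T = 300 K with k = 0.0019872 kcal·mol⁻¹·K⁻¹.
5. **Aromatic stacking** — per-frame classification of a probe ring
   (a Phe side chain) against the damaged base and its complement by ring
   centroid separation, plane-normal angle and lateral offset.

Because the full microsecond-scale MD data set is far too large to ship,
the package includes a first-class **synthetic-data generator**
(`mdworkbench.synthetic`) that plants known structure — discriminative
bonds among background bonds, Gaussian conformational wells with
class-dependent occupancy, flexible regions, ±1-coupled atom pairs,
hydrogen-bond triads and stacking poses — so every stage has a
parameter-recovery test with exact ground truth.

## Worked example

`examples/01_hbond_motif_tree.py` generates the study-sized planted matrix
(3 damage classes × 5000 frames, 2 discriminative bonds at 0.9-vs-0.05
occupancy among 50 background bonds at 0.3) and fits the tree:

```
feature matrix: 15000 frames x 52 candidate bonds
full tree: depth 22, training accuracy 100.00%
two-level tree: splits on ['SYN:Bnd000A–SYN:Bnd000B', 'SYN:Bnd001A–SYN:Bnd001B'], accuracy 88.76%
planted discriminative bonds were columns [0, 1]
```

The fitted tree grows deep enough to memorise the training frames
(accuracy 100%), but pruned to two split levels it keeps only the two
planted bonds and still labels 88.76% of frames correctly — the same
"two hydrogen bonds carry most of the signal" structure the method is
designed to expose on real trajectories.  The leaf table shows the
count-ratio class probabilities, e.g. frames with the first bond only are
Carbo with probability 0.9457, and the prune curve ends at the 66.67%
majority-baseline loss.

The other examples each run one capability end to end:

| script | capability |
|---|---|
| `examples/02_conformational_clustering.py` | iMWK-means + rescaling; K = 3 recovered, ARI 1.0, occupancy table |
| `examples/03_rmsf_dccm_landscape.py` | RMSF (flexible atoms ~3× rigid), DCCM (+0.995/−0.905 planted pairs), PCA (PC1+2 = 98%), ΔG landscape |
| `examples/04_phe_stacking.py` | stacking-state fractions; 100% agreement with planted states |
| `examples/05_full_pipeline.py` | config-driven run of everything; byte-identical rerun |

A thin CLI wraps the config-driven pipeline:

```sh
workbench demo --out out_dir --seed 0        # synthetic end-to-end demo
workbench run --config pipeline.yml          # file-based inputs
```

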