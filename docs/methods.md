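# Methods

This note documents the models, the parameter choices that matter, the
numerical conventions, and what the synthetic data does and does not
establish about real data.

## The state-transition model

Two groups of cells measured under different conditions are unpaired: no
cell is observed twice. The analysis constructs the missing pairing. For a
cell profile `x` in condition A, a **pseudo-partner** is built as the mean
of its `pairing_k` nearest condition-B cells in a joint PCA embedding of
both groups (top `n_pairing_pcs` components of the pooled, centred
matrix). Two PLS2 regressions (NIPALS, per-gene centring, no scaling —
the data are already log-normalised) are fitted on these pairs, one per
direction; applying the A→B model to a cell yields its **virtual
counterpart**, and

```
transition(cell in A) = virtual − real          (A→B direction)
transition(cell in B) = real − virtual          (sign-harmonised to A→B)
```

The working assumption, which is also the method's reason to exist, is
that between-cell heterogeneity (cell types, states) is large relative to
the condition effect. Matching then connects cells of the same
type/state across conditions, the shared structure cancels in the pair
difference, and the condition-driven shift remains.

Two conventions were genuinely open and are fixed here: the transition
sign is `virtual − real` expressed in the A→B direction, and "dual PLS"
is read as two directed regression models rather than one symmetric
two-block decomposition. Neither choice affects magnitudes, only signs
and bookkeeping.

### Why `pairing_k` is 20

Raw nearest-neighbour matching has a directional selection bias: a cell
displaced by the condition shift preferentially selects opposite-group
neighbours that happen to lie along the shift, which absorbs part of the
effect into the pairing and attenuates the recovered shift unevenly
across genes. Averaging the partner over a generous neighbourhood
(k = 20) regresses it toward the local state mean, which is unbiased;
with k = 5 the planted-shift correlation drops from ≈0.92 to ≈0.89 on the
reference simulation. Two alternatives were evaluated and rejected:
centring each group on its own mean before matching (removes the bias but
mis-pairs unbalanced marker partitions, where the group-mean difference is
owned by a subgroup), and projecting out the mean-displacement direction
(makes shifted and unshifted cells of the same type indistinguishable, so
their partners mix). `pairing_k = |B|` degenerates to mutual-centroid
pairing and is useful as a sensitivity check.

### Gene filtering

Genes enter the PLS on excess variability: per-gene CV is compared
against a baseline trend — the lower-quartile CV within 20 mean-quantile
bins, a robust proxy for the technical-noise floor at that expression
level — and kept when `CV > gene_filter_min_cv × baseline` (default
multiplier 1, threshold 0 keeps every non-constant gene). On the
reference simulation this retains ≥95% of planted-effect genes.

### Transition clustering and assignment

Transition profiles are embedded by PCA (≤30 components) and clustered on
a shared-nearest-neighbour graph (k = 15, Jaccard weights pruned below
1/15) with Leiden/RBConfiguration. The default resolution is **0.3**,
deliberately coarser than the 1.0 used for expression clustering:
transition space holds few dynamic states, and the stable cells form one
diffuse near-zero cloud that a high resolution would fragment, inflating
the number of clusters offered to the assignment test. At 0.3 the null
calibration stays clean (0/50 effect-free simulations assign any cluster
at α = 0.05) while planted subpopulations still separate.

Assignment itself is the exact one-sided hypergeometric tail
`P(X ≥ x)` for each (cluster, condition); a cluster can be assigned to
several conditions, and to none — then it is labelled **stable**. Note
one structural property: when a cluster captures an affected
subpopulation, its *complement* is automatically depleted of that
condition and will often be assigned to the other condition with an
equally extreme p-value. That is correct behaviour of the test, not a
false positive.

### Marker-gene partitions

`gene_partition_run` reruns the analysis with groups defined by raw count
positivity of one gene (count > 0; the threshold is a fixed convention —
no published cut exists). Two caveats follow from the pairing model:
both positivity groups must span the same cell types (run the partition
within one annotated lineage), and the positive group should span both
conditions. If positivity coincides exactly with a uniformly shifted
subpopulation, every cross-group pair differs by the same shift and the
method correctly reports a single uniform transition state — there is no
cluster/positivity association to find in that degenerate case.

## Preprocessing conventions

* QC keeps cells with detected genes in **[200, 3000]** and mitochondrial
  UMI fraction **≤ 0.10** (removal criteria are strict inequalities), then
  genes detected in **≥ 3** retained cells. The two criteria are iterated
  to a fixed point, so the output dataset itself satisfies both and the
  filter is idempotent; the gene criterion is evaluated after the cell
  criterion within each sweep.
* Log-normalisation: `ln(1 + count/total × 10⁴)`; zeros are preserved and
  per-cell depth cancels.
* HVGs (default 2000): dispersion = variance/mean of the log-normalised
  values, z-scored within 20 mean-quantile bins; zero-variance genes rank
  strictly last; remaining ties break by gene name.
* PCA: per-gene z-score clipped at ±10, full SVD, and a deterministic
  sign convention (the largest-|loading| entry of each component is made
  positive).
* Mitochondrial genes are recognised by the case-insensitive `mt-` symbol
  prefix, the mouse convention.
* Cross-sample anchor-based batch integration is out of scope; the merged
  matrix is embedded by one joint PCA. The synthetic data carries no
  batch structure, so this choice is untested against real batch effects.
* Community-detection algorithm and seed are explicit parameters; cluster
  *counts* at a given resolution are not treated as reproducible
  quantities across implementations.

## Network and enrichment conventions

* STRING combined scores are kept at **≥ 400** (inclusive; the "medium
  confidence" 0.4 cut on the 0–1000 scale); duplicate edges collapse to
  the maximum score; degree-zero nodes are pruned.
* Hub score = median of degree, betweenness and closeness centralities,
  each already normalised to [0, 1] (betweenness pair-normalised,
  closeness with the Wasserman–Faust component correction), so the median
  is scale-consistent without further normalisation. The median drives
  the ranking; no chi-square statistic is computed on it.
* MCODE-style complexes: vertex weight = (highest k-core number of the
  closed neighbourhood) × (that core's density); seeds are unclaimed
  weight maxima; greedy expansion admits neighbours within
  `node_score_cutoff` (0.2) of the seed weight; candidates are reduced to
  the connected 2-core containing the seed; complexes are vertex-disjoint
  and ranked by density × size. The published "fluff" and "haircut"
  options are omitted.
* ORA: one-sided hypergeometric over-representation only. The background
  universe defaults to the union of the collection's genes and should be
  set explicitly to all QC-surviving genes for single-cell queries;
  enrichment p-values are meaningless without an honest universe, and
  web-service results computed against proprietary universes are not
  comparable term-for-term.
* "Bonferroni FDR" is contradictory vocabulary; both corrections are
  implemented (`bonferroni`: `min(1, m·p)`; `bh`: step-up with enforced
  monotonicity), the marker pipeline defaults to Bonferroni, and ORA
  defaults to BH.

## The synthetic-data generator

`simulate_counts` draws negative-binomial UMIs, `NB(mean μ, dispersion
α)` with `Var = μ + αμ²`, where
`μ(cell i, gene g) = lib_i × p_g × exp(type-signature + planted shift)`:

* `p_g`: log-normal relative abundances, normalised;
* `lib_i`: log-normal library sizes (mean 2000, σ = 0.3 on the log
  scale);
* type signatures: each of the `n_cell_types` types shifts a random 10%
  of non-mitochondrial genes by ±[0.5, 1] × `cell_type_effect_scale`
  (ln scale). Transition genes are deliberately *eligible* for
  signatures — the masking scenario requires the heterogeneity to sit on
  the very genes carrying the effect;
* the planted shift: `transition_effect` (ln scale) added for the
  affected cells — `affected_fraction` of one (condition, cell type)
  pair — on `transition_genes`;
* a `mito_gene_fraction` share of genes is named `mt-…` and excluded from
  signatures so QC fractions stay stable.

Reference configuration (the defaults): 500 genes, 1000 cells per
condition (sham, day1), two cell types, `cell_type_effect_scale = 5`,
`transition_effect = 1`, `affected_fraction = 0.5`, dispersion 0.1 —
heterogeneity five times the effect, i.e. the masking regime the method
targets. No published effect sizes exist for the real transitions;
these values were chosen once for testability.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects beyond condition, UMI saturation, compositional coupling between
genes (rates are not renormalised after shifts), or realistic gene–gene
correlation. Passing tests therefore establish correctness of the
machinery and recoverability under the stated noise model, not
performance on real tissue.

`simulate_paired_omics` plants exactly `n_overlap` genes passing
|log2FC| ≥ 1 and p < 0.05 in both tables; every other gene fails at least
one filter in its own table (some shared "decoy" genes fail on one side
only, so the intersection is decided by the filters, not by mere
presence).

## Problem sizes and determinism

The test suite and the acceptance script run the recovery analysis at the
reference configuration over 10 seeds, the null calibration over 50
simulations at 200 cells/condition × 200 genes, and the exact-enumeration
sweeps at N ≤ 30 (hypergeometric) and n ≤ 8 (rank-sum permutations);
graph oracles are exhaustive over all labeled graphs on ≤5 nodes plus 75
random graphs on 6–8 nodes. Everything is seeded: identical
configuration + seed reproduces byte-identical simulations, clusterings
and manifests; the pipeline derives per-stage seeds from the global seed
by stable hashing.

## Known limitations

* The recovered transition is expressed in log-normalised units while the
  planted shift lives on the ln-mean scale; genes near expression
  saturation (or silenced by a strong negative type signature in the
  affected type) show compressed transitions, which bounds the
  planted-shift correlation around 0.92 at the reference configuration.
* Pairing assumes every state in one group has counterparts in the other;
  states unique to one condition are forced onto their nearest neighbours
  and their transitions absorb state differences.
* PLS with pseudo-pairs is a global linear map; strongly nonlinear
  per-state responses are captured only piecewise through the pairing.
* The hypergeometric assignment treats cells as exchangeable; it ignores
  per-sample (animal-level) correlation, which real designs have.
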