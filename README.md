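# stxmicro

Detecting condition-driven cell-state transitions in multi-condition
single-cell RNA-seq — built for experiments like microglial profiling of
mouse brain across sham surgery and days 1/3/7 after transient middle
cerebral artery occlusion (tMCAO), where the transcriptional response of a
cell subpopulation is masked by much stronger cell-type heterogeneity.

## Who this is for

Computational biologists analysing multi-condition scRNA-seq experiments
(droplet UMI counts with per-cell condition labels) together with bulk
RNA-seq and proteomic differential tables, who want the full chain —
quality control, state-transition inference, multi-omics intersection,
protein-interaction hub scoring, dense-complex detection, and
over-representation analysis — as a tested, scriptable Python library
instead of a collection of web services.

## The core method

Direct cluster-versus-cluster comparisons miss condition effects whose
amplitude is small relative to cell-type differences. The state-transition
analysis implemented here works around that with **real–virtual cell
pairs**:

1. Genes are filtered by excess coefficient of variation over the
   mean–CV noise trend.
2. Each cell in condition *A* is pseudo-paired with the mean profile of
   its *k* nearest condition-*B* neighbours in a joint PCA embedding (and
   symmetrically for *B*).
3. Two partial-least-squares regressions ("dual PLS", one per direction)
   are fitted on these pairs; each cell is projected into the opposite
   condition's space, giving its **virtual counterpart**.
4. The per-cell transition is `virtual − real` (rows of *B* cells are
   sign-harmonised into the A→B direction). Shared heterogeneity cancels
   in the pair difference; what remains is the condition-driven shift.
5. Transition profiles are Leiden-clustered on an SNN graph, and each
   cluster is assigned to the condition(s) over-represented in it by a
   one-sided hypergeometric test: for a cluster of size *n* containing
   *x* of the *K* cells of a condition among *N* total,
   `p = P(X ≥ x), X ~ Hypergeom(N, K, n)`; clusters with no condition at
   `p < 0.05` are called **stable**.

Around this core the package provides: the standard QC chain (cells kept
with 200–3000 detected genes and ≤10% mitochondrial UMIs, genes in ≥3
cells; log-normalisation; 2000 HVGs; 30 PCs; Leiden at resolution 1.0;
marker-panel annotation), |log2FC| ≥ 1 & p < 0.05 filtering and
intersection of bulk/proteome differential tables, STRING-style PPI graphs
with hub score = median(degree, betweenness, closeness centrality),
MCODE-style dense-complex detection, and hypergeometric ORA against GMT
gene-set collections with Bonferroni/Benjamini–Hochberg correction. A
negative-binomial simulator with planted effects generates every input for
testing.

## Worked example

```python
from stxmicro import SimConfig, simulate_counts, log_normalize
from stxmicro.scstar import run_scstar, SCSTARParams

# two cell types whose signatures are 5x stronger than the planted effect;
# half the type-0 cells in "day1" carry a +1 (ln-scale) shift on 40 genes
ds, truth = simulate_counts(SimConfig(seed=1))
ds = log_normalize(ds)
st = run_scstar(ds, ("sham", "day1"), SCSTARParams(seed=1))

print(len(set(st.transition_cluster)), "transition clusters")
print(st.cluster_labels)
print(st.assignment[st.assignment.assigned])
```

Output:

```
2 transition clusters
{'0': {'sham': 1.0989720467409848e-86}, '1': {'day1': 1.0989720467409848e-86}}
  cluster condition     x     n     K     N             p  assigned
1       0      sham  1000  1742  1000  2000  1.098972e-86      True
2       1      day1   258   258  1000  2000  1.098972e-86      True
```

Cluster 1 is exactly the planted affected subpopulation (all 258 affected
cells at this seed): every one of its cells comes from day1, so the
hypergeometric test assigns it to that condition, while the complementary
cluster holds all 1000 sham cells and is assigned to sham. The mean
transition profile of the affected cells correlates with the planted shift
vector at r = 0.93 at this seed (0.92 averaged over 10 seeds).

The same analysis is available from the shell:

```bash
stxmicro simulate --seed 1 --out sim/
stxmicro preprocess --in sim/ --out ds.h5ad
stxmicro scstar --in ds.h5ad --pairs sham:day1 --out scstar_out/
stxmicro run --config pipeline.yaml   # full simulate→…→enrichment chain
```

## Layout

| Module | Contents |
|---|---|
| `stxmicro.simdata` | NB count simulator with planted shifts; paired omics tables; PPI/GMT fixtures |
| `stxmicro.preprocess` | MTX reading, QC, log-normalisation, HVG, PCA, Leiden, annotation |
| `stxmicro.scstar` | gene filter, pseudo-pairing, dual PLS, transitions, assignment, markers |
| `stxmicro.omics` | differential-table filtering and intersection |
| `stxmicro.network` | PPI graph, centralities, hub scores, MCODE-style complexes |
| `stxmicro.enrichment` | GMT, hypergeometric ORA, p-value corrections, complex reports |
| `stxmicro.pipeline` | YAML config, orchestration, provenance manifest |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
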