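# ampnet

Compositional φ-proportionality networks and diversity analysis for amplicon
sequence-variant (SV) tables from crop-rotation soil surveys.

## The problem

DNA metabarcoding of agricultural soils (16S rRNA for prokaryotes, 18S for
eukaryotes) yields per-sample read counts of thousands of SVs. Such counts
are *compositional*: only relative information survives sequencing, so naive
correlations between taxa are distorted by the closure constraint. `ampnet`
implements the downstream analysis used to compare soil communities across a
two-field maize–cabbage rotation design — 2 fields × 2 crops × 3 growth
stages × 3 replicates = 36 samples — for ecologists who want the whole chain
from count table to classified co-occurrence networks in one tested package:

- **α/β-diversity** — rarefaction to even depth, Shannon index
  H = −Σᵢ pᵢ ln pᵢ with all-pairs Tukey–Kramer tests, Bray–Curtis
  dissimilarity BC(a,b) = 1 − 2·Σmin(aᵢ,bᵢ)/(Σa+Σb), nonmetric
  multidimensional scaling (Kruskal stress-1, SMACOF majorization), and
  one-way PERMANOVA (pseudo-F, R², permutation p with exact enumeration for
  small designs).
- **Compositional association** — per sample group (field × crop), counts
  are clr-transformed via Monte-Carlo Dirichlet instances
  (clrᵢ = log pᵢ − mean log p, M = 128 draws, prior 0.5), and every SV pair
  is scored with the proportionality coefficient

  φ(i→j) = Var(clrᵢ − clrⱼ) / Var(clrᵢ),

  symmetrized by the maximum of the two directions and averaged over
  instances. φ ≈ 0 means the two SVs co-vary proportionally.
- **Networks** — edges where φ < 0.12 (18S) or φ < 0.08 (16S); SVs with at
  least one edge are node SVs (nSVs). Connected components ("clusters") are
  ordered by size; nodes are classified across the four group networks as
  *core* (top 10 % / 5 % by degree, boundary ties included), *common*
  (present in all four networks) and *crop-/field-specific* (present in both
  networks of one level, absent from both of the other).
- **Chemistry** — percent-normalization of the 12 soil parameters,
  farthest-neighbor (complete-linkage) clustering, redundancy analysis (RDA)
  of the clr community matrix on standardized chemistry, and per-parameter
  feature association ranking.
- **Synthetic communities** — a generator that plants proportional SV
  modules (a shared per-sample log-normal latent factor), group-level
  abundance shifts and chemistry tied to the design, with full ground truth,
  so every statistic above can be validated by recovery instead of trust.

## Worked example

```python
from ampnet import (generate_community, subset_by_group, clr_ensemble,
                    phi_matrix, build_conetwork, compare_networks)
from ampnet.io_tables import drop_group_zero_svs, FIELDS, CROPS

ft, tax, meta, truth = generate_community(seed=7)   # 36 samples x 50 SVs
nets = {}
for f in FIELDS:
    for c in CROPS:
        sub = drop_group_zero_svs(subset_by_group(ft, meta, f, c))
        phi = phi_matrix(clr_ensemble(sub, M=128, prior=0.5, seed=3))
        net = build_conetwork(phi, threshold=0.12, group=(f, c))
        nets[(f, c)] = net
        print(f"{f} {c}: {len(net.nodes)} nSVs, {net.n_edges} edges, "
              f"largest cluster {len(net.components[0])}")
cmp = compare_networks(nets, core_fraction=0.10)

planted = truth.same_module_pairs()
edges = set().union(*({frozenset(e) for e in n.graph.edges} for n in nets.values()))
tp = len(edges & planted)
print(f"recovery: precision {tp/len(edges):.2f}, recall {tp/len(planted):.2f}")
```

prints the per-group network summaries and the ground-truth recovery:

```
field_1 maize: 23 nSVs, 42 edges, largest cluster 5
field_1 cabbage: 23 nSVs, 35 edges, largest cluster 5
field_2 maize: 24 nSVs, 42 edges, largest cluster 5
field_2 cabbage: 23 nSVs, 43 edges, largest cluster 5
recovery: precision 1.00, recall 1.00
```

Each group network finds ~23 nSVs in clusters of up to 5 nodes — exactly the
five planted modules of five proportional SVs — and pooling the four group
edge sets recovers the planted same-module pairs with precision and recall
1.00. `cmp.common`, `cmp.core`, `cmp.crop_specific` and `cmp.field_specific`
hold the classification ledger.

The same analysis from the shell:

```bash
ampnet simulate --preset eukaryote --seed 7 --out sim/
ampnet run-all --inputs sim/ --seed 7 --out run/
```

`run/` then contains the full output ledger: relative-abundance tables,
Shannon + Tukey–Kramer results, Bray–Curtis matrix, NMDS coordinates,
PERMANOVA JSON, chemistry heatmap matrix and dendrogram, RDA score tables,
four GraphML networks with edge lists, per-φ-value TSVs and the
`node_ledger.tsv` classification table.

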