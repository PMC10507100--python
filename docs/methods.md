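# Methods

This note documents the models behind `ampnet`, the defaults that matter,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Compositional model and the φ statistic

Sequencing yields closed compositions: per sample only the proportions
p₁…p_D of the D SVs are identified. The centered log-ratio,
clrᵢ = log pᵢ − (1/D)·Σⱼ log pⱼ, maps a composition to a zero-sum real
vector on which variances are meaningful. Zeros are handled the ALDEx2 way:
each sample's clr is not a single vector but M Monte-Carlo instances drawn
from Dirichlet(counts + prior); statistics are computed per instance and
aggregated. Defaults: M = 128, prior = 0.5. A `point_estimate` mode
(single composition (counts + prior)/Σ) backs the deterministic analyses
(RDA, oracle tests).

Association between SVs i and j within one sample group is the
proportionality coefficient

    φ(i→j) = Var_samples(clrᵢ − clrⱼ) / Var_samples(clrᵢ)

with unbiased (n−1) variances. φ = 0 iff clrᵢ − clrⱼ is constant across the
group's samples (perfect proportionality); for independent series of equal
variance φ → 2. φ is invariant to the log base and, in point-estimate mode,
to per-sample count scaling. Two declared conventions (the upstream tooling
does not document its own): the two directions are symmetrized by their
**maximum** — an edge requires both directions to be proportional — and
Monte-Carlo instances are aggregated by the **mean** of per-instance φ.
Both are config switches (`symmetrization` ∈ {max, min, mean},
`aggregation` ∈ {mean, max}).

Because each instance's φ includes Dirichlet sampling variance, the
mean-of-instances aggregate is biased upward for low-count SVs (roughly
2/count extra variance in the log-ratio difference). At the default design
(9 samples per group, depths 20k–60k over 50 SVs) this moves a minority of
truly-proportional pairs above the edge threshold in any single group
network; it is why module recovery is evaluated on the union of the four
group networks (see below).

## Networks and node classification

Within each of the four field × crop groups, SVs that are all-zero in the
group are excluded (their log-ratios are meaningless; the SVs stay in the
table), φ is computed on the remaining SVs, and an undirected edge is drawn
where φ < threshold, strictly: 0.12 for 18S, 0.08 for 16S. Node SVs (nSVs)
are the SVs with degree ≥ 1. Clusters are connected components, numbered by
size descending with ties broken by smallest member id, so cluster 1 is the
largest.

Classification across the four networks:

- **core** (per network): k = ⌈fraction × node count⌉ top nodes by degree
  (0.10 for 18S, 0.05 for 16S); every node tied with the k-th degree is
  included, so no node with an equal claim is dropped and core sets can
  exceed k.
- **common**: intersection of the four node sets.
- **crop-specific** (and analogously field-specific): present in *both*
  networks of one crop and absent from *both* networks of the other. This
  is the strict reading; the per-field union variant is computable from the
  same node sets but is not the default.

## Diversity statistics

- **Rarefaction**: one multivariate-hypergeometric draw per sample
  (without replacement) to a common depth, default the minimum sample
  total; shallower samples are dropped with a warning; the seed is recorded.
  Rarefied counts feed only α/β-diversity — networks and RDA use clr on
  unrarefied counts.
- **Shannon**: natural log by default (flag for other bases), zero terms
  dropped.
- **Tukey–Kramer**: pooled within-group variance, q = |Δmean|/SE with
  SE = √((MSW/2)(1/nᵢ+1/nⱼ)), p from the studentized range distribution on
  N−k df. Zero pooled variance with unequal means is reported at the
  machine floor and flagged rather than erroring.
- **PERMANOVA**: SS_total = (1/n)Σ_{i<j}d²ᵢⱼ, SS_within pooled per group
  with 1/n_g weights, pseudo-F = (SS_b/(k−1))/(SS_w/(n−k)). When the number
  of distinct labelings is ≤ 10 000 the p-value is exact enumeration
  (count/total, observed labeling included — hence p = 1/3 on the 4-point
  two-group fixture); otherwise seeded sampling with the +1 correction,
  default 999 permutations, so p is never exactly 0.
- **NMDS**: SMACOF majorization of Kruskal stress-1 with monotone
  regression of configuration distances on dissimilarities; ties follow
  Kruskal's primary approach (pairs sorted by dissimilarity, then current
  distance, isotonic over the sequence). Start 0 is classical scaling, the
  remaining `n_starts − 1` (default 19) are random; convergence when the
  stress improvement drops below 1e-7; the best solution is rotated onto
  the first converged one (orthogonal Procrustes) so repeated runs agree in
  orientation. Stress is recorded per iteration and is non-increasing
  within a start.

## Chemistry and RDA

The 12 soil parameters (CEC, pH_H2O, pH_KCl, NO3_N, NH4_N, K2O, MgO, CaO,
EC, Tr_P2O5, Humus, WC) are measured on 12 composite cells
(field × crop × stage). For the heatmap, each parameter column is expressed
as percent of its column total (columns sum to 100); rows are clustered by
complete linkage on Euclidean distances. For RDA the 12 rows are broadcast
to the 3 replicates of each cell — the only alignment consistent with
ordinating 36 communities against 12 chemistry rows.

RDA: center the point-estimate clr matrix Y, center and (by default)
standardize the chemistry X, fit Ŷ = X(XᵀX)⁻¹XᵀY by least squares, SVD the
fitted values. Eigenvalues are axis variances sᵢ²/(n−1);
`constrained_fraction` = Σλ / total variance of Y. Biplot vectors are
correlations of each parameter with the site scores scaled by
√(λ_axis/Σλ), so arrow length reads as association strength. Rank-deficient
chemistry is fit on its column space with a warning; p ≥ n errors. The
per-parameter association table (the supplementary-table analogue) uses
plain Pearson correlation between each feature's clr profile and the
parameter, restricted to the 350 most abundant features when abundances are
supplied; the RDA biplot remains the visualization-level readout.

## Synthetic communities

The generator emulates the 36-sample design. For SV i in sample s of group
g:

    log a(s,i) = bᵢ + δ(i,g) + λ(s, m(i)) + ε(s,i)

- bᵢ ~ N(0, 1): per-SV log-normal baseline (spread of mean abundances).
- δ(i,g) ~ N(0, 0.75): per-group log-fold shift, fixed per SV — the
  "field/crop changes community composition" signal that PERMANOVA and RDA
  detect.
- λ(s,m) ~ N(0, module_latent_sd = 1.0): latent factor shared by all
  members of module m within sample s — the planted proportionality the φ
  networks must recover. Default 5 disjoint modules of 5 SVs among 50.
- ε(s,i): idiosyncratic noise, sd = within_module_noise_sd = 0.05 for
  module members; background SVs instead get independent noise at the
  latent scale (sd = module_latent_sd) so cross pairs carry ordinary
  variability rather than being near-constant.

Counts are multinomial at a depth uniform on [20 000, 60 000] (optional
Dirichlet-multinomial overdispersion, off by default — multinomial noise
suffices for recovery testing). Taxonomy is drawn from preset phylum pools
(Ascomycota, Basidiomycota, Cercozoa, Ciliophora, Mucoromycota, NA for the
eukaryote preset; Pseudomonadota, Acidobacteriota, Actinomycetota,
Gemmatimonadota, Planctomycetota, NA for the prokaryote preset). Chemistry
is generated at the 12-cell level as baseline + shifts keyed by field, crop
or stage + Gaussian noise with sd proportional to each parameter's baseline
(parameters span three orders of magnitude), clipped at 0 and, for WC, to
[0, 1]; the default shift map plants fertilizer-driven N/EC in (early)
maize cells, humus in field_1, and water/nutrient ions in field_2.

What the benchmark shows: that the full chain — clr Monte-Carlo, φ,
thresholding, classification — recovers planted proportional structure
(pooled over the four group networks: precision and recall 1.0 at the
default preset), that PERMANOVA is calibrated under the null (rejection
rate ≈ 5 % at α = 0.05 over 200 simulations), and that the pipeline is
deterministic under a master seed. What it does not show: behaviour under
real-data pathologies — thousands of rare SVs, structural zeros, taxonomic
misassignment, overlapping or nested modules, depth confounded with group —
none of which the generator emulates. Headline counts from the original
two-field survey (total SV counts, specific R² values, common/specific nSV
counts, cluster sizes of 33–97 and 203–292) depend on the deposited raw
reads and the upstream denoising stack and are not reproduced at this
scale; the pipeline reports the analogous quantities for its own inputs.

## Numerical and design choices

- Problem sizes in tests and the acceptance script (50 SVs, M ≤ 128,
  999/99 permutations, 200 null replicates, 8–20 NMDS starts) are chosen so
  the whole suite runs in about a minute while keeping every statistic in
  its asymptotically meaningful regime.
- Seeds: every stochastic stage derives its seed from the master seed via
  `numpy.random.SeedSequence([master, stage_index])`, keeping all seeds
  below 2³¹ and stages independent.
- φ with zero-variance features: their rows are NaN, logged, and excluded
  from network building rather than erroring (a constant clr series has no
  meaningful ratio variance).
- Variance-of-difference is computed via V_i + V_j − 2C_ij from one
  covariance pass and clipped at 0 against rounding; the vectorized form is
  tested to 1e-10 against a double-loop oracle.
- Length filtering is strictly `length < min_len` (an SV of exactly the
  minimum is kept); tables without length annotations pass through with a
  warning.
- The taxonomy sentinel is the literal string "NA" at every rank, treated
  as an ordinary category in aggregation and pie summaries.
- Minor-taxon pooling keeps taxa whose share of grand-total reads is
  strictly above the threshold (0.5 % for 18S, 1 % for 16S) and pools the
  rest into a `minor` bin, so relative-abundance rows always sum to 1.

## Known limitations

- The Tukey–Kramer test assumes equal within-group variances; no Welch-type
  correction is provided.
- NMDS stress-1 monotonicity is guaranteed per majorization step, not
  across restarts; pathological tie structures could in principle cycle,
  though none has been observed.
- φ thresholds are taken as given (0.12 / 0.08); no data-driven threshold
  selection or FDR control on edges is implemented.
- Community detection beyond connected components (modularity, Leiden) is
  deliberately out of scope.
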