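# Methods

`airway-recovery` implements the ecological-statistics core of a
longitudinal, multi-site respiratory-microbiome analysis: a smoking-
cessation cohort sampled at the anterior nares ("nose"), oropharynx, and
bronchoalveolar lavage (BAL), with never-smokers (NS) as the healthy
reference and smokers followed from active smoking (AS) through six weeks
(FS6w) and one year (FS1y) of cessation. Because raw cohort sequencing
data are not part of the package, every method is validated against a
synthetic cohort generator with known ground truth; this note records the
models, the defaults and why, and what the synthetic validation does and
does not establish.

## The synthetic cohort generator

`synthetic_cohort.simulate_cohort` composes each sample's expected relative
abundances from four multiplicative ingredients and then sequences them
with a multinomial draw:

1. **Metacommunity baseline.** Relative abundances are log-normal
   (`metacommunity_sigma`, default 1.5), reproducing the long-tailed
   rank-abundance shape of 16S data.
2. **Habitat filtering (selection).** A trait evolves by Brownian motion
   along a unit-depth pure-birth (Yule) phylogeny
   (`trait_sigma`, default 1, the BM rate per unit branch length). Each
   site imposes a Gaussian filter `exp(-s_eff (trait - optimum)^2)` with
   optima at evenly spaced trait quantiles (0.1 to 0.9 across sites), so
   a site's community is phylogenetically clustered when `s_eff` is large.
   `s_eff = selection_strength x site_selection_scale[site]`; the default
   scale map (nose 0.25, oropharynx 0.25, BAL 2.0) makes the lung the
   deterministically filtered, low-biomass compartment and the upper
   airways weakly filtered, matching the ecological contrast the design
   is built around.
3. **Subject structure (individuality and dispersal).** Each subject
   carries (a) a log-normal random effect per taxon with SD `subject_sd`
   (default 0.8) applied to the shared component — this is what the
   individuality statistic recovers — and (b) a private pool occupying a
   random half of the taxon pool, whose abundances are the metacommunity
   values perturbed by a log-normal factor of scale `pool_sigma`
   (default 1.5). The sample composition is
   `dispersal_rate x shared + (1 - dispersal_rate) x private`
   (default 0.7). `pool_sigma` separates two stochastic regimes:
   with large `pool_sigma` subjects are compositionally idiosyncratic
   (dispersal limitation); with `pool_sigma = 0` a private pool is a
   stochastic re-draw of the metacommunity — the same process as the
   Raup-Crick null — which is what ecological drift looks like to these
   statistics.
4. **Group effects.** A random 10% of taxa are responders with a fixed
   sign; group x site log-fold shifts (AS strongest in nose and BAL,
   FS6w half, FS1y a quarter) emulate smoking perturbation with partial,
   site-specific recovery.

Sequencing depth is multinomial at `depth_mean` (default 43,223 reads, the
design's average) times a log-normal factor (sigma 0.3). BAL samples
additionally receive 3% contaminant mass from a reagent profile that
dominates 5 generated blank-control samples; contaminant and responder
taxa are disjoint. Cohort sizes default to the emulated design: 10 NS,
15 smokers re-measured at six weeks, a seeded 5-subject subset at one
year. All outputs are pure functions of `SimConfig.seed`.

**Regime presets.** `regime_preset(regime, seed)` freezes the conditions
under which each assembly process is expressed, chosen from the mechanism
descriptions above: homogeneous selection needs a narrow conserved filter
*and* turnover inside the filtered clade (selection_strength 8,
dispersal 0, pool_sigma 0.8, a 500-taxon pool at depth 10,000 so
within-sample richness is high enough for a stable null); dispersal
limitation needs idiosyncratic pools (dispersal 0.1, pool_sigma 1.5);
drift needs stochastic occupancy with shared abundances (pool_sigma 0).

**What the generator does not emulate:** sequencing error and chimeras,
taxonomic misassignment, compositional correlations induced by biological
interaction networks (network edges in synthetic data come only from
shared latent structure the tests plant explicitly), batch effects, and
real within-subject temporal autocorrelation beyond the persistent
subject effect. Passing tests therefore demonstrate that the statistics
recover the *modelled* mechanisms at desk scale, not that they are robust
to every artefact of real amplicon data.

## Preprocessing

- **Decontamination.** A taxon is removed iff it is present in >= 50% of
  blanks *and* its mean relative abundance in blanks is >= 1x its mean
  relative abundance in biological samples. Both thresholds are exposed.
  This two-condition prevalence x abundance-ratio rule was chosen as the
  simplest auditable blank-based rule; it is a stand-in for whatever a
  given lab's decontamination protocol is, and its parameter-recovery test
  (recall >= 0.9, false-removal <= 0.05 on 30 planted contaminants)
  defines its contract.
- **CSS normalization.** Per sample, the scaling factor is the sum of
  counts up to the `l`-th quantile of the sample's *positive* counts
  (type-7 interpolation), output scaled per-thousand. `l` is fixed at 0.5
  rather than adaptively selected: adaptive quantile selection is
  unstable on small synthetic tables and adds an uncontrolled degree of
  freedom.
- **Genus aggregation** sums ASV counts by genus label
  (sentinel `unassigned`), conserving per-sample totals exactly.
- **Prevalence** is subject-level: a subject counts as positive if any of
  its samples in the stratum carries the taxon.

## Diversity and cohort statistics

- **Alpha.** Observed richness; Pielou evenness `H/ln(S)` with the
  single-taxon convention `J = 1`.
- **Beta.** Bray-Curtis with the all-zero-pair -> 0 convention; weighted
  UniFrac by a single postorder accumulation of per-branch descendant
  abundance fractions, normalized variant dividing by
  `sum l_b (A_b + B_b)`. Both are tested against deliberately naive
  enumerations to 1e-10 and cross-checked against scikit-bio.
- **PERMANOVA.** Anderson's pseudo-F on squared distances; p-value with
  the add-one convention. With `strata`, permutations shuffle factor
  labels only *within* each stratum (subjects, for repeated measures),
  using independent per-stratum shuffles from one seeded stream; a factor
  constant within every stratum is rejected (no admissible permutations).
  Calibration: type-I error 0.02-0.09 at alpha = 0.05 over 200 null
  repeated-measures simulations, power > 0.9 at a large site effect.
- **Individuality** is distance-to-group-centroid in principal-coordinate
  space (the betadisper construction): Gower-centered eigendecomposition;
  axes with negative eigenvalues contribute subtractively to the squared
  distance, floored at zero. The statistic rises monotonically with the
  generator's `subject_sd` — effect *directions*, not magnitudes, are the
  intended comparison surface.
- **Recovery trajectory** is `1 - median Bray-Curtis distance` to the NS
  baseline samples at the same site (median over mean for robustness to
  baseline outliers; configurable). Validated by mixture cohorts:
  similarity grows monotonically as FS profiles are interpolated from AS
  toward NS.
- **Log-fold baseline.** `log2((x + pseudo)/(baseline_mean + pseudo))`
  against the NS site mean, pseudo-count defaulting to half the smallest
  positive normalized value so the statistic is determinate at zeros and
  scale-aware.

## Community assembly (betaNTI / RCbray)

betaMNTD is the abundance-weighted mean nearest-taxon patristic distance
between two communities (shared taxa contribute zero). betaNTI is its
z-score against a null that shuffles tip labels on the patristic distance
matrix — richness and abundance structure held fixed — with one shared
permutation stream per analysis under the seed; a degenerate null
(sd = 0) yields z = 0 rather than +-inf. The null taxon universe spans
every taxon observed anywhere in the analysed table, not just the
stratum: selection within a site is judged against the whole observed
pool, which is also what makes habitat filtering detectable.

RCbray rebuilds each community probabilistically from the pooled
metacommunity: draw the sample's observed richness of taxa with
probability proportional to occurrence frequency, allocate its observed
total abundance proportional to pooled relative abundance, and score
`RC = 2 (#{BC_null < BC_obs} + 0.5 #{BC_null = BC_obs}) / n_null - 1`.
The metacommunity pools all samples jointly by default (configurable).

Classification: betaNTI > 2 variable selection, < -2 homogeneous
selection; otherwise RC > 0.95 dispersal limitation, RC < -0.95
homogenizing dispersal, else undominated drift. Boundary equalities fall
to the stochastic/undominated side (conservative). `n_null` defaults to
999; the test battery and the analysis scripts use 199 so the full
cohort re-runs in minutes; both are seeded. Pairs are classified within
(group x site) strata, matching a per-site presentation of results.

## Co-occurrence networks

Nodes are core ASVs (subject prevalence >= 0.5 in the stratum); edges are
Pearson correlations of `log(CSS + 1)` abundances with |r| >= 0.3, sign
retained (a clr transform is available behind a flag). Path-based metrics
(average path length, betweenness, closeness) use the dissimilarity map
`w = sqrt(2 (1 - r))`; modularity and eigenvector centrality use |r| as
affinity. Module detection takes the best-modularity partition over
greedy agglomeration plus three seeded Louvain restarts — the greedy
heuristic alone can fall >5% short of the optimum on small graphs, and
the combination is verified against exhaustive partition search on
<= 8 nodes. Robustness is the mean largest-component retention after
removing ceil(0.5 N) random nodes, 100 seeded trials. Hubs are nodes at
or above the 0.95 empirical quantile of eigenvector centrality on the
largest component, numerically tied nodes all included. The robustness
and hub definitions are this package's own documented choices among the
several in circulation; group-contrast directions, not absolute values,
are the comparison surface.

## Pipeline and reproducibility

`pipeline.run_pipeline` chains ingest/simulate -> decontaminate -> CSS ->
diversity -> core/Venn -> assembly -> networks, writing every table as
TSV with fixed `%.10g` float formatting; identical configurations produce
byte-identical numeric outputs (asserted by checksum in the acceptance
battery). One global seed expands to per-stage seeds as
`(seed x 97 + stage_index) mod (2^31 - 1)`. Thresholds default to the
emulated design's values: core prevalence 0.8, network prevalence
0.5, |r| 0.3, |betaNTI| 2, |RCbray| 0.95. Config files are YAML with
unknown keys rejected and ranges checked.

## Problem sizes

The validation battery runs at sizes chosen to make the effects under
study statistically unambiguous while keeping a full re-run in minutes:
50 random instances for the distance oracles; 20 samples on a 100-tip
tree with 199 nulls and 5 seeds for null calibration; the regime presets
above on 3 seeds; 200 simulations for PERMANOVA calibration; 5 seeds for
individuality and decontamination recovery; 20 random graphs and 50
planted-hub replicates for the network oracles. The demonstration cohort
in `analysis/` uses the full design (135 samples, 300 ASVs, 43k reads).

## Known limitations

- The individuality and recovery statistics are canonical constructions
  (betadisper-style dispersion; median similarity-to-baseline), not
  reproductions of any specific lab's formulas; only effect directions
  should be compared across implementations.
- RCbray's null is sensitive to how the metacommunity is pooled; per-site
  pooling can change absolute RC values near the +-0.95 boundary.
- The betaNTI null shuffles taxa labels only; phylogeny-wide
  autocorrelation structure in the null is not preserved beyond the
  distance matrix itself.
- Greedy/Louvain modularity is exact only on the tiny graphs where
  exhaustive search verifies it; on larger graphs it is a bounded-slack
  heuristic like in any network toolkit.
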