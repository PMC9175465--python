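# Methods

## Problem and pipeline

`comorbnet` studies how the choice of co-occurrence measure shapes a
multimorbidity network. The input is a binary person × condition
incidence matrix for a cohort of multimorbid individuals (each with at
least two recorded chronic conditions). The pipeline is:

1. **Dyad screening.** Every unordered condition pair is summarised by
   its 2×2 contingency table (a = both, b = x only, c = y only,
   d = neither, n total). A dyad is a *candidate* when its joint
   frequency a is at least the minimum support (default 15, to limit
   small-count statistical error). Candidates are retained when the
   association is significant at α = 0.01 and positive (φ > 0);
   significance uses Pearson's χ² (1 df, no continuity correction)
   when all four expected cell counts strictly exceed 5 — the standard
   Cochran rule — and Fisher's exact two-sided test otherwise.
2. **Seven measures** (lift, relative risk, phi, Jaccard, cosine,
   Kulczynski, joint prevalence) are computed for every retained dyad.
   Relative risk is symmetrised by taking the larger of its two
   directions.
3. **Networks** are built per measure under three edge strata: all
   retained associations, the strongest 50% (`floor(0.5·m)` edges),
   and the strongest 200. Nodes enter only through kept edges.
4. **Communities** via weighted Louvain; **centrality** via unweighted
   degree (top 20); **cross-measure comparison** via adjusted Rand
   index of partitions, percent of shared edges, and top-20 central
   node agreement, each rolled up as median (Q1–Q3) over the 21
   unordered measure pairs.
5. **Edge characterisation** by condition prevalence bands — low
   (<1%), moderate (1 to <7%), high (≥7%) — and by the median (Q1–Q3)
   of edge joint prevalence and endpoint prevalence difference.

## Synthetic cohort model

Real administrative cohorts cannot be redistributed, so the
`synthetic` module generates cohorts from a **latent-block logistic
model**, the simplest generative model that exposes every behaviour
the pipeline measures: controllable marginal prevalences *and*
clustered co-occurrence.

- Conditions are assigned round-robin to `n_blocks` blocks
  (deterministic, so the planted truth is reproducible).
- Each individual independently activates each block with probability
  `block_activation_prob` (q).
- Condition j is present with probability
  `sigmoid(logit(p0_j) + block_effect · 1[its block is active])`.
- The base rate `p0_j` is calibrated by Brent root-finding (tolerance
  1e-12 on the logit) so the pre-restriction marginal equals the
  target prevalence; calibration failure to bracket raises a
  configuration error naming the condition.
- Optionally, individuals with fewer than two conditions are dropped;
  prevalence is then recomputed on the analysis cohort, and that
  realised prevalence is what the network layer bands and reports.

Target prevalences are drawn from a three-band spectrum: uniform in
[0.001, 0.01), [0.01, 0.07) and [0.07, 0.30), with band counts
apportioned by largest remainder. The 0.30 cap reflects that even the
most common chronic condition categories sit near a quarter of a
multimorbid cohort.

The reference study conditions (`mixed_spectrum_config`) are 200,000
individuals, 140 conditions mixed 45% low / 35% moderate / 20% high,
10 blocks, block effect 3.0 and activation 0.08. The cohort size and
low activation are linked design choices: a rare-rare condition pair
can only clear support 15 when co-occurrence is concentrated in a
small activated subpopulation, and when joint counts sit well above
the support boundary the relative-risk measure is not distorted by
near-empty b/c cells (a small-sample artifact in which almost-nested
pairs acquire arbitrarily large risk ratios). Population registries
are of this order of magnitude, not thousands.

What the generator does **not** emulate: diagnosis-coding noise,
age/sex structure, care-seeking behaviour, disease progression, or
cross-block correlation between conditions (blocks are activated
independently). Consequently, passing tests show the pipeline's
*relative* behaviour across measures under clustered sparse binary
data; they do not certify absolute community counts or similarity
values for any real cohort, which depend on the data's full dependence
structure.

## Numerical and design choices

- **Retention is strict**: p < α and φ > 0. A non-positive φ cannot
  represent co-occurrence; φ = 0 could not be significant anyway.
- **Expected-frequency rule** covers all four cells with a strict
  `> 5` comparison (a table with an expected cell of exactly 5 goes to
  Fisher). The Yates continuity correction is off by default and
  exposed as a flag, since conventions differ across software.
- **Infinite relative risk** (b = 0 or c = 0 with a > 0) is kept as a
  flagged `inf` edge weight and ranks above all finite weights for
  edge selection. For community detection only, infinite weights are
  replaced by 10× the largest finite weight in the network so the
  modularity objective stays finite while dominance is preserved.
- **Ranking ties** at a stratum cutoff break by ascending pair label,
  so top-k networks contain exactly min(k, m) edges and are nested in
  k. Published top-200 networks may handle ties differently; density
  inconsistencies in reported tables suggest some variant counting,
  which this package resolves by fixing determinism.
- **Top fraction uses floor** — 7845 retained associations give 3922
  at 50% — matching reported stratum sizes.
- **Quantiles** use linear interpolation between order statistics
  (numpy default).
- **Prevalence bands** are closed on the left of each upper band: 1%
  is moderate, 7% is high.
- **ARI scope** is the intersection of the two networks' node sets
  (restrictive strata give different node sets per measure; ARI needs
  both labelings on a common set). An intersection below two nodes
  yields NaN and is excluded from summaries.
- **Edge-agreement denominator** is the common edge count when the two
  networks are equally sized (always true within a stratum), else the
  smaller count.
- **Louvain** runs once per seed at resolution 1.0 by default;
  `n_restarts` is available but defaults to 1. Community ids are
  relabelled contiguously ordered by each community's smallest node
  label, so partitions are deterministic given the seed.
- **Exhaustive dyad enumeration** replaces frequent-itemset machinery:
  for pairs with unbounded confidence the two are mathematically
  identical, and enumeration is simpler to verify.

## Test and simulation scale

Unit and property tests run on micro-instances with brute-force
oracles (per-person counting loops, pair-count ARI, adjacency-matrix
modularity, exhaustive partition search up to 8 nodes). Simulation
checks use 20,000 individuals × 20 conditions for the null
(type-I-error) check, 50,000 × 30 for planted-block recovery, and the
200,000 × 140 reference conditions for the prevalence-band directional
checks, each over three replicate seeds; these sizes give stable
directions while keeping the full suite under a minute.

## Known limitations

- No multiple-testing correction is applied in the screen (kept
  deliberately; at α = 0.01 with ~10⁴ dyads some false retentions are
  expected and the null simulation quantifies them).
- Degree centrality is the only centrality measure; weighted
  centralities would interact with measure scale in ways the
  comparison framework does not model.
- The latent-block model cannot produce the weak all-against-all
  association background of real health data, so absolute edge
  agreement and ARI values on synthetic cohorts are higher than one
  should expect on registry data.
- Exact community counts are not reproducible across Louvain
  implementations or seeds; only modularity-level and direction
  claims are stable.
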