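# Methods

## Model

The unit of analysis is a *study universe*: a gene universe with two
gene-set collections over it (pathways, networks), a set of diseases with
gene lists and phase-stratified drug lists, and a drug→target relation.
All quantities are plain set-overlap statistics; there is no inference
about mechanism, only about co-membership of disease genes and drug
targets in the same gene set.

**Stage 1 — coverage.** For element *i* (a pathway or a network) and
disease *j* with gene set `Dg_j` and pooled drug-target set `T_j`:

- `SPG_i = Σ_j |P_i ∩ Dg_j|` — summed disease-gene overlap,
- `SPT_i = Σ_j |P_i ∩ T_j|` — summed drug-target overlap,
- `S_i = Σ_j α_ij`, `α_ij = 1` iff `|P_i ∩ Dg_j| > 0` and `|P_i ∩ T_j| > 0`
  — the number of diseases for which the element carries *both* a disease
  gene and a drug target of that same disease.

Counting elements with positive values of each score yields four coverage
counts per collection (`with_genes`, `with_targets`, `with_both`,
`with_same_disease_pair`), compared between the two collections with a
chi-square test of independence. The same-disease count is the strictest
and is the one that distinguishes genuine disease–drug co-localization
from coincidental coverage by different diseases.

**Stage 2 — per-group ranking.** Diseases carry group labels (a 15-code
vocabulary by default). Within a group, `SNG_i` sums network–disease-gene
overlaps and `SND_i = Σ_j β_ij` counts drug–disease pairs whose drug has a
target inside the network. `β_ij` counts drugs, not targets, so a
multi-target drug contributes once per disease; a drug treating two group
diseases contributes twice unless deduplication is requested
(`dedup_drugs`), which is off by default because the pair, not the
molecule, is the unit of therapeutic evidence.

**Stage 3 — drug categorization and rates.** For disease *j*, the
*related networks* are those containing at least one of its disease genes
and at least one of its drugs' targets. Each of the disease's drugs is
assigned the highest applicable category:

1. `disease_gene` — the drug directly targets one of `Dg_j`;
2. `related_network_partner` — the drug targets a gene that shares a
   network with a gene of `Dg_j`;
3. `other_network` — the drug targets a gene in some network unrelated to
   `Dg_j`;
4. `no_network` — the drug targets no network gene (or nothing).

The rate table holds the category percentages per (disease, phase) cell,
for phases all/clinical/approved. Diseases entering the table are chosen
by a selection rule mirroring common practice: take the `n_top` diseases
by clinical-drug count, then drop the ones with the fewest approved drugs
and the fewest risk genes (defaults 9, 1, 2 → six diseases analyzed).

**Denominator choice.** Two denominators are supported.

- `dna` (default): drugs targeting at least one network. The three
  in-network categories partition this set, so percentages sum to 100 in
  every cell. Consequence: the DISEASE and PHASE marginal means are all
  equal (100/#categories), making those two ANOVA main effects
  *identically zero by construction*. This is not a bug; it is the
  compositional constraint of a closed percentage table. Only TARGET and
  its interactions carry information.
- `all_drugs` with `include_no_network=False`: percentages of all of the
  disease's drugs falling in each of the three in-network categories.
  These do not sum to a constant, so DISEASE and PHASE main effects are
  free; a rising PHASE effect then means in-network targeting as a whole
  grows along the pipeline.

Both are exposed because they answer different questions: `dna` asks how
the in-network mass is *distributed*, `all_drugs` asks how much mass is in
network-mapped targets at all. `examples/04_factorial_analysis.py` shows
both on the same universe.

**Statistics.** The three-way ANOVA is the balanced, one-observation-per-
cell decomposition: main-effect and two-way-interaction sums of squares
from marginal means, with the three-way interaction serving as the error
term (the standard resolution when there is no replication). F statistics
follow F distributions under the usual normality assumption — treated
here as descriptive effect-size summaries, since percentages of small
counts are neither normal nor homoscedastic. Tukey HSD uses the
studentized range distribution (`scipy.stats.studentized_range`) with the
ANOVA residual as the error mean square. The chi-square test is
`scipy.stats.chi2_contingency` without Yates continuity correction, so the
statistic equals the textbook closed form on 2×2 tables.

## Synthetic generator

`generate_universe(SynthConfig)` draws a universe with planted structure
and returns it with its ground truth. The defaults are the study
conditions; they were chosen for structural realism before any acceptance
measurement and are not tuned to outcomes.

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 2000 | large enough that networks tile only part of the universe |
| `n_networks`, `network_size_range` | 120, (2, 10) | many small elements, matching the fine-grained collection |
| `n_pathways`, `networks_per_pathway_range`, `extra_genes_per_pathway` | 30, (2, 6), 8 | pathways are unions of whole networks plus extra genes, guaranteeing network ⊆ pathway nesting |
| `n_groups`, `diseases_per_group` | 15, 2 | the default group vocabulary, two diseases each |
| `pool_networks_per_group` | 5 | disjoint per-group network pools covering only part of the collection, so group structure is recoverable but not trivial |
| `group_enrichment` (γ) | 0.8 | probability a disease gene is drawn from the group pool rather than uniformly |
| `disease_genes_per_disease`, `gwas_genes_per_disease`, `gwas_pool_fraction` | 8, 5, 0.5 | Mendelian lists are short; risk genes are noisier (half off-pool) |
| `druggable_fraction` | 0.15 | drug targets come from a 300-gene druggable subset — targets cluster on few genes, as in reality |
| `n_drugs`, `targets_per_drug_range` | 250, (1, 3) | mostly single-target drugs |
| `drugs_per_disease_range` | (30, 80) | selected diseases in such studies are drug-rich; also keeps every (disease, phase) denominator positive |
| `clinical_rate`, `approval_rate` | 0.5, 0.25 | drawn independently per drug–disease pair; approved need not be a subset of clinical, since approval without a recorded trial link occurs in real data |
| `approval_odds_multiplier` (ρ) | 1.0 | the planted signal: approval probability for genetically supported pairs is `ρ·p/(1+(ρ−1)·p)` — an odds multiplication, which stays in (0, 1) for any ρ |

A drug–disease pair is *genetically supported* when the drug targets a
network containing one of the disease's genes — exactly the
`related`-category membership the analysis measures, so recovery is a true
round trip.

`expected_fold(config)` gives the closed-form approved-vs-all rate fold
implied by ρ: with baseline approval probability `p₀`, boosted probability
`p_ρ`, and supported fraction `q` among drugs targeting any network, the
fold is `p_ρ / (q·p_ρ + (1−q)·p₀)`. `q` does not depend on ρ and is
estimated from a handful of generator replicates; at ρ = 1 the function
returns exactly 1. The fold is sub-linear in ρ and saturates as `q → 1`.

**What the generator emulates:** partial coverage of the gene universe by
networks, pathway–network nesting, group-clustered disease genes, a
concentrated druggable genome, phase attrition, and a genetic-support
approval advantage.

**What it does not emulate:** overlapping networks sharing genes across
pathways, hub target genes with power-law drug degree, disease comorbidity
(multi-group diseases), correlated clinical/approval outcomes within drug
classes, and any time dimension. Absolute counts are not calibrated to
any database release; only the structural signals are meaningful.

## Numerical choices

- All scores and counts are integer set-cardinality computations;
  equality with brute-force enumeration oracles is tested exactly, not to
  a tolerance.
- ANOVA sums of squares conserve the total to 1e-9 by construction of the
  marginal-mean decomposition and are cross-checked against
  statsmodels OLS ANOVA to 1e-8 relative.
- Zero residual (constant or perfectly additive tables) is flagged rather
  than producing division-by-zero; F is reported as 0 for null effects and
  infinity for non-null ones.
- A zero fold-change baseline yields NaN, not an error or infinity: the
  fold is undefined, not infinite evidence.
- The pipeline manifest hashes inputs and outputs (SHA-256) and contains
  no timestamps, so identical inputs and seed give byte-identical
  manifests.
- Derived seeds are reduced modulo 2³¹.

## Limitations

- The ANOVA treats cell percentages as exchangeable observations; with one
  observation per cell the three-way interaction is not testable and all
  p-values lean on a normality assumption that small-count percentages
  violate. Use them as effect-size summaries.
- The `dna`-denominator table is compositional; its DISEASE and PHASE main
  effects are structurally zero and should not be interpreted as "no
  effect" (see the denominator discussion above).
- Direct disease-gene targeting (`disease_gene` category) is rare under
  the generator defaults because targets are drawn from the druggable
  subset independently of disease genes; the informative planted category
  is `related_network_partner`.
- Group recovery uses the top-1 SNG network only; rank-based metrics over
  deeper lists would be stricter but depend on pool size.
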