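# netdrugmap

Gene-set overlap analysis of disease genes and drug targets on two kinds of
gene sets: large mosaic **pathway maps** and small, functionally coherent
**network elements**. The scientific question is whether the fine-grained
network view better localizes disease mechanisms and drug action, and in
particular whether drugs that target a network containing their own
disease's genes are enriched among approved drugs relative to the full drug
pipeline — the "genetic support improves approval odds" signal, measured at
network resolution.

## The model

The inputs are five relations over a gene universe:

- pathway → genes and network → genes (two `GeneSetCollection`s),
- disease *j* → disease genes `Dg_j` (Mendelian genes alone, or integrated
  with GWAS-derived risk genes),
- drug → target genes, and
- disease *j* → drugs per pipeline phase (`all ⊇ clinical`, `all ⊇ approved`),
  with diseases carrying one or more group labels (nervous, metabolic, …).

From these the package computes three stages of statistics:

1. **Coverage** (per element *i* of either collection):
   `SPG_i = Σ_j |P_i ∩ Dg_j|`, `SPT_i = Σ_j |P_i ∩ T_j|` where `T_j` is the
   union of disease *j*'s drug targets, and `S_i = Σ_j α_ij` with
   `α_ij = 1` iff element *i* overlaps both the genes *and* the targets of
   the same disease *j*. Counting elements with positive scores gives the
   coverage table compared between pathways and networks by a chi-square
   test (`compare_universes`).
2. **Per-group network ranking**: `SNG_i` sums network–disease-gene overlaps
   within a disease group; `SND_i = Σ_j β_ij` counts drug–disease pairs
   whose drug has a target inside network *i* (`group_score_table`,
   `top_k`).
3. **Per-disease drug categorization**: each drug is assigned the highest
   applicable category — targets a disease gene > targets a network partner
   of a disease gene > targets some other network > targets no network —
   and the (disease × phase × category) percentage table is analyzed with a
   balanced three-way ANOVA plus Tukey HSD (`rate_table`,
   `three_way_anova`, `tukey_hsd`). The approved-vs-all percentage ratio is
   the pipeline fold change (`pipeline_fold_change`).

Because licensed database snapshots cannot ship with the package, a
synthetic generator (`generate_universe`) produces universes with known
ground truth: per-group network pools, a group-enrichment probability γ for
disease-gene placement, and an approval **odds multiplier ρ** applied to
drugs whose target shares a network with their disease's genes. All
analysis code is exercised against this generator and against brute-force
oracles. See [docs/methods.md](docs/methods.md) for the full model and
parameter rationale.

## Worked example

`examples/05_enrichment_recovery.py` plants an approval odds advantage and
checks that the measured approved-vs-all rate fold matches the closed-form
expectation:

```
$ python examples/05_enrichment_recovery.py
rho=1: measured fold 1.051 +/- 0.024, expected 1.000
rho=2: measured fold 1.501 +/- 0.029, expected 1.506
rho=4: measured fold 2.000 +/- 0.030, expected 2.017
```

`examples/04_factorial_analysis.py` runs the three-way ANOVA on the rate
table under both supported denominators (ρ = 4, seed 1):

```
denominator = dna:
         DISEASE: F=     0.000  p=1
           PHASE: F=     0.000  p=1
          TARGET: F=  6327.041  p=9.57e-29 ****
    PHASExTARGET: F=     4.594  p=0.00855 **

denominator = all_drugs:
         DISEASE: F=     1.131  p=0.376
           PHASE: F=     8.026  p=0.00276 **
          TARGET: F=   790.900  p=9.21e-20 ****
    PHASExTARGET: F=     4.673  p=0.00794 **
```

Under the default denominator (drugs targeting ≥ 1 network) the category
percentages sum to 100 within every (disease, phase) cell, so the DISEASE
and PHASE main effects are identically zero by construction; the
`all_drugs` denominator with only in-network categories frees them. Both
are available; the choice is a modelling decision documented in
[docs/methods.md](docs/methods.md).

The other examples cover pathway-vs-network coverage comparison (`01`),
per-group network ranking against the planted pools (`02`), and the drug
category rate table with its pipeline fold change (`03`). A thin CLI wraps
the same pipeline for file-based use:

```
netdrugmap run-all --input-dir data/ --output-dir out/ --seed 1
```

(also `validate`, `coverage`, `rank`, `rates`, `stats`, and `simulate` for
individual stages; inputs are plain two/three-column TSV files, see
`netdrugmap.io`).

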