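# epibrom

Functional-group inference for epiphytic bromeliads from leaf, tank and
physiological traits.

Epiphytic Bromeliaceae have classically been split into *tank* species,
which impound water between overlapping leaf bases, and *atmospheric*
species, which absorb water over the leaf surface through trichomes.
Trait data collected across the Neotropics support a finer, five-group
scheme: **C3 tanks** and **CAM tanks** among the deep-tank species, and
**nebulophytes** (narrow, acicular, fog-intercepting leaves),
**pseudobulbs** (succulent, ant-housing leaf bases) and **shallow tanks**
(2–61 mL, dew-dependent) among the atmospherics.  `epibrom` implements
the full inference pipeline behind that scheme as a reusable, tested
Python library for trait ecologists:

- **Trait tables** — a species × trait data model for a 25-trait registry
  (tank capacity TC, leaf area LA, leaf index LI = LL/LW, δ13C, δ15N,
  SLA, trichome and stomatal densities, …) with per-cell provenance and
  allometric gap-filling:
  LA = LW·LL / 1.5 and TC = 0.0041·LA² + 1.929·LA − 22.285 mL (clamped at
  0), plus the photosynthetic-pathway call CAM ⇔ δ13C ≥ −20 ‰.
- **Phylogenetic imputation** — a 70 % coverage filter, then missing
  cells filled under a multivariate Brownian-motion model fitted by EM on
  a user-supplied phylogeny (joint covariance C ⊗ R over species and
  traits), out-of-range rejection, and a genus-mean fallback.
- **Two-way Ward clustering** — an agglomerator written from first
  principles (minimal within-cluster SSE increase, deterministic
  tie-breaking) over the log10/0–1-rescaled trait matrix, for species and
  traits simultaneously, with dendrogram cutting at k groups.
- **Discriminant validation** — group centroids with a shrunk pooled
  covariance, squared Mahalanobis distances between groups,
  nearest-centroid classification.
- **Rule engine** — a deterministic classifier assigning any species with
  sufficient traits to one of the five groups (pseudobulb → acicular →
  pathway × tank-capacity thresholds), with explicit *unclassifiable*
  outcomes instead of silent defaults.
- **Group statistics** — Spearman correlation matrices, Kruskal–Wallis +
  Wilcoxon rank-sum post-hocs and ANOVA + Tukey HSD with compact letter
  displays, climate-niche contrasts on occurrence records, and
  species-presence summaries per FAO ecological zone.
- **Synthetic data** — a seeded generator producing five-archetype trait
  tables, Yule phylogenies with Brownian trait signal, missingness, and
  per-group climate niches, so the entire pipeline is testable without
  any downloads.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate_dataset.py --seed 0
python analysis/02_gapfill_traits.py
python analysis/03_cluster_and_validate.py
python analysis/04_classify_groups.py
python analysis/05_trait_statistics.py
python analysis/06_environmental_niches.py
```

At seed 0 this prints, among other things:

```
simulated 76 species x 16 traits (88 cells masked, 7.2%), 1520 occurrence records -> results/data
83 missing cells: 70 filled by the phylogenetic model (13 rejected as out of range), 13 by genus means, 0 left empty -> results/gapfill
clustered 75 species x 16 traits; k=5 cut vs generator labels: ARI 1.000; discriminant training agreement 100.0%
rule classification of 75 species (recovery vs generator labels 97.3%); 1 cluster labels overridden
62 of 105 trait pairs significantly correlated at alpha=0.05; 5 strong (rho^2 > 0.6)
14 of 15 traits differ among the five groups (Kruskal-Wallis)
```

Reading the key numbers: 7.2 % of the 76 × 16 trait cells are masked to
mimic realistic missingness; most are recovered by the Brownian-motion
imputer and the rest by genus means.  The Ward cut at k = 5 reproduces
the generator's functional groups exactly (adjusted Rand index 1.0), the
discriminant model separates them perfectly on the training data, and
the threshold rules recover 97 % of the labels from raw traits alone.
The squared-Mahalanobis table printed by step 03 quantifies the group
separation in transformed trait space; the compact-letter tables from
steps 05–06 mark which groups differ per trait and per climate variable
(groups sharing a letter do not differ at α = 0.05).

The same pipeline runs from the command line on user data
(`epibrom run --config cfg.yaml`), and `epibrom simulate`, `classify`
and `stats` expose the individual stages.  A real study supplies a trait
CSV (`species,genus,<trait abbreviations>`; empty cell = missing,
optional `tankless`/`acicular` flag columns), an optional newick
phylogeny, and an optional occurrence-records CSV
(`species,lat,lon,VPD,PPT,TMIN,TMAX,ET0,AI,Elev,ecozone`).

## Layout

```
src/epibrom/       library: registry, trait_db, phylo_impute, preprocess,
                   cluster_da, fg_classify, group_stats, synthetic,
                   benchmarks, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    model and design notes
```
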