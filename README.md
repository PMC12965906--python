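# genecol

Genecological seed-transfer modeling: from common-garden trait tables and
source-climate normals to **fixed-boundary seed zones** (multivariate
regression trees) and **focal-point seed-transfer maps** (random-forest
transfer functions).

## Who this is for

Restoration ecologists and seed-program managers who run provenance
(common-garden) studies: many wildland source populations grown together
in a few shared gardens, so that population-level trait differences
reflect genetics rather than environment.  The toolkit turns the resulting
plant-level measurements into mapped seed-transfer guidance.

## The model pipeline

1. **Variance components** (`varcomp`).  Each trait is decomposed with all
   design factors random: garden, block nested in garden, population,
   family nested in population, and residual — REML for Gaussian traits, a
   mixed GLM on the link scale for counts (Poisson/log) and survival
   (binomial/logit).  Traits whose population-level share is negligible
   (< 0.001 %) in any garden are dropped everywhere.
2. **Trait axes** (`axes`).  Population mean values per trait × garden
   column are centered, scaled, and decomposed by PCA; the number of
   significant axes comes from a Monte Carlo test on cumulative eigenvalue
   sums against within-column permutations.
3. **Plasticity** (`plasticity`).  Per population and trait, the SD of
   garden means across gardens; Pearson correlations with the 23 climate
   normals, Benjamini–Hochberg adjusted.
4. **Seed zones** (`zones`).  A multivariate regression tree partitions
   populations on climate, choosing at each node the split that minimizes
   the within-child sum of squared distances to centroids in PC trait
   space: for node *t* split into *l*, *r*,
   `gain = SS(t) − SS(l) − SS(r)`, kept when `gain ≥ cp · SS(root)`
   (default cp = 0.015) with at least 5 populations per child.  Splits
   grouped by decreasing gain yield hierarchical zone codes (A / A1 / A1a
   …), so zones can be merged or subdivided to match risk tolerance.
5. **Transfer functions** (`forest`).  One random forest per significant
   axis (500 trees, ⌊p/3⌋ predictors per split, bootstrap, min leaf 5),
   with RSS-decrease importance and partial-dependence curves.
6. **Maps** (`project`, `focal`).  Models project over a multi-band
   climate grid; cells more than one SD beyond the sampled range of any
   variable are masked.  A focal-point map shows, per cell, the Euclidean
   distance in predicted PC trait space from a chosen location — smaller
   distance, safer transfer.

A bundled synthetic-study generator (`simulate`) reproduces the full study
design (98 populations × 2 families × 3 gardens × 6 blocks), climate
gradients with realistic collinearity, a 3-zone latent structure, and a
plasticity-by-mildness gradient, so every stage is testable end to end.

## Worked example

```bash
genecol simulate --seed 11 --out demo/study
genecol varcomp  --plants demo/study/plants.csv --out demo/vc
genecol axes     --plants demo/study/plants.csv \
                 --retained demo/vc/retained.json -B 499 --seed 11 --out demo/ax
genecol zones    --scores demo/ax/traitspace.json \
                 --climate demo/study/climate.csv --out demo/zn
genecol project  --model demo/zn/zonetree.json --grid demo/study/grid \
                 --climate demo/study/climate.csv --out demo/pr
```

which prints, stage by stage:

```
wrote study (3528 plants, 98 populations) to demo/study
27 trait x garden combinations retained; excluded traits: none
26 significant axes (99% of total variance)
8 zones: A1, A2, A3, A4, A5, A6, B, C
zone raster with 8 zones written to demo/pr
```

and `demo/zn/tree.txt` begins:

```
TD < 23.3367  (gain 10.0%, level 1)
  EXT < 31.2114  (gain 2.8%, level 2)
    [A1] n=5 ss=177.474
    ...
  MWMT < 23.7326  (gain 3.7%, level 1)
    [B] n=32 ss=584.536
    [C] n=33 ss=207.425
```

Reading this: all nine traits kept population-level variation in every
garden, so 9 traits × 3 gardens = 27 columns entered the PCA.  The tree's
two primary splits are on continentality (TD) and mean warmest-month
temperature (MWMT) — exactly the variables that define the generator's
latent zones — giving three primary zones (A, B, C), with zone A further
subdivided; the level-1 splits explain 13.7 % of the multivariate trait
variance (`variance_by_level.csv`).  The zone raster carries an integer
per unmasked cell plus a JSON legend mapping integers to zone codes.

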