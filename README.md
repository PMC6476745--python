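# sedistrat

Depth-stratification analysis of sediment 16S rRNA gene communities.

Lake and marine sediments archive their microbial communities vertically:
the surface hosts a rich assemblage fed by fresh organic matter, while the
energy-starved deeper layers appear to be assembled by *selective survival*
— a small set of taxa continuously present from the surface down
("persisting OTUs") carries most of the reads at depth, while the majority
of surface taxa fade out. `sedistrat` implements the analysis workflow used
to detect that signature in depth-resolved amplicon surveys, plus a
synthetic-community generator that makes every stage testable without any
sequence download.

## What it computes

Given OTU count tables (generic TSV, mothur `.shared` + `.cons.taxonomy`,
or BIOM 1.0 JSON) with per-sample core/depth metadata:

* **Normalisation** — dataset-wide singleton removal, rarefaction of every
  sample to the smallest library by multivariate-hypergeometric subsampling,
  Good's coverage `1 − F1/N`, relative abundances.
* **Layer handling** — replicate cores averaged per depth layer (mean and
  average deviation), and rebinning of one layering scheme onto another by
  thickness-weighted overlap (e.g. fine 1-cm archaeal layers onto coarse
  pooled bacterial layers).
* **Taxon groups and guilds** — a versioned YAML dictionary classifies
  lineages into well-characterized vs poorly-known groups and into
  methanogen/methanotroph guilds; per-layer group sums, guild maxima, and
  the acetoclastic:hydrogenotrophic methanogen ratio, including its
  stoichiometric expectation for complete hexose degradation
  (hexose → 2 acetate + 2 CO₂ + 4 H₂; 2 acetate → 2 CH₄ and
  4 H₂ + CO₂ → 1 CH₄, i.e. 2:1).
* **Persistence statistics** — the survival curve
  `S(k) = |{OTUs present in layers 1..k}|` (cumulative intersection from the
  surface, so `S(deepest)` is the persisting-OTU count), and the persisting
  set's per-layer share of richness and of summed relative abundance.
* **Geochemistry** — δ notation `δ = [(R_sample/R_standard) − 1]·10³` (‰),
  C:N and DNA:RNA ratios with explicit below-detection propagation, and the
  branched-fatty-acid biomass proxy
  `BrFA = i14:0 + i15:0 + a15:0 + i16:0 + i17:0 + a17:0 + i18:0`.
* **Simulation** — lognormal surface communities with a persistent cohort
  (slow exponential decay with depth) against fast-decaying transients, or
  a neutral-turnover alternative (random identity replacement per layer
  transition), two replicate cores with Dirichlet overdispersion, and
  multinomial read sampling at fixed library sizes; ground truth is kept
  for recovery scoring.

## Worked example

Simulate a survey and analyse it from the written files:

```sh
sedistrat simulate --seed 11 --outdir sim --format mothur
cat > config.yaml <<'YAML'
seed: 11
outdir: out
inputs:
  metadata: sim/samples.tsv
  archaea: {path: sim/archaea.shared, format: mothur, taxonomy: sim/archaea.cons.taxonomy}
  bacteria: {path: sim/bacteria.shared, format: mothur, taxonomy: sim/bacteria.cons.taxonomy}
  geochem: sim/geochem.tsv
YAML
sedistrat analyze --config config.yaml
```

prints

```
archaea: 47 persisting OTUs; richness fraction 12.7%-45.6%; abundance fraction 12.0%-94.2%
bacteria: 215 persisting OTUs; richness fraction 10.2%-38.5%; abundance fraction 31.9%-95.1%
outputs written to out
```

Read: of 371 archaeal and 2103 bacterial surface OTUs only 47 and 215 are
present in every layer down to 26 cm, yet at the deepest layer those few
OTUs carry 94% and 95% of the reads — the selective-survival signature
(few persisting OTUs, most of the community). The output bundle contains
per-layer TSVs (`*_survival_curve.tsv`, `*_persistence.tsv`,
`*_group_profile.tsv`, `*_guild_maxima.tsv`, `*_pathway_ratio.tsv`,
`geochem_metrics.tsv`) and a `manifest.json` with the seed, the config hash
and a SHA-256 per file, so a rerun is verifiable byte for byte. The same
workflow is available in Python via `sedistrat.RunConfig` and
`sedistrat.run_pipeline`, and runs on any conforming table (no simulation
required).

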