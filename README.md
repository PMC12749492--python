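# forelandeco

Quantitative ecology and bioenergetics of microbial colonisation of
glacier forelands.

As glaciers retreat they expose barren mineral soils that microorganisms
colonise within years. This package implements, as a tested and reusable
pipeline, the quantitative machinery needed to ask *who* colonises such
chronosequences and *what pays their energy bills*:

* **Habitat specialisation index (SI).** For each taxon, the coefficient
  of variation of its relative abundance across samples,
  `SI = sd(p) / mean(p)` (sample sd, n−1). Taxa below the first quartile
  of the community SI distribution are habitat *generalists*, above the
  third quartile habitat *specialists*, otherwise *intermediates*
  (linear-interpolation quantiles, strict inequalities).
* **Zeta diversity.** ζ<sub>i</sub> is the mean number of taxa jointly
  present across i sites (optionally Jaccard-normalised by each
  combination's union). The package evaluates orders 1–6 exhaustively or
  by Monte-Carlo subsampling, fits power-law vs exponential decline
  models by AIC (exponential decline ⇒ stochastic assembly, power law ⇒
  deterministic niche assembly), regresses ζ on mean pairwise
  great-circle distance (distance decay), and partitions pairwise-ζ
  variation between two predictor groups via adjusted R².
* **Marker-gene profiling.** DIAMOND/BLAST-style hits against curated
  metabolic marker families are filtered with per-family identity and
  coverage thresholds, normalised to RPKM, and expressed as the *average
  gene copy per organism* — family RPKM over the mean RPKM of universal
  single-copy ribosomal protein families.
* **Biogeochemical rates.** First-order trace-gas oxidation constants
  from microcosm headspace series (log-linear and asymptotic fits, AIC
  selection, heat-killed control subtraction), static-chamber fluxes in
  nmol m⁻² s⁻¹, slurry nutrient transformation rates (linear vs
  exponential by AIC), and qPCR standard-curve quantification.
* **Power per cell.** ΔG = ΔG° + RT ln Q over gas-phase activities,
  combined with bulk oxidation rates and oxidiser cell counts:
  `P = rate × |ΔG| / n_cells`, compared against the empirical microbial
  maintenance window of 10⁻¹⁷–10⁻¹² W cell⁻¹.

A synthetic-data module generates every input the pipeline consumes —
a two-glacier chronosequence (an Antarctic foreland with three soil-age
classes and a Swiss alpine foreland with four, plus depth profiles) with
planted generalists, early opportunists and late specialists — so the
whole pipeline is testable end-to-end with known ground truth.

## Worked example

```python
from forelandeco import community_structure as cs, synthetic_data as sd

design = sd.swiss_design(seed=1)                  # 4 age classes, 15 topsoils
matrix, truth = sd.generate_community(design, sd.default_truths(), 100_000)
table = cs.classify_specialisation(cs.specialisation_index(matrix))
print(table["habitat_class"].value_counts().to_dict())
print(round(table["q1"].iloc[0], 3), round(table["q3"].iloc[0], 3))
print(sd.guild_recovery(truth, table))
```

prints

```
{'intermediate': 10, 'generalist': 5, 'specialist': 5}
0.38 1.757
{'precision_generalist': 1.0, 'recall_generalist': 0.625,
 'precision_specialist': 1.0, 'recall_specialist': 0.4166666666666667}
```

Five of twenty taxa fall below the SI first quartile (0.38) and all five
are planted generalists; the five above the third quartile (1.76) are
all planted high-variance taxa. Recall is bounded by the quartile rule
itself: with 8 planted generalists among 20 taxa, at most ~5 taxa can be
labelled generalist.

The full pipeline runs from one command and writes a reproducibility
manifest:

```sh
foreland run --seed 1 --outdir foreland_out
```

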