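# ocuscrub

Decontamination and temporal analysis of low-biomass 16S rRNA OTU tables.

Surfaces such as the healthy conjunctiva carry so little microbial biomass
that DNA from reagents, kits and handling rivals or exceeds the genuine
signal after PCR amplification. Simply discarding every OTU seen in a
negative control throws away real residents, because the most abundant
members of a low-biomass community also show up (at low levels) in blanks.
`ocuscrub` implements the statistical alternative: model the abundance an
OTU *should* have if it were reagent-borne, and keep only the OTUs whose
abundance in subject samples far exceeds that prediction. It is written
for microbiome researchers working with ocular-surface, skin, placenta,
airway or similar low-biomass amplicon studies.

## The model

Let `s_o` be the mean luminosity-weighted relative abundance of OTU *o*
over subject samples and `c_o` the same quantity over negative controls
(blank swabs or nuclease-free water). A reagent contaminant enters every
reaction at a fixed absolute amount, so across contaminant OTUs
`log s_o` is linear in `log c_o`. The filter fits, by ordinary least
squares over OTUs,

```
log(s_o + ε) = α + β · log(c_o + ε) + e_o,     ε = ½ · min nonzero mean
```

and retains OTU *o* iff its residual exceeds `m` prediction standard
errors of the fitted value,

```
e_o  >  m · σ̂ · sqrt(1/n + (x_o − x̄)² / Σ(x_i − x̄)²),      σ̂ = sqrt(RSS/(n−2)),  m = 5,
```

i.e. iff the subject abundance exceeds the predicted abundance by more
than the factor `exp(m·SE(x_o))`. The full pipeline runs nine ordered
steps: a 10,000-read sample-depth filter, conversion to relative
abundances, weighting by relative PCR band luminosity (a surrogate for
target DNA concentration), per-sample-type means, a 0.0001% rare-OTU
filter, two successive blank-control regression passes and one
water-control pass. Each step's sample/OTU attrition is logged in a
`FilterReport`.

Around the filter the package provides:

* **`synthetic_data`** — a generator for complete synthetic low-biomass
  experiments (counts, metadata, taxonomy, band luminosities) with known
  resident/contaminant ground truth, built on the same contamination
  model the filter assumes;
* **`core_microbiome`** — presence/absence reduction and prevalence
  analysis across subjects and time points at OTU/genus/phylum level,
  including the strict core ("present in all subjects at all time
  points") and relaxed variants;
* **`diversity`** — richness, Shannon index (nats), Bray-Curtis
  dissimilarity on relative abundances, Monte-Carlo rarefaction curves
  and per-taxon temporal coefficients of variation, exported as TSV for
  downstream mixed-model / PERMANOVA work in external tools.

## Worked example

```python
import ocuscrub as oc

cfg = oc.SimulationConfig(seed=1, n_contaminant_otus=2000)
bundle = oc.generate_experiment(cfg)
result = oc.run_contaminant_pipeline(bundle.counts, bundle.metadata, bundle.luminosity)
print(result.report.to_text())
confusion = oc.truth_confusion(result.retained_otus, bundle.truth)
print(f"sensitivity={confusion.sensitivity:.3f} specificity={confusion.specificity:.3f}")
```

prints

```
contaminant filter report
=========================
(a) remove samples with fewer than 10000 reads: removed 4 samples, 0 OTUs -> 143 samples, 2040 OTUs retained
(b) convert counts to within-sample relative abundances: removed 0 samples, 0 OTUs -> 143 samples, 2040 OTUs retained
(c) weight by relative band luminosity (proportional): removed 0 samples, 0 OTUs -> 143 samples, 2040 OTUs retained
(d) mean weighted relative abundance per sample type: removed 0 samples, 0 OTUs -> 143 samples, 2040 OTUs retained
(e) remove OTUs below 1e-06 of total subject abundance: removed 0 samples, 0 OTUs -> 143 samples, 2040 OTUs retained
(f) blank-control regression, first pass (fit): removed 0 samples, 0 OTUs -> 143 samples, 2040 OTUs retained
      regression on blank_control: slope=0.6248, intercept=-0.9967, residual SE=0.8547, n=2040, retention factor at the predictor mean=1.0992
(g) blank-control regression, first pass: removed 0 samples, 1272 OTUs -> 143 samples, 768 OTUs retained
(h) blank-control regression, second pass: removed 0 samples, 635 OTUs -> 143 samples, 133 OTUs retained
(i) water-control regression pass: removed 0 samples, 94 OTUs -> 143 samples, 39 OTUs retained
sensitivity=0.775 specificity=0.996
```

Reading it: four samples fell below the 10,000-read floor; the regression
cascade collapsed 2,040 OTUs to 39, discarding 1,992 of the 2,000 planted
contaminants (specificity 0.996) while keeping 31 of the 40 planted
residents on this seed (the median across seeds is higher — see the
reproduction script below). The per-pass slopes show the model at work:
the first fits track the contaminant trend (slope ≈ 0.6), while the final
water pass, fitted on a mostly-resident set, is flat (slope ≈ −0.3) —
control abundance no longer predicts subject abundance, which is
precisely why those OTUs are kept.

The same workflow is available from the shell:

```sh
ocuscrub simulate --seed 1 --out sim/
ocuscrub validate --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --taxonomy sim/taxonomy.tsv --luminosity sim/luminosity.tsv
ocuscrub filter --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --luminosity sim/luminosity.tsv --out filtered/
ocuscrub core --counts filtered/filtered_counts.tsv --metadata sim/metadata.tsv \
    --taxonomy sim/taxonomy.tsv --rank genus --out core/
ocuscrub diversity --counts filtered/filtered_counts.tsv \
    --metadata sim/metadata.tsv --out diversity/
```

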