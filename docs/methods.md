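# Methods

## Problem setting

Low-biomass amplicon sequencing (ocular surface, skin, airway, placenta)
confounds genuine residents with DNA introduced by swabs, extraction
kits, PCR reagents and handling. Presence in a negative control cannot by
itself disqualify an OTU: the most abundant genuine residents also appear
at low levels in blanks. The package therefore treats decontamination as
a regression problem — predict what a reagent-borne OTU's subject
abundance should be from its control abundance, and keep the OTUs whose
subject abundance is far in excess of that prediction.

## The contaminant-filtering model

### Inputs

An integer OTU count table (samples × OTUs), per-sample metadata
(subject / blank-swab control / water control, subject id, time point), a
per-sample PCR band luminosity, and (for taxon-level summaries) an OTU
taxonomy map. Band luminosity acts as a surrogate for per-sample target
DNA concentration — i.e. microbial biomass recovered from the swab.

### Steps

1. **(a) Depth filter.** Samples with fewer than `min_depth` reads
   (default 10,000) are removed; the boundary is strict, so a sample at
   exactly 10,000 reads stays. Removal applies to all sample types; the
   pipeline aborts if a whole control type disappears.
2. **(b) Relative abundances.** Counts are divided by each sample's
   total, decoupling all later steps from sequencing depth.
3. **(c) Luminosity weighting.** Each sample's relative abundances are
   multiplied by its *relative* band luminosity `w = L / L_max`. The
   weighting re-introduces biomass information that relative abundances
   discard: a faint band means little target DNA, so its composition
   should count for little when estimating what is genuinely abundant in
   subjects. The complementary convention `(L_max − L) / L_max` — which
   gives the brightest band weight zero and would annihilate the
   highest-biomass sample, contradicting luminosity's role as a biomass
   surrogate — is available behind `FilterConfig(luminosity_mode="literal")`
   for comparison, but is not the default.
4. **(d) Sample-type means.** For each OTU, the arithmetic mean weighted
   relative abundance over subject samples, blank controls and water
   controls (zeros included).
5. **(e) Rare-OTU filter.** OTUs holding less than `rare_fraction`
   (default 1e-6, i.e. 0.0001%) of the *summed subject-sample means* are
   removed, again with a strict boundary. The subject-only basis is
   deliberate: abundance driven purely by controls should not rescue an
   OTU from the rare filter.
6. **(f–g) Blank-control regression.** Across the surviving OTUs,
   ordinary least squares of `y = log(subject mean + ε)` on
   `x = log(blank mean + ε)`. The pseudocount ε is half the smallest
   non-zero mean among the values entering the fit, applied to both axes;
   this keeps OTUs absent from controls as extreme positive residuals —
   retainable, which is the filter's intent. An OTU is retained iff its
   residual strictly exceeds `m · SE(x_o)`, where `m = se_multiplier`
   (default 5) and `SE(x) = σ̂ · sqrt(1/n + (x − x̄)²/Sxx)` is the
   standard error of the fitted value at its predictor position
   (σ̂ = sqrt(RSS/(n−2)) is the residual standard error, reported on
   every fit). On the abundance scale the rule reads: keep OTU *o* iff
   its subject abundance exceeds the prediction by more than the factor
   `exp(m · SE(x_o))` — the threshold lives on the log scale and is
   back-transformed through the exponential.
7. **(h) Second blank pass.** The regression is refitted *from scratch*
   (including a fresh pseudocount) on the retained OTUs and the same
   retention rule applied again.
8. **(i) Water pass.** One further pass with the water-control means as
   predictor. A single pass is run here, not two.

Every step appends a record (samples removed, OTUs removed/retained,
regression parameters where applicable) to a `FilterReport`; OTU counts
are non-increasing across steps by construction, and an empty final set
is a reported outcome, not an error.

### Why the threshold uses the fitted-value standard error

Two readings of "the prediction standard error multiplied by five" are
possible: the scalar residual standard error σ̂, or the per-point
standard error of the fitted value SE(x). The scalar reading is
arithmetically self-defeating for a repeated filter: if k points satisfy
`e > 5σ̂` then `RSS ≥ 25k·RSS/(n−2)`, so *at most (n−2)/25 points can
ever be retained per pass*, and three successive passes could keep at
most n/25³ of the input — the cascade necessarily terminates near the
empty set on any input. The fitted-value reading has no such cap, scales
sensibly with the number of OTUs, and is what `predict.lm(..., se.fit=TRUE)`
returns in R, where this family of analyses is typically run. The
package therefore thresholds on `5 · SE(x_o)`.

### Degenerate inputs and numerical choices

* Natural logarithms throughout; Shannon diversity likewise in nats.
* A regression needs ≥ 3 OTUs and non-zero predictor variance; the
  pipeline raises (annotated with its step letter) if a fit is
  impossible, except that a pass reached with 1–2 surviving OTUs is
  skipped with a note rather than failing the whole run.
* Retention inequalities are strict, so a perfect fit (σ̂ = 0) retains
  nothing: if controls predict subjects exactly, nothing is in excess.
* Input tables are canonicalised (sorted sample/OTU axes) before
  filtering, making results bit-identical under permutation of input
  rows and columns.
* Weights of exactly zero (a sample with no visible band) produce
  all-zero rows that stay in the table and are flagged in the report.

## The synthetic experiment generator

The generator emulates a longitudinal low-biomass swab study and is the
package's test bed; every parameter is a `SimulationConfig` field.

* **Design:** 45 subjects × 3 time points, 9 blank-swab and 3 water
  controls; sequencing depths from a normal (mean 54,652, sd 28,912)
  truncated at 1,000 reads — controls are sequenced to full depth like
  any other library.
* **Residents:** a pool of 40 true OTUs. Each subject has a stable core
  of 8 drawn from the pool (planted at every visit); the rest appear
  sporadically (presence probability 0.3 per sample). Per-subject OTU
  propensities are log-normal (sd 1.0), per-sample target biomass is
  log-normal (sd 0.5), and abundances wobble between visits by a
  log-normal factor (sd 0.3). These sizes put 10–40 resident OTUs in a
  typical sample, matching the emulated setting.
* **Contaminants:** a pool of 150 OTUs (default) whose reagent
  concentration is log-normal across OTUs (sd 1.0) and enters *every*
  reaction — subject and control alike — independent of sample biomass,
  with per-reaction log-normal variability (sd 1.5) around each
  concentration. The fixed absolute spike is what makes control
  abundance a linear predictor of subject abundance on the log scale;
  the per-reaction variability reflects the order-of-magnitude spread
  blank-sequencing studies report between reactions, and without it the
  generator would present the filter with an unrealistically
  deterministic contaminant line (see Limitations).
* **Controls:** carry a small fraction (default 0.01) of the mean
  subject resident profile (handling carry-over) plus the contaminant
  spikes, so contaminant reads dominate them.
* **Luminosity:** proportional to each sample's total resident (target)
  biomass with multiplicative log-normal noise (sd 0.2); with the noise
  at zero it is exactly proportional.
* Counts are a multinomial draw of each sample's combined relative
  abundances at its depth, so per-sample counts sum to the drawn depth
  exactly. The full bundle is a deterministic function of the config
  (seed included): identical configs give bit-identical bundles.
* Taxonomy is assigned round-robin from a fixed list of genera familiar
  from ocular-surface work (Corynebacterium, Sphingomonas, Streptococcus,
  Acinetobacter, Pseudomonas, Staphylococcus, ...), with every tenth OTU
  left unclassified at genus to exercise the unclassified pooling.

What it does **not** emulate: read-level error, chimeras, taxonomic
misassignment, batch/run structure, compositional correlations between
residents, or subject drop-out. Passing tests on this generator show the
pipeline implements its model correctly and recovers planted structure
under that model's assumptions — not that the model is adequate for any
particular real dataset.

## Core-microbiome analysis

Presence is a thresholded reduction of counts (default ≥ 1 read;
configurable because presence at heterogeneous depth is threshold-
sensitive). Duplicate samples per (subject, time) are OR-combined; a
(subject, time) cell with no sample is *missing*, never absent. Subjects
with any missing cell are excluded from prevalence denominators — a
study with drop-outs is summarised over its complete subjects. The
strict core is the taxon set present in all complete subjects at all
time points; relaxed cores lower the subject fraction and/or accept
any-time presence, and both relaxations are monotone. Taxon-level
analyses first collapse the count table along a taxonomy map
(phylum…genus), pooling rank-unclassified OTUs into one `unclassified`
taxon; collapsing conserves totals exactly. Culture isolation tables
enter as ordinary boolean presence tables and are summarised as
per-taxon isolation proportions overall and per time point.

## Diversity and temporal stability

Richness counts OTUs with ≥ 1 read. Shannon is −Σ p ln p (nats).
Bray-Curtis is computed on relative abundances, not raw counts, so
five-fold depth differences between samples do not masquerade as
community differences. Rarefaction draws reads without replacement
(multivariate hypergeometric) and reports mean richness over replicate
draws per depth; at full depth it equals the observed richness exactly,
and the test suite checks it against the closed-form hypergeometric
expectation. Temporal stability is the per-taxon coefficient of
variation (sample sd, n−1, over mean) of per-time mean relative
abundance; taxa with under two observed time points or zero mean are
reported missing. CV is scale-invariant, so it compares stability across
taxa of very different abundance. Statistical testing (mixed models,
PERMANOVA, dispersion tests) is deliberately out of scope; the module
exports tidy TSV tables for those tools instead.

## Known limitations

* **Recovery degrades when residents are a large share of the OTU
  pool.** The 5·SE outlier rule assumes genuine residents are rare among
  the regression points. At the default simulation (40 resident vs 150
  contaminant OTUs — residents are 21% of points) the first pass
  correctly isolates the residents, but the mandatory repeat passes then
  regress a homogeneous resident-only cloud and can only keep its own
  upper tail; median sensitivity over seeds is ~0 even though
  specificity is ~1. In the contaminant-rich regime the method is built
  for (residents ~2% of points, e.g. 40 vs 2,000) the same pipeline
  reaches median sensitivity ≳ 0.9 at specificity ≳ 0.99. This is a
  property of the published procedure, not of the implementation; the
  acceptance suite pins both behaviours.
* The end-to-end retained set is not monotone in `rare_fraction`:
  changing the OTU pool refits the regression, so downstream retention
  can flip either way. Monotonicity holds at the step level (the rare
  filter retains nested sets; regression retention at a fixed fit is
  non-increasing in `se_multiplier`) and is tested there.
* Whether the upstream study weighted controls by their own (faint) band
  luminosities, and whether the water pass iterates, are not
  recoverable from the procedure's description; the package weights all
  samples and runs a single water pass.
* The luminosity weighting direction follows the biomass-surrogate
  rationale (`L / L_max`); the inverted variant is provided for
  comparison but produces filters that discard exactly the
  highest-biomass evidence.
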