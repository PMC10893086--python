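# Methods

`chemomix` implements a multi-chemical-omics workflow for two-treatment
culture experiments on microalgae: three abundance layers — an
elementome (elemental concentrations per g dry mass), a metabolome
(GC-MS peak areas) and a volatilome (GC×GC peak areas with water
blanks and technical duplicates) — are normalised to a per-cell
comparable unit, screened analyte-by-analyte for treatment differences
under false-discovery-rate control, integrated into one table for
ordination and a permutational ANOVA, and finally mined for
co-varying modules with a significance-gated rank-correlation network.

## Normalisation ladders

Each layer has a fixed ladder recorded step by step in the table's
provenance list:

* **Elementome**: concentration (µg per g dry mass) × pellet dry mass
  (g) ÷ total cells in the sampled aliquot (cells mL⁻¹ × aliquot mL)
  → µg per cell.
* **Metabolome**: peak area ÷ internal-standard (D-sorbitol-6-¹³C)
  area ÷ total cells in the 50 mL aliquot.
* **Volatilome** (hygiene chain, in order): internal-standard
  (chlorobenzene-d5) normalisation → technical-duplicate averaging →
  known-artefact removal (case-insensitive exact name match) → blank
  subtraction → presence filtering → division by cell density.

Two readings of the blank rule are possible; the default treats an
analyte detected in strictly more than half of the water blanks as
genuine background, subtracts its mean detected blank abundance from
every sample, and demotes results ≤ 0 to non-detects.  Outright
removal of background analytes is available (`mode="remove"`), but
subtraction is the default because removal would also delete
biological signal that genuinely exceeds background.  The presence
filter keeps an analyte only if detected in at least four of six
biological replicates within at least one treatment group; "at least
one group" (rather than both) is deliberate, since treatment-unique
volatiles are a finding, not noise.  Technical duplicates are averaged
over *detected* values (a single detection carries through): dropouts
are common in thermal-desorption duplicates and zero-imputation would
bias means downward.

The per-cell step divides elements and metabolites by total aliquot
cells and volatiles by cell density (cells mL⁻¹); both are recorded in
the ladder so the unit is unambiguous.

Cytometry counts are blank-corrected by subtracting the mean blank
event count, floored at zero (counts cannot be negative).

## Transforms and stoichiometry

Joint analysis uses the natural log with an analyte-specific
pseudo-count: half the smallest detected positive value of that
analyte, applied only when zeros or non-detects exist.  This preserves
rank order and adapts to each analyte's scale; a single global
constant would distort layers with different units.  Mean-centring and
(for heatmap display) autoscaling (mean 0, sample sd with n−1) follow;
both are idempotent and tested as such.  C:N:P ratios convert mass
fractions to moles (C 12.011, N 14.007, P 30.974 g mol⁻¹) and scale so
P = 1, the convention of the Redfield reference ratio 106:16:1.

## Univariate testing

Welch's unequal-variance t (Satterthwaite degrees of freedom) and the
Wilcoxon rank-sum test are available per analyte, two-sided.  The
Wilcoxon p is exact (full permutation distribution) when n₁+n₂ ≤ 20
with no ties, otherwise a tie- and continuity-corrected normal
approximation.  Adjustment is Benjamini–Hochberg within the table
being tested (per layer, not pooled across layers).  The pipeline
defaults are Welch for elements and Wilcoxon for metabolites,
volatiles and the integrated table.  Volatile non-detects enter as
zeros — structural absence is a biologically meaningful difference —
but analytes detected in only one treatment group are *not* rank
tested: they are reported through the presence/absence partition
(heat-only / control-only / shared) instead, since a rank test against
an all-zero group adds nothing beyond the partition itself.

## Ordination and PERMANOVA

PCA is the singular value decomposition of the column-centred
samples × analytes matrix; component k explains σₖ²/Σσ²·100 percent of
variance, and signs are fixed so each loading's largest entry is
positive.  PERMANOVA is implemented from first principles on a
distance matrix (Euclidean on the log-transformed, mean-centred
integrated table by default): SS_total = Σ_{i<j} d²ᵢⱼ/N, within-group
sums analogously per group, pseudo-F = (SS_between/(a−1)) /
(SS_within/(N−a)), and p = (#{F_perm ≥ F_obs}+1)/(n_perm+1) under free
label permutations (default 9999, explicit seed).  On Euclidean
distances of univariate data the pseudo-F equals the classical ANOVA
F, which the tests exploit as a closed-form oracle; the implementation
is also cross-checked against scikit-bio.  Permutations are free
relabelings: the original experiment nested replicates in two water
baths per treatment, a structure this package does not model — p
values are calibrated for exchangeable replicates only.  Heatmap
ordering uses Euclidean/Ward agglomeration (linkage choice ours; only
the distance is inherited from the upstream analysis).

## Correlation network

Among significantly different analytes, Spearman correlations are
computed with mid-ranks over all pooled samples (n = 12), gated by
Holm's step-down correction over all C(s,2) analyte pairs at
α = 0.05, and kept as signed undirected edges.  Clusters are the
connected components (≥ 2 nodes), reproducing small two-compound
modules; the k-core (k = 3: every member correlated with at least
three others in the subgraph) annotates the densely connected
"central" nodes.  The k-core is order-independent and is verified
against exhaustive subset search on small graphs.

**Exact small-sample p-values.** With a dozen samples, Holm over
thousands of pairs places the per-pair level at 10⁻⁵–10⁻⁶.  The
customary t approximation t = ρ√((n−2)/(1−ρ²)) understates the true
tail probability several-fold in that regime (3–30× at n = 12), which
on null data inflated the family-wise error of the gated network to
~17 % per 100 datasets and admitted spurious "bridge" edges between
unrelated modules.  Tie-free pairs at n ≤ 13 are therefore tested
against the exact permutation null of S = Σdᵢ², computed once per n by
a subset dynamic programme and verified against full enumeration at
small n; pairs with ties, or larger n, fall back to the t
approximation (`p_method="t"` forces the classical behaviour).  With
the exact null the family-wise error of the gated network on null data
is 3–6 % per 100 datasets.

## Synthetic data generator

The generator emulates the study design: 2 treatments × 6 biological
replicates; 17 elements, 120 metabolites, 163 volatiles; 5 water
blanks; duplicate volatile measurements; cell densities near
1.3–1.5 × 10⁵ cells mL⁻¹ (heat slightly lower, mirroring the measured
means); ~10 mg dry pellets.  Log-scale abundance per analyte a and
biological sample s:

    log x_as = μ_a + β_a·1[s ∈ heat] + λ_a f_{k(a),s} + ε_as

* A configurable fraction (default 0.18) of each layer is
  differential; |β| is drawn near the configured effect size (default
  2 natural-log units, i.e. ~7-fold) with signs 3:1 in favour of
  heat-elevated, matching the observed predominance of stress-induced
  increases.
* One standard-normal latent factor per planted cluster (default
  sizes 23, 5, 3, 2, 2, the largest mixing metabolites and volatiles)
  induces within-module correlation.  The total within-group variance
  is held at σ² (default sd 0.5) for every analyte; cluster members
  split it as λ² = loading·σ² shared and (1−loading)·σ² residual, so
  `cluster_loading` (default 0.9) *is* the within-module residual
  correlation and planting a cluster never changes the noise any
  single analyte exhibits.  With the defaults, pooled within-module
  correlation is ≈ 0.98 — above the Holm gate — while the correlation
  induced among unrelated differential analytes by the shared
  treatment response is ≈ 0.8, below it.  Because an entire module
  rides one factor, a factor draw that happens to align with the
  treatment axis weakens (or strengthens) all of its members at once;
  dataset-level recovery is therefore heavier-tailed than independent
  analytes would suggest, and recovery statistics are quoted as means
  over ≥ 20 datasets.
* Volatiles add a detection model: measurements in an analyte's
  low-abundance half drop out with probability 0.1; 66 analytes are
  structurally heat-only and 11 control-only (forced non-detects in
  the other group, not low abundance); ~10 % extra contaminant
  analytes appear in all blanks and at the same level in every sample,
  half of them with recognisable artefact names for the exclusion
  list.
* C, N and P are planted with the study stoichiometry — control
  C:N:P of 14:3:1 (molar, P = 1) shifting to 24:6:1 under heat — with
  a tighter residual sd (0.15): elemental mass fractions are
  physiologically regulated, and this keeps ratios identifiable at
  n = 6.
* Observed values embed the inverse of each ladder (concentrations
  carry cells/dry-mass, peak areas carry cells and the
  internal-standard fluctuation), so the ladders recover the per-cell
  biology exactly; the cell-density difference between groups is a
  deliberate global confounder that only normalisation removes.

What the generator does **not** emulate: retention-time or spectral
structure, instrument drift, batch effects, heteroscedastic
analyte-specific noise, missingness in elements/metabolites, or the
two-water-bath nesting.  Passing recovery tests therefore demonstrate
that the statistical chain is correct under the declared model, not
that it is robust to real-data pathologies outside it.

Randomness derives from a single integer seed fanned out to
independent streams per table, so identical configurations reproduce
byte-identical CSVs.

Recovery is scored as: sensitivity over planted differential analytes
that were tested; false-discovery proportion counting calls outside
the planted differential and structurally unique sets; and the
adjusted Rand index between planted cluster labels and recovered
component labels over planted members (members absent from the network
count as singletons).

## Pipeline, sizes and runtimes

The orchestrated run (TOML config, single seed, strict key validation)
writes every intermediate table, result CSVs, graph exports, a summary
and a manifest; re-running a manifest's config reproduces all outputs
bit-for-bit.  Simulation-backed checks use these problem sizes: null
calibration at 500 datasets (40-analyte tables) for rejection rates,
500 datasets for PERMANOVA type-I error (199 permutations each), 100
null datasets at the study's network size (53 analytes) for
family-wise error of the gated network, and 20 full-pipeline datasets
at the default study shape for recovery; the full test suite completes
in a couple of minutes on one CPU.  Null calibration is measured on
normalised tables — raw tables contain the planted cell-density
confounder by design.

## Known limitations

* The exact Spearman null covers tie-free pairs only; heavy zero-ties
  among volatiles fall back to the t approximation and share its tail
  behaviour.
* Pooled-sample correlation cannot fully separate co-membership from
  co-response: two strongly responding but unrelated analytes have a
  rank correlation of ~0.75 by treatment separation alone, and with
  only 12 samples occasional spurious edges (or whole-factor
  alignments) survive the gate, merging clusters in a minority of
  datasets.
* PERMANOVA assumes exchangeable replicates (no water-bath strata).
* Per-group correlation (n = 6) is available behind a flag but has
  essentially no power under a family-wise gate and is not the
  default.
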