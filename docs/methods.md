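# Methods

## Quantitative profiling model

Sequencing observes a multinomial draw over genera with probabilities
proportional to (cells of genus j) × (16S copy number c_j): multi-copy
operons inflate a taxon's read share relative to its cell share. The
profiling stage inverts this bias — reads are divided by c_j and
renormalised — and then leaves the compositional simplex by rescaling
with the flow-cytometry total density (cells/g, mean of triplicates) and
with the weight of the luminal contents of the compartment:

    rel_j = (r_j / c_j) / Σ_k (r_k / c_k)
    cells/g_j = rel_j × density
    cells/compartment_j = cells/g_j × wet_weight

Whole-compartment load is used (rather than per gram) because diet also
changes the amount of luminal content; changes in content volume are
then reflected in total load. Wet weight defines "weight inside the
compartment" — contents are weighed wet, and the dry weight is retained
separately for water-content and flux computations. Feces carry no
content weight, so per-compartment load is undefined there and the load
operations reject fecal samples; fecal analyses stay per gram or
relative.

Zero-read taxa get absolute abundance exactly 0; no pseudocount enters
at the profiling stage, keeping detection limits explicit. Pseudocounts
appear only in fold-change computation, where they keep log ratios
finite. The default pseudocount is the smallest non-zero value of the
matrix being compared, which adapts automatically to the very different
scales of compartment loads (~1e9 cells) and relative fractions
(~1e-4); a fixed value can be configured. Taxa missing from the
copy-number table fall back to a configurable default of 1.0 (no
correction) with a logged warning, since reference databases do not
cover every genus.

## Differential abundance and artifact flags

For each intestinal compartment, the 50 genera with the highest mean
abundance (absolute scale, both diets pooled, ties broken
lexicographically) are compared between diets at day 7 on both scales:
L2FC = log2((mean_FFD + pc)/(mean_CD + pc)), with a two-sided two-sample
t-test per taxon and scale. Welch's unequal-variance test is the
default (robust to the heteroscedasticity that multiplicative noise
creates); Student's equal-variance form is available. Significance is
declared after Benjamini–Hochberg correction at α = 0.05 across the top
taxa of the compartment (Bonferroni optional); the correction used is
recorded in the report header.

Flags encode the compositional artifact: `relative_only_increase`
(significant relative increase without absolute significance — the
pseudo-bloom signature), `relative_only_decrease` symmetrically, and
`discordant_sign` when both scales are significant with opposite signs.
The underlying identity: if taxon j's absolute abundance distribution is
diet-invariant while total load scales by ρ < 1, then as n → ∞ its
relative L2FC → −log2 ρ and its absolute L2FC → 0.

## Diversity

Alpha diversity (observed richness, Shannon with natural log,
Gini–Simpson 1 − Σp²) is computed on counts rarefied without
replacement (multivariate hypergeometric) to a common depth, default
1763 reads, after discarding samples below 1000 reads; the rarefaction
seed is part of the pipeline configuration. The Gini–Simpson form is
reported because it is bounded on [0, 1]; Shannon uses the natural log,
matching the conventions of the vegan ecosystem. Beta diversity is
Bray–Curtis on unrarefied copy-number-corrected relative abundances
(the rarefy-before-beta choice is genuinely open; computing on relative
abundances uses all reads and is logged in the run manifest), ordinated
by PCoA (Gower double-centering, eigendecomposition; delegated to
scikit-bio). Bray–Curtis is a semimetric, so mildly negative PCoA
eigenvalues are expected and reported, not errors.

PERMANOVA is implemented in-package on the Gower-centered inner-product
matrix G = −½ J D² J: for nested hat matrices H_1 ⊂ H_2 ⊂ … (one per
factor, caller's order), sequential (Type I) sums of squares are
SS_k = tr(H_k G) − tr(H_{k−1} G), pseudo-F uses the full-model residual,
R²_k = SS_k / tr(G), and p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) under
sample-label permutation (default 999 permutations). For a single
factor this reproduces the classical within/among-group formulation
exactly (cross-checked against scikit-bio and against an exhaustive
enumeration oracle in the tests). Note the attainable minimum p is
limited by permutations that reproduce the observed grouping; with
small balanced groups (4+4) that floor is ≈ 0.03.

## Guild clustering and concordance

Taxon co-abundance guilds are found per compartment on absolute
abundances, diets pooled: distance 1 − Spearman ρ between taxon
profiles, Ward linkage (scipy's variance-increase criterion applied to
the condensed distance matrix; the variant is recorded in output
metadata), cluster count k chosen to maximise mean silhouette width
over k = 2…8. Constant taxon profiles have undefined correlations and
are dropped with a warning. Per-cluster totals (sum over member taxa
per sample) are compared between diets by t-test. Overall agreement of
taxon rankings is Kendall's W from midrank sums with the standard tie
correction, with the χ² = m(n−1)W approximation for significance.

## Tracer flux, stoichiometry, and expression

Mucus secretion is read out from ¹³C enrichment of washed luminal
biomass after intravenous ¹³C/¹⁵N-threonine injection (the
threonine-rich Muc2 domain incorporates the tracer). Atom fraction
excess is (atom% − baseline)/100, clamped at 0; the baseline is the
mean atom% ¹³C of the unlabeled-control animals when present, else the
natural-abundance constant 1.07 atom%. Secreted-carbon flux per
compartment is AFE × (%C/100) × dry weight of the compartment's
contents in mg (dry weight = measured dry content weight; the EA-IRMS
aliquot mass is carried but does not enter the flux). "Amount of ¹³C"
is read as excess over the unlabeled baseline — the control injections
only make sense under that reading. ¹⁵N values are carried in reports
but unused in the flux. C:N is the mass ratio %C/%N; water content is
100 × (wet − dry)/wet, clamped to [0, 100].

qPCR expression uses the 2^−ΔΔCt method: ΔCt = Ct(target) −
Ct(housekeeping) per sample (muc2 normalised to 36B4), ΔΔCt = mean
ΔCt(treatment) − mean ΔCt(reference), fold change 2^−ΔΔCt; the estimator
is invariant to plate-wide Ct offsets.

## Host-statistics workflow

Every endpoint runs through the same recipe: Shapiro–Wilk on the
residuals of the untransformed two-way OLS fit gates (at α = 0.05) a
single square-root retry (requiring non-negative data); Levene's test
in the median-centered Brown–Forsythe variant reports
homoscedasticity; the two-way ANOVA with interaction uses Type II sums
of squares, which equal the classical decomposition for balanced
designs and adjust each main effect for the other in unbalanced ones
(the study design is mildly unbalanced, 18 vs 20 mice). Per-factor R²
is the factor's share of total SS, matching "ANOVA, R² = …"-style
reporting; significant factors trigger pairwise Student's t-tests with
Bonferroni adjustment over the comparisons performed. A factor
collapsed to one level reduces the fit to a one-way ANOVA; an
all-constant endpoint yields zero SS and NA tests.

## Synthetic-study generator

The generator emulates the study design: two diets × 10 mice, stool at
days 0/2/7, terminal small intestine/cecum/colon at day 7, and a
tracer layer with 2 unlabeled-control mice per diet. Ground truth
(per-sample true loads, guild labels, closed-form L2FCs, expected
fluxes) is stored alongside the observables.

True per-gram loads are baseline_load × baseline_fraction, times an FFD
multiplier at days > 0: mucus-degrader multipliers are honoured exactly
(default 1.0, constant load) and the remaining taxa are rescaled by a
common factor so the FFD total equals diet_load_ratio × the CD total
exactly — hence the planted degrader's closed-form L2FCs (0 absolute,
−log2 ratio relative). Multiplicative lognormal noise enters as (i) a
per-mouse random effect (σ = 0.3) shared across a mouse's samples,
(ii) a latent factor per correlation block (σ = 0.4) — blocks are
"declining bulk" vs "constant degraders", giving guild clustering a
recoverable planted 2-partition — and (iii) per-taxon noise (σ = 0.2).
Observables add flow-cytometry triplicates (lognormal, CV 0.15 —
positive and right-skewed, as cell counts are), negative-binomial
library sizes (mean 50 000, dispersion 20, so the 1000-read filter has
work to do), and multinomial reads with probabilities ∝ load × copy
number. Content wet weights are lognormal per compartment; means are
diet-independent in the default scenario so the per-gram and
per-compartment load ratios coincide and the planted fold changes stay
closed-form (per-diet weight means are configurable for scenarios that
emulate the observed FFD weight reduction). None of the noise
magnitudes is reported by the source study; they are stated assumptions
chosen as realistic for flow cytometry and amplicon libraries, and all
are exposed in the scenario YAML.

The default `cecum_collapse` scenario: 50 genera with abundance ∝
1/rank, 31 fiber-responsive taxa (multipliers 0.08–0.16), 4 constant
mucus degraders (*Akkermansia*, *Faecalibaculum*, unclassified
*Bacteroidales*, *Desulfovibrio*), 15 neutral passengers (multiplier
0.2, rescaled with the bulk), total FFD load 20 % of CD, identical
baseline fractions across compartments (a simplification; real
compartments differ). Tracer parameters plant lower ¹³C excess and %C
under FFD, so expected FFD flux < CD flux.

What the generator does *not* emulate: sequencing error and chimeras,
strain-level dynamics, time-resolved population dynamics,
compartment-specific community composition, and taxon-taxon
interactions beyond the two-block correlation structure. Passing tests
therefore demonstrate correctness of the pipeline's algebra and
statistical behaviour under the stated noise model, not performance on
real amplicon data.

## Problem sizes and numerical choices

Acceptance-style checks run the full scenario over 20 seeds (≈ 8 s);
null calibrations use 500 PERMANOVA simulations × 999 permutations and
1000 ANOVA simulations (≈ 25 s together); these sizes give Monte-Carlo
standard errors of ~0.01 on rejection rates, well inside the ±0.02
assertion bands. Ties in top-k selection break lexicographically;
rarefaction at exactly the library size returns the sample unchanged;
an all-zero sample is representable but rejected by diversity and
correction operations with explicit errors. Floating-point TSV output
uses 12 significant digits, enough for bit-stable round trips of
integer counts and ~1e-12 relative round trips of reals.

## Known limitations

- Flow-cytometry densities and 16S loads are treated as the same
  currency; real QMP must reconcile cell counts with sequenceable cells.
- The pipeline consumes genus-level tables; ASV inference, taxonomy
  assignment, and FCS gating are upstream and out of scope.
- PERMANOVA permutes labels freely; restricted permutation schemes
  (e.g. within-mouse) are not implemented, and repeated stool samples
  from the same mouse are treated as exchangeable, as are the day-2/7
  repeated measures in the ANOVA battery.
- The mucus-degrader guild is planted as exactly constant; biological
  "constancy" is noisier, so real flag rates will be lower than the
  generator's.
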