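# Methods

## The measurement model

The package simulates two complementary readouts of promoter CpG
methylation in tissue DNA and the diagnostic statistics built on them.

**Coordinates and census.** A promoter window is held on the sense strand
in 1-based coordinates of its source record, with a declared TSS. CpG
dinucleotides are numbered by signed ordinals in 5′→3′ order: sites whose C
precedes the TSS count down to −1, sites at or after the TSS count up from
+1, and 0 is never used. A CpG whose C coincides with the TSS gets +1
("at/after the TSS is positive"). Numbering is ordinal over detected sites,
not base-pair distance. The census splits at a TSS-relative nucleotide
boundary (default −48): a site is 5′ iff its C lies strictly upstream of
`tss + boundary`. The bundled synthetic reference reproduces the geometry
the analysis needs — 32 CpGs (−28…+4) over a 389-nt core, 21/11 at −48 —
and extends 3′ by three more CpGs (+5…+7) because the 3′ MSP reverse primer
reaches past the sequenced core; the extension bounds are a package choice
(the assay definition fixes which sites must exist, not where the window
must end). Background bases are generated deterministically with no
accidental CpG and with non-CpG C/G on both strands so conversion QC is
well defined on either strand.

**Bisulfite chemistry.** Per strand: a CpG cytosine survives conversion iff
that strand of the molecule is methylated at the site; every non-CpG
cytosine converts to thymine independently with probability `efficiency`
(deterministic at 1.0). By default unmethylated CpG cytosines always
convert, isolating the QC statistic from methylation state; a
`cpg_retention` flag also subjects them to incomplete conversion for users
who want that failure mode. The QC statistic is the fraction of non-CpG
reference cytosines read as T; samples pass QC iff the rate is strictly
above 0.95. A strand with zero non-CpG cytosines has an undefined rate and
is reported as a pass with a warning.

**Pooled sequencing.** The chromatogram model reduces a sample to the
molecule-mean methylated fraction per site and strand, plus additive
Gaussian noise (sd 0.02, clipped to [0, 1]) standing in for peak-height
measurement error. Sense calls: NONE below the 0.10 detection limit, LOW
from 0.10 to 0.50 inclusive, HIGH above 0.50. The boundary placements
follow the assay validation: 10% mixtures are detected (so exactly 0.10 is
LOW) and "50% or less" is LOW. The antisense read saturates — C peaks
dominate already at 10% methylated template — so it is modelled as a
two-level DETECTED/UNDETECTED call at the same limit rather than a
different threshold, since no saturation curve is available. The
reconstitution verdict is taken at sample level (the highest call across
census sites): at a per-site fraction sitting exactly on the detection
limit, any single site is a coin flip against noise, while the sample-level
verdict is what "consistently detects 10% methylated DNA" describes and is
stable across ≥99% of replicates.

**Block summaries.** Category percentages (none/low/high) are computed over
site × sample units per tissue class and block; the per-sample detected
fraction is the share of sites called LOW or HIGH, summarised as mean ± SD
(ddof 1). Group contrasts use the pooled-variance (Student's) two-sided t
test; with zero pooled variance the convention is p = 1 for equal means and
p = 0 otherwise.

**MSP.** An assay is a set of covered CpG site numbers (forward primer,
optional hydrolysis probe, reverse primer) on a stated strand. The
chemistry difference between the bundled assays is represented purely by
whether probe sites join the covered set: the 5′ MethyLight assay requires
11 jointly methylated sites, the 3′ dye-based assay 7. A molecule is
positive iff every covered site is methylated on the assayed strand,
optionally flipped with a per-molecule mispriming probability (default 0).
Quantification draws 300 molecules per reaction with replacement
(aliquoting from abundant extract; input normalisation to 300 copies is
taken as given), in duplicate, and averages before thresholding. The
10-copy cutoff is inclusive — it is the limit of quantification, and the
published wording does not resolve strictness — and is configurable;
readings below it are "not detectable".

**Diagnostics.** Sensitivity = % cases at/above the cutoff, specificity =
% controls below it, each with a Wilson 95% CI. AUROC is the Mann–Whitney
probability with ties credited ½ (computed by scikit-learn; tests verify
the identity against brute-force pairwise counting). Fisher's exact test
is two-sided by the point-probability rule (scipy; verified against
exhaustive hypergeometric enumeration) — documented because tail-doubling
alternatives differ. Kruskal–Wallis is tie-corrected with an optional
merge map applied first (small stage/grade groups pooled). The two-marker
rule is positive iff AFP > 20 ng/mL or the MSP call is positive; cases
without an AFP value are excluded from combination analyses and logged.
Specificity can be computed against two control sets
(hepatitis+cirrhosis, with or without adjacent non-tumour tissue).

## The synthetic cohort generator

The generator is the study-condition stand-in for patient material, which
was never deposited. Methylation of each molecule follows a two-level
mixture per block: the molecule carries block methylation with probability
`f_meth`, and a carrier is methylated at each site with probability
`p_site`, symmetrically on both strands except that a methylated site is
hemimethylated (one random strand cleared) with probability `sym_error`
(default 0.05, "mostly symmetrical with rare nonsymmetrical sites"). The
two levels let molecule-level co-methylation density — what MSP
interrogates — vary independently of the per-site marginal
`f_meth · p_site` that pooled sequencing sees.

Default parameters are synthetic; only their ordering structure is
constrained by the biology being emulated:

| class | 5′ f_meth / p_site | 3′ f_meth / p_site |
|---|---|---|
| normal liver | 0.03 / 0.30 | 0.80 / 0.80 |
| hepatitis | 0.03 / 0.30 | 0.45 / 0.70 |
| cirrhosis | 0.04 / 0.30 | 0.20 / 0.70 |
| adjacent non-HCC | 0.25 / 0.60 | 0.50 / 0.75 |
| HCC | 0.45 / 0.80 | 0.50 / 0.85 |
| fetal liver, non-liver | 0 / 0 | 0 / 0 |

i.e. 3′ methylation in every adult liver-lineage class and in no other
tissue; 5′ density ordered HCC > adjacent non-HCC ≫ the benign liver
classes.

Sample-to-sample heterogeneity: `generate_sample` draws each sample's
carrier fraction from a Beta distribution with mean `f_meth` and
concentration `sample_dispersion` (default 8). Without it, every sample of
a class would be statistically identical and MSP positivity would be
all-or-nothing per class, contradicting the large per-class SDs of the
published block summaries. Molecule-level draws (`generate_molecule`)
bypass the dispersion so that per-site marginals are exactly binomial
around `f_meth · p_site · (1 − sym_error/2)`, which is what the
parameter-recovery check asserts.

Serum AFP for HCC cases is log-normal with log-sd 2.2 and log-mean chosen
so that P(AFP < 20 ng/mL) ≈ 0.54, matching the observed AFP-negative share;
AFP is independent of methylation state (no significant association was
observed in the source material). Clinicopathological attributes (stage,
grade, viral status) are drawn from the published frequency tables and are
decorative for stratified rank tests.

What the generator does **not** emulate: tumour purity and cellular
deconvolution, copy-number effects, PCR amplification bias and
amplification-curve shape, primer thermodynamics, chromatogram basecalling,
correlated co-methylation beyond the single carrier level, and any
AFP–methylation dependence. Passing tests therefore show internal
consistency of the measurement and decision rules under a plausible
molecular model — not real-data performance; the published patient-level
AUROCs (0.760/0.775) and specificities are treated as context, not
reproduction targets.

## Published-tally fixtures

`reproduce-printed` recomputes summary statistics from count fixtures
(`data/printed_counts.yaml`) through the same diagnostics code as the
simulated pipeline: the AFP/MSP quadrant tallies of 115 HCC cases (the
split of the 53 AFP-positive cases into 24 MSP+ / 29 MSP− is a
reconstruction — it assumes all 45 MSP-positive cases had a known AFP — and
none of the reported marginals depend on it), the 45/120 and 4/120
positivity counts, and the 2×2 control table implied by specificities of
97.1% vs 60% on 70 controls each. Per-case values expanded from counts are
synthetic placeholders kept away from every threshold. One rounding note:
21/62 = 33.87%, which rounds to 33.9 at one decimal although the source
printed 33.8.

## Numerics, sizes, determinism

Every stochastic function takes a `numpy.random.Generator`; the pipeline
derives one generator per stage from the run seed, so each stage is
idempotent given the seed and the full run is byte-identical across
repeats. Default problem sizes — 190-sample cohorts at 300 molecules per
sample for the pipeline, 500 samples for the specificity-contrast check,
200 reconstitution replicates, 20 000 molecules for enumeration
cross-checks — were chosen so every check runs in seconds while keeping
Monte-Carlo error well inside the asserted bounds (binomial SEs at these
sizes are ≲ 1 percentage point). Chromatogram noise is truncated by
clipping rather than renormalised; the induced bias at interior fractions
is < 0.005 and is immaterial to calls at the 0.10/0.50 boundaries.

## Known limitations

- The sample-level reconstitution verdict assumes every census site shares
  the pool's methylated fraction; real standards can have site-to-site
  variation in conversion and amplification.
- Conversion failures are independent per cytosine; real incomplete
  conversion is often clustered per molecule.
- The aliquoting model samples with replacement, appropriate when the
  extract holds many more than 300 genome equivalents.
- Ordinal site numbering means censuses from different windows of the same
  locus agree only if their upstream site counts match.
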