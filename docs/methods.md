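# Methods

## Peptide mass model

Neutral monoisotopic masses are additive: Σ residue masses (pyteomics
`std_aa_mass`, five-decimal monoisotopic values) + one water
(18.0105647 Da) + modification deltas + label deltas.  The heavy label
models a ¹³C₆,¹⁵N₄-arginine internal standard: every arginine gains
6 × 1.0033548 + 4 × 0.9970349 = 10.0083 Da.  Carbamidomethylation
(+57.02146 Da) is applied as a residue rule on cysteine.  Ions are
protonated at 1.00728 Da per charge; y-ions are the C-terminal *i*
residues plus water, b-ions the N-terminal *i* residues.  Only y/b
series are supported — the built-in assay uses y-ions exclusively — and
no average-mass mode or neutral losses.

Display rounding is half-up to one decimal (the convention under which
all printed assay transition values are reproduced); internal arithmetic
stays at full precision.  For the LTCQGNAQWDGPEPR + carbamidomethyl
neutral mass the additive sum is 1727.7686 Da; printed one-decimal m/z
values are insensitive to the third decimal.

## Chromatogram and matrix simulation

Each transition trace is a Gaussian peak centred at the peptide's
retention time; light and heavy channels co-elute by construction.  The
integrated area is concentration × response factor × relative fragment
intensity, multiplied by mean-one log-normal noise of configurable CV
(`area_cv`) — the standard multiplicative error behaviour of peak
areas — with an optional additive Gaussian baseline, clipped at zero.
Calibration series follow the assay design: a 1:2 serial dilution
(default top 1000 fmol/μL, 11 points — the stated 1 pmol/μL → 0.5
fmol/μL 11-point ladder is arithmetically inconsistent, so both
parameters are explicit — bottom ≈ 0.977 fmol/μL), constant 50 fmol/μL
heavy spike, triplicate, plus a heavy-only zero calibrator and a solvent
blank used for carryover checks only, never in the fit.

Abundance matrices are log2-normal: per-protein baselines N(20, 2²),
residual noise σ = 0.3 (log2), defaults mirroring the plasma design of
8 knockout vs 10 wild-type samples and 2000 proteins with a 10% DE
fraction at |log2FC| = 1.5, random sign.  Batch structure is
piecewise-constant over equal-sized consecutive run-order blocks
(default 3 blocks, offsets N(0, 0.2²) log2, shared across proteins —
i.e. rank-one, which acquisition-drift offsets approximately are).
Zeros arise by left-censoring below a linear-intensity threshold
(default 1e5 ≈ 2^16.6, giving ~4% zeros), tying missingness to low
abundance as the imputation rule assumes.  Age (8–14 weeks) and sex are
drawn per sample with optional per-protein covariate slopes (default 0).

What the generators do **not** emulate: peptide-level interference and
chromatographic drift between runs, correlated protein co-regulation,
heavy-tailed intensity error, non-rank-one batch structure, and
missingness not explained by abundance.  Passing tests therefore show
the pipeline is correct under its own model assumptions and calibrated
under the stated noise; they do not certify performance on any
particular instrument's output.

## Quantitation and validation

Peaks are integrated by the trapezoid rule over apex ± 3σ (σ from the
half-maximum width of the summed heavy channels; the same window is
applied to light so the ratio is unaffected by window choice), with
optional constant or edge-estimated baseline subtraction and negative
areas clipped to zero.  Light and heavy apexes further apart than
0.05 min raise a co-elution warning.  Calibration is weighted least
squares with 1/x weights (x = nominal concentration) because the ladder
spans three orders of magnitude; unweighted fitting is available.
Back-calculated concentrations below zero report 0 with a below-range
flag.  Validation pools back-calculated replicates per level across
analyses: %CV = sd/mean·100 (undefined, hence unevaluable, for a single
replicate), %RE = (mean − nominal)/nominal·100, pass at ≤ 15 / ≤ 15, and
the LOD is operationalised as the lowest passing calibrator.  The
validation is applied to back-calculated concentrations (the %RE
definition requires them), not raw ratios.  The rdotp "near the LOD"
relaxation (0.8 instead of 0.9) applies when the back-calculated
concentration is within 2× LOD.  The per-protein conversion is
concentration × reconstitution volume, default 30 μL per 100 μg digest —
the unique volume consistent with both published concentration/amount
pairs (228/7.6 = 405/13.5 = 30) — exposed and logged as a parameter.

The Wilcoxon rank-sum comparison uses exact enumeration when the
combined sample is ≤ 12 without ties, otherwise the tie-corrected normal
approximation (scipy's implementation; validated against full
enumeration up to 4 + 4 in the tests).

## Differential-expression model

Stage order: top-3 roll-up (the three peptides with the highest mean
intensity across samples, fixed per protein so every sample sums the
same peptides) → filtering → imputation → TMM → batch removal →
precision weights → moderated test.  Each stage logs its input/output
dimensions.

*Filtering.*  A protein is dropped when its mean intensity is ≤ 0 in
**every** condition — dropping proteins absent in only one genotype
would delete exactly the biology a knockout comparison seeks — or when
it is near-zero-variance: most frequent value covering ≥ 90% of samples
and a most-frequent / second-most-frequent count ratio above 95/5.  Both
parameters are configurable.

*Imputation.*  Each zero becomes half the smallest non-zero value of its
own protein row.  Resolving the "next non-zero value" within the protein
makes the result invariant to sample ordering; a column-order-dependent
rule would not be reproducible.

*TMM.*  Per sample, the precision-weighted mean of log2 ratios against a
reference sample (upper quartile closest to the mean upper quartile),
after two-sided rank trimming of 30% of M-values and 5% of A-values per
tail, with delta-method inverse-variance weights — the edgeR convention,
against which the implementation is cross-checked.  Factors are
geometric-mean-1; the effective per-sample divisor (library size × TMM
factor, rescaled to geometric mean 1) preserves the overall intensity
scale.

*Batch removal.*  On the log2 matrix, condition means are set aside,
batch means of the remainder are computed, and the principal components
of that batch-mean submatrix explaining ≥ 95% (configurable) of its
variance are subtracted — the batch-known variant of ANOVA
simultaneous-component correction.  Condition means are untouched by
construction up to design imbalance.  A second residual-filtering stage
is deliberately not applied by default: removing 95% of *residual*
variance would strip biological signal.  Designs in which every batch
contains a single condition are rejected as confounded.  Batch blocks
default to equal-sized consecutive run-order groups (block count
configurable) since acquisition-order drift is the effect being
modelled.

*Precision weights.*  Intensities are treated as count-like:
y = log2((x + 0.5)/(lib + 1)·10⁶) with column totals as library sizes —
the count-oriented transformation the workflow applies to proteomic
intensities.  Square-root residual SDs from a preliminary fit are
lowess-smoothed (span 0.5) against mean log intensity; each
observation's weight is trend⁻⁴ at its fitted log-intensity, with
constant extrapolation beyond the trend range.  Weights are computed
after batch removal, on the corrected matrix.

*Moderated test.*  Per-protein weighted least squares on genotype with
age and sex covariates; empirical-Bayes hyperparameters (d₀, s₀²) by
moment matching on log residual variances (digamma/trigamma moments,
trigamma inverted by Newton iteration); posterior variance
s̃² = (d₀s₀² + d·s²)/(d₀ + d); t = β/(SE_unscaled·s̃) on d₀ + d degrees
of freedom.  d₀ = 0 reduces to the ordinary t; d₀ = ∞ pools completely.
Robust hyperparameter estimation is not used.  BH adjustment is the
standard step-up; calls are strict: adjusted p < 0.05 **and** linear
|FC| > 1.5.

*Enrichment.*  Upper-tail hypergeometric p = P(X ≥ k) on a universe
defaulting to the quantified proteins (a detection-matched background,
standard for proteomic over-representation); one-sided only.
"% members" uses the dysregulated-set size as denominator.  Tissues are
analysed separately; cross-tissue overlap is pure set counting.

## Numerical and degenerate-input choices

- Calibration requires ≥ 2 distinct non-zero levels; a zero heavy-area
  sum raises a distinct no-internal-standard error; an all-zero rdotp
  vector raises rather than returning a low score.
- Zero-slope curves cannot be inverted (error), matrix columns with
  non-positive entries are rejected by TMM/batch/PCA (imputation must
  precede), and residual all-zero rows are rejected by the imputer with
  a pointer to filtering.
- Aliased designs are rejected before fitting; rank-deficient per-protein
  fits yield NA.
- PCA operates on centred (optionally unit-variance) log2 intensities
  with a full SVD solver.

## Problem sizes in the validation studies

The seeded studies in `tandemquant.studies` use: 5 analyses × 11 levels
× triplicate chromatograms for calibration precision; 50 null runs of
1000 proteins and one planted-DE run of 2000 proteins on the 8-vs-10
design for the operating characteristics; 500 proteins × 18 samples for
the batch-removal study.  These sizes give Monte-Carlo error well below
the margins being tested while keeping each study in the seconds-to-
minutes range.

## Known limitations

- The moderated test assumes the scaled-F variance model; heavy-tailed
  variance outliers would call for the robust variant, which is not
  implemented.
- Batch correction assumes batch effects are low-rank across proteins;
  fully protein-specific batch noise is attenuated only insofar as it
  loads on the leading components.
- The voom trend is interpolated piecewise-linearly from the lowess fit,
  so weights differ from limma's in the fourth decimal; the cross-check
  test bounds the discrepancy.
- The LOD estimator (lowest passing calibrator) is a software
  operationalisation; instrument-reported detection limits estimated
  from signal-to-noise will differ.
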