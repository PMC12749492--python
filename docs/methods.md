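# Methods

This note records the models implemented in `forelandeco`, their
assumptions, the defaults that matter, and the design choices made where
the methodology was genuinely open.

## Habitat specialisation index

The SI of a taxon is the coefficient of variation of its relative
abundance across a sample set: sample standard deviation (n−1
denominator, chosen for the small-n designs the package targets — nine
topsoils per foreland is typical) divided by the mean. The ratio is
sd/mean, not the inverse: only this direction is consistent with
classifying low-variance, evenly occupying taxa as generalists *below*
the first quartile. Quartiles use linear interpolation between order
statistics (the convention of common statistical environments) and are
recorded in every output table so classifications are auditable. Ties sit
exactly on a threshold are intermediate (strict inequalities). Taxa with
zero mean abundance — and, for amplicon-style tables, taxa under an
optional abundance floor (default 0.005 % mean relative abundance,
applied at whatever taxonomic level the input table carries) — are
flagged absent and excluded from classification rather than silently
dropped. Classification refuses fewer than eight taxa, below which
quartiles are unstable.

Consequence of the quartile rule: at most ~25 % of taxa can be labelled
generalist, so *recall* against planted guilds is only meaningful when
generalists are planted at about a quarter of taxa; against arbitrary
plantings the package reports precision of the assigned labels as the
recovery metric.

## Zeta diversity

ζ<sub>i</sub> is the mean, over combinations of i sites, of the number of
taxa present in all of them; Jaccard normalisation divides each
combination's intersection by its union (empty union contributes 0).
Combinations are enumerated exhaustively up to a cap (100 000) and
otherwise sampled uniformly without replacement within a draw, with
replacement across draws (default 1 000 draws, seeded). Raw ζ₁ equals
mean site richness exactly, and raw ζ is non-increasing in order on any
exhaustive evaluation.

Decline fitting regresses ln ζ on i (exponential) and on ln i (power
law) by OLS, dropping zero ζ values with a warning; AIC uses the full
Gaussian likelihood with maximum-likelihood variance and k = 3 for both
models, making the comparison a pure fit contest; |ΔAIC| < 2 is flagged
indistinguishable. Distance decay regresses per-combination Jaccard ζ on
the mean pairwise haversine distance (sphere radius 6371.0088 km; a
planar flag exists for projected coordinates) by OLS — the regression
family inside the reference R tooling is not documented, and linear OLS
is the declared stand-in. Variation partitioning is deliberately a
simplification of multi-site generalised dissimilarity modelling: the
response is pairwise (order 2) Jaccard ζ, predictors are absolute
between-site differences of environment variables, and the pure/shared/
unexplained fractions come from adjusted R² of the two marginal and the
full linear models. Adjusted R² counts predictors by design-matrix rank,
so shared variance between the two groups (up to exact copies) is
handled; a group that is *internally* collinear is rejected with a
pointer to the collinearity pre-filter (iterative removal of the
lower-priority member of any pair with |Pearson r| ≥ 0.9). Negative
fractions are floored at zero and renormalised, with raw values retained.

## Marker-gene profiling

Hit tables are BLAST/DIAMOND outfmt-6 rows with appended query and
subject coverage. Read mode retains hits with query coverage ≥ 80 % and
per-family identity thresholds (default 50 %; relaxed to 40 % for *rho*;
60 % for *nuoF*, group-4 [NiFe]- and [FeFe]-hydrogenases, *mmoX*,
*coxL*, *amoA*, *nxrA*, *rbcL*; 70 % for *psbA*, *isoA*, *atpA*, *aro*,
*ygfK*; 75 % for *hbsT*; 80 % for *psaA*). MAG-protein mode retains hits
at least 40 aa long *or* with ≥ 80 % query or subject coverage, with
identity overrides *atpA* 60, *psbA* 60, *rdhA* 45, *cyc2* 35, *rho* 30.
Unlisted families take the defaults. Best-hit-per-query resolution (by
bitscore, deterministic tie-break) precedes thresholding so counts are
well defined, and filtering is idempotent.

RPKM treats the reference length as mean protein length × 3 nt — the
length convention is a config knob since databases document protein
lengths — and counts single reads. The per-organism normaliser is the
mean RPKM of manifest-flagged universal single-copy ribosomal protein
families (15 in the default manifest; the set is manifest-driven).
`percent_of_cells` is deliberately uncapped: values above 100 % flag
multi-copy genes. MAG signature-gene counts divide by the completeness
fraction, estimating content of the complete genome.

## Rates, fluxes and qPCR

Microcosm headspace series are fitted with the pure first-order model
(log-linear OLS on ln c) and the asymptotic model
c(t) = c∞ + (c₀−c∞)e^(−kt) (nonlinear least squares, c∞ ≥ 0), selected
by AIC (Gaussian residual likelihood; small-sample AICc behind a flag
since n is typically 5–9). Heat-killed controls are subtracted at the
rate-constant level; negative net rates are floored at zero and flagged
rather than reported. The oxidation rate at atmospheric concentration is
k × (headspace moles of the gas at its atmospheric mixing ratio, ideal
gas law) per g dry soil — a normalisation at the atmospheric working
point rather than at the fitted initial concentration. Dry mass is wet
mass × (1 − gravimetric moisture); if moisture is missing, wet mass is
used with a warning. Constants are centralised:
R = 8.31446 J mol⁻¹ K⁻¹, 1 atm = 101 325 Pa.

Chamber fluxes use the nine-point, 90-minute schedule (four samples in
the first ten minutes, then increasingly long intervals); linear and
saturating-exponential models are AIC-selected and the chosen model's
slope at t = 0 is converted with the molar density of air and the
chamber's effective height (volume/area); sign is preserved (negative =
uptake). Nutrient slurry rates follow the same linear-vs-exponential AIC
choice with the initial slope signed so accumulation is positive. qPCR
requires ≥ 4 standard dilutions spanning ≥ 3 decades, averages replicate
Cp first, rejects non-negative slopes, flags unknowns outside the
standard range as extrapolations, and reports efficiency
(10^(−1/slope) − 1) × 100.

## Bioenergetics

ΔG = ΔG° + RT ln Q with gas-phase activities p/p° (p° = 1 atm), liquid
water at activity 1. ΔG° values are derived from standard Gibbs
formation energies (kJ mol⁻¹: H₂O(l) −237.14, CO −137.17, CO₂ −394.39,
CH₄ −50.5), giving −237.1 (H₂ + ½O₂ → H₂O), −257.2 (CO + ½O₂ → CO₂) and
−818.2 (CH₄ + 2O₂ → CO₂ + 2H₂O) — configuration data, not magic numbers
in logic. Default co-reactant activities: O₂ 0.209 atm, CO₂ 420 ppmv.
No enthalpy-based temperature correction of ΔG° is applied; all three
oxidations remain exergonic across the plausible soil grid (270–310 K,
10⁻³–10 ppmv), asserted by a grid-scan test. Power per cell is
rate (mol g⁻¹ s⁻¹) × |ΔG| (J mol⁻¹) / oxidiser cells per g, with the
oxidiser count = total 16S rRNA gene copies (no per-genome copy-number
correction — a documented limitation) × min(gene copies per organism, 1),
since a cell with at least one copy is one oxidiser. The maintenance
window used for classification is 10⁻¹⁷–10⁻¹² W cell⁻¹.

## Synthetic chronosequence generator

The generator emulates the two-foreland design: Antarctic classes
<5 / ~10 / ~21 yr with three topsoil sites each; Swiss classes 0–7 /
8–27 / 28–57 / 58–127 yr with 15 topsoils (and optional 10-cm depth
intervals to 50 cm). Sites are laid out along a transect with older
classes further from the glacier front, and carry age-correlated
physicochemistry (pH falling, carbon rising, sulfur falling with age)
for the variation-partitioning stage.

Communities are multinomial draws (default 10⁵ reads per sample — the
read depth is a free parameter, as typical amplicon depths are) from
expected relative abundances built as planted mean × guild trend ×
lognormal noise calibrated so the noise CV equals the taxon's target CV.
Early opportunists decline and late specialists rise geometrically
across age classes; the default young:old fold in the end-to-end
evaluation is 20, consistent with observed opportunist declines from
~2 % of the community to under 0.1 % and ~17-fold shifts in
specialist-associated activities over such chronosequences. Negative
simulated concentrations anywhere in the generator are truncated at zero
(detector floor), not resampled. One integer seed drives named
sub-streams (`stream(seed, name)`), so adding a stage never perturbs
another stage's draws and every table is byte-for-byte reproducible.

Two incidence generators encode the assembly-model contrast: independent
placement (presence with probability p — expected ζ<sub>i</sub> = S·pⁱ,
an exact exponential decline) and contiguous niche ranges with widths
uniform on 1..max_width (at full width expected ζ<sub>i</sub> ∝
C(n+1, i+1)/C(n, i) ≈ 1/(i+1), a power law). Narrow ranges
(max_width ≈ n/2) leave four-way ζ near zero everywhere so the pairwise
distance-decay coefficient is the steeper one, mirroring the
empirically observed ordering.

What the generator does *not* emulate: real rank-abundance tails
(thousands of rare ASVs), spatial autocorrelation beyond the single
transect axis, compositional covariance between taxa, PCR/sequencing
bias, or depth-dependent community shifts. Passing tests therefore
demonstrate correctness of the estimators under the planted model, not
robustness to every property of field data.

## Problem sizes and tolerances

Simulation-calibrated checks use: 200 seeds for decline model selection
(10 sites × 50 taxa, exhaustive combinations), 100 seeds for kinetics
(five points over 24 h, noise sd 0.01 ppmv) and chamber flux (nine
points, noise sd 0.005 ppmv) recovery, 10⁶ reads for marker-carrier
recovery (tolerance three Poisson sigmas of the filtered hit count), and
the 15-topsoil Swiss layout at 10⁵ reads for the end-to-end
classification. Monte-Carlo zeta is validated against exhaustive
enumeration within three standard errors. Nonlinear fits fall back to
the log-linear model with a warning when they fail to converge;
degenerate inputs (all-zero samples, co-located sites, constant
predictors, invalid standard curves) raise errors naming the offender.
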