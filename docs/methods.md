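# Methods

## Melting-curve model

Each protein-condition curve is the reference-normalized soluble fraction
FC(T) at the ten gradient temperatures, modelled as

    f(T) = (1 − p) / (1 + exp(b − a/T)) + p,    T in °C

with a > 0 (°C-scaled shape), b > 0 (dimensionless offset) and plateau
p ∈ [0, 0.49] (asymptotic soluble fraction at high temperature, capturing
incomplete aggregation). The model describes irreversible thermal
aggregation as read out by TPP; no reversible two-state thermodynamics
(ΔG, van 't Hoff) is implied, and temperatures enter in °C. The melting
point is the closed form Tm = a / (b + ln(1 − 2p)), defined when p < 1/2
and b + ln(1 − 2p) > 0; it satisfies f(Tm) = 1/2 exactly and is verified
against a bisection oracle in the tests. The reported slope is the analytic
df/dT at T = Tm, −(1/2)(1/2 − p)a/((1 − p)Tm²). Defining the slope at Tm
rather than at the curve's true inflection in T is a deliberate convention:
the two points differ slightly for this parameterization, but the
Tm-evaluated slope is simpler, monotone-related, and directly tied to the
quantity the QC thresholds govern.

### Fitting

Bounded trust-region least squares (scipy `least_squares`, bounds a > 0,
b ∈ (0, 500], p ∈ [0, 0.49], relative tolerance 1e−8, ≤ 5000 function
evaluations) on the finite fold changes; at least 5 finite points are
required, otherwise a non-converged fit with NaN summaries is returned —
fitting never raises mid-pipeline. The deterministic start takes p₀ from
the curve floor (clipped to [0, 0.3]), Tm₀ as the temperature whose fold
change is nearest 0.5, b₀ = 10 and a₀ = b₀·Tm₀. If that start fails to
converge, or converges with R² < 0.8, a fallback multi-start is run: a
closed-form logit-linear estimate (regressing ln(1/FC − 1) on 1/T through
the transition points, which lands near the truth even for very steep
curves with b ≈ 25–60 where the b₀ = 10 start can stall in a shallow local
optimum) plus a 3×3 grid over b₀ ∈ {5, 10, 15} × p₀ ∈ {0, 0.1, 0.2}, keeping
the lowest-residual converged solution. R² is 1 − SSres/SStot on the fold
changes.

### Stringency QC

A (control, treatment) fit pair is analyzable when both fits converged with
a defined Tm, both R² ≥ 0.8, the control plateau is < 0.3, and both slopes
are ≤ −0.06 /°C. These three thresholds are the "highest stringency"
defaults and are exposed as configuration (`QCCriteria`) because different
instruments and gradients warrant different cuts. The plateau criterion
applies to the control curve (a treatment may legitimately raise the
plateau; the control must still melt essentially completely). Failing
proteins are retained in `fits.tsv` / `excluded.tsv` with reason codes
(`r2`, `plateau`, `slope`, `converged`, `no_reference`) rather than
silently dropped.

## Stability calling

ΔTm = Tm(treatment) − Tm(control), positive = stabilized. Within each
treatment, ΔTm values of all QC-passing proteins are standardized with the
sample (n−1) standard deviation; the per-treatment population matches how
the per-column z-score heat map of such experiments is built, and the
sample sd is pinned so tests are exact at small n. Calls use |z| ≥ 1.96
(two-sided 5% normal quantile), boundary inclusive. Because standardization
is within-treatment, the rule detects *relative* shifts: adding a constant
to every ΔTm in a treatment changes no call (a property test). No
multiple-testing correction is applied by default, mirroring the plain
z-threshold rule; Benjamini–Hochberg machinery exists in
`feature_analysis` and can be applied to call p-values by a caller who
wants it. Concordance summaries count, per protein, the crowders with
significant calls and label direction profiles all-stabilized /
all-destabilized / mixed.

## Dataset QC analytics

Spearman matrices are pairwise-complete with average-rank ties and need ≥ 3
shared observations per pair. PCA treats samples as observations and
proteins as variables, complete-case (rows with any missing value dropped,
no imputation), via SVD of the column-centered matrix; component signs are
fixed by making the largest-magnitude loading positive, so outputs are
deterministic. Expression comparisons between conditions use the
lowest-temperature channel as the abundance proxy (configurable to an
LFQ-style column). Mann–Whitney comparisons use exact enumeration for
tie-free samples with n ≤ 8 and the tie-corrected normal approximation
otherwise. Aggregation profiles report the per-temperature mean of
1 − FC clipped to [0, 1], with the unclipped mean alongside so
over-recovery is visible rather than hidden.

## Mechanism regressions

Per-crowder stability summaries are computed over the common set of
proteins passing QC in *every* condition, so crowders are compared on
identical support. Three summary modes (mean Tm, mean ΔTm, median ΔTm) are
exported side by side because "the melting temperature per crowder" admits
all three readings; mean Tm is the default. Each summary is regressed (OLS)
on each numeric reagent descriptor — molecular weight, intrinsic viscosity,
polar atom fraction, hydrophobicity index, and any extra numeric column in
the property table — reporting slope, R² (identically the squared Pearson
correlation), n, and a small-sample caveat flag (n < 10; with six crowders
every regression carries it). Descriptor values are user-supplied via a
documented TSV template; no defaults are invented. Under the
preferential-exclusion model the surface-chemistry descriptors (polar atom
fraction, hydrophobicity) should carry the correlation; under a
crowding/viscosity model, size and viscosity should.

## Feature analysis

GRAVY uses the Kyte–Doolittle scale and protein mass the ExPASy average
(or monoisotopic) residue masses plus one water, both embedded as data
tables and cross-checked against Biopython's ProtParam in the tests.
Keyword enrichment is a self-contained Fisher exact test (two-sided) on the
2×2 table (in/out of foreground × has/lacks keyword) with
Benjamini–Hochberg q-values across tested keywords; keywords absent from
the foreground are skipped. The natural background is the set of
TPP-analyzable proteins (those entering the calls), not the whole proteome.
Aromaticity, aliphatic index and instability index are available as
optional descriptors; no stability association is claimed for them.

## Synthetic data generator

The generator emulates the study design: 300 proteins, the
10-point 30–70 °C gradient, one control plus six crowders
(ficoll70/ficoll400/dextran40/dextran86/peg1/peg8), 3% of proteins
stabilized and 3% destabilized, shift magnitudes ~N(5, 1) °C, control Tm
~N(52, 5) °C truncated to [44, 58], plateaus uniform on [0, 0.25], slopes
at Tm uniform on [0.10, 0.22] /°C in magnitude, protein abundances
log-uniform over 1e7–1e10, and 5% CV multiplicative log-normal noise on
intensities (mean-one, a typical model for reporter-ion data; missing
values optional via `missing_rate`, default 0). Affected proteins are
shifted in 1 + Binomial(5, 0.25) crowders, concertedly in one direction; a
`left_skew` flag moves a quarter of the stabilized mass to destabilized to
mimic a mild excess of negative shifts. Shifts are injected exactly by
re-solving b for the target Tm while holding a and p fixed, so the true
ΔTm of every pair is analytic.

Identifiability constraints are built in, because they define which
proteins a TPP analysis can quantify at all: every condition's Tm stays
inside [36, 64] °C (shift magnitudes are clipped to the available headroom,
minimum 2.5 °C), and the shape parameter a is raised where necessary so
every curve is fully folded at the 30 °C reference (soluble fraction within
~1e-5 of 1). A curve whose transition starts below the reference
temperature cannot be recovered from reference-normalized data — the
normalization itself destroys the information — so such proteins are out of
scope for the generator as they would be for the assay.

What the generator does *not* emulate: peptide-level variation and
peptide→protein rollup, TMT co-isolation/ratio compression,
abundance-dependent noise, batch or run-order effects, or correlated
missingness. Tests passing on synthetic data therefore demonstrate the
correctness of the estimator and calling machinery under the stated noise
model, not robustness to every artifact of real LC-MS data.

## Evaluation

`truth_evaluation` scores calls against the generator truth: sensitivity
(true shifted pairs called significant), specificity (true null pairs
called null), sign accuracy (true shifted pairs called in the true
direction; uncalled or misdirected both count as wrong), and three-way
class accuracy. QC-excluded pairs count as null calls.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
emulated study scale (300 proteins × 7 conditions = 2100 curve fits per
experiment, twice: noiseless and 5% CV), which completes in well under a
minute each on one CPU; smaller seeded experiments (10–120 proteins) cover
plumbing and determinism. Oracle sweeps use 1000 random parameter sets for
the closed-form/bisection melting-point check and full permutation or
hypergeometric enumeration for the statistic oracles. Determinism contract:
a single integer seed drives every draw; equal configs produce
byte-identical written experiments, and write→read round trips are lossless
(shortest-repr floats, round-trip parsing) so stage-wise CLI runs reproduce
in-memory runs exactly. Results tables are written with 10 significant
digits.

## Known limitations

* Tm is an aggregation midpoint, not a thermodynamic melting temperature;
  it depends on heating protocol and buffer and is meaningful chiefly as a
  within-experiment comparison between conditions.
* With six crowders, mechanism regressions have n = 6; R² values at that n
  are indicative, not inferential, and are flagged accordingly.
* The z-score rule controls no FDR: at α = 0.05 two-sided, ~5% of null
  pairs per treatment are expected to be called, concentrated at the tails
  of each treatment's empirical ΔTm distribution.
* Whether slope should be evaluated at Tm or at the inflection point in T,
  and whether temperatures should enter in K rather than °C, are
  conventions; this package pins Tm-evaluated slope and °C.
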