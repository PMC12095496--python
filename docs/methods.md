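# Methods

## Scope and model structure

The package covers three connected pieces of machinery for synthetic
(chemically synthesized) SpCas9 gRNAs: a linear activity score built from
five spacer features, a linear HDR-efficiency predictor for single-stranded
DNA donors, and the algebra that converts comparative-screen measurements
(cell death + amplicon sequencing, ±DNA donor × ±M3814) into in vivo gRNA
activity and inferred cryptic repair. Both predictive models follow the
statsmodels convention: a model object holds the data, `fit()` returns a
results object carrying coefficients, standard errors, and diagnostics, and
prediction, penalty decomposition, and `summary()` hang off the results.

## Activity metric and screen equations

Amplicon sequencing samples only surviving cells, so editing frequencies
are related to the initial population through cell death:

- death-corrected NGS frequency = (100 − death) · freq / 100
- gRNA activity = death + (100 − death) · freq / 100

The second is the first plus cell death; the package asserts this
composition identity to machine precision. The large-scale-repair
correction factor (100 − max activity)/(100 − activity) converts
death-corrected frequencies into population shares once unamplifiable
alleles exist; it equals (100 − D − L)/(100 − D) under the sampling model
in which cells carrying large-scale lesions survive but contribute no
amplicon.

## EVA activity score

Features, with units and rationale:

| feature | meaning | default handling |
|---|---|---|
| ΔG(spacer) | unimolecular MFE of the 20-nt spacer RNA at 37 °C, kcal/mol | clipped: min(ΔG, −3); positive MFE reported as 0 |
| #GA | GA-dinucleotide count (overlapping scan; equivalent to non-overlapping for a 2-mer) | linear, more GA favorable |
| MIT | aggregate off-target specificity, 0–100 | clipped: min(MIT, 75) |
| G17 | G immediately 5′ of the cut (position 17) | binary penalty |
| C20 | C immediately before the PAM (position 20) | binary penalty |

Positions are 1-based with 20 PAM-proximal; the blunt cut sits between
positions 17 and 18, so a guide's single integer cut coordinate is the
0-based index of the base immediately 3′ of the cut on the protospacer
strand (3 bp 5′ of the PAM). The clip boundaries express that free energy
above −3 kcal/mol and specificity above 75 carry no additional benefit;
they are stored on the results object and configurable.

Fitting is unweighted OLS (statsmodels) of replicate-mean activity on the
clipped design matrix, with an explicit rank check that names collinear
columns. Predictions are clamped to [0, 100]; a score below 50 flags an
inefficient guide. The per-feature *penalty decomposition* is taken
relative to a zero-penalty reference guide (ΔG and MIT at their clip
boundaries, GA count at a reference value, no G17/C20); the GA reference
defaults to the training maximum and is stored on the results object. The
decomposition is exactly additive: penalties sum to (zero-penalty score −
unclamped prediction).

G17 and C20 enter as single binary indicators (rather than one-hot base
encodings at those positions), the minimal encoding consistent with
"G disfavored at 17, C disfavored at 20".

The packaged default coefficient set (`data/eva_default.json`, provenance
`package-default-synthetic`) is a synthetic calibration chosen once to
respect every sign constraint with a zero-penalty score of 100; users
fitting their own screens should prefer `fit()` and export `to_config()`.

### Feature selection

`prune_features` implements the two-stage screen used to arrive at a
compact feature set: keep candidates significantly correlated with the
response (two-tailed Pearson, α = 0.05), then walk survivors in order of
decreasing |r| (ties by name) and drop any feature correlated at |r| ≥ 0.5
with an already-kept, better-correlated one. The cross-correlation cutoff
is a package choice (no published value exists) and is exposed as a
parameter.

### MIT specificity

Per-site score: 100 · Π(1 − W[p]) · 1/(((19 − d̄)/19)·4 + 1) · 1/n², with
the 20-entry Hsu experimental weight vector (packaged JSON, swappable),
d̄ the mean pairwise mismatch distance, n the mismatch count; a perfect
match scores 100, and the guide-level aggregate is 100·100/(100 + Σ site
scores) over off-target sites only. Off-target enumeration scans both
strands for NGG/NAG PAMs with ≤ 4 mismatches (CRISPOR convention),
excluding the on-target locus by coordinates; it is intended for targeted
loci and toy genomes, not chromosome-scale scans.

## HDR model

Predicted HDR = clamp( decay(d) · (b0 + b1·EVA + b2·ΔG_donor + b3·penalty),
0, min(EVA, 100) ). Donors fold as written (the delivered single-stranded
species), with DNA (Mathews 2004) parameters; ViennaRNA's parameter tables
are process-global, so the DNA path saves and restores the RNA tables.
The distance decay is exponential, decay(d) = 2^(−|d|/5): 1 at the cut,
0.5 at 5 nt, anchored by the observed halving of HDR efficiency five
nucleotides from the cut; the half-distance is a model field so an
empirical curve can replace it. Distance 0 denotes the base immediately 3′
of the cut on the spacer strand; signed offsets are stored and |d| is used.

The 12-entry substitution-penalty table is built as (1 − ref_ease ×
alt_ease) · 20 percentage points with ref_ease {A,C: 1.0; T,G: 0.5} and
alt_ease {C,T: 1.0; A,G: 0.7}, normalised so C→T carries zero penalty.
This encodes three qualitative constraints: C→T is ≥ 2.5-fold more
efficient than G→A (ratio 2.86 here), T/G are about twice as hard to
substitute away as A/C, and changes into purines are disfavored. The table
is a plain dict on the model and can be replaced wholesale by empirical
values. Multi-edit donors are scored conservatively with the farthest
edit's decay and the worst edit's penalty.

`hdr_share` = substitutions/(substitutions + indels) returns NaN on a zero
denominator — "nothing edited" is deliberately distinct from "no HDR".

## Cryptic-repair inference

Per target, activities are computed for every condition from replicate
means (arithmetic mean before inference). The maximum across conditions
estimates true cleavage. The ±M3814 comparison uses the donor-present pair
when available, else the donor-absent pair. With Δ = activity(+M3814) −
activity(−M3814):

- |Δ| ≤ 5 points → "comparable", both cryptic amounts 0;
- Δ > 5 → perfect tendency, perfect repair = max − activity(−M3814);
- Δ < −5 → large-scale tendency, large-scale repair = max −
  activity(+M3814), and +M3814 NGS frequencies are rescaled by the
  correction factor.

The ±5-point band is configurable. Inferred amounts are non-negative by
construction (max ≥ every activity); a defensive warning covers data that
violate this. Maximum activity is taken single-pass, without iteratively
re-deriving it from rescaled frequencies. Targets missing a ±M3814 pair
are flagged unavailable rather than guessed.

## Synthetic data generator

The generator emulates the screen design (78 targets × 3 replicates × 4
conditions) in activity space. Per target: true maximum activity uniform
on [33, 93] (the published combined range), cell death a uniform 10–50%
fraction of activity capped at 50 points, exactly one cryptic tendency
drawn with probabilities 0.19/0.49/0.32 (perfect/large-scale/comparable,
the published split), cryptic amounts uniform on [8, 30] points (above
the ±5 band — smaller amounts are by construction indistinguishable from
"comparable"), and an HDR share of 0.2–0.6 with donor, raised 1.5-fold
(capped at 0.9) under M3814. Measured NGS frequencies are obtained by
inverting the activity equation per condition, so zero-noise inference
recovers the partition exactly; Gaussian noise (default s.d. 3 points,
consistent with replicate correlations around 0.95) is then added per
replicate and truncated to valid ranges. No-donor conditions report zero
substitutions, as amplicon analysis discards unexpected substitutions as
sequencing error.

Feature-space simulators draw the five guide features (and HDR inputs)
from realistic marginal distributions whose planted linear responses stay
strictly inside [0, 100] — necessary so that truncation never bends the
noiseless response and OLS recovery is exact. What passing these tests
shows is that the estimators invert their own generative models correctly
and tolerate measurement noise at the screen's replicate-noise level; it
does not show that real screens satisfy the linearity, independence, or
single-tendency assumptions.

## Numerical choices and limitations

- Quantiles are linear-interpolation (type 7) throughout; the quartile
  benchmark reports NaN fractions with an explicit zero count when no
  guide is flagged inefficient.
- Targetability windows are inclusive: |cut − variant| ≤ 10 by default.
- Genomic intervals are 0-based half-open internally and in BED output;
  the BED9 track maps score 0–100 linearly to 0–1000 and colors ≥ 50
  green, < 50 orange.
- Pearson correlations return NaN (not 0) on zero-variance input.
- Folding values are tied to the ViennaRNA backend (Turner 2004 RNA /
  Mathews 2004 DNA at 37 °C); other parameter sets shift ΔG by fractions
  of a kcal/mol, which the clip at −3 largely absorbs. Regression fixtures
  record backend provenance and use loose tolerances.
- The activity model is linear and trained on small screens; it is an
  upper-bound-style predictor — best at flagging inefficient guides — not
  a calibrated per-guide efficiency estimate. Cas12a guides, chromatin
  context, and tracrRNA architecture effects are out of scope.
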