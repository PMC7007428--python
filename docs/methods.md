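# Methods

This note documents the models, numerical choices and open design decisions
behind `specgrade`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

A raw spectrum of patient *p*, replicate *r* is

    s_pr(ν) = g_r · Σ_b A_b · J_pb · φ_b(ν) · E_c(ν) + base(ν) + ε(ν)

* **Bands** φ_b: unit-peak Gaussian (default) or Lorentzian profiles. The
  default set holds ten biofingerprint assignments (lipid C=O 1750, Amide I
  1650, Amide II 1550, CH₂ 1470, Amide III 1260, phosphates 1225/1080,
  carbohydrate 1155, glycogen 1030, phosphorylation 970 cm⁻¹; amplitudes
  0.20–1.00 with Amide I strongest, widths 14–28 cm⁻¹), three broad
  background envelopes (3300, 2925 cm⁻¹ and a wide fingerprint hump), and a
  narrow (9 cm⁻¹) secondary band of amplitude 0.12 at every marker
  wavenumber so class effects act on a genuine local absorption.
* **Class effects** E_c: each marker effect multiplies the spectrum by
  `f^w(ν)` with `f = 1 + magnitude` (up) or `1/(1 + magnitude)` (down) and
  *w* a unit-peak Gaussian at the marker wavenumber with the matched band's
  width. This makes an up/down pair an exact inverse, puts the perturbation
  extremum at the marker, and leaves the rest of the spectrum untouched.
  Default magnitudes: 0.05 for the grade II profile (eight markers), 0.15
  for the grade I-recurrence profile (eight markers), with the published
  ↑/↓ directions. Grade II effects are deliberately the smaller ones: grade I
  vs. grade II is the hard comparison (validation accuracy ~75–90, AUC
  ~0.85–0.99 across seeds), both recurrence comparisons are near-perfect.
* **Patient effect** J_pb: lognormal per-band amplitude jitter (log-sd
  0.40) shared by all of a patient's replicates. A scalar per-patient gain
  would be exactly removed by the preprocessing chain and would leave no
  within-patient correlation to test patient-grouped splitting against, so
  the patient effect must perturb band *ratios*; 40 % band-amplitude
  variability is what makes validation performance imperfect at the default
  effect sizes.
* **Nuisance terms**: per-replicate lognormal gain g_r (log-sd 0.10,
  ATR contact-pressure scatter), a fixed gentle linear baseline, and white
  noise of sd 0.004 absorbance units per point.
* **Acquisition grid**: 4000–400 cm⁻¹ stored high→low. The instrument
  resolution is 8 cm⁻¹; points are laid every 4 cm⁻¹ (the usual one-level
  zero-filling), so the 1800–900 cm⁻¹ window holds 226 points.

What the generator does **not** emulate: Mie/resonant-Mie scattering,
ATR penetration-depth dispersion, atmospheric CO₂/H₂O lines, paraffin
residues, instrument drift between sessions, and any real covariance
structure between biochemical bands. Tests passing on this cohort therefore
demonstrate the correctness and calibration of the *algorithms*, not
clinical performance on tissue.

`generate_cohort` accepts `carrier_effects`, a mapping from patient IDs to
extra effect lists, used to plant the recurrence-trend profile into named
grade I patients for screen validation.

## Preprocessing

Truncation keeps the closed interval [900, 1800] cm⁻¹. The derivative filter
is Savitzky-Golay with window 7, polynomial order 2, derivative 2, scaled by
1/Δν² (mathematical second derivative with respect to wavenumber; absorbance
peaks become negative lobes). Edges are handled by evaluating the outermost
full window's fitted polynomial at the edge offsets, so the output keeps the
input length. Vector normalisation divides each row by its Euclidean norm;
an all-zero row is an error naming the spectrum. Order of operations is
truncate → derivative → normalise: differentiating inside the window only
avoids leakage from out-of-window structure, and normalising last makes the
chain exactly invariant to positive gain and to constant/linear baselines.

## Outlier screen

PCA on the mean-centred preprocessed matrix; by default the component count
is the smallest reaching 95 % cumulative explained variance. T²ᵢ = Σₖ
t²ᵢₖ/λₖ with limit k(n−1)(n+1)/(n(n−k)) · F₁₋α(k, n−k); Qᵢ is the squared
residual norm with the Jackson–Mudholkar limit from the discarded
eigenvalues. A spectrum is flagged only when it exceeds **both** limits
(α = 0.05). The AND rule keeps the clean-data flag rate near α² (measured
~0.2 % on the default cohort), matching a workflow in which a clean cohort
yields no removals; the report is advisory — nothing is dropped
automatically.

## Partitioning

Kennard-Stone greedy maximin on Euclidean distances, ties broken to the
smallest index (deterministic). The split runs per class on patient-mean
preprocessed spectra; `round(0.7·n_class)` patients go to training, and all
replicates follow their patient. Cross-validation folds are venetian blinds
(fold *j* = every 10th training object starting at *j*) over training
patients in dataset order, then expanded to spectra. A spectrum-level mode
exists (`level="spectrum"`) for emulating replicate-splitting workflows; it
is not the default because replicate leakage inflates validation scores.

## Classifiers

**PCA-LDA.** SVD-based PCA to k scores, then a linear discriminant: assign
to the class minimising D²_c + (−2 log π_c), with D²_c the Mahalanobis
distance to the class centroid under the pooled within-class covariance
(divisor n−2; ridge 10⁻⁸·tr(S)/k added under a warning if the condition
number exceeds 10¹²). Priors π_c default to the observed class frequencies;
this is what produces the majority-class skew seen on imbalanced cohorts
(validation sensitivity ≫ specificity when the positive class is the
majority), and `priors="equal"`, which removes the skew, is one keyword
away. The signed decision score is g(neg) − g(pos), ties to the positive
class.

**PLS-DA.** NIPALS PLS1 on a ±1 coding: w ∝ Eᵀf, t = Ew, p = Eᵀt/tᵀt,
q = fᵀt/tᵀt, deflating E and f each round; b = W(PᵀW)⁻¹q. The decision
threshold on the predicted response is *estimated*, not fixed at 0: the
fitted-response midpoint of the two class means by default, and in the
pipeline the midpoint of **cross-validated** (out-of-fold) class-mean
responses. A fixed 0 threshold on imbalanced data is majority-biased
(the centred coding shifts with class frequencies), and the fitted midpoint
still misses the shrinkage of unseen objects toward the majority; the CV
midpoint sees that shrinkage and keeps the two validation error rates
consistent (measured means 84/84 sens/spec vs. 90/71 for threshold 0 over
ten seeds of the imbalanced default design). `threshold=0.0` restores the
naive rule.

**Component selection.** For k = 1..k_max, fold-out accuracy over the
venetian-blinds folds; the chosen k is the smallest within one standard
error of the best mean (1-SE rule). The pipeline also accepts fixed
per-comparison counts (`k_policy="fixed"`, defaults 10/11, 17/17 and 12/13
PCs/LVs for the three comparisons) for reproducing fixed-component
analyses.

**Conventions.** The PLS/DBM "+" class is G2 (vs. G1), G1R (vs. G1) and G2
(vs. G1R). Metric tables take the comparison's first-listed (larger) class
as positive — the orientation in which a majority-skewed model reads as
high sensitivity / low specificity.

## Evaluation

Counts and percent metrics as in the README formulas; undefined ratios
(empty class) are NaN, never 0. ROC curves sweep the unique score values,
grouping ties into single steps; AUC is the trapezoidal area and equals the
normalised Mann-Whitney U statistic (property-tested against a pairwise
brute force). Metrics are reported at spectrum level and, when patient IDs
are supplied, after per-patient majority vote (ties to the
lexicographically larger label). Percentages are kept as raw fractions
internally and rounded only for display.

## Biomarkers

DBM = mean(class₊) − mean(class₋) of preprocessed spectra; wavenumbers with
|coefficient| strictly above the threshold (default 0.01 — a scale that is
only meaningful on unit-norm derivative spectra) are flagged. Peak detection
on a PLS regression vector takes strict local maxima of |b| (plateaus count
once, at their leftmost point; a monotone vector falls back to the
endpoints with a warning) and returns the n = 8 largest. ANOVA is one-way
fixed-effects on the preprocessed intensity at one axis column (nearest
neighbour within half a spacing, else an error), observations = individual
spectra; with replicate correlation these p-values are optimistic, which is
stated rather than corrected, and no multiple-testing correction across
wavenumbers is applied. Direction is "up" iff the first class's mean
exceeds the second's at that column; exact ties call "down" with a warning.
Band-assignment strings are an annotation-only nearest-neighbour lookup.

Coefficient magnitudes are only marker-interpretable when the model is
parsimonious: once the response is essentially fitted, further latent
variables chase noise and can place large coefficients at uninformative
wavenumbers. The recurrence screen and the recovery tests therefore read
markers from a 1-LV model (the class-covariance direction); the 1-SE rule
reaches the same place on well-separated data.

## Recurrence screen

For each grade I patient: deviation = patient-mean preprocessed spectrum
minus the grade I class mean computed **without** that patient
(leave-one-out, avoiding self-bias). A marker "matches" when the deviation's
sign at the marker wavenumber equals the marker's recurrence direction;
exact zeros do not match. Rules: `all` (default; null flag rate ≈ 0.5⁸ ≈
0.4 % for eight markers), `majority` (> half), `fraction:q`. The default is
the strictest reading of "follows the recurrence trend"; the result is a
candidate list for follow-up, not a prognosis.

## Problem sizes used in the tests

The test-suite simulations run at the native cohort scale (≤ 990 spectra ×
226 fingerprint points), with 20–50 seeded replicates for the stochastic
calibration checks; the full three-comparison pipeline completes in well
under a minute on one CPU.

## Known limitations

* Synthetic-data realism as listed above; effect magnitudes are modelling
  choices, not measurements.
* Two-class discriminants only; the three-class problem is handled as three
  pairwise comparisons.
* ANOVA treats replicate spectra as independent; a patient-mean mode is
  available through the `groups` argument.
* The Q control limit falls back to a small h₀ constant when the discarded
  eigenvalue spectrum is too heavy-tailed for the Jackson-Mudholkar
  approximation.
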