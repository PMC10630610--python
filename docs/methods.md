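# Methods

## Scope

The package implements the analysis chain from per-subject
region-by-region FA connectomes and interictal iEEG band powers to
patient-level surgical-outcome statistics.  Upstream image processing
(tractography, registration, resection-mask drawing) and spike analysis
are out of scope; the contracts start at connectivity matrices, contact
coordinates/band powers, and regional pre/post-operative volumes.

## Connectivity abnormality model

Processing order is fixed: **harmonize → covariate-adjust → z-score**.

*Harmonization* is parametric empirical-Bayes location/scale ComBat,
written in `combat.py`.  Per connection, batch location and scale
parameters are estimated on the feature-standardised data and shrunk
toward their batch-wide means (normal prior for location,
inverse-gamma for scale, iterative joint solution to 1e-4).  Age and
sex enter the design matrix as protected covariates.  Batch parameters
are estimated on controls only and applied to patients, so patients
never influence the reference; a single-batch cohort passes through
unchanged.  The implementation is cross-checked in the test suite
against Bioconductor `sva::ComBat` (agreement ≤ 1e-4 on a shared
dataset).

*Covariate adjustment* fits, per connection, weight ~ age + sex over
controls with a Huber M-estimator (tuning constant 1.345, the standard
95%-efficiency choice).  Covariates are centred at the control means,
so the fitted intercept is the robust location μᵢ at reference
covariates; this makes μᵢ resistant to outlier controls.  σᵢ is the
SD (n−1 denominator) of the covariate-adjusted control weights.
Patients are adjusted with the control-fitted coefficients.
Connections with σᵢ < 1e−12 are flagged degenerate and excluded from
z-scores and regional means rather than raising.

*Choices left open by the problem and fixed here:* σᵢ is computed
after covariate adjustment (the alternative, before, is a one-line
change); absent (non-atlas) connections are never imputed as zero; the
regional ranking score is −R_kj so FA reductions rank high, with an
optional clamp at zero for positive-z regions (off by default).

## iEEG abnormality model

Welch PSD uses 2 s Hann segments, 50% overlap, constant detrend —
common defaults giving 0.5 Hz resolution, ~69 averaged segments over a
70 s epoch.  Band power is the mean PSD within the band edges (bands
half-open, gamma closed at 80 Hz).  The five log₁₀ band powers are
divided by their sum; the operation refuses non-positive band powers
and near-zero log sums loudly (the synthetic generator scales signals
so all log powers are positive).  The ≥70 s duration contract is
validated; seizure-distance is an upstream data-selection contract.

Contacts map to the closest grey-matter region **representative
point** — the centroid, or the nearest point of a per-region point
cloud when one is attached — with the strict <5 mm rule; exact ties
break to the lexicographically smaller region id for determinism.
Regional band power is the unweighted mean over assigned contacts;
regions without contacts are absent, not zero.  Normative map regions
covered by fewer than two participants, or with zero spread in any
band, are flagged and refuse z-scoring by name.

## Resection

Strict `reduction > threshold` with threshold 0.10 by default;
post-operative growth counts as spared.  Raising the threshold can
only shrink the resected set (tested as a property).

## Outcome statistics

- **D_RS**: normalised Mann–Whitney U over all (resected, spared)
  region pairs, ties credited 0.5; 0 when the largest abnormalities
  are all resected.  Connectivity D_RS uses all scored regions; iEEG
  D_RS only implanted regions.
- **Separability**: linear SVM, effectively hard margin (C = 1e6), no
  feature scaling (both axes are already z-score-derived);
  "separable" = 100% training accuracy, decided exactly by a linear
  feasibility program before the SVM fit.  The maximal-abnormality
  probe is the componentwise maximum of the patient's observed scores,
  so the call is data-scaled.
- **Contingency**: Yates-corrected chi-square throughout (the
  correction clamped at zero); Wald log-normal odds-ratio CI;
  Haldane–Anscombe +0.5 applied whenever a cell is zero, which also
  covers degenerate tables with zero margins.  The non-separable
  subgroup is tested with the exact two-sided binomial (doubling the
  smaller tail).
- **Two-cut tree**: exhaustive search over root axis, root threshold
  (midpoints of sorted unique values), branch to refine, and child
  threshold on the other modality; leaves take majority labels with
  ties defaulting to seizure-free.  Ties in training accuracy break by
  larger worst-case margin, then lexicographic configuration order, so
  the fit is deterministic.  LOOCV refits the full search per fold; a
  fold left with one outcome class predicts that class.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, with
all randomness derived from a single seed through tagged streams
(identical config ⇒ identical cohort):

- 96 controls split over two scanner batches (per-connection additive
  shift 0.05 and noise scale 1.1 on the second batch), ages uniform
  18–60, per-connection age slopes ~N(0, 0.002 FA/yr) and sex effects
  ~N(0, 0.02 FA), residual noise SD 0.05 FA; weights clipped to [0,1].
- 43 patients by default.  The pathological zone is an EZ core of 3
  regions carrying the full effect plus a 2-region penumbra at half
  strength; connections incident to the zone are reduced by
  (weight × 2.5) pooled control SDs, and zone band powers are shifted
  by (weight × 2.5) normative spreads in the delta band.  The graded
  zone is what makes per-patient resected/spared scatters separable in
  both directions, mirroring the cohort structure the analysis is
  meant to detect; without it, off-target resections are never
  separable from spared normal tissue.
- Resection removes the whole zone with probability 0.8, otherwise an
  equal-size off-target set; volumes implement the >10% rule (resected
  regions lose 40–80%, spared ±3%).  The outcome is seizure-free iff
  the EZ core is fully resected, flipped with probability 0.05, stored
  as ILAE 1–6 and binarised at ILAE ≤ 2.
- Implantation covers the pathological zone, resected regions with
  probability 0.9 each, and random fill to 30% of regions (sparse,
  hypothesis-driven coverage); 2 contacts per region within 0.8× the
  5 mm radius of the centroid, plus 5% stray contacts placed far
  outside the atlas box to exercise the unassigned path.
- The normative iEEG cohort (234 participants) draws 5-band profiles
  around (0.30, 0.25, 0.20, 0.15, 0.10) with spread 0.02,
  normalised to sum to 1; full regional coverage keeps the map defined
  everywhere.
- The time-series generator sums per-band spectrally shaped white
  noise scaled to requested integrated-power fractions, plus a 0.1%
  broadband floor so every band power stays positive, at an overall
  variance (1e6 µV²) keeping log₁₀ band powers positive.

**What the generator does not emulate:** spatial correlation of FA
along shared tracts, anatomically realistic electrode trajectories,
heterogeneous per-patient EZ sizes and effect magnitudes, regional
coverage gaps in the normative iEEG cohort, and non-Gaussian artefact
structure.  Tests passing on this cohort therefore demonstrate
correctness of the computations and recoverability of planted effects
at realistic sizes — not clinical performance; synthetic outcome
metrics (AUCs ≈ 0.85–1.0) are cleaner than clinical data would give.

## Numerical choices

- Degenerate connection/band SDs: threshold 1e−12, excluded or refused
  by name, never silently zeroed.
- Atlas default 32 regions (desk scale; analyses and acceptance run in
  seconds); the study-scale 128 regions is a config field.  Synthetic
  centroids keep ≥3× the assignment radius apart so contact assignment
  is unambiguous by construction.
- Band-power normalisation tolerance 1e−9; connectivity I/O round-trips
  are exact to float repr.
- Seeds are combined as `default_rng([seed, tag, index])`, all below
  2³¹.

## Known limitations

- The SVM zone boundary is linear only; curved resection margins in
  abnormality space are out of scope.
- Multi-window iEEG epochs default to a single 70 s window.
- The two-cut tree is intentionally restricted (one cut per modality);
  it is not a general CART.
- Wald odds-ratio intervals are anti-conservative for very sparse
  tables even with the +0.5 correction; exact intervals are not
  provided.
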