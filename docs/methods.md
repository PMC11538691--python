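# Methods

## IDR extraction and composition classes

A residue is called disordered when its predictor score is ≥ 0.5, the
conventional cutoff for IUPRED-family predictors; the score files are
ingested as `POS RES SCORE` tables and never computed here. An IDR is a
*maximal* run of disordered residues — its flanking residues, when they
exist, score below the cutoff — and qualifies for the screen when it is
strictly longer than `min_idr_length` (default 50, i.e. ≥ 51 residues,
the literal reading of "more than 50 consecutive residues"). Both
numbers are `ScreenConfig` fields.

Per-sequence composition is evaluated over the concatenation of **all**
qualifying IDRs rather than only the longest one. Either convention is
defensible; concatenation was chosen because the classification concerns
a sequence's total disordered content, and for the synthetic cohorts
(one designed IDR per sequence) the two coincide. `X` residues count
toward the region length but toward no class, which biases the class
fractions least for proteome-style inputs. Histidine joins neither
charge class — at neutral pH it is mostly uncharged — but is tallied
separately so the charge model can titrate it.

All three classification thresholds are strict inequalities:
f_aromatic exactly 0.09 is *not* aromatic-rich, f_negative exactly 0.03
is *not* negative-sparse, and net charge 0 is its own "balanced" class.
The 9% aromatic cutoff is not arbitrary: it is the sum of the
proteome-average frequencies of W (1.5%), Y (3.5%) and F (4.0%), so
"aromatic-rich" means "more aromatic than an average protein".
Percentages are reported at one decimal, rounded half-away-from-zero.

## Charge model

Each ionizable side chain contributes its Henderson–Hasselbalch expected
charge: −1/(1+10^(pKa−pH)) for acidic groups, +1/(1+10^(pH−pKa)) for
basic ones. Default pKa values are consensus intrinsic values — D 3.9,
E 4.3, H 6.5, K 10.4, R 12.3 — with C and Y excluded by default
(their ionization is rarely relevant below pH 9 and their default
exclusion keeps the formal-charge census and the titration model
consistent at neutral pH). Terminal groups (N-term 8.0, C-term 3.7) are
off by default because the quantity of interest is side-chain charge of
an internal region; both the pKa map and the termini flag are
configurable and echoed into every report. The model is sequence-only:
no environment-dependent pKa shifts, no cation-π or π-π energetics, and
no attempt to predict condensation thresholds from charge — the model
quantifies charge attenuation (e.g. a two-aspartate region retains 56%
of its pH 7 charge at pH 4), nothing more.

## Binding and relaxation fits

The combined amide chemical-shift perturbation is
`sqrt((ΔδH² + (ΔδN/5)²)/2)`; the 1/5 nitrogen scaling is the standard
amide-nitrogen normalization and is a configurable parameter.

K_D fitting always uses the exact ligand-depletion (quadratic one-site)
isotherm, never the weak-binding hyperbola, because the protein
concentrations in this regime (tens to hundreds of µM) are comparable to
K_D. Two algebraic rewrites keep the isotherm stable in floating point:
the discriminant `(K_D+[L]+[P])² − 4[P][L]` is computed as
`(K_D+[P]−[L])² + 4·K_D·[L]` (identical, manifestly non-negative, no
cancellation near stoichiometric [L] = [P]) and the root
`(b − √disc)/(2[P])` as `2[L]/(b + √disc)` (no cancellation at large
[L]). Starting values are Δδmax⁰ = the largest observed shift and
K_D⁰ = the ligand concentration at half-maximal shift by interpolation,
with bounds K_D ≥ 0, Δδmax > 0; fits go through lmfit's
Levenberg–Marquardt and 1-σ uncertainties come from the fit covariance.
A titration whose observations are all below 1e-6 ppm is flagged
non-binding instead of fit. Fits are deterministic for identical inputs.

R₂ comes from a nonlinear least-squares fit of I(t) = I₀·e^(−R₂t),
seeded by the log-linear regression. The fitting error is a parametric
Monte Carlo: the best-fit curve is perturbed `n_mc` times (default 1000)
with Gaussian noise at the spectrum noise sd and refit; the reported
error is the standard deviation of the refitted R₂ values. The point
estimate uses only the raw data and is therefore independent of `n_mc`
and seed, and the error vanishes as the noise sd does. Data whose
best-fit rate is non-positive (non-decaying series) are a domain error,
not a silent negative rate.

## Assay quantification

The calibration is an ordinary least-squares line of A594/A466 ratio on
standard concentration; inversion is `(ratio − intercept)/slope`, with
below-range (negative) concentrations returned raw under a warning. The
level statistic 1 − [s]/[t] is likewise never clamped: a level of −0.05
from supernatant noise is reported with an out-of-range warning so the
aggregation step sees the real measurement. Replicates are averaged *at
the level stage* (level per replicate, then mean ± sample sd), a choice
the triplicate design leaves open; averaging ratios first differs only
at second order in the noise. A280-derived concentrations bypass the
calibration and enter the same level computation, with the provenance
recorded per measurement.

## Synthetic-data generators

The generators define the study conditions the tests and the acceptance
script run under.

* **Cohort** (default for the headline run: 1263 sequences, 720
  net-negative of which 480 negative-sparse, 300 net-positive, 243
  balanced, 700 aromatic-rich). Each sequence is a folded filler region
  (scores 0.1) followed by one designed IDR (scores 0.9, length 60–120).
  Class-defining residues (D/E, K/R, W/F/Y) are placed at uniformly
  random IDR positions with at least one residue's margin from every
  threshold, so exact-fraction rounding can never flip a class; the
  filler alphabet {G,S,A,P,Q,N} is charge- and aromatic-neutral. The
  truth table lists every designed flag.
* **Titration**: truth K_D = 100 µM, Δδmax = 0.2 ppm, [P] = 50 µM on the
  8-point ligand grid 0–1600 µM, additive Gaussian noise of sd
  0.002 ppm — a realistic CSP measurement precision.
* **Decay**: truth R₂ = 12 s⁻¹, I₀ = 100, at the six standard delays
  17–102 ms, intensity noise sd 1 (1% of I₀).
* **Relative-change assay**: conditions at levels 0.8 / 0.64 / 0.4, i.e.
  variants sedimenting 20% and 50% less than the reference, read out
  through a designed calibration line (ratio = 0.05·conc + 0.40) with
  ratio noise sd 0.005.

All randomness derives from one spec-level seed through named substreams
(`sequence`, `*-noise`), so regenerating one output never perturbs
another. What the generators deliberately do **not** emulate: realistic
disorder-score profiles (tracks are two-level), homolog phylogeny or
real galectin sequence statistics, correlated or peak-overlap NMR noise,
and pipetting-style multiplicative assay error. Passing tests therefore
demonstrate that each estimator inverts its own forward model at
realistic noise — not that the models capture every feature of real
measurements.

## Problem sizes and numerical choices

The standard verification runs use: the 1263-sequence cohort (single
screen, < 1 min), 100-seed K_D recovery studies at sd 0.002 ppm,
1000-replicate Monte Carlo for R₂ errors, 1000 random tracks (length
≤ 200) for the segmentation brute-force cross-check, and a 10×10
(K_D, [P]) grid for the isotherm law suite at 1e-9 tolerance. The
segmentation oracle enumerates every (start, end) pair and is retained
in the test suite as an independent check on the linear-scan extractor.
Reports are JSON/TSV, written atomically (temp file + rename), and embed
the full configuration so identical inputs yield byte-identical outputs.

## Known limitations

* The screen ingests disorder scores; it cannot be more accurate than
  the upstream predictor, and the 0.5 cutoff is a convention, not a fit.
* The charge model ignores pKa shifts from local structure and
  electrostatic coupling, which matter for folded domains.
* The K_D fit assumes a single binding site and fast exchange (shifts,
  not intensities, report binding).
* Level values outside [0, 1] are propagated, so downstream relative
  changes can exceed 1 for very noisy inputs; inspect the warnings.
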