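# galphase

Quantitative analysis pipeline for intrinsically disordered region (IDR)
driven protein phase separation, built around the galectin-3 paradigm: a
protein whose disordered N-terminal domain (NTD) carries only two charged
residues (both aspartates) but an unusual excess of aromatics, and whose
condensation and lectin-driven agglutination respond to salt and pH.

The package is aimed at protein biophysicists and bioinformaticians who
need to (i) screen sequence cohorts for long, compositionally biased
IDRs, (ii) model how pH reshapes an IDR's net charge, (iii) extract
binding constants and relaxation rates from solution-NMR titrations, and
(iv) quantify sedimentation assays — with seeded synthetic-data
generators standing in for every raw input, so each stage is testable
closed-loop.

## The statistics at the core

**IDR composition screen.** From per-residue disorder scores, maximal
runs of score ≥ 0.5 spanning strictly more than 50 consecutive residues
are called IDRs. Over the concatenated IDR residues of each sequence the
screen counts aromatics (W, F, Y), positives (K, R) and negatives (D, E;
histidine tallied separately), and classifies: *aromatic-rich* when
f<sub>arom</sub> > 9% (the summed proteome-average frequencies
W 1.5% + Y 3.5% + F 4.0%), charge class by the sign of K+R − D+E, and
*negative-sparse* when a net-negative IDR has f<sub>neg</sub> < 3%.

**Charge model.** Expected side-chain charge by Henderson–Hasselbalch:
an acidic group contributes −1/(1 + 10^(pKa−pH)), a basic group
+1/(1 + 10^(pH−pKa)); summing over a region gives a net-charge-vs-pH
curve that is monotone non-increasing in pH.

**NMR observables.** Combined amide chemical-shift perturbation
Δδ<sup>av</sup> = √((Δδ<sub>H</sub>² + (Δδ<sub>N</sub>/5)²)/2); the
one-site ligand-depletion isotherm

```
Δδ_obs = Δδ_max · [(K_D+[L]+[P]) − √((K_D+[L]+[P])² − 4[P][L])] / (2[P])
```

fit by nonlinear least squares (exact quadratic form, since [P] is
comparable to K_D); and mono-exponential transverse relaxation
I(t) = I₀·e^(−R₂t) with Monte Carlo fitting errors.

**Assay quantification.** Bradford A594/A466 ratios are calibrated
against BSA standards by ordinary least squares, inverted to
concentrations, and the sedimentation statistic is the level
1 − [s]/[t] for supernatant [s] and total [t] (pellet = [t] − [s] by
construction).

## Worked example

Run the numbered analyses (each writes its tables under `results/`):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_screen_cohort.py
```

which prints

```
screened 1263 sequences; 1263 carry a long IDR
net-negative IDRs: 720 (57.0%)
sparse-negative within net-negative: 480 (66.7%)
aromatic-rich: 700 (55.4%)
classification mismatches vs designed truth: 0
```

i.e. a 1263-sequence cohort designed with 720 net-negative IDRs screens
to exactly 57.0% net-negative, two-thirds of which are negative-sparse —
and every per-sequence classification matches the generator's truth
table. The fitting stages behave the same way:

```bash
python analysis/04_fit_binding.py
# fitted K_D = 101.94 +/- 2.76 uM (truth 100.0)
# median |K_D error| over 100 seeds at noise sd 0.002 ppm: 2.71%
python analysis/06_quantify_assays.py
# WT: level 0.796 +/- 0.006 (n=3)
# GQQ: 20.2% less sedimentation than WT
# GEE: 49.2% less sedimentation than WT
```

The same stages are available as a CLI
(`galphase simulate|screen|fit-kd|fit-r2|assay|charge`); run
`galphase --help` for the subcommand reference.

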