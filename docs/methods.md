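# Methods

## Model and conventions

The response (relative FTC activity, or log10 FRAP activity) is modeled as a
linear function of position-resolved amino-acid descriptor variables by
PLS1 regression. Conventions fixed throughout:

- **Autoscaling.** Every X variable is scaled to zero mean / unit variance
  (sd with ddof = 1); the response is mean-centered but not scaled. Columns
  with sd < 1e-12 are flagged and scaled to zeros rather than dividing by
  zero.
- **Q².** 1 − PRESS/TSS, with TSS about the mean of *all* samples (the
  common chemometric convention) and PRESS summed over held-out predictions.
  Default cross-validation is leave-one-out (deterministic, standard for
  n ≤ ~200 peptide QSAR) with scaling re-estimated inside each training
  fold; a `global` pre-scaling mode and seeded k-fold are available via
  `CVScheme` for sensitivity analysis.
- **Component choice.** optPC = argmax Q² over 1..min(20, n−1, p); ties go
  to the smaller model. The cap of 20 covers the largest component count
  appearing in the reproduced tables.
- **PLS algorithm.** NIPALS PLS1 with X- and y-deflation, returning the
  whole coefficient path (one coefficient vector per component count) from
  a single fit — this is what makes LOO component searches and the
  1000-sub-model loops affordable. Fits plateau gracefully when the data
  run out of rank. Numba-compiled; verified against scikit-learn's
  `PLSRegression` and against a brute-force per-fold refit oracle (1e-10).

## MPA outlier elimination

Per iteration: 1000 sub-datasets of ⌊0.8 n⌋ samples are drawn **with
replacement** (bootstrap); each sub-dataset gets its own autoscaled PLS
model with the component count chosen once per iteration by LOO on the
current full data; every out-of-bag sample records its prediction error.
The per-sample profile is the **signed** mean error: an outlier appears as
a systematic bias while ordinary samples scatter around zero. Samples
outside mean ± 3·SD of the profile are flagged; the worst flagged sample is
removed and the procedure repeats until nothing is flagged.

Two design points deserve emphasis, because the obvious alternatives fail:

- With the mean *absolute* error the profile distribution is skewed and the
  3σ band chases its own tail — on the FTC data the loop removes 18 samples
  instead of stabilizing after the genuine outliers. The signed statistic
  reproduces the expected terminal behaviour (a handful of removals on FTC,
  none on FRAP). `statistic="absolute"` remains available.
- Draws without replacement change little on FTC but flag one borderline
  FRAP sample; bootstrap draws are the default.

With a 10σ planted outlier the procedure recovers it in 20/20 seeded
synthetic runs; in roughly a third of those runs one or two borderline
samples are additionally removed (the huge planted shift inflates the
profile SD, and its removal re-shapes the distribution). A three-sigma rule
on ~60–100 samples is simply this trigger-happy; on clean synthetic data
(no planted outlier) removals stay ≤ 2.

## BOSS variable selection

Each shrinkage iteration: draw 1000 weighted bootstrap samples of size
p_live in variable space (the distinct drawn indices form a sub-model); fit
each sub-model with min(optPC_full, subset size, n−1) components on the
globally scaled data; normalize each sub-model's absolute coefficient
vector to sum 1. The **best 2% of sub-models by training RMSE** vote: their
summed normalized coefficients become the next sampling weights, and
variables with zero accumulated weight leave the live set (soft shrinkage —
survival is driven by weights, never a hard top-k cut). Every iteration's
live set is scored by a seeded 5-fold CV; the loop runs until one variable
remains, ten stagnant iterations, or a cap of 120; the best-scoring subset
over the trajectory is refit on the full data with a LOO component search
and reported (Q², R², optPC).

Letting *all* sub-models vote turns out to remove almost nothing: every
variable keeps picking up small coefficient mass, the live set stalls above
100 variables, and the selected models underperform. Restricting the vote
to the best-fitting sub-models supplies the selection pressure that drives
uninformative variables to zero weight within ~40–120 iterations and yields
compact subsets (~20–40 variables) with clearly higher cross-validated Q².
Training RMSE is used for the ranking because all sub-models of an
iteration share n and the component count, and per-sub-model CV would cost
1000× more.

Aggregation runs BOSS with consecutive seeds (default 100 runs) and counts
per-variable selection frequencies; `top_variables` returns labels above a
frequency threshold (default 75% of runs), descending.

## Synthetic data

`SyntheticSpec` states a world: n random tripeptides (uniform over the
20-letter alphabet), an activity that is a sparse linear function of
n_signal autoscaled encoded variables (coefficients ~ N(0, effect_size²))
plus N(0, noise_sd²) noise, optional planted outliers shifted by a multiple
of the response SD, and an optional power-of-ten link so that a log10
transform restores linearity (emulating the raw-FRAP nonlinearity).
Defaults: n = 100, scales Z-scale + VHSE (33 variables), 5 signal
variables, effect_size 1.0, noise_sd 0.3 — a signal-to-noise regime
comparable to the real datasets (Q² ~ 0.5–0.8). The generator does **not**
emulate assay chemistry, activity magnitudes, sequence composition bias, or
correlated measurement error; a green synthetic test establishes that an
algorithm recovers known structure, not that it reproduces laboratory
numbers.

## Descriptor scale provenance

Nine scales are transcribed from their published tables (Z-scale, 5Z-scale,
VHSE, T-scale, ST-scale, E-scale, MS-WHIM1, ISA-ECI, and V-scale — the
last reconstructed from the canonical van-der-Waals-volume / net-charge /
hydrophobicity property tables; autoscaling makes affine normalization
differences irrelevant). Seven scales — DPPS, MS-WHIM2, FASGAI, VSW,
G-scale, HESH, HSEHPCSV — are **synthetic stand-ins**: PCA scores (unit
variance, deterministic sign convention) of RDKit-computed descriptors of
the 20 free amino acids (or capped side-chain fragments), matched to each
scale's published dimensionality and property scope. Files carry a
`provenance:` header and a checksum verified at load.

Consequences: aggregate model quality is insensitive to this substitution —
the integrated-matrix and BOSS Q² values land within a few hundredths of
the reproduced study's — but *variable identity* is not comparable for
stand-in scales. Frequency rankings that name stand-in variables
(`N-G-7`, `C-VSW-5`, …) cannot be expected to match published lists, and
one borderline FTC outlier (sample 188) is not flagged with these scales.

## Numerical choices

- NIPALS stop tolerance 1e-12 on weight and score norms; exhausted rank
  repeats the last valid coefficients so Q² curves plateau.
- LOO PRESS is float64 everywhere; BOSS sub-model fits (used only to rank
  variables and sub-models) run in float32 for throughput.
- All randomness flows from `numpy.random.default_rng` seeds; one generator
  per elimination/BOSS call, consumed sequentially, so trajectories are
  bit-reproducible.
- A lone outlier in an n-sample profile deviates by at most √(n−1)·SD, so
  the three-sigma rule cannot fire on a flat profile until n > 10; the
  elimination loop refuses datasets with n < 10.

## Known limitations

- The cross-validation scheme of the original tables is unstated; LOO was
  chosen for determinism. Reproduced Q² values can differ in the second
  decimal for this reason alone.
- Stand-in scales (above) limit variable-identity comparisons.
- Only tripeptides are validated; the encoder accepts longer peptides with
  positional labels `P1..PL` but that path is untested against data.
- BOSS aggregate statistics assume consecutive seeds; they are Monte-Carlo
  estimates with SD(Q²) ≈ 0.004 across runs.
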