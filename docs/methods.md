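# Methods

## Power-vector convention

Astigmatism is carried as the double-angle vector (EQ, C0, C45) with
*full-cylinder* projections: for a cylinder C at axis α,
C0 = C·cos 2α and C45 = C·sin 2α (not the half-magnitude Jackson
crossed-cylinder J0/J45). Two facts pin this choice down: the defocus
equivalent DEQ = √(EQ² + ¼C0² + ¼C45²) reduces to the textbook
√(M² + (C/2)²) only under full-cylinder scaling, and published cohort SDs
of C0/C45 (≈0.86 dpt for keratometry) are full-cylinder-sized. Sign
orientation: with-the-rule astigmatism (steep corneal meridian near 90°)
has C0 > 0, so a *negative* C0 correction means "add astigmatism
against-the-rule". Axes are degrees mod 180; a zero cylinder reports
axis 0. Left eyes are mirrored to right eyes by negating C45 (an
involution), so a single model serves both sides.

## Reconstruction model (recCP)

A simplified pseudophakic eye with three thin refracting elements on one
axis: spectacle plane at 12 mm vertex distance, thin-lens cornea, thin-lens
IOL at the Haigis ELP = a₀ + a₁·ACD + a₂·AL (defaults are the
IOLCon-optimised MX60P constants 0.1835/0.3153/0.1725). Indices: air 1.0,
aqueous = vitreous 1.336. All vergence arithmetic uses metres; the
transfer across a homogeneous gap is v′ = v/(1 − v·d/n) with d signed
(negative = backwards), which is its own exact inverse.

Image side: with the retina conjugate, the vergence leaving the IOL is
n_V/(AL − ELP); subtracting the IOL power and transferring backwards by
ELP gives V2′ at the cornea (spherical — the IOL is non-toric). Object
side: lane vergence −1/6 dpt (6 m lane) plus the refraction's meridional
power, per principal meridian, transferred through the vertex distance
gives V2. recCP = V2′ − V2 per meridian. Two numerical readings of the
printed formulas were resolved deliberately:

* "V3′ = (AL−ELP)/n_V" is a *reduced distance*; its reciprocal is the
  vergence. Taken literally it would be ~0.014 "dpt".
* the IOL→cornea transfer must run backwards (distance −ELP), i.e.
  V2′ = V3/(1 + V3·ELP/n_A). The forward sign would put the cornea at
  ≈65 dpt; the backward sign lands at the physiologic ≈43 dpt and is
  confirmed by an independent ray-transfer-matrix oracle in the tests.

Per-meridian propagation is valid because only rotationally symmetric
elements lie between the planes, so principal axes are preserved. The
cornea is thin (ELP measured from its front vertex); corneal thickness,
toric IOLs and IOL tilt are out of scope. `forward_refraction` inverts
the chain analytically and round-trips with the reconstruction to 1e−9
dpt; it is the backbone of the synthetic generator and of the oracle
tests.

## Prediction models

Inputs and outputs are the astigmatism components (C0, C45) only; the
spherical equivalent is not modelled.

* **Constant centroid correction** — offset = mean(Y) − mean(X). Zeroes
  the training centroid, leaves the error-ellipse area untouched; the
  baseline any learned model must beat.
* **Bivariate linear regression** — y = A·x + b by maximum likelihood.
  With complete data the ECM iteration's fixed point *is* per-output OLS,
  so the implementation solves OLS and evaluates the bivariate normal
  log-likelihood at the ML (divide-by-N) residual covariance; ECM would
  only differ under missing data, which the cohort schema excludes.
  Collinear designs raise an error.
* **Shallow network** — 2→12→12→2, tanh hidden activations, linear
  output. Unspecified training details are package choices: inputs and
  outputs rescaled to [−1, 1] over the training range, full-batch Adam
  (lr 0.02), max 1000 epochs, validation MSE checked every 5 epochs with
  early stopping after 6 failed checks, best-by-validation weights
  returned, Glorot-uniform init from a fixed seed. Deterministic given
  the seed; non-convergence returns best-so-far weights with diagnostics.

Data are split 60/20/20 (train/validation/test) by a seeded permutation
with sizes round(0.6N)/round(0.2N)/remainder, reproducing 305/102/102 at
N = 509. The network is the only consumer of the validation split.

## Evaluation statistics

Prediction errors are recCP − prediction per eye. Reported per
modality × model × split: the error centroid, the 95% error-ellipse area
π·χ²₂(0.95)·√det Σ (χ²₂(0.95) = 5.991465; sample covariance with n−1),
the mean vector difference MVD (mean 2-D error length, dpt) and the mean
squared error MSE (mean squared length, dpt²; MSE ≥ MVD² by Jensen). The
dpt² unit for MSE follows the table convention rather than the abstract's
"dpt". Quantiles in summary rows use linear interpolation; the ellipse
convention is validated by Monte-Carlo coverage (0.950 ± 0.003 at 10⁵
draws) and by reproducing a published area from printed SDs under the
zero-correlation simplification (<0.1%).

## Synthetic cohort: the stated world

No patient data are available, so the generator emulates the cohort the
analysis assumes — and is explicit about what it does *not* emulate.

* Biometry: truncated normals — AL 24.03 ± 1.45 mm on [21, 30],
  ACD 3.32 ± 0.40, LT 4.58 ± 0.46, CD 12.02 ± 0.55. The ACD SD printed in
  the source summary (1.53 mm) is physiologically implausible and
  inconsistent with its own 95% CI (2.50–4.05 mm ⇒ SD ≈ 0.40); 0.40 is
  the default, configurable.
* True cornea: EQ ~ N(43.0, 1.5²) dpt; (C0, C45) bivariate normal with
  mean (−0.3149, −0.0498) and SDs (0.6706, 0.4482) dpt — the recCP
  distribution — with correlation ρ = 0 by default (not published).
* IOLP solves the forward model for a −0.25 dpt target refraction and is
  rounded to 0.5 dpt steps; the refraction is computed with the exact
  forward model and, by default, quantized to clinical granularity
  (0.25 dpt sphere/cylinder, 5° axis). Oracle tests switch quantization
  off, where recCP equals the hidden truth to 1e−9.
* Modality linkage: each measurement is generated by inverting its
  published regression, x_m = A_m⁻¹(y − b_m) + η, η ~ N(0, σ_m²I), so
  fitting the regression on a generated cohort is a parameter-recovery
  experiment whose ground truth is the published model set. σ_m defaults
  to 0.25 dpt per component for every modality — typical test–retest
  repeatability of keratometric astigmatism. Modality equivalent powers
  get small fixed offsets (total-corneal-power modalities ≈0.5 dpt below
  keratometry) plus 0.15 dpt noise; they do not enter any model.
* Laterality: OS with probability 261/509; OS records are stored in the
  eye's own frame (C45 un-mirrored) and re-mirrored on analysis.

Limitations of this stated world. (1) Because x_m inverts the published
A_m (whose diagonals are ≈0.5), the generated *measurements* spread about
1/0.54 ≈ 1.9× wider than recCP, whereas real cohorts show measured SDs
(≈0.86 dpt) only modestly above recCP's (≈0.67): in reality the <1
regression diagonals arise mostly from imperfect measurement–refraction
correlation, not from a wider measurement scale. Raw-difference and
constant-model statistics on synthetic cohorts are therefore larger than
the published ones and are not comparison targets. (2) With noise on x,
regressing y on x is an errors-in-variables problem: recovery of
(A_m, b_m) is exact at σ_m = 0 and attenuated by roughly
σ_m²/Var(x) ≲ 1% at σ_m ≤ 0.25. The parameter-recovery acceptance test
therefore simulates noise on the response with exogenous x, and the
generator-based recovery test runs at σ_m = 0. (3) No correlations
between biometry and corneal astigmatism, no bilateral correlation, no
age/sex structure. A green test on this world establishes the pipeline's
algebra and statistics, not clinical performance.

## Design choices where the design was open

* Refraction cylinder form on input: plus or minus accepted; conversions
  are form-invariant (transposition maps to the same power vector).
* The published data-dependent fit statistics (training logL, per-split
  MSE tables) depend on the unavailable cohort and are carried only as
  metadata on the published models, never as reproduction targets.
* Pipeline determinism: one master seed, sub-seeds spawned via
  `numpy.random.SeedSequence` for simulation, splitting and network
  initialisation; reports are byte-reproducible given the seed.
* Report schema: one row per modality × {raw, constant, reg, net} ×
  {training, test} with centroid, ellipse area, MVD, MSE; the "raw" rows
  are recCP minus the measurement. Plot data (per-eye error vectors and
  100-vertex ellipse polygons) are exported as CSV; no figures are
  rendered.

## Degenerate inputs and tolerances

Vergence transfers raise on a focus exactly at the target plane; the
reconstruction raises on AL ≤ ELP; `forward_refraction` rejects corneal
EQ outside [30, 60] dpt. Zero-variance error clouds have no ellipse
(degenerate-covariance error). Round-trip tolerances: sphero↔vector
1e−12; reconstruction↔forward 1e−9 dpt. Cohort CSVs are written with 17
significant digits and parsed with round-trip float precision, so
write→read is lossless.
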