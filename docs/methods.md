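# Methods

`trimscope` analyses microscopy-based single-cell readouts of Trim-Away
protein degradation in resealed (SLO-permeabilized, then closed) cell
populations, and ships a synthetic cyclic-immunofluorescence (CycIF)
generator that plays the role of the raw microscopy data. Every stage of the
image pipeline can therefore be validated against known per-cell ground
truth. This note records the model, its assumptions, the defaults that
matter, and what passing tests do and do not establish.

## Population model

Each simulated cell carries latent truths sampled independently unless noted:

* **Permeabilization.** SLO pore formation is cholesterol dependent, so the
  probability that cell *i* is permeabilized at dose *d* follows a Hill curve
  at a per-cell effective dose:

      p_i = (d·c_i)^h / ((d·c_i)^h + K^h),   c_i ~ LogNormal(0, σ_chol)

  with h = 2, σ_chol = 0.3. K is not set by hand: it is calibrated by
  Monte-Carlo root finding so that E[p] at the optimal dose (0.2 µg/ml
  equivalent) equals the measured 74.6% antibody-positive fraction for
  HEK293T cells. The main text reports 0.2 µg/ml as optimal while the figure
  legend says 0.1 µg/ml; the presets follow the main text, and the
  discrepancy is simply noted.
* **Delivery.** Permeabilized cells receive an antibody amount
  A_i ~ LogNormal(ln 300, 0.7) AU; non-permeabilized cells receive none.
  The non-targeting control (NC) condition draws the identical distribution —
  the control IgG is delivered and stained the same way — so gating behaves
  identically across conditions.
* **Resealing failure.** A small fraction of permeabilized cells fail to
  reseal ("died", the propidium-iodide-positive cells): Bernoulli with
  default probability 0.01 among permeabilized cells. The `reseal-fail`
  preset scales this so the *overall* died rate is the observed ~1%.
* **Degradation kinetics.** The source study reports endpoint reductions,
  not a rate law, so the kinetic form is a design choice: first-order decay
  saturating in both antibody and TRIM21, with an optional resistant pool,

      X_i = X0_i · [f_res + (1 − f_res) · exp(−k_i t)],
      k_i = k_max · A_i/(A_i + K_A) · T_i/(T_i + K_T),

  with K_A = 150 AU, K_T = 300 AU half-saturations near the respective
  distribution medians. This is the simplest form that produces the
  qualitative behaviours of interest: deeper knockdown with longer
  incubation, limitation by TRIM21 abundance, and incomplete degradation of
  a partly inaccessible target (f_res = 0.15 for the mTOR preset, motivated
  by its lysosome-associated pool). No resynthesis term is modelled; presets
  stay at incubations ≤ 12 h, where recovery is negligible.
* **Downstream signalling.** Phospho channels track the remaining target as
  P_i = β·X_i^γ·exp(ε), ε ~ N(0, σ). A high-pS6 subpopulation (probability
  0.15, fold 2.5) models cell-cycle-driven S6 phosphorylation that is
  independent of the targeted kinase. Total Akt and S6 are independent
  lognormals.
* **Spatial mode.** `center_gradient` emulates adherent electroporation
  between central electrodes: permeabilization is thinned by a radial
  logistic falloff g(r) = 1 − a·σ(s·(r/R − m)) with defaults a = 0.9,
  m = 0.3, s = 10, giving an antibody-positive core and a mostly negative
  periphery.

## Calibration

`calibrate_knockdown` solves for k_max (all else fixed) so the expected
*bulk* knockdown — 1 − E[X | targeting]/E[X | NC] over all resealed cells,
permeabilized or not, i.e. the western-blot-equivalent readout — equals a
stated value. The expectation is evaluated on a 50,000-cell Monte-Carlo
population with a fixed calibration seed, and brentq root finding in log k
exploits the monotonicity of knockdown in k_max. Infeasible targets are
rejected with the analytic ceiling, permeabilized mass × (1 − f_res).
Presets are calibrated to the measured bulk reductions: IKKα 40% (30 min),
65% (3 h), 41% (endogenous TRIM21 only), 59%/31% (two-step resealing with /
without supplemented TRIM21 protein, encoded as high / low TRIM21
lognormals), mTOR 44% (12 h, f_res > 0).

## Rendering

Cells sit on a jittered grid guaranteeing a 26 px minimum spacing in a
1024×1024 field (0.33 µm/px, 40× confocal scale; ~700 cells per field by
default — multi-field experiments are simple iteration with derived seeds).
Nuclei are filled ellipses (semi-axes 5.5–8.5 px; died cells shrunken to
0.6×); the cell region is the nucleus thickened 12 px with nearest-centre
collision clipping; per-cell channel intensities are uniform over their
compartment (antibody over the whole cell, target over cytoplasm plus 0.5×
in the nucleus, phospho/baseline channels over cytoplasm, PI over the
nucleus of died cells). Per-cell true means are rounded to integer AU so a
noise-free render reproduces them *exactly* after 16-bit quantization —
this is what makes the exactness contracts in the tests possible.

Acquisition artifacts per round: integer stage drift drawn from
round(N(0, 2 px)) (round 1 is always (0,0)); bleaching carryover adds 2% of
the previous round's same-slot scene before noise; a background plane
(8 AU) with a linear illumination gradient (3 AU amplitude); Poisson shot
noise on signal+background; Gaussian read noise (sd 2 AU); clipping to
uint16. Optics are deliberately not modelled (no PSF, no z-blur, no cell
motion): registration and segmentation on these images are easier than on
real confocal data, so pipeline accuracies measured here are upper bounds.

## Pipeline

* **Registration** is translation-only (fixed plate, repositioned stage):
  normalized frequency-domain cross-correlation of each round's Hoechst
  image against round 1, sub-pixel refinement at 0.1 px (upsample 10), via
  `skimage.registration.phase_cross_correlation`. Shifts above 10% of the
  image width are flagged low-confidence, not silently accepted. Integer
  shifts are applied as exact pixel moves, fractional ones bilinearly;
  exposed borders are zero-filled and excluded through a validity mask.
* **Segmentation**: Otsu threshold (fixed-threshold override available),
  hole filling, minimum area 25 px, optional watershed splitting seeded at
  local maxima of the smoothed distance transform (seed separation 15 px,
  larger than one nucleus's ridge, so single ellipses never oversplit).
  Cells touching the border or invalid pixels are flagged and excluded from
  statistics by default.
* **Quantification** measures mean and sum intensity of the *cell* region
  for every round/channel (columns `r{round}_{channel}_{mean|sum}`); the
  cytosol region is used only for per-cell Pearson colocalization. No
  background subtraction by default (raw intensities); the preset pipelines
  enable per-field median-of-non-cell-pixels subtraction because the
  additive background otherwise biases the ratio-of-means knockdown toward
  zero.
* **Died-cell exclusion** thresholds the PI-like channel at
  median + 10 × 1.4826·MAD of the per-cell means (scale floored at 1 AU so
  noise-free fields behave): a data-driven rule mirroring the study's
  propidium-iodide identification, exact on synthetic fields.
* **Gating**: positive threshold = 99th percentile of a no-delivery control
  null (the study never states its rule numerically; the rule and null
  source are recorded in output metadata).
* **Knockdown** = 1 − mean(target | treated)/mean(target | control), ratio
  of means rather than mean of ratios, matching densitometry aggregation;
  per-cell-bootstrap percentile CI (default 1000 resamples, seeded; the
  pipeline presets use fewer where only the point estimate matters). Modes:
  bulk (all usable cells), gated (antibody-positive only), top-percentile.
* **Separation curve**: absolute standardized mean difference (or KS
  statistic) between conditions after filtering both arms to their top
  delivery percentile, at levels {100, 50, 25, 10, 5}; subsets under 20
  cells are marked unreliable.
* **Statistics**: Welch's t with Welch–Satterthwaite df; many-to-one
  comparisons use per-group Welch tests with Holm adjustment — a deliberate
  approximation of Dunnett-style testing that avoids multivariate-t
  critical values, conservative for the family sizes used here.
* **Embedding**: t-SNE (scikit-learn) on pooled z-scored features,
  perplexity 30, fixed seed; coordinates are visual QC only and no
  quantitative claim attaches to their geometry.

## Numerical and degenerate-input choices

All randomness flows through `numpy` Generators keyed by (stream, seed), so
adding a round or channel never perturbs the sampled population, and
identical configs are bit-identical end to end (CSV output uses a fixed
float format to keep reruns byte-identical). Thresholding an all-background
image yields an empty label image with a warning, not an error; empty
cytosols, zero-variance correlation regions, and non-positive ratio
denominators become flagged missing values, never imputations; constant
images, mismatched shapes/labels, and infeasible calibration targets raise
informative errors.

## Problem sizes

Recovery analyses use ≥ 2000 segmented cells per condition (three 1024²
fields) and 5600 cells for the resealing-failure rate, sizes at which the
binomial/bootstrap noise of each recovered statistic is comfortably inside
the ±3-percentage-point comparison bands; tests use smaller 256²–900²
fields where only contracts, not population statistics, are at stake.

## What the synthetic data does not show

The generator reproduces the *statistical* structure of the experiment —
delivery heterogeneity, bystander dilution, TRIM21 limitation, correlated
downstream signals, drift/bleed/noise — but not optical realism, nuclear
texture, confluent cell boundaries, or segmentation-hostile artifacts.
Passing recovery targets therefore validates the estimators and pipeline
plumbing, not segmentation robustness on real confocal images; the latter
would need annotated real data.
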