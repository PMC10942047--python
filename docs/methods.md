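# Methods

## Reader model and posterior

Each image carries a latent probability *x* that a single physician records
the finding.  Readers are exchangeable and conditionally independent given
*x*.  The two-stage protocol yields a diagnosis group
D ∈ {(P,PP), (P,PN), (P,NN), (N,PP), (N,PN), (N,NN)}: the first stage is the
union of two readers (P with likelihood x² + 2x(1−x), N with (1−x)²), the
second stage keeps two readers' calls individually (PP: x², PN: 2x(1−x),
NN: (1−x)²).  The group likelihood is the product of the stage likelihoods —
a polynomial of degree ≤ 4 with non-negative values on [0, 1].

With a uniform prior (no prior information about x is assumed), posteriors
and their means are exact rationals via the Beta integral
∫₀¹ xᵃ(1−x)ᵇ dx = a!·b!/(a+b+1)!.  All normalizers and expectations are
computed in `fractions.Fraction` arithmetic; floating-point quadrature
appears only as an independent oracle in the tests.  The combinatorial
factor 2 in the PN likelihood cancels in the posterior but is kept for
consistency between raw stage likelihoods.  A Beta(a, b) prior would slot
into the same Beta-integral identities, but the package intentionally fixes
the uniform case; the six expectations are (7/9, 4/7, 3/8, 1/2, 1/3, 1/6)
and the (P,PP) normalizer is 10/3.

The logit-space density is obtained by the change of variables u = logit(x):
p_u(u|D) = p_x(σ(u)|D)·σ(u)(1−σ(u)).  Note the ordering of expectations is
monotone within a stage but not across stages ((P,NN) = 3/8 < (N,PP) = 1/2):
two concordant recheck positives outweigh a screening flag.

## λ-scaling calibration

A BCE-trained classifier emits logits u of its class probability.  The
scaled output u* = −λu (probability p* = σ(u*)) introduces one free scale
per finding to absorb how sharply the model's output distribution is
resolved relative to the reader posterior.  λ is fitted by minimizing, over
λ ∈ [10⁻³, 10] with a bounded scalar search (tolerance 10⁻⁴), the unweighted
mean over available groups of the distance between:

* the Gaussian-KDE (Silverman bandwidth) of {−λuᵢ : i ∈ D}, and
* the analytic posterior logit density p_u(·|D),

evaluated on a uniform 512-point grid on [−10, 10].  The default distance is
the L2 norm of the density difference; a Cramér–von-Mises-style CDF distance
is available (`distance="cvm"`).  The "distance between distributions" is
under-determined as a statement, so the discretization is declared here:
density-L2 on a fixed grid, deterministic given the inputs.  Groups with
fewer than 10 members are dropped from the objective (warning below two
usable groups; error at zero).  Per-subject logits are averaged across the
K CV models before scaling by default; `per_model=True` pools them instead.

Sign convention: the generative model and the fit default assume u* = −λu,
i.e. raw logits *decrease* with finding probability.  Backends trained with
BCE emit logits that increase with probability; for those the pipeline (and
`--sign +1`) flips the convention.  Fitting λ on c·u returns λ̂/c
(equivariance), which the tests verify at 2%.

## Synthetic cohort generator

The generator defines the study conditions for every statistical check:

* **Severity mixture** per finding: background component
  (Exponential(0.12)) for unaffected subjects and an affected component
  (Uniform(1.55, 3.0)) with mixture weights 0.045476 / 0.009999.
* **Link**: p = σ(a(s − s₀)) with slope a = 3 and threshold s₀ = 2, putting
  affected subjects' p in ≈(0.2, 0.95) and background p near 0.003.  The
  weights were solved against the quadrature oracle
  (`first_stage_positive_rate`) so the merged first-stage positive rates are
  4.46% and 1.58% — the class imbalance of apical pleural thickening and
  scoliosis in large adult screening cohorts.
* **Annotations**: four independent Bernoulli(p) calls per subject/finding;
  stage-one union, stage-two individual.
* **Logits**: u = −(logit(p) + ε)/λ_true with ε ~ N(0, σ²), σ = 0.3 and
  λ_true = 0.79 / 0.22 per finding by default, so −λ_true·u is a noisy
  logit of p.  p is clamped to [10⁻⁶, 1−10⁻⁶] before the logit.
* **Images** (toy): constant background 0.40, an apical band (top 15% of
  rows) brightened proportionally to severity 1, and a bright vertical
  spine ridge whose lateral sinusoidal displacement grows with severity 2;
  additive Gaussian pixel noise (σ = 0.04).  Region masks (`apex_mask`,
  `background_mask`, `spine_mask`) make contrast checks exact.

Two named configurations fix the conditions of specific analyses:

* `uniform_latent_config` — latent p ~ U(0, 1).  Under a flat latent
  density the distribution of p within group D *is* the uniform-prior
  posterior, so this is the matched condition for λ recovery and for
  comparing group means against the analytic expectations.  Under the
  prevalence-realistic default the latent density is far from flat, the
  group-conditional means shift toward it, and the fitted λ absorbs part of
  the mismatch — the correlation stays high but below the matched case,
  which is the expected behavior, not a defect.
* `separable_config` — balanced mixture (π = 0.5) with a high-severity
  affected component (p ≈ 0.82–0.95) and clean background, so merged
  first-stage labels almost always reflect visible image content.  This is
  the classifier benchmark: under the low-prevalence default, a large share
  of positive labels (especially for the rarer finding) comes from
  background images carrying no signal, which caps achievable AUC well
  below 0.9 regardless of the model.

What the generator does **not** emulate: reader correlation and fatigue,
severity-dependent reader sensitivity profiles beyond the logistic link,
anatomical image content, scanner/exposure variation.  Passing tests
demonstrate the statistical mechanism (posterior, calibration, evaluation)
and the trainability of the pipeline, not clinical performance.

## Classifier backend and protocol

The default backend is a compact CNN written in numpy: three 3×3
convolution blocks (8/16/32 channels, ReLU, 2×2 max-pool) and a dense
two-logit head over the **flattened** final feature maps.  Flattening (not
global average pooling) is deliberate: the scoliosis signal is positional —
a laterally displaced ridge — and spatial pooling would erase it.  Training
is Adam at the protocol's initial learning rate 10⁻⁴, batch 64, 5 epochs by
default (loss: sum of the two per-finding BCE-with-logits terms); the
scaled-down benchmark runs use 3 epochs on 64×64 images, which already
saturates held-out AUC on the separable cohort.  Gradients are manual
(im2col/col2im); training is a pure function of (data order, seed).

Protocol pieces follow the screening study design: centered square crop
(default 3000 px) then bilinear resize to 256×256; augmentation of ±5°
rotation then integer shifts up to round(0.05·side) px per axis (13 px at
side 256), zero-filled, rotation before shift; 10-fold CV after excluding a
held-out test set (default 1,000 subjects) with one model trained from
scratch per fold.  Grad-CAM weights are the spatial means of
∂(finding logit)/∂(last-conv maps); the heatmap is the ReLU of the weighted
sum, bilinearly upsampled and max-normalized.

Metrics: AUC by the Mann–Whitney rank statistic with midrank tie handling;
F1/precision/recall/specificity/accuracy at threshold 0.5 (the table
convention; the threshold is a reporting choice, not part of the model).
Precision with no predicted positives is 0 with a warning.

## Evaluation

Group statistics use the sample SD (ddof = 1).  The posterior correlation is
Pearson's r between the non-empty groups' mean calibrated probabilities and
the exact expectations (≥ 3 non-empty groups required); group means are
computed on p* by default, with a raw-σ(u) option.  Between-model
reproducibility is the Pearson r over held-out subjects for each of the
K(K−1)/2 model pairs (45 at K = 10), overall and restricted to second-stage
outcome subsets.  Cohen's κ uses the standard two-rater binary form
(p_o − p_e)/(1 − p_e), undefined at p_e = 1.

## Numerical choices and problem sizes

* Exact rational arithmetic for all posterior summaries; quadrature
  tolerances 10⁻¹⁰ (probability space) and 10⁻⁸ (logit space) in tests.
* KDE-grid calibration: 512 points on [−10, 10]; posterior densities are
  effectively zero outside ±10 for all six groups.
* Pipeline stage seeds are spawned from the single run seed via
  `numpy.random.SeedSequence`, so every artifact is bit-identical across
  reruns of the same (config, seed).
* Test problem sizes: λ recovery uses 10 seeds × n = 20,000 subjects with
  σ = 0.3; the end-to-end correlation check n = 10,000; the classifier
  benchmark 2,000 images at 64×64 with a 500-subject held-out set; group
  frequency and agreement checks use 10⁵–2·10⁵ draws.  These sizes hold the
  Monte-Carlo error comfortably inside the asserted tolerances while
  keeping the default suite quick.

## Known limitations

* Exchangeable readers only: no per-reader sensitivity/specificity, no
  reader correlation; κ in the synthetic world reflects only the Bernoulli
  mechanism.
* The λ fit assumes the annotated cohort's latent-p distribution matches
  the posterior's prior (flat); systematic deviation biases λ̂ (see above).
* The CNN backend is CPU-scale and single-threaded; it is a reference
  implementation of the training protocol, not a competitive radiograph
  classifier.
* Toy images are geometric stand-ins; Grad-CAM checks verify localization
  of synthetic structures only.
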