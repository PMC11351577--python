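# Methods

This note records the model, its assumptions, the parameters that matter,
and the design decisions taken where the architecture left choices open.

## Pipeline and assumptions

The classifier assumes genuinely **paired** modalities: each subject has
one CXR and one CT image, keyed by `subject_id`, and the two feature
vectors are fused per subject. Images are 8-bit grayscale on a 1–255 scale;
a file value of 0 is floored to 1 (not rejected) so ordinary PNGs load.
Preprocessing resizes to a square side (default 1024 px) with bilinear
interpolation, chosen for determinism and ubiquity; results are re-clamped
to [1, 255].

Stages run strictly in order: per-modality CNN features → concatenation
(CXR block first, split index recorded so fusion is losslessly invertible)
→ SVD compression to five features → five-qubit variational circuit (or an
identity pass-through in the ablation) → 100/50/20/3 dense softmax head.

## Backbones

The default backbone is a tiny seeded CNN: two conv(3×3, valid, stride 1) +
max-pool(2) blocks of 8 and 16 filters, then a 64-unit ReLU dense feature
layer, on 64×64 input scaled to [0, 1]. Weight initialization is He-normal
from a stage-namespaced generator. Fine-tuning appends a 3-logit softmax
head on z-scored features (the scaler is part of the head, stored and
applied at inference); the convolutional body stays frozen by default —
the cheapest faithful reading of "fine-tuned", and configurable.

The six large backbones of the original architecture are reachable only
through `PretrainedBackboneAdapter`, which declares each model's feature
layer and dimension (512 for the VGGs, 2048 for the rest) and accepts a
caller-supplied forward function; their pretrained weights are external
artifacts this package does not bundle or imitate.

## SVD compression

The fused training matrix is column-mean centered before the thin SVD.
Centering is required for the denoising interpretation (directions of
maximal variance, equivalently top eigenvectors of the centered Gram
matrix) and can be switched off. The projector stores the mean, the top-5
right singular vectors and their singular values; each basis column is
sign-fixed so its largest-magnitude entry is nonnegative, making results
reproducible across linear-algebra backends. The projector is fit on the
training split only — anything else leaks test data into the
representation — and inference applies the stored mean and basis.

## Quantum layer

The simulator is a dense statevector engine (complex amplitudes over all
2^n basis states, little-endian: qubit 0 is the least-significant bit),
capped at 12 qubits; the classifier uses 5. Gates are validated unitary to
1e-12 at construction. Measurement returns deterministic Pauli-Z
expectations, |0⟩ ↦ +1; a shot-sampling mode exists for demonstration but
never feeds training, keeping the optimization deterministic.

The ansatz is: Hadamard wall, RY(xᵢ) angle embedding (one feature per
qubit), then `n_var_layers` (default 2) blocks of per-qubit RY(θ) followed
by a linear CNOT chain 0→1→…→4. The phase (S) gate is provided in the gate
library but not placed in the default ansatz, since its position in the
original circuit diagram is not specified. Features are mapped to angles in
[0, π] by a per-feature min–max scaler fit on training data (constant
features map to π/2; out-of-range inference values are clamped). On that
interval the composition H → RY(φ) → ⟨Z⟩ equals −sin(φ), which is injective
on [0, π] up to its endpoints, so the embedding preserves feature ordering.

Gradients of the variational angles use the parameter-shift rule, which is
exact for RY/RZ generators; tests require agreement with central finite
differences (h = 1e-5) to 1e-5, and the measured worst-case disagreement is
orders of magnitude smaller.

## Head and training

The dense head uses ReLU hidden layers, He initialization and a
softmax/cross-entropy output; its backward pass also returns the gradient
with respect to the five inputs so the circuit parameters are trained
through the chain rule (head input gradient × parameter-shift Jacobian).
Joint training uses minibatch Adam (defaults: lr 1e-3, batch 16, β₁ 0.9,
β₂ 0.999, ε 1e-8); `lr = 0` and `epochs = 0` are exact no-ops by contract.
Subjects are split 70/15/15 stratified by class from a seeded generator;
the projector, scaler and all trained weights depend only on the training
split. History rows report training accuracy and loss as percentages; loss
is normalized by ln 3 so a uniform predictor scores 100%. Optional
patience-based early stopping is provided but off by default.

The **traditional** baseline replaces the circuit with an identity
pass-through of the five SVD features into the same head, produced by the
same code path, so hybrid-vs-traditional comparisons differ in exactly one
stage.

## Phantom generator

The generator emulates the statistical structure the pipeline depends on,
not radiological appearance. Per subject it draws a lesion latent —
count, centers, radii, intensity offsets — and renders it twice: CT as
sharp disks on a quiet background (base 60, noise σ/2), CXR as the same
disks Gaussian-blurred (σ = 2 px) at 0.8 weight over a rib-stripe
background (base 120, sinusoidal stripes of amplitude 15 and period 9 rows)
with full noise (σ = 4 gray levels). Class conditions are ordered by
construction: malignant draws 2–4 lesions of radius 8–12 px and intensity
60–90; benign 1–2 lesions of radius 3–5 px and intensity 30–50; normal
none. Default study size is 300 subjects at 64×64 px with class proportions
25/25/50 (normal/benign/malignant), echoing a screening-style mix in which
half the scans carry malignant findings.

What passing tests therefore show: the pipeline recovers class structure
that is genuinely present across two differently-rendered modalities, with
correct dimensions, no split leakage, and exact gradients. What they do not
show: performance on real radiographs, whose lesions are not disks, whose
backgrounds are anatomy rather than stripes, and whose class boundaries are
far noisier.

## Numerical choices and degenerate inputs

- State norms must be within 1e-6 of 1 at construction; gate application
  preserves norm to better than 1e-9 over 50-gate sequences (tested).
- Metric cells that evaluate 0/0 are defined as 0 and flagged rather than
  raised, keeping batch evaluation total. Percentages are rounded to two
  decimals only at reporting time.
- ROC threshold sweeps group tied scores into single steps; the trapezoidal
  area then equals the pairwise concordance statistic (tested exhaustively
  up to n = 50).
- One-vs-rest collapse treats malignant as the positive class by default;
  the choice is a parameter, not a hard-coded convention.
- Class counts in generated datasets use largest-remainder rounding so they
  always sum to the requested subject count.
- All randomness derives from one root seed through CRC32-namespaced
  SeedSequences, so stages are independently re-runnable and whole runs are
  bit-reproducible.

## Problem sizes

Desk-scale defaults were chosen so a full study runs in about a minute on
one CPU: 300 subjects, 64×64 images, 30 epochs for the end-to-end smoke
study; smaller sizes (tens of subjects, ≤ 12 epochs) for unit tests and
examples. The 5-qubit circuit costs 32 complex amplitudes per state, so the
parameter-shift Jacobian (20 extra circuit runs per sample) dominates
hybrid training time.

## Known limitations

- Only the per-subject-paired reading of two-modality fusion is
  implemented; fusing across unpaired datasets is undefined here.
- The adapter for large pretrained backbones declares contracts but cannot
  run without caller-supplied weights/forward functions.
- The simulator is dense and single-threaded; 12 qubits is a practical
  ceiling and no noise model is provided.
- Published evaluation tables for this family of models contain internal
  inconsistencies (e.g. an overall accuracy of 92.12% alongside an error
  tally whose arithmetic gives 92.00%, and abstract-level metrics that
  differ from the corresponding table row). The metric formulas here are
  the standard ones; those discrepancies are documented, not reconciled.
- Data augmentation (rotation/flip/scale) is a recognized preprocessing
  step for this task but is left as a disabled configuration stub because
  no parameterization was specified.
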