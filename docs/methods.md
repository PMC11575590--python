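# Methods

## Model

The quantity modeled is the dimensionless molar Gibbs excess energy
ḡ(x₁, T) = g^E/(RT) of a binary liquid mixture. The network is

    ḡ(x₁, T) = x₁(1−x₁) · d_cos(h₁, h₂) · g_NN,
    h_i  = f_θ(z_i),                       z_i = standardized raw embedding E_i
    c_i  = [h_i, T*, x_i],                 x_1 = x₁, x_2 = 1−x₁
    g_NN = f_φ( f_α(c₁) + f_α(c₂) )

with R = 8.31446 J/(mol·K), T in Kelvin, and T* the standardized
temperature. f_θ (D→H→H) and f_φ (H→H→1) have one hidden layer, f_α
(H+2→H→H→H) has two; SiLU activation on all hidden layers; H defaults to
96 nodes and the raw embedding width D to 384. Pressure is not an input:
its influence on liquid-phase activity coefficients is small and is
neglected throughout (also in the VLE conversion, which treats the vapor as
an ideal-gas mixture).

Activity coefficients are derivatives of ḡ:

    ln γ₁ = ḡ + (1−x₁)·ḡ′,   ln γ₂ = ḡ − x₁·ḡ′   (ḡ′ = ∂ḡ/∂x₁ at constant T)

Four consistency properties hold for arbitrary weights, by construction:
pure-component limits (the x₁(1−x₁) factor), ideality of pseudo-binary
"mixtures" of a component with itself (the cosine-distance factor),
permutation equivariance (sum aggregation over streams that each carry
their own mole fraction — concatenating x₁ to both streams would break the
set symmetry, which is why each stream gets x_i), and the Gibbs–Duhem
equation (both ln γ_i are derivatives of one smooth scalar). The checkers
in `thermo` measure the numerical residuals of these identities rather than
assuming them.

## Differentiation and training mathematics

No autodiff framework is used; the package implements exactly what it
needs, in numpy (`_net.py`):

* **Prediction path**: second-order forward mode propagates (value, ∂/∂x₁,
  ∂²/∂x₁²) through f_α and f_φ (the x₁-dependence enters only through the
  concatenated composition features, with seed derivatives +1 and −1 in the
  two streams). ln γ needs the first derivative; the Gibbs–Duhem checker
  needs the second. Finite differences appear only in tests, as an
  independent oracle (central, step 1e-6 for first derivatives, 1e-4 for
  second differences, which is the accuracy-optimal region for 64-bit
  floats).
* **Training path**: the loss is a function of both ḡ and ḡ′, so reverse
  mode runs over the first-order dual forward pass: each layer's backward
  rule propagates adjoints of the value channel and of the derivative
  channel jointly (for SiLU this couples through f″). The cosine-distance
  factor is differentiated analytically; its gradient vanishes identically
  at h₁ = h₂. The full gradient is verified against central finite
  differences for every parameter tensor in the test suite.
* **Optimizer**: AdamW (decoupled weight decay, applied to all parameters,
  default λ = 0.01), β = (0.9, 0.999), ε = 1e-8.

Numerical choices: cosine similarity is clipped to [−1, 1]; a row whose two
raw embeddings are bitwise identical short-circuits to d_cos = 0 exactly,
so the pseudo-binary zero holds at machine precision instead of ~1e-16 (the
analytic d_cos gradient is zero there, so training is unaffected). A
component embedding with norm below 1e-12 raises `ZeroVector` rather than
being clamped: a zero f_θ output is a pathological parameterization and
silently "consistent" output would be meaningless. Weights initialize
uniform fan-in (U(±1/√fan_in)) from a recorded seed.

## Embeddings and scaling

Backends share one interface. The default, offline backend maps any
component tag to a deterministic unit-norm Gaussian vector keyed on
SHA-256(seed:tag) — bitwise reproducible across platforms, no chemistry.
The optional chemical-language-model backend produces the 384-dimensional
CLS-token embedding of a pretrained SMILES transformer (max 512 tokens) and
raises `BackendUnavailable` when its dependencies are absent; callers fall
back explicitly, never silently. Embeddings are computed once per unique
component and cached; gradients never flow into them.

Embeddings and temperature are standardized with statistics fitted on the
training rows only (both component columns stacked), population std
(ddof=0), zero-variance dimensions set to std 1 with a warning. Mole
fractions are never scaled. The scalers are serialized inside the
checkpoint (a single JSON artifact also carrying layer sizes, activation
name, backend id and the training config), so a loaded checkpoint
reproduces predictions bit-for-bit.

## Training protocol

Defaults follow the reference protocol: smooth-L1 loss (β = 0.25) over
every available ln γ label (one-sided records contribute one term; mean
reduction over label terms), batch size 512, AdamW lr 1e-3 (5e-4 available),
plateau scheduler ×0.1 with patience 10 epochs on the validation loss
(strict improvement, no min-delta), early stopping after 30 epochs, best
validation checkpoint returned. Splitting is system-wise: the unit of
assignment is the unordered component pair, so no mixture appears in two
sets; partition at ⌊0.8n⌋/⌊0.9n⌋ after a seeded shuffle.

## Synthetic data

The generator emulates the observable a VLE-derived dataset provides —
noisy ln γ_i(T, x₁) labels for binary systems — from analytic g^E models
whose consistency is exact by construction:

* two-parameter Margules, ḡ = x₁x₂(A₂₁x₁ + A₁₂x₂), with A_ij(T) = a_ij +
  b_ij/T, a ∈ [−0.5, 2.0] (the range of moderately non-ideal organic
  mixtures), b ∈ [−60, 60] K (≈ ±0.2 shift in A across 290–360 K, enough to
  exercise the temperature input without dominating it);
* NRTL with τ ∈ [−0.5, 1.5] and non-randomness α ∈ [0.2, 0.47] (the range
  used in practice), temperature-independent.

Per system: 15 compositions uniform on (0,1), temperatures uniform on
290–360 K, i.i.d. Gaussian label noise of sd 0.02 (the order of a careful
VLE experiment's uncertainty in ln γ), optional one-sided
infinite-dilution records at x₁ ∈ {0, 1}. Component tags are plain strings
routed to the hash backend. What this does *not* emulate: the chemistry
(embeddings carry no structural information, so generalization to unseen
*components* is not probed), the skewed per-system data counts of real
databases, correlated/systematic measurement error, and gross outliers.
Passing the recovery test therefore demonstrates that the architecture,
differentiation and optimizer can fit and interpolate consistent mixture
data — not that the hash backend predicts chemistry.

## The parameter-recovery experiment

Conditions: 20 Margules systems × 15 points, noise sd 0.02, hash embeddings
(D = 32), H = 32; per system 9 points train / 3 validation / 3 test
(within-system composition holdout, so the measured error is interpolation
to unseen state points of known systems). Success is held-out
MAE(ln γ) < 0.05 — below that level the model has recovered the underlying
curves to within a few times the label noise.

The optimization schedule is rescaled for the dataset size: the epoch-based
patience values of the reference protocol presuppose hundreds of optimizer
updates per epoch, while 270 training points at batch 512 would give one.
The experiment uses batch 16 and patience 100 (scheduler) / 300 (early
stop) epochs with an epoch cap of 3000, holding the optimization budget
between schedule events roughly constant in *updates*; learning rate, decay
factor, weight decay and loss β are unchanged. Runs finish in 500–900
epochs (~10 s on one CPU) with held-out MAE ≈ 0.02–0.03 across seeds.

## VLE diagrams

Isothermal p-x-y diagrams invert extended Raoult's law directly:
p = x₁γ₁p₁^S + x₂γ₂p₂^S, y₁ = x₁γ₁p₁^S/p, with Antoine vapor pressures
(each parameter set declares its temperature unit, pressure unit, log base
and validity range; evaluation outside the range warns). Default grid 101
points. An azeotrope is an interior root of y₁(x₁) − x₁, bracketed on the
grid and refined by bisection on the continuous model to 1e-6 in x₁.
Classification: the azeotropic pressure above both pure-component vapor
pressures ⇒ pressure-maximum (low-boiling); below ⇒ high-boiling. (The
slope dp/dx₁ is exactly zero at an azeotrope, so it cannot classify.)

## Known limitations

* Binary mixtures only; multicomponent systems, excess enthalpies and
  pressure dependence are out of scope.
* The offline backend makes component identity purely nominal; accuracy
  numbers obtained with it say nothing about extrapolation across real
  chemistry.
* The plateau/early-stop bookkeeping uses strict improvement with no
  min-delta; on very noisy validation sets this can stop late.
* Training is CPU-bound numpy; it is sized for desk-scale datasets
  (10²–10⁴ points), not database-scale regression.
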