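# gammanet

A hard-constraint neural network for the molar Gibbs excess energy of binary
liquid mixtures, and thermodynamically consistent activity coefficients
derived from it by exact differentiation.

## The problem

Activity coefficients γ_i describe the non-ideality of components in a
liquid mixture and underpin phase-equilibrium calculations (distillation,
extraction, crystallization). Plain neural networks can regress ln γ_i well,
but nothing forces their predictions to obey thermodynamics: the two
coefficients of a binary mixture are coupled by the Gibbs–Duhem equation,
must be unity for pure components, and must be invariant under relabeling
the components. Models that violate these laws are unusable in practice.

`gammanet` builds the laws into the architecture instead of into the loss.
The network predicts one scalar function, the molar Gibbs excess energy

    g^E(x₁, T) = x₁(1−x₁) · d_cos(f_θ(E₁), f_θ(E₂)) · R·T · g_NN(x₁, T*)

where E_i are fixed per-component embedding vectors, f_θ is a component
embedding network, d_cos is the cosine distance between the two refined
embeddings, and g_NN = f_φ(f_α(c₁) + f_α(c₂)) is a deep set over the two
component streams c_i = [f_θ(E_i), T*, x_i] (each stream carries its *own*
mole fraction). The activity coefficients follow by exact differentiation:

    ln γ₁ = ḡ + (1−x₁)·dḡ/dx₁,   ln γ₂ = ḡ − x₁·dḡ/dx₁,   ḡ = g^E/RT

Consequences, for *any* network weights, before any training:

* x₁(1−x₁) → g^E and both ln γ_i vanish at the pure-component limits;
* d_cos → a "mixture" of a component with itself is exactly ideal;
* the sum aggregation → predictions are permutation-equivariant;
* differentiating one smooth scalar → Gibbs–Duhem holds identically.

Training only improves accuracy; consistency is structural.

Everything runs offline on numpy: the forward pass, exact first- and
second-order differentiation in x₁ (forward mode), gradients of the loss —
which itself contains dḡ/dx₁ — with respect to all weights (reverse mode
over forward mode), and an AdamW optimizer. Components are embedded either
by a pretrained chemical language model (optional, needs `transformers`) or
by a deterministic hash-based fallback that makes the whole pipeline
reproducible with no downloads.

## Worked example

Generate a synthetic training set from analytic Margules models (20 systems,
15 points each, label noise 0.02), train a small model, predict, and check
consistency:

```sh
$ gammanet synth --systems 20 --points 15 --noise 0.02 --seed 11 --out data
wrote 300 records to data/synthetic_gamma.csv (truth: data/synthetic_truth.json)

$ gammanet train --data data/synthetic_gamma.csv --out model.json \
    --hidden 32 --embedding-dim 32 --batch-size 16 --max-epochs 400 --seed 0
saved checkpoint to model.json; best val loss 0.08968; test median system MAE 0.1205

$ gammanet predict --checkpoint model.json --smiles1 SYN_000 --smiles2 SYN_001 --t 320
 x_1  ln_gamma_1  ln_gamma_2  gE_J_per_mol
0.00    0.264157    0.000000      0.000000
0.02    0.253653    0.000106     13.774130
0.04    0.243364    0.000424     26.983762
...
```

`ln_gamma_1` at x₁=0 is the infinite-dilution coefficient of component 1;
`ln_gamma_2` is exactly 0 there (pure component 2), and `gE_J_per_mol`
vanishes at both ends — the hard constraints at work. The `train` command
splits *system-wise* (no component pair appears in two sets), so its test
MAE measures extrapolation to unseen mixtures; interpolation to held-out
compositions of known systems reaches MAE(ln γ) < 0.05 at this scale (see
the acceptance suite).

```sh
$ gammanet check --checkpoint model.json --smiles1 SYN_000 --smiles2 SYN_001
            criterion                grid  max_violation    tolerance  passed
pure_component_limits         x1 in {0,1}   0.000000e+00 1.000000e-12    True
 identical_components    99-point x1 grid   0.000000e+00 1.000000e-10    True
          gibbs_duhem    99-point x1 grid   2.775558e-17 1.000000e-06    True
          permutation x1 in {0.1,0.5,0.9}   0.000000e+00 1.000000e-10    True
```

Isothermal p-x-y phase diagrams (with azeotrope detection) come from
`gammanet vle --checkpoint … --antoine antoine.csv --t 350 --out diagram.csv`.

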