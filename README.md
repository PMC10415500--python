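# turingfit

Predicting reaction–diffusion model parameters from a *single* observed
Turing pattern.

## The problem

Reaction–diffusion systems of the form

    ∂u/∂t = f(u) + D Δu

can undergo a *Turing (diffusion-driven) instability*: a homogeneous
equilibrium u\* that is stable for the reaction-only dynamics is destabilized
by diffusion at finite wavenumbers, producing stationary spots, stripes or
labyrinths. The inverse problem — given one steady-state pattern, recover the
kinetic parameters that generated it — is hard because the arrangement of
local structure depends on unknown random initial conditions.

`turingfit` addresses this for the dimensionless two-species
Gierer–Meinhardt activator–inhibitor model

    f(u) = ( a − b·u₁ + u₁²/(u₂(1 + c·u₁²)),  u₁² − u₂ ),
    D = s·diag(1, δ),

with basal production *a*, degradation *b*, saturation *c*, inhibitor
diffusion ratio δ and diffusion scale *s*. It is aimed at researchers in
mathematical biology and machine learning who want a self-contained,
simulation-trained pattern→parameter pipeline.

## The method

1. **Simulation.** Patterns are integrated on an n×n torus with an implicit
   Euler scheme; each step's linear solve diagonalizes in Fourier space
   (block-circulant `I − hδL`), and the nonlinear part is handled by a
   fixed-point iteration with adaptive step halving.
2. **Invariant representation.** The pattern becomes a weighted grid graph
   (unit weight within high/low plateaus, small weight ε across the mean
   crossing). Effective resistances R(v,v′) between each node and all nodes
   within radius *r* are binned into a **resistance distance histogram
   (RDH)** — a B-bin point in the probability simplex that is exactly
   invariant to shifts, 90° rotations and reflections of the pattern, and
   nearly invariant to the initial conditions.
3. **Learning.** Pattern→parameter maps are learned from simulated training
   pairs with
   * ε-insensitive **support-vector regression** with the **Wasserstein
     kernel** `exp(−d²_W/γ)` (1-D optimal transport between histograms,
     closed form via quantile functions) for single parameters,
   * an **operator-valued-kernel** joint regressor (input Wasserstein kernel ×
     conditional covariance of a Gaussian output kernel, Kronecker system
     solved matrix-free with GMRES, pre-image by gradient descent) for the
     full parameter vector,
   * small **feedforward ReLU networks** as a baseline.

   Accuracy is reported as NRMSE (RMSE divided by the mean target value);
   0.2 is a good prediction, 0.05 an excellent one.

All estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`), so they compose with sklearn model selection.

## Worked example

```python
from turingfit import KernelSVR
from turingfit.simulate import SimulationConfig
from turingfit.workbench import (SweepSpec, generate_dataset, featurize_dataset,
                                 FeatureConfig, DEFAULT_GAMMA_GRID, DEFAULT_LAM_GRID)
from turingfit.evaluate import split_dataset, grid_search

# 30 patterns with c ~ U[0, 1.15] (a=0.02, b=1, delta=100, s=0.25), 32x32
manifest = generate_dataset(SweepSpec.c_sweep(30, n_r=32, base_seed=5),
                            SimulationConfig(t_final=500))
X, Y, r_max = featurize_dataset(manifest, FeatureConfig(radius=8.0))
print(X.shape, round(r_max, 1))          # (30, 12) 43.4

y = Y[:, 2] / Y[:, 2].max()              # normalized saturation parameter c
tr, va, te = split_dataset(30, seed=0)

def fit_one(params, Xd, yd):
    est = KernelSVR(kernel="wasserstein", gamma=params["gamma"],
                    lam=params["lam"], epsilon=0.01)
    return est.fit(Xd, yd).predict

res = grid_search(fit_one, {"gamma": list(DEFAULT_GAMMA_GRID),
                            "lam": list(DEFAULT_LAM_GRID)},
                  X[tr], y[tr], X[va], y[va], X_test=X[te], Y_test=y[te])
print(round(res.best_val_nrmse, 3), round(res.test_nrmse, 3))  # 0.192 0.115
```

The first print shows the feature matrix (one 12-bin RDH per pattern) and
the calibrated histogram ceiling. The grid search picks the kernel scale γ
and regularization λ on the validation split; the final test NRMSE of
about 0.12 means predictions of *c* are off by roughly 12 % of its typical
magnitude — from 18 training patterns at a coarse 32×32 resolution.

A command-line interface wraps the main steps:

```bash
turingfit simulate --a 0.02 --b 1 --c 0.5 --delta 100 --s 0.25 \
    --n-r 64 --seed 7 --out pattern.npy
turingfit featurize pattern.npy --radius 8 --out features.json
turingfit check-turing --a 0.02 --b 1 --c 1.2 --delta 50 --s 0.5  # exit 1
```

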