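# dynfc

Whole-brain mean-field simulation and static/dynamic functional-connectivity
fitting.

`dynfc` is for computational neuroscientists who want to relate individual
resting-state functional connectivity (FC) to neurophysiological parameters
through a generative brain-network model. It simulates regional activity
with the reduced Wong-Wang excitatory/inhibitory mean-field model coupled
through a structural connectome, converts it to BOLD with the
Balloon-Windkessel hemodynamic model, and fits simulations to *both* static
FC and dynamic FC metrics of each subject by grid search. Downstream stages
quantify how fitted parameters and fit qualities relate to FC features
(permutation-tested correlations with FDR control; ridge-regression
prediction with nested cross-validation and permutation feature
importance), and probe the network by perturbing the coupling of one region
at a time. A synthetic-data module generates connectomes and ground-truth
cohorts so the entire pipeline is testable without any data download.

## The model

Each region i holds an excitatory (E) and inhibitory (I) population with
synaptic gating variables S in [0, 1]:

    I_i^E = w_E I_0 + w_p J_N S_i^E + G J_N Σ_j C_ij S_j^E − J_i S_i^I
    I_i^I = w_I I_0 + J_N S_i^E − S_i^I
    r^P   = H(I^P) = (a_P I^P − b_P) / (1 − exp(−d_P (a_P I^P − b_P)))
    dS_i^E/dt = −S_i^E/τ_E + (1 − S_i^E) γ_E r_i^E + σ ν_i(t)
    dS_i^I/dt = −S_i^I/τ_I + r_i^I + σ ν_i(t)

C is the structural connectome; the four free parameters are the global
coupling **G**, the excitatory NMDA coupling **J_N**, the local feedback
inhibition **J_i**, and the excitatory recurrence **w_p**. Excitatory
gating drives the Balloon-Windkessel hemodynamics to produce BOLD.

Fits compare simulated and empirical metrics by Pearson correlation: static
FC (sFC, Fisher-z region-pair correlations), FC variance over tapered
sliding windows (FCV), temporal correlation of the binarized dynamic graph
(TC), and node cohesion of matched communities (NC). The *combined*
criterion selects the grid point minimising √((1−r_sFC)² + (1−r_TC)²), so
one parameter set jointly reproduces static and dynamic connectivity.

## Worked example

```python
import numpy as np
from dynfc import (ModelParameters, SimulationConfig, ParameterGrid,
                   SlidingWindowSpec, integrate, compute_metrics,
                   simulate_library, grid_search)
from dynfc.synthetic import generate_connectome

sc = generate_connectome(n_regions=15, density=0.35, seed=42)
spec = SlidingWindowSpec()          # 60 s windows, 2 s step, 6 s taper
cfg = SimulationConfig(duration=874.0, burn_in=10.0, tr=0.72, seed=11)

# a "subject": ground truth G = 4.0, fresh noise seed
truth = ModelParameters(G=4.0, J_N=0.15, J_i=3.0, w_p=1.4, sigma=0.01)
bold = integrate(sc, truth, SimulationConfig(duration=874.0, burn_in=10.0,
                                             tr=0.72, seed=99)).bold
emp = compute_metrics(bold, spec=spec, include=("sfc", "tc"))

# library over a coupling grid, one simulation per point
grid = ParameterGrid(G_values=tuple(np.arange(2.0, 6.01, 0.5)),
                     J_N_values=(0.15,), J_i_values=(3.0,), w_p_values=(1.4,))
library = simulate_library(sc, grid, cfg, window_spec=spec, include=("sfc", "tc"))

best = grid_search(emp, library)["combined"]
print(f"winner G={best.best_params.G}  r_sfc={best.best_fits.r_sfc:.3f}  "
      f"r_tc={best.best_fits.r_tc:.3f}  combined={best.best_fits.combined:.3f}")
```

Output:

```
winner G=4.5  r_sfc=0.993  r_tc=0.419  combined=0.581
```

The winning entry sits one grid step from the generating G = 4.0: it
reproduces the subject's static FC almost perfectly (r_sfc 0.993) and its
dynamic neighbourhood persistence (r_tc 0.419) far better than remote grid
points (combined distance 1.365 at G = 2.0 against 0.581 here — smaller is
better). Coupling is recovered to grid resolution, which is what the
pattern-based fit can deliver near the model's saturated branch.

The same workflow scales to cohorts via `fit_subjects`, and
`dynfc.pipeline.run_pipeline` chains synthesis, simulation, fitting,
association, prediction, and perturbation into one seeded, cached,
bit-reproducible run (`dynfc pipeline --config config.yaml` from the
shell; see `docs/methods.md` for the model and every default).

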