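# Methods

`dynfc` implements a whole-brain computational-modelling pipeline: regional
brain activity is simulated with a reduced Wong-Wang excitatory/inhibitory
(E/I) mean-field model coupled through a structural connectome, transformed
to BOLD with the Balloon-Windkessel hemodynamic model, and fitted to static
and dynamic functional-connectivity (FC) metrics by grid search. Downstream
stages relate the fitted parameters and fit qualities to FC features
(univariate permutation-tested correlations; multivariate ridge
prediction) and probe the network by perturbing the coupling of one region
at a time.

## The neural mass model

Each of N regions holds an excitatory and an inhibitory population with
synaptic gating variables S^E, S^I in [0, 1]. Input currents (nA):

    I_i^E = w_E*I_0 + w_p*J_N*S_i^E + G_i*J_N * sum_j C_ij S_j^E(t - d_ij) - J_i*S_i^I
    I_i^I = w_I*I_0 + J_N*S_i^E - S_i^I

with C the connectome weights and d_ij = length_ij / conduction speed
(delays optional; the default integrates without delays, because no
conduction speed is canonical and delays change little at TR-scale BOLD).
Firing rates use the soft-threshold transfer function
H(x) = (a x - b)/(1 - exp(-d (a x - b))), which is total and continuous
(the removable singularity at a x = b takes the value 1/d; the
implementation switches to a 3-term series for |d(ax-b)| < 1e-6, giving
agreement with 50-digit evaluation to better than 1e-9). Gating evolves as

    dS^E/dt = -S^E/tau_E + (1 - S^E) gamma_E r^E + sigma nu(t)
    dS^I/dt = -S^I/tau_I + r^I + sigma nu(t)

integrated by Euler-Maruyama with independent Gaussian increments
sigma*sqrt(dt)*N(0,1) per population and region, and S clipped to [0, 1]
after every step.

### Free parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| G | global coupling (scales long-range input) | – | 1.0 |
| J_N | excitatory (NMDA) synaptic coupling | nA | 0.15 |
| J_i | local feedback inhibitory coupling | nA | 1.0 |
| w_p | local excitatory recurrence weight | – | 1.4 |

All remaining constants default to the canonical published values of the
model (a_E=310 nC⁻¹, b_E=125 Hz, d_E=0.16 s, a_I=615, b_I=177, d_I=0.087,
tau_E=0.1 s, tau_I=0.01 s, gamma_E=0.641, I_0=0.382 nA, w_E=1.0, w_I=0.7,
sigma=0.01 nA) and are all overridable. `regional_G_override` replaces the
scalar G in chosen regions only, which is how the perturbation stage
implements region-wise coupling changes.

### Numerical choices

* dt = 1 ms, burn-in 10 s (discarded), TR = 0.72 s. The integrator is
  first-order (verified by a dt-halving convergence test); model fixed
  points are exact fixed points of the Euler map, so noise-free runs reach
  equilibria to solver precision.
* Noise increments are drawn chunk-wise from one `numpy` Generator stream,
  so runs are bit-identical for identical (seed, config) and the increment
  stream is independent of chunk size. Noise-free runs skip the seeded
  initial-state jitter and are therefore seed-independent.
* Hemodynamic states (vasodilatory signal, inflow, volume,
  deoxyhemoglobin; Friston/Obata constants kappa=0.65 s⁻¹,
  gamma_f=0.41 s⁻¹, tau_h=0.98 s, alpha=0.32, rho=0.34, V0=0.02) are
  advanced at every dt — including burn-in, so the recorded BOLD starts
  settled — and driven directly by S^E. BOLD =
  V0*(k1(1-q) + k2(1-q/v) + k3(1-v)), sampled every TR.
* Conduction delays, when enabled, use a ring buffer with
  delay = round(length/(speed*dt)) steps.

## Connectome preparation

Structural connectomes are symmetric non-negative weight and length
matrices with zero diagonal (weights > 0 implies length > 0). Group
averaging is element-wise (entries are sorted before summation so the mean
is exactly invariant to subject order). The robust rescaling removes the
median of the nonzero entries and divides by their interquartile range,
clips negatives to zero (the coupling term needs C_ij >= 0; this
sparsifies the weakest half of connections), and rounds to the nearest
even integer with half-away-from-zero ties (so the worked reference case
{2,4,6,8} maps to {0,0,0,2}). Scaling statistics use nonzero entries only,
so absent connections stay absent.

## FC metrics

* **sFC** — Pearson correlation of each region pair over the scan,
  Fisher-z transformed (|r| clipped at 1-1e-7), diagonal zero.
* **Windowed FC** — W = floor((T·TR - window)/step) + 1 tapered windows
  (window 60 s, step 2 s); the taper is a rectangle convolved with a
  Gaussian (sigma 6 s), normalised to sum one; a very wide taper recovers
  the unweighted Pearson estimate. At the study geometry (1200 samples,
  TR 0.72 s) this yields 403 windows; published descriptions of the same
  construction report 420 windows for this geometry, a discrepancy no
  reading of (60 s, 2 s, 864 s) reproduces, so the geometry is configurable
  and the count documented rather than forced.
* **FCV** — per-pair sample variance (ddof=1) of windowed FC.
* **Dynamic graph** — per window, the top floor(0.10·N(N-1)/2)
  upper-triangle connectivities become edges (ties broken by value then
  lexicographic pair order; the per-window count is exact by
  construction). Density is per-window so temporal comparisons are not
  driven by global amplitude drifts.
* **TC** — per-node neighbourhood persistence between consecutive windows
  (isolated-node terms count 0, keeping the metric bounded in [0, 1]).
* **NC** — per-pair count of joint community switches. Communities come
  from per-window greedy (CNM) modularity maximisation — deterministic and
  guaranteed to terminate, which Louvain-style local moving is not on
  every binarized snapshot — with greedy maximal-Jaccard label matching
  across windows (ties toward the smaller label; new communities get
  fresh labels; isolated nodes are singletons).
* **Global efficiency** — mean inverse shortest-path length over ordered
  pairs, distance = 1/weight, disconnected pairs contribute 0. Node graph
  metrics: weighted strength, normalised betweenness, closeness (distances
  1/weight; negative FC entries dropped).

Two recording sessions are combined by element-wise averaging of the
metric sets.

## Fitting

One BOLD run is simulated per point of a (G, J_N, J_i, w_p) grid on the
group-average connectome; this *library* is computed once and reused for
every subject (fitting itself never simulates). Fits are Pearson
correlations over the strict upper triangle (matrices) or the raw
N-vectors (TC). Besides per-metric optima (argmax of r), the *combined*
criterion minimises the Euclidean distance of (r_sfc, r_tc) from the ideal
point (1, 1) — the direction is chosen so that improving either fit always
improves the criterion, which maximising the norm of (r_sfc, r_tc) would
not. Ties break toward the lexicographically smallest parameter tuple.

The multistability screen runs short noise-free simulations from a
low-activity and a high-activity initial state per (J_N, J_i, w_p, G) and
flags combinations whose branches settle more than 1 Hz apart in mean
excitatory rate for at least one G. For the E/I constants used here an
*isolated* region is monostable at canonical recurrence (verified by
fixed-point counting); multistability is a network phenomenon — a low and
a high branch coexisting over a band of G — unless recurrence is pushed
far above the canonical value.

## Synthetic data

The generators replace the empirical inputs (group-average diffusion-MRI
connectome; parcellated resting-state BOLD of a healthy cohort) with
ground-truth analogues:

* **Parcellation** — alternating hemispheres, mirrored centroids,
  balanced assignment to the seven canonical resting-state networks.
* **Connectome** — distance-dependent random graph (connection probability
  ∝ exp(-d/60 mm), boosted ×3 for a 15 % hub fraction), Euclidean tract
  lengths, lognormal weights, a distance-MST union guaranteeing
  connectivity, and weights normalised to mean row-sum 1 so that G in
  [0, 10] spans the model's full dynamic range (sub-critical through the
  network bifurcation to saturation). Without this normalisation the
  network saturates by G ≈ 1 and the coupling grid degenerates.
* **Cohort** — per-subject parameters drawn from truncated normals
  (defaults G ~ N(3.0, 0.6), J_N ~ N(0.15, 0.02), J_i ~ N(3.0, 0.2),
  w_p ~ N(1.4, 0.1)) and forward-simulated with subject-specific noise
  seeds; 1200 samples at TR 0.72 s. The operating point sits in the
  multistable band found by the screen (strong feedback inhibition keeps
  the low branch alive; the network bifurcation falls near G ≈ 3.5), where
  static and dynamic FC are G-sensitive. Cohorts are pure functions of
  (spec, seed).
* **Planted linear targets** — k signal columns with Rademacher (±1)
  coefficients plus Gaussian noise calibrated to a requested population
  R²; equal coefficient magnitudes make every planted feature carry the
  same detectable share, which is what a support-recovery check needs.
* **Phase-randomised surrogates** preserve per-region spectra while
  destroying cross-region phase structure, for model-mismatch tests.

Because cohorts come from the package's own forward model, parameter
recovery is well-posed: a recovered parameter means the fitting stage
found the generating grid point, not that the model family fits arbitrary
data. What these tests do *not* show: behaviour under empirical BOLD
artefacts (motion, physiological noise, scanner drift), hemodynamic
variability across regions, or model mismatch — the surrogate generator
exists to probe the latter separately.

### Identifiability at desk scale

Pattern-based (Pearson) fits discard overall FC magnitude, so the coupling
G is identified mainly by *which* regions sit on the high branch and by
temporal-correlation differences near the bifurcation. G trades off
against the local parameters (all shift the bifurcation), so joint-grid
fitted G is coarse: the recovery check asks for the generating (G, J_N) at
or adjacent to truth. The association study isolates the G axis (local
parameters fixed at their generating values in the library), the clean
design for a cohort whose only varied truth is G.

## Association, prediction, perturbation

* Permutation p-values permute the outcome across subjects (features
  fixed, one shared stream), two-sided, with the add-one estimator
  p = (1+k)/(n_perm+1) — never exactly zero and uniformly distributed
  under the null. FDR is Benjamini-Hochberg, applied within each
  outcome-by-feature-family block. Group contrasts use Welch's t-test.
  Edge features follow the row-major strict upper triangle, so the
  N(N-1)/2 indexing is reproducible.
* Prediction pipelines standardise and PCA-transform inside training folds
  only. Edge models keep the minimal number of components with cumulative
  explained variance > 0.90; node models keep all. The ridge penalty is
  selected from 100 log-spaced values in [0.01, 100] by inner CV (5 folds
  x 2 repeats); the outer loop (5 x 2) reports the mean and SEM of the
  held-out coefficient of determination, which can be negative (worse
  than a constant model). The inner ridge path is solved for all penalties
  at once from one SVD, which is algebraically identical to refitting per
  penalty. Permutation importance permutes original (pre-PCA) columns
  through the frozen full-data pipeline; because that pipeline is linear
  in X, a permuted column shifts predictions by beta_f (x_f[perm] - x_f),
  which the implementation uses directly. Held-out folds whose target is
  constant have undefined R² and are skipped.
* Perturbation sweeps one region's G over a grid while everything else —
  parameters, noise seed — stays fixed, so deltas (default minus
  perturbed; positive = the perturbation made it worse) reflect the
  parameter change alone, and the sweep value equal to the default G is
  exactly zero by construction. Efficiency is computed on the plain
  (non-Fisher) simulated correlation matrix with negative entries dropped.
  Map-map correlations use spin-test nulls: centroids projected to the
  unit sphere, random rotations (the right hemisphere gets the x-mirrored
  rotation), nearest-neighbour reassignment within hemisphere, add-one
  two-sided p. Hemisphere-restricted rotations duplicate boundary regions;
  the null preserves the spatial autocorrelation structure, not the exact
  value multiset.

## Pipeline and reproducibility

`run_pipeline` chains connectome → cohort → metrics → library → fit →
associate → predict → perturb. Each stage writes TSV/CSV outputs plus a
JSON manifest (config hash, derived seeds, package version); a stage whose
manifest matches the config hash is skipped and its cached outputs are
reloaded, so re-runs do not re-simulate. Stage seeds derive from the
master seed by fixed offsets. Identical master seeds give bit-identical
CSV outputs and manifests. The `desk` preset (15 regions, 12 subjects,
5x4x4x4 grid, ~60 s BOLD, 20 s windows) runs in minutes on one CPU; the
`full` preset mirrors the study-scale geometry (70 regions, 200 subjects,
101x10x10x10 grid, 60 s windows) and is intended for cluster execution.

## Known limitations

* The synthetic cohort shares its forward model with the fitting stage;
  absolute fit values are optimistic relative to empirical data.
* G identifiability is coarse away from the network bifurcation (see
  above); J_i and w_p are only weakly identifiable from FC pattern fits,
  consistent with their null associations downstream.
* Louvain community structure on near-random desk-scale graphs is noisy;
  NC is the least stable metric, and the node-cohesion fit is accordingly
  the weakest selection criterion.
* The spin test assumes centroids are meaningfully projectable to a
  sphere; for strongly non-spherical layouts the null conserves less of
  the spatial structure.
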