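"""Synthetic connectomes, parcellations, and ground-truth cohorts.

These generators stand in for the empirical inputs (a group-average
diffusion-MRI connectome and parcellated resting-state BOLD of a healthy
cohort) so every pipeline stage is testable without downloads.  Default
geometry mirrors the modelled cohort: ~70 cortical regions in seven
resting-state networks, 1200-sample BOLD runs at TR = 0.72 s.

Connectomes are sparse, symmetric, hub-heavy, distance-dependent graphs
with Euclidean tract lengths; cohorts are produced by the package's own
forward model with known per-subject parameters, which makes parameter
recovery a well-posed test.  A phase-randomised surrogate generator is
included for model-mismatch checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .connectomes import (
    CANONICAL_NETWORKS,
    BoldSeries,
    Parcellation,
    StructuralConnectome,
)
from .dmf import ModelParameters, SimulationConfig, integrate

__all__ = [
    "SyntheticCohortSpec",
    "generate_parcellation",
    "generate_connectome",
    "generate_cohort",
    "generate_linear_target",
    "phase_randomized_surrogate",
]


def generate_parcellation(
    n_regions: int = 70, n_networks: int = 7, seed: int = 0
) -> Parcellation:
    """Random bilateral parcellation with balanced network assignment.

    Hemispheres alternate region by region; centroids of each left/right
    pair mirror across the midline (x = 0).  Networks are assigned in a
    balanced way (each of the ``n_networks`` labels covers an equal share,
    up to remainder) and shuffled deterministically.
    """
    if n_networks > n_regions:
        raise ValueError("more networks than regions")
    if n_networks > len(CANONICAL_NETWORKS):
        raise ValueError(f"at most {len(CANONICAL_NETWORKS)} networks supported")
    rng = np.random.default_rng(seed)
    hemis = tuple("left" if i % 2 == 0 else "right" for i in range(n_regions))
    centroids = np.empty((n_regions, 3))
    for i in range(0, n_regions, 2):
        # random point in a hemispheric shell, 30-80 mm from the origin
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        r = rng.uniform(30.0, 80.0)
        p = v * r
        p[0] = -abs(p[0]) - 5.0  # left of midline
        centroids[i] = p
        if i + 1 < n_regions:
            centroids[i + 1] = p * np.array([-1.0, 1.0, 1.0])
    nets = np.array(
        [CANONICAL_NETWORKS[k % n_networks] for k in range(n_regions)], dtype=object
    )
    rng.shuffle(nets)
    names = tuple(
        f"{'lh' if h == 'left' else 'rh'}_region{i:03d}" for i, h in enumerate(hemis)
    )
    return Parcellation(
        region_names=names,
        hemisphere=hemis,
        rsn_assignment=tuple(nets),
        centroids=centroids,
    )


def generate_connectome(
    n_regions: int = 70,
    density: float = 0.35,
    hub_fraction: float = 0.15,
    decay_scale: float = 60.0,
    seed: int = 0,
    parcellation: Parcellation | None = None,
) -> StructuralConnectome:
    """Sparse symmetric hub-heavy connectome with distance-like lengths.

    Region centroids come from ``parcellation`` (generated when absent);
    tract lengths are Euclidean centroid distances.  Edges are drawn without
    replacement with probability proportional to exp(-d / decay_scale),
    boosted for a designated fraction of hub regions, until
    round(density * N(N-1)/2) edges exist; a minimum spanning tree over
    distance is always included, so the graph is connected.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    parc = parcellation or generate_parcellation(n_regions, seed=seed)
    if parc.n_regions != n_regions:
        raise ValueError("parcellation size mismatch")
    cent = parc.centroids
    dist = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n_regions, k=1)
    n_pairs = iu.size
    n_edges = int(round(density * n_pairs))

    n_hubs = max(1, int(round(hub_fraction * n_regions)))
    hubs = rng.choice(n_regions, size=n_hubs, replace=False)
    hub_mask = np.zeros(n_regions, bool)
    hub_mask[hubs] = True

    prob = np.exp(-dist[iu, ju] / decay_scale)
    prob *= np.where(hub_mask[iu] | hub_mask[ju], 3.0, 1.0)
    prob /= prob.sum()

    chosen = np.zeros(n_pairs, bool)
    if n_edges >= n_pairs:
        chosen[:] = True
    else:
        pick = rng.choice(n_pairs, size=n_edges, replace=False, p=prob)
        chosen[pick] = True
        # guarantee connectivity via the distance MST
        mst = minimum_spanning_tree(np.triu(dist, k=1)).toarray()
        mi, mj = np.nonzero(mst)
        pair_index = {}
        for k in range(n_pairs):
            pair_index[(iu[k], ju[k])] = k
        for a, b in zip(mi, mj):
            a, b = (a, b) if a < b else (b, a)
            chosen[pair_index[(a, b)]] = True

    weights = np.zeros((n_regions, n_regions))
    lengths = np.zeros((n_regions, n_regions))
    sel = np.flatnonzero(chosen)
    w = np.exp(rng.normal(0.0, 0.4, sel.size)) * np.exp(
        -dist[iu[sel], ju[sel]] / (2.0 * decay_scale)
    )
    w *= np.where(hub_mask[iu[sel]] | hub_mask[ju[sel]], 2.0, 1.0)
    weights[iu[sel], ju[sel]] = w
    weights[ju[sel], iu[sel]] = w
    # Normalise to mean row-sum 1 so the global coupling G spans the model's
    # full dynamic range (sub-critical to saturated) over grids within [0, 10].
    weights /= weights.sum(axis=1).mean()
    lengths[iu[sel], ju[sel]] = dist[iu[sel], ju[sel]]
    lengths[ju[sel], iu[sel]] = dist[iu[sel], ju[sel]]
    return StructuralConnectome(weights=weights, lengths=lengths, parcellation=parc)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Ground-truth cohort description.

    ``parameter_distribution`` maps each free parameter to (mean, sd); an sd
    of zero fixes the parameter.  Defaults mirror the modelled cohort's
    geometry (1200 samples at TR 0.72 s) with moderate between-subject
    variation around canonical operating values.
    """

    n_regions: int = 70
    n_subjects: int = 200
    parameter_distribution: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "G": (3.0, 0.6),
            "J_N": (0.15, 0.02),
            "J_i": (3.0, 0.2),
            "w_p": (1.4, 0.1),
        }
    )
    noise_seed_base: int = 1000
    bold_length: int = 1200
    tr: float = 0.72

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ValueError("need at least 4 regions")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        for name, (_, sd) in self.parameter_distribution.items():
            if sd < 0:
                raise ValueError(f"negative sd for {name}")


_PARAM_BOUNDS = {"G": (0.0, 10.0), "J_N": (0.01, 2.0), "J_i": (0.01, 5.0), "w_p": (0.0, 3.0)}


def _draw_params(rng: np.random.Generator, spec: SyntheticCohortSpec) -> ModelParameters:
    drawn = {}
    for name, (mean, sd) in spec.parameter_distribution.items():
        lo, hi = _PARAM_BOUNDS[name]
        if sd == 0:
            drawn[name] = float(np.clip(mean, lo, hi))
            continue
        val = rng.normal(mean, sd)
        while not (lo <= val <= hi):  # truncate by redraw
            val = rng.normal(mean, sd)
        drawn[name] = float(val)
    return ModelParameters(**drawn)


def generate_cohort(
    sc: StructuralConnectome,
    spec: SyntheticCohortSpec,
    burn_in: float = 10.0,
    config_template: SimulationConfig | None = None,
) -> list[tuple[BoldSeries, ModelParameters]]:
    """Forward-simulate a cohort with known ground-truth parameters.

    Subject s draws its parameters from ``noise_seed_base + s`` and its
    simulation noise from ``noise_seed_base + 100000 + s``, so cohorts are
    pure functions of (spec, connectome).
    """
    if sc.n_regions != spec.n_regions:
        raise ValueError("connectome size does not match the cohort spec")
    duration = spec.bold_length * spec.tr + burn_in
    out = []
    for s in range(spec.n_subjects):
        param_rng = np.random.default_rng(spec.noise_seed_base + s)
        params = _draw_params(param_rng, spec)
        cfg = SimulationConfig(
            duration=duration,
            burn_in=burn_in,
            tr=spec.tr,
            seed=int(spec.noise_seed_base + 100_000 + s),
        ) if config_template is None else SimulationConfig(
            dt=config_template.dt,
            duration=duration,
            burn_in=burn_in,
            tr=spec.tr,
            seed=int(spec.noise_seed_base + 100_000 + s),
            conduction_speed=config_template.conduction_speed,
        )
        try:
            res = integrate(sc, params, cfg)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"simulation failed for subject {s}: {exc}") from exc
        bold = BoldSeries(data=res.bold, tr=spec.tr, subject_id=f"sub-{s:03d}")
        out.append((bold, params))
    return out


def generate_linear_target(
    features: np.ndarray,
    k_signal: int,
    noise_r2: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Target = linear mix of ``k_signal`` random columns + calibrated noise.

    Planted coefficients are Rademacher (+-1): equal magnitudes with random
    signs, so every planted feature carries the same detectable signal
    share.  Gaussian noise variance is set so the population R-squared of
    the generating model equals ``noise_r2`` (1 = noiseless, 0 = pure
    noise).  Returns the target and the index array of true signal columns.
    """
    X = np.asarray(features, float)
    if not (0 <= noise_r2 <= 1):
        raise ValueError("noise_r2 must lie in [0, 1]")
    if k_signal > X.shape[1]:
        raise ValueError("k_signal exceeds the feature count")
    rng = np.random.default_rng(seed)
    support = np.sort(rng.choice(X.shape[1], size=k_signal, replace=False))
    beta = rng.choice([-1.0, 1.0], size=k_signal)
    signal = X[:, support] @ beta
    if noise_r2 == 0:
        return rng.standard_normal(X.shape[0]), support
    sig_var = signal.var()
    if noise_r2 == 1 or sig_var == 0:
        return signal, support
    noise_sd = np.sqrt(sig_var * (1.0 - noise_r2) / noise_r2)
    return signal + rng.normal(0.0, noise_sd, X.shape[0]), support


def phase_randomized_surrogate(series: BoldSeries, seed: int = 0) -> BoldSeries:
    """Phase-randomised surrogate preserving each region's power spectrum.

    Useful for model-mismatch tests: the surrogate shares amplitudes with
    the original but destroys cross-region phase relations.
    """
    rng = np.random.default_rng(seed)
    data = series.data
    T = data.shape[0]
    spec = np.fft.rfft(data, axis=0)
    phases = rng.uniform(0, 2 * np.pi, spec.shape)
    phases[0] = 0.0
    if T % 2 == 0:
        phases[-1] = 0.0
    surrogate = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=T, axis=0)
    return BoldSeries(data=surrogate, tr=series.tr, subject_id=series.subject_id + "_surr")
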