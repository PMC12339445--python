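"""Region-wise coupling perturbation of the fitted group-level model.

Starting from the default parameter set — the combined-criterion winner
against group-average empirical metrics — the global coupling G of one
region at a time is swept over a range of values while every other region
keeps the default.  For each perturbed simulation we record the change
(default run minus perturbed run, so positive deltas mean the perturbation
*worsened* the quantity) in three global outcomes: the sFC fit, the TC fit,
and the global efficiency of the simulated sFC.  The same noise seed is
shared between default and perturbed runs so deltas reflect the parameter
change, not the noise realisation; in particular the sweep value equal to
the default G reproduces the default run exactly and all deltas are 0.

Impact maps (per-region delta means/variances) are related to graph-metric
maps with spatial-autocorrelation-preserving spin-test nulls: region
centroids are projected on a sphere, randomly rotated (mirrored rotations
for the two hemispheres), and reassigned by nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .connectomes import Parcellation, StructuralConnectome
from .metrics import FCMetricSet
from .dmf import ModelParameters, SimulationConfig, integrate
from .fitting import compute_fit, grid_search
from .metrics import SlidingWindowSpec, compute_metrics, global_efficiency, static_fc

__all__ = [
    "PerturbationOutcome",
    "NodeMap",
    "fit_group_default",
    "regional_sweep",
    "sweep_all_regions",
    "spin_permutations",
    "correlate_maps",
]


@dataclass(frozen=True)
class PerturbationOutcome:
    """Per-G deltas (default minus perturbed) for one perturbed region."""

    region: int
    G_values: np.ndarray
    delta_sfc_fit: np.ndarray
    delta_tc_fit: np.ndarray
    delta_efficiency: np.ndarray
    failed_G: tuple[float, ...] = ()

    def summary(self) -> dict[str, float]:
        out = {}
        for name in ("delta_sfc_fit", "delta_tc_fit", "delta_efficiency"):
            v = getattr(self, name)
            v = v[np.isfinite(v)]
            out[f"{name}_mean"] = float(v.mean())
            out[f"{name}_var"] = float(v.var(ddof=0))
        return out


@dataclass(frozen=True)
class NodeMap:
    """A per-region scalar map with a label (impact, centrality, ...)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 1:
            raise ValueError("a node map is a flat per-region vector")
        object.__setattr__(self, "values", v)


def fit_group_default(
    sc: StructuralConnectome,
    group_emp: FCMetricSet,
    library: Mapping[tuple[float, float, float, float], FCMetricSet],
    base_params: ModelParameters | None = None,
) -> ModelParameters:
    """Combined-criterion winner against the group-average metrics.

    ``group_emp`` should be the element-wise average of the subject metric
    sets; the returned parameters are the perturbation baseline.
    """
    sel = grid_search(group_emp, library, subject_id="group", base_params=base_params)
    if "combined" not in sel:
        raise ValueError("library lacks the sFC/TC metrics the combined criterion needs")
    return sel["combined"].best_params


def _run_outcomes(
    sc: StructuralConnectome,
    params: ModelParameters,
    config: SimulationConfig,
    group_emp: FCMetricSet,
    spec: SlidingWindowSpec,
    density: float,
) -> tuple[float, float, float]:
    res = integrate(sc, params, config)
    sim = compute_metrics(res.bold, spec=spec, density=density, include=("sfc", "tc"))
    fit = compute_fit(sim, group_emp)
    # efficiency on the plain (non-Fisher) simulated correlation matrix;
    # negative correlations carry no path weight
    plain = static_fc(res.bold, fisher=False)
    eff = global_efficiency(np.where(plain > 0, plain, 0.0))
    return fit.r_sfc, fit.r_tc, eff


def regional_sweep(
    sc: StructuralConnectome,
    default_params: ModelParameters,
    region: int,
    G_values: Sequence[float],
    config: SimulationConfig,
    group_emp: FCMetricSet,
    window_spec: SlidingWindowSpec | None = None,
    density: float = 0.10,
    default_outcomes: tuple[float, float, float] | None = None,
) -> PerturbationOutcome:
    """Sweep one region's coupling over ``G_values``; deltas vs the default.

    Integration failures at individual G values are recorded in
    ``failed_G`` and excluded from the summary statistics (their delta is
    NaN).  Passing precomputed ``default_outcomes`` avoids re-running the
    unperturbed simulation for every region.
    """
    n = sc.n_regions
    if not (0 <= region < n):
        raise ValueError("region index out of range")
    spec = window_spec or SlidingWindowSpec(tr=config.tr)
    if default_outcomes is None:
        default_outcomes = _run_outcomes(sc, default_params, config, group_emp, spec, density)
    d_sfc, d_tc, d_eff = default_outcomes

    G_values = np.asarray(list(G_values), float)
    delta_sfc = np.full(G_values.size, np.nan)
    delta_tc = np.full(G_values.size, np.nan)
    delta_eff = np.full(G_values.size, np.nan)
    failed: list[float] = []
    for k, g in enumerate(G_values):
        if g == default_params.G:
            # identical parameters and seed: the perturbed run is the
            # default run, so the deltas are exactly zero by construction
            delta_sfc[k] = delta_tc[k] = delta_eff[k] = 0.0
            continue
        override = np.full(n, np.nan)
        override[region] = g
        cfg = replace(config, regional_G_override=override)
        try:
            p_sfc, p_tc, p_eff = _run_outcomes(sc, default_params, cfg, group_emp, spec, density)
        except Exception:  # noqa: BLE001 - recorded, excluded from summaries
            failed.append(float(g))
            continue
        delta_sfc[k] = d_sfc - p_sfc
        delta_tc[k] = d_tc - p_tc
        delta_eff[k] = d_eff - p_eff
    return PerturbationOutcome(
        region=region,
        G_values=G_values,
        delta_sfc_fit=delta_sfc,
        delta_tc_fit=delta_tc,
        delta_efficiency=delta_eff,
        failed_G=tuple(failed),
    )


def sweep_all_regions(
    sc: StructuralConnectome,
    default_params: ModelParameters,
    G_values: Sequence[float],
    config: SimulationConfig,
    group_emp: FCMetricSet,
    regions: Sequence[int] | None = None,
    window_spec: SlidingWindowSpec | None = None,
    density: float = 0.10,
) -> pd.DataFrame:
    """Per-region sweep summary (mean and variance of each delta)."""
    spec = window_spec or SlidingWindowSpec(tr=config.tr)
    default_out = _run_outcomes(sc, default_params, config, group_emp, spec, density)
    regions = range(sc.n_regions) if regions is None else regions
    rows = []
    for r in regions:
        out = regional_sweep(
            sc, default_params, r, G_values, config, group_emp,
            window_spec=spec, density=density, default_outcomes=default_out,
        )
        rows.append({"region": r, **out.summary(), "n_failed": len(out.failed_G)})
    return pd.DataFrame(rows)


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    # uniform random rotation via QR of a Gaussian matrix, det fixed to +1
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def spin_permutations(
    parc: Parcellation, n_spins: int, seed: int = 0
) -> np.ndarray:
    """Spatial-autocorrelation-preserving permutations of region indices.

    Centroids are projected onto the unit sphere; each spin applies one
    random rotation to the left hemisphere and its x-mirrored counterpart
    to the right, then reassigns every region to its nearest rotated
    neighbour within the same hemisphere.  Returns (n_spins, N) index
    arrays (the identity rotation reproduces the input map).
    """
    cent = parc.centroids
    hemi = np.asarray(parc.hemisphere)
    unit = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    mirror = np.diag([-1.0, 1.0, 1.0])
    perms = np.empty((n_spins, parc.n_regions), dtype=np.int64)
    for s in range(n_spins):
        R = _rotation_matrix(rng)
        for side, rot in (("left", R), ("right", mirror @ R @ mirror)):
            idx = np.flatnonzero(hemi == side)
            if idx.size == 0:
                continue
            rotated = unit[idx] @ rot.T
            # nearest original region for each rotated position
            d = rotated @ unit[idx].T  # cosine similarity
            perms[s, idx] = idx[np.argmax(d, axis=1)]
    return perms


def correlate_maps(
    impact: NodeMap,
    reference: NodeMap,
    parc: Parcellation,
    n_spins: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson r between two region maps with a spin-test p-value.

    The null rotates the impact map ``n_spins`` times; p is the two-sided
    add-one estimator (floor 1/(n_spins+1)).
    """
    x = impact.values
    y = reference.values
    if x.size != y.size or x.size != parc.n_regions:
        raise ValueError("maps and parcellation must align")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate map variance")
    r_obs = float(pearsonr(x, y)[0])
    perms = spin_permutations(parc, n_spins, seed=seed)
    null = np.empty(n_spins)
    for s in range(n_spins):
        null[s] = pearsonr(x[perms[s]], y)[0]
    p = (1.0 + np.sum(np.abs(null) >= abs(r_obs) - 1e-12)) / (n_spins + 1.0)
    return r_obs, float(p)
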