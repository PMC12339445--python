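"""End-to-end pipeline: synthesise -> simulate -> fit -> analyse.

Ties the stages together reproducibly: a synthetic connectome and cohort
(or user-supplied files), the simulation library over a parameter grid,
per-subject grid-search fits, univariate associations, multivariate
prediction, and the regional perturbation sweep.  Every stage writes
TSV/CSV outputs plus a JSON manifest (config hash, derived seeds, package
version); completed stages are skipped on re-run when the config hash
matches, and identical master seeds give bit-identical outputs.

Two scale presets exist: ``desk`` (15 regions, 5x4x4x4 grid, ~60 s BOLD,
minutes on one CPU — smoke tests and development) and ``full`` (70 regions,
101x10x10x10 grid, the study-scale geometry — cluster-intended).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    association_table,
    edge_feature_table,
    node_feature_table,
)
from .connectomes import BoldSeries, write_bold, write_connectome
from .dmf import SimulationConfig
from .fitting import ParameterGrid, fit_subjects, simulate_library
from .metrics import FCMetricSet, SlidingWindowSpec, average_metric_sets, compute_metrics
from .perturbation import fit_group_default, sweep_all_regions
from .prediction import PredictionSpec, ridge_nested_cv
from .synthetic import SyntheticCohortSpec, generate_cohort, generate_connectome

__all__ = ["PipelineConfig", "run_pipeline", "desk_config", "full_config"]

# Stage seeds derive from the master seed by fixed offsets so any stage
# subset re-runs identically; all derived seeds stay below 2**31.
_SEED_OFFSETS = {
    "connectome": 1,
    "cohort": 2,
    "library": 3,
    "associate": 4,
    "predict": 5,
}


def _derived_seed(master_seed: int, stage: str) -> int:
    return int((master_seed * 8 + _SEED_OFFSETS[stage]) % (2**31 - 1))


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration (YAML-serialisable)."""

    output_dir: str = "pipeline_out"
    master_seed: int = 0
    scale: str = "desk"
    n_regions: int = 15
    n_subjects: int = 12
    bold_length: int = 84
    tr: float = 0.72
    connectome_density: float = 0.35
    G_values: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0)
    J_N_values: tuple[float, ...] = (0.12, 0.14, 0.16, 0.18)
    J_i_values: tuple[float, ...] = (2.5, 3.0, 3.5, 4.0)
    w_p_values: tuple[float, ...] = (1.2, 1.4, 1.6, 1.8)
    window_length: float = 20.0
    window_step: float = 2.0
    taper_sigma: float = 3.0
    graph_density: float = 0.10
    burn_in: float = 10.0
    cohort_G: tuple[float, float] = (3.0, 0.6)
    cohort_J_N: tuple[float, float] = (0.15, 0.02)
    cohort_J_i: tuple[float, float] = (3.0, 0.2)
    cohort_w_p: tuple[float, float] = (1.4, 0.1)
    n_perm_association: int = 2000
    prediction_targets: tuple[str, ...] = ("G", "J_N", "r_sfc", "r_tc")
    perturb_regions: tuple[int, ...] = (0, 1, 2, 3, 4)
    perturb_G_values: tuple[float, ...] = (
        0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0
    )

    def grid(self) -> ParameterGrid:
        return ParameterGrid(
            G_values=self.G_values,
            J_N_values=self.J_N_values,
            J_i_values=self.J_i_values,
            w_p_values=self.w_p_values,
        )

    def window_spec(self) -> SlidingWindowSpec:
        return SlidingWindowSpec(
            window_length=self.window_length,
            step=self.window_step,
            taper_sigma=self.taper_sigma,
            tr=self.tr,
        )

    def sim_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            duration=self.bold_length * self.tr + self.burn_in,
            burn_in=self.burn_in,
            tr=self.tr,
            seed=seed,
        )

    def config_hash(self) -> str:
        # hash the scientific configuration only, not the destination path,
        # so identically seeded runs in different directories are recognised
        # as the same run
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tupled = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(**tupled)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
                fh,
                sort_keys=True,
            )


def desk_config(**overrides) -> PipelineConfig:
    """Desk-scale preset: minutes on one CPU."""
    return replace(PipelineConfig(), **overrides)


def full_config(**overrides) -> PipelineConfig:
    """Study-scale preset (70 regions, 101x10x10x10 grid): cluster-intended."""
    def _lin(lo: float, hi: float, n: int) -> tuple[float, ...]:
        return tuple(float(v) for v in np.round(np.linspace(lo, hi, n), 6))

    base = PipelineConfig(
        scale="full",
        n_regions=70,
        n_subjects=200,
        bold_length=1200,
        G_values=_lin(0.0, 10.0, 101),
        J_N_values=_lin(0.10, 0.28, 10),
        J_i_values=_lin(2.0, 4.7, 10),
        w_p_values=_lin(1.0, 2.35, 10),
        window_length=60.0,
        taper_sigma=6.0,
        n_perm_association=100_000,
        prediction_targets=("G", "J_N", "J_i", "w_p", "r_sfc", "r_fcv", "r_tc", "r_nc"),
        perturb_regions=tuple(range(70)),
        perturb_G_values=tuple(np.round(np.linspace(0.0, 10.0, 101), 6)),
    )
    return replace(base, **overrides)


def _write_manifest(out: Path, stage: str, config: PipelineConfig, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "dynfc_version": __version__,
        "written_at": "deterministic",  # no wall-clock in outputs: keeps runs bit-identical
        **extra,
    }
    with open(out / f"{stage}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_done(out: Path, stage: str, config: PipelineConfig) -> bool:
    path = out / f"{stage}.manifest.json"
    if not path.exists():
        return False
    try:
        with open(path) as fh:
            manifest = json.load(fh)
    except (OSError, json.JSONDecodeError):
        return False
    return manifest.get("config_hash") == config.config_hash()


def _metric_frame(mset: FCMetricSet) -> pd.DataFrame:
    n = mset.sfc.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    cols = {
        "sfc": mset.sfc[iu, ju],
        "fcv": mset.fcv[iu, ju] if mset.fcv is not None else np.full(iu.size, np.nan),
        "nc": mset.nc[iu, ju] if mset.nc is not None else np.full(iu.size, np.nan),
    }
    return pd.DataFrame({"i": iu, "j": ju, **cols})


def _frame_to_metrics(edges: pd.DataFrame, tc: np.ndarray, n: int) -> FCMetricSet:
    def _sym(col: str) -> np.ndarray | None:
        vals = edges[col].to_numpy(float)
        if np.all(np.isnan(vals)):
            return None
        m = np.zeros((n, n))
        m[edges["i"], edges["j"]] = vals
        return m + m.T

    return FCMetricSet(sfc=_sym("sfc"), fcv=_sym("fcv"), tc=tc, nc=_sym("nc"))


_LIB_KEYS = ("G", "J_N", "J_i", "w_p")


def _library_frame(library: dict, n: int) -> pd.DataFrame:
    iu, ju = np.triu_indices(n, k=1)
    rows = []
    for point, mset in sorted(library.items()):
        row = dict(zip(_LIB_KEYS, point))
        for name in ("sfc", "fcv", "nc"):
            m = getattr(mset, name)
            for k, (i, j) in enumerate(zip(iu, ju)):
                row[f"{name}_{k}"] = m[i, j] if m is not None else np.nan
        for k, v in enumerate(mset.tc):
            row[f"tc_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _frame_to_library(df: pd.DataFrame, n: int) -> dict:
    iu, ju = np.triu_indices(n, k=1)
    library = {}
    for _, row in df.iterrows():
        point = tuple(float(row[k]) for k in _LIB_KEYS)
        parts = {}
        for name in ("sfc", "fcv", "nc"):
            vals = np.array([row[f"{name}_{k}"] for k in range(iu.size)])
            if np.all(np.isnan(vals)):
                parts[name] = None
            else:
                m = np.zeros((n, n))
                m[iu, ju] = vals
                parts[name] = m + m.T
        tc = np.array([row[f"tc_{k}"] for k in range(n)])
        library[point] = FCMetricSet(tc=tc, **parts)
    return library


def run_pipeline(config: PipelineConfig, progress: bool = False) -> dict:
    """Execute all stages; returns the run manifest as a dict.

    Stage order: connectome -> cohort -> metrics -> library -> fit ->
    associate -> predict -> perturb.  A stage whose manifest matches the
    current config hash is skipped (its outputs are reused); a failing
    stage raises with the stage name, keeping earlier outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    spec = config.window_spec()
    timings: dict[str, float] = {}

    def _log(msg: str) -> None:
        if progress:
            print(f"[dynfc] {msg}", flush=True)

    # --- connectome ---------------------------------------------------
    t0 = time.time()
    sc = generate_connectome(
        n_regions=config.n_regions,
        density=config.connectome_density,
        seed=_derived_seed(config.master_seed, "connectome"),
    )
    if not _stage_done(out, "connectome", config):
        write_connectome(
            sc, out / "weights.tsv", out / "lengths.tsv", out / "metadata.csv"
        )
        _write_manifest(out, "connectome", config, {"n_regions": config.n_regions})
    timings["connectome"] = time.time() - t0

    # --- cohort -------------------------------------------------------
    t0 = time.time()
    subject_ids = [f"sub-{s:03d}" for s in range(config.n_subjects)]
    bold_dir = out / "bold"
    if _stage_done(out, "cohort", config):
        cohort_bold = {
            sid: BoldSeries(
                data=np.loadtxt(bold_dir / f"{sid}.tsv", delimiter="\t", ndmin=2),
                tr=config.tr, subject_id=sid,
            )
            for sid in subject_ids
        }
    else:
        cohort_spec = SyntheticCohortSpec(
            n_regions=config.n_regions,
            n_subjects=config.n_subjects,
            parameter_distribution={
                "G": config.cohort_G,
                "J_N": config.cohort_J_N,
                "J_i": config.cohort_J_i,
                "w_p": config.cohort_w_p,
            },
            noise_seed_base=_derived_seed(config.master_seed, "cohort"),
            bold_length=config.bold_length,
            tr=config.tr,
        )
        _log(f"cohort: {config.n_subjects} subjects x {config.bold_length} samples")
        cohort = generate_cohort(sc, cohort_spec, burn_in=config.burn_in)
        bold_dir.mkdir(exist_ok=True)
        truth_rows = []
        for series, params in cohort:
            write_bold(series, bold_dir / f"{series.subject_id}.tsv")
            truth_rows.append(
                {"subject": series.subject_id, "G": params.G, "J_N": params.J_N,
                 "J_i": params.J_i, "w_p": params.w_p}
            )
        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
        # reload from disk so cached and fresh runs share the same bytes
        cohort_bold = {
            sid: BoldSeries(
                data=np.loadtxt(bold_dir / f"{sid}.tsv", delimiter="\t", ndmin=2),
                tr=config.tr, subject_id=sid,
            )
            for sid in subject_ids
        }
        _write_manifest(out, "cohort", config, {"n_subjects": config.n_subjects})
    timings["cohort"] = time.time() - t0

    # --- per-subject metrics ------------------------------------------
    t0 = time.time()
    _log("metrics stage")
    mdir = out / "metrics"
    if _stage_done(out, "metrics", config):
        emp_sets = {
            sid: _frame_to_metrics(
                pd.read_csv(mdir / f"{sid}_edges.csv"),
                pd.read_csv(mdir / f"{sid}_tc.csv")["tc"].to_numpy(float),
                config.n_regions,
            )
            for sid in subject_ids
        }
    else:
        emp_sets = {
            sid: compute_metrics(
                cohort_bold[sid], spec=spec, density=config.graph_density,
                seed=_derived_seed(config.master_seed, "cohort"),
            )
            for sid in subject_ids
        }
        mdir.mkdir(exist_ok=True)
        for sid, mset in emp_sets.items():
            _metric_frame(mset).to_csv(mdir / f"{sid}_edges.csv", index=False)
            pd.DataFrame({"tc": mset.tc}).to_csv(mdir / f"{sid}_tc.csv", index=False)
        _write_manifest(out, "metrics", config, {"n_subjects": len(emp_sets)})
    timings["metrics"] = time.time() - t0

    # --- simulation library -------------------------------------------
    t0 = time.time()
    grid = config.grid()
    if _stage_done(out, "library", config):
        library = _frame_to_library(
            pd.read_csv(out / "library_metrics.csv"), config.n_regions
        )
    else:
        _log(f"library: {grid.size} grid points")
        library = simulate_library(
            sc, grid,
            config.sim_config(seed=_derived_seed(config.master_seed, "library")),
            window_spec=spec, density=config.graph_density,
        )
        _library_frame(library, config.n_regions).to_csv(
            out / "library_metrics.csv", index=False
        )
        _write_manifest(out, "library", config, {"n_points": grid.size})
    timings["library"] = time.time() - t0

    # --- per-subject fits ---------------------------------------------
    t0 = time.time()
    _log("fit stage")
    if _stage_done(out, "fit", config):
        fits = pd.read_csv(out / "fits.csv")
    else:
        fits = fit_subjects(emp_sets, library)
        fits.to_csv(out / "fits.csv", index=False)
        _write_manifest(out, "fit", config, {"n_rows": len(fits)})
    timings["fit"] = time.time() - t0

    # --- associations --------------------------------------------------
    t0 = time.time()
    _log("associate stage")
    combined = fits[fits.criterion == "combined"].set_index("subject")
    outcome_cols = ["G", "J_N", "J_i", "w_p", "r_sfc", "r_fcv", "r_tc", "r_nc"]
    outcomes = combined[outcome_cols]
    order = list(outcomes.index)
    edge_feats = edge_feature_table([emp_sets[s].sfc for s in order])
    node_feats = node_feature_table([emp_sets[s].tc for s in order])
    if not _stage_done(out, "associate", config):
        assoc = pd.concat(
            [
                association_table(
                    outcomes, feats,
                    n_perm=config.n_perm_association,
                    seed=_derived_seed(config.master_seed, "associate"),
                )
                for feats in (edge_feats, node_feats)
            ],
            ignore_index=True,
        )
        assoc.to_csv(out / "associations.csv", index=False)
        _write_manifest(out, "associate", config, {"n_rows": len(assoc)})
    timings["associate"] = time.time() - t0

    # --- prediction -----------------------------------------------------
    t0 = time.time()
    _log("predict stage")
    if not _stage_done(out, "predict", config):
        pred_rows = []
        for kind, feats in (("edge_sfc", edge_feats), ("node_tc", node_feats)):
            for target in config.prediction_targets:
                y = outcomes[target].to_numpy(float)
                if y.std() == 0:
                    continue
                pspec = PredictionSpec(
                    feature_kind=kind, target=target,
                    pca_variance=0.90 if kind == "edge_sfc" else None,
                    seed=_derived_seed(config.master_seed, "predict"),
                )
                res = ridge_nested_cv(feats, y, pspec)
                pred_rows.append(
                    {"target": target, "feature_kind": kind,
                     "r2_mean": res.r2_mean, "r2_sem": res.r2_sem,
                     "best_alpha": res.best_alpha}
                )
        pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
        _write_manifest(out, "predict", config, {"n_models": len(pred_rows)})
    timings["predict"] = time.time() - t0

    # --- perturbation ---------------------------------------------------
    t0 = time.time()
    _log("perturb stage")
    if not _stage_done(out, "perturb", config):
        group_emp = average_metric_sets(list(emp_sets.values()))
        default_params = fit_group_default(sc, group_emp, library)
        sweep = sweep_all_regions(
            sc, default_params, config.perturb_G_values,
            config.sim_config(seed=_derived_seed(config.master_seed, "library")),
            group_emp,
            regions=[r for r in config.perturb_regions if r < config.n_regions],
            window_spec=spec, density=config.graph_density,
        )
        sweep.to_csv(out / "perturbation.csv", index=False)
        _write_manifest(
            out, "perturb", config,
            {"default_params": {"G": default_params.G, "J_N": default_params.J_N,
                                "J_i": default_params.J_i, "w_p": default_params.w_p}},
        )
    timings["perturb"] = time.time() - t0

    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "dynfc_version": __version__,
        "stages": list(timings),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(
            {k: v for k, v in manifest.items() if k != "timings_s"},
            fh, indent=2, sort_keys=True,
        )
    return manifest
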