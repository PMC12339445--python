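"""Structural connectomes, region metadata, and parcellated BOLD I/O.

A structural connectome is a pair of symmetric non-negative N x N matrices:
tract *weights* (connection strength, unitless after scaling) and tract
*lengths* (mm, which set conduction delays).  Region metadata carries names,
hemisphere, a resting-state-network (RSN) assignment into the seven canonical
networks, and centroid coordinates used only for spin tests.

File dialect: tab-separated matrices without header; BOLD tables with samples
in rows and regions in columns; metadata as CSV with columns
``region,hemisphere,network,x,y,z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_NETWORKS",
    "Parcellation",
    "StructuralConnectome",
    "BoldSeries",
    "read_connectome",
    "write_connectome",
    "average_connectomes",
    "robust_scale_connectome",
    "read_bold",
    "write_bold",
]

#: The seven canonical resting-state networks used to summarise regional
#: results (visual, somatomotor, dorsal/ventral attention, limbic,
#: frontoparietal, default mode).
CANONICAL_NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")


class ConnectomeFormatError(ValueError):
    """Malformed connectome or BOLD file (shape, dtype, parse failure)."""


class ConnectomeValidationError(ValueError):
    """Well-formed file whose contents violate a connectome invariant."""


@dataclass(frozen=True)
class Parcellation:
    """Region metadata for an N-region cortical parcellation."""

    region_names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    rsn_assignment: tuple[str, ...]
    centroids: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        n = len(self.region_names)
        if not (len(self.hemisphere) == len(self.rsn_assignment) == n):
            raise ConnectomeValidationError("metadata lists have unequal lengths")
        if len(set(self.region_names)) != n:
            raise ConnectomeValidationError("region names are not unique")
        bad_hemi = set(self.hemisphere) - {"left", "right"}
        if bad_hemi:
            raise ConnectomeValidationError(f"unknown hemisphere labels: {bad_hemi}")
        bad_net = set(self.rsn_assignment) - set(CANONICAL_NETWORKS)
        if bad_net:
            raise ConnectomeValidationError(f"unknown network labels: {bad_net}")
        cent = np.asarray(self.centroids, dtype=float)
        if cent.shape != (n, 3) or not np.all(np.isfinite(cent)):
            raise ConnectomeValidationError("centroids must be a finite (N, 3) array")
        object.__setattr__(self, "centroids", cent)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


def _validate_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectomeFormatError(f"{name} matrix is not square: shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ConnectomeValidationError(f"{name} matrix contains NaN/Inf")
    if np.any(m < 0):
        raise ConnectomeValidationError(f"{name} matrix has negative entries")
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > 1e-8:
        raise ConnectomeValidationError(
            f"{name} matrix asymmetric beyond tolerance (max |A-A.T| = {asym:g})"
        )
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass(frozen=True)
class StructuralConnectome:
    """Tract weights and lengths on a parcellation.

    ``weights[i, j]`` is the coupling substrate C_ij of the mean-field model;
    ``lengths[i, j]`` (mm) sets the conduction delay between regions i and j.
    Both matrices are symmetric with zero diagonal, and a positive weight
    implies a positive length.
    """

    weights: np.ndarray
    lengths: np.ndarray
    parcellation: Parcellation | None = None

    def __post_init__(self) -> None:
        w = _validate_matrix(self.weights, "weights")
        l = _validate_matrix(self.lengths, "lengths")
        if w.shape != l.shape:
            raise ConnectomeFormatError(
                f"weights {w.shape} and lengths {l.shape} dimension mismatch"
            )
        if np.any((w > 0) & (l <= 0)):
            raise ConnectomeValidationError(
                "positive weight with non-positive tract length"
            )
        if self.parcellation is not None and self.parcellation.n_regions != w.shape[0]:
            raise ConnectomeFormatError(
                "parcellation size does not match matrix dimension"
            )
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lengths", l)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BoldSeries:
    """Parcellated BOLD time courses: a T x N matrix sampled every ``tr`` s."""

    data: np.ndarray
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] < 2:
            raise ConnectomeFormatError("BOLD data must be T x N with T >= 2")
        if not np.all(np.isfinite(d)):
            raise ConnectomeValidationError("BOLD data contains NaN/Inf")
        if self.tr <= 0:
            raise ConnectomeValidationError("tr must be positive")
        object.__setattr__(self, "data", d)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Scan length in seconds."""
        return self.n_samples * self.tr


def _read_matrix(path: str | Path) -> np.ndarray:
    try:
        m = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ConnectomeFormatError(f"{path}: {exc}") from exc
    return m


def read_parcellation(metadata_path: str | Path) -> Parcellation:
    """Read region metadata CSV (columns region,hemisphere,network,x,y,z)."""
    df = pd.read_csv(metadata_path)
    required = {"region", "hemisphere", "network", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ConnectomeFormatError(f"metadata missing columns: {sorted(missing)}")
    return Parcellation(
        region_names=tuple(df["region"].astype(str)),
        hemisphere=tuple(df["hemisphere"].astype(str)),
        rsn_assignment=tuple(df["network"].astype(str)),
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def read_connectome(
    weights_path: str | Path,
    lengths_path: str | Path,
    metadata_path: str | Path | None = None,
) -> StructuralConnectome:
    """Read and validate a structural connectome from TSV matrices.

    Matrices are symmetrised by averaging with their transpose when the
    maximum asymmetry is within 1e-8; larger asymmetry raises
    :class:`ConnectomeValidationError`.
    """
    weights = _read_matrix(weights_path)
    lengths = _read_matrix(lengths_path)
    if weights.shape != lengths.shape:
        raise ConnectomeFormatError(
            f"weights {weights.shape} vs lengths {lengths.shape} dimension mismatch"
        )
    parc = read_parcellation(metadata_path) if metadata_path is not None else None
    return StructuralConnectome(weights=weights, lengths=lengths, parcellation=parc)


def write_connectome(
    sc: StructuralConnectome,
    weights_path: str | Path,
    lengths_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a connectome back to the TSV/CSV dialect ``read_connectome`` reads."""
    np.savetxt(weights_path, sc.weights, delimiter="\t")
    np.savetxt(lengths_path, sc.lengths, delimiter="\t")
    if metadata_path is not None and sc.parcellation is not None:
        p = sc.parcellation
        pd.DataFrame(
            {
                "region": p.region_names,
                "hemisphere": p.hemisphere,
                "network": p.rsn_assignment,
                "x": p.centroids[:, 0],
                "y": p.centroids[:, 1],
                "z": p.centroids[:, 2],
            }
        ).to_csv(metadata_path, index=False)


def average_connectomes(
    connectomes: Sequence[StructuralConnectome],
) -> StructuralConnectome:
    """Element-wise mean of weights and lengths across subjects.

    All connectomes must share N and region order.  The group-average
    connectome is the simulation substrate: one average matrix pair serves
    every subject's fit.
    """
    if len(connectomes) == 0:
        raise ValueError("cannot average an empty list of connectomes")
    n = connectomes[0].n_regions
    if any(c.n_regions != n for c in connectomes):
        raise ConnectomeFormatError("connectomes differ in region count")
    # sort per entry before summing so the mean is exactly invariant to the
    # order of the input list (float addition is not associative)
    weights = np.sort(np.stack([c.weights for c in connectomes]), axis=0).mean(axis=0)
    lengths = np.sort(np.stack([c.lengths for c in connectomes]), axis=0).mean(axis=0)
    return StructuralConnectome(
        weights=weights, lengths=lengths, parcellation=connectomes[0].parcellation
    )


def _even_round(x: np.ndarray) -> np.ndarray:
    # Nearest even integer; exact midpoints (odd integers) round away from 0.
    return np.floor(x / 2.0 + 0.5) * 2.0


def _robust_scale_matrix(m: np.ndarray) -> np.ndarray:
    nz = m > 0
    vals = m[nz]
    if vals.size == 0:
        raise ValueError("matrix has no nonzero entries")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError("zero IQR over nonzero entries: degenerate input")
    out = np.zeros_like(m)
    out[nz] = np.clip((vals - med) / iqr, 0.0, None)
    out = _even_round(out)
    np.fill_diagonal(out, 0.0)
    return out


def robust_scale_connectome(sc: StructuralConnectome) -> StructuralConnectome:
    """Outlier-robust rescaling of weights and lengths, each to even integers.

    Over the nonzero entries of each matrix separately: subtract the median,
    divide by the interquartile range, clip resulting negatives to zero (the
    coupling term requires C_ij >= 0, so the weakest half of connections is
    sparsified), and round to the nearest even integer.  Absent connections
    stay absent; the diagonal stays zero and symmetry is preserved.
    """
    weights = _robust_scale_matrix(sc.weights)
    lengths = _robust_scale_matrix(sc.lengths)
    # A surviving weight needs a positive delay-defining length; keep the
    # scaled length but floor it at 2 (the smallest positive even value)
    # wherever a positive weight would otherwise lose its length.
    orphan = (weights > 0) & (lengths == 0)
    lengths[orphan] = 2.0
    return StructuralConnectome(
        weights=weights, lengths=lengths, parcellation=sc.parcellation
    )


def read_bold(
    path: str | Path, tr: float, subject_id: str = "", n_regions: int | None = None
) -> BoldSeries:
    """Read a T x N BOLD table (TSV, samples in rows, regions in columns)."""
    import warnings

    try:
        with warnings.catch_warnings():
            # an empty file raises our own format error below
            warnings.filterwarnings("ignore", message=".*no data.*")
            data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ConnectomeFormatError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise ConnectomeFormatError(f"{path}: empty BOLD file")
    if n_regions is not None and data.shape[1] != n_regions:
        raise ConnectomeFormatError(
            f"{path}: {data.shape[1]} regions, expected {n_regions}"
        )
    sid = subject_id or Path(path).stem
    return BoldSeries(data=data, tr=tr, subject_id=sid)


def write_bold(series: BoldSeries, path: str | Path) -> None:
    np.savetxt(path, series.data, delimiter="\t")
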