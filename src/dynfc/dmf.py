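"""Reduced Wong-Wang excitatory/inhibitory mean-field model on a connectome.

Each region holds one excitatory (E) and one inhibitory (I) population with
average synaptic gating variables S^E, S^I in [0, 1].  Input currents are

    I_i^E = w_E*I_0 + w_p*J_N*S_i^E + G_i*J_N * sum_j C_ij * S_j^E(t - d_ij)
            - J_i*S_i^I
    I_i^I = w_I*I_0 + J_N*S_i^E - S_i^I

with C the structural-connectome weights and d_ij = length_ij / conduction
speed the axonal delay.  Firing rates follow the soft-threshold transfer
function H(x) = (a*x - b) / (1 - exp(-d*(a*x - b))) and gating evolves as

    dS^E/dt = -S^E/tau_E + (1 - S^E) * gamma_E * r^E + sigma*nu(t)
    dS^I/dt = -S^I/tau_I + r^I + sigma*nu(t)

integrated by Euler-Maruyama with independent Gaussian increments
sigma*sqrt(dt)*N(0,1) per population and region, gating clipped to [0, 1]
after every step.  Excitatory gating drives the Balloon-Windkessel
hemodynamic model to produce a simulated BOLD signal sampled every ``tr``.

Free parameters: the global coupling G (optionally per-region, for
perturbation experiments), the excitatory NMDA coupling J_N (nA), the local
feedback inhibition J_i (nA), and the excitatory recurrence weight w_p.
Remaining constants default to the canonical published values of the model
and are all overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .connectomes import StructuralConnectome

__all__ = [
    "ModelParameters",
    "HemodynamicParameters",
    "SimulationConfig",
    "SimulationResult",
    "IntegrationError",
    "transfer_function",
    "compute_currents",
    "balloon_windkessel",
    "integrate",
]


class IntegrationError(RuntimeError):
    """Numerical divergence (NaN/Inf) during integration."""


@dataclass(frozen=True)
class ModelParameters:
    """Free parameters plus fixed constants of the E/I mean-field model.

    The four free parameters are ``G`` (global coupling, unitless), ``J_N``
    (excitatory NMDA synaptic coupling, nA), ``J_i`` (local feedback
    inhibitory coupling, nA) and ``w_p`` (local excitatory recurrence,
    unitless).  Fixed constants carry the canonical values of the reduced
    Wong-Wang E/I model: transfer-function gains a (nC^-1), thresholds b
    (Hz), saturation d (s), synaptic time constants tau (s), kinetic rate
    gamma_E, external input I_0 (nA) with scaling weights w_E/w_I, and noise
    amplitude sigma (nA).
    """

    G: float = 1.0
    J_N: float = 0.15
    J_i: float = 1.0
    w_p: float = 1.4
    a_E: float = 310.0
    b_E: float = 125.0
    d_E: float = 0.16
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 0.1
    tau_I: float = 0.01
    gamma_E: float = 0.641
    sigma: float = 0.01
    I_0: float = 0.382
    w_E: float = 1.0
    w_I: float = 0.7

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if min(self.a_E, self.a_I, self.d_E, self.d_I) <= 0:
            raise ValueError("transfer-function gains must be positive")


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel constants (Friston 2003 / Obata 2004 defaults).

    kappa: vasodilatory signal decay rate (s^-1); gamma_f: flow-dependent
    elimination (s^-1); tau_h: hemodynamic transit time (s); alpha: Grubb's
    vessel stiffness exponent; rho: resting oxygen extraction fraction;
    V0 and k1..k3: BOLD output coefficients.
    """

    kappa: float = 0.65
    gamma_f: float = 0.41
    tau_h: float = 0.98
    alpha: float = 0.32
    rho: float = 0.34
    V0: float = 0.02
    k1: float = 7.0 * 0.34
    k2: float = 2.0
    k3: float = 2.0 * 0.34 - 0.2

    def __post_init__(self) -> None:
        if min(self.kappa, self.gamma_f, self.tau_h, self.V0) <= 0:
            raise ValueError("hemodynamic rates must be strictly positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.rho < 1):
            raise ValueError("rho must lie in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``duration`` is total simulated time including the discarded ``burn_in``.
    ``conduction_speed`` (mm/s) enables tract-length delays; ``None`` selects
    the documented no-delays mode.  ``regional_G_override`` replaces the
    scalar G in selected regions (NaN entries keep the default), used by the
    perturbation module.  ``state_stride`` subsamples the stored neural time
    courses (in integration steps); BOLD is always integrated at full dt
    resolution and sampled every ``tr``.
    """

    dt: float = 0.001
    duration: float = 874.0
    burn_in: float = 10.0
    tr: float = 0.72
    seed: int = 0
    conduction_speed: Optional[float] = None
    regional_G_override: Optional[np.ndarray] = None
    init_gating: float = 0.001
    state_stride: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.duration > self.burn_in >= 0):
            raise ValueError("need duration > burn_in >= 0")
        if self.tr < self.dt:
            raise ValueError("tr must be at least dt")
        if self.conduction_speed is not None and self.conduction_speed <= 0:
            raise ValueError("conduction_speed must be positive (or None)")


@dataclass(frozen=True)
class SimulationResult:
    """Neural and BOLD time courses from one simulation run.

    ``S_E``/``S_I``/``r_E`` are sampled every ``state_stride`` steps after
    burn-in (the last row is the terminal state); ``bold`` is sampled every
    ``tr``.  ``noise_increments`` holds the exact Euler-Maruyama increments
    (steps, N, 2) when the run was asked to store them.
    """

    S_E: np.ndarray
    S_I: np.ndarray
    r_E: np.ndarray
    bold: np.ndarray
    config_echo: SimulationConfig
    params_echo: ModelParameters
    noise_increments: Optional[np.ndarray] = None


def transfer_function(current, a: float, b: float, d: float):
    """Population transfer function H(x) = (a*x-b)/(1-exp(-d*(a*x-b))).

    Total and continuous: at a*x - b = 0 the removable singularity takes the
    analytic limit 1/d; the function is non-negative everywhere and
    asymptotically linear for large positive drive.
    """
    x = np.asarray(current, dtype=float)
    u = a * x - b
    z = d * u
    small = np.abs(z) < 1e-6
    # z/(1 - e^-z) = 1 + z/2 + z^2/12 - z^4/720 + ...
    series = (1.0 + 0.5 * z + z * z / 12.0) / d
    denom = np.where(small, 1.0, 1.0 - np.exp(-np.where(small, 1.0, z)))
    out = np.where(small, series, u / denom)
    if out.ndim == 0:
        return float(out)
    return out


def compute_currents(
    S_E: np.ndarray,
    S_I: np.ndarray,
    delayed_S_E: np.ndarray,
    params: ModelParameters,
    sc: StructuralConnectome,
    regional_G_override: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Input currents to both populations for one network state.

    ``delayed_S_E`` is an N x N matrix whose row i holds the excitatory
    gating of every source region j as seen from region i (lagged by the
    conduction delay d_ij; without delays every row equals the current
    ``S_E``).  Returns ``(I_E, I_I)`` in nA.
    """
    S_E = np.asarray(S_E, float)
    S_I = np.asarray(S_I, float)
    delayed = np.asarray(delayed_S_E, float)
    n = sc.n_regions
    if S_E.shape != (n,) or S_I.shape != (n,) or delayed.shape != (n, n):
        raise ValueError("state dimensions do not match the connectome")
    G_vec = _resolve_G(params.G, regional_G_override, n)
    coupling = np.einsum("ij,ij->i", sc.weights, delayed)
    I_E = (
        params.w_E * params.I_0
        + params.w_p * params.J_N * S_E
        + G_vec * params.J_N * coupling
        - params.J_i * S_I
    )
    I_I = params.w_I * params.I_0 + params.J_N * S_E - S_I
    return I_E, I_I


def _resolve_G(G: float, override: Optional[np.ndarray], n: int) -> np.ndarray:
    G_vec = np.full(n, float(G))
    if override is not None:
        override = np.asarray(override, float)
        if override.shape != (n,):
            raise ValueError("regional_G_override must have one entry per region")
        mask = ~np.isnan(override)
        G_vec[mask] = override[mask]
    return G_vec


@njit(cache=True, inline="always")
def _H(x, a, b, d):
    u = a * x - b
    z = d * u
    if abs(z) < 1e-6:
        return (1.0 + 0.5 * z + z * z / 12.0) / d
    return u / (1.0 - np.exp(-z))


@njit(cache=True)
def _neural_chunk(
    C,
    delay,
    use_delay,
    hist,
    pos,
    S_E,
    S_I,
    G_vec,
    J_N,
    J_i,
    w_p,
    w_E,
    w_I,
    I_0,
    a_E,
    b_E,
    d_E,
    a_I,
    b_I,
    d_I,
    tau_E,
    tau_I,
    gamma_E,
    dt,
    noise_E,
    noise_I,
    out_SE,
    out_SI,
    out_rE,
):
    n_steps = noise_E.shape[0]
    N = C.shape[0]
    L = hist.shape[0]
    rE_buf = np.empty(N)
    rI_buf = np.empty(N)
    for t in range(n_steps):
        for i in range(N):
            acc = 0.0
            if use_delay:
                for j in range(N):
                    cij = C[i, j]
                    if cij != 0.0:
                        acc += cij * hist[(pos - delay[i, j]) % L, j]
            else:
                for j in range(N):
                    acc += C[i, j] * S_E[j]
            I_E = w_E * I_0 + w_p * J_N * S_E[i] + G_vec[i] * J_N * acc - J_i * S_I[i]
            I_I = w_I * I_0 + J_N * S_E[i] - S_I[i]
            rE_buf[i] = _H(I_E, a_E, b_E, d_E)
            rI_buf[i] = _H(I_I, a_I, b_I, d_I)
        for i in range(N):
            se = S_E[i] + (
                -S_E[i] / tau_E + (1.0 - S_E[i]) * gamma_E * rE_buf[i]
            ) * dt + noise_E[t, i]
            si = S_I[i] + (-S_I[i] / tau_I + rI_buf[i]) * dt + noise_I[t, i]
            if se < 0.0:
                se = 0.0
            elif se > 1.0:
                se = 1.0
            if si < 0.0:
                si = 0.0
            elif si > 1.0:
                si = 1.0
            S_E[i] = se
            S_I[i] = si
            out_SE[t, i] = se
            out_SI[t, i] = si
            out_rE[t, i] = rE_buf[i]
        pos = (pos + 1) % L
        for i in range(N):
            hist[pos, i] = S_E[i]
    return pos


@njit(cache=True)
def _hemo_chunk(z_chunk, s, f, v, q, kappa, gamma_f, tau_h, inv_alpha, rho, V0, k1, k2, k3, dt, out_bold):
    n_steps = z_chunk.shape[0]
    N = z_chunk.shape[1]
    for t in range(n_steps):
        for i in range(N):
            fi = f[i]
            vi = v[i]
            outflow = vi ** inv_alpha
            ds = z_chunk[t, i] - kappa * s[i] - gamma_f * (fi - 1.0)
            df = s[i]
            dv = (fi - outflow) / tau_h
            dq = (
                fi * (1.0 - (1.0 - rho) ** (1.0 / fi)) / rho - outflow * q[i] / vi
            ) / tau_h
            s[i] += dt * ds
            f[i] += dt * df
            v[i] += dt * dv
            q[i] += dt * dq
            if f[i] < 1e-6:
                f[i] = 1e-6
            if v[i] < 1e-6:
                v[i] = 1e-6
            out_bold[t, i] = V0 * (
                k1 * (1.0 - q[i]) + k2 * (1.0 - q[i] / v[i]) + k3 * (1.0 - v[i])
            )


def balloon_windkessel(
    S_E: np.ndarray,
    hemo: HemodynamicParameters | None = None,
    dt: float = 0.001,
    tr: float = 0.72,
) -> np.ndarray:
    """Transform excitatory gating to BOLD via the Balloon-Windkessel model.

    Integrates the four-state hemodynamic ODEs (vasodilatory signal s,
    inflow f, venous volume v, deoxyhemoglobin q) per region with the
    excitatory synaptic activity as drive, starting from baseline
    (0, 1, 1, 1), and emits BOLD = V0*(k1(1-q) + k2(1-q/v) + k3(1-v))
    downsampled to one sample per ``tr``.
    """
    hemo = hemo or HemodynamicParameters()
    S_E = np.asarray(S_E, float)
    if S_E.ndim != 2:
        raise ValueError("S_E must be a T x N array")
    T, N = S_E.shape
    if T * dt < tr:
        raise ValueError("input shorter than one BOLD sample")
    s = np.zeros(N)
    f = np.ones(N)
    v = np.ones(N)
    q = np.ones(N)
    bold_full = np.empty((T, N))
    _hemo_chunk(
        S_E, s, f, v, q, hemo.kappa, hemo.gamma_f, hemo.tau_h, 1.0 / hemo.alpha,
        hemo.rho, hemo.V0, hemo.k1, hemo.k2, hemo.k3, dt, bold_full,
    )
    if not np.all(np.isfinite(bold_full)):
        bad = int(np.argwhere(~np.isfinite(bold_full))[0][0])
        raise IntegrationError(f"hemodynamic divergence at step {bad}")
    stride = int(round(tr / dt))
    return bold_full[stride - 1 :: stride].copy()


_CHUNK = 8192


def integrate(
    sc: StructuralConnectome,
    params: ModelParameters,
    config: SimulationConfig,
    hemo: HemodynamicParameters | None = None,
    store_increments: bool = False,
) -> SimulationResult:
    """Euler-Maruyama integration of the coupled E/I model plus hemodynamics.

    The stochastic increments are sigma*sqrt(dt)*N(0,1), drawn from a
    ``numpy.random.default_rng(seed)`` stream that is identical for
    identical ``(seed, config)``, so repeated runs are bit-identical.  With
    ``sigma = 0`` the run is fully deterministic and seed-independent
    (initial-state jitter is only applied to stochastic runs).  Gating is
    clipped to [0, 1] after every step; the hemodynamic states are advanced
    at every dt (including burn-in, so the recorded BOLD starts settled) and
    sampled every ``tr`` after burn-in.
    """
    hemo = hemo or HemodynamicParameters()
    n = sc.n_regions
    dt = config.dt
    total_steps = int(round(config.duration / dt))
    burn_steps = int(round(config.burn_in / dt))
    keep_steps = total_steps - burn_steps
    tr_stride = int(round(config.tr / dt))
    state_stride = config.state_stride or tr_stride

    rng = np.random.default_rng(config.seed)
    S_E = np.full(n, config.init_gating)
    S_I = np.full(n, config.init_gating)
    stochastic = params.sigma > 0
    if stochastic:
        S_E = S_E + rng.uniform(0.0, 1e-3, n)
        S_I = S_I + rng.uniform(0.0, 1e-3, n)
    np.clip(S_E, 0.0, 1.0, out=S_E)
    np.clip(S_I, 0.0, 1.0, out=S_I)

    if config.conduction_speed is not None:
        delay = np.round(sc.lengths / (config.conduction_speed * dt)).astype(np.int64)
        np.fill_diagonal(delay, 0)
        use_delay = bool(delay.max() > 0)
    else:
        delay = np.zeros((n, n), dtype=np.int64)
        use_delay = False
    L = int(delay.max()) + 1
    hist = np.tile(S_E, (L, 1))
    pos = 0

    G_vec = _resolve_G(params.G, config.regional_G_override, n)
    noise_scale = params.sigma * np.sqrt(dt)

    n_bold = keep_steps // tr_stride
    n_state = keep_steps // state_stride
    out_SE = np.empty((n_state, n))
    out_SI = np.empty((n_state, n))
    out_rE = np.empty((n_state, n))
    bold = np.empty((n_bold, n))
    incr = np.empty((total_steps, n, 2)) if store_increments else None

    hs = np.zeros(n)
    hf = np.ones(n)
    hv = np.ones(n)
    hq = np.ones(n)

    chunk_SE = np.empty((_CHUNK, n))
    chunk_SI = np.empty((_CHUNK, n))
    chunk_rE = np.empty((_CHUNK, n))
    chunk_bold = np.empty((_CHUNK, n))

    step = 0
    while step < total_steps:
        m = min(_CHUNK, total_steps - step)
        if stochastic:
            noise = rng.standard_normal((m, n, 2)) * noise_scale
        else:
            noise = np.zeros((m, n, 2))
        if store_increments:
            incr[step : step + m] = noise
        pos = _neural_chunk(
            sc.weights, delay, use_delay, hist, pos, S_E, S_I, G_vec,
            params.J_N, params.J_i, params.w_p, params.w_E, params.w_I,
            params.I_0, params.a_E, params.b_E, params.d_E, params.a_I,
            params.b_I, params.d_I, params.tau_E, params.tau_I,
            params.gamma_E, dt, noise[:, :, 0], noise[:, :, 1],
            chunk_SE[:m], chunk_SI[:m], chunk_rE[:m],
        )
        if not np.all(np.isfinite(chunk_SE[:m])):
            bad = step + int(np.argwhere(~np.isfinite(chunk_SE[:m]))[0][0])
            raise IntegrationError(f"neural divergence at step {bad}")
        _hemo_chunk(
            chunk_SE[:m], hs, hf, hv, hq, hemo.kappa, hemo.gamma_f, hemo.tau_h,
            1.0 / hemo.alpha, hemo.rho, hemo.V0, hemo.k1, hemo.k2, hemo.k3,
            dt, chunk_bold[:m],
        )
        # global post-burn-in indices of this chunk's steps
        idx = np.arange(step, step + m) - burn_steps
        keep = idx >= 0
        if keep.any():
            for stride, src, dst in (
                (state_stride, chunk_SE, out_SE),
                (state_stride, chunk_SI, out_SI),
                (state_stride, chunk_rE, out_rE),
                (tr_stride, chunk_bold, bold),
            ):
                sel = keep & ((idx + 1) % stride == 0)
                if sel.any():
                    rows = (idx[sel] + 1) // stride - 1
                    dst[rows] = src[: m][sel]
        step += m

    if not np.all(np.isfinite(bold)):
        raise IntegrationError("hemodynamic divergence in sampled BOLD")
    return SimulationResult(
        S_E=out_SE,
        S_I=out_SI,
        r_E=out_rE,
        bold=bold,
        config_echo=config,
        params_echo=params,
        noise_increments=incr,
    )


def simulate_bold(
    sc: StructuralConnectome,
    params: ModelParameters,
    config: SimulationConfig,
    hemo: HemodynamicParameters | None = None,
):
    """Convenience wrapper returning only the simulated BOLD (T_bold x N)."""
    return integrate(sc, params, config, hemo=hemo).bold
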