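"""Neuronal dynamics and the haemodynamic observation model.

The bilinear neuronal system is integrated exactly over each microtime bin
(inputs are piecewise constant, so the per-bin propagator is a matrix
exponential).  Neuronal activity then drives, per region, the four-state
balloon/Windkessel cascade (vasodilatory signal s, normalised blood flow f,
venous volume v, deoxyhaemoglobin q):

    ds/dt = eps * z - decay * s - gamma * (f - 1)
    df/dt = s
    dv/dt = (f - v**(1/alpha)) / transit
    dq/dt = (f * E(f)/E0 - v**(1/alpha) * q/v) / transit,  E(f) = 1-(1-E0)**(1/f)

with the nonlinear BOLD read-out (percent signal change)

    y = 100 * V0 * (k1 (1-q) + k2 (1 - q/v) + k3 (1 - v)),
    k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.

The flow-dependent feedback rate gamma is fixed at 0.32 1/s.  Scans are taken
at (k + slice_offset) * TR; the slice-timing offset defaults to 0.5 TR.

Everything is vectorised over a leading batch axis so that finite-difference
sensitivities of the whole forward model can be computed in one pass; the
per-bin recursions are compiled with numba.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import expm

from .design import InputSeries
from .network import DCMParams, HemoParams, NetworkSpec, param_names, _locate

__all__ = [
    "StateTrajectory",
    "BoldTimeSeries",
    "neuronal_drift",
    "effective_connectivity",
    "integrate_neuronal",
    "hemodynamic_bold",
    "simulate_bold",
    "is_stable",
    "BatchedForward",
]

GAMMA_FLOW = 0.32  # 1/s, flow-dependent elimination in the vasodilatory signal


@dataclass
class StateTrajectory:
    """Neuronal activity on the microtime grid; z[t] is the state at t*dt."""

    z: np.ndarray   # (n_bins, n_nodes)
    dt: float


@dataclass
class BoldTimeSeries:
    """Sampled BOLD (percent signal change), one column per region."""

    y: np.ndarray           # (n_scans, n_nodes)
    tr: float
    slice_offset: float = 0.5
    node_labels: tuple[str, ...] = ()

    @property
    def n_scans(self) -> int:
        return self.y.shape[0]

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr

    def scan_times(self) -> np.ndarray:
        return (np.arange(self.n_scans) + self.slice_offset) * self.tr


def effective_connectivity(params: DCMParams, u: np.ndarray,
                           spec: NetworkSpec | None = None) -> np.ndarray:
    """A + sum_j u_j B^j with the log-scaled self-connection diagonal (Hz)."""
    inputs = list(params.B)
    u = np.asarray(u, float)
    if u.shape != (len(inputs),):
        raise ValueError(f"expected {len(inputs)} inputs, got {u.shape}")
    E = params.A.copy()
    np.fill_diagonal(E, 0.0)
    log_diag = params.self_log.copy()
    for j, name in enumerate(inputs):
        Bj = params.B[name]
        off = Bj.copy()
        np.fill_diagonal(off, 0.0)
        E += u[j] * off
        log_diag = log_diag + u[j] * np.diag(Bj)
    E[np.diag_indices_from(E)] = -0.5 * np.exp(log_diag)
    return E


def neuronal_drift(z: np.ndarray, u: np.ndarray, params: DCMParams) -> np.ndarray:
    """dz/dt = (A + sum_j u_j B^j) z + C u."""
    z = np.asarray(z, float)
    u = np.asarray(u, float)
    if z.shape[0] != params.A.shape[0]:
        raise ValueError("state dimension does not match A")
    if u.shape[0] != params.C.shape[1]:
        raise ValueError("input dimension does not match C")
    return effective_connectivity(params, u) @ z + params.C @ u


def realizable_input_corners(input_names) -> np.ndarray:
    """Extreme input combinations the experimental design can realise.

    Perception and imagery boxcars never overlap, and the vividness modulator
    is nonzero only during imagery frames (mean-centred 1-4 ratings, hence
    bounded by +-2.1 around any category mean).  For non-canonical input sets
    every binary on/off combination is used instead.
    """
    names = list(input_names)
    if names == list(("perception", "imagery", "vividness")):
        return np.array([
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, -2.1],
            [0.0, 1.0, 0.0],
            [0.0, 1.0, 2.1],
        ])
    J = len(names)
    return np.array([[(m >> j) & 1 for j in range(J)] for m in range(2 ** J)],
                    dtype=float)


def is_stable(params: DCMParams, margin: float = 0.0,
              u_set: np.ndarray | None = None) -> bool:
    """Stability guard: Re eig(A + sum_j u_j B^j) < 0 at every realisable input.

    The signed effective connectivity is checked at each input combination the
    design can produce (or at the rows of ``u_set`` when given, e.g. the
    unique rows of an actual input series), so inhibitory modulation counts
    as the negative feedback it is.
    """
    if u_set is None:
        u_set = realizable_input_corners(list(params.B))
    worst = -np.inf
    for u in np.atleast_2d(u_set):
        E = effective_connectivity(params, u)
        worst = max(worst, float(np.max(np.real(np.linalg.eigvals(E)))))
    return worst < -margin


# ---------------------------------------------------------------------------
# compiled recursions
# ---------------------------------------------------------------------------

@njit(cache=True)
def _propagate_neuronal(M, d, uid):  # pragma: no cover - compiled
    """z_{t+1} = M[uid_t] z_t + d[uid_t], batched; records state at bin start."""
    nb, K, n, _ = M.shape
    T = uid.shape[0]
    z = np.zeros((nb, T, n))
    state = np.zeros((nb, n))
    for t in range(T):
        for b in range(nb):
            for i in range(n):
                z[b, t, i] = state[b, i]
        for b in range(nb):
            k = uid[t]
            new = np.zeros(n)
            for i in range(n):
                acc = d[b, k, i]
                for jj in range(n):
                    acc += M[b, k, i, jj] * state[b, jj]
                new[i] = acc
            for i in range(n):
                state[b, i] = new[i]
    return z


@njit(cache=True, inline="always")
def _hemo_deriv(sc, fc, vc, qc, zz, kap, gamma, tau, ia, rho, ln1e):  # pragma: no cover
    if fc < 1e-8:
        fc = 1e-8
    if vc < 1e-8:
        vc = 1e-8
    if qc < 1e-8:
        qc = 1e-8
    fout = vc ** ia
    ds = zz - kap * sc - gamma * (fc - 1.0)
    dv = (fc - fout) / tau
    dq = (fc * (1.0 - np.exp(ln1e / fc)) / rho - fout * qc / vc) / tau
    return ds, sc, dv, dq


@njit(cache=True)
def _integrate_hemo(z, dt, decay, gamma, transit, ialpha, e0, eff):  # pragma: no cover
    """RK4 balloon/Windkessel per (batch, node); returns v, q at bin starts."""
    nb, T, n = z.shape
    v_out = np.ones((nb, T, n))
    q_out = np.ones((nb, T, n))
    s = np.zeros((nb, n))
    f = np.ones((nb, n))
    v = np.ones((nb, n))
    q = np.ones((nb, n))
    for t in range(T):
        for b in range(nb):
            for i in range(n):
                v_out[b, t, i] = v[b, i]
                q_out[b, t, i] = q[b, i]
        for b in range(nb):
            for i in range(n):
                zz = z[b, t, i] * eff[b, i]
                kap = decay[b, i]
                tau = transit[b, i]
                ia = ialpha[b, i]
                rho = e0[b, i]
                ln1e = np.log(1.0 - rho)
                s0, f0, v0, q0 = s[b, i], f[b, i], v[b, i], q[b, i]
                # four RK4 stages with the neuronal drive frozen over the bin
                ks1, kf1, kv1, kq1 = _hemo_deriv(s0, f0, v0, q0, zz, kap,
                                                 gamma, tau, ia, rho, ln1e)
                ks2, kf2, kv2, kq2 = _hemo_deriv(
                    s0 + 0.5 * dt * ks1, f0 + 0.5 * dt * kf1,
                    v0 + 0.5 * dt * kv1, q0 + 0.5 * dt * kq1,
                    zz, kap, gamma, tau, ia, rho, ln1e)
                ks3, kf3, kv3, kq3 = _hemo_deriv(
                    s0 + 0.5 * dt * ks2, f0 + 0.5 * dt * kf2,
                    v0 + 0.5 * dt * kv2, q0 + 0.5 * dt * kq2,
                    zz, kap, gamma, tau, ia, rho, ln1e)
                ks4, kf4, kv4, kq4 = _hemo_deriv(
                    s0 + dt * ks3, f0 + dt * kf3, v0 + dt * kv3, q0 + dt * kq3,
                    zz, kap, gamma, tau, ia, rho, ln1e)
                s[b, i] = s0 + dt * (ks1 + 2 * ks2 + 2 * ks3 + ks4) / 6.0
                f[b, i] = f0 + dt * (kf1 + 2 * kf2 + 2 * kf3 + kf4) / 6.0
                v[b, i] = v0 + dt * (kv1 + 2 * kv2 + 2 * kv3 + kv4) / 6.0
                q[b, i] = q0 + dt * (kq1 + 2 * kq2 + 2 * kq3 + kq4) / 6.0
    return v_out, q_out


def _bold_readout(v: np.ndarray, q: np.ndarray, e0: np.ndarray, v0: float) -> np.ndarray:
    """Nonlinear BOLD equation; e0 broadcastable against the node axis."""
    k1 = 7.0 * e0
    k2 = 2.0
    k3 = 2.0 * e0 - 0.2
    return 100.0 * v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def _bin_propagators(Aeff_dt: np.ndarray, Cu_dt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-bin propagators via the augmented-matrix exponential.

    expm([[A dt, Cu dt], [0, 0]]) = [[M, d], [0, 1]] gives both the state map
    M and the constant-input increment d without solving a linear system, so
    marginally stable draws do not need special casing.
    """
    *lead, n, _ = Aeff_dt.shape
    G = np.zeros((*lead, n + 1, n + 1))
    G[..., :n, :n] = Aeff_dt
    G[..., :n, n] = Cu_dt
    X = expm(G)
    return np.ascontiguousarray(X[..., :n, :n]), np.ascontiguousarray(X[..., :n, n])


def integrate_neuronal(params: DCMParams, inputs: InputSeries,
                       strict: bool = True) -> StateTrajectory:
    """Integrate the bilinear system from z(0) = 0 over the input series."""
    U_unique, uid = np.unique(inputs.u, axis=0, return_inverse=True)
    if not is_stable(params, u_set=U_unique):
        if strict:
            raise ValueError("unstable system: some eigenvalue of the "
                             "effective connectivity has a nonnegative real "
                             "part at a realised input combination")
        warnings.warn("integrating a potentially unstable system", RuntimeWarning)
    inputs_order = list(params.B)
    if inputs.names != inputs_order:
        raise ValueError(f"input order mismatch: {inputs.names} vs {inputs_order}")
    K = U_unique.shape[0]
    n = params.A.shape[0]
    Aeff = np.zeros((K, n, n))
    Cu = np.zeros((K, n))
    for k in range(K):
        Aeff[k] = effective_connectivity(params, U_unique[k])
        Cu[k] = params.C @ U_unique[k]
    M, d = _bin_propagators(Aeff * inputs.dt, Cu * inputs.dt)
    z = _propagate_neuronal(M[None], d[None], uid.astype(np.int64))[0]
    return StateTrajectory(z=z, dt=inputs.dt)


def hemodynamic_bold(traj: StateTrajectory, hemo: HemoParams) -> np.ndarray:
    """Continuous-time BOLD (percent) on the trajectory's microtime grid."""
    hemo.validate()
    if not np.all(np.isfinite(traj.z)):
        raise ValueError("non-finite neuronal trajectory")
    z = traj.z[None]
    v, q = _integrate_hemo(
        np.ascontiguousarray(z), traj.dt,
        np.atleast_2d(hemo.decay), GAMMA_FLOW, np.atleast_2d(hemo.transit),
        1.0 / np.atleast_2d(hemo.stiffness), np.atleast_2d(hemo.e0),
        np.atleast_2d(hemo.efficacy),
    )
    return _bold_readout(v, q, hemo.e0[None, None, :], hemo.v0)[0]


def _sample_scans(signal: np.ndarray, dt: float, tr: float,
                  slice_offset: float) -> np.ndarray:
    """Linear interpolation of a microtime signal at (k + slice_offset) * TR."""
    T = signal.shape[-2]
    duration = T * dt
    n_scans = int(np.floor(duration / tr))
    times = (np.arange(n_scans) + slice_offset) * tr
    grid = np.arange(T) * dt
    idx = np.clip(np.searchsorted(grid, times, side="right") - 1, 0, T - 2)
    w = (times - grid[idx]) / dt
    return (1 - w)[..., :, None] * signal[..., idx, :] + w[..., :, None] * signal[..., idx + 1, :]


def simulate_bold(spec: NetworkSpec, params: DCMParams, inputs: InputSeries,
                  tr: float = 2.0, seed: int | np.random.SeedSequence = 0,
                  slice_offset: float = 0.5, strict: bool = True) -> BoldTimeSeries:
    """Simulate noisy sampled BOLD from the full generative model."""
    if tr <= 0:
        raise ValueError("TR must be > 0")
    if tr < inputs.dt:
        raise ValueError(f"TR={tr} shorter than microtime dt={inputs.dt}")
    params.validate(spec)
    traj = integrate_neuronal(params, inputs, strict=strict)
    bold = hemodynamic_bold(traj, params.hemo)
    y = _sample_scans(bold, inputs.dt, tr, slice_offset)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sd, size=y.shape)
    return BoldTimeSeries(y=y, tr=tr, slice_offset=slice_offset,
                          node_labels=tuple(spec.nodes))


# ---------------------------------------------------------------------------
# batched forward map for inversion
# ---------------------------------------------------------------------------

class BatchedForward:
    """Maps flat parameter vectors to predicted BOLD, vectorised over a batch.

    Precomputes the unique-input decomposition of the design and the index
    maps from parameter names to matrix slots, so that finite-difference
    sensitivities of the whole forward model cost a single batched pass.
    """

    def __init__(self, spec: NetworkSpec, inputs: InputSeries, tr: float,
                 slice_offset: float = 0.5, estimate_hemo: bool = True,
                 base: DCMParams | None = None):
        self.spec = spec
        self.tr = tr
        self.dt = inputs.dt
        self.slice_offset = slice_offset
        self.estimate_hemo = estimate_hemo
        self.base = base.copy() if base is not None else DCMParams.zeros(spec)
        self.names = param_names(spec, estimate_hemo)
        self.U_unique, uid = np.unique(inputs.u, axis=0, return_inverse=True)
        self.uid = uid.astype(np.int64)
        n = spec.n_nodes
        J = len(spec.inputs)
        # index maps: parameter slot -> (kind, coordinates)
        self._slots = [ _locate(nm, spec) for nm in self.names ]
        self.n_scans = int(np.floor(len(self.uid) * self.dt / tr))
        self.n_nodes = n
        self.n_inputs = J

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """theta (P,) or (B, P) -> predicted BOLD (B, n_scans, n_nodes)."""
        theta = np.atleast_2d(np.asarray(theta, float))
        nb, P = theta.shape
        if P != len(self.names):
            raise ValueError(f"expected {len(self.names)} parameters, got {P}")
        n, J = self.n_nodes, self.n_inputs
        Aoff = np.tile(self.base.A[None], (nb, 1, 1))
        Aoff[:, np.arange(n), np.arange(n)] = 0.0
        selflog = np.tile(self.base.self_log[None], (nb, 1))
        Boff = np.zeros((nb, J, n, n))
        Bdiag = np.zeros((nb, J, n))
        for j, inp in enumerate(self.spec.inputs):
            Bj = self.base.B[inp]
            Boff[:, j] = Bj[None]
            Boff[:, j, np.arange(n), np.arange(n)] = 0.0
            Bdiag[:, j] = np.diag(Bj)[None]
        C = np.tile(self.base.C[None], (nb, 1, 1))
        transit = np.tile(self.base.hemo.transit[None], (nb, 1))
        decay = np.tile(self.base.hemo.decay[None], (nb, 1))
        input_index = {inp: j for j, inp in enumerate(self.spec.inputs)}
        for i, slot in enumerate(self._slots):
            kind = slot[0]
            if kind == "A":
                Aoff[:, slot[1], slot[2]] = theta[:, i]
            elif kind == "Aself":
                selflog[:, slot[1]] = theta[:, i]
            elif kind == "B":
                j = input_index[slot[1]]
                if slot[2] == slot[3]:
                    Bdiag[:, j, slot[2]] = theta[:, i]
                else:
                    Boff[:, j, slot[2], slot[3]] = theta[:, i]
            elif kind == "C":
                C[:, slot[1], slot[2]] = theta[:, i]
            elif kind == "transit":
                transit[:, slot[1]] = 2.0 * np.exp(theta[:, i])
            elif kind == "decay":
                decay[:, slot[1]] = 0.64 * np.exp(theta[:, i])

        Uu = self.U_unique                      # (K, J)
        K = Uu.shape[0]
        Aeff = Aoff[:, None] + np.einsum("kj,bjmn->bkmn", Uu, Boff)
        logd = selflog[:, None] + np.einsum("kj,bjm->bkm", Uu, Bdiag)
        Aeff[:, :, np.arange(n), np.arange(n)] = -0.5 * np.exp(np.clip(logd, -20, 20))
        Cu = np.einsum("bnj,kj->bkn", C, Uu)
        with np.errstate(over="ignore", invalid="ignore"):
            M, d = _bin_propagators(Aeff * self.dt, Cu * self.dt)
        bad = ~np.isfinite(M).all(axis=(1, 2, 3))
        M[bad] = 0.0
        d[bad] = 0.0
        z = _propagate_neuronal(M, d, self.uid)
        # guard against runaway trajectories from unstable proposals
        zmax = np.max(np.abs(z), axis=(1, 2))
        unstable = bad | ~np.isfinite(zmax) | (zmax > 1e6)
        z[unstable] = 0.0
        hemo = self.base.hemo
        v, q = _integrate_hemo(
            np.ascontiguousarray(z), self.dt,
            np.ascontiguousarray(decay), GAMMA_FLOW,
            np.ascontiguousarray(transit),
            np.tile(1.0 / hemo.stiffness[None], (nb, 1)),
            np.tile(hemo.e0[None], (nb, 1)),
            np.tile(hemo.efficacy[None], (nb, 1)),
        )
        bold = _bold_readout(v, q, hemo.e0[None, None, :], hemo.v0)
        y = _sample_scans(bold, self.dt, self.tr, self.slice_offset)
        y[unstable] = np.inf   # poison the fit so such steps are rejected
        return y
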