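"""Variational Laplace model inversion.

The posterior over model parameters is approximated by a Gaussian whose mean
and covariance are updated by Gauss-Newton ascent on the Laplace free energy

    F = E_q[log p(y | theta, lambda)] - KL(q(theta) || p(theta))
                                      - KL(q(lambda) || p(lambda)),

with observation noise modelled as i.i.d. Gaussian with a single log-precision
hyperparameter ``lambda``.  For models whose forward map is linear in the
parameters the scheme is exact and F equals the log marginal likelihood.

Steps that fail to increase F are rejected and a Levenberg-style regulariser
doubled, so the sequence of accepted free energies is non-decreasing by
construction.  The inversion uses no internal randomness.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .dynamics import BatchedForward, BoldTimeSeries
from .design import InputSeries
from .network import NetworkSpec
from .posterior import GaussianPosterior, PriorSpec

__all__ = ["InversionOptions", "LinearForward", "free_energy",
           "fit_forward", "variational_laplace"]


@dataclass
class InversionOptions:
    tol: float = 1e-4            # stop when the accepted F gain drops below this (nats)
    max_iter: int = 128
    fd_step: float = 1e-4        # relative finite-difference step
    max_rejects: int = 10        # LM rejections per iteration before giving up
    estimate_noise: bool = True
    log_precision: float = 0.0   # prior mean (and fixed value when not estimated)
    log_precision_var: float = 1.0
    init_damping: float = 0.25


class LinearForward:
    """A forward model y = X theta; used for oracle checks and toy problems."""

    def __init__(self, X: np.ndarray, names: list[str]):
        self.X = np.asarray(X, float)
        self.names = list(names)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, float))
        return theta @ self.X.T


def _flatten(y) -> np.ndarray:
    if isinstance(y, BoldTimeSeries):
        y = y.y
    return np.asarray(y, float).reshape(-1)


def _jacobian(forward, mu: np.ndarray, fd_step: float):
    """One-sided finite-difference sensitivities, one batched forward pass."""
    P = mu.size
    h = fd_step * (1.0 + np.abs(mu))
    thetas = np.vstack([mu[None], mu[None] + np.diag(h)])
    preds = forward.predict(thetas).reshape(P + 1, -1)
    f0 = preds[0]
    J = (preds[1:] - f0[None]).T / h[None]
    return f0, J


def _laplace_f(r, J, mu, cov, prior: PriorSpec, lam, lam_var, opts: InversionOptions):
    """Free energy of q = N(mu, cov) given residual r and sensitivities J."""
    N = r.size
    k = mu.size
    var0 = prior.effective_variances()
    elam = np.exp(lam)
    JS = J @ cov
    S = float(r @ r + np.einsum("ij,ij->", JS, J))
    ell = -0.5 * elam * S + 0.5 * N * lam - 0.5 * N * np.log(2 * np.pi)
    d = mu - prior.mean
    sign, logdet_cov = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    kl_theta = 0.5 * (np.sum(np.diag(cov) / var0) + np.sum(d * d / var0) - k
                      + np.sum(np.log(var0)) - logdet_cov)
    kl_lam = 0.0
    if opts.estimate_noise:
        v0 = opts.log_precision_var
        dl = lam - opts.log_precision
        kl_lam = 0.5 * (lam_var / v0 + dl * dl / v0 - 1 + np.log(v0 / lam_var))
    return float(ell - kl_theta - kl_lam)


def _update_lambda(r, J, Pi0, lam, opts: InversionOptions):
    """Conditionally maximise F over the noise log-precision (Newton steps)."""
    if not opts.estimate_noise:
        return opts.log_precision, np.nan
    N = r.size
    v0 = opts.log_precision_var
    for _ in range(8):
        elam = np.exp(lam)
        H = elam * (J.T @ J) + Pi0
        cov = np.linalg.inv(H)
        JS = J @ cov
        S = float(r @ r + np.einsum("ij,ij->", JS, J))
        g = -0.5 * elam * S + 0.5 * N - (lam - opts.log_precision) / v0
        h = -0.5 * elam * S - 1.0 / v0
        step = np.clip(-g / h, -2.0, 2.0)
        lam = lam + step
        if abs(step) < 1e-6:
            break
    lam_var = 1.0 / (0.5 * np.exp(lam) * S + 1.0 / v0)
    return lam, lam_var


def fit_forward(forward, y, prior: PriorSpec,
                opts: InversionOptions | None = None) -> GaussianPosterior:
    """Gauss-Newton / Levenberg variational Laplace for a generic forward model."""
    opts = opts or InversionOptions()
    y = _flatten(y)
    if list(forward.names) != list(prior.names):
        raise ValueError("prior names do not match the forward model's parameters")
    m0 = prior.mean.copy()
    var0 = prior.effective_variances()
    Pi0 = np.diag(1.0 / var0)
    mu = m0.copy()
    lam = opts.log_precision
    lam_var = opts.log_precision_var if opts.estimate_noise else np.nan
    damping = opts.init_damping
    f_hist: list[float] = []
    converged = False

    f0, J = _jacobian(forward, mu, opts.fd_step)
    if not np.all(np.isfinite(J)):
        bad = forward.names[int(np.argmax(~np.isfinite(J).all(axis=0)))]
        raise FloatingPointError(f"non-finite gradient for parameter {bad!r}")
    r = y - f0

    for _ in range(opts.max_iter):
        lam, lam_var = _update_lambda(r, J, Pi0, lam, opts)
        elam = np.exp(lam)
        H = elam * (J.T @ J) + Pi0
        cov = np.linalg.inv(H)
        f_cur = _laplace_f(r, J, mu, cov, prior, lam, lam_var, opts)
        if not f_hist:
            f_hist.append(f_cur)
        g = elam * (J.T @ r) - Pi0 @ (mu - m0)
        accepted = False
        for _reject in range(opts.max_rejects + 1):
            H_lm = H + damping * np.diag(np.diag(H))
            dmu = np.linalg.solve(H_lm, g)
            mu_new = mu + dmu
            f_new_pred = forward.predict(mu_new[None]).reshape(-1)
            r_new = y - f_new_pred
            if np.all(np.isfinite(r_new)):
                f_new = _laplace_f(r_new, J, mu_new, cov, prior, lam, lam_var, opts)
            else:
                f_new = -np.inf
            if f_new > f_hist[-1]:
                accepted = True
                break
            damping *= 2.0
        if not accepted:
            break
        gain = f_new - f_hist[-1]
        mu, r = mu_new, r_new
        f_hist.append(f_new)
        damping = max(damping / 2.0, 1e-8)
        f0, J = _jacobian(forward, mu, opts.fd_step)
        if not np.all(np.isfinite(J)):
            bad = forward.names[int(np.argmax(~np.isfinite(J).all(axis=0)))]
            raise FloatingPointError(f"non-finite gradient for parameter {bad!r}")
        r = y - f0
        if gain < opts.tol:
            converged = True
            break

    lam, lam_var = _update_lambda(r, J, Pi0, lam, opts)
    elam = np.exp(lam)
    cov = np.linalg.inv(elam * (J.T @ J) + Pi0)
    cov = (cov + cov.T) / 2.0
    f_final = _laplace_f(r, J, mu, cov, prior, lam, lam_var, opts)
    return GaussianPosterior(
        names=list(prior.names), mean=mu, cov=cov, free_energy=f_final,
        info={
            "converged": bool(converged),
            "log_precision": float(lam),
            "log_precision_var": float(lam_var) if np.isfinite(lam_var) else None,
            "f_history": [float(v) for v in f_hist],
            "n_iterations": len(f_hist) - 1,
            "options": asdict(opts),
        },
    )


def variational_laplace(data: BoldTimeSeries, inputs: InputSeries,
                        spec: NetworkSpec, prior: PriorSpec,
                        opts: InversionOptions | None = None,
                        estimate_hemo: bool = True) -> GaussianPosterior:
    """Invert the full neuronal + haemodynamic model for one subject."""
    forward = BatchedForward(spec, inputs, tr=data.tr,
                             slice_offset=data.slice_offset,
                             estimate_hemo=estimate_hemo)
    if forward.n_scans != data.n_scans:
        raise ValueError(
            f"data ({data.n_scans} scans) and inputs "
            f"({forward.n_scans} scans) are not time-aligned")
    return fit_forward(forward, data, prior, opts)


def free_energy(q: GaussianPosterior, prior: PriorSpec, data,
                spec: NetworkSpec | None = None,
                inputs: InputSeries | None = None,
                forward=None, opts: InversionOptions | None = None) -> float:
    """Laplace free energy of an arbitrary Gaussian q for given data.

    The noise log-precision is set to its conditional optimum under q unless
    ``opts.estimate_noise`` is False, in which case ``opts.log_precision`` is
    used as a fixed, known value.
    """
    opts = opts or InversionOptions()
    if list(q.names) != list(prior.names):
        raise ValueError("q and prior must share parameter names")
    if forward is None:
        if spec is None or inputs is None:
            raise ValueError("provide either a forward model or (spec, inputs)")
        forward = BatchedForward(spec, inputs, tr=data.tr,
                                 slice_offset=data.slice_offset)
    y = _flatten(data)
    f0, J = _jacobian(forward, q.mean, opts.fd_step)
    r = y - f0
    var0 = prior.effective_variances()
    if np.any(~np.isfinite(1.0 / var0)):
        raise ValueError("singular prior covariance outside the switched_off set")
    lam, lam_var = opts.log_precision, opts.log_precision_var
    if opts.estimate_noise:
        lam, lam_var = _update_lambda(r, J, np.diag(1.0 / var0), lam, opts)
    return _laplace_f(r, J, q.mean, q.cov, prior, lam, lam_var, opts)
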