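"""Parametric empirical Bayes: a group-level GLM over subject posteriors.

The hierarchy is

    theta_i = (x_i (x) I) beta + b_i,    b_i ~ N(0, Sigma_b)

where ``theta_i`` are a subject's (subset of) connectivity parameters,
``x_i`` the subject's row of the between-subject design matrix (first column
all ones = group mean), and ``Sigma_b = exp(-gamma) * D`` a between-subject
covariance with a single log-precision hyperparameter ``gamma``.

Each subject's first-level posterior enters as a likelihood over
``theta_i`` after its first-level prior is removed (information-form
subtraction), so subjects contribute in proportion to their first-level
precision rather than equally.  Conditional on ``gamma`` the model is
linear-Gaussian in ``beta`` and is solved exactly; ``gamma`` itself is
optimised by scalar free-energy ascent.  The procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .posterior import GaussianPosterior, PriorSpec
from .reduction import (ModelSpace, bayesian_model_average,
                        family_posterior_probability, search_reduced_models)

__all__ = ["PEBOptions", "PEBModel", "fit_peb", "peb_prune"]


@dataclass
class PEBOptions:
    between_variance: float = 1.0 / 16.0   # base random-effects variance D (Hz^2)
    gamma_prior_mean: float = 0.0
    gamma_prior_var: float = 1.0 / 16.0
    gamma_bounds: tuple[float, float] = (-8.0, 8.0)
    max_first_level_variance: float = 1e6  # cap on prior-removed subject variances


@dataclass
class PEBModel:
    X: np.ndarray
    covariate_names: list[str]
    parameter_names: list[str]            # shared first-level subset
    group_posterior: GaussianPosterior    # over covariate x parameter effects
    group_prior: PriorSpec
    gamma: float
    free_energy: float
    subject_posteriors: list[GaussianPosterior]
    options: PEBOptions

    def effect(self, covariate: str, parameter: str) -> tuple[float, float]:
        """(posterior mean, sd) of one group-level effect."""
        return self.group_posterior[f"{covariate}:{parameter}"]

    def to_dict(self) -> dict:
        sds = self.group_posterior.sd()
        return {
            "design_matrix": self.X.tolist(),
            "covariates": list(self.covariate_names),
            "parameters": list(self.parameter_names),
            "gamma": float(self.gamma),
            "free_energy": float(self.free_energy),
            "group_mean": dict(zip(self.group_posterior.names,
                                   self.group_posterior.mean.tolist())),
            "group_sd": dict(zip(self.group_posterior.names, sds.tolist())),
        }


def _strip_first_level_prior(post: GaussianPosterior, prior: PriorSpec,
                             subset: list[str], opts: PEBOptions):
    """Information-form likelihood of the subset parameters implied by the data.

    Returns (Pi_tilde, eta_tilde): the subject posterior's marginal precision
    minus the first-level prior precision (floored at zero so the likelihood
    never sharpens artificially) and the matching information vector.
    """
    marg = post.marginal(subset)
    pr = prior.subset(subset)
    Pi = np.linalg.inv(marg.cov)
    Pi = (Pi + Pi.T) / 2
    Pi0 = pr.precision()
    Pi_t = Pi - Pi0
    eta_t = Pi @ marg.mean - Pi0 @ pr.mean
    # The subtraction is PSD for a proper first level; directions flattened to
    # (numerically) zero precision carry no data information, so both their
    # precision and their information-vector components are zeroed out.
    w, V = np.linalg.eigh((Pi_t + Pi_t.T) / 2)
    floor = 1.0 / opts.max_first_level_variance
    flat = w < max(floor, 1e-8 * np.max(np.abs(w), initial=floor))
    w = np.where(flat, floor, w)
    Pi_t = (V * w) @ V.T
    coords = V.T @ eta_t
    eta_t = V @ np.where(flat, 0.0, coords)
    return Pi_t, eta_t


def _beta_evidence(gamma: float, Pi_list, eta_list, X, D, group_prior: PriorSpec):
    """Exact conditional log-evidence and beta posterior given gamma."""
    p = D.shape[0]
    ns, q = X.shape
    Pi_b = np.diag(np.exp(gamma) / np.diag(D))
    Lam = np.zeros((q * p, q * p))
    eta = np.zeros(q * p)
    log_ev = 0.0
    for i in range(ns):
        Pi_t, eta_t = Pi_list[i], eta_list[i]
        P = Pi_b + Pi_t
        L = np.linalg.cholesky(P)
        Pinv = np.linalg.inv(P)
        W = Pi_b - Pi_b @ Pinv @ Pi_b          # = (Sigma_b + Pi_t^-1)^-1
        # kron structure: effects ordered covariate-major (beta_c over params)
        xi = X[i]
        Lam += np.kron(np.outer(xi, xi), W)
        eta += np.kron(xi, Pi_b @ Pinv @ eta_t)
        log_ev += (-0.5 * (-np.sum(np.log(np.diag(Pi_b)))
                           + 2 * np.sum(np.log(np.diag(L))))
                   + 0.5 * eta_t @ Pinv @ eta_t)
    S_beta = np.diag(group_prior.effective_variances())
    Lam_post = Lam + np.linalg.inv(S_beta)
    eta_post = eta + np.linalg.solve(S_beta, group_prior.mean)
    cov_post = np.linalg.inv(Lam_post)
    cov_post = (cov_post + cov_post.T) / 2
    mu_post = cov_post @ eta_post
    sign, ld_post = np.linalg.slogdet(Lam_post)
    log_ev += 0.5 * (eta_post @ mu_post
                     - group_prior.mean @ np.linalg.solve(S_beta, group_prior.mean))
    log_ev += -0.5 * np.sum(np.log(np.diag(S_beta))) - 0.5 * ld_post
    return float(log_ev), mu_post, cov_post


def fit_peb(
    subject_posteriors: list[GaussianPosterior],
    X: np.ndarray,
    subset: list[str] | None = None,
    first_level_prior: PriorSpec | None = None,
    group_prior: PriorSpec | None = None,
    covariate_names: list[str] | None = None,
    options: PEBOptions | None = None,
) -> PEBModel:
    """Fit the two-level Gaussian hierarchy over subject posteriors.

    ``subset`` selects the shared first-level parameters modelled at the
    group level (defaults to all).  ``first_level_prior`` is the prior the
    subjects were inverted under; it is removed from each posterior so the
    group model sees only the data's contribution.  The default group prior
    for each (covariate, parameter) effect reuses that parameter's
    first-level prior.
    """
    if len(subject_posteriors) < 1:
        raise ValueError("need at least one subject")
    if first_level_prior is None:
        raise ValueError("first_level_prior is required")
    names0 = list(subject_posteriors[0].names)
    for sp in subject_posteriors[1:]:
        if list(sp.names) != names0:
            raise ValueError("subject posteriors do not share parameter names")
    subset = list(subset) if subset is not None else names0
    missing = set(subset) - set(names0)
    if missing:
        raise ValueError(f"subset names absent from subjects: {sorted(missing)}")
    X = np.atleast_2d(np.asarray(X, float))
    ns, q = X.shape
    if ns != len(subject_posteriors):
        raise ValueError("design matrix rows must match the number of subjects")
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("design matrix X is rank deficient")
    covariate_names = list(covariate_names) if covariate_names else (
        ["mean"] + [f"cov{j}" for j in range(1, q)])
    opts = options or PEBOptions()

    p = len(subset)
    group_names = [f"{c}:{par}" for c in covariate_names for par in subset]
    if group_prior is None:
        fl = first_level_prior.subset(subset)
        var = np.tile(fl.variances, q)
        group_prior = PriorSpec(group_names, np.zeros(q * p), var)
    elif list(group_prior.names) != group_names:
        raise ValueError("group prior names must be '<covariate>:<parameter>'")

    stripped = [_strip_first_level_prior(sp, first_level_prior, subset, opts)
                for sp in subject_posteriors]
    Pi_list = [s[0] for s in stripped]
    eta_list = [s[1] for s in stripped]
    D = np.eye(p) * opts.between_variance

    def neg_f(gamma: float) -> float:
        log_ev, _, _ = _beta_evidence(gamma, Pi_list, eta_list, X, D, group_prior)
        lp = -0.5 * (gamma - opts.gamma_prior_mean) ** 2 / opts.gamma_prior_var
        return -(log_ev + lp)

    res = minimize_scalar(neg_f, bounds=opts.gamma_bounds, method="bounded",
                          options={"xatol": 1e-4})
    gamma = float(res.x)
    log_ev, mu, cov = _beta_evidence(gamma, Pi_list, eta_list, X, D, group_prior)
    free_energy = log_ev - 0.5 * (gamma - opts.gamma_prior_mean) ** 2 / opts.gamma_prior_var
    group_post = GaussianPosterior(group_names, mu, cov, free_energy=free_energy,
                                   info={"gamma": gamma})
    return PEBModel(
        X=X, covariate_names=covariate_names, parameter_names=subset,
        group_posterior=group_post, group_prior=group_prior, gamma=gamma,
        free_energy=float(free_energy), subject_posteriors=list(subject_posteriors),
        options=opts,
    )


def peb_prune(
    model: PEBModel,
    switchable: list[str] | None = None,
    pp_threshold: float = 0.95,
) -> tuple[GaussianPosterior, dict[str, float], ModelSpace]:
    """Prune group effects that do not contribute to the model evidence.

    Searches reduced group models over ``switchable`` effects (default: the
    group-mean modulatory B entries), computes each effect's family posterior
    probability, and returns the Bayesian model average, the Pp table and the
    searched space.  An effect is called significant when Pp >= threshold.
    """
    post = model.group_posterior
    if switchable is None:
        switchable = [n for n in post.names
                      if n.startswith("mean:B") or n.startswith("mean:Bself")]
    if not switchable:
        raise ValueError("no switchable group effects")
    clamped = set(switchable) & model.group_prior.switched_off
    if clamped == set(switchable):
        # no model in the space can turn these on: Pp = 0 by convention
        return post, {name: 0.0 for name in switchable}, None
    space = search_reduced_models(post, model.group_prior, list(switchable))
    pp = {name: family_posterior_probability(space, name) for name in switchable}
    bma = bayesian_model_average(space)
    return bma, pp, space
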