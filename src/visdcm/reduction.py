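"""Bayesian model reduction, model-space search, family inference and BMA.

When a reduced model differs from the full model only in its priors, its
posterior and log-evidence change are available in closed form from the full
model's posterior (precision arithmetic on Gaussians).  "Switching a
parameter off" means clamping its prior variance to a near-zero value so that
all precisions stay finite.

A model space over k switchable parameters is enumerated exhaustively when
2^k is affordable and otherwise explored greedily; family posterior
probabilities and evidence-weighted model averages are computed from the
evaluated models with a flat prior over models and log-sum-exp arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .posterior import CLAMP_VARIANCE, GaussianPosterior, PriorSpec

__all__ = [
    "ModelSpace",
    "bayesian_model_reduction",
    "search_reduced_models",
    "family_posterior_probability",
    "bayesian_model_average",
]


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return ld


def bayesian_model_reduction(
    full_post: GaussianPosterior,
    full_prior: PriorSpec,
    reduced_prior: PriorSpec,
) -> tuple[GaussianPosterior, float]:
    """Posterior and evidence change of a model with modified priors.

    Returns the reduced posterior and ``delta_F`` (nats, relative to the full
    model), from the Gaussian identity: the reduced posterior precision is
    ``P_q + P_rp - P_p`` with the matching information-vector and
    log-normaliser terms.
    """
    if not (list(full_post.names) == list(full_prior.names) == list(reduced_prior.names)):
        raise ValueError("full posterior, full prior and reduced prior must "
                         "share parameter names")
    Pi_q = np.linalg.inv(full_post.cov)
    Pi_q = (Pi_q + Pi_q.T) / 2
    var_p = full_prior.effective_variances()
    var_rp = reduced_prior.effective_variances()
    Pi_p = np.diag(1.0 / var_p)
    Pi_rp = np.diag(1.0 / var_rp)
    m_q, m_p, m_rp = full_post.mean, full_prior.mean, reduced_prior.mean

    Pi_rq = Pi_q + Pi_rp - Pi_p
    Pi_rq = (Pi_rq + Pi_rq.T) / 2
    eta_rq = Pi_q @ m_q + Pi_rp @ m_rp - Pi_p @ m_p
    try:
        L = np.linalg.cholesky(Pi_rq)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "reduced posterior precision is not positive definite; "
            "use a larger clamp variance for switched-off parameters"
        ) from err
    m_rq = np.linalg.solve(Pi_rq, eta_rq)
    cov_rq = np.linalg.inv(Pi_rq)
    cov_rq = (cov_rq + cov_rq.T) / 2

    delta_f = 0.5 * (
        _logdet(Pi_q) - _logdet(Pi_rq) - np.sum(np.log(var_rp)) + np.sum(np.log(var_p))
    ) + 0.5 * (
        eta_rq @ m_rq
        - m_q @ Pi_q @ m_q
        - np.sum(m_rp * m_rp / var_rp)
        + np.sum(m_p * m_p / var_p)
    )
    reduced = GaussianPosterior(
        names=list(full_post.names), mean=m_rq, cov=cov_rq,
        free_energy=full_post.free_energy + delta_f
        if np.isfinite(full_post.free_energy) else delta_f,
    )
    return reduced, float(delta_f)


@dataclass
class ModelSpace:
    """Reduced models (on/off per switchable parameter) with their evidences.

    ``delta_f`` is relative to the all-on (full) model, which is always
    present with ``delta_f == 0``.  Posteriors are recomputed on demand to
    keep large exhaustive spaces cheap to hold.
    """

    switchable: list[str]
    indicators: np.ndarray          # (n_models, k) bool; True = parameter on
    delta_f: np.ndarray             # (n_models,)
    full_post: GaussianPosterior
    full_prior: PriorSpec
    clamp_variance: float = CLAMP_VARIANCE
    exhaustive: bool = True

    @property
    def n_models(self) -> int:
        return len(self.delta_f)

    def reduced_prior(self, idx: int) -> PriorSpec:
        off = [n for n, on in zip(self.switchable, self.indicators[idx]) if not on]
        return self.full_prior.switch_off(off)

    def posterior(self, idx: int) -> GaussianPosterior:
        post, _ = bayesian_model_reduction(self.full_post, self.full_prior,
                                           self.reduced_prior(idx))
        return post

    def best(self) -> int:
        return int(np.argmax(self.delta_f))

    def to_dict(self) -> dict:
        return {
            "switchable": list(self.switchable),
            "exhaustive": bool(self.exhaustive),
            "models": [
                {"indicator": "".join("1" if b else "0" for b in row),
                 "delta_f": float(df)}
                for row, df in zip(self.indicators, self.delta_f)
            ],
        }


def _delta_f_for(indicator, full_post, full_prior, switchable) -> float:
    off = [n for n, on in zip(switchable, indicator) if not on]
    if not off:
        return 0.0
    _, df = bayesian_model_reduction(full_post, full_prior,
                                     full_prior.switch_off(off))
    return df


def search_reduced_models(
    full_post: GaussianPosterior,
    full_prior: PriorSpec,
    switchable: list[str],
    max_exhaustive_k: int = 16,
) -> ModelSpace:
    """Search models formed by switching subsets of parameters off.

    Exhaustive ``2^k`` enumeration for ``k <= max_exhaustive_k``; beyond that
    a greedy descent repeatedly removes the parameter whose clamping most
    increases the evidence, evaluating every single-parameter removal at each
    step, and the space holds all models visited (flagged non-exhaustive).
    """
    k = len(switchable)
    if k < 1:
        raise ValueError("need at least one switchable parameter")
    missing = set(switchable) - set(full_post.names)
    if missing:
        raise ValueError(f"switchable names absent from posterior: {sorted(missing)}")

    if k <= max_exhaustive_k:
        n_models = 2 ** k
        indicators = np.ones((n_models, k), dtype=bool)
        delta_f = np.zeros(n_models)
        for m in range(n_models):
            ind = [(m >> i) & 1 == 0 for i in range(k)]  # m=0 -> all on
            indicators[m] = ind
            delta_f[m] = _delta_f_for(ind, full_post, full_prior, switchable)
        return ModelSpace(list(switchable), indicators, delta_f,
                          full_post, full_prior, exhaustive=True)

    current = np.ones(k, dtype=bool)
    seen: dict[tuple, float] = {tuple(current): 0.0}
    improved = True
    while improved and current.any():
        improved = False
        best_gain, best_idx = 0.0, -1
        for i in np.flatnonzero(current):
            trial = current.copy()
            trial[i] = False
            key = tuple(trial)
            if key not in seen:
                seen[key] = _delta_f_for(trial, full_post, full_prior, switchable)
            if seen[key] - seen[tuple(current)] > best_gain:
                best_gain, best_idx = seen[key] - seen[tuple(current)], i
        if best_idx >= 0:
            current[best_idx] = False
            improved = True
    indicators = np.array([list(key) for key in seen], dtype=bool)
    delta_f = np.array(list(seen.values()))
    return ModelSpace(list(switchable), indicators, delta_f,
                      full_post, full_prior, exhaustive=False)


def family_posterior_probability(space: ModelSpace, name: str) -> float:
    """P(parameter present | data): evidence mass of the on-family.

    Flat prior over the models in the space; an empty on-family returns 0 by
    convention (the parameter cannot be present in any considered model).
    """
    if space.n_models == 0:
        raise ValueError("empty model space")
    if name not in space.switchable:
        raise ValueError(f"{name!r} is not a switchable parameter")
    j = space.switchable.index(name)
    on = space.indicators[:, j]
    if not on.any():
        return 0.0
    if on.all():
        return 1.0
    log_on = logsumexp(space.delta_f[on])
    log_all = logsumexp(space.delta_f)
    return float(np.exp(log_on - log_all))


def bayesian_model_average(space: ModelSpace,
                           max_models: int = 256) -> GaussianPosterior:
    """Moment-matched Gaussian of the evidence-weighted posterior mixture.

    Weights are the softmax of the model evidences (flat model prior).  Only
    the ``max_models`` best models are expanded; the rest carry negligible
    weight by construction.
    """
    if space.n_models == 0:
        raise ValueError("empty model space")
    order = np.argsort(space.delta_f)[::-1][:max_models]
    logw = space.delta_f[order] - logsumexp(space.delta_f[order])
    w = np.exp(logw)
    k = len(space.full_post.names)
    mean = np.zeros(k)
    second = np.zeros((k, k))
    for wi, idx in zip(w, order):
        post = space.posterior(int(idx))
        mean += wi * post.mean
        second += wi * (post.cov + np.outer(post.mean, post.mean))
    cov = second - np.outer(mean, mean)
    cov = (cov + cov.T) / 2
    return GaussianPosterior(
        names=list(space.full_post.names), mean=mean, cov=cov,
        free_energy=space.full_post.free_energy + float(np.max(space.delta_f)),
        info={"n_models_averaged": int(len(order))},
    )
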