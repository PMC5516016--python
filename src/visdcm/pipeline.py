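"""The group effective-connectivity analysis, end to end.

Stages: eigenvariate extraction (when voxel data are present), per-subject
variational Laplace inversion of the full model, Bayesian model reduction
over the imagery driving locations, a PEB model of the modulatory effects
with pruning and model averaging, and the pooled top-down versus bottom-up
coupling contrasts.

Directional pooling over the four-region hierarchy (OCC at the bottom, IFG
at the top): bottom-up (forward) coupling comprises the connections leaving
OCC and those entering IFG; top-down (backward) coupling the connections
entering OCC and those leaving IFG.  The two lateral FG<->IPS connections
belong to neither set and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .inversion import InversionOptions, variational_laplace
from .network import NetworkSpec, param_names
from .peb import PEBOptions, fit_peb, peb_prune
from .posterior import GaussianPosterior, PriorSpec, default_priors
from .reduction import (bayesian_model_average,
                        family_posterior_probability, search_reduced_models)
from .synth import StudyDataset

__all__ = [
    "BOTTOM_UP_CONNECTIONS",
    "TOP_DOWN_CONNECTIONS",
    "ContrastResult",
    "extract_eigenvariate",
    "fit_subjects",
    "driving_input_search",
    "modulation_analysis",
    "pool_connectivity_contrast",
    "pairwise_contrast",
]

#: (target, source) pairs; bottom-up = out of OCC or into IFG
BOTTOM_UP_CONNECTIONS = (
    ("FG", "OCC"), ("IPS", "OCC"), ("IFG", "OCC"), ("IFG", "FG"), ("IFG", "IPS"),
)
#: top-down = into OCC or out of IFG
TOP_DOWN_CONNECTIONS = (
    ("OCC", "FG"), ("OCC", "IPS"), ("OCC", "IFG"), ("FG", "IFG"), ("IPS", "IFG"),
)


def extract_eigenvariate(voxels: np.ndarray,
                         nuisance: np.ndarray | None = None) -> np.ndarray:
    """Summary time series of a region: first PC of nuisance-adjusted voxels.

    Nuisance regressors are removed from every voxel by ordinary least
    squares; the first principal component of the adjusted voxel x time
    matrix is scaled to the mean voxel standard deviation and signed to
    correlate positively with the mean adjusted voxel.
    """
    voxels = np.atleast_2d(np.asarray(voxels, float))
    V, T = voxels.shape
    adjusted = voxels
    if nuisance is not None:
        N = np.atleast_2d(np.asarray(nuisance, float))
        if N.shape[0] != T:
            N = N.T
        if N.shape[0] != T:
            raise ValueError("nuisance regressors do not match the time axis")
        beta, *_ = np.linalg.lstsq(N, voxels.T, rcond=None)
        adjusted = voxels - (N @ beta).T
    if not np.any(adjusted):
        raise ValueError("all-zero adjusted voxel data")
    _, _, Vt = np.linalg.svd(adjusted - adjusted.mean(axis=1, keepdims=True),
                             full_matrices=False)
    pc = Vt[0]
    mean_sd = adjusted.std(axis=1).mean()
    pc = pc * (mean_sd / pc.std()) if pc.std() > 0 else pc
    ref = adjusted.mean(axis=0)
    if np.dot(pc, ref - ref.mean()) < 0:
        pc = -pc
    return pc


def fit_subjects(
    study: StudyDataset,
    spec: NetworkSpec,
    priors: PriorSpec | None = None,
    opts: InversionOptions | None = None,
    n_jobs: int = 1,
) -> list[GaussianPosterior]:
    """Invert every subject of a study (optionally in parallel; results are
    identical to serial execution since the inversion is deterministic)."""
    study.validate()
    if priors is None:
        priors = default_priors(param_names(spec))
    opts = opts or InversionOptions()

    def one(sub):
        return variational_laplace(sub.bold, sub.inputs, spec, priors, opts)

    if n_jobs != 1:
        from joblib import Parallel, delayed
        return list(Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in study.subjects))
    return [one(s) for s in study.subjects]


def driving_input_search(
    subject_posteriors: list[GaussianPosterior],
    X: np.ndarray,
    first_level_prior: PriorSpec,
    peb_options: PEBOptions | None = None,
) -> dict:
    """Where does imagery drive the network?  BMR over the 2^4 = 16 models.

    Fits a PEB model on the driving (C) parameters, exhaustively reduces
    over the four imagery driving locations (perception is fixed to drive
    OCC), and reports per-node family posterior probabilities and the BMA
    group estimates.
    """
    c_names = [n for n in subject_posteriors[0].names if n.startswith("C:")]
    if not c_names:
        raise ValueError("subject posteriors contain no driving (C) parameters")
    model = fit_peb(subject_posteriors, X, subset=c_names,
                    first_level_prior=first_level_prior, options=peb_options)
    switchable = [f"mean:{n}" for n in c_names if n.startswith("C:imagery:")]
    space = search_reduced_models(model.group_posterior, model.group_prior,
                                  switchable)
    pp = {name.removeprefix("mean:C:imagery:"):
          family_posterior_probability(space, name) for name in switchable}
    bma = bayesian_model_average(space)
    best = space.indicators[space.best()]
    winning = [name.removeprefix("mean:C:imagery:")
               for name, on in zip(switchable, best) if on]
    return {"peb": model, "space": space, "pp": pp, "bma": bma,
            "winning_drive_set": winning}


def modulation_analysis(
    subject_posteriors: list[GaussianPosterior],
    X: np.ndarray,
    first_level_prior: PriorSpec,
    peb_options: PEBOptions | None = None,
    pp_threshold: float = 0.95,
) -> dict:
    """Group PEB over baseline and modulatory coupling, pruned by BMR.

    The group model covers all A and B parameters; the reduction search
    switches only the condition-specific (B) effects, and the Pp table has
    one row per (input, connection).
    """
    sub_names = subject_posteriors[0].names
    subset = [n for n in sub_names if n.split(":")[0] in ("A", "Aself", "B", "Bself")]
    model = fit_peb(subject_posteriors, X, subset=subset,
                    first_level_prior=first_level_prior, options=peb_options)
    bma, pp, space = peb_prune(model, pp_threshold=pp_threshold)
    table = {name.removeprefix("mean:"): {
                "pp": float(p),
                "mean": float(bma[name][0]),
                "sd": float(bma[name][1]),
                "significant": bool(p >= pp_threshold)}
             for name, p in pp.items()}
    return {"peb": model, "space": space, "bma": bma, "pp": pp,
            "table": table, "pp_threshold": pp_threshold}


@dataclass
class ContrastResult:
    """Posterior of a pooled directional coupling change (Hz)."""

    label: str
    names: list[str]
    weights: np.ndarray
    posterior_mean: float
    posterior_sd: float
    pp_greater_than_zero: float
    pp_pairwise: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "connections": list(self.names),
            "posterior_mean_hz": self.posterior_mean,
            "posterior_sd_hz": self.posterior_sd,
            "pp_greater_than_zero": self.pp_greater_than_zero,
            "pp_pairwise": dict(self.pp_pairwise),
        }


def _direction_names(direction: str, condition: str, prefix: str) -> list[str]:
    sets = {"bottom_up": BOTTOM_UP_CONNECTIONS, "top_down": TOP_DOWN_CONNECTIONS}
    if direction not in sets:
        raise ValueError(f"direction must be bottom_up or top_down, got {direction!r}")
    return [f"{prefix}B:{condition}:{t}<-{s}" for t, s in sets[direction]]


def _linear_functional(post: GaussianPosterior, w: np.ndarray) -> tuple[float, float]:
    mu = float(w @ post.mean)
    var = float(w @ post.cov @ w)
    return mu, float(np.sqrt(max(var, 0.0)))


def pool_connectivity_contrast(
    group_posterior: GaussianPosterior,
    direction: str,
    condition: str,
    equal_weights: bool = True,
) -> ContrastResult:
    """Pooled change of one direction set under one condition, vs baseline.

    The pooled quantity is the (by default equally weighted) mean of the k=5
    modulatory B entries of the direction set; its posterior is the exact
    Gaussian of the linear functional and ``pp_greater_than_zero`` its upper
    tail probability at zero.
    """
    prefix = "mean:" if group_posterior.names[0].startswith("mean:") else ""
    names = _direction_names(direction, condition, prefix)
    missing = [n for n in names if n not in group_posterior.names]
    if missing:
        raise ValueError(f"group posterior lacks entries: {missing}")
    w = np.zeros(len(group_posterior.names))
    wt = (1.0 / len(names)) if equal_weights else 1.0
    for n in names:
        w[group_posterior.index(n)] = wt
    mu, sd = _linear_functional(group_posterior, w)
    pp = 0.5 if sd == 0 and mu == 0 else float(norm.sf(0.0, loc=mu, scale=max(sd, 1e-300)))
    return ContrastResult(
        label=f"{direction}_{condition}", names=names, weights=w,
        posterior_mean=mu, posterior_sd=sd, pp_greater_than_zero=pp,
    )


def pairwise_contrast(
    group_posterior: GaussianPosterior,
    direction: str,
    condition_a: str,
    condition_b: str,
    equal_weights: bool = True,
) -> float:
    """P(pooled coupling stronger during condition_a than condition_b)."""
    prefix = "mean:" if group_posterior.names[0].startswith("mean:") else ""
    na = _direction_names(direction, condition_a, prefix)
    nb = _direction_names(direction, condition_b, prefix)
    w = np.zeros(len(group_posterior.names))
    wt = (1.0 / len(na)) if equal_weights else 1.0
    for n in na:
        w[group_posterior.index(n)] += wt
    for n in nb:
        w[group_posterior.index(n)] -= wt
    mu, sd = _linear_functional(group_posterior, w)
    if sd == 0:
        return 0.5 if mu == 0 else float(mu > 0)
    return float(norm.sf(0.0, loc=mu, scale=sd))


def all_contrasts(group_posterior: GaussianPosterior,
                  equal_weights: bool = True) -> dict[str, ContrastResult]:
    """The four pooled contrasts plus the pairwise condition comparisons."""
    out = {}
    for direction in ("bottom_up", "top_down"):
        for condition in ("perception", "imagery"):
            res = pool_connectivity_contrast(group_posterior, direction,
                                             condition, equal_weights)
            other = "imagery" if condition == "perception" else "perception"
            res.pp_pairwise[f"stronger_than_{other}"] = pairwise_contrast(
                group_posterior, direction, condition, other, equal_weights)
            out[res.label] = res
    return out
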