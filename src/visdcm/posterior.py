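"""Named Gaussian distributions used for priors and posteriors alike."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GaussianPosterior", "PriorSpec", "default_priors"]

#: prior variance used to switch a parameter off while keeping precisions finite
CLAMP_VARIANCE = 1e-8


@dataclass
class GaussianPosterior:
    """A Gaussian over a named parameter vector, with its free energy."""

    names: list[str]
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float = np.nan
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        k = len(self.names)
        if len(set(self.names)) != k:
            raise ValueError("parameter names must be unique")
        if self.mean.shape != (k,) or self.cov.shape != (k, k):
            raise ValueError("mean/cov dimensions do not match names")

    def validate(self, tol: float = 1e-10) -> None:
        if np.max(np.abs(self.cov - self.cov.T)) > tol:
            raise ValueError("covariance not symmetric")
        if np.min(np.linalg.eigvalsh((self.cov + self.cov.T) / 2)) < -tol:
            raise ValueError("covariance has a negative eigenvalue")

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __getitem__(self, name: str) -> tuple[float, float]:
        """(mean, sd) of one named parameter."""
        i = self.index(name)
        return float(self.mean[i]), float(np.sqrt(max(self.cov[i, i], 0.0)))

    def marginal(self, names: list[str]) -> "GaussianPosterior":
        idx = [self.index(n) for n in names]
        return GaussianPosterior(
            names=list(names),
            mean=self.mean[idx],
            cov=self.cov[np.ix_(idx, idx)],
            free_energy=self.free_energy,
        )

    def to_dict(self) -> dict:
        tril = self.cov[np.tril_indices(len(self.names))]
        return {
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "cov_lower_triangle": tril.tolist(),
            "free_energy": None if np.isnan(self.free_energy) else float(self.free_energy),
            "converged": self.info.get("converged"),
            "options": self.info.get("options"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianPosterior":
        names = list(d["names"])
        k = len(names)
        cov = np.zeros((k, k))
        cov[np.tril_indices(k)] = d["cov_lower_triangle"]
        cov = cov + np.tril(cov, -1).T
        fe = d.get("free_energy")
        info = {}
        if d.get("converged") is not None:
            info["converged"] = d["converged"]
        if d.get("options") is not None:
            info["options"] = d["options"]
        return cls(names=names, mean=np.asarray(d["mean"], float), cov=cov,
                   free_energy=np.nan if fe is None else float(fe), info=info)


@dataclass
class PriorSpec:
    """Independent Gaussian priors; switched-off parameters are variance-clamped."""

    names: list[str]
    mean: np.ndarray
    variances: np.ndarray
    switched_off: frozenset[str] = frozenset()

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.variances = np.asarray(self.variances, float)
        self.switched_off = frozenset(self.switched_off)
        k = len(self.names)
        if self.mean.shape != (k,) or self.variances.shape != (k,):
            raise ValueError("prior mean/variance dimensions do not match names")
        if np.any(self.variances < 0):
            raise ValueError("prior variances must be >= 0")
        unknown = self.switched_off - set(self.names)
        if unknown:
            raise ValueError(f"switched_off names not in prior: {sorted(unknown)}")

    def effective_variances(self) -> np.ndarray:
        """Variances with the switched-off clamp applied."""
        v = self.variances.copy()
        for name in self.switched_off:
            i = self.names.index(name)
            v[i] = min(v[i], CLAMP_VARIANCE)
        return np.maximum(v, 1e-16)

    def precision(self) -> np.ndarray:
        return np.diag(1.0 / self.effective_variances())

    def switch_off(self, names) -> "PriorSpec":
        return PriorSpec(
            names=list(self.names),
            mean=self.mean.copy(),
            variances=self.variances.copy(),
            switched_off=self.switched_off | frozenset(names),
        )

    def subset(self, names: list[str]) -> "PriorSpec":
        idx = [self.names.index(n) for n in names]
        return PriorSpec(
            names=list(names),
            mean=self.mean[idx],
            variances=self.variances[idx],
            switched_off=self.switched_off & set(names),
        )

    def as_posterior(self) -> GaussianPosterior:
        return GaussianPosterior(
            names=list(self.names),
            mean=self.mean.copy(),
            cov=np.diag(self.effective_variances()),
        )


def default_priors(names: list[str]) -> PriorSpec:
    """Weakly-informative shrinkage priors keyed off the parameter-name prefix.

    Between-region A and B entries: N(0, 1/16) Hz (sd 0.25, covering the
    sub-hertz couplings typical of haemodynamic-level effective
    connectivity); driving C entries: N(0, 1); self-connection log-scalings:
    N(0, 1/16) (sd 0.25, tolerating roughly +-65% variation of the intrinsic
    decay rate); haemodynamic log-scalings: N(0, 1/256).  Package defaults,
    not values taken from any particular dataset.
    """
    variances = []
    for name in names:
        kind = name.split(":", 1)[0]
        if kind in ("A", "B", "Bself", "Aself"):
            variances.append(1.0 / 16.0)
        elif kind == "C":
            variances.append(1.0)
        elif kind in ("transit", "decay"):
            variances.append(1.0 / 256.0)
        else:
            variances.append(1.0)
    return PriorSpec(names=list(names), mean=np.zeros(len(names)),
                     variances=np.asarray(variances))
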