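"""Network specification and parameterisation of the bilinear neuronal model.

The neuronal state equation is

    dz/dt = (A + sum_j u_j B^j) z + C u

with ``A`` the endogenous (baseline) coupling, ``B^j`` the modulation of
coupling by experimental input ``u_j``, and ``C`` the direct driving influence
of the inputs.  All between-region entries are rates in Hz.

Index convention: **row = target, column = source**, i.e. ``A[t, s]`` is the
influence of region ``s`` on region ``t``.  (Papers that write "A_{i,j} of a
connection from area i to area j" use the transpose of this layout.)

Self-connections use the standard log-scaling convention: the effective
diagonal is ``-0.5 * exp(a_self + sum_j u_j b_self^j)`` Hz, so the unitless
self parameters scale a fixed -0.5 Hz decay and the system cannot acquire a
positive self-feedback by estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NODES",
    "INPUTS",
    "NetworkSpec",
    "HemoParams",
    "DCMParams",
    "param_names",
    "params_to_vector",
    "vector_to_params",
]

NODES = ("OCC", "FG", "IPS", "IFG")
INPUTS = ("perception", "imagery", "vividness")


def _as_bool(mask, shape, name):
    m = np.asarray(mask, dtype=bool)
    if m.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {m.shape}")
    return m


@dataclass
class NetworkSpec:
    """Which A/B/C entries exist and which inputs modulate which connections."""

    nodes: tuple[str, ...] = NODES
    inputs: tuple[str, ...] = INPUTS
    a_mask: np.ndarray | None = None
    b_masks: dict[str, np.ndarray] | None = None
    c_mask: np.ndarray | None = None

    def __post_init__(self):
        n, j = len(self.nodes), len(self.inputs)
        if self.a_mask is None:
            self.a_mask = np.ones((n, n), dtype=bool)
        self.a_mask = _as_bool(self.a_mask, (n, n), "a_mask")
        np.fill_diagonal(self.a_mask, True)  # self-connections always exist
        if self.b_masks is None:
            self.b_masks = {name: np.zeros((n, n), dtype=bool) for name in self.inputs}
        for name in self.inputs:
            self.b_masks[name] = _as_bool(
                self.b_masks.get(name, np.zeros((n, n), bool)), (n, n), f"b_masks[{name}]"
            )
        if self.c_mask is None:
            self.c_mask = np.zeros((n, j), dtype=bool)
        self.c_mask = _as_bool(self.c_mask, (n, j), "c_mask")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, node: str) -> int:
        return self.nodes.index(node)

    @classmethod
    def visual_imagery(cls) -> "NetworkSpec":
        """The four-region visual network (OCC, FG, IPS, IFG).

        All endogenous connections exist.  Perception and imagery may modulate
        every between-region connection; vividness may additionally modulate
        the OCC self-connection.  Perception drives OCC; imagery may drive any
        node (its driving location is decided by model reduction).
        """
        n = len(NODES)
        offdiag = ~np.eye(n, dtype=bool)
        b_viv = offdiag.copy()
        b_viv[0, 0] = True  # OCC self-connection
        b_masks = {
            "perception": offdiag.copy(),
            "imagery": offdiag.copy(),
            "vividness": b_viv,
        }
        c_mask = np.zeros((n, len(INPUTS)), dtype=bool)
        c_mask[0, 0] = True        # perception -> OCC
        c_mask[:, 1] = True        # imagery -> any node (searched)
        return cls(nodes=NODES, inputs=INPUTS, a_mask=np.ones((n, n), bool),
                   b_masks=b_masks, c_mask=c_mask)


@dataclass
class HemoParams:
    """Per-node balloon/Windkessel haemodynamics (canonical 3T constants).

    decay: vasodilatory-signal decay rate (1/s); transit: mean venous transit
    time (s); stiffness: Grubb vessel exponent; e0: resting oxygen extraction
    fraction; efficacy: neurovascular coupling gain (activity units -> 1/s).
    """

    decay: np.ndarray
    transit: np.ndarray
    stiffness: np.ndarray
    e0: np.ndarray
    efficacy: np.ndarray
    v0: float = 0.04  # resting venous blood volume fraction

    @classmethod
    def canonical(cls, n_nodes: int) -> "HemoParams":
        return cls(
            decay=np.full(n_nodes, 0.64),
            transit=np.full(n_nodes, 2.0),
            stiffness=np.full(n_nodes, 0.32),
            e0=np.full(n_nodes, 0.4),
            efficacy=np.full(n_nodes, 1.0),
        )

    def validate(self) -> None:
        for name in ("decay", "transit", "stiffness", "e0", "efficacy"):
            arr = getattr(self, name)
            if np.any(np.asarray(arr) <= 0):
                raise ValueError(f"non-physical hemodynamic parameter: {name} must be > 0")
        if np.any(self.e0 >= 1):
            raise ValueError("resting oxygen extraction e0 must be < 1")

    def copy(self) -> "HemoParams":
        return HemoParams(self.decay.copy(), self.transit.copy(),
                          self.stiffness.copy(), self.e0.copy(),
                          self.efficacy.copy(), self.v0)


@dataclass
class DCMParams:
    """Numerical parameters of one subject's generative model.

    ``A`` holds between-region coupling (Hz) with an ignored diagonal;
    ``self_log`` holds the unitless log-scalings of the -0.5 Hz
    self-connections.  ``B[input]`` off-diagonal entries are additive Hz
    changes; diagonal entries are additive log-scalings of the
    self-connection.  ``C`` is nodes x inputs (Hz).
    """

    A: np.ndarray
    self_log: np.ndarray
    B: dict[str, np.ndarray]
    C: np.ndarray
    hemo: HemoParams
    noise_sd: float = 0.0

    def copy(self) -> "DCMParams":
        return DCMParams(
            A=self.A.copy(),
            self_log=self.self_log.copy(),
            B={k: v.copy() for k, v in self.B.items()},
            C=self.C.copy(),
            hemo=self.hemo.copy(),
            noise_sd=self.noise_sd,
        )

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "DCMParams":
        n, j = spec.n_nodes, len(spec.inputs)
        return cls(
            A=np.zeros((n, n)),
            self_log=np.zeros(n),
            B={name: np.zeros((n, n)) for name in spec.inputs},
            C=np.zeros((n, j)),
            hemo=HemoParams.canonical(n),
        )

    def validate(self, spec: NetworkSpec) -> None:
        n = spec.n_nodes
        if self.A.shape != (n, n) or self.self_log.shape != (n,):
            raise ValueError("A/self_log dimensions do not match the network spec")
        off = self.A.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off[~spec.a_mask] != 0):
            raise ValueError("nonzero A entry outside the allowed a_mask")
        for name in spec.inputs:
            if np.any(self.B[name][~spec.b_masks[name]] != 0):
                raise ValueError(f"nonzero B[{name}] entry outside its mask")
        if np.any(self.C[~spec.c_mask] != 0):
            raise ValueError("nonzero C entry outside the c_mask")
        self.hemo.validate()

    def to_dict(self) -> dict:
        return {
            "index_convention": "row = target, column = source",
            "A": self.A.tolist(),
            "self_log": self.self_log.tolist(),
            "B": {k: v.tolist() for k, v in self.B.items()},
            "C": self.C.tolist(),
            "hemo": {
                "decay": self.hemo.decay.tolist(),
                "transit": self.hemo.transit.tolist(),
                "stiffness": self.hemo.stiffness.tolist(),
                "e0": self.hemo.e0.tolist(),
                "efficacy": self.hemo.efficacy.tolist(),
                "v0": self.hemo.v0,
            },
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCMParams":
        hemo = HemoParams(
            decay=np.asarray(d["hemo"]["decay"], float),
            transit=np.asarray(d["hemo"]["transit"], float),
            stiffness=np.asarray(d["hemo"]["stiffness"], float),
            e0=np.asarray(d["hemo"]["e0"], float),
            efficacy=np.asarray(d["hemo"]["efficacy"], float),
            v0=float(d["hemo"]["v0"]),
        )
        return cls(
            A=np.asarray(d["A"], float),
            self_log=np.asarray(d["self_log"], float),
            B={k: np.asarray(v, float) for k, v in d["B"].items()},
            C=np.asarray(d["C"], float),
            hemo=hemo,
            noise_sd=float(d["noise_sd"]),
        )


# ---------------------------------------------------------------------------
# flat parameter vector <-> DCMParams
# ---------------------------------------------------------------------------

def param_names(spec: NetworkSpec, estimate_hemo: bool = True) -> list[str]:
    """Ordered names of the free parameters implied by the network masks.

    Naming: ``A:tgt<-src``, ``Aself:node``, ``B:input:tgt<-src``,
    ``Bself:input:node``, ``C:input:node``, ``transit:node``, ``decay:node``.
    """
    nodes = spec.nodes
    names: list[str] = []
    n = spec.n_nodes
    for t in range(n):
        for s in range(n):
            if t != s and spec.a_mask[t, s]:
                names.append(f"A:{nodes[t]}<-{nodes[s]}")
    for t in range(n):
        names.append(f"Aself:{nodes[t]}")
    for j, inp in enumerate(spec.inputs):
        m = spec.b_masks[inp]
        for t in range(n):
            for s in range(n):
                if t != s and m[t, s]:
                    names.append(f"B:{inp}:{nodes[t]}<-{nodes[s]}")
        for t in range(n):
            if m[t, t]:
                names.append(f"Bself:{inp}:{nodes[t]}")
    for j, inp in enumerate(spec.inputs):
        for t in range(n):
            if spec.c_mask[t, j]:
                names.append(f"C:{inp}:{nodes[t]}")
    if estimate_hemo:
        for t in range(n):
            names.append(f"transit:{nodes[t]}")
        for t in range(n):
            names.append(f"decay:{nodes[t]}")
    return names


def _locate(name: str, spec: NetworkSpec):
    nodes = list(spec.nodes)
    kind, _, rest = name.partition(":")
    if kind == "A":
        t, _, s = rest.partition("<-")
        return ("A", nodes.index(t), nodes.index(s))
    if kind == "Aself":
        return ("Aself", nodes.index(rest))
    if kind == "B":
        inp, _, conn = rest.partition(":")
        t, _, s = conn.partition("<-")
        return ("B", inp, nodes.index(t), nodes.index(s))
    if kind == "Bself":
        inp, _, node = rest.partition(":")
        return ("B", inp, nodes.index(node), nodes.index(node))
    if kind == "C":
        inp, _, node = rest.partition(":")
        return ("C", nodes.index(node), list(spec.inputs).index(inp))
    if kind in ("transit", "decay"):
        return (kind, nodes.index(rest))
    raise ValueError(f"unrecognised parameter name {name!r}")


def params_to_vector(params: DCMParams, spec: NetworkSpec,
                     estimate_hemo: bool = True) -> np.ndarray:
    names = param_names(spec, estimate_hemo)
    theta = np.zeros(len(names))
    for i, name in enumerate(names):
        loc = _locate(name, spec)
        if loc[0] == "A":
            theta[i] = params.A[loc[1], loc[2]]
        elif loc[0] == "Aself":
            theta[i] = params.self_log[loc[1]]
        elif loc[0] == "B":
            theta[i] = params.B[loc[1]][loc[2], loc[3]]
        elif loc[0] == "C":
            theta[i] = params.C[loc[1], loc[2]]
        elif loc[0] == "transit":
            theta[i] = np.log(params.hemo.transit[loc[1]] / 2.0)
        elif loc[0] == "decay":
            theta[i] = np.log(params.hemo.decay[loc[1]] / 0.64)
    return theta


def vector_to_params(theta: np.ndarray, spec: NetworkSpec,
                     estimate_hemo: bool = True,
                     base: DCMParams | None = None) -> DCMParams:
    names = param_names(spec, estimate_hemo)
    theta = np.asarray(theta, float)
    if theta.shape != (len(names),):
        raise ValueError(f"expected {len(names)} parameters, got {theta.shape}")
    p = (base.copy() if base is not None else DCMParams.zeros(spec))
    for i, name in enumerate(names):
        loc = _locate(name, spec)
        if loc[0] == "A":
            p.A[loc[1], loc[2]] = theta[i]
        elif loc[0] == "Aself":
            p.self_log[loc[1]] = theta[i]
        elif loc[0] == "B":
            p.B[loc[1]][loc[2], loc[3]] = theta[i]
        elif loc[0] == "C":
            p.C[loc[1], loc[2]] = theta[i]
        elif loc[0] == "transit":
            p.hemo.transit[loc[1]] = 2.0 * np.exp(theta[i])
        elif loc[0] == "decay":
            p.hemo.decay[loc[1]] = 0.64 * np.exp(theta[i])
    return p
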