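"""Kinetic parameter sets for the ubiquitination model variants.

All enzyme pools are steady: the total ubiquitin ligase (u_bar), the
deubiquitinating enzyme (v_bar), the kinase (y) and the phosphatase (z)
do not oscillate.  Rhythmicity of the degradation rate, when it appears,
is therefore an emergent property of mass-action kinetics under periodic
protein production, not of time-of-day-controlled proteolysis.

Units: concentrations nM, first-order rates h^-1, second-order rates
nM^-1 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

__all__ = ["UbParams", "PhosphoParams", "MultiRouteParams", "PER2Params",
           "RouteBlock", "load_params", "dump_params"]


@dataclass
class UbParams:
    """Phospho-independent ubiquitination constants.

    Attributes
    ----------
    u_bar : total ubiquitin ligase pool, nM
    v_bar : total deubiquitinating enzyme pool, nM (0 disables the branch)
    a0 : ligase-substrate binding rate, nM^-1 h^-1
    a1 : ligase release of un-ubiquitinated substrate, h^-1
    a2 : ligase release of ubiquitinated substrate, h^-1
    b0, b1 : deubiquitinase binding / release, nM^-1 h^-1 and h^-1
    q : ubiquitination rate of ligase-bound substrate, h^-1
    s : deubiquitination + release rate, h^-1
    r0 : degradation rate of ubiquitinated protein, h^-1 -- the hard
         ceiling of any realized r(t)
    """

    u_bar: float
    a0: float
    a1: float
    a2: float
    q: float
    r0: float
    v_bar: float = 0.0
    b0: float = 0.0
    b1: float = 0.0
    s: float = 0.0

    def __post_init__(self):
        for name in ("u_bar", "a0", "a1", "a2", "q", "v_bar", "b0", "b1", "s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")


@dataclass
class PhosphoParams:
    """Phosphorylation chain preceding ubiquitination.

    ``n`` phosphorylation events are required before the ligase can act
    (n=0 means phospho-independent).  k[i] lumps kinase binding,
    phosphoryl transfer and release at site i+1; l[i] is the phosphatase
    counterpart.
    """

    n: int
    y: float = 0.0  # kinase pool, nM
    z: float = 0.0  # phosphatase pool, nM
    k: Sequence[float] = field(default_factory=tuple)  # nM^-1 h^-1, length n
    l: Sequence[float] = field(default_factory=tuple)  # nM^-1 h^-1, length n

    def __post_init__(self):
        self.k = tuple(float(v) for v in self.k)
        self.l = (tuple(float(v) for v in self.l) if len(self.l)
                  else tuple(0.0 for _ in self.k))
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.n > 0 and (len(self.k) != self.n or len(self.l) != self.n):
            raise ValueError(f"k and l must have length n={self.n}")
        if self.y < 0 or self.z < 0 or any(v < 0 for v in self.k) or any(v < 0 for v in self.l):
            raise ValueError("phospho parameters must be non-negative")

    @classmethod
    def tied(cls, n: int, y: float, k: float, z: float = 0.0, l: float = 0.0) -> "PhosphoParams":
        """All sites share one kinase binding rate (k1=...=kn)."""
        return cls(n=n, y=y, z=z, k=(k,) * n, l=(l,) * n)

    @property
    def k_min(self) -> float:
        """Lowest kinase binding rate across sites: the rate-limiting step."""
        if self.n == 0:
            raise ValueError("k_min undefined for n=0")
        return min(self.k)


@dataclass
class RouteBlock:
    """One phospho-state-specific degradation route (ligase + DUB block)."""

    u_bar: float = 0.0
    a0: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    q: float = 0.0
    s: float = 0.0
    b0: float = 0.0
    b1: float = 0.0
    v_bar: float = 0.0
    r0: float = 1.0

    @property
    def enabled(self) -> bool:
        return self.u_bar > 0


@dataclass
class MultiRouteParams:
    """Tetra-phosphorylation chain with a distinct ligase route per state.

    Route i (i=1..4) degrades the i-th phospho-form; a route with
    u_bar=0 is disabled.  With only route 4 enabled and its constants set
    to the single-route values, the model reduces exactly to the n=4
    phospho-dependent chain.
    """

    phospho: PhosphoParams
    routes: Sequence[RouteBlock]

    def __post_init__(self):
        self.routes = tuple(self.routes)
        if self.phospho.n != 4:
            raise ValueError("multi-route model requires an n=4 phosphorylation chain")
        if len(self.routes) != 4:
            raise ValueError("exactly four route blocks required")

    @property
    def any_enabled(self) -> bool:
        return any(rt.enabled for rt in self.routes)


@dataclass
class PER2Params:
    """Realistic PER2 degradation: FASP phospho-chain plus beta-TrCP site.

    The FASP region carries a four-site chain (k1..k4, l1..l4, kinase pool
    y standing in for CK1 delta/epsilon, phosphatase pool z).  Every FASP
    state i=0..4 has its own ubiquitination block drawing on one shared
    ligase pool u_bar.  Independently, phosphorylation of the beta-TrCP
    site (k_beta, l_beta) feeds a separate ligase pool u_bar_beta.
    """

    phospho: PhosphoParams  # n=4 FASP chain
    state_blocks: Sequence[RouteBlock]  # i = 0..4, share u_bar/v_bar of block 0
    u_bar: float
    k_beta: float
    l_beta: float
    beta_block: RouteBlock
    u_bar_beta: float
    v_bar: float = 0.0
    v_bar_beta: float = 0.0

    def __post_init__(self):
        self.state_blocks = tuple(self.state_blocks)
        if self.phospho.n != 4:
            raise ValueError("PER2 model requires an n=4 FASP chain")
        if len(self.state_blocks) != 5:
            raise ValueError("five state blocks (i=0..4) required")
        if min(self.u_bar, self.u_bar_beta, self.k_beta, self.l_beta,
               self.v_bar, self.v_bar_beta) < 0:
            raise ValueError("PER2 parameters must be non-negative")


# ----------------------------------------------------------------------
# YAML round-trip


def dump_params(params, path) -> None:
    """Serialize any parameter dataclass to YAML with a variant tag."""
    payload = {"variant": type(params).__name__, "values": asdict(params)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_params(path):
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    variant = payload.get("variant")
    values = payload.get("values", {})
    if variant == "UbParams":
        return UbParams(**values)
    if variant == "PhosphoParams":
        return PhosphoParams(**values)
    if variant == "MultiRouteParams":
        return MultiRouteParams(
            phospho=PhosphoParams(**values["phospho"]),
            routes=[RouteBlock(**rt) for rt in values["routes"]],
        )
    if variant == "PER2Params":
        return PER2Params(
            phospho=PhosphoParams(**values["phospho"]),
            state_blocks=[RouteBlock(**b) for b in values["state_blocks"]],
            u_bar=values["u_bar"],
            k_beta=values["k_beta"],
            l_beta=values["l_beta"],
            beta_block=RouteBlock(**values["beta_block"]),
            u_bar_beta=values["u_bar_beta"],
            v_bar=values.get("v_bar", 0.0),
            v_bar_beta=values.get("v_bar_beta", 0.0),
        )
    raise ValueError(f"unknown parameter variant {variant!r} in {path}")
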