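"""Data model for stochastic mass-action chemical reaction networks.

A reaction network couples a species list with a set of reactions, each
defined by reactant and product stoichiometric vectors (nu, nu') and a
positive mass-action rate constant kappa.  The network is interpreted as a
continuous-time Markov jump process: reaction k fires at state x with
propensity

    a_k(x) = kappa_k * prod_i  x_i * (x_i - 1) * ... * (x_i - nu_ik + 1)

(the falling-factorial stochastic mass-action convention; for networks whose
reactant multiplicities are all 0 or 1 this is the plain product of reactant
counts).

The module also ships the three worked example networks used throughout the
package: the two-species Togashi-Kaneko autocatalytic cycle, a heat-shock
response network, and an SIR epidemic network with demographic turnover.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "NetworkSpecError",
    "build_network",
    "parse_reaction",
    "propensity",
    "builtin_model",
    "BUILTIN_MODELS",
]


class NetworkSpecError(ValueError):
    """Raised when a network specification is malformed."""


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: reactants -> products at rate ``rate``.

    ``reactants`` and ``products`` are length-s nonnegative integer
    stoichiometric vectors aligned with the owning network's species list.
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float
    name: str = ""

    @property
    def jump(self) -> tuple[int, ...]:
        """Net change nu' - nu when this reaction fires."""
        return tuple(p - r for r, p in zip(self.reactants, self.products))


@dataclass
class ReactionNetwork:
    """A validated mass-action reaction network.

    Attributes
    ----------
    species : list of str
        Species identifiers; their order fixes the coordinate system of all
        stoichiometric vectors and state vectors.
    reactions : list of Reaction
    initial_state : ndarray of int or None
        Optional default initial molecular counts.
    """

    species: list[str]
    reactions: list[Reaction]
    initial_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise NetworkSpecError("network needs at least one species")
        if len(self.reactions) < 1:
            raise NetworkSpecError("network needs at least one reaction")
        if self.initial_state is not None:
            self.initial_state = np.asarray(self.initial_state, dtype=np.int64)
            if self.initial_state.shape != (self.s,):
                raise NetworkSpecError("initial_state dimension mismatch")
            if np.any(self.initial_state < 0):
                raise NetworkSpecError("initial_state has negative counts")

    # -- dimensions ---------------------------------------------------------
    @property
    def s(self) -> int:
        """Number of species."""
        return len(self.species)

    @property
    def m(self) -> int:
        """Number of reactions."""
        return len(self.reactions)

    # -- matrix views -------------------------------------------------------
    @property
    def reactant_matrix(self) -> np.ndarray:
        """(m, s) integer matrix of reactant stoichiometries nu_ik."""
        return np.array([r.reactants for r in self.reactions], dtype=np.int64)

    @property
    def product_matrix(self) -> np.ndarray:
        return np.array([r.products for r in self.reactions], dtype=np.int64)

    @property
    def jump_matrix(self) -> np.ndarray:
        """(m, s) integer matrix of net changes nu' - nu."""
        return self.product_matrix - self.reactant_matrix

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.reactions], dtype=np.float64)

    # -- structural queries -------------------------------------------------
    def jump_collisions(self) -> list[tuple[int, ...]]:
        """Groups of reaction indices sharing an identical jump vector.

        The identification method assumes each reaction has a unique
        stoichiometric (jump) vector; colliding reactions are merged into a
        single category at identification time.  Returns a list of tuples of
        reaction indices, one per jump vector shared by >= 2 reactions.
        """
        groups: dict[tuple[int, ...], list[int]] = {}
        for k, r in enumerate(self.reactions):
            groups.setdefault(r.jump, []).append(k)
        return [tuple(v) for v in groups.values() if len(v) > 1]

    @property
    def jump_vectors_unique(self) -> bool:
        return not self.jump_collisions()

    @property
    def reference_eligible(self) -> bool:
        """True iff the network has at least one pure-birth reaction.

        A pure-birth reaction consumes nothing and produces a single copy of
        one species; its propensity is constant, which is what lets it serve
        as the reference category of the multinomial logit.
        """
        for r in self.reactions:
            if sum(r.reactants) == 0 and sorted(r.products) == [0] * (self.s - 1) + [1]:
                return True
        return False


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(\d+)?\s*([A-Za-z_][A-Za-z0-9_]*)\s*$")


def _parse_side(side: str, species_index: Mapping[str, int]) -> tuple[int, ...]:
    """Parse one side of a reaction string ('A1 + 2 A2', '0' or '' = empty)."""
    s = len(species_index)
    stoich = [0] * s
    side = side.strip()
    if side in ("", "0", "∅", "empty"):
        return tuple(stoich)
    for term in side.split("+"):
        mobj = _TERM_RE.match(term)
        if not mobj:
            raise NetworkSpecError(f"cannot parse reaction term {term!r}")
        count = int(mobj.group(1) or 1)
        name = mobj.group(2)
        if name not in species_index:
            raise NetworkSpecError(f"unknown species {name!r}")
        if count < 0:
            raise NetworkSpecError(f"negative stoichiometry in {term!r}")
        stoich[species_index[name]] += count
    return tuple(stoich)


def parse_reaction(text: str, species: Sequence[str]) -> Reaction:
    """Parse 'A1 + A2 -> 2 A1 @ 200' into a :class:`Reaction`."""
    idx = {name: i for i, name in enumerate(species)}
    if "@" in text:
        body, rate_str = text.rsplit("@", 1)
        rate = float(rate_str)
    else:
        raise NetworkSpecError(f"reaction string {text!r} missing '@ rate'")
    if "->" not in body:
        raise NetworkSpecError(f"reaction string {text!r} missing '->'")
    lhs, rhs = body.split("->", 1)
    return _make_reaction(_parse_side(lhs, idx), _parse_side(rhs, idx), rate, text.strip())


def _make_reaction(
    reactants: tuple[int, ...], products: tuple[int, ...], rate: float, name: str
) -> Reaction:
    if rate <= 0 or not np.isfinite(rate):
        raise NetworkSpecError(f"reaction {name!r}: rate constant must be positive")
    if reactants == products:
        raise NetworkSpecError(
            f"reaction {name!r}: zero net change is not representable by stoichiometry"
        )
    return Reaction(reactants=reactants, products=products, rate=rate, name=name)


def build_network(spec: Mapping | str | Path) -> ReactionNetwork:
    """Build and validate a :class:`ReactionNetwork` from a specification.

    ``spec`` is either a mapping or a path to a YAML file with keys
    ``species`` (list of names), ``reactions`` (list of either reaction
    strings ``"A1 + A2 -> 2 A1 @ 200"`` or mappings with ``lhs``, ``rhs``,
    ``rate``) and optional ``initial_state``.

    Colliding jump vectors are permitted (they are merged downstream at
    categorization); call :meth:`ReactionNetwork.jump_collisions` for the
    collision report.
    """
    if isinstance(spec, (str, Path)):
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    species = list(spec["species"])
    if len(set(species)) != len(species):
        raise NetworkSpecError("duplicate species names")
    idx = {name: i for i, name in enumerate(species)}
    reactions: list[Reaction] = []
    for entry in spec["reactions"]:
        if isinstance(entry, str):
            reactions.append(parse_reaction(entry, species))
        else:
            lhs = _parse_side(str(entry["lhs"]), idx)
            rhs = _parse_side(str(entry["rhs"]), idx)
            name = entry.get("name", f"{entry['lhs']} -> {entry['rhs']}")
            reactions.append(_make_reaction(lhs, rhs, float(entry["rate"]), name))
    x0 = spec.get("initial_state")
    if isinstance(x0, Mapping):
        x0 = [x0.get(name, 0) for name in species]
    net = ReactionNetwork(species=species, reactions=reactions, initial_state=x0)
    collisions = net.jump_collisions()
    if collisions:
        named = "; ".join(
            " == ".join(net.reactions[k].name or f"#{k}" for k in group)
            for group in collisions)
        warnings.warn(
            f"jump vectors are not pairwise distinct ({named}); colliding "
            "reactions will be merged into one category at identification",
            stacklevel=2)
    return net


# ---------------------------------------------------------------------------
# Propensities
# ---------------------------------------------------------------------------

def propensity(net: ReactionNetwork, x: Sequence[int] | np.ndarray) -> np.ndarray:
    """Stochastic mass-action propensities a_k(x) for every reaction.

    Uses the falling-factorial convention
    a_k(x) = kappa_k * prod_i x_i (x_i - 1) ... (x_i - nu_ik + 1);
    a required reactant at count 0 gives propensity 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (net.s,):
        raise ValueError("state dimension mismatch")
    a = net.rates.copy()
    nu = net.reactant_matrix
    for k in range(net.m):
        for i in range(net.s):
            for c in range(nu[k, i]):
                a[k] *= x[i] - c
    return np.maximum(a, 0.0)


# ---------------------------------------------------------------------------
# Built-in example networks
# ---------------------------------------------------------------------------

def _tk_spec(kappa1, kappa2, lam1, lam2, delta1, delta2) -> dict:
    return {
        "species": ["A1", "A2"],
        "reactions": [
            f"A1 + A2 -> 2 A1 @ {kappa1}",
            f"A1 + A2 -> 2 A2 @ {kappa2}",
            f"0 -> A1 @ {lam1}",
            f"0 -> A2 @ {lam2}",
            f"A1 -> 0 @ {delta1}",
            f"A2 -> 0 @ {delta2}",
        ],
        "initial_state": [49, 1],
    }


def _hsr_spec(kappa2: float | None) -> dict:
    # Reactions in rate-constant order kappa_1..kappa_12; kappa2 = None drops
    # the natural production of P2 entirely (a zero-rate reaction is removed).
    reactions = ["0 -> P1 @ 10"]
    if kappa2 is not None:
        reactions.append(f"0 -> P2 @ {kappa2}")
    reactions += [
        "P2 -> P1 + P2 @ 1",
        "P1 -> P1 + P2 @ 1",
        "R1 -> 2 R1 @ 1",
        "P1 -> R1 @ 1",
        "P2 -> R1 @ 1",
        "R1 -> P2 @ 1",
        "P1 -> 0 @ 1",
        "P2 -> 0 @ 1",
        "R1 -> 0 @ 1",
        "R1 + P2 -> 0 @ 0.01",
    ]
    return {"species": ["P1", "P2", "R1"], "reactions": reactions,
            "initial_state": [50, 50, 50]}


_SIR_SPEC = {
    "species": ["S", "I", "R"],
    "reactions": [
        "S + I -> 2 I @ 0.004",   # transmission, beta/n
        "I -> R @ 0.2",           # recovery, gamma
        "0 -> S @ 3",             # birth/immigration, mu*n
        "S -> 0 @ 0.001",         # death/emigration, nu
        "I -> 0 @ 0.001",
        "R -> 0 @ 0.001",
    ],
    "initial_state": [100, 1, 0],
}

BUILTIN_MODELS: dict[str, tuple[str, ...]] = {
    "tk": ("symmetric", "asymmetric"),
    "hsr": ("case1", "case2"),
    "sir_demog": ("default",),
}


def builtin_model(name: str, case: str | None = None) -> ReactionNetwork:
    """Return a published example network with its default initial state.

    ``tk``: two-species autocatalytic cycle with inflow/outflow; cases
    ``symmetric`` (kappa=200, lambda=0.2, delta=0.0078, from (49, 1)) and
    ``asymmetric`` (kappa=(20, 19), lambda=(2, 1), delta=(0.078, 0.03)).

    ``hsr``: three-species heat-shock response network; ``case1`` has all 12
    reactions (kappa1=kappa2=10, kappa12=0.01, others 1), ``case2`` removes
    the natural production of P2 (11 reactions).

    ``sir_demog``: SIR with demographic turnover, beta/n=0.004, gamma=0.2,
    inflow 3, per-capita removal 0.001, from (S, I, R) = (100, 1, 0).
    """
    name = name.lower()
    if name == "tk":
        case = case or "symmetric"
        if case == "symmetric":
            return build_network(_tk_spec(200, 200, 0.2, 0.2, 0.0078, 0.0078))
        if case == "asymmetric":
            return build_network(_tk_spec(20, 19, 2, 1, 0.078, 0.03))
    elif name == "hsr":
        case = case or "case1"
        if case == "case1":
            return build_network(_hsr_spec(10))
        if case == "case2":
            return build_network(_hsr_spec(None))
    elif name == "sir_demog":
        if case in (None, "default"):
            return build_network(_SIR_SPEC)
    raise NetworkSpecError(f"unknown builtin model {name!r} / case {case!r}")
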