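"""Declarative chemical reaction networks and mass-action ODE right-hand sides.

A :class:`ReactionNetwork` stores species, reactions and rate constants and
compiles to a pure ``(t, y) -> dy/dt`` function via :func:`build_rhs`.  Flow
(CSTR) balances, reaction ablation and conserved-moiety extraction are layered
on top of the same declarative description, so the generic builder — not
hand-coded equations — is the single source of truth for every model variant.

Concentrations are molar throughout; the time unit is carried explicitly on
the network (``"s"``, ``"h"`` or ``"d"``) and all rate constants and dilution
rates are expressed per that unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.linalg import null_space

__all__ = [
    "ConfigurationError",
    "Species",
    "Reaction",
    "FlowConditions",
    "ReactionNetwork",
    "build_rhs",
    "apply_flow",
    "ablate_reaction",
    "conserved_moieties",
    "fmoc_oscillator",
    "load_network",
    "save_network",
    "TIME_UNIT_HOURS",
    "PARAMETER_SETS",
]

#: Conversion factors from a declared time unit to hours.
TIME_UNIT_HOURS: dict[str, float] = {"s": 1.0 / 3600.0, "min": 1.0 / 60.0, "h": 1.0, "d": 24.0}


class ConfigurationError(ValueError):
    """A network or run definition is internally inconsistent."""


@dataclass(frozen=True)
class Species:
    """A chemical species; ``index`` is 1-based and matches the declaration order.

    ``constant`` species are carried in the state vector with their derivative
    pinned to zero (e.g. a buffered catalyst) so indices stay aligned with the
    source network description.
    """

    index: int
    name: str
    constant: bool = False


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction.

    ``rate_exponents`` defaults to the reactant stoichiometry; supplying it
    explicitly allows catalytic species that enter the rate law with zero net
    stoichiometry.  ``suppressed_species`` lists species indices whose state
    update from this reaction has been ablated (partial pathway removal); the
    rate law itself is untouched.
    """

    label: str
    reactants: Mapping[int, int]
    products: Mapping[int, int]
    rate_key: str
    rate_exponents: Mapping[int, float] | None = None
    suppressed_species: frozenset[int] = frozenset()

    def exponents(self) -> Mapping[int, float]:
        if self.rate_exponents is not None:
            return self.rate_exponents
        return dict(self.reactants)


@dataclass(frozen=True)
class FlowConditions:
    """Inflow concentrations (M, per species position) and dilution rate (1/time).

    ``dilution_rate == 0`` reduces exactly to a closed (batch) reactor.
    """

    inflow: np.ndarray
    dilution_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "inflow", np.asarray(self.inflow, dtype=float))
        if self.dilution_rate < 0:
            raise ConfigurationError("dilution rate must be >= 0")
        if np.any(self.inflow < 0):
            raise ConfigurationError("inflow concentrations must be >= 0")


@dataclass(frozen=True)
class ReactionNetwork:
    """Species, reactions and the named rate-constant vector kappa."""

    species: Sequence[Species]
    reactions: Sequence[Reaction]
    kappa: Mapping[str, float]
    time_unit: str = "h"
    name: str = "network"

    def __post_init__(self) -> None:
        indices = [s.index for s in self.species]
        if sorted(indices) != list(range(1, len(indices) + 1)):
            raise ConfigurationError(
                f"species indices must be unique and contiguous from 1, got {indices}"
            )
        if self.time_unit not in TIME_UNIT_HOURS:
            raise ConfigurationError(f"unknown time unit {self.time_unit!r}")
        for k, v in self.kappa.items():
            # zero is tolerated (an inert reaction), negatives are not
            if v is not None and v < 0:
                raise ConfigurationError(f"rate constant {k!r} must be >= 0, got {v}")

    # -- structural views -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def names(self) -> list[str]:
        return [s.name for s in sorted(self.species, key=lambda s: s.index)]

    @property
    def constant_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_species, dtype=bool)
        for s in self.species:
            mask[s.index - 1] = s.constant
        return mask

    def rate_vector(self) -> np.ndarray:
        """kappa resolved per reaction, in declaration order."""
        ks = np.empty(len(self.reactions))
        for j, r in enumerate(self.reactions):
            if r.rate_key not in self.kappa:
                raise ConfigurationError(f"unknown rate-constant key {r.rate_key!r}")
            val = self.kappa[r.rate_key]
            if val is None:
                raise ConfigurationError(
                    f"rate constant {r.rate_key!r} has no value; supply one "
                    "(placeholder parameter sets must be filled in by the user)"
                )
            ks[j] = val
        return ks

    def stoichiometric_matrix(self, effective: bool = False) -> np.ndarray:
        """Net stoichiometry S (species x reactions).

        With ``effective=True``, rows of constant species and entries listed in
        a reaction's ``suppressed_species`` are zeroed — this is the matrix the
        compiled RHS actually applies.
        """
        S = np.zeros((self.n_species, len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for idx, coef in r.reactants.items():
                S[idx - 1, j] -= coef
            for idx, coef in r.products.items():
                S[idx - 1, j] += coef
            if effective:
                for idx in r.suppressed_species:
                    S[idx - 1, j] = 0.0
        if effective:
            S[self.constant_mask, :] = 0.0
        return S

    def exponent_matrix(self) -> np.ndarray:
        """Rate-law exponents E (reactions x species)."""
        E = np.zeros((len(self.reactions), self.n_species))
        for j, r in enumerate(self.reactions):
            for idx, e in r.exponents().items():
                if e < 0:
                    raise ConfigurationError(f"negative rate-law exponent in {r.label!r}")
                E[j, idx - 1] = e
        return E

    def rescaled(self, to_unit: str) -> "ReactionNetwork":
        """Return an equivalent network expressed in another time unit.

        Every rate constant carries dimension 1/time (times concentration
        powers), so a change of time unit multiplies all of kappa by the same
        factor and leaves concentrations untouched.
        """
        factor = TIME_UNIT_HOURS[to_unit] / TIME_UNIT_HOURS[self.time_unit]
        kappa = {k: (None if v is None else v * factor) for k, v in self.kappa.items()}
        return replace(self, kappa=kappa, time_unit=to_unit)


def _monomials(y: np.ndarray, E: np.ndarray) -> np.ndarray:
    """prod_s y_s^E[j,s] for each reaction j; y may be batched (..., n_species)."""
    base = np.asarray(y, dtype=float)[..., None, :]
    # Non-integer exponents are only defined for y >= 0; integer powers pass
    # small solver-induced negatives through unchanged.
    if not np.all(E == np.round(E)):
        base = np.clip(base, 0.0, None)
    with np.errstate(invalid="ignore"):
        return np.prod(np.power(base, E), axis=-1)


def build_rhs(network: ReactionNetwork) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile ``dy/dt = S . v(y)`` with ``v_j = k_j prod_s y_s^e_js``.

    The returned closure is a pure function of ``(t, y)`` (autonomous), accepts
    batched states of shape ``(..., n_species)`` and pins constant-species
    derivatives to zero.
    """
    k = network.rate_vector()
    E = network.exponent_matrix()
    S_eff = network.stoichiometric_matrix(effective=True)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        v = k * _monomials(y, E)
        return v @ S_eff.T

    return rhs


def reaction_rates(network: ReactionNetwork, y: np.ndarray) -> np.ndarray:
    """Per-reaction rates v(y), batched over leading axes of ``y``."""
    return network.rate_vector() * _monomials(y, network.exponent_matrix())


def apply_flow(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    flow: FlowConditions,
    constant_mask: np.ndarray,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Add the CSTR balance ``D (y_in - y)`` to a batch RHS.

    In/outflow acts on non-constant species only; constant species stay pinned.
    """
    D = float(flow.dilution_rate)
    y_in = np.asarray(flow.inflow, dtype=float)
    active = ~np.asarray(constant_mask, dtype=bool)
    if y_in.shape != active.shape:
        raise ConfigurationError(
            f"inflow vector has length {y_in.shape[0]}, expected {active.shape[0]}"
        )

    def flowed(t: float, y: np.ndarray) -> np.ndarray:
        return rhs(t, y) + active * (D * (y_in - y))

    return flowed


def ablate_reaction(
    network: ReactionNetwork,
    reaction_label: str,
    species: Sequence[int] | None = None,
) -> ReactionNetwork:
    """Remove a reaction's contribution, wholly or for selected species only.

    With ``species`` given, only those species' state updates lose the
    reaction's term while the rest of the ODE system remains unaltered —
    the construct used to emulate a partially hidden inhibition pathway.
    Without it, the reaction is deleted outright.
    """
    labels = [r.label for r in network.reactions]
    if reaction_label not in labels:
        raise ConfigurationError(f"unknown reaction label {reaction_label!r}")
    if species is None:
        reactions = [r for r in network.reactions if r.label != reaction_label]
    else:
        valid = {s.index for s in network.species}
        bad = set(species) - valid
        if bad:
            raise ConfigurationError(f"unknown species indices {sorted(bad)}")
        reactions = [
            replace(r, suppressed_species=r.suppressed_species | frozenset(species))
            if r.label == reaction_label
            else r
            for r in network.reactions
        ]
    return replace(network, reactions=list(reactions))


def conserved_moieties(network: ReactionNetwork, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis (rows) of the left null space of S over non-constant species.

    Each basis vector ``w`` satisfies ``w^T S = 0``; the weighted total
    ``w . y(t)`` (non-constant species) is invariant along any batch solve.
    Returns an array of shape ``(n_moieties, n_active_species)``.
    """
    active = ~network.constant_mask
    S = network.stoichiometric_matrix()[active, :]
    basis = null_space(S.T, rcond=tol)
    return basis.T


# ---------------------------------------------------------------------------
# Built-in networks and parameter sets
# ---------------------------------------------------------------------------

#: Named kappa/flow parameter sets for the 7-species deprotection oscillator.
#:
#: ``toy_oscillator`` is a fully self-contained synthetic parameterization
#: (hours, molar) producing sustained limit-cycle oscillations in flow; it was
#: located by numerical search (see scripts/find_toy_oscillator.py) and frozen
#: here so no external data is needed to exercise any part of the toolkit.
#:
#: ``terharmsel2023`` is a placeholder for the experimentally fitted constants
#: of the original flow-reactor study; those values are not distributed here
#: and must be supplied by the user before this set can be solved.
PARAMETER_SETS: dict[str, dict] = {
    "toy_oscillator": {
        "time_unit": "h",
        "kappa": {"k_tr": 0.9, "k_ac": 650.0, "k_inh1": 2500.0, "k_inh2": 0.9},
        "nmp_conc": 0.2,
        "flow": {
            "dilution_rate": 0.28,
            "inflow": {2: 0.1, 3: 0.07, 4: 1.8},
        },
        "y0": {3: 0.07, 5: 0.2},
    },
    "terharmsel2023": {
        "time_unit": "h",
        "kappa": {"k_tr": None, "k_ac": None, "k_inh1": None, "k_inh2": None},
        "nmp_conc": None,
        "flow": {"dilution_rate": None, "inflow": {}},
        "y0": {},
    },
}

_FMOC_SPECIES = [
    Species(1, "piperidine"),
    Species(2, "fmoc_piperidine"),
    Species(3, "p_nitrophenyl_acetate"),
    Species(4, "phenyl_acetate"),
    Species(5, "n_methylpiperidine", constant=True),
    Species(6, "dibenzofulvene"),
    Species(7, "n_acetyl_piperidine"),
]

_FMOC_REACTIONS = [
    # Base-triggered deprotection, catalysed by the constant tertiary amine (5).
    Reaction(
        "trigger",
        reactants={2: 1},
        products={1: 1, 6: 1},
        rate_key="k_tr",
        rate_exponents={2: 1, 5: 1},
    ),
    # Autocatalytic deprotection: the liberated amine (1) deprotects more fuel.
    Reaction(
        "autocatalysis",
        reactants={1: 1, 2: 1},
        products={1: 2, 6: 1},
        rate_key="k_ac",
    ),
    # Fast inhibition: acetylation of the autocatalyst by the activated ester.
    Reaction(
        "fast_inhibition",
        reactants={1: 1, 3: 1},
        products={7: 1},
        rate_key="k_inh1",
    ),
    # Slow inhibition: acetylation by the slow-reacting ester reservoir.
    Reaction(
        "slow_inhibition",
        reactants={1: 1, 4: 1},
        products={7: 1},
        rate_key="k_inh2",
    ),
]


def fmoc_oscillator(params: str | Mapping = "toy_oscillator") -> ReactionNetwork:
    """The 7-species autocatalytic deprotection oscillator.

    ``params`` names a set in :data:`PARAMETER_SETS` or is a mapping with the
    same layout.  The network topology is fixed; only kappa and the time unit
    come from the parameter set.
    """
    if isinstance(params, str):
        try:
            pset = PARAMETER_SETS[params]
        except KeyError:
            raise ConfigurationError(f"unknown parameter set {params!r}") from None
    else:
        pset = dict(params)
    name = params if isinstance(params, str) else "fmoc_oscillator"
    return ReactionNetwork(
        species=list(_FMOC_SPECIES),
        reactions=list(_FMOC_REACTIONS),
        kappa=dict(pset["kappa"]),
        time_unit=pset.get("time_unit", "h"),
        name=f"fmoc_oscillator[{name}]",
    )


def toy_flow_conditions(
    fmoc_in: float | None = None, pa_in: float | None = None
) -> FlowConditions:
    """Flow conditions of the frozen toy parameter set.

    The two inflow concentrations scanned in phase-space analyses (fuel ester,
    species 2, and slow inhibitor, species 4) can be overridden per call.
    """
    pset = PARAMETER_SETS["toy_oscillator"]
    inflow = np.zeros(len(_FMOC_SPECIES))
    for idx, c in pset["flow"]["inflow"].items():
        inflow[idx - 1] = c
    if fmoc_in is not None:
        inflow[1] = fmoc_in
    if pa_in is not None:
        inflow[3] = pa_in
    return FlowConditions(inflow=inflow, dilution_rate=pset["flow"]["dilution_rate"])


def toy_initial_state() -> np.ndarray:
    """Initial concentrations (M) of the frozen toy scenario."""
    pset = PARAMETER_SETS["toy_oscillator"]
    y0 = np.zeros(len(_FMOC_SPECIES))
    for idx, c in pset["y0"].items():
        y0[idx - 1] = c
    return y0


# ---------------------------------------------------------------------------
# Network definition files
# ---------------------------------------------------------------------------


def load_network(path) -> tuple[ReactionNetwork, FlowConditions | None]:
    """Read a network definition (YAML) and the optional flow block."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"network file {path} is empty or malformed")
    try:
        species = [
            Species(int(s["index"]), str(s["name"]), bool(s.get("constant", False)))
            for s in doc["species"]
        ]
        reactions = [
            Reaction(
                label=str(r["label"]),
                reactants={int(k): int(v) for k, v in (r.get("reactants") or {}).items()},
                products={int(k): int(v) for k, v in (r.get("products") or {}).items()},
                rate_key=str(r["rate_constant"]),
                rate_exponents=(
                    {int(k): float(v) for k, v in r["rate_exponents"].items()}
                    if "rate_exponents" in r
                    else None
                ),
            )
            for r in doc["reactions"]
        ]
        network = ReactionNetwork(
            species=species,
            reactions=reactions,
            kappa={str(k): (None if v is None else float(v)) for k, v in doc["kappa"].items()},
            time_unit=str(doc.get("time_unit", "h")),
            name=str(doc.get("name", "network")),
        )
    except KeyError as exc:
        raise ConfigurationError(f"network file missing key {exc}") from exc
    flow = None
    if "flow" in doc and doc["flow"]:
        inflow = np.zeros(network.n_species)
        for idx, c in (doc["flow"].get("inflow") or {}).items():
            inflow[int(idx) - 1] = float(c)
        flow = FlowConditions(inflow=inflow, dilution_rate=float(doc["flow"]["dilution_rate"]))
    return network, flow


def save_network(network: ReactionNetwork, path, flow: FlowConditions | None = None) -> None:
    doc: dict = {
        "name": network.name,
        "time_unit": network.time_unit,
        "species": [
            {"index": s.index, "name": s.name, **({"constant": True} if s.constant else {})}
            for s in sorted(network.species, key=lambda s: s.index)
        ],
        "reactions": [
            {
                "label": r.label,
                "rate_constant": r.rate_key,
                "reactants": {int(k): int(v) for k, v in r.reactants.items()},
                "products": {int(k): int(v) for k, v in r.products.items()},
                **(
                    {"rate_exponents": {int(k): float(v) for k, v in r.rate_exponents.items()}}
                    if r.rate_exponents is not None
                    else {}
                ),
            }
            for r in network.reactions
        ],
        "kappa": {k: (None if v is None else float(v)) for k, v in network.kappa.items()},
    }
    if flow is not None:
        doc["flow"] = {
            "dilution_rate": float(flow.dilution_rate),
            "inflow": {
                i + 1: float(c) for i, c in enumerate(np.asarray(flow.inflow)) if c != 0.0
            },
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
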